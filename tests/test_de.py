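import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import kstest

from conftest import genes_for, two_group_nb_counts
from hybridx import de
from hybridx.io import CountMatrix, SampleMeta
from hybridx.stats import bh_adjust


def _make_cm(values, n_a=3, n_b=3):
    samples = [SampleMeta(f"dom_DIP_r{r}", "dom", "DIP", r) for r in range(1, n_a + 1)]
    samples += [SampleMeta(f"mus_DIP_r{r}", "mus", "DIP", r) for r in range(1, n_b + 1)]
    counts = pd.DataFrame(
        np.asarray(values), index=[f"g{i}" for i in range(len(values))],
        columns=[s.sample_id for s in samples],
    )
    return CountMatrix(counts=counts, samples=samples)


CONTRAST = de.ContrastSpec("dom_vs_mus_DIP", ("dom", "DIP"), ("mus", "DIP"))


class TestFpkm:
    def test_direct_formula(self):
        cm = _make_cm([[100] * 6, [10 ** 6 - 100] * 6])
        genes = genes_for(cm)
        fpkm = de.compute_fpkm(cm, genes)
        # count 100, length 1000 bp, library 1e6 -> FPKM 100
        assert fpkm.iloc[0, 0] == pytest.approx(100.0)

    def test_zero_count_zero_fpkm(self):
        cm = _make_cm([[0] * 6, [500] * 6])
        assert de.compute_fpkm(cm, genes_for(cm)).iloc[0, 0] == 0.0

    def test_filter_boundary_and_pass(self):
        fpkm = pd.DataFrame(
            [[1.5, 1.2, 1.1, 0, 0, 0], [1.0] * 6, [0.0] * 6],
            index=["pass", "boundary", "zero"], columns=list("abcdef"),
        )
        flags = de.filter_expressed(fpkm, scope="cell_type", contrast_samples=list("abcdef"))
        assert flags.to_dict() == {"pass": True, "boundary": False, "zero": False}


class TestDispersions:
    def test_poisson_data_gives_small_common(self):
        rng = np.random.default_rng(0)
        cm = _make_cm(rng.poisson(200, size=(2000, 6)))
        d = de.estimate_dispersions(cm, [cm.sample_ids("dom"), cm.sample_ids("mus")])
        assert d.common <= 0.05

    def test_nb_dispersion_recovery(self):
        commons = []
        for seed in range(10):
            cm, _ = two_group_nb_counts(2000, dispersion=0.25, seed=seed)
            d = de.estimate_dispersions(cm, [cm.sample_ids("dom"), cm.sample_ids("mus")])
            commons.append(d.common)
        assert 0.15 <= np.mean(commons) <= 0.35

    def test_infinite_prior_weight_collapses_to_common(self):
        cm, _ = two_group_nb_counts(200, dispersion=0.1, seed=1)
        groups = [cm.sample_ids("dom"), cm.sample_ids("mus")]
        d = de.estimate_dispersions(cm, groups, prior_weight=np.inf)
        assert np.allclose(d.tagwise, d.common)
        assert d.bcv == pytest.approx(np.sqrt(d.common))


class TestBH:
    def test_step_up_hand_example(self):
        # m = 4, p = (.01,.02,.03,.04): adjusted all 0.04 by the step-up rule
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()


class TestLrt:
    def test_identical_counts_null_identity(self):
        cm = _make_cm([[50] * 6, [7] * 6])
        d = de.DispersionEstimates(common=0.05, tagwise=np.full(2, 0.05))
        res = de.test_de(cm, genes_for(cm), CONTRAST, d)
        assert np.allclose(res["logfc"], 0.0)
        assert np.allclose(res["p_raw"], 1.0)

    def test_lrt_nonnegative(self, small_expression):
        _, genes, cm, _ = small_expression
        groups = [cm.sample_ids("musXdom", "DIP"), cm.sample_ids("mus", "DIP")]
        d = de.estimate_dispersions(cm, groups)
        spec = de.ContrastSpec("musXdom_vs_mus_DIP", ("musXdom", "DIP"), ("mus", "DIP"))
        res = de.test_de(cm, genes, spec, d)
        assert (res["lrt"] >= 0).all()
        assert ((res["p_adj"] >= res["p_raw"] - 1e-12)).all()
        assert (res.loc[~res["expressed_in_cell_type"], "is_de"] == False).all()  # noqa: E712

    def test_agrees_with_brute_force_maximizer(self):
        """The vectorized Newton fit matches an independent 1-D optimizer."""
        rng = np.random.default_rng(3)
        cm, _ = two_group_nb_counts(20, dispersion=0.08, seed=3, mean_scale=80.0)
        y = cm.counts.to_numpy(dtype=float)
        libs = de.library_sizes(cm)
        off = np.log(libs.to_numpy())
        disp = np.full(20, 0.08)

        def loglik(beta, yrow, offs, phi):
            r = 1.0 / phi
            mu = np.exp(beta + offs)
            return float(np.sum(gammaln(yrow + r) - gammaln(r) - gammaln(yrow + 1)
                                + r * np.log(r / (r + mu))
                                + yrow * np.log(mu / (r + mu))))

        _, ll_null = de.nb_group_loglik(y, off, disp)
        _, ll_a = de.nb_group_loglik(y[:, :3], off[:3], disp)
        _, ll_b = de.nb_group_loglik(y[:, 3:], off[3:], disp)
        for g in rng.choice(20, size=20, replace=False):
            brute = []
            for cols in (slice(None), slice(0, 3), slice(3, 6)):
                res = minimize_scalar(
                    lambda b: -loglik(b, y[g, cols], off[cols], 0.08),
                    bounds=(-10, 20), method="bounded",
                    options={"xatol": 1e-10},
                )
                brute.append(-res.fun)
            ours = 2 * (ll_a[g] + ll_b[g] - ll_null[g])
            theirs = 2 * (brute[1] + brute[2] - brute[0])
            assert abs(ours - theirs) < 1e-3

    def test_null_p_uniform_under_permutation(self):
        """Label-permuted null data give uniform p-values (KS at alpha 0.01)."""
        cm, _ = two_group_nb_counts(2000, dispersion=0.03, seed=7)
        d = de.estimate_dispersions(cm, [cm.sample_ids("dom"), cm.sample_ids("mus")])
        res = de.test_de(cm, genes_for(cm), CONTRAST, d)
        assert kstest(res["p_raw"], "uniform").pvalue > 0.01

    def test_trimmed_normalization_factors_center_on_one(self, small_expression):
        _, _, cm, _ = small_expression
        libs_raw = de.library_sizes(cm, "libsize")
        libs_tmm = de.library_sizes(cm, "trimmed")
        ratio = (libs_tmm / libs_raw).to_numpy()
        assert np.exp(np.abs(np.log(ratio))).max() < 1.5
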