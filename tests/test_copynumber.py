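import numpy as np
import pandas as pd
import pytest

from hybridx import copynumber as cn
from hybridx import simulate as sim
from hybridx.io import CoverageTrack


def _track(rows):
    return CoverageTrack(intervals=pd.DataFrame(rows, columns=["chromosome", "start", "end", "depth"]))


def _flat_track(length, depth, elevated=()):
    rows, pos = [], 0
    bounds = sorted(elevated)
    for s, e, d in bounds:
        if pos < s:
            rows.append(("chrSim", pos, s, depth))
        rows.append(("chrSim", s, e, d))
        pos = e
    if pos < length:
        rows.append(("chrSim", pos, length, depth))
    return _track(rows)


class TestFindParalogs:
    def test_exact_self_hit(self):
        rng = np.random.default_rng(0)
        backbone = "".join(rng.choice(list("ACGT"), size=5000))
        query = backbone[1000:1800]
        hits = cn.find_paralogs(query, {"chr1": backbone})
        assert [(c, s, e) for c, s, e, _ in hits.intervals] == [("chr1", 1000, 1800)]
        assert hits.intervals[0][3] == pytest.approx(1.0)

    def test_planted_copies_found_decoy_excluded(self, small_amplicon):
        _, genome, _, truth, _ = small_amplicon
        hits = cn.find_paralogs(truth.query, genome)
        found = {(s, e) for _, s, e, _ in hits.intervals}
        assert found == set(truth.intervals)

    def test_97pct_filter_excludes_decoy_at_99pct_copies(self):
        for seed in range(5):
            cfg = sim.AmpliconSimConfig(ref_copies=3, true_copies=3, copy_identity=0.99, seed=seed)
            genome, _, truth = sim.simulate_amplicon_genome(cfg)
            hits = cn.find_paralogs(truth.query, genome)
            assert len(hits.intervals) == 3
            decoy_s, decoy_e = truth.decoy_interval
            assert all(not (s < decoy_e and decoy_s < e) for _, s, e, _ in hits.intervals)

    def test_reverse_complement_found(self):
        rng = np.random.default_rng(1)
        backbone = list("".join(rng.choice(list("ACGT"), size=6000)))
        query = "".join(rng.choice(list("ACGT"), size=800))
        rc = query.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        backbone[2000:2800] = rc
        hits = cn.find_paralogs(query, {"chr1": "".join(backbone)})
        assert [(s, e) for _, s, e, _ in hits.intervals] == [(2000, 2800)]

    def test_short_query_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            cn.find_paralogs("ACGT", {"chr1": "ACGTACGT" * 100})


class TestInformativeSites:
    def test_unique_query(self):
        rng = np.random.default_rng(2)
        backbone = "".join(rng.choice(list("ACGT"), size=4000))
        query = backbone[500:1000]
        sites = cn.build_informative_sites(query, {"chr1": backbone})
        assert sites.modal_multiplicity == 1
        assert len(sites.kmers) == len(query) - sites.k + 1

    def test_three_identical_copies(self):
        rng = np.random.default_rng(3)
        query = "".join(rng.choice(list("ACGT"), size=600))
        parts = ["".join(rng.choice(list("ACGT"), size=1500)) for _ in range(4)]
        backbone = parts[0] + query + parts[1] + query + parts[2] + query + parts[3]
        sites = cn.build_informative_sites(query, {"chr1": backbone})
        assert sites.modal_multiplicity == 3
        assert all(len(k.locations) == 3 for k in sites.kmers)

    def test_single_mismatch_in_near_list_not_exact(self):
        # query of 301 bp with the mutation at its center: most kmers span the
        # mutated position, so the modal multiplicity counts only the exact copy
        rng = np.random.default_rng(4)
        query = "".join(rng.choice(list("ACGT"), size=301))
        mutated = list(query)
        mutated[150] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[150]]
        backbone = ("".join(rng.choice(list("ACGT"), size=2000)) + query
                    + "".join(rng.choice(list("ACGT"), size=2000)) + "".join(mutated)
                    + "".join(rng.choice(list("ACGT"), size=2000)))
        sites = cn.build_informative_sites(query, {"chr1": backbone})
        assert sites.modal_multiplicity == 1
        mutated_start = 2000 + 301 + 2000
        spanning = [k for k in sites.kmers if k.query_pos <= 150 < k.query_pos + sites.k]
        assert spanning
        for k in spanning:
            mms = {s: m for _, s, m, _ in k.locations}
            assert mms[2000 + k.query_pos] == 0          # exact at the source copy
            assert mms[mutated_start + k.query_pos] == 1  # one mismatch at the mutant

    def test_mismatch_scan_agrees_with_brute_force_hamming(self):
        rng = np.random.default_rng(5)
        cfg = sim.AmpliconSimConfig(backbone_length=20_000, gene_length=500,
                                    ref_copies=2, true_copies=4, copy_identity=0.99, seed=6)
        genome, _, truth = sim.simulate_amplicon_genome(cfg)
        g = np.frombuffer(genome["chrSim"].encode(), dtype=np.uint8)
        sites = cn.build_informative_sites(truth.query, genome, k=101)
        comp = str.maketrans("ACGT", "TGCA")
        checked = 0
        for km in sites.kmers[:: max(1, len(sites.kmers) // 25)]:
            kmer = truth.query[km.query_pos: km.query_pos + 101]
            expected = set()
            for strand, seq in (("+", kmer), ("-", kmer.translate(comp)[::-1])):
                q = np.frombuffer(seq.encode(), dtype=np.uint8)
                for s in range(len(g) - 101 + 1):
                    mm = int((g[s: s + 101] != q).sum())
                    if mm <= 2:
                        expected.add(("chrSim", s, mm, strand))
            assert set(km.locations) == expected
            checked += 1
        assert checked >= 20


class TestRegionCoverage:
    def test_single_haploid_region(self):
        paralogs = cn.ParalogSet("fam", [("chrSim", 1000, 2000, 1.0)], 1000)
        track = _flat_track(100_000, 20.0, elevated=[(1000, 2000, 10.0)])
        est = cn.cn_from_region_coverage(paralogs, track)
        assert est.estimate == pytest.approx(1.0)

    def test_three_regions_hand_example(self):
        ivs = [(10_000, 11_000), (20_000, 21_000), (30_000, 31_000)]
        paralogs = cn.ParalogSet("fam", [("chrSim", s, e, 1.0) for s, e in ivs], 1000)
        track = _flat_track(100_000, 20.0, elevated=[(s, e, 30.0) for s, e in ivs])
        est = cn.cn_from_region_coverage(paralogs, track)
        assert est.estimate == pytest.approx(9.0)  # (30+30+30) / (20/2)

    def test_linear_in_copy_number_on_noiseless_depth(self):
        ivs = [(10_000, 12_000), (40_000, 42_000)]
        paralogs = cn.ParalogSet("fam", [("chrSim", s, e, 1.0) for s, e in ivs], 2000)
        est = {}
        for n_copies in (6, 12):
            d = n_copies / 2 * 10.0
            track = _flat_track(100_000, 20.0, elevated=[(s, e, d) for s, e in ivs])
            est[n_copies] = cn.cn_from_region_coverage(paralogs, track).estimate
        assert est[12] == pytest.approx(2 * est[6], abs=1e-9)

    def test_zero_background_rejected(self):
        paralogs = cn.ParalogSet("fam", [("chrSim", 0, 1000, 1.0)], 1000)
        track = _flat_track(2_000, 0.0, elevated=[(0, 1000, 5.0)])
        with pytest.raises(ValueError):
            cn.cn_from_region_coverage(paralogs, track)


class TestInformativeSiteEstimator:
    def test_reference_matched_sample(self, small_amplicon):
        cfg, genome, _, truth, _ = small_amplicon
        balanced = sim.AmpliconSimConfig(ref_copies=3, true_copies=3, seed=5)
        _, _, truth_b = sim.simulate_amplicon_genome(balanced)
        depth = sim.simulate_depth(truth_b, balanced)
        genome_b, _, _ = sim.simulate_amplicon_genome(balanced)
        sites = cn.build_informative_sites(truth_b.query, genome_b)
        est = cn.cn_from_informative_sites(sites, depth, genome_b)
        assert est.estimate == pytest.approx(3.0, rel=0.1)

    def test_gc_correction_null_effect(self, small_amplicon):
        _, genome, _, truth, depth = small_amplicon
        sites = cn.build_informative_sites(truth.query, genome)
        on = cn.cn_from_informative_sites(sites, depth, genome, gc_correct=True)
        off = cn.cn_from_informative_sites(sites, depth, genome, gc_correct=False)
        assert abs(on.estimate - off.estimate) / off.estimate < 0.02

    def test_estimator_agreement(self, small_amplicon):
        _, genome, _, truth, depth = small_amplicon
        paralogs = cn.find_paralogs(truth.query, genome)
        sites = cn.build_informative_sites(truth.query, genome)
        a = cn.cn_from_region_coverage(paralogs, depth).estimate
        b = cn.cn_from_informative_sites(sites, depth, genome).estimate
        assert abs(a - b) / ((a + b) / 2) < 0.10

    def test_empty_sites_rejected(self, small_amplicon):
        _, genome, _, truth, depth = small_amplicon
        empty = cn.InformativeSiteSet("fam", 101, 1, [], [])
        with pytest.raises(ValueError, match="empty"):
            cn.cn_from_informative_sites(empty, depth, genome)


class TestFamilyRatio:
    @pytest.mark.parametrize(
        "sly,slx_total,printed",
        [(130.0, 100.0, 1.3), (215.0, 35.0, 6.1), (130.0, 35.0, 3.7), (215.0, 100.0, 2.15)],
    )
    def test_reported_ratios(self, sly, slx_total, printed):
        from hybridx.stats import round_sig

        ratio = cn.compute_family_ratio(sly, slx_total)
        assert round_sig(ratio, 2) == round_sig(printed, 2)

    def test_identity_ratio(self):
        assert cn.compute_family_ratio(50.0, 30.0, 20.0) == pytest.approx(1.0)

    def test_zero_denominator(self):
        with pytest.raises(ValueError, match="denominator"):
            cn.compute_family_ratio(10.0, 0.0, 0.0)
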