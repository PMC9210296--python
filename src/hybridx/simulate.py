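"""Synthetic data generators emulating the study's structure.

Four generators, one per data modality:

* ``simulate_expression`` — gene-level NB counts for 4 crosses x 3
  spermatogenesis stages x n replicates, with meiotic sex chromosome
  inactivation (MSCI) silencing the X in diplotene of the fertile crosses and
  configurable de-repression of X genes in the hybrids.
* ``simulate_amplicon_genome`` / ``simulate_depth`` — a toy genome carrying an
  ampliconic gene family of known reference copy number R and sample copy
  number N, with Poisson read depth whose paralog pile-up encodes N/R.
* ``simulate_phenotypes`` — per-animal reproductive traits and 100-sperm
  morphology category counts from per-cross multinomials.
* ``simulate_zf_protein`` — tandem C2H2 zinc-finger arrays with known
  recognition-helix -1/3/6 triplets.

Every generator is a pure function of its config + seed: one
``numpy.random.default_rng`` stream per call, no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CELL_TYPES, CROSSES, CountMatrix, CoverageTrack, SampleMeta

HYBRIDS = ("musXdom", "domXmus")
#: which parental cross shares the hybrid's X chromosome (X comes from the mother)
X_PARENT = {"musXdom": "mus", "domXmus": "dom"}

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSimConfig:
    """Design and effect sizes for the expression simulation.

    ``dispersion`` is the NB dispersion phi in the variance function
    var = mu + phi * mu^2; the default 0.1748**2 matches the study's observed
    biological coefficient of variation. ``msci_silencing`` multiplies X-gene
    means in diplotene of the fertile crosses (and sets the hybrid diplotene
    baseline, since de-repression is expressed relative to the silenced
    parental X). ``disrupt_frac_dip``/``disrupt_frac_rs`` give, per hybrid,
    the fraction of X genes whose mean is multiplied by 2**disrupt_logfc in
    that stage.
    """

    n_genes: int = 3000
    frac_x: float = 0.05
    replicates: int = 3
    baseline_mean: float = 500.0
    dispersion: float = 0.1748 ** 2
    msci_silencing: float = 0.02
    disrupt_frac_dip: Mapping[str, float] = field(
        default_factory=lambda: {"musXdom": 0.4, "domXmus": 0.2}
    )
    disrupt_frac_rs: Mapping[str, float] = field(
        default_factory=lambda: {"musXdom": 0.3, "domXmus": 0.0}
    )
    disrupt_logfc: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.disrupt_frac_dip, (int, float)):
            self.disrupt_frac_dip = {h: float(self.disrupt_frac_dip) for h in HYBRIDS}
        if isinstance(self.disrupt_frac_rs, (int, float)):
            self.disrupt_frac_rs = {h: float(self.disrupt_frac_rs) for h in HYBRIDS}
        if self.n_genes < 1 or self.replicates < 1:
            raise ValueError("n_genes and replicates must be positive")
        if not 0 < self.frac_x < 1:
            raise ValueError("frac_x must be in (0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for frac in (self.msci_silencing, *self.disrupt_frac_dip.values(),
                     *self.disrupt_frac_rs.values()):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, phi) as a gamma-Poisson mixture; var = mu + phi mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_expression(cfg: ExpressionSimConfig) -> tuple[pd.DataFrame, CountMatrix, pd.DataFrame]:
    """Generate (GeneTable, CountMatrix, truth table) for the full design.

    The truth table has one row per gene x cell type x hybrid with the planted
    log2 fold change of that hybrid relative to the parent sharing its X.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    n_x = max(1, int(round(cfg.frac_x * n)))

    # annotation: X genes first by construction; autosomes over 5 chromosomes
    # (dense enough that a 250-gene window scan has room at the default size)
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    chroms = np.array(["X"] * n_x + [f"chr{1 + i % 5}" for i in range(n - n_x)])
    exonic = np.exp(rng.uniform(np.log(500), np.log(5000), size=n)).astype(int)
    starts = np.zeros(n, dtype=int)
    ends = np.zeros(n, dtype=int)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = np.cumsum(rng.integers(10_000, 100_000, size=len(idx)))
        starts[idx] = pos
        ends[idx] = pos + exonic[idx] * 2
    genes = pd.DataFrame(
        {
            "chromosome": chroms,
            "start": starts,
            "end": ends,
            "gene_id": gene_ids,
            "exonic_length": exonic,
        }
    )
    genes = genes.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    genes["order_index"] = np.arange(len(genes))
    genes["is_x"] = genes["chromosome"] == "X"

    # per-gene baselines and per-gene cell-type offsets (drive stage clustering)
    base = cfg.baseline_mean * rng.lognormal(0.0, 0.6, size=n)
    stage_mult = {ct: rng.lognormal(0.0, 0.5, size=n) for ct in CELL_TYPES}

    is_x = np.arange(n) < n_x  # X genes are the first n_x ids by construction
    x_idx = np.flatnonzero(is_x)

    # choose disrupted X genes per hybrid and stage
    disrupted: dict[tuple[str, str], np.ndarray] = {}
    for hybrid in HYBRIDS:
        for ct, fracs in (("DIP", cfg.disrupt_frac_dip), ("RS", cfg.disrupt_frac_rs)):
            k = int(round(fracs.get(hybrid, 0.0) * len(x_idx)))
            chosen = rng.choice(x_idx, size=k, replace=False) if k else np.array([], dtype=int)
            disrupted[(hybrid, ct)] = np.sort(chosen)

    samples: list[SampleMeta] = []
    columns: list[np.ndarray] = []
    for cross in CROSSES:
        for ct in CELL_TYPES:
            mean = base * stage_mult[ct]
            if ct == "DIP":
                mean = mean.copy()
                mean[is_x] *= cfg.msci_silencing  # MSCI, fertile baseline
            if cross in HYBRIDS:
                hit = disrupted.get((cross, ct), np.array([], dtype=int))
                if len(hit):
                    mean = mean.copy()
                    mean[hit] *= 2.0 ** cfg.disrupt_logfc
            for rep in range(1, cfg.replicates + 1):
                samples.append(SampleMeta(f"{cross}_{ct}_r{rep}", cross, ct, rep))
                columns.append(_nb_draw(rng, mean, cfg.dispersion))

    counts = pd.DataFrame(
        np.column_stack(columns), index=gene_ids, columns=[s.sample_id for s in samples]
    )
    counts = counts.loc[genes["gene_id"]]  # row order matches the GeneTable
    cm = CountMatrix(counts=counts, samples=samples)

    rows = []
    for hybrid in HYBRIDS:
        for ct in CELL_TYPES:
            hit = set(disrupted.get((hybrid, ct), ()))
            for i, gid in enumerate(gene_ids):
                lfc = cfg.disrupt_logfc if i in hit else 0.0
                rows.append((gid, ct, hybrid, lfc, lfc != 0.0))
    truth = pd.DataFrame(rows, columns=["gene_id", "cell_type", "hybrid", "true_logfc", "is_disrupted"])
    return genes, cm, truth


# ---------------------------------------------------------------------------
# ampliconic genome + depth


@dataclass
class AmpliconSimConfig:
    """Toy genome carrying one ampliconic family.

    R near-identical copies of the query gene are planted in the reference
    (``ref_copies``); the sample being "sequenced" carries ``true_copies`` N,
    so multimapped read depth inside each reference copy is (N/R) x the
    haploid mean depth. A decoy below the 97% paralog-identity threshold
    exercises the filter's lower side.
    """

    backbone_length: int = 200_000
    gene_length: int = 2_000
    ref_copies: int = 4
    true_copies: int = 40
    # ampliconic repeats are defined by near-perfect (>99.9%) internal identity;
    # the decoy sits below the 97% paralog filter
    copy_identity: float = 0.999
    decoy_identity: float = 0.92
    haploid_mean_depth: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.decoy_identity < 0.97 <= self.copy_identity <= 1.0):
            raise ValueError("need copy_identity >= 0.97 > decoy_identity")
        if self.ref_copies < 1 or self.true_copies < 1:
            raise ValueError("copy counts must be positive")


@dataclass
class AmpliconTruth:
    chromosome: str
    genome_length: int
    query: str
    intervals: list[tuple[int, int]]  # planted paralog intervals (0-based, half-open)
    decoy_interval: tuple[int, int]
    ref_copies: int
    true_copies: int


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base independently with probability ``rate`` (always to a different base)."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = BASES[BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def simulate_amplicon_genome(cfg: AmpliconSimConfig) -> tuple[dict[str, str], dict[str, str], AmpliconTruth]:
    """Return ({chrom: genome seq}, {name: query seq}, truth).

    Plants ``ref_copies`` mutated copies of a random query gene plus one decoy
    at ``decoy_identity`` at non-overlapping positions on a random backbone.
    """
    rng = np.random.default_rng(cfg.seed)
    n_slots = cfg.ref_copies + 1
    if n_slots * cfg.gene_length * 2 > cfg.backbone_length:
        raise ValueError(
            f"backbone of {cfg.backbone_length} bp cannot hold {n_slots} copies "
            f"of {cfg.gene_length} bp without crowding"
        )
    backbone = _random_seq(rng, cfg.backbone_length)
    query = _random_seq(rng, cfg.gene_length)

    # evenly partition the backbone into slots, jitter starts within each slot
    slot = cfg.backbone_length // n_slots
    starts = []
    for i in range(n_slots):
        lo = i * slot
        hi = (i + 1) * slot - cfg.gene_length
        starts.append(int(rng.integers(lo, hi)))
    rng.shuffle(starts)
    copy_starts, decoy_start = sorted(starts[:-1]), starts[-1]

    intervals = []
    for s in copy_starts:
        copy = _mutate(rng, query, 1.0 - cfg.copy_identity)
        backbone[s: s + cfg.gene_length] = copy
        intervals.append((s, s + cfg.gene_length))
    decoy = _mutate(rng, query, 1.0 - cfg.decoy_identity)
    backbone[decoy_start: decoy_start + cfg.gene_length] = decoy

    genome = {"chrSim": backbone.tobytes().decode()}
    queries = {"queryGene": query.tobytes().decode()}
    truth = AmpliconTruth(
        chromosome="chrSim",
        genome_length=cfg.backbone_length,
        query=queries["queryGene"],
        intervals=intervals,
        decoy_interval=(decoy_start, decoy_start + cfg.gene_length),
        ref_copies=cfg.ref_copies,
        true_copies=cfg.true_copies,
    )
    return genome, queries, truth


def simulate_depth(truth: AmpliconTruth, cfg: AmpliconSimConfig) -> CoverageTrack:
    """Per-base Poisson depth over the toy genome.

    Diploid backbone at 2 x haploid mean; inside each planted paralog interval
    the N sample copies pile onto R reference locations, giving mean
    (N/R) x haploid depth; the decoy stays diploid-background (its divergence
    keeps sample-family reads from mapping there).
    """
    rng = np.random.default_rng((cfg.seed, 1))
    c = cfg.haploid_mean_depth
    mean = np.full(truth.genome_length, 2.0 * c)
    for s, e in truth.intervals:
        mean[s:e] = (truth.true_copies / truth.ref_copies) * c
    depth = rng.poisson(mean).astype(float)

    # run-length encode into bedGraph-style intervals
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(depth)]))
    df = pd.DataFrame(
        {
            "chromosome": truth.chromosome,
            "start": starts,
            "end": ends,
            "depth": depth[starts],
        }
    )
    return CoverageTrack(intervals=df)


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class CrossPhenotypeConfig:
    """Per-cross trait means/SDs and the 4-category sperm-morphology multinomial."""

    testes_mg_g: float
    sv_mg_g: float
    motility: float
    sperm_count: float
    morph_probs: tuple[float, float, float, float]
    testes_sd: float = 0.8
    sv_sd: float = 0.8
    motility_sd: float = 0.08
    sperm_count_sd: float = 3.0


#: defaults echo the ordering of the study's crosses: fertile parents with
#: nearly all normal sperm, both hybrids with small testes / low counts, and
#: the musXdom hybrid with the most severe morphology.
DEFAULT_PHENOTYPES: dict[str, CrossPhenotypeConfig] = {
    "dom": CrossPhenotypeConfig(11.3, 5.2, 0.82, 14.8, (0.97, 0.02, 0.01, 0.00)),
    "mus": CrossPhenotypeConfig(9.5, 5.6, 0.87, 17.8, (0.97, 0.02, 0.01, 0.00)),
    "domXmus": CrossPhenotypeConfig(6.3, 5.7, 0.83, 4.2, (0.20, 0.25, 0.25, 0.30)),
    "musXdom": CrossPhenotypeConfig(6.5, 5.4, 0.65, 5.8, (0.08, 0.15, 0.20, 0.57)),
}

N_SPERM_SCORED = 100


def simulate_phenotypes(
    n_per_cross: int,
    effects: Mapping[str, CrossPhenotypeConfig] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal trait table: cross, weights, motility, count, morphology counts."""
    if n_per_cross < 1:
        raise ValueError("n_per_cross must be positive")
    effects = dict(DEFAULT_PHENOTYPES if effects is None else effects)
    rng = np.random.default_rng(seed)
    rows = []
    for cross, cfg in effects.items():
        probs = np.asarray(cfg.morph_probs, dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError(f"morphology probabilities for {cross!r} must be a distribution")
        for i in range(n_per_cross):
            morph = rng.multinomial(N_SPERM_SCORED, probs)
            rows.append(
                {
                    "animal_id": f"{cross}_{i + 1}",
                    "cross": cross,
                    "testes_mg_g": max(0.0, rng.normal(cfg.testes_mg_g, cfg.testes_sd)),
                    "sv_mg_g": max(0.0, rng.normal(cfg.sv_mg_g, cfg.sv_sd)),
                    "motility": float(np.clip(rng.normal(cfg.motility, cfg.motility_sd), 0, 1)),
                    "sperm_count": max(0.0, rng.normal(cfg.sperm_count, cfg.sperm_count_sd)),
                    "morph_normal": int(morph[0]),
                    "morph_slight": int(morph[1]),
                    "morph_abnormal": int(morph[2]),
                    "morph_severe": int(morph[3]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# zinc-finger arrays


# 28-residue C2H2 repeat: C-x2-C-x12-H-x3-H-x7. Offsets within the repeat:
# C at 0 and 3, first zinc histidine H1 at 16, second at 20. The DNA-contacting
# recognition-helix positions -1/3/6 sit at H1-7, H1-4, H1-1 = 9, 12, 15.
_FINGER_TEMPLATE = list("CGECGRGFSRSDELTRHIRTHTGEKPYA")
_TRIPLET_OFFSETS = (9, 12, 15)
_FIRST_FINGER_TRIPLET = "QSG"  # the invariant first finger

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def simulate_zf_protein(
    n_fingers: int, triplets: Sequence[str], seed: int = 0, name: str = "zf_sim"
) -> tuple[dict[str, str], list[str]]:
    """Build a tandem C2H2 array with requested -1/3/6 triplets.

    Finger 1 is fixed (the nonvariant finger the typing step discards);
    ``triplets`` supplies the -1/3/6 residues for fingers 2..n_fingers. Returns
    ({name: protein}, planted triplets).
    """
    if n_fingers < 2:
        raise ValueError("need at least 2 fingers (first is nonvariant)")
    if len(triplets) != n_fingers - 1:
        raise ValueError(
            f"expected {n_fingers - 1} triplets for {n_fingers} fingers, got {len(triplets)}"
        )
    for t in triplets:
        if len(t) != 3 or any(a not in AMINO_ACIDS for a in t):
            raise ValueError(f"invalid triplet {t!r}")
    del seed  # deterministic construction; kept for interface uniformity

    def make_finger(triplet: str) -> str:
        f = _FINGER_TEMPLATE.copy()
        for off, res in zip(_TRIPLET_OFFSETS, triplet):
            f[off] = res
        return "".join(f)

    protein = "MA" + make_finger(_FIRST_FINGER_TRIPLET)
    for t in triplets:
        protein += make_finger(t.upper())
    return {name: protein}, [t.upper() for t in triplets]
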