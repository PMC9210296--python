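"""Ampliconic gene-family copy number from relative sequencing depth.

Ampliconic families (Slx/Slxl1 on the X, Sly on the Y) exist as dozens to
hundreds of near-identical copies that collapse onto few reference loci, so
copy number must be inferred from read depth relative to the genome-wide
average. Two estimators are provided:

* region coverage — find reference paralogs of the query gene (>= 97%
  identity), sum the per-region mean depths, and divide by half the
  genome-wide mean (half because the bulk of the genome is diploid while the
  sex chromosomes in males are haploid);
* informative sites — extract all 101-bp kmers of the query, find the modal
  number of exact genome matches m, keep kmers mapping exactly m times,
  enumerate every location those kmers hit with <= 2 mismatches, and average
  the summed (optionally GC-corrected) relative depths over kmers.

All kmer mapping is an internal exact-match seed index plus a pigeonhole
mismatch scan on both strands; no external aligner is involved, so results
are bit-reproducible from the same inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CoverageTrack
from .stats import round_sig

_COMP = str.maketrans("ACGT", "TGCA")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass
class SeedIndex:
    """Exact-match index of every length-``seed`` substring of a genome."""

    seed: int
    arrays: dict[str, np.ndarray]  # chrom -> uint8 sequence
    table: dict[bytes, list[tuple[str, int]]]

    @classmethod
    def build(cls, genome: dict[str, str], seed: int) -> "SeedIndex":
        arrays = {c: _encode(s) for c, s in genome.items()}
        table: dict[bytes, list[tuple[str, int]]] = {}
        for chrom, arr in arrays.items():
            raw = arr.tobytes()
            for i in range(len(raw) - seed + 1):
                table.setdefault(raw[i: i + seed], []).append((chrom, i))
        return cls(seed=seed, arrays=arrays, table=table)

    def _candidates(self, kmer: np.ndarray) -> set[tuple[str, int]]:
        """Pigeonhole candidate starts: any <=2-mismatch hit of a kmer split into
        three seed-length parts must match one part exactly."""
        k = len(kmer)
        raw = kmer.tobytes()
        cands: set[tuple[str, int]] = set()
        for off in (0, self.seed, 2 * self.seed):
            if off + self.seed > k:
                break
            for chrom, pos in self.table.get(raw[off: off + self.seed], ()):
                start = pos - off
                if 0 <= start <= len(self.arrays[chrom]) - k:
                    cands.add((chrom, start))
        return cands

    def find(self, kmer: np.ndarray, max_mismatch: int) -> list[tuple[str, int, int]]:
        """All (chrom, start, n_mismatches) with Hamming distance <= max_mismatch."""
        k = len(kmer)
        out = []
        for chrom, start in self._candidates(kmer):
            mm = int((self.arrays[chrom][start: start + k] != kmer).sum())
            if mm <= max_mismatch:
                out.append((chrom, start, mm))
        return sorted(out)


def _strand_hits(index: SeedIndex, kmer_str: str, max_mismatch: int) -> list[tuple[str, int, int, str]]:
    """Hits of a kmer on both strands, in forward coordinates."""
    fwd = [(c, s, m, "+") for c, s, m in index.find(_encode(kmer_str), max_mismatch)]
    rev = [(c, s, m, "-") for c, s, m in index.find(_encode(_revcomp(kmer_str)), max_mismatch)]
    return fwd + rev


# ---------------------------------------------------------------------------
# paralog discovery


@dataclass
class ParalogSet:
    family: str
    intervals: list[tuple[str, int, int, float]]  # (chrom, start, end, identity)
    query_length: int


def find_paralogs(
    query: str,
    genome: dict[str, str],
    family: str = "family",
    min_identity: float = 0.97,
    min_aligned_frac: float = 0.9,
    seed: int = 31,
    max_hits: int = 1000,
) -> ParalogSet:
    """Locate near-identical copies of ``query`` in ``genome`` on both strands.

    Exact ``seed``-mers vote for candidate ungapped offsets; each candidate
    locus is scored by full-span ungapped identity and kept when identity >=
    ``min_identity`` over at least ``min_aligned_frac`` of the query length.
    Overlapping hits are merged keeping the higher identity.
    """
    if len(query) < seed:
        raise ValueError(f"query of {len(query)} bp is shorter than the {seed}-bp seed")
    index = SeedIndex.build(genome, seed)
    qlen = len(query)

    hits: list[tuple[str, int, int, float]] = []
    for qseq in (query.upper(), _revcomp(query)):
        q = _encode(qseq)
        offsets: set[tuple[str, int]] = set()
        raw = q.tobytes()
        for i in range(0, qlen - seed + 1):
            for chrom, pos in index.table.get(raw[i: i + seed], ()):
                offsets.add((chrom, pos - i))
        for chrom, off in offsets:
            arr = index.arrays[chrom]
            g_start = max(off, 0)
            g_end = min(off + qlen, len(arr))
            span = g_end - g_start
            if span < min_aligned_frac * qlen:
                continue
            matches = int((arr[g_start:g_end] == q[g_start - off: g_end - off]).sum())
            identity = matches / span
            if identity >= min_identity:
                hits.append((chrom, g_start, g_end, identity))

    # merge overlaps, keeping the higher-identity interval
    hits.sort(key=lambda h: (h[0], h[1], -h[3]))
    merged: list[tuple[str, int, int, float]] = []
    for h in hits:
        if merged and merged[-1][0] == h[0] and h[1] < merged[-1][2]:
            if h[3] > merged[-1][3]:
                merged[-1] = h
            continue
        merged.append(h)
    return ParalogSet(family=family, intervals=merged[:max_hits], query_length=qlen)


# ---------------------------------------------------------------------------
# estimator 1: region coverage


@dataclass
class CopyNumberEstimate:
    family: str
    method: str  # "region_coverage" or "informative_sites"
    estimate: float
    n_regions_or_sites: int
    genome_mean_depth: float


def _background_mean(
    arrays: dict[str, np.ndarray], exclude: list[tuple[str, int, int]]
) -> float:
    """Length-weighted mean depth outside the excluded intervals.

    On a full-size genome the family's own regions are a negligible fraction
    and this equals the genome-wide average; on a desk-scale toy genome the
    amplicon pile-up would otherwise inflate its own denominator.
    """
    masks = {c: np.ones(len(a), dtype=bool) for c, a in arrays.items()}
    for chrom, start, end in exclude:
        if chrom in masks:
            masks[chrom][max(start, 0): end] = False
    total = 0.0
    n = 0
    for chrom, arr in arrays.items():
        m = masks[chrom]
        total += float(arr[m].sum())
        n += int(m.sum())
    if n == 0:
        raise ValueError("no background bases left after exclusion")
    return total / n


def cn_from_region_coverage(paralogs: ParalogSet, depth: CoverageTrack) -> CopyNumberEstimate:
    """Sum of per-region mean depths divided by half the genome-wide mean.

    Each single-copy diploid-like region contributes ~1 haploid unit, so the
    total is the family's haploid copy count. The genome-wide mean is taken
    over the genome excluding the family's own regions (see
    :func:`_background_mean`).
    """
    if depth.genome_mean <= 0:
        raise ValueError("genome mean depth is zero")
    arrays = depth.depth_arrays()
    total = 0.0
    for chrom, start, end, _ident in paralogs.intervals:
        if chrom not in arrays or end > len(arrays[chrom]):
            raise ValueError(f"depth track does not cover {chrom}:{start}-{end}")
        total += float(arrays[chrom][start:end].mean())
    background = _background_mean(arrays, [(c, s, e) for c, s, e, _ in paralogs.intervals])
    if background <= 0:
        raise ValueError("zero background depth")
    estimate = total / (background / 2.0)
    return CopyNumberEstimate(
        family=paralogs.family,
        method="region_coverage",
        estimate=estimate,
        n_regions_or_sites=len(paralogs.intervals),
        genome_mean_depth=background,
    )


# ---------------------------------------------------------------------------
# estimator 2: informative sites


@dataclass
class KmerSites:
    query_pos: int
    locations: list[tuple[str, int, int, str]]  # (chrom, start, mismatches, strand)


@dataclass
class InformativeSiteSet:
    family: str
    k: int
    modal_multiplicity: int
    kmers: list[KmerSites]
    #: union of every query kmer's mismatch-tolerant windows: the genome span
    #: attributable to the family, excluded from the background depth
    family_intervals: list[tuple[str, int, int]]


def build_informative_sites(
    query: str,
    genome: dict[str, str],
    family: str = "family",
    k: int = 101,
    map_cap: int = 500,
    max_mismatch: int = 2,
) -> InformativeSiteSet:
    """Informative sites: locations of query kmers that map a modal number of times.

    For each of the len-k+1 query kmers, exact genome matches are counted on
    both strands (kmers above ``map_cap`` hits are discarded); m is the modal
    positive count, ties broken toward the smaller value; kmers mapping
    exactly m times are retained and all their <= ``max_mismatch``-mismatch
    locations recorded.
    """
    if len(query) < k:
        raise ValueError(f"query of {len(query)} bp is shorter than k={k}")
    seed = k // 3  # three disjoint parts support a <=2-mismatch pigeonhole
    index = SeedIndex.build(genome, seed)

    query = query.upper()
    exact_counts: list[int] = []
    near_hits: list[list[tuple[str, int, int, str]]] = []
    family_windows: set[tuple[str, int]] = set()
    for i in range(len(query) - k + 1):
        near = _strand_hits(index, query[i: i + k], max_mismatch)
        near_hits.append(near)
        family_windows.update((c, s) for c, s, _m, _st in near)
        n_exact = sum(1 for _c, _s, m, _st in near if m == 0)
        exact_counts.append(n_exact if n_exact <= map_cap else -1)

    counts = np.array(exact_counts)
    usable = counts[counts > 0]
    if (counts == -1).all():
        raise ValueError("every kmer exceeds the mapping cap; family too repetitive")
    if len(usable) == 0:
        raise ValueError("no query kmer maps exactly anywhere in the genome")
    values, freqs = np.unique(usable, return_counts=True)
    m = int(values[np.flatnonzero(freqs == freqs.max())[0]])  # smallest on ties

    kmers = [
        KmerSites(query_pos=int(i), locations=near_hits[i])
        for i in np.flatnonzero(counts == m)
    ]
    # merge the per-window family footprint into intervals
    merged: list[tuple[str, int, int]] = []
    for chrom, s in sorted(family_windows):
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], s + k))
        else:
            merged.append((chrom, s, s + k))
    return InformativeSiteSet(
        family=family, k=k, modal_multiplicity=m, kmers=kmers, family_intervals=merged
    )


def _gc_fraction(arr: np.ndarray) -> float:
    return float(((arr == ord("G")) | (arr == ord("C"))).mean())


def cn_from_informative_sites(
    sites: InformativeSiteSet,
    depth: CoverageTrack,
    genome: dict[str, str],
    gc_correct: bool = True,
    gc_bin_width: float = 0.02,
    gc_sample_windows: int = 1000,
    gc_seed: int = 0,
) -> CopyNumberEstimate:
    """Mean over retained kmers of the summed relative depth at their locations.

    Relative depth at a location is the mean depth over its k-bp window
    divided by half the genome-wide mean. GC correction divides by the
    per-2%-GC-bin median relative depth of randomly sampled genome windows,
    normalized to the global median so an unbiased genome is untouched.
    """
    if not sites.kmers:
        raise ValueError("empty informative site set")
    if depth.genome_mean <= 0:
        raise ValueError("genome mean depth is zero")
    arrays = depth.depth_arrays()
    encoded = {c: _encode(s) for c, s in genome.items()}
    k = sites.k
    half_mean = _background_mean(arrays, sites.family_intervals) / 2.0
    if half_mean <= 0:
        raise ValueError("zero background depth")

    factor_by_bin: dict[int, float] = {}
    if gc_correct:
        rng = np.random.default_rng(gc_seed)
        chroms = sorted(arrays)
        lengths = np.array([len(arrays[c]) - k for c in chroms], dtype=float)
        probs = lengths / lengths.sum()
        rels: dict[int, list[float]] = {}
        all_rels = []
        for _ in range(gc_sample_windows):
            c = chroms[rng.choice(len(chroms), p=probs)]
            s = int(rng.integers(0, len(arrays[c]) - k))
            rel = float(arrays[c][s: s + k].mean()) / half_mean
            b = int(_gc_fraction(encoded[c][s: s + k]) / gc_bin_width)
            rels.setdefault(b, []).append(rel)
            all_rels.append(rel)
        global_median = float(np.median(all_rels))
        for b, vals in rels.items():
            med = float(np.median(vals))
            if med > 0 and global_median > 0:
                factor_by_bin[b] = med / global_median

    contributions = []
    for km in sites.kmers:
        total = 0.0
        for chrom, start, _mm, _strand in km.locations:
            rel = float(arrays[chrom][start: start + k].mean()) / half_mean
            if gc_correct:
                b = int(_gc_fraction(encoded[chrom][start: start + k]) / gc_bin_width)
                rel /= factor_by_bin.get(b, 1.0)
            total += rel
        contributions.append(total)
    return CopyNumberEstimate(
        family=sites.family,
        method="informative_sites",
        estimate=float(np.mean(contributions)),
        n_regions_or_sites=sum(len(km.locations) for km in sites.kmers),
        genome_mean_depth=2.0 * half_mean,
    )


# ---------------------------------------------------------------------------
# family ratios


def compute_family_ratio(
    sly: CopyNumberEstimate | float,
    slx: CopyNumberEstimate | float,
    slxl1: CopyNumberEstimate | float = 0.0,
    sig_digits: int | None = None,
) -> float:
    """Sly / (Slx + Slxl1) copy-number ratio, optionally rounded to significant digits.

    The denominator pools the two coamplified X-linked families, matching how
    the imbalance between reciprocal hybrids is expressed.
    """
    def val(x):
        return x.estimate if isinstance(x, CopyNumberEstimate) else float(x)

    num = val(sly)
    den = val(slx) + val(slxl1)
    if num < 0 or val(slx) < 0 or val(slxl1) < 0:
        raise ValueError("copy-number estimates must be non-negative")
    if den <= 0:
        raise ValueError("zero Slx + Slxl1 denominator")
    ratio = num / den
    return round_sig(ratio, sig_digits) if sig_digits else ratio
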