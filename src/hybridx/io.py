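"""Readers and writers for the tabular and track formats the pipeline touches.

Conventions
-----------
* All interval formats (annotation, bedGraph) are 0-based, half-open.
* All tables are tab-delimited with a single header line and LF endings, so a
  write-then-read round trip is byte-identical for canonical (sorted) inputs.
* Readers validate and fail loudly with the offending record named; they never
  silently coerce malformed fields.

Sample metadata follows the study design: four crosses (two parental species
controls ``dom`` and ``mus`` plus the reciprocal F1 hybrids ``musXdom`` and
``domXmus``, named mother x father) by three FACS-enriched spermatogenesis
stages (``LZ`` leptotene/zygotene, ``DIP`` diplotene, ``RS`` round spermatid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CROSSES = ("dom", "mus", "musXdom", "domXmus")
CELL_TYPES = ("LZ", "DIP", "RS")

X_CHROMOSOME = "X"


@dataclass(frozen=True)
class SampleMeta:
    """One RNA-seq library: a (cross, cell type, replicate) cell of the design."""

    sample_id: str
    cross: str
    cell_type: str
    replicate: int

    def __post_init__(self):
        if self.cross not in CROSSES:
            raise ValueError(f"unknown cross {self.cross!r} for sample {self.sample_id!r}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r} for sample {self.sample_id!r}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1 for sample {self.sample_id!r}")


@dataclass
class CountMatrix:
    """Gene-level integer counts (genes x samples) plus per-sample metadata."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids, int dtype
    samples: list[SampleMeta]

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise ValueError("count matrix columns do not match sample metadata order")
        triples = [(s.cross, s.cell_type, s.replicate) for s in self.samples]
        if len(set(triples)) != len(triples):
            raise ValueError("duplicate (cross, cell_type, replicate) triples in metadata")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def sample_ids(self, cross: str | None = None, cell_type: str | None = None) -> list[str]:
        """Sample ids, optionally restricted to one cross and/or cell type."""
        out = []
        for s in self.samples:
            if cross is not None and s.cross != cross:
                continue
            if cell_type is not None and s.cell_type != cell_type:
                continue
            out.append(s.sample_id)
        return out


@dataclass
class CoverageTrack:
    """Sorted, non-overlapping depth intervals with the genome-wide mean depth."""

    intervals: pd.DataFrame  # columns: chromosome, start, end, depth
    genome_mean: float = field(init=False)

    def __post_init__(self):
        df = self.intervals
        for chrom, sub in df.groupby("chromosome", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts >= ends).any():
                bad = sub[starts >= ends].iloc[0]
                raise ValueError(f"empty/inverted interval {chrom}:{bad['start']}-{bad['end']}")
            order = np.argsort(starts, kind="stable")
            if (ends[order][:-1] > starts[order][1:]).any():
                i = int(np.nonzero(ends[order][:-1] > starts[order][1:])[0][0])
                raise ValueError(
                    f"overlapping intervals on {chrom}: "
                    f"{starts[order][i]}-{ends[order][i]} and {starts[order][i+1]}-{ends[order][i+1]}"
                )
        lengths = (df["end"] - df["start"]).to_numpy(dtype=float)
        self.genome_mean = float((df["depth"].to_numpy() * lengths).sum() / lengths.sum())

    def depth_arrays(self) -> dict[str, np.ndarray]:
        """Expand to per-base depth arrays keyed by chromosome (desk-scale genomes)."""
        out: dict[str, np.ndarray] = {}
        for chrom, sub in self.intervals.groupby("chromosome", sort=False):
            arr = np.zeros(int(sub["end"].max()), dtype=float)
            for s, e, d in zip(sub["start"], sub["end"], sub["depth"]):
                arr[int(s): int(e)] = d
            out[chrom] = arr
        return out


# ---------------------------------------------------------------------------
# readers


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cross", "cell_type", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns {sorted(missing)}")
    metas = []
    for _, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except ValueError:
            raise ValueError(f"non-integer replicate {row['replicate']!r} for sample {row['sample_id']!r}")
        metas.append(SampleMeta(row["sample_id"], row["cross"], row["cell_type"], rep))
    return metas


def read_count_table(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV of integer counts plus its sample metadata."""
    metas = read_sample_metadata(meta_path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    known = {m.sample_id for m in metas}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"samples in counts absent from metadata: {unknown}")
    absent = [m.sample_id for m in metas if m.sample_id not in df.columns]
    if absent:
        raise ValueError(f"samples in metadata absent from counts: {absent}")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {raw!r} at gene {df.index[i]!r}, sample {col!r}"
                )
            values[i, j] = v
    counts = pd.DataFrame(values, index=df.index, columns=df.columns)
    counts = counts[[m.sample_id for m in metas]]
    return CountMatrix(counts=counts, samples=metas)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene table; returns the canonical GeneTable frame.

    Columns in: chromosome, start, end, gene_id, exonic_length (tab-separated,
    header line). Columns out add ``order_index`` (rank by chromosome then
    start) and ``is_x``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "gene_id": str})
    required = {"chromosome", "start", "end", "gene_id", "exonic_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation {path} missing columns {sorted(missing)}")
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"gene {bad['gene_id']!r} has start >= end ({bad['start']} >= {bad['end']})")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    if (df["exonic_length"] <= 0).any():
        bad = df[df["exonic_length"] <= 0].iloc[0]
        raise ValueError(f"gene {bad['gene_id']!r} has non-positive exonic length")
    df = df.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    df["order_index"] = np.arange(len(df))
    df["is_x"] = df["chromosome"] == X_CHROMOSOME
    return df


def read_coverage_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a bedGraph depth track (0-based half-open) into a CoverageTrack."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 bedGraph fields, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError:
                raise ValueError(f"{path}:{ln}: malformed bedGraph record {line!r}")
    if not rows:
        raise ValueError(f"{path}: empty bedGraph")
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "depth"])
    if (df["depth"] < 0).any():
        raise ValueError(f"{path}: negative depth value")
    df = df.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    return CoverageTrack(intervals=df)


# ---------------------------------------------------------------------------
# writers (canonical TSV/bedGraph, LF endings, 6 significant digits for floats)


def write_count_table(cm: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")
    meta = pd.DataFrame(
        [(s.sample_id, s.cross, s.cell_type, s.replicate) for s in cm.samples],
        columns=["sample_id", "cross", "cell_type", "replicate"],
    )
    meta.to_csv(meta_path, sep="\t", index=False, lineterminator="\n")


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    cols = ["chromosome", "start", "end", "gene_id", "exonic_length"]
    genes[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_coverage_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, d in track.intervals.itertuples(index=False):
            fh.write(f"{chrom}\t{s}\t{e}\t{d:.6g}\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic result-table writer: TSV, header line, 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def write_run_summary(path: str | Path, **fields) -> None:
    """JSON run summary (parameters, seeds, input digests) for reproducibility."""
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Sequence[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")
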