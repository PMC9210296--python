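"""PRDM9 zinc-finger allele typing from protein sequence.

PRDM9's DNA-binding specificity — and its role in hybrid male sterility —
is carried by the C-terminal tandem array of C2H2 zinc fingers, and within
each finger by the recognition-helix residues at positions -1, 3 and 6.
Alleles are typed by locating the fingers, reading those three residues per
finger (dropping the invariant first finger), and comparing the resulting
signature against a table of known alleles (e.g. the sterile msc1/dom3
combination carried by the strains in this cross design).

Fingers are found with the C2H2 consensus pattern C-x(2,4)-C-x(12)-H-x(3,5)-H
scanned left to right without overlap; with H1 the first zinc-coordinating
histidine, the -1/3/6 triplet sits at offsets H1-7, H1-4, H1-1.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd

_C2H2 = re.compile(r"C.{2,4}?C.{12}(H).{3,5}?H")


@dataclass
class ZincFinger:
    start: int  # 0-based residue index of the motif
    end: int
    triplet: tuple[str, str, str]


@dataclass
class ZincFingerArray:
    protein_id: str
    fingers: list[ZincFinger]

    @property
    def signature(self) -> list[str]:
        return ["".join(f.triplet) for f in self.fingers]


def extract_zf_triplets(protein: str, protein_id: str = "query", exclude_first: bool = True) -> ZincFingerArray:
    """Locate C2H2 fingers and read their -1/3/6 recognition-helix residues.

    The first finger is dropped by default (PRDM9's first finger is
    nonvariant and carries no typing information). A protein with no motif
    match returns an empty array with a warning.
    """
    protein = protein.upper()
    fingers = []
    for match in _C2H2.finditer(protein):
        h1 = match.start(1)  # the first zinc-coordinating histidine
        fingers.append(
            ZincFinger(
                start=match.start(),
                end=match.end(),
                triplet=(protein[h1 - 7], protein[h1 - 4], protein[h1 - 1]),
            )
        )
    if not fingers:
        warnings.warn(f"no C2H2 motif found in {protein_id!r}")
    if exclude_first and fingers:
        fingers = fingers[1:]
    return ZincFingerArray(protein_id=protein_id, fingers=fingers)


@dataclass
class AlleleCall:
    protein_id: str
    call: str  # allele name or "novel"
    nearest: list[str]  # nearest alleles (several when tied)
    distance: int | None  # per-finger Hamming distance to the nearest allele


def match_allele(array: ZincFingerArray, table: dict[str, list[str]]) -> AlleleCall:
    """Exact signature match against an allele table, else "novel" with distances.

    Distance to an allele is the number of fingers whose triplet differs;
    signatures of different lengths add the length difference. Equidistant
    nearest alleles are all reported (the tie is surfaced, not broken).
    """
    if not table:
        raise ValueError("empty allele table")
    if not array.fingers:
        raise ValueError("empty zinc-finger array")
    sig = array.signature
    for name, ref in table.items():
        if list(ref) == sig:
            return AlleleCall(array.protein_id, name, [name], 0)
    dists = {}
    for name, ref in table.items():
        n = min(len(ref), len(sig))
        d = sum(1 for i in range(n) if ref[i] != sig[i]) + abs(len(ref) - len(sig))
        dists[name] = d
    best = min(dists.values())
    nearest = sorted(n for n, d in dists.items() if d == best)
    return AlleleCall(array.protein_id, "novel", nearest, best)


def read_allele_table(path) -> dict[str, list[str]]:
    """TSV with columns ``allele`` and ``triplets`` (comma-separated 3-letter codes)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"allele", "triplets"} <= set(df.columns):
        raise ValueError("allele table needs columns: allele, triplets")
    if df["allele"].duplicated().any():
        raise ValueError("duplicate allele names")
    table = {}
    for _, row in df.iterrows():
        sig = [t.strip().upper() for t in row["triplets"].split(",") if t.strip()]
        if not sig:
            raise ValueError(f"allele {row['allele']!r} has an empty signature")
        table[row["allele"]] = sig
    return table
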