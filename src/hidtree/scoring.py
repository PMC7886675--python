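"""Distinguishing score (DS) of genotype markers.

For a marker evaluated over an accession subset with AN accessions, UN missing
calls, HN heterozygous calls and TG distinct homozygous classes with fractions
P_{i/i}:

    DS = (AN - UN - HN) / AN * sum_{i < j} P_{i/i} * P_{j/j}

The score rewards markers with few missing/heterozygous calls and an even
split of homozygous classes.  For a bi-allelic marker this reduces to
((AN-UN-HN)/AN) * P_{0/0} * P_{1/1}, maximal at 0.25 for a clean 50:50 split;
in general the TG-class maximum is (TG-1)/(2*TG), attained at equal class
fractions.

Two conventions exist for the denominator of P_{i/i}; both are implemented:

``"homozygous"`` (default)
    P_{i/i} = count(i/i) / (AN - UN - HN).  Fractions always sum to 1 and the
    prefactor is the sole missing/het penalty.
``"all"``
    P_{i/i} = count(i/i) / AN, penalising missing/het calls a second time
    through the fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix_io import GenotypeMatrix, HET_CODE, MISSING_CODE

__all__ = ["MarkerStats", "tally_marker", "ds_score", "rank_markers", "score_table"]

#: pseudo-allele index used for the heterozygote-as-third-class extension
HET_CLASS_ALLELE = 2


@dataclass
class MarkerStats:
    """Per-marker tallies over an accession subset."""

    an: int
    un: int
    hn: int
    hom_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.an != self.un + self.hn + sum(self.hom_counts.values()):
            raise ValueError(
                "inconsistent tallies: AN must equal UN + HN + sum(hom counts)"
            )

    @property
    def tg(self) -> int:
        """Number of distinct homozygous genotype classes present."""
        return len(self.hom_counts)

    def p(self, denominator: str = "homozygous") -> dict[int, float]:
        """Homozygous class fractions P_{i/i} (empty when no homozygous calls)."""
        if denominator == "homozygous":
            total = self.an - self.un - self.hn
        elif denominator == "all":
            total = self.an
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        if total <= 0 or not self.hom_counts:
            return {}
        return {a: c / total for a, c in self.hom_counts.items()}


def tally_marker(
    matrix: GenotypeMatrix,
    marker: str,
    subset: Sequence[str] | None = None,
    het_as_class: bool = False,
) -> MarkerStats:
    """Tally a marker's calls over a subset of accessions.

    With ``het_as_class``, heterozygous calls form their own genotype class
    ("2/2") instead of counting into HN.
    """
    if subset is None:
        subset = matrix.accession_ids
    if not subset:
        raise ValueError("accession subset must be non-empty")
    row = matrix.codes[matrix.marker_row(marker)]
    cols = [matrix.accession_col(a) for a in subset]
    codes = row[cols]
    return _tally_codes(codes, het_as_class=het_as_class)


def _tally_codes(codes: np.ndarray, het_as_class: bool = False) -> MarkerStats:
    un = int((codes == MISSING_CODE).sum())
    hn = int((codes == HET_CODE).sum())
    hom_counts: dict[int, int] = {}
    for a in sorted({int(c) for c in codes if c >= 0}):
        hom_counts[a] = int((codes == a).sum())
    if het_as_class and hn:
        if any(a >= HET_CLASS_ALLELE for a in hom_counts):
            raise ValueError(
                "heterozygote-as-class requires a bi-allelic matrix: allele "
                f"index >= {HET_CLASS_ALLELE} present alongside heterozygous calls"
            )
        hom_counts[HET_CLASS_ALLELE] = hn
        hn = 0
    return MarkerStats(an=len(codes), un=un, hn=hn, hom_counts=hom_counts)


def ds_score(stats: MarkerStats, denominator: str = "homozygous") -> float:
    """DS of tallied marker stats; 0 when fewer than two homozygous classes."""
    if stats.an == 0:
        raise ValueError("DS is undefined for an empty accession set")
    if stats.tg < 2:
        return 0.0
    p = stats.p(denominator)
    s1 = sum(p.values())
    s2 = sum(v * v for v in p.values())
    pair_sum = (s1 * s1 - s2) / 2.0
    return (stats.an - stats.un - stats.hn) / stats.an * pair_sum


def _ds_vector(
    matrix: GenotypeMatrix,
    cols: Sequence[int],
    het_as_class: bool = False,
    denominator: str = "homozygous",
) -> np.ndarray:
    """DS of every marker restricted to the given accession columns (vectorised)."""
    sub = matrix.codes[:, cols]
    an = sub.shape[1]
    un = (sub == MISSING_CODE).sum(axis=1)
    hn = (sub == HET_CODE).sum(axis=1)
    max_allele = int(sub.max()) if sub.size and sub.max() >= 0 else -1
    counts = [(sub == a).sum(axis=1) for a in range(max_allele + 1)]
    if het_as_class:
        if max_allele >= HET_CLASS_ALLELE and np.any(hn > 0):
            raise ValueError(
                "heterozygote-as-class requires a bi-allelic matrix"
            )
        while len(counts) < HET_CLASS_ALLELE + 1:
            counts.append(np.zeros(matrix.n_markers, dtype=np.int64))
        counts[HET_CLASS_ALLELE] = counts[HET_CLASS_ALLELE] + hn
        hn = np.zeros_like(hn)
    cstack = np.vstack(counts) if counts else np.zeros((0, matrix.n_markers), dtype=np.int64)
    hom_total = cstack.sum(axis=0)
    tg = (cstack > 0).sum(axis=0)
    denom_total = hom_total if denominator == "homozygous" else np.full_like(hom_total, an)
    if denominator not in ("homozygous", "all"):
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = cstack / np.where(denom_total > 0, denom_total, 1)
        s1 = p.sum(axis=0)
        s2 = (p * p).sum(axis=0)
        ds = (an - un - hn) / an * (s1 * s1 - s2) / 2.0
    ds = np.where(tg >= 2, ds, 0.0)
    return ds


def _ds_exact(
    matrix: GenotypeMatrix,
    cols: Sequence[int],
    het_as_class: bool = False,
    denominator: str = "homozygous",
) -> list[Fraction]:
    """Exact rational DS per marker over the given accession columns.

    With integer tallies DS is a rational: the pairwise sum over class
    fractions equals (T^2 - sum c_i^2) / (2 d^2) for class counts c_i with
    total T and fraction denominator d, so

        DS = (AN - UN - HN) * (T^2 - sum c_i^2) / (2 * AN * d^2).

    Ranking on the exact value keeps the ascending-row tie-break stable where
    mathematically equal scores would otherwise differ in the last float ulp.
    """
    if denominator not in ("homozygous", "all"):
        raise ValueError(f"unknown denominator {denominator!r}")
    sub = matrix.codes[:, cols]
    an = sub.shape[1]
    un = (sub == MISSING_CODE).sum(axis=1)
    hn = (sub == HET_CODE).sum(axis=1)
    max_allele = int(sub.max()) if sub.size and sub.max() >= 0 else -1
    counts = [(sub == a).sum(axis=1).astype(np.int64) for a in range(max_allele + 1)]
    if het_as_class:
        if max_allele >= HET_CLASS_ALLELE and np.any(hn > 0):
            raise ValueError("heterozygote-as-class requires a bi-allelic matrix")
        while len(counts) < HET_CLASS_ALLELE + 1:
            counts.append(np.zeros(matrix.n_markers, dtype=np.int64))
        counts[HET_CLASS_ALLELE] = counts[HET_CLASS_ALLELE] + hn
        hn = np.zeros_like(hn)
    if counts:
        cstack = np.vstack(counts)
        total = cstack.sum(axis=0)
        sumsq = (cstack * cstack).sum(axis=0)
        tg = (cstack > 0).sum(axis=0)
    else:
        total = np.zeros(matrix.n_markers, dtype=np.int64)
        sumsq = np.zeros(matrix.n_markers, dtype=np.int64)
        tg = np.zeros(matrix.n_markers, dtype=np.int64)
    informative = (an - un - hn).astype(np.int64)
    out: list[Fraction] = []
    for i in range(matrix.n_markers):
        if tg[i] < 2 or total[i] == 0:
            out.append(Fraction(0))
            continue
        d = int(total[i]) if denominator == "homozygous" else an
        num = int(informative[i]) * (int(total[i]) ** 2 - int(sumsq[i]))
        out.append(Fraction(num, 2 * an * d * d))
    return out


def rank_markers(
    matrix: GenotypeMatrix,
    subset: Sequence[str] | None = None,
    excluded: Iterable[str] = (),
    het_as_class: bool = False,
    denominator: str = "homozygous",
) -> list[tuple[str, float]]:
    """Markers sorted by descending DS over the subset.

    Ties break by ascending matrix row index (DS is compared in exact
    arithmetic so the tie-break is immune to float rounding); excluded
    markers are dropped; markers with fewer than two homozygous classes in
    the subset score 0.
    """
    if subset is None:
        subset = matrix.accession_ids
    if not subset:
        raise ValueError("accession subset must be non-empty")
    cols = [matrix.accession_col(a) for a in subset]
    ds = _ds_exact(matrix, cols, het_as_class=het_as_class, denominator=denominator)
    excluded = set(excluded)
    order = sorted(
        (i for i in range(matrix.n_markers) if matrix.marker_ids[i] not in excluded),
        key=lambda i: (-ds[i], i),
    )
    return [(matrix.marker_ids[i], float(ds[i])) for i in order]


def score_table(
    matrix: GenotypeMatrix,
    het_as_class: bool = False,
    denominator: str = "homozygous",
) -> pd.DataFrame:
    """Whole-set per-marker table of AN, UN, HN, TG and DS (matrix row order)."""
    cols = list(range(matrix.n_accessions))
    ds = _ds_vector(matrix, cols, het_as_class=het_as_class, denominator=denominator)
    rows = []
    for i, marker in enumerate(matrix.marker_ids):
        stats = _tally_codes(matrix.codes[i], het_as_class=het_as_class)
        rows.append(
            {
                "marker": marker,
                "AN": stats.an,
                "UN": stats.un,
                "HN": stats.hn,
                "TG": stats.tg,
                "DS": float(ds[i]),
            }
        )
    return pd.DataFrame(rows).set_index("marker")
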