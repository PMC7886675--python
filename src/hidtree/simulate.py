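"""Synthetic genotype matrices with controlled structure.

Two generators cover the regimes the method must handle:

* :func:`perfect_matrix` — hierarchically perfect bi-allelic markers over
  ``2**M`` accessions, one marker per internal node of the perfect binary
  tree down to a chosen depth.  No het/missing calls; the greedy builder
  recovers the generating topology exactly, which makes it the ground-truth
  fixture for tree construction.
* :func:`noisy_matrix` — i.i.d. cells with configurable homozygote balance,
  heterozygosity rate and missingness rate.  HapMap populations commonly show
  heterozygosity around 0.2, which is the regime the defaults target.  No
  linkage structure is modelled (the method never uses it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_io import GenotypeMatrix

__all__ = ["SimulationSpec", "perfect_matrix", "noisy_matrix"]


@dataclass
class SimulationSpec:
    """Parameters of a noisy i.i.d. matrix.

    hom_balance is the probability that a homozygous call is "0/0" (0.5 is
    the DS-optimal balanced regime); het_rate and missing_rate are the
    per-cell probabilities of "0/1" and "./.".
    """

    n_accessions: int
    n_markers: int
    hom_balance: float = 0.5
    het_rate: float = 0.2
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("need at least 2 accessions")
        if self.n_markers < 1:
            raise ValueError("need at least 1 marker")
        if not 0.0 < self.hom_balance < 1.0:
            raise ValueError("hom_balance must be in (0, 1)")
        if not 0.0 <= self.het_rate < 1.0 or not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("het_rate and missing_rate must be in [0, 1)")
        if self.het_rate + self.missing_rate >= 1.0:
            raise ValueError("het_rate + missing_rate must be < 1")


def _acc_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"ACC{i + 1:0{width}d}" for i in range(n)]


def _marker_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"M{i + 1:0{width}d}" for i in range(n)]


def perfect_matrix(M: int, N: int = 0) -> GenotypeMatrix:
    """Hierarchically perfect bi-allelic markers for ``2**M`` accessions.

    Markers are laid out in breadth-first order over the internal nodes of a
    perfect binary tree down to depth ``M - N - 1``, giving ``2**(M-N) - 1``
    markers.  The marker of a node covers a contiguous accession block: the
    left half is "0/0", the right half "1/1", and accessions outside the
    block are "0/0".  The constant outside-block fill makes each node's
    marker the unique DS maximiser within its own block, so greedy
    construction at threshold ``2**N`` deterministically recovers the
    generating topology.
    """
    if M < 1 or M > 12:
        raise ValueError("M must be in 1..12")
    if N < 0 or N >= M:
        raise ValueError("N must satisfy 0 <= N < M")
    n_acc = 2**M
    n_markers = 2 ** (M - N) - 1
    tokens = np.full((n_markers, n_acc), "0/0", dtype=object)
    k = 0
    for depth in range(M - N):
        block = 2 ** (M - depth)
        for b in range(2**depth):
            start = b * block
            tokens[k, start + block // 2 : start + block] = "1/1"
            k += 1
    return GenotypeMatrix(_marker_ids(n_markers), _acc_ids(n_acc), tokens)


def noisy_matrix(spec: SimulationSpec) -> GenotypeMatrix:
    """i.i.d. random matrix: MISSING w.p. missing_rate, HET w.p. het_rate,
    otherwise "0/0" w.p. hom_balance and "1/1" w.p. 1 - hom_balance."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_markers, spec.n_accessions)
    u = rng.random(shape)
    v = rng.random(shape)
    tokens = np.where(
        u < spec.missing_rate,
        "./.",
        np.where(
            u < spec.missing_rate + spec.het_rate,
            "0/1",
            np.where(v < spec.hom_balance, "0/0", "1/1"),
        ),
    ).astype(object)
    return GenotypeMatrix(_marker_ids(spec.n_markers), _acc_ids(spec.n_accessions), tokens)
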