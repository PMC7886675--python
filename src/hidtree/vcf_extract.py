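"""Genotype-matrix extraction and filtering from VCF variant files.

Reproduces the classic genotype-marker-extraction-and-filtering step that
turns a HapMap variant-calling file into the plain-text matrix the tree
builder consumes: select a variant type (long INDELs are the usual choice,
since their presence/absence is visible as a PCR product-size difference),
then drop low-quality markers by missingness, heterozygosity and DS.

Only the per-sample GT field is consulted; QUAL/DP are ignored and FILTER is
ignored unless ``pass_only`` is set.  Default thresholds are package
conventions, not values from any published pipeline, and are fully
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np
import pysam

from .matrix_io import GenotypeMatrix, _parse_token
from .scoring import _tally_codes, ds_score

__all__ = [
    "VariantClass",
    "ExtractionConfig",
    "ExtractionError",
    "EmptyResultError",
    "classify_variant",
    "extract_matrix",
]


class VariantClass(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"
    OTHER = "OTHER"


class ExtractionError(ValueError):
    pass


class EmptyResultError(ExtractionError):
    """No marker survived the configured filters."""


@dataclass
class ExtractionConfig:
    variant_type: str = "INDEL"  # SNP | INDEL | ANY
    min_indel_length: int = 10
    biallelic_only: bool = True
    max_missing_rate: float = 0.2
    max_het_rate: float = 0.2
    min_ds: float = 0.05
    pass_only: bool = False
    ds_denominator: str = "homozygous"

    def __post_init__(self) -> None:
        self.variant_type = self.variant_type.upper()
        if self.variant_type not in ("SNP", "INDEL", "ANY"):
            raise ValueError(f"variant_type must be SNP, INDEL or ANY, not {self.variant_type!r}")
        if self.min_indel_length < 0:
            raise ValueError("min_indel_length must be >= 0")
        for name in ("max_missing_rate", "max_het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.min_ds < 0.5:
            raise ValueError("min_ds must be in [0, 0.5), below the theoretical DS maximum")


def _is_symbolic(allele: str) -> bool:
    return allele.startswith("<") or "[" in allele or "]" in allele or allele == "*"


def classify_variant(ref: str, alts: list[str]) -> VariantClass:
    """SNP if every allele is a single base; INDEL if any REF/ALT length
    difference exists; symbolic or breakend alleles (and length-preserving
    multi-base substitutions) are OTHER."""
    if not ref or any(not a for a in alts):
        raise ValueError("empty allele string")
    if not alts:
        raise ValueError("at least one ALT allele required")
    if _is_symbolic(ref) or any(_is_symbolic(a) for a in alts):
        return VariantClass.OTHER
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return VariantClass.SNP
    if any(len(a) != len(ref) for a in alts):
        return VariantClass.INDEL
    return VariantClass.OTHER


def _gt_token(sample) -> str:
    gt = sample.get("GT")
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return "./."
    if len(gt) == 1:  # haploid call, promoted to a homozygous diploid token
        return f"{gt[0]}/{gt[0]}"
    return "/".join(str(a) for a in gt[:2])


def extract_matrix(
    vcf: Union[str, Path, pysam.VariantFile],
    config: ExtractionConfig | None = None,
) -> GenotypeMatrix:
    """Extract a filtered genotype matrix from a VCF/BCF file.

    Retained markers satisfy all of: variant-type match, INDEL length >=
    min_indel_length (INDEL mode), biallelic if required, missing rate <=
    max_missing_rate, het rate <= max_het_rate, DS >= min_ds.  Marker ids are
    "CHROM:POS", suffixed ":<k>" on collision; accession order follows the
    VCF sample order.
    """
    if config is None:
        config = ExtractionConfig()
    vf = vcf if isinstance(vcf, pysam.VariantFile) else pysam.VariantFile(str(vcf))
    samples = list(vf.header.samples)
    if not samples:
        raise ExtractionError("VCF has no sample columns; cannot build a matrix")
    marker_ids: list[str] = []
    id_counts: dict[str, int] = {}
    token_rows: list[list[str]] = []
    code_rows: list[list[int]] = []
    an = len(samples)
    for rec in vf:
        alts = list(rec.alts or ())
        if not alts:
            continue
        if config.pass_only and rec.filter.keys() not in ([], ["PASS"]):
            continue
        vclass = classify_variant(rec.ref, alts)
        if config.variant_type == "SNP" and vclass is not VariantClass.SNP:
            continue
        if config.variant_type == "INDEL":
            if vclass is not VariantClass.INDEL:
                continue
            indel_len = max(abs(len(a) - len(rec.ref)) for a in alts)
            if indel_len < config.min_indel_length:
                continue
        if config.biallelic_only and len(alts) > 1:
            continue
        tokens: list[str] = []
        codes: list[int] = []
        for s in samples:
            tok = _gt_token(rec.samples[s])
            code, norm = _parse_token(tok)
            tokens.append(norm)
            codes.append(code)
        stats = _tally_codes(np.asarray(codes, dtype=np.int16))
        if stats.un / an > config.max_missing_rate:
            continue
        if stats.hn / an > config.max_het_rate:
            continue
        if ds_score(stats, denominator=config.ds_denominator) < config.min_ds:
            continue
        base = f"{rec.chrom}:{rec.pos}"
        k = id_counts.get(base, 0)
        id_counts[base] = k + 1
        marker_ids.append(base if k == 0 else f"{base}:{k}")
        token_rows.append(tokens)
        code_rows.append(codes)
    if not marker_ids:
        raise EmptyResultError("no marker survived the configured filters")
    tokens_arr = np.array(token_rows, dtype=object)
    codes_arr = np.array(code_rows, dtype=np.int16)
    return GenotypeMatrix(marker_ids, samples, tokens_arr, codes_arr)
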