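"""Plain-text genotype marker matrix I/O.

The matrix dialect is tab- (or whitespace-) delimited text: the first row
lists accession identifiers (optionally preceded by a corner label, which is
tolerated and ignored), every following row starts with a marker identifier
followed by one diploid genotype token per accession.  Tokens follow the VCF
GT convention: ``i/i`` homozygous, ``i/j`` (i != j) heterozygous, any allele
position equal to ``.`` makes the whole call missing.  Phased separators
``|`` are normalised to ``/`` on read.

Rows are markers, columns are accessions — the orientation produced by
``bcftools query -f '[\\t%GT]\\n'`` over a HapMap VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, TextIO, Union

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "GenotypeCall",
    "GenotypeMatrix",
    "MatrixFormatError",
    "MatrixValidationError",
    "TokenError",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "matrix_summary",
    "HET_CODE",
    "MISSING_CODE",
]

#: integer codes used in the numeric view of a matrix; homozygous calls use
#: their (non-negative) allele index directly.
HET_CODE = -1
MISSING_CODE = -2


class MatrixFormatError(ValueError):
    """Structurally malformed matrix text (ragged, empty, bad token)."""


class MatrixValidationError(ValueError):
    """Well-formed text violating matrix invariants (duplicate ids, ...)."""


class TokenError(MatrixFormatError):
    """A genotype token that cannot be interpreted as a diploid GT."""


class Category(str, Enum):
    HOM = "HOM"
    HET = "HET"
    MISSING = "MISSING"


def _parse_token(token: str, lenient_haploid: bool = False) -> tuple[int, str]:
    """Parse one GT token into (code, normalised token).

    code >= 0 is the allele index of a homozygous call; HET_CODE / MISSING_CODE
    otherwise.  Raises :class:`TokenError` on anything unparseable.
    """
    norm = token.replace("|", "/")
    parts = norm.split("/")
    if len(parts) == 1:
        if not lenient_haploid:
            raise TokenError(
                f"haploid token {token!r}: matrix entries must be diploid "
                "(use lenient_haploid=True to map 'i' -> 'i/i')"
            )
        a = parts[0]
        if a == ".":
            return MISSING_CODE, "./."
        if not a.isdigit():
            raise TokenError(f"unparseable genotype token {token!r}")
        return int(a), f"{a}/{a}"
    if len(parts) != 2:
        raise TokenError(f"unparseable genotype token {token!r}")
    a, b = parts
    if a == "." or b == ".":
        # any missing allele position renders the call uninformative
        if (a == "." or a.isdigit()) and (b == "." or b.isdigit()):
            return MISSING_CODE, norm
        raise TokenError(f"unparseable genotype token {token!r}")
    if not (a.isdigit() and b.isdigit()):
        raise TokenError(f"unparseable genotype token {token!r}")
    ai, bi = int(a), int(b)
    if ai == bi:
        return ai, norm
    return HET_CODE, norm


@dataclass(frozen=True)
class GenotypeCall:
    """One cell of the matrix: homozygous(allele), heterozygous, or missing."""

    category: Category
    allele: int | None = None
    raw_token: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if (self.category is Category.HOM) != (self.allele is not None):
            raise ValueError("allele must be present iff the call is HOM")

    @classmethod
    def from_token(cls, token: str, lenient_haploid: bool = False) -> "GenotypeCall":
        code, norm = _parse_token(token, lenient_haploid=lenient_haploid)
        return cls.from_code(code, norm)

    @classmethod
    def from_code(cls, code: int, raw_token: str | None = None) -> "GenotypeCall":
        if code >= 0:
            tok = raw_token if raw_token is not None else f"{code}/{code}"
            return cls(Category.HOM, code, tok)
        if code == HET_CODE:
            return cls(Category.HET, None, raw_token or "0/1")
        return cls(Category.MISSING, None, raw_token or "./.")

    @property
    def token(self) -> str:
        return self.raw_token

    @property
    def is_hom(self) -> bool:
        return self.category is Category.HOM


class GenotypeMatrix:
    """Rectangular grid of genotype calls with marker and accession labels.

    Internally stores the normalised token strings (for faithful round-trips)
    and an integer code view (for fast tallying).
    """

    def __init__(
        self,
        marker_ids: Iterable[str],
        accession_ids: Iterable[str],
        tokens: np.ndarray,
        codes: np.ndarray | None = None,
    ) -> None:
        self.marker_ids: list[str] = list(marker_ids)
        self.accession_ids: list[str] = list(accession_ids)
        tokens = np.asarray(tokens, dtype=object)
        if tokens.ndim != 2:
            raise MatrixValidationError("token grid must be 2-dimensional")
        if not self.marker_ids or not self.accession_ids:
            raise MatrixValidationError("matrix needs at least one marker and one accession")
        if tokens.shape != (len(self.marker_ids), len(self.accession_ids)):
            raise MatrixValidationError(
                f"token grid shape {tokens.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.accession_ids)} accessions"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise MatrixValidationError("duplicate marker ids")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise MatrixValidationError("duplicate accession ids")
        self.tokens = tokens
        if codes is None:
            codes = np.empty(tokens.shape, dtype=np.int16)
            for idx, tok in np.ndenumerate(tokens):
                codes[idx] = _parse_token(tok)[0]
        self.codes = np.asarray(codes, dtype=np.int16)
        self._marker_index = {m: i for i, m in enumerate(self.marker_ids)}
        self._accession_index = {a: j for j, a in enumerate(self.accession_ids)}

    # -- shape & lookup -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.n_markers, self.n_accessions

    def marker_row(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def accession_col(self, accession_id: str) -> int:
        try:
            return self._accession_index[accession_id]
        except KeyError:
            raise KeyError(f"unknown accession id {accession_id!r}") from None

    def call(self, marker_id: str, accession_id: str) -> GenotypeCall:
        i = self.marker_row(marker_id)
        j = self.accession_col(accession_id)
        return GenotypeCall.from_code(int(self.codes[i, j]), str(self.tokens[i, j]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.marker_ids == other.marker_ids
            and self.accession_ids == other.accession_ids
            and np.array_equal(self.codes, other.codes)
        )

    def __repr__(self) -> str:
        return f"<GenotypeMatrix {self.n_markers} markers x {self.n_accessions} accessions>"


def _open_source(source: Union[str, Path, TextIO]) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "rt"), True
    return source, False


def read_genotype_matrix(
    source: Union[str, Path, TextIO],
    lenient_haploid: bool = False,
) -> GenotypeMatrix:
    """Read a genotype marker matrix from text.

    First non-blank row: accession ids (a leading corner label is tolerated and
    dropped when the header is one field longer than expected).  Each data row:
    marker id followed by one GT token per accession.
    """
    fh, close = _open_source(source)
    try:
        rows = [line.split() for line in fh if line.strip()]
    finally:
        if close:
            fh.close()
    if not rows:
        raise MatrixFormatError("empty matrix file")
    header = rows[0]
    data = rows[1:]
    if not data:
        raise MatrixFormatError("matrix has a header but no marker rows")
    width = len(data[0])  # marker id + n tokens
    if len(header) == width:
        header = header[1:]  # corner label
    if len(header) != width - 1:
        raise MatrixFormatError(
            f"header has {len(header)} accession ids but first data row has "
            f"{width - 1} genotype columns"
        )
    accession_ids = header
    marker_ids: list[str] = []
    tokens = np.empty((len(data), len(accession_ids)), dtype=object)
    codes = np.empty((len(data), len(accession_ids)), dtype=np.int16)
    for r, row in enumerate(data):
        if len(row) != width:
            raise MatrixFormatError(
                f"ragged row {r + 1} (marker {row[0]!r}): expected "
                f"{width - 1} genotype columns, found {len(row) - 1}"
            )
        marker_ids.append(row[0])
        for c, tok in enumerate(row[1:]):
            try:
                code, norm = _parse_token(tok, lenient_haploid=lenient_haploid)
            except TokenError as exc:
                raise TokenError(
                    f"row {r + 1} (marker {row[0]!r}), column "
                    f"{accession_ids[c]!r}: {exc}"
                ) from None
            tokens[r, c] = norm
            codes[r, c] = code
    return GenotypeMatrix(marker_ids, accession_ids, tokens, codes)


def write_genotype_matrix(
    matrix: GenotypeMatrix,
    sink: Union[str, Path, TextIO],
) -> None:
    """Write a matrix in the same tab-delimited dialect ``read`` accepts.

    Output is byte-deterministic for a given matrix.
    """
    if isinstance(sink, (str, Path)):
        with open(sink, "wt") as fh:
            write_genotype_matrix(matrix, fh)
        return
    sink.write("MarkerID\t" + "\t".join(matrix.accession_ids) + "\n")
    for i, marker in enumerate(matrix.marker_ids):
        sink.write(marker + "\t" + "\t".join(matrix.tokens[i, :]) + "\n")


def matrix_summary(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call-quality tallies.

    Columns: AN (accessions), UN (missing), HN (heterozygous), TG (distinct
    homozygous classes) and one ``hom_<i>`` count column per allele index
    observed anywhere in the matrix.  AN = UN + HN + sum of hom counts holds
    for every marker.
    """
    codes = matrix.codes
    an = matrix.n_accessions
    un = (codes == MISSING_CODE).sum(axis=1)
    hn = (codes == HET_CODE).sum(axis=1)
    max_allele = int(codes.max()) if codes.max() >= 0 else -1
    out = {"AN": np.full(matrix.n_markers, an), "UN": un, "HN": hn}
    tg = np.zeros(matrix.n_markers, dtype=int)
    for a in range(max_allele + 1):
        cnt = (codes == a).sum(axis=1)
        out[f"hom_{a}"] = cnt
        tg += (cnt > 0).astype(int)
    out["TG"] = tg
    frame = pd.DataFrame(out, index=pd.Index(matrix.marker_ids, name="marker"))
    cols = ["AN", "UN", "HN", "TG"] + [c for c in frame.columns if c.startswith("hom_")]
    return frame[cols]
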