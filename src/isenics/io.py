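"""Readers, writers and alignment for expression matrices and gene sets.

Formats
-------
* Expression matrices: TSV/CSV with gene symbols in the first column and a
  header row of sample/cell identifiers, or a MatrixMarket coordinate file
  with companion ``genes.tsv`` / ``barcodes.tsv`` files (one identifier per
  line) next to it.
* Gene sets: standard GMT (name, description, tab-separated genes).  A signed
  signature is stored as two records, ``<NAME>_POS`` and ``<NAME>_NEG``;
  an unsigned signature is either a plain ``<NAME>`` record or ``<NAME>_POS``
  alone.
* Gene lists: one symbol per line; ``#`` starts a comment.

Gene identifiers are case-sensitive symbols; no alias resolution is
performed.  Duplicate gene rows are collapsed by summation (logged) before
any scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import InsufficientOverlapError, ParseError, ValidationError

log = logging.getLogger(__name__)

SCALES = ("tpm", "log1p_tpm", "counts")


@dataclass
class ExpressionMatrix:
    """A genes x units (samples or cells) numeric expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene symbols, one per row.
    unit_ids : list of str
        Unique sample or cell identifiers, one per column.
    values : ndarray of shape (n_genes, n_units)
        Finite expression values; non-negative for ``tpm``/``counts``.
    scale : {"tpm", "log1p_tpm", "counts"}
    """

    gene_ids: list[str]
    unit_ids: list[str]
    values: np.ndarray
    scale: str = "tpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValidationError("duplicate unit_ids")
        if self.values.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.unit_ids)} units"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")
        if self.scale in ("tpm", "counts") and np.any(self.values < 0):
            raise ValidationError(f"negative values under scale={self.scale}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.unit_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale: str = "tpm") -> "ExpressionMatrix":
        """Build from a genes x units DataFrame, collapsing duplicate gene rows by sum."""
        frame = _collapse_duplicates(frame)
        return cls(
            gene_ids=[str(g) for g in frame.index],
            unit_ids=[str(u) for u in frame.columns],
            values=frame.to_numpy(dtype=float),
            scale=scale,
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.unit_ids), self.values[rows], self.scale)

    def subset_units(self, units: list[str]) -> "ExpressionMatrix":
        idx = {u: i for i, u in enumerate(self.unit_ids)}
        cols = [idx[u] for u in units]
        return ExpressionMatrix(list(self.gene_ids), list(units), self.values[:, cols], self.scale)


@dataclass
class SignedGeneSet:
    """A named signature with a positive and an optional negative gene set.

    ``negative`` empty means an unsigned signature (SenMayo/SenCID style);
    CellAge/siAge-style signatures carry both directions.
    """

    name: str
    positive: set[str]
    negative: set[str] = field(default_factory=set)
    min_overlap: int = 2

    def __post_init__(self) -> None:
        self.positive = set(self.positive)
        self.negative = set(self.negative)
        if not self.positive:
            raise ValidationError(f"signature {self.name!r}: positive set is empty")
        both = self.positive & self.negative
        if both:
            raise ValidationError(
                f"signature {self.name!r}: genes in both positive and negative sets: "
                f"{sorted(both)}"
            )
        if self.min_overlap < 1:
            raise ValidationError("min_overlap must be >= 1")

    @property
    def signed(self) -> bool:
        return len(self.negative) > 0


@dataclass
class GeneList:
    """A named flat gene list (SASP genes, immune-related genes, ICP genes...)."""

    name: str
    genes: set[str]

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        if not self.genes:
            raise ValidationError(f"gene list {self.name!r} is empty")


def _collapse_duplicates(frame: pd.DataFrame) -> pd.DataFrame:
    if frame.index.has_duplicates:
        n = int(frame.index.duplicated().sum())
        log.info("collapsing %d duplicate gene rows by summation", n)
        frame = frame.groupby(level=0, sort=False).sum()
    return frame


def read_matrix(path: str | Path, format: str | None = None, scale: str = "tpm") -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV or a MatrixMarket triplet.

    ``format`` is one of ``tsv``, ``csv``, ``mtx_triplet``; when omitted it is
    inferred from the file suffix.  For ``mtx_triplet``, ``genes.tsv`` and
    ``barcodes.tsv`` must sit next to the ``.mtx`` file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx_triplet"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ParseError(f"cannot infer matrix format from suffix of {path}")
    if format == "mtx_triplet":
        return _read_mtx_triplet(path, scale)
    sep = "\t" if format == "tsv" else ","
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # malformed header / ragged rows
        raise ParseError(f"failed to parse {path} line {_bad_line(exc)}: {exc}") from exc
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: header row defines no sample columns (line 1)")
    non_numeric = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric values in columns {non_numeric}")
    return ExpressionMatrix.from_frame(frame, scale=scale)


def _bad_line(exc: Exception) -> str:
    msg = str(exc)
    return msg[msg.index("line") :].split(",")[0] if "line" in msg else "?"


def _read_mtx_triplet(path: Path, scale: str) -> ExpressionMatrix:
    genes_path = path.parent / "genes.tsv"
    barcodes_path = path.parent / "barcodes.tsv"
    for companion in (genes_path, barcodes_path):
        if not companion.exists():
            raise FileNotFoundError(f"companion file missing for {path}: {companion}")
    mat = scipy.io.mmread(path)
    dense = np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=float)
    genes = [ln.split("\t")[0].strip() for ln in genes_path.read_text().splitlines() if ln.strip()]
    barcodes = [ln.strip() for ln in barcodes_path.read_text().splitlines() if ln.strip()]
    if dense.shape != (len(genes), len(barcodes)):
        raise ParseError(
            f"{path}: matrix is {dense.shape} but genes.tsv/barcodes.tsv give "
            f"({len(genes)}, {len(barcodes)})"
        )
    frame = pd.DataFrame(dense, index=genes, columns=barcodes)
    return ExpressionMatrix.from_frame(frame, scale=scale)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix to TSV/CSV with full float precision (round-trip safe)."""
    sep = "\t" if format == "tsv" else ","
    matrix.to_frame().to_csv(Path(path), sep=sep, float_format="%.17g")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping of record name -> gene list."""
    path = Path(path)
    records: dict[str, list[str]] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path} line {i}: GMT record needs name, description, >=1 gene")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if name in records:
            raise ParseError(f"{path} line {i}: duplicate record name {name!r}")
        records[name] = genes
    return records


def read_signed_gmt(path: str | Path, signature_name: str, min_overlap: int = 2) -> SignedGeneSet:
    """Assemble a :class:`SignedGeneSet` from ``<name>_POS`` / ``<name>_NEG`` GMT records.

    A plain ``<name>`` record (no ``_POS`` suffix) is accepted as an unsigned
    signature.  A missing positive record raises ``KeyError``; overlap between
    the POS and NEG records raises :class:`ValidationError` naming the genes.
    """
    records = read_gmt(path)
    pos_key = f"{signature_name}_POS"
    if pos_key in records:
        positive = records[pos_key]
    elif signature_name in records:
        positive = records[signature_name]
    else:
        raise KeyError(
            f"no record {pos_key!r} (or unsigned {signature_name!r}) in {path}; "
            f"available: {sorted(records)}"
        )
    negative = records.get(f"{signature_name}_NEG", [])
    return SignedGeneSet(
        name=signature_name, positive=set(positive), negative=set(negative), min_overlap=min_overlap
    )


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list; ``#`` comments and blanks skipped."""
    path = Path(path)
    genes = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return GeneList(name=name or path.stem, genes=set(genes))


def align_genes(matrix: ExpressionMatrix, geneset: SignedGeneSet) -> SignedGeneSet:
    """Restrict a signature to genes present in ``matrix``.

    Idempotent.  Raises :class:`InsufficientOverlapError` when fewer than
    ``min_overlap`` positive genes survive, or when the signature is signed
    and fewer than ``min_overlap`` negative genes survive.
    """
    present = set(matrix.gene_ids)
    positive = geneset.positive & present
    negative = geneset.negative & present
    dropped = (len(geneset.positive) - len(positive)) + (len(geneset.negative) - len(negative))
    if dropped:
        log.info("align_genes(%s): dropped %d symbols absent from matrix", geneset.name, dropped)
    if len(positive) < geneset.min_overlap:
        raise InsufficientOverlapError(
            f"signature {geneset.name!r}: only {len(positive)} positive genes in matrix "
            f"(min_overlap={geneset.min_overlap})"
        )
    if geneset.negative and len(negative) < geneset.min_overlap:
        raise InsufficientOverlapError(
            f"signature {geneset.name!r}: only {len(negative)} negative genes in matrix "
            f"(min_overlap={geneset.min_overlap})"
        )
    return replace(geneset, positive=positive, negative=negative)
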