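"""Core data containers and text-format I/O.

Matrices are gene x sample throughout. TSV/CSV matrices carry sample IDs in
the header row and gene IDs in the first column; MatrixMarket triplets use
1-based indices with companion ``<path>.rows`` / ``<path>.cols`` name files
(one identifier per line). Signature definitions are read from GMT
(``name<TAB>description<TAB>gene...``) or a two-column TSV
(``signature<TAB>gene`` per row).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

from .errors import (
    DuplicateIdentifier,
    EmptyInput,
    EmptySignature,
    InvalidParameter,
    IOFailure,
    MalformedMatrix,
    SampleMismatch,
)

#: Signature names required for classification, in canonical column order.
CLEARSEQ_SIGNATURES: tuple[str, ...] = (
    "ccrcc3_up",
    "ccrcc3_down",
    "ccrcc2_up",
    "ccrcc1_up",
    "ccrcc4_up",
    "ccrcc1and4_up",
    "cell_cycle",
    "t_effector",
)

#: Subtype labels, in canonical order.
SUBTYPE_LABELS: tuple[str, ...] = ("ccrcc1", "ccrcc2", "ccrcc3", "ccrcc4")


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DuplicateIdentifier(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


def normalize_gene(symbol: str) -> str:
    """Canonical form used for gene matching: trimmed, upper-cased."""
    return symbol.strip().upper()


@dataclass
class CountMatrix:
    """Raw integer counts, genes x samples.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique identifiers; order matches the rows/columns of ``counts``.
    counts
        Nonnegative integer array of shape ``(len(gene_ids), len(sample_ids))``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        arr = np.asarray(self.counts)
        if arr.size == 0 or len(self.gene_ids) == 0 or len(self.sample_ids) == 0:
            raise EmptyInput("count matrix must have at least one gene and one sample")
        if arr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise MalformedMatrix(
                f"count matrix shape {arr.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(arr.dtype, np.number):
            raise MalformedMatrix("count matrix contains non-numeric values")
        if np.any(~np.isfinite(arr.astype(float))):
            raise MalformedMatrix("count matrix contains missing or non-finite values")
        if np.any(arr < 0):
            raise MalformedMatrix("count matrix contains negative values")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.any(arr != np.round(arr)):
                raise MalformedMatrix("count matrix contains non-integer values")
            arr = arr.astype(np.int64)
        self.counts = np.asarray(arr, dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset(self, gene_mask: np.ndarray | None = None,
               sample_mask: np.ndarray | None = None) -> "CountMatrix":
        """Return a new matrix restricted to masked genes/samples."""
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask, bool)
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        return CountMatrix(
            [g for g, k in zip(self.gene_ids, gm) if k],
            [s for s, k in zip(self.sample_ids, sm) if k],
            self.counts[np.ix_(gm, sm)],
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: batch, optional known subtype and tissue."""

    sample_ids: list[str]
    batch: list[str]
    known_subtype: list[str | None] = field(default_factory=list)
    tissue: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        if len(self.batch) != len(self.sample_ids):
            raise MalformedMatrix("metadata batch column length mismatch")
        if not self.known_subtype:
            self.known_subtype = [None] * len(self.sample_ids)
        if not self.tissue:
            self.tissue = [None] * len(self.sample_ids)

    def batch_for(self, sample_ids: Sequence[str]) -> list[str]:
        lookup = dict(zip(self.sample_ids, self.batch))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise SampleMismatch(f"samples absent from metadata: {missing[:5]}")
        return [lookup[s] for s in sample_ids]


@dataclass
class GeneSignature:
    """A named, deduplicated gene list."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        genes = [g.strip() for g in self.genes if g.strip()]
        if not genes:
            raise EmptySignature(f"signature {self.name!r} has no genes")
        # deduplicate on the canonical form, preserving first occurrence
        seen: set[str] = set()
        out: list[str] = []
        for g in genes:
            key = normalize_gene(g)
            if key not in seen:
                seen.add(key)
                out.append(g)
        self.genes = out


class SignatureRegistry:
    """Ordered collection of named signatures.

    ``classification_ready`` is true iff all eight canonical names are
    present; classification and featurization require a ready registry.
    """

    def __init__(self, signatures: Iterable[GeneSignature] = ()) -> None:
        self._sigs: dict[str, GeneSignature] = {}
        for sig in signatures:
            self.add(sig)

    def add(self, sig: GeneSignature) -> None:
        if sig.name in self._sigs:
            raise DuplicateIdentifier(f"duplicate signature name: {sig.name!r}")
        self._sigs[sig.name] = sig

    def __getitem__(self, name: str) -> GeneSignature:
        return self._sigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sigs

    def __len__(self) -> int:
        return len(self._sigs)

    def __iter__(self):
        return iter(self._sigs.values())

    @property
    def names(self) -> list[str]:
        return list(self._sigs)

    @property
    def classification_ready(self) -> bool:
        return all(name in self._sigs for name in CLEARSEQ_SIGNATURES)

    def gene_union(self) -> list[str]:
        """Union of all signature genes, first-seen order preserved."""
        seen: set[str] = set()
        out: list[str] = []
        for sig in self:
            for g in sig.genes:
                key = normalize_gene(g)
                if key not in seen:
                    seen.add(key)
                    out.append(g)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: Path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=object)
    except OSError as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise EmptyInput(f"{path} is empty") from exc
    return df


def read_count_matrix(path: str | Path, dialect: str = "tsv") -> CountMatrix:
    """Read a count matrix from TSV, CSV, or a MatrixMarket triplet.

    For ``mtx_triplet`` the row (gene) and column (sample) names are read
    from ``<path>.rows`` and ``<path>.cols``.
    """
    path = Path(path)
    if dialect in ("tsv", "csv"):
        df = _read_table(path, "\t" if dialect == "tsv" else ",")
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise EmptyInput(f"{path} has no data rows or columns")
        if df.isna().any().any():
            raise MalformedMatrix(f"{path} contains missing values")
        try:
            values = df.astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise MalformedMatrix(f"{path} contains non-numeric cells: {exc}") from exc
        return CountMatrix(
            [str(g) for g in df.index], [str(s) for s in df.columns], values
        )
    if dialect == "mtx_triplet":
        rows_path = path.with_name(path.name + ".rows")
        cols_path = path.with_name(path.name + ".cols")
        for p in (path, rows_path, cols_path):
            if not p.exists():
                raise IOFailure(f"required file missing: {p}")
        try:
            mat = mmread(str(path))
        except ValueError as exc:
            raise MalformedMatrix(f"cannot parse MatrixMarket file {path}: {exc}") from exc
        genes = rows_path.read_text().split()
        samples = cols_path.read_text().split()
        dense = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
        return CountMatrix(genes, samples, dense)
    raise InvalidParameter(f"unknown matrix dialect: {dialect!r}")


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    try:
        cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata TSV with columns sample_id, batch[, known_subtype, tissue]."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=object)
    except OSError as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc
    if "sample_id" not in df.columns or "batch" not in df.columns:
        raise MalformedMatrix(f"{path} must have sample_id and batch columns")
    known = (
        [None if pd.isna(x) else str(x) for x in df["known_subtype"]]
        if "known_subtype" in df.columns
        else []
    )
    tissue = (
        [None if pd.isna(x) else str(x) for x in df["tissue"]]
        if "tissue" in df.columns
        else []
    )
    return SampleMetadata(
        [str(s) for s in df["sample_id"]],
        [str(b) for b in df["batch"]],
        known,
        tissue,
    )


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": meta.sample_ids,
            "batch": meta.batch,
            "known_subtype": meta.known_subtype,
            "tissue": meta.tissue,
        }
    ).to_csv(path, sep="\t", index=False)


def read_signatures(path: str | Path, format: str = "gmt") -> SignatureRegistry:
    """Read signature definitions from GMT or a two-column TSV."""
    path = Path(path)
    try:
        lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    except OSError as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc
    registry = SignatureRegistry()
    if format == "gmt":
        for ln in lines:
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise EmptySignature(f"GMT line for {parts[0]!r} lists no genes")
            registry.add(GeneSignature(parts[0].strip(), parts[2:]))
        return registry
    if format == "two_column_tsv":
        groups: dict[str, list[str]] = {}
        order: list[str] = []
        start = 0
        if lines and lines[0].split("\t")[:2] == ["signature", "gene"]:
            start = 1
        for ln in lines[start:]:
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) < 2:
                raise MalformedMatrix(f"bad two-column signature line: {ln!r}")
            name = parts[0].strip()
            if name not in groups:
                groups[name] = []
                order.append(name)
            groups[name].append(parts[1])
        for name in order:
            registry.add(GeneSignature(name, groups[name]))
        return registry
    raise InvalidParameter(f"unknown signature format: {format!r}")


def write_signatures(registry: SignatureRegistry, path: str | Path,
                     format: str = "gmt") -> None:
    lines = []
    if format == "gmt":
        for sig in registry:
            lines.append("\t".join([sig.name, "na", *sig.genes]))
    elif format == "two_column_tsv":
        lines.append("signature\tgene")
        for sig in registry:
            lines.extend(f"{sig.name}\t{g}" for g in sig.genes)
    else:
        raise InvalidParameter(f"unknown signature format: {format!r}")
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc
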