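"""Per-sample signature scoring.

A signature score is the median (bulk default) or mean (single-cell mode)
of the expression of the signature's member genes in a sample. Gene symbols
are matched case-insensitively after trimming. A signature is scored only
when at least ``min_fraction`` of its genes are present in the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InsufficientSignatureCoverage,
    InvalidParameter,
    MissingSignature,
    NonpositiveDenominator,
)
from .io_formats import (
    CLEARSEQ_SIGNATURES,
    GeneSignature,
    SignatureRegistry,
    normalize_gene,
)
from .preprocess import ExpressionMatrix

AGGREGATORS = ("median", "mean")


@dataclass
class SignatureScoreMatrix:
    """Sample x signature scores with provenance.

    ``genes_used`` maps each scored signature to the subset of its genes
    found in the expression matrix (matrix spelling).
    """

    sample_ids: list[str]
    signature_names: list[str]
    scores: np.ndarray
    aggregator: str = "median"
    genes_used: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids), len(self.signature_names)):
            raise InvalidParameter("score matrix shape inconsistent with ID lists")
        if not np.all(np.isfinite(self.scores)):
            raise InvalidParameter("signature scores must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, name: str) -> np.ndarray:
        if name not in self.signature_names:
            raise MissingSignature(f"signature column {name!r} absent")
        return self.scores[:, self.signature_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.sample_ids, columns=self.signature_names
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   aggregator: str = "median") -> "SignatureScoreMatrix":
        return cls(
            [str(s) for s in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
            aggregator=aggregator,
        )


def _present_genes(expr: ExpressionMatrix, sig: GeneSignature) -> tuple[list[str], list[int]]:
    lookup: dict[str, int] = {}
    for i, g in enumerate(expr.gene_ids):
        lookup.setdefault(normalize_gene(g), i)
    present, rows = [], []
    for g in sig.genes:
        idx = lookup.get(normalize_gene(g))
        if idx is not None:
            present.append(expr.gene_ids[idx])
            rows.append(idx)
    return present, rows


def score_signature(expr: ExpressionMatrix, sig: GeneSignature,
                    aggregator: str = "median",
                    min_fraction: float = 0.5) -> tuple[np.ndarray, list[str]]:
    """Score one signature for every sample.

    Returns the per-sample score vector and the list of genes used.
    """
    if aggregator not in AGGREGATORS:
        raise InvalidParameter(f"aggregator must be one of {AGGREGATORS}")
    present, rows = _present_genes(expr, sig)
    if len(present) < max(1, min_fraction * len(sig.genes)):
        missing = [g for g in sig.genes
                   if normalize_gene(g) not in {normalize_gene(p) for p in present}]
        raise InsufficientSignatureCoverage(
            f"signature {sig.name!r}: only {len(present)}/{len(sig.genes)} genes "
            f"present (need >= {min_fraction:.0%}); missing: {missing}"
        )
    sub = expr.values[rows]
    agg = np.median if aggregator == "median" else np.mean
    return agg(sub, axis=0), present


def score_all(expr: ExpressionMatrix, registry: SignatureRegistry,
              aggregator: str = "median",
              min_fraction: float = 0.5,
              require_ready: bool = True) -> SignatureScoreMatrix:
    """Score every signature in the registry.

    Column order is the canonical order for the eight classification
    signatures followed by any extra signatures in registry order.
    """
    if require_ready and not registry.classification_ready:
        missing = [n for n in CLEARSEQ_SIGNATURES if n not in registry]
        raise MissingSignature(
            f"registry is not classification-ready; missing: {missing}"
        )
    ordered = [n for n in CLEARSEQ_SIGNATURES if n in registry]
    ordered += [n for n in registry.names if n not in ordered]
    cols, genes_used = [], {}
    for name in ordered:
        vec, used = score_signature(expr, registry[name], aggregator, min_fraction)
        cols.append(vec)
        genes_used[name] = used
    return SignatureScoreMatrix(
        list(expr.sample_ids), ordered, np.column_stack(cols),
        aggregator=aggregator, genes_used=genes_used,
    )


def signature_ratio(scores: SignatureScoreMatrix, numerator: str,
                    denominator: str) -> np.ndarray:
    """Elementwise ratio of two signature score columns."""
    num = scores.column(numerator)
    den = scores.column(denominator)
    if np.any(den <= 0):
        raise NonpositiveDenominator(
            f"signature {denominator!r} has nonpositive scores; ratios need a "
            "positive scale — check that the expression transform is log-like "
            "on normalized counts (values >= 0), not centered/z-scored"
        )
    return num / den
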