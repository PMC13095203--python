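import numpy as np
import pytest

from clearseq import (
    CLEARSEQ_SIGNATURES,
    CountMatrix,
    ExpressionMatrix,
    GeneSignature,
    SignatureRegistry,
)
from clearseq.signatures import SignatureScoreMatrix


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """The 3-gene x 2-sample worked example used across modules."""
    return CountMatrix(
        ["GENE_A", "GENE_B", "GENE_C"],
        ["s1", "s2"],
        np.array([[2, 4], [4, 8], [6, 12]]),
    )


@pytest.fixture
def registry8() -> SignatureRegistry:
    """All eight signatures, three synthetic genes each."""
    reg = SignatureRegistry()
    for name in CLEARSEQ_SIGNATURES:
        stem = name.upper()
        reg.add(GeneSignature(name, [f"{stem}.{i}" for i in range(1, 4)]))
    return reg


def make_scores(columns: dict[str, np.ndarray]) -> SignatureScoreMatrix:
    """Build a score matrix from per-signature column vectors."""
    n = len(next(iter(columns.values())))
    names = list(CLEARSEQ_SIGNATURES)
    data = np.column_stack([np.asarray(columns[name], float) for name in names])
    return SignatureScoreMatrix([f"s{i}" for i in range(n)], names, data)


def constant_scores(n: int, fill: float = 5.0,
                    **overrides) -> SignatureScoreMatrix:
    """Score matrix with constant columns except the given overrides."""
    cols = {name: np.full(n, fill) for name in CLEARSEQ_SIGNATURES}
    for name, values in overrides.items():
        cols[name] = np.asarray(values, float)
    return make_scores(cols)


@pytest.fixture
def expr_small(registry8) -> ExpressionMatrix:
    """Deterministic 24-gene x 6-sample expression matrix covering registry8."""
    rng = np.random.default_rng(42)
    genes = [g for sig in registry8 for g in sig.genes]
    values = rng.uniform(1.0, 8.0, size=(len(genes), 6))
    return ExpressionMatrix(genes, [f"s{i}" for i in range(6)], values)
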