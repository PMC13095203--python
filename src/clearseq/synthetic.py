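"""Synthetic cohorts with planted subtype and batch structure.

Two generators: ``simulate_scores`` draws signature-score matrices directly
(for classifier-level tests), and ``simulate_counts`` builds a full
negative-binomial count cohort with per-subtype effects on signature genes
and multiplicative batch effects (for end-to-end pipeline tests).

Counts are NB with variance mu + phi * mu^2. Subtype effects are log2
shifts of ``effect_size`` within-class standard deviations, where the
within-class SD of a gene's log2 expression is approximated by
sqrt(1/mu + phi) / ln 2. Batch effects multiply the mean, i.e. act
additively on the log scale, so a location-model batch correction can
remove them.

Planted archetypes: ccrcc1 is proliferative/myeloid (ccrcc1_up,
ccrcc1and4_up, cell_cycle up), ccrcc2 is angiogenic (ccrcc2_up up),
ccrcc3 is normal kidney-like ("low everything": ccrcc3_up up, ccrcc3_down,
ccrcc2_up, cell_cycle, and t_effector down), ccrcc4 is inflamed/aggressive (ccrcc4_up,
t_effector, ccrcc1and4_up, cell_cycle up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameter
from .io_formats import (
    CLEARSEQ_SIGNATURES,
    SUBTYPE_LABELS,
    CountMatrix,
    GeneSignature,
    SampleMetadata,
    SignatureRegistry,
)
from .signatures import SignatureScoreMatrix

#: Which signatures are shifted up (+1) or down (-1) in each subtype.
ARCHETYPES: dict[str, dict[str, int]] = {
    "ccrcc1": {"ccrcc1_up": 1, "ccrcc1and4_up": 1, "cell_cycle": 1},
    "ccrcc2": {"ccrcc2_up": 1},
    "ccrcc3": {"ccrcc3_up": 1, "ccrcc3_down": -1, "ccrcc2_up": -1,
               "cell_cycle": -1, "t_effector": -1},
    "ccrcc4": {"ccrcc4_up": 1, "t_effector": 1, "ccrcc1and4_up": 1,
               "cell_cycle": 1},
}

#: Subtype proportions aligned with the decision tree's forced fractions
#: (20% ccrcc3; half of the rest ccrcc2; 40% of the remainder ccrcc4).
DEFAULT_PROPORTIONS: tuple[float, ...] = (0.24, 0.40, 0.20, 0.16)


def default_registry(genes_per_signature: int = 5) -> SignatureRegistry:
    """A registry of synthetic gene symbols, one block per signature."""
    if genes_per_signature < 1:
        raise InvalidParameter("genes_per_signature must be >= 1")
    registry = SignatureRegistry()
    for name in CLEARSEQ_SIGNATURES:
        stem = name.upper().replace("AND", "N")
        registry.add(GeneSignature(
            name, [f"{stem}_G{i + 1:03d}" for i in range(genes_per_signature)]
        ))
    return registry


# ---------------------------------------------------------------------------
# score-space simulation
# ---------------------------------------------------------------------------

SCORE_STRUCTURES = ("tie_free_uniform", "four_centroid", "adversarial_no_ccrcc3")


def simulate_scores(n: int, structure: str = "tie_free_uniform",
                    params: dict | None = None,
                    seed: int = 0) -> tuple[SignatureScoreMatrix, list[str] | None]:
    """Draw a synthetic signature-score matrix.

    Returns ``(scores, labels)`` where labels are the planted subtypes for
    ``four_centroid`` and None otherwise.

    * ``tie_free_uniform``: all eight scores iid continuous Uniform(low, high)
      with a positive floor, so every decision statistic is tie-free almost
      surely.
    * ``four_centroid``: class centroids offset by ``separation`` within-class
      SDs on each subtype's defining signatures (Gaussian noise).
    * ``adversarial_no_ccrcc3``: tie-free scores post-edited so every sample
      in the upper 20% of the ccrcc3 ratio gets a t_effector score above the
      cohort maximum, guaranteeing the joint ccrcc3 criteria never hold.
    """
    if n < 1:
        raise InvalidParameter("n must be >= 1")
    if structure not in SCORE_STRUCTURES:
        raise InvalidParameter(f"unknown structure {structure!r}")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    names = list(CLEARSEQ_SIGNATURES)

    if structure in ("tie_free_uniform", "adversarial_no_ccrcc3"):
        low = float(params.pop("low", 1.0))
        high = float(params.pop("high", 10.0))
        if params:
            raise InvalidParameter(f"unknown params: {sorted(params)}")
        if not 0 < low < high:
            raise InvalidParameter("need 0 < low < high for uniform scores")
        scores = rng.uniform(low, high, size=(n, len(names)))
        if structure == "adversarial_no_ccrcc3":
            ratio = scores[:, names.index("ccrcc3_up")] / scores[:, names.index("ccrcc3_down")]
            top = ratio > np.percentile(ratio, 80.0)
            te = names.index("t_effector")
            ceiling = scores[:, te].max()
            # distinct values strictly above every existing t_effector score
            scores[top, te] = ceiling + rng.uniform(1.0, 2.0, size=int(top.sum()))
        mat = SignatureScoreMatrix(
            [f"S{i + 1:04d}" for i in range(n)], names, scores
        )
        return mat, None

    # four_centroid
    separation = float(params.pop("separation", 4.0))
    within_sd = float(params.pop("within_sd", 1.0))
    base = float(params.pop("base", 10.0))
    proportions = tuple(params.pop("proportions", DEFAULT_PROPORTIONS))
    if params:
        raise InvalidParameter(f"unknown params: {sorted(params)}")
    if separation < 0 or within_sd <= 0 or base <= 0:
        raise InvalidParameter("need separation >= 0, within_sd > 0, base > 0")
    if abs(sum(proportions) - 1) > 1e-9 or min(proportions) < 0:
        raise InvalidParameter("proportions must be nonnegative and sum to 1")
    labels = rng.choice(SUBTYPE_LABELS, size=n, p=proportions)
    centroids = {
        lbl: np.array([
            base + separation * within_sd * ARCHETYPES[lbl].get(sig, 0)
            for sig in names
        ])
        for lbl in SUBTYPE_LABELS
    }
    scores = np.vstack([
        centroids[lbl] + rng.normal(0, within_sd, size=len(names))
        for lbl in labels
    ])
    scores = np.maximum(scores, 0.1)  # keep ratio denominators positive
    mat = SignatureScoreMatrix(
        [f"S{i + 1:04d}" for i in range(n)], names, scores
    )
    return mat, [str(x) for x in labels]


# ---------------------------------------------------------------------------
# count-space simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Parameters of a planted-structure NB count cohort."""

    n_samples: int = 200
    subtype_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    n_background_genes: int = 200
    genes_per_signature: int = 5
    effect_size: float = 4.0
    nb_dispersion: float = 0.05
    base_mean_range: tuple[float, float] = (100.0, 2000.0)
    batch_labels: tuple[str, ...] = ("batch1",)
    batch_fold_effects: tuple[float, ...] = (1.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise InvalidParameter("n_samples must be >= 1")
        if len(self.subtype_proportions) != 4:
            raise InvalidParameter("need 4 subtype proportions")
        if abs(sum(self.subtype_proportions) - 1) > 1e-9:
            raise InvalidParameter("subtype proportions must sum to 1")
        if min(self.subtype_proportions) < 0:
            raise InvalidParameter("subtype proportions must be nonnegative")
        if self.effect_size < 0:
            raise InvalidParameter("effect_size must be >= 0")
        if self.nb_dispersion <= 0:
            raise InvalidParameter("nb_dispersion must be > 0")
        if not 0 < self.base_mean_range[0] <= self.base_mean_range[1]:
            raise InvalidParameter("invalid base_mean_range")
        if len(self.batch_labels) != len(self.batch_fold_effects):
            raise InvalidParameter("batch labels and fold effects must align")
        if min(self.batch_fold_effects) <= 0:
            raise InvalidParameter("batch fold effects must be positive")
        if self.seed is None:
            raise InvalidParameter("seed is mandatory")


@dataclass
class SyntheticCohort:
    """A simulated cohort with its ground truth."""

    counts: CountMatrix
    metadata: SampleMetadata
    registry: SignatureRegistry
    true_subtypes: list[str]
    mean_matrix: np.ndarray = field(repr=False, default=None)


def simulate_counts(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw an NB count cohort with planted subtype and batch structure."""
    rng = np.random.default_rng(spec.seed)
    registry = default_registry(spec.genes_per_signature)
    sig_genes = registry.gene_union()
    gene_ids = sig_genes + [f"BG_G{i + 1:05d}" for i in range(spec.n_background_genes)]
    n_genes, n = len(gene_ids), spec.n_samples

    # which signature each gene belongs to (background genes -> None)
    gene_sig = {}
    for sig in registry:
        for g in sig.genes:
            gene_sig[g] = sig.name

    log_lo, log_hi = np.log(spec.base_mean_range[0]), np.log(spec.base_mean_range[1])
    base_mean = np.exp(rng.uniform(log_lo, log_hi, size=n_genes))

    subtypes = rng.choice(SUBTYPE_LABELS, size=n, p=spec.subtype_proportions)
    batches = rng.choice(len(spec.batch_labels), size=n)
    batch_fold = np.asarray(spec.batch_fold_effects)[batches]

    # per-gene within-class SD of log2 expression, NB delta-method approx
    sigma_log2 = np.sqrt(1.0 / base_mean + spec.nb_dispersion) / math.log(2)

    lfc = np.zeros((n_genes, n))
    for j, lbl in enumerate(subtypes):
        directions = ARCHETYPES[lbl]
        for i, g in enumerate(gene_ids):
            d = directions.get(gene_sig.get(g, ""), 0)
            if d:
                lfc[i, j] = spec.effect_size * sigma_log2[i] * d

    mean = base_mean[:, None] * np.exp2(lfc) * batch_fold[None, :]
    r = 1.0 / spec.nb_dispersion           # NB shape: var = mu + mu^2/r
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    cm = CountMatrix(gene_ids, sample_ids, counts)
    meta = SampleMetadata(
        sample_ids,
        [spec.batch_labels[b] for b in batches],
        [str(s) for s in subtypes],
    )
    return SyntheticCohort(cm, meta, registry, [str(s) for s in subtypes], mean)
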