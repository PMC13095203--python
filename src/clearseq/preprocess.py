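"""Count preprocessing: expression filters, normalization, batch correction.

The pipeline order is fixed: CPM gene filter -> library-depth sample filter
(totals over retained genes) -> median-of-ratios size factors -> variance
stabilizing transform -> empirical-Bayes batch correction. Both filters use
strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateReference,
    EmptyAfterFilter,
    InsufficientBatch,
    InvalidParameter,
    UnknownBatch,
)
from .io_formats import CountMatrix, SampleMetadata


@dataclass
class ExpressionMatrix:
    """Variance-stabilized expression values, genes x samples.

    ``size_factors`` records the per-sample normalization applied;
    ``transform`` names the stabilizing transform ("log2_norm_plus1",
    "vst_closed_form", or "precomputed"); ``batch_corrected`` flags whether
    batch correction has been applied.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    size_factors: np.ndarray | None = None
    transform: str = "precomputed"
    batch_corrected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InvalidParameter(
                f"expression shape {self.values.shape} inconsistent with ID lists"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameter("expression matrix contains non-finite values")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if np.any(self.size_factors <= 0):
                raise InvalidParameter("size factors must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids),
            list(self.sample_ids),
            self.values.copy(),
            None if self.size_factors is None else self.size_factors.copy(),
            self.transform,
            self.batch_corrected,
        )


def cpm(counts: CountMatrix) -> np.ndarray:
    """Counts per million, using each sample's total over all genes."""
    totals = counts.counts.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        raise InvalidParameter("every sample must have a positive total count")
    return counts.counts * 1e6 / totals


def filter_genes_cpm(counts: CountMatrix, cpm_threshold: float = 1.0,
                     min_samples: int = 50) -> np.ndarray:
    """Boolean gene mask: CPM strictly above ``cpm_threshold`` in at least
    ``min_samples`` samples. CPM denominators are sample totals over all
    genes, computed before any filtering."""
    if min_samples > counts.n_samples:
        raise InvalidParameter(
            f"min_samples={min_samples} exceeds cohort size {counts.n_samples}"
        )
    if min_samples < 1:
        raise InvalidParameter("min_samples must be >= 1")
    n_passing = (cpm(counts) > cpm_threshold).sum(axis=1)
    return n_passing >= min_samples


def filter_samples_depth(counts: CountMatrix, retained_genes: np.ndarray,
                         min_total: int = 500_000) -> np.ndarray:
    """Boolean sample mask: total count over retained genes strictly above
    ``min_total``."""
    retained_genes = np.asarray(retained_genes, dtype=bool)
    if retained_genes.shape != (counts.n_genes,):
        raise InvalidParameter("gene mask length does not match matrix")
    totals = counts.counts[retained_genes].sum(axis=0)
    mask = totals > min_total
    if not mask.any():
        raise EmptyAfterFilter(
            f"no sample exceeds min_total={min_total} over retained genes"
        )
    return mask


def size_factors_median_of_ratios(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    The per-gene reference is the geometric mean across samples, restricted
    to genes with all-positive counts; each sample's factor is the median
    over those genes of count/reference.
    """
    arr = counts.counts.astype(float)
    positive = np.all(arr > 0, axis=1)
    if not positive.any():
        raise DegenerateReference("no gene has positive counts in every sample")
    log_arr = np.log(arr[positive])
    log_ref = log_arr.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_arr - log_ref, axis=0))
    return factors


def vst(counts: CountMatrix, size_factors: np.ndarray,
        transform: str = "log2_norm_plus1") -> ExpressionMatrix:
    """Variance-stabilizing transform of size-factor-normalized counts.

    The default is ``log2(count / size_factor + 1)`` — monotone in counts
    within a sample and invariant to joint scaling of a sample's counts and
    its size factor. The transform name is recorded so a dispersion-based
    closed form can be slotted in upstream via the "precomputed" path.
    """
    size_factors = np.asarray(size_factors, dtype=float)
    if size_factors.shape != (counts.n_samples,):
        raise InvalidParameter("size factor vector length mismatch")
    if np.any(size_factors <= 0):
        raise InvalidParameter("size factors must be positive")
    if transform != "log2_norm_plus1":
        raise InvalidParameter(f"unknown transform: {transform!r}")
    values = np.log2(counts.counts / size_factors + 1.0)
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.sample_ids), values,
        size_factors=size_factors, transform=transform,
    )


# ---------------------------------------------------------------------------
# parametric empirical-Bayes batch correction (location/scale model,
# no biological covariates)
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted batch-adjustment model.

    Per gene: a pooled mean (``grand_mean``) and pooled variance
    (``pooled_var``) used for standardization. Per (batch, gene): the
    shrunken location (``gamma_star``) and scale (``delta_sq_star``)
    estimates, alongside the raw estimates and the batch-level
    empirical-Bayes hyperparameters.
    """

    gene_ids: list[str]
    batches: list[str]
    grand_mean: np.ndarray            # (genes,)
    pooled_var: np.ndarray            # (genes,)
    gamma_hat: np.ndarray             # (batches, genes) raw locations
    delta_sq_hat: np.ndarray          # (batches, genes) raw scales
    gamma_star: np.ndarray            # (batches, genes) EB-shrunken
    delta_sq_star: np.ndarray         # (batches, genes) EB-shrunken
    gamma_bar: np.ndarray = field(default=None)   # (batches,) prior means
    tau_sq_bar: np.ndarray = field(default=None)  # (batches,) prior variances
    a_prior: np.ndarray = field(default=None)     # (batches,) inv-gamma shape
    b_prior: np.ndarray = field(default=None)     # (batches,) inv-gamma rate

    def __post_init__(self) -> None:
        if np.any(self.delta_sq_star <= 0):
            raise InvalidParameter("batch scale estimates must be positive")


def _aprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _eb_iterate(z_batch: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
                g_bar: float, t2: float, a: float, b: float,
                conv: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Iterative solution of the EB posterior-mode equations for one batch."""
    n = z_batch.shape[1]
    g_new, d_new = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_old, d_old = g_new, d_new
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        ssq = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * ssq + b) / (n / 2 + a - 1)
        change = max(
            (np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)).max(),
            (np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)).max(),
        )
    return g_new, d_new


def combat_fit(expr: ExpressionMatrix, metadata: SampleMetadata,
               empirical_bayes: bool = True) -> BatchModel:
    """Fit the parametric empirical-Bayes batch model.

    Genes are standardized by the grand mean and pooled variance; per-batch
    location and scale estimates on the standardized data are shrunk toward
    batch-level normal / inverse-gamma priors fitted across genes. With
    ``empirical_bayes=False`` the raw per-batch estimates are used directly
    (no shrinkage), which equalizes batch means exactly and preserves each
    gene's grand mean to machine precision.
    """
    batch_labels = np.asarray(metadata.batch_for(expr.sample_ids))
    batches = sorted(set(batch_labels))
    if len(batches) < 2:
        raise InsufficientBatch("batch correction needs at least 2 batches")
    counts = {b: int((batch_labels == b).sum()) for b in batches}
    small = [b for b, c in counts.items() if c < 2]
    if small:
        raise InsufficientBatch(f"batches with < 2 samples: {small}")

    y = expr.values
    n_total = y.shape[1]
    batch_masks = [batch_labels == b for b in batches]
    batch_means = np.stack([y[:, m].mean(axis=1) for m in batch_masks])

    # weighted grand mean and pooled residual variance around batch means
    weights = np.array([counts[b] / n_total for b in batches])
    grand_mean = weights @ batch_means
    fitted = np.zeros_like(y, dtype=float)
    for bm, mean in zip(batch_masks, batch_means):
        fitted[:, bm] = mean[:, None]
    pooled_var = ((y - fitted) ** 2).sum(axis=1) / n_total
    if np.any(pooled_var <= 0):
        raise InvalidParameter(
            "a gene is constant within every batch; remove constant genes first"
        )

    z = (y - grand_mean[:, None]) / np.sqrt(pooled_var)[:, None]

    n_batches, n_genes = len(batches), y.shape[0]
    gamma_hat = np.empty((n_batches, n_genes))
    delta_sq_hat = np.empty((n_batches, n_genes))
    gamma_star = np.empty((n_batches, n_genes))
    delta_sq_star = np.empty((n_batches, n_genes))
    gamma_bar = np.empty(n_batches)
    tau_sq_bar = np.empty(n_batches)
    a_prior = np.empty(n_batches)
    b_prior = np.empty(n_batches)

    for i, bm in enumerate(batch_masks):
        zb = z[:, bm]
        gamma_hat[i] = zb.mean(axis=1)
        delta_sq_hat[i] = zb.var(axis=1, ddof=1)
        gamma_bar[i] = gamma_hat[i].mean()
        tau_sq_bar[i] = gamma_hat[i].var(ddof=1)
        a_prior[i] = _aprior(delta_sq_hat[i])
        b_prior[i] = _bprior(delta_sq_hat[i])
        if empirical_bayes:
            gamma_star[i], delta_sq_star[i] = _eb_iterate(
                zb, gamma_hat[i], delta_sq_hat[i],
                gamma_bar[i], tau_sq_bar[i], a_prior[i], b_prior[i],
            )
        else:
            gamma_star[i] = gamma_hat[i]
            delta_sq_star[i] = delta_sq_hat[i]

    return BatchModel(
        gene_ids=list(expr.gene_ids),
        batches=batches,
        grand_mean=grand_mean,
        pooled_var=pooled_var,
        gamma_hat=gamma_hat,
        delta_sq_hat=delta_sq_hat,
        gamma_star=gamma_star,
        delta_sq_star=delta_sq_star,
        gamma_bar=gamma_bar,
        tau_sq_bar=tau_sq_bar,
        a_prior=a_prior,
        b_prior=b_prior,
    )


def combat_apply(expr: ExpressionMatrix, model: BatchModel,
                 metadata: SampleMetadata) -> ExpressionMatrix:
    """Adjust expression values with a fitted batch model."""
    if list(model.gene_ids) != list(expr.gene_ids):
        raise InvalidParameter("batch model was fitted on different genes")
    batch_labels = metadata.batch_for(expr.sample_ids)
    unseen = sorted(set(batch_labels) - set(model.batches))
    if unseen:
        raise UnknownBatch(f"batch labels not in fitted model: {unseen}")
    index = {b: i for i, b in enumerate(model.batches)}
    sd = np.sqrt(model.pooled_var)
    z = (expr.values - model.grand_mean[:, None]) / sd[:, None]
    adjusted = np.empty_like(z)
    for b in set(batch_labels):
        i = index[b]
        mask = np.array([lbl == b for lbl in batch_labels])
        adjusted[:, mask] = (
            z[:, mask] - model.gamma_star[i][:, None]
        ) / np.sqrt(model.delta_sq_star[i])[:, None]
    values = adjusted * sd[:, None] + model.grand_mean[:, None]
    out = expr.copy()
    out.values = values
    out.batch_corrected = True
    return out


def correct_batches(expr: ExpressionMatrix,
                    metadata: SampleMetadata) -> ExpressionMatrix:
    """Fit + apply in one step; single-batch input passes through unchanged."""
    labels = set(metadata.batch_for(expr.sample_ids))
    if len(labels) < 2:
        return expr
    model = combat_fit(expr, metadata)
    return combat_apply(expr, model, metadata)


@dataclass
class PreprocessConfig:
    cpm_threshold: float = 1.0
    min_samples: int = 50
    min_total: int = 500_000
    transform: str = "log2_norm_plus1"
    batch_correct: bool = True


def run_preprocess(counts: CountMatrix, metadata: SampleMetadata | None = None,
                   config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Full filter -> normalize -> transform -> batch-correct pipeline."""
    config = config or PreprocessConfig()
    gene_mask = filter_genes_cpm(counts, config.cpm_threshold, config.min_samples)
    if not gene_mask.any():
        raise EmptyAfterFilter("no gene passes the CPM filter")
    sample_mask = filter_samples_depth(counts, gene_mask, config.min_total)
    filtered = counts.subset(gene_mask, sample_mask)
    factors = size_factors_median_of_ratios(filtered)
    expr = vst(filtered, factors, config.transform)
    if config.batch_correct and metadata is not None:
        expr = correct_batches(expr, metadata)
    return expr
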