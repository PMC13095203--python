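"""Subtype assignment by the four-step percentile decision tree.

Step 1 labels ccrcc3: the ccrcc3_up/ccrcc3_down ratio must lie strictly
above the cohort 80th percentile (the upper 20%) while ccrcc2_up,
cell_cycle, and t_effector lie at or below their cohort 50th, 64th, and
75th percentiles. Step 2 labels ccrcc2 among the remaining samples when
the ccrcc2_up/ccrcc1and4_up ratio is strictly above that subset's 50th
percentile. Step 3 labels ccrcc4 among the still-unlabeled samples when
the ccrcc4_up/ccrcc1_up ratio is strictly above that subset's 60th
percentile (the upper 40%). Step 4 labels the remainder ccrcc1.

"Upper"/"higher than" comparisons are strict ``>``; "lower"/"lowest"
criteria are inclusive ``<=``. Percentiles use linear interpolation on
sorted values (the k-th of n sorted values sits at percent 100*(k-1)/(n-1)).

Cohort-percentile mode requires ``n >= min_cohort`` samples; the realized
cutoffs it records can be extracted and reapplied as absolute cutoffs to
small cohorts or single samples (fixed-cutoff mode).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CohortTooSmall,
    EmptyInput,
    IncompleteThresholds,
    InvalidParameter,
    IOFailure,
    SampleMismatch,
)
from .io_formats import SUBTYPE_LABELS
from .signatures import SignatureScoreMatrix, signature_ratio

#: Names of the six decision statistics, in evaluation order.
DECISION_STATISTICS: tuple[str, ...] = (
    "ccrcc3_ratio",     # ccrcc3_up / ccrcc3_down
    "ccrcc2_up",
    "cell_cycle",
    "t_effector",
    "ccrcc2_ratio",     # ccrcc2_up / ccrcc1and4_up
    "ccrcc4_ratio",     # ccrcc4_up / ccrcc1_up
)

#: Names of the six realized cutoffs, matching DECISION_STATISTICS.
CUTOFF_NAMES: tuple[str, ...] = (
    "p3_ratio",
    "p3_ccrcc2up",
    "p3_cellcycle",
    "p3_teffector",
    "p2_ratio",
    "p4_ratio",
)


def percentile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation percentile of a non-empty finite vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyInput("percentile of an empty vector")
    if not np.all(np.isfinite(arr)):
        raise InvalidParameter("percentile input must be finite")
    if not 0 <= q <= 100:
        raise InvalidParameter("q must be in [0, 100]")
    return float(np.percentile(arr, q, method="linear"))


@dataclass(frozen=True)
class ThresholdSet:
    """Percentile configuration and, in fixed mode, absolute cutoffs.

    Percentile fields are expressed as the percentile *rank* of the cutoff:
    ``p3_ratio_pct = 80`` means the upper 20% pass, ``p4_ratio_pct = 60``
    means the upper 40% pass.
    """

    p3_ratio_pct: float = 80.0
    p3_ccrcc2up_pct: float = 50.0
    p3_cellcycle_pct: float = 64.0
    p3_teffector_pct: float = 75.0
    p2_ratio_pct: float = 50.0
    p4_ratio_pct: float = 60.0
    mode: str = "cohort_percentile"
    cutoffs: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name in ("p3_ratio_pct", "p3_ccrcc2up_pct", "p3_cellcycle_pct",
                     "p3_teffector_pct", "p2_ratio_pct", "p4_ratio_pct"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise InvalidParameter(f"{name}={v} must lie in (0, 100)")
        if self.mode not in ("cohort_percentile", "fixed_cutoff"):
            raise InvalidParameter(f"unknown threshold mode: {self.mode!r}")
        if self.mode == "fixed_cutoff":
            cutoffs = self.cutoffs or {}
            missing = [n for n in CUTOFF_NAMES if n not in cutoffs]
            if missing:
                raise IncompleteThresholds(f"missing fixed cutoffs: {missing}")
            bad = [n for n in CUTOFF_NAMES if not np.isfinite(cutoffs[n])]
            if bad:
                raise IncompleteThresholds(f"non-finite fixed cutoffs: {bad}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "percentiles": {
                "p3_ratio_pct": self.p3_ratio_pct,
                "p3_ccrcc2up_pct": self.p3_ccrcc2up_pct,
                "p3_cellcycle_pct": self.p3_cellcycle_pct,
                "p3_teffector_pct": self.p3_teffector_pct,
                "p2_ratio_pct": self.p2_ratio_pct,
                "p4_ratio_pct": self.p4_ratio_pct,
            },
            "mode": self.mode,
            "cutoffs": self.cutoffs,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            try:
                Path(path).write_text(text)
            except OSError as exc:
                raise IOFailure(f"cannot write {path}: {exc}") from exc
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ThresholdSet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(mode=payload["mode"], cutoffs=payload.get("cutoffs"),
                   **payload["percentiles"])


@dataclass
class SubtypeCall:
    """One sample's label plus the evidence behind it."""

    sample_id: str
    label: str
    rule_trace: str
    statistics: dict[str, float]

    def __post_init__(self) -> None:
        if self.label not in SUBTYPE_LABELS:
            raise InvalidParameter(f"unknown subtype label {self.label!r}")


@dataclass
class CohortClassification:
    """All calls for a cohort plus the realized cutoff values."""

    calls: list[SubtypeCall]
    realized_cutoffs: dict[str, float]
    mode: str = "cohort_percentile"
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {lbl: 0 for lbl in SUBTYPE_LABELS}
        for call in self.calls:
            counts[call.label] += 1
        self.class_counts = counts

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.calls]

    @property
    def sample_ids(self) -> list[str]:
        return [c.sample_id for c in self.calls]


def decision_statistics(scores: SignatureScoreMatrix) -> dict[str, np.ndarray]:
    """The six per-sample statistics the tree compares against cutoffs."""
    return {
        "ccrcc3_ratio": signature_ratio(scores, "ccrcc3_up", "ccrcc3_down"),
        "ccrcc2_up": scores.column("ccrcc2_up").astype(float),
        "cell_cycle": scores.column("cell_cycle").astype(float),
        "t_effector": scores.column("t_effector").astype(float),
        "ccrcc2_ratio": signature_ratio(scores, "ccrcc2_up", "ccrcc1and4_up"),
        "ccrcc4_ratio": signature_ratio(scores, "ccrcc4_up", "ccrcc1_up"),
    }


def _apply_tree(stats: dict[str, np.ndarray], cutoffs: dict[str, float],
                sample_ids: Sequence[str]) -> list[SubtypeCall]:
    """Run the four steps with concrete cutoff values."""
    n = len(sample_ids)
    is3 = (
        (stats["ccrcc3_ratio"] > cutoffs["p3_ratio"])
        & (stats["ccrcc2_up"] <= cutoffs["p3_ccrcc2up"])
        & (stats["cell_cycle"] <= cutoffs["p3_cellcycle"])
        & (stats["t_effector"] <= cutoffs["p3_teffector"])
    )
    is2 = ~is3 & (stats["ccrcc2_ratio"] > cutoffs["p2_ratio"])
    is4 = ~is3 & ~is2 & (stats["ccrcc4_ratio"] > cutoffs["p4_ratio"])

    calls = []
    for i, sid in enumerate(sample_ids):
        if is3[i]:
            label = "ccrcc3"
            trace = (
                f"step1: ratio {stats['ccrcc3_ratio'][i]:.6g}>{cutoffs['p3_ratio']:.6g}"
                f" & ccrcc2_up {stats['ccrcc2_up'][i]:.6g}<={cutoffs['p3_ccrcc2up']:.6g}"
                f" & cell_cycle {stats['cell_cycle'][i]:.6g}<={cutoffs['p3_cellcycle']:.6g}"
                f" & t_effector {stats['t_effector'][i]:.6g}<={cutoffs['p3_teffector']:.6g}"
            )
        elif is2[i]:
            label = "ccrcc2"
            trace = (
                f"step2: ccrcc2_ratio {stats['ccrcc2_ratio'][i]:.6g}"
                f">{cutoffs['p2_ratio']:.6g}"
            )
        elif is4[i]:
            label = "ccrcc4"
            trace = (
                f"step3: ccrcc4_ratio {stats['ccrcc4_ratio'][i]:.6g}"
                f">{cutoffs['p4_ratio']:.6g}"
            )
        else:
            label = "ccrcc1"
            trace = "step4: remainder"
        calls.append(
            SubtypeCall(
                sample_id=str(sid),
                label=label,
                rule_trace=trace,
                statistics={k: float(stats[k][i]) for k in DECISION_STATISTICS},
            )
        )
    return calls


def classify_cohort(scores: SignatureScoreMatrix,
                    thresholds: ThresholdSet | None = None,
                    min_cohort: int = 20) -> CohortClassification:
    """Cohort-percentile classification.

    Step-1 percentiles are taken over all samples; the step-2 percentile
    over non-ccrcc3 samples; the step-3 percentile over samples that are
    neither ccrcc3 nor ccrcc2. The realized cutoffs are recorded so they
    can be reused in fixed-cutoff mode.
    """
    thresholds = thresholds or ThresholdSet()
    if thresholds.mode != "cohort_percentile":
        raise InvalidParameter("classify_cohort requires cohort_percentile mode")
    n = scores.n_samples
    if n < min_cohort:
        raise CohortTooSmall(
            f"cohort mode needs >= {min_cohort} samples (got {n}); use "
            "fixed_cutoff mode with cutoffs extracted from a reference cohort"
        )
    stats = decision_statistics(scores)

    cutoffs = {
        "p3_ratio": percentile(stats["ccrcc3_ratio"], thresholds.p3_ratio_pct),
        "p3_ccrcc2up": percentile(stats["ccrcc2_up"], thresholds.p3_ccrcc2up_pct),
        "p3_cellcycle": percentile(stats["cell_cycle"], thresholds.p3_cellcycle_pct),
        "p3_teffector": percentile(stats["t_effector"], thresholds.p3_teffector_pct),
    }
    is3 = (
        (stats["ccrcc3_ratio"] > cutoffs["p3_ratio"])
        & (stats["ccrcc2_up"] <= cutoffs["p3_ccrcc2up"])
        & (stats["cell_cycle"] <= cutoffs["p3_cellcycle"])
        & (stats["t_effector"] <= cutoffs["p3_teffector"])
    )
    rest = ~is3
    cutoffs["p2_ratio"] = percentile(
        stats["ccrcc2_ratio"][rest], thresholds.p2_ratio_pct
    )
    is2 = rest & (stats["ccrcc2_ratio"] > cutoffs["p2_ratio"])
    rest2 = rest & ~is2
    cutoffs["p4_ratio"] = percentile(
        stats["ccrcc4_ratio"][rest2], thresholds.p4_ratio_pct
    )

    calls = _apply_tree(stats, cutoffs, scores.sample_ids)
    return CohortClassification(calls, cutoffs, mode="cohort_percentile")


def classify_fixed(scores: SignatureScoreMatrix,
                   thresholds: ThresholdSet) -> CohortClassification:
    """Fixed-cutoff classification; valid for any n >= 1."""
    if thresholds.mode != "fixed_cutoff":
        raise IncompleteThresholds("classify_fixed requires fixed_cutoff mode")
    stats = decision_statistics(scores)
    cutoffs = dict(thresholds.cutoffs)
    calls = _apply_tree(stats, cutoffs, scores.sample_ids)
    return CohortClassification(calls, cutoffs, mode="fixed_cutoff")


def extract_cutoffs(classification: CohortClassification) -> ThresholdSet:
    """Package a cohort run's realized cutoffs for single-sample reuse."""
    if classification.mode != "cohort_percentile":
        raise InvalidParameter("cutoffs can only be extracted from a cohort run")
    return ThresholdSet(
        mode="fixed_cutoff",
        cutoffs={k: float(v) for k, v in classification.realized_cutoffs.items()},
    )


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

@dataclass
class ConfusionTable:
    """Cross-tabulation of two label vectors with integer row percentages."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    row_percentages: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise InvalidParameter("confusion counts must be nonnegative")
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        pct[~np.isfinite(pct)] = 0.0
        # round-half-away-from-zero, as printed percentages are rounded
        self.row_percentages = np.floor(pct + 0.5).astype(int)

    def to_frame(self, percentages: bool = False) -> pd.DataFrame:
        data = self.row_percentages if percentages else self.counts
        return pd.DataFrame(data, index=self.row_labels, columns=self.col_labels)


def concordance(labels_a: Sequence[str], labels_b: Sequence[str],
                classes: Sequence[str] = SUBTYPE_LABELS) -> ConfusionTable:
    """4x4 cross-tabulation (rows = method A) with row percentages."""
    if len(labels_a) != len(labels_b):
        raise SampleMismatch(
            f"label vectors differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if len(labels_a) == 0:
        raise EmptyInput("cannot cross-tabulate empty label vectors")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    unknown = sorted({*labels_a, *labels_b} - set(classes))
    if unknown:
        raise InvalidParameter(f"labels outside the class set: {unknown}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for a, b in zip(labels_a, labels_b):
        counts[index[a], index[b]] += 1
    return ConfusionTable(classes, list(classes), counts)


def confusion_from_counts(counts: np.ndarray,
                          row_labels: Sequence[str] = SUBTYPE_LABELS,
                          col_labels: Sequence[str] = SUBTYPE_LABELS) -> ConfusionTable:
    """Build a ConfusionTable directly from a printed count table."""
    return ConfusionTable(list(row_labels), list(col_labels), np.asarray(counts))


# ---------------------------------------------------------------------------
# classification I/O (TSV round-trip)
# ---------------------------------------------------------------------------

def write_classification(classification: CohortClassification,
                         path: str | Path) -> None:
    """Write calls as TSV: sample_id, subtype, the six decision statistics,
    the realized cutoffs (repeated per row), and the rule trace."""
    if not classification.calls:
        raise EmptyInput("no calls to write")
    rows = []
    for call in classification.calls:
        row = {"sample_id": call.sample_id, "subtype": call.label}
        for k in DECISION_STATISTICS:
            row[f"stat_{k}"] = repr(call.statistics[k])
        for k in CUTOFF_NAMES:
            row[f"cutoff_{k}"] = repr(float(classification.realized_cutoffs[k]))
        row["rule_trace"] = call.rule_trace.replace("\t", " ")
        rows.append(row)
    try:
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc


def read_classification(path: str | Path) -> CohortClassification:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                         float_precision="round_trip")
    except OSError as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc
    calls = []
    for _, row in df.iterrows():
        calls.append(
            SubtypeCall(
                sample_id=str(row["sample_id"]),
                label=str(row["subtype"]),
                rule_trace=str(row.get("rule_trace", "")),
                statistics={k: float(row[f"stat_{k}"]) for k in DECISION_STATISTICS},
            )
        )
    cutoffs = {k: float(df.iloc[0][f"cutoff_{k}"]) for k in CUTOFF_NAMES}
    return CohortClassification(calls, cutoffs)
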