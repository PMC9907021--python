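"""Interobserver variability benchmarking.

Within-group pairwise agreement, expert-derived acceptability thresholds,
ROI-specific surface-Dice tolerances, Mann-Whitney group comparisons, and
consensus-vs-threshold evaluation.

The clinical-acceptability bar for a (ROI, metric) is the *median pairwise
value among experts*: if a candidate segmentation agrees with the expert
consensus at least as well as experts agree with each other, it is deemed
acceptable.  The surface-Dice tolerance tau for an ROI is likewise derived
from the experts: the median pairwise mean surface distance, so that
surface deviations smaller than typical expert-to-expert deviation do not
count against a contour.

Undefined pairwise values (empty masks) are recorded as missing and
excluded from medians and tests, never imputed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BinaryMask, Expertise, ObserverContour
from .metrics import (
    HIGHER_IS_BETTER,
    Metric,
    UndefinedMetricError,
    compute_metric,
    surface_distance_stats,
)

logger = logging.getLogger("contourbench")

__all__ = [
    "PairwiseMatrix",
    "AcceptabilityThreshold",
    "InsufficientGroupError",
    "pairwise_metric_values",
    "expert_acceptability_threshold",
    "determine_sdsc_tolerance",
    "compare_groups_mwu",
    "significance_band",
    "evaluate_consensus_vs_threshold",
]


class InsufficientGroupError(ValueError):
    """Fewer observers (or defined pair values) than the statistic needs."""


@dataclass(frozen=True)
class PairwiseMatrix:
    """Unordered-pair metric values within one observer group."""

    case_id: str
    roi_name: str
    group: Expertise
    metric: Metric
    pairs: tuple[tuple[str, str], ...]
    values: tuple[float, ...]  # NaN marks an undefined pair
    tolerance_mm: float | None = None

    def defined_values(self) -> np.ndarray:
        v = np.asarray(self.values, dtype=float)
        return v[~np.isnan(v)]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class AcceptabilityThreshold:
    """Median expert pairwise value for one (case, ROI, metric)."""

    case_id: str
    roi_name: str
    metric: Metric
    value: float


def pairwise_metric_values(
    contours: list[ObserverContour],
    metric: Metric | str,
    tau_mm: float | None = None,
) -> PairwiseMatrix:
    """Evaluate a symmetric metric on every unordered observer pair.

    Undefined pairs (e.g. an empty mask for a surface metric) are recorded
    as NaN with a logged reason.
    """
    metric = Metric(metric)
    if len(contours) < 2:
        raise InsufficientGroupError(
            f"need >= 2 observers, got {len(contours)}"
        )
    groups = {c.expertise for c in contours}
    cases = {c.case_id for c in contours}
    rois = {c.roi_name for c in contours}
    if len(groups) != 1 or len(cases) != 1 or len(rois) != 1:
        raise ValueError("contours must share one (case, roi, expertise) group")
    ordered = sorted(contours, key=lambda c: c.observer_id)
    pairs, values = [], []
    for a, b in itertools.combinations(ordered, 2):
        pairs.append((a.observer_id, b.observer_id))
        try:
            values.append(float(compute_metric(metric, a.mask, b.mask, tau_mm)))
        except UndefinedMetricError as exc:
            logger.info(
                "undefined %s pair (%s, %s): %s",
                metric.value, a.observer_id, b.observer_id, exc,
            )
            values.append(float("nan"))
    first = ordered[0]
    return PairwiseMatrix(
        case_id=first.case_id,
        roi_name=first.roi_name,
        group=first.expertise,
        metric=metric,
        pairs=tuple(pairs),
        values=tuple(values),
        tolerance_mm=tau_mm,
    )


def expert_acceptability_threshold(matrix: PairwiseMatrix) -> AcceptabilityThreshold:
    """Median over defined expert pair values."""
    if matrix.group != Expertise.EXPERT:
        raise ValueError("acceptability thresholds are derived from experts only")
    vals = matrix.defined_values()
    if vals.size == 0:
        raise InsufficientGroupError(
            "no defined expert pair values; threshold undefined"
        )
    return AcceptabilityThreshold(
        case_id=matrix.case_id,
        roi_name=matrix.roi_name,
        metric=matrix.metric,
        value=float(np.median(vals)),
    )


def determine_sdsc_tolerance(expert_contours: list[ObserverContour]) -> float:
    """ROI-specific surface-Dice tolerance tau (mm): the median pairwise
    mean surface distance among experts."""
    usable = [c for c in expert_contours if not c.mask.is_empty()]
    if len(usable) < 2:
        raise InsufficientGroupError(
            "tolerance needs >= 2 experts with nonempty masks"
        )
    msds = []
    for a, b in itertools.combinations(sorted(usable, key=lambda c: c.observer_id), 2):
        msd, _ = surface_distance_stats(a.mask, b.mask)
        msds.append(float(msd))
    return float(np.median(msds))


def significance_band(p: float) -> str:
    """Conventional star banding: ns p>0.05; * 0.01<p<=0.05;
    ** 0.001<p<=0.01; *** 0.0001<p<=0.001; **** p<=0.0001."""
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


def compare_groups_mwu(
    expert_values, nonexpert_values, method: str | None = None
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U comparing expert vs nonexpert pair values.

    Returns (U statistic for the expert sample, p, significance band).
    The exact distribution is used when both samples have n <= 8 and no
    ties; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(expert_values, dtype=float)
    y = np.asarray(nonexpert_values, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise InsufficientGroupError("both samples must be nonempty")
    if method is None:
        method = "exact" if (x.size <= 8 and y.size <= 8) else "asymptotic"
    if method == "exact" and len(np.unique(np.concatenate([x, y]))) < x.size + y.size:
        method = "asymptotic"  # scipy's exact method does not handle ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return float(res.statistic), p, significance_band(p)


def evaluate_consensus_vs_threshold(
    consensus_a: BinaryMask,
    consensus_b: BinaryMask,
    threshold: AcceptabilityThreshold,
    tau_mm: float | None = None,
) -> tuple[float, bool, str]:
    """Compare two consensus masks and judge against an acceptability bar.

    For similarity metrics (DSC, SDSC) the bar is crossed when
    value >= threshold; for distance metrics when value <= threshold.
    Undefined metrics are recorded missing with crossed = False.
    Returns (value, crossed, reason)."""
    try:
        value = float(
            compute_metric(threshold.metric, consensus_a, consensus_b, tau_mm)
        )
    except UndefinedMetricError as exc:
        return float("nan"), False, f"undefined: {exc}"
    if HIGHER_IS_BETTER.get(threshold.metric, True):
        crossed = value >= threshold.value
    else:
        crossed = value <= threshold.value
    return value, bool(crossed), ""


def pairwise_matrix_to_frame(matrix: PairwiseMatrix) -> pd.DataFrame:
    """One CSV-ready row per observer pair."""
    return pd.DataFrame(
        {
            "case_id": matrix.case_id,
            "roi_name": matrix.roi_name,
            "group": matrix.group.value,
            "obs_a": [a for a, _ in matrix.pairs],
            "obs_b": [b for _, b in matrix.pairs],
            "metric": matrix.metric.value,
            "value": matrix.values,
            "tolerance_mm": (
                np.nan if matrix.tolerance_mm is None else float(matrix.tolerance_mm)
            ),
        }
    )
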