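"""Observer skill stratification and cross-case performance correlation.

Case-level performance of an observer is the unweighted mean, over the
ROIs they contoured, of their agreement with the expert consensus for each
ROI.  These scores support two analyses:

* cross-case correlation — do observers who score well on one case also
  score well on another? (Pearson r on observers present in both cases);
* tertile stratification — split observers into low/medium/high classes at
  the 1/3 and 2/3 quantiles of their case-level scores, then fuse each
  class separately and ask which classes produce an acceptable consensus.

Quantiles use linear interpolation between order statistics; bins are
left-open/right-closed (low: value <= t1; medium: t1 < value <= t2;
high: value > t2), which for n distinct scores splits 124 observers
42/41/41 and 66 observers 22/22/22.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import AcceptabilityThreshold, evaluate_consensus_vs_threshold
from .io import BinaryMask, ObserverContour
from .metrics import Metric, UndefinedMetricError, compute_metric
from .staple import STAPLE, StapleConfig

__all__ = [
    "CaseLevelScore",
    "TertileAssignment",
    "case_level_performance",
    "correlate_case_performance",
    "tertile_stratify",
    "class_consensus_evaluation",
]

CLASSES = ("low", "medium", "high")


class NoScoreError(ValueError):
    """Observer contoured zero ROIs with a defined metric."""


class InsufficientOverlapError(ValueError):
    """Fewer than 3 observers present in both cases."""


class DegenerateStratificationError(ValueError):
    """All scores identical; tertile edges undefined."""


@dataclass(frozen=True)
class CaseLevelScore:
    observer_id: str
    case_id: str
    metric: Metric
    value: float
    n_rois_used: int


@dataclass(frozen=True)
class TertileAssignment:
    case_id: str
    metric: Metric
    bin_edges: tuple[float, float, float, float]  # min, t1, t2, max
    classes: dict[str, str]  # observer_id -> low|medium|high

    def members(self, cls: str) -> list[str]:
        return sorted(o for o, c in self.classes.items() if c == cls)

    def class_sizes(self) -> dict[str, int]:
        return {c: len(self.members(c)) for c in CLASSES}


def case_level_performance(
    observer_contours: list[ObserverContour],
    expert_consensus_by_roi: dict[str, BinaryMask],
    metric: Metric | str = Metric.DSC,
    tau_by_roi: dict[str, float] | None = None,
) -> CaseLevelScore:
    """Mean observer-vs-expert-consensus metric over the observer's ROIs.

    ROIs with an undefined metric are excluded (and counted out of
    ``n_rois_used``); an observer with no usable ROI raises.
    """
    metric = Metric(metric)
    if not observer_contours:
        raise NoScoreError("observer contoured zero ROIs")
    obs_ids = {c.observer_id for c in observer_contours}
    case_ids = {c.case_id for c in observer_contours}
    if len(obs_ids) != 1 or len(case_ids) != 1:
        raise ValueError("contours must belong to one observer and one case")
    values = []
    for c in observer_contours:
        if c.roi_name not in expert_consensus_by_roi:
            raise KeyError(f"no expert consensus for ROI {c.roi_name!r}")
        tau = (tau_by_roi or {}).get(c.roi_name)
        try:
            values.append(
                float(
                    compute_metric(
                        metric, c.mask, expert_consensus_by_roi[c.roi_name], tau
                    )
                )
            )
        except UndefinedMetricError:
            continue
    if not values:
        raise NoScoreError(
            f"observer {next(iter(obs_ids))!r}: metric undefined on all ROIs"
        )
    return CaseLevelScore(
        observer_id=next(iter(obs_ids)),
        case_id=next(iter(case_ids)),
        metric=metric,
        value=float(np.mean(values)),
        n_rois_used=len(values),
    )


def correlate_case_performance(
    scores_case_a: list[CaseLevelScore], scores_case_b: list[CaseLevelScore]
) -> tuple[float, float, int]:
    """Pearson r (and two-sided p, t-distribution with n-2 df) between the
    case-level scores of observers present in both cases."""
    a_by_obs = {s.observer_id: s.value for s in scores_case_a}
    b_by_obs = {s.observer_id: s.value for s in scores_case_b}
    overlap = sorted(set(a_by_obs) & set(b_by_obs))
    if len(overlap) < 3:
        raise InsufficientOverlapError(
            f"need >= 3 overlapping observers, got {len(overlap)}"
        )
    x = np.array([a_by_obs[o] for o in overlap])
    y = np.array([b_by_obs[o] for o in overlap])
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(overlap)


def tertile_stratify(scores: list[CaseLevelScore]) -> TertileAssignment:
    """Split observers into low/medium/high classes at the 1/3 and 2/3
    score quantiles (linear interpolation; low <= t1 < medium <= t2 < high)."""
    if len(scores) < 3:
        raise ValueError(f"need >= 3 scores, got {len(scores)}")
    case_ids = {s.case_id for s in scores}
    metrics = {s.metric for s in scores}
    if len(case_ids) != 1 or len(metrics) != 1:
        raise ValueError("scores must share one case and one metric")
    vals = np.array([s.value for s in scores])
    if np.allclose(vals, vals[0]):
        raise DegenerateStratificationError("all scores identical")
    t1, t2 = np.quantile(vals, [1.0 / 3.0, 2.0 / 3.0], method="linear")
    edges = (float(vals.min()), float(t1), float(t2), float(vals.max()))
    classes = {}
    for s in scores:
        if s.value <= t1:
            classes[s.observer_id] = "low"
        elif s.value <= t2:
            classes[s.observer_id] = "medium"
        else:
            classes[s.observer_id] = "high"
    return TertileAssignment(
        case_id=next(iter(case_ids)),
        metric=next(iter(metrics)),
        bin_edges=edges,
        classes=classes,
    )


def class_consensus_evaluation(
    assignment: TertileAssignment,
    contours_by_roi: dict[str, list[ObserverContour]],
    expert_consensus_by_roi: dict[str, BinaryMask],
    thresholds: dict[tuple[str, str], AcceptabilityThreshold],
    tau_by_roi: dict[str, float] | None = None,
    staple_config: StapleConfig | None = None,
) -> pd.DataFrame:
    """Fuse each skill class per ROI and judge it against the expert bar.

    ``thresholds`` maps (roi_name, metric name) -> threshold.  Classes with
    fewer than 2 members contoured on an ROI are recorded missing.  Returns
    a table with one row per (class, ROI, metric).
    """
    cfg = staple_config or StapleConfig()
    rows = []
    metrics = sorted({m for (_, m) in thresholds}, key=str)
    for roi_name, contours in sorted(contours_by_roi.items()):
        by_obs = {c.observer_id: c for c in contours}
        for cls in CLASSES:
            members = [by_obs[o] for o in assignment.members(cls) if o in by_obs]
            consensus = None
            if len(members) >= 2:
                consensus = (
                    STAPLE([m.mask for m in members], config=cfg).fit().consensus_mask
                )
            for metric_name in metrics:
                key = (roi_name, metric_name)
                if key not in thresholds:
                    continue
                thr = thresholds[key]
                row = {
                    "class": cls,
                    "roi_name": roi_name,
                    "metric": metric_name,
                    "n_members": len(members),
                    "threshold": thr.value,
                }
                if consensus is None:
                    row.update(value=np.nan, crossed=False,
                               reason="class has < 2 members for ROI")
                else:
                    tau = (tau_by_roi or {}).get(roi_name)
                    value, crossed, reason = evaluate_consensus_vs_threshold(
                        consensus, expert_consensus_by_roi[roi_name], thr, tau
                    )
                    row.update(value=value, crossed=crossed, reason=reason)
                rows.append(row)
    return pd.DataFrame(rows)
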