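"""Bootstrap minimum-observer experiments.

How good does a nonexpert consensus get as more nonexperts are added?  For
each subset size k, draw k nonexperts *with replacement* (duplicates enter
the consensus as independent raters), fuse them with STAPLE, and score the
consensus against the expert consensus.  Repeating this gives, per size, a
bootstrap distribution whose mean and percentile 95% CI form the curve;
the minimum number of observers is the smallest k whose mean crosses the
expert acceptability threshold.

Default sizes are 2-10, 15, 20, 25 (capped at the available nonexperts)
with 100 iterations per size.  Crossing is judged on the bootstrap mean
(the plotted line), first crossing even if the curve later dips.  A curve
is flagged *nonsaturating* when the mean at the maximum size falls more
than delta (default 0.01) below the peak mean — the regime where adding
more observers hurts the consensus.

RNG: one master seed; per-(ROI, size) streams are derived with
``SeedSequence`` so sizes and ROIs can run in any order with identical
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark import AcceptabilityThreshold
from .io import BinaryMask, ObserverContour
from .metrics import HIGHER_IS_BETTER, Metric, UndefinedMetricError, compute_metric
from .staple import STAPLE, StapleConfig

__all__ = [
    "DEFAULT_SIZES",
    "BootstrapCurve",
    "MinObserverResult",
    "bootstrap_consensus_curve",
    "subset_draws",
    "minimum_observers",
    "detect_nonsaturation",
    "plot_bootstrap_curve",
]

DEFAULT_SIZES = (2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 25)
DEFAULT_N_ITER = 100


@dataclass(frozen=True)
class BootstrapCurve:
    case_id: str
    roi_name: str
    metric: Metric
    sizes: tuple[int, ...]
    values: dict[int, np.ndarray] = field(repr=False)  # per size, n_iter values
    threshold: float | None = None  # expert acceptability reference
    max_observer_value: float | None = None  # all-nonexpert consensus reference
    n_iter: int = DEFAULT_N_ITER
    seed: int | None = None
    tolerance_mm: float | None = None

    def mean(self, size: int) -> float:
        v = self.values[size]
        v = v[~np.isnan(v)]
        return float(v.mean()) if v.size else float("nan")

    def ci95(self, size: int) -> tuple[float, float]:
        v = self.values[size]
        v = v[~np.isnan(v)]
        if not v.size:
            return float("nan"), float("nan")
        return float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))

    def means(self) -> list[float]:
        return [self.mean(k) for k in self.sizes]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.sizes:
            for it, v in enumerate(self.values[k]):
                rows.append(
                    {
                        "case_id": self.case_id,
                        "roi_name": self.roi_name,
                        "metric": self.metric.value,
                        "size": k,
                        "iter": it,
                        "value": v,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MinObserverResult:
    case_id: str
    roi_name: str
    metric: Metric
    k_min: int | None
    nonsaturating: bool
    description: str = ""


def _subset_rng(master_seed: int, roi_name: str, size: int) -> np.random.Generator:
    # stable stream per (roi, size): order/parallelism independent
    roi_key = int.from_bytes(roi_name.encode()[:8].ljust(8, b"\0"), "little")
    ss = np.random.SeedSequence([master_seed, roi_key % (2**31), size])
    return np.random.default_rng(ss)


def subset_draws(
    n_observers: int, size: int, n_iter: int, seed: int, roi_name: str = ""
) -> np.ndarray:
    """The (n_iter, size) with-replacement observer index draws used by
    :func:`bootstrap_consensus_curve` for one (ROI, size) stream."""
    rng = _subset_rng(seed, roi_name, size)
    return rng.integers(0, n_observers, size=(n_iter, size))


def bootstrap_consensus_curve(
    nonexperts: list[ObserverContour],
    expert_consensus: BinaryMask,
    threshold: AcceptabilityThreshold | float | None = None,
    sizes: tuple[int, ...] = DEFAULT_SIZES,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    metric: Metric | str = Metric.DSC,
    tau_mm: float | None = None,
    staple_config: StapleConfig | None = None,
) -> BootstrapCurve:
    """Bootstrap consensus quality vs the number of nonexperts fused.

    Sizes beyond the available observer count are capped (and deduplicated);
    iterations whose consensus leaves the metric undefined are recorded as
    missing.
    """
    if len(nonexperts) < 2:
        raise ValueError("need >= 2 nonexperts to bootstrap")
    if expert_consensus.is_empty():
        raise ValueError("expert consensus mask is empty")
    metric = Metric(metric)
    n = len(nonexperts)
    capped = []
    for k in sizes:
        kk = min(int(k), n)
        if kk != k:
            import logging

            logging.getLogger("contourbench").info(
                "bootstrap size %d capped to %d available nonexperts", k, n
            )
        if kk not in capped:
            capped.append(kk)
    ordered = sorted(nonexperts, key=lambda c: c.observer_id)
    masks = [c.mask for c in ordered]
    cfg = staple_config or StapleConfig()
    case_id, roi_name = ordered[0].case_id, ordered[0].roi_name

    values: dict[int, np.ndarray] = {}
    for k in capped:
        draws = subset_draws(n, k, n_iter, seed, roi_name)
        out = np.empty(n_iter)
        for it in range(n_iter):
            subset = [masks[j] for j in draws[it]]
            try:
                consensus = STAPLE(subset, config=cfg).fit().consensus_mask
                out[it] = float(
                    compute_metric(metric, consensus, expert_consensus, tau_mm)
                )
            except (UndefinedMetricError, ValueError):
                out[it] = np.nan
        values[k] = out

    thr = float(threshold.value) if isinstance(threshold, AcceptabilityThreshold) else (
        float(threshold) if threshold is not None else None
    )
    max_val: float | None = None
    try:
        full = STAPLE(masks, config=cfg).fit().consensus_mask
        max_val = float(compute_metric(metric, full, expert_consensus, tau_mm))
    except (UndefinedMetricError, ValueError):
        max_val = None
    return BootstrapCurve(
        case_id=case_id,
        roi_name=roi_name,
        metric=metric,
        sizes=tuple(capped),
        values=values,
        threshold=thr,
        max_observer_value=max_val,
        n_iter=n_iter,
        seed=seed,
        tolerance_mm=tau_mm,
    )


def minimum_observers(curve: BootstrapCurve) -> MinObserverResult:
    """Smallest subset size whose bootstrap mean crosses the threshold
    (first crossing, even if the curve later dips); None if never crossed."""
    if curve.threshold is None:
        raise ValueError("curve carries no threshold to cross")
    higher_better = HIGHER_IS_BETTER.get(curve.metric, True)
    k_min = None
    for k in curve.sizes:
        m = curve.mean(k)
        if np.isnan(m):
            continue
        if (m >= curve.threshold) if higher_better else (m <= curve.threshold):
            k_min = k
            break
    if len(curve.sizes) >= 3:
        nonsat, desc = detect_nonsaturation(curve)
    else:
        nonsat, desc = False, "fewer than 3 sizes; saturation not assessed"
    return MinObserverResult(
        case_id=curve.case_id,
        roi_name=curve.roi_name,
        metric=curve.metric,
        k_min=k_min,
        nonsaturating=nonsat,
        description=desc,
    )


def detect_nonsaturation(
    curve: BootstrapCurve, delta: float = 0.01
) -> tuple[bool, str]:
    """Flag curves whose mean at the maximum size falls more than ``delta``
    below the peak mean (performance decays as observers are added)."""
    if len(curve.sizes) < 3:
        raise ValueError("nonsaturation needs >= 3 sizes")
    means = np.array(curve.means())
    ok = ~np.isnan(means)
    if ok.sum() < 3:
        return False, "insufficient defined sizes"
    sizes = np.array(curve.sizes)[ok]
    means = means[ok]
    if not HIGHER_IS_BETTER.get(curve.metric, True):
        means = -means
    peak_i = int(np.argmax(means))
    deficit = float(means[peak_i] - means[-1])
    nonsat = deficit > delta
    desc = (
        f"peak {abs(means[peak_i]):.4f} at size {int(sizes[peak_i])}, "
        f"terminal {abs(means[-1]):.4f} at size {int(sizes[-1])}, "
        f"deficit {deficit:.4f}"
    )
    return nonsat, desc


def plot_bootstrap_curve(curve: BootstrapCurve, path=None):
    """Basic line plot: mean with 95% CI band and reference lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    means = curve.means()
    lo = [curve.ci95(k)[0] for k in curve.sizes]
    hi = [curve.ci95(k)[1] for k in curve.sizes]
    ax.plot(curve.sizes, means, "-o", ms=3, label=f"mean {curve.metric.value}")
    ax.fill_between(curve.sizes, lo, hi, alpha=0.25, label="95% CI")
    if curve.threshold is not None:
        ax.axhline(curve.threshold, color="k", ls=":", label="expert IOV threshold")
    if curve.max_observer_value is not None:
        ax.axhline(curve.max_observer_value, color="gray", ls=":",
                   label="all-nonexpert consensus")
    ax.set_xlabel("number of nonexperts in consensus")
    ax.set_ylabel(curve.metric.value)
    ax.set_title(f"{curve.case_id}/{curve.roi_name}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
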