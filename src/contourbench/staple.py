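"""STAPLE consensus fusion of multiple observer masks.

STAPLE (Simultaneous Truth And Performance Level Estimation) treats each
observer j as a per-voxel Bernoulli rater characterized by a sensitivity
p_j = P(D_ij = 1 | T_i = 1) and specificity q_j = P(D_ij = 0 | T_i = 0),
and estimates the hidden true segmentation T together with all (p_j, q_j)
by expectation-maximization:

E-step::

    a_i = g_i * prod_j [ p_j if D_ij else (1 - p_j) ]
    b_i = (1 - g_i) * prod_j [ q_j if not D_ij else (1 - q_j) ]
    W_i = a_i / (a_i + b_i)          # posterior P(T_i = 1 | D)

M-step::

    p_j = sum_{i: D_ij=1} W_i / sum_i W_i
    q_j = sum_{i: D_ij=0} (1 - W_i) / sum_i (1 - W_i)

Products accumulate in log space; p, q and the prior are clamped to
[eps, 1 - eps].  The prior g is a global scalar (the mean observer
foreground proportion over the analysis region) unless fixed explicitly.
The consensus mask binarizes W at a threshold (default 0.95, the
convention for clinical consensus contours).

Specificity depends on how much background the grid carries, so the EM
runs on the union bounding box of all masks dilated by a margin; the
posterior is re-embedded into the full grid afterwards (W = 0 outside).

The model/results split follows the usual statistical-modelling idiom:
``STAPLE(masks, config).fit()`` returns a :class:`STAPLEResults` carrying
the probability map, the binarized consensus, per-rater performance
estimates and the convergence trace; :func:`staple_em` is the functional
shorthand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import BinaryMask, require_grid_compatible

__all__ = [
    "StapleConfig",
    "CropRecord",
    "STAPLE",
    "STAPLEResults",
    "DegenerateInputError",
    "crop_to_region",
    "staple_em",
    "majority_vote",
]

EPS = 1e-7


class DegenerateInputError(ValueError):
    """All input masks empty, or fewer masks than the algorithm needs."""


@dataclass(frozen=True)
class StapleConfig:
    """Tunables of the EM fit.

    threshold
        Posterior cut for the binarized consensus, in (0, 1).
    max_iterations, convergence_tol
        EM stops when the mean absolute change in W drops below the
        tolerance or the iteration cap is hit.
    init_sensitivity, init_specificity
        Starting values p0, q0 for every rater.
    prior
        ``None`` -> global scalar prior equal to the mean observer
        foreground proportion over the cropped region (computed once);
        a float in (0, 1) -> fixed prior.
    crop_margin_voxels
        Dilation of the union bounding box before the EM runs.
    """

    threshold: float = 0.95
    max_iterations: int = 100
    convergence_tol: float = 1e-6
    init_sensitivity: float = 0.99999
    init_specificity: float = 0.99999
    prior: float | None = None
    crop_margin_voxels: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must lie in (0,1): {self.threshold}")
        for name in ("init_sensitivity", "init_specificity"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1): {v}")
        if self.prior is not None and not 0 < self.prior < 1:
            raise ValueError(f"fixed prior must lie in (0,1): {self.prior}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.crop_margin_voxels < 0:
            raise ValueError("crop_margin_voxels must be >= 0")


@dataclass(frozen=True)
class CropRecord:
    """Bounding box (inclusive start, exclusive stop per axis) within the
    full grid, allowing cropped results to be re-embedded exactly."""

    full_shape: tuple[int, int, int]
    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    def embed(self, cropped: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.full_shape, fill, dtype=cropped.dtype)
        out[self.slices] = cropped
        return out


def crop_to_region(
    masks: list[BinaryMask], margin: int = 5
) -> tuple[list[BinaryMask], CropRecord]:
    """Crop all masks to the union bounding box dilated by ``margin`` voxels,
    clipped to the grid."""
    if not masks:
        raise DegenerateInputError("no masks given")
    require_grid_compatible(*masks)
    union = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        union |= m.voxels
    if not union.any():
        raise DegenerateInputError("all masks are empty")
    idx = np.argwhere(union)
    start = np.maximum(idx.min(axis=0) - margin, 0)
    stop = np.minimum(idx.max(axis=0) + 1 + margin, union.shape)
    record = CropRecord(
        full_shape=union.shape,
        start=tuple(int(x) for x in start),
        stop=tuple(int(x) for x in stop),
    )
    origin0 = np.array(masks[0].origin) + start * np.array(masks[0].spacing)
    cropped = [
        BinaryMask(
            m.voxels[record.slices].copy(), m.spacing, tuple(float(o) for o in origin0)
        )
        for m in masks
    ]
    return cropped, record


class STAPLE:
    """EM model for consensus segmentation from multiple observer masks.

    Parameters
    ----------
    masks
        Grid-compatible observer masks (>= 1; a single mask short-circuits
        to itself with p = q = 1 - eps).
    config
        :class:`StapleConfig`; keyword arguments override single fields.
    rater_ids
        Optional labels for the performance table (default m0, m1, ...).
    """

    def __init__(
        self,
        masks: list[BinaryMask],
        config: StapleConfig | None = None,
        rater_ids: list[str] | None = None,
        **overrides,
    ):
        if not masks:
            raise DegenerateInputError("no masks given")
        require_grid_compatible(*masks)
        if not any(not m.is_empty() for m in masks):
            raise DegenerateInputError("all masks are empty")
        self.masks = list(masks)
        cfg = config or StapleConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        self.config = cfg
        self.rater_ids = (
            list(rater_ids)
            if rater_ids is not None
            else [f"m{j}" for j in range(len(masks))]
        )
        if len(self.rater_ids) != len(self.masks):
            raise ValueError("rater_ids must match number of masks")

    def fit(self) -> "STAPLEResults":
        cfg = self.config
        cropped, record = crop_to_region(self.masks, cfg.crop_margin_voxels)
        geometry = self.masks[0]

        if len(cropped) == 1:
            w_crop = cropped[0].voxels.astype(float)
            return self._results(
                w_crop, record,
                p=np.array([1 - EPS]), q=np.array([1 - EPS]),
                iterations=0, converged=True, trace=[],
            )

        D = np.stack([m.voxels.reshape(-1) for m in cropped])  # (J, N)
        J, N = D.shape
        Df = D.astype(float)

        if cfg.prior is not None:
            gamma = float(cfg.prior)
        else:
            gamma = float(np.clip(Df.mean(), EPS, 1 - EPS))
        log_g1 = np.log(gamma)
        log_g0 = np.log1p(-gamma)

        p = np.full(J, cfg.init_sensitivity)
        q = np.full(J, cfg.init_specificity)
        W = np.full(N, gamma)
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, cfg.max_iterations + 1):
            p = np.clip(p, EPS, 1 - EPS)
            q = np.clip(q, EPS, 1 - EPS)
            # E-step, log-space products over raters
            log_a = log_g1 + Df.T @ np.log(p) + (1 - Df).T @ np.log1p(-p)
            log_b = log_g0 + (1 - Df).T @ np.log(q) + Df.T @ np.log1p(-q)
            if not (np.all(np.isfinite(log_a)) and np.all(np.isfinite(log_b))):
                raise FloatingPointError(
                    f"non-finite EM intermediate at iteration {it}"
                )
            W_new = 1.0 / (1.0 + np.exp(log_b - log_a))
            delta = float(np.abs(W_new - W).mean())
            W = W_new
            trace.append(delta)
            # M-step
            sum_w = W.sum()
            sum_1mw = (1.0 - W).sum()
            p = (Df @ W) / max(sum_w, EPS)
            q = ((1 - Df) @ (1.0 - W)) / max(sum_1mw, EPS)
            if delta < cfg.convergence_tol:
                converged = True
                break

        w_crop = W.reshape(cropped[0].shape)
        return self._results(
            w_crop, record,
            p=np.clip(p, EPS, 1 - EPS), q=np.clip(q, EPS, 1 - EPS),
            iterations=it, converged=converged, trace=trace,
        )

    def _results(self, w_crop, record, p, q, iterations, converged, trace):
        geometry = self.masks[0]
        W_full = record.embed(w_crop.astype(float), fill=0.0)
        consensus = BinaryMask(
            W_full >= self.config.threshold, geometry.spacing, geometry.origin
        )
        return STAPLEResults(
            probability_map=W_full,
            consensus_mask=consensus,
            sensitivity=np.asarray(p, dtype=float),
            specificity=np.asarray(q, dtype=float),
            rater_ids=list(self.rater_ids),
            iterations_run=iterations,
            converged=converged,
            trace=list(trace),
            crop=record,
            config=self.config,
        )


@dataclass(frozen=True)
class STAPLEResults:
    """Fitted consensus: posterior probability map W on the full grid,
    the thresholded consensus mask, and per-rater performance estimates."""

    probability_map: np.ndarray
    consensus_mask: BinaryMask
    sensitivity: np.ndarray
    specificity: np.ndarray
    rater_ids: list[str]
    iterations_run: int
    converged: bool
    trace: list[float] = field(repr=False)
    crop: CropRecord = field(repr=False)
    config: StapleConfig = field(repr=False)

    @property
    def performance(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observer_id": self.rater_ids,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def summary(self) -> str:
        lines = [
            "STAPLE consensus fit",
            "====================",
            f"raters: {len(self.rater_ids)}   threshold: {self.config.threshold}",
            f"iterations: {self.iterations_run}   converged: {self.converged}",
            f"consensus foreground voxels: {self.consensus_mask.n_foreground}",
            "",
            self.performance.to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            ),
        ]
        return "\n".join(lines)


def staple_em(
    masks: list[BinaryMask],
    config: StapleConfig | None = None,
    rater_ids: list[str] | None = None,
    **overrides,
) -> STAPLEResults:
    """Functional shorthand for ``STAPLE(masks, config).fit()``."""
    return STAPLE(masks, config=config, rater_ids=rater_ids, **overrides).fit()


def majority_vote(masks: list[BinaryMask], fraction: float = 0.5) -> BinaryMask:
    """Voxel true iff at least ``fraction`` of the masks mark it true."""
    if not masks:
        raise DegenerateInputError("no masks given")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0,1]: {fraction}")
    require_grid_compatible(*masks)
    counts = np.zeros(masks[0].shape, dtype=np.int32)
    for m in masks:
        counts += m.voxels
    need = fraction * len(masks) * (1 - 1e-12)  # >= fraction, float-safe
    return BinaryMask(counts >= need, masks[0].spacing, masks[0].origin)
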