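"""Synthetic multi-observer contouring cohorts.

Real multi-observer segmentation studies pair a handful of recognized
experts (consistent, low boundary noise) with a larger pool of nonexperts
(noisier, often systematically over-segmenting).  This module emulates
that setting so every pipeline stage is testable without patient data:

* a ground-truth structure per ROI (sphere, ellipsoid, or a smoothed-noise
  blob) on a small anisotropic grid;
* Bernoulli observers — each truth voxel kept with probability p
  (sensitivity) and each background voxel flipped on with probability
  1 - q (specificity), independently per voxel.  This is exactly the
  generative model STAPLE inverts, so EM parameter recovery on these
  cohorts is a closed-loop check;
* boundary observers — the truth's signed distance field perturbed by a
  smooth random field (amplitude sigma mm, Gaussian correlation length
  ``smoothness`` mm) plus a constant signed margin ``bias_mm``
  (positive inflates, negative erodes), then re-thresholded at zero.
  This produces the spatially correlated contouring errors real observers
  make, which the per-voxel Bernoulli model does not.

Everything is reproducible from one master seed; per-observer seed streams
are keyed by (observer index, ROI index) so adding observers never changes
existing observers' masks.

The default study-like preset pairs 8 experts (sigma = 1 mm, unbiased)
with 25 nonexperts (sigma = 2 mm, bias +1.5 mm), both groups with a 2 mm
per-observer style spread, on a CT-like 2 x 1 x 1 mm grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import (
    BinaryMask,
    Cohort,
    CohortManifest,
    Expertise,
    ObserverContour,
    write_mask,
)

__all__ = [
    "TruthShapeConfig",
    "BernoulliNoise",
    "BoundaryNoise",
    "RoiSimConfig",
    "CohortSimConfig",
    "generate_truth_mask",
    "simulate_observer_bernoulli",
    "simulate_observer_boundary",
    "simulate_observer",
    "signed_distance_mm",
    "generate_cohort",
    "study_like_config",
    "bernoulli_config",
]


@dataclass(frozen=True)
class TruthShapeConfig:
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    family: str = "sphere"  # sphere | ellipsoid | blob
    size_mm: tuple[float, float, float] = (12.0, 12.0, 12.0)  # semi-axes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("sphere", "ellipsoid", "blob"):
            raise ValueError(f"unknown shape family: {self.family}")
        extent = np.array(self.grid_shape) * np.array(self.spacing)
        if np.any(2 * np.array(self.size_mm) >= extent):
            raise ValueError(
                f"shape of size {self.size_mm} mm does not fit grid extent "
                f"{tuple(extent)} mm"
            )


@dataclass(frozen=True)
class BernoulliNoise:
    """Per-voxel rater model: sensitivity p, specificity q."""

    p: float = 0.9
    q: float = 0.99

    def __post_init__(self) -> None:
        if not (0 < self.p < 1 and 0 < self.q < 1):
            raise ValueError("p and q must lie in (0,1)")


@dataclass(frozen=True)
class BoundaryNoise:
    """Smooth boundary perturbation: radial scale sigma (mm), signed
    systematic margin bias (mm), correlation length smoothness (mm), and a
    per-observer style offset (mm).

    ``style_sd_mm`` draws one constant margin per observer from
    N(0, style_sd^2) on top of ``bias_mm``: observers differ systematically
    (tight vs generous contouring styles), which drives pairwise
    interobserver disagreement well beyond what zero-mean boundary noise
    alone produces, while group consensus still averages the styles out —
    the regime real expert groups show.
    """

    sigma_mm: float = 1.0
    bias_mm: float = 0.0
    smoothness_mm: float = 6.0
    style_sd_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_mm < 0:
            raise ValueError("sigma_mm must be >= 0")
        if self.smoothness_mm <= 0:
            raise ValueError("smoothness_mm must be > 0")
        if self.style_sd_mm < 0:
            raise ValueError("style_sd_mm must be >= 0")


@dataclass(frozen=True)
class RoiSimConfig:
    roi_name: str
    truth: TruthShapeConfig
    expert_noise: BernoulliNoise | BoundaryNoise
    nonexpert_noise: BernoulliNoise | BoundaryNoise


@dataclass(frozen=True)
class CohortSimConfig:
    case_id: str = "synthetic"
    rois: tuple[RoiSimConfig, ...] = ()
    n_experts: int = 8
    n_nonexperts: int = 25
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 2:
            raise ValueError("n_experts must be >= 2 (thresholds need pairs)")
        if not self.rois:
            raise ValueError("at least one ROI config required")


def _centered_coords_mm(shape, spacing) -> list[np.ndarray]:
    """Per-axis physical coordinates relative to the grid center."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]


def generate_truth_mask(config: TruthShapeConfig) -> BinaryMask:
    """Deterministic single-component ground-truth structure."""
    shape, spacing = config.grid_shape, config.spacing
    zc, yc, xc = np.meshgrid(*_centered_coords_mm(shape, spacing), indexing="ij")
    rng = np.random.default_rng(config.seed)
    if config.family in ("sphere", "ellipsoid"):
        a, b, c = config.size_mm
        if config.family == "sphere":
            a = b = c = config.size_mm[0]
        vox = (zc / a) ** 2 + (yc / b) ** 2 + (xc / c) ** 2 <= 1.0
    else:  # blob: smoothed noise thresholded to a target volume
        noise = rng.standard_normal(shape)
        sigma_vox = [config.size_mm[0] / (2.0 * s) for s in spacing]
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        # envelope keeps the blob central and bounded
        a, b, c = config.size_mm
        envelope = 1.0 - ((zc / a) ** 2 + (yc / b) ** 2 + (xc / c) ** 2)
        fieldv = smooth / max(smooth.std(), 1e-12) + 2.0 * envelope
        target = 0.5 * (4.0 / 3.0) * np.pi * a * b * c / np.prod(spacing)
        thresh = np.quantile(fieldv, 1.0 - target / fieldv.size)
        vox = fieldv >= thresh
    vox = _largest_component(vox)
    if not vox.any():
        raise ValueError("generated truth is empty")
    return BinaryMask(vox, spacing)


def _largest_component(vox: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(vox, structure=ndimage.generate_binary_structure(3, 1))
    if n <= 1:
        return vox
    sizes = ndimage.sum_labels(vox, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def simulate_observer_bernoulli(
    truth: BinaryMask, p: float, q: float, seed: int
) -> BinaryMask:
    """Independent per-voxel Bernoulli observer with sensitivity p and
    specificity q."""
    if not (0 < p < 1 and 0 < q < 1):
        raise ValueError("p and q must lie in (0,1)")
    rng = np.random.default_rng(seed)
    u = rng.random(truth.shape)
    vox = np.where(truth.voxels, u < p, u < (1 - q))
    return BinaryMask(vox, truth.spacing, truth.origin)


def _smooth_field_mm(shape, spacing, smoothness_mm, sigma_mm, rng) -> np.ndarray:
    """White noise convolved with a Gaussian of width smoothness (mm),
    rescaled to standard deviation sigma (mm)."""
    noise = rng.standard_normal(shape)
    sigma_vox = [smoothness_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return smooth * (sigma_mm / sd)


def signed_distance_mm(mask: BinaryMask) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary in mm (positive
    outside, negative inside)."""
    d_out = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.spacing)
    d_in = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing)
    return d_out - d_in


def _boundary_observer_from_sdf(
    truth: BinaryMask, sdf, sigma_mm, bias_mm, smoothness_mm, seed, style_sd_mm
) -> BinaryMask:
    rng = np.random.default_rng(seed)
    style = rng.normal(0.0, style_sd_mm) if style_sd_mm > 0 else 0.0
    fieldv = _smooth_field_mm(truth.shape, truth.spacing, smoothness_mm, sigma_mm, rng)
    vox = sdf <= bias_mm + style + fieldv
    if not vox.any():
        raise ValueError("boundary perturbation erased the mask entirely")
    return BinaryMask(vox, truth.spacing, truth.origin)


def simulate_observer_boundary(
    truth: BinaryMask,
    sigma_mm: float,
    bias_mm: float,
    smoothness_mm: float,
    seed: int,
    style_sd_mm: float = 0.0,
) -> BinaryMask:
    """Perturb the truth boundary with a smooth random field plus a constant
    signed margin, by re-thresholding the signed distance field at zero.

    The total margin is ``bias_mm`` plus, when ``style_sd_mm`` > 0, one
    per-observer draw from N(0, style_sd^2) — a systematic contouring
    style."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if truth.is_empty():
        raise ValueError("truth mask is empty")
    sdf = signed_distance_mm(truth)
    return _boundary_observer_from_sdf(
        truth, sdf, sigma_mm, bias_mm, smoothness_mm, seed, style_sd_mm
    )


def simulate_observer(
    truth: BinaryMask,
    noise: BernoulliNoise | BoundaryNoise,
    seed: int,
    _sdf=None,
) -> BinaryMask:
    if isinstance(noise, BernoulliNoise):
        return simulate_observer_bernoulli(truth, noise.p, noise.q, seed)
    if _sdf is None:
        _sdf = signed_distance_mm(truth)
    return _boundary_observer_from_sdf(
        truth, _sdf, noise.sigma_mm, noise.bias_mm, noise.smoothness_mm, seed,
        noise.style_sd_mm,
    )


def _observer_seed(master_seed: int, obs_index: int, roi_index: int) -> int:
    # stable stream per (observer, roi): adding observers never reseeds others
    ss = np.random.SeedSequence([master_seed, obs_index, roi_index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _build_contours(
    config: CohortSimConfig,
) -> tuple[dict[str, BinaryMask], list[ObserverContour]]:
    truths: dict[str, BinaryMask] = {}
    contours: list[ObserverContour] = []
    for roi_index, roi in enumerate(config.rois):
        truth = generate_truth_mask(roi.truth)
        truths[roi.roi_name] = truth
        # the signed distance field is shared by all boundary observers
        sdf = signed_distance_mm(truth)
        for i in range(config.n_experts):
            seed = _observer_seed(config.master_seed, i, roi_index)
            contours.append(
                ObserverContour(
                    observer_id=f"expert_{i:02d}",
                    expertise=Expertise.EXPERT,
                    case_id=config.case_id,
                    roi_name=roi.roi_name,
                    mask=simulate_observer(truth, roi.expert_noise, seed, _sdf=sdf),
                )
            )
        for i in range(config.n_nonexperts):
            seed = _observer_seed(config.master_seed, 1000 + i, roi_index)
            contours.append(
                ObserverContour(
                    observer_id=f"nonexpert_{i:02d}",
                    expertise=Expertise.NONEXPERT,
                    case_id=config.case_id,
                    roi_name=roi.roi_name,
                    mask=simulate_observer(truth, roi.nonexpert_noise, seed, _sdf=sdf),
                )
            )
    return truths, contours


def generate_cohort(
    config: CohortSimConfig, out_dir: str | Path | None = None
) -> tuple[Cohort, dict[str, BinaryMask], CohortManifest | None]:
    """Simulate a cohort; optionally write masks + manifest + JSON sidecar.

    Returns (cohort, truths-by-roi, manifest or None).  With ``out_dir``
    set, writes one NIfTI per observer mask plus ``truth_<roi>.nii.gz``,
    ``manifest.csv`` and ``sim_config.json``.
    """
    truths, contours = _build_contours(config)
    cohort = Cohort(contours)
    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for c in contours:
            fname = f"{c.case_id}_{c.roi_name}_{c.observer_id}.nii.gz"
            write_mask(c.mask, out_dir / fname)
            entries.append((c.case_id, c.roi_name, c.observer_id, c.expertise,
                            Path(fname)))
        for roi_name, truth in truths.items():
            write_mask(truth, out_dir / f"truth_{roi_name}.nii.gz")
        manifest = CohortManifest(entries=entries)
        manifest.to_csv(out_dir / "manifest.csv")
        with open(out_dir / "sim_config.json", "w") as fh:
            json.dump(asdict(config), fh, indent=2, default=str)
    return cohort, truths, manifest


def study_like_config(
    seed: int = 0,
    n_experts: int = 8,
    n_nonexperts: int = 25,
    grid: tuple[int, int, int] = (36, 64, 64),
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0),
    size_mm: tuple[float, float, float] = (16.0, 16.0, 16.0),
    nonexpert_bias_mm: float = 1.5,
    style_sd_mm: float = 2.0,
    include_unbiased_roi: bool = True,
) -> CohortSimConfig:
    """Study-like preset: few consistent experts vs many noisy nonexperts.

    Geometry mimics a planning-CT organ: a 16 mm-radius structure on a
    2 mm-slice, 1 mm-in-plane grid.  Experts contour with 1 mm boundary
    noise, nonexperts with 2 mm; both groups carry a 2 mm per-observer
    style spread, which puts the expert median pairwise DSC near 0.85-0.9
    (the typical expert interobserver range) while keeping the group
    consensus central.

    Two ROIs by default: one where nonexperts are only noisier, and one
    where they additionally over-segment systematically (+1.5 mm margin)
    — the regime in which nonexpert consensus inflates relative to expert
    consensus.
    """
    expert_noise = BoundaryNoise(
        sigma_mm=1.0, bias_mm=0.0, style_sd_mm=style_sd_mm
    )
    rois = []
    if include_unbiased_roi:
        rois.append(
            RoiSimConfig(
                roi_name="ROI_unbiased",
                truth=TruthShapeConfig(
                    grid_shape=grid, spacing=spacing, size_mm=size_mm, seed=seed
                ),
                expert_noise=expert_noise,
                nonexpert_noise=BoundaryNoise(
                    sigma_mm=2.0, bias_mm=0.0, style_sd_mm=style_sd_mm
                ),
            )
        )
    rois.append(
        RoiSimConfig(
            roi_name="ROI_biased",
            truth=TruthShapeConfig(
                grid_shape=grid, spacing=spacing, size_mm=size_mm, seed=seed + 1
            ),
            expert_noise=expert_noise,
            nonexpert_noise=BoundaryNoise(
                sigma_mm=2.0, bias_mm=nonexpert_bias_mm, style_sd_mm=style_sd_mm
            ),
        )
    )
    return CohortSimConfig(
        case_id="synthetic",
        rois=tuple(rois),
        n_experts=n_experts,
        n_nonexperts=n_nonexperts,
        master_seed=seed,
    )


def bernoulli_config(
    seed: int = 0,
    n_experts: int = 8,
    n_nonexperts: int = 25,
    expert_p: float = 0.95,
    expert_q: float = 0.995,
    nonexpert_p: float = 0.90,
    nonexpert_q: float = 0.99,
    grid: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5),
) -> CohortSimConfig:
    """Bernoulli preset matching the STAPLE generative model exactly."""
    return CohortSimConfig(
        case_id="synthetic",
        rois=(
            RoiSimConfig(
                roi_name="ROI_bernoulli",
                truth=TruthShapeConfig(grid_shape=grid, spacing=spacing, seed=seed),
                expert_noise=BernoulliNoise(p=expert_p, q=expert_q),
                nonexpert_noise=BernoulliNoise(p=nonexpert_p, q=nonexpert_q),
            ),
        ),
        n_experts=n_experts,
        n_nonexperts=n_nonexperts,
        master_seed=seed,
    )
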