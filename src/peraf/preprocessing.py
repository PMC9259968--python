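"""Temporal preprocessing and subject-level quality control.

The pipeline assumes spatially aligned volumes and performs, in order:

1. discard of the initial volumes acquired before magnetisation equilibrium
   (default 15),
2. motion-based subject exclusion (any translation above 1.5 mm or rotation
   above 1.5 degrees on any axis at any timepoint),
3. nuisance regression of the mean white-matter and ventricle signals from
   every voxel series by ordinary least squares,
4. linear detrending.

Regression and detrending centre residuals near zero, which would destroy
the positive-mean denominator PerAF needs, so both steps restore the
original voxel mean to the residual series. Amplitude maps (not the 4D
series) are smoothed with a 3D Gaussian kernel afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .images import AmplitudeMap, BoldImage, voxel_sizes_mm
from .synthetic import FWHM_TO_SIGMA, MotionTrace

DEFAULT_DISCARD = 15
DEFAULT_MAX_TRANSLATION_MM = 1.5
DEFAULT_MAX_ROTATION_DEG = 1.5


@dataclass
class PreprocessReport:
    """Per-subject record of what preprocessing did."""

    subject_id: str
    volumes_discarded: int = 0
    motion_excluded: bool = False
    exclusion_reason: str | None = None
    nuisance_regressors: list = field(default_factory=list)
    voxels_dropped: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def write_reports(reports: list[PreprocessReport], out_dir: str | Path) -> None:
    """Emit the per-subject reports as TSV and JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "preprocess_report.json").write_text(
        json.dumps([r.to_dict() for r in reports], indent=2))
    cols = ["subject_id", "volumes_discarded", "motion_excluded",
            "exclusion_reason", "nuisance_regressors", "voxels_dropped"]
    with open(out_dir / "preprocess_report.tsv", "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            d = r.to_dict()
            d["nuisance_regressors"] = ",".join(d["nuisance_regressors"])
            fh.write("\t".join(str(d[c]) for c in cols) + "\n")


def discard_initial_volumes(bold: BoldImage, k: int = DEFAULT_DISCARD) -> BoldImage:
    """Drop the first ``k`` volumes; the spatial grid is unchanged."""
    if k < 0:
        raise ValidationError(f"k must be >= 0, got {k}")
    if k >= bold.n_timepoints:
        raise ValidationError(
            f"cannot discard {k} volumes from a {bold.n_timepoints}-timepoint image")
    if k == 0:
        return bold
    return BoldImage(data=bold.data[..., k:], affine=bold.affine, tr_s=bold.tr_s,
                     meta={**bold.meta, "volumes_discarded": k})


def motion_exclusion(trace: MotionTrace,
                     max_translation_mm: float = DEFAULT_MAX_TRANSLATION_MM,
                     max_rotation_deg: float = DEFAULT_MAX_ROTATION_DEG
                     ) -> tuple[bool, str | None]:
    """Flag a subject whose head motion exceeds the thresholds.

    Excluded iff any |translation| strictly exceeds ``max_translation_mm``
    on any axis at any timepoint, or any |rotation| strictly exceeds
    ``max_rotation_deg``. The reason names the first violation.
    """
    if trace.n_timepoints < 1:
        raise ValidationError("empty motion trace")
    for kind, values, limit, unit in (
            ("translation", trace.translations, max_translation_mm, "mm"),
            ("rotation", trace.rotations, max_rotation_deg, "deg")):
        over = np.abs(values) > limit
        if over.any():
            t, ax = np.argwhere(over)[0]
            axis = "xyz"[ax]
            return True, (f"{kind} {values[t, ax]:+.3f} {unit} on axis {axis} "
                          f"at timepoint {t} exceeds {limit} {unit}")
    return False, None


def _mask_mean_series(data: np.ndarray, mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != data.shape[:3]:
        raise ValidationError(f"regressor mask '{name}' shape {mask.shape} "
                              f"!= grid {data.shape[:3]}")
    if not mask.any():
        raise ValidationError(f"regressor mask '{name}' is empty")
    return data[mask].mean(axis=0)


def nuisance_regression(bold: BoldImage, regressor_masks: list[np.ndarray],
                        regressor_names: list[str] | None = None) -> BoldImage:
    """Regress mask-mean nuisance series out of every voxel, mean restored.

    The design matrix is [intercept, mean series of each mask]; residuals
    get the original voxel mean added back so the series mean is unchanged.
    A regressor that is constant or collinear with the others is rejected
    by name.
    """
    if regressor_names is None:
        regressor_names = [f"regressor_{i + 1}" for i in range(len(regressor_masks))]
    if len(regressor_names) != len(regressor_masks):
        raise ValidationError("regressor_names and regressor_masks lengths differ")
    data = bold.data.astype(float)
    nt = bold.n_timepoints
    cols = [np.ones(nt)]
    for name, mask in zip(regressor_names, regressor_masks):
        series = _mask_mean_series(data, mask, name)
        if series.std() == 0:
            raise ValidationError(f"nuisance regressor '{name}' is constant")
        cols.append(series)
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValidationError(
            f"nuisance design is rank-deficient (rank {rank} < {design.shape[1]}); "
            f"regressors {regressor_names} are collinear")
    flat = data.reshape(-1, nt).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    out = (resid + flat.mean(axis=0, keepdims=True)).T.reshape(data.shape)
    return BoldImage(data=out, affine=bold.affine, tr_s=bold.tr_s,
                     meta={**bold.meta,
                           "nuisance_regressors": list(regressor_names)})


def linear_detrend(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares line from a series, restoring its mean."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValidationError("linear_detrend needs a 1D series with n >= 3")
    t = np.arange(x.size, dtype=float)
    t = t - t.mean()
    slope = (t @ (x - x.mean())) / (t @ t)
    return x - slope * t


def detrend_bold(bold: BoldImage) -> BoldImage:
    """Voxelwise linear detrend of a 4D image (mean preserved)."""
    data = bold.data.astype(float)
    nt = bold.n_timepoints
    if nt < 3:
        raise ValidationError("detrend needs >= 3 timepoints")
    t = np.arange(nt, dtype=float)
    t = t - t.mean()
    flat = data.reshape(-1, nt)
    slope = (flat - flat.mean(axis=1, keepdims=True)) @ t / (t @ t)
    out = (flat - slope[:, None] * t[None, :]).reshape(data.shape)
    return BoldImage(data=out, affine=bold.affine, tr_s=bold.tr_s,
                     meta={**bold.meta, "detrended": True})


def gaussian_smooth_map(amap: AmplitudeMap, fwhm_mm: float) -> AmplitudeMap:
    """3D Gaussian smoothing of a map (sigma = FWHM / 2.3548 per axis, mm).

    ``fwhm_mm = 0`` is the identity. Boundary handling is reflective, which
    conserves the total of an interior impulse; smoothing is applied to the
    full grid, so mask-edge voxels mix with the 0 sentinel outside the mask
    (negligible for interior masks, documented for transparency).
    """
    if fwhm_mm < 0:
        raise ValidationError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return amap
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes_mm(amap.affine)
    out = gaussian_filter(amap.data, sigma=tuple(sigma_vox), mode="reflect")
    out[~amap.mask] = 0.0
    return AmplitudeMap(data=out, affine=amap.affine, metric=amap.metric,
                        mask=amap.mask, meta={**amap.meta, "smooth_fwhm_mm": fwhm_mm})


def preprocess_subject(bold: BoldImage, subject_id: str,
                       regressor_masks: list[np.ndarray] | None = None,
                       regressor_names: list[str] | None = None,
                       motion: MotionTrace | None = None,
                       k_discard: int = DEFAULT_DISCARD,
                       max_translation_mm: float = DEFAULT_MAX_TRANSLATION_MM,
                       max_rotation_deg: float = DEFAULT_MAX_ROTATION_DEG
                       ) -> tuple[BoldImage | None, PreprocessReport]:
    """Run the temporal pipeline for one subject in the canonical order.

    Order: volume discard -> motion QC -> nuisance regression -> detrend.
    Returns ``(None, report)`` when the subject is motion-excluded.
    """
    report = PreprocessReport(subject_id=subject_id)
    out = discard_initial_volumes(bold, k_discard)
    report.volumes_discarded = k_discard
    if motion is not None:
        excluded, reason = motion_exclusion(motion, max_translation_mm,
                                            max_rotation_deg)
        if excluded:
            report.motion_excluded = True
            report.exclusion_reason = reason
            return None, report
    if regressor_masks:
        names = regressor_names or [f"regressor_{i + 1}"
                                    for i in range(len(regressor_masks))]
        out = nuisance_regression(out, regressor_masks, names)
        report.nuisance_regressors = list(names)
    out = detrend_bold(out)
    return out, report
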