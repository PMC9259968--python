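"""Synthetic two-group BOLD cohorts with planted regional amplitude effects.

The generator emulates the statistical structure of a resting-state
acquisition: every voxel carries a positive baseline intensity, a
band-limited (default 0.01-0.08 Hz) Gaussian fluctuation of known amplitude,
and white measurement noise. The "patient" group has its fluctuation
amplitude multiplied by ``effect_factor`` (< 1 means reduced amplitude)
inside a set of spherical effect ROIs, mimicking regional amplitude
decreases, so every downstream stage can be scored against ground truth.

Band-limited signal is synthesised in the frequency domain: Fourier
coefficients are nonzero only on the rFFT bins inside ``fluct_band_hz`` and
carry independent Gaussian real/imaginary parts (random phases), which gives
exact band control. After optional spatial smoothing of the signal
component, each voxel's series is rescaled so its sample standard deviation
equals the target amplitude exactly; the planted effect is therefore sharp
at the ROI boundary and unbiased by smoothing-induced variance loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import StageError, ValidationError
from .images import BoldImage, save_mask

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

PATIENT = "patient"
CONTROL = "control"

# Default planted-effect spheres (center voxel, radius in voxels) on the
# default 24^3 grid: two disjoint interior spheres of 123 voxels each,
# comfortably above the 40-voxel cluster-size rule used downstream.
_DEFAULT_ROIS = (((7, 8, 12), 3.0), ((16, 15, 12), 3.0))


@dataclass
class SimulationConfig:
    """Ground-truth description of a synthetic cohort.

    Defaults describe the study design the pipeline targets: two groups of
    18 subjects, 245 timepoints at TR = 2 s (230 remain after the 15-volume
    discard), 3 mm voxels on a 24^3 grid, fluctuation amplitude 2% of the
    baseline with white noise at 1%, and a 50% amplitude reduction planted
    in two spherical ROIs for the patient group.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_timepoints: int = 245
    n_per_group: int = 18
    baseline_intensity: float = 1000.0
    fluct_amplitude: float = 20.0
    fluct_band_hz: tuple[float, float] = (0.01, 0.08)
    effect_rois: tuple = _DEFAULT_ROIS
    effect_factor: float = 0.5
    noise_sd: float = 10.0
    spatial_fwhm_mm: float = 6.0
    subject_amp_cv: float = 0.10
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValidationError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        for name in ("voxel_size_mm", "tr_s", "baseline_intensity"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_timepoints < 2:
            raise ValidationError("n_timepoints must be >= 2")
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        if self.fluct_amplitude < 0 or self.noise_sd < 0 or self.spatial_fwhm_mm < 0:
            raise ValidationError("amplitudes, noise_sd and spatial_fwhm_mm must be >= 0")
        low, high = self.fluct_band_hz
        nyquist = 1.0 / (2.0 * self.tr_s)
        if not (0 < low < high <= nyquist + 1e-12):
            raise ValidationError(
                f"fluct_band_hz must satisfy 0 < low < high <= Nyquist "
                f"({nyquist:.4g} Hz for tr_s={self.tr_s}), got {self.fluct_band_hz}")
        if not (0 < self.effect_factor <= 1):
            raise ValidationError(f"effect_factor must be in (0, 1], got {self.effect_factor}")
        if not (0 <= self.subject_amp_cv < 1):
            raise ValidationError("subject_amp_cv must be in [0, 1)")
        self.effect_rois = tuple((tuple(int(c) for c in center), float(radius))
                                 for center, radius in self.effect_rois)
        for center, radius in self.effect_rois:
            if radius < 0:
                raise ValidationError(f"ROI radius must be >= 0, got {radius}")
            for c, s in zip(center, self.grid_shape):
                if c - radius < 0 or c + radius > s - 1:
                    raise ValidationError(
                        f"effect ROI (center={center}, radius={radius}) "
                        f"does not lie fully inside grid {self.grid_shape}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_rois"] = [[list(c), r] for c, r in self.effect_rois]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "effect_rois" in d:
            d["effect_rois"] = tuple((tuple(c), r) for c, r in d["effect_rois"])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "fluct_band_hz" in d:
            d["fluct_band_hz"] = tuple(d["fluct_band_hz"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What was planted: effect ROI masks, expected amplitude ratio, labels."""

    roi_masks: list  # list of binary 3D arrays, pairwise disjoint
    true_amplitude_ratio: float  # expected patient/control PerAF inside ROIs
    labels: list  # (subject_id, group) pairs, in cohort order

    def __post_init__(self):
        total = np.zeros_like(self.roi_masks[0], dtype=int) if self.roi_masks else None
        for m in self.roi_masks:
            total = total + m.astype(int)
        if total is not None and total.max() > 1:
            raise ValidationError("ground-truth ROI masks overlap")


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters: translations (mm), rotations (deg)."""

    translations: np.ndarray  # (n, 3) mm
    rotations: np.ndarray     # (n, 3) degrees

    def __post_init__(self):
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValidationError("translations and rotations must both be (n, 3)")

    @property
    def n_timepoints(self) -> int:
        return self.translations.shape[0]

    def save(self, path) -> Path:
        """Write the 6-column realignment-parameter text convention."""
        path = Path(path)
        np.savetxt(path, np.hstack([self.translations, self.rotations]), fmt="%.6f")
        return path

    @classmethod
    def load(cls, path) -> "MotionTrace":
        arr = np.atleast_2d(np.loadtxt(path))
        if arr.shape[1] != 6:
            raise ValidationError(f"{path}: motion trace must have 6 columns, got {arr.shape[1]}")
        return cls(translations=arr[:, :3], rotations=arr[:, 3:])


def make_sphere_mask(grid_shape, center, radius: float) -> np.ndarray:
    """Binary mask of voxels within Euclidean distance ``radius`` of ``center``.

    The sphere is clipped to the grid; the center voxel must lie inside it.
    """
    if radius < 0:
        raise ValidationError(f"radius must be >= 0, got {radius}")
    grid_shape = tuple(int(s) for s in grid_shape)
    center = tuple(int(c) for c in center)
    for c, s in zip(center, grid_shape):
        if not (0 <= c < s):
            raise ValidationError(f"center {center} outside grid {grid_shape}")
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius ** 2


def effect_roi_masks(config: SimulationConfig) -> list[np.ndarray]:
    return [make_sphere_mask(config.grid_shape, center, radius)
            for center, radius in config.effect_rois]


def band_bins(n_timepoints: int, tr_s: float, band: tuple[float, float]) -> np.ndarray:
    """Indices of rFFT frequency bins inside [low, high], excluding DC."""
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_s)
    low, high = band
    idx = np.flatnonzero((freqs >= low - 1e-12) & (freqs <= high + 1e-12) & (freqs > 0))
    return idx


def _band_limited_unit_signal(rng: np.random.Generator, n_voxels: int,
                              n_timepoints: int, tr_s: float,
                              band: tuple[float, float]) -> np.ndarray:
    """(n_voxels, t) Gaussian series with spectral support only inside band.

    Synthesised as sum_k a_k cos(2 pi f_k t) + b_k sin(2 pi f_k t) over the
    rFFT grid frequencies f_k inside the band, with a_k, b_k iid standard
    normal — i.e. random amplitudes and phases on exactly the in-band bins.
    Scaled by 1/sqrt(n_bins) so each series has unit population variance.
    """
    idx = band_bins(n_timepoints, tr_s, band)
    if idx.size == 0:
        raise ValidationError(
            f"no rFFT bins inside band {band} for n={n_timepoints}, tr={tr_s}s")
    t = np.arange(n_timepoints)[:, None]
    phase = 2.0 * np.pi * t * idx[None, :] / n_timepoints  # (t, bins)
    basis = np.concatenate([np.cos(phase), np.sin(phase)], axis=1)  # (t, 2*bins)
    coeffs = rng.standard_normal((n_voxels, 2 * idx.size))
    return (coeffs @ basis.T) / np.sqrt(idx.size)


def generate_subject_bold(config: SimulationConfig, group: str,
                          subject_seed: int) -> BoldImage:
    """One subject's 4D BOLD volume.

    Every voxel series is ``baseline + band-limited signal + white noise``;
    patient-group voxels inside the effect ROIs have the signal amplitude
    multiplied by ``effect_factor``. Positivity is enforced by construction
    (baseline well above the fluctuation scale); in the unlikely event of a
    non-positive intensity the whole volume is shifted up and the shift is
    recorded in ``meta['positivity_shift']``.
    """
    if group not in (PATIENT, CONTROL):
        raise ValidationError(f"group must be '{PATIENT}' or '{CONTROL}', got {group!r}")
    if config.fluct_amplitude == 0 and config.noise_sd == 0:
        data = np.full((*config.grid_shape, config.n_timepoints),
                       config.baseline_intensity, dtype=np.float32)
        return BoldImage(data=data, affine=config.affine, tr_s=config.tr_s,
                         meta={"group": group, "subject_seed": int(subject_seed),
                               "positivity_shift": 0.0})

    rng = np.random.default_rng(subject_seed)
    nvox = int(np.prod(config.grid_shape))
    nt = config.n_timepoints

    signal = _band_limited_unit_signal(rng, nvox, nt, config.tr_s, config.fluct_band_hz)
    signal = signal.reshape(*config.grid_shape, nt)

    if config.spatial_fwhm_mm > 0:
        sigma_vox = config.spatial_fwhm_mm * FWHM_TO_SIGMA / config.voxel_size_mm
        signal = gaussian_filter(signal, sigma=(sigma_vox,) * 3 + (0,), mode="reflect")

    # Rescale each voxel's series to exactly the target amplitude.
    amp = config.fluct_amplitude
    if config.subject_amp_cv > 0:
        amp = amp * max(0.1, 1.0 + config.subject_amp_cv * rng.standard_normal())
    amp_map = np.full(config.grid_shape, amp)
    if group == PATIENT:
        for m in effect_roi_masks(config):
            amp_map[m] *= config.effect_factor

    if config.fluct_amplitude > 0:
        sd = signal.std(axis=3, keepdims=True)
        sd[sd == 0] = 1.0
        signal = signal / sd * amp_map[..., None]
    else:
        signal = np.zeros_like(signal)

    data = (config.baseline_intensity + signal
            + config.noise_sd * rng.standard_normal(signal.shape))
    shift = 0.0
    dmin = float(data.min())
    if dmin <= 0:
        shift = -dmin + 1e-3
        data = data + shift
    return BoldImage(data=data.astype(np.float32), affine=config.affine,
                     tr_s=config.tr_s,
                     meta={"group": group, "subject_seed": int(subject_seed),
                           "positivity_shift": shift})


def subject_plan(config: SimulationConfig) -> list[tuple[str, str, int]]:
    """Reproducible (subject_id, group, seed) triples for a cohort.

    Per-subject seeds are drawn from a generator seeded with the master
    seed, so cohorts are reproducible and subjects mutually independent.
    """
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * config.n_per_group)
    plan = []
    for i in range(config.n_per_group):
        plan.append((f"sub-P{i + 1:02d}", PATIENT, int(seeds[i])))
    for i in range(config.n_per_group):
        plan.append((f"sub-C{i + 1:02d}", CONTROL, int(seeds[config.n_per_group + i])))
    return plan


def expected_amplitude_ratio(config: SimulationConfig) -> float:
    """Expected patient/control PerAF ratio inside the effect ROIs.

    PerAF is proportional to the total series standard deviation, so the
    planted ratio is sqrt((f^2 a^2 + s^2) / (a^2 + s^2)) with f the effect
    factor, a the fluctuation amplitude and s the white-noise SD.
    """
    a2, s2 = config.fluct_amplitude ** 2, config.noise_sd ** 2
    return float(np.sqrt((config.effect_factor ** 2 * a2 + s2) / (a2 + s2)))


def generate_cohort(config: SimulationConfig,
                    out_dir: str | Path | None = None
                    ) -> tuple[list[BoldImage], GroundTruth]:
    """Generate a full two-group cohort; optionally write it to disk.

    When ``out_dir`` is given, writes one ``.nii.gz`` per subject, a
    ``labels.tsv`` (``subject_id<TAB>group``), the ground-truth ROI masks
    and the configuration JSON alongside.
    """
    plan = subject_plan(config)
    images = [generate_subject_bold(config, group, seed) for _, group, seed in plan]
    truth = GroundTruth(
        roi_masks=effect_roi_masks(config),
        true_amplitude_ratio=expected_amplitude_ratio(config),
        labels=[(sid, group) for sid, group, _ in plan],
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
            for (sid, group, _), img in zip(plan, images):
                img.save(out_dir / f"{sid}_bold.nii.gz")
            with open(out_dir / "labels.tsv", "w") as fh:
                fh.write("subject_id\tgroup\n")
                for sid, group, _ in plan:
                    fh.write(f"{sid}\t{group}\n")
            for i, m in enumerate(truth.roi_masks, start=1):
                save_mask(m, config.affine, out_dir / f"effect_roi_{i}.nii.gz")
            (out_dir / "simulation_config.json").write_text(
                json.dumps(config.to_dict(), indent=2, sort_keys=True))
        except OSError as exc:
            raise StageError("simulate",
                             f"failed to write cohort under {out_dir}: {exc}") from exc
    return images, truth


def generate_motion_trace(n_timepoints: int, max_disp_mm: float | None = 1.0,
                          seed: int = 0, step_mm: float = 0.05,
                          step_deg: float = 0.02) -> MotionTrace:
    """Bounded random-walk head-motion trace.

    Translations (mm) and rotations (degrees) follow independent Gaussian
    random walks starting at zero. When ``max_disp_mm`` is given it is a
    hard cap: translations are clipped to ``[-max_disp_mm, +max_disp_mm]``
    (rotations to the same numeric bound in degrees). Pass ``None`` to
    leave the walk unconstrained, e.g. to generate deliberate violations.
    """
    if n_timepoints < 1:
        raise ValidationError("n_timepoints must be >= 1")
    rng = np.random.default_rng(seed)
    trans = np.cumsum(rng.standard_normal((n_timepoints, 3)) * step_mm, axis=0)
    rot = np.cumsum(rng.standard_normal((n_timepoints, 3)) * step_deg, axis=0)
    trans[0] = 0.0
    rot[0] = 0.0
    if max_disp_mm is not None:
        if max_disp_mm < 0:
            raise ValidationError("max_disp_mm must be >= 0")
        trans = np.clip(trans, -max_disp_mm, max_disp_mm)
        rot = np.clip(rot, -max_disp_mm, max_disp_mm)
    return MotionTrace(translations=trans, rotations=rot)
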