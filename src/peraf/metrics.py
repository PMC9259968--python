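"""Amplitude metrics for BOLD time series: PerAF, ALFF and fALFF.

PerAF (percent amplitude of fluctuation) of a series x_1..x_n with mean mu is

    PerAF = 100 * (1/n) * sum_i |x_i - mu| / mu        (mu = mean of x)

i.e. the mean absolute deviation expressed as a percentage of the mean
signal. It is invariant under positive rescaling of the series (c*x gives
the same PerAF), which makes it comparable across voxels and scanners with
arbitrary BOLD units; it is deliberately *not* invariant under additive
offsets, because mu sits in the denominator.

ALFF is the mean of the single-sided amplitude spectrum over a low-frequency
band (default 0.01-0.08 Hz); it scales linearly with the signal. fALFF is
the band amplitude sum divided by the total amplitude sum over all nonzero
frequencies, a scale-free fraction in [0, 1]. Spectra use the plain
periodogram (no tapering) so closed-form sinusoid checks hold exactly.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .images import AmplitudeMap, BoldImage
from .synthetic import band_bins

DEFAULT_BAND_HZ = (0.01, 0.08)

#: Voxels whose mean falls at or below eps * cohort baseline are excluded
#: from PerAF maps instead of producing huge percentages.
MEAN_EPS = 1e-6


def _validate_series(x: np.ndarray, min_n: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError(f"time series must be 1D, got {x.ndim}D")
    if x.size < min_n:
        raise ValidationError(f"need at least {min_n} timepoints, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("time series contains non-finite values")
    return x


def peraf_series(x: np.ndarray) -> float:
    """PerAF (%) of one time series; requires a strictly positive mean."""
    x = _validate_series(x)
    mu = x.mean()
    if mu <= 0:
        raise ValidationError(
            f"PerAF undefined for non-positive series mean (mu={mu:.6g})")
    return float(100.0 * np.mean(np.abs(x - mu)) / mu)


def peraf_map(bold: BoldImage, mask: np.ndarray) -> AmplitudeMap:
    """Voxelwise PerAF over a binary mask.

    Voxels whose temporal mean is not strictly positive (relative to the
    in-mask median mean, tolerance :data:`MEAN_EPS`) are dropped from the
    output mask and counted in ``meta['voxels_dropped']``.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != bold.grid_shape:
        raise ValidationError(
            f"mask shape {mask.shape} != BOLD grid {bold.grid_shape}")
    if not mask.any():
        raise ValidationError("empty analysis mask")
    data = bold.data.astype(float)
    mu = data.mean(axis=3)
    baseline = float(np.median(mu[mask]))
    ok = mask & (mu > MEAN_EPS * max(baseline, 1.0))
    dropped = int(mask.sum() - ok.sum())
    out = np.zeros(bold.grid_shape)
    mad = np.mean(np.abs(data - mu[..., None]), axis=3)
    out[ok] = 100.0 * mad[ok] / mu[ok]
    return AmplitudeMap(data=out, affine=bold.affine, metric="PerAF", mask=ok,
                        meta={"voxels_dropped": dropped,
                              "n_timepoints": bold.n_timepoints})


def mean_scale_map(amap: AmplitudeMap, mask: np.ndarray | None = None) -> AmplitudeMap:
    """Divide a map by its within-mask global mean (mPerAF-style scaling).

    The output has within-mask mean exactly 1.
    """
    mask = amap.mask if mask is None else (np.asarray(mask).astype(bool) & amap.mask)
    if not mask.any():
        raise ValidationError("empty mask for mean scaling")
    gmean = float(amap.data[mask].mean())
    if gmean <= 0:
        raise ValidationError(
            f"global within-mask mean must be positive, got {gmean:.6g}")
    out = np.zeros_like(amap.data)
    out[mask] = amap.data[mask] / gmean
    metric = "mPerAF" if amap.metric in ("PerAF", "mPerAF") else amap.metric
    return AmplitudeMap(data=out, affine=amap.affine, metric=metric, mask=mask,
                        meta={**amap.meta, "global_mean": gmean})


def amplitude_spectrum(x: np.ndarray, tr_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum of a demeaned series.

    Returns (frequencies, amplitudes) over the positive rFFT bins; a pure
    sinusoid of amplitude A at a grid frequency maps to amplitude A at its
    bin (interior bins; the Nyquist bin is not doubled).
    """
    x = _validate_series(x, min_n=4)
    if not tr_s > 0:
        raise ValidationError(f"tr_s must be positive, got {tr_s}")
    n = x.size
    coeffs = np.fft.rfft(x - x.mean())
    amps = 2.0 * np.abs(coeffs) / n
    if n % 2 == 0:
        amps[-1] /= 2.0  # Nyquist bin is not shared between two sides
    freqs = np.fft.rfftfreq(n, d=tr_s)
    return freqs[1:], amps[1:]


def alff_series(x: np.ndarray, tr_s: float,
                band: tuple[float, float] = DEFAULT_BAND_HZ) -> float:
    """Mean amplitude across frequency bins inside ``band`` (signal units)."""
    x = _validate_series(x, min_n=4)
    idx = band_bins(x.size, tr_s, band)
    if idx.size == 0:
        freqs = np.fft.rfftfreq(x.size, d=tr_s)
        raise ValidationError(
            f"band {band} contains no frequency bins; grid spacing is "
            f"{freqs[1]:.5g} Hz for n={x.size}, tr={tr_s}s")
    freqs, amps = amplitude_spectrum(x, tr_s)
    in_band = np.isin(np.arange(1, x.size // 2 + 1), idx)
    return float(amps[in_band].mean())


def falff_series(x: np.ndarray, tr_s: float,
                 band: tuple[float, float] = DEFAULT_BAND_HZ) -> float:
    """Band amplitude sum / total amplitude sum, in [0, 1].

    A constant series has zero total amplitude and no defined fraction;
    that is an error rather than 0/0.
    """
    x = _validate_series(x, min_n=4)
    idx = band_bins(x.size, tr_s, band)
    if idx.size == 0:
        raise ValidationError(f"band {band} contains no frequency bins for n={x.size}")
    _, amps = amplitude_spectrum(x, tr_s)
    total = amps.sum()
    if total <= 0:
        raise ValidationError("fALFF undefined: series has zero total amplitude")
    in_band = np.isin(np.arange(1, x.size // 2 + 1), idx)
    return float(amps[in_band].sum() / total)


def amplitude_map(bold: BoldImage, mask: np.ndarray, metric: str = "PerAF",
                  band: tuple[float, float] = DEFAULT_BAND_HZ) -> AmplitudeMap:
    """Whole-brain map for any supported metric (PerAF, ALFF, fALFF)."""
    if metric == "PerAF":
        return peraf_map(bold, mask)
    if metric not in ("ALFF", "fALFF"):
        raise ValidationError(f"unsupported map metric {metric!r}")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != bold.grid_shape:
        raise ValidationError(
            f"mask shape {mask.shape} != BOLD grid {bold.grid_shape}")
    if not mask.any():
        raise ValidationError("empty analysis mask")
    fn = alff_series if metric == "ALFF" else falff_series
    out = np.zeros(bold.grid_shape)
    ok = mask.copy()
    data = bold.data.astype(float)
    for ijk in np.argwhere(mask):
        series = data[tuple(ijk)]
        try:
            out[tuple(ijk)] = fn(series, bold.tr_s, band)
        except ValidationError:
            ok[tuple(ijk)] = False
    return AmplitudeMap(data=out, affine=bold.affine, metric=metric, mask=ok,
                        meta={"band_hz": list(band),
                              "voxels_dropped": int(mask.sum() - ok.sum())})
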