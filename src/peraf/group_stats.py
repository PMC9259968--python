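"""Voxelwise two-sample contrasts with cluster-extent multiple-comparison
correction.

The contrast is a pooled-variance two-sample t-test at every mask voxel
(df = n1 + n2 - 2). Suprathreshold voxels (two-tailed, voxel-level p) are
grouped into connected components — positive and negative tails separately,
under 6-, 18- or 26-connectivity — and a cluster is declared significant by
extent: either the fixed replication rule (size strictly greater than 40
voxels) or a Monte-Carlo (AlphaSim-style) minimum cluster size that
controls the family-wise probability of any false-positive cluster.

The Monte-Carlo null simulates smooth Gaussian random fields on the
analysis mask, thresholds them at the same voxel-level p, records the
maximum cluster size per iteration, and returns the (1 - alpha) quantile
plus one as the minimum significant size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .errors import ValidationError
from .images import AmplitudeMap, save_mask
from .synthetic import FWHM_TO_SIGMA

#: connectivity name -> scipy generate_binary_structure rank
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}

DEFAULT_VOXEL_P = 0.01
DEFAULT_CLUSTER_ALPHA = 0.05
DEFAULT_MIN_CLUSTER_VOXELS = 40
DEFAULT_CONNECTIVITY = 18


def connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValidationError(
            f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}, "
            f"got {connectivity}")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


@dataclass
class StatMap:
    """Voxelwise t-statistics for group A minus group B."""

    t: np.ndarray
    df: int
    mask: np.ndarray
    affine: np.ndarray
    n_a: int
    n_b: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.t.shape != self.mask.shape:
            raise ValidationError("t-map and mask shapes differ")
        if self.df != self.n_a + self.n_b - 2:
            raise ValidationError(
                f"df must equal n_a + n_b - 2 = {self.n_a + self.n_b - 2}, got {self.df}")


@dataclass
class ClusterRecord:
    """One suprathreshold connected component."""

    label: int
    size: int
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_t: float
    direction: str  # 'a>b' (positive t) or 'a<b' (negative t)
    significant: bool = False


@dataclass
class ClusterTable:
    """Clusters sorted by size (descending), plus threshold provenance."""

    records: list
    voxel_p: float
    t_threshold: float
    connectivity: int
    df: int
    size_threshold: int | None = None  # significance rule actually applied

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    @property
    def significant(self) -> list:
        return [r for r in self.records if r.significant]

    def to_rows(self) -> list[dict]:
        return [{
            "label": r.label, "size": r.size,
            "peak_x_mm": r.peak_mm[0], "peak_y_mm": r.peak_mm[1],
            "peak_z_mm": r.peak_mm[2], "peak_t": r.peak_t,
            "direction": r.direction, "significant": r.significant,
        } for r in self.records]

    def save(self, path_prefix: str | Path) -> None:
        """Write the table as TSV (Table-2-shaped columns) and JSON."""
        prefix = Path(path_prefix)
        rows = self.to_rows()
        cols = ["label", "peak_x_mm", "peak_y_mm", "peak_z_mm", "size",
                "peak_t", "direction", "significant"]
        with open(prefix.parent / (prefix.name + ".tsv"), "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        payload = {"voxel_p": self.voxel_p, "t_threshold": self.t_threshold,
                   "connectivity": self.connectivity, "df": self.df,
                   "size_threshold": self.size_threshold, "clusters": rows}
        (prefix.parent / (prefix.name + ".json")).write_text(
            json.dumps(payload, indent=2))


@dataclass
class MonteCarloSpec:
    """Monte-Carlo correction parameters.

    When ``group_sizes`` is set, each null iteration simulates that many
    smoothed Gaussian subject maps and thresholds their pooled two-sample
    t-field — the exact null of the contrast being corrected. Without it,
    single smoothed Gaussian z-fields are used (the classic AlphaSim
    model), which is slightly conservative at low degrees of freedom.
    """

    n_iterations: int = 1000
    fwhm_mm: float = 6.0
    seed: int = 0
    group_sizes: tuple[int, int] | None = None


@dataclass
class CorrectionSpec:
    """Cluster-extent correction: fixed minimum size OR Monte-Carlo.

    Exactly one mode is active. In fixed mode a cluster is significant iff
    its size strictly exceeds ``min_cluster_voxels`` (the ">40 voxels"
    replication rule). In Monte-Carlo mode the simulation returns the
    minimum significant size m and a cluster is significant iff size >= m.
    """

    voxel_p: float = DEFAULT_VOXEL_P
    cluster_alpha: float = DEFAULT_CLUSTER_ALPHA
    min_cluster_voxels: int | None = DEFAULT_MIN_CLUSTER_VOXELS
    monte_carlo: MonteCarloSpec | None = None
    connectivity: int = DEFAULT_CONNECTIVITY

    def __post_init__(self):
        if not (0 < self.voxel_p < 1) or not (0 < self.cluster_alpha < 1):
            raise ValidationError("voxel_p and cluster_alpha must lie in (0, 1)")
        if (self.min_cluster_voxels is None) == (self.monte_carlo is None):
            raise ValidationError(
                "exactly one of min_cluster_voxels / monte_carlo must be set")
        connectivity_structure(self.connectivity)


def voxelwise_ttest(group_a: list[AmplitudeMap], group_b: list[AmplitudeMap],
                    mask: np.ndarray | None = None) -> StatMap:
    """Pooled-variance two-sample t (A minus B) at every mask voxel.

    Zero-variance voxels get t = 0 and are counted in
    ``meta['zero_variance_voxels']`` rather than producing infinities.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 maps")
    maps = list(group_a) + list(group_b)
    ref = maps[0]
    for m in maps[1:]:
        if m.grid_shape != ref.grid_shape or not np.allclose(m.affine, ref.affine):
            raise ValidationError("all maps must share one grid and affine")
    if mask is None:
        mask = np.logical_and.reduce([m.mask for m in maps])
    mask = np.asarray(mask).astype(bool)
    a = np.stack([m.data[mask] for m in group_a])
    b = np.stack([m.data[mask] for m in group_b])
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    diff = a.mean(axis=0) - b.mean(axis=0)
    ss = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    pooled = ss / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    tvals = np.zeros_like(diff)
    nz = se > 0
    tvals[nz] = diff[nz] / se[nz]
    out = np.zeros(ref.grid_shape)
    out[mask] = tvals
    return StatMap(t=out, df=df, mask=mask, affine=ref.affine, n_a=na, n_b=nb,
                   meta={"zero_variance_voxels": int((~nz).sum())})


def _label_tail(tail_mask: np.ndarray, structure: np.ndarray) -> tuple[np.ndarray, int]:
    return ndimage.label(tail_mask, structure=structure)


def extract_clusters(stat: StatMap, voxel_p: float = DEFAULT_VOXEL_P,
                     connectivity: int = DEFAULT_CONNECTIVITY) -> ClusterTable:
    """Connected components of suprathreshold voxels, per tail.

    The voxel threshold is the two-tailed critical t for ``voxel_p`` at the
    map's df. Positive and negative tails are labelled separately; the
    table is sorted by size descending. An empty table is a valid result.
    """
    if not (0 < voxel_p < 1):
        raise ValidationError(f"voxel_p must lie in (0, 1), got {voxel_p}")
    structure = connectivity_structure(connectivity)
    t_crit = float(stats.t.ppf(1.0 - voxel_p / 2.0, stat.df))
    records = []
    next_label = 1
    for sign, direction in ((1, "a>b"), (-1, "a<b")):
        tail = stat.mask & (sign * stat.t > t_crit)
        labelled, n = _label_tail(tail, structure)
        for comp in range(1, n + 1):
            idx = np.argwhere(labelled == comp)
            tvals = stat.t[tuple(idx.T)]
            peak_pos = int(np.argmax(np.abs(tvals)))
            ijk = tuple(int(v) for v in idx[peak_pos])
            mm = tuple(float(v) for v in (stat.affine @ np.array([*ijk, 1.0]))[:3])
            records.append(ClusterRecord(
                label=next_label, size=int(idx.shape[0]), peak_ijk=ijk,
                peak_mm=mm, peak_t=float(tvals[peak_pos]), direction=direction))
            next_label += 1
    records.sort(key=lambda r: (-r.size, r.label))
    for new_label, r in enumerate(records, start=1):
        r.label = new_label
    return ClusterTable(records=records, voxel_p=voxel_p, t_threshold=t_crit,
                        connectivity=connectivity, df=stat.df)


def max_null_cluster_size(z: np.ndarray, mask: np.ndarray, z_crit: float,
                          structure: np.ndarray) -> int:
    """Largest suprathreshold cluster (either tail) of one null field."""
    best = 0
    for sign in (1, -1):
        labelled, n = ndimage.label(mask & (sign * z > z_crit), structure=structure)
        if n:
            best = max(best, int(np.bincount(labelled.ravel())[1:].max()))
    return best


def monte_carlo_cluster_threshold(mask: np.ndarray, fwhm_mm: float,
                                  voxel_p: float = DEFAULT_VOXEL_P,
                                  cluster_alpha: float = DEFAULT_CLUSTER_ALPHA,
                                  n_iterations: int = 1000, seed: int = 0,
                                  voxel_size_mm: float = 1.0,
                                  connectivity: int = DEFAULT_CONNECTIVITY,
                                  group_sizes: tuple[int, int] | None = None) -> int:
    """AlphaSim-style minimum significant cluster size.

    Each iteration draws a smooth null statistic field on the grid,
    thresholds both tails at the two-tailed critical value for
    ``voxel_p``, and records the largest cluster within the mask. The
    returned size is the smallest integer m whose empirical null
    exceedance probability P(max cluster >= m) is at most
    ``cluster_alpha``: a cluster at least this large occurs under the
    null with probability about ``cluster_alpha``.

    With ``group_sizes=(n_a, n_b)`` the null field is the pooled
    two-sample t-map of n_a + n_b independent smoothed Gaussian subject
    maps (thresholded at the t quantile for df = n_a + n_b - 2), matching
    the statistic being corrected; otherwise a single smoothed Gaussian
    field thresholded at the normal quantile is used.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValidationError("empty mask for Monte-Carlo threshold")
    if n_iterations < 100:
        raise ValidationError("n_iterations must be >= 100 for a usable quantile")
    if fwhm_mm < 0 or voxel_size_mm <= 0:
        raise ValidationError("fwhm_mm must be >= 0 and voxel_size_mm > 0")
    structure = connectivity_structure(connectivity)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    rng = np.random.default_rng(seed)

    def smooth_field() -> np.ndarray:
        z = rng.standard_normal(mask.shape)
        if sigma_vox > 0:
            z = ndimage.gaussian_filter(z, sigma=sigma_vox, mode="reflect")
        return z / z[mask].std()

    if group_sizes is None:
        crit = float(stats.norm.ppf(1.0 - voxel_p / 2.0))

        def null_field() -> np.ndarray:
            return smooth_field()
    else:
        na, nb = (int(v) for v in group_sizes)
        if na < 2 or nb < 2:
            raise ValidationError("group_sizes entries must both be >= 2")
        df = na + nb - 2
        crit = float(stats.t.ppf(1.0 - voxel_p / 2.0, df))

        def null_field() -> np.ndarray:
            maps = np.stack([smooth_field() for _ in range(na + nb)])
            a, b = maps[:na], maps[na:]
            diff = a.mean(axis=0) - b.mean(axis=0)
            ss = (((a - a.mean(axis=0)) ** 2).sum(axis=0)
                  + ((b - b.mean(axis=0)) ** 2).sum(axis=0))
            se = np.sqrt(ss / df * (1.0 / na + 1.0 / nb))
            se[se == 0] = np.inf
            return diff / se

    maxima = np.empty(n_iterations, dtype=int)
    for i in range(n_iterations):
        maxima[i] = max_null_cluster_size(null_field(), mask, crit, structure)
    # smallest m with empirical P(max >= m) <= alpha
    for m in range(1, int(maxima.max()) + 2):
        if np.mean(maxima >= m) <= cluster_alpha:
            return m
    return int(maxima.max()) + 1  # pragma: no cover


def significant_clusters(table: ClusterTable, spec: CorrectionSpec,
                         mask: np.ndarray | None = None,
                         voxel_size_mm: float = 1.0) -> ClusterTable:
    """Mark the clusters that survive the extent rule in ``spec``.

    Non-significant clusters are kept in the table for transparency.
    """
    if spec.monte_carlo is not None:
        if mask is None:
            raise ValidationError("Monte-Carlo correction needs the analysis mask")
        m = monte_carlo_cluster_threshold(
            mask, spec.monte_carlo.fwhm_mm, spec.voxel_p, spec.cluster_alpha,
            spec.monte_carlo.n_iterations, spec.monte_carlo.seed,
            voxel_size_mm=voxel_size_mm, connectivity=spec.connectivity,
            group_sizes=spec.monte_carlo.group_sizes)
        size_threshold = m - 1  # significant iff size >= m  <=>  size > m - 1
    else:
        size_threshold = int(spec.min_cluster_voxels)
    records = [ClusterRecord(**{**r.__dict__, "significant": r.size > size_threshold})
               for r in table.records]
    return ClusterTable(records=records, voxel_p=table.voxel_p,
                        t_threshold=table.t_threshold,
                        connectivity=table.connectivity, df=table.df,
                        size_threshold=size_threshold)


def cluster_label_map(table: ClusterTable, stat: StatMap,
                      significant_only: bool = True) -> np.ndarray:
    """Labelled 3D volume of (significant) clusters, 0 = background."""
    structure = connectivity_structure(table.connectivity)
    out = np.zeros(stat.t.shape, dtype=int)
    wanted = table.significant if significant_only else table.records
    for r in wanted:
        sign = 1 if r.direction == "a>b" else -1
        tail = stat.mask & (sign * stat.t > table.t_threshold)
        labelled, _ = ndimage.label(tail, structure=structure)
        comp = labelled[r.peak_ijk]
        out[labelled == comp] = r.label
    return out


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a & b).sum() / denom)


def save_cluster_masks(table: ClusterTable, stat: StatMap,
                       out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = cluster_label_map(table, stat, significant_only=False)
    save_mask(labels > 0, stat.affine, out_dir / "clusters_all.nii.gz")
    sig = cluster_label_map(table, stat, significant_only=True)
    import nibabel as nib
    nib.save(nib.Nifti1Image(sig.astype(np.int16), stat.affine),
             str(out_dir / "clusters_significant_labels.nii.gz"))
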