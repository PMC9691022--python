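"""Operations on 3D statistic maps: thresholding, overlap coefficients,
box-shaped regions of interest, voxel-wise ICC and pattern correlation.

Maps are plain 3D arrays wrapped in :class:`StatMap`. Synthetic maps use
voxel-index geometry (the grid origin sits at the centre of the first voxel
and axes are scaled by the voxel size); affines read from real NIfTI files
are passed through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StatMap",
    "BinaryMask",
    "RegionICC",
    "threshold_map",
    "jaccard",
    "dice",
    "box_roi",
    "voxelwise_icc",
    "pattern_correlation",
    "to_nifti",
    "load_stat_map",
]


@dataclass
class StatMap:
    """A 3D statistic grid (t or beta values) with its degrees of freedom."""

    data: np.ndarray
    df: int | None = None
    kind: str = "t"
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("StatMap data must be a 3D array")
        if self.kind not in ("t", "beta"):
            raise ValueError("kind must be 't' or 'beta'")
        if self.kind == "t" and self.df is not None and self.df <= 0:
            raise ValueError("df must be positive for t-maps")


@dataclass
class BinaryMask:
    """Boolean voxel grid, shape-compatible with its source map."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("BinaryMask data must be a 3D array")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def threshold_map(m: StatMap, p: float = 0.01, side: str = "upper") -> BinaryMask:
    """Binarize a t-map at an uncorrected significance level.

    ``side='upper'`` keeps voxels whose t-value exceeds the one-sided upper
    critical value of the t distribution with ``m.df`` degrees of freedom
    (activation contrasts); ``side='two'`` thresholds ``|t|`` at level p/2.
    """
    if m.kind != "t":
        raise ValueError("only t-maps can be thresholded; beta maps are for correlation")
    if m.df is None:
        raise ValueError("t-map has no degrees of freedom recorded")
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    if side == "upper":
        crit = stats.t.ppf(1.0 - p, m.df)
        mask = m.data > crit
    elif side == "two":
        crit = stats.t.ppf(1.0 - p / 2.0, m.df)
        mask = np.abs(m.data) > crit
    else:
        raise ValueError("side must be 'upper' or 'two'")
    return BinaryMask(mask, voxel_size=m.voxel_size, affine=m.affine)


def _check_shapes(a: BinaryMask, b: BinaryMask) -> None:
    if a.data.shape != b.data.shape:
        raise ValueError(f"mask shapes differ: {a.data.shape} vs {b.data.shape}")


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """|A∩B| / |A∪B|; defined as 0 when both masks are empty."""
    _check_shapes(a, b)
    union = np.logical_or(a.data, b.data).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(a.data, b.data).sum()
    return float(inter / union)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """2|A∩B| / (|A| + |B|); defined as 0 when both masks are empty."""
    _check_shapes(a, b)
    total = a.data.sum() + b.data.sum()
    if total == 0:
        return 0.0
    inter = np.logical_and(a.data, b.data).sum()
    return float(2.0 * inter / total)


def box_roi(
    center_mm: tuple[float, float, float],
    size_mm: tuple[float, float, float],
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> BinaryMask:
    """Axis-aligned box ROI in millimetre coordinates on an index-geometry grid.

    A voxel belongs to the box when its centre lies in the half-open interval
    [center - size/2, center + size/2) on every axis, so a 20 x 16 x 16 mm box
    on a 2 mm grid covers exactly 10 x 8 x 8 voxels.
    """
    mask = np.ones(shape, dtype=bool)
    for ax, (c, s, n, vs) in enumerate(zip(center_mm, size_mm, shape, voxel_size)):
        coords = np.arange(n) * vs
        inside = (coords >= c - s / 2.0) & (coords < c + s / 2.0)
        sl = [np.newaxis] * 3
        sl[ax] = slice(None)
        mask &= inside[tuple(sl)]
    if not mask.any():
        warnings.warn("box ROI does not intersect the grid; mask is empty", stacklevel=2)
    return BinaryMask(mask, voxel_size=voxel_size)


@dataclass
class RegionICC:
    """Mean voxel-wise ICC over a region."""

    mean_icc: float
    n_voxels: int
    n_skipped: int
    icc_type: str
    per_voxel: np.ndarray = field(repr=False, default=None)


def voxelwise_icc(
    maps_t0,
    maps_t1,
    region: BinaryMask,
    icc_type: str = "abs",
) -> RegionICC:
    """ICC of every region voxel across participants (T0 vs T1), averaged.

    ``maps_t0``/``maps_t1`` are sequences of :class:`StatMap` (or 3D arrays)
    aligned by participant. Degenerate voxels with no variance at all are
    skipped and counted.
    """
    x0 = np.stack([m.data if isinstance(m, StatMap) else np.asarray(m) for m in maps_t0])
    x1 = np.stack([m.data if isinstance(m, StatMap) else np.asarray(m) for m in maps_t1])
    if x0.shape != x1.shape:
        raise ValueError("T0 and T1 map stacks differ in shape")
    n = x0.shape[0]
    if n < 3:
        raise ValueError("voxelwise ICC requires at least 3 participants")
    sel = region.data
    if x0.shape[1:] != sel.shape:
        raise ValueError("region shape does not match map shape")
    a = x0[:, sel]  # (n, V)
    b = x1[:, sel]
    k = 2
    grand = (a + b).mean(axis=0) / k
    rm = (a + b) / k  # row (subject) means, (n, V)
    cm = np.stack([a.mean(axis=0), b.mean(axis=0)])  # (2, V)
    ssr = k * ((rm - grand) ** 2).sum(axis=0)
    ssc = n * ((cm - grand) ** 2).sum(axis=0)
    sst = ((a - grand) ** 2).sum(axis=0) + ((b - grand) ** 2).sum(axis=0)
    sse = np.maximum(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if icc_type == "con":
        denom = msr + (k - 1) * mse
    elif icc_type == "abs":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        raise ValueError("icc_type must be 'abs' or 'con'")
    degenerate = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (msr - mse) / denom
    est[degenerate] = np.nan
    valid = ~degenerate
    if not valid.any():
        raise ValueError("all region voxels are degenerate")
    return RegionICC(
        mean_icc=float(est[valid].mean()),
        n_voxels=int(valid.sum()),
        n_skipped=int(degenerate.sum()),
        icc_type=icc_type,
        per_voxel=est,
    )


def pattern_correlation(a: StatMap, b: StatMap, region: BinaryMask | None = None) -> float:
    """Pearson correlation of two maps' voxel values over a region."""
    if a.data.shape != b.data.shape:
        raise ValueError("maps differ in shape")
    if region is None:
        x, y = a.data.ravel(), b.data.ravel()
    else:
        if region.data.shape != a.data.shape:
            raise ValueError("region shape does not match map shape")
        if not region.data.any():
            raise ValueError("region is empty")
        x, y = a.data[region.data], b.data[region.data]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pattern correlation undefined: zero variance in region")
    return float(stats.pearsonr(x, y)[0])


def to_nifti(m: StatMap | BinaryMask):
    """Convert to a :class:`nibabel.Nifti1Image`; df/kind go into descrip."""
    import nibabel as nib

    affine = m.affine
    if affine is None:
        affine = np.diag(list(m.voxel_size) + [1.0])
    if isinstance(m, BinaryMask):
        img = nib.Nifti1Image(m.data.astype(np.uint8), affine)
    else:
        img = nib.Nifti1Image(m.data.astype(np.float32), affine)
        img.header["descrip"] = f"kind={m.kind};df={m.df}".encode()
    return img


def load_stat_map(path, df: int | None = None, kind: str | None = None) -> StatMap:
    """Read a statistic map from NIfTI; df/kind fall back to the descrip field."""
    import nibabel as nib

    img = nib.load(str(path))
    descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="replace")
    meta = dict(p.split("=", 1) for p in descrip.split(";") if "=" in p)
    if kind is None:
        kind = meta.get("kind", "t")
    if df is None and meta.get("df") not in (None, "None"):
        df = int(meta["df"])
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return StatMap(np.asarray(img.dataobj, dtype=float), df=df, kind=kind,
                   voxel_size=vs, affine=np.asarray(img.affine))
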