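"""Image chain from grey-level microCT volume to a clean bone mask.

The chain mirrors standard whole-bone micro-FE practice:

1. fit a plane to the (embedding-block) support surface,
2. rigidly rotate the volume so that plane becomes horizontal, resampling
   with a Lanczos-3 windowed-sinc interpolator,
3. smooth with a 3×3×3 Gaussian kernel (σ = 0.65 voxels),
4. threshold at the midpoint of the background and bone histogram peaks,
5. keep only the largest 6-connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import VoxelImage

__all__ = [
    "FittedPlane",
    "ThresholdResult",
    "fit_plane",
    "align_to_axis",
    "gaussian_filter",
    "histogram_threshold",
    "segment",
    "connectivity_filter",
]


@dataclass(frozen=True)
class FittedPlane:
    """Total-least-squares plane through a point cloud."""

    normal: np.ndarray  # unit 3-vector, z-component >= 0
    point: np.ndarray  # a point on the plane (the centroid), mm
    rms_residual: float  # orthogonal-distance RMS, mm


@dataclass(frozen=True)
class ThresholdResult:
    """Bimodal-histogram segmentation threshold.

    ``threshold`` is exactly the midpoint of the two peak grey levels.
    """

    threshold: float
    background_peak: float
    bone_peak: float


def fit_plane(points) -> FittedPlane:
    """Fit a plane by total least squares (orthogonal regression).

    The normal is the singular vector of the centered points with the
    smallest singular value; it is oriented to have a non-negative
    z-component.  Requires >= 3 non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear (or coincident) points: the two smallest singular values
    # both vanish and the plane is not unique
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("points are collinear; plane is undefined")
    normal = vt[2]
    if normal[2] < 0 or (normal[2] == 0 and (normal[0] < 0 or (normal[0] == 0 and normal[1] < 0))):
        normal = -normal
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return FittedPlane(normal=normal, point=centroid, rms_residual=rms)


def _rotation_to_z(normal):
    """Rotation matrix taking ``normal`` to +z about axis normal×z."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(n, z)
    s = np.linalg.norm(axis)
    c = float(n @ z)
    if s < 1e-15:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _lanczos3_weights(frac):
    """Lanczos-3 kernel weights at offsets −2−f … 3−f, normalized to sum 1.

    Normalization restores the partition of unity the truncated sinc loses,
    which makes the interpolator exactly constant-preserving; at integer
    offsets the kernel is 1 at 0 and 0 elsewhere, so grid points reproduce
    exactly.
    """
    a = 3.0
    offsets = np.arange(-2, 4)[None, :] - frac[:, None]  # (P, 6)
    x = np.clip(np.abs(offsets), 1e-12, None)
    w = np.where(
        np.abs(offsets) < 1e-12,
        1.0,
        a * np.sin(np.pi * x) * np.sin(np.pi * x / a) / (np.pi ** 2 * x ** 2),
    )
    w[np.abs(offsets) >= a] = 0.0
    return w / w.sum(axis=1, keepdims=True)


def align_to_axis(img: VoxelImage, plane: FittedPlane) -> VoxelImage:
    """Rotate the volume so the fitted plane becomes horizontal.

    The rigid rotation takes ``plane.normal`` to (0,0,1) about the axis
    normal×z, pivoting at the volume center; the rotated volume is
    resampled onto the original grid with a separable, weight-normalized
    Lanczos-3 kernel (exact at grid points, so an already-horizontal plane
    is a no-op, and exactly constant-preserving).  Samples whose 6×6×6
    support falls outside the source domain use edge replication, and
    sample centers outside the domain are filled with the image's
    background mode (most frequent value of a 256-bin histogram).
    """
    R = _rotation_to_z(plane.normal)
    if np.allclose(R, np.eye(3), atol=1e-12):
        return img.with_data(img.data.copy())

    counts, edges = np.histogram(img.data, bins=256)
    m = int(np.argmax(counts))
    in_bin = (img.data >= edges[m]) & (img.data <= edges[m + 1])
    fill = float(np.median(img.data[in_bin]))

    shape = img.shape
    center = (np.asarray(shape) - 1) / 2.0  # rotation pivot, index units
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    src = (idx - center) @ R + center  # inverse rotation of output coords

    base = np.floor(src).astype(np.int64)
    frac = src - base

    wx = _lanczos3_weights(frac[:, 0])
    wy = _lanczos3_weights(frac[:, 1])
    wz = _lanczos3_weights(frac[:, 2])

    data = np.asarray(img.data, dtype=float)
    out = np.zeros(len(src))
    # separable gather: z first (collapse 6 -> 1), then y, then x
    for dx in range(6):
        ix = np.clip(base[:, 0] - 2 + dx, 0, shape[0] - 1)
        acc_x = np.zeros(len(src))
        for dy in range(6):
            iy = np.clip(base[:, 1] - 2 + dy, 0, shape[1] - 1)
            acc_y = np.zeros(len(src))
            for dz in range(6):
                iz = np.clip(base[:, 2] - 2 + dz, 0, shape[2] - 1)
                acc_y += wz[:, dz] * data[ix, iy, iz]
            acc_x += wy[:, dy] * acc_y
        out += wx[:, dx] * acc_x

    outside = (
        (src[:, 0] < -0.5) | (src[:, 0] > shape[0] - 0.5)
        | (src[:, 1] < -0.5) | (src[:, 1] > shape[1] - 0.5)
        | (src[:, 2] < -0.5) | (src[:, 2] > shape[2] - 0.5)
    )
    out[outside] = fill
    return img.with_data(out.reshape(shape))


def gaussian_kernel_3x3x3(sigma: float = 0.65) -> np.ndarray:
    """Sampled (not integrated) 3×3×3 Gaussian kernel, normalized to sum 1."""
    ax = np.array([-1.0, 0.0, 1.0])
    g1 = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    return k / k.sum()


def gaussian_filter(img: VoxelImage, sigma: float = 0.65) -> VoxelImage:
    """Denoise with the 3×3×3 sampled Gaussian (σ in voxels, default 0.65),
    reflect padding at the borders."""
    k = gaussian_kernel_3x3x3(sigma)
    data = ndimage.convolve(img.data.astype(float), k, mode="reflect")
    return img.with_data(data)


def histogram_threshold(
    img: VoxelImage,
    n_bins: int = 256,
    smooth_bins: int = 5,
    min_peak_separation_bins: int = 10,
) -> ThresholdResult:
    """Single-level threshold at the midpoint of the background and bone
    histogram peaks.

    The histogram uses ``n_bins`` equal bins between the image minimum and
    maximum, smoothed by a ``smooth_bins``-wide moving average.  The two
    most populous local maxima separated by at least
    ``min_peak_separation_bins`` bins are taken as the background (lower
    grey) and bone (higher grey) peaks.  A unimodal histogram raises, with
    the advice to supply a manual threshold.
    """
    vals = np.asarray(img.data, dtype=float).ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise ValueError(
            "image is constant; histogram has a single peak — "
            "supply a manual threshold"
        )
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(counts.astype(float), kernel, mode="same")

    # strict-neighbor local maxima (plateaus count via >=)
    is_max = np.zeros(n_bins, dtype=bool)
    is_max[1:-1] = (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] >= smooth[2:]) & (
        (smooth[1:-1] > smooth[:-2]) | (smooth[1:-1] > smooth[2:])
    )
    is_max[0] = smooth[0] > smooth[1]
    is_max[-1] = smooth[-1] > smooth[-2]
    peak_bins = np.nonzero(is_max)[0]

    # greedy prominence pick: highest peaks first, enforcing separation
    order = peak_bins[np.argsort(smooth[peak_bins])[::-1]]
    chosen = []
    for b in order:
        if all(abs(b - c) >= min_peak_separation_bins for c in chosen):
            chosen.append(int(b))
        if len(chosen) == 2:
            break
    if len(chosen) < 2:
        raise ValueError(
            "histogram is not bimodal; supply a manual threshold instead"
        )
    # genuine bimodality has a valley between the peaks; spurious secondary
    # maxima in the flank of a single mode do not
    b_lo, b_hi = sorted(chosen)
    valley = smooth[b_lo: b_hi + 1].min()
    if valley > 0.5 * min(smooth[b_lo], smooth[b_hi]):
        raise ValueError(
            "histogram is not bimodal (no valley between candidate peaks); "
            "supply a manual threshold instead"
        )
    g1, g2 = sorted(centers[b] for b in chosen)
    return ThresholdResult(
        threshold=float(0.5 * (g1 + g2)),
        background_peak=float(g1),
        bone_peak=float(g2),
    )


def segment(img: VoxelImage, threshold: float) -> VoxelImage:
    """Binary mask of voxels with value >= threshold (inclusive, so thin
    structures at exactly the threshold survive)."""
    return img.with_data(
        (np.asarray(img.data) >= threshold).astype(np.uint8), value_kind="mask"
    )


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # faces only


def connectivity_filter(mask: VoxelImage) -> VoxelImage:
    """Keep only the largest 6-connected (face-connected) component.

    Ties between equally large components are broken by the component
    containing the lowest minimum linear voxel index.  Isolated fragments
    cannot transfer load, so removing them also guarantees a non-singular
    stiffness matrix.
    """
    if mask.value_kind != "mask":
        raise ValueError(f"expected a mask image, got {mask.value_kind!r}")
    data = mask.data.astype(bool)
    if not data.any():
        raise ValueError("empty mask")
    labels, n = ndimage.label(data, structure=_STRUCT6)
    if n == 1:
        return mask.with_data(data.astype(np.uint8))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = np.nonzero(sizes == sizes.max())[0] + 1
    if len(best) > 1:
        flat = labels.ravel()
        first = {
            lab: int(np.nonzero(flat == lab)[0][0]) for lab in best
        }
        keep = min(best, key=lambda lab: first[lab])
    else:
        keep = best[0]
    return mask.with_data((labels == keep).astype(np.uint8))
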