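"""Isolation of arterial voxels from 4D-MRA difference images.

The cascade: pair-wise label/control subtraction, brain masking, slice-wise
multi-scale Frangi vesselness in the three cartesian planes, per-plane
binarization and voxel-wise intersection, morphological area opening, and
an edge-preserving joint bilateral smoothing of the difference series that
uses the vessel mask as its guide image (so smoothing does not bleed across
the vessel/background boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from skimage import feature, morphology
from sklearn.base import BaseEstimator

PLANES = ("XY", "YZ", "ZX")
#: slice axis (the axis iterated over) for each cartesian plane
_PLANE_AXIS = {"XY": 2, "YZ": 0, "ZX": 1}

#: FWHM of a Gaussian in units of its sd
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class InflowSeries:
    """Label-control difference series with acquisition timing and geometry.

    ``data`` is (x, y, z, t) in arbitrary signal units; ``times`` are the
    label durations (ms) of the volumes; ``voxel_dims`` the voxel pitch in
    mm; slice index 0 is the most caudal acquired slice.
    """

    data: np.ndarray
    times: np.ndarray
    voxel_dims: tuple[float, float, float]
    brain_mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.times = np.asarray(self.times, float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[3] != self.times.size:
            raise ValueError(
                f"time axis length {self.data.shape[3]} != "
                f"{self.times.size} configured times"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def temporal_max(self) -> np.ndarray:
        """Per-voxel maximum over time: the brightest appearance of each
        vessel, used as the input to the vesselness filter."""
        return self.data.max(axis=3)

    def with_data(self, data: np.ndarray) -> "InflowSeries":
        return InflowSeries(data=data, times=self.times,
                           voxel_dims=self.voxel_dims,
                           brain_mask=self.brain_mask, affine=self.affine)


@dataclass
class FrangiParams:
    """Parameters of the slice-wise 2D Frangi vesselness filter.

    ``scales`` are Gaussian sds in pixels; ``beta`` the blobness
    sensitivity; ``c`` the structureness sensitivity in signal units, or
    ``"auto"`` for half the maximum Hessian norm per slice.
    """

    scales: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0)
    beta: float = 0.5
    c: float | str = "auto"
    bright_on_dark: bool = True

    def __post_init__(self) -> None:
        if len(self.scales) == 0 or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be non-empty and positive")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class VesselMask:
    """Binary arterial-voxel mask plus the provenance that produced it."""

    mask: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.mask, dtype=dtype)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def pairwise_subtract(label, control, times=None, voxel_dims=(1.0, 1.0, 1.0),
                      brain_mask=None, affine=None) -> InflowSeries:
    """Control-minus-label difference series, one volume per time point.

    The sign convention makes inflowing labelled blood positive.
    """
    label = np.asarray(label, float)
    control = np.asarray(control, float)
    if label.shape != control.shape:
        raise ValueError(
            f"label shape {label.shape} != control shape {control.shape}"
        )
    if times is None:
        raise ValueError("times must be provided")
    times = np.asarray(times, float)
    if times.size != label.shape[3]:
        raise ValueError(
            f"time axis (axis 3) has {label.shape[3]} volumes but "
            f"{times.size} times were configured"
        )
    return InflowSeries(data=control - label, times=times,
                        voxel_dims=tuple(voxel_dims), brain_mask=brain_mask,
                        affine=affine)


def _frangi_2d(image, params: FrangiParams) -> np.ndarray:
    """2D Frangi vesselness of one slice, maximum over scales.

    Hessian eigenvalues are computed with Gaussian derivatives at each
    scale and normalised by sigma^2 so responses are comparable across
    scales (a Gaussian ridge of sd t then responds maximally near
    sigma = sqrt(2) t).  With ``|l1| <= |l2|``, vesselness is 0 where
    l2 >= 0 (bright ridges curve downward), else
    ``exp(-R_B^2/2 beta^2) * (1 - exp(-S^2/2 c^2))`` with blobness
    R_B = l1/l2 and structureness S = sqrt(l1^2 + l2^2);
    c="auto" uses half the maximum S of the slice per scale.
    """
    sign = 1.0 if params.bright_on_dark else -1.0
    lam = []
    for sigma in params.scales:
        H = feature.hessian_matrix(image * sign, sigma=sigma,
                                   use_gaussian_derivatives=True)
        ev = feature.hessian_matrix_eigvals(H) * sigma**2
        small = np.abs(ev[0]) <= np.abs(ev[1])
        lam.append((np.where(small, ev[0], ev[1]),
                    np.where(small, ev[1], ev[0])))
    if params.c == "auto":
        # one c per slice across all scales (half the maximum Hessian norm)
        smax2 = max(float((l1**2 + l2**2).max()) for l1, l2 in lam)
        if smax2 == 0:
            return np.zeros(image.shape)
        c = 0.5 * np.sqrt(smax2)
    else:
        c = float(params.c)
    best = np.zeros(image.shape)
    for lam1, lam2 in lam:
        s2 = lam1**2 + lam2**2
        with np.errstate(invalid="ignore", divide="ignore"):
            rb2 = np.where(lam2 != 0, (lam1 / lam2) ** 2, 0.0)
        v = np.exp(-rb2 / (2.0 * params.beta**2)) * (
            1.0 - np.exp(-s2 / (2.0 * c**2)))
        v[lam2 >= 0] = 0.0
        np.maximum(best, v, out=best)
    return best


def frangi_vesselness_slicewise(volume, plane: str,
                                params: FrangiParams | None = None
                                ) -> np.ndarray:
    """2D Frangi vesselness applied slice-by-slice in one cartesian plane.

    Each 2D slice is filtered at every scale (scale-normalised Hessian
    eigenvalues; blobness and structureness weighting per Frangi) and the
    per-pixel maximum over scales is returned.  Output values lie in
    [0, 1]; constant slices map to 0.
    """
    params = params or FrangiParams()
    volume = np.asarray(volume, float)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume must be finite-valued")
    if plane not in _PLANE_AXIS:
        raise ValueError(f"plane must be one of {PLANES}")
    axis = _PLANE_AXIS[plane]
    out = np.zeros_like(volume)
    for k in range(volume.shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = k
        image = volume[tuple(sl)]
        if np.ptp(image) == 0:
            continue
        out[tuple(sl)] = _frangi_2d(image, params)
    return np.clip(out, 0.0, 1.0)


def binarize_and_intersect(responses, threshold: float = 0.05,
                           provenance: dict | None = None) -> VesselMask:
    """Binarize each directional vesselness field and intersect.

    Each field is thresholded at ``threshold`` times its own maximum; the
    final mask keeps only voxels common to all directional masks.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    responses = [np.asarray(r, float) for r in responses]
    mask = None
    for r in responses:
        m = r >= threshold * r.max() if r.max() > 0 else np.zeros(r.shape, bool)
        mask = m if mask is None else (mask & m)
    prov = dict(provenance or {})
    prov["threshold"] = threshold
    return VesselMask(mask=mask, provenance=prov)


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def area_open(mask, min_size: int, connectivity: int = 26) -> np.ndarray:
    """Remove connected components smaller than ``min_size`` voxels.

    ``connectivity`` is the 3D neighbourhood (6, 18 or 26); components with
    at least ``min_size`` voxels are untouched.  Anti-extensive and
    idempotent.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    mask = np.asarray(mask, bool)
    # remove_small_objects' max_size removes components <= its value, so
    # components with >= min_size voxels are kept
    return morphology.remove_small_objects(
        mask, max_size=min_size - 1,
        connectivity=_CONNECTIVITY_RANK[connectivity],
    )


def _spatial_kernels(fwhm_voxels, radii):
    sigmas = [f / FWHM_PER_SIGMA for f in fwhm_voxels]
    return [
        np.exp(-0.5 * (np.arange(-r, r + 1) / s) ** 2)
        for r, s in zip(radii, sigmas)
    ]


def guided_bilateral_smooth(series: InflowSeries, guide,
                            fwhm_voxels=(5.0, 5.0, 4.0),
                            range_sigma: float = 0.25) -> InflowSeries:
    """Joint (guided) bilateral smoothing of the difference series.

    Per time point, each voxel is replaced by a normalised weighted average
    of its neighbours; the spatial weight is a Gaussian with per-axis sd
    ``fwhm / (2 sqrt(2 ln 2))`` and the range weight is a Gaussian on the
    *guide* image intensity difference, so values do not mix across guide
    edges (here: the vessel-mask boundary).  Border weights are
    renormalised, making the filter an exact identity on constant inputs.
    """
    if any(f <= 0 for f in fwhm_voxels):
        raise ValueError("fwhm_voxels must be positive")
    guide = np.asarray(guide, float)
    if guide.shape != series.shape:
        raise ValueError("guide grid differs from series grid")
    data = series.data
    radii = [max(1, int(np.ceil(2.0 * f / FWHM_PER_SIGMA)))
             for f in fwhm_voxels]
    kernels = _spatial_kernels(fwhm_voxels, radii)

    guide_vals = np.unique(guide)
    if guide_vals.size <= 2:
        out = _bilateral_binary(data, guide, kernels, range_sigma)
    else:
        out = _bilateral_general(data, guide, kernels, radii, range_sigma)
    return series.with_data(out)


def _sep_blur(vol, kernels):
    """Separable correlation with border renormalisation (4D: last axis t)."""
    num = vol
    for ax, k in enumerate(kernels):
        num = ndimage.correlate1d(num, k, axis=ax, mode="constant", cval=0.0)
    return num


def _bilateral_binary(data, guide, kernels, range_sigma):
    """Fast path for a binary guide.

    With a two-level guide the range weight takes only two values: 1 for
    neighbours in the same guide class as the centre and
    ``exp(-dv^2 / (2 range_sigma^2))`` otherwise, so the filter reduces to
    two separable Gaussian blurs blended per class.
    """
    levels = np.unique(guide)
    if levels.size == 1:
        alpha = 1.0
        in_class = np.ones(guide.shape, bool)
    else:
        dv = float(levels[1] - levels[0])
        alpha = np.exp(-0.5 * (dv / range_sigma) ** 2) if range_sigma > 0 else 0.0
        in_class = guide == levels[1]
    w1 = in_class.astype(float)[..., None]
    w0 = 1.0 - w1
    num1 = _sep_blur(data * w1, kernels)
    num0 = _sep_blur(data * w0, kernels)
    den1 = _sep_blur(np.broadcast_to(w1, data.shape).copy(), kernels)
    den0 = _sep_blur(np.broadcast_to(w0, data.shape).copy(), kernels)
    # centre in class 1: same-class weight on num1, alpha on num0 (and v.v.)
    num_c1 = num1 + alpha * num0
    den_c1 = den1 + alpha * den0
    num_c0 = num0 + alpha * num1
    den_c0 = den0 + alpha * den1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(w1 > 0, num_c1 / den_c1, num_c0 / den_c0)
    return out


def _bilateral_general(data, guide, kernels, radii, range_sigma):
    """Direct windowed evaluation for an arbitrary grayscale guide."""
    num = np.zeros_like(data)
    den = np.zeros(data.shape[:3])
    inv2rs2 = 0.0 if range_sigma <= 0 else 0.5 / range_sigma**2
    shape = data.shape[:3]
    for dx in range(-radii[0], radii[0] + 1):
        for dy in range(-radii[1], radii[1] + 1):
            for dz in range(-radii[2], radii[2] + 1):
                ws = (kernels[0][dx + radii[0]] * kernels[1][dy + radii[1]]
                      * kernels[2][dz + radii[2]])
                src = tuple(
                    slice(max(0, -d), min(s, s - d))
                    for d, s in zip((dx, dy, dz), shape)
                )
                dst = tuple(
                    slice(max(0, d), min(s, s + d))
                    for d, s in zip((dx, dy, dz), shape)
                )
                dg = guide[src] - guide[dst]
                w = ws * np.exp(-(dg * dg) * inv2rs2)
                num[dst] += w[..., None] * data[src]
                den[dst] += w
    return num / den[..., None]


def kernel_extent_mm(fwhm_voxels, voxel_dims) -> tuple[float, ...]:
    """Physical extent (mm) of a smoothing kernel stated in voxels."""
    f = np.asarray(fwhm_voxels, float)
    d = np.asarray(voxel_dims, float)
    if np.any(f <= 0) or np.any(d <= 0):
        raise ValueError("entries must be positive")
    return tuple(float(v) for v in f * d)


def isolate_vessels(label, control, brain_mask=None, times=None,
                    voxel_dims=(1.0, 1.0, 1.0),
                    frangi: FrangiParams | None = None,
                    threshold: float = 0.05, min_size: int = 50,
                    connectivity: int = 26,
                    fwhm_voxels=(5.0, 5.0, 4.0), range_sigma: float = 0.25,
                    affine=None) -> tuple[VesselMask, InflowSeries]:
    """Run the full vessel-isolation cascade.

    Subtraction, brain masking, temporal-maximum image, slice-wise Frangi in
    three planes, per-plane binarization with intersection, area opening,
    and guided bilateral smoothing of the difference series using the final
    mask as guide.  Returns the final mask (with full parameter provenance)
    and the smoothed series.
    """
    series = pairwise_subtract(label, control, times=times,
                               voxel_dims=voxel_dims, brain_mask=brain_mask,
                               affine=affine)
    frangi = frangi or FrangiParams()
    data = series.data
    if brain_mask is not None:
        brain_mask = np.asarray(brain_mask, bool)
        data = data * brain_mask[..., None]
        series = series.with_data(data)
    tmax = series.temporal_max()
    responses = [
        frangi_vesselness_slicewise(tmax, plane, frangi) for plane in PLANES
    ]
    prov = {
        "frangi_scales": list(frangi.scales),
        "beta": frangi.beta,
        "c": frangi.c,
        "min_size": min_size,
        "connectivity": connectivity,
        "fwhm_voxels": list(fwhm_voxels),
        "range_sigma": range_sigma,
        "kernel_extent_mm": list(kernel_extent_mm(fwhm_voxels, voxel_dims)),
    }
    vmask = binarize_and_intersect(responses, threshold, provenance=prov)
    mask = vmask.mask
    if brain_mask is not None:
        mask = mask & brain_mask
    mask = area_open(mask, min_size=min_size, connectivity=connectivity)
    final = VesselMask(mask=mask, provenance=vmask.provenance)
    smoothed = guided_bilateral_smooth(series, mask.astype(float),
                                       fwhm_voxels=fwhm_voxels,
                                       range_sigma=range_sigma)
    return final, smoothed


class VesselIsolator(BaseEstimator):
    """sklearn-style transformer wrapping the vessel-isolation cascade.

    ``fit(label, control)`` runs the cascade and stores the final vessel
    mask as ``mask_``; ``transform`` returns the smoothed difference
    series.  All cascade parameters are constructor arguments and are
    recorded in ``mask_.provenance``.
    """

    def __init__(self, times=None, voxel_dims=(1.0, 1.0, 1.0),
                 frangi_scales=(1.0, 1.5, 2.0, 3.0), beta=0.5, c="auto",
                 threshold=0.05, min_size=50, connectivity=26,
                 fwhm_voxels=(5.0, 5.0, 4.0), range_sigma=0.25):
        self.times = times
        self.voxel_dims = voxel_dims
        self.frangi_scales = frangi_scales
        self.beta = beta
        self.c = c
        self.threshold = threshold
        self.min_size = min_size
        self.connectivity = connectivity
        self.fwhm_voxels = fwhm_voxels
        self.range_sigma = range_sigma

    def fit(self, label, control=None, brain_mask=None):
        mask, series = isolate_vessels(
            label, control, brain_mask=brain_mask, times=self.times,
            voxel_dims=self.voxel_dims,
            frangi=FrangiParams(scales=tuple(self.frangi_scales),
                                beta=self.beta, c=self.c),
            threshold=self.threshold, min_size=self.min_size,
            connectivity=self.connectivity, fwhm_voxels=self.fwhm_voxels,
            range_sigma=self.range_sigma,
        )
        self.mask_ = mask
        self.series_ = series
        return self

    def transform(self, label=None, control=None) -> InflowSeries:
        if not hasattr(self, "mask_"):
            raise RuntimeError("VesselIsolator is not fitted")
        return self.series_

    def fit_transform(self, label, control=None, brain_mask=None):
        return self.fit(label, control, brain_mask=brain_mask).transform()
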