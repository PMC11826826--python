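"""Per-voxel fitting of the two-piece saturation inflow model.

The difference signal at a vessel voxel is zero until the leading edge of
the labelled bolus arrives, then rises along a saturation curve::

    f(t) = 0                       for t <= b
    f(t) = m * t / (h + t)         for t >  b   ("literal" branch)
    f(t) = m * (t-b) / (h + t-b)   for t >  b   ("continuous" branch)

The breakpoint ``b`` is the macrovascular arterial transit time (mATT);
``m`` is the saturation level the signal approaches at late label durations
and ``h`` the time at which the saturating branch reaches ``m/2``.  Both
branch forms are exposed: the literal form is discontinuous at the
breakpoint, the continuous form shifts the saturation origin to ``b``.

Fitting profiles the breakpoint on a dense grid with an inner least-squares
fit of ``(m, h)``, then polishes the best candidate.  With the literal
branch the residuals depend on ``b`` only through which samples fall in the
zero piece, so ``b`` is identifiable only up to the interval between
adjacent sample times; ties in the error are broken toward the smallest
(earliest) breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

STATUS_OK = 0
STATUS_BELOW_NOISE = 1
STATUS_NO_BREAKPOINT = 2
STATUS_FAIL = 3
STATUS_NAMES = {
    STATUS_OK: "ok",
    STATUS_BELOW_NOISE: "below_noise",
    STATUS_NO_BREAKPOINT: "no_breakpoint",
    STATUS_FAIL: "fail",
}


def piecewise_saturation(t, b, m, h, variant: str = "literal"):
    """Evaluate the two-piece saturation model.

    Parameters broadcast; ``t`` in ms.  Returns 0 for ``t <= b`` and the
    saturating branch for ``t > b``.
    """
    t = np.asarray(t, float)
    b = np.asarray(b, float)
    m = np.asarray(m, float)
    h = np.asarray(h, float)
    if np.any(h <= 0):
        raise ValueError("h must be > 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        if variant == "literal":
            branch = m * t / (h + t)
        elif variant == "continuous":
            # the pre-arrival piece masks any t <= b lane where h + (t-b)
            # would be non-positive
            dt = t - b
            branch = m * dt / (h + dt)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        out = np.where(t > b, branch, 0.0)
    return out if out.ndim else float(out)


@dataclass
class SaturationFit:
    """Result of a single-voxel fit."""

    b: float
    m: float
    h: float
    sse: float
    r2: float
    status: int

    @property
    def status_name(self) -> str:
        return STATUS_NAMES[self.status]

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


@dataclass
class FitOptions:
    """Options for the breakpoint fit.

    ``b_max`` defaults to the last sample time plus the final inter-sample
    gap, allowing arrival later than the last label duration; ``grid_step``
    is the breakpoint candidate spacing (ms) before polishing;
    ``noise_floor`` marks curves whose maximum never exceeds it as
    below-noise.
    """

    variant: str = "literal"
    b_max: float | None = None
    grid_step: float = 10.0
    noise_floor: float = 0.0
    h_bounds: tuple[float, float] = (1.0, 2.0e4)
    n_h_grid: int = 80

    def resolve_b_max(self, times: np.ndarray) -> float:
        if self.b_max is not None:
            return float(self.b_max)
        return float(times[-1] + (times[-1] - times[-2]))


def _design_tensor(times, b_grid, h_grid, variant):
    """Saturation-branch basis g(b, h, t), zero on the pre-arrival piece.

    The basis does not depend on the data, so it is built once per
    (times, grid) combination and shared by every voxel.
    """
    t = times[None, None, :]                          # (1,1,T)
    bg = b_grid[:, None, None]                        # (B,1,1)
    hg = h_grid[None, :, None]                        # (1,H,1)
    if variant == "literal":
        g = np.broadcast_to(t / (hg + t),
                            (len(b_grid), len(h_grid), times.size)).copy()
    else:
        dt = t - bg
        g = np.zeros((len(b_grid), len(h_grid), times.size))
        np.divide(dt, hg + dt, out=g, where=dt > 0)
    g[~np.broadcast_to(t > bg, g.shape)] = 0.0
    return g


def _grid_profile(times, Y, b_grid, h_grid, variant, chunk=256):
    """Per-breakpoint error profile, minimised over (m, h), per curve.

    For fixed (b, h) the model is linear in m with closed form
    ``sum(y*g)/sum(g*g)`` over the saturating samples, clipped at zero; the
    residual identity ``sse = sum(y^2) - m^2 sum(g^2)`` (for unclipped m)
    turns the whole search into one matrix product per chunk of curves.

    Returns arrays of shape (n_curves, len(b_grid)): sse, m and h at the
    best h per breakpoint candidate.
    """
    g = _design_tensor(times, b_grid, h_grid, variant)
    B, H, T = g.shape
    gf = g.reshape(B * H, T)
    gg = np.sum(gf * gf, axis=1)                      # (B*H,)
    ok = gg > 0
    n = Y.shape[0]
    sse_b = np.empty((n, B))
    m_b = np.empty((n, B))
    h_b = np.empty((n, B))
    for s in range(0, n, chunk):
        y = Y[s:s + chunk]
        yy = np.sum(y * y, axis=1)                    # (c,)
        num = y @ gf.T                                # (c, B*H)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(ok[None, :], num / gg[None, :], 0.0)
        m = np.maximum(m, 0.0)
        # clipped m=0 gives sse = yy exactly, consistent with the identity
        sse = (yy[:, None] - m * m * gg[None, :]).reshape(-1, B, H)
        j = np.argmin(sse, axis=2)                    # best h per (curve, b)
        ci, bi = np.meshgrid(np.arange(sse.shape[0]), np.arange(B),
                             indexing="ij")
        sse_b[s:s + chunk] = sse[ci, bi, j]
        m_b[s:s + chunk] = m.reshape(-1, B, H)[ci, bi, j]
        h_b[s:s + chunk] = h_grid[j]
    return sse_b, m_b, h_b


def _argmin_smallest_b(sse_row):
    """Index of the minimum, resolving near-ties toward the smallest b."""
    i = int(np.argmin(sse_row))
    tol = 1e-9 * max(sse_row[i], 1.0) + 1e-12
    return int(np.nonzero(sse_row <= sse_row[i] + tol)[0][0])


def _polish(times, curve, b, m, h, options: FitOptions,
            b_bounds=None):
    """Local refinement of a grid candidate by bounded least squares.

    All three parameters for the continuous branch (the breakpoint moves
    within ``b_bounds``, by default one grid step around its candidate);
    ``m`` and ``h`` only for the literal branch, whose error is piecewise
    constant in ``b``.  Returns (b, m, h, sse) or raises on optimiser
    failure.
    """
    variant = options.variant
    b_max = options.resolve_b_max(times)
    if variant == "continuous":
        if b_bounds is None:
            lo = max(b - options.grid_step, 0.0)
            hi = min(b + options.grid_step, b_max)
        else:
            lo, hi = b_bounds
        b = min(max(b, lo), hi)

        def resid(p):
            return piecewise_saturation(times, p[0], p[1], p[2],
                                        variant) - curve

        def jac(p):
            bb, mm, hh = p
            dt = times - bb
            act = dt > 0
            dtp = np.where(act, dt, 1.0)
            denom = hh + dtp
            J = np.zeros((times.size, 3))
            J[:, 0] = np.where(act, -mm * hh / denom**2, 0.0)
            J[:, 1] = np.where(act, dtp / denom, 0.0)
            J[:, 2] = np.where(act, -mm * dtp / denom**2, 0.0)
            return J

        res = least_squares(
            resid, x0=[b, max(m, 1e-6), h], jac=jac,
            bounds=([lo, 1e-9, options.h_bounds[0]],
                    [hi, np.inf, options.h_bounds[1]]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        sse = float(np.sum(res.fun**2))
        return float(res.x[0]), float(res.x[1]), float(res.x[2]), sse

    def resid_mh(p):
        return piecewise_saturation(times, b, p[0], p[1], variant) - curve

    def jac_mh(p):
        mm, hh = p
        act = times > b
        denom = hh + times
        J = np.zeros((times.size, 2))
        J[:, 0] = np.where(act, times / denom, 0.0)
        J[:, 1] = np.where(act, -mm * times / denom**2, 0.0)
        return J

    res = least_squares(
        resid_mh, x0=[max(m, 1e-6), h], jac=jac_mh,
        bounds=([1e-9, options.h_bounds[0]], [np.inf, options.h_bounds[1]]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    sse = float(np.sum(res.fun**2))
    return float(b), float(res.x[0]), float(res.x[1]), sse


def _validate_inputs(times, Y):
    if times.size < 4:
        raise ValueError("need at least 4 time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if Y.shape[1] != times.size:
        raise ValueError("times and curves must have equal length")
    if not np.all(np.isfinite(Y)):
        raise ValueError("curve contains non-finite values")


def _interval_edges(times, b_max):
    """Inter-sample intervals partitioning [0, b_max].

    Within one interval the set of samples on the saturating branch is
    constant, so the profiled error is smooth there (continuous branch)
    or constant (literal branch).
    """
    edges = np.concatenate(([0.0], times[times < b_max], [b_max]))
    return np.unique(edges)


def _fit_curves(times, Y, options: FitOptions) -> list[SaturationFit]:
    """Shared batch path behind :func:`fit_voxel` and :func:`fit_map`.

    Coarse (b, h) grid profiling, then — for the continuous branch — a
    bounded least-squares polish started from the best grid candidate of
    the winning inter-sample interval and of its two neighbours (the
    coarse h grid can misrank adjacent intervals when a sample sits barely
    above the true breakpoint); the best polished solution wins, ties
    toward the smallest breakpoint.
    """
    times = np.asarray(times, float)
    Y = np.asarray(Y, float)
    _validate_inputs(times, Y)
    b_max = options.resolve_b_max(times)
    b_grid = np.arange(0.0, b_max + 0.5 * options.grid_step,
                       options.grid_step)
    b_grid = np.minimum(b_grid, b_max)
    h_grid = np.geomspace(*options.h_bounds, options.n_h_grid)
    sse_b, m_b, h_b = _grid_profile(times, Y, b_grid, h_grid, options.variant)
    edges = _interval_edges(times, b_max)
    # interval index of every b candidate (intervals are (e_i, e_{i+1}])
    cell_of = np.clip(np.searchsorted(edges, b_grid, side="left") - 1, 0,
                      len(edges) - 2)
    cell_of[b_grid == 0.0] = 0

    fits: list[SaturationFit] = []
    for k, curve in enumerate(Y):
        sstot = float(np.sum((curve - curve.mean()) ** 2))
        if curve.max() < options.noise_floor or sstot == 0.0:
            fits.append(SaturationFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                                      STATUS_BELOW_NOISE))
            continue
        i = _argmin_smallest_b(sse_b[k])
        b, m, h, sse = b_grid[i], m_b[k, i], h_b[k, i], sse_b[k, i]
        if m <= 0:
            fits.append(SaturationFit(np.nan, np.nan, np.nan, float(sse),
                                      np.nan, STATUS_BELOW_NOISE))
            continue
        try:
            if options.variant == "continuous":
                def polish_cell(c):
                    j = int(np.argmin(np.where(cell_of == c, sse_b[k],
                                               np.inf)))
                    return _polish(times, curve, b_grid[j], m_b[k, j],
                                   h_b[k, j], options,
                                   b_bounds=(edges[c], edges[c + 1]))

                ci = cell_of[i]
                b, m, h, sse = polish_cell(ci)
                exact = sse <= 1e-16 * sstot
                # the coarse h grid can misrank adjacent inter-sample
                # intervals, so neighbours are polished too; when the
                # winner fits exactly, only the left neighbour can still
                # win (smallest-b tie-break)
                others = [ci - 1] if exact else [ci - 1, ci + 1]
                for c in others:
                    if not 0 <= c < len(edges) - 1:
                        continue
                    bp, mp, hp, sp = polish_cell(c)
                    if sp < sse - 1e-12 or (sp <= sse + 1e-12 and bp < b):
                        b, m, h, sse = bp, mp, hp, sp
            else:
                bp, mp, hp, sse_pol = _polish(times, curve, b, m, h, options)
                if sse_pol <= sse:
                    b, m, h, sse = bp, mp, hp, sse_pol
        except Exception:
            fits.append(SaturationFit(np.nan, np.nan, np.nan, float(sse),
                                      np.nan, STATUS_FAIL))
            continue
        if not np.isfinite(b) or m <= 0:
            fits.append(SaturationFit(np.nan, np.nan, np.nan, float(sse),
                                      np.nan, STATUS_BELOW_NOISE))
            continue
        if b >= b_max - 1e-9 and np.all(curve <= options.noise_floor):
            fits.append(SaturationFit(np.nan, np.nan, np.nan, float(sse),
                                      np.nan, STATUS_NO_BREAKPOINT))
            continue
        r2 = float(np.clip(1.0 - sse / sstot, 0.0, 1.0))
        fits.append(SaturationFit(float(b), float(m), float(h), float(sse),
                                  r2, STATUS_OK))
    return fits


def fit_voxel(times, curve, options: FitOptions | None = None) -> SaturationFit:
    """Fit the two-piece model to one voxel's inflow curve.

    Profiles the breakpoint on a grid over ``[0, b_max]``, solving the inner
    ``(m, h)`` least-squares problem per candidate, then polishes the best
    solution.  Ties are broken toward the smallest breakpoint.
    """
    curve = np.asarray(curve, float)
    return _fit_curves(times, curve[None, :], options or FitOptions())[0]


@dataclass
class MattMap:
    """Volumetric breakpoint map with companion quality maps.

    All fields are NaN (``status`` = below-noise/fail codes) outside voxels
    that were fitted with status ok.
    """

    matt: np.ndarray       # ms
    amplitude: np.ndarray  # saturation level m
    quality: np.ndarray    # r2
    status: np.ndarray     # int codes, STATUS_* (255 outside the mask)
    mask: np.ndarray       # the vessel mask that was fitted

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.matt)

    def status_tally(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.status == code))
            for code, name in STATUS_NAMES.items()
        }


def fit_map(series, mask, options: FitOptions | None = None,
            times=None) -> MattMap:
    """Fit every voxel of a vessel mask and assemble volumetric maps.

    ``series`` may be an :class:`~mattmap.isolation.InflowSeries` or a plain
    4D array (then ``times`` is required).
    """
    data, t = _series_data(series, times)
    mask = np.asarray(mask, bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask and series grids differ")
    if not mask.any():
        raise ValueError("empty vessel mask")
    options = options or FitOptions()

    matt = np.full(mask.shape, np.nan)
    amp = np.full(mask.shape, np.nan)
    r2 = np.full(mask.shape, np.nan)
    status = np.full(mask.shape, 255, np.uint8)
    idx = np.nonzero(mask)
    fits = _fit_curves(t, data[idx], options)
    for i, fit in enumerate(fits):
        at = (idx[0][i], idx[1][i], idx[2][i])
        status[at] = fit.status
        if fit.ok:
            matt[at] = fit.b
            amp[at] = fit.m
            r2[at] = fit.r2
    return MattMap(matt=matt, amplitude=amp, quality=r2, status=status,
                   mask=mask)


def matt_total(matt_map: MattMap, percentile: float = 100.0) -> float:
    """Global maximum (or q-th percentile) of the defined breakpoint map.

    The maximum indicates the total time taken for the label to reach the
    most distal visible vessels.
    """
    vals = matt_map.matt[matt_map.defined]
    if vals.size == 0:
        raise ValueError("no defined voxels in map")
    if percentile >= 100.0:
        return float(vals.max())
    return float(np.percentile(vals, percentile))


def estimate_noise_floor(series, mask, brain_mask=None, factor: float = 2.0,
                         times=None) -> float:
    """Detection threshold from mask-adjacent background.

    ``factor`` times the robust sd (1.4826 * MAD) of the first-time-point
    difference signal over background voxels (brain minus vessel mask).
    """
    data, _ = _series_data(series, times)
    mask = np.asarray(mask, bool)
    bg = ~mask if brain_mask is None else np.asarray(brain_mask, bool) & ~mask
    vals = data[..., 0][bg]
    if vals.size == 0:
        return 0.0
    mad = np.median(np.abs(vals - np.median(vals)))
    return float(factor * 1.4826 * mad)


def _series_data(series, times):
    if hasattr(series, "times") and hasattr(series, "data"):
        return np.asarray(series.data, float), np.asarray(series.times, float)
    if times is None:
        raise ValueError("times required when series is a plain array")
    return np.asarray(series, float), np.asarray(times, float)


class SaturationCurveFit(BaseEstimator):
    """Batch breakpoint estimator over a matrix of inflow curves.

    sklearn-style estimator: ``fit(X)`` with ``X`` of shape
    ``(n_curves, n_times)`` fits every row independently and exposes the
    fitted parameters as trailing-underscore attributes.

    Parameters
    ----------
    times : sequence of float
        Label durations (ms) of the columns of ``X``.
    variant : {"literal", "continuous"}
        Branch form of the saturating piece.
    b_max, grid_step, noise_floor
        See :class:`FitOptions`.

    Attributes
    ----------
    breakpoint_ : ndarray (n_curves,)  fitted mATT in ms (NaN if not ok)
    saturation_ : ndarray (n_curves,)  fitted m
    half_rise_ : ndarray (n_curves,)   fitted h in ms
    r2_ : ndarray (n_curves,)
    status_ : ndarray (n_curves,) int codes
    """

    def __init__(self, times=None, variant: str = "literal",
                 b_max: float | None = None, grid_step: float = 10.0,
                 noise_floor: float = 0.0):
        self.times = times
        self.variant = variant
        self.b_max = b_max
        self.grid_step = grid_step
        self.noise_floor = noise_floor

    def _options(self) -> FitOptions:
        return FitOptions(variant=self.variant, b_max=self.b_max,
                          grid_step=self.grid_step,
                          noise_floor=self.noise_floor)

    def fit(self, X, y=None):
        if self.times is None:
            raise ValueError("times must be set before fitting")
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        t = np.asarray(self.times, float)
        fits = _fit_curves(t, X, self._options())
        self.breakpoint_ = np.array([f.b for f in fits])
        self.saturation_ = np.array([f.m for f in fits])
        self.half_rise_ = np.array([f.h for f in fits])
        self.r2_ = np.array([f.r2 for f in fits])
        self.sse_ = np.array([f.sse for f in fits])
        self.status_ = np.array([f.status for f in fits])
        return self

    def predict(self, times=None) -> np.ndarray:
        """Model curves at the given times, shape (n_curves, n_times)."""
        t = np.asarray(self.times if times is None else times, float)
        return np.stack(
            [
                piecewise_saturation(t, b, m, h, self.variant)
                if np.isfinite(b)
                else np.zeros_like(t)
                for b, m, h in zip(self.breakpoint_, self.saturation_,
                                   self.half_rise_)
            ]
        )
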