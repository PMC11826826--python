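"""Seeded synthetic 4D-MRA phantoms with known arrival-time ground truth.

The generator emulates the statistical structure the mATT pipeline assumes:
a branching vascular tree grown from the most caudal slice toward cranial
slices, with the true breakpoint (arrival time) increasing linearly with the
path distance travelled along the tree; an inflow difference-signal series
following the two-piece saturation model; blob-like high-signal artifacts
near the brain base (to exercise area opening); a rectangular block
parcellation standing in for a fine brain atlas; and a tissue arrival-time
map coupled to the vascular ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitting import piecewise_saturation

#: label durations (ms) of the reference acquisition protocol
DEFAULT_TIMES = (100.0, 200.0, 400.0, 600.0, 800.0, 1200.0, 1600.0, 2200.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic 4D-MRA study.

    Attributes
    ----------
    shape : tuple of int
        Volume shape (x, y, z); z indexes slices, slice 0 is most caudal.
    voxel_dims : tuple of float
        Voxel pitch in mm per axis.
    times : tuple of float
        Label durations (ms) of the acquired time points, strictly increasing.
    gradient : float
        Increase of the true breakpoint per unit path length, ms/mm.
    b0 : float
        True breakpoint at the tree inlet, ms.
    noise_sigma : float
        SD of additive Gaussian noise on the difference signal (signal units).
    background_level : float
        Static tissue signal level inside the brain (signal units).
    blob_count : int
        Number of blob artifacts placed within the 8 most caudal slices.
    seed : int
        Seed for all randomness; identical configs reproduce identical data.
    m0, m_taper : float
        Saturation level at the inlet and its linear per-mm taper, so distal
        vessels are fainter (m is floored at ``m_min``).
    h0 : float
        Half-rise time of the saturation branch, ms.
    n_trunks : int
        Number of independent tree roots seeded in the inlet slice.
    variant : str
        Forward-model branch form, ``"literal"`` or ``"continuous"``.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_dims: tuple[float, float, float] = (0.6, 0.6, 0.8)
    times: tuple[float, ...] = DEFAULT_TIMES
    gradient: float = 7.7
    b0: float = 650.0
    noise_sigma: float = 1.0
    background_level: float = 100.0
    blob_count: int = 3
    seed: int = 0
    m0: float = 10.0
    m_taper: float = 0.08
    m_min: float = 3.0
    h0: float = 400.0
    n_trunks: int = 3
    branch_prob: float = 0.06
    max_walkers: int = 12
    variant: str = "continuous"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if t.size < 2 or np.any(np.diff(t) <= 0) or np.any(t <= 0):
            raise ValueError("times must be positive and strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.gradient < 0:
            raise ValueError("gradient must be >= 0")


@dataclass
class VesselTruth:
    """Ground-truth vessel voxels and their per-voxel model parameters."""

    voxels: np.ndarray          # (N, 3) int coordinates
    path_distance: np.ndarray   # (N,) mm from the tree inlet
    true_b: np.ndarray          # (N,) ms, ground-truth breakpoint (mATT)
    true_m: np.ndarray          # (N,) saturation level, signal units
    true_h: np.ndarray          # (N,) half-rise time, ms
    inlet_slice: int
    voxel_dims: tuple[float, float, float]
    shape: tuple[int, int, int]
    branch_id: np.ndarray = field(default=None)  # (N,) walker id, for tests

    def __len__(self) -> int:
        return len(self.voxels)

    def mask(self) -> np.ndarray:
        """Binary 3D mask of all vessel voxels."""
        out = np.zeros(self.shape, bool)
        out[tuple(self.voxels.T)] = True
        return out

    def b_volume(self) -> np.ndarray:
        """3D volume of true breakpoints, NaN outside the vessel tree."""
        out = np.full(self.shape, np.nan)
        out[tuple(self.voxels.T)] = self.true_b
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.voxels[:, 0],
                "y": self.voxels[:, 1],
                "z": self.voxels[:, 2],
                "path_distance": self.path_distance,
                "true_b": self.true_b,
                "true_m": self.true_m,
                "true_h": self.true_h,
            }
        )


def _paint_ball(center, radius, shape):
    """Integer voxels within ``radius`` (voxel units) of a float center."""
    lo = [max(0, int(np.floor(c - radius))) for c in center]
    hi = [min(s - 1, int(np.ceil(c + radius))) for c, s in zip(center, shape)]
    pts = []
    for x in range(lo[0], hi[0] + 1):
        for y in range(lo[1], hi[1] + 1):
            for z in range(lo[2], hi[2] + 1):
                d2 = ((x - center[0]) ** 2 + (y - center[1]) ** 2
                      + (z - center[2]) ** 2)
                if d2 <= radius * radius:
                    pts.append((x, y, z))
    return pts


def generate_vessel_tree(config: SimulationConfig) -> VesselTruth:
    """Grow a branching vessel tree with cranially increasing arrival times.

    Walkers start in the inlet (most caudal) slice and advance along a
    persistent direction with a cranial drift and small random curvature,
    emulating the smooth course of intracranial arteries; each step adds
    its physical length to the walker's path distance, and the true
    breakpoint at a voxel is ``b0 + gradient * path_distance``.  A tube of
    tapering calibre (proximal trunks ~3 voxels across, distal branches
    ~1 voxel) is painted around each centreline.  Deterministic for a
    fixed config (seed included).
    """
    shape = tuple(int(s) for s in config.shape)
    for ax, s in zip("xyz", shape):
        if s < 16:
            raise ValueError(f"shape too small along {ax}: {s} < 16")
    rng = np.random.default_rng(config.seed)
    dims = np.asarray(config.voxel_dims, float)
    centre = np.array([(s - 1) / 2.0 for s in shape])
    semi = np.array([0.95 * s / 2.0 for s in shape])
    brain = brain_mask_for(config)

    occupied: set[tuple[int, int, int]] = set()
    recs: list[tuple[tuple[int, int, int], float, int]] = []

    def record(pos: tuple[int, int, int], dist: float, wid: int) -> None:
        if pos not in occupied and brain[pos]:
            occupied.add(pos)
            recs.append((pos, dist, wid))

    # walker state: (position, direction, path distance, id, generation)
    walkers = []
    next_id = 0
    for _ in range(config.n_trunks):
        x = rng.uniform(shape[0] * 0.4, shape[0] * 0.6)
        y = rng.uniform(shape[1] * 0.4, shape[1] * 0.6)
        d = np.array([rng.normal(0, 0.2), rng.normal(0, 0.2), 1.0])
        walkers.append((np.array([x, y, 0.0]), d / np.linalg.norm(d), 0.0,
                        next_id, 0))
        next_id += 1

    max_steps = 4 * shape[2]
    while walkers:
        pos, direction, dist, wid, gen = walkers.pop()
        steps = 0
        while steps < max_steps and pos[2] < shape[2] - 1.5:
            # persistent direction with gentle random curvature + drift
            direction = direction + rng.normal(0.0, 0.12, 3)
            direction[2] += 0.08  # cranial drift
            # steer inward near the brain-ellipsoid boundary so the tree
            # stays inside the masked volume
            rel = (pos - centre) / semi
            u = float(np.sum(rel * rel))
            if u > 0.55:
                inward = -rel / max(np.linalg.norm(rel), 1e-9)
                inward[2] = max(inward[2], 0.0)
                direction = direction + 2.5 * (u - 0.55) * inward
            direction /= np.linalg.norm(direction)
            if direction[2] < 0.15:  # keep heading cranially
                direction[2] = 0.15
                direction /= np.linalg.norm(direction)
            new = pos + direction
            new[0] = np.clip(new[0], 2.0, shape[0] - 3.0)
            new[1] = np.clip(new[1], 2.0, shape[1] - 3.0)
            seglen = float(np.linalg.norm((new - pos) * dims))
            pos, dist = new, dist + seglen
            radius = max(0.8, 1.6 - 0.3 * gen)
            for ipos in _paint_ball(pos, radius, shape):
                record(ipos, dist, wid)
            if (
                len(walkers) + 1 < config.max_walkers
                and rng.random() < config.branch_prob
            ):
                tilt = rng.normal(0.0, 0.5, 3)
                bdir = direction + tilt
                bdir /= np.linalg.norm(bdir)
                walkers.append((pos.copy(), bdir, dist, next_id, gen + 1))
                next_id += 1
            steps += 1

    voxels = np.array([r[0] for r in recs], int).reshape(-1, 3)
    path_distance = np.array([r[1] for r in recs], float)
    branch_id = np.array([r[2] for r in recs], int)
    true_b = config.b0 + config.gradient * path_distance
    true_m = np.maximum(config.m0 - config.m_taper * path_distance, config.m_min)
    true_h = np.full(len(voxels), config.h0)
    return VesselTruth(
        voxels=voxels,
        path_distance=path_distance,
        true_b=true_b,
        true_m=true_m,
        true_h=true_h,
        inlet_slice=0,
        voxel_dims=tuple(config.voxel_dims),
        shape=shape,
        branch_id=branch_id,
    )


def generate_tube_phantom(config: SimulationConfig, n_tubes: int = 4,
                          radius: float = 1.6, tilt: float = 0.25
                          ) -> VesselTruth:
    """Nearly straight tubes rising from the inlet slice: a controlled
    fixture for the vessel-isolation cascade.

    Each tube runs caudal to cranial with a small fixed oblique tilt; the
    true breakpoint grows linearly with arc length at ``config.gradient``.
    Unlike the branching tree, geometry here is deliberately simple so
    filter retention can be measured against an unambiguous target.
    """
    shape = tuple(int(s) for s in config.shape)
    rng = np.random.default_rng(config.seed)
    brain = brain_mask_for(config)
    dims = np.asarray(config.voxel_dims, float)
    occupied: set[tuple[int, int, int]] = set()
    recs: list[tuple[tuple[int, int, int], float, int]] = []
    for tube in range(n_tubes):
        x = rng.uniform(shape[0] * 0.3, shape[0] * 0.7)
        y = rng.uniform(shape[1] * 0.3, shape[1] * 0.7)
        d = np.array([rng.uniform(-tilt, tilt), rng.uniform(-tilt, tilt), 1.0])
        d /= np.linalg.norm(d)
        pos = np.array([x, y, 0.0])
        dist = 0.0
        while pos[2] < shape[2] - 1.5:
            new = pos + d
            dist += float(np.linalg.norm((new - pos) * dims))
            pos = new
            for ipos in _paint_ball(pos, radius, shape):
                if ipos not in occupied and brain[ipos]:
                    occupied.add(ipos)
                    recs.append((ipos, dist, tube))
    voxels = np.array([r[0] for r in recs], int).reshape(-1, 3)
    path_distance = np.array([r[1] for r in recs], float)
    true_b = config.b0 + config.gradient * path_distance
    true_m = np.maximum(config.m0 - config.m_taper * path_distance,
                        config.m_min)
    return VesselTruth(
        voxels=voxels, path_distance=path_distance, true_b=true_b,
        true_m=true_m, true_h=np.full(len(voxels), config.h0),
        inlet_slice=0, voxel_dims=tuple(config.voxel_dims), shape=shape,
        branch_id=np.array([r[2] for r in recs], int),
    )


def brain_mask_for(config: SimulationConfig) -> np.ndarray:
    """Ellipsoidal brain mask inscribed in the volume (axes at 95% half-size)."""
    shape = config.shape
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    c = [(s - 1) / 2.0 for s in shape]
    r = [0.95 * s / 2.0 for s in shape]
    d2 = sum(((g - ci) / ri) ** 2 for g, ci, ri in zip(grids, c, r))
    return d2 <= 1.0


def _blob_artifacts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Ellipsoidal high-signal blobs within the 8 most caudal slices.

    Sizes straddle the default area-opening threshold so the morphological
    stage has components both to remove and (without it) to keep.
    """
    vol = np.zeros(config.shape)
    nz = min(8, config.shape[2])
    for i in range(config.blob_count):
        cx = rng.integers(6, config.shape[0] - 6)
        cy = rng.integers(6, config.shape[1] - 6)
        cz = rng.integers(1, nz - 1) if nz > 2 else 0
        # alternate small/large radii: components of roughly 7-250 voxels
        rad = (1.2, 1.6, 1.0) if i % 2 == 0 else (3.0, 3.5, 2.0)
        grids = np.ogrid[tuple(slice(0, s) for s in config.shape)]
        d2 = sum(
            ((g - c) / r) ** 2 for g, c, r in zip(grids, (cx, cy, cz), rad)
        )
        vol[d2 <= 1.0] = 12.0
    return vol


def simulate_inflow_series(
    truth: VesselTruth, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate label and control series for a vessel phantom.

    The control series is the static background; the label series is
    ``control - dM`` where ``dM`` at a vessel voxel follows the two-piece
    saturation model with that voxel's true parameters, plus zero-mean
    Gaussian noise (sd ``noise_sigma``) everywhere inside the brain, plus
    blob artifacts near the inlet slice.  ``control - label`` therefore
    reproduces the noisy difference signal exactly.

    Returns
    -------
    (label, control) : two 4D arrays of shape ``shape + (len(times),)``.
    """
    if np.any(truth.voxels < 0) or np.any(
        truth.voxels >= np.asarray(config.shape)
    ):
        raise ValueError("truth voxels fall outside config.shape")
    rng = np.random.default_rng(config.seed + 1)
    times = np.asarray(config.times, float)
    brain = brain_mask_for(config)
    shape4 = config.shape + (len(times),)

    control = np.zeros(config.shape)
    control[brain] = config.background_level
    vox = tuple(truth.voxels.T)
    control[vox] += truth.true_m  # vessels are bright in magnitude images

    dm = np.zeros(shape4)
    for k, t in enumerate(times):
        dm[vox + (k,)] = piecewise_saturation(
            t, truth.true_b, truth.true_m, truth.true_h, variant=config.variant
        )
    blobs = _blob_artifacts(config, rng)
    dm += blobs[..., None] * (times / times[-1])
    if config.noise_sigma > 0:
        noise = rng.normal(0.0, config.noise_sigma, shape4)
        dm[brain] += noise[brain]

    control4 = np.repeat(control[..., None], len(times), axis=3)
    label = control4 - dm
    return label, control4


def generate_block_atlas(
    shape: tuple[int, int, int], blocks: tuple[int, int, int]
) -> np.ndarray:
    """Partition a volume into contiguous rectangular regions labelled 1..N.

    A stand-in for a fine anatomical parcellation; label 0 is reserved for
    background and never produced.
    """
    shape = tuple(int(s) for s in shape)
    blocks = tuple(int(b) for b in blocks)
    for ax, (b, s) in enumerate(zip(blocks, shape)):
        if b < 1 or b > s:
            raise ValueError(
                f"blocks[{ax}]={b} must be in [1, shape[{ax}]={s}]"
            )
    idx = [
        np.minimum((np.arange(s) * b) // s, b - 1)
        for s, b in zip(shape, blocks)
    ]
    ix, iy, iz = np.meshgrid(*idx, indexing="ij")
    return (ix * blocks[1] * blocks[2] + iy * blocks[2] + iz + 1).astype(
        np.int32
    )


def simulate_tissue_att(
    truth: VesselTruth,
    shape: tuple[int, int, int],
    tissue_delay: float = 600.0,
    noise_sigma: float = 100.0,
    seed: int = 0,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Tissue arrival-time map coupled to the vascular ground truth.

    Each brain voxel inherits the true breakpoint of its nearest vessel voxel
    (Euclidean distance in mm) plus a fixed parenchymal delay and Gaussian
    noise, guaranteeing the positive macrovascular/tissue arrival-time
    association that the ROI correlation analysis recovers.
    """
    if len(truth) == 0:
        raise ValueError("empty vessel truth")
    if tissue_delay < 0:
        raise ValueError("tissue_delay must be >= 0")
    from scipy import ndimage

    vm = np.zeros(shape, bool)
    vm[tuple(truth.voxels.T)] = True
    bvol = np.zeros(shape)
    bvol[tuple(truth.voxels.T)] = truth.true_b
    _, idx = ndimage.distance_transform_edt(
        ~vm, sampling=truth.voxel_dims, return_indices=True
    )
    att = bvol[tuple(idx)] + tissue_delay
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        att = att + rng.normal(0.0, noise_sigma, shape)
    if brain_mask is not None:
        att = np.where(brain_mask, att, np.nan)
    return att


def make_phantom(config: SimulationConfig):
    """Convenience bundle: tree, label/control series and brain mask."""
    truth = generate_vessel_tree(config)
    label, control = simulate_inflow_series(truth, config)
    return truth, label, control, brain_mask_for(config)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=int(seed))
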