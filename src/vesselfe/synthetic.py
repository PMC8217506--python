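"""Synthetic angioarchitecture, tissue volumes and impact scenarios.

The real angioarchitecture behind this pipeline was reconstructed from
synchrotron phase-contrast imaging of a rat brain and is not public.  This
module generates stochastic stand-ins with the same summary statistics:
vessel diameters between 10 and 100 µm with a mean of 17.85 µm, and a vessel
volume fraction of 5.4% of the tissue volume.  It also builds voxel intensity
volumes for the meshing stage and controlled-cortical-impact (CCI) loading
scenarios for the solver.

All generators take an explicit integer seed; there is no hidden global
random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .errors import CalibrationError, ConfigError

__all__ = [
    "VesselNetwork",
    "VoxelImage",
    "CCIScenario",
    "NetworkCalibration",
    "NetworkStats",
    "default_calibration",
    "generate_network",
    "network_stats",
    "generate_tissue_image",
    "make_cci_scenario",
]

# Hard diameter bounds of the reconstructed vasculature (µm).
MIN_DIAMETER_UM = 10.0
MAX_DIAMETER_UM = 100.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VesselNetwork:
    """Centreline graph of a vascular network.

    Attributes
    ----------
    nodes : (N, 3) float array, µm
    radii : (N,) float array, µm  (per-node radius)
    segments : (M, 2) int array   (node index pairs)
    metadata : dict               (generation parameters, seed, ...)
    """

    nodes: np.ndarray
    radii: np.ndarray
    segments: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.segments = np.asarray(self.segments, dtype=int).reshape(-1, 2)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_lengths(self) -> np.ndarray:
        a, b = self.segments[:, 0], self.segments[:, 1]
        return np.linalg.norm(self.nodes[b] - self.nodes[a], axis=1)

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        if self.n_segments == 0:
            raise ValueError("network has no segments")
        if np.any(self.radii < MIN_DIAMETER_UM / 2 - 1e-9):
            raise ValueError("node radius below the 5 µm floor")
        if np.any(self.segments[:, 0] == self.segments[:, 1]):
            raise ValueError("segment with identical endpoints")
        if self.segments.min() < 0 or self.segments.max() >= self.n_nodes:
            raise ValueError("segment references a node out of range")
        if np.any(self.segment_lengths() <= 0.0):
            raise ValueError("zero-length segment")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.segments.ravel()] = True
        if not used.all():
            raise ValueError("orphan node (referenced by no segment)")


@dataclass
class VoxelImage:
    """3D scalar intensity volume with voxel spacing metadata."""

    intensities: np.ndarray
    spacing: np.ndarray  # µm per voxel, per axis
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float).ravel(), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).ravel()
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on all axes")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple:
        return self.intensities.shape


@dataclass
class CCIScenario:
    """Controlled-cortical-impact loading programme.

    A rigid flat-tipped cylinder is driven into the top surface at constant
    velocity to ``impact_depth``, held for ``dwell_time``, then (optionally)
    retracted at the same speed.  Units: µm, ms.
    """

    impactor_radius: float = 2500.0
    impact_depth: float = 2000.0  # 2 mm CCI
    impact_velocity: float = 4000.0  # µm/ms
    dwell_time: float = 0.1
    retract: bool = True
    total_sim_time: float | None = None
    edge_fillet: float = 0.0  # µm; rounded rim of the flat tip (0 = sharp)

    def __post_init__(self) -> None:
        if self.impact_velocity <= 0:
            raise ConfigError("impact_velocity must be positive")
        if self.impact_depth < 0:
            raise ConfigError("impact_depth must be non-negative")
        if self.impactor_radius <= 0:
            raise ConfigError("impactor_radius must be positive")
        if self.total_sim_time is None:
            self.total_sim_time = (
                self.time_to_peak + self.dwell_time
                + (self.time_to_peak if self.retract else 0.0)
            )
        if self.total_sim_time < self.time_to_peak:
            raise ConfigError("total_sim_time shorter than the loading ramp")
        if not 0 <= self.edge_fillet <= self.impactor_radius:
            raise ConfigError("edge_fillet must be in [0, impactor_radius]")

    @property
    def time_to_peak(self) -> float:
        return self.impact_depth / self.impact_velocity

    def indentation(self, t: float | np.ndarray) -> np.ndarray:
        """Impactor indentation depth (µm) at time t (ms)."""
        t = np.asarray(t, dtype=float)
        ramp = self.time_to_peak
        d = np.minimum(t, ramp) * self.impact_velocity
        if self.retract:
            t_ret = ramp + self.dwell_time
            d = np.where(
                t > t_ret,
                np.maximum(self.impact_depth - (t - t_ret) * self.impact_velocity, 0.0),
                d,
            )
        return d

    def face_height(self, r: np.ndarray) -> np.ndarray:
        """Tip surface height above the flat face at radial distance r (µm).

        Zero on the flat portion, quarter-circle relief over the filleted
        rim, so a nonzero ``edge_fillet`` removes the flat-punch edge
        singularity.
        """
        r = np.asarray(r, dtype=float)
        re = self.edge_fillet
        if re <= 0:
            return np.zeros_like(r)
        d = np.clip(r - (self.impactor_radius - re), 0.0, re)
        return re - np.sqrt(np.maximum(re**2 - d**2, 0.0))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass
class NetworkCalibration:
    """Targets and shape parameters of the network generator.

    The diameter law is a lognormal truncated to [min_diameter, max_diameter];
    ``diameter_log_mu`` is fitted so the truncated mean equals
    ``target_mean_diameter``.  Tree growth stops when the accumulated vessel
    volume reaches ``target_volume_fraction`` of the domain volume.
    """

    target_mean_diameter: float = 17.85  # µm
    target_volume_fraction: float = 0.054
    min_diameter: float = MIN_DIAMETER_UM
    max_diameter: float = MAX_DIAMETER_UM
    diameter_log_sigma: float = 0.55
    diameter_log_mu: float | None = None  # fitted when None
    mean_segment_length: float = 60.0  # µm
    segment_length_cv: float = 0.30
    bifurcation_prob: float = 0.35
    bifurcation_angle_mean: float = 35.0  # deg, each branch off parent axis
    bifurcation_angle_spread: float = 12.0  # deg
    continuation_jitter: float = 10.0  # deg
    murray_exponent: float = 3.0  # used by radius_mode="murray"
    radius_mode: str = "lognormal"  # "lognormal" (calibrated) or "murray"
    cross_link_fraction: float = 0.03
    min_segment_length: float = 5.0  # µm; shorter clipped branches are dropped
    tree_max_segments: int = 120
    boundary_margin: float | None = None  # µm; default max radius

    def __post_init__(self) -> None:
        if self.diameter_log_mu is None:
            self.diameter_log_mu = _fit_truncated_lognormal_mu(
                self.target_mean_diameter,
                self.diameter_log_sigma,
                self.min_diameter,
                self.max_diameter,
            )


def default_calibration() -> NetworkCalibration:
    """Calibration matching the reconstructed angioarchitecture statistics."""
    return NetworkCalibration()


def _truncated_lognormal_mean(mu: float, sigma: float, a: float, b: float) -> float:
    la, lb = math.log(a), math.log(b)
    za, zb = (la - mu) / sigma, (lb - mu) / sigma
    denom = ndtr(zb) - ndtr(za)
    num = ndtr(zb - sigma) - ndtr(za - sigma)
    return math.exp(mu + 0.5 * sigma**2) * num / denom


def _fit_truncated_lognormal_mu(target: float, sigma: float, a: float, b: float) -> float:
    if not (a < target < b):
        raise CalibrationError(
            f"target mean diameter {target} outside truncation bounds [{a}, {b}]"
        )
    f = lambda mu: _truncated_lognormal_mean(mu, sigma, a, b) - target
    return brentq(f, math.log(a) - 5 * sigma, math.log(b) + 5 * sigma, xtol=1e-12)


def _sample_truncated_lognormal(
    rng: np.random.Generator, n: int, mu: float, sigma: float, a: float, b: float
) -> np.ndarray:
    za, zb = (math.log(a) - mu) / sigma, (math.log(b) - mu) / sigma
    u = rng.uniform(ndtr(za), ndtr(zb), size=n)
    return np.exp(mu + sigma * ndtri(u))


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate_towards(direction: np.ndarray, angle_deg: float, azimuth: float) -> np.ndarray:
    """Unit vector at ``angle_deg`` off ``direction``, at the given azimuth."""
    d = direction / np.linalg.norm(direction)
    # orthonormal frame around d
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    a = math.radians(angle_deg)
    return math.cos(a) * d + math.sin(a) * (math.cos(azimuth) * e1 + math.sin(azimuth) * e2)


def _frustum_volume(r0: np.ndarray, r1: np.ndarray, length: np.ndarray) -> np.ndarray:
    return np.pi * length / 3.0 * (r0**2 + r0 * r1 + r1**2)


def generate_network(
    domain_size: Sequence[float],
    calibration: NetworkCalibration | None = None,
    seed: int = 0,
) -> VesselNetwork:
    """Grow a branching vascular network inside a rectangular domain.

    Bifurcating trees are seeded at random interior points and grown segment
    by segment until the accumulated vessel volume (conical-frustum sum)
    reaches the calibrated volume fraction of the domain; a small fraction of
    capillary cross-links between nearby nodes of different trees is added
    afterwards.  Segment diameters are drawn iid from the calibrated
    truncated-lognormal law (``radius_mode="lognormal"``), or decay from a
    root diameter by Murray's law (``radius_mode="murray"``).

    Raises
    ------
    CalibrationError
        If the requested volume fraction cannot be reached in the domain.
    """
    cal = calibration if calibration is not None else default_calibration()
    domain = np.asarray(domain_size, dtype=float).ravel()
    if domain.shape != (3,) or np.any(domain <= 0):
        raise ConfigError("domain_size must be a positive 3-vector")

    margin = cal.boundary_margin
    if margin is None:
        margin = cal.max_diameter / 2.0
    lo = np.full(3, margin)
    hi = domain - margin
    if np.any(hi <= lo):
        raise CalibrationError(
            "domain too small for the boundary margin; no interior to grow in"
        )

    rng = np.random.default_rng(seed)
    # cross-links are appended after growth and add roughly their count share
    # of volume, so trees stop proportionally short of the target
    target_volume = (cal.target_volume_fraction * float(np.prod(domain))
                     / (1.0 + cal.cross_link_fraction))
    # hard cap: generous multiple of the expected segment count
    mean_r2 = (cal.target_mean_diameter / 2.0) ** 2
    expected_seg_volume = math.pi * mean_r2 * cal.mean_segment_length
    max_segments = max(int(20 * target_volume / expected_seg_volume), 1000)

    positions: list[np.ndarray] = []
    radii: list[float] = []
    segments: list[tuple[int, int]] = []
    tree_ids: list[int] = []  # per node
    total_volume = 0.0
    tree = 0

    def draw_diameter(n: int = 1) -> np.ndarray:
        return _sample_truncated_lognormal(
            rng, n, cal.diameter_log_mu, cal.diameter_log_sigma,
            cal.min_diameter, cal.max_diameter,
        )

    def clip_inside(p: np.ndarray) -> np.ndarray:
        return np.clip(p, lo, hi)

    while total_volume < target_volume:
        if len(segments) > max_segments:
            raise CalibrationError(
                "volume fraction unreachable: segment cap exceeded "
                f"({max_segments} segments, fraction so far "
                f"{total_volume / (target_volume / cal.target_volume_fraction):.4f})"
            )
        # --- grow one tree ---
        root = rng.uniform(lo, hi)
        root_d = float(draw_diameter(1)[0])
        if cal.radius_mode == "murray":
            # roots start thick so the Murray cascade spans the diameter range
            root_d = float(
                np.clip(root_d * 2.0, cal.min_diameter, cal.max_diameter)
            )
        root_id = len(positions)
        positions.append(root)
        radii.append(root_d / 2.0)
        tree_ids.append(tree)
        # frontier entries: (node_id, direction, diameter of incoming edge)
        frontier = [(root_id, _random_unit(rng), root_d)]
        n_tree_segments = 0
        while frontier and n_tree_segments < cal.tree_max_segments:
            if total_volume >= target_volume:
                break
            node_id, direction, d_in = frontier.pop(0)
            if rng.uniform() < cal.bifurcation_prob:
                angles = np.abs(rng.normal(
                    cal.bifurcation_angle_mean, cal.bifurcation_angle_spread, 2))
                az = rng.uniform(0, 2 * math.pi)
                children = [
                    _rotate_towards(direction, angles[0], az),
                    _rotate_towards(direction, angles[1], az + math.pi),
                ]
            else:
                jitter = abs(rng.normal(0.0, cal.continuation_jitter))
                children = [
                    _rotate_towards(direction, jitter, rng.uniform(0, 2 * math.pi))
                ]
            if cal.radius_mode == "murray":
                if len(children) == 2:
                    w = rng.uniform(0.3, 0.7)
                    split = np.array([w, 1.0 - w])
                else:
                    split = np.array([1.0])
                child_d = d_in * split ** (1.0 / cal.murray_exponent)
                child_d = np.clip(child_d, cal.min_diameter, cal.max_diameter)
            else:
                child_d = draw_diameter(len(children))
            for new_dir, d_new in zip(children, child_d):
                if total_volume >= target_volume:
                    break
                length = cal.mean_segment_length * float(
                    np.clip(rng.normal(1.0, cal.segment_length_cv), 0.4, 1.8)
                )
                p_new = clip_inside(positions[node_id] + length * new_dir)
                actual_len = float(np.linalg.norm(p_new - positions[node_id]))
                if actual_len < cal.min_segment_length:
                    continue  # clipped to a wall; drop this branch
                new_id = len(positions)
                positions.append(p_new)
                radii.append(float(d_new) / 2.0)
                tree_ids.append(tree)
                segments.append((node_id, new_id))
                total_volume += float(
                    _frustum_volume(
                        np.asarray(radii[node_id]), np.asarray(d_new / 2.0),
                        np.asarray(actual_len),
                    )
                )
                n_tree_segments += 1
                if cal.radius_mode == "murray" and d_new <= cal.min_diameter:
                    continue  # terminal capillary
                frontier.append((new_id, new_dir, float(d_new)))
        tree += 1

    if not segments:
        raise CalibrationError("no segments generated (degenerate calibration)")

    nodes = np.asarray(positions)
    radii_arr = np.asarray(radii)
    segs = np.asarray(segments, dtype=int)
    tree_arr = np.asarray(tree_ids)

    # --- capillary cross-links between nearby nodes of different trees ---
    n_cross = int(round(cal.cross_link_fraction * len(segs)))
    if n_cross > 0 and tree > 1:
        kdt = cKDTree(nodes)
        pairs = kdt.query_pairs(r=2.0 * cal.mean_segment_length, output_type="ndarray")
        if len(pairs):
            mask = tree_arr[pairs[:, 0]] != tree_arr[pairs[:, 1]]
            dist = np.linalg.norm(nodes[pairs[:, 0]] - nodes[pairs[:, 1]], axis=1)
            mask &= dist > cal.min_segment_length
            pairs = pairs[mask]
            if len(pairs):
                pick = rng.choice(len(pairs), size=min(n_cross, len(pairs)),
                                  replace=False)
                existing = {tuple(sorted(s)) for s in segs.tolist()}
                extra = [tuple(sorted(p)) for p in pairs[pick].tolist()
                         if tuple(sorted(p)) not in existing]
                if extra:
                    segs = np.vstack([segs, np.asarray(extra, dtype=int)])

    net = VesselNetwork(
        nodes=nodes,
        radii=radii_arr,
        segments=segs,
        metadata={
            "seed": int(seed),
            "domain_size": domain.tolist(),
            "calibration": {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                            for k, v in asdict(cal).items()},
            "n_trees": tree,
        },
    )
    net.validate()
    return net


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


@dataclass
class NetworkStats:
    segment_count: int
    mean_diameter: float  # µm; per-segment diameter = sum of endpoint radii
    min_diameter: float
    max_diameter: float
    total_length: float  # µm
    total_volume: float  # µm³ (frustum sum)
    mean_segment_volume: float  # µm³
    volume_fraction: float | None  # only when a domain volume is known


def network_stats(
    net: VesselNetwork, domain_volume: float | None = None
) -> NetworkStats:
    """Summary statistics of a network.

    Per-segment volume is the conical frustum spanned by the two nodal radii;
    per-segment diameter is the mean of the two endpoint diameters.  The
    volume fraction is total vessel volume over ``domain_volume`` (falls back
    to the generating domain recorded in the metadata, if any).
    """
    if net.n_segments == 0:
        raise ValueError("cannot compute statistics of an empty network")
    a, b = net.segments[:, 0], net.segments[:, 1]
    lengths = net.segment_lengths()
    r0, r1 = net.radii[a], net.radii[b]
    diameters = r0 + r1  # = (2 r0 + 2 r1) / 2
    volumes = _frustum_volume(r0, r1, lengths)
    if domain_volume is None and "domain_size" in net.metadata:
        domain_volume = float(np.prod(net.metadata["domain_size"]))
    vf = float(volumes.sum() / domain_volume) if domain_volume else None
    return NetworkStats(
        segment_count=int(net.n_segments),
        mean_diameter=float(diameters.mean()),
        min_diameter=float(diameters.min()),
        max_diameter=float(diameters.max()),
        total_length=float(lengths.sum()),
        total_volume=float(volumes.sum()),
        mean_segment_volume=float(volumes.mean()),
        volume_fraction=vf,
    )


# ---------------------------------------------------------------------------
# tissue image
# ---------------------------------------------------------------------------

DEFAULT_SPACING_UM = 5.92  # isotropic voxel size of the source imaging
FOREGROUND_INTENSITY = 200.0
BACKGROUND_INTENSITY = 40.0
DEFAULT_THRESHOLD = 128.0
VESSEL_INTENSITY = 255.0


def generate_tissue_image(
    domain_size: Sequence[float],
    spacing: float | Sequence[float] = DEFAULT_SPACING_UM,
    net: VesselNetwork | None = None,
    seed: int = 0,
    shape: str = "block",
    corner_radius_frac: float = 0.08,
    noise_sd: float = 5.0,
) -> VoxelImage:
    """Rasterize a brain-block (or sphere) tissue mask into an intensity volume.

    Foreground voxels get intensity ~200, background ~40, so the default
    segmentation threshold of 128 separates them under the ±3σ noise band.
    ``shape="block"`` fills the domain with a box with rounded corners
    (a smooth stand-in for the smoothed outer brain surface);
    ``shape="sphere"`` inscribes a ball (used for analytic-volume checks);
    ``shape="full"`` fills everything.  If ``net`` is given, voxels whose
    centre lies within a segment's radius of its centreline are marked with
    the vessel intensity (255).
    """
    import warnings

    domain = np.asarray(domain_size, dtype=float).ravel()
    sp = np.broadcast_to(np.asarray(spacing, dtype=float).ravel(), (3,)).copy()
    if np.any(sp <= 0):
        raise ConfigError("spacing must be positive")
    dims = np.maximum(np.round(domain / sp).astype(int), 1)
    rng = np.random.default_rng(seed)

    centers = [
        (np.arange(n) + 0.5) * s for n, s in zip(dims, sp)
    ]
    X, Y, Z = np.meshgrid(*centers, indexing="ij")

    if shape == "full":
        mask = np.ones(tuple(dims), dtype=bool)
    elif shape == "sphere":
        c = domain / 2.0
        r = domain.min() / 2.0
        mask = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r**2
    elif shape == "block":
        # box with rounded corners: signed distance of a rounded box
        rc = corner_radius_frac * domain.min()
        half = domain / 2.0 - rc
        qx = np.maximum(np.abs(X - domain[0] / 2) - half[0], 0.0)
        qy = np.maximum(np.abs(Y - domain[1] / 2) - half[1], 0.0)
        qz = np.maximum(np.abs(Z - domain[2] / 2) - half[2], 0.0)
        mask = qx**2 + qy**2 + qz**2 <= rc**2
    else:
        raise ConfigError(f"unknown tissue shape {shape!r}")

    img = np.where(mask, FOREGROUND_INTENSITY, BACKGROUND_INTENSITY)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
        # keep the two classes strictly separated by the default threshold
        img = np.where(
            mask,
            np.clip(img, DEFAULT_THRESHOLD + 1.0, None),
            np.clip(img, None, DEFAULT_THRESHOLD - 1.0),
        )

    if net is not None:
        if sp.max() > net.radii.min():
            warnings.warn(
                "voxel spacing coarser than the smallest vessel radius; "
                "thin vessels may not be rasterized",
                stacklevel=2,
            )
        img = _stamp_vessels(img, sp, net)

    return VoxelImage(intensities=img, spacing=sp, origin=np.zeros(3))


def _stamp_vessels(img: np.ndarray, sp: np.ndarray, net: VesselNetwork) -> np.ndarray:
    out = img.copy()
    dims = np.asarray(img.shape)
    for (ia, ib) in net.segments:
        pa, pb = net.nodes[ia], net.nodes[ib]
        ra, rb = net.radii[ia], net.radii[ib]
        length = np.linalg.norm(pb - pa)
        n_pts = max(int(np.ceil(2 * length / sp.min())), 2)
        ts = np.linspace(0.0, 1.0, n_pts)
        for t in ts:
            p = pa + t * (pb - pa)
            r = ra + t * (rb - ra)
            lo = np.maximum(np.floor((p - r) / sp - 0.5).astype(int), 0)
            hi = np.minimum(np.ceil((p + r) / sp - 0.5).astype(int) + 1, dims)
            if np.any(hi <= lo):
                continue
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            gx = [(np.arange(l, h) + 0.5) * s for l, h, s in zip(lo, hi, sp)]
            LX, LY, LZ = np.meshgrid(*gx, indexing="ij")
            ball = (LX - p[0]) ** 2 + (LY - p[1]) ** 2 + (LZ - p[2]) ** 2 <= r**2
            region = out[sl]
            region[ball] = VESSEL_INTENSITY
    return out


# ---------------------------------------------------------------------------
# CCI scenario
# ---------------------------------------------------------------------------

_SCENARIO_REQUIRED = ("impact_depth", "impact_velocity", "impactor_radius")

_SCENARIO_DEFAULTS = {
    "impact_depth": 2000.0,  # µm: 2 mm cortical impact
    "impact_velocity": 4000.0,  # µm/ms (assumed surgical default)
    "impactor_radius": 2500.0,  # µm (assumed)
    "dwell_time": 0.1,  # ms (assumed)
    "retract": True,
    "total_sim_time": None,
    "edge_fillet": 0.0,
}


def make_cci_scenario(config: dict | None = None) -> CCIScenario:
    """Build a validated CCI scenario from a flat config dict.

    Missing keys fall back to the documented defaults; only the 2 mm impact
    depth is anchored in the experiment this pipeline emulates, the impactor
    geometry and speed are explicit assumptions.  Unknown keys raise
    ``ConfigError`` listing them, as do invalid values.
    """
    cfg = dict(_SCENARIO_DEFAULTS)
    if config:
        unknown = sorted(set(config) - set(_SCENARIO_DEFAULTS))
        if unknown:
            raise ConfigError(f"unknown scenario fields: {unknown}")
        cfg.update(config)
    missing = [k for k in _SCENARIO_REQUIRED if cfg.get(k) is None]
    if missing:
        raise ConfigError(f"scenario missing required fields: {missing}")
    return CCIScenario(**cfg)
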