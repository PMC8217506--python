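"""Mapping of peak vessel axial stress onto tissue elements and exceedance areas.

Each tissue element is assigned the maximum (over neighbouring beams and
over time) vessel axial stress; thresholding the map on a coronal slice
yields the brain-area exceedance metrics that are compared against
histological markers of blood-brain-barrier damage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .errors import ConfigError
from .meshing import BeamMesh, HexMesh
from .solver import SimulationHistory

__all__ = [
    "VesselStressMap",
    "DEFAULT_THRESHOLDS_KPA",
    "map_vessel_stress",
    "threshold_area",
    "regress_area_vs_observation",
]

DEFAULT_THRESHOLDS_KPA = (150.0, 200.0, 250.0, 300.0)


@dataclass
class VesselStressMap:
    """Per-element peak vessel axial stress (kPa).

    ``value`` is NaN for elements with no beam in their neighbourhood (an
    explicit "no vessel" marker, never zero); ``provenance`` holds the beam
    element that produced the maximum (-1 where none).
    """

    value: np.ndarray  # (E,)
    provenance: np.ndarray  # (E,)
    neighbourhood_radius: float
    tensile_only: bool = True
    metadata: dict = field(default_factory=dict)

    @property
    def has_vessel(self) -> np.ndarray:
        return ~np.isnan(self.value)


def map_vessel_stress(
    history: SimulationHistory,
    mesh: HexMesh,
    beams: BeamMesh,
    neighbourhood_radius: float | None = None,
    tensile_only: bool = True,
) -> VesselStressMap:
    """Assign each hex element the peak axial stress of nearby beams.

    The neighbourhood is a ball of ``neighbourhood_radius`` (default: one
    element edge length) around the undeformed element centroid, gathered
    over undeformed beam midpoints.  The per-beam peak is the maximum over
    all output frames; with ``tensile_only`` (default) compressive stress is
    clipped at zero before taking the maximum, so the map reflects tension.
    """
    if neighbourhood_radius is None:
        if mesh.element_size is None:
            raise ConfigError(
                "neighbourhood_radius required for meshes without a uniform "
                "element size"
            )
        neighbourhood_radius = float(mesh.element_size)
    if neighbourhood_radius <= 0:
        raise ConfigError("neighbourhood_radius must be positive")
    if history.beam_stress.shape[1] != beams.n_elements:
        raise ConfigError("history does not match the beam mesh")

    peak = history.beam_stress.copy()
    if tensile_only:
        peak = np.maximum(peak, 0.0)
    peak = peak.max(axis=0)  # (B,)

    centroids = mesh.centroids()
    mids = beams.midpoints()
    kdt = cKDTree(mids)
    neigh = kdt.query_ball_point(centroids, r=neighbourhood_radius)

    value = np.full(mesh.n_elements, np.nan)
    prov = np.full(mesh.n_elements, -1, dtype=int)
    for e, idx in enumerate(neigh):
        if not idx:
            continue
        idx = np.asarray(idx)
        k = idx[np.argmax(peak[idx])]
        value[e] = peak[k]
        prov[e] = k
    return VesselStressMap(
        value=value,
        provenance=prov,
        neighbourhood_radius=float(neighbourhood_radius),
        tensile_only=tensile_only,
    )


def threshold_area(
    vmap: VesselStressMap,
    mesh: HexMesh,
    thresholds=DEFAULT_THRESHOLDS_KPA,
    roi: int | None = None,
    slice_axis: int = 1,
    slice_coord: float | None = None,
) -> dict:
    """Exceedance area per threshold on a coronal element slice.

    The slice is the element layer whose centroids are nearest to
    ``slice_coord`` along ``slice_axis`` (default: the mid-plane of axis 1).
    Area = (number of slice elements, restricted to ``roi`` if given, whose
    mapped value exceeds the threshold) × element face area, reported in mm²
    together with the fraction of the ROI slice area.  Monotone
    non-increasing in the threshold by construction.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ConfigError("thresholds must be sorted ascending")
    if mesh.element_size is None:
        raise ConfigError("threshold areas need a uniform element size")
    centroids = mesh.centroids()
    coords = centroids[:, slice_axis]
    if slice_coord is None:
        slice_coord = 0.5 * (coords.min() + coords.max())
    layers = np.unique(np.round(coords, 6))
    layer = layers[np.argmin(np.abs(layers - slice_coord))]
    in_slice = np.abs(coords - layer) < 1e-6

    if roi is not None:
        labels = np.unique(mesh.region_labels)
        if roi not in labels:
            raise ConfigError(f"unknown ROI label {roi!r} (have {labels.tolist()})")
        in_slice &= mesh.region_labels == roi

    face_area_mm2 = (mesh.element_size * 1e-3) ** 2
    roi_count = int(in_slice.sum())
    vals = vmap.value[in_slice]
    areas = {}
    fractions = {}
    for thr in thresholds:
        cnt = int(np.sum(vals > thr))  # NaN (no vessel) compares False
        areas[float(thr)] = cnt * face_area_mm2
        fractions[float(thr)] = cnt / roi_count if roi_count else 0.0
    return {
        "area_mm2": areas,
        "fraction": fractions,
        "roi_slice_area_mm2": roi_count * face_area_mm2,
        "slice_coord": float(layer),
        "slice_axis": slice_axis,
    }


def regress_area_vs_observation(areas, observations):
    """OLS of observed extravasation area on predicted exceedance area.

    Returns (slope, intercept, r_squared, p_value) with the two-sided p for
    the slope.  Requires >= 3 paired samples and non-degenerate predictor.
    """
    x = np.asarray(areas, dtype=float)
    y = np.asarray(observations, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("areas and observations must be matching 1D arrays")
    if len(x) < 3:
        raise ConfigError("need at least 3 paired samples")
    if np.ptp(x) == 0:
        raise ConfigError("zero variance in the predictor")
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )
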