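"""Vessel-direction vs parenchymal stress/strain statistics.

For every beam element and output frame this module joins the vessel axial
stress with the stress and strain state of the neighbouring tissue (the host
element of the beam midpoint), decomposes the tensors into principal and
deviatoric parts, and computes the angle between the vessel axis and the
first principal directions.  On top of that table it provides Pearson /
first-order partial correlations, log-linear regression, and the
tension-vs-compression ROC of the angle predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .meshing import BeamMesh, HexMesh
from .solver import CouplingMap, SimulationHistory, point_locate

logger = logging.getLogger(__name__)

__all__ = [
    "beam_direction",
    "principal_decomposition",
    "deviatoric_part",
    "vessel_angle",
    "build_records",
    "correlation_suite",
    "tension_compression_roc",
    "CorrelationResult",
    "RocResult",
]


# ---------------------------------------------------------------------------
# tensor / direction primitives
# ---------------------------------------------------------------------------


def beam_direction(node_a, node_b) -> np.ndarray:
    """Unit vector along a beam; downstream use is sign-free."""
    a = np.asarray(node_a, dtype=float)
    b = np.asarray(node_b, dtype=float)
    d = b - a
    n = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("coincident beam nodes have no direction")
    return d / n


def principal_decomposition(tensor: np.ndarray):
    """Eigenvalues (descending) and matching orthonormal eigenvectors.

    Accepts a batch (..., 3, 3); input must be symmetric to 1e-9 relative.
    Eigenvectors are returned as columns: ``vectors[..., :, i]`` belongs to
    ``values[..., i]``.
    """
    A = np.asarray(tensor, dtype=float)
    norm = np.linalg.norm(A, axis=(-2, -1), keepdims=True)
    asym = np.linalg.norm(A - np.swapaxes(A, -1, -2), axis=(-2, -1))
    if np.any(asym > 1e-9 * np.maximum(norm[..., 0, 0], 1e-30)):
        raise ValueError("tensor is not symmetric")
    w, V = np.linalg.eigh(A)
    # eigh sorts ascending; flip to descending
    return w[..., ::-1], V[..., :, ::-1]


def deviatoric_part(tensor: np.ndarray) -> np.ndarray:
    """dev(A) = A - tr(A)/3 I, batched."""
    A = np.asarray(tensor, dtype=float)
    tr = np.trace(A, axis1=-2, axis2=-1)
    return A - tr[..., None, None] / 3.0 * np.eye(3)


def vessel_angle(direction, principal_direction) -> np.ndarray:
    """Angle in degrees in [0, 90] between a vessel axis and a principal
    direction; sign-free through the absolute dot product."""
    d = np.asarray(direction, dtype=float)
    p = np.asarray(principal_direction, dtype=float)
    for v, name in ((d, "direction"), (p, "principal_direction")):
        n = np.linalg.norm(v, axis=-1)
        if np.any(np.abs(n - 1.0) > 1e-6):
            raise ValueError(f"{name} must be a unit vector")
    c = np.clip(np.abs(np.sum(d * p, axis=-1)), 0.0, 1.0)
    return np.degrees(np.arccos(c))


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


def build_records(
    history: SimulationHistory,
    mesh: HexMesh,
    beams: BeamMesh,
    coupling: CouplingMap | None = None,
) -> pd.DataFrame:
    """One row per (beam element, output frame) joining vessel and tissue state.

    The neighbouring tissue of a beam is the host element of its undeformed
    midpoint.  Columns: time [ms], beam, host_element, axial_stress [kPa],
    dir_{xyz}, s1 / s1_dev [kPa] and e1 / e1_dev (first principal total and
    deviatoric stress/strain), angle_stress / angle_stress_dev /
    angle_strain / angle_strain_dev [deg].
    """
    if history.beam_stress.shape[1] != beams.n_elements:
        raise ConfigError("history does not match the beam mesh")
    host, _ = point_locate(mesh, beams.midpoints())
    nF, nB = history.beam_stress.shape

    sig = history.hex_stress[:, host]  # (F, B, 3, 3)
    eps = history.hex_strain[:, host]
    dirs = history.beam_direction  # (F, B, 3)

    def principal_and_angle(T):
        w, V = np.linalg.eigh(T.reshape(-1, 3, 3))
        first = w[:, -1].reshape(nF, nB)
        vec = V[:, :, -1].reshape(nF, nB, 3)
        cosang = np.clip(np.abs(np.sum(dirs * vec, axis=-1)), 0.0, 1.0)
        return first, np.degrees(np.arccos(cosang))

    s1, ang_s = principal_and_angle(sig)
    s1d, ang_sd = principal_and_angle(deviatoric_part(sig))
    e1, ang_e = principal_and_angle(eps)
    e1d, ang_ed = principal_and_angle(deviatoric_part(eps))

    tgrid = np.repeat(history.times, nB)
    bgrid = np.tile(np.arange(nB), nF)
    return pd.DataFrame(
        {
            "time": tgrid,
            "beam": bgrid,
            "host_element": np.tile(host, nF),
            "axial_stress": history.beam_stress.ravel(),
            "dir_x": dirs[..., 0].ravel(),
            "dir_y": dirs[..., 1].ravel(),
            "dir_z": dirs[..., 2].ravel(),
            "s1": s1.ravel(),
            "s1_dev": s1d.ravel(),
            "e1": e1.ravel(),
            "e1_dev": e1d.ravel(),
            "angle_stress": ang_s.ravel(),
            "angle_stress_dev": ang_sd.ravel(),
            "angle_strain": ang_e.ravel(),
            "angle_strain_dev": ang_ed.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    r: float
    p: float
    partial_r: float | None
    slope: float
    intercept: float
    r_squared: float
    n_used: int
    n_dropped: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def correlation_suite(
    records: pd.DataFrame,
    x: str,
    y: str,
    control: str | None = None,
    transform: str | None = None,
) -> CorrelationResult:
    """Pearson R (two-sided p), optional first-order partial R, and OLS of
    (optionally log10-transformed) ``y`` on ``x``.

    ``transform="log10"`` drops rows with non-positive ``y`` (count logged
    and reported).  The partial correlation controls for ``control``:
    r_xy.z = (r_xy - r_xz r_zy) / sqrt((1 - r_xz²)(1 - r_zy²)).
    """
    cols = [x, y] + ([control] if control else [])
    df = records[cols].dropna()
    n_dropped = 0
    yv = df[y].to_numpy()
    if transform == "log10":
        keep = yv > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("log10 transform dropped %d non-positive rows", n_dropped)
        df = df[keep]
        yv = np.log10(df[y].to_numpy())
    elif transform not in (None, "none"):
        raise ConfigError(f"unknown transform {transform!r}")
    if len(df) < 3:
        raise ConfigError("fewer than 3 records after filtering")
    xv = df[x].to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ConfigError("zero variance in x or y")

    r, p = stats.pearsonr(xv, yv)
    partial = None
    if control:
        zv = df[control].to_numpy()
        if np.ptp(zv) == 0:
            raise ConfigError("zero variance in the control variable")
        rxz = _pearson(xv, zv)
        rzy = _pearson(zv, yv)
        num = r - rxz * rzy
        den = np.sqrt(max((1 - rxz**2) * (1 - rzy**2), 0.0))
        if den < 1e-12:
            # control collinear with x or y: the residual variance is zero,
            # so the partial correlation is 0 if the numerator also vanishes
            if abs(num) < 1e-12:
                partial = 0.0
            else:
                raise ConfigError(
                    "control variable collinear with x or y; partial "
                    "correlation undefined"
                )
        else:
            partial = num / den
    reg = stats.linregress(xv, yv)
    return CorrelationResult(
        r=float(r),
        p=float(p),
        partial_r=None if partial is None else float(partial),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
        n_used=int(len(df)),
        n_dropped=n_dropped,
    )


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_tension: int
    n_compression: int


def _rank_auc(score: np.ndarray, label: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic, ties counted half."""
    ranks = stats.rankdata(score)
    n_pos = int(label.sum())
    n_neg = len(label) - n_pos
    u = ranks[label].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def tension_compression_roc(
    records: pd.DataFrame,
    predictor: str = "angle_stress",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Can the vessel-to-principal-direction angle separate tension from
    compression?

    Records with axial stress exactly 0 are excluded.  A smaller angle
    predicts tension, so the score is the negated predictor.  The 95% CI is
    a stratified bootstrap (resampling tension and compression records
    separately).
    """
    df = records[[predictor, "axial_stress"]].dropna()
    df = df[df["axial_stress"] != 0.0]
    label = (df["axial_stress"] > 0).to_numpy()
    if label.all() or not label.any():
        raise ConfigError("both tension and compression records are required")
    score = -df[predictor].to_numpy()  # small angle -> tension

    auc = _rank_auc(score, label)
    rng = np.random.default_rng(seed)
    pos = score[label]
    neg = score[~label]
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        s = np.concatenate([bp, bn])
        lab = np.zeros(len(s), dtype=bool)
        lab[: len(bp)] = True
        boots[i] = _rank_auc(s, lab)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(
        auc=float(auc),
        ci_low=float(lo),
        ci_high=float(hi),
        n_tension=int(label.sum()),
        n_compression=int((~label).sum()),
    )
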