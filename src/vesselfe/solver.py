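"""Explicit central-difference dynamics for hex meshes with embedded beams.

The tissue mesh is integrated with one-point (reduced) integration and
viscous hourglass control; vessels are two-node axial members whose nodes
are slaved to their host hexahedron through trilinear interpolation
(constraint-based beam-in-solid coupling), with beam internal forces
distributed back to the host nodes with the transposed weights.  A rigid
flat-tipped cylindrical impactor is driven by the CCI scenario through a
penalty contact.  Submodels re-run a refined region of interest with
displacement boundary conditions interpolated from a parent solution.

Internal unit system: µm, ms, kPa, with densities scaled so the system is
consistent (kg/m³ × 1e-9); velocities in µm/ms numerically equal m/s.  All
interfaces use µm / ms / kPa / kg/m³.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from . import hexutil
from .errors import CouplingError, SolverError, InstabilityError, ConfigError
from ._kernels import hex_step
from .materials import OgdenPronyMaterial, VesselMaterial
from .meshing import BeamMesh, HexMesh, SubModel
from .synthetic import CCIScenario

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingMap",
    "SimulationHistory",
    "SolverControls",
    "PrescribedMotion",
    "point_locate",
    "build_coupling",
    "stable_timestep",
    "run_macro",
    "run_submodel",
]

# density (kg/m³) → internal mass unit so that µm/ms/kPa is consistent
_DENSITY_SCALE = 1e-9
_EYE3 = np.eye(3)
# The 1D CFL estimate L/c is optimistic in 3D: the triaxial dilatational
# mode of a hexahedron is a factor sqrt(3) stiffer, so the integrator runs
# at half the 1D estimate (margin below 1/sqrt(3) ≈ 0.577).
_MODE_FACTOR = 0.5


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class CouplingMap:
    """Host element and natural coordinates for every beam node."""

    host_element: np.ndarray  # (nb,)
    natural: np.ndarray  # (nb, 3)
    weights: np.ndarray  # (nb, 8) cached shape-function values


@dataclass
class SimulationHistory:
    """Output frames sampled at a fixed interval (default 0.01 ms).

    Positions in µm, stresses in kPa, strains dimensionless (Green-Lagrange),
    beam directions are current-configuration unit vectors.
    """

    times: np.ndarray  # (F,)
    positions: np.ndarray  # (F, N, 3)
    hex_stress: np.ndarray  # (F, E, 3, 3) Cauchy
    hex_strain: np.ndarray  # (F, E, 3, 3) Green-Lagrange
    beam_stress: np.ndarray  # (F, B) axial, tension positive
    beam_direction: np.ndarray  # (F, B, 3)
    beam_positions: np.ndarray | None = None  # (F, Bn, 3) slaved node positions
    energy: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def displacements(self, reference: np.ndarray) -> np.ndarray:
        return self.positions - reference[None, :, :]


@dataclass
class PrescribedMotion:
    """Displacement-driven node set: ``positions_at(t)`` returns (k, 3) µm."""

    node_ids: np.ndarray
    positions_at: Callable[[float], np.ndarray]


@dataclass
class SolverControls:
    output_interval: float = 0.01  # ms
    safety: float = 0.9
    hourglass_coeff: float = 0.05  # viscous part
    hourglass_stiffness: float = 0.2  # elastic part, × instantaneous shear
    contact_stiffness_scale: float = 0.1  # × nodal m/dt²
    contact_damping: float = 0.2  # fraction of critical
    energy_tolerance: float = 0.05
    check_energy: bool = True
    total_time: float | None = None  # ms; default from the scenario
    fix_bottom: bool = True
    # "free" lateral faces, or "symmetric_y": zero normal motion on the two
    # y-extreme faces (plane-strain-like confinement, emulating skull
    # constraint transverse to the section of interest)
    lateral_bc: str = "free"
    impactor_center: tuple | None = None  # (x, y) µm; default mesh centre
    prescribed: PrescribedMotion | None = None
    initial_velocity: np.ndarray | None = None  # (N, 3) µm/ms


# ---------------------------------------------------------------------------
# coupling
# ---------------------------------------------------------------------------


def point_locate(
    mesh: HexMesh,
    points: np.ndarray,
    k_candidates: int = 27,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Find the host element and natural coordinates of interior points.

    Candidate elements come from a centroid KD-tree; containment is decided
    by the Newton inverse isoparametric map (|xi| <= 1 + tol).  Points on
    shared faces are assigned to the containing element with the lowest id.

    Raises ``CouplingError`` listing the points outside every element.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    ecoords = mesh.element_coords()
    kdt = cKDTree(mesh.centroids())
    k = min(k_candidates, mesh.n_elements)
    _, cand = kdt.query(points, k=k)
    cand = np.atleast_2d(cand)
    if cand.shape[0] != n:
        cand = cand.reshape(n, -1)

    host = np.full(n, -1, dtype=int)
    xi_out = np.zeros((n, 3))
    flat_pts = np.repeat(points, cand.shape[1], axis=0)
    flat_el = cand.ravel()
    xi, conv = hexutil.inverse_map(ecoords[flat_el], flat_pts)
    inside = conv & np.all(np.abs(xi) <= 1.0 + tol, axis=1)
    inside = inside.reshape(n, -1)
    xi = xi.reshape(n, -1, 3)
    for i in range(n):
        ok = np.nonzero(inside[i])[0]
        if len(ok) == 0:
            continue
        pick = ok[np.argmin(cand[i, ok])]  # lowest element id wins ties
        host[i] = cand[i, pick]
        xi_out[i] = xi[i, pick]
    missing = np.nonzero(host < 0)[0]
    if len(missing):
        raise CouplingError(
            f"{len(missing)} point(s) outside every element "
            f"(first ids: {missing[:10].tolist()})"
        )
    return host, np.clip(xi_out, -1.0, 1.0)


def build_coupling(mesh: HexMesh, beams: BeamMesh) -> CouplingMap:
    """Tie every beam node to its host hexahedron.

    The inverse isoparametric map is solved by Newton iteration; the
    round-trip reconstruction ``sum_a N_a(xi) x_a`` must match the beam node
    position to 1e-9 µm (relative to the element size), else the node is
    reported.
    """
    host, xi = point_locate(mesh, beams.nodes)
    W = hexutil.shape_functions(xi)  # (nb, 8)
    recon = np.einsum("na,nai->ni", W, mesh.nodes[mesh.elements[host]])
    err = np.linalg.norm(recon - beams.nodes, axis=1)
    scale = np.maximum(np.abs(beams.nodes).max(), 1.0)
    bad = np.nonzero(err > 1e-9 * scale)[0]
    if len(bad):
        raise CouplingError(
            f"coupling round-trip residual too large for beam node(s) "
            f"{bad[:10].tolist()} (max {err.max():.3e} µm)"
        )
    return CouplingMap(host_element=host, natural=xi, weights=W)


# ---------------------------------------------------------------------------
# timestep
# ---------------------------------------------------------------------------

_EDGES = np.array(
    [[0, 1], [1, 2], [2, 3], [3, 0], [4, 5], [5, 6], [6, 7], [7, 4],
     [0, 4], [1, 5], [2, 6], [3, 7]]
)


def stable_timestep(
    mesh: HexMesh,
    beams: BeamMesh | None,
    tissue: OgdenPronyMaterial,
    vessel: VesselMaterial | None = None,
    safety: float = 0.9,
) -> float:
    """CFL-stable timestep (ms): safety × min element length / wave speed."""
    if tissue.density <= 0:
        raise ValueError("zero or negative tissue density")
    ec = mesh.element_coords()
    edge_len = np.linalg.norm(
        ec[:, _EDGES[:, 1], :] - ec[:, _EDGES[:, 0], :], axis=2
    ).min(axis=1)
    c_t = tissue.dilatational_wave_speed() * 1e3  # m/s -> µm/ms
    dt = (edge_len / c_t).min()
    if beams is not None and beams.n_elements > 0:
        if vessel is None:
            raise ValueError("vessel material required when beams are present")
        dt_b = (beams.lengths() / (vessel.wave_speed() * 1e3)).min()
        # slaved beam nodes inherit tissue mass; the beam CFL is still a
        # conservative guard for stiff thin vessels
        dt = min(dt, dt_b)
    return float(safety * dt)


def _run_dt(
    mesh: HexMesh,
    beams: BeamMesh | None,
    tissue: OgdenPronyMaterial,
    vessel: VesselMaterial | None,
    safety: float,
) -> float:
    """Integration timestep actually used by the explicit loop.

    The tissue CFL estimate is reduced by ``_MODE_FACTOR`` (triaxial mode).
    Beam nodes are slaved to the solid, so instead of the free-truss CFL the
    beams are limited by the axial-spring criterion on the lightest host
    node: dt <= sqrt(m_min / k_max) with k = E A / L (a factor-2 margin
    below the exact 2/omega bound).
    """
    dt = _MODE_FACTOR * stable_timestep(mesh, None, tissue, None, safety)
    if beams is not None and beams.n_elements > 0 and vessel is not None:
        ec = mesh.element_coords()
        v_min = hexutil.hex_volumes(ec).min()
        m_min = tissue.density * _DENSITY_SCALE * v_min / 8.0
        A0 = np.pi * beams.element_radii() ** 2
        k_max = (vessel.elastic_modulus * A0 / beams.lengths()).max()
        dt = min(dt, safety * float(np.sqrt(m_min / k_max)))
    return dt


# ---------------------------------------------------------------------------
# integrator core
# ---------------------------------------------------------------------------


class _Contact:
    """Rigid flat-tipped cylindrical impactor, penalty normal contact."""

    def __init__(self, scenario: CCIScenario, mesh: HexMesh,
                 controls: SolverControls, masses: np.ndarray, dt: float):
        self.scenario = scenario
        x, y = (
            controls.impactor_center
            if controls.impactor_center is not None
            else (
                0.5 * (mesh.nodes[:, 0].min() + mesh.nodes[:, 0].max()),
                0.5 * (mesh.nodes[:, 1].min() + mesh.nodes[:, 1].max()),
            )
        )
        self.cx, self.cy = x, y
        self.z_top = mesh.nodes[:, 2].max()
        height = self.z_top - mesh.nodes[:, 2].min()
        if scenario.impact_depth > height:
            raise ConfigError(
                f"impact depth {scenario.impact_depth} µm exceeds block height "
                f"{height} µm"
            )
        self.r2 = scenario.impactor_radius**2
        self.k = controls.contact_stiffness_scale * masses / dt**2
        self.c = 2.0 * controls.contact_damping * np.sqrt(self.k * masses)

    def force(self, t: float, x: np.ndarray, v: np.ndarray) -> np.ndarray:
        ind = float(self.scenario.indentation(t))
        z_face = self.z_top - ind
        radial2 = (x[:, 0] - self.cx) ** 2 + (x[:, 1] - self.cy) ** 2
        cand = radial2 <= self.r2
        f = np.zeros_like(x)
        if cand.any():
            surf = z_face + self.scenario.face_height(np.sqrt(radial2[cand]))
            g = x[cand, 2] - surf
            pen = g > 0
            fz = np.where(pen,
                          -self.k[cand] * g - self.c[cand] * v[cand, 2], 0.0)
            f[cand, 2] = np.minimum(np.where(pen, fz, 0.0), 0.0)  # no adhesion
        return f


def _run_explicit(
    mesh: HexMesh,
    beams: BeamMesh | None,
    tissue: OgdenPronyMaterial,
    vessel: VesselMaterial | None,
    controls: SolverControls,
    total_time: float,
    contact: _Contact | None = None,
    coupling: CouplingMap | None = None,
    x0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    dt: float | None = None,
    t_start: float = 0.0,
) -> SimulationHistory:
    X = mesh.nodes
    elems = mesh.elements
    nE = mesh.n_elements
    nN = mesh.n_nodes

    # reference kinematics (one-point integration)
    J0 = np.einsum("eai,aj->eij", X[elems], hexutil.CENTER_GRADIENTS)
    detJ0 = np.linalg.det(J0)
    if np.any(detJ0 <= 0):
        raise SolverError(f"inverted reference element {int(np.argmin(detJ0))}")
    V0 = 8.0 * detJ0
    # gradN w.r.t. reference coordinates: gradN_a = J0^{-T} dN_a/dxi
    gradN = np.einsum("eji,aj->eai", np.linalg.inv(J0), hexutil.CENTER_GRADIENTS)

    rho_t = tissue.density * _DENSITY_SCALE
    masses = np.zeros(nN)
    np.add.at(masses, elems.ravel(), np.repeat(rho_t * V0 / 8.0, 8))

    # hourglass base vectors (orthogonalized against the linear field)
    hg_pattern = np.stack(
        [
            hexutil.HEX_NATURAL[:, 0] * hexutil.HEX_NATURAL[:, 1],
            hexutil.HEX_NATURAL[:, 1] * hexutil.HEX_NATURAL[:, 2],
            hexutil.HEX_NATURAL[:, 0] * hexutil.HEX_NATURAL[:, 2],
            hexutil.HEX_NATURAL.prod(axis=1),
        ]
    )  # (4, 8)
    gX = np.einsum("ib,ebj->eij", hg_pattern, X[elems])  # (E, 4, 3)
    # normalized (1/sqrt(8)) hourglass base, orthogonalized against the
    # linear field so affine motions generate no hourglass force
    gamma = (hg_pattern[None, :, :]
             - np.einsum("eij,eaj->eia", gX, gradN)) / np.sqrt(8.0)
    c_t = tissue.dilatational_wave_speed() * 1e3  # µm/ms
    hg_coef = controls.hourglass_coeff * rho_t * c_t * V0 ** (2.0 / 3.0) / 4.0
    hg_stiff = (controls.hourglass_stiffness
                * tissue.instantaneous_shear_modulus * V0 ** (1.0 / 3.0))

    # beams
    have_beams = beams is not None and beams.n_elements > 0
    if have_beams:
        if coupling is None:
            coupling = build_coupling(mesh, beams)
        if vessel is None:
            raise ConfigError("vessel material required when beams are present")
        Wb = coupling.weights  # (nb, 8)
        host_nodes = elems[coupling.host_element]  # (nb, 8)
        be = beams.elements
        A0 = np.pi * beams.element_radii() ** 2
        L0 = beams.lengths()
        rho_v = vessel.density * _DENSITY_SCALE
        bmass = rho_v * A0 * L0
        node_bmass = np.zeros(beams.n_nodes)
        np.add.at(node_bmass, be.ravel(), np.repeat(bmass / 2.0, 2))
        np.add.at(
            masses, host_nodes.ravel(), (node_bmass[:, None] * Wb).ravel()
        )
        nB = beams.n_elements
    else:
        nB = 0

    if dt is None:
        dt = _run_dt(mesh, beams if have_beams else None, tissue, vessel,
                     controls.safety)
    n_steps = max(int(np.ceil(total_time / dt - 1e-12)), 1)
    dt = total_time / n_steps

    fixed = np.zeros(nN, dtype=bool)
    if controls.fix_bottom and contact is not None:
        fixed[X[:, 2] <= X[:, 2].min() + 1e-9] = True
    if controls.lateral_bc == "symmetric_y":
        sym_y = (X[:, 1] <= X[:, 1].min() + 1e-9) | \
                (X[:, 1] >= X[:, 1].max() - 1e-9)
    elif controls.lateral_bc == "free":
        sym_y = None
    else:
        raise ConfigError(f"unknown lateral_bc {controls.lateral_bc!r}")
    presc = controls.prescribed
    if presc is not None:
        fixed[presc.node_ids] = False  # prescribed overrides fixing

    x = X.copy() if x0 is None else np.asarray(x0, dtype=float).copy()
    v = np.zeros_like(x) if v0 is None else np.asarray(v0, dtype=float).copy()
    if controls.initial_velocity is not None:
        v = np.asarray(controls.initial_velocity, dtype=float).copy()
    v[fixed] = 0.0

    # viscoelastic internal variables and material constant arrays
    n_prony = len(tissue.prony_terms)
    G_arr = np.array([g for g, _ in tissue.prony_terms])
    tau_arr = np.array([tau for _, tau in tissue.prony_terms])
    decay = np.exp(-dt / tau_arr)
    h_coef = G_arr * (1.0 - decay) * tau_arr / dt
    h = np.zeros((nE, n_prony, 3, 3))
    E_prev = np.zeros((nE, 3, 3))
    K_bulk = tissue.bulk_modulus
    mu_arr = np.array([m for m, _ in tissue.ogden_terms])
    alpha_arr = np.array([a for _, a in tissue.ogden_terms])
    t_elem = np.zeros((nE, 8, 3))
    hg_elem = np.zeros((nE, 8, 3))
    sigma_buf = np.zeros((nE, 3, 3))
    eps_buf = np.zeros((nE, 3, 3))

    # output buffers
    n_frames = int(np.floor(total_time / controls.output_interval + 1e-9)) + 1
    out_t = np.empty(n_frames)
    out_x = np.empty((n_frames, nN, 3))
    out_sig = np.empty((n_frames, nE, 3, 3))
    out_eps = np.empty((n_frames, nE, 3, 3))
    out_bsig = np.empty((n_frames, nB))
    out_bdir = np.empty((n_frames, nB, 3))
    out_bpos = np.empty((n_frames, beams.n_nodes if have_beams else 0, 3))
    energy_log = {"time": [], "kinetic": [], "internal": [], "external": [],
                  "hourglass": []}

    W_ext = 0.0
    W_int = 0.0
    D_hg = 0.0
    frame = 0
    inv_m = 1.0 / masses[:, None]

    def hex_forces(xc, vc, update_state: bool, t_now: float):
        """Compiled element loop: stress, hourglass and nodal forces."""
        Jmin, Jarg = hex_step(
            xc[elems], vc[elems], (xc - X)[elems], gradN, gamma,
            hg_coef, hg_stiff, V0, mu_arr, alpha_arr, K_bulk,
            decay, h_coef, h, E_prev, update_state,
            t_elem, hg_elem, sigma_buf, eps_buf,
        )
        if Jmin <= 0.0:
            raise SolverError(
                f"element {Jarg} inverted or diverged at t={t_start + t_now:.5f} ms"
            )

    def scatter_add(f, contrib_flat):
        for i in range(3):
            f[:, i] += np.bincount(elems_flat, weights=contrib_flat[:, i],
                                   minlength=nN)

    elems_flat = elems.ravel()

    def beam_state(xc):
        xb = np.einsum("na,nai->ni", Wb, xc[host_nodes])
        d = xb[be[:, 1]] - xb[be[:, 0]]
        ell = np.linalg.norm(d, axis=1)
        dirs = d / ell[:, None]
        sigma = vessel.elastic_modulus * (ell / L0 - 1.0)
        return xb, dirs, sigma

    def record(t, xc, t_now=0.0):
        nonlocal frame
        hex_forces(xc, v, update_state=False, t_now=t_now)
        out_t[frame] = t
        out_x[frame] = xc
        out_sig[frame] = sigma_buf.copy()
        out_eps[frame] = eps_buf.copy()
        if have_beams:
            xb, dirs, bs = beam_state(xc)
            out_bsig[frame] = bs
            out_bdir[frame] = dirs
            out_bpos[frame] = xb
        ke = 0.5 * float((masses[:, None] * v**2).sum())
        energy_log["time"].append(t)
        energy_log["kinetic"].append(ke)
        energy_log["internal"].append(W_int)
        energy_log["external"].append(W_ext)
        energy_log["hourglass"].append(D_hg)
        frame += 1
        return ke

    logger.info(
        "explicit run: %d hex, %d beams, %d nodes, dt=%.3e ms, %d steps",
        nE, nB, nN, dt, n_steps,
    )

    record(t_start, x)
    next_out = controls.output_interval
    t = 0.0
    for step in range(n_steps):
        t_new = t + dt
        hex_forces(x, v, update_state=True, t_now=t)
        f_stress = np.zeros_like(x)
        scatter_add(f_stress, -t_elem.reshape(-1, 3))
        f_hg = np.zeros_like(x)
        scatter_add(f_hg, hg_elem.reshape(-1, 3))

        # beam internal forces, distributed to host nodes
        if have_beams:
            _, dirs, sigma_b = beam_state(x)
            Nf = sigma_b * A0  # axial force
            fb = np.zeros((beams.n_nodes, 3))
            np.add.at(fb, be[:, 0], Nf[:, None] * dirs)
            np.add.at(fb, be[:, 1], -Nf[:, None] * dirs)
            np.add.at(f_stress, host_nodes.ravel(),
                      (Wb[:, :, None] * fb[:, None, :]).reshape(-1, 3))

        fc = contact.force(t_new, x, v) if contact is not None else 0.0
        f = f_stress + f_hg + fc

        a = f * inv_m
        a[fixed] = 0.0
        if sym_y is not None:
            a[sym_y, 1] = 0.0
        v_new = v + dt * a
        v_new[fixed] = 0.0
        if sym_y is not None:
            v_new[sym_y, 1] = 0.0
        x_new = x + dt * v_new

        if presc is not None:
            ids = presc.node_ids
            xp = presc.positions_at(t_start + t_new)
            vp = (xp - x[ids]) / dt
            x_new[ids] = xp
            v_new[ids] = vp

        # work bookkeeping at midpoint velocities: makes the discrete
        # work-energy identity exact, so any drift flags an accounting or
        # constraint error rather than quadrature noise
        v_mid = 0.5 * (v + v_new)
        W_int -= float((f_stress * v_mid).sum()) * dt
        D_hg -= float((f_hg * v_mid).sum()) * dt
        if contact is not None:
            W_ext += float((fc * v_mid).sum()) * dt
        if presc is not None:
            fc_presc = masses[ids, None] * (v_new[ids] - v[ids]) / dt - f[ids]
            W_ext += float((fc_presc * v_mid[ids]).sum()) * dt

        v, x = v_new, x_new
        t = t_new

        if t >= next_out - 1e-9 and frame < n_frames:
            ke = record(t_start + t, x)
            next_out += controls.output_interval
            if controls.check_energy:
                scale = max(abs(W_ext), ke + abs(W_int), 1e-6)
                residual = (ke + W_int + D_hg) - W_ext
                if ke + abs(W_int) > 1e-4 and abs(residual) > \
                        controls.energy_tolerance * scale:
                    raise InstabilityError(
                        f"energy balance drift {residual:.3e} exceeds "
                        f"{controls.energy_tolerance:.0%} of {scale:.3e} "
                        f"at t={t_start + t:.4f} ms"
                    )

    for k in energy_log:
        energy_log[k] = np.asarray(energy_log[k])
    return SimulationHistory(
        times=out_t[:frame],
        positions=out_x[:frame],
        hex_stress=out_sig[:frame],
        hex_strain=out_eps[:frame],
        beam_stress=out_bsig[:frame],
        beam_direction=out_bdir[:frame],
        beam_positions=out_bpos[:frame] if have_beams else None,
        energy=energy_log,
        metadata={
            "dt": dt,
            "n_steps": n_steps,
            "n_elements": nE,
            "n_beams": nB,
            "n_nodes": nN,
        },
    )


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def run_macro(
    mesh: HexMesh,
    beams: BeamMesh | None,
    tissue: OgdenPronyMaterial,
    vessel: VesselMaterial | None,
    scenario: CCIScenario,
    controls: SolverControls | None = None,
    coupling: CouplingMap | None = None,
) -> SimulationHistory:
    """Macroscale CCI run: impactor contact on the top face, fixed bottom."""
    controls = controls or SolverControls()
    total = controls.total_time if controls.total_time is not None \
        else scenario.total_sim_time
    dt = _run_dt(mesh, beams, tissue, vessel, controls.safety)
    masses_proxy = np.zeros(mesh.n_nodes)
    # nodal masses for contact stiffness scaling (tissue only, adequate)
    J0 = np.einsum("eai,aj->eij", mesh.nodes[mesh.elements],
                   hexutil.CENTER_GRADIENTS)
    V0 = 8.0 * np.linalg.det(J0)
    np.add.at(masses_proxy, mesh.elements.ravel(),
              np.repeat(tissue.density * _DENSITY_SCALE * V0 / 8.0, 8))
    contact = None
    if scenario.impact_depth > 0:
        contact = _Contact(scenario, mesh, controls, masses_proxy, dt)
    return _run_explicit(
        mesh, beams, tissue, vessel, controls, total,
        contact=contact, coupling=coupling, dt=dt,
    )


def run_submodel(
    sub: SubModel,
    parent_history: SimulationHistory,
    parent_mesh: HexMesh,
    tissue: OgdenPronyMaterial,
    vessel: VesselMaterial | None = None,
    controls: SolverControls | None = None,
) -> SimulationHistory:
    """Re-run a refined region with parent-interpolated boundary displacements.

    Boundary (and initial) node positions are interpolated trilinearly in
    space through the stored parent natural coordinates and linearly in time
    between parent output frames; the interior is integrated explicitly
    without contact.
    """
    controls = controls or SolverControls()
    times = parent_history.times
    if len(times) < 2:
        raise SolverError("parent history needs at least two frames")
    t0, t1 = float(times[0]), float(times[-1])
    total = controls.total_time if controls.total_time is not None else t1 - t0
    if total > t1 - t0 + 1e-9:
        raise SolverError("submodel window outside the parent time range")

    host = sub.node_parent_element
    Wn = hexutil.shape_functions(sub.node_parent_xi)  # (Nn, 8)
    host_nodes = parent_mesh.elements[host]  # (Nn, 8)

    def interp_all(t: float) -> np.ndarray:
        tt = np.clip(t, t0, t1)
        j = min(int(np.searchsorted(times, tt, side="right")), len(times) - 1)
        i = j - 1
        wgt = (tt - times[i]) / (times[j] - times[i]) if j > i else 0.0
        par = (1.0 - wgt) * parent_history.positions[i] \
            + wgt * parent_history.positions[j]
        return np.einsum("na,nai->ni", Wn, par[host_nodes])

    bnd = sub.boundary_nodes

    def boundary_at(t: float) -> np.ndarray:
        return interp_all(t)[bnd]

    x0 = interp_all(t0)
    v0 = (interp_all(t0 + (times[1] - times[0])) - x0) / (times[1] - times[0])

    ctl = SolverControls(**{**controls.__dict__})
    ctl.prescribed = PrescribedMotion(node_ids=bnd, positions_at=boundary_at)
    ctl.fix_bottom = False
    ctl.total_time = total
    beams = sub.beams if sub.beams.n_elements > 0 else None
    return _run_explicit(
        sub.mesh, beams, tissue, vessel, ctl, total,
        contact=None, x0=x0, v0=v0, t_start=t0,
    )
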