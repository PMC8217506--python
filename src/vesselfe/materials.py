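"""Constitutive models: Ogden-Prony tissue law and linear-elastic vessels.

The tissue is a nearly incompressible Ogden hyperelastic solid,

    Psi_inf = sum_p mu_p / alpha_p (l1^a_p + l2^a_p + l3^a_p - 3),

with strain-rate dependence through a deviatoric Prony-series convolution on
the Green-Lagrange strain,

    S(t) = S_inf + int_0^t G(t - T) dE_dev/dT dT,
    G(t) = sum_i G_i exp(-t / tau_i),

integrated with the standard recursive exponential update (exact for
piecewise-linear strain histories).  Near-incompressibility is enforced by a
volumetric penalty K (J - 1); the relaxation series has no long-term constant
term, so G(t) -> 0.

Vessels are linear elastic: axial stress = E * axial strain, tension
positive.  Units throughout: kPa, ms, kg/m³ (densities), stretches and
strains dimensionless.

Default tissue constants are package defaults representative of reported
rat-brain properties (kPa-scale shear modulus, strong strain stiffening,
millisecond-scale relaxation); see docs/methods.md.  All constants are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OgdenPronyMaterial",
    "VesselMaterial",
    "ViscoState",
    "default_tissue_material",
    "default_vessel_material",
    "ogden_principal_stress",
    "ogden_principal_kirchhoff_dev",
    "prony_relaxation_modulus",
    "viscoelastic_stress_update",
    "beam_axial_stress",
]


@dataclass
class OgdenPronyMaterial:
    """Ogden hyperelastic + Prony viscoelastic tissue material."""

    ogden_terms: tuple = ((1.2, 4.0),)  # (mu_p [kPa], alpha_p [-])
    prony_terms: tuple = ((3.0, 0.5), (1.0, 5.0))  # (G_i [kPa], tau_i [ms])
    density: float = 1040.0  # kg/m³
    # effective Poisson ratio sets the volumetric penalty; the default keeps
    # vessel axial stress under hydrostatic load below 1% of the pressure
    # (K ≈ 2.5e4 × mu_0), the regime the mechanism analyses rely on
    poisson_ratio: float = 0.49998

    def __post_init__(self) -> None:
        if self.ground_shear_modulus <= 0:
            raise ValueError("sum(mu_p * alpha_p) must be positive")
        if any(tau <= 0 for _, tau in self.prony_terms):
            raise ValueError("Prony relaxation times must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")

    @property
    def ground_shear_modulus(self) -> float:
        """mu_0 = sum(mu_p alpha_p) / 2, the long-term small-strain shear modulus (kPa)."""
        return 0.5 * sum(mu * a for mu, a in self.ogden_terms)

    @property
    def instantaneous_shear_modulus(self) -> float:
        return self.ground_shear_modulus + sum(g for g, _ in self.prony_terms)

    @property
    def bulk_modulus(self) -> float:
        """Volumetric penalty stiffness K (kPa) from the effective Poisson ratio."""
        nu = self.poisson_ratio
        mu = self.ground_shear_modulus
        return 2.0 * mu * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))

    def dilatational_wave_speed(self) -> float:
        """m/s, using the instantaneous shear modulus (CFL-relevant)."""
        m_pa = 1e3 * (self.bulk_modulus + 4.0 / 3.0 * self.instantaneous_shear_modulus)
        return float(np.sqrt(m_pa / self.density))


@dataclass
class VesselMaterial:
    """Linear elastic vessel wall material (defaults as printed for the model
    this package emulates; the 104 kg/m³ density is kept as printed although
    it is plausibly a typo for 1040 -- see docs/methods.md)."""

    elastic_modulus: float = 1400.0  # kPa (1.4 MPa)
    poisson_ratio: float = 0.38
    density: float = 104.0  # kg/m³

    def __post_init__(self) -> None:
        if self.elastic_modulus <= 0:
            raise ValueError("elastic modulus must be positive")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.density <= 0:
            raise ValueError("density must be positive")

    def wave_speed(self) -> float:
        """Axial wave speed sqrt(E/rho), m/s."""
        return float(np.sqrt(1e3 * self.elastic_modulus / self.density))


def default_tissue_material() -> OgdenPronyMaterial:
    return OgdenPronyMaterial()


def default_vessel_material() -> VesselMaterial:
    return VesselMaterial()


@dataclass
class ViscoState:
    """Internal variables of the Prony convolution (one stress-like tensor
    per term) plus the previous Green-Lagrange strain.  Leading axes allow
    batching over elements."""

    h: np.ndarray  # (..., n_terms, 3, 3)
    E_prev: np.ndarray  # (..., 3, 3)

    @classmethod
    def zero(cls, mat: OgdenPronyMaterial, batch: tuple = ()) -> "ViscoState":
        n = len(mat.prony_terms)
        return cls(
            h=np.zeros(batch + (n, 3, 3)),
            E_prev=np.zeros(batch + (3, 3)),
        )


# ---------------------------------------------------------------------------
# stress functions
# ---------------------------------------------------------------------------


def ogden_principal_stress(
    stretches, mat: OgdenPronyMaterial, zero_stress_axis: int | None = None
):
    """Long-term principal Cauchy stresses for an incompressible Ogden solid.

    ``sigma_i = sum_p mu_p stretch_i^alpha_p - p`` with the hydrostatic
    pressure ``p`` fixed by the boundary condition of the test: if
    ``zero_stress_axis`` is given, ``p`` makes that principal stress vanish
    (e.g. the lateral axes in uniaxial tension); otherwise ``p`` is the mean,
    returning the deviatoric principal stresses.  This principal-space form
    backs the closed-form checks; the solver uses the compressible 3D
    push-forward (`ogden_principal_kirchhoff_dev`).
    """
    lam = np.asarray(stretches, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("stretches must have 3 components")
    if np.any(lam <= 0):
        raise ValueError("principal stretches must be positive")
    s = np.zeros_like(lam)
    for mu, a in mat.ogden_terms:
        s = s + mu * lam**a
    if zero_stress_axis is None:
        p = s.mean(axis=-1, keepdims=True)
    else:
        p = s[..., zero_stress_axis, None]
    return s - p


def ogden_principal_kirchhoff_dev(lam_bar: np.ndarray, mat: OgdenPronyMaterial):
    """Deviatoric principal Kirchhoff stresses from isochoric stretches.

    ``tau_i = sum_p mu_p (lb_i^a_p - (lb_1^a_p + lb_2^a_p + lb_3^a_p)/3)``.
    Input shape (..., 3).
    """
    tau = np.zeros_like(lam_bar)
    for mu, a in mat.ogden_terms:
        la = lam_bar**a
        tau = tau + mu * (la - la.mean(axis=-1, keepdims=True))
    return tau


def prony_relaxation_modulus(t, mat: OgdenPronyMaterial):
    """G(t) = sum_i G_i exp(-t / tau_i), kPa. t in ms, t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("relaxation modulus undefined for negative time")
    g = np.zeros_like(t)
    for G, tau in mat.prony_terms:
        g = g + G * np.exp(-t / tau)
    return g


def _dev(A: np.ndarray) -> np.ndarray:
    tr = np.trace(A, axis1=-2, axis2=-1)
    return A - tr[..., None, None] / 3.0 * np.eye(3)


def viscoelastic_stress_update(
    state: ViscoState,
    E_new: np.ndarray,
    dt: float,
    mat: OgdenPronyMaterial,
    S_inf: np.ndarray | None = None,
) -> tuple[np.ndarray, ViscoState]:
    """One step of the deviatoric Prony convolution on Green-Lagrange strain.

    Recursive exponential integration, exact for strain histories that are
    linear within the step:

        h_i^{n+1} = exp(-dt/tau_i) h_i^n
                    + G_i (tau_i/dt) (1 - exp(-dt/tau_i)) dev(dE)

    Returns the second Piola-Kirchhoff stress ``S = S_inf + sum_i h_i`` (with
    ``S_inf = 0`` when not supplied) and the updated state.  Batched over
    leading axes.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    E_new = np.asarray(E_new, dtype=float)
    if E_new.shape[-2:] != (3, 3):
        raise ValueError("strain tensor must be (..., 3, 3)")
    if state.h.shape[-3] != len(mat.prony_terms):
        raise ValueError("state dimensions do not match the Prony series")
    dE_dev = _dev(E_new - state.E_prev)
    h_new = np.empty_like(state.h)
    for i, (G, tau) in enumerate(mat.prony_terms):
        x = dt / tau
        decay = np.exp(-x)
        h_new[..., i, :, :] = (
            decay * state.h[..., i, :, :] + G * (1.0 - decay) / x * dE_dev
        )
    S = h_new.sum(axis=-3)
    if S_inf is not None:
        S = S + S_inf
    return S, ViscoState(h=h_new, E_prev=E_new.copy())


def beam_axial_stress(axial_strain, mat: VesselMaterial):
    """Vessel axial stress (kPa) from engineering axial strain; tension positive."""
    strain = np.asarray(axial_strain, dtype=float)
    if np.any(strain <= -1.0):
        raise ValueError("axial strain must exceed -1")
    return mat.elastic_modulus * strain
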