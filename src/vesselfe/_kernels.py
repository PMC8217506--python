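"""Compiled per-element kernels for the explicit solver (numba).

One serial loop over hexahedra evaluates the deformation gradient, the
Ogden + volumetric-penalty stress (via a hand-coded Jacobi eigensolver for
the right Cauchy-Green tensor), the recursive deviatoric Prony update, and
the one-point internal nodal forces.  Kept free of Python objects so the
whole step runs at C speed on one core.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _eigh3(A, w, V):
    """Cyclic Jacobi eigendecomposition of a symmetric 3x3 matrix.

    Fills ``w`` (ascending) and ``V`` (columns = eigenvectors).
    """
    B = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            B[i, j] = A[i, j]
            V[i, j] = 1.0 if i == j else 0.0
    for _ in range(30):
        off = B[0, 1] ** 2 + B[0, 2] ** 2 + B[1, 2] ** 2
        if off < 1e-30 * (B[0, 0] ** 2 + B[1, 1] ** 2 + B[2, 2] ** 2 + 1e-300):
            break
        for p in range(2):
            for q in range(p + 1, 3):
                if abs(B[p, q]) < 1e-300:
                    continue
                theta = (B[q, q] - B[p, p]) / (2.0 * B[p, q])
                t = (1.0 if theta >= 0 else -1.0) / (
                    abs(theta) + np.sqrt(theta * theta + 1.0)
                )
                c = 1.0 / np.sqrt(t * t + 1.0)
                s = t * c
                for k in range(3):
                    bkp = B[k, p]
                    bkq = B[k, q]
                    B[k, p] = c * bkp - s * bkq
                    B[k, q] = s * bkp + c * bkq
                for k in range(3):
                    bpk = B[p, k]
                    bqk = B[q, k]
                    B[p, k] = c * bpk - s * bqk
                    B[q, k] = s * bpk + c * bqk
                for k in range(3):
                    vkp = V[k, p]
                    vkq = V[k, q]
                    V[k, p] = c * vkp - s * vkq
                    V[k, q] = s * vkp + c * vkq
    for i in range(3):
        w[i] = B[i, i]
    # insertion sort ascending, keeping columns in sync
    for i in range(1, 3):
        key = w[i]
        c0, c1, c2 = V[0, i], V[1, i], V[2, i]
        j = i - 1
        while j >= 0 and w[j] > key:
            w[j + 1] = w[j]
            V[0, j + 1] = V[0, j]
            V[1, j + 1] = V[1, j]
            V[2, j + 1] = V[2, j]
            j -= 1
        w[j + 1] = key
        V[0, j + 1] = c0
        V[1, j + 1] = c1
        V[2, j + 1] = c2


@njit(cache=True)
def hex_step(
    xe,  # (E, 8, 3) gathered current nodal coordinates
    ve,  # (E, 8, 3) gathered nodal velocities (hourglass damping)
    de,  # (E, 8, 3) gathered nodal displacements (hourglass stiffness)
    gradN,  # (E, 8, 3) reference shape gradients at the centre
    gamma,  # (E, 4, 8) orthogonalized hourglass base vectors
    hgv,  # (E,) viscous hourglass coefficient
    hgs,  # (E,) elastic hourglass coefficient
    V0,  # (E,)
    mu,  # (n_ogden,)
    alpha,  # (n_ogden,)
    K,  # bulk penalty, kPa
    decay,  # (n_prony,) exp(-dt/tau)
    hcoef,  # (n_prony,) G_i (1-exp(-dt/tau)) tau/dt
    h,  # (E, n_prony, 3, 3) in/out internal variables
    E_prev,  # (E, 3, 3) in/out
    update,  # bool: advance the viscous state
    t_elem,  # (E, 8, 3) out: resisting stress forces
    hg_elem,  # (E, 8, 3) out: applied hourglass forces
    sigma_out,  # (E, 3, 3) out: Cauchy stress
    eps_out,  # (E, 3, 3) out: Green-Lagrange strain
):
    """One-point Ogden-Prony stress, hourglass and internal forces.

    Returns the smallest Jacobian determinant (inversion check) and the
    element attaining it.
    """
    nE = xe.shape[0]
    n_og = mu.shape[0]
    n_pr = decay.shape[0]
    Jmin = 1e300
    Jargmin = -1
    F = np.empty((3, 3))
    C = np.empty((3, 3))
    S = np.empty((3, 3))
    P = np.empty((3, 3))
    w = np.empty(3)
    V = np.empty((3, 3))
    lam_bar = np.empty(3)
    la = np.empty(3)
    for e in range(nE):
        for i in range(3):
            for j in range(3):
                s = 0.0
                for a in range(8):
                    s += xe[e, a, i] * gradN[e, a, j]
                F[i, j] = s
        J = (
            F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
            - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
            + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0])
        )
        if not np.isfinite(J):
            J = -1.0
        if J < Jmin:
            Jmin = J
            Jargmin = e
        if J <= 0.0:
            continue
        for i in range(3):
            for j in range(3):
                s = 0.0
                for k in range(3):
                    s += F[k, i] * F[k, j]
                C[i, j] = s
                eps_out[e, i, j] = 0.5 * (C[i, j] - (1.0 if i == j else 0.0))
        _eigh3(C, w, V)
        Jm13 = J ** (-1.0 / 3.0)
        for i in range(3):
            wi = w[i]
            if wi < 1e-30:
                wi = 1e-30
            lam_bar[i] = np.sqrt(wi) * Jm13
        # deviatoric principal Kirchhoff stresses
        t0 = 0.0
        t1 = 0.0
        t2 = 0.0
        for p in range(n_og):
            la[0] = lam_bar[0] ** alpha[p]
            la[1] = lam_bar[1] ** alpha[p]
            la[2] = lam_bar[2] ** alpha[p]
            m = (la[0] + la[1] + la[2]) / 3.0
            t0 += mu[p] * (la[0] - m)
            t1 += mu[p] * (la[1] - m)
            t2 += mu[p] * (la[2] - m)
        vol = K * (J - 1.0) * J
        a0 = (t0 + vol) / w[0]
        a1 = (t1 + vol) / w[1]
        a2 = (t2 + vol) / w[2]
        for i in range(3):
            for j in range(3):
                S[i, j] = (
                    a0 * V[i, 0] * V[j, 0]
                    + a1 * V[i, 1] * V[j, 1]
                    + a2 * V[i, 2] * V[j, 2]
                )
        # Prony overstress on dev(dE)
        trd = (
            eps_out[e, 0, 0] - E_prev[e, 0, 0]
            + eps_out[e, 1, 1] - E_prev[e, 1, 1]
            + eps_out[e, 2, 2] - E_prev[e, 2, 2]
        ) / 3.0
        for q in range(n_pr):
            for i in range(3):
                for j in range(3):
                    dEd = eps_out[e, i, j] - E_prev[e, i, j]
                    if i == j:
                        dEd -= trd
                    hn = decay[q] * h[e, q, i, j] + hcoef[q] * dEd
                    S[i, j] += hn
                    if update:
                        h[e, q, i, j] = hn
        if update:
            for i in range(3):
                for j in range(3):
                    E_prev[e, i, j] = eps_out[e, i, j]
        # P = F S ; nodal forces ; Cauchy = P Fᵀ / J
        for i in range(3):
            for j in range(3):
                s = 0.0
                for k in range(3):
                    s += F[i, k] * S[k, j]
                P[i, j] = s
        for i in range(3):
            for j in range(3):
                s = 0.0
                for k in range(3):
                    s += P[i, k] * F[j, k]
                sigma_out[e, i, j] = s / J
        for a in range(8):
            for i in range(3):
                s = 0.0
                for j in range(3):
                    s += P[i, j] * gradN[e, a, j]
                t_elem[e, a, i] = V0[e] * s
        # hourglass: viscous on mode velocities + elastic on mode displacements
        for a in range(8):
            for k in range(3):
                hg_elem[e, a, k] = 0.0
        for i in range(4):
            for k in range(3):
                q = 0.0
                qd = 0.0
                for a in range(8):
                    q += gamma[e, i, a] * ve[e, a, k]
                    qd += gamma[e, i, a] * de[e, a, k]
                coef = hgv[e] * q + hgs[e] * qd
                for a in range(8):
                    hg_elem[e, a, k] -= gamma[e, i, a] * coef
    return Jmin, Jargmin
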