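"""Closed-form propagation of the two-compartment infusion system.

For a segment on which infusion rate, clearances and volumes are constant the
amount vector A = (A_central, A_peripheral) obeys dA/dt = M A + b with

    M = [[-(k10 + k12), k21], [k12, -k21]],   b = (rate, 0),

k10 = CL/V_C, k12 = Q/V_C, k21 = Q/V_P.  The update over a step dt is

    A(dt) = exp(M dt) A(0) + (integral_0^dt exp(M u) du) b,

evaluated through the spectral (Lagrange) form of the 2x2 matrix functions.
Because Q > 0 the two eigenvalues are always distinct, and the formula stays
valid when total clearance is zero (one eigenvalue is then 0; the integral
term uses expm1 so the limit is exact to machine precision).

Two implementations share the algebra: a pure-Python scalar step used by the
estimation inner loops (where call overhead dominates) and a numpy step
vectorized over subjects used by the Monte Carlo engine.
"""

from __future__ import annotations

import math

import numpy as np


def step_scalar(ac, ap, dt, rate, cl, q, vc, vp):
    """Advance one subject's amounts by ``dt`` hours under constant
    coefficients; returns (ac', ap').  Pure Python for speed in tight loops."""
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    l1 = 0.5 * (-s + disc)  # slow eigenvalue (closest to 0)
    l2 = 0.5 * (-s - disc)
    e1 = math.exp(l1 * dt)
    e2 = math.exp(l2 * dt)
    inv_d = 1.0 / (l1 - l2)
    c1 = (e1 - e2) * inv_d
    c0 = (l1 * e2 - l2 * e1) * inv_d
    m11 = -(k10 + k12)
    # E = c1*M + c0*I
    nac = (c1 * m11 + c0) * ac + (c1 * k21) * ap
    nap = (c1 * k12) * ac + (c0 - c1 * k21) * ap
    if rate != 0.0:
        g1 = math.expm1(l1 * dt) / l1 if l1 != 0.0 else dt
        g2 = math.expm1(l2 * dt) / l2
        gc1 = (g1 - g2) * inv_d
        gc0 = (l1 * g2 - l2 * g1) * inv_d
        nac += (gc1 * m11 + gc0) * rate
        nap += (gc1 * k12) * rate
    return nac, nap


def step_vector(ac, ap, dt, rate, cl, q, vc, vp):
    """Vectorized version of :func:`step_scalar`; all arguments broadcast.

    ``ac``/``ap`` are arrays over subjects; ``dt`` and ``rate`` are scalars
    (shared schedule), the parameters may be scalars or per-subject arrays.
    """
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    l1 = 0.5 * (-s + disc)
    l2 = 0.5 * (-s - disc)
    e1 = np.exp(l1 * dt)
    e2 = np.exp(l2 * dt)
    inv_d = 1.0 / (l1 - l2)
    c1 = (e1 - e2) * inv_d
    c0 = (l1 * e2 - l2 * e1) * inv_d
    m11 = -(k10 + k12)
    nac = (c1 * m11 + c0) * ac + (c1 * k21) * ap
    nap = (c1 * k12) * ac + (c1 * (-k21) + c0) * ap
    if rate != 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            g1 = np.where(l1 != 0.0, np.expm1(l1 * dt) / np.where(l1 != 0.0, l1, 1.0), dt)
        g2 = np.expm1(l2 * dt) / l2
        gc1 = (g1 - g2) * inv_d
        gc0 = (l1 * g2 - l2 * g1) * inv_d
        nac = nac + (gc1 * m11 + gc0) * rate
        nap = nap + (gc1 * k12) * rate
    return nac, nap
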