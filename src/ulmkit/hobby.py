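"""Closed Hobby-spline interpolation through control vertices.

Given an ordered ring of knots, Hobby's scheme chooses tangent directions by
solving a cyclic tridiagonal system on the chord lengths and turning angles,
then places cubic Bezier control points with Hobby's velocity function, so
the resulting closed curve is visually smooth and passes through every knot.
The tension parameter shortens the control handles; tension -> infinity
approaches the knot polygon.
"""

from __future__ import annotations

import numpy as np


def _velocity(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Hobby's velocity function rho(theta, phi)."""
    st, sp = np.sin(theta), np.sin(phi)
    ct, cp = np.cos(theta), np.cos(phi)
    a = np.sqrt(2.0)
    b = (np.sqrt(5.0) - 1.0) / 2.0
    c = (3.0 - np.sqrt(5.0)) / 2.0
    num = 2.0 + a * (st - sp / 16.0) * (sp - st / 16.0) * (ct - cp)
    den = 1.0 + b * ct + c * cp
    return num / den


def _solve_cyclic_tridiagonal(A: np.ndarray, B: np.ndarray, C: np.ndarray,
                              D: np.ndarray) -> np.ndarray:
    """Solve the cyclic system A_i x_{i-1} + B_i x_i + C_i x_{i+1} = D_i."""
    n = len(B)
    M = np.zeros((n, n))
    idx = np.arange(n)
    M[idx, idx] = B
    M[idx, (idx - 1) % n] = A
    M[idx, (idx + 1) % n] = C
    return np.linalg.solve(M, D)


def hobby_closed(vertices: np.ndarray, tension: float = 1.0,
                 samples_per_segment: int = 32) -> np.ndarray:
    """Closed Hobby spline through ``vertices`` ((n, 2) array, ordered ring).

    Returns the sampled boundary as an (n*samples_per_segment, 2) array; the
    curve passes through every vertex. ``tension`` >= 0.75 is the usual
    range; larger values pull the curve toward the knot polygon.
    """
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 planar vertices")
    if tension <= 0:
        raise ValueError("tension must be > 0")
    z = pts[:, 0] + 1j * pts[:, 1]
    n = len(z)
    chord = np.roll(z, -1) - z  # c_i = z_{i+1} - z_i
    d = np.abs(chord)
    if np.any(d == 0):
        raise ValueError("consecutive duplicate vertices")
    arg = np.angle(chord)
    # turning angle at knot i: from chord_{i-1} to chord_i, wrapped to (-pi, pi]
    gamma = arg - np.roll(arg, 1)
    gamma = (gamma + np.pi) % (2 * np.pi) - np.pi

    d_prev = np.roll(d, 1)
    A = 1.0 / d_prev
    B = 2.0 / d_prev + 2.0 / d
    C = 1.0 / d
    D = -(2.0 * gamma / d_prev + np.roll(gamma, -1) / d)
    theta = _solve_cyclic_tridiagonal(A, B, C, D)
    phi_next = -np.roll(gamma, -1) - np.roll(theta, -1)  # arrival angle at z_{i+1}

    rho = _velocity(theta, phi_next)
    sigma = _velocity(phi_next, theta)
    u = z + (rho * d / (3.0 * tension)) * np.exp(1j * (arg + theta))
    v = np.roll(z, -1) - (sigma * d / (3.0 * tension)) * np.exp(1j * (arg - phi_next))

    t = np.linspace(0.0, 1.0, samples_per_segment, endpoint=False)
    curve = []
    for i in range(n):
        p0, p1, p2, p3 = z[i], u[i], v[i], z[(i + 1) % n]
        b = ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * p1
             + 3 * (1 - t) * t ** 2 * p2 + t ** 3 * p3)
        curve.append(b)
    zz = np.concatenate(curve)
    return np.column_stack([zz.real, zz.imag])
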