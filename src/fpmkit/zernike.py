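"""Zernike polynomials on the unit disk, Noll-indexed.

Used to parameterize pupil phase aberrations. Coefficients are in radians
of wavefront phase; polynomials follow the classical (non-normalized)
convention Z = R_n^|m|(rho) * {cos,sin}(|m| theta).
"""

from __future__ import annotations

from math import factorial

import numpy as np

__all__ = ["noll_to_nm", "zernike_noll", "zernike_phase"]


def noll_to_nm(j: int) -> tuple[int, int]:
    """Map Noll index j (1-based) to radial degree n and azimuthal order m.

    Noll's ordering: j=1 piston, j=2/3 tilt, j=4 defocus, j=5/6 astigmatism,
    j=7/8 coma, j=11 spherical, ...
    """
    if j < 1:
        raise ValueError("Noll index starts at 1")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * (j1 // 2))
    return n, m


def _radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_n^m (m >= 0)."""
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * factorial(n - k)) / (
            factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k)
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike_noll(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate the j-th Noll Zernike polynomial at polar coordinates."""
    n, m = noll_to_nm(j)
    r = _radial(n, abs(m), rho)
    if m > 0:
        return r * np.cos(m * theta)
    if m < 0:
        return r * np.sin(-m * theta)
    return r


def zernike_phase(
    coeffs: list[float] | tuple[float, ...], rho: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Phase map sum_j coeffs[j-1] * Z_j(rho, theta), coeffs Noll-ordered from j=1."""
    phase = np.zeros_like(rho)
    for i, c in enumerate(coeffs):
        if c != 0.0:
            phase += c * zernike_noll(i + 1, rho, theta)
    return phase
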