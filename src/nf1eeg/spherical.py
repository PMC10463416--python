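"""Spherical-spline machinery: scalp interpolation and the Surface Laplacian.

Both operations rest on the same Legendre-series kernels over the cosine of
the angular distance between unit-sphere electrode positions:

    g(x) = (1/4pi) sum_{n=1}^{N} (2n+1) / (n(n+1))^m     P_n(x)
    h(x) = (1/4pi) sum_{n=1}^{N} (2n+1) / (n(n+1))^(m-1) P_n(x)

``g`` interpolates the potential; ``h`` yields its surface Laplacian
(current-source-density convention, units uV per steradian-squared up to a
head-radius scale that drops out of every contrast computed here).
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import legval


def _cosine_distances(pos_a: np.ndarray, pos_b: np.ndarray) -> np.ndarray:
    cos = pos_a @ pos_b.T
    return np.clip(cos, -1.0, 1.0)


def _kernel(cosdist: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    n = np.arange(1, n_terms + 1, dtype=float)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2.0 * n + 1.0) / (n * (n + 1.0)) ** m
    return legval(cosdist, coeffs) / (4.0 * np.pi)


def spline_interpolation_matrix(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    m: int = 4,
    n_terms: int = 50,
    reg: float = 1e-5,
) -> np.ndarray:
    """Matrix mapping potentials at ``good_pos`` to estimates at ``bad_pos``.

    Solves the Perrin spline system (G + reg*I) c + c0 = v, sum(c) = 0 and
    evaluates g-kernel interpolation at the bad sites.  Returns
    (n_bad, n_good).
    """
    good_pos = np.asarray(good_pos, float)
    bad_pos = np.asarray(bad_pos, float)
    n_good = good_pos.shape[0]
    if n_good < 3:
        raise ValueError("need at least 3 good electrodes for spline interpolation")
    G = _kernel(_cosine_distances(good_pos, good_pos), m, n_terms)
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G + reg * np.eye(n_good)
    A[:n_good, n_good] = 1.0
    A[n_good, :n_good] = 1.0
    A_inv = np.linalg.inv(A)
    g_bad = _kernel(_cosine_distances(bad_pos, good_pos), m, n_terms)
    # [g_bad | 1] @ A_inv maps the padded rhs [v; 0] to interpolated values.
    lhs = np.hstack([g_bad, np.ones((bad_pos.shape[0], 1))])
    return (lhs @ A_inv)[:, :n_good]


def surface_laplacian_operator(
    pos: np.ndarray,
    m: int = 4,
    n_terms: int = 10,
    reg: float = 1e-5,
) -> np.ndarray:
    """Linear operator L such that L @ v is the spherical-spline Laplacian of v.

    A spatially uniform potential maps to (numerically) zero.  Coincident
    electrode positions make the spline system singular and raise.
    """
    pos = np.asarray(pos, float)
    n_ch = pos.shape[0]
    cos = _cosine_distances(pos, pos)
    off_diag = cos[~np.eye(n_ch, dtype=bool)]
    if off_diag.size and off_diag.max() > 1.0 - 1e-12:
        raise ValueError("degenerate montage: coincident electrode positions")
    G = _kernel(cos, m, n_terms) + reg * np.eye(n_ch)
    H = _kernel(cos, m - 1, n_terms)
    G_inv = np.linalg.inv(G)
    ones = np.ones(n_ch)
    Gi1 = G_inv @ ones
    denom = ones @ Gi1
    # c = G_inv v - (1' G_inv v / 1' G_inv 1) G_inv 1 ; Laplacian = H c
    C = G_inv - np.outer(Gi1, Gi1) / denom
    return H @ C
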