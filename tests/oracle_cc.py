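"""Brute-force reference implementation of the two-layer estimator.

Deliberately coded along a different route than the package: orthonormal
bases from ``scipy.linalg.orth`` / ``null_space``, minimal-norm least squares
from ``scipy.linalg.lstsq`` (gelsd), and covariances from ``pinvh`` of the
Gram matrices.  Used only as an independent oracle in tests.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla


def oracle_train(S: np.ndarray, G: np.ndarray, b: np.ndarray, alpha: float = 1e10) -> dict:
    m, n = S.shape
    f, *_ = sla.lstsq(S.T, b, lapack_driver="gelsd")
    L = S.T @ G
    dg, *_ = sla.lstsq(L, b, lapack_driver="gelsd")

    Q = sla.orth(S) if np.any(S) else np.zeros((m, 0))
    P_R = Q @ Q.T
    P_N = np.eye(m) - P_R
    rank_S = Q.shape[1]
    rank_L = int(np.linalg.matrix_rank(L)) if np.any(L) else 0

    res_rc = b - S.T @ f
    res_gc = b - L @ dg
    dof_rc = n - rank_S
    dof_gc = n - rank_L
    assert dof_rc > 0 and dof_gc > 0, "oracle instance must leave residual dof"
    s2_rc = float(res_rc @ res_rc) / dof_rc
    s2_gc = float(res_gc @ res_gc) / dof_gc

    Sigma_rc = s2_rc * sla.pinvh(S @ S.T)
    Sigma_gc = s2_gc * sla.pinvh(L.T @ L)

    w = P_R @ f + P_N @ (G @ dg)
    V = P_R @ Sigma_rc @ P_R + P_N @ G @ Sigma_gc @ G.T @ P_N
    V = 0.5 * (V + V.T)

    N_L = sla.null_space(L) if L.size else np.eye(G.shape[1])
    A = N_L.T @ G.T @ P_N  # alpha-term factor; V_alpha = alpha^2 * A^T A
    return {
        "w": w,
        "V": V,
        "V_alpha": alpha**2 * (A.T @ A),
        "A": A,
        "alpha": alpha,
        "sigma2_rc": s2_rc,
        "sigma2_gc": s2_gc,
        "rank_S": rank_S,
        "rank_L": rank_L,
        "P_R": P_R,
        "P_N": P_N,
    }


def oracle_estimate(ora: dict, x: np.ndarray, coverage_tol: float = 1e-10):
    dg0 = float(x @ ora["w"])
    rem = ora["A"] @ x
    rem_norm = float(np.linalg.norm(rem))
    covered = rem_norm <= coverage_tol * float(np.linalg.norm(x))
    se2 = float(x @ ora["V"] @ x)
    if not covered:
        se2 += (ora["alpha"] * rem_norm) ** 2
    return dg0, float(np.sqrt(max(se2, 0.0))), covered


def random_instance(rng: np.random.Generator):
    """Tiny random rank-deficient instance (m<=8, n<=6, g<=4) with dof>=1.

    Built as r independent base reactions plus integer combinations of them,
    so both layers always keep residual degrees of freedom.
    """
    m = int(rng.integers(3, 9))
    g = int(rng.integers(1, 5))
    r = int(rng.integers(1, 4))
    n_extra = int(rng.integers(1, 4))
    while True:
        base = rng.integers(-2, 3, size=(m, r)).astype(float)
        if np.all(np.any(base != 0, axis=0)):
            break
    combos = rng.integers(-2, 3, size=(r, n_extra)).astype(float)
    S = np.hstack([base, base @ combos])
    G = rng.integers(0, 3, size=(m, g)).astype(float)
    b = rng.normal(scale=10.0, size=S.shape[1])
    return S, G, b
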