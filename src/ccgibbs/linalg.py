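"""Rank-aware pseudoinverses and orthogonal projectors.

Both regression layers of the component-contribution method are built on
Moore–Penrose pseudoinverses of (generally rank-deficient) stoichiometric
matrices, and on the orthogonal projectors onto the column space of a matrix
and the null space of its transpose.  Everything here is dense SVD: training
matrices are at most hundreds by thousands, well within desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProjectorPair",
    "pseudoinverse",
    "projectors",
    "null_space_projector",
    "default_rel_tol",
]


def default_rel_tol(shape: tuple[int, int]) -> float:
    """Default relative rank cutoff: max(rows, cols) * machine epsilon."""
    return max(shape) * np.finfo(float).eps


@dataclass(frozen=True)
class ProjectorPair:
    """Complementary orthogonal projectors associated with a matrix M.

    ``P_range`` projects onto the column space of M, ``P_null`` onto the
    null space of M^T.  They are symmetric, idempotent and sum to the
    identity.
    """

    P_range: np.ndarray
    P_null: np.ndarray
    rank: int

    @property
    def dim(self) -> int:
        return self.P_range.shape[0]


def _validate(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got ndim={M.ndim}")
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains non-finite entries")
    return M


def pseudoinverse(M: np.ndarray, rel_tol: float | None = None) -> tuple[np.ndarray, int]:
    """Moore–Penrose pseudoinverse with explicit rank determination.

    Singular values below ``rel_tol * sigma_max`` are treated as zero.

    Parameters
    ----------
    M
        Matrix to invert, shape (r, c); entries must be finite.
    rel_tol
        Relative singular-value cutoff; defaults to
        ``max(r, c) * machine epsilon``.

    Returns
    -------
    (M_pinv, rank)
        The pseudoinverse (shape (c, r)) and the numerical rank.
    """
    M = _validate(M)
    if rel_tol is None:
        rel_tol = default_rel_tol(M.shape)
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    if M.size == 0:
        return M.T.copy(), 0
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return np.zeros_like(M.T), 0
    cutoff = rel_tol * s[0]
    rank = int(np.count_nonzero(s > cutoff))
    s_inv = np.zeros_like(s)
    s_inv[:rank] = 1.0 / s[:rank]
    M_pinv = (Vt.T * s_inv) @ U.T
    return M_pinv, rank


def null_space_projector(M: np.ndarray, rel_tol: float | None = None) -> tuple[np.ndarray, int]:
    """Projector onto null(M), built from an explicit null-space basis.

    Constructing the projector as V₂V₂ᵀ from the trailing right singular
    vectors (rather than as I − M⁺M) makes it *exactly* the zero matrix when
    M has full column rank — important when the projector is later scaled by
    a huge constant, where epsilon-level residue would be amplified into
    garbage.  Returns ``(P_null, rank)``.
    """
    M = _validate(M)
    c = M.shape[1]
    if M.size == 0 or c == 0:
        return np.eye(c), 0
    if rel_tol is None:
        rel_tol = default_rel_tol(M.shape)
    _, s, Vt = np.linalg.svd(M, full_matrices=True)
    if s.size == 0 or s[0] == 0.0:
        return np.eye(c), 0
    rank = int(np.count_nonzero(s > rel_tol * s[0]))
    if rank == c:
        return np.zeros((c, c)), rank
    V2 = Vt[rank:].T
    P = V2 @ V2.T
    return 0.5 * (P + P.T), rank


def projectors(M: np.ndarray, rel_tol: float | None = None) -> ProjectorPair:
    """Orthogonal projectors onto range(M) and null(M^T).

    ``P_range = M M^+`` and ``P_null = I - P_range``; both are explicitly
    symmetrized to suppress floating-point asymmetry.
    """
    M = _validate(M)
    M_pinv, rank = pseudoinverse(M, rel_tol)
    n = M.shape[0]
    P_range = M @ M_pinv
    P_range = 0.5 * (P_range + P_range.T)
    P_null = np.eye(n) - P_range
    P_null = 0.5 * (P_null + P_null.T)
    return ProjectorPair(P_range=P_range, P_null=P_null, rank=rank)
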