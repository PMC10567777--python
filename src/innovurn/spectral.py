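"""Perron-Frobenius analysis of the interaction matrices.

For an irreducible triggering matrix ``Gamma`` (columns summing to < 1) the
novelty counters of all agents grow like ``t**gamma_star`` where
``gamma_star`` is the Perron-Frobenius eigenvalue of ``Gamma`` — the common
Heaps exponent — and the ratio ``D*_{t,h} / D*_{t,j}`` converges to
``u_h / u_j``, the ratio of the left-eigenvector centrality scores.  When the
adoption matrix ``W`` is irreducible, each color's adoption counts split
uniformly (1/N each) across agents in the limit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ReducibleMatrixError",
    "SpectralSummary",
    "is_irreducible",
    "perron_summary",
    "predicted_limits",
]

RESIDUAL_TOL = 1e-10


class ReducibleMatrixError(ValueError):
    """Raised when an operation requires an irreducible matrix."""


@dataclasses.dataclass(frozen=True)
class SpectralSummary:
    """Perron-Frobenius eigen-data of an irreducible non-negative matrix.

    ``gamma_star`` is the PF eigenvalue; ``v`` the right eigenvector
    (positive, entries summing to 1); ``u`` the left eigenvector (positive,
    scaled so that ``v @ u = 1``).
    """

    gamma_star: float
    v: np.ndarray
    u: np.ndarray
    irreducible: bool = True

    @property
    def N(self) -> int:
        return int(self.v.size)


def is_irreducible(M) -> bool:
    """True iff the support digraph (edge j->h when M[j,h] > 0) is strongly connected."""
    A = np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"matrix must be square, got shape {A.shape}")
    if np.any(A < 0):
        raise ValueError("matrix must be non-negative")
    if A.shape[0] == 1:
        return True
    support = csr_matrix((A > 0).astype(np.int8))
    n_comp, _ = connected_components(support, directed=True, connection="strong")
    return int(n_comp) == 1


def perron_summary(Gamma) -> SpectralSummary:
    """Perron-Frobenius eigenvalue and positive left/right eigenvectors of Gamma.

    Requires irreducibility; a reducible matrix raises
    :class:`ReducibleMatrixError` (the block decomposition of reducible
    systems is outside this package's scope).  Residual norms of both
    eigen-equations are verified to ``1e-10``.
    """
    G = np.asarray(Gamma, dtype=float)
    if not is_irreducible(G):
        raise ReducibleMatrixError(
            "Gamma is reducible: Perron-Frobenius predictions require a "
            "strongly connected interaction graph; the reducible-case "
            "block/growth-rate analysis is not implemented here"
        )

    def pf_vector(M: np.ndarray) -> tuple[float, np.ndarray]:
        vals, vecs = np.linalg.eig(M)
        # for non-negative matrices the spectral radius is itself an
        # eigenvalue and strictly dominates every other real part
        idx = int(np.argmax(vals.real))
        lam = vals[idx]
        vec = vecs[:, idx].real
        if vec.sum() < 0:
            vec = -vec
        return float(lam.real), vec

    lam_r, v = pf_vector(G)
    lam_l, u = pf_vector(G.T)
    gamma_star = 0.5 * (lam_r + lam_l)
    if np.any(v <= 0) or np.any(u <= 0):
        raise ReducibleMatrixError(
            "Perron-Frobenius eigenvectors are not strictly positive; "
            "matrix is numerically reducible"
        )
    v = v / v.sum()
    u = u / float(v @ u)
    res_r = float(np.linalg.norm(G @ v - gamma_star * v))
    res_l = float(np.linalg.norm(u @ G - gamma_star * u))
    if max(res_r, res_l) > RESIDUAL_TOL:
        raise ArithmeticError(
            f"eigen-residual {max(res_r, res_l):.3e} exceeds {RESIDUAL_TOL}"
        )
    # PF bound: eigenvalue between min and max column sums
    colsum = G.sum(axis=0)
    assert colsum.min() - 1e-12 <= gamma_star <= colsum.max() + 1e-12
    return SpectralSummary(gamma_star=gamma_star, v=v, u=u, irreducible=True)


def predicted_limits(summary: SpectralSummary) -> dict:
    """Limit-theorem predictions from a spectral summary.

    Returns the common Heaps exponent (``gamma_star``), the reciprocal-
    symmetric matrix of limiting ratios ``D*_{t,h} / D*_{t,j} -> u_h / u_j``,
    and — for two agents — ``log10(u_1 / u_2)``, the quantity estimated from
    data as the intercept difference of the two novelty curves.
    """
    u = summary.u
    ratio = u[:, None] / u[None, :]
    out = {
        "heaps_exponent": summary.gamma_star,
        "ratio_matrix": ratio,
        "log10_ratio": float(np.log10(u[0] / u[1])) if summary.N == 2 else None,
    }
    return out
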