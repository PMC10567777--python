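"""Parameter containers for a network of interacting urn-with-triggering processes.

A system of ``N`` innovation (species-sampling) processes is parametrized either
by integer ball counts — the *raw* parametrization of the literal urn scheme —
or by the *normalized* quantities obtained by dividing each urn's counts by the
per-step ball increment of the target urn:

    theta_h  = N0_h / rho_h         (baseline novelty propensity of urn h)
    gamma_jh = nu_jh / rho_h        (novelty triggering of source j on target h)
    lambda_jh = rho_hat_jh / rho_h  (same-color reinforcement of j on h)
    w_jh     = rho_jh / rho_h       (total adoption weight of j on h)

with the balance condition ``rho_hat + nu = rho`` (so ``W = Gamma + Lambda``),
every column of ``W`` summing to exactly 1 and every column of ``Gamma``
summing to strictly less than 1.

Matrix orientation convention, used throughout the package and its file
formats: entry ``[j, h]`` (row ``j``, column ``h``) is the influence of
*source* agent ``j`` on *target* agent ``h``.  Column sums therefore aggregate
all influences acting on one target.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "RawParams",
    "ExactParams",
    "NormalizedParams",
    "normalize",
    "denormalize",
    "poisson_dirichlet",
    "independent_union",
    "load_params",
    "dump_params",
]

#: tolerance used for float-valued column-sum / consistency checks
COLSUM_TOL = 1e-12


class ParameterError(ValueError):
    """Raised when a parameter set violates the model constraints."""


def _as_int_matrix(x, name: str, n: int) -> np.ndarray:
    a = np.asarray(x)
    if a.shape != (n, n):
        raise ParameterError(f"{name} must be an {n}x{n} matrix, got shape {a.shape}")
    if not np.issubdtype(a.dtype, np.integer):
        b = np.asarray(a, dtype=float)
        if not np.all(b == np.round(b)):
            raise ParameterError(f"{name} must contain integers")
        a = np.round(b).astype(np.int64)
    else:
        a = a.astype(np.int64)
    if np.any(a < 0):
        raise ParameterError(f"{name} must be non-negative")
    return a


@dataclasses.dataclass(frozen=True)
class RawParams:
    """Integer ball-count parametrization of the interacting urn system.

    Attributes
    ----------
    N0 : (N,) int array
        Initial number of distinct singleton balls in each urn (all > 0).
    rho_hat : (N, N) int array
        Same-color balls added to urn ``h`` when the color drawn from urn
        ``j`` is new to the system.
    nu : (N, N) int array
        Number of fresh-color balls injected into urn ``h`` by a novelty of
        urn ``j`` (urn ``h == j`` additionally replaces the drawn ball, i.e.
        gets ``nu[h, h] + 1`` fresh colors).
    rho : (N, N) int array
        Same-color balls added to urn ``h`` when the color drawn from urn
        ``j`` is old.  The balance condition ``rho_hat + nu == rho`` makes
        the per-step ball increment of urn ``h`` the constant column sum
        ``rho_h = sum_j rho[j, h]``.
    """

    N0: np.ndarray
    rho_hat: np.ndarray
    nu: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        N0 = np.asarray(self.N0)
        if N0.ndim != 1 or N0.size < 1:
            raise ParameterError("N0 must be a non-empty vector")
        n = N0.size
        if not np.issubdtype(N0.dtype, np.integer):
            b = np.asarray(N0, dtype=float)
            if not np.all(b == np.round(b)):
                raise ParameterError("N0 must contain integers")
            N0 = np.round(b).astype(np.int64)
        else:
            N0 = N0.astype(np.int64)
        if np.any(N0 <= 0):
            raise ParameterError("N0 entries must be positive")
        rho_hat = _as_int_matrix(self.rho_hat, "rho_hat", n)
        nu = _as_int_matrix(self.nu, "nu", n)
        rho = _as_int_matrix(self.rho, "rho", n)
        bad = np.argwhere(rho_hat + nu != rho)
        if bad.size:
            j, h = (int(v) for v in bad[0])
            raise ParameterError(
                "balance condition rho_hat + nu == rho violated at "
                f"(j={j}, h={h}): {int(rho_hat[j, h])} + {int(nu[j, h])} "
                f"!= {int(rho[j, h])}"
            )
        diag = np.diag(rho)
        if np.any(diag <= 0):
            h = int(np.argmax(diag <= 0))
            raise ParameterError(f"rho[{h},{h}] must be > 0")
        if np.any(np.diag(rho_hat) <= 0):
            h = int(np.argmax(np.diag(rho_hat) <= 0))
            raise ParameterError(f"rho_hat[{h},{h}] must be > 0")
        # rho == 0 forces nu == 0 via the balance condition; asserted anyway.
        if np.any((rho == 0) & (nu != 0)):
            raise ParameterError("rho[j,h] = 0 requires nu[j,h] = 0")
        for name, val in (("N0", N0), ("rho_hat", rho_hat), ("nu", nu), ("rho", rho)):
            object.__setattr__(self, name, val)
            val.setflags(write=False)

    @property
    def N(self) -> int:
        return int(self.N0.size)

    @property
    def rho_col(self) -> np.ndarray:
        """Per-step ball increment ``rho_h`` of each urn (column sums of rho)."""
        return self.rho.sum(axis=0)


@dataclasses.dataclass(frozen=True)
class ExactParams:
    """Rational mirror of :class:`NormalizedParams` for exact-arithmetic oracles."""

    theta: tuple
    Gamma: tuple
    Lambda: tuple

    @property
    def N(self) -> int:
        return len(self.theta)

    def w(self, j: int, h: int) -> Fraction:
        return self.Gamma[j][h] + self.Lambda[j][h]


def _as_float_matrix(x, name: str, n: int) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (n, n):
        raise ParameterError(f"{name} must be an {n}x{n} matrix, got shape {a.shape}")
    return a


@dataclasses.dataclass(frozen=True)
class NormalizedParams:
    """Normalized parameters (theta, Gamma, Lambda) of the interacting system.

    ``W = Gamma + Lambda`` is derived.  Entry ``[j, h]`` is the influence of
    source ``j`` on target ``h``; columns of ``W`` sum to 1 and columns of
    ``Gamma`` sum to < 1.  An optional :class:`ExactParams` mirror carries the
    same values as exact rationals when the instance was built from integer
    ball counts or rational inputs.
    """

    theta: np.ndarray
    Gamma: np.ndarray
    Lambda: np.ndarray
    exact: ExactParams | None = dataclasses.field(default=None, compare=False)

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float).ravel()
        if theta.size < 1:
            raise ParameterError("theta must be a non-empty vector")
        n = theta.size
        if np.any(theta <= 0):
            raise ParameterError("theta entries must be > 0")
        Gamma = _as_float_matrix(self.Gamma, "Gamma", n)
        Lambda = _as_float_matrix(self.Lambda, "Lambda", n)
        if np.any(Gamma < 0) or np.any(Gamma > 1):
            raise ParameterError("Gamma entries must lie in [0, 1]")
        if np.any(np.diag(Gamma) >= 1):
            raise ParameterError("diagonal Gamma entries must be < 1")
        if np.any(Lambda < 0) or np.any(Lambda > 1):
            raise ParameterError("Lambda entries must lie in [0, 1]")
        if np.any(np.diag(Lambda) <= 0):
            raise ParameterError("diagonal Lambda entries must be > 0")
        W = Gamma + Lambda
        colsum = W.sum(axis=0)
        if np.any(np.abs(colsum - 1.0) > COLSUM_TOL):
            h = int(np.argmax(np.abs(colsum - 1.0)))
            raise ParameterError(
                f"column {h} of W = Gamma + Lambda sums to {colsum[h]!r}, expected 1"
            )
        gsum = Gamma.sum(axis=0)
        if np.any(gsum >= 1.0):
            h = int(np.argmax(gsum >= 1.0))
            raise ParameterError(f"column {h} of Gamma sums to {gsum[h]!r} >= 1")
        for name, val in (("theta", theta), ("Gamma", Gamma), ("Lambda", Lambda)):
            object.__setattr__(self, name, val)
            val.setflags(write=False)

    @property
    def N(self) -> int:
        return int(self.theta.size)

    @property
    def W(self) -> np.ndarray:
        return self.Gamma + self.Lambda

    @classmethod
    def from_rationals(
        cls,
        theta: Sequence,
        Gamma: Sequence[Sequence],
        Lambda: Sequence[Sequence],
    ) -> "NormalizedParams":
        """Build from exact rational entries, keeping the exact mirror."""
        th = tuple(Fraction(x) for x in theta)
        G = tuple(tuple(Fraction(x) for x in row) for row in Gamma)
        L = tuple(tuple(Fraction(x) for x in row) for row in Lambda)
        n = len(th)
        for h in range(n):
            s = sum(G[j][h] + L[j][h] for j in range(n))
            if s != 1:
                raise ParameterError(f"column {h} of W must sum to exactly 1, got {s}")
        exact = ExactParams(theta=th, Gamma=G, Lambda=L)
        return cls(
            theta=np.array([float(x) for x in th]),
            Gamma=np.array([[float(x) for x in row] for row in G]),
            Lambda=np.array([[float(x) for x in row] for row in L]),
            exact=exact,
        )


def normalize(raw: RawParams) -> NormalizedParams:
    """Convert integer ball counts to normalized parameters (exact rationals).

    ``theta_h = N0_h / rho_h``, ``gamma_jh = nu_jh / rho_h``,
    ``lambda_jh = rho_hat_jh / rho_h`` with ``rho_h`` the column sum of
    ``rho``.  The returned instance carries an exact rational mirror; its
    ``W`` columns sum to 1 exactly.
    """
    rho_col = raw.rho_col
    n = raw.N
    theta = [Fraction(int(raw.N0[h]), int(rho_col[h])) for h in range(n)]
    Gamma = [
        [Fraction(int(raw.nu[j, h]), int(rho_col[h])) for h in range(n)]
        for j in range(n)
    ]
    Lambda = [
        [Fraction(int(raw.rho_hat[j, h]), int(rho_col[h])) for h in range(n)]
        for j in range(n)
    ]
    return NormalizedParams.from_rationals(theta, Gamma, Lambda)


def denormalize(params: NormalizedParams, rho_col: Sequence[int]) -> RawParams:
    """Reconstruct integer ball counts from normalized parameters.

    The caller supplies the per-urn ball increment ``rho_h`` (a common
    denominator): every product ``theta_h * rho_h``, ``gamma_jh * rho_h`` and
    ``w_jh * rho_h`` must be an integer, otherwise a :class:`ParameterError`
    asks for a larger denominator.  ``normalize(denormalize(p, r))``
    reproduces ``p`` exactly for rational ``p``.
    """
    rc = np.asarray(rho_col)
    n = params.N
    if rc.shape != (n,):
        raise ParameterError(f"rho_col must be a length-{n} vector")
    if np.any(rc <= 0) or not np.all(rc == np.round(np.asarray(rc, dtype=float))):
        raise ParameterError("rho_col entries must be positive integers")
    rc = rc.astype(np.int64)

    if params.exact is not None:
        theta = list(params.exact.theta)
        G = [list(row) for row in params.exact.Gamma]
        L = [list(row) for row in params.exact.Lambda]
    else:
        theta = [Fraction(x).limit_denominator(10**12) for x in params.theta]
        G = [
            [Fraction(x).limit_denominator(10**12) for x in row]
            for row in params.Gamma
        ]
        L = [
            [Fraction(x).limit_denominator(10**12) for x in row]
            for row in params.Lambda
        ]

    def to_int(frac: Fraction, what: str) -> int:
        v = frac
        if v.denominator != 1:
            raise ParameterError(
                f"{what} = {v} is not an integer; choose a larger common "
                "denominator rho_h"
            )
        return int(v)

    N0 = np.array(
        [to_int(theta[h] * rc[h], f"theta[{h}]*rho[{h}]") for h in range(n)],
        dtype=np.int64,
    )
    nu = np.array(
        [
            [to_int(G[j][h] * rc[h], f"Gamma[{j},{h}]*rho[{h}]") for h in range(n)]
            for j in range(n)
        ],
        dtype=np.int64,
    )
    rho_hat = np.array(
        [
            [to_int(L[j][h] * rc[h], f"Lambda[{j},{h}]*rho[{h}]") for h in range(n)]
            for j in range(n)
        ],
        dtype=np.int64,
    )
    return RawParams(N0=N0, rho_hat=rho_hat, nu=nu, rho=rho_hat + nu)


def poisson_dirichlet(theta, gamma) -> NormalizedParams:
    """Single-process Poisson-Dirichlet (Pitman-Yor) special case.

    Birth probability ``(theta + gamma * D_t) / (theta + t)``; an old color
    with count ``K`` is drawn with probability ``(K - gamma) / (theta + t)``.
    Requires ``theta > 0`` and ``0 <= gamma < 1``; ``gamma = 0`` is the
    Hoppe/Dirichlet urn.
    """
    th = Fraction(theta)
    g = Fraction(gamma)
    if th <= 0:
        raise ParameterError(f"theta must be > 0, got {theta}")
    if not (0 <= g < 1):
        raise ParameterError(f"gamma must lie in [0, 1), got {gamma}")
    return NormalizedParams.from_rationals([th], [[g]], [[1 - g]])


def independent_union(param_list: Sequence[NormalizedParams]) -> NormalizedParams:
    """Stack independent systems block-diagonally (no cross-influence).

    With all off-block ``w_jh = 0`` the sub-systems never share colors: each
    runs as an isolated urn system inside the joint state.
    """
    if not param_list:
        raise ParameterError("param_list must not be empty")
    if len(param_list) == 1:
        return param_list[0]
    sizes = [p.N for p in param_list]
    n = sum(sizes)
    if all(p.exact is not None for p in param_list):
        zero = Fraction(0)
        theta: list = []
        G = [[zero] * n for _ in range(n)]
        L = [[zero] * n for _ in range(n)]
        off = 0
        for p in param_list:
            ex = p.exact
            theta.extend(ex.theta)
            for j in range(p.N):
                for h in range(p.N):
                    G[off + j][off + h] = ex.Gamma[j][h]
                    L[off + j][off + h] = ex.Lambda[j][h]
            off += p.N
        return NormalizedParams.from_rationals(theta, G, L)
    theta_f = np.concatenate([p.theta for p in param_list])
    Gf = np.zeros((n, n))
    Lf = np.zeros((n, n))
    off = 0
    for p in param_list:
        Gf[off : off + p.N, off : off + p.N] = p.Gamma
        Lf[off : off + p.N, off : off + p.N] = p.Lambda
        off += p.N
    return NormalizedParams(theta=theta_f, Gamma=Gf, Lambda=Lf)


# ---------------------------------------------------------------------------
# config file I/O

def _params_from_mapping(doc: Mapping) -> NormalizedParams | RawParams:
    if "theta" in doc:
        for key in ("Gamma", "Lambda"):
            if key not in doc:
                raise ParameterError(
                    f"normalized parameter file must define '{key}' alongside 'theta'"
                )
        return NormalizedParams(
            theta=np.asarray(doc["theta"], dtype=float),
            Gamma=np.asarray(doc["Gamma"], dtype=float),
            Lambda=np.asarray(doc["Lambda"], dtype=float),
        )
    if "N0" in doc:
        for key in ("rho_hat", "nu"):
            if key not in doc:
                raise ParameterError(
                    f"raw parameter file must define '{key}' alongside 'N0'"
                )
        rho_hat = np.asarray(doc["rho_hat"])
        nu = np.asarray(doc["nu"])
        rho = np.asarray(doc["rho"]) if "rho" in doc else rho_hat + nu
        return RawParams(N0=np.asarray(doc["N0"]), rho_hat=rho_hat, nu=nu, rho=rho)
    raise ParameterError(
        "parameter file must define either 'theta'/'Gamma'/'Lambda' or "
        "'N0'/'rho_hat'/'nu'"
    )


def load_params(path, as_normalized: bool = True):
    """Load parameters from a YAML config file.

    Accepts either the normalized form (``theta``, ``Gamma``, ``Lambda``;
    ``W`` is derived) or the raw ball-count form (``N0``, ``rho_hat``, ``nu``
    and optionally ``rho``).  With ``as_normalized=True`` (default) raw
    parameters are normalized on load.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # YAML errors carry line/column marks
            raise ParameterError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ParameterError(f"{path}: top level must be a mapping")
    try:
        p = _params_from_mapping(doc)
    except ParameterError as exc:
        raise ParameterError(f"{path}: {exc}") from exc
    if as_normalized and isinstance(p, RawParams):
        return normalize(p)
    return p


def dump_params(params, path) -> None:
    """Write parameters to a YAML config file (inverse of :func:`load_params`)."""
    if isinstance(params, RawParams):
        doc = {
            "N0": params.N0.tolist(),
            "rho_hat": params.rho_hat.tolist(),
            "nu": params.nu.tolist(),
            "rho": params.rho.tolist(),
        }
    else:
        doc = {
            "theta": params.theta.tolist(),
            "Gamma": params.Gamma.tolist(),
            "Lambda": params.Lambda.tolist(),
        }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
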