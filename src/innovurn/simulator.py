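"""Exact generative simulation of N interacting urn-with-triggering processes.

At every time-step one ball is drawn from each of the ``N`` urns
simultaneously (conditionally independently given the past).  Agent ``h``
produces a system-wide novelty with probability

    Z*_{t,h} = (theta_h + sum_j gamma_jh D*_{t,j}) / (theta_h + t)

and adopts the old color ``c`` (originated by agent ``j*(c)``) with probability

    P_t(h,c) = (sum_j w_jh K_t(j,c) - gamma_{j*(c),h}) / (theta_h + t)

where ``D*_{t,j}`` counts the novelties produced by agent ``j`` and
``K_t(j,c)`` the adoptions of color ``c`` by agent ``j`` up to time ``t``.

The simulation operates directly at the probability level — identical in law
to materializing balls, but O(#colors) per draw.  Two independent oracles
live alongside it for verification: a literal integer ball-counting urn
system (:class:`LiteralUrnSystem`) and an exact rational-arithmetic
enumeration of the full outcome tree (:func:`enumerate_paths`).

Determinism contract: agents are drawn in index order consuming one uniform
each from a single seeded generator; fresh color ids are consecutive
integers in order of first appearance, ties within a step broken by agent
index.  Trajectories are therefore bit-reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .params import NormalizedParams, ParameterError, RawParams, normalize

__all__ = [
    "SystemState",
    "Trajectory",
    "simulate",
    "new_probability",
    "old_color_distribution",
    "expected_dstar_recursion",
    "LiteralUrnSystem",
    "literal_probabilities",
    "exact_probabilities",
    "enumerate_paths",
]

_NEG_TOL = 1e-9


class SystemState:
    """Mutable state of the interacting urn system at time ``t``.

    Maintains, per color ``c``: the adoption counts ``K_t(j, c)`` for every
    agent ``j``, the originator ``j*(c)`` and the first-extraction time; and
    per agent the novelty counter ``D*_{t,h}`` and discovery counter
    ``D_{t,h}``.  The array ``A[h, c] = sum_j w_jh K_t(j,c) - gamma_{j*(c),h}``
    (the numerator of the old-color probability) is kept incrementally.
    """

    __slots__ = (
        "params",
        "t",
        "n_colors",
        "dstar",
        "d",
        "_K",
        "_A",
        "_orig",
        "_first",
        "_cap",
    )

    def __init__(self, params: NormalizedParams, capacity: int = 64):
        self.params = params
        self.t = 0
        self.n_colors = 0
        n = params.N
        self.dstar = np.zeros(n, dtype=np.int64)
        self.d = np.zeros(n, dtype=np.int64)
        self._cap = max(int(capacity), 1)
        self._K = np.zeros((n, self._cap), dtype=np.int64)
        self._A = np.zeros((n, self._cap), dtype=float)
        self._orig = np.zeros(self._cap, dtype=np.int64)
        self._first = np.zeros(self._cap, dtype=np.int64)

    # -- views ---------------------------------------------------------------
    @property
    def counts(self) -> np.ndarray:
        """Adoption counts ``K_t(j, c)`` as an (N, n_colors) array (read-only view)."""
        return self._K[:, : self.n_colors]

    @property
    def originators(self) -> np.ndarray:
        """Originating agent ``j*(c)`` of each color (0-based)."""
        return self._orig[: self.n_colors]

    @property
    def first_times(self) -> np.ndarray:
        """1-based time-step of each color's first extraction."""
        return self._first[: self.n_colors]

    @property
    def dstar_total(self) -> int:
        """System-wide novelty count ``D*_t = sum_h D*_{t,h}`` (= number of colors)."""
        return self.n_colors

    # -- probabilities -------------------------------------------------------
    def new_probability(self, h: int) -> float:
        """Birth probability ``Z*_{t,h}`` of agent ``h`` at the current time."""
        self._check_agent(h)
        p = self.params
        return float(
            (p.theta[h] + p.Gamma[:, h] @ self.dstar) / (p.theta[h] + self.t)
        )

    def old_color_probabilities(self, h: int) -> np.ndarray:
        """Vector of old-color probabilities ``P_t(h, c)`` indexed by color id."""
        self._check_agent(h)
        num = self._A[h, : self.n_colors]
        if num.size and num.min() < -_NEG_TOL:
            raise AssertionError(
                "negative old-color numerator; parameters violate w >= gamma"
            )
        return np.maximum(num, 0.0) / (self.params.theta[h] + self.t)

    def old_color_distribution(self, h: int) -> dict:
        """Mapping color id -> probability ``P_t(h, c)``."""
        return dict(enumerate(self.old_color_probabilities(h)))

    def _check_agent(self, h: int) -> None:
        if not 0 <= h < self.params.N:
            raise IndexError(f"agent index {h} out of range for N={self.params.N}")

    # -- updates -------------------------------------------------------------
    def _grow(self) -> None:
        new_cap = self._cap * 2
        n = self.params.N
        for name, fill in (("_K", 0), ("_A", 0.0), ("_orig", 0), ("_first", 0)):
            old = getattr(self, name)
            if old.ndim == 2:
                fresh = np.zeros((n, new_cap), dtype=old.dtype)
                fresh[:, : self._cap] = old
            else:
                fresh = np.zeros(new_cap, dtype=old.dtype)
                fresh[: self._cap] = old
            setattr(self, name, fresh)
        self._cap = new_cap

    def _register_new(self, j: int) -> int:
        if self.n_colors >= self._cap:
            self._grow()
        c = self.n_colors
        self.n_colors += 1
        self._K[j, c] = 1
        # numerator of P(h, c) right after creation: w_jh * 1 - gamma_jh = lambda_jh
        self._A[:, c] = self.params.Lambda[j, :]
        self._orig[c] = j
        self._first[c] = self.t + 1
        self.dstar[j] += 1
        self.d[j] += 1
        return c

    def _reinforce(self, j: int, c: int) -> None:
        if self._K[j, c] == 0:
            self.d[j] += 1
        self._K[j, c] += 1
        self._A[:, c] += self.params.W[j, :]

    def step(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Advance one time-step; returns (color ids, novelty flags) per agent.

        All draws use the frozen time-``t`` state (simultaneity); updates are
        applied afterwards, novelties first in agent-index order so that
        fresh ids are deterministic.
        """
        p = self.params
        n = p.N
        t = self.t
        C = self.n_colors
        colors = np.empty(n, dtype=np.int64)
        is_new = np.zeros(n, dtype=bool)
        u = rng.random(n)
        for h in range(n):
            x = u[h] * (p.theta[h] + t)
            new_mass = p.theta[h] + p.Gamma[:, h] @ self.dstar
            if C == 0 or x < new_mass:
                is_new[h] = True
            else:
                num = self._A[h, :C]
                cum = np.cumsum(num)
                c = int(np.searchsorted(cum, x - new_mass, side="right"))
                colors[h] = min(c, C - 1)
        for h in range(n):
            if is_new[h]:
                colors[h] = self._register_new(h)
        for h in range(n):
            if not is_new[h]:
                self._reinforce(h, colors[h])
        self.t = t + 1
        return colors, is_new

    def apply_observed(self, colors: Sequence[int], is_new: Sequence[bool]) -> None:
        """Apply one observed step (used when replaying an external stream)."""
        for h in range(self.params.N):
            if is_new[h]:
                self._register_new(h)
        for h in range(self.params.N):
            if not is_new[h]:
                self._reinforce(h, int(colors[h]))
        self.t += 1

    def check_invariants(self) -> None:
        """Assert count conservation and the counter chain; cheap, O(N * colors)."""
        K = self.counts
        assert np.all(K.sum(axis=1) == self.t), "sum_c K_t(j,c) != t"
        assert int(self.dstar.sum()) == self.n_colors
        d_direct = (K >= 1).sum(axis=1)
        assert np.all(self.d == d_direct)
        assert np.all(self.dstar <= self.d)
        assert np.all(self.d <= self.n_colors)


# module-level functional aliases matching the operation names
def new_probability(state: SystemState, h: int) -> float:
    return state.new_probability(h)


def old_color_distribution(state: SystemState, h: int) -> dict:
    return state.old_color_distribution(h)


@dataclasses.dataclass
class Trajectory:
    """Realized event stream of a simulation run.

    Events are stored flat, ``N`` per time-step in agent order: arrays ``t``
    (1-based), ``agent`` (0-based), ``color`` (0-based consecutive ids) and
    ``is_new`` (True iff first system-wide occurrence).
    """

    params: NormalizedParams
    seed: int
    T: int
    t: np.ndarray
    agent: np.ndarray
    color: np.ndarray
    is_new: np.ndarray
    state: SystemState | None = None

    @property
    def N(self) -> int:
        return self.params.N

    def steps(self) -> Iterable[tuple[np.ndarray, np.ndarray]]:
        """Iterate (colors, novelty flags) per time-step, agents in index order."""
        n = self.N
        for s in range(self.T):
            sl = slice(s * n, (s + 1) * n)
            yield self.color[sl], self.is_new[sl]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "category": self.agent + 1,
                "item": self.color + 1,
                "is_new": self.is_new.astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        """Write the event stream as UTF-8 TSV with 1-based t/category/item."""
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def simulate(
    params: NormalizedParams, T: int, seed: int, keep_state: bool = True
) -> Trajectory:
    """Run the system for ``T`` time-steps from a fresh state.

    Reproducible: the same ``(params, T, seed)`` yields a bit-identical
    trajectory.  ``keep_state=True`` attaches the final :class:`SystemState`.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    rng = np.random.default_rng(seed)
    state = SystemState(params)
    n = params.N
    t_arr = np.repeat(np.arange(1, T + 1, dtype=np.int64), n)
    agent = np.tile(np.arange(n, dtype=np.int64), T)
    color = np.empty(T * n, dtype=np.int64)
    newf = np.empty(T * n, dtype=bool)
    for s in range(T):
        c, isn = state.step(rng)
        color[s * n : (s + 1) * n] = c
        newf[s * n : (s + 1) * n] = isn
    return Trajectory(
        params=params,
        seed=int(seed),
        T=int(T),
        t=t_arr,
        agent=agent,
        color=color,
        is_new=newf,
        state=state if keep_state else None,
    )


def expected_dstar_recursion(params: NormalizedParams, T: int) -> np.ndarray:
    """Exact mean of the novelty counters, rows t = 0..T, columns agents.

    The denominator ``theta_h + t`` is deterministic, so the conditional
    expectation closes on itself:
    ``E D*_{t+1,h} = E D*_{t,h} + (theta_h + sum_j gamma_jh E D*_{t,j}) / (theta_h + t)``.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    n = params.N
    out = np.zeros((T + 1, n))
    for t in range(T):
        out[t + 1] = out[t] + (params.theta + out[t] @ params.Gamma) / (
            params.theta + t
        )
    return out


# ---------------------------------------------------------------------------
# literal ball-counting oracle

class LiteralUrnSystem:
    """Integer ball bookkeeping that follows the urn update rules verbatim.

    Tracks, for each urn, the number of balls of never-extracted colors and a
    per-extracted-color ball count, applying the replacement rules ball by
    ball.  Exists solely as a test oracle for the probability engine:
    :meth:`probabilities` returns exact :class:`~fractions.Fraction` values.
    """

    def __init__(self, raw: RawParams):
        self.raw = raw
        self.t = 0
        n = raw.N
        self.new_balls = [int(raw.N0[h]) for h in range(n)]
        self.balls: list[dict[int, int]] = [dict() for _ in range(n)]
        self.extracted: set[int] = set()

    def probabilities(self, h: int) -> tuple[Fraction, dict[int, Fraction]]:
        """(new-color probability, old-color probability map) for urn ``h``."""
        raw = self.raw
        total = self.new_balls[h] + sum(self.balls[h].values())
        expected_total = int(raw.N0[h]) + int(raw.rho_col[h]) * self.t
        assert total == expected_total, "ball conservation violated"
        newp = Fraction(self.new_balls[h], total)
        old = {c: Fraction(k, total) for c, k in self.balls[h].items() if k > 0}
        return newp, old

    def apply_step(self, colors: Sequence[int], is_new: Sequence[bool]) -> None:
        """Apply one simultaneous extraction (one event per urn)."""
        raw = self.raw
        n = raw.N
        for j in range(n):
            c = int(colors[j])
            if is_new[j]:
                if c in self.extracted:
                    raise ValueError(f"color {c} flagged new but already extracted")
                self.extracted.add(c)
                # the drawn ball came from urn j's never-extracted pool
                self.new_balls[j] -= 1
                assert self.new_balls[j] >= 0
                for h in range(n):
                    add_same = int(raw.rho_hat[j, h])
                    add_new = int(raw.nu[j, h]) + (1 if h == j else 0)
                    if add_same:
                        self.balls[h][c] = self.balls[h].get(c, 0) + add_same
                    self.new_balls[h] += add_new
            else:
                if c not in self.extracted:
                    raise ValueError(f"color {c} flagged old but never extracted")
                for h in range(n):
                    add = int(raw.rho[j, h])
                    if add:
                        self.balls[h][c] = self.balls[h].get(c, 0) + add
        self.t += 1


def literal_probabilities(
    raw: RawParams, trajectory: Trajectory, upto: int | None = None
) -> list[tuple[Fraction, dict[int, Fraction]]]:
    """Replay a trajectory through the literal urn system.

    Returns, for the state after ``upto`` steps (default: all), the exact
    (new probability, old-color map) of every urn.
    """
    sys = LiteralUrnSystem(raw)
    upto = trajectory.T if upto is None else upto
    for s, (colors, is_new) in enumerate(trajectory.steps()):
        if s >= upto:
            break
        sys.apply_step(colors, is_new)
    return [sys.probabilities(h) for h in range(raw.N)]


# ---------------------------------------------------------------------------
# exact rational probability engine and outcome-tree enumeration

def exact_probabilities(
    params: NormalizedParams,
    K: Sequence[Sequence[int]],
    orig: Sequence[int],
    t: int,
    h: int,
) -> tuple[Fraction, list[Fraction]]:
    """Exact ``Z*_{t,h}`` and old-color probabilities from rational parameters.

    ``K`` is the (N x n_colors) adoption-count table, ``orig`` the originator
    of each color.  Requires ``params.exact`` (rational mirror) to be present.
    """
    ex = params.exact
    if ex is None:
        raise ParameterError("exact rational parameters required")
    n = ex.N
    dstar = [0] * n
    for o in orig:
        dstar[o] += 1
    denom = ex.theta[h] + t
    newp = (ex.theta[h] + sum(ex.Gamma[j][h] * dstar[j] for j in range(n))) / denom
    old = []
    for c in range(len(orig)):
        num = sum(ex.w(j, h) * K[j][c] for j in range(n)) - ex.Gamma[orig[c]][h]
        old.append(num / denom)
    return newp, old


def enumerate_paths(params: NormalizedParams, T: int):
    """Enumerate the full outcome tree to horizon ``T`` with exact probabilities.

    Yields ``(events, probability)`` pairs where ``events`` is a tuple over
    time-steps of per-agent ``(color_id, is_new)`` tuples using the same
    deterministic color labelling as the simulator.  Probabilities are exact
    Fractions and sum to 1.  Exponential in ``T`` — small horizons only.
    """
    ex = params.exact
    if ex is None:
        raise ParameterError("exact rational parameters required for enumeration")
    n = ex.N
    results: list[tuple[tuple, Fraction]] = []

    def recurse(t, K, orig, prefix, prob):
        if t == T:
            results.append((tuple(prefix), prob))
            return
        C = len(orig)
        # options per agent: ('new',) or an existing color id, with exact probs
        per_agent = []
        for h in range(n):
            newp, old = exact_probabilities(params, K, orig, t, h)
            opts = [(None, newp)] if newp > 0 else []
            opts += [(c, p) for c, p in enumerate(old) if p > 0]
            per_agent.append(opts)

        def choose(h, chosen, p):
            if h == n:
                # apply: novelties first in agent order get consecutive ids
                K2 = [list(row) for row in K]
                orig2 = list(orig)
                labeled = []
                for hh, c in enumerate(chosen):
                    if c is None:
                        cid = len(orig2)
                        orig2.append(hh)
                        for row in K2:
                            row.append(0)
                        K2[hh][cid] = 1
                        labeled.append((cid, True))
                    else:
                        labeled.append((c, False))
                for hh, (cid, isnew) in enumerate(labeled):
                    if not isnew:
                        K2[hh][cid] += 1
                recurse(
                    t + 1,
                    tuple(tuple(r) for r in K2),
                    tuple(orig2),
                    prefix + [tuple(labeled)],
                    p,
                )
                return
            for c, pc in per_agent[h]:
                choose(h + 1, chosen + [c], p * pc)

        choose(0, [], prob)

    recurse(0, tuple(() for _ in range(n)), (), [], Fraction(1))
    return results
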