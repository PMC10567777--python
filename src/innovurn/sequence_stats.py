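"""Observables of categorized event streams.

Turns a stream of ``(time-step, category, item)`` records — simulated or
prepared from an external corpus — into the model's observables: the novelty
curves ``D*_{t,h}`` (distinct items whose first system-wide occurrence was in
category ``h``), the discovery curves ``D_{t,h}`` (distinct items seen in
category ``h``), the occupancy table ``K_T(h, c)`` and, for two categories,
the quantiles of the per-item adoption proportion grouped by item frequency
("table composition" in the Chinese-restaurant reading).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulator import Trajectory

__all__ = [
    "StreamError",
    "EventStream",
    "DiscoveryCurves",
    "OccupancyTable",
    "CompositionQuantiles",
    "ingest",
    "equalize_lengths",
    "discovery_curves",
    "occupancy",
    "composition_quantiles",
]

DEFAULT_QUANTILES = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


class StreamError(ValueError):
    """Raised for malformed or inconsistent event streams."""


@dataclasses.dataclass(frozen=True)
class EventStream:
    """Validated categorized event stream.

    ``t`` (1-based time-steps), ``category`` (1..N) and ``item`` (string
    labels) are parallel arrays sorted by ``(t, category)``; every time-step
    carries exactly one record per category.
    """

    t: np.ndarray
    category: np.ndarray
    item: np.ndarray
    N: int

    @property
    def T(self) -> int:
        return int(self.t[-1]) if self.t.size else 0

    def __len__(self) -> int:
        return int(self.t.size)

    def records(self) -> Iterable[tuple[int, int, str]]:
        return zip(self.t.tolist(), self.category.tolist(), self.item.tolist())

    @classmethod
    def from_trajectory(cls, traj: Trajectory) -> "EventStream":
        return cls(
            t=traj.t.copy(),
            category=(traj.agent + 1).astype(np.int64),
            item=np.array([str(c + 1) for c in traj.color], dtype=object),
            N=traj.N,
        )

    @classmethod
    def from_pair(
        cls, items1: Sequence, items2: Sequence, collision_policy: str = "error"
    ) -> "EventStream":
        """Pair two equal-length single-category sequences (implicit time = row)."""
        if len(items1) != len(items2):
            raise StreamError(
                f"sequences must have equal length, got {len(items1)} and "
                f"{len(items2)}; subsample first (equalize_lengths)"
            )
        T = len(items1)
        t = np.repeat(np.arange(1, T + 1, dtype=np.int64), 2)
        cat = np.tile(np.array([1, 2], dtype=np.int64), T)
        item = np.empty(2 * T, dtype=object)
        item[0::2] = [str(x) for x in items1]
        item[1::2] = [str(x) for x in items2]
        return ingest(
            list(zip(t.tolist(), cat.tolist(), item.tolist())),
            N=2,
            collision_policy=collision_policy,
        )

    def to_tsv(self, path) -> None:
        """Serialize as the package's TSV dialect (t, category, item, is_new)."""
        first = set()
        new_flags = np.zeros(len(self), dtype=int)
        for i, it in enumerate(self.item):
            if it not in first:
                first.add(it)
                new_flags[i] = 1
        pd.DataFrame(
            {
                "t": self.t,
                "category": self.category,
                "item": self.item,
                "is_new": new_flags,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, N: int | None = None, collision_policy: str = "error"):
        df = pd.read_csv(path, sep="\t", dtype={"item": str})
        for col in ("t", "category", "item"):
            if col not in df.columns:
                raise StreamError(f"{path}: missing column '{col}'")
        n = int(df["category"].max()) if N is None else int(N)
        return ingest(
            list(zip(df["t"], df["category"], df["item"])),
            N=n,
            collision_policy=collision_policy,
        )


def ingest(
    records: Iterable[tuple[int, int, str]],
    N: int,
    collision_policy: str = "error",
) -> EventStream:
    """Validate raw ``(t, category, item)`` records into an :class:`EventStream`.

    Every time-step must contain exactly one record per category 1..N.  If an
    item's first system-wide occurrence happens simultaneously in two
    categories, the ``error`` policy aborts; under ``tiebreak`` the lowest
    category index is deemed the originator (the records are kept, sorted by
    ``(t, category)``, so downstream counters use that convention).
    """
    if collision_policy not in ("error", "tiebreak"):
        raise ValueError(f"unknown collision_policy {collision_policy!r}")
    recs = sorted(
        ((int(t), int(c), str(i)) for t, c, i in records), key=lambda r: (r[0], r[1])
    )
    if not recs:
        raise StreamError("empty record set")
    t_arr = np.array([r[0] for r in recs], dtype=np.int64)
    c_arr = np.array([r[1] for r in recs], dtype=np.int64)
    i_arr = np.array([r[2] for r in recs], dtype=object)
    if np.any(c_arr < 1) or np.any(c_arr > N):
        bad = int(np.argmax((c_arr < 1) | (c_arr > N)))
        raise StreamError(
            f"record {bad}: category {c_arr[bad]} outside 1..{N}"
        )
    T = int(t_arr[-1])
    if len(recs) != T * N or t_arr[0] != 1:
        raise StreamError(
            f"expected exactly {N} records for each time-step 1..{T}, "
            f"got {len(recs)} records"
        )
    expected_t = np.repeat(np.arange(1, T + 1), N)
    expected_c = np.tile(np.arange(1, N + 1), T)
    mism = np.nonzero((t_arr != expected_t) | (c_arr != expected_c))[0]
    if mism.size:
        k = int(mism[0])
        raise StreamError(
            f"record {k}: expected (t={expected_t[k]}, category={expected_c[k]}), "
            f"got (t={t_arr[k]}, category={c_arr[k]}); every time-step needs one "
            "record per category"
        )
    if collision_policy == "error":
        seen: set = set()
        for s in range(T):
            step_new = {}
            for k in range(s * N, (s + 1) * N):
                it = i_arr[k]
                if it not in seen:
                    if it in step_new:
                        raise StreamError(
                            f"item {it!r} first occurs simultaneously in "
                            f"categories {step_new[it]} and {c_arr[k]} at "
                            f"t={s + 1}; pass collision_policy='tiebreak' to "
                            "attribute it to the lower category"
                        )
                    step_new[it] = int(c_arr[k])
            seen.update(step_new)
    return EventStream(t=t_arr, category=c_arr, item=i_arr, N=int(N))


def equalize_lengths(
    seq1: Sequence, seq2: Sequence, seed: int
) -> tuple[list, list]:
    """Subsample the longer of two sequences to the shorter one's length.

    Removal is uniform without replacement (seeded) and preserves the
    original order of the surviving records — mirroring the random thinning
    used to equalize two observed category sequences.
    """
    if len(seq1) == 0 or len(seq2) == 0:
        raise StreamError("cannot equalize empty sequences")
    a, b = list(seq1), list(seq2)
    if len(a) == len(b):
        return a, b
    rng = np.random.default_rng(seed)
    if len(a) > len(b):
        keep = np.sort(rng.choice(len(a), size=len(b), replace=False))
        return [a[i] for i in keep], b
    keep = np.sort(rng.choice(len(b), size=len(a), replace=False))
    return a, [b[i] for i in keep]


@dataclasses.dataclass(frozen=True)
class DiscoveryCurves:
    """Per-category novelty/discovery counters over t = 1..T.

    ``dstar[t-1, h-1] = D*_{t,h}``, ``d[t-1, h-1] = D_{t,h}`` and
    ``total[t-1] = D*_t = sum_h D*_{t,h}``.
    """

    dstar: np.ndarray
    d: np.ndarray
    total: np.ndarray

    @property
    def T(self) -> int:
        return int(self.dstar.shape[0])

    @property
    def N(self) -> int:
        return int(self.dstar.shape[1])

    def series(self) -> dict[str, np.ndarray]:
        """Named 1..T series for fitting: dstar_h, d_h per category plus total."""
        out = {}
        for h in range(self.N):
            out[f"dstar_{h + 1}"] = self.dstar[:, h]
            out[f"d_{h + 1}"] = self.d[:, h]
        out["dstar_total"] = self.total
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": np.arange(1, self.T + 1)}
        for name, arr in self.series().items():
            cols[name] = arr
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def discovery_curves(stream: EventStream) -> DiscoveryCurves:
    """Compute ``D*_{t,h}``, ``D_{t,h}`` and ``D*_t`` from a validated stream."""
    T, N = stream.T, stream.N
    dstar = np.zeros((T, N), dtype=np.int64)
    d = np.zeros((T, N), dtype=np.int64)
    seen_sys: set = set()
    seen_cat: list[set] = [set() for _ in range(N)]
    ds = np.zeros(N, dtype=np.int64)
    dc = np.zeros(N, dtype=np.int64)
    idx = 0
    items = stream.item
    cats = stream.category
    for s in range(T):
        for _ in range(N):
            it = items[idx]
            h = int(cats[idx]) - 1
            if it not in seen_sys:
                seen_sys.add(it)
                ds[h] += 1
            if it not in seen_cat[h]:
                seen_cat[h].add(it)
                dc[h] += 1
            idx += 1
        dstar[s] = ds
        d[s] = dc
    return DiscoveryCurves(dstar=dstar, d=d, total=dstar.sum(axis=1))


@dataclasses.dataclass(frozen=True)
class OccupancyTable:
    """Final adoption counts per item: ``K_T(h, c)``, originator, first time.

    ``table`` is indexed by item with columns ``K_1..K_N``, ``originator``
    (1-based category of first occurrence) and ``first_t``.
    """

    table: pd.DataFrame
    N: int
    T: int

    def totals(self) -> pd.Series:
        return self.table[[f"K_{h + 1}" for h in range(self.N)]].sum(axis=1)


def occupancy(stream: EventStream) -> OccupancyTable:
    """Tabulate adoption counts ``K_T(h, c)`` for every observed item."""
    df = pd.DataFrame(
        {"t": stream.t, "category": stream.category, "item": stream.item}
    )
    if df.empty:
        return OccupancyTable(table=pd.DataFrame(), N=stream.N, T=0)
    counts = pd.crosstab(df["item"], df["category"])
    counts = counts.reindex(columns=range(1, stream.N + 1), fill_value=0)
    counts.columns = [f"K_{h}" for h in range(1, stream.N + 1)]
    first = df.drop_duplicates("item", keep="first").set_index("item")
    out = counts.copy()
    out["originator"] = first["category"]
    out["first_t"] = first["t"]
    # column sums must each equal T (one adoption per category per step)
    k_cols = out[[f"K_{h}" for h in range(1, stream.N + 1)]]
    assert (k_cols.sum(axis=0) == stream.T).all()
    return OccupancyTable(table=out, N=stream.N, T=stream.T)


@dataclasses.dataclass(frozen=True)
class CompositionQuantiles:
    """Quantiles of the per-item adoption proportion, binned by item frequency.

    One row per occupied bin: half-open log10-total interval ``[lo, hi)``,
    number of items, and the requested quantiles of
    ``K_T(ref, c) / sum_j K_T(j, c)``.
    """

    bins: pd.DataFrame
    probs: tuple
    ref_category: int
    min_total: int
    bin_width: float


def composition_quantiles(
    table: OccupancyTable,
    probs: Sequence[float] = DEFAULT_QUANTILES,
    min_total: int = 10,
    bin_width: float = 0.5,
    ref_category: int = 1,
) -> CompositionQuantiles:
    """Empirical composition quantiles along item frequency.

    Items adopted fewer than ``min_total`` times are dropped; the rest are
    grouped into half-open intervals of width ``bin_width`` in log10 of the
    total count, anchored at ``log10(min_total)``; within each bin the
    requested quantiles (linear-interpolation estimator) of the reference
    category's proportion are computed.  Under an irreducible adoption matrix
    the high-frequency bins concentrate at ``1/N``.
    """
    if not 1 <= ref_category <= table.N:
        raise ValueError(f"ref_category must be in 1..{table.N}")
    totals = table.totals()
    keep = totals[totals >= min_total]
    if keep.empty:
        raise StreamError(
            f"no items with total count >= {min_total}; nothing to bin"
        )
    prop = table.table.loc[keep.index, f"K_{ref_category}"] / keep
    logt = np.log10(keep.to_numpy(dtype=float))
    anchor = np.log10(min_total)
    bin_idx = np.floor((logt - anchor) / bin_width + 1e-12).astype(int)
    rows = []
    probs = tuple(float(p) for p in probs)
    for b in sorted(set(bin_idx.tolist())):
        mask = bin_idx == b
        vals = prop.to_numpy(dtype=float)[mask]
        qs = np.quantile(vals, probs, method="linear")
        row = {
            "log10_lo": anchor + b * bin_width,
            "log10_hi": anchor + (b + 1) * bin_width,
            "n_items": int(mask.sum()),
        }
        row.update({f"q{p:g}": q for p, q in zip(probs, qs)})
        rows.append(row)
    return CompositionQuantiles(
        bins=pd.DataFrame(rows),
        probs=probs,
        ref_category=ref_category,
        min_total=min_total,
        bin_width=bin_width,
    )
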