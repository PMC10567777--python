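import numpy as np
import pandas as pd
import pytest

from innovurn import (
    EventStream,
    StreamError,
    composition_quantiles,
    discovery_curves,
    equalize_lengths,
    ingest,
    occupancy,
    simulate,
)


TOY = [(1, 1, "A"), (1, 2, "B"), (2, 1, "B"), (2, 2, "C")]


class TestIngest:
    def test_valid_stream(self):
        s = ingest(TOY, N=2)
        assert s.T == 2 and s.N == 2 and len(s) == 4

    def test_simultaneous_first_occurrence_errors(self):
        with pytest.raises(StreamError, match="simultaneously"):
            ingest([(1, 1, "A"), (1, 2, "A")], N=2)

    def test_tiebreak_attributes_to_lower_category(self):
        s = ingest([(1, 1, "A"), (1, 2, "A")], N=2, collision_policy="tiebreak")
        occ = occupancy(s)
        assert occ.table.loc["A", "originator"] == 1

    def test_missing_category_errors(self):
        with pytest.raises(StreamError):
            ingest([(1, 1, "A"), (1, 2, "B"), (2, 1, "C")], N=2)

    def test_unknown_category_errors(self):
        with pytest.raises(StreamError, match="category"):
            ingest([(1, 1, "A"), (1, 3, "B")], N=2)


class TestEqualize:
    def test_equal_lengths_unchanged(self):
        a, b = equalize_lengths(list("abcde"), list("fghij"), seed=1)
        assert a == list("abcde") and b == list("fghij")

    def test_longer_sequence_subsampled_order_preserved(self):
        long = [f"x{i}" for i in range(12)]
        short = [f"y{i}" for i in range(10)]
        a, b = equalize_lengths(long, short, seed=7)
        assert len(a) == len(b) == 10
        idx = [long.index(v) for v in a]
        assert idx == sorted(idx)
        a2, _ = equalize_lengths(long, short, seed=7)
        assert a2 == a

    def test_extreme_imbalance(self):
        a, b = equalize_lengths([str(i) for i in range(10**5)], list("abcdefghij"), seed=0)
        assert len(a) == 10

    def test_empty_rejected(self):
        with pytest.raises(StreamError):
            equalize_lengths([], ["a"], seed=0)


class TestDiscoveryCurves:
    def test_toy_stream_by_definition(self):
        c = discovery_curves(ingest(TOY, N=2))
        # B first occurred in category 2 at t=1; C in category 2 at t=2
        assert c.dstar[1].tolist() == [1, 2]
        assert c.d[1].tolist() == [2, 2]
        assert c.total[1] == 3
        assert np.all(np.diff(c.dstar, axis=0) >= 0)
        assert np.all(c.dstar <= c.d)
        assert np.all(c.d <= c.total[:, None])

    def test_matches_simulator_counters_exactly(self, worked_example):
        traj = simulate(worked_example, T=500, seed=2)
        c = discovery_curves(EventStream.from_trajectory(traj))
        assert c.dstar[-1].tolist() == traj.state.dstar.tolist()
        assert c.d[-1].tolist() == traj.state.d.tolist()
        assert c.total[-1] == traj.state.n_colors

    def test_single_category_all_distinct(self):
        s = ingest([(t, 1, f"w{t}") for t in range(1, 11)], N=1)
        c = discovery_curves(s)
        np.testing.assert_array_equal(c.dstar[:, 0], np.arange(1, 11))
        np.testing.assert_array_equal(c.d[:, 0], np.arange(1, 11))

    def test_pure_and_order_stable(self):
        s = ingest(TOY, N=2)
        a, b = discovery_curves(s), discovery_curves(s)
        np.testing.assert_array_equal(a.dstar, b.dstar)
        np.testing.assert_array_equal(a.d, b.d)


class TestOccupancy:
    def test_toy_counts_and_originators(self):
        occ = occupancy(ingest(TOY, N=2))
        t = occ.table
        assert t.loc["A", "K_1"] == 1 and t.loc["A", "K_2"] == 0
        assert t.loc["B", "K_1"] == 1 and t.loc["B", "K_2"] == 1
        assert t.loc["B", "originator"] == 2 and t.loc["B", "first_t"] == 1
        assert t.loc["C", "originator"] == 2
        # one adoption per category per time-step
        assert t[["K_1", "K_2"]].sum(axis=0).tolist() == [2, 2]

    def test_empty_stream_gives_empty_table(self):
        empty = EventStream(
            t=np.array([], dtype=np.int64),
            category=np.array([], dtype=np.int64),
            item=np.array([], dtype=object),
            N=2,
        )
        assert occupancy(empty).table.empty


class TestCompositionQuantiles:
    def test_hand_computed_median(self):
        # totals 10, 10, 12 all fall in the first bin [10, 10^1.5)
        table = pd.DataFrame(
            {
                "K_1": [6, 5, 9],
                "K_2": [4, 5, 3],
                "originator": [1, 1, 1],
                "first_t": [1, 1, 1],
            },
            index=["a", "b", "c"],
        )
        from innovurn.sequence_stats import OccupancyTable

        occ = OccupancyTable(table=table, N=2, T=20)
        cq = composition_quantiles(occ, probs=[0.5])
        assert len(cq.bins) == 1
        assert cq.bins.loc[0, "n_items"] == 3
        assert cq.bins.loc[0, "q0.5"] == pytest.approx(0.6)
        assert cq.bins.loc[0, "log10_lo"] == pytest.approx(1.0)

    def test_min_total_filter_excludes_small_tables(self):
        from innovurn.sequence_stats import OccupancyTable

        table = pd.DataFrame(
            {"K_1": [6, 5], "K_2": [4, 4], "originator": [1, 1], "first_t": [1, 1]},
            index=["a", "b"],
        )
        occ = OccupancyTable(table=table, N=2, T=19)
        cq = composition_quantiles(occ, probs=[0.5])
        assert cq.bins.loc[0, "n_items"] == 1  # total 9 dropped

    def test_balanced_tables_give_half_everywhere(self):
        from innovurn.sequence_stats import OccupancyTable

        table = pd.DataFrame(
            {
                "K_1": [10, 20, 40],
                "K_2": [10, 20, 40],
                "originator": [1, 1, 1],
                "first_t": [1, 1, 1],
            },
            index=list("abc"),
        )
        occ = OccupancyTable(table=table, N=2, T=140)
        cq = composition_quantiles(occ, probs=[0.1, 0.5, 0.9])
        qcols = [c for c in cq.bins.columns if c.startswith("q")]
        assert np.allclose(cq.bins[qcols].to_numpy(), 0.5)

    def test_empty_after_filter_errors(self):
        from innovurn.sequence_stats import OccupancyTable

        table = pd.DataFrame(
            {"K_1": [2], "K_2": [3], "originator": [1], "first_t": [1]}, index=["a"]
        )
        with pytest.raises(StreamError):
            composition_quantiles(OccupancyTable(table=table, N=2, T=5))

    def test_top_bin_median_approaches_half_as_t_grows(self, worked_example):
        """Uniform-composition limit: monotone trend toward 1/2 (seeded)."""
        devs = []
        for T in (1000, 10000, 60000):
            traj = simulate(worked_example, T=T, seed=31)
            occ = occupancy(EventStream.from_trajectory(traj))
            cq = composition_quantiles(occ, probs=[0.5])
            top = cq.bins.iloc[-1]
            devs.append(abs(top["q0.5"] - 0.5))
        assert devs[-1] <= devs[0]
        assert devs[-1] < 0.1


class TestRoundTrip:
    def test_tsv_round_trip(self, tmp_path, worked_example):
        traj = simulate(worked_example, T=50, seed=8)
        s = EventStream.from_trajectory(traj)
        path = tmp_path / "stream.tsv"
        s.to_tsv(path)
        s2 = EventStream.from_tsv(path, N=2)
        np.testing.assert_array_equal(s.t, s2.t)
        np.testing.assert_array_equal(s.item.astype(str), s2.item.astype(str))

    def test_from_pair_requires_equal_lengths(self):
        with pytest.raises(StreamError, match="equal length"):
            EventStream.from_pair(["a", "b"], ["c"])
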