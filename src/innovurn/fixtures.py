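"""Small reproducible fixture datasets for tests, demos and error-path checks."""

from __future__ import annotations

from pathlib import Path

from .params import NormalizedParams, dump_params
from .sequence_stats import EventStream
from .simulator import simulate

__all__ = ["worked_example_params", "make_fixtures"]


def worked_example_params() -> NormalizedParams:
    """Two symmetric agents with moderate triggering and adoption coupling.

    theta = (1, 1), Gamma = [[0.2, 0.1], [0.1, 0.2]], W = [[0.7, 0.3],
    [0.3, 0.7]].  After the forced double novelty of the first step, agent 1
    faces Z* = 0.65 and old-color probabilities 0.25 / 0.10 — handy closed
    numbers for documentation and tests.
    """
    return NormalizedParams.from_rationals(
        theta=[1, 1],
        Gamma=[["1/5", "1/10"], ["1/10", "1/5"]],
        Lambda=[["1/2", "1/5"], ["1/5", "1/2"]],
    )


def make_fixtures(out_dir, seed: int) -> dict[str, Path]:
    """Write canned fixtures; regenerates bit-identically from the seed.

    Produces the worked-example parameter file, a T=1000 trajectory stream,
    and malformed streams triggering each documented ingestion error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    params = worked_example_params()
    paths["params"] = out / "worked_example.yaml"
    dump_params(params, paths["params"])

    traj = simulate(params, T=1000, seed=seed, keep_state=False)
    paths["stream"] = out / "worked_example_stream.tsv"
    EventStream.from_trajectory(traj).to_tsv(paths["stream"])

    header = "t\tcategory\titem\tis_new\n"
    paths["missing_category"] = out / "malformed_missing_category.tsv"
    paths["missing_category"].write_text(
        header + "1\t1\tA\t1\n1\t2\tB\t1\n2\t1\tC\t1\n", encoding="utf-8"
    )
    paths["simultaneous_novelty"] = out / "malformed_simultaneous_novelty.tsv"
    paths["simultaneous_novelty"].write_text(
        header + "1\t1\tA\t1\n1\t2\tA\t1\n", encoding="utf-8"
    )
    paths["unknown_category"] = out / "malformed_unknown_category.tsv"
    paths["unknown_category"].write_text(
        header + "1\t1\tA\t1\n1\t3\tB\t1\n", encoding="utf-8"
    )
    return paths
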