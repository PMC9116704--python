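"""Benchmark runner: masks at increasing percentages, repeated runs, NRF.

Ground truth is the NJ tree of the complete source matrix.  For each
missing-data percentage a set of masks is drawn; each mask is imputed
several times under each configuration profile (masks are shared across
profiles and runs so comparisons are paired), and every run is scored by
the NRF of its NJ tree against the truth.  Aggregates report mean, min,
max and standard deviation of NRF per percentage.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .criteria import ls_score, me_score, nrf, rf_distance
from .imputer import ImputationConfig, impute
from .matrix_core import DistanceMatrix, inject_missing
from .neighbor_joining import nj_tree

DEFAULT_PERCENTAGES = tuple(range(5, 65, 5))


@dataclass
class BenchmarkSpec:
    source: DistanceMatrix
    percentages: tuple[int, ...] = DEFAULT_PERCENTAGES
    masks_per_pct: int = 10
    runs_per_mask: int = 5
    profiles: dict[str, ImputationConfig] = field(
        default_factory=lambda: {"split-ls-rand": ImputationConfig.split_ls_rand()}
    )
    seed: int = 0
    dataset_name: str = "dataset"

    def __post_init__(self) -> None:
        if self.masks_per_pct < 1 or self.runs_per_mask < 1:
            raise ValueError("masks_per_pct and runs_per_mask must be >= 1")
        if not self.profiles:
            raise ValueError("at least one profile is required")


@dataclass
class BenchmarkReport:
    rows: pd.DataFrame
    aggregates: pd.DataFrame


def run_benchmark(spec: BenchmarkSpec) -> BenchmarkReport:
    """Execute the full percentage x mask x run x profile grid.

    A failed run is recorded with its error message in the ``error``
    column and NaN scores; it is never silently dropped.
    """
    src = spec.source
    truth = nj_tree(src)
    root = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for pct in spec.percentages:
        for mask_id in range(spec.masks_per_pct):
            mask_rng, run_root = root.spawn(2)
            mask = inject_missing(src, pct / 100.0, mask_rng)
            for run_id in range(spec.runs_per_mask):
                for name, cfg in spec.profiles.items():
                    run_rng = run_root.spawn(1)[0]
                    row = {
                        "dataset": spec.dataset_name, "pct_missing": pct,
                        "mask_id": mask_id, "run_id": run_id, "profile": name,
                        "rf": np.nan, "nrf_pct": np.nan, "ls": np.nan,
                        "me": np.nan, "iterations": 0, "wall_time": np.nan,
                        "error": "",
                    }
                    t0 = time.perf_counter()
                    try:
                        res = impute(src, mask, cfg, rng=run_rng)
                        rf = rf_distance(res.tree, truth)
                        row.update(
                            rf=rf, nrf_pct=100.0 * nrf(rf, src.n),
                            ls=ls_score(res.imputed, res.tree),
                            me=me_score(res.tree), iterations=res.iterations,
                        )
                    except Exception as exc:  # recorded, not dropped
                        row["error"] = f"{type(exc).__name__}: {exc}"
                    row["wall_time"] = time.perf_counter() - t0
                    rows.append(row)
    df = pd.DataFrame(rows)
    agg = (
        df[df["error"] == ""]
        .groupby(["dataset", "profile", "pct_missing"])["nrf_pct"]
        .agg(["mean", "min", "max", "std"])
        .reset_index()
    )
    return BenchmarkReport(rows=df, aggregates=agg)


def accumulate_nrf(
    rows: pd.DataFrame,
    expected_cells: list[tuple] | None = None,
    by: tuple[str, ...] = ("dataset", "pct_missing"),
) -> float:
    """Sum of per-cell mean NRF percentages over a benchmark grid.

    Cells are the groups defined by ``by``.  If ``expected_cells`` is
    given, any absent cell raises an error naming the gaps.
    """
    if rows is None or len(rows) == 0:
        raise ValueError("empty benchmark grid: no rows to accumulate")
    ok = rows[rows["error"] == ""] if "error" in rows.columns else rows
    means = ok.groupby(list(by))["nrf_pct"].mean()
    if expected_cells is not None:
        present = set(means.index)
        missing = [c for c in expected_cells if c not in present]
        if missing:
            raise ValueError(f"benchmark grid incomplete; missing cells: {missing}")
    return float(means.sum())
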