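"""Experiment grid orchestration: methods x sample sizes x repetitions.

Each grid cell (method, n, repetition) draws ``n`` samples without
replacement from a fixed pool (fresh draw per repetition), infers an
association matrix, scores it against the reference adjacency with every
pairwise metric at the F1-optimal threshold, and computes the four
centrality MAEs of the binarized network.  Results are tidy rows; per-cell
seeds are derived from the master seed by hashing the cell identifier, so
any row can be regenerated in isolation and cell execution order never
matters.  A manifest makes reruns resumable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import centrality as centrality_mod
from . import evaluation
from .inference import METHODS, SampleSizeError, infer, min_samples

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_SIZES = (5, 10, 20, 50, 100, 200)


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid settings: which methods, at which sample sizes, how many times."""

    methods: tuple[str, ...]
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    repetitions: int = 100
    seed: int = 0
    log_transform: bool = False
    include_centrality: bool = True
    pclrc_iterations: int = 1000
    output_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if any(n < 3 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 3")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def cell_seed(master: int, method: str, n: int, repetition: int) -> int:
    """Stable per-cell seed: SHA-256 of the cell identifier, folded to 31 bits."""
    digest = hashlib.sha256(f"{master}:{method}:{n}:{repetition}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _evaluate_cell(samples, adjacency, method: str, seed: int, config: ExperimentConfig) -> list[dict]:
    kwargs = {"iterations": config.pclrc_iterations} if method.startswith("pclrc") else {}
    assoc = infer(samples, method, seed=seed, **kwargs)
    results = evaluation.evaluate_all(assoc, adjacency)
    rows = [
        {"metric": name, "value": res.value, "threshold": res.threshold}
        for name, res in results.items()
    ]
    if config.include_centrality:
        pred = evaluation.binarize(assoc, results["F1"].threshold)
        for measure, comparison in centrality_mod.all_errors(pred, adjacency).items():
            rows.append({"metric": f"{measure}_mae", "value": comparison.mae, "threshold": None})
    return rows


def run_grid(pool, adjacency, config: ExperimentConfig) -> pd.DataFrame:
    """Run the full grid and return tidy results.

    Methods whose precondition demands more samples than a grid size offers
    are skipped at that size with a logged reason.  Per-cell failures are
    recorded and skipped, never aborting the grid; a summary of failures is
    logged at exit.  When ``config.output_dir`` is set, results and a
    completion manifest are written there and completed cells are skipped on
    rerun.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    manifest_path = out_dir / "manifest.json" if out_dir else None
    done: dict[str, list] = {}
    if manifest_path and manifest_path.exists():
        done = json.loads(manifest_path.read_text())
        logger.info("resuming: %d cells already complete", len(done))

    pool_values = pool
    if config.log_transform:
        from .synthetic_data import SampleMatrix

        pool_values = SampleMatrix(pool.names, np.log(np.maximum(pool.values, 1e-12)) - np.log(1e-12))

    rows: list[dict] = []
    failures: list[tuple[str, int, int, str]] = []
    m = pool.n_samples
    if max(config.sample_sizes) > m:
        raise ValueError(f"pool of {m} samples cannot supply n={max(config.sample_sizes)}")
    for method in config.methods:
        for n in config.sample_sizes:
            needed = min_samples(method)
            if n < needed:
                logger.info("method %s omitted at n=%d (needs >= %d samples)", method, n, needed)
                continue
            for rep in range(config.repetitions):
                key = f"{method}:{n}:{rep}"
                seed = cell_seed(config.seed, method, n, rep)
                if key in done:
                    for row in done[key]:
                        rows.append(row)
                    continue
                rng = np.random.default_rng(seed)
                idx = rng.choice(m, size=n, replace=False)
                try:
                    cell_rows = _evaluate_cell(pool_values.subset(idx), adjacency, method, seed, config)
                except Exception as exc:  # record and continue
                    failures.append((method, n, rep, str(exc)))
                    logger.warning("cell %s failed: %s", key, exc)
                    continue
                for row in cell_rows:
                    row.update({"method": method, "n_samples": n, "repetition": rep, "seed": seed})
                    rows.append(row)
                done[key] = [
                    {k: (v if not isinstance(v, np.generic) else v.item()) for k, v in row.items()}
                    for row in cell_rows
                ]
    if failures:
        logger.warning("grid finished with %d failed cells: %s", len(failures), failures[:10])
    df = pd.DataFrame(rows, columns=["method", "n_samples", "repetition", "seed", "metric", "value", "threshold"])
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "results.csv", index=False)
        manifest_path.write_text(json.dumps(done))
    return df


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and 95% percentile CI per (method, n_samples, metric)."""
    if results.empty:
        return pd.DataFrame(columns=["method", "n_samples", "metric", "mean", "ci_low", "ci_high"])

    def agg(group: pd.Series) -> pd.Series:
        lo, hi = centrality_mod.percentile_ci(group)
        return pd.Series({"mean": group.mean(), "ci_low": lo, "ci_high": hi})

    out = (
        results.groupby(["method", "n_samples", "metric"])["value"]
        .apply(agg)
        .unstack()
        .reset_index()
    )
    return out
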