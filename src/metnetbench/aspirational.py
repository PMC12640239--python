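"""Aspirational association matrices: uniform noise plus controllable signal.

The aspirational matrix isolates how evaluation metrics respond to signal
quality, independent of any inference algorithm: every unordered metabolite
pair receives one U[0, 1] draw (mirrored, so the matrix is exactly
symmetric) plus ``signal`` times the ground-truth adjacency entry,

    Asp(x, y, signal) = U[0, 1] + signal * Adj(x, y),

so entries lie in [0, 1 + signal] and at signal = 1 every true edge scores
strictly above every non-edge.  Sweeping the signal from 0 to 1 maps out
each metric's usable range and variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import centrality as centrality_mod
from . import evaluation
from .inference import NONNEGATIVE, AssociationMatrix

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = tuple(np.round(np.arange(1, 51) * 0.02, 2))  # 0.02 .. 1.00


@dataclass(frozen=True)
class AspirationalConfig:
    """Signal levels and repetition counts for a sweep.

    Defaults: fifty signal levels 0.02, 0.04, ..., 1.00 with 100 matrices
    per level (the grid used to characterize metric behaviour).
    """

    signal_levels: tuple[float, ...] = DEFAULT_LEVELS
    matrices_per_level: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= s <= 1 for s in self.signal_levels):
            raise ValueError("signal levels must lie in [0, 1]")
        if self.matrices_per_level < 1:
            raise ValueError("matrices_per_level must be >= 1")


def aspirational_matrix(adj, signal: float, seed: int = 0) -> AssociationMatrix:
    """One aspirational matrix at the given signal level (deterministic per seed)."""
    if not 0 <= signal <= 1:
        raise ValueError("signal must lie in [0, 1]")
    n = len(adj.names)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    noise = np.zeros((n, n))
    draws = rng.uniform(0.0, 1.0, size=iu.size)
    noise[iu, ju] = draws
    noise[ju, iu] = draws
    values = noise + signal * np.asarray(adj.values, dtype=float)
    np.fill_diagonal(values, 0.0)
    return AssociationMatrix(tuple(adj.names), values, NONNEGATIVE)


PAIRWISE_METRICS = ("F1", "MCC", "FDR", "AUROC", "AUPR")


def signal_sweep(
    adj,
    config: AspirationalConfig = AspirationalConfig(),
    metrics: tuple[str, ...] = PAIRWISE_METRICS,
    include_centrality: bool = True,
) -> pd.DataFrame:
    """Evaluate metrics on aspirational matrices across the signal range.

    For each (level, repetition) one matrix is generated and every requested
    pairwise metric is computed — F1 and MCC at the F1-optimal threshold,
    AUROC/AUPR threshold-free — plus, optionally, the four centrality MAEs
    of the network binarized at the F1-optimal threshold.  Returns a tidy
    frame with columns (signal, repetition, metric, value).
    """
    rows = []
    for li, signal in enumerate(config.signal_levels):
        for rep in range(config.matrices_per_level):
            seed = int(np.random.SeedSequence((config.seed, li, rep)).generate_state(1)[0] % (2**31))
            asp = aspirational_matrix(adj, signal, seed=seed)
            results = evaluation.evaluate_all(asp, adj)
            for metric in metrics:
                rows.append(
                    {"signal": signal, "repetition": rep, "metric": metric, "value": results[metric].value}
                )
            if include_centrality:
                tau = results["F1"].threshold
                pred = evaluation.binarize(asp, tau)
                for measure, comparison in centrality_mod.all_errors(pred, adj).items():
                    rows.append(
                        {
                            "signal": signal,
                            "repetition": rep,
                            "metric": f"{measure}_mae",
                            "value": comparison.mae,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean and 95% percentile interval per (signal, metric)."""
    def agg(group: pd.Series) -> pd.Series:
        lo, hi = centrality_mod.percentile_ci(group)
        return pd.Series({"mean": group.mean(), "ci_low": lo, "ci_high": hi})

    return sweep.groupby(["signal", "metric"])["value"].apply(agg).unstack().reset_index()
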