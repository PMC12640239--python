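"""Bootstrapped consensus networks and cross-condition differential edges.

To compare two biological conditions, each condition's sample pool is
bootstrapped (sampling with replacement), a network is inferred from each
bootstrap, and the condition's *consensus network* keeps the edges that
appear in strictly more than a reliability threshold (default 50%) of the
bootstrap networks.  Differential edges between two conditions are the
symmetric difference of their consensus edge sets.  A split-half check —
building consensus networks from each half of the bootstraps and counting
their disagreements — gauges whether the consensus has stabilized.

Note bootstrap resampling here is *with* replacement, unlike PCLRC's
without-replacement subsampling; the two must not be conflated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import evaluation
from .inference import infer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for one condition's bootstrap consensus.

    Thresholding of each bootstrap's association matrix: the F1-optimal
    threshold against ``reference`` when one is supplied; a fixed ``tau``
    when given; otherwise a rank rule keeping the ``top_k`` strongest pairs
    (with ``top_k`` defaulting to the reference edge count when a reference
    exists).
    """

    n_bootstrap: int = 100
    bootstrap_size: int = 100
    reliability_threshold: float = 0.5
    nia: str = "clr_pearson"
    seed: int = 0
    tau: float | None = None
    top_k: int | None = None
    keep_networks: bool = True

    def __post_init__(self) -> None:
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be >= 2")
        if not 0 < self.reliability_threshold < 1:
            raise ValueError("reliability_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class ConsensusNetwork:
    """Reliable edges plus the per-pair bootstrap frequency matrix."""

    reliable: evaluation.BinaryNetwork
    frequency: np.ndarray
    threshold: float
    networks: tuple[evaluation.BinaryNetwork, ...] | None = None

    @property
    def names(self) -> tuple[str, ...]:
        return self.reliable.names


def _binarize_bootstrap(assoc, config: BootstrapConfig, reference) -> evaluation.BinaryNetwork:
    if reference is not None:
        tau, _ = evaluation.optimal_threshold(assoc, reference, "F1")
        return evaluation.binarize(assoc, tau)
    if config.tau is not None:
        return evaluation.binarize(assoc, config.tau)
    if config.top_k is None:
        raise ValueError("without a reference, BootstrapConfig needs tau or top_k")
    mags = assoc.magnitudes()
    n = mags.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    flat = mags[iu, ju]
    k = min(config.top_k, flat.size)
    order = np.argsort(-flat, kind="stable")[:k]
    b = np.zeros((n, n), dtype=np.int8)
    b[iu[order], ju[order]] = 1
    b |= b.T
    return evaluation.BinaryNetwork(assoc.names, b, threshold_used="top_k")


def bootstrap_consensus(samples, config: BootstrapConfig, reference=None) -> ConsensusNetwork:
    """Bootstrap the sample pool and keep reliably recurring edges.

    Each bootstrap draws ``bootstrap_size`` samples with replacement, infers
    an association matrix with the configured algorithm, and binarizes it.
    Edge frequencies across bootstraps form the consensus; the reliable set
    keeps pairs with frequency strictly above the threshold.  A bootstrap
    whose draw degenerates (constant column breaking the inference) is
    retried with a fresh draw, up to 10 consecutive times.
    """
    m = samples.n_samples
    if m < 3:
        raise ValueError("sample pool must hold >= 3 samples")
    top_k = config.top_k
    if top_k is None and config.tau is None and reference is not None:
        pass  # per-bootstrap F1-optimal threshold against the reference
    rng = np.random.default_rng(config.seed)
    n = len(samples.names)
    counts = np.zeros((n, n))
    networks = []
    for b in range(config.n_bootstrap):
        for attempt in range(11):
            idx = rng.integers(0, m, size=config.bootstrap_size)
            boot = samples.subset(idx)
            try:
                assoc = infer(boot, config.nia, seed=int(rng.integers(0, 2**31 - 1)))
                break
            except ValueError as exc:
                logger.warning("bootstrap %d attempt %d failed (%s); redrawing", b, attempt, exc)
        else:
            raise RuntimeError(f"bootstrap {b}: more than 10 consecutive degenerate draws")
        net = _binarize_bootstrap(assoc, config, reference)
        counts += net.values
        if config.keep_networks:
            networks.append(net)
    freq = counts / config.n_bootstrap
    reliable = evaluation.BinaryNetwork(
        samples.names, (freq > config.reliability_threshold).astype(np.int8), threshold_used="consensus"
    )
    return ConsensusNetwork(
        reliable=reliable,
        frequency=freq,
        threshold=config.reliability_threshold,
        networks=tuple(networks) if config.keep_networks else None,
    )


def differential_edges(a: ConsensusNetwork, b: ConsensusNetwork) -> tuple[list, list]:
    """Edges reliable in exactly one condition (symmetric difference by side)."""
    if a.names != b.names:
        raise ValueError("name mismatch between consensus networks")
    edges_a = a.reliable.edge_set()
    edges_b = b.reliable.edge_set()
    return sorted(edges_a - edges_b), sorted(edges_b - edges_a)


def _reliable_from(networks, threshold: float) -> evaluation.BinaryNetwork:
    names = networks[0].names
    freq = sum(net.values.astype(float) for net in networks) / len(networks)
    return evaluation.BinaryNetwork(names, (freq > threshold).astype(np.int8), threshold_used="consensus")


@dataclass(frozen=True)
class SplitHalfResult:
    only_first: list
    only_second: list
    agreement: int

    @property
    def disagreement(self) -> int:
        return len(self.only_first) + len(self.only_second)


def split_half_agreement(per_bootstrap_networks, reliability_threshold: float = 0.5) -> SplitHalfResult:
    """Compare reliable sets from the first and second halves of the bootstraps.

    The already-generated networks are partitioned by index (odd counts put
    the extra network in the first half).  Returns the edges unique to each
    half and the count of shared reliable edges.
    """
    nets = list(per_bootstrap_networks)
    if len(nets) < 4:
        raise ValueError("split-half needs >= 4 bootstrap networks")
    half = (len(nets) + 1) // 2
    if len(nets) % 2:
        logger.info("odd bootstrap count %d: first half gets %d networks", len(nets), half)
    first = _reliable_from(nets[:half], reliability_threshold).edge_set()
    second = _reliable_from(nets[half:], reliability_threshold).edge_set()
    return SplitHalfResult(
        only_first=sorted(first - second),
        only_second=sorted(second - first),
        agreement=len(first & second),
    )


def edge_presence_trace(per_bootstrap_networks, edge: tuple[str, str]) -> int:
    """Number of bootstrap networks containing the given edge."""
    nets = list(per_bootstrap_networks)
    names = nets[0].names
    a, b = edge
    if a not in names or b not in names:
        raise ValueError(f"unknown node name in edge {edge!r}")
    i, j = names.index(a), names.index(b)
    return int(sum(net.values[i, j] for net in nets))
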