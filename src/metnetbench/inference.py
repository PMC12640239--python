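"""Network inference algorithms: samples-by-metabolites table -> association matrix.

Families implemented
--------------------
* correlation: Pearson, Spearman, Kendall, biweight midcorrelation (bicor),
  partial correlation from the (pseudo)inverse covariance
* information-theoretic: k-nearest-neighbour mutual information, with the
  CLR (context likelihood of relatedness) z-score post-processing and the
  MRNET maximum-relevance / minimum-redundancy pruning
* regression: per-target ensembles of regression trees (GENIE3-style
  importance scores), symmetrized by the elementwise maximum
* resampling: PCLRC — repeated subsampling where the top fraction of
  CLR-processed associations is recorded; the output is each pair's
  selection frequency

Every algorithm returns a symmetric :class:`AssociationMatrix` with a zeroed
diagonal.  Correlation-family outputs are signed in [-1, 1]; MI, CLR, MRNET,
tree importances and PCLRC frequencies are nonnegative.  Consumers that
threshold or rank signed matrices take absolute values first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

SIGNED = "signed_correlation"
NONNEGATIVE = "nonnegative"


class SampleSizeError(ValueError):
    """Too few samples for the requested estimator."""


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric pairwise association scores over named metabolites."""

    names: tuple[str, ...]
    values: np.ndarray
    family: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if v.shape != (n, n):
            raise ValueError(f"association shape {v.shape} does not match {n} names")
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValueError("association matrix is not symmetric")
        if self.family not in (SIGNED, NONNEGATIVE):
            raise ValueError(f"unknown family {self.family!r}")
        v = 0.5 * (v + v.T)  # remove float asymmetry exactly
        np.fill_diagonal(v, 0.0)
        if self.family == NONNEGATIVE and (v < 0).any():
            raise ValueError("nonnegative-family matrix has negative entries")
        object.__setattr__(self, "values", v)

    def magnitudes(self) -> np.ndarray:
        """Absolute-valued entries — the scale used for ranking/thresholding."""
        return np.abs(self.values)


@dataclass(frozen=True)
class MIEstimatorConfig:
    """k-nearest-neighbour mutual information estimator settings."""

    k_neighbors: int = 3

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass(frozen=True)
class PCLRCConfig:
    """PCLRC resampling settings (without-replacement subsampling)."""

    subsample_fraction: float = 0.75
    top_fraction: float = 0.30
    iterations: int = 1000
    base_method: str = "pearson"
    seed: int = 0
    top_per_node: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must lie in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


# ---------------------------------------------------------------------------
# correlation family
# ---------------------------------------------------------------------------


def _bicor_matrix(x: np.ndarray) -> np.ndarray:
    """Biweight midcorrelation of the columns of x.

    Weights w = (1-u^2)^2 for |u| < 1 with u = (x - median) / (9 * MAD);
    columns with zero MAD get zero association (flagged by the caller).
    """
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    ok = mad > 0
    u = np.zeros_like(x)
    u[:, ok] = (x[:, ok] - med[ok]) / (9.0 * mad[ok])
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1)
    xt = (x - med) * w
    xt[:, ~ok] = 0.0
    norms = np.sqrt(np.sum(xt**2, axis=0))
    norms[norms == 0] = 1.0
    xn = xt / norms
    return xn.T @ xn


def correlation_association(samples, method: str = "pearson") -> AssociationMatrix:
    """Pairwise correlation matrix: pearson, spearman, kendall or bicor."""
    x = np.asarray(samples.values, dtype=float)
    m, n = x.shape
    if m < 3:
        raise SampleSizeError(f"correlation needs >= 3 samples, got {m}")
    constant = np.ptp(x, axis=0) == 0
    if constant.any() and method in ("pearson", "bicor"):
        logger.warning("constant columns %s -> association 0", [samples.names[i] for i in np.flatnonzero(constant)])
    if method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(x, rowvar=False)
    elif method == "spearman":
        res = stats.spearmanr(x)
        c = np.atleast_2d(res.statistic)
        if c.shape != (n, n):  # scipy returns a scalar for two columns
            c = np.array([[1.0, float(res.statistic)], [float(res.statistic), 1.0]])
    elif method == "kendall":
        c = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                tau = stats.kendalltau(x[:, i], x[:, j]).statistic
                c[i, j] = c[j, i] = tau
    elif method == "bicor":
        c = _bicor_matrix(x)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    c = np.nan_to_num(c, nan=0.0)
    return AssociationMatrix(samples.names, np.clip(c, -1.0, 1.0), SIGNED)


def partial_correlation(samples, shrinkage: bool = False) -> AssociationMatrix:
    """Partial correlation from the (pseudo)inverse of the sample covariance.

    pcor(i, j) = -P_ij / sqrt(P_ii * P_jj) where P is the precision matrix.
    With n <= p the covariance is singular; the Moore-Penrose pseudoinverse is
    used, or a Ledoit-Wolf shrinkage estimate when ``shrinkage`` is set.
    """
    x = np.asarray(samples.values, dtype=float)
    if x.shape[0] < 3:
        raise SampleSizeError(f"partial correlation needs >= 3 samples, got {x.shape[0]}")
    if shrinkage:
        from sklearn.covariance import LedoitWolf

        cov = LedoitWolf().fit(x).covariance_
        prec = np.linalg.pinv(cov, hermitian=True)
    else:
        cov = np.cov(x, rowvar=False)
        prec = np.linalg.pinv(cov, hermitian=True)
    d = np.sqrt(np.abs(np.diag(prec)))
    d[d == 0] = 1.0
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = 0.5 * (pcor + pcor.T)
    return AssociationMatrix(samples.names, np.clip(pcor, -1.0, 1.0), SIGNED)


# ---------------------------------------------------------------------------
# information-theoretic family
# ---------------------------------------------------------------------------


def mutual_information(samples, config: MIEstimatorConfig = MIEstimatorConfig(), seed: int = 0) -> AssociationMatrix:
    """Pairwise mutual information (nats) via the kNN entropy estimator.

    Each unordered pair gets one estimate (mirrored), computed with the
    Kraskov-style continuous kNN estimator; a tiny seeded jitter breaks exact
    ties before the neighbour search.  Negative estimates are clipped to 0.
    """
    from sklearn.feature_selection import mutual_info_regression

    x = np.asarray(samples.values, dtype=float)
    m, n = x.shape
    if m <= config.k_neighbors:
        raise SampleSizeError(f"MI with k={config.k_neighbors} needs more than {config.k_neighbors} samples, got {m}")
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        logger.warning("constant columns %s -> MI 0", [samples.names[i] for i in np.flatnonzero(constant)])
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if constant[i] or constant[j]:
                continue
            est = mutual_info_regression(
                x[:, [i]], x[:, j],
                n_neighbors=config.k_neighbors,
                random_state=seed,
            )[0]
            mi[i, j] = mi[j, i] = max(0.0, float(est))
    return AssociationMatrix(samples.names, mi, NONNEGATIVE)


def clr_transform(assoc: AssociationMatrix) -> AssociationMatrix:
    """Context likelihood of relatedness: symmetric z-score post-processing.

    Each entry is re-expressed against its row backgrounds:
    z_i(j) = (a_ij - mean_i) / sd_i over row i with the diagonal excluded,
    and the output is sqrt(max(0, z_i)^2 + max(0, z_j)^2).  Signed inputs are
    absolute-valued first.  Rows with zero variance get z = 0.
    """
    a = assoc.magnitudes()
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    mean = np.array([a[i, off[i]].mean() for i in range(n)])
    sd = np.array([a[i, off[i]].std() for i in range(n)])
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("zero row variance for %s -> z=0", [assoc.names[i] for i in np.flatnonzero(zero_var)])
    sd_safe = np.where(zero_var, 1.0, sd)
    z = (a - mean[:, None]) / sd_safe[:, None]
    z[zero_var, :] = 0.0
    zp = np.maximum(z, 0.0)
    out = np.sqrt(zp**2 + zp.T**2)
    np.fill_diagonal(out, 0.0)
    return AssociationMatrix(assoc.names, out, NONNEGATIVE)


def mrnet(assoc: AssociationMatrix) -> AssociationMatrix:
    """MRNET: greedy maximum-relevance / minimum-redundancy edge scoring.

    For each target t, features are selected greedily by the MRMR difference
    criterion  score(f) = assoc(f, t) - mean_{s in S} assoc(f, s)  over the
    already-selected set S (redundancy 0 for the first pick).  The pairwise
    score of (f, t) is the MRMR score at the moment f is selected, floored at
    0; the output is the elementwise maximum of the two directions.
    """
    a = assoc.magnitudes()
    if assoc.family == SIGNED:
        logger.info("mrnet: using absolute values of a signed matrix")
    n = a.shape[0]
    directed = np.zeros((n, n))  # directed[f, t]
    for t in range(n):
        candidates = [f for f in range(n) if f != t]
        selected: list[int] = []
        while candidates:
            scores = []
            for f in candidates:
                redundancy = float(np.mean(a[f, selected])) if selected else 0.0
                scores.append(a[f, t] - redundancy)
            best = int(np.argmax(scores))  # ties -> lowest index (argmax is first max)
            f = candidates.pop(best)
            directed[f, t] = max(0.0, scores[best])
            selected.append(f)
    out = np.maximum(directed, directed.T)
    np.fill_diagonal(out, 0.0)
    return AssociationMatrix(assoc.names, out, NONNEGATIVE)


# ---------------------------------------------------------------------------
# regression family
# ---------------------------------------------------------------------------


def tree_importance(samples, n_trees: int = 100, seed: int = 0) -> AssociationMatrix:
    """Per-target regression-tree-ensemble importances, symmetrized by max.

    Each metabolite in turn is masked and predicted from the others with a
    seeded random forest (sqrt predictor subsampling, no depth cap); the
    impurity-reduction importances, normalized per target, give the directed
    scores A[predictor, target].
    """
    from sklearn.ensemble import RandomForestRegressor

    x = np.asarray(samples.values, dtype=float)
    m, n = x.shape
    if m < 5:
        raise SampleSizeError(f"tree_importance needs >= 5 samples, got {m}")
    rng = np.random.default_rng(seed)
    directed = np.zeros((n, n))
    for t in range(n):
        predictors = [f for f in range(n) if f != t]
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        forest.fit(x[:, predictors], x[:, t])
        directed[predictors, t] = forest.feature_importances_
    out = np.maximum(directed, directed.T)
    np.fill_diagonal(out, 0.0)
    return AssociationMatrix(samples.names, out, NONNEGATIVE)


# ---------------------------------------------------------------------------
# resampling family
# ---------------------------------------------------------------------------


def _top_pair_mask(values: np.ndarray, top_fraction: float, per_node: bool) -> np.ndarray:
    """Boolean n x n mask of the top-fraction off-diagonal pairs (symmetric)."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = np.zeros((n, n), dtype=bool)
    if per_node:
        k = max(1, int(round(top_fraction * (n - 1))))
        for i in range(n):
            row = values[i].copy()
            row[i] = -np.inf
            top = np.argsort(-row, kind="stable")[:k]
            mask[i, top] = True
        mask |= mask.T
    else:
        flat = values[iu, ju]
        k = int(round(top_fraction * flat.size))
        if k > 0:
            order = np.argsort(-flat, kind="stable")[:k]
            mask[iu[order], ju[order]] = True
            mask |= mask.T
    return mask


def pclrc(samples, config: PCLRCConfig) -> AssociationMatrix:
    """PCLRC: selection frequency of top CLR-processed associations.

    Per iteration: draw ceil(fraction * m) samples without replacement,
    compute the base association, apply the CLR transform and mark the top
    ``top_fraction`` of off-diagonal pairs.  The output entry for a pair is
    the fraction of iterations in which it was marked, in [0, 1].
    """
    m = samples.n_samples
    sub_m = int(np.ceil(config.subsample_fraction * m))
    if sub_m < 3:
        raise SampleSizeError(f"PCLRC subsample of {sub_m} samples is too small (need >= 3)")
    rng = np.random.default_rng(config.seed)
    n = len(samples.names)
    counts = np.zeros((n, n))
    for it in range(config.iterations):
        idx = rng.choice(m, size=sub_m, replace=False)
        base = infer(samples.subset(idx), config.base_method, seed=int(rng.integers(0, 2**31 - 1)))
        processed = clr_transform(base)
        counts += _top_pair_mask(processed.values, config.top_fraction, config.top_per_node)
    freq = counts / config.iterations
    np.fill_diagonal(freq, 0.0)
    return AssociationMatrix(samples.names, freq, NONNEGATIVE)


# ---------------------------------------------------------------------------
# method registry
# ---------------------------------------------------------------------------

#: canonical method identifiers accepted by :func:`infer`
METHODS = (
    "pearson", "spearman", "kendall", "bicor", "pcor", "mi",
    "clr_pearson", "clr_spearman", "clr_mi", "mrnet", "genie3",
    "pclrc", "pclrc_mi",
)


def min_samples(method: str, k_neighbors: int = 3, subsample_fraction: float = 0.75) -> int:
    """Smallest sample count at which a method's preconditions hold.

    Resampling methods need their *subsample* to satisfy the base method's
    precondition, which is why PCLRC over mutual information drops out at the
    smallest benchmark sizes.
    """
    base = {"mi": k_neighbors + 1, "clr_mi": k_neighbors + 1, "genie3": 5, "mrnet": k_neighbors + 1}.get(method, 3)
    if method.startswith("pclrc"):
        inner = k_neighbors + 1 if method == "pclrc_mi" else 3
        return int(np.ceil(inner / subsample_fraction))
    return base


def infer(samples, method: str, seed: int = 0, **kwargs) -> AssociationMatrix:
    """Dispatch a network inference algorithm by identifier."""
    if method in ("pearson", "spearman", "kendall", "bicor"):
        return correlation_association(samples, method)
    if method == "pcor":
        return partial_correlation(samples, **kwargs)
    if method == "mi":
        return mutual_information(samples, kwargs.get("config", MIEstimatorConfig()), seed=seed)
    if method == "clr_pearson":
        return clr_transform(correlation_association(samples, "pearson"))
    if method == "clr_spearman":
        return clr_transform(correlation_association(samples, "spearman"))
    if method == "clr_mi":
        return clr_transform(mutual_information(samples, kwargs.get("config", MIEstimatorConfig()), seed=seed))
    if method == "mrnet":
        return mrnet(mutual_information(samples, kwargs.get("config", MIEstimatorConfig()), seed=seed))
    if method == "genie3":
        return tree_importance(samples, n_trees=kwargs.get("n_trees", 100), seed=seed)
    if method == "pclrc":
        cfg = kwargs.get("config") or PCLRCConfig(seed=seed, iterations=kwargs.get("iterations", 1000))
        return pclrc(samples, cfg)
    if method == "pclrc_mi":
        cfg = kwargs.get("config") or PCLRCConfig(
            seed=seed, base_method="mi", iterations=kwargs.get("iterations", 1000)
        )
        return pclrc(samples, cfg)
    raise ValueError(f"unknown inference method {method!r}; known: {METHODS}")
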