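"""Alpha/beta diversity, coverage curves, and abundance-recovery statistics.

Alpha diversity is computed on bootstrap rarefactions of a count column
(default depth grid 250..2750 step 250, 100 bootstraps) with the QIIME 1
conventions: bias-corrected Chao1, Shannon in bits (base 2, configurable),
Simpson as 1 - D, and Good's coverage 1 - F1/N. Beta diversity is
Bray-Curtis with classical-scaling PCoA and average-linkage clustering.
Recovery statistics mirror a spike-in calibration: per-member Pearson r^2
of read counts against true copy numbers across spike levels, pooled
Spearman rho, and the marker:reference-gene enrichment convention of a
ratio of log10 copy numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sstats
from skbio.stats.ordination import pcoa as _skbio_pcoa
from skbio.stats.distance import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RarefactionParams", "AlphaResult", "BetaResult", "RecoveryStats",
    "chao1", "shannon", "simpson_1md", "goods_coverage",
    "alpha_diversity", "coverage_curve", "bray_curtis", "pcoa", "hcluster",
    "dendrogram_to_newick", "filter_clusters", "recovery_stats",
    "ratio_of_logs",
]


# ------------------------------------------------------------ closed forms

def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1: S + F1(F1-1) / (2(F2+1))."""
    c = np.asarray(counts)
    c = c[c > 0]
    s = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s + f1 * (f1 - 1) / (2 * (f2 + 1))


def shannon(counts: np.ndarray, base: float = 2.0) -> float:
    """Shannon H' = -sum p log p (base 2 by default)."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    p = c / c.sum()
    return float(-(p * np.log(p) / np.log(base)).sum())


def simpson_1md(counts: np.ndarray) -> float:
    """Simpson evenness as 1 - D = 1 - sum p^2."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    p = c / c.sum()
    return float(1.0 - (p**2).sum())


def goods_coverage(counts: np.ndarray) -> float:
    """Good's coverage 1 - F1/N (F1 singletons, N reads)."""
    c = np.asarray(counts)
    n = c.sum()
    if n == 0:
        return 0.0
    f1 = int((c == 1).sum())
    return float(1.0 - f1 / n)


_METRICS = {
    "chao1": chao1,
    "shannon": shannon,
    "simpson_1mD": simpson_1md,
    "goods_coverage": goods_coverage,
}


# ------------------------------------------------------------- rarefaction

@dataclass(frozen=True)
class RarefactionParams:
    depths: tuple[int, ...] = tuple(range(250, 2751, 250))
    reps: int = 100
    seed: int = 0
    shannon_base: float = 2.0

    def __post_init__(self) -> None:
        d = list(self.depths)
        if not d or any(x <= 0 for x in d) or d != sorted(d):
            raise ValueError("depths must be positive and increasing")


@dataclass
class AlphaResult:
    """Bootstrap means and sds of alpha metrics per rarefaction depth."""

    table: pd.DataFrame  # index depth; columns metric / metric_sd

    def mean(self, metric: str, depth: int) -> float:
        return float(self.table.loc[depth, metric])


def _rarefy(rng: np.random.Generator, counts: np.ndarray, depth: int) -> np.ndarray:
    return rng.multivariate_hypergeometric(counts, depth)


def alpha_diversity(column: pd.Series, params: RarefactionParams | None = None) -> AlphaResult:
    """Alpha metrics averaged over bootstrap subsamples at each depth.

    Depths exceeding the column total are skipped with a warning.
    """
    params = params or RarefactionParams()
    rng = np.random.default_rng(params.seed)
    counts = column.to_numpy().astype(np.int64)
    total = int(counts.sum())
    rows = []
    for depth in params.depths:
        if depth > total:
            logger.warning("depth %d exceeds column total %d: skipped", depth, total)
            continue
        vals = {m: np.empty(params.reps) for m in _METRICS}
        for r in range(params.reps):
            sub = _rarefy(rng, counts, depth)
            for m, fn in _METRICS.items():
                if m == "shannon":
                    vals[m][r] = fn(sub, base=params.shannon_base)
                else:
                    vals[m][r] = fn(sub)
        row = {"depth": depth}
        for m in _METRICS:
            row[m] = vals[m].mean()
            row[f"{m}_sd"] = vals[m].std(ddof=1) if params.reps > 1 else 0.0
        rows.append(row)
    if not rows:
        raise ValueError("no requested depth is attainable for this column")
    return AlphaResult(pd.DataFrame(rows).set_index("depth"))


def coverage_curve(
    columns: dict[str, pd.Series],
    marker_fraction: dict[str, float],
    params: RarefactionParams | None = None,
) -> pd.DataFrame:
    """Good's coverage vs *total* sequencing effort per method.

    Mapped-read depths are rescaled by each method's on-target read
    fraction: effort = depth / marker_fraction, so methods are compared at
    the cost of total sequencing rather than mapped reads.
    """
    params = params or RarefactionParams()
    rows = []
    for method, column in columns.items():
        mf = marker_fraction[method]
        if not (0 < mf <= 1):
            raise ValueError(f"{method}: marker fraction {mf} must be in (0, 1]")
        alpha = alpha_diversity(column, params)
        for depth, r in alpha.table.iterrows():
            rows.append(
                {
                    "method": method,
                    "depth": int(depth),
                    "effort": depth / mf,
                    "goods_coverage": r["goods_coverage"],
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- beta

def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distance between samples (columns of a count table)."""
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = table.to_numpy(dtype=float).T
    if (X.sum(axis=1) <= 0).any():
        raise ValueError("zero-sum sample column")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=table.columns, columns=table.columns)


@dataclass
class BetaResult:
    distances: pd.DataFrame
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    negative_eigenvalue_magnitude: float
    linkage: np.ndarray = field(default=None)  # scipy linkage matrix


def pcoa(distances: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Classical-scaling principal coordinates of a distance matrix.

    Returns (coordinates, eigenvalues, |most negative eigenvalue|);
    negative eigenvalues are zeroed (no Cailliez correction), their
    magnitude reported.
    """
    D = distances.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    dm = DistanceMatrix(D, ids=[str(i) for i in distances.index])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(dm, method="eigh")
    eig = np.maximum(res.eigvals.to_numpy(), 0.0)
    # the ordination engine clamps negative eigenvalues; recover their
    # magnitude from the double-centered Gram spectrum for reporting
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    gram_eig = np.linalg.eigvalsh(-0.5 * J @ (D**2) @ J)
    neg_mag = float(max(0.0, -gram_eig.min()))
    coords = pd.DataFrame(
        res.samples.to_numpy(), index=distances.index,
        columns=[f"PC{i+1}" for i in range(res.samples.shape[1])],
    )
    return coords, eig, neg_mag


def hcluster(distances: pd.DataFrame) -> np.ndarray:
    """Deterministic average-linkage clustering of a distance matrix."""
    cond = squareform(distances.to_numpy(dtype=float), checks=False)
    if cond.size == 0:  # single sample
        return np.empty((0, 4))
    return hierarchy.average(cond)


def dendrogram_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    if linkage.size == 0:
        return f"{labels[0]};"
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    body = f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)})"
    return body + ";"


def beta_diversity(table: pd.DataFrame) -> BetaResult:
    D = bray_curtis(table)
    coords, eig, neg = pcoa(D)
    return BetaResult(
        distances=D, coordinates=coords, eigenvalues=eig,
        negative_eigenvalue_magnitude=neg, linkage=hcluster(D),
    )


def filter_clusters(table: pd.DataFrame, min_fraction: float = 0.005) -> pd.DataFrame:
    """Keep clusters reaching ``min_fraction`` of reads in any one sample."""
    frac = table / table.sum(axis=0)
    keep = (frac >= min_fraction).any(axis=1)
    return table.loc[keep]


# --------------------------------------------------------------- recovery

def ratio_of_logs(marker_log10_copies: float, reference_log10_copies: float) -> float:
    """Marker:reference-gene enrichment as a ratio of log10 copy numbers."""
    if reference_log10_copies == 0:
        return 0.0 if marker_log10_copies == 0 else np.inf
    return marker_log10_copies / reference_log10_copies


@dataclass
class RecoveryStats:
    per_member_r2: pd.Series          # Pearson r^2, counts vs true copies
    pooled_spearman: float
    enrichment_ratios: pd.DataFrame | None = None


def recovery_stats(
    truth: pd.DataFrame,
    counts: pd.DataFrame,
    reference_log10: pd.DataFrame | None = None,
    marker_log10: pd.DataFrame | None = None,
) -> RecoveryStats:
    """Quantitative recovery of spike levels from mapped read counts.

    ``truth`` and ``counts`` are member x sample tables (same shape; sample
    columns are spike levels). Per member: Pearson r^2 across levels
    (undefined under zero variance -> NaN). Pooled: Spearman rho over all
    member x level pairs. Optional log10 copy tables yield the
    ratio-of-logs enrichment table.
    """
    common = [c for c in truth.columns if c in counts.columns]
    if len(common) < 3:
        raise ValueError("need >= 3 paired observations per member")
    t = truth[common]
    c = counts.loc[truth.index, common]
    r2 = {}
    for member in t.index:
        x = t.loc[member].to_numpy(dtype=float)
        y = c.loc[member].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r2[member] = np.nan
        else:
            r, _ = sstats.pearsonr(x, y)
            r2[member] = r * r
    rho, _ = sstats.spearmanr(t.to_numpy().ravel(), c.to_numpy().ravel())
    enrich = None
    if reference_log10 is not None and marker_log10 is not None:
        enrich = marker_log10 / reference_log10.to_numpy()
    return RecoveryStats(
        per_member_r2=pd.Series(r2, name="pearson_r2"),
        pooled_spearman=float(rho),
        enrichment_ratios=enrich,
    )
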