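"""Empirical-Bayes moderated t-statistics, FDR, enrichment and co-expression.

The two-group comparison fits, per gene, an ordinary linear model (group
means and pooled residual variance s^2 with d = nA + nB - 2 residual degrees
of freedom) and shrinks the per-gene variances toward a common prior. The
prior (d0, s0^2) is estimated from the distribution of log s^2 across genes
by method of moments: for z = log(s^2),

    E[z] = log(s0^2) + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)
    Var[z] = trigamma(d/2) + trigamma(d0/2)

so d0 follows by inverting the trigamma function (Newton iteration) on the
excess variance of z, and s0^2 from the mean. The posterior variance is the
weighted average s~^2 = (d0 s0^2 + d s^2) / (d0 + d) and the moderated
t-statistic t = log2fc / (s~ sqrt(1/nA + 1/nB)) is referred to a t
distribution with d + d0 degrees of freedom (standard normal when d0 is
infinite). Multiple testing is corrected by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .filtering import Design
from .quantify import AbundanceMatrix, LOG2

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


@dataclass
class ModeratedTestModel:
    """Fitted variance-shrinkage hyperparameters and per-gene variances."""

    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance
    d_resid: float  # residual df per gene
    s_sq: np.ndarray  # per-gene residual variances
    s_tilde_sq: np.ndarray  # posterior (shrunken) variances
    df_total: float  # d_resid + d0

    def __post_init__(self) -> None:
        if self.d_resid < 1:
            raise ValueError("residual degrees of freedom must be >= 1")
        if self.s0_sq < 0:
            raise ValueError("prior variance must be >= 0")


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma is positive; cannot invert a non-positive value")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def _fit_variance_prior(s_sq: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-gene variances."""
    positive = s_sq[s_sq > 0]
    if positive.size < 2:
        raise ValueError("need >= 2 genes with positive residual variance to fit the prior")
    z = np.log(positive)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    n = e.size
    excess = float(((e - e_mean) ** 2).sum() / (n - 1)) - float(polygamma(1, d / 2.0))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def fit_moderated_t(
    matrix: AbundanceMatrix,
    design: Design,
    *,
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, ModeratedTestModel]:
    """Moderated two-group t-test per gene on a log2 protein matrix.

    The contrast is taken from ``design.contrast`` (group A minus group B).
    ``prior_df`` overrides the estimated d0 (0 recovers the classical pooled
    t-test; ``inf`` a z-statistic against the prior variance).
    """
    if matrix.scale != LOG2:
        raise ValueError("moderated t operates on a log2-scale matrix")
    if design.contrast is None:
        raise ValueError("design has no contrast defined")
    group_a, group_b = design.contrast
    samples_a = design.samples_of_group(group_a)
    samples_b = design.samples_of_group(group_b)
    n_a, n_b = len(samples_a), len(samples_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each contrast group needs >= 2 samples")
    d = n_a + n_b - 2
    if d < 1:
        raise ValueError("zero residual degrees of freedom")

    xa = matrix.data[samples_a].to_numpy()
    xb = matrix.data[samples_b].to_numpy()
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    rss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s_sq = rss / d

    if prior_df is None:
        d0, s0_sq = _fit_variance_prior(s_sq, d)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_variance_prior(s_sq, d)

    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df_total = d + d0

    log2fc = mean_a - mean_b
    se = np.sqrt(s_tilde_sq * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)))
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df=df_total)
    p = np.where((log2fc == 0) & (se == 0), 1.0, p)

    ratio = np.exp2(log2fc)
    fold_change = np.maximum(ratio, 1.0 / np.maximum(ratio, np.finfo(float).tiny))
    direction = np.where(log2fc > 0, f"higher_in_{group_a}", f"higher_in_{group_b}")
    direction = np.where(log2fc == 0, "unchanged", direction)

    result = pd.DataFrame(
        {
            "gene": matrix.data.index,
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
            "log2fc": log2fc,
            "fold_change": fold_change,
            "direction": direction,
            "t": t,
            "p_value": p,
        }
    ).set_index("gene", drop=False)
    result.index.name = None
    result["adj_p_value"] = bh_adjust(result["p_value"].to_numpy())

    model = ModeratedTestModel(
        d0=d0, s0_sq=s0_sq, d_resid=float(d), s_sq=s_sq, s_tilde_sq=s_tilde_sq, df_total=df_total
    )
    logger.info(
        "moderated t: %d genes, d=%d, d0=%.4g, s0^2=%.4g", len(result), d, d0, s0_sq
    )
    return result, model


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    result: pd.DataFrame, alpha: float = 0.005
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Partition genes at the FDR threshold (boundary value is significant).

    Returns the table with ``significant`` filled in plus the counts of the
    three classes (higher in A, higher in B, unchanged).
    """
    out = result.copy()
    out["significant"] = out["adj_p_value"] <= alpha
    directions = [c for c in out["direction"].unique() if c != "unchanged"]
    counts = {"unchanged": int((~out["significant"]).sum())}
    for direction in sorted(directions):
        counts[direction] = int((out["significant"] & (out["direction"] == direction)).sum())
    return out, counts


# ---------------------------------------------------------------------------
# gene-set enrichment (2x2 chi-square)
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """Chi-square test of DE status against gene-set membership."""

    table: np.ndarray  # [[set&DE, set&nonDE], [nonset&DE, nonset&nonDE]]
    statistic: float
    p_value: float
    odds_ratio: float
    df: int = 1
    yates: bool = False

    def to_dict(self) -> dict:
        return {
            "table": self.table.tolist(),
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "continuity_correction": self.yates,
        }


def enrichment_from_counts(
    set_de: int, set_total: int, universe_de: int, universe_total: int, *, yates: bool = False
) -> EnrichmentResult:
    """Chi-square enrichment from marginal counts (set within a universe)."""
    a = set_de
    b = set_total - set_de
    c = universe_de - set_de
    d = (universe_total - set_total) - c
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError(f"inconsistent marginal counts yield negative cells: {table.tolist()}")
    if set_total == 0 or universe_total == 0:
        raise ValueError("empty gene set or universe")
    stat, p, df, _ = sps.chi2_contingency(table, correction=yates)
    if (table == 0).any():
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        table=table, statistic=float(stat), p_value=float(p), odds_ratio=float(odds),
        df=int(df), yates=yates,
    )


def enrichment_chisq(
    de_flags: pd.Series, gene_set: set[str], *, yates: bool = False
) -> EnrichmentResult:
    """Are genes of ``gene_set`` over-represented among DE genes?

    ``de_flags`` is a boolean Series indexed by gene symbol over the full
    analysis universe. Defaults to Pearson's chi-square without continuity
    correction; set ``yates=True`` for the corrected variant.
    """
    if len(de_flags) == 0:
        raise ValueError("empty gene universe")
    members = de_flags.index.isin(gene_set)
    if not members.any():
        raise ValueError("gene set does not overlap the analysis universe")
    flags = de_flags.astype(bool).to_numpy()
    return enrichment_from_counts(
        set_de=int((members & flags).sum()),
        set_total=int(members.sum()),
        universe_de=int(flags.sum()),
        universe_total=len(flags),
        yates=yates,
    )


# ---------------------------------------------------------------------------
# co-expression
# ---------------------------------------------------------------------------


def correlation_matrix(matrix: AbundanceMatrix, genes: list[str] | None = None) -> pd.DataFrame:
    """Gene x gene Pearson correlation of log2 abundances across samples."""
    log_mat = matrix.to_log2()
    data = log_mat.data
    if genes is not None:
        missing = [g for g in genes if g not in data.index]
        if missing:
            raise ValueError(f"genes not in matrix: {missing[:5]}")
        data = data.loc[genes]
    if data.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlations")
    r = np.corrcoef(data.to_numpy())
    out = pd.DataFrame(r, index=data.index, columns=data.index)
    np.fill_diagonal(out.values, 1.0)
    return out


@dataclass
class ClusterResult:
    """Average-linkage sample dendrogram on correlation distance."""

    linkage: np.ndarray
    labels: list[str]
    newick: str = field(default="", repr=False)

    def cut(self, k: int) -> dict[str, int]:
        """Cluster label per sample when cutting the tree into k clusters."""
        assignments = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))


def _linkage_to_newick(node: hierarchy.ClusterNode, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_to_newick(node.left, labels)
    right = _linkage_to_newick(node.right, labels)
    dl = max(node.dist - node.left.dist, 0.0)
    dr = max(node.dist - node.right.dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def hierarchical_cluster(matrix: AbundanceMatrix) -> ClusterResult:
    """Cluster samples by 1 - Pearson correlation of log2 abundances,
    average linkage. Samples are ordered by id before clustering so the
    result is invariant to input column order."""
    log_mat = matrix.to_log2()
    if log_mat.data.shape[1] < 3:
        raise ValueError("need >= 3 samples to cluster")
    data = log_mat.data[sorted(log_mat.data.columns)]
    corr = np.corrcoef(data.to_numpy(), rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = list(data.columns)
    tree = hierarchy.to_tree(z)
    newick = _linkage_to_newick(tree, labels) + ";"
    return ClusterResult(linkage=z, labels=labels, newick=newick)
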