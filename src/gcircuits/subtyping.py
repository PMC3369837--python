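"""Expression normalization, hierarchical subtyping and differential expression.

The normalization pipeline mirrors classic two-batch bead-array processing:
per-gene geometric-mean scaling of later labeling batches onto the first,
background subtraction, capping of negatives at zero, addition of a +30
intensity constant, quantile normalization across samples, log2 transform,
and a variance filter keeping genes with SD > 0.25.

Subtyping clusters samples by Ward linkage (ward.D2 semantics) on
1 − Pearson correlation distances; the tree is cut at k clusters (HC
groups) and at k = 2 for the top-level molecular-subtype (MS) split.
Differential expression uses a gene-wise Welch t statistic with Bonferroni
control — a deliberately plain substitute for moderated-statistic packages,
with the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import logger


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationConfig:
    background: float = 0.0
    intensity_offset: float = 30.0
    sd_filter: float = 0.25
    reference_batch: object = None      # default: first batch label in order


def _geomean(x: np.ndarray) -> np.ndarray:
    """Row-wise geometric mean over the positive entries; rows without any
    positive entry give 0 (background-corrected intensities may be <= 0)."""
    pos = x > 0
    logs = np.where(pos, np.log(np.where(pos, x, 1.0)), 0.0)
    counts = pos.sum(axis=1)
    with np.errstate(invalid="ignore"):
        m = np.where(counts > 0, logs.sum(axis=1) / np.maximum(counts, 1), -np.inf)
    return np.where(counts > 0, np.exp(m), 0.0)


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization: every column's sorted values are
    replaced by the across-column mean of sorted values at each rank, so
    all columns share an identical sorted value vector afterwards."""
    x = df.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    ranks = np.empty_like(order)
    cols = np.arange(x.shape[1])
    ranks[order, cols] = np.arange(x.shape[0])[:, None]
    reference = np.sort(x, axis=0).mean(axis=1)
    return pd.DataFrame(reference[ranks], index=df.index, columns=df.columns)


def batch_scale(raw: pd.DataFrame, batches: pd.Series,
                reference: object = None) -> pd.DataFrame:
    """Scale each non-reference batch so its per-gene geometric mean matches
    the reference batch (label of the first column by default). Genes with a
    non-positive geometric mean in the reference batch are dropped."""
    batches = batches.reindex(raw.columns)
    if batches.isna().any():
        missing = list(batches.index[batches.isna()])
        raise ValueError(f"samples without batch label: {missing[:10]}")
    ref = reference if reference is not None else batches.iloc[0]
    x = raw.to_numpy(dtype=float).copy()
    ref_cols = (batches == ref).to_numpy()
    if not ref_cols.any():
        raise ValueError(f"reference batch {ref!r} has no samples")
    ref_gm = _geomean(x[:, ref_cols])
    keep = ref_gm > 0
    if not keep.all():
        logger.warning("dropping %d genes with non-positive geometric mean "
                       "in reference batch", int((~keep).sum()))
        x, ref_gm = x[keep], ref_gm[keep]
    for batch in pd.unique(batches):
        if batch == ref:
            continue
        cols = (batches == batch).to_numpy()
        gm = _geomean(x[:, cols])
        scale = np.where(gm > 0, ref_gm / np.where(gm > 0, gm, 1.0), 1.0)
        x[:, cols] *= scale[:, None]
    return pd.DataFrame(x, index=raw.index[keep], columns=raw.columns)


def normalize_expression(raw: pd.DataFrame, batches: pd.Series,
                         config: NormalizationConfig | None = None,
                         ) -> pd.DataFrame:
    """Run the full pipeline on a raw genes x samples intensity matrix.

    ``batches`` maps sample -> batch label; the first label encountered in
    column order is the reference unless ``config.reference_batch`` says
    otherwise. Genes with a non-positive geometric mean in the reference
    batch are dropped with a warning. Returns the normalized log2 matrix
    after the SD filter.
    """
    config = config or NormalizationConfig()
    df = batch_scale(raw, batches, config.reference_batch)
    x = df.to_numpy()
    x -= config.background
    x[x < 0] = 0.0
    x += config.intensity_offset
    df = quantile_normalize(pd.DataFrame(x, index=df.index, columns=df.columns))
    df = np.log2(df)
    sd = df.std(axis=1, ddof=1)
    return df.loc[sd > config.sd_filter]


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class SubtypeAssignment:
    """HC cluster (k-cut) and MS class (2-cut) per sample."""

    hc: pd.Series          # sample -> "HC1".."HCk"
    ms: pd.Series          # sample -> "MS1"/"MS2"
    linkage_matrix: np.ndarray


def _ordered_labels(expression: pd.DataFrame, flat: np.ndarray,
                    prefix: str, order_gene: str | None) -> pd.Series:
    """Relabel raw cluster ids; ordered by decreasing mean expression of
    ``order_gene`` when available, else by decreasing cluster size."""
    ids = pd.unique(flat)
    if order_gene is not None and order_gene in expression.index:
        key = {i: -expression.loc[order_gene].to_numpy()[flat == i].mean()
               for i in ids}
    else:
        key = {i: -(flat == i).sum() for i in ids}
    ranked = sorted(ids, key=lambda i: (key[i], i))
    mapping = {i: f"{prefix}{rank + 1}" for rank, i in enumerate(ranked)}
    return pd.Series([mapping[i] for i in flat], index=expression.columns)


def hca_clusters(expression: pd.DataFrame, k: int,
                 order_gene: str | None = "FGFR3") -> SubtypeAssignment:
    """Ward clustering of samples on 1 − Pearson correlation distances.

    The tree is cut at ``k`` (HC groups) and at 2 (MS classes). Cluster
    labels are ordered by decreasing mean expression of ``order_gene``
    (when present), else by size — HC1 is the most FGFR3-high cluster,
    matching the convention that FGFR3-driven tumors head the list.
    """
    n = expression.shape[1]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= {n}")
    x = expression.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = expression.columns[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"sample {bad!r} has constant expression; "
                         "correlation undefined")
    corr = np.corrcoef(x, rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    hc = _ordered_labels(expression, fcluster(z, k, criterion="maxclust"),
                         "HC", order_gene)
    ms = _ordered_labels(expression, fcluster(z, 2, criterion="maxclust"),
                         "MS", order_gene)
    return SubtypeAssignment(hc=hc, ms=ms, linkage_matrix=z)


# ---------------------------------------------------------------------------
# rank-based gene categorization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneCategory:
    gene: str
    categories: pd.Series           # sample -> "low"/"intermediate"/"high"
    thresholds: tuple[float, ...]   # value-scale thresholds actually applied


def categorize_gene_expression(expression: pd.DataFrame, gene: str,
                               thresholds: tuple[float, ...],
                               as_quantiles: bool = True) -> GeneCategory:
    """Partition samples by ordered thresholds on one gene's expression.

    With ``as_quantiles`` the thresholds are sample-rank quantiles in
    (0, 1); otherwise they are expression values. One threshold gives
    low/high, two give low/intermediate/high. A sample exactly at a
    boundary goes to the lower category.
    """
    if gene not in expression.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be non-decreasing")
    if len(thresholds) not in (1, 2):
        raise ValueError("need 1 (low/high) or 2 (low/intermediate/high) "
                         "thresholds")
    v = expression.loc[gene]
    cuts = (tuple(float(np.quantile(v.to_numpy(), q)) for q in thresholds)
            if as_quantiles else tuple(float(t) for t in thresholds))
    if len(cuts) == 1:
        labels = np.where(v <= cuts[0], "low", "high")
    else:
        labels = np.where(v <= cuts[0], "low",
                          np.where(v <= cuts[1], "intermediate", "high"))
    return GeneCategory(gene=gene,
                        categories=pd.Series(labels, index=v.index),
                        thresholds=cuts)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(expression: pd.DataFrame, group_a, group_b,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Gene-wise Welch t-test between two sample groups, Bonferroni-adjusted.

    Returns a DataFrame with columns ``t, p, p_bonf, direction,
    significant, zero_variance``; genes with zero variance in both groups
    get p = 1 and are flagged. ``direction`` is "up" when group_a's mean is
    higher.
    """
    a = expression[list(group_a)].to_numpy(dtype=float)
    b = expression[list(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError("need >= 3 samples per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    t[zero_var] = 0.0
    p[zero_var] = 1.0
    p = np.nan_to_num(p, nan=1.0)
    m = expression.shape[0]
    p_bonf = np.minimum(1.0, m * p)
    return pd.DataFrame({
        "t": t, "p": p, "p_bonf": p_bonf,
        "direction": np.where(a.mean(axis=1) >= b.mean(axis=1), "up", "down"),
        "significant": p_bonf < alpha,
        "zero_variance": zero_var,
    }, index=expression.index)
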