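"""Pairwise alteration association tests, MDS embedding and network assembly.

Co-occurrence and mutual exclusivity between binary alteration features are
scored with one-sided hypergeometric tail probabilities: for features with
margins K_a, K_b over N samples and observed overlap x,
``p_positive = P(X >= x)`` and ``p_negative = P(X <= x)`` for
X ~ Hypergeometric(N, K_a, K_b). Tails are accumulated in log space from
exact log-pmf terms. Bonferroni controls the family of all tested tails.
Feature geometry is visualized by classical (Torgerson) multidimensional
scaling on Jaccard distances between carrier sets, and the "genomic
circuits" are the connected components of the significant-edge network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .io import logger
from .recurrence import AlterationMatrix


def _log_hypergeom_pmf(k: np.ndarray, N: int, Ka: int, Kb: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N, Ka, Kb)."""
    k = np.asarray(k)
    return (gammaln(Ka + 1) - gammaln(k + 1) - gammaln(Ka - k + 1)
            + gammaln(N - Ka + 1) - gammaln(Kb - k + 1)
            - gammaln(N - Ka - Kb + k + 1)
            - (gammaln(N + 1) - gammaln(Kb + 1) - gammaln(N - Kb + 1)))


def hypergeometric_pair_test(carriers_a: frozenset, carriers_b: frozenset,
                             n_samples: int) -> tuple[float, float, int]:
    """Exact one-sided tail p-values for a feature pair.

    Returns ``(p_positive, p_negative, overlap)`` where p_positive is the
    probability of an overlap at least as large as observed under the
    hypergeometric null and p_negative of one at least as small.
    """
    Ka, Kb = len(carriers_a), len(carriers_b)
    if Ka == 0 or Kb == 0:
        raise ValueError("empty feature margin; exclude the feature first")
    if Ka > n_samples or Kb > n_samples:
        raise ValueError("margin exceeds sample universe")
    x = len(carriers_a & carriers_b)
    lo, hi = max(0, Ka + Kb - n_samples), min(Ka, Kb)
    upper = np.arange(x, hi + 1)
    lower = np.arange(lo, x + 1)
    p_pos = float(np.exp(logsumexp(_log_hypergeom_pmf(upper, n_samples, Ka, Kb))))
    p_neg = float(np.exp(logsumexp(_log_hypergeom_pmf(lower, n_samples, Ka, Kb))))
    return min(p_pos, 1.0), min(p_neg, 1.0), x


def fisher_group_association(matrix: AlterationMatrix, feature: str,
                             group_labels: pd.Series) -> pd.DataFrame:
    """Two-sided 2x2 Fisher exact test of one feature against each group.

    For every group label, samples are split in-group vs out-group and
    cross-tabulated with feature carriage. Groups of size 0 are skipped.
    Returns a DataFrame indexed by group with columns ``odds_ratio, p,
    in_group_carriers, out_group_carriers``.
    """
    j = matrix.features.index(feature)
    carrier = pd.Series(matrix.values[:, j], index=matrix.samples)
    labels = group_labels.reindex(matrix.samples)
    rows = {}
    for g in pd.unique(labels.dropna()):
        in_g = (labels == g).to_numpy()
        if in_g.sum() == 0:
            continue
        a = int((carrier.to_numpy() & in_g).sum())
        b = int((~carrier.to_numpy() & in_g).sum())
        c = int((carrier.to_numpy() & ~in_g).sum())
        d = int((~carrier.to_numpy() & ~in_g).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows[g] = {"odds_ratio": odds, "p": p,
                   "in_group_carriers": a, "out_group_carriers": c}
    return pd.DataFrame.from_dict(rows, orient="index")


def bonferroni_adjust(pvals, alpha: float = 0.05):
    """min(1, m*p) per p-value plus significance flags at ``alpha``."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.minimum(1.0, p.size * p)
    return adjusted, adjusted < alpha


@dataclass(frozen=True)
class AssociationEdge:
    feature_a: str
    feature_b: str
    overlap: int
    direction: str            # "positive" | "negative"
    p: float
    p_bonf: float
    significant: bool


def pairwise_association(matrix: AlterationMatrix, alpha: float = 0.05,
                         features: list[str] | None = None,
                         ) -> list[AssociationEdge]:
    """All-pairs hypergeometric tests with joint Bonferroni control.

    Both tails of every pair enter one Bonferroni family (m = 2 x number of
    pairs); empty features are excluded with a warning. Returns one edge
    per (pair, direction).
    """
    features = features if features is not None else list(matrix.features)
    carriers = {}
    for f in features:
        c = matrix.carriers(f)
        if not c:
            logger.warning("feature %s has no carriers; excluded", f)
        else:
            carriers[f] = c
    names = list(carriers)
    n = len(matrix.samples)
    raw: list[tuple[str, str, int, str, float]] = []
    for fa, fb in itertools.combinations(names, 2):
        p_pos, p_neg, x = hypergeometric_pair_test(carriers[fa], carriers[fb], n)
        raw.append((fa, fb, x, "positive", p_pos))
        raw.append((fa, fb, x, "negative", p_neg))
    adjusted, flags = bonferroni_adjust([r[4] for r in raw], alpha)
    return [AssociationEdge(fa, fb, x, d, p, float(pb), bool(sig))
            for (fa, fb, x, d, p), pb, sig in zip(raw, adjusted, flags)]


def edges_to_frame(edges: list[AssociationEdge]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in edges])


# ---------------------------------------------------------------------------
# Jaccard MDS
# ---------------------------------------------------------------------------

def jaccard_distance_matrix(matrix: AlterationMatrix,
                            features: list[str]) -> np.ndarray:
    cols = [matrix.features.index(f) for f in features]
    x = matrix.values[:, cols].astype(bool)
    inter = x.T.astype(int) @ x.astype(int)
    sizes = x.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return d


def classical_mds(d: np.ndarray, dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson MDS: double-center −D²/2 and eigendecompose.

    Returns (coordinates, eigenvalues); coordinates use the ``dims``
    leading non-negative eigenpairs (axes beyond the matrix rank are zero).
    """
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, dims))
    floor = max(vals[0], 0.0) * 1e-12   # suppress numerically-zero eigenpairs
    for k in range(min(dims, n)):
        if vals[k] > floor:
            coords[:, k] = vecs[:, k] * np.sqrt(vals[k])
    return coords, vals


def jaccard_mds(matrix: AlterationMatrix, dims: int = 2,
                min_freq: float = 0.05) -> pd.DataFrame:
    """Embed alteration features by classical MDS on Jaccard distances.

    FGA/HD features rarer than ``min_freq`` are excluded (as are empty
    features); points are features, matching the convention that the map
    shows aberrations, not samples.
    """
    keep = []
    for f in matrix.features:
        row = matrix.meta.loc[f]
        if row.get("kind") in ("FGA", "HD") and row["frequency"] < min_freq:
            continue
        if row["frequency"] == 0:
            logger.warning("feature %s has no carriers; excluded from MDS", f)
            continue
        keep.append(f)
    d = jaccard_distance_matrix(matrix, keep)
    coords, vals = classical_mds(d, dims)
    out = pd.DataFrame(coords, index=keep,
                       columns=[f"dim{i+1}" for i in range(dims)])
    out.attrs["eigenvalues"] = vals
    return out


def assemble_network(edges: list[AssociationEdge]) -> nx.Graph:
    """Keep nodes incident to >= 1 significant edge; components = circuits."""
    g = nx.Graph()
    for e in edges:
        if e.significant:
            g.add_edge(e.feature_a, e.feature_b,
                       direction=e.direction, p_bonf=e.p_bonf,
                       overlap=e.overlap)
    return g


def network_components(g: nx.Graph) -> list[set[str]]:
    return [set(c) for c in nx.connected_components(g)]
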