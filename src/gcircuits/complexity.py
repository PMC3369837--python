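"""Per-sample genomic-complexity metrics and group comparisons.

Two direct measures summarise how rearranged a genome is: **nFGA**, the
number of focal amplicons after merging events less than 1 Mbp apart, and
**fBAC**, the fraction of probes in any altered state. An indirect measure
is the **CIN score**: the mean gene-wise standardized expression of a
chromosome-instability signature. TP53-pathway status combines TP53
mutation with MDM2 amplification or overexpression. IHC tumor-cell protein
scores multiply staining intensity (0-3) by the fraction of positive
nuclei (10% grid), averaged over cores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import FocalEvent, NEUTRAL
from .config import CnaConfig
from .io import ProbeMap, logger


@dataclass(frozen=True)
class ComplexityProfile:
    sample_id: str
    nfga: int
    fbac: float
    cin_score: float | None = None

    def __post_init__(self) -> None:
        if self.nfga < 0 or not 0 <= self.fbac <= 1:
            raise ValueError("invalid complexity profile")


def compute_nfga(sample_events: Sequence[FocalEvent], probe_map: ProbeMap,
                 config: CnaConfig | None = None) -> int:
    """Number of merged focal amplicons for one sample."""
    from .calling import merge_amplicons
    config = config or CnaConfig()
    fgas = [e for e in sample_events if e.kind == "FGA"]
    return len(merge_amplicons(fgas, probe_map, config.merge_gap_bp))


def compute_fbac(call_row: np.ndarray) -> float:
    """Fraction of altered probes; missing probes count as unaltered."""
    return float(np.count_nonzero(call_row != NEUTRAL) / call_row.size)


def signature_score(expression: pd.DataFrame,
                    gene_list: Sequence[str]) -> pd.Series:
    """Mean gene-wise z-scored expression over a signature, per sample.

    ``expression`` is a normalized log2 genes x samples matrix. Signature
    genes absent from the matrix are logged and skipped; no gene found is
    an error.
    """
    present = [g for g in gene_list if g in expression.index]
    missing = [g for g in gene_list if g not in expression.index]
    if missing:
        logger.warning("signature genes missing from matrix: %s", missing[:10])
    if not present:
        raise ValueError("no signature gene found in expression matrix")
    sub = expression.loc[present]
    sd = sub.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0)


def classify_tp53_mdm2(mutations: pd.DataFrame,
                       events_by_sample: Mapping[str, Sequence[FocalEvent]],
                       mdm2_expression_high: Mapping[str, bool],
                       mdm2_interval: tuple[str, int, int],
                       ) -> dict[str, bool | None]:
    """TP53-pathway alteration status per sample.

    Altered iff TP53 is mutated, OR a focal amplification intersects the
    MDM2 probe interval, OR the MDM2 expression category is high. A sample
    missing any of the three inputs gets status ``None`` (unknown).
    """
    chrom, lo, hi = mdm2_interval
    tp53 = mutations[mutations["gene"] == "TP53"]
    tp53_status = dict(zip(tp53["sample_id"], tp53["status"] == "mutated"))
    out: dict[str, bool | None] = {}
    for sid in sorted(set(tp53_status) | set(events_by_sample)
                      | set(mdm2_expression_high)):
        if (sid not in tp53_status or sid not in events_by_sample
                or sid not in mdm2_expression_high):
            out[sid] = None
            continue
        mdm2_amp = any(e.kind == "FGA" and e.chrom == chrom
                       and e.start <= hi and lo <= e.end
                       for e in events_by_sample[sid])
        out[sid] = bool(tp53_status[sid] or mdm2_amp
                        or mdm2_expression_high[sid])
    return out


@dataclass(frozen=True)
class IHCMeasurement:
    """Immunohistochemistry measurement: 1-2 cores per sample."""

    sample_id: str
    marker: str
    intensities: tuple[int, ...]       # per core, each in {0,1,2,3}
    fractions: tuple[float, ...]       # per core, on the 10% grid

    def __post_init__(self) -> None:
        if not 1 <= len(self.intensities) <= 2 or \
                len(self.intensities) != len(self.fractions):
            raise ValueError("expect 1-2 cores with matching fractions")
        if any(i not in (0, 1, 2, 3) for i in self.intensities):
            raise ValueError("intensity must be in {0,1,2,3}")
        for f in self.fractions:
            if not 0 <= f <= 1 or abs(round(f * 10) - f * 10) > 1e-9:
                raise ValueError(f"fraction {f} not on the 10% grid")


def ihc_score(measurement: IHCMeasurement) -> float:
    """Tumor-cell protein score: intensity x positive fraction x 100,
    averaged over cores (scale 0-300)."""
    per_core = [i * f * 100.0 for i, f in zip(measurement.intensities,
                                              measurement.fractions)]
    return float(np.mean(per_core))


def group_stats(values: Sequence[float], groups: Sequence,
                test: str, values2: Sequence[float] | None = None,
                ) -> tuple[float, float]:
    """Two-sided group comparison or correlation: (statistic, p).

    ``test`` is one of ``wilcoxon_rank_sum`` (exact null for n <= 25 per
    group), ``one_way_anova``, ``welch_t`` or ``pearson_r`` (for which
    ``values2`` supplies the second variable).
    """
    values = np.asarray(values, dtype=float)
    if test == "pearson_r":
        if values2 is None:
            raise ValueError("pearson_r needs values2")
        r, p = stats.pearsonr(values, np.asarray(values2, dtype=float))
        return float(r), float(p)
    labels = np.asarray(groups)
    samples = [values[labels == g] for g in pd.unique(labels)]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs >= 2 observations")
    if test == "wilcoxon_rank_sum":
        if len(samples) != 2:
            raise ValueError("wilcoxon_rank_sum needs exactly 2 groups")
        method = "exact" if max(map(len, samples)) <= 25 else "asymptotic"
        res = stats.mannwhitneyu(samples[0], samples[1],
                                 alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "one_way_anova":
        res = stats.f_oneway(*samples)
        return float(res.statistic), float(res.pvalue)
    if test == "welch_t":
        if len(samples) != 2:
            raise ValueError("welch_t needs exactly 2 groups")
        res = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def complexity_table(events_by_sample, call_matrix,
                     config: CnaConfig | None = None,
                     cin_scores: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample nFGA / fBAC (and CIN score when supplied) as a DataFrame."""
    config = config or CnaConfig()
    rows = []
    for i, sid in enumerate(call_matrix.sample_ids):
        rows.append({
            "sample_id": sid,
            "nFGA": compute_nfga(events_by_sample[sid],
                                 call_matrix.probe_map, config),
            "fBAC": compute_fbac(call_matrix.states[i]),
            "cin_score": (float(cin_scores[sid])
                          if cin_scores is not None and sid in cin_scores
                          else np.nan),
        })
    return pd.DataFrame(rows).set_index("sample_id")
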