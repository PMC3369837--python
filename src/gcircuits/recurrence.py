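"""Recurrent-region discovery: peak cores, boundary extension, masking.

Per-probe support counts (how many samples are altered at each probe) are
computed per chromosome. Every maximal plateau of locally maximal support
whose height reaches the kind's minimum (FGA 3, HD 2, MRD 15) becomes a
*core* region — the minimal shared interval. To tolerate noisy breakpoints,
each core is then extended to the maximal contiguous run supported by at
least (max − 2) samples (max − 1 for HDs). Regions with heavy germline-CNV
overlap are masked out; MRDs overlapping an HD region are replaced by the
HD boundaries; MRDs spanning most of a chromosome arm are suppressed in
favour of the arm-level call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import FocalEvent, GAIN, AMP, LOSS, HD as HD_STATE
from .config import CnaConfig
from .io import ProbeMap, logger


@dataclass(frozen=True)
class RecurrentRegion:
    """A recurrent FGA / HD / MRD region on the shared probe grid.

    ``core`` is the peak plateau (every probe there has support equal to
    ``max_support``); ``extended`` is the noise-tolerant interval containing
    it. Probe indices are global and inclusive.
    """

    kind: str                 # "FGA" | "HD" | "MRD"
    chrom: str
    core_start: int
    core_end: int
    ext_start: int
    ext_end: int
    max_support: int
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not (self.ext_start <= self.core_start <= self.core_end <= self.ext_end):
            raise ValueError("core interval must lie within extended interval")

    @property
    def core(self) -> tuple[int, int]:
        return (self.core_start, self.core_end)

    @property
    def extended(self) -> tuple[int, int]:
        return (self.ext_start, self.ext_end)


@dataclass(frozen=True)
class ArmRegion:
    """A recurrent chromosome-arm gain or loss."""

    kind: str                 # "ARM_GAIN" | "ARM_LOSS"
    arm: str
    frequency: float
    members: frozenset[str]


def support_counts(altered_masks: Mapping[str, np.ndarray],
                   probe_map: ProbeMap) -> np.ndarray:
    """Number of altered samples at each probe."""
    counts = np.zeros(len(probe_map), dtype=int)
    for mask in altered_masks.values():
        counts += mask.astype(int)
    return counts


def events_to_masks(events_by_sample: Mapping[str, Sequence[FocalEvent]],
                    kind: str, n_probes: int) -> dict[str, np.ndarray]:
    """Per-sample boolean probe masks from focal events of one kind."""
    masks = {}
    for sid, events in events_by_sample.items():
        m = np.zeros(n_probes, dtype=bool)
        for e in events:
            if e.kind == kind:
                m[e.start:e.end + 1] = True
        masks[sid] = m
    return masks


def deletion_masks(states: np.ndarray, sample_ids: Sequence[str],
                   ) -> dict[str, np.ndarray]:
    """Per-sample deleted-probe masks (LOSS or HD state) feeding MRD calls."""
    return {sid: (states[i] == LOSS) | (states[i] == HD_STATE)
            for i, sid in enumerate(sample_ids)}


def _plateaus(counts: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant runs that are local maxima (chromosome-local indices).

    A plateau qualifies if its height strictly exceeds both flanking values;
    a missing flank (chromosome end) counts as lower.
    """
    n = counts.size
    if n == 0:
        return []
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left_lower = i == 0 or counts[i - 1] < counts[i]
        right_lower = j == n - 1 or counts[j + 1] < counts[i]
        if left_lower and right_lower:
            out.append((i, j))
        i = j + 1
    return out


def extend_boundaries(counts: np.ndarray, core: tuple[int, int],
                      kind: str, slack: int | None = None) -> tuple[int, int]:
    """Extend a core plateau to the maximal run with support >= max − slack.

    ``counts`` are chromosome-local; the returned interval is truncated at
    the chromosome ends by construction. Slack is 2, or 1 for HDs.
    """
    if slack is None:
        slack = 1 if kind == "HD" else 2
    lo, hi = core
    threshold = counts[lo] - slack
    while lo > 0 and counts[lo - 1] >= threshold:
        lo -= 1
    while hi < counts.size - 1 and counts[hi + 1] >= threshold:
        hi += 1
    return (lo, hi)


def detect_recurrent_regions(altered_masks: Mapping[str, np.ndarray],
                             kind: str, probe_map: ProbeMap,
                             config: CnaConfig | None = None,
                             ) -> list[RecurrentRegion]:
    """Discover recurrent regions of one kind from per-sample altered masks.

    For FGA/HD pass masks derived from focal events
    (:func:`events_to_masks`); for MRD pass deleted-probe masks
    (:func:`deletion_masks`). Every peak plateau with support >= the kind's
    minimum yields one region; regions identical in (core, extended) are
    deduplicated.
    """
    config = config or CnaConfig()
    min_support = config.min_support(kind)
    slack = config.slack(kind)
    counts = support_counts(altered_masks, probe_map)
    regions: list[RecurrentRegion] = []
    seen: set[tuple] = set()
    for chrom in probe_map.chroms:
        sl = probe_map.chrom_slice(chrom)
        local = counts[sl]
        for lo, hi in _plateaus(local):
            if local[lo] < min_support:
                continue
            elo, ehi = extend_boundaries(local, (lo, hi), kind, slack)
            g = (sl.start + lo, sl.start + hi, sl.start + elo, sl.start + ehi)
            if g in seen:
                continue
            seen.add(g)
            members = frozenset(
                sid for sid, m in altered_masks.items()
                if m[g[2]:g[3] + 1].any())
            regions.append(RecurrentRegion(
                kind=kind, chrom=chrom,
                core_start=g[0], core_end=g[1],
                ext_start=g[2], ext_end=g[3],
                max_support=int(local[lo]), members=members))
    return regions


def apply_cnv_mask(regions: Sequence[RecurrentRegion],
                   cnv_intervals: Sequence[tuple[str, int, int, str]] | None,
                   probe_map: ProbeMap,
                   cnv_overlap_max: float = 0.5) -> list[RecurrentRegion]:
    """Drop regions whose extended interval is CNV-covered beyond the cutoff.

    Coverage is measured in bp of the extended genomic interval overlapped
    by the union of CNV intervals on the same chromosome.
    """
    if cnv_intervals is None:
        logger.warning("no CNV intervals supplied; keeping all regions")
        return list(regions)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _name in cnv_intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        acc = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[chrom] = [(s, e) for s, e in acc]
    kept = []
    for r in regions:
        start, end = probe_map.genomic_span(r.ext_start, r.ext_end)
        covered = sum(max(0, min(end, e) - max(start, s))
                      for s, e in merged.get(r.chrom, []))
        if covered / (end - start) > cnv_overlap_max:
            logger.info("CNV mask removes %s region %s:%d-%d (%.0f%% covered)",
                        r.kind, r.chrom, start, end, 100 * covered / (end - start))
        else:
            kept.append(r)
    return kept


def resolve_mrd_hd_overlap(mrds: Sequence[RecurrentRegion],
                           hds: Sequence[RecurrentRegion],
                           ) -> list[RecurrentRegion]:
    """Replace MRDs that intersect an HD extended interval by the HD region(s).

    An MRD overlapping several HDs is replaced by all of them; duplicates are
    collapsed. Non-overlapping MRDs pass through unchanged.
    """
    out: list[RecurrentRegion] = []
    used_hds: set[tuple] = set()
    for mrd in mrds:
        overlapping = [hd for hd in hds
                       if hd.chrom == mrd.chrom
                       and hd.ext_start <= mrd.ext_end
                       and mrd.ext_start <= hd.ext_end]
        if not overlapping:
            out.append(mrd)
            continue
        for hd in overlapping:
            key = (hd.chrom, hd.core, hd.extended)
            if key not in used_hds:
                used_hds.add(key)
                out.append(hd)
    return out


def suppress_arm_scale_mrds(mrds: Sequence[RecurrentRegion],
                            probe_map: ProbeMap,
                            max_arm_fraction: float = 0.5,
                            ) -> list[RecurrentRegion]:
    """Drop MRDs covering more than max_arm_fraction of any chromosome arm.

    Such deletions are too large to define a minimal region meaningfully;
    the arm-level call represents them instead. The cutoff is a strict
    inequality (a region at exactly the cutoff is kept).
    """
    if not 0 < max_arm_fraction <= 1:
        raise ValueError("max_arm_fraction must lie in (0, 1]")
    kept = []
    for r in mrds:
        drop = False
        for arm in probe_map.arms:
            idx = probe_map.arm_probes(arm)
            if idx.size == 0 or probe_map.chrom_of(int(idx[0])) != r.chrom:
                continue
            inside = np.count_nonzero((idx >= r.ext_start) & (idx <= r.ext_end))
            if inside / idx.size > max_arm_fraction:
                drop = True
                break
        if not drop:
            kept.append(r)
        else:
            logger.info("suppressing arm-scale MRD on %s (probes %d-%d)",
                        r.chrom, r.ext_start, r.ext_end)
    return kept


def recurrent_arm_regions(arm_calls: Mapping[str, Mapping[str, str]],
                          config: CnaConfig | None = None) -> list[ArmRegion]:
    """Arm gains/losses present in strictly more than 10% of samples."""
    config = config or CnaConfig()
    n = len(arm_calls)
    if n == 0:
        return []
    arms = sorted({a for calls in arm_calls.values() for a in calls})
    out = []
    for arm in arms:
        for direction, kind in (("gain", "ARM_GAIN"), ("loss", "ARM_LOSS")):
            members = frozenset(sid for sid, calls in arm_calls.items()
                                if calls.get(arm) == direction)
            freq = len(members) / n
            if freq > config.arm_recurrence_fraction:
                out.append(ArmRegion(kind=kind, arm=arm, frequency=freq,
                                     members=members))
    return out


@dataclass
class AlterationMatrix:
    """Binary samples x alteration-features table feeding networks and MDS."""

    samples: list[str]
    features: list[str]
    values: np.ndarray                  # bool, samples x features
    meta: pd.DataFrame                  # per-feature kind / frequency / flags

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.astype(int), index=self.samples,
                            columns=self.features)

    def carriers(self, feature: str) -> frozenset[str]:
        j = self.features.index(feature)
        return frozenset(s for s, v in zip(self.samples, self.values[:, j]) if v)


def region_feature_name(r: RecurrentRegion, probe_map: ProbeMap) -> str:
    start, end = probe_map.genomic_span(r.ext_start, r.ext_end)
    return f"{r.kind}:{r.chrom}:{start}-{end}"


def build_alteration_matrix(regions: Sequence[RecurrentRegion],
                            events_by_sample: Mapping[str, Sequence[FocalEvent]],
                            del_masks: Mapping[str, np.ndarray],
                            arm_regions: Sequence[ArmRegion],
                            mutations: pd.DataFrame | None,
                            probe_map: ProbeMap,
                            config: CnaConfig | None = None,
                            ) -> AlterationMatrix:
    """Assemble the binary samples x features matrix.

    A sample carries a region feature iff one of its events (FGA/HD kinds)
    or its deleted-probe runs (MRD kind) intersects the region's extended
    interval. Arm features come from the recurrent arm calls, mutation
    features from the long-form mutation table. FGA/HD features rarer than
    ``mds_min_freq`` are flagged ``excluded_for_mds`` but kept for all other
    analyses.
    """
    config = config or CnaConfig()
    samples = sorted(events_by_sample)
    if set(del_masks) != set(samples):
        offenders = sorted(set(del_masks) ^ set(samples))
        raise ValueError(f"sample id mismatch across tables: {offenders[:10]}")
    if mutations is not None:
        extra = sorted(set(mutations["sample_id"]) - set(samples))
        if extra:
            raise ValueError(f"sample id mismatch across tables: {extra[:10]}")

    columns: list[np.ndarray] = []
    names: list[str] = []
    meta_rows: list[dict] = []

    for r in regions:
        col = np.zeros(len(samples), dtype=bool)
        for i, sid in enumerate(samples):
            if r.kind in ("FGA", "HD"):
                col[i] = any(e.kind == r.kind and e.chrom == r.chrom
                             and e.start <= r.ext_end and r.ext_start <= e.end
                             for e in events_by_sample[sid])
            else:
                col[i] = bool(del_masks[sid][r.ext_start:r.ext_end + 1].any())
        names.append(region_feature_name(r, probe_map))
        columns.append(col)
        meta_rows.append({"kind": r.kind, "chrom": r.chrom,
                          "max_support": r.max_support})
    for a in arm_regions:
        col = np.array([s in a.members for s in samples])
        names.append(f"{a.kind}:{a.arm}")
        columns.append(col)
        meta_rows.append({"kind": a.kind, "chrom": "", "max_support": ""})
    if mutations is not None:
        mutated = mutations[mutations["status"] == "mutated"]
        for gene in sorted(mutated["gene"].unique()):
            carriers = set(mutated.loc[mutated["gene"] == gene, "sample_id"])
            names.append(f"MUT:{gene}")
            columns.append(np.array([s in carriers for s in samples]))
            meta_rows.append({"kind": "MUT", "chrom": "", "max_support": ""})

    values = (np.column_stack(columns) if columns
              else np.zeros((len(samples), 0), dtype=bool))
    meta = pd.DataFrame(meta_rows, index=names)
    meta["frequency"] = values.mean(axis=0) if len(names) else []
    meta["excluded_for_mds"] = [
        k in ("FGA", "HD") and f < config.mds_min_freq
        for k, f in zip(meta.get("kind", []), meta.get("frequency", []))]
    return AlterationMatrix(samples, names, values, meta)


def discover_all_regions(events_by_sample, del_masks, probe_map,
                         config: CnaConfig | None = None,
                         cnv_intervals=None) -> list[RecurrentRegion]:
    """Full recurrent-region workflow: FGA + HD + MRD with all filters."""
    config = config or CnaConfig()
    n = len(probe_map)
    fga = detect_recurrent_regions(
        events_to_masks(events_by_sample, "FGA", n), "FGA", probe_map, config)
    hd = detect_recurrent_regions(
        events_to_masks(events_by_sample, "HD", n), "HD", probe_map, config)
    mrd = detect_recurrent_regions(del_masks, "MRD", probe_map, config)
    mrd = suppress_arm_scale_mrds(mrd, probe_map, config.mrd_max_arm_fraction)
    resolved = resolve_mrd_hd_overlap(mrd, hd)
    # HDs already reported on their own stay unique after resolution
    seen: set[tuple] = set()
    combined: list[RecurrentRegion] = []
    for r in list(fga) + list(hd) + list(resolved):
        key = (r.kind, r.chrom, r.core, r.extended)
        if key not in seen:
            seen.add(key)
            combined.append(r)
    return apply_cnv_mask(combined, cnv_intervals, probe_map,
                          config.cnv_overlap_max)
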