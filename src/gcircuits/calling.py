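"""Copy-number state calling from segmented log2 profiles.

Two layers of calls are made per sample:

* **Gain/loss** — the profile is smoothed in a 250 kb midpoint-centred
  window and compared against a sample-adaptive threshold (SAT), a robust
  per-sample noise scale. Probes whose smoothed value exceeds +SAT are
  GAIN, below −SAT are LOSS.
* **Amplification/homozygous deletion** — the *unsmoothed* segmented values
  are thresholded at log2 >= 0.8 (AMP) / <= −0.8 (HD), and only runs longer
  than three consecutive probes qualify; shorter excursions stay GAIN/LOSS.

The extreme state wins where both apply (AMP over GAIN, HD over LOSS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import CnaConfig
from .io import ProbeMap, SegmentedProfile

# probe state codes
HD, LOSS, NEUTRAL, GAIN, AMP = -2, -1, 0, 1, 2
STATE_NAMES = {HD: "HD", LOSS: "LOSS", NEUTRAL: "NEUTRAL", GAIN: "GAIN", AMP: "AMP"}


@dataclass(frozen=True)
class FocalEvent:
    """A per-sample focal event: a maximal run of AMP (kind FGA) or HD probes."""

    sample_id: str
    chrom: str
    start: int           # global probe index, inclusive
    end: int             # global probe index, inclusive
    kind: str            # "FGA" | "HD"
    mean_log2: float

    def n_probes(self) -> int:
        return self.end - self.start + 1


@dataclass
class CallMatrix:
    """Samples x probes state calls plus per-sample SAT values."""

    sample_ids: list[str]
    states: np.ndarray          # int8, samples x probes
    sats: np.ndarray            # per-sample SAT
    probe_map: ProbeMap

    def row(self, sample_id: str) -> np.ndarray:
        return self.states[self.sample_ids.index(sample_id)]

    def to_frame(self):
        import pandas as pd
        names = np.vectorize(STATE_NAMES.get)(self.states)
        return pd.DataFrame(names, index=self.sample_ids,
                            columns=self.probe_map.probe_ids)


def smooth_profile(profile: SegmentedProfile, probe_map: ProbeMap,
                   window_bp: int = 250_000) -> np.ndarray:
    """Mean of non-missing values over probes whose midpoints lie within
    +/- window_bp/2 of each probe midpoint, same chromosome only."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    mid = probe_map.midpoints
    v = profile.values
    out = np.full_like(v, np.nan)
    half = window_bp / 2.0
    for chrom in probe_map.chroms:
        sl = probe_map.chrom_slice(chrom)
        m, x = mid[sl], v[sl]
        ok = ~np.isnan(x)
        xs = np.where(ok, x, 0.0)
        csum = np.concatenate(([0.0], np.cumsum(xs)))
        cnum = np.concatenate(([0], np.cumsum(ok.astype(int))))
        lo = np.searchsorted(m, m - half, side="left")
        hi = np.searchsorted(m, m + half, side="right")
        n = cnum[hi] - cnum[lo]
        s = csum[hi] - csum[lo]
        with np.errstate(invalid="ignore"):
            out[sl] = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return out


def estimate_sat(profile: SegmentedProfile, multiplier: float = 2.5,
                 floor: float = 0.05, probe_map: ProbeMap | None = None,
                 ) -> float:
    """Sample-adaptive threshold: multiplier x robust noise scale.

    The noise scale is a normal-consistent MAD of probe-to-probe first
    differences divided by sqrt(2). Because segmented profiles are piecewise
    constant, exact-zero differences (probes sharing a segment) carry no
    noise information and are dropped before the MAD, so the estimate tracks
    the segment-to-segment scatter; a floor guards the fully degenerate
    case. Differences are taken within chromosomes when a probe map is
    given.
    """
    v = profile.values[~np.isnan(profile.values)]
    if v.size < 30:
        raise ValueError(f"{profile.sample_id}: need >= 30 non-missing probes, "
                         f"have {v.size}")
    if probe_map is not None:
        diffs = []
        for chrom in probe_map.chroms:
            sl = probe_map.chrom_slice(chrom)
            x = profile.values[sl]
            x = x[~np.isnan(x)]
            if x.size > 1:
                diffs.append(np.diff(x))
        d = np.concatenate(diffs) if diffs else np.empty(0)
    else:
        d = np.diff(v)
    d = d[d != 0.0] / np.sqrt(2.0)
    if d.size < 3:
        return floor
    mad = 1.4826 * np.median(np.abs(d - np.median(d)))
    return float(max(multiplier * mad, floor))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start, end) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1]) - 1)
            for i in range(0, len(edges), 2)]


def call_probe_states(profile: SegmentedProfile, smoothed: np.ndarray,
                      sat: float, config: CnaConfig,
                      probe_map: ProbeMap) -> np.ndarray:
    """Per-probe states: GAIN/LOSS from smoothed values vs SAT, AMP/HD from
    unsmoothed segmented values at +/-0.8 over runs of >= min_focal_probes."""
    if sat <= 0:
        raise ValueError("SAT must be positive")
    v = profile.values
    states = np.zeros(len(v), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        states[smoothed > sat] = GAIN
        states[smoothed < -sat] = LOSS
    for chrom in probe_map.chroms:
        sl = probe_map.chrom_slice(chrom)
        x = v[sl]
        for threshold_mask, code in (
                (np.nan_to_num(x, nan=-np.inf) >= config.amp_log2, AMP),
                (np.nan_to_num(x, nan=np.inf) <= config.hd_log2, HD)):
            for lo, hi in _runs(threshold_mask):
                if hi - lo + 1 >= config.min_focal_probes:
                    states[sl.start + lo: sl.start + hi + 1] = code
    return states


def extract_focal_events(sample_id: str, states: np.ndarray, values: np.ndarray,
                         probe_map: ProbeMap) -> list[FocalEvent]:
    """Maximal AMP runs become FGA events; maximal HD runs become HD events."""
    events = []
    for chrom in probe_map.chroms:
        sl = probe_map.chrom_slice(chrom)
        for code, kind in ((AMP, "FGA"), (HD, "HD")):
            for lo, hi in _runs(states[sl] == code):
                seg = values[sl.start + lo: sl.start + hi + 1]
                events.append(FocalEvent(
                    sample_id=sample_id, chrom=chrom,
                    start=sl.start + lo, end=sl.start + hi, kind=kind,
                    mean_log2=float(np.nanmean(seg))))
    return events


def merge_amplicons(events: Sequence[FocalEvent], probe_map: ProbeMap,
                    merge_gap_bp: int = 1_000_000) -> list[FocalEvent]:
    """Union same-chromosome, same-kind events whose genomic gap is < merge_gap_bp.

    The merged count is the sample's amplicon count (events < 1 Mbp apart
    are one amplicon).
    """
    if not events:
        return []
    kinds = {e.kind for e in events}
    samples = {e.sample_id for e in events}
    if len(kinds) > 1 or len(samples) > 1:
        raise ValueError("merge_amplicons expects events of one sample and kind")
    out: list[FocalEvent] = []
    for chrom in sorted({e.chrom for e in events}):
        evs = sorted((e for e in events if e.chrom == chrom), key=lambda e: e.start)
        current = evs[0]
        for e in evs[1:]:
            gap = probe_map.genomic_span(e.start, e.end)[0] - \
                probe_map.genomic_span(current.start, current.end)[1]
            if gap < merge_gap_bp:
                n1, n2 = current.n_probes(), e.n_probes()
                current = FocalEvent(
                    current.sample_id, chrom, current.start, max(current.end, e.end),
                    current.kind,
                    (current.mean_log2 * n1 + e.mean_log2 * n2) / (n1 + n2))
            else:
                out.append(current)
                current = e
        out.append(current)
    return out


def call_arm_events(states: np.ndarray, probe_map: ProbeMap,
                    config: CnaConfig) -> dict[str, str]:
    """Per-arm call in {"gain", "loss", "none"}.

    Gain iff the fraction of the arm's probes in {GAIN, AMP} strictly
    exceeds ``arm_probe_fraction`` (loss analogous); when both fractions
    qualify the larger wins and ties give "none". Missing probes count in
    the denominator as unaltered.
    """
    calls: dict[str, str] = {}
    for arm in probe_map.arms:
        idx = probe_map.arm_probes(arm)
        if idx.size == 0:
            import logging
            logging.getLogger("gcircuits").warning("arm %s has no probes", arm)
            continue
        s = states[idx]
        f_gain = float(np.mean((s == GAIN) | (s == AMP)))
        f_loss = float(np.mean((s == LOSS) | (s == HD)))
        call = "none"
        if f_gain > config.arm_probe_fraction or f_loss > config.arm_probe_fraction:
            if f_gain > f_loss:
                call = "gain"
            elif f_loss > f_gain:
                call = "loss"
        calls[arm] = call
    return calls


def call_cohort(profiles: Sequence[SegmentedProfile], probe_map: ProbeMap,
                config: CnaConfig | None = None):
    """Run smoothing, SAT estimation and state calling for every profile.

    Returns ``(CallMatrix, events, arm_calls)`` where ``events`` maps
    sample id -> list of FocalEvent and ``arm_calls`` maps sample id ->
    per-arm call dict.
    """
    config = config or CnaConfig()
    states = np.zeros((len(profiles), len(probe_map)), dtype=np.int8)
    sats = np.zeros(len(profiles))
    events: dict[str, list[FocalEvent]] = {}
    arm_calls: dict[str, dict[str, str]] = {}
    sample_ids = []
    for i, p in enumerate(profiles):
        sm = smooth_profile(p, probe_map, config.window_bp)
        sat = estimate_sat(p, config.sat_multiplier, config.sat_floor, probe_map)
        row = call_probe_states(p, sm, sat, config, probe_map)
        states[i] = row
        sats[i] = sat
        sample_ids.append(p.sample_id)
        events[p.sample_id] = extract_focal_events(p.sample_id, row, p.values,
                                                   probe_map)
        arm_calls[p.sample_id] = call_arm_events(row, probe_map, config)
    return CallMatrix(sample_ids, states, sats, probe_map), events, arm_calls
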