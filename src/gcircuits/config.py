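"""Configuration objects for the copy-number calling and recurrence pipeline.

All genomic thresholds used downstream live in :class:`CnaConfig` so that a
single object documents the analysis conditions of a run. Defaults follow the
tiling-BAC-array conventions the pipeline was designed around: high-level
amplification / homozygous-deletion cutoffs at segmented log2 = ±0.8, a 250 kb
smoothing window for gain/loss calling against a sample-adaptive threshold
(SAT), a 1 Mbp amplicon-merging gap, and recurrence minima of 3 samples for
focal amplifications (FGA), 2 for homozygous deletions (HD) and 15 for minimal
regions of deletion (MRD).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class CnaConfig:
    """Thresholds for copy-number state calling and recurrent-region discovery.

    Parameters
    ----------
    window_bp
        Width of the midpoint-centred smoothing window (bp) used before
        gain/loss calling.
    sat_multiplier
        SAT = multiplier x robust per-sample noise scale.
    sat_floor
        Lower bound for the SAT; guards degenerate (noiseless) profiles.
    amp_log2, hd_log2
        Segmented-log2 cutoffs for high-level amplification / homozygous
        deletion (applied unsmoothed).
    min_focal_probes
        Minimum run length, in consecutive probes, for a focal AMP/HD call
        ("longer than three consecutive probes" read as >= 4).
    merge_gap_bp
        Same-chromosome focal events closer than this are one amplicon.
    arm_probe_fraction
        Fraction of an arm's probes that must be gained/lost (strictly
        exceeded) for an arm-level call.
    arm_recurrence_fraction
        Fraction of samples (strictly exceeded) for an arm event to count as
        recurrent.
    fga_min_support, hd_min_support, mrd_min_support
        Minimum peak support for recurrent FGA / HD / MRD regions.
    boundary_slack, hd_boundary_slack
        Core regions are extended to include probes supported by at least
        (max - slack) samples; HDs use the tighter slack.
    cnv_overlap_max
        Regions whose extended interval is covered by germline CNVs beyond
        this fraction are masked out.
    mrd_max_arm_fraction
        MRDs spanning more than this fraction of a chromosome arm are
        suppressed (the arm-level call represents the event instead).
    mds_min_freq
        FGA/HD features rarer than this are excluded from MDS embedding.
    """

    window_bp: int = 250_000
    sat_multiplier: float = 2.5
    sat_floor: float = 0.05
    amp_log2: float = 0.8
    hd_log2: float = -0.8
    min_focal_probes: int = 4
    merge_gap_bp: int = 1_000_000
    arm_probe_fraction: float = 0.5
    arm_recurrence_fraction: float = 0.10
    fga_min_support: int = 3
    hd_min_support: int = 2
    mrd_min_support: int = 15
    boundary_slack: int = 2
    hd_boundary_slack: int = 1
    cnv_overlap_max: float = 0.5
    mrd_max_arm_fraction: float = 0.5
    mds_min_freq: float = 0.05

    def __post_init__(self) -> None:
        if self.amp_log2 <= 0 or self.hd_log2 >= 0:
            raise ValueError("require amp_log2 > 0 > hd_log2")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.min_focal_probes < 1:
            raise ValueError("min_focal_probes must be >= 1")
        for name in ("arm_probe_fraction", "arm_recurrence_fraction",
                     "cnv_overlap_max", "mrd_max_arm_fraction", "mds_min_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if min(self.fga_min_support, self.hd_min_support, self.mrd_min_support) < 1:
            raise ValueError("support minima must be >= 1")

    def min_support(self, kind: str) -> int:
        return {"FGA": self.fga_min_support,
                "HD": self.hd_min_support,
                "MRD": self.mrd_min_support}[kind]

    def slack(self, kind: str) -> int:
        return self.hd_boundary_slack if kind == "HD" else self.boundary_slack

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CnaConfig":
        return cls(**json.loads(Path(path).read_text()))


MUTATION_PANEL = ("FGFR3", "PIK3CA", "KRAS", "HRAS", "NRAS", "CDKN2A", "TP53")
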