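"""Synthetic tumor cohort with recorded ground truth.

The generator emulates the structure of a 146-sample urothelial-carcinoma
cohort on a reduced BAC-like probe grid (3000 probes over 4 synthetic
chromosomes with p/q arms). Samples belong to one of four groups:

* **circuitA** — FGFR3-mutant-like tumors: whole-arm "9q"-style loss
  (arm 2q here), a nested subset with a CDKN2A-style homozygous deletion,
  an occasional CCND1-style focal amplification, high CCND1/FGFR3
  expression; low hazard.
* **circuitB** — E2F3/RB1-like tumors: a 6p22-style focal amplification,
  an RB1-style homozygous deletion, a 5p-style arm gain, minimal deletion
  regions at PTEN/17p-style loci, low FGFR3/RB1/PTEN expression; higher
  hazard.
* **keratinized** — an expression-defined subgroup of the complex class
  with an extra keratin-like gene program and the worst hazard.
* **background** — noise and random passengers only.

Copy-number profiles are piecewise constant: baseline segments get one
Gaussian offset each (the input is *segmented* data, so noise lives at the
segment level), and planted or passenger events overwrite their interval
with the target log2 plus one segment-level draw. Expression is generated
on the raw intensity scale (log-normal with group effects) with a
multiplicative labeling-batch factor and background subtraction, so the
normalization pipeline has realistic work to do. Survival is exponential
with group-specific hazards and independent exponential censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MUTATION_PANEL
from .io import ProbeMap, SegmentedProfile

GROUPS = ("circuitA", "circuitB", "keratinized", "background")


@dataclass(frozen=True)
class PlantedRegion:
    """A planted copy-number event; ``lo``/``hi`` are chromosome-local probe
    indices (inclusive) for focal kinds, ignored for ARM kinds."""

    name: str
    kind: str                         # FGA | HD | MRD | ARM_GAIN | ARM_LOSS
    chrom: str
    lo: int = 0
    hi: int = 0
    arm: str = ""
    target_log2: float = 0.0
    carrier_frac: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, f in self.carrier_frac.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"carrier fraction {f} outside [0, 1]")


def default_planted_regions() -> list[PlantedRegion]:
    return [
        PlantedRegion("CDKN2A_HD", "HD", "chr2", 120, 128,
                      target_log2=-1.6, carrier_frac={"circuitA": 0.5}),
        PlantedRegion("NINEQ_LOSS", "ARM_LOSS", "chr2", arm="2q",
                      target_log2=-0.5, carrier_frac={"circuitA": 0.85}),
        PlantedRegion("CCND1_FGA", "FGA", "chr1", 600, 610,
                      target_log2=1.4, carrier_frac={"circuitA": 0.35}),
        PlantedRegion("SIXP22_FGA", "FGA", "chr3", 80, 91,
                      target_log2=1.5, carrier_frac={"circuitB": 0.8}),
        PlantedRegion("RB1_HD", "HD", "chr4", 500, 508,
                      target_log2=-1.5, carrier_frac={"circuitB": 0.6}),
        PlantedRegion("FOURQ_LOSS", "ARM_LOSS", "chr4", arm="4q",
                      target_log2=-0.5,
                      carrier_frac={"circuitB": 0.7, "keratinized": 0.7}),
        PlantedRegion("FIVEP_GAIN", "ARM_GAIN", "chr1", arm="1p",
                      target_log2=0.5,
                      carrier_frac={"circuitB": 0.8, "keratinized": 0.5}),
        PlantedRegion("THREEQ_LOSS", "ARM_LOSS", "chr3", arm="3q",
                      target_log2=-0.5,
                      carrier_frac={"circuitB": 0.5, "keratinized": 0.5}),
        PlantedRegion("PTEN_MRD", "MRD", "chr3", 520, 539,
                      target_log2=-0.5,
                      carrier_frac={"circuitB": 0.6, "keratinized": 0.4,
                                    "background": 0.1}),
        PlantedRegion("SEVENTEENP_MRD", "MRD", "chr4", 100, 117,
                      target_log2=-0.5,
                      carrier_frac={"circuitB": 0.5, "keratinized": 0.5}),
    ]


@dataclass
class ExpressionConfig:
    n_genes: int = 2000
    subtype_shift: float = 1.0        # log2 separation between MS classes
    gene_noise_sd: float = 0.5
    batch_factor: float = 1.3         # multiplicative bias of batch 2
    n_subtype_genes: int = 150
    n_keratin_genes: int = 40
    keratin_shift: float = 0.75
    marker_shift: float = 1.2
    baseline_mean_log2: float = 7.0
    baseline_sd_log2: float = 1.5
    background_offset: float = 10.0   # subtracted post-hoc (can go negative)
    intensity_noise_sd: float = 2.0


@dataclass
class SurvivalConfig:
    hazards: Mapping[str, float] = field(default_factory=lambda: {
        "circuitA": 0.004, "background": 0.004,
        "circuitB": 0.015, "keratinized": 0.035})
    censor_rate: float = 0.3

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hazards.values()):
            raise ValueError("hazards must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")


@dataclass
class SimulationConfig:
    n_samples: int = 146
    n_probes: int = 3000              # over 4 chromosomes with p/q arms
    probe_spacing_bp: int = 100_000
    proportions: Mapping[str, float] = field(default_factory=lambda: {
        "circuitA": 0.40, "circuitB": 0.30,
        "keratinized": 0.12, "background": 0.18})
    planted_regions: Sequence[PlantedRegion] = field(
        default_factory=default_planted_regions)
    segment_noise_sd: float = 0.08
    segments_per_chrom: float = 8.0   # mean baseline segments per chromosome
    passenger_fga_rate: float = 0.05  # Poisson mean per sample
    passenger_hd_rate: float = 0.01
    passenger_broad_rate: float = 0.3  # broad hemizygous gains+losses
    mutation_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "FGFR3": {"circuitA": 0.75, "background": 0.10,
                      "circuitB": 0.02, "keratinized": 0.02},
            "PIK3CA": {"circuitA": 0.25, "background": 0.05,
                       "circuitB": 0.05, "keratinized": 0.05},
            "TP53": {"circuitA": 0.10, "background": 0.10,
                     "circuitB": 0.50, "keratinized": 0.60},
            "KRAS": {g: 0.04 for g in GROUPS},
            "HRAS": {g: 0.04 for g in GROUPS},
            "NRAS": {g: 0.02 for g in GROUPS},
            "CDKN2A": {g: 0.05 for g in GROUPS},
        })
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions must sum to 1, got {total}")


@dataclass
class PlantedTruth:
    """A planted region resolved to global probe coordinates, with carriers."""

    name: str
    kind: str
    chrom: str
    start: int                     # global probe index, inclusive
    end: int
    arm: str
    target_log2: float
    carriers: frozenset[str]
    circuit: str                   # group contributing most carriers


@dataclass
class GroundTruth:
    group_labels: pd.Series        # sample -> group
    ms_labels: pd.Series           # sample -> MS1/MS2
    planted: list[PlantedTruth]
    ms_up_genes: list[str]         # higher in MS2 (complex) tumors
    ms_down_genes: list[str]
    cin_genes: list[str]           # == ms_up_genes; CIN-signature stand-in
    keratin_genes: list[str]
    mdm2_high: frozenset[str]
    hazards: Mapping[str, float]
    batches: pd.Series

    def planted_footprints(self, kind: str) -> list[tuple[str, int, int]]:
        """Intervals a reported region of ``kind`` may legitimately overlap.

        FGAs may only match planted amplifications; HDs planted homozygous
        deletions; MRDs any planted deletion (MRD, HD or arm loss), since
        deletion support of every depth feeds MRD discovery.
        """
        ok_kinds = {"FGA": {"FGA"}, "HD": {"HD"},
                    "MRD": {"MRD", "HD", "ARM_LOSS"}}[kind]
        return [(p.chrom, p.start, p.end) for p in self.planted
                if p.kind in ok_kinds]


@dataclass
class Cohort:
    probe_map: ProbeMap
    profiles: list[SegmentedProfile]
    expression_raw: pd.DataFrame   # genes x samples, raw intensity scale
    batches: pd.Series
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    ihc: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# probe grid
# ---------------------------------------------------------------------------

def make_probe_map(n_probes: int = 3000, n_chroms: int = 4,
                   spacing_bp: int = 100_000,
                   p_fraction: float = 0.4) -> ProbeMap:
    """Evenly tiled synthetic probe grid with p/q arms per chromosome."""
    per_chrom = n_probes // n_chroms
    if per_chrom < 10:
        raise ValueError("too few probes per chromosome")
    ids, chroms, starts, ends, arms = [], [], [], [], []
    for c in range(1, n_chroms + 1):
        n_p = int(per_chrom * p_fraction)
        for i in range(per_chrom):
            ids.append(f"probe_{c}_{i:04d}")
            chroms.append(f"chr{c}")
            starts.append(i * spacing_bp)
            ends.append((i + 1) * spacing_bp)
            arms.append(f"{c}p" if i < n_p else f"{c}q")
    return ProbeMap(ids, chroms, starts, ends, arms)


# ---------------------------------------------------------------------------
# copy-number profile synthesis
# ---------------------------------------------------------------------------

def plant_focal_event(profile: SegmentedProfile, interval: tuple[int, int],
                      target_log2: float, probe_map: ProbeMap,
                      ) -> SegmentedProfile:
    """Set segmented values on a (global, inclusive) probe interval to
    ``target_log2``; the interval must lie within one chromosome."""
    lo, hi = interval
    if not 0 <= lo <= hi < len(probe_map):
        raise ValueError(f"interval {interval} outside probe grid")
    if probe_map.chrom_of(lo) != probe_map.chrom_of(hi):
        raise ValueError(f"interval {interval} spans chromosomes")
    values = profile.values.copy()
    values[lo:hi + 1] = target_log2
    return SegmentedProfile(profile.sample_id, values)


def _baseline_profile(rng: np.random.Generator, probe_map: ProbeMap,
                      noise_sd: float, segments_per_chrom: float) -> np.ndarray:
    values = np.zeros(len(probe_map))
    for chrom in probe_map.chroms:
        sl = probe_map.chrom_slice(chrom)
        n = sl.stop - sl.start
        n_seg = max(1, rng.poisson(segments_per_chrom))
        cuts = np.sort(rng.choice(np.arange(1, n), size=min(n_seg - 1, n - 1),
                                  replace=False)) if n_seg > 1 else np.empty(0, int)
        bounds = np.concatenate(([0], cuts, [n]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            values[sl.start + a: sl.start + b] = rng.normal(0.0, noise_sd)
    return values


def _overwrite(values: np.ndarray, lo: int, hi: int, target: float,
               rng: np.random.Generator, noise_sd: float) -> None:
    values[lo:hi + 1] = target + rng.normal(0.0, noise_sd)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(groups: pd.Series, hazards: Mapping[str, float],
                      censor_rate: float,
                      rng: np.random.Generator | int) -> pd.DataFrame:
    """Exponential event times with independent exponential censoring.

    The censoring hazard is set per group so that the expected censored
    fraction equals ``censor_rate``. Returns a clinical-style frame with
    ``sample_id, followup_months, dss_event``.
    """
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    unknown = set(groups.unique()) - set(hazards)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    rows = []
    for sid, g in groups.items():
        lam = hazards[g]
        t_event = rng.exponential(1.0 / lam)
        if censor_rate > 0:
            lam_c = lam * censor_rate / (1.0 - censor_rate)
            t_cens = rng.exponential(1.0 / lam_c)
        else:
            t_cens = np.inf
        rows.append({"sample_id": sid,
                     "followup_months": float(min(t_event, t_cens)),
                     "dss_event": bool(t_event <= t_cens)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort; deterministic given config.seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    probe_map = make_probe_map(config.n_probes, 4, config.probe_spacing_bp)

    # group assignment (exact counts from proportions, largest remainder)
    n = config.n_samples
    quotas = {g: config.proportions.get(g, 0.0) * n for g in GROUPS}
    counts = {g: int(np.floor(q)) for g, q in quotas.items()}
    remainder = n - sum(counts.values())
    for g in sorted(GROUPS, key=lambda g: quotas[g] - counts[g], reverse=True):
        if remainder <= 0:
            break
        counts[g] += 1
        remainder -= 1
    labels = np.concatenate([[g] * counts[g] for g in GROUPS])
    rng.shuffle(labels)
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    group_labels = pd.Series(labels, index=sample_ids, name="group")
    ms_labels = group_labels.map({"circuitA": "MS1", "background": "MS1",
                                  "circuitB": "MS2", "keratinized": "MS2"})

    # planted events: resolve to global coordinates and draw carriers
    planted: list[PlantedTruth] = []
    for region in config.planted_regions:
        if region.kind in ("ARM_GAIN", "ARM_LOSS"):
            idx = probe_map.arm_probes(region.arm)
            start, end = int(idx[0]), int(idx[-1])
        else:
            sl = probe_map.chrom_slice(region.chrom)
            start, end = sl.start + region.lo, sl.start + region.hi
            if not (sl.start <= start <= end < sl.stop):
                raise ValueError(f"planted region {region.name} outside "
                                 f"probe grid of {region.chrom}")
        carriers = set()
        for g, frac in region.carrier_frac.items():
            members = [s for s, lab in group_labels.items() if lab == g]
            k = int(round(frac * len(members)))
            carriers.update(rng.choice(members, size=k, replace=False))
        circuit = max(region.carrier_frac, key=region.carrier_frac.get) \
            if region.carrier_frac else "background"
        planted.append(PlantedTruth(
            region.name, region.kind, region.chrom, start, end, region.arm,
            region.target_log2, frozenset(carriers), circuit))

    # profiles
    profiles = []
    n_probes = len(probe_map)
    chrom_bounds = {c: probe_map.chrom_slice(c) for c in probe_map.chroms}
    for sid in sample_ids:
        values = _baseline_profile(rng, probe_map, config.segment_noise_sd,
                                   config.segments_per_chrom)
        # broad passenger gains/losses (hemizygous depth)
        for _ in range(rng.poisson(config.passenger_broad_rate)):
            chrom = probe_map.chroms[rng.integers(len(probe_map.chroms))]
            sl = chrom_bounds[chrom]
            length = max(20, int(rng.exponential(60)))
            lo = int(rng.integers(sl.start, max(sl.start + 1, sl.stop - length)))
            hi = min(sl.stop - 1, lo + length - 1)
            target = 0.45 if rng.random() < 0.5 else -0.45
            _overwrite(values, lo, hi, target, rng, config.segment_noise_sd)
        # planted arm events then planted focal events (focal wins overlaps)
        for p in planted:
            if sid in p.carriers and p.kind in ("ARM_GAIN", "ARM_LOSS"):
                _overwrite(values, p.start, p.end, p.target_log2, rng,
                           config.segment_noise_sd)
        for p in planted:
            if sid in p.carriers and p.kind not in ("ARM_GAIN", "ARM_LOSS"):
                _overwrite(values, p.start, p.end, p.target_log2, rng,
                           config.segment_noise_sd)
        # focal passengers
        for rate, target, base_len in ((config.passenger_fga_rate, 1.2, 5),
                                       (config.passenger_hd_rate, -1.2, 4)):
            for _ in range(rng.poisson(rate)):
                chrom = probe_map.chroms[rng.integers(len(probe_map.chroms))]
                sl = chrom_bounds[chrom]
                length = base_len + int(rng.poisson(2))
                lo = int(rng.integers(sl.start, max(sl.start + 1,
                                                    sl.stop - length)))
                hi = min(sl.stop - 1, lo + length - 1)
                _overwrite(values, lo, hi, target, rng, config.segment_noise_sd)
        profiles.append(SegmentedProfile(sid, values))

    # expression
    expr_cfg = config.expression
    gene_names = [f"G{i:04d}" for i in range(expr_cfg.n_genes)]
    markers = ["FGFR3", "CCND1", "RB1", "PTEN", "CDKN2A", "RAF1", "E2F3",
               "MDM2"]
    gene_names[:len(markers)] = markers
    n_ms = expr_cfg.n_subtype_genes
    ms_up = gene_names[len(markers):len(markers) + n_ms // 2]
    ms_down = gene_names[len(markers) + n_ms // 2:len(markers) + n_ms]
    keratin = gene_names[len(markers) + n_ms:
                         len(markers) + n_ms + expr_cfg.n_keratin_genes]

    mu = rng.normal(expr_cfg.baseline_mean_log2, expr_cfg.baseline_sd_log2,
                    size=expr_cfg.n_genes)
    level = np.tile(mu[:, None], (1, n))
    is_ms2 = (ms_labels == "MS2").to_numpy()
    is_ker = (group_labels == "keratinized").to_numpy()
    is_a = (group_labels == "circuitA").to_numpy()
    is_b = (group_labels == "circuitB").to_numpy()
    half = expr_cfg.subtype_shift / 2.0
    gi = {g: i for i, g in enumerate(gene_names)}
    for g in ms_up:
        level[gi[g]] += np.where(is_ms2, half, -half)
    for g in ms_down:
        level[gi[g]] += np.where(is_ms2, -half, half)
    for g in keratin:
        level[gi[g]] += np.where(is_ker, expr_cfg.keratin_shift, 0.0)
    shift = expr_cfg.marker_shift
    level[gi["FGFR3"]] += np.where(is_a, shift, np.where(is_ms2, -shift, 0.0))
    level[gi["CCND1"]] += np.where(is_a, shift, 0.0)
    level[gi["RB1"]] += np.where(is_b, -shift, 0.0)
    level[gi["PTEN"]] += np.where(is_ms2, -shift, 0.0)
    level[gi["CDKN2A"]] += np.where(is_b, shift * 0.8, 0.0)
    level[gi["E2F3"]] += np.where(is_b, shift, 0.0)
    level[gi["RAF1"]] += 0.0
    mdm2_high = frozenset(
        s for s, r in zip(sample_ids, rng.random(n))
        if r < (0.15 if ms_labels[s] == "MS2" else 0.05))
    level[gi["MDM2"]] += np.array([1.5 if s in mdm2_high else 0.0
                                   for s in sample_ids])

    level += rng.normal(0.0, expr_cfg.gene_noise_sd, size=level.shape)
    intensity = np.power(2.0, level)
    batches = pd.Series(np.where(rng.random(n) < 0.5, "batch1", "batch2"),
                        index=sample_ids, name="batch")
    intensity[:, (batches == "batch2").to_numpy()] *= expr_cfg.batch_factor
    intensity += rng.normal(0.0, expr_cfg.intensity_noise_sd,
                            size=intensity.shape)
    intensity -= expr_cfg.background_offset
    expression_raw = pd.DataFrame(intensity, index=gene_names,
                                  columns=sample_ids)

    # mutations
    mut_rows = []
    for gene in MUTATION_PANEL:
        rates = config.mutation_rates.get(gene, {})
        for sid in sample_ids:
            p = rates.get(group_labels[sid], 0.0)
            mut_rows.append({"sample_id": sid, "gene": gene,
                             "status": "mutated" if rng.random() < p
                             else "wildtype"})
    mutations = pd.DataFrame(mut_rows)

    # clinical (stage/grade loosely tied to group) + survival
    stage_probs = {"circuitA": [0.6, 0.3, 0.1], "background": [0.5, 0.3, 0.2],
                   "circuitB": [0.15, 0.25, 0.6], "keratinized": [0.05, 0.2, 0.75]}
    grade_probs = {"circuitA": [0.4, 0.5, 0.1], "background": [0.3, 0.5, 0.2],
                   "circuitB": [0.0, 0.3, 0.7], "keratinized": [0.0, 0.2, 0.8]}
    stages = [rng.choice(["Ta", "T1", ">=T2"], p=stage_probs[group_labels[s]])
              for s in sample_ids]
    grades = [rng.choice(["G1", "G2", "G3"], p=grade_probs[group_labels[s]])
              for s in sample_ids]
    surv = simulate_survival(group_labels, config.survival.hazards,
                             config.survival.censor_rate, rng)
    clinical = surv.assign(stage=stages, grade=grades)[
        ["sample_id", "stage", "grade", "followup_months", "dss_event"]]

    # IHC: two cores per sample (first three samples single-core), score
    # intensity tied to the marker's expression quartile
    ihc_rows = []
    for marker in ("FGFR3", "CCND1", "RB1", "CDKN2A"):
        v = expression_raw.loc[marker]
        quartile = pd.qcut(v.rank(method="first"), 4, labels=False).to_numpy()
        for i, sid in enumerate(sample_ids):
            n_cores = 1 if i < 3 else 2
            for core in range(n_cores):
                base = int(quartile[i])
                intensity_score = int(np.clip(
                    base + rng.integers(-1, 2), 0, 3))
                fraction = float(rng.integers(3, 11)) / 10.0 \
                    if intensity_score > 0 else 0.0
                ihc_rows.append({"sample_id": sid, "marker": marker,
                                 "core": core + 1,
                                 "intensity": intensity_score,
                                 "fraction": fraction})
    ihc = pd.DataFrame(ihc_rows)

    truth = GroundTruth(
        group_labels=group_labels, ms_labels=ms_labels, planted=planted,
        ms_up_genes=list(ms_up), ms_down_genes=list(ms_down),
        cin_genes=list(ms_up), keratin_genes=list(keratin),
        mdm2_high=mdm2_high, hazards=dict(config.survival.hazards),
        batches=batches)
    return Cohort(probe_map=probe_map, profiles=profiles,
                  expression_raw=expression_raw, batches=batches,
                  mutations=mutations, clinical=clinical, ihc=ihc,
                  truth=truth)
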