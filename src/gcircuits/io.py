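"""Domain containers and file I/O.

Coordinate convention: all internal genomic coordinates are 0-based
half-open, matching BED. Every per-probe vector in the pipeline is aligned
to a shared :class:`ProbeMap`; the probe order defined there is the single
source of truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gcircuits")


class ProbeMap:
    """Ordered genomic probe grid (clone coordinates plus chromosome arm).

    Probes are sorted by (chrom, start); ids are unique; each probe belongs
    to exactly one arm (e.g. ``"9q"``).
    """

    def __init__(self, probe_id: Sequence[str], chrom: Sequence[str],
                 start: Sequence[int], end: Sequence[int], arm: Sequence[str]):
        df = pd.DataFrame({
            "probe_id": np.asarray(probe_id, dtype=object),
            "chrom": np.asarray(chrom, dtype=object),
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "arm": np.asarray(arm, dtype=object),
        })
        if df["probe_id"].duplicated().any():
            dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"probe {df.at[bad, 'probe_id']}: start >= end")
        # stable sort by (chrom, start); chromosome blocks must be contiguous
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self._df = df
        self._index = {pid: i for i, pid in enumerate(df["probe_id"])}
        self._chrom_slices: dict[str, slice] = {}
        for c in df["chrom"].unique():
            idx = np.flatnonzero((df["chrom"] == c).to_numpy())
            self._chrom_slices[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        self._arm_indices: dict[str, np.ndarray] = {
            a: np.flatnonzero((df["arm"] == a).to_numpy())
            for a in df["arm"].unique()
        }

    # -- basic protocol -----------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ProbeMap) and self._df.equals(other._df)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def probe_ids(self) -> np.ndarray:
        return self._df["probe_id"].to_numpy()

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_slices)

    @property
    def midpoints(self) -> np.ndarray:
        return (self._df["start"].to_numpy() + self._df["end"].to_numpy()) / 2.0

    def chrom_slice(self, chrom: str) -> slice:
        return self._chrom_slices[chrom]

    def arm_probes(self, arm: str) -> np.ndarray:
        """Global probe indices belonging to a chromosome arm."""
        return self._arm_indices[arm]

    @property
    def arms(self) -> list[str]:
        return list(self._arm_indices)

    def index_of(self, probe_id: str) -> int:
        return self._index[probe_id]

    def chrom_of(self, i: int) -> str:
        return self._df.at[i, "chrom"]

    def genomic_span(self, lo: int, hi: int) -> tuple[int, int]:
        """(start, end) bp of the inclusive probe-index interval [lo, hi]."""
        return int(self._df.at[lo, "start"]), int(self._df.at[hi, "end"])

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self._df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeMap":
        df = pd.read_csv(path, sep="\t")
        required = {"probe_id", "chrom", "start", "end", "arm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"probe map missing columns: {sorted(missing)}")
        return cls(df["probe_id"], df["chrom"], df["start"], df["end"], df["arm"])


@dataclass
class SegmentedProfile:
    """Per-sample segmented log2 ratios aligned to a ProbeMap (NaN = missing)."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = np.isfinite(self.values) | np.isnan(self.values)
        if not finite.all():
            raise ValueError(f"{self.sample_id}: non-finite segmented values")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_segmented_profiles(path: str | Path, probe_map: ProbeMap,
                            missing_tolerance: float = 0.0,
                            ) -> list[SegmentedProfile]:
    """Read a tab-delimited profile table, long or wide form (auto-detected).

    Long form has columns ``sample_id, probe_id, log2``; wide form is probe
    rows x sample columns with the probe id in the first column. Values are
    aligned to ``probe_map`` order; probes absent from the file become NaN.

    Raises if the fraction of file probe ids unknown to the probe map exceeds
    ``missing_tolerance``, or on duplicate (sample, probe) rows or
    non-numeric values.
    """
    raw = pd.read_csv(path, sep="\t", dtype=object)
    cols = [c.strip() for c in raw.columns]
    raw.columns = cols
    if {"sample_id", "probe_id", "log2"} <= set(cols):
        return _profiles_from_long(raw, probe_map, missing_tolerance, path)
    return _profiles_from_wide(raw, probe_map, missing_tolerance, path)


def _check_unknown(probe_ids: Iterable[str], probe_map: ProbeMap,
                   tolerance: float, path) -> list[str]:
    probe_ids = list(probe_ids)
    unknown = [p for p in probe_ids if p not in probe_map._index]
    if probe_ids and len(unknown) / len(probe_ids) > tolerance:
        raise ValueError(
            f"{path}: {len(unknown)} probe ids not in probe map "
            f"(tolerance {tolerance}): {unknown[:10]}")
    if unknown:
        logger.warning("%s: ignoring %d unknown probe ids (e.g. %s)",
                       path, len(unknown), unknown[:3])
    return unknown


def _to_float(series: pd.Series, context: str) -> np.ndarray:
    out = pd.to_numeric(series, errors="coerce")
    bad = series.notna() & out.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{context}: non-numeric log2 value "
                         f"{series.iloc[row]!r} at data row {row + 1}")
    return out.to_numpy(dtype=float)


def _profiles_from_long(df: pd.DataFrame, probe_map: ProbeMap,
                        tolerance: float, path) -> list[SegmentedProfile]:
    dup = df.duplicated(subset=["sample_id", "probe_id"])
    if dup.any():
        r = df.loc[dup].iloc[0]
        raise ValueError(f"{path}: duplicate row for sample "
                         f"{r['sample_id']!r}, probe {r['probe_id']!r}")
    unknown = set(_check_unknown(df["probe_id"].unique(), probe_map, tolerance, path))
    values = _to_float(df["log2"], str(path))
    profiles = []
    for sid, sub_idx in df.groupby("sample_id", sort=True).groups.items():
        vec = np.full(len(probe_map), np.nan)
        sub = df.loc[sub_idx]
        for pid, v in zip(sub["probe_id"], values[np.asarray(sub_idx)]):
            if pid not in unknown:
                vec[probe_map.index_of(pid)] = v
        profiles.append(SegmentedProfile(str(sid), vec))
    return profiles


def _profiles_from_wide(df: pd.DataFrame, probe_map: ProbeMap,
                        tolerance: float, path) -> list[SegmentedProfile]:
    probe_col = df.columns[0]
    if df[probe_col].duplicated().any():
        pid = df.loc[df[probe_col].duplicated(), probe_col].iloc[0]
        raise ValueError(f"{path}: duplicate probe row {pid!r}")
    unknown = set(_check_unknown(df[probe_col], probe_map, tolerance, path))
    keep = ~df[probe_col].isin(unknown)
    rows = np.array([probe_map.index_of(p) for p in df.loc[keep, probe_col]])
    profiles = []
    for sample in df.columns[1:]:
        vec = np.full(len(probe_map), np.nan)
        vec[rows] = _to_float(df.loc[keep, sample], f"{path} column {sample!r}")
        profiles.append(SegmentedProfile(str(sample), vec))
    return profiles


def write_segmented_profiles(profiles: Sequence[SegmentedProfile],
                             probe_map: ProbeMap, path: str | Path) -> None:
    """Write profiles in wide form (probe rows x sample columns)."""
    data = {"probe_id": probe_map.probe_ids}
    for p in profiles:
        data[p.sample_id] = p.values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_interval_file(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED file (0-based half-open) into sorted (chrom, start, end, name)."""
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty interval "
                                 f"(start {start} >= end {end})")
            name = parts[3] if len(parts) > 3 else ""
            intervals.append((chrom, start, end, name))
    intervals.sort(key=lambda iv: (iv[0], iv[1], iv[2]))
    return intervals


# ---------------------------------------------------------------------------
# region tables (shared with the recurrence module)
# ---------------------------------------------------------------------------

REGION_COLUMNS = ["kind", "chrom", "core_start_probe", "core_end_probe",
                  "ext_start_probe", "ext_end_probe", "start_bp", "end_bp",
                  "max_support", "members"]


def write_region_table(regions, probe_map: ProbeMap, path: str | Path,
                       format: str = "tsv") -> None:
    """Write recurrent regions as TSV (lossless) or BED (extended interval).

    BED rows use the 0-based half-open extended interval with
    ``kind:chrom:core`` in the name column and the support in the score
    column. The TSV form round-trips through :func:`read_region_table`.
    """
    path = Path(path)
    if format == "bed":
        with open(path, "w") as fh:
            for r in regions:
                start, end = probe_map.genomic_span(r.ext_start, r.ext_end)
                name = f"{r.kind}:{r.chrom}:{r.core_start}-{r.core_end}"
                fh.write(f"{r.chrom}\t{start}\t{end}\t{name}\t{r.max_support}\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown region table format {format!r}")
    rows = []
    for r in regions:
        start, end = probe_map.genomic_span(r.ext_start, r.ext_end)
        rows.append({
            "kind": r.kind, "chrom": r.chrom,
            "core_start_probe": probe_map.probe_ids[r.core_start],
            "core_end_probe": probe_map.probe_ids[r.core_end],
            "ext_start_probe": probe_map.probe_ids[r.ext_start],
            "ext_end_probe": probe_map.probe_ids[r.ext_end],
            "start_bp": start, "end_bp": end,
            "max_support": r.max_support,
            "members": ",".join(sorted(r.members)),
        })
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_region_table(path: str | Path, probe_map: ProbeMap):
    """Read back a TSV region table written by :func:`write_region_table`."""
    from .recurrence import RecurrentRegion  # local import: avoid cycle

    df = pd.read_csv(path, sep="\t", dtype={"members": object})
    regions = []
    for _, r in df.iterrows():
        members = (frozenset(str(r["members"]).split(","))
                   if pd.notna(r["members"]) and str(r["members"]) else frozenset())
        regions.append(RecurrentRegion(
            kind=r["kind"], chrom=r["chrom"],
            core_start=probe_map.index_of(r["core_start_probe"]),
            core_end=probe_map.index_of(r["core_end_probe"]),
            ext_start=probe_map.index_of(r["ext_start_probe"]),
            ext_end=probe_map.index_of(r["ext_end_probe"]),
            max_support=int(r["max_support"]), members=members))
    return regions


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Genes/features x samples matrix with the feature id in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_mutation_table(path: str | Path,
                        panel: Sequence[str] | None = None) -> pd.DataFrame:
    """Long-form mutation calls: sample_id, gene, status in {wildtype, mutated}."""
    df = pd.read_csv(path, sep="\t", dtype=object)
    required = {"sample_id", "gene", "status"}
    if not required <= set(df.columns):
        raise ValueError(f"mutation table needs columns {sorted(required)}")
    bad_status = set(df["status"]) - {"wildtype", "mutated"}
    if bad_status:
        raise ValueError(f"unknown mutation status values: {sorted(bad_status)}")
    if panel is not None:
        off = set(df["gene"]) - set(panel)
        if off:
            raise ValueError(f"genes outside configured panel: {sorted(off)}")
    if df.duplicated(subset=["sample_id", "gene"]).any():
        r = df[df.duplicated(subset=["sample_id", "gene"])].iloc[0]
        raise ValueError(f"duplicate mutation row: {r['sample_id']}/{r['gene']}")
    return df


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Clinical records: sample_id, stage, grade, followup_months, dss_event."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "stage", "grade", "followup_months", "dss_event"}
    if not required <= set(df.columns):
        raise ValueError(f"clinical table needs columns {sorted(required)}")
    if (df["followup_months"] < 0).any():
        raise ValueError("negative follow-up time")
    df["dss_event"] = df["dss_event"].astype(bool)
    return df
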