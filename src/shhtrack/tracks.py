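"""Single-cell track containers and plain-text table I/O.

A *track* is one cell followed through a timelapse: time in hours post
fertilization (hpf), 3D position (LMDV = lateral-medial/dorsal-ventral
patterning-axis distance from the midline, AP = anterior-posterior, z =
depth, all in micrometres), per-channel fluorescence intensity (arbitrary
units) and the fraction of saturated pixels inside the segmented sphere.
Tracks carry a fate label from a closed vocabulary and a region tag.

Tables are long-format CSV/TSV, one row per cell per time point, with
channels as suffixed columns (``intensity_response``, ``sat_frac_response``,
...). Time is always float hours (hpf).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Acquisition channels: the signalling-response reporter, the fate reporter,
#: and the ubiquitous tracking label.
CHANNELS = ("response", "fate", "tracking")

#: Closed fate vocabulary, ventral to dorsal (plus the fallback label).
FATES = ("MFP", "LFP", "pMN", "dorsal", "unknown")

#: Ordering used wherever fates must be ranked along the patterning axis.
FATE_ORDER_VENTRAL_TO_DORSAL = ("MFP", "LFP", "pMN", "dorsal")

_MANDATORY_COLUMNS = ("cell_id", "t", "pos_lmdv", "pos_ap")


class SchemaError(ValueError):
    """A mandatory column is missing or malformed."""


class DuplicateRecordError(ValueError):
    """Two records share the same (cell_id, t)."""


class ValidationError(ValueError):
    """A field violates a track invariant."""


@dataclass
class Track:
    """One cell's time-ordered records plus its fate and region labels.

    Records are stored column-wise: ``t`` and the position arrays share one
    length-n grid; ``intensity`` / ``sat_frac`` / ``mask`` map channel name to
    a length-n array. ``mask[ch]`` is True where a record is excluded from
    analysis for that channel (e.g. saturated); masked records stay in the
    table.
    """

    cell_id: str
    t: np.ndarray
    pos_lmdv: np.ndarray
    pos_ap: np.ndarray
    pos_z: np.ndarray
    intensity: dict[str, np.ndarray]
    sat_frac: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] = field(default_factory=dict)
    fate: str = "unknown"
    region: str = ""
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size < 2:
            raise ValidationError(f"track {self.cell_id}: needs >=2 records")
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError(f"track {self.cell_id}: t not strictly increasing")
        for name in ("pos_lmdv", "pos_ap", "pos_z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValidationError(f"track {self.cell_id}: {name} length mismatch")
            setattr(self, name, arr)
        for ch, arr in self.intensity.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.t.shape:
                raise ValidationError(f"track {self.cell_id}: intensity[{ch}] length mismatch")
            if np.any(arr < 0):
                raise ValidationError(f"track {self.cell_id}: negative intensity[{ch}]")
            self.intensity[ch] = arr
        for ch, arr in self.sat_frac.items():
            arr = np.asarray(arr, dtype=float)
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError(f"track {self.cell_id}: sat_frac[{ch}] outside [0,1]")
            self.sat_frac[ch] = arr
        for ch in self.intensity:
            if ch not in self.mask:
                self.mask[ch] = np.zeros(self.t.shape, dtype=bool)
        if self.fate not in FATES:
            raise ValidationError(f"track {self.cell_id}: fate {self.fate!r} not in {FATES}")

    @property
    def n_records(self) -> int:
        return self.t.size

    def copy(self) -> "Track":
        return replace(
            self,
            t=self.t.copy(),
            pos_lmdv=self.pos_lmdv.copy(),
            pos_ap=self.pos_ap.copy(),
            pos_z=self.pos_z.copy(),
            intensity={ch: a.copy() for ch, a in self.intensity.items()},
            sat_frac={ch: a.copy() for ch, a in self.sat_frac.items()},
            mask={ch: a.copy() for ch, a in self.mask.items()},
        )


@dataclass
class Cohort:
    """A set of tracks from one (or more pooled) timelapse dataset(s)."""

    tracks: list[Track]
    sampling_interval: float = 6.0  # minutes
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be > 0")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def interval_hr(self) -> float:
        return self.sampling_interval / 60.0

    def copy(self) -> "Cohort":
        return Cohort([tr.copy() for tr in self.tracks], self.sampling_interval, dict(self.metadata))


def _normalize_header(columns) -> dict[str, str]:
    return {c.lower().strip(): c for c in columns}


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Flatten a cohort into the long-format table (one row per record)."""
    rows = []
    for tr in cohort.tracks:
        d = {
            "cell_id": np.repeat(tr.cell_id, tr.n_records),
            "t": tr.t,
            "pos_lmdv": tr.pos_lmdv,
            "pos_ap": tr.pos_ap,
            "pos_z": tr.pos_z,
        }
        for ch in CHANNELS:
            if ch in tr.intensity:
                d[f"intensity_{ch}"] = tr.intensity[ch]
                d[f"sat_frac_{ch}"] = tr.sat_frac.get(ch, np.zeros(tr.n_records))
                d[f"mask_{ch}"] = tr.mask[ch].astype(int)
        d["fate"] = np.repeat(tr.fate, tr.n_records)
        d["region"] = np.repeat(tr.region, tr.n_records)
        d["dataset_id"] = np.repeat(tr.dataset_id, tr.n_records)
        rows.append(pd.DataFrame(d))
    if not rows:
        cols = list(_MANDATORY_COLUMNS) + ["pos_z"]
        for ch in CHANNELS:
            cols += [f"intensity_{ch}", f"sat_frac_{ch}", f"mask_{ch}"]
        cols += ["fate", "region", "dataset_id"]
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)


def frame_to_cohort(df: pd.DataFrame, sampling_interval: float = 6.0) -> Cohort:
    """Group a long-format table into validated tracks (sorted by t)."""
    header = _normalize_header(df.columns)
    for col in _MANDATORY_COLUMNS:
        if col not in header:
            raise SchemaError(f"missing mandatory column: {col}")
    df = df.rename(columns={v: k for k, v in header.items()})

    channels = [ch for ch in CHANNELS if f"intensity_{ch}" in df.columns]
    for ch in channels:
        if f"sat_frac_{ch}" not in df.columns:
            warnings.warn(f"sat_frac_{ch} missing; treating as 0", stacklevel=2)
            df[f"sat_frac_{ch}"] = 0.0
        df[f"sat_frac_{ch}"] = df[f"sat_frac_{ch}"].fillna(0.0)
    if "pos_z" not in df.columns:
        df["pos_z"] = 0.0
    for col, default in (("fate", "unknown"), ("region", ""), ("dataset_id", "")):
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].fillna(default)

    bad_fates = sorted(set(df["fate"]) - set(FATES))
    if bad_fates:
        logger.warning("unknown fate labels mapped to 'unknown': %s", bad_fates)
        df.loc[df["fate"].isin(bad_fates), "fate"] = "unknown"

    tracks = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("t")
        tvals = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(tvals) == 0):
            raise DuplicateRecordError(f"duplicate (cell_id, t) records for cell {cell_id}")
        intensity = {ch: grp[f"intensity_{ch}"].to_numpy(dtype=float) for ch in channels}
        sat = {ch: grp[f"sat_frac_{ch}"].to_numpy(dtype=float) for ch in channels}
        mask = {}
        for ch in channels:
            col = f"mask_{ch}"
            if col in grp.columns:
                mask[ch] = grp[col].to_numpy().astype(bool)
        tracks.append(
            Track(
                cell_id=str(cell_id),
                t=tvals,
                pos_lmdv=grp["pos_lmdv"].to_numpy(dtype=float),
                pos_ap=grp["pos_ap"].to_numpy(dtype=float),
                pos_z=grp["pos_z"].to_numpy(dtype=float),
                intensity=intensity,
                sat_frac=sat,
                mask=mask,
                fate=str(grp["fate"].iloc[0]),
                region=str(grp["region"].iloc[0]),
                dataset_id=str(grp["dataset_id"].iloc[0]),
            )
        )
    return Cohort(tracks, sampling_interval=sampling_interval)


def read_track_table(path, dialect: str = "csv", sampling_interval: float = 6.0) -> Cohort:
    """Read a CSV/TSV track table into a validated :class:`Cohort`.

    Header matching is case-insensitive. Rows are grouped by ``cell_id`` and
    sorted by ``t``; unknown fate strings map to ``"unknown"`` with a logged
    warning; a missing ``sat_frac_*`` column is treated as zero with a warning.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep)
    return frame_to_cohort(df, sampling_interval=sampling_interval)


def write_track_table(cohort: Cohort, path, dialect: str = "csv") -> None:
    """Write a cohort as a long-format table read_track_table round-trips."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    cohort_to_frame(cohort).to_csv(path, sep=sep, index=False)


@dataclass
class FateRuleConfig:
    """Rule-based fate assignment from end-stage position and fate reporter.

    Intended for synthetic cohorts and smoke tests; real labels come from
    manual curation and are never overwritten unless ``force``.

    Bands are in micrometres of |LMDV| at ``reference_time`` (hpf): medial
    floor plate inside ``mfp_max``, lateral floor plate inside ``lfp_max``;
    beyond that, fate-reporter-positive cells are motor-neuron progenitors
    and cells past ``dorsal_frac`` of the ventral-dorsal extent are dorsal.
    """

    reference_time: float = 16.0
    mfp_max: float = 4.5
    lfp_max: float = 12.0
    dorsal_frac: float = 0.4
    vd_extent: float = 60.0
    fate_intensity_threshold: float = 3.0
    time_tolerance: float = 0.25  # max distance (hr) to the nearest sample


def _fate_at_reference(track: Track, rules: FateRuleConfig) -> str:
    idx = int(np.argmin(np.abs(track.t - rules.reference_time)))
    if abs(track.t[idx] - rules.reference_time) > rules.time_tolerance:
        return "unknown"
    lmdv = abs(track.pos_lmdv[idx])
    fate_int = track.intensity.get("fate", np.zeros(track.n_records))[idx]
    fate_positive = fate_int > rules.fate_intensity_threshold
    if lmdv <= rules.mfp_max:
        return "MFP"
    if lmdv <= rules.lfp_max:
        return "LFP"
    if fate_positive:
        return "pMN"
    if lmdv > rules.dorsal_frac * rules.vd_extent:
        return "dorsal"
    return "unknown"


def assign_fates_rulebased(
    cohort: Cohort, rules: FateRuleConfig | None = None, force: bool = False
) -> Cohort:
    """Assign fates by position bands at the reference time plus fate-reporter
    positivity. Existing non-"unknown" labels are kept unless ``force``."""
    rules = rules or FateRuleConfig()
    out = cohort.copy()
    for tr in out.tracks:
        if tr.fate != "unknown" and not force:
            continue
        tr.fate = _fate_at_reference(tr, rules)
    return out
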