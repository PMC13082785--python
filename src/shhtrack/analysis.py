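"""Cohort-level track analysis.

Fate-averaged traces, onset re-alignment of activity traces, K-means
clustering of reporter trajectories with coverage filters, and per-cell
response/position metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .activity import ActivityTrace
from .tracks import Cohort, Track

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fate-averaged traces


def average_by_fate(cohort: Cohort, channel: str = "response") -> dict[str, pd.DataFrame]:
    """Pointwise mean +/- SD intensity per fate.

    At each grid time the statistics run over the tracks with an unmasked
    observation there; n is reported per time point. SD uses divisor n-1
    (0 when n == 1).
    """
    grids: dict[str, dict[float, list[float]]] = {}
    for tr in cohort:
        if channel not in tr.intensity:
            continue
        ok = ~tr.mask[channel]
        for t, v in zip(tr.t[ok], tr.intensity[channel][ok]):
            grids.setdefault(tr.fate, {}).setdefault(round(float(t), 9), []).append(float(v))
    out = {}
    for fate, per_t in grids.items():
        ts = sorted(per_t)
        mean = [np.mean(per_t[t]) for t in ts]
        sd = [np.std(per_t[t], ddof=1) if len(per_t[t]) > 1 else 0.0 for t in ts]
        n = [len(per_t[t]) for t in ts]
        out[fate] = pd.DataFrame({"t": ts, "mean": mean, "sd": sd, "n": n})
    return out


# ---------------------------------------------------------------------------
# onset re-alignment


def realign_by_onset(traces: list[ActivityTrace]) -> list[ActivityTrace]:
    """Shift each trace's time axis so its detected onset is 0 (relative
    hours from onset). Traces without a detected onset are excluded and
    counted in the log."""
    aligned, skipped = [], 0
    for tr in traces:
        if tr.onset_time is None:
            skipped += 1
            continue
        new = tr.copy()
        new.x_norm = None if tr.x_norm is None else tr.x_norm.copy()
        new.t = tr.t - tr.onset_time
        new.onset_time = 0.0
        aligned.append(new)
    if skipped:
        logger.info("realign_by_onset: %d trace(s) without onset excluded", skipped)
    return aligned


def cross_cell_sd(
    traces: list[ActivityTrace],
    use_norm: bool = True,
    min_frac: float = 0.8,
    decimals: int = 6,
) -> float:
    """Mean across time of the cross-cell SD of activity, restricted to time
    points covered by at least ``min_frac`` of the traces (matched coverage),
    SD divisor n-1. Works on absolute or onset-relative grids."""
    per_t: dict[float, list[float]] = {}
    for tr in traces:
        vals = tr.x_norm if (use_norm and tr.x_norm is not None) else tr.x_raw
        for t, v in zip(np.round(tr.t, decimals), vals):
            per_t.setdefault(float(t), []).append(float(v))
    need = min_frac * len(traces)
    sds = [np.std(v, ddof=1) for v in per_t.values() if len(v) >= need and len(v) > 1]
    if not sds:
        raise ValueError("no time points with sufficient coverage")
    return float(np.mean(sds))


# ---------------------------------------------------------------------------
# K-means clustering with coverage filters


@dataclass
class ClusterResult:
    k: int
    assignments: dict[str, int]  # cell_id -> cluster
    centroids: np.ndarray
    wcss_curve: dict[int, float]
    grid: np.ndarray  # common (truncated) time grid
    included: list[str]
    excluded: dict[str, str]  # cell_id -> reason
    fate_contribution: pd.DataFrame | None = None


def _coverage_filter(cohort: Cohort, channel: str, coverage: float):
    """Apply the two coverage rules: keep time points observed by more than
    ``coverage`` of the traces, then keep tracks observed at more than
    ``coverage`` of the kept time points."""
    times = sorted({round(float(t), 9) for tr in cohort for t in tr.t})
    times = np.asarray(times)
    counts = np.zeros(times.size)
    obs: dict[str, dict[float, float]] = {}
    for tr in cohort:
        ok = ~tr.mask[channel]
        d = {round(float(t), 9): float(v) for t, v in zip(tr.t[ok], tr.intensity[channel][ok])}
        obs[tr.cell_id] = d
        counts += np.isin(times, list(d)).astype(float)
    keep_t = times[counts > coverage * len(cohort.tracks)]
    included, excluded = [], {}
    for tr in cohort:
        n_obs = sum(1 for t in keep_t if t in obs[tr.cell_id])
        if n_obs > coverage * keep_t.size:
            included.append(tr.cell_id)
        else:
            excluded[tr.cell_id] = (
                f"coverage {n_obs}/{keep_t.size} <= {coverage:.0%} of truncated grid"
            )
    return keep_t, obs, included, excluded


def fate_contribution_matrix(assignments: dict[str, int], fates: dict[str, str], k: int) -> pd.DataFrame:
    """Rows = fates, columns = clusters; each row holds, for that fate, the
    fraction of its cells falling in each cluster (rows sum to 1)."""
    fate_names = sorted({fates[c] for c in assignments})
    mat = np.zeros((len(fate_names), k))
    for cell, cl in assignments.items():
        mat[fate_names.index(fates[cell]), cl] += 1
    sums = mat.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1
    return pd.DataFrame(mat / sums, index=fate_names, columns=[f"cluster_{i}" for i in range(k)])


def cluster_tracks(
    cohort: Cohort,
    channel: str = "response",
    k_range=range(5, 26),
    k_override: int | None = None,
    coverage: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
    standardize: bool = False,
) -> ClusterResult:
    """K-means clustering of reporter trajectories.

    Tracks are truncated to the time points observed by >``coverage`` of
    traces; tracks observed at >``coverage`` of the remaining points are
    included and their missing points filled by linear interpolation. WCSS
    (inertia) is computed over ``k_range``; the elbow is the k with the
    largest positive second difference of WCSS, overridable to a fixed k.
    Input order is canonicalized by cell_id before seeding, so the result is
    permutation-invariant.
    """
    keep_t, obs, included, excluded = _coverage_filter(cohort, channel, coverage)
    included = sorted(included)
    if not included:
        raise ValueError("no tracks pass the coverage filters")
    X = np.empty((len(included), keep_t.size))
    for i, cell in enumerate(included):
        d = obs[cell]
        have = np.array(sorted(d))
        X[i] = np.interp(keep_t, have, [d[t] for t in have])
    if standardize:
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)

    ks = [k for k in k_range if k <= len(included)]
    if not ks and k_override is None:
        raise ValueError(f"k_range {list(k_range)} exceeds n_tracks {len(included)}")
    wcss = {}
    models = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(X)
        wcss[k] = float(km.inertia_)
        models[k] = km
    if k_override is not None:
        k_best = k_override
        if k_best not in models:
            if k_best > len(included):
                raise ValueError(f"k={k_best} exceeds n_tracks {len(included)}")
            km = KMeans(n_clusters=k_best, n_init=n_init, random_state=seed)
            km.fit(X)
            models[k_best] = km
            wcss.setdefault(k_best, float(km.inertia_))
    elif len(ks) >= 3:
        curve = np.array([wcss[k] for k in ks])
        d2 = curve[:-2] - 2 * curve[1:-1] + curve[2:]
        k_best = ks[1 + int(np.argmax(d2))]
    else:
        k_best = ks[-1]
    km = models[k_best]
    assignments = {cell: int(lbl) for cell, lbl in zip(included, km.labels_)}
    fates = {tr.cell_id: tr.fate for tr in cohort}
    return ClusterResult(
        k=k_best,
        assignments=assignments,
        centroids=km.cluster_centers_,
        wcss_curve=wcss,
        grid=keep_t,
        included=included,
        excluded=excluded,
        fate_contribution=fate_contribution_matrix(assignments, fates, k_best),
    )


# ---------------------------------------------------------------------------
# per-cell metrics


@dataclass
class ResponseMetrics:
    """Per-cell summaries of inferred promoter activity and position."""

    cell_id: str
    fate: str = "unknown"
    region: str = ""
    max_response: float | None = None  # peak x in window, AU/hr^2
    avg_response: float | None = None  # mean x in window
    response_time: float | None = None  # total hours with x > on-threshold
    lmdv_early: float | None = None  # um at the early query time
    lmdv_late: float | None = None
    ap_early: float | None = None
    ap_late: float | None = None
    speed_early: float | None = None  # um/hr, path length over 2-hr window
    speed_late: float | None = None
    speed_net_early: float | None = None  # um/hr, net displacement variant
    speed_net_late: float | None = None


def compute_response_metrics(
    trace: ActivityTrace,
    window: tuple[float, float] = (10.0, 15.0),
    on_threshold: float = 0.05,
    interval_hr: float = 0.1,
    min_points: int = 5,
) -> ResponseMetrics:
    """Window peak, window mean, and total supra-threshold time of x_raw.

    Response time counts every point with x above the on-threshold times the
    sampling interval, so multiple disjoint supra-threshold runs all count.
    Metrics are left missing when fewer than ``min_points`` fall in the
    window.
    """
    out = ResponseMetrics(trace.cell_id, trace.fate, trace.region)
    sel = (trace.t >= window[0]) & (trace.t <= window[1])
    if sel.sum() < min_points:
        return out
    x = trace.x_raw[sel]
    out.max_response = float(np.max(x))
    out.avg_response = float(np.mean(x))
    out.response_time = float(np.sum(x > on_threshold) * interval_hr)
    return out


def _nearest_index(t: np.ndarray, q: float, tol: float):
    i = int(np.argmin(np.abs(t - q)))
    return i if abs(t[i] - q) <= tol else None


def compute_position_metrics(
    track: Track,
    metrics: ResponseMetrics | None = None,
    early: float = 11.5,
    late: float = 14.5,
    half_window: float = 1.0,
    tol: float = 0.25,
) -> ResponseMetrics:
    """LMDV/AP positions at the query times (nearest sample within ``tol``
    hours) and speeds over 2-hr windows centered on them.

    Speed is path length (sum of 3D step displacements) divided by the
    window duration; the net-displacement variant is reported alongside.
    """
    out = metrics or ResponseMetrics(track.cell_id, track.fate, track.region)
    pos = np.column_stack([track.pos_lmdv, track.pos_ap, track.pos_z])
    for name, q in (("early", early), ("late", late)):
        i = _nearest_index(track.t, q, tol)
        if i is not None:
            setattr(out, f"lmdv_{name}", float(track.pos_lmdv[i]))
            setattr(out, f"ap_{name}", float(track.pos_ap[i]))
        lo, hi = q - half_window, q + half_window
        sel = (track.t >= lo - 1e-9) & (track.t <= hi + 1e-9)
        if sel.sum() >= 2 and track.t[sel][0] <= lo + tol and track.t[sel][-1] >= hi - tol:
            pw = pos[sel]
            steps = np.linalg.norm(np.diff(pw, axis=0), axis=1)
            span = float(track.t[sel][-1] - track.t[sel][0])
            setattr(out, f"speed_{name}", float(steps.sum() / span))
            setattr(out, f"speed_net_{name}", float(np.linalg.norm(pw[-1] - pw[0]) / span))
    return out


def response_metrics_table(
    cohort: Cohort,
    traces: list[ActivityTrace],
    window: tuple[float, float] = (10.0, 15.0),
    on_threshold: float = 0.05,
) -> pd.DataFrame:
    """Combined response + position metrics, one row per cell."""
    by_id = {tr.cell_id: tr for tr in cohort}
    rows = []
    for trace in traces:
        m = compute_response_metrics(
            trace, window, on_threshold, interval_hr=cohort.interval_hr
        )
        track = by_id.get(trace.cell_id)
        if track is not None:
            m = compute_position_metrics(track, m)
        rows.append(vars(m))
    return pd.DataFrame(rows)
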