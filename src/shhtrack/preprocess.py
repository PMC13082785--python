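"""Intensity-correction chain for raw tracks.

Fixed order: saturation masking -> bleed-through subtraction -> moving-average
smoothing -> trimming to the analysis window. Each step returns a new Track;
masked records are retained in the table but excluded downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tracks import Cohort, Track

logger = logging.getLogger(__name__)


class EstimationError(ValueError):
    """Not enough data to estimate a correction parameter."""


class DegenerateInputError(ValueError):
    """Input too short/empty for the requested operation."""


def saturation_mask(track: Track, channel: str = "response", max_frac: float = 0.05) -> Track:
    """Mask records whose saturated-pixel fraction *exceeds* ``max_frac``.

    The inequality is strict: a record at exactly the limit is kept.
    """
    out = track.copy()
    sat = out.sat_frac.get(channel)
    if sat is None:
        return out
    out.mask[channel] = out.mask[channel] | (sat > max_frac)
    return out


def estimate_bleedthrough(
    cohort: Cohort,
    from_channel: str = "fate",
    to_channel: str = "response",
    min_records: int = 50,
    basal_quantile: float = 0.25,
    n_iter: int = 5,
) -> float:
    """Estimate the bleed-through ratio rho of ``from_channel`` into
    ``to_channel`` from all unmasked records of a dataset.

    The recipient channel mixes intrinsic signal, a constant background
    floor, and ``rho`` times the donor. The estimator iterates: restrict to
    records whose donor-corrected recipient signal sits in the lowest
    ``basal_quantile`` (cells/times where the recipient reporter is basal),
    then fit a robust Theil-Sen line of recipient on donor over that subset;
    the intercept absorbs the background floor and the slope estimates rho.
    """
    xs, ys = [], []
    for tr in cohort:
        if from_channel not in tr.intensity or to_channel not in tr.intensity:
            continue
        ok = ~(tr.mask[from_channel] | tr.mask[to_channel])
        xs.append(tr.intensity[from_channel][ok])
        ys.append(tr.intensity[to_channel][ok])
    if not xs:
        raise EstimationError("no records with both channels")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < min_records:
        raise EstimationError(f"need >= {min_records} unmasked records, got {x.size}")
    if np.allclose(x, x[0]):
        raise EstimationError("donor channel has no dynamic range")

    rho = 0.0
    for _ in range(n_iter):
        resid = y - rho * x
        cut = np.quantile(resid, basal_quantile)
        sel = resid <= cut
        if sel.sum() < 10 or np.ptp(x[sel]) == 0:
            sel = np.ones_like(sel)
        res = stats.theilslopes(y[sel], x[sel])
        rho = float(np.clip(res.slope, 0.0, 0.999))
    return rho


def correct_bleedthrough(
    track: Track,
    rho: float,
    from_channel: str = "fate",
    to_channel: str = "response",
) -> Track:
    """Subtract ``rho * from_channel`` from ``to_channel``, clipping at 0."""
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    out = track.copy()
    out.intensity[to_channel] = np.maximum(
        out.intensity[to_channel] - rho * out.intensity[from_channel], 0.0
    )
    return out


def _moving_average_masked(values: np.ndarray, good: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated edges; masked points shrink the
    window (no interpolation). Masked positions keep their raw value."""
    n = values.size
    half_lo = (window - 1) // 2
    half_hi = window // 2
    out = values.copy()
    v = np.where(good, values, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cn = np.concatenate([[0], np.cumsum(good.astype(int))])
    for i in range(n):
        if not good[i]:
            continue
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi + 1)
        cnt = cn[hi] - cn[lo]
        if cnt:
            out[i] = (cs[hi] - cs[lo]) / cnt
    return out


def smooth_track(
    track: Track,
    window: int = 6,
    iterations: int = 1,
    channels=None,
) -> Track:
    """Moving-average smoothing of the intensity channels.

    Centered window, applied ``iterations`` times; edges use shrunken
    (truncated) windows; masked points are excluded from window means and
    shrink the window rather than being interpolated.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > track.n_records:
        raise DegenerateInputError(
            f"window {window} exceeds track length {track.n_records}"
        )
    out = track.copy()
    if window == 1:
        return out
    for ch in channels or list(out.intensity):
        good = ~out.mask[ch]
        vals = out.intensity[ch]
        for _ in range(iterations):
            vals = _moving_average_masked(vals, good, window)
        out.intensity[ch] = vals
    return out


def trim_window(track: Track, start: float = 10.0, end: float = 15.0) -> Track | None:
    """Retain records with ``start <= t <= end``; None (with a warning) if
    nothing remains or fewer than 2 records survive."""
    if start >= end:
        raise ValueError("start must be < end")
    keep = (track.t >= start) & (track.t <= end)
    if keep.sum() < 2:
        warnings.warn(
            f"track {track.cell_id} has no records in [{start}, {end}]; dropped",
            stacklevel=2,
        )
        return None
    out = track.copy()
    out.t = out.t[keep]
    out.pos_lmdv = out.pos_lmdv[keep]
    out.pos_ap = out.pos_ap[keep]
    out.pos_z = out.pos_z[keep]
    out.intensity = {ch: a[keep] for ch, a in out.intensity.items()}
    out.sat_frac = {ch: a[keep] for ch, a in out.sat_frac.items()}
    out.mask = {ch: a[keep] for ch, a in out.mask.items()}
    return out


@dataclass
class PreprocessParams:
    sat_max_frac: float = 0.05
    bleed_ratio: float | None = None  # None -> estimate from the cohort
    bleed_from: str = "fate"
    bleed_to: str = "response"
    smooth_window: int = 6
    smooth_iterations: int = 1
    window_start: float = 10.0
    window_end: float = 15.0


def preprocess_cohort(cohort: Cohort, params: PreprocessParams | None = None) -> Cohort:
    """Run the full chain on every track: mask -> bleed-through -> smooth ->
    trim. Tracks left empty by trimming are dropped (counted in metadata)."""
    params = params or PreprocessParams()
    masked = []
    for tr in cohort:
        out = tr
        for ch in tr.intensity:
            if ch in tr.sat_frac:
                out = saturation_mask(out, ch, params.sat_max_frac)
        masked.append(out)
    work = Cohort(masked, cohort.sampling_interval, dict(cohort.metadata))

    rho = params.bleed_ratio
    if rho is None:
        try:
            rho = estimate_bleedthrough(work, params.bleed_from, params.bleed_to)
        except EstimationError:
            logger.warning("bleed-through estimation failed; assuming rho=0")
            rho = 0.0

    processed = []
    dropped = 0
    for tr in work:
        if rho > 0 and params.bleed_from in tr.intensity and params.bleed_to in tr.intensity:
            tr = correct_bleedthrough(tr, rho, params.bleed_from, params.bleed_to)
        if params.smooth_window > 1 and params.smooth_window <= tr.n_records:
            tr = smooth_track(tr, params.smooth_window, params.smooth_iterations)
        tr = trim_window(tr, params.window_start, params.window_end)
        if tr is None:
            dropped += 1
            continue
        processed.append(tr)
    meta = dict(cohort.metadata)
    meta.update({"bleed_ratio": rho, "n_dropped_by_trim": dropped})
    return Cohort(processed, cohort.sampling_interval, meta)
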