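"""Promoter-activity inference and reporter mRNA half-life estimation.

For a stable fluorescent protein, intensity obeys dI/dt = c1*m and the
reporter mRNA obeys dm/dt = x - m*ln2/t_half, so the (scaled) promoter
activity can be read off the measured intensity directly:

    c*x(t) = I''(t) + I'(t) * ln2 / t_half

``infer_activity`` evaluates this on smoothed, uniformly sampled tracks with
finite differences. ``fit_halflife_heatshock`` estimates t_half from a pulse
experiment: after a transcription pulse ends, -ln(1 - I/I_max) is linear in
time with slope ln2/t_half.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .tracks import Cohort, Track

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


class ParameterError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class FitError(ValueError):
    pass


@dataclass
class ActivityTrace:
    """Inferred promoter activity of one cell.

    ``x_raw`` is c*x in AU/hr^2 on the interior grid (the first and last
    processed samples, where only one-sided difference stencils exist, are
    dropped). ``x_norm`` is ``x_raw`` scaled so the dataset-wide maximum is 1;
    it is None until :func:`normalize_activity` runs.
    """

    cell_id: str
    t: np.ndarray  # hpf (or hours from onset after re-alignment)
    x_raw: np.ndarray
    x_norm: np.ndarray | None = None
    onset_time: float | None = None
    fate: str = "unknown"
    region: str = ""

    @property
    def n(self) -> int:
        return self.t.size

    def copy(self) -> "ActivityTrace":
        return replace(
            self,
            t=self.t.copy(),
            x_raw=self.x_raw.copy(),
            x_norm=None if self.x_norm is None else self.x_norm.copy(),
        )


@dataclass
class HalfLifeFit:
    """Pulse-decay half-life fit: t_half = ln2 / slope."""

    slope: float  # hr^-1, pooled across cells
    t_half: float  # hr
    i_max: float  # mean plateau intensity, AU
    fit_range: tuple[float, float]  # time span of points used, hr
    r_squared: float  # pooled goodness of fit
    n_cells: int
    per_cell_slopes: np.ndarray


def _longest_unmasked_run(mask: np.ndarray) -> slice:
    best = slice(0, 0)
    start = None
    for i, bad in enumerate(np.concatenate([mask, [True]])):
        if not bad and start is None:
            start = i
        elif bad and start is not None:
            if i - start > best.stop - best.start:
                best = slice(start, i)
            start = None
    return best


def infer_activity(
    track: Track,
    channel: str = "response",
    t_half: float = 3.0,
    uniform_tol: float = 1e-3,
) -> ActivityTrace:
    """Invert a processed intensity track to a promoter-activity trace.

    Uses central differences for I' and I'' on the uniform sampling grid of
    the longest unmasked run (>=5 consecutive points required); the two
    boundary points, where only one-sided stencils exist, are excluded, so
    the returned grid covers the run's interior. Negative values of x are
    kept (no clipping).
    """
    if t_half <= 0:
        raise ParameterError("t_half must be > 0")
    run = _longest_unmasked_run(track.mask[channel])
    n = run.stop - run.start
    if n < 5:
        raise InsufficientDataError(
            f"track {track.cell_id}: needs >=5 consecutive unmasked points, got {n}"
        )
    t = track.t[run]
    I = track.intensity[channel][run]
    dt = np.diff(t)
    h = float(np.mean(dt))
    if np.any(np.abs(dt - h) > uniform_tol * h):
        raise ParameterError(
            f"track {track.cell_id}: non-uniform sampling; resample before inference"
        )
    d1 = np.empty(n)
    d1[1:-1] = (I[2:] - I[:-2]) / (2 * h)
    d1[0] = (-3 * I[0] + 4 * I[1] - I[2]) / (2 * h)
    d1[-1] = (3 * I[-1] - 4 * I[-2] + I[-3]) / (2 * h)
    d2 = np.empty(n)
    d2[1:-1] = (I[2:] - 2 * I[1:-1] + I[:-2]) / (h * h)
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    x = d2 + d1 * (LN2 / t_half)
    return ActivityTrace(
        cell_id=track.cell_id,
        t=t[1:-1].copy(),
        x_raw=x[1:-1],
        fate=track.fate,
        region=track.region,
    )


def normalize_activity(traces: list[ActivityTrace]) -> list[ActivityTrace]:
    """Scale all traces by the dataset-wide maximum of x_raw (max -> 1)."""
    if not traces:
        raise InsufficientDataError("no traces to normalize")
    peak = max(float(np.max(tr.x_raw)) for tr in traces)
    if peak <= 0:
        raise FitError("all activities non-positive; cannot normalize")
    out = []
    for tr in traces:
        new = tr.copy()
        new.x_norm = new.x_raw / peak
        out.append(new)
    return out


def detect_onset(
    trace: ActivityTrace,
    threshold: float = 0.025,
    persistence: int = 3,
) -> float | None:
    """First time point starting a run of >= ``persistence`` consecutive
    points with normalized activity above ``threshold``; None if absent."""
    if trace.x_norm is None:
        raise ParameterError("trace must be normalized before onset detection")
    above = trace.x_norm > threshold
    count = 0
    for i, a in enumerate(above):
        count = count + 1 if a else 0
        if count >= persistence:
            return float(trace.t[i - persistence + 1])
    return None


def attach_onsets(
    traces: list[ActivityTrace], threshold: float = 0.025, persistence: int = 3
) -> list[ActivityTrace]:
    out = []
    for tr in traces:
        new = tr.copy()
        new.x_norm = tr.x_norm
        new.onset_time = detect_onset(tr, threshold, persistence)
        out.append(new)
    return out


def fit_halflife_heatshock(
    cohort: Cohort,
    pulse_end: float = 0.5,
    channel: str = "response",
    imax_frac: float = 0.10,
    imax_rule=None,
    cut: float = 0.95,
    min_points: int = 5,
) -> HalfLifeFit:
    """Estimate mRNA half-life from a heat-shock pulse cohort.

    Per cell: the plateau I_max is ``imax_rule(I)`` (default: mean of the
    last ``imax_frac`` of time points); the transform y = -ln(1 - I/I_max) is
    evaluated from the pulse end up to the first time I/I_max reaches
    ``cut`` — near the plateau the transform amplifies small fluctuations,
    so the whole late portion is discarded; a least-squares line gives the
    per-cell slope. Slopes are pooled by mean; t_half = ln2/slope.
    """
    if imax_rule is None:
        def imax_rule(I):
            k = max(1, int(round(imax_frac * I.size)))
            return float(np.mean(I[-k:]))

    slopes, imaxes, rsq, tmin, tmax = [], [], [], np.inf, -np.inf
    for tr in cohort:
        I = tr.intensity[channel]
        i_max = imax_rule(I)
        if i_max <= 0:
            continue
        frac = I / i_max
        crossed = np.nonzero((tr.t >= pulse_end) & (frac >= cut))[0]
        t_stop = tr.t[crossed[0]] if crossed.size else np.inf
        sel = (tr.t >= pulse_end) & (tr.t < t_stop) & (frac >= 0) & (frac < 1)
        if sel.sum() < min_points:
            continue
        t = tr.t[sel]
        y = -np.log(1.0 - frac[sel])
        A = np.vstack([t, np.ones_like(t)]).T
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        slopes.append(coef[0])
        imaxes.append(i_max)
        sst = float(np.sum((y - y.mean()) ** 2))
        ssr = float(res[0]) if res.size else 0.0
        rsq.append(1.0 - ssr / sst if sst > 0 else 1.0)
        tmin, tmax = min(tmin, t[0]), max(tmax, t[-1])
    if len(slopes) == 0:
        raise InsufficientDataError("no track with >=5 usable transformed points")
    slope = float(np.mean(slopes))
    if slope <= 0:
        raise FitError(f"non-positive pooled slope {slope:.3g}; intensity is not saturating")
    return HalfLifeFit(
        slope=slope,
        t_half=LN2 / slope,
        i_max=float(np.mean(imaxes)),
        fit_range=(float(tmin), float(tmax)),
        r_squared=float(np.mean(rsq)),
        n_cells=len(slopes),
        per_cell_slopes=np.asarray(slopes),
    )
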