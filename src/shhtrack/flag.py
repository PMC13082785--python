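"""The "French flag" fate-prediction statistic.

Cells are ranked by a scalar metric (high to low, i.e. ventral to dorsal
along the expected response gradient) and partitioned by k-1 ordered
thresholds into bands, one per fate in ventral-to-dorsal order. The
thresholds are placed to maximize the fraction of cells whose fate matches
their band; that fraction (as a percentage) measures how sharply the metric
predicts fate. A permutation baseline (label shuffling) gives the chance
level.

The threshold search is exact: a dynamic program over cut positions finds
the global optimum of the ordinal banding (ties broken toward the most
balanced band sizes), equivalent to exhaustive enumeration of all ordered
cut placements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import FATE_ORDER_VENTRAL_TO_DORSAL


@dataclass
class FlagResult:
    metric: str
    ranked_cells: list[str]  # metric high -> low
    ranked_values: np.ndarray
    fate_order: list[str]  # ventral -> dorsal, i.e. along the ranking
    band_boundaries: list[int]  # k-1 cut positions in the ranking
    thresholds: list[float]  # metric values at the cuts
    predicted: dict[str, str]  # cell_id -> predicted fate
    accuracy: float  # percent correct, all cells
    pairwise_accuracy: dict[str, float]  # adjacent fate pairs, percent
    n_per_fate: dict[str, int]
    chance_mean: float | None = None  # permutation baseline, percent
    chance_sd: float | None = None


def _prefix_counts(band_idx: np.ndarray, n_bands: int) -> np.ndarray:
    """P[j, i] = number of cells with fate-band j among the first i ranked."""
    n = band_idx.size
    P = np.zeros((n_bands, n + 1), dtype=np.int64)
    for j in range(n_bands):
        P[j, 1:] = np.cumsum(band_idx == j)
    return P


def _best_accuracy(band_idx: np.ndarray, n_bands: int) -> int:
    """Maximum number of correct cells over all ordered cut placements
    (prefix-max dynamic program, O(k*n))."""
    P = _prefix_counts(band_idx, n_bands)
    dp = P[0].astype(np.int64)
    for j in range(1, n_bands):
        dp = np.maximum.accumulate(dp - P[j]) + P[j]
    return int(dp[-1])


def _fit_cuts(band_idx: np.ndarray, n_bands: int):
    """Optimal ordered cut positions; ties broken by minimal sum of squared
    band sizes (the most balanced placement). Returns (boundaries, correct)."""
    n = band_idx.size
    P = _prefix_counts(band_idx, n_bands)
    dp = P[0].astype(np.int64)
    cost = np.arange(n + 1, dtype=np.int64) ** 2  # band-size^2 so far
    back: list[np.ndarray] = []
    for j in range(1, n_bands):
        g = dp - P[j]
        new_dp = np.empty(n + 1, dtype=np.int64)
        new_cost = np.empty(n + 1, dtype=np.int64)
        bp = np.empty(n + 1, dtype=np.int64)
        for i in range(n + 1):
            seg = g[: i + 1]
            best = seg.max()
            cand = np.nonzero(seg == best)[0]
            sizes = (i - cand) ** 2
            tie = cost[cand] + sizes
            p = cand[int(np.argmin(tie))]
            new_dp[i] = best + P[j, i]
            new_cost[i] = cost[p] + (i - p) ** 2
            bp[i] = p
        dp, cost = new_dp, new_cost
        back.append(bp)
    bounds = []
    i = n
    for bp in reversed(back):
        i = int(bp[i])
        bounds.append(i)
    bounds.reverse()
    return bounds, int(dp[-1])


def _order_fates(present: set[str]) -> list[str]:
    ordered = [f for f in FATE_ORDER_VENTRAL_TO_DORSAL if f in present]
    extra = sorted(present - set(ordered))
    return ordered + extra


def fit_flag(
    values,
    fates,
    cell_ids=None,
    metric: str = "metric",
    fate_order: list[str] | None = None,
    min_per_fate: int = 2,
) -> FlagResult:
    """Rank cells by ``values`` (high -> low) and fit the ordinal fate bands.

    ``fate_order`` lists fates ventral-to-dorsal (i.e. expected metric
    high-to-low); by default the canonical order restricted to the fates
    present. Fates with fewer than ``min_per_fate`` cells are excluded with
    a warning. Accuracy is 100 * correct / n; adjacent-pair accuracies are
    computed the same way on each pair's subset.
    """
    values = np.asarray(values, dtype=float)
    fates = np.asarray(fates, dtype=object)
    if cell_ids is None:
        cell_ids = np.array([f"cell-{i}" for i in range(values.size)], dtype=object)
    else:
        cell_ids = np.asarray(cell_ids, dtype=object)

    counts = pd.Series(fates).value_counts()
    small = [f for f in counts.index if counts[f] < min_per_fate]
    if small:
        warnings.warn(f"fates with n < {min_per_fate} excluded: {small}", stacklevel=2)
        keep = ~np.isin(fates, small)
        values, fates, cell_ids = values[keep], fates[keep], cell_ids[keep]
    present = set(fates)
    if len(present) < 2:
        raise ValueError("need at least 2 fates with enough cells")
    order = fate_order or _order_fates(present)
    order = [f for f in order if f in present]

    rank = np.argsort(-values, kind="stable")
    rv, rf, rc = values[rank], fates[rank], cell_ids[rank]
    band_idx = np.array([order.index(f) for f in rf])
    bounds, correct = _fit_cuts(band_idx, len(order))

    n = rv.size
    predicted = {}
    edges = [0] + bounds + [n]
    for j, fate in enumerate(order):
        for i in range(edges[j], edges[j + 1]):
            predicted[str(rc[i])] = fate
    thresholds = []
    for b in bounds:
        if b == 0:
            thresholds.append(float(rv[0]))
        elif b == n:
            thresholds.append(float(rv[-1]))
        else:
            thresholds.append(float((rv[b - 1] + rv[b]) / 2))

    pairwise = {}
    for a, b in zip(order[:-1], order[1:]):
        sel = np.isin(rf, [a, b])
        sub = np.array([0 if f == a else 1 for f in rf[sel]])
        pairwise[f"{a}|{b}"] = 100.0 * _best_accuracy(sub, 2) / sub.size

    return FlagResult(
        metric=metric,
        ranked_cells=[str(c) for c in rc],
        ranked_values=rv,
        fate_order=order,
        band_boundaries=bounds,
        thresholds=thresholds,
        predicted=predicted,
        accuracy=100.0 * correct / n,
        pairwise_accuracy=pairwise,
        n_per_fate={f: int(counts[f]) for f in order},
    )


def permutation_baseline(
    values,
    fates,
    n_perm: int = 1000,
    seed: int = 0,
    fate_order: list[str] | None = None,
):
    """Chance level of the flag accuracy: shuffle fate labels ``n_perm``
    times, refit the thresholds, and summarize the accuracy distribution.
    Deterministic per seed. Returns (mean, sd) in percent."""
    values = np.asarray(values, dtype=float)
    fates = np.asarray(fates, dtype=object)
    order = fate_order or _order_fates(set(fates))
    rank = np.argsort(-values, kind="stable")
    band_idx = np.array([order.index(f) for f in fates[rank]])
    rng = np.random.default_rng(seed)
    n = band_idx.size
    accs = np.empty(n_perm)
    for p in range(n_perm):
        accs[p] = 100.0 * _best_accuracy(rng.permutation(band_idx), len(order)) / n
    return float(accs.mean()), float(accs.std(ddof=1))


def flag_with_baseline(
    values, fates, cell_ids=None, metric="metric", n_perm=1000, seed=0
) -> FlagResult:
    res = fit_flag(values, fates, cell_ids, metric=metric)
    mean, sd = permutation_baseline(values, fates, n_perm=n_perm, seed=seed)
    res.chance_mean, res.chance_sd = mean, sd
    return res


RESPONSE_METRICS = ("max_response", "avg_response", "response_time")
POSITION_METRICS = ("lmdv_late", "ap_late")
#: metrics where LOW values are ventral (ranking must be inverted)
INVERTED_METRICS = {"lmdv_early", "lmdv_late"}


def compare_metrics(
    metrics_table: pd.DataFrame,
    metric_names=RESPONSE_METRICS,
    group_col: str = "region",
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag accuracy per metric per group (e.g. anterior vs posterior), with
    the permutation chance baseline alongside."""
    rows = []
    for group, grp in metrics_table.groupby(group_col):
        for name in metric_names:
            sub = grp.dropna(subset=[name])
            vals = sub[name].to_numpy(dtype=float)
            if name in INVERTED_METRICS:
                vals = -vals
            res = flag_with_baseline(
                vals,
                sub["fate"].to_numpy(),
                sub["cell_id"].to_numpy(),
                metric=name,
                n_perm=n_perm,
                seed=seed,
            )
            rows.append(
                {
                    group_col: group,
                    "metric": name,
                    "n": len(sub),
                    "accuracy_pct": res.accuracy,
                    "chance_mean_pct": res.chance_mean,
                    "chance_sd_pct": res.chance_sd,
                    **{f"pair_{k}": v for k, v in res.pairwise_accuracy.items()},
                }
            )
    return pd.DataFrame(rows)


def robustness_sweep(
    cohort_raw,
    t_half_values=(1.0, 2.0, 3.0, 4.0, 5.0),
    smooth_windows=(3, 6, 9),
    smooth_iterations=(1,),
    metric_names=RESPONSE_METRICS,
    on_threshold: float = 0.05,
    window: tuple[float, float] = (10.0, 15.0),
) -> pd.DataFrame:
    """Re-run preprocess -> inference -> metrics -> flag over a grid of
    assumed mRNA half-life and smoothing parameters; returns a tidy table of
    accuracies so the stability of metric rankings can be assessed."""
    from .activity import infer_activity, normalize_activity
    from .analysis import response_metrics_table
    from .preprocess import PreprocessParams, preprocess_cohort

    rows = []
    for w in smooth_windows:
        for it in smooth_iterations:
            params = PreprocessParams(
                smooth_window=w,
                smooth_iterations=it,
                window_start=window[0],
                window_end=window[1],
            )
            processed = preprocess_cohort(cohort_raw, params)
            for th in t_half_values:
                traces = [infer_activity(tr, t_half=th) for tr in processed]
                traces = normalize_activity(traces)
                table = response_metrics_table(
                    processed, traces, window=window, on_threshold=on_threshold
                )
                for name in metric_names:
                    sub = table.dropna(subset=[name])
                    res = fit_flag(
                        sub[name].to_numpy(dtype=float),
                        sub["fate"].to_numpy(),
                        sub["cell_id"].to_numpy(),
                        metric=name,
                    )
                    rows.append(
                        {
                            "t_half": th,
                            "smooth_window": w,
                            "smooth_iterations": it,
                            "metric": name,
                            "accuracy_pct": res.accuracy,
                        }
                    )
    return pd.DataFrame(rows)
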