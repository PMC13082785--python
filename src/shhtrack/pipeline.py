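"""End-to-end pipeline: simulate/load -> preprocess -> infer -> metrics ->
cluster -> flag, with a YAML config, provenance logging and fixed seeds."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .activity import attach_onsets, fit_halflife_heatshock, infer_activity, normalize_activity
from .analysis import average_by_fate, cluster_tracks, response_metrics_table
from .flag import RESPONSE_METRICS, compare_metrics
from .preprocess import PreprocessParams, preprocess_cohort
from .simulate import PRESETS, generate_heatshock_dataset, heatshock_preset
from .tracks import read_track_table, write_track_table

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved on disk."""


@dataclass
class PipelineConfig:
    """All knobs of the analysis chain, with the defaults used throughout."""

    input_path: str | None = None  # track table; exclusive with preset
    dialect: str = "csv"
    preset: str | None = None  # anterior-like | posterior-like | heatshock
    # preprocessing
    sat_max_frac: float = 0.05
    bleed_ratio: float | None = None  # None = estimate automatically
    smooth_window: int = 6
    smooth_iterations: int = 1
    window_start: float = 10.0
    window_end: float = 15.0
    # activity model
    t_half: float = 3.0
    onset_threshold: float = 0.025
    onset_persistence: int = 3
    on_threshold: float = 0.05  # AU/hr^2
    # clustering
    k_min: int = 5
    k_max: int = 25
    k_override: int | None = None
    # statistics
    n_perm: int = 200
    seed: int = 0
    figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(
            sat_max_frac=self.sat_max_frac,
            bleed_ratio=self.bleed_ratio,
            smooth_window=self.smooth_window,
            smooth_iterations=self.smooth_iterations,
            window_start=self.window_start,
            window_end=self.window_end,
        )


def _load_cohort(config: PipelineConfig, outdir: Path):
    if config.preset == "heatshock":
        pars = heatshock_preset()
        cohort = generate_heatshock_dataset(seed=config.seed, **pars)
        return cohort, True
    if config.preset is not None:
        from .simulate import generate_cohort

        cfg = PRESETS[config.preset](seed=config.seed)
        cohort, _ = generate_cohort(cfg)
        write_track_table(cohort, outdir / "simulated_tracks.csv")
        return cohort, False
    if config.input_path is None:
        raise StageError("stage load: neither input_path nor preset given")
    return read_track_table(config.input_path, config.dialect), False


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages, writing tables, figures (optional) and a provenance
    log under ``outdir``. Returns a summary dict of headline numbers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed}
    provenance = {
        "version": __version__,
        "config": dataclasses.asdict(config),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    cohort, is_heatshock = _load_cohort(config, outdir)

    if is_heatshock:
        try:
            fit = fit_halflife_heatshock(cohort)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage halflife: {exc}") from exc
        report = (
            f"n_cells\t{fit.n_cells}\n"
            f"slope_hr^-1\t{fit.slope:.6f}\n"
            f"t_half_hr\t{fit.t_half:.6f}\n"
            f"i_max\t{fit.i_max:.6f}\n"
            f"fit_range_hr\t{fit.fit_range[0]:.3f}..{fit.fit_range[1]:.3f}\n"
            f"r_squared\t{fit.r_squared:.6f}\n"
        )
        (outdir / "halflife_fit.txt").write_text(report)
        summary["t_half_hr"] = fit.t_half
        return summary

    try:
        processed = preprocess_cohort(cohort, config.preprocess_params())
        write_track_table(processed, outdir / "processed_tracks.csv")
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage preprocess: {exc}") from exc
    summary["n_tracks"] = len(processed)
    summary["bleed_ratio"] = processed.metadata.get("bleed_ratio")

    try:
        traces = [infer_activity(tr, t_half=config.t_half) for tr in processed]
        traces = normalize_activity(traces)
        traces = attach_onsets(traces, config.onset_threshold, config.onset_persistence)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage infer: {exc}") from exc
    import pandas as pd

    act = pd.concat(
        [
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "t": tr.t,
                    "x_raw": tr.x_raw,
                    "x_norm": tr.x_norm,
                    "onset_time": tr.onset_time if tr.onset_time is not None else np.nan,
                }
            )
            for tr in traces
        ],
        ignore_index=True,
    )
    act.to_csv(outdir / "activity_traces.csv", index=False)

    try:
        metrics = response_metrics_table(
            processed,
            traces,
            window=(config.window_start, config.window_end),
            on_threshold=config.on_threshold,
        )
        metrics.to_csv(outdir / "response_metrics.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage metrics: {exc}") from exc

    try:
        clu = cluster_tracks(
            processed,
            k_range=range(config.k_min, config.k_max + 1),
            k_override=config.k_override,
            seed=config.seed,
        )
        pd.DataFrame(
            {"cell_id": clu.included, "cluster": [clu.assignments[c] for c in clu.included]}
        ).to_csv(outdir / "cluster_assignments.csv", index=False)
        clu.fate_contribution.to_csv(outdir / "fate_contribution.csv")
        pd.DataFrame(
            {"k": list(clu.wcss_curve), "wcss": list(clu.wcss_curve.values())}
        ).to_csv(outdir / "wcss_curve.csv", index=False)
        summary["k"] = clu.k
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage cluster: {exc}") from exc

    try:
        flag_table = compare_metrics(
            metrics,
            metric_names=RESPONSE_METRICS,
            group_col="region",
            n_perm=config.n_perm,
            seed=config.seed,
        )
        flag_table.to_csv(outdir / "flag_summary.csv", index=False)
        summary["flag"] = {
            f"{row.region}:{row.metric}": round(row.accuracy_pct, 2)
            for row in flag_table.itertuples()
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage flag: {exc}") from exc

    if config.figures:
        from . import plots

        figdir = outdir / "figures"
        figdir.mkdir(exist_ok=True)
        plots.save_average_traces(average_by_fate(processed), figdir / "average_traces.png")
        plots.save_flag_summary(flag_table, figdir / "flag_summary.png")

    return summary
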