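"""End-to-end orchestration: simulate/load → extract → analyze → compare.

The pipeline turns a run configuration into a per-animal metrics table and
a statistics report.  All randomness flows from the seed recorded in the
configuration, so a fixed config reproduces its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calcium, kinematics, stats
from .kinematics import BendTrace, CycleSet, MidlineTrack
from .synthgen import (
    MuscleMap,
    RoiTraceSet,
    SynthConfig,
    _animal_seed,
    emit_fluorescence,
    make_anatomy,
    simulate_midline,
)

logger = logging.getLogger("wormcycle")

#: Muscles summarized per animal in the metrics table.
FOCUS_MUSCLES = ("vm21", "vm24", "dm21", "dm24")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: synthetic generation (``synth`` parameters +
    ``conditions`` overrides) or on-disk files (``input_dir`` with trace and
    midline CSVs per animal, as written by ``wormcycle simulate``).
    """

    out_dir: str = "wormcycle_out"
    behavior: str = "swim"  # condition label family: swim or crawl
    input_dir: str | None = None
    synth: dict = field(default_factory=dict)
    conditions: dict = field(default_factory=lambda: {"control": {}})
    n_animals: int = 10
    # analysis parameters
    min_period: float = 0.3
    min_prominence: float = 0.2
    smooth_window: int = 3
    normalization: str = "ratio"  # or "dff"
    ratio_mode: str = "peak"  # or "mean"
    resample_step: float = 50.0  # µm, for path curvature
    # stats parameters
    alpha: float = 0.05
    power_reps: int = 1000
    seed: int = 0
    make_plots: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def synth_config(self, **extra) -> SynthConfig:
        base = dict(self.synth)
        if self.behavior == "crawl":
            base.setdefault("emission_model", "crawl_antiphase")
        base.update(extra)
        if "gain_overrides" in base and isinstance(base["gain_overrides"], dict):
            base["gain_overrides"] = tuple(base["gain_overrides"].items())
        return SynthConfig(seed=self.seed, **base)


def analyze_animal(
    track: MidlineTrack,
    traces: RoiTraceSet,
    anatomy: MuscleMap,
    config: RunConfig,
    animal_id: str = "animal",
    condition: str = "control",
    vertex_index: int | None = None,
) -> dict:
    """Compute one animal's metrics row from its midline and traces."""
    if vertex_index is None:
        vertex_index = int(round(0.8 * (track.n_points - 1)))
    bend = kinematics.bend_angle(
        track, tip_index=track.n_points - 1, anterior_index=0,
        vertex_index=vertex_index,
    )
    cycles = kinematics.detect_cycles(
        bend, config.min_period, config.min_prominence, config.smooth_window
    )
    row: dict = {"animal": animal_id, "condition": condition, "n_cycles": cycles.n_cycles}
    row["speed_um_s"] = kinematics.centroid_speed(track)
    try:
        row["path_curvature_rad_um"] = kinematics.path_curvature(
            track.centroid(), config.resample_step
        )
    except ValueError:
        row["path_curvature_rad_um"] = np.nan
    if cycles.n_cycles == 0:
        logger.warning("%s: no cycles detected", animal_id)
        return row
    exc = kinematics.angular_excursion(bend, cycles)
    slopes = kinematics.half_cycle_slopes(bend, cycles)
    disp = kinematics.lateral_displacement(track.coords[:, 0], cycles)
    row.update(
        excursion_deg=exc.mean,
        slope_d_deg_s=slopes.mean_d,
        slope_v_deg_s=slopes.mean_v,
        lateral_d_um=disp.mean_d,
        lateral_v_um=disp.mean_v,
        lateral_ratio=disp.ratio,
    )
    mats: dict[str, calcium.NormalizedCycleMatrix] = {}
    for name in FOCUS_MUSCLES:
        try:
            cell = anatomy[name]
        except KeyError:
            continue
        raw = traces.traces.get(cell.name)
        if raw is None:
            continue
        norm = calcium.normalize_background(
            raw, traces.background, mode=config.normalization
        )
        mat = calcium.time_normalize_cycles(norm, cycles, muscle=name)
        mats[name] = mat
        half = calcium.half_cycle_means(mat)
        row[f"{name}_auc"] = calcium.cycle_auc(mat)
        row[f"{name}_half1"] = half.first
        row[f"{name}_half2"] = half.second
    if "vm21" in mats and "vm24" in mats:
        row["vm21_vm24_ratio"] = calcium.activation_ratio(
            mats["vm21"], mats["vm24"], mode=config.ratio_mode
        )
    return row


def _iter_synthetic_animals(config: RunConfig, condition: str, overrides: dict):
    cfg = config.synth_config(**overrides)
    anatomy = make_anatomy(cfg)
    for i in range(config.n_animals):
        acfg = cfg.replace(seed=_animal_seed(cfg.seed, i))
        track, truth = simulate_midline(acfg)
        traces = emit_fluorescence(truth, anatomy, acfg)
        yield f"{condition}_{i:03d}", track, traces, anatomy


def _iter_file_animals(config: RunConfig):
    from . import io as wio

    root = Path(config.input_dir)
    manifests = sorted(root.glob("*_manifest.json"))
    if not manifests:
        raise FileNotFoundError(f"no *_manifest.json found in {root}")
    for mpath in manifests:
        with open(mpath) as fh:
            manifest = json.load(fh)
        cfg = manifest["config"]
        fps = float(cfg["fps"])
        anatomy = make_anatomy(
            SynthConfig(quadrant_counts=tuple(cfg["quadrant_counts"].items()))
        )
        for entry in manifest["animals"]:
            files = entry["files"]
            try:
                track = wio.read_midline_csv(root / files["midline"], fps)
                traces = wio.read_trace_csv(root / files["traces"], fps)
            except Exception as exc:  # surface the offending file
                raise ValueError(f"malformed input for {entry['id']}: {exc}") from exc
            yield entry["id"], track, traces, anatomy, manifest["condition"]


def run_pipeline(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Run the full pipeline; returns (metrics table, stats report).

    Writes ``metrics.csv``, ``stats_report.json``, ``manifest.json`` and —
    when ``make_plots`` is set — per-animal QC figures into ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    if config.input_dir is not None:
        for aid, track, traces, anatomy, cond in _iter_file_animals(config):
            rows.append(analyze_animal(track, traces, anatomy, config, aid, cond))
    else:
        for cond, overrides in config.conditions.items():
            for aid, track, traces, anatomy in _iter_synthetic_animals(
                config, cond, overrides
            ):
                rows.append(analyze_animal(track, traces, anatomy, config, aid, cond))
                if config.make_plots:
                    _qc_plot(out, aid, track, traces, anatomy, config)
    if not rows:
        raise ValueError("no animals analyzed (empty input)")
    table = pd.DataFrame(rows)
    table.to_csv(out / "metrics.csv", index=False)

    report = _compare_conditions(table, config)
    from . import io as wio

    wio.write_json_report(out / "stats_report.json", report)
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {"config": config.to_dict(), "config_hash": config.config_hash,
             "n_animals": len(table), "package": "wormcycle 0.1.0"},
            fh, indent=1, sort_keys=True,
        )
    return table, report


def _compare_conditions(table: pd.DataFrame, config: RunConfig) -> dict:
    conditions = list(dict.fromkeys(table["condition"]))
    metrics = [
        c for c in table.columns
        if c not in ("animal", "condition") and table[c].dtype.kind == "f"
    ]
    report: dict = {"alpha": config.alpha, "conditions": conditions, "metrics": {}}
    if len(conditions) < 2:
        return report
    for metric in metrics:
        groups = [
            table.loc[table["condition"] == c, metric].dropna().to_numpy()
            for c in conditions
        ]
        if any(len(g) < 4 for g in groups):
            continue
        try:
            if len(conditions) == 2:
                res = stats.auto_compare_two(
                    groups[0], groups[1], alpha=config.alpha,
                    labels=tuple(conditions), power_reps=config.power_reps,
                    seed=config.seed,
                )
            else:
                res = stats.auto_compare_many(
                    groups, alpha=config.alpha, labels=conditions
                )
        except ValueError as exc:
            report["metrics"][metric] = {"error": str(exc)}
            continue
        entry = {
            "test": res.test_name,
            "statistic": res.statistic,
            "pvalue": res.pvalue,
            "significant": res.significant,
            "groups": res.group_summaries,
            "normal": res.normal,
            "equal_variance": res.equal_variance,
        }
        if res.power is not None:
            entry["power"] = res.power.power
            entry["power_se"] = res.power.se
        if res.posthoc is not None:
            entry["posthoc"] = res.posthoc
        report["metrics"][metric] = entry
    return report


def _qc_plot(out: Path, animal_id: str, track, traces, anatomy, config: RunConfig):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vertex = int(round(0.8 * (track.n_points - 1)))
    bend = kinematics.bend_angle(track, track.n_points - 1, 0, vertex)
    cycles = kinematics.detect_cycles(
        bend, config.min_period, config.min_prominence, config.smooth_window
    )
    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=False)
    axes[0].plot(bend.times, bend.values, lw=1)
    for b in cycles.boundaries:
        axes[0].axvline(b / bend.fps, color="r", ls="--", lw=0.5)
    axes[0].set(xlabel="time (s)", ylabel="bend (deg)", title=animal_id)
    if cycles.n_cycles:
        cell = anatomy["dm21"]
        norm = calcium.normalize_background(
            traces.traces[cell.name], traces.background, config.normalization
        )
        mat = calcium.time_normalize_cycles(norm, cycles)
        im = axes[1].imshow(
            mat.matrix, aspect="auto", extent=(0, 1, mat.n_cycles, 0)
        )
        fig.colorbar(im, ax=axes[1], label="F (norm.)")
        axes[1].set(xlabel="cycle fraction", ylabel="cycle", title="dm21")
    fig.tight_layout()
    fig.savefig(out / f"{animal_id}_qc.png", dpi=100)
    plt.close(fig)
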