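# wormcycle

Cycle-resolved quantification of *C. elegans* undulatory locomotion and
body-wall-muscle calcium activity.

During locomotion the worm bends dorsoventrally in a periodic rhythm, and
GCaMP fluorescence in individual body-wall myocytes reports their
activation within that rhythm. The two gaits differ qualitatively: during
crawling, dorsal and ventral muscles activate antagonistically, each
peaking at its own bend extremum; during swimming they co-activate,
peaking when the segment is straight — at cycle fractions 0.25 and 0.75
when φ = 0 is placed at the dorsal-bend maximum. Dorsoventral *asymmetry*
of activation (e.g. the ventral tail myocyte vm21 versus its neighbour
vm24) is the quantity of biological interest: its loss changes tail
kinematics and the swim path.

`wormcycle` provides, for researchers analyzing such recordings:

- **kinematics** — signed bend angle at a body point, undulation-cycle
  segmentation, angular excursion, half-cycle slopes, head lateral
  displacement per sweep, centroid speed, and path curvature
  (Σ|turning angle| / distance, rad/µm);
- **calcium** — background normalization (F/F_bg or ΔF/F), resampling of
  each cycle onto the longest-cycle fraction grid, half-cycle means, AUC
  per cycle, peak phase, and between-muscle activation ratios;
- **stats** — the field-standard decision tree (IQR outlier removal,
  Shapiro-Wilk and Brown-Forsythe gates, Student/Welch/rank-sum, ANOVA +
  Holm-Sidak or Kruskal-Wallis + Dunn) with Monte-Carlo power for every
  branch;
- **synthgen** — a forward simulator of midline motion and muscle
  fluorescence under both activation regimes with configurable
  dorsoventral amplitude, duration and gain asymmetries, so every
  pipeline stage can be validated against known ground truth;
- a **CLI** (`wormcycle simulate / analyze / compare / all`) over the
  same library.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Simulate two ten-animal cohorts — a control with vm21 at full emission
gain, and a knockdown mimic with vm21 suppressed to 0.4× — then compare
the vm21/vm24 activation ratio between conditions:

```python
from wormcycle.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="demo_out",
    synth={"duration": 44.0, "baseline": 0.0},
    conditions={
        "control": {},
        "pezo1_mimic": {"gain_overrides": (("vm21", 40.0),)},
    },
    n_animals=10,
    ratio_mode="mean",
    power_reps=2000,
    seed=42,
)
table, report = run_pipeline(cfg)
r = report["metrics"]["vm21_vm24_ratio"]
print(table.groupby("condition")["vm21_vm24_ratio"].agg(["mean", "std"]).round(3))
print(f"test: {r['test']}  p = {r['pvalue']:.3g}  power = {r['power']:.3f}")
```

prints

```
              mean    std
condition
control      1.001  0.031
pezo1_mimic  0.397  0.021
test: Student t  p = 2.61e-21  power = 1.000
```

The per-animal activation ratios recover the simulated gains (1.0 and
0.4) to within a few percent at noise σ/g = 0.1, the dispatch chooses the
Student t branch (both groups normal, equal variance), and the
Monte-Carlo power at the observed effect size is saturated. `demo_out/`
additionally receives `metrics.csv` (one row per animal: speed, path
curvature, excursion, half-cycle slopes, lateral displacements, per-muscle
AUC and half-cycle means), `stats_report.json` and a run manifest with the
config hash.

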