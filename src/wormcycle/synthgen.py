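"""Forward simulation of worm locomotion and muscle fluorescence.

The generator produces midline tracks and per-muscle GCaMP-like traces with
known ground truth, so every analysis stage in the package has a recoverable
target.  It emulates the two canonical muscle-activation regimes of
*C. elegans* locomotion:

``crawl_antiphase``
    dorsal and ventral muscles activate antagonistically, each peaking at
    its own bend extremum;
``swim_coactive``
    dorsal and ventral muscles co-activate, peaking when the body segment
    is straight (cycle fractions 0.25 and 0.75) and silent at the bend
    extremes.

Model summary
-------------
The phase at the reference body point is ``phi(t) = (t/T) mod 1`` with
``phi = 0`` at the dorsal-bend maximum.  The bend wave is a unit-amplitude
*warped* sinusoid: its positive (dorsal) lobe is scaled by ``a_d``, the
negative (ventral) lobe by ``a_v``, and the ventro-dorsal sweep is
compressed to occupy a fraction ``f_D`` of the period.  Each muscle at
body-axis position ``s`` sees the wave delayed by ``s/λ``.

The geometric midline is a two-arm articulated model: a straight anterior
body axis and a straight tail arm hinged at the tail-gap body fraction,
with hinge angle equal to the warped wave at the reference point.  This
makes the three-point chord angle measured by
:func:`wormcycle.kinematics.bend_angle` recover the generated bend exactly.
Forward translation uses a stroke-dependent thrust model: instantaneous
speed is weighted by the amplitude gain of the muscle group driving the
current sweep (``a_v`` during the dorso-ventral sweep, ``a_d`` during the
ventro-dorsal sweep), so amplitude asymmetry produces the corresponding
asymmetry in per-sweep head displacement.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .kinematics import MidlineTrack

__all__ = [
    "MuscleCell",
    "MuscleMap",
    "SynthConfig",
    "GroundTruth",
    "RoiTraceSet",
    "make_anatomy",
    "resolve_muscle_name",
    "simulate_midline",
    "emit_fluorescence",
    "render_frames",
    "simulate_cohort",
    "warped_wave",
]

QUADRANTS = ("DL", "DR", "VL", "VR")
#: Default body-wall myocyte count per quadrant.  The ventral counts (VL=23,
#: VR=24) are fixed anatomy; the dorsal quadrants default to 24 and are
#: overridable in :class:`SynthConfig`.
DEFAULT_COUNTS = {"DL": 24, "DR": 24, "VL": 23, "VR": 24}


@dataclass(frozen=True)
class MuscleCell:
    quadrant: str  # DL, DR, VL, VR
    index: int  # 1-based, anterior -> posterior within the quadrant
    s: float  # body-axis position in [0, 1]

    @property
    def name(self) -> str:
        return f"{self.quadrant}{self.index:02d}"

    @property
    def is_dorsal(self) -> bool:
        return self.quadrant in ("DL", "DR")


@dataclass
class MuscleMap:
    """Body-wall muscle layout: cells grouped in four longitudinal quadrants."""

    cells: list[MuscleCell]

    def __post_init__(self) -> None:
        for q in QUADRANTS:
            cells = self.quadrant(q)
            idx = [c.index for c in cells]
            if len(set(idx)) != len(idx):
                raise ValueError(f"duplicate indices in quadrant {q}")
            s = [c.s for c in sorted(cells, key=lambda c: c.index)]
            if any(b <= a for a, b in zip(s, s[1:])):
                raise ValueError(f"s must increase with index in quadrant {q}")

    def quadrant(self, q: str) -> list[MuscleCell]:
        return [c for c in self.cells if c.quadrant == q]

    def count(self, q: str) -> int:
        return len(self.quadrant(q))

    def __len__(self) -> int:
        return len(self.cells)

    def __getitem__(self, name: str) -> MuscleCell:
        quadrants, i = resolve_muscle_name(name)
        for q in quadrants:
            for c in self.cells:
                if c.quadrant == q and c.index == i:
                    return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.cells]


def resolve_muscle_name(name: str) -> tuple[tuple[str, ...], int]:
    """Resolve a muscle name to (candidate quadrants, index).

    Accepts explicit quadrant names (``"VL21"``, ``"DR05"``) and the
    conventional ventral/dorsal shorthand: ``"vm21"`` resolves to the
    ventral-left quadrant at index 21 when it exists, falling back to
    ventral-right — so with the asymmetric ventral anatomy (VL has only 23
    cells) ``"vm24"`` names the most posterior ventral cell, VR24.
    """
    name = name.strip()
    head = name.rstrip("0123456789")
    digits = name[len(head):]
    if not digits:
        raise ValueError(f"muscle name {name!r} lacks an index")
    idx = int(digits)
    head = head.upper().rstrip("M")
    mapping = {
        "V": ("VL", "VR"),
        "D": ("DL", "DR"),
        "VL": ("VL",),
        "VR": ("VR",),
        "DL": ("DL",),
        "DR": ("DR",),
    }
    if head not in mapping:
        raise ValueError(f"unrecognized muscle name {name!r}")
    return mapping[head], idx


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic recording.

    Defaults emulate the study conditions: 10 fps for 17 s, a 2 s swim
    cycle, 45° peak bend, and additive Gaussian noise at one tenth of the
    per-muscle gain.
    """

    fps: float = 10.0
    duration: float = 17.0
    n_points: int = 33
    amplitude: float = 45.0  # degrees, peak bend before lobe scaling
    period: float = 2.0  # s
    wavelength: float = 1.5  # body lengths
    gain_dorsal: float = 1.0  # a_d, dorsal-lobe amplitude gain
    gain_ventral: float = 1.0  # a_v, ventral-lobe amplitude gain
    f_dorsal: float = 0.5  # f_D, fraction of T in the ventro-dorsal sweep
    emission_model: str = "swim_coactive"  # or "crawl_antiphase"
    baseline: float = 100.0  # B, a.u.
    gain: float = 100.0  # default per-muscle emission gain g_m, a.u.
    gain_overrides: tuple[tuple[str, float], ...] = ()  # e.g. (("vm21", 40.0),)
    background_level: float = 50.0  # F_bg0, a.u.
    noise_sd: float = 10.0  # sigma, a.u.
    bleach_tau: float | None = None  # s; None = no bleaching
    seed: int = 0
    um_per_body_length: float = 1000.0
    quadrant_counts: tuple[tuple[str, int], ...] = tuple(DEFAULT_COUNTS.items())
    hinge_s: float = 0.8  # tail-gap articulation point, body fraction
    anterior_weight: float = 0.5  # share of the hinge angle taken by the axis
    translation_speed: float = 150.0  # µm/s mean forward speed

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.period <= 0 or self.duration <= 0:
            raise ValueError("fps, period and duration must be positive")
        if not (0.0 < self.f_dorsal < 1.0):
            raise ValueError("f_dorsal must lie in (0, 1)")
        if self.baseline < 0 or self.gain < 0 or self.noise_sd < 0:
            raise ValueError("baseline, gain and noise_sd must be non-negative")
        if self.n_points < 3:
            raise ValueError("n_points must be at least 3")
        if not (0.0 < self.hinge_s < 1.0):
            raise ValueError("hinge_s must lie in (0, 1)")
        if self.emission_model not in ("crawl_antiphase", "swim_coactive"):
            raise ValueError(f"unknown emission model {self.emission_model!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))

    @property
    def hinge_index(self) -> int:
        """Midline point index of the articulation (reference) vertex."""
        return min(max(int(round(self.hinge_s * (self.n_points - 1))), 1),
                   self.n_points - 2)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gain_overrides"] = dict(self.gain_overrides)
        d["quadrant_counts"] = dict(self.quadrant_counts)
        return d


@dataclass
class GroundTruth:
    """Noise-free truth of one simulated recording."""

    phase: np.ndarray  # phi(t) in [0, 1) at the reference point
    bend_ref: np.ndarray  # reference-point bend angle, degrees
    cycle_boundaries: np.ndarray  # interior frames where phi == 0
    config: SynthConfig
    noise_free_traces: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class RoiTraceSet:
    """Per-muscle raw fluorescence traces with a shared background trace."""

    traces: dict[str, np.ndarray]  # muscle name -> raw trace, a.u.
    background: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        n = len(self.background)
        for name, tr in self.traces.items():
            if len(tr) != n:
                raise ValueError(f"trace {name} length differs from background")

    @property
    def n_frames(self) -> int:
        return len(self.background)

    @property
    def names(self) -> list[str]:
        return list(self.traces)


def make_anatomy(config: SynthConfig | None = None) -> MuscleMap:
    """Default body-wall anatomy: 24/24 dorsal, 23 VL and 24 VR myocytes.

    Within each quadrant of *n* cells, cell *k* sits at body-axis position
    ``s = (k − ½)/n``, strictly increasing anterior→posterior.
    """
    config = config or SynthConfig()
    counts = dict(config.quadrant_counts)
    cells = []
    for q in QUADRANTS:
        n = int(counts.get(q, DEFAULT_COUNTS[q]))
        for k in range(1, n + 1):
            cells.append(MuscleCell(q, k, (k - 0.5) / n))
    return MuscleMap(cells)


def warped_wave(
    phase: np.ndarray, f_dorsal: float = 0.5,
    gain_dorsal: float = 1.0, gain_ventral: float = 1.0,
) -> np.ndarray:
    """Warped unit sinusoid: +gain_dorsal at phase 0, −gain_ventral at 1−f_D.

    The dorso-ventral (descending) sweep occupies phase ``[0, 1−f_D)`` and
    the ventro-dorsal (ascending) sweep ``[1−f_D, 1)``; each half is a
    time-rescaled cosine half-period, so half-cycle slopes scale as
    ``1/(1−f_D)`` and ``1/f_D``.
    """
    phase = np.asarray(phase, dtype=float) % 1.0
    f_v = 1.0 - f_dorsal
    u = np.where(phase < f_v, 0.5 * phase / f_v, 0.5 + 0.5 * (phase - f_v) / f_dorsal)
    base = np.cos(2.0 * np.pi * u)
    return np.where(base >= 0.0, gain_dorsal * base, gain_ventral * base)


def _bend_at(config: SynthConfig, s: float | np.ndarray, t: np.ndarray) -> np.ndarray:
    """Signed bend (degrees, + = dorsal) of the traveling wave at position s."""
    phase = (t / config.period - (np.asarray(s) - config.hinge_s) / config.wavelength) % 1.0
    return config.amplitude * warped_wave(
        phase, config.f_dorsal, config.gain_dorsal, config.gain_ventral
    )


def simulate_midline(config: SynthConfig) -> tuple[MidlineTrack, GroundTruth]:
    """Simulate the articulated midline and the ground-truth bend wave."""
    t = config.times
    phase = (t / config.period) % 1.0
    bend_ref = _bend_at(config, config.hinge_s, t)

    n = config.n_points
    L = config.um_per_body_length
    seg_len = L / (n - 1)
    hinge_idx = config.hinge_index

    th = np.radians(bend_ref)[:, None]  # (frames, 1)
    w_a = config.anterior_weight
    seg_dir = np.where(
        np.arange(n - 1)[None, :] < hinge_idx, -w_a * th, (1.0 - w_a) * th
    )
    dx = np.cos(seg_dir) * seg_len
    dy = np.sin(seg_dir) * seg_len
    pts = np.zeros((config.n_frames, n, 2))
    pts[:, 1:, 0] = np.cumsum(dx, axis=1)
    pts[:, 1:, 1] = np.cumsum(dy, axis=1)
    pts -= pts.mean(axis=1, keepdims=True)  # anchor at the centroid

    # stroke-dependent thrust: the sweep driven by the stronger muscle group
    # translates the body faster
    descending = phase < (1.0 - config.f_dorsal)
    a_d, a_v = config.gain_dorsal, config.gain_ventral
    denom = a_d + a_v
    if denom > 0:
        v = config.translation_speed * 2.0 * np.where(descending, a_v, a_d) / denom
    else:
        v = np.full_like(t, config.translation_speed)
    x_off = np.concatenate([[0.0], np.cumsum(v[:-1]) / config.fps])
    pts[:, :, 0] += x_off[:, None]

    # interior frames where the reference point is at its dorsal maximum
    k = np.arange(1, int(np.ceil(config.duration / config.period)) + 1)
    bframes = np.round(k * config.period * config.fps).astype(int)
    bframes = bframes[(bframes > 0) & (bframes < config.n_frames - 1)]

    track = MidlineTrack(pts, config.fps, note="synthetic (µm native)")
    truth = GroundTruth(phase, bend_ref, bframes, config)
    return track, truth


def emit_fluorescence(
    truth: GroundTruth,
    anatomy: MuscleMap,
    config: SynthConfig,
    muscles: Sequence[str] | None = None,
) -> RoiTraceSet:
    """Emit per-muscle fluorescence traces from the ground-truth bend wave.

    With ``κ_m(t)`` the local bend signed positive toward muscle *m*'s own
    side and ``κ̂`` its per-trace maximum magnitude:

    - ``crawl_antiphase``: ``F = B + g·max(0, κ)/κ̂ + ε`` — each muscle
      peaks at its own bend extremum and is silent on the opposite sweep;
    - ``swim_coactive``: ``F = B + g·(1 − |κ|/κ̂) + ε`` — both sides peak
      at straight posture.

    ``ε ~ N(0, σ²)`` i.i.d.; optional bleaching multiplies the noise-free
    signal by ``exp(−t/τ)``.  The background trace is ``F_bg0 + ε``.
    ``muscles`` restricts emission to a subset of named cells (all by
    default); note the subset changes the noise stream consumed per cell.
    """
    t = config.times
    rng = np.random.default_rng(config.seed)
    traces: dict[str, np.ndarray] = {}
    decay = np.exp(-t / config.bleach_tau) if config.bleach_tau else 1.0
    gain_map = {anatomy[name].name: float(g) for name, g in config.gain_overrides}
    cells = (
        anatomy.cells if muscles is None else [anatomy[m] for m in muscles]
    )
    for cell in cells:
        side = 1.0 if cell.is_dorsal else -1.0
        kappa = side * _bend_at(config, cell.s, t)
        khat = float(np.max(np.abs(kappa)))
        g = gain_map.get(cell.name, config.gain)
        if khat == 0.0:
            if g != 0.0:
                raise ValueError("degenerate bend trace")
            signal = np.full_like(t, config.baseline)
        elif config.emission_model == "crawl_antiphase":
            signal = config.baseline + g * np.maximum(0.0, kappa) / khat
        else:  # swim_coactive
            signal = config.baseline + g * (1.0 - np.abs(kappa) / khat)
        signal = signal * decay
        truth.noise_free_traces[cell.name] = signal
        traces[cell.name] = signal + rng.normal(0.0, config.noise_sd, size=len(t))
    background = config.background_level + rng.normal(
        0.0, config.noise_sd, size=len(t)
    )
    return RoiTraceSet(traces, background, config.fps)


def _interp_midline_point(track: MidlineTrack, s: float) -> np.ndarray:
    """Midline position at body fraction s per frame, shape (frames, 2)."""
    idx = s * (track.n_points - 1)
    lo = int(np.floor(idx))
    hi = min(lo + 1, track.n_points - 1)
    w = idx - lo
    return (1 - w) * track.coords[:, lo] + w * track.coords[:, hi]


def render_frames(
    track: MidlineTrack,
    traces: RoiTraceSet,
    anatomy: MuscleMap,
    config: SynthConfig,
    um_per_px: float = 10.0,
    blob_sigma_px: float = 2.0,
    mask_radius_px: float | None = None,
    image_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """Render the recording as an image stack with per-muscle ROI masks.

    Each muscle in ``traces`` becomes a Gaussian blob at its body-axis
    position on the midline, with peak intensity equal to its trace value,
    over a uniform background of level ``F_bg0``.  Returns
    ``(stack, masks, background_mask)`` where each mask is a per-frame
    boolean disk following the blob (ROIs track the muscle) and the
    background mask is a static corner region away from the worm.
    """
    if traces.n_frames != track.n_frames:
        raise ValueError("trace and midline frame counts differ")
    mask_radius_px = mask_radius_px or 3.0 * blob_sigma_px
    xy_px = track.coords / um_per_px
    margin = 4 * mask_radius_px + 2
    lo = xy_px.reshape(-1, 2).min(axis=0) - margin
    hi = xy_px.reshape(-1, 2).max(axis=0) + margin
    if image_shape is None:
        w = int(np.ceil(hi[0] - lo[0]))
        h = int(np.ceil(hi[1] - lo[1]))
        image_shape = (h, w)
    h, w = image_shape
    if (hi[0] - lo[0]) > w or (hi[1] - lo[1]) > h:
        raise ValueError("image too small to contain the worm")

    n_frames = track.n_frames
    stack = np.full((n_frames, h, w), float(config.background_level))
    masks = {name: np.zeros((n_frames, h, w), dtype=bool) for name in traces.names}
    yy, xx = np.mgrid[0:h, 0:w]
    for name in traces.names:
        cell = anatomy[name]
        pos = _interp_midline_point(track, cell.s) / um_per_px - lo
        tr = traces.traces[name]
        for f in range(n_frames):
            cx, cy = pos[f]
            x0, x1 = int(max(cx - 5 * blob_sigma_px, 0)), int(min(cx + 5 * blob_sigma_px + 1, w))
            y0, y1 = int(max(cy - 5 * blob_sigma_px, 0)), int(min(cy + 5 * blob_sigma_px + 1, h))
            sub_y, sub_x = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
            r2 = (sub_x - cx) ** 2 + (sub_y - cy) ** 2
            stack[f, y0:y1, x0:x1] += tr[f] * np.exp(-r2 / (2 * blob_sigma_px**2))
            masks[name][f, y0:y1, x0:x1] |= r2 <= mask_radius_px**2
    side = int(2 * mask_radius_px) + 1
    bg_mask = np.zeros((h, w), dtype=bool)
    bg_mask[:side, :side] = True
    return stack, masks, bg_mask


def _animal_seed(master_seed: int, ordinal: int) -> int:
    """Deterministic per-animal sub-seed from the master seed (counter-based)."""
    ss = np.random.SeedSequence([int(master_seed), int(ordinal)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    config: SynthConfig,
    n_animals: int,
    out_dir: str | Path,
    overrides: dict | None = None,
    write_tiff: bool = False,
    condition: str = "control",
) -> dict:
    """Simulate a cohort and write it to disk; returns the manifest dict.

    Per animal: a long-format trace CSV (frame, roi, intensity, background),
    a midline CSV (frame, point, x_um, y_um), a ground-truth JSON and
    optionally a rendered TIFF stack.  Each animal gets a sub-seed derived
    deterministically from the master seed, so a fixed master seed yields a
    byte-identical dataset.
    """
    from . import io as wio  # local import to avoid cycles

    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.replace(**(overrides or {}))
    anatomy = make_anatomy(cfg)
    manifest = {
        "condition": condition,
        "config": cfg.to_dict(),
        "overrides": dict(overrides or {}),
        "n_animals": n_animals,
        "animals": [],
    }
    seen = set()
    for i in range(n_animals):
        animal_id = f"{condition}_{i:03d}"
        acfg = cfg.replace(seed=_animal_seed(cfg.seed, i))
        track, truth = simulate_midline(acfg)
        traces = emit_fluorescence(truth, anatomy, acfg)
        paths = {
            "traces": out_dir / f"{animal_id}_traces.csv",
            "midline": out_dir / f"{animal_id}_midline.csv",
            "truth": out_dir / f"{animal_id}_truth.json",
        }
        if any(p in seen for p in paths.values()):
            raise ValueError(f"output path collision for animal {animal_id}")
        seen.update(paths.values())
        wio.write_trace_csv(paths["traces"], traces)
        wio.write_midline_csv(paths["midline"], track)
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "config": acfg.to_dict(),
                    "cycle_boundaries": truth.cycle_boundaries.tolist(),
                },
                fh, indent=1, sort_keys=True,
            )
        entry = {
            "id": animal_id,
            "seed": acfg.seed,
            "files": {k: p.name for k, p in paths.items()},
        }
        if write_tiff:
            import tifffile

            stack, masks, bg_mask = render_frames(track, traces, anatomy, acfg)
            tif = out_dir / f"{animal_id}_stack.tif"
            tifffile.imwrite(tif, stack.astype(np.float32))
            entry["files"]["stack"] = tif.name
        manifest["animals"].append(entry)
    cfg_json = json.dumps(manifest["config"], sort_keys=True)
    manifest["config_hash"] = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    with open(out_dir / f"{condition}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
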