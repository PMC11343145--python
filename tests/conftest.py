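import numpy as np
import pytest

import wormcycle as wc


@pytest.fixture(scope="session")
def anatomy():
    return wc.make_anatomy()


@pytest.fixture(scope="session")
def swim_recording(anatomy):
    """Noise-free swim recording with the reference vertex at dm21.

    17 s at 10 fps, 2 s period: the conditions under which straight-posture
    activation peaks must land at cycle fractions 0.25 and 0.75.
    """
    cfg = wc.SynthConfig(noise_sd=0.0, hinge_s=anatomy["dm21"].s)
    track, truth = wc.simulate_midline(cfg)
    traces = wc.emit_fluorescence(truth, anatomy, cfg)
    return cfg, track, truth, traces


@pytest.fixture(scope="session")
def swim_cycles(swim_recording):
    cfg, track, truth, traces = swim_recording
    bend = wc.bend_angle(track, -1, 0, cfg.hinge_index)
    return bend, wc.detect_cycles(bend)


def brute_force_peaks(x, distance=1, prominence=0.0):
    """Independent peak scan: strict interior local maxima, then greedy
    highest-first spacing enforcement, then a prominence filter."""
    x = np.asarray(x, dtype=float)
    cand = [
        i for i in range(1, len(x) - 1)
        if x[i] > x[i - 1] and x[i] > x[i + 1]
    ]
    kept = []
    for i in sorted(cand, key=lambda i: -x[i]):
        if all(abs(i - j) >= distance for j in kept):
            kept.append(i)
    out = []
    for i in sorted(kept):
        left = x[:i][::-1]
        right = x[i + 1:]
        lmin = left.min() if len(left) else x[i]
        rmin = right.min() if len(right) else x[i]
        higher_l = np.where(left > x[i])[0]
        higher_r = np.where(right > x[i])[0]
        lbase = left[: higher_l[0]].min() if len(higher_l) else lmin
        rbase = right[: higher_r[0]].min() if len(higher_r) else rmin
        prom = x[i] - max(lbase, rbase)
        if prom >= prominence:
            out.append(i)
    return np.array(out, dtype=int)
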