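import numpy as np
import pytest

from nirsprune import RawIntensityRecording, SimulationConfig, generate_recording

FS = 10.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(intensity, fs=FS, **meta):
    rec = RawIntensityRecording(
        intensity=np.asarray(intensity, dtype=float), sampling_rate=fs
    )
    rec.participant.update(meta)
    return rec


@pytest.fixture
def clean_cardiac_recording():
    """Noise-free, motion-free recording with perfect coupling on 4 channels."""
    cfg = SimulationConfig(
        n_channels=4,
        duration=60.0,
        coupling_quality=(1.0,) * 4,
        motion_rate=0.0,
        cse_probability=0.0,
        trc_indices=(),
        noise_sd=0.0,
        instability_scale=0.0,
        response_amplitude=0.0,
        seed=7,
    )
    rec, truth = generate_recording(cfg)
    return rec, truth


def brute_force_sci(x1, x2):
    """Pearson correlation via explicit sums (population convention)."""
    n = len(x1)
    m1 = sum(x1) / n
    m2 = sum(x2) / n
    num = sum((a - m1) * (b - m2) for a, b in zip(x1, x2))
    d1 = sum((a - m1) ** 2 for a in x1) ** 0.5
    d2 = sum((b - m2) ** 2 for b in x2) ** 0.5
    return num / (d1 * d2)


def brute_force_psp(x1, x2):
    """PSP via explicit loops: normalize, lag-by-lag cross-correlation, direct DFT."""
    import math

    n = len(x1)

    def norm(x):
        mu = sum(x) / n
        sd = math.sqrt(sum((v - mu) ** 2 for v in x) / n)
        return [(v - mu) / sd for v in x]

    a = norm(list(x1))
    b = norm(list(x2))
    # rho[j] for lag k = j - (n-1): sum over t of a[t] * b[t - k]
    rho = []
    for j in range(2 * n - 1):
        k = j - (n - 1)
        s = 0.0
        for t in range(n):
            u = t - k
            if 0 <= u < n:
                s += a[t] * b[u]
        rho.append(s / n)
    m = 2 * n - 1
    w = [0.54 - 0.46 * math.cos(2 * math.pi * i / (m - 1)) for i in range(m)]
    tri = [1.0 - abs(j - (n - 1)) / n for j in range(m)]
    ref = sum(wi * ti for wi, ti in zip(w, tri))
    y = [wi * ri for wi, ri in zip(w, rho)]
    best = 0.0
    for f in range(m // 2 + 1):
        re = sum(y[j] * math.cos(2 * math.pi * f * j / m) for j in range(m))
        im = -sum(y[j] * math.sin(2 * math.pi * f * j / m) for j in range(m))
        best = max(best, math.hypot(re, im))
    amplitude = 2.0 * best / ref
    return amplitude**2 / 2.0


def brute_force_motion_flags(dod, fs, t_motion=1.0, t_mask=1.0, stdev_thresh=15.0, amp_thresh=0.4):
    """Sample-by-sample sliding-window scan matching the documented rule."""
    import math

    n = len(dod)
    win = min(int(round(t_motion * fs)), n)
    diffs = [dod[i + 1] - dod[i] for i in range(n - 1)]
    if diffs:
        mu = sum(diffs) / len(diffs)
        sd = math.sqrt(sum((d - mu) ** 2 for d in diffs) / len(diffs))
    else:
        sd = 0.0
    thresh = min(amp_thresh, stdev_thresh * sd) if sd > 0 else amp_thresh
    flags = [False] * n
    for s in range(n - win + 1):
        seg = dod[s : s + win]
        if max(seg) - min(seg) > thresh:
            for i in range(s, s + win):
                flags[i] = True
    pad = int(round(t_mask * fs))
    out = list(flags)
    for i, f in enumerate(flags):
        if f:
            for j in range(max(0, i - pad), min(n, i + pad + 1)):
                out[j] = True
    return np.asarray(out)
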