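"""The three channel-exclusion procedures on one recording.

Runs the full prepruning-and-pruning chain: dead-channel (CSE) exclusion at
the 3e-4 intensity floor, per-channel motion detection on optical-density
changes, 3-s clean-window derivation, then CV-difference pruning and the
windowed SCI/PSP procedure (full and SCI-only variants).
"""

from collections import Counter

from nirsprune import (
    MotionConfig,
    QTConfig,
    SimulationConfig,
    clean_window_indices,
    detect_motion,
    find_cse,
    generate_recording,
    percent_motion,
    prune_cv,
    prune_qtnirs,
    sci_only_variant,
    window_bounds,
)

config = SimulationConfig(duration=180.0, motion_rate=3.0, cse_probability=0.1, seed=7)
recording, truth = generate_recording(config)

cse = find_cse(recording)
mask = detect_motion(recording, MotionConfig())
bounds = window_bounds(recording.n_samples, recording.sampling_rate)
clean = {c: clean_window_indices(mask.flags[c], bounds) for c in range(recording.n_channels)}
acceptable = [c for c in range(recording.n_channels) if c not in cse]

print(f"{len(truth.motion_events)} injected motion events; "
      f"PoM = {percent_motion(mask, channels=acceptable):.1f}% of windows")
print(f"CSE channels (intensity < 3e-4): {sorted(cse)} "
      f"(ground truth: {sorted(truth.cse_channels)})")

for name, result in (
    ("CV (wavelength CV difference > 0.2)", prune_cv(recording, clean, cse_channels=cse)),
    ("SCI-only (sci > 0.6 in >= 75% of windows)",
     sci_only_variant(recording, clean, QTConfig(), cse_channels=cse)),
    ("full SCI/PSP (sci > 0.6 and psp > 0.045)",
     prune_qtnirs(recording, clean, QTConfig(), cse_channels=cse)),
):
    counts = Counter(result.statuses.values())
    print(f"{name}: CR = {result.channels_retained}/{recording.n_channels}  {dict(counts)}")

# CR ("channels retained") is the per-participant retention count the
# downstream comparison stage models; the SCI/PSP procedure prunes the
# poorly coupled channels that CV's wavelength-difference criterion misses.
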