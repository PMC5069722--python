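"""Generate a synthetic recording session and inspect its amplitude structure.

Builds a small amputee-like dataset (4 postures x 7 wrist positions x 3
repetitions), prints the per-class channel RMS — the spatial amplitude code
the classifiers exploit — and shows how wrist position rescales extrinsic
channels far more than intrinsic ones.
"""

import numpy as np

from emgsel import default_layout, generate_dataset, preset

layout = default_layout(n_extrinsic=3, n_intrinsic=2)
cfg = preset("amputee-like", layout=layout, repetitions=3, seed=0)
trials = generate_dataset(cfg)
print(f"{len(trials)} trials of {trials[0].duration_s:.0f} s "
      f"x {layout.n_channels} channels at {layout.sampling_rate:.0f} Hz\n")

print("mean channel RMS by motion class (all positions pooled):")
print("  class   " + "  ".join(f"{c:>6}" for c in layout.channel_ids))
for mc in ("rest", "open", "key", "chuck"):
    rms = np.mean(
        [np.sqrt(np.mean(t.signal**2, axis=1)) for t in trials
         if t.motion_class == mc],
        axis=0,
    )
    print(f"  {mc:<7}" + "  ".join(f"{v:6.3f}" for v in rms))

print("\nRMS spread across wrist positions (open grasp), per channel:")
for c, ch in enumerate(layout.channel_ids):
    by_pos = {}
    for t in trials:
        if t.motion_class == "open":
            by_pos.setdefault(t.wrist_position, []).append(
                np.sqrt(np.mean(t.signal[c] ** 2))
            )
    means = [np.mean(v) for v in by_pos.values()]
    print(f"  {ch}: max/min position RMS ratio = {max(means) / min(means):.2f}")

print("\nRest sits at the noise floor; extrinsic channels (ext*) swing far "
      "more across positions than intrinsic ones (int*), which is the wrist-"
      "position effect the evaluation module quantifies.")
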