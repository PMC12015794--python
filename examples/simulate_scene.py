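"""Generate a small synthetic cohort and write it in the on-disk layout.

The simulator emulates what a pose estimator would emit for a videotaped
free-play observation: per-frame Body25 JSON files for a child (who flaps
and jumps on schedule) plus static adults, from two mirrored Full HD
cameras, with ground-truth interval annotations alongside.
"""

from pathlib import Path

import mannerkit as mk

out_dir = Path("scratch/example_sim")
config = mk.default_cohort(n_subjects=2, segment_duration_s=12.0, seed=1)
cohort = mk.simulate_cohort(config, out_dir=out_dir)

n_frames = len(cohort.frames[("s01", "cam1")])
print(f"subjects: {config.n_subjects}, cameras: {config.n_cameras}")
print(f"frames per stream: {n_frames} "
      f"({config.segment_duration_s} s x {config.fps} fps)")
print(f"annotation intervals: {len(cohort.annotations)}")
print(cohort.truth.head(5).to_string(index=False))
print(f"wrote frame files + annotations.csv + sim_config.yaml under {out_dir}")
# Each truth row gives one scripted interval per camera with its expected
# number of 15-frame windows and [flapping, jumping] label bits.
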