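"""From tracked keypoints to balanced (15, 60) training windows.

Preprocessing: keypoints with confidence < 0.6 are zeroed, coordinates
are normalized by the frame resolution, the six arm keypoints of up to
five persons are laid side by side (60 features/frame), and annotated
intervals are tiled into non-overlapping 15-frame windows. Undersampling
then balances no-mannerism windows 1:1 against the positives.
"""

from collections import Counter

import mannerkit as mk

config = mk.default_cohort(n_subjects=4, segment_duration_s=24.0, seed=2)
cohort = mk.simulate_cohort(config)

windows = mk.windows_from_sim(cohort)
print(f"windows from {config.n_subjects} subjects x 2 cameras: {len(windows)}")
print(f"window shape: {windows[0].features.shape}  (timesteps x features)")

counts = Counter(w.label.as_tuple() for w in windows)
print("label distribution before balancing:", dict(counts))

balanced = mk.select_and_balance(windows, seed=2)
pos = sum(w.label.is_positive for w in balanced)
print(f"after balancing: {len(balanced)} windows "
      f"({pos} with mannerisms, {len(balanced) - pos} without)")
# (0,0)=no mannerism, (1,0)=flapping, (0,1)=jumping, (1,1)=both; balancing
# draws exactly as many no-mannerism windows as there are positives.
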