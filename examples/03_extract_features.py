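"""From a recording to its 168-value Fourier feature vector.

Each straight segment yields 42 main frequencies (Hz) + 42 phases; the
per-record vector averages front and back segments separately:
[front freqs | front phases | back freqs | back phases].  The printed
ankle main frequency recovers the generating stride frequency.
"""

from gaitmood import (
    GaitParams,
    aggregate_record,
    preprocess_record,
    segment_features,
    simulate_record,
)
from gaitmood.features import FEATURE_NAMES_168
from gaitmood.joints import MOTION_COLUMNS_42

params = GaitParams(stride_freq=1.1, noise_sd=0.0, seed=2)
record = simulate_record(params)
segments = preprocess_record(record)
seg_feats = [segment_features(s, record.frame_rate) for s in segments]
vector = aggregate_record(seg_feats, provenance="example")

print(f"segments: {len(segments)} "
      f"({vector.n_front} front, {vector.n_back} back)")
print(f"feature vector length: {vector.values.shape[0]}")

col = MOTION_COLUMNS_42.index("AnkleL_z")
name = FEATURE_NAMES_168[col]
print(f"{name} = {vector.values[col]:.3f} Hz "
      f"(generator stride frequency: {params.stride_freq} Hz)")
# The extracted main frequency sits within one FFT bin (~0.2 Hz for a
# ~150-frame segment) of the stride frequency that generated the walk.
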