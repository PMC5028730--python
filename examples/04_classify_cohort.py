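"""End-to-end emotion classification on a synthetic cohort.

Simulates 20 subjects walking once neutrally and once 'angry' (cadence
+0.15 Hz, arm swing x1.3), extracts the 168 Fourier features per record
and runs seeded stratified 10-fold cross-validation with the four
wrapped classifiers.  Accuracy is the pooled proportion of correctly
classified records; ~0.5 would be chance.
"""

from gaitmood import (
    EmotionEffect,
    GaitParams,
    aggregate_record,
    evaluate_all,
    make_binary_task,
    preprocess_record,
    segment_features,
    simulate_cohort,
)
from gaitmood.features import records_to_table

effects = [
    EmotionEffect(label="neutral"),
    EmotionEffect(label="angry", delta_freq=0.15, amp_scale_arms=1.3),
]
records = simulate_cohort(20, GaitParams(), effects, seed=0)

vectors, ids, labels = [], [], []
for rec in records:
    segs = preprocess_record(rec)
    vectors.append(
        aggregate_record(
            [segment_features(s, rec.frame_rate) for s in segs],
            provenance=rec.subject_id,
        )
    )
    ids.append((rec.subject_id, rec.condition, rec.camera_id))
    labels.append(rec.condition)

table = records_to_table(vectors, ids, labels)
task = make_binary_task(table, "angry", "neutral")
print(f"task: angry vs neutral, {task.n_instances} records")
for name, report in evaluate_all(task, seed=0).items():
    print(f"  {name:13s} accuracy {report.accuracy:.3f}")
# The cadence shift separates the classes through the frequency
# features; accuracies well above 0.5 show the pipeline recovers it.
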