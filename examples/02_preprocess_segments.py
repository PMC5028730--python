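"""Run the preprocessing chain and inspect the straight-walking segments.

Shows each stage's output shape and the segments the turn detector
keeps: their orientation (front = toward the camera), start/stop row
and length in frames.  Segments shorter than 40 frames (less than one
stride) are discarded.
"""

from gaitmood import (
    GaitParams,
    differentiate,
    gauss_smooth,
    segment_record,
    select_joints,
    simulate_record,
    to_body_frame,
)

record = simulate_record(GaitParams(duration=30.0, seed=1))

selected = select_joints(record)
body = to_body_frame(selected)
smoothed = gauss_smooth(body)
differenced = differentiate(smoothed)
print(f"selected:    {selected.values.shape} (stage={selected.stage})")
print(f"body frame:  {body.values.shape}")
print(f"smoothed:    {smoothed.values.shape}")
print(f"differenced: {differenced.values.shape}")

segments = segment_record(differenced)
for seg in segments:
    print(f"  segment rows {seg.start:4d}..{seg.stop:4d}  "
          f"{seg.orientation:5s}  {seg.n_frames} frames")
print(f"{len(segments)} straight-walking segments "
      "(turn windows and short runs dropped)")
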