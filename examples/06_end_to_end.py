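"""Full pipeline on a synthetic scene: simulate, detect, classify, score, trigger.

Renders the benign reference scene (20 frames, three high-contrast
flocks of six birds), runs motion detection and the heuristic
classifier on every frame, scores flock recall against the simulator's
ground truth, and replays the detections through the trigger policy.
"""

import flockwatch as fw
from flockwatch.classify import ObjectClass
from flockwatch.evaluation import recall
from flockwatch.pipeline import detect_and_classify, score_sequence
from flockwatch.trigger import FlockTrigger

frames, annotations = fw.generate_scene(fw.benign_reference_scene(seed=1))
per_frame = detect_and_classify(frames, fw.HeuristicClassifier())

counts = score_sequence(per_frame, annotations, start_frame=1)
flock = counts[ObjectClass.FLOCK]
print(f"flock ground truth (frames 1-19): {flock.gt}")
print(f"flocks detected correctly:        {flock.tp}  (missed {flock.fn}, false {flock.fp})")
print(f"flock recall:                     {recall(flock)}%")

events = FlockTrigger().run(per_frame)
print(f"trigger events: {len(events)} (first at frame "
      f"{events[0].frame_index if events else '-'})")

print(
    "\nThe detector finds every bird blob, the classifier groups each cluster\n"
    "of six into a flock, and matching at IoU 0.5 against the simulator's\n"
    "ground truth gives the recall above (frame 0 only initialises the\n"
    "detector).  Every frame with a qualifying flock fires the actuator."
)
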