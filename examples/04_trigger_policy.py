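"""Replay a detection stream through the flock-only actuation policy.

A confident individual bird never fires the actuator; a flock at the
30% confidence threshold (inclusive) does.  With two-frame confirmation
the flock must persist before the event is emitted.
"""

from flockwatch import BoundingBox, Detection, FlockTrigger, ObjectClass, TriggerPolicy

box = BoundingBox(40, 30, 90, 60)
stream = [
    [Detection(box, ObjectClass.BIRD, 0.99)],   # frame 0: lone bird, very confident
    [],                                          # frame 1: nothing
    [Detection(box, ObjectClass.FLOCK, 0.29)],  # frame 2: flock below threshold
    [Detection(box, ObjectClass.FLOCK, 0.35)],  # frame 3: flock above threshold
    [Detection(box, ObjectClass.FLOCK, 0.41)],  # frame 4: still there
]

for confirm in (1, 2):
    machine = FlockTrigger(TriggerPolicy(confidence_threshold=0.30, confirm_frames=confirm))
    events = machine.run(stream)
    print(f"confirm_frames={confirm}: events at frames "
          f"{[e.frame_index for e in events]} "
          f"(confidences {[e.confidence for e in events]})")

print(
    "\nWith immediate firing the actuator triggers at frames 3 and 4; requiring\n"
    "two consecutive confirmations delays the first event to frame 4.  The bird\n"
    "and the sub-threshold flock never fire."
)
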