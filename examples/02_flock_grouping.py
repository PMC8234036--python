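"""Group clustered bird detections into flocks (five or more birds).

Shows the boundary of the flock definition: four birds flying together
stay individual birds, five become a single flock whose box hulls the
members and whose confidence is the members' mean.
"""

from flockwatch import BoundingBox, Detection, ObjectClass, group_flocks


def birds(n):
    return [
        Detection(BoundingBox(10 + 8 * i, 10, 14 + 8 * i, 14), ObjectClass.BIRD, 0.6 + 0.05 * i)
        for i in range(n)
    ]


for n in (4, 5):
    grouped = group_flocks(birds(n), proximity=10)
    labels = [f"{d.label.value}({d.confidence:.2f})" for d in grouped]
    print(f"{n} clustered birds -> {labels}")

print(
    "\nFour nearby birds pass through unchanged; five or more are replaced by\n"
    "one flock detection — the only class allowed to fire the scaring actuator."
)
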