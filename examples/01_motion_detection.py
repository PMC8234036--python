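"""Detect moving birds in a synthetic vineyard scene with frame differencing.

Builds a short sequence with one bird crossing a static background plus a
patch of quivering leaves, runs the differential detector, and shows how
the accumulated-background filter silences the quiver while the bird
keeps firing.
"""

import flockwatch as fw
from flockwatch.motion import MotionDetector

scene = fw.SceneConfig(
    width=96, height=64, n_frames=16, seed=4, noise_sigma=0.0,
    quiver=(fw.QuiverPatch(region=fw.BoundingBox(60, 40, 84, 56), amplitude=18),),
    objects=(fw.ObjectSpec(kind="bird", start=(6.0, 20.0), velocity=(3.0, 0.0),
                           size=3, intensity=255),),
)
frames, _ = fw.generate_scene(scene)

detector = MotionDetector()  # threshold 25, accumulator rate 0.05, min area 4
for frame in frames:
    boxes, store = detector.process(frame)
    print(f"frame {frame.index:2d}: {len(boxes)} object(s) {[b.as_list() for b in boxes]}")

print(
    "\nEach line lists the bounding boxes of moving objects in that frame.\n"
    "The leaf-quiver patch fires in the first frames but is absorbed by the\n"
    "accumulated background; the bird (fresh pixels every frame) is detected\n"
    "in every frame after the first, which only initialises the detector."
)
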