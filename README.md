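# woundmetry

Metric wound measurement from photographs, for clinicians and imaging
researchers following chronic wounds — diabetic foot ulcers in particular —
where a wound's area and perimeter over time track healing.

A photograph alone has no scale. `woundmetry` assumes each photo contains a
printed square **fiducial marker** of known physical size and that an
object detector (or a human) has supplied bounding boxes for the wounds and
the marker. It then:

1. **segments** each wound inside its box with GrabCut — iterated energy
   minimization alternating K-component Gaussian-mixture color models with
   a global graph min-cut, written from scratch on `scipy`'s max-flow;
2. **registers** the marker to its reference image: ORB feature
   correspondences, a direct-linear-transform (DLT) solve of the 2k×8
   system for the 3×3 homography `T` (bottom-right entry fixed to 1), and a
   photometric polish;
3. **gates** image quality on the rotation angle of `T` (beyond 15° the
   image is not analyzed further);
4. **transports** each wound contour through `T` into the marker's
   reference plane and reports area (mm²) and perimeter (mm), serialized as
   deterministic JSON reports.

A seeded synthetic-scene generator (perturbed-ellipse wounds of three
classes plus a warped marker, with exact ground truth) makes every stage
testable without patient data, and a dataset-preparation module handles the
detector-side bookkeeping: augmentation to a per-class target, Pascal-VOC
XML → CSV conversion with a fixed class-id map, and train/test splitting.

See `docs/methods.md` for the model, parameters, and limitations.

## Worked example

Generate three synthetic scenes with ground-truth annotations, convert the
annotations, and measure:

```sh
woundmetry synth --per-class 1 --out-dir scenes --seed 5
woundmetry dataset convert --xml-dir scenes --out ann.csv
python -c "from PIL import Image; from woundmetry.synthetic import make_reference_marker; \
           Image.fromarray(make_reference_marker()).save('marker.png')"
woundmetry measure scenes --detections ann.csv \
    --marker-ref marker.png --marker-mm 30 --out reports
```

which logs, per image:

```
INFO woundmetry: blocked_vessel_0000.png: blocked_vessel area 219.7 mm^2 perimeter 54.9 mm
INFO woundmetry: suture_0000.png: suture area 116.5 mm^2 perimeter 48.4 mm
INFO woundmetry: ulceration_0000.png: ulceration area 211.2 mm^2 perimeter 53.5 mm
```

Each `reports/*.json` holds the wound class, its contour in reference
coordinates, area and perimeter in physical units, the 3×3 transform, its
rotation angle and quality-gate decision, the RMS registration residual,
and the parameter hash. The same measurement is available in Python:

```python
import numpy as np
from woundmetry import DetectionRecord, MarkerReference, measure_wounds
from woundmetry.synthetic import default_scene_spec, generate_scene, make_reference_marker

image, truth = generate_scene(default_scene_spec("ulceration", seed=3, rotation_deg=5.0))
reference = MarkerReference.from_physical_side(make_reference_marker(), 30.0)
detections = [DetectionRecord(truth.boxes[0], "ulceration"),
              DetectionRecord(truth.marker_box, "marker")]
result = measure_wounds(image, detections, reference)
wound = result.measurements[0]
print(f"{wound.area_mm2:.1f} mm^2 vs truth {truth.areas_mm2[0]:.1f} mm^2")
# 270.2 mm^2 vs truth 270.7 mm^2
```

An image whose marker is rotated beyond 15° yields an empty measurement
list and `unanalyzable: true` in the report (exit code stays 0 — that is a
quality decision, not an error).

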