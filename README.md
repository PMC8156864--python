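# schooltrack

Online multi-fish tracking for backlit top-view footage of zebrafish
schools, built on shape-index appearance features and a parallel pair of
SORT-style trackers. It is aimed at behavioral researchers who need
per-individual trajectories from lab recordings of many visually identical
fish, where frequent crossings and occlusions defeat simple blob trackers,
and at anyone who wants a fully testable reference implementation: the
package ships a synthetic fish-school simulator with exact ground truth, so
every stage runs and is scored without any recorded video.

## The method

**Detection.** Frames are background-subtracted against a per-pixel temporal
median of the first *n* frames, and moving blobs are size-filtered connected
components of |background − frame| > threshold. Within each blob, the image
is treated as a height field and its local second-order geometry is
summarised by the shape index

```
s(x, y) = (2/π) · arctan((K₁ + K₂) / (K₂ − K₁)),   K₁ ≥ K₂,
```

where K₁, K₂ are the eigenvalues of the Hessian of the Gaussian-smoothed
image at scale σ. s maps every pixel onto [−1, 1] independently of contrast
and is banded into the nine Koenderink surface types. Two bands matter here:

* at σ_head (default 8 px) the opaque fish head is a dark local minimum —
  the **spherical cup** band, s ∈ [−1, −7/8); its size-filtered connected
  components become head boxes `h = B`;
* at σ_ridge (default 4 px) the body centerline is a dark line — the
  **rut** band, s ∈ [−5/8, −3/8); the band is thinned to the valley floor,
  Hough-transformed into a bundle of (ρ, θ) lines, and DBSCAN groups the
  bundle into one cluster per fish. Each cluster yields a body detection
  `b = (R, ω)`: R is the least-squares intersection of its lines and the
  motion state ω = max θ − min θ (degrees) measures how bent — hence how
  unsteadily swimming — the fish is.

**Tracking.** Head and body detections feed two cooperating SORT-style
trackers. Each confirmed track carries a constant-velocity Kalman filter on
(u, v, u̇, v̇); per frame, predicted boxes (inflated by 1 + k·ω/180, so
turning fish get wider association gates) are matched to detections by
Hungarian assignment on the IOU-distance cost c = 1 − IOU, with a minimum-IOU
gate. Unassigned detections enter a temporary-track pool and earn an
identity only after `min_hits` consecutive associations — recycling the
nearest lost ID if one exists; tracks unassociated for more than `max_age`
frames retire their ID to the lost pool. The head tracker is primary; when
a head goes undetected but the paired body track is matched, the head is
recovered as body point + last head-minus-body offset (rotated by the change
in body axis), and when both features vanish the track coasts on its
prediction. Tracking is strictly online: frame *t*'s output depends only on
frames ≤ *t*.

**Evaluation.** Predicted head points are matched to ground truth per frame
(Hungarian on distance, gated). The report contains detection
precision/recall, the occlusion rate (occlusion events per fish per frame),
the detection rate from occlusions, the correct tracking ratio
CTR = Σ correct frames / (fish × frames), the correct identification ratio
CIR (fraction of occlusion events after which every involved fish keeps its
pre-event identity) and the ID-switch count.

## Worked example

Simulate a 5-fish school, track it, and score the result against the
simulator's ground truth:

```bash
schooltrack simulate --n-fish 5 --frames 120 --seed 42 --out seq --truth gt.csv
schooltrack track --input seq --out traj.csv
schooltrack evaluate --pred traj.csv --truth gt.csv --dist-max 30 --start-frame 10
```

which prints

```
wrote 120 frames to seq
5 identities, 590 records -> traj.csv
{
  "precision": 100.0,
  "recall": 100.0,
  "occlusion_rate": 0.0,
  "detection_rate_from_occlusions": null,
  "ctr": 100.0,
  "cir": null,
  "ids": 0
}
```

Reading: the tracker holds exactly 5 identities over 120 frames (590
records — identities appear after a 3-frame confirmation burn-in, which
`--start-frame 10` excludes from scoring). Every detection matched a true
fish (precision) and every fish was found (recall); every fish-frame
carried the right identity (CTR = 100%) with no identity switches
(ids = 0). This seed produced no crossings, so the occlusion-conditional
scores (`detection_rate_from_occlusions`, `cir`) are undefined (`null`).
To force crossings, add e.g. `--cross 0,1,5,90`, which scripts fish 0 and 1
into an oblique path crossing between frames 5 and 90.

The same pipeline is available as a library:

```python
from schooltrack import SchoolSimConfig, simulate_school, track_video, evaluate_tracking

frames, truth = simulate_school(SchoolSimConfig(n_fish=5, n_frames=120, seed=42))
trajectory = track_video(frames)
report = evaluate_tracking(trajectory, truth, dist_max=30, start_frame=10)
print(report.rounded())
```

`schooltrack config --dump` prints every tunable with its default; a YAML
file plus `--set key=value` overrides configure all stages.

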