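# daphtrack

Automatic high-throughput video tracking of *Daphnia magna* for
behavioural ecotoxicology.

*Daphnia magna* is the standard bioindicator of acute aquatic toxicity:
its swimming activity drops measurably under exposure to heavy metals
and other pollutants, and regulatory assays score **immobility** — an
animal that stops moving counts as affected. Continuous monitoring
devices film animals in backlit flow cells (typically 15 fps) and need
software that turns raw video into per-animal trajectories and from
those into toxicity endpoints. `daphtrack` implements that full chain:

1. **Detection** — the background is the per-pixel rolling mean of the
   previous 20 s of frames; candidate objects are connected components
   of the absolute difference image, binarized at a threshold chosen
   automatically by 2-means clustering of the pixel values
   (threshold = (μ₁+μ₂)/2, the midpoint of the two cluster means).
2. **Classification** — each candidate's crop is resized to 8×8 by area
   averaging and described by its 64 Sobel gradient magnitudes; a
   random forest or RBF-SVM separates animals from nuisance objects
   (droplets, sediment, ghost smears).
3. **Tracking** — SORT-style online tracking: each track carries a
   constant-velocity Kalman state **x** = [u, v, s, r, u̇, v̇, ṡ]
   (centre, box area, aspect ratio and rates), and detections are
   assigned to predicted tracks by the Hungarian algorithm on the mixed
   similarity

   C₍ᵢⱼ₎ = (1−λ)·max(0, (max_d − d₍ᵢⱼ₎)/max_d) + λ·IOU₍ᵢⱼ₎

   combining normalized centroid distance with bounding-box overlap.
4. **Evaluation** — CLEAR MOT (MOTA, MOTP, ID switches) and identity
   metrics (IDP, IDR, IDF1) computed from MOT-Challenge CSV files.
5. **Behaviour & toxicity** — per-frame displacements, per-20-s average
   distances, removal of animals stationary ≥ 20 s, mobile counts, and
   a two-parameter log-logistic dose-response fit
   P(immobile | c) = 1/(1+(EC50/c)^slope) by maximum binomial
   likelihood.

A seeded synthetic scene generator (`daphtrack.synthgen`) renders dark
elliptical swimmers on a light background with static and drifting
nuisance objects plus per-frame ground truth, so every stage is
testable end to end without proprietary video.

## Worked example

```python
import daphtrack as dt
from daphtrack.config import PipelineConfig
from daphtrack.pipeline import default_classifier, run_pipeline_frames
from daphtrack.evaluate import evaluate_tracking, metrics_report

scene = dt.SceneParams(seed=7)          # 512x288, 450 frames @ 15 fps,
frames, gt = dt.generate_video(scene)   # 5 animals + 5 nuisance objects
cfg = PipelineConfig(seed=7)
clf = default_classifier(cfg, scene=scene)
res = run_pipeline_frames(frames, cfg, clf)
m = evaluate_tracking(gt, res.trajectories,
                      frames=range(res.start_frame, len(frames)))
print(metrics_report(m).to_string(index=False))
print(res.summary)
```

prints

```
Method  IDF1   IDP   IDR  IDs  MOTA  MOTP
  ours 100.0 100.0 100.0    0 100.0 100.0
{'n_trajectories': 5, 'mobile_count': 5, 'stationary_count': 0,
 'mean_distance': 1.1850731455787382, 'se_distance': 0.040071114721123915}
```

i.e. after the 20-s background warm-up (300 frames) every animal is
detected, classified and tracked without a single identity switch
(MOTA/MOTP/IDF1 all 100 %), all five animals are mobile, and they swim
1.19 ± 0.04 px/frame on average.

Dose-response fitting from an immobility count table:

```bash
$ daphtrack ec50 --table dose_response.csv
EC50 = 1.363, slope = 2.43, logLik = -35.046
```

where `dose_response.csv` holds `concentration,n_total,n_immobile`
rows; the EC50 is the concentration immobilizing half the animals.

The other subcommands mirror the pipeline stages: `daphtrack simulate`
(synthetic scene to PNG frames + MOT ground truth), `train` (patch
classifier), `track` (video to trajectories), `evaluate` (MOT metrics),
`behavior` (locomotory statistics).

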