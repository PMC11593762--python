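# entrofuse

Entropy-weighted ensemble fusion and evaluation of volumetric binary
segmentations, aimed at mitochondria segmentation in FIB-SEM image
stacks (and any similar 3D binary-mask problem).

Individual segmentation models fail in complementary ways: a
detection-based model may drop an entire organelle that a voxelwise
model finds, and vice versa. `entrofuse` combines the predictions of
several models into a single, usually better mask by weighting each
model with the Shannon entropy of its calibration-metric profile and
averaging voxelwise.

## The method

For each model *j* in the ensemble, a vector of evaluation metrics
**Em**_j = (JI_F, JI_B, m_IoU, DSC, accuracy, precision, recall) is
computed on labeled calibration data. The vector is normalized to a
distribution p_i = m_i / Σ_l m_l and scored by its Shannon entropy

    H_j = −Σ_i p_i log₂ p_i        (divided by log₂ L in the default
                                    normalized convention, so H_j ∈ [0, 1])

Weights follow the entropy weight method — lower entropy, higher weight:

    w_j = (1 − H_j) / Σ_k (1 − H_k),   then renormalized to Σ w_j = 1

and the fused prediction is the voxelwise convex combination

    P(v) = Σ_j w_j · m_j(v),    mask(v) = 1  iff  P(v) ≥ t   (default t = 0.5)

The package also provides the full evaluation-metric suite built on an
exact integer confusion-count core (Jaccard foreground/background,
mean IoU, Dice, pixel accuracy, error rate, precision, recall/TPR,
TNR, and rank-based AUROC), slicewise preprocessing (CLAHE with clip
limit 2 on an 8×8 tile grid, then a 3×3 Gaussian blur), and a
synthetic phantom generator so the whole pipeline is testable without
datasets or trained networks.

## Worked example

Two models that each miss one distinct object (but are otherwise
perfect) are fused; weights are calibrated on a separate phantom of
identical spheres so both models prove equally good and receive
exactly half the weight each:

```python
from entrofuse import *

truth = generate_ground_truth(PhantomSpec(shape=(16, 32, 32), n_objects=4, seed=4))
pred_a, pred_b = scenario_complementary_fn(truth, n_missed_per_model=1, seed=4)

cal_truth = generate_ground_truth(
    PhantomSpec(shape=(16, 32, 32), n_objects=4, shape_mix=0.0,
                radius_range=(2, 2), tube_length_range=(6, 6), seed=99))
cal_a, cal_b = scenario_complementary_fn(cal_truth, n_missed_per_model=1, seed=4)

result = calibrate_and_fuse([(cal_a, cal_truth), (cal_b, cal_truth)],
                            [pred_a, pred_b], threshold=0.5)
for w in result.weights:
    print(f"{w.model_id}: H={w.entropy:.6f}  weight={w.normalized_weight:.3f}")
for pred in (pred_a, pred_b, ModelPrediction("fused", result.fused_mask)):
    cc = confusion_counts(pred, truth)
    print(f"{pred.model_id:8s} Dice={dice(cc):.4f}  JI_F={jaccard(cc):.4f}  "
          f"accuracy={pixel_accuracy(cc):.4f}")
```

prints

```
model_a: H=0.996437  weight=0.500
model_b: H=0.996437  weight=0.500
model_a  Dice=0.8799  JI_F=0.7856  accuracy=0.9891
model_b  Dice=0.9056  JI_F=0.8275  accuracy=0.9912
fused    Dice=1.0000  JI_F=1.0000  accuracy=1.0000
```

Each model alone misses one object (Dice < 1); with exactly equal
weights, every voxel predicted by either model reaches the inclusive
0.5 threshold, so the fused mask is the union of the two predictions —
here, the exact ground truth.

The same pipeline is scriptable from the shell:

```sh
entrofuse simulate --out-dir sim --seed 4 --shape 16 32 32 --n-objects 4 \
    --scenario complementary
entrofuse fuse --calib model_a=sim/truth.tif --calib model_b=sim/truth.tif \
    --calib-truth sim/truth.tif \
    --pred model_a=sim/pred_model_a.tif --pred model_b=sim/pred_model_b.tif \
    --out-dir fused
entrofuse eval --truth sim/truth.tif --pred fused=fused/fused_mask.tif \
    --out-dir report
```

`fused/weights.json` records each model's entropy and weight;
`report/metrics.csv` / `metrics.txt` hold the per-model metric table.

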