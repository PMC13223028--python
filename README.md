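# rehabprog

Explainable prognosis modelling for sensor-based neurorehabilitation.

Clinicians running physiotherapy programmes want a per-trial estimate of a
patient's functional recovery — a normalized score in [0, 1] reflecting
movement quality and the probability of regaining functional independence
— computed from what a markerless depth camera records during the session:
25 skeletal joints per frame (3-D position, quaternion orientation, and
colour-/depth-plane projections), a per-frame clinical indicator series,
and static covariates. They also want to see *which moments of the
exercise* drove the estimate, so the model's reasoning can be checked
against the key rehabilitation phases a therapist would mark.

`rehabprog` implements such a pipeline end to end:

* **Reinforced representation learning** (`rehabprog.rrl_core`) — a 1-D
  convolutional encoder maps each frame's 275 multimodal features to an
  embedding `z_t`; the trial is a finite-horizon MDP with states
  `s_t = z_t` whose continuous actions refine the embedding,
  `z*_t = z_t + tanh(a_t)`. An actor–critic with a diagonal-Gaussian
  policy maximizes the composite reward
  `r_t = α·Acc(t) + β·Align(t)` (α = 0.6, β = 0.4), where `Acc` and
  `Align` measure how well an auxiliary per-frame score matches the trial
  label and the per-frame clinical recovery scale γ_t, using one-step TD
  advantages `Â_t = r_t + ζ·V_{t+1} − V_t`.
* **Attention-explainable prediction** (`rehabprog.xpt_core`) — refined
  embeddings are fused with the clinical series, contextualized with
  sinusoidal positions plus a clinical context vector, encoded by a
  multi-head self-attention transformer, pooled by temporal attention
  `α_t = softmax(uᵀ tanh(W_a h_t))`, `v = Σ α_t h_t`, and mapped to
  `ŷ = σ(W_o v + b_o)`. Training minimises the dual objective
  `L_total = L_pred + λ·H(α)`: prediction loss plus an attention-entropy
  penalty that drives the weights toward sparse, inspectable time points.
* **Evaluation suite** (`rehabprog.eval_metrics`) — classification and
  regression metrics, Brier score and reliability binning, subject-wise
  cross-validation planning (no participant spans two splits), Cohen's κ
  for inter-rater agreement, paired fold t-tests, attention entropy, and
  the attention alignment score (AAS: overlap of the most-attended frames
  with therapist-annotated key-event windows, reported with its chance
  level).
* **Explainability artifacts** (`rehabprog.explainability`) —
  temporal×joint attention heatmaps, native Shapley attributions
  (exact enumeration or permutation sampling) over named kinematic
  summary features, and correct/incorrect case reports.
* **Synthetic cohort generator** (`rehabprog.cohortsim`) — no public
  dataset with this structure exists, so the package ships a seeded
  generator producing quality-parameterized joint trajectories with
  label-relevant key events confined to annotated windows, per-frame
  clinical scales, and a multi-rater annotation panel with controllable
  agreement. This is first-class, tested code: all shipped experiments
  run on it.

The networks run on a small NumPy reverse-mode autodiff engine included
in the package; every gradient path is verified against central finite
differences in the test suite.

## Worked example

```python
import numpy as np
import rehabprog as rp
from rehabprog.interface_io import cohort_arrays
from rehabprog.pipeline import cross_validate
from rehabprog.training import DESK_TRAIN_CONFIG

cfg = rp.GeneratorConfig(seed=7)          # 60 subjects x 2 exercises, T=100
samples, profiles = rp.generate_cohort(cfg)
data = cohort_arrays(samples)

cv = cross_validate(data, rp.default_model_config(cfg),
                    DESK_TRAIN_CONFIG, k=5, val_fraction=0.1, seed=0)
p = cv.pooled
print(f"accuracy {p.accuracy:.3f}  F1 {p.f1:.3f}  RMSE {p.rmse:.3f}  "
      f"MAE {p.mae:.3f}  R2 {p.r2:.3f}")
print(f"AAS {p.aas:.3f} (chance {p.aas_chance:.3f})  AE {p.ae_mean:.3f}  "
      f"Brier {p.brier:.3f}")
```

On one CPU this trains five folds (a few minutes) and prints:

```
accuracy 0.867  F1 0.873  RMSE 0.124  MAE 0.096  R2 0.755
AAS 0.077 (chance 0.100)  AE 0.906  Brier 0.124
```

Reading: pooled over all held-out subjects, the model classifies
functional independence (score ≥ 0.5) correctly 86.7 % of the time and
explains 75.5 % of the recovery-score variance; the attention is sparse
(entropy 0.91 vs ln 100 ≈ 4.6 for uniform) but its overlap with the
therapist-annotated key-event windows sits at the chance level — see
`docs/methods.md` (Known limitations) for why temporal-attention
alignment does not emerge at this cohort scale and which ablation makes
it appear.

The same pipeline is scriptable from the shell:

```bash
rehabprog simulate --config run.yaml --out data/
rehabprog train    --config run.yaml --data data/ --out run/ --fold 0
rehabprog evaluate --config run.yaml --data data/ --out eval/
rehabprog ablate   --config run.yaml --data data/ --out ablation/
rehabprog explain  --config run.yaml --data data/ \
                   --model run/checkpoint.h5 --out explain/
```

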