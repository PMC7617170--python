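# physeg

Physics-informed, acquisition-invariant brain tissue segmentation from
quantitative MRI, with calibrated volumetric uncertainty and multi-site
harmonisation.

## The problem

Conventional MR images are qualitative: the same brain scanned with
different sequence parameters (inversion time, repetition time, flip
angle…) produces different contrasts, and segmentation tools trained on
one contrast regime drift on another.  In multi-site studies this turns
acquisition choices into spurious biological signal.  `physeg`
approaches the problem from quantitative maps: given per-voxel R1, R2*
and proton density (an MPM), any contrast can be *simulated* with
closed-form static signal equations, and tissue labels can be derived
from R1 directly, independent of any contrast.  A segmentation network
trained on simulated contrasts — told the acquisition parameters it is
seeing, and penalised whenever the same anatomy under different
contrasts yields different features — becomes largely invariant to the
acquisition, and its Monte-Carlo sampling uncertainty flags parameter
regimes it cannot handle.

It is intended for researchers in quantitative neuroimaging who want
contrast-robust tissue volumes, calibrated volumetric error bounds, and
site-comparable statistics.

## The model

- **Simulation**: MPRAGE
  `b = G_S·PD·(1 − 2e^{−TI/T1}/(1 + e^{−TR/T1}))` with `TR = TI + pTD`,
  and SPGR
  `b = G_S·PD·sinθ·(1−e^{−TR/T1})/(1−cosθ·e^{−TR/T1})·e^{−TE/T2*}`.
- **Physics Gold Standard labels**: per-voxel class responsibilities of
  R1 under fixed tissue Gaussians — GM 𝒩(0.683, 0.080²),
  WM 𝒩(1.036, 0.080²), CSF 𝒩(0.240, 0.030²) s⁻¹ — constant across every
  simulated contrast of a subject.
- **Network**: a 3-D U-Net (30→60→120→240 channels) whose encoded
  acquisition vector is injected through a two-layer branch at two
  points, with Monte-Carlo dropout and an optional heteroscedastic σ
  branch.
- **Stratification loss**: batches hold N same-subject, same-location,
  different-contrast patches with one shared label; the mean pairwise
  squared feature difference `(1/C(N,2))·Σ_{a<b} mean (F_a − F_b)²` is
  penalised so features become contrast-invariant.
- **Heteroscedastic loss attenuation**:
  `L = mean_v log (1/T) Σ_t exp(CE(f + σε_t))`, reducing exactly to
  cross-entropy at σ = 0.
- **Percentile volumes**: T sampled segmentations, voxelwise-sorted,
  summed → a monotone volume sequence V_p; a monotone piecewise-linear
  map fitted on validation subjects calibrates nominal to empirical
  percentiles, giving volume intervals with the advertised coverage.
- **ComBat-style harmonisation**: `y = α + Xβ + γ_i + δ_i·ε` per
  feature, method-of-moments per site, exactly idempotent, preserving
  age trends.

The network, losses and training loop run on a small numpy
reverse-mode autodiff core (`physeg.nn`) — CPU-only, bit-reproducible
under a fixed seed.  See `docs/methods.md` for assumptions, defaults,
and design decisions.

## Worked example

Simulate two MPRAGE contrasts of a synthetic head phantom, label it
from R1, and segment both contrasts with a freshly trained desk-scale
model:

```python
import numpy as np
from physeg import (
    PhantomSpec, generate_phantom, pgs_labels, MPRAGEParams,
    mprage_signal, TrainConfig, train,
)
from physeg.train import evaluate_fan

# four phantom subjects: three to train on, one held out
subjects = []
for i in range(4):
    mpm, _ = generate_phantom(PhantomSpec(shape=(32, 32, 32), seed=i))
    subjects.append((mpm, pgs_labels(mpm)))

config = TrainConfig.smoke(physics=True, strat=True, seed=0,
                           max_iterations=300, iterations_per_epoch=50,
                           max_epochs=6)
net, history = train(subjects[:2], subjects[2:3], config)

fan = [MPRAGEParams(ti=ti, ptd=1.05) for ti in (0.6, 0.9, 1.2)]
dice, cov, _ = evaluate_fan(net, *subjects[3], fan)
print({k: round(v, 3) for k, v in dice.items()})
print({k: round(v, 4) for k, v in cov.items()})
```

```
{'csf': 0.828, 'gm': 0.832, 'wm': 0.671}
{'csf': 0.0584, 'gm': 0.0502, 'wm': 0.0528}
```

The first line is the Dice overlap of the network's segmentation with
the held-out subject's Physics Gold Standard, averaged over the three
inversion times; the second is the coefficient of variation of each
tissue's soft volume across those contrasts — the acquisition-invariance
surrogate (about 5–6% volume spread across contrasts after 300 CPU
iterations on two training subjects; longer training at larger patches
tightens both).

The same pipeline is scriptable from the shell:

```bash
physeg phantom --out work/phantom --seed 1
physeg simulate --r1 work/phantom/phantom00_r1.nii.gz \
    --r2s work/phantom/phantom00_r2s.nii.gz \
    --pd work/phantom/phantom00_pd.nii.gz \
    --mask work/phantom/phantom00_mask.nii.gz \
    --n 5 --seed 2 --out work/sim
physeg make-labels --r1 work/phantom/phantom00_r1.nii.gz \
    --r2s work/phantom/phantom00_r2s.nii.gz \
    --pd work/phantom/phantom00_pd.nii.gz \
    --mask work/phantom/phantom00_mask.nii.gz \
    --out work/labels.nii.gz
```

plus `physeg train`, `physeg sample`, `physeg calibrate`,
`physeg ugrid`, `physeg evaluate`, `physeg harmonise`, `physeg trends`.

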