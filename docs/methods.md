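# Methods

`physeg` implements a physics-informed, acquisition-invariant pipeline
for brain tissue segmentation from quantitative MRI, together with the
uncertainty and harmonisation machinery needed to turn segmentations
into calibrated, site-comparable volume measurements.  This note records
the model, its assumptions, the tunable parameters, and the design
decisions taken where more than one reasonable construction existed.

## Signal model

Quantitative multi-parametric maps (MPMs) describe each voxel by its
longitudinal relaxation rate R1 (s⁻¹), effective transverse relaxation
rate R2* (s⁻¹), and proton density PD (a.u.) — intrinsic tissue
properties independent of any acquisition.  Contrast-weighted images are
simulated by closed-form *static* signal equations, which ignore the
temporal dynamics of the sequence (no Bloch simulation, k-space, or
readout effects):

- **MPRAGE** (inversion-prepared T1-weighted gradient echo):
  `b(x) = G_S · PD(x) · (1 − 2 e^{−TI/T1(x)} / (1 + e^{−TR/T1(x)}))`,
  with `T1 = 1/R1` and the exact identity `TR = TI + TD + τ = TI + pTD`.
  The pseudo delay `pTD = TD + τ` is the natural second free parameter:
  sampling (TI, pTD) spans the (TI, TR) plane without violating
  `TR ≥ TI`.
- **SPGR** (spoiled gradient echo):
  `b(x) = G_S · PD(x) · sinθ · (1 − E)/(1 − cosθ·E) · e^{−TE/T2*}`,
  `E = e^{−TR/T1}`.

The scanner gain `G_S` is a global multiplicative constant (default 1).
The MPRAGE signal is kept *signed* by default — it is negative for
inversion times short of a tissue's null point — because that is what
the closed form produces; a magnitude mode mimics typical
reconstructions.  All times are SI seconds internally; configuration
interfaces accept milliseconds and degrees, the units in which sequence
parameters are conventionally printed.

Default parameter ranges: MPRAGE training TI ∈ [600, 1200] ms and
pTD ∈ [500, 1600] ms (so TR ∈ [1100, 2800] ms); out-of-distribution
evaluation extends TI to [100, 2000] ms.  SPGR training TR ∈ [15, 100]
ms, TE ∈ [4, 10] ms, flip angle ∈ [15, 75]°.  Uncertainty grids span
TI ∈ [400, 2000] ms × pTD ∈ [200, 2000] ms (MPRAGE) and TR × flip angle
with TE fixed at 4 ms (SPGR).

## Physics Gold Standard labels

Tissue labels are derived from R1 alone, never from a simulated
contrast, so one subject has exactly one label map regardless of how
many contrasts are simulated from it.  Each class is a Gaussian over R1:
GM 𝒩(0.683, 0.080²), WM 𝒩(1.036, 0.080²), CSF 𝒩(0.240, 0.030²), all
s⁻¹.  These values are only physiologically consistent read as *rates*
(T1 ≈ 1.46/0.97/4.17 s at 3T), and that is how they are used.  A voxel's
soft label is the posterior responsibility of each class under these
fixed Gaussians with equal priors; there is no per-subject EM refit by
default (labels are then exactly reproducible and constant per subject),
though an optional EM mode refines sds and priors with the means frozen.
Background is an explicit fourth channel (exactly 1 outside the
intracranial mask) so losses are defined on whole patches.  Hard labels
are the channel argmax with ties broken to the lower channel index
(CSF < GM < WM < background).

## Synthetic phantoms

The phantom generator exists so that every downstream stage is testable
without any real data.  It emulates the statistical structure the method
assumes: a skull-stripped three-compartment head (WM core ⊂ GM ribbon ⊂
CSF shell, nested randomly deformed ellipsoids), per-class R1 drawn from
the label-model Gaussians (spatially smoothed, preserving the class
mean), class-constant R2* and PD chosen for plausible contrast (CSF/GM/WM
R2* = 1/16/21 s⁻¹, PD = 1.0/0.85/0.70 — the label model never reads
them), and Gaussian-blurred one-hot labels that create partial-volume
boundary voxels.  What phantoms deliberately lack: cortical folding,
extra-cranial tissue, realistic noise texture, B1/B0 artefacts.  Tests
passing on phantoms therefore demonstrate the *mechanics* of the method
(simulation, labelling, invariance pressure, calibration), not clinical
segmentation accuracy.

## Network

A 3-D U-Net conditioned on the acquisition: the encoded physics vector —
MPRAGE (TR, TI, e^{−TR}, e^{−TI}); SPGR (TR, TE, FA_rad, e^{−TR},
e^{−TE}, sin FA), times in seconds, no further scaling — passes through
two fully connected layers (width 40) and is tiled over the spatial grid
and concatenated to the feature maps after the second encoder
convolution and after the second-to-last decoder convolution.  (The SPGR
vector's fifth entry is e^{−TE}; an inversion-time term is undefined for
SPGR.)  Channels start at 30 and double after each of the four
contracting blocks (30→60→120→240 at the bottleneck); each block is two
(3³ convolution + leaky-ReLU) pairs with a stride-2 first convolution;
upsampling is non-parametric trilinear interpolation with skip
concatenations; because the first convolution already halves the grid,
the final expansive block has no skip.  Dropout follows every activation
except the output convolutions (rate 0.5, first layer 0.05).  The
optional heteroscedastic branch mirrors the output block after the final
upsampling and ends in a softplus, giving per-voxel per-class noise
scales σ ≥ 0.

The "penultimate features" used by the stratification loss are the
activations entering the final 1³ output convolution, taken *before*
the second physics concatenation: the physics tile differs across batch
members by construction, and penalising that fixed difference would add
an un-optimisable constant to the loss.

The network, its losses, and training run on a small reverse-mode
automatic-differentiation core over numpy (`physeg.nn`): broadcasting
arithmetic, matmul, 3-D convolution as 27 shifted channel-mixing
matmuls, separable trilinear resampling as per-axis matrix products, and
stable log-sum-exp.  Parameters and activations are float32 by default
(float64 is available and is used for finite-difference gradient
verification in the tests); execution is single-threaded numpy, so runs
are bit-reproducible for a fixed seed.

## Losses

With soft targets c and probabilities p = softmax(f), the base loss is
the soft-target cross-entropy −Σ c log p averaged over voxels.

**Stratification.**  A batch holds N patches of one subject at one
location, simulated with N independent parameter draws, and one shared
label patch.  The stratification term is the mean over unique member
pairs of the mean squared element-wise feature difference — zero iff all
members agree, permutation-invariant, and added with *positive* sign and
weight λ = 1 by default: the objective enforces similarity between
same-anatomy features across contrasts.  Per-pair reduction is a mean
over elements so λ is resolution-independent.

**Heteroscedastic attenuation.**  The logits are perturbed with
reparameterised noise ε_t ~ 𝒩(0, σ²) and the per-draw cross-entropies
are averaged in the log domain over T draws (default 10):
`L = mean_v log (1/T) Σ_t exp(CE_t(v))`, computed with log-sum-exp over
classes and draws.  With σ ≡ 0 every draw coincides and L reduces
*exactly* to the cross-entropy above for any T (the per-voxel reduction
is a mean for the same reason).  Gradients flow to both f and σ, so the
network can buy loss reduction by declaring noise where it is genuinely
uncertain.

## Training

Batches of 4 patches (full scale 128³; desk-scale smoke preset 24³
with a 2-level, 8-channel network), Adam (1e-3), 150 iterations per
epoch by default.  The ablation arms are pure flags: `physics` (the
conditioning branch), `strat` (the stratification term), and
`pregenerated` (contrasts drawn from a fixed fan of 121 equally spaced
TIs prepared in advance, versus on-demand uniform sampling — the
"augmentation" regime).  Spatial augmentations (one affine + free-form
deformation per batch) are shared by all members and the label —
anything else would break the shared-label invariant the stratification
loss needs — while intensity corruptions (blur, polynomial bias field
with in-mask mean 1, in-mask Gaussian noise) are per-member.  There is
deliberately no gamma/contrast augmentation: contrast must remain
attributable to the sequence parameters.  Default corruption magnitudes
(bias amplitude 0.3, noise sd 0.02–0.1 of mean in-mask intensity, blur
0–1 voxel, ±10°/±10%/±2 voxels affine, 4³ deformation grid with ±4-voxel
displacement) are implementation defaults sized for 128³ patches; a
deformation whose crude fold-over check fails is resampled (5 tries).

Validation combines quality and invariance: mean over the three tissues
of (Dice against the PGS − volume CoV across a 5-contrast fan),
maximised; a plain sum of Dice and CoV cannot be coherently extremised
since the two move oppositely.  Early stopping after 7 epochs without
improvement; the best-metric weights are restored.

## Uncertainty

Epistemic uncertainty: T stochastic forward passes with dropout active
(T = 50 by default).  Aleatoric: T draws of softmax(f + σε).  A stack of
T probability maps becomes *percentile volumes*: each voxel's T values
are sorted ascending, giving T voxelwise-sorted maps whose voxel sums
V_p are non-decreasing in p.  Class volumes are soft (sums of
responsibilities), not argmax counts.

Calibration: for each validation subject, locate the quantile at which
the true volume falls within its V_p sequence (linear interpolation,
clamped with a warning outside the sampled range).  A monotone
piecewise-linear map (7 knots, endpoints pinned at 0→0 and 1→1, isotonic
projection) is fitted so those quantiles become uniform — the map is the
empirical quantile function of the observed quantiles evaluated on the
knot grid.  A calibrated level-c interval reads V at the mapped
[(1−c)/2, (1+c)/2] percentiles; the default c = 0.5 is the interquartile
range.  Epistemic and aleatoric sampling are kept separate (aleatoric
volume variance is orders of magnitude smaller; on the 2-voxel toy the
variance decomposition is exact).  Uncertainty-versus-parameter grids
tabulate mean volume and calibrated width (and its log, for contouring)
per tissue over a Cartesian parameter grid.

## Harmonisation

Per-subject tissue volumes y from multiple sites follow a location/scale
site-effect model around a shared covariate (age) trend:
`y = α + Xβ + γ_i + δ_i ε`.  Estimation is method-of-moments per site —
with three volume features there is nothing for empirical-Bayes
shrinkage to pool over — and is constructed to be *exactly* idempotent:
each site gets its own OLS fit; α/β are the subject-count-weighted means
of per-site coefficients; γ_i is the site-vs-shared fit difference at
the grand covariate mean (weighted zero-sum by construction, and best
determined there); δ_i is the within-site residual sd over the
ANOVA-pooled within-site sd.  Harmonisation subtracts the site fit,
rescales residuals by 1/δ_i, and restores the shared fit — refitting on
harmonised data recovers γ = 0, δ = 1 identically.  (A pooled-OLS
standardisation was considered and rejected: per-site residual rescaling
breaks global orthogonality, so repeated harmonisation would drift at
O(n^{−1/2}).)

Trend statistics: per-site OLS lines of feature vs age within cohorts
("Young" sites: mean age < 16; "Old": > 22; sites between, or with < 3
subjects, are excluded), summarised by across-site mean and sd of
intercepts and gradients.  Spread comparisons use the classic Levene
test (ANOVA on absolute deviations from group means, scipy).  Covariate
preservation is checked by K-fold cross-validated RMSE of a linear age
model on the three volumes (scikit-learn): harmonisation that scrubs
biology pushes this toward sd(age).

## Metrics

Dice on hard labels, with empty-vs-empty defined as 1.  Directed
Hausdorff from the surface voxels of A (erosion boundary) to the nearest
voxel of B, in millimetres via the voxel spacing, computed with a k-d
tree; empty masks yield inf with a warning.  CoV is the sample (n−1)
standard deviation over the mean of a subject's volumes across
contrasts.

## Problem sizes and numerical choices

The package trains on CPU, so the bundled study conditions are
deliberately desk-scale: 32³ phantoms, 24³ patches, a 2-level 8-channel
network with dropout 0.1, 300 Adam iterations, batches of 4, a fan of
11 inversion times spanning 100–2000 ms on 2 held-out phantoms, 3
training seeds, and T = 20 Monte-Carlo samples.  The full-scale
configuration (128³ patches, 30-channel 4-level network, dropout
0.5/0.05, T = 50, patience 7) is the default in the configuration schema
and is exercised structurally (built and run forward) in the tests.
Degenerate inputs are handled explicitly: empty phantom compartments,
non-nested geometry, mismatched NIfTI grids, non-finite volumes,
all-underflowing label densities (nearest-mean assignment with a
warning), fold-over deformations, empty metric masks, unseen
harmonisation sites, and sub-minimum site sizes all raise or warn as
documented.

## Known limitations

Only sequences expressible as static equations are simulatable; the
labels support coarse three-tissue segmentation, not finer parcellation;
phantom experiments demonstrate mechanism, not clinical accuracy; the
desk-scale directional comparisons (acquisition invariance, OoD
uncertainty growth) are stochastic by nature and are evaluated across
seeds rather than per-run.
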