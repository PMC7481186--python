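# Methods

This note documents the models, parameters and design choices behind the
package: what the synthetic-data generator simulates and deliberately does
not, how each analysis stage is defined, and the numerical decisions that
affect results.

## The synthetic experiment

Everything downstream operates on data from a simulated version of the
illusory-face experiment: 96 stimuli (32 human faces, 32 illusory faces,
32 matched objects yoked one-to-one to the illusory faces), MEG epochs of
−100..1000 ms at 1000 Hz across 160 channels with 24 repeats per stimulus
over 6 runs for 22 subjects, fMRI beta patterns for 96 stimuli × 7 runs in
four ROIs for 16 subjects, and 0–10 face-ness ratings from 20 raters.
Desk-scale configurations shrink subjects, exemplars, channels and the
time grid; all counts are configuration parameters.

### Representational trajectory (MEG)

The generator's central object is a time-varying 3×3 category-distance
matrix Δ(t) plus a within-category exemplar spread σ_ex(t), interpolated
piecewise-linearly between keyframes and exactly zero before the response
onset (default 80 ms).  The default trajectory encodes the empirically
observed dynamics:

| time (ms) | d(human, illusory) | d(human, matched) | d(illusory, matched) | σ_ex |
|-----------|-------------------:|------------------:|---------------------:|-----:|
| 130       | 0.80               | 1.00              | 0.40                 | 0.30 |
| 160       | 1.20               | 1.80              | 1.00                 | 0.40 |
| 260       | 1.60               | 1.80              | 0.25                 | 0.40 |
| 500       | 0.80               | 0.90              | 0.15                 | 0.30 |
| 1000      | 0.30               | 0.35              | 0.05                 | 0.20 |

i.e. all pairs separable by 130 ms; a 160 ms peak at which the illusory
faces sit closer to the human faces than the matched objects do and are
maximally distinct from their matched objects; by 260 ms the illusory
faces regroup with the objects while the human/object distinction peaks
again; a weak decaying tail afterwards.  Every keyframe is checked for
Euclidean embeddability (Torgerson double-centering; a negative
eigenvalue beyond tolerance is rejected at build time), and linear
interpolation between valid keyframes preserves the triangle inequality.

### From latent geometry to sensors

At each timepoint the three category centroids are embedded in a 2-D
latent subspace whose pairwise distances equal Δ(t) — two dimensions
suffice for any valid 3×3 distance matrix.  Each stimulus adds a fixed
per-exemplar offset in an orthogonal 2-D subspace, scaled by σ_ex(t);
offsets are drawn once per dataset and shared across subjects (stimulus
identity is stable), with yoked illusory/matched pairs correlated
(default 0.5) to mimic the visual similarity of yoked photographs.
Sensor data are a subject-specific random linear mixture of the latent
vector, times `signal_gain`, plus i.i.d. unit-variance Gaussian noise per
sample.  Temporal autocorrelation is not simulated: all analyses are
per-timepoint.

A third latent block carries a stimulus-*independent* evoked response:
48 dimensions with smoothly drifting direction over time, scaled by the
signal envelope (`evoked_gain`, default 10).  This component exists for a
specific reason.  The neural RDM metric is 1 − Spearman between patterns.
Without a shared response component, pattern correlation measures only
the *angle* between mean-centered patterns and need not vary
monotonically with the injected latent distances; a strong common
component makes 1 − correlation increase monotonically with distance.
Two further subtleties fix its form: (i) it must vary over time, because
PCA preprocessing removes the time-constant mean, and (ii) it must span
many directions, because a rank-one component collapses onto a single
principal component where rank (Spearman) correlation barely sees it —
exactly as the spatially extended, topography-changing evoked fields of
real MEG span many sensors.  Per-trial sensor noise additionally acts as
rank dithering; with the default noise (SD 1.0) the category-averaged
RDM reproduces the injected distance *ordering* at all keyframes.

### fMRI profiles

Each simulated ROI is defined by its own 3×3 category-distance matrix,
an exemplar spread, and a voxel-count range (drawn per subject from the
reported per-ROI size ranges).  Defaults: FFA and OFA separate illusory
faces from matched objects (d = 0.8 and 0.75, FFA slightly stronger, in
line with the reported effect sizes d≈0.64 vs d≈0.59); LO and PPA carry
the face/object distinction but zero illusory/matched separation.  Betas
are an ROI-specific random voxel projection of (centroid + offset +
constant baseline) plus run-level Gaussian noise (default SD 3.0, chosen
so ROI accuracies land in a plausible 55–70% band rather than
saturating).  Exemplar offsets are drawn from each dataset's own seed, so
independently generated MEG and fMRI datasets share *category geometry
only* — this is what makes "fusion significant only for ROIs carrying
illusory-face geometry" a well-posed recovery target.  With the default
yoke correlation active in both modalities, yoked similarity is a genuine
stimulus property shared across datasets and induces a small veridical
fusion correlation even in geometry-free ROIs; fusion validation
therefore disables yoke offset correlation to isolate category-geometry
transfer.

### Ratings and images

Per-image latent means are drawn from the category's Normal(mean, SD) —
defaults 9.96/0.10, 6.27/0.79, 0.70/0.36 — then each rater adds
independent noise (SD 0.25) and ratings clip to the 0–10 scale.  The
ceiling truncates human-face ratings slightly (the nominal mean lies
within one rater-SD of 10), biasing their sample mean down by roughly
0.1; tests account for this known truncation.

The stimulus *images* shipped by the generator are synthetic stand-ins,
not photographs: procedurally drawn textures in which each yoked pair
shares an object-like texture, illusory-face images superimpose a
moderate-contrast face configuration (eyes, mouth, head outline), and
human-face images show the configuration at high contrast on a clean
background.  They preserve the one property that matters for
image-computable models — face-configural structure shared between human
and illusory images and absent from matched objects — and claim no
visual resemblance to the original stimuli.  Conclusions about the real
photographs require the real photographs.

## Analysis stages

**Preprocessing.**  Downsampling is bin-mean (each output sample is the
mean of its block of source samples; times are bin centers) — a
deterministic anti-aliasing choice consistent with "5 ms resolution"
semantics.  PCA is fitted once per subject on all trial-timepoints
(observations = trials × timepoints, variables = channels) and the
smallest k components reaching 99% cumulative variance are kept; fitting
on the full epoch including the pre-stimulus window is this package's
choice where the alternative (post-onset only) is equally defensible.
Decoding consumes single trials; RDMs consume per-stimulus trial
averages.

**Decoding.**  LDA uses a pooled within-class covariance shrunk toward a
scaled identity, `(1−γ)S + γ(tr S/p)I`, with γ = 0.05 by default (trials
≪ features at high component counts); γ = 1 reduces exactly to nearest
centroid, and exactly zero within-class scatter falls back to the
identity scale (also nearest centroid).  Ties break toward the
lexicographically first label.  SVM is a linear soft-margin SVC, C = 1.
Scheme defaults follow the modality: exhaustive exemplar combinations
for MEG, combined run-by-exemplar for ROI betas, paired exemplar holdout
for the searchlight (which also uses the same linear SVM — no separate
solver).  For the illusory/matched pair, paired holdout follows the yoke
links so visually similar partners always leave training together.
Accuracy aggregates over folds first, then subjects.

**RSA.**  RDM vectorization is the strict row-major lower triangle
everywhere, so two RDMs with the same label order are always compared
cell-for-cell.  The group RDM is the arithmetic mean of subject RDMs, no
rank transform.  Kendall's tau-a is implemented directly (pair counting
with ties counted as neither) because common library implementations are
tau-b.  Classical MDS is Torgerson double-centering with a deterministic
sign convention (first nonzero loading of each axis positive).
Permutation p-values use the +1/+1 convention, so p is never 0.  Model
and fusion correlations exclude human faces by default; their strong
response otherwise dominates the correlation.  Fusion pairs the
group-average fMRI RDM with each MEG subject's RDMs (the cohorts are
different people) and draws inference across MEG subjects.

**Group statistics.**  TFCE uses E = 0.5, H = 2, dh = 0.1 (the standard
defaults; the parameterization is recorded in outputs).  Sign-flip
permutation uses the max-TFCE distribution across time for family-wise
control, one-tailed by default for the directional hypotheses
(decoding > chance, tau > 0); for 12 or fewer subjects all 2^n sign
patterns are enumerated instead of sampled.  t-maps cap |t| at 100:
zero across-subject variance (every subject at ceiling) otherwise
produces unbounded t and an unbounded TFCE height integral; no
realistic t approaches the cap.  BH-FDR and Bonferroni adjustments come
from statsmodels.

**GBVS and GIST.**  GBVS builds, per feature map (intensity contrast,
RG/BY color opponency, four Gabor orientations, two scales, interpolated
to 32×32), a fully connected Markov chain over locations with transition
weight |log(m_i/m_j)|·exp(−d²/(2σ²)), σ = 0.15 × map width; the
activation is the chain's stationary distribution, a second identically
structured pass concentrates mass, and channels sum with equal weights
to a map normalized to total 1.  The stationary distribution is obtained
by a dense linear solve for the exact fixed point (constant cost
regardless of spectral gap; near-uniform maps make plain power iteration
arbitrarily slow), with power iteration retained as an option and
cross-checked in tests.  GIST converts to grayscale at 256×256, applies
local contrast normalization (linear high-pass — removing any global
luminance offset exactly — then divisive normalization), filters with a
Fourier-domain Gabor bank (8 orientations × 4 scales), and pools mean
energies on a 4×4 grid → 512 values.  The original GBVS/GIST parameter
settings used with the real stimuli are not fully specified anywhere;
both implementations record their parameterization on every output so
settings are always inspectable, and the behavioral/model RDM
construction (absolute difference of per-image mean ratings; Spearman
default for model RDM correlations) is likewise a recorded configuration
choice.

## Validation strategy and problem sizes

The test suite validates in four layers: exact oracles (tau-a vs
exhaustive pair counting, MDS reconstruction of Euclidean RDMs, TFCE of
a unit impulse = 0.385, BH by hand, LDA closed form, GBVS stationary
distribution vs dense eigenvector, the 123-voxel radius-3 sphere);
statistical calibration under nulls (null decoding inside the binomial
99% band, super-uniform permutation p-values, TFCE family-wise error at
its nominal 5% over 200 replicate experiments); recovery of the injected
trajectory at reduced size (8 subjects, 8 exemplars per category, 64
channels, 50 timepoints at 100 Hz — sizes chosen to keep the full suite
comfortably interactive); and model/behavior recovery on the synthetic
images and ratings.  Passing these shows the machinery is correct and
calibrated and that the stated qualitative effects are recoverable when
present; it does not certify effect sizes or latencies in real
recordings, which depend on physiological noise structure (temporal
autocorrelation, artifacts, inter-subject misalignment) that the
generator intentionally omits.

## Known limitations

- No biophysical forward model, hemodynamic convolution, eye movements,
  artifacts or temporal autocorrelation in the simulated data.
- Spearman-based RDMs on low-dimensional latent signals are only
  ordinally faithful given a spread multi-directional evoked component
  and dithering noise (see above); with near-zero sensor noise the rank
  transform can distort cell orderings.
- Synthetic images are configural sketches; image-model statistics on
  them are qualitative checks of the machinery, not replications of the
  published image statistics.
- Fusion at desk scale has limited item counts (16–64 items → 120–2016
  RDM pairs), so chance geometric overlap between two fixed RDM
  structures is a real, subject-invariant effect of order 1/√pairs;
  single-timepoint detections outside the signal epoch are expected at
  the designed family-wise rate and beyond it when shared stimulus
  structure (yoking) is simulated in both modalities.
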