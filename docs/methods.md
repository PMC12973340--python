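# Methods

## Overview

`connvae` detects single-subject anomalies in multimodal brain connectivity.
Two matrices describe each subject over a fixed parcellation: functional
connectivity (FC, Pearson correlations of regional resting-state BOLD
signals, values in [−1, 1]) and structural connectivity (SC, streamline
counts from diffusion tractography normalized by the tractogram size,
non-negative and sparse). A variational autoencoder (VAE) is trained on
healthy subjects to reconstruct the concatenated, normalized upper triangles
of both matrices. Because the model learns only normative covariation,
lesion-induced deviations survive poorly in its reconstructions;
reconstruction error, calibrated against a healthy reference population,
becomes the anomaly signal. Network-level statistics (NAD, GD, OI) then
summarize which functional systems are altered per patient and how the
single-modality and integrated (FC+SC) views agree.

## Parcellation

The reference scheme has 210 parcels: 100 cortical parcels per hemisphere
labelled with the 17 Yeo networks (Schaefer-style), plus 5 subcortical
regions per hemisphere (thalamus, caudate, putamen, pallidum, hippocampus).
For network statistics the subcortical regions of each hemisphere are merged
into a single "Subcortical" network, giving 18 hemisphere-specific networks
per hemisphere, 36 in total. Parcel order is the single source of truth:
every matrix, vector, and flag index-aligns with it.

## Normalization chain

1. **SC counts → weights.** Counts are divided by the total number of
   streamlines (default 10⁷). Entries counting exactly one streamline are
   set to zero (single-streamline connections are tractography noise).
2. **Power-law harmonization.** SC weights are mapped by
   `(sc / sc_max)^α · (1 − ε)` with α chosen on the healthy *training* split
   by grid search (0.01…1.00, step 0.01) minimizing the Kolmogorov–Smirnov
   distance to the |FC| weight distribution. This brings the heavy-tailed SC
   distribution onto the FC scale so one normalization can serve both
   modalities. α and `sc_max` are frozen after fitting and reused for every
   other subject, including patients.
3. **Inverse hyperbolic tangent.** Both FC and transformed SC pass through
   `artanh` (entries clipped to ±(1 − ε), ε = 10⁻⁶, so the map stays
   finite). The model output is mapped back with `tanh`.
4. **Vectorization.** The strict upper triangles (row-major, i < j) of zFC
   and zSC are concatenated, zFC first. At P = 210 each block has 21,945
   entries and the model input length is N = 43,890.

Open choices made here: Fisher-z of FC and the artanh normalization are one
elementwise map (they are the same function); α is fitted on pooled
subject-level weights of the healthy training split rather than on a group
mean. Missing parcels (e.g., necrosis-excluded) carry a NaN sentinel through
FC estimation, are excluded from α fitting, and are zero-filled (the artanh
fixed point) in model vectors.

## The β-normalized VAE

Fully connected encoder (N→512→256→128) with leaky-ReLU activations
(slope 0.01), two linear heads producing 8 latent means and log-variances,
and a mirrored decoder (8→128→256→512→N) whose final layer is linear so the
artanh-domain targets are reachable. The loss is

    L = MSE(x, x̂) + β_norm · KL(q(z|x) ‖ N(0, I)),   β_norm = β·M/N

with β = 1, M = 8 latent dimensions, and the KL in closed form per sample,
½Σ(exp(logvar) + mean² − 1 − logvar). Normalizing β by M/N makes the KL
weight comparable across input sizes; with β_norm = 0 the objective reduces
exactly to a deterministic autoencoder. MSE is averaged over batch and
features, KL over batch, so reported losses are per-feature quantities.

Training uses Adam (lr 10⁻³), batch size 8, up to 2000 epochs with early
stopping (patience 750) on the total validation loss; validation passes use
the latent mean (deterministic), training draws one reparameterized sample
per input. The incoming weights count as the epoch −1 baseline, so the
returned model is never worse on validation than its starting point. All
randomness (initialization, shuffling, reparameterization draws) derives
from one seed; identical seeds give bitwise-identical loss histories.

The implementation is pure NumPy — linear layers, hand-derived
backpropagation, and Adam — and the analytic gradients are verified against
central finite differences in the test suite.

**Transfer learning.** The healthy-trained model is fine-tuned on a small
set of mildly affected patients (7 train / 3 validation) with the full
network trainable at a reduced learning rate (10⁻⁴ by default; an encoder
freeze is configurable but off, since the best layer subset to adapt is an
open question at this data scale). Validation for early stopping uses the
total loss, KL included.

**Inference.** Reconstruction always uses the latent mean — no sampling —
so it is deterministic. The decoder output is split into FC and SC blocks,
devectorized, passed through `tanh`, and reconstructed SC values below zero
are clamped to 0. Reconstructed SC stays in the power-law-transformed
domain; all downstream SC comparisons happen there.

## Anomaly statistic

Built exclusively from the healthy *test* split, reconstructed with the
healthy-trained model:

- **Masks.** Group-mean FC and transformed-SC matrices are thresholded at
  the 80th percentile (linear interpolation, strict inequality) of their
  upper-triangle weight distributions, retaining only the strongest ~20% of
  edges per modality. Signed FC weights are used (the strongest positive
  couplings); an absolute-value variant is configurable. The SC percentile
  is computed over all upper-triangle entries, zeros included.
- **Edge statistics.** Per masked edge, the mean and sample SD of the
  absolute original-vs-reconstruction differences across healthy test
  subjects. A subject's difference matrix is z-scored edge-wise against
  these; edges with SD < 10⁻¹² fall back to the pooled (mean) masked-edge SD
  of that modality. The z-score stands in for the original ad-hoc
  normalization, is isolated in one function, and can be replaced without
  touching the rest of the chain.
- **Integration.** The FC+SC difference matrix is the elementwise sum of the
  two normalized difference matrices, supported on the union of the masks.
- **Parcel scores.** Each parcel scores the mean normalized difference over
  its mask-retained row edges (mean rather than sum so parcels with unequal
  mask degree are comparable). Parcels with no retained edges score NaN and
  are never flagged.
- **Thresholds.** One scalar per modality: mean + 3·SD of the pooled healthy
  test parcel scores (parcels × subjects pooled; a per-parcel variant is
  available behind a flag). A parcel is impaired when its score strictly
  exceeds the threshold. For Gaussian scores this flags ≈ 0.135% — the
  calibration the test suite checks.

## Network metrics

For each of the 36 networks with K parcels, NAD = 100 · (impaired
parcels)/K. GD is the number of networks with NAD > 0, computed per modality
(the NAD > 0 decision is made on the exact integer count, not the float
percentage). OI_FC = 100 · |altered_FC ∩ altered_FC+SC| / |altered_FC|
(undefined when the denominator set is empty), and analogously OI_SC.
Networks are stratified by lesion tissue with precedence tumor > edema >
healthy; a network is in a tissue class when *any* of its parcels has an
overlap fraction above the threshold (default 0, i.e., any overlap). GD
indices are associated with tumor (T) and lesion (T+O) volumes by Pearson
correlation, OI values by Spearman, with Benjamini–Hochberg adjustment
across the family of tests run in one call.

Cohort summaries partition each altered network occurrence into exclusive
modality combinations. The six named combinations (FC only, SC only, FC+SC
only, FC∩FC+SC, SC∩FC+SC, FC∩SC∩FC+SC) leave one non-empty subset
unaccounted for — FC∩SC without the integrated modality — so a seventh
category completes the partition and the conservation property holds
exactly.

## Synthetic cohort

The generator emulates, at the matrix level, the data features the pipeline
depends on. It makes no attempt at biophysical realism (no hemodynamics, no
tractography error model); what passing tests show is that the *pipeline*
recovers planted effects under realistic matrix structure, not that it would
behave identically on acquired MRI data.

- **Healthy FC**: hemisphere-specific network block structure (within-network
  mean 0.5, between 0.1) plus a fixed template jitter (SD 0.1) giving a
  broad, continuous edge-weight distribution as in real group-mean FC, then
  per-subject symmetric Gaussian noise (SD 0.05), clipped inside (−1, 1).
- **Healthy SC**: edge support is Bernoulli with probability increasing in
  the FC rank (mean density 0.25), and log streamline counts also shift with
  the FC rank (coupling 2.0), so the strongest structural edges concentrate
  within networks — the property that keeps lesion damage structurally
  local. Counts are log-normal, divided by 10⁷; per-subject multiplicative
  log-normal jitter (SD 0.2).
- **Glioma subjects**: a lesion grows from a seed parcel on a
  parcel-adjacency graph (parcels sharing a hemisphere-network are mutually
  adjacent, plus a ring ordering within each hemisphere — a contiguity proxy
  since no geometry exists at matrix level). Tumor parcels are within
  `tumor_radius` hops, an edema ring beyond that. SC edges incident to tumor
  parcels are multiplied by `sc_effect` (default 0.3); FC rows of a
  deterministic distal network (the contralateral network diametrically
  opposite the lesion network in network order) are shifted by
  `fc_effect_distal` (default −0.3) and re-clipped. This plants the
  proximal-SC / distal-FC dissociation the detection stage is asked to
  recover. Fine-tuning patients carry the same lesion geometry with effects
  scaled toward null (scale 0.25), mirroring the use of minimally affected
  patients for domain adaptation. Volumes are parcel-count proxies (1000
  mm³ per parcel); only their ordering is meaningful.
- **Effect sizes are not literature-derived.** No quantitative
  glioma-induced connectivity change was available to calibrate against;
  defaults were chosen once for detectability and are documented as
  arbitrary.

Default study conditions: P = 60 parcels, 6 networks per hemisphere, 60
healthy training / 20 validation / 20 test subjects, 7 + 3 fine-tuning
patients, 10 patient test subjects. These sizes keep a full study — cohort,
300-epoch training, fine-tuning, reference, detection, metrics — around five
minutes on one CPU while leaving every pipeline stage statistically
meaningful. The reduced problem size (relative to a 210-parcel cohort of
hundreds of subjects) mainly lowers the input dimension N, which raises
β_norm accordingly; the loss scale is therefore not comparable to runs at
full dimension.

## Numerical choices and edge cases

- Symmetry tolerance for input matrices is 10⁻⁹: smaller asymmetries are
  averaged away, larger ones are data errors and rejected.
- All-equal matrices produce an empty percentile mask (warning), a NaN rank
  correlation, and NaN parcel scores — never silent zeros.
- Degenerate α fitting (all SC weights identical) returns α = 1 with a
  warning.
- Early stopping compares against the best seen validation loss with strict
  improvement; ties count as non-improvement.
- Pipeline stage outputs are rewritten on every run rather than cached:
  a full re-run costs minutes at this scale and recomputation removes a
  cache-staleness failure mode. Idempotence is guaranteed by seeding — a
  same-seed re-run is bitwise identical.
- The manifest records an access log of which stage read which subject; the
  test suite asserts patient test data is first touched at detection.

## Known limitations

- The per-edge z-score normalization of difference matrices is a declared
  substitute for the original unspecified procedure.
- Lesion growth on the network-adjacency graph is a topological proxy;
  parcels adjacent in space but in different networks are never lesioned
  together.
- Network-level flags saturate quickly: one impaired parcel alters a
  network, so GD is a coarse measure on small parcellations.
- The FC-only vs joint-training comparison is directional at a single seed
  and is reported as a warning rather than a hard failure when the ordering
  inverts; easy synthetic data can make the two ties.
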