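# connvae

Single-subject anomaly detection for multimodal brain connectomes.

Gliomas do not just damage tissue locally — they perturb the brain's
functional and structural networks, often far from the lesion. `connvae` is
a research package for detecting such perturbations at the level of the
individual patient, by fusing **functional connectivity** (FC, Pearson
correlations of regional resting-state BOLD signals) and **structural
connectivity** (SC, normalized streamline counts from diffusion
tractography) in a single normative model. It is aimed at neuroimaging
methods researchers who already have parcellated connectivity matrices and
want a tested, reproducible implementation of the full analysis chain —
from raw matrices to network-level alteration statistics — plus a synthetic
cohort generator so every stage can be exercised without clinical data.

## The model

Each subject is represented by the concatenated upper triangles of their
normalized FC and SC matrices over a 210-parcel scheme (200 Schaefer-style
cortical parcels carrying the 17 Yeo network labels + 10 subcortical
regions; 18 networks per hemisphere after subcortical merging). SC is first
harmonized to the FC scale by a data-driven power law,
`(sc/sc_max)^α`, with α fitted by a Kolmogorov–Smirnov grid search on the
healthy training split; both modalities then pass through an inverse
hyperbolic tangent. A β-normalized variational autoencoder

    L = MSE(x, x̂) + β·(M/N) · KL( q(z|x) ‖ N(0, I) )

(β = 1, latent size M = 8, input size N = 2·P(P−1)/2; encoder 512–256–128,
leaky-ReLU, Adam, early stopping) is trained on healthy subjects only, then
adapted to the patient domain by fine-tuning on a few minimally affected
patients. Reconstruction errors, masked to the strongest 20% of healthy
edges and z-scored against healthy-test per-edge statistics, give each
parcel an anomaly score per modality (FC, SC, and their sum FC+SC); a
parcel is *impaired* when its score exceeds the healthy mean + 3 SD. Per
network n with K parcels:

    NAD_n  = 100/K · Σ_k impaired_k          (network alteration degree)
    GD     = #{ n : NAD_n > 0 }              (global disruption, per modality)
    OI_FC  = 100 · |FC ∩ FC+SC| / |FC|       (overlap index; likewise OI_SC)

GD is tested against tumor (T) and lesion (T+O) volumes with Pearson
correlation, OI with Spearman, Benjamini–Hochberg corrected.

The VAE is implemented in NumPy (hand-derived backpropagation, verified
against finite differences in the test suite), so the package has no deep
learning framework dependency and results are bitwise reproducible from a
seed.

## Worked example

Simulate a small cohort and run the complete pipeline:

```sh
connvae simulate --spec demo_spec.yaml --out demo_cohort --seed 7
# wrote 27 subjects; manifest: demo_cohort/cohort.json
connvae run --cohort demo_cohort/cohort.json --out demo_run --seed 7 \
            --epochs 40 --patience 60
```

where `demo_spec.yaml` shrinks the generator (`parcel_count: 20`,
`networks_per_hemisphere: 3`, 8/4/6 healthy train/val/test, 3+2 fine-tune
patients, 4 test patients). The run prints its stage summary:

```json
{
 "preprocess": {"alpha": 0.96, "sc_max": 0.00262, "n_train": 8},
 "train":      {"epochs_run": 40, "best_val_total": 0.0550},
 "finetune":   {"n_train": 3, "n_val": 2, "epochs_run": 40},
 "reference":  {"n_test": 6, "thr": {"FC": 1.444, "SC": 1.408, "FCSC": 1.493}},
 "detect":     {"n_patients": 4}
}
```

`alpha` is the fitted power-law exponent, `best_val_total` the best
validation loss (per-feature scale), and `thr` the per-modality anomaly
thresholds (healthy mean + 3 SD of parcel scores). `demo_run/` then holds
the parcel×subject impaired tables, per-subject metrics, cohort summary and
volume associations. `subject_metrics.tsv` reads:

```
subject_id   GD_FC  GD_SC  GD_FCSC  OI_FC  OI_SC  volume_T  volume_TO  lesion_hemisphere
glioma_0023  2      1      0        0.0    0.0    5000.0    8000.0     right
glioma_0024  0      2      1               50.0   4000.0    6000.0     left
glioma_0025  1      1      0        0.0    0.0    4000.0    8000.0     right
glioma_0026  2      0      1        50.0          4000.0    7000.0     left
```

— e.g., patient `glioma_0024` has two SC-altered networks, one of which is
also altered in the integrated FC+SC view (OI_SC = 50%), and no FC-altered
networks (OI_FC is the undefined sentinel, left blank). At this toy scale
(40 epochs, 20 parcels) detection is coarse; the default study conditions
(60 parcels, 60/20/20 healthy subjects, 300 epochs) give a group-mean FC
reconstruction rank correlation of 0.99, healthy false-positive rates near
1% per modality, and full recovery of the planted tumor-parcel SC
attenuation — the quantities the acceptance script reports.

## Layout

- `connvae.parcellation` — parcel/hemisphere/network scheme, subcortical merging
- `connvae.io` — matrix and cohort-manifest I/O, domain types, run config
- `connvae.simulate` — synthetic healthy + glioma cohorts with ground truth
- `connvae.preprocess` — FC estimation, count normalization, power-law fit,
  artanh normalization, model vectors
- `connvae.vae` — the β-normalized VAE: build, train, fine-tune, reconstruct
- `connvae.anomaly` — healthy reference, difference statistics, impairment flags
- `connvae.metrics` — NAD/GD/OI, tissue stratification, volume associations
- `connvae.pipeline`, `connvae.cli` — end-to-end orchestration and the
  `connvae` command

See `docs/methods.md` for the full methodological account, including every
design decision and known limitation.
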