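"""End-to-end orchestration: preprocess -> train -> fine-tune -> detect -> metrics.

Stage order enforces the study design: normalization parameters and the model
come from the healthy training/validation splits, the anomaly reference
(masks, edge statistics, thresholds) exclusively from the healthy test split
reconstructed with the healthy-trained model, and patient test matrices are
first read at the detection stage (an access log makes this auditable).
Re-running with the same seed reproduces every numeric output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import anomaly as anom
from . import io as cio
from . import metrics as nm
from . import preprocess as prep
from . import vae as vae_mod
from .parcellation import ParcellationScheme, read_parcellation


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineManifest:
    config: dict
    vae_config: dict
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    access_log: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"config": self.config, "vae_config": self.vae_config,
                "stages": self.stages, "outputs": self.outputs,
                "access_log": self.access_log}


def _split(records: list[cio.SubjectRecord], cohort: str, split: str
           ) -> list[cio.SubjectRecord]:
    return [r for r in records if r.cohort == cohort and r.split == split]


def run_pipeline(
    cohort_manifest,
    out_dir,
    config: cio.RunConfig | None = None,
    vae_config: vae_mod.VAEConfig | None = None,
    skip_finetune: bool = False,
    finetune_overrides: dict | None = None,
) -> PipelineManifest:
    """Run the full anomaly-detection pipeline on a cohort manifest."""
    cohort_manifest = Path(cohort_manifest)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or cio.RunConfig()
    vae_config = vae_config or vae_mod.VAEConfig(seed=config.seed)

    with open(cohort_manifest) as fh:
        payload = json.load(fh)
    scheme = read_parcellation(cohort_manifest.parent / payload["scheme_path"])
    records = cio.read_cohort_manifest(cohort_manifest, scheme)

    manifest = PipelineManifest(config=config.to_dict(), vae_config=vae_config.to_dict())
    stage = "preprocess"

    def load(rec: cio.SubjectRecord):
        manifest.access_log.append({"stage": stage, "subject_id": rec.subject_id})
        return cio.load_subject_matrices(rec, cohort_manifest, scheme)

    try:
        # ---- preprocess: fit normalization on healthy train, freeze ----
        healthy_train = _split(records, "healthy", "train")
        healthy_val = _split(records, "healthy", "validation")
        if not healthy_train or not healthy_val:
            raise PipelineError("manifest lacks healthy train/validation splits")
        train_pairs = [load(r) for r in healthy_train]
        sc_pool = np.concatenate([
            prep.vectorize_upper(sc.values)[prep.vectorize_upper(sc.values) > 0]
            for _, sc in train_pairs
        ])
        fc_pool = np.concatenate([prep.vectorize_upper(fc.values)
                                  for fc, _ in train_pairs])
        params = prep.fit_civier_exponent(sc_pool, fc_pool)
        with open(out_dir / "normalization_params.json", "w") as fh:
            json.dump(params.to_dict(), fh)
        manifest.stages["preprocess"] = {"alpha": params.alpha, "sc_max": params.sc_max,
                                         "n_train": len(healthy_train)}

        def vectors(pairs):
            return np.stack([
                prep.subject_model_vector(fc, sc, params).values for fc, sc in pairs
            ])

        train_x = vectors(train_pairs)
        val_x = vectors([load(r) for r in healthy_val])

        # ---- train on healthy data ----
        stage = "train"
        model = vae_mod.train_vae(train_x, val_x, vae_config)
        model.save(out_dir / "model_healthy")
        manifest.stages["train"] = {
            "epochs_run": len(model.history),
            "best_val_total": min(h["val_total"] for h in model.history),
        }

        # ---- fine-tune on mildly affected patients ----
        stage = "finetune"
        if skip_finetune:
            detect_model = model
            manifest.stages["finetune"] = {"skipped": True}
        else:
            ft_train = _split(records, "glioma", "finetune_train")
            ft_val = _split(records, "glioma", "finetune_val")
            if not ft_train or not ft_val:
                raise PipelineError("manifest lacks fine-tune splits")
            ft_train_x = vectors([load(r) for r in ft_train])
            ft_val_x = vectors([load(r) for r in ft_val])
            detect_model = vae_mod.fine_tune(model, ft_train_x, ft_val_x,
                                             finetune_overrides)
            detect_model.save(out_dir / "model_finetuned")
            manifest.stages["finetune"] = {
                "n_train": len(ft_train), "n_val": len(ft_val),
                "epochs_run": len(detect_model.history) - len(model.history),
            }

        # ---- healthy reference from the healthy test split ----
        stage = "reference"
        healthy_test = _split(records, "healthy", "test")
        if len(healthy_test) < 2:
            raise PipelineError("need >= 2 healthy test subjects for the reference")
        originals, recons = [], []
        for rec in healthy_test:
            fc, sc = load(rec)
            zsc_t = prep.apply_power_transform(sc, params)
            vec = prep.subject_model_vector(fc, sc, params)
            fc_r, sc_r = vae_mod.reconstruct_subject(model, vec, params)
            originals.append((fc.values, zsc_t.values))
            recons.append((fc_r.values, sc_r.values))
        ref = anom.build_healthy_reference(
            originals, recons, config.percentile_cutoff, config.threshold_sd_multiplier)
        ref.save(out_dir / "healthy_reference.json")
        manifest.stages["reference"] = {"n_test": len(healthy_test), "thr": ref.thr}

        # ---- detect on patient test subjects ----
        stage = "detect"
        patient_test = _split(records, "glioma", "test")
        if not patient_test:
            raise PipelineError("manifest lacks glioma test subjects")
        results: list[anom.AnomalyResult] = []
        for rec in patient_test:
            fc, sc = load(rec)
            zsc_t = prep.apply_power_transform(sc, params)
            vec = prep.subject_model_vector(fc, sc, params)
            fc_r, sc_r = vae_mod.reconstruct_subject(detect_model, vec, params)
            results.append(anom.detect_subject(fc.values, fc_r.values, zsc_t.values,
                                               sc_r.values, ref, rec.subject_id))
        impaired_tables = {}
        for key in anom.MODALITY_KEYS:
            stacked = anom.stack_cohort([r.impaired[key] for r in results])
            df = pd.DataFrame(stacked.astype(int), index=list(scheme.parcel_ids),
                              columns=[r.subject_id for r in results])
            path = out_dir / f"impaired_parcels_{key}.tsv"
            df.to_csv(path, sep="\t")
            impaired_tables[key] = str(path.name)
        manifest.stages["detect"] = {"n_patients": len(results)}
        manifest.outputs["impaired_tables"] = impaired_tables

        # ---- network metrics ----
        stage = "metrics"
        per_subject = [
            nm.subject_metrics(res.impaired, scheme, rec)
            for res, rec in zip(results, patient_test)
        ]
        metrics_rows = [{
            "subject_id": m.subject_id,
            **{f"GD_{k}": m.gd[k] for k in anom.MODALITY_KEYS},
            "OI_FC": m.oi_fc, "OI_SC": m.oi_sc,
            "volume_T": rec.volume_T, "volume_TO": rec.volume_TO,
            "lesion_hemisphere": rec.lesion_hemisphere,
        } for m, rec in zip(per_subject, patient_test)]
        metrics_df = pd.DataFrame(metrics_rows)
        metrics_df.to_csv(out_dir / "subject_metrics.tsv", sep="\t", index=False)
        summary = nm.cohort_summary(per_subject, scheme)
        summary.to_csv(out_dir / "cohort_summary.tsv", sep="\t", index=False)
        tests = []
        for k in anom.MODALITY_KEYS:
            for vol in ("volume_T", "volume_TO"):
                tests.append((f"GD_{k}~{vol}", metrics_df[f"GD_{k}"].to_numpy(),
                              metrics_df[vol].to_numpy(), "pearson"))
        for oi in ("OI_FC", "OI_SC"):
            for vol in ("volume_T", "volume_TO"):
                tests.append((f"{oi}~{vol}", metrics_df[oi].to_numpy(),
                              metrics_df[vol].to_numpy(), "spearman"))
        assoc = nm.association_table(tests)
        assoc.to_csv(out_dir / "associations.tsv", sep="\t", index=False)
        manifest.outputs.update({
            "subject_metrics": "subject_metrics.tsv",
            "cohort_summary": "cohort_summary.tsv",
            "associations": "associations.tsv",
            "healthy_reference": "healthy_reference.json",
            "normalization_params": "normalization_params.json",
        })
    except Exception as err:
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1)
    return manifest
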