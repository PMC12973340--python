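"""Shared fixtures: one synthetic cohort and one trained model per session.

The heavy objects (the simulated study cohort, the 300-epoch healthy model,
the fine-tuned model, and the healthy reference) are session-scoped so the
reconstruction, calibration, and metric tests all reuse a single training
run, mirroring how the pipeline itself uses one model for every subject.
"""

from __future__ import annotations

import numpy as np
import pytest

from connvae import anomaly as anom
from connvae import preprocess as prep
from connvae import vae as vae_mod
from connvae.simulate import (
    SimulationSpec,
    simulate_cohort,
    simulate_glioma_subject,
    simulate_group_template,
    simulate_healthy_subject,
)

SESSION_SEED = 0


@pytest.fixture(scope="session")
def sim_spec() -> SimulationSpec:
    return SimulationSpec(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def scheme(sim_spec):
    return sim_spec.scheme()


@pytest.fixture(scope="session")
def templates(sim_spec):
    return simulate_group_template(sim_spec)


@pytest.fixture(scope="session")
def cohort(sim_spec):
    return simulate_cohort(sim_spec)


def split_of(cohort, cohort_name, split):
    return [s for s in cohort if s.record.cohort == cohort_name and s.record.split == split]


@pytest.fixture(scope="session")
def norm_params(cohort) -> prep.NormalizationParams:
    train = split_of(cohort, "healthy", "train")
    sc_pool = np.concatenate([
        prep.vectorize_upper(s.sc.values)[prep.vectorize_upper(s.sc.values) > 0]
        for s in train
    ])
    fc_pool = np.concatenate([prep.vectorize_upper(s.fc.values) for s in train])
    return prep.fit_civier_exponent(sc_pool, fc_pool)


def stack_vectors(subjects, params):
    return np.stack([
        prep.subject_model_vector(s.fc, s.sc, params).values for s in subjects
    ])


@pytest.fixture(scope="session")
def healthy_model(cohort, norm_params) -> vae_mod.TrainedVAE:
    """The healthy-trained model: 60 train / 20 validation, 300 epochs."""
    train_x = stack_vectors(split_of(cohort, "healthy", "train"), norm_params)
    val_x = stack_vectors(split_of(cohort, "healthy", "validation"), norm_params)
    cfg = vae_mod.VAEConfig(seed=SESSION_SEED, max_epochs=300, patience=750)
    return vae_mod.train_vae(train_x, val_x, cfg)


@pytest.fixture(scope="session")
def finetuned_model(cohort, norm_params, healthy_model) -> vae_mod.TrainedVAE:
    ft_train = stack_vectors(split_of(cohort, "glioma", "finetune_train"), norm_params)
    ft_val = stack_vectors(split_of(cohort, "glioma", "finetune_val"), norm_params)
    return vae_mod.fine_tune(healthy_model, ft_train, ft_val,
                             {"max_epochs": 100, "patience": 50})


def reconstruct(subject, model, params):
    vec = prep.subject_model_vector(subject.fc, subject.sc, params)
    return vae_mod.reconstruct_subject(model, vec, params)


def transformed_sc(subject, params):
    return prep.apply_power_transform(subject.sc, params).values


@pytest.fixture(scope="session")
def reference(cohort, norm_params, healthy_model) -> anom.HealthyReference:
    """Masks, edge statistics, and thresholds from the healthy test split."""
    test = split_of(cohort, "healthy", "test")
    originals, recons = [], []
    for s in test:
        fc_r, sc_r = reconstruct(s, healthy_model, norm_params)
        originals.append((s.fc.values, transformed_sc(s, norm_params)))
        recons.append((fc_r.values, sc_r.values))
    return anom.build_healthy_reference(originals, recons)


def detect(subject, model, params, ref):
    fc_r, sc_r = reconstruct(subject, model, params)
    return anom.detect_subject(subject.fc.values, fc_r.values,
                               transformed_sc(subject, params), sc_r.values,
                               ref, subject.record.subject_id)


@pytest.fixture(scope="session")
def patient_results(cohort, norm_params, finetuned_model, reference):
    """(subject, AnomalyResult) for every glioma test subject."""
    patients = split_of(cohort, "glioma", "test")
    return [(s, detect(s, finetuned_model, norm_params, reference)) for s in patients]


@pytest.fixture(scope="session")
def healthy_holdout_results(sim_spec, templates, norm_params, finetuned_model, reference):
    """Healthy subjects generated outside every training/reference split,
    scored with the same model and reference as the patients."""
    out = []
    for k in range(20):
        fc, sc, rec = simulate_healthy_subject(templates, sim_spec, 2000 + k,
                                               f"holdout_{k:02d}", "test")
        subject = type("S", (), {"fc": fc, "sc": sc, "record": rec})()
        out.append((subject, detect(subject, finetuned_model, norm_params, reference)))
    return out


@pytest.fixture(scope="session")
def tiny_spec() -> SimulationSpec:
    """A miniature cohort for fast end-to-end pipeline tests."""
    return SimulationSpec(
        parcel_count=20, networks_per_hemisphere=3, n_train=8, n_val=4,
        n_test=6, n_finetune_train=3, n_finetune_val=2, n_patient_test=4,
        tumor_radius=1, seed=11,
    )
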