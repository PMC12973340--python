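"""Synthetic healthy and glioma-like FC/SC cohorts with known ground truth.

The generator emulates, at the matrix level, the features the pipeline relies
on: block-structured functional connectivity (stronger within hemisphere-
specific networks than between), sparse non-negative structural connectivity
whose nonzero pattern couples monotonically to FC, inter-subject variability,
and glioma subjects with a contiguous tumor/edema lesion that attenuates SC
near the lesion while shifting FC in a network distal to it.  Effect sizes are
not literature-derived; they are fixed package defaults chosen for
detectability and documented in the methods note.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .parcellation import ParcellationScheme, synthetic_scheme


class SimulationError(ValueError):
    pass


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic cohort.

    Counts mirror a desk-scale version of the study design: a healthy cohort
    split into train/validation/test, seven patients for fine-tuning with
    three more for its validation, and a held-out patient test set.
    """

    parcel_count: int = 60
    networks_per_hemisphere: int = 6
    n_train: int = 60
    n_val: int = 20
    n_test: int = 20
    n_finetune_train: int = 7
    n_finetune_val: int = 3
    n_patient_test: int = 10
    fc_within: float = 0.5
    fc_between: float = 0.1
    template_jitter_sd: float = 0.1
    subject_noise_sd: float = 0.05
    sc_density: float = 0.25
    sc_weight_law: tuple[float, float] = (6.5, 1.0)  # log-mean, log-sd of counts
    sc_fc_coupling: float = 2.0  # log-count shift from low- to high-FC edges
    sc_jitter_sd: float = 0.2
    total_streamlines: float = 1e7
    lesion_seed_parcel: int | None = None  # None: sampled per glioma subject
    tumor_radius: int = 2
    edema_radius: int = 1
    sc_effect: float = 0.3
    fc_effect_distal: float = -0.3
    finetune_effect_scale: float = 0.25
    volume_per_parcel: float = 1000.0  # mm^3 proxy; only ordering matters
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fc_within", "fc_between"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise SimulationError(f"{name} must lie in (-1, 1)")
        if not 0 <= self.sc_effect <= 1:
            raise SimulationError("sc_effect must lie in [0, 1]")
        for name in ("parcel_count", "networks_per_hemisphere", "n_train", "n_val",
                     "n_test", "n_finetune_train", "n_finetune_val", "n_patient_test"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")

    def scheme(self) -> ParcellationScheme:
        return synthetic_scheme(self.parcel_count, self.networks_per_hemisphere)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Per-subject planted perturbations, index-aligned with the scheme."""

    subject_id: str
    sc_perturbed: tuple[int, ...] = ()
    fc_perturbed: tuple[int, ...] = ()
    lesion_label: tuple[str, ...] = ()  # per parcel: tumor | edema | none


def _rng(spec_seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec_seed, *key])))


def _symmetric_noise(rng: np.random.Generator, p: int, sd: float) -> np.ndarray:
    noise = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    noise[iu] = rng.normal(0.0, sd, size=len(iu[0]))
    return noise + noise.T


FC_CLIP = 1.0 - 1e-6


def _clean_fc(values: np.ndarray) -> np.ndarray:
    values = np.clip((values + values.T) / 2.0, -FC_CLIP, FC_CLIP)
    np.fill_diagonal(values, 0.0)
    return values


def simulate_group_template(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Group-level FC and SC templates shared by all simulated subjects."""
    if spec.fc_within <= spec.fc_between:
        import warnings

        warnings.warn("fc_within <= fc_between: block structure will be inverted")
    scheme = spec.scheme()
    p = scheme.n_parcels
    rng = _rng(spec.seed, 0)
    same_net = scheme.network_index[:, None] == scheme.network_index[None, :]
    fc = np.where(same_net, spec.fc_within, spec.fc_between).astype(float)
    fc = _clean_fc(fc + _symmetric_noise(rng, p, spec.template_jitter_sd))

    # SC support and weight both couple monotonically to template FC (rank
    # coupling): high-FC (within-network) pairs are both more likely to be
    # connected and carry more streamlines, as in real connectomes where the
    # strongest structural edges are short-range/within-system.
    iu = np.triu_indices(p, k=1)
    ranks = np.argsort(np.argsort(fc[iu]))
    u = (ranks + 0.5) / len(ranks)
    prob = np.clip(2.0 * spec.sc_density * u, 0.0, 1.0)
    support = rng.random(len(prob)) < prob
    mu, sigma = spec.sc_weight_law
    log_counts = rng.normal(mu + spec.sc_fc_coupling * u, sigma)
    counts = np.where(support, np.maximum(np.round(np.exp(log_counts)), 2.0), 0.0)
    sc = np.zeros((p, p))
    sc[iu] = counts / spec.total_streamlines
    sc = sc + sc.T
    return fc, sc


def simulate_healthy_subject(
    templates: tuple[np.ndarray, np.ndarray],
    spec: SimulationSpec,
    subject_seed: int,
    subject_id: str = None,
    split: str = "train",
) -> tuple[cio.ConnectivityMatrix, cio.ConnectivityMatrix, cio.SubjectRecord]:
    fc_t, sc_t = templates
    p = fc_t.shape[0]
    if subject_id is None:
        subject_id = f"healthy_{subject_seed:04d}"
    rng = _rng(spec.seed, 1, subject_seed)
    if spec.subject_noise_sd > 0:
        fc = _clean_fc(fc_t + _symmetric_noise(rng, p, spec.subject_noise_sd))
    else:
        fc = fc_t.copy()
    if spec.sc_jitter_sd > 0:
        jitter = np.exp(_symmetric_noise(rng, p, spec.sc_jitter_sd))
        sc = sc_t * jitter
    else:
        sc = sc_t.copy()
    rec = cio.SubjectRecord(subject_id=subject_id, cohort="healthy", split=split)
    rec.validate(p)
    return (
        cio.ConnectivityMatrix(subject_id, "FC", fc),
        cio.ConnectivityMatrix(subject_id, "SC", sc),
        rec,
    )


def parcel_adjacency(scheme: ParcellationScheme) -> list[set[int]]:
    """Lesion-growth adjacency: parcels sharing (hemisphere, network) are
    mutually adjacent, plus a ring ordering within each hemisphere.  A proxy
    for spatial contiguity; no geometry is available at the matrix level."""
    n = scheme.n_parcels
    adj: list[set[int]] = [set() for _ in range(n)]
    for idx in range(scheme.n_networks):
        members = scheme.parcels_in_network(idx)
        for a in members:
            adj[a].update(int(m) for m in members if m != a)
    for hemi in ("left", "right"):
        members = [i for i in range(n) if scheme.hemisphere[i] == hemi]
        k = len(members)
        for j, a in enumerate(members):
            for b in (members[(j - 1) % k], members[(j + 1) % k]):
                if b != a:
                    adj[a].add(b)
                    adj[b].add(a)
    return adj


def _hops_from(seed: int, adj: list[set[int]], max_hops: int) -> dict[int, int]:
    dist = {seed: 0}
    frontier = [seed]
    for d in range(1, max_hops + 1):
        nxt = []
        for a in frontier:
            for b in adj[a]:
                if b not in dist:
                    dist[b] = d
                    nxt.append(b)
        frontier = nxt
    return dist


def _distal_network(scheme: ParcellationScheme, seed_parcel: int) -> int:
    """Deterministic distal-network rule: the contralateral hemisphere's
    network diametrically opposite (in network order) the lesion network."""
    seed_net = int(scheme.network_index[seed_parcel])
    hemi = scheme.hemisphere[seed_parcel]
    other = "right" if hemi == "left" else "left"
    own = [i for i, (h, _) in enumerate(scheme.networks) if h == hemi]
    opp = [i for i, (h, _) in enumerate(scheme.networks) if h == other]
    local = own.index(seed_net)
    return opp[(local + len(opp) // 2) % len(opp)]


def simulate_glioma_subject(
    templates: tuple[np.ndarray, np.ndarray],
    spec: SimulationSpec,
    subject_seed: int,
    subject_id: str = None,
    split: str = "test",
    sc_effect: float | None = None,
    fc_effect_distal: float | None = None,
) -> tuple[cio.ConnectivityMatrix, cio.ConnectivityMatrix, cio.SubjectRecord, GroundTruth]:
    """A glioma-like subject: healthy-style variability plus a planted lesion.

    SC edges incident to tumor parcels are attenuated by ``sc_effect``; FC
    rows of the designated distal network are shifted by ``fc_effect_distal``.
    """
    scheme = spec.scheme()
    p = scheme.n_parcels
    if subject_id is None:
        subject_id = f"glioma_{subject_seed:04d}"
    sc_effect = spec.sc_effect if sc_effect is None else sc_effect
    fc_effect = spec.fc_effect_distal if fc_effect_distal is None else fc_effect_distal

    fc_m, sc_m, _ = simulate_healthy_subject(templates, spec, subject_seed, subject_id)
    fc, sc = fc_m.values.copy(), sc_m.values.copy()

    rng = _rng(spec.seed, 2, subject_seed)
    if spec.lesion_seed_parcel is not None:
        seed_parcel = int(spec.lesion_seed_parcel)
        if not 0 <= seed_parcel < p:
            raise SimulationError("lesion_seed_parcel outside scheme")
        tumor_radius = spec.tumor_radius
    else:
        seed_parcel = int(rng.integers(0, p))
        tumor_radius = int(rng.integers(1, spec.tumor_radius + 1))

    adj = parcel_adjacency(scheme)
    dist = _hops_from(seed_parcel, adj, tumor_radius + spec.edema_radius)
    hemi = scheme.hemisphere[seed_parcel]
    in_hemi = [i for i in dist if scheme.hemisphere[i] == hemi]
    tumor = sorted(i for i in in_hemi if dist[i] <= tumor_radius)
    edema = sorted(i for i in in_hemi if tumor_radius < dist[i])
    hemi_size = sum(1 for h in scheme.hemisphere if h == hemi)
    if len(tumor) + len(edema) >= hemi_size:
        raise SimulationError("lesion exceeds hemisphere")

    null_effect = sc_effect == 1.0 and fc_effect == 0.0

    if sc_effect != 1.0:
        scale = np.ones((p, p))
        scale[tumor, :] *= sc_effect
        scale[:, tumor] *= sc_effect
        # tumor-tumor edges attenuated once, not squared
        scale[np.ix_(tumor, tumor)] = sc_effect
        sc = sc * scale

    distal_net = _distal_network(scheme, seed_parcel)
    distal = scheme.parcels_in_network(distal_net)
    if fc_effect != 0.0:
        shift = np.zeros((p, p))
        shift[distal, :] += fc_effect
        shift[:, distal] += fc_effect
        shift[np.ix_(distal, distal)] = fc_effect
        fc = _clean_fc(fc + shift)

    tumor_fraction = np.zeros(p)
    edema_fraction = np.zeros(p)
    tumor_fraction[tumor] = 1.0
    edema_fraction[edema] = 1.0
    labels = ["none"] * p
    for i in edema:
        labels[i] = "edema"
    for i in tumor:
        labels[i] = "tumor"

    rec = cio.SubjectRecord(
        subject_id=subject_id,
        cohort="glioma",
        split=split,
        tumor_fraction=tumor_fraction,
        edema_fraction=edema_fraction,
        volume_T=spec.volume_per_parcel * len(tumor),
        volume_TO=spec.volume_per_parcel * (len(tumor) + len(edema)),
        lesion_hemisphere=hemi,
    )
    rec.validate(p)
    truth = GroundTruth(
        subject_id=subject_id,
        sc_perturbed=() if null_effect or sc_effect == 1.0 else tuple(tumor),
        fc_perturbed=() if null_effect or fc_effect == 0.0 else tuple(int(i) for i in distal),
        lesion_label=tuple(labels),
    )
    return (
        cio.ConnectivityMatrix(subject_id, "FC", fc),
        cio.ConnectivityMatrix(subject_id, "SC", sc),
        rec,
        truth,
    )


@dataclass
class SyntheticSubject:
    record: cio.SubjectRecord
    fc: cio.ConnectivityMatrix
    sc: cio.ConnectivityMatrix
    truth: GroundTruth | None = None


def simulate_cohort(spec: SimulationSpec) -> list[SyntheticSubject]:
    """The full study cohort: healthy train/validation/test plus glioma
    fine-tune (mild effects) and test (full effects) subjects."""
    templates = simulate_group_template(spec)
    subjects: list[SyntheticSubject] = []
    counter = 0
    for split, n in (("train", spec.n_train), ("validation", spec.n_val),
                     ("test", spec.n_test)):
        for _ in range(n):
            fc, sc, rec = simulate_healthy_subject(
                templates, spec, counter, f"healthy_{counter:04d}", split)
            subjects.append(SyntheticSubject(rec, fc, sc))
            counter += 1
    # fine-tune patients carry deliberately mild lesions, mirroring the use of
    # minimally affected patients for domain adaptation
    mild_sc = 1.0 - (1.0 - spec.sc_effect) * spec.finetune_effect_scale
    mild_fc = spec.fc_effect_distal * spec.finetune_effect_scale
    for split, n, sc_eff, fc_eff in (
        ("finetune_train", spec.n_finetune_train, mild_sc, mild_fc),
        ("finetune_val", spec.n_finetune_val, mild_sc, mild_fc),
        ("test", spec.n_patient_test, spec.sc_effect, spec.fc_effect_distal),
    ):
        for _ in range(n):
            fc, sc, rec, truth = simulate_glioma_subject(
                templates, spec, counter, f"glioma_{counter:04d}", split,
                sc_effect=sc_eff, fc_effect_distal=fc_eff)
            subjects.append(SyntheticSubject(rec, fc, sc, truth))
            counter += 1
    return subjects


def write_cohort(subjects: list[SyntheticSubject], out_dir, *,
                 spec: SimulationSpec | None = None) -> Path:
    """Write matrices, ground truth, and a manifest; returns the manifest path."""
    if not subjects:
        raise SimulationError("empty subject list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "matrices").mkdir(exist_ok=True)
    records = []
    truths = {}
    for s in subjects:
        fc_path = f"matrices/{s.record.subject_id}_FC.txt"
        sc_path = f"matrices/{s.record.subject_id}_SC.txt"
        cio.write_matrix(s.fc, out_dir / fc_path)
        cio.write_matrix(s.sc, out_dir / sc_path)
        s.record.fc_path = fc_path
        s.record.sc_path = sc_path
        records.append(s.record)
        if s.truth is not None:
            truths[s.record.subject_id] = dataclasses.asdict(s.truth)
    if spec is not None:
        scheme = spec.scheme()
        from .parcellation import write_parcellation

        write_parcellation(scheme, out_dir / "parcellation.tsv")
        with open(out_dir / "simulation_spec.json", "w") as fh:
            json.dump(spec.to_dict(), fh, indent=1)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=1)
    manifest = out_dir / "cohort.json"
    cio.write_cohort_manifest(records, manifest, scheme_path="parcellation.tsv")
    return manifest
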