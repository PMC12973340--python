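"""Domain containers and plain-text I/O for connectivity matrices and cohorts.

Matrix files are whitespace-delimited text with a one-line header comment
carrying subject id and modality, so fixtures stay inspectable.  Cohort
manifests are JSON.  Parcel order is the single source of truth: every matrix
and per-parcel vector index-aligns with the :class:`ParcellationScheme` of the
run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .parcellation import ParcellationScheme

SYMMETRY_TOL = 1e-9

#: Modalities a matrix may be tagged with.
MODALITIES = (
    "FC", "SC", "SC_counts", "zFC", "zSC", "FC_recon", "SC_recon",
    "diff_FC", "diff_SC", "diff_FCSC",
)

COHORTS = ("healthy", "glioma")
SPLITS = ("train", "validation", "test", "finetune_train", "finetune_val")
LESION_HEMISPHERES = ("left", "right", "bilateral", "none")


class FormatError(ValueError):
    """Raised for malformed input files or invariant violations."""


@dataclass
class ConnectivityMatrix:
    """One subject's symmetric square connectivity matrix."""

    subject_id: str
    modality: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise FormatError(f"unknown modality {self.modality!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise FormatError(f"matrix must be square, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise FormatError("matrix contains non-finite values")
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym > SYMMETRY_TOL:
            raise FormatError(f"matrix asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL}")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if self.modality == "FC" and (v.min() < -1.0 or v.max() > 1.0):
            raise FormatError("FC entries must lie in [-1, 1]")
        if self.modality in ("SC", "SC_counts") and v.min() < 0.0:
            raise FormatError("SC entries must be non-negative")
        self.values = v

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class SubjectRecord:
    """Cohort membership, split assignment, and lesion annotation."""

    subject_id: str
    cohort: str
    split: str
    tumor_fraction: np.ndarray | None = None
    edema_fraction: np.ndarray | None = None
    volume_T: float = 0.0
    volume_TO: float = 0.0
    lesion_hemisphere: str = "none"
    excluded_parcels: tuple[int, ...] = ()
    fc_path: str | None = None
    sc_path: str | None = None

    def validate(self, n_parcels: int) -> None:
        if self.cohort not in COHORTS:
            raise FormatError(f"unknown cohort {self.cohort!r}")
        if self.split not in SPLITS:
            raise FormatError(f"unknown split {self.split!r}")
        if self.lesion_hemisphere not in LESION_HEMISPHERES:
            raise FormatError(f"unknown lesion hemisphere {self.lesion_hemisphere!r}")
        if self.cohort == "healthy":
            for frac in (self.tumor_fraction, self.edema_fraction):
                if frac is not None and np.any(np.asarray(frac) != 0):
                    raise FormatError("healthy subject with nonzero lesion fractions")
            if self.lesion_hemisphere != "none":
                raise FormatError("healthy subject with a lesion hemisphere")
            self.tumor_fraction = np.zeros(n_parcels)
            self.edema_fraction = np.zeros(n_parcels)
        else:
            if self.tumor_fraction is None or self.edema_fraction is None:
                raise FormatError(f"glioma subject {self.subject_id} without lesion fractions")
            self.tumor_fraction = np.asarray(self.tumor_fraction, dtype=float)
            self.edema_fraction = np.asarray(self.edema_fraction, dtype=float)
        for name, frac in (("tumor", self.tumor_fraction), ("edema", self.edema_fraction)):
            if frac.shape != (n_parcels,):
                raise FormatError(f"{name}_fraction length mismatch for {self.subject_id}")
            if frac.min() < 0 or frac.max() > 1:
                raise FormatError(f"{name}_fraction outside [0, 1] for {self.subject_id}")
        if np.any(self.tumor_fraction + self.edema_fraction > 1 + 1e-12):
            raise FormatError(
                f"tumor_fraction + edema_fraction > 1 at some parcel for {self.subject_id}"
            )


@dataclass
class RunConfig:
    """Run-level parameters shared by all stages."""

    seed: int = 0
    parcel_count: int = 210
    percentile_cutoff: float = 80.0
    threshold_sd_multiplier: float = 3.0
    total_streamlines: float = 1e7

    def __post_init__(self) -> None:
        if not 0 < self.percentile_cutoff < 100:
            raise FormatError("percentile_cutoff must be in (0, 100)")
        if self.threshold_sd_multiplier <= 0:
            raise FormatError("threshold_sd_multiplier must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_matrix(matrix: ConnectivityMatrix, path) -> None:
    """Write a matrix as delimited text, header comment first."""
    path = Path(path)
    header = f"subject={matrix.subject_id} modality={matrix.modality}"
    np.savetxt(path, matrix.values, fmt="%.17g", header=header)


def read_matrix(path, modality: str, scheme: ParcellationScheme | None = None,
                subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a delimited matrix file and validate it against ``scheme``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing matrix file {path}")
    with open(path) as fh:
        first = fh.readline()
    if subject_id is None:
        subject_id = path.stem
        if first.startswith("#"):
            for token in first[1:].split():
                if token.startswith("subject="):
                    subject_id = token.split("=", 1)[1]
    values = np.loadtxt(path, ndmin=2)
    if scheme is not None and values.shape != (scheme.n_parcels, scheme.n_parcels):
        raise FormatError(
            f"matrix shape {values.shape} does not match scheme "
            f"({scheme.n_parcels} parcels)"
        )
    return ConnectivityMatrix(subject_id=subject_id, modality=modality, values=values)


def _record_to_json(rec: SubjectRecord) -> dict:
    d = {
        "subject_id": rec.subject_id,
        "cohort": rec.cohort,
        "split": rec.split,
        "volume_T": rec.volume_T,
        "volume_TO": rec.volume_TO,
        "lesion_hemisphere": rec.lesion_hemisphere,
        "fc_path": rec.fc_path,
        "sc_path": rec.sc_path,
    }
    if rec.excluded_parcels:
        d["excluded_parcels"] = list(rec.excluded_parcels)
    if rec.cohort == "glioma":
        d["tumor_fraction"] = np.asarray(rec.tumor_fraction).tolist()
        d["edema_fraction"] = np.asarray(rec.edema_fraction).tolist()
    return d


def write_cohort_manifest(records: list[SubjectRecord], path, *,
                          scheme_path: str | None = None,
                          extra: dict | None = None) -> None:
    payload = {
        "scheme_path": scheme_path,
        "subjects": [_record_to_json(r) for r in records],
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_cohort_manifest(path, scheme: ParcellationScheme,
                         check_files: bool = True) -> list[SubjectRecord]:
    """Read and validate a JSON cohort manifest."""
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    entries = payload.get("subjects", [])
    if not entries:
        raise FormatError("empty cohort")
    records = []
    for e in entries:
        rec = SubjectRecord(
            subject_id=e["subject_id"],
            cohort=e["cohort"],
            split=e["split"],
            tumor_fraction=np.asarray(e["tumor_fraction"], dtype=float)
            if "tumor_fraction" in e else None,
            edema_fraction=np.asarray(e["edema_fraction"], dtype=float)
            if "edema_fraction" in e else None,
            volume_T=float(e.get("volume_T", 0.0)),
            volume_TO=float(e.get("volume_TO", 0.0)),
            lesion_hemisphere=e.get("lesion_hemisphere", "none"),
            excluded_parcels=tuple(e.get("excluded_parcels", ())),
            fc_path=e.get("fc_path"),
            sc_path=e.get("sc_path"),
        )
        rec.validate(scheme.n_parcels)
        if check_files:
            for p in (rec.fc_path, rec.sc_path):
                if p is not None and not (path.parent / p).exists():
                    raise FormatError(f"missing matrix file {p} for {rec.subject_id}")
        records.append(rec)
    return records


def load_subject_matrices(rec: SubjectRecord, manifest_path, scheme: ParcellationScheme
                          ) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    base = Path(manifest_path).parent
    fc = read_matrix(base / rec.fc_path, "FC", scheme, subject_id=rec.subject_id)
    sc = read_matrix(base / rec.sc_path, "SC", scheme, subject_id=rec.subject_id)
    return fc, sc
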