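"""Healthy reference construction and per-subject impaired-parcel flagging.

The reference is built exclusively from the healthy test split: group-mean FC
and (transformed) SC matrices, 80th-percentile edge masks on each, per-edge
statistics of the masked absolute reconstruction differences, and one pooled
scalar threshold per modality equal to mean + 3 SD of the healthy parcel
scores.  Patients are scored against this reference; a parcel is impaired
when its score strictly exceeds the modality threshold.

All SC-side computation stays in the power-law-transformed domain, the same
domain the model reconstructs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ConnectivityMatrix
from .parcellation import ParcellationScheme

MODALITY_KEYS = ("FC", "SC", "FCSC")


@dataclass
class HealthyReference:
    """Masks, per-edge error statistics, and thresholds from healthy test data."""

    mean_fc: np.ndarray
    mean_sc: np.ndarray
    mask_fc: np.ndarray  # boolean, strict upper triangle support
    mask_sc: np.ndarray
    edge_mean: dict[str, np.ndarray] = field(default_factory=dict)
    edge_sd: dict[str, np.ndarray] = field(default_factory=dict)
    pooled_sd: dict[str, float] = field(default_factory=dict)
    thr: dict[str, float] = field(default_factory=dict)
    percentile_cutoff: float = 80.0
    sd_multiplier: float = 3.0

    @property
    def mask_fcsc(self) -> np.ndarray:
        return self.mask_fc | self.mask_sc

    def save(self, path) -> None:
        payload = {
            "percentile_cutoff": self.percentile_cutoff,
            "sd_multiplier": self.sd_multiplier,
            "thr": self.thr,
            "pooled_sd": self.pooled_sd,
            "mean_fc": self.mean_fc.tolist(),
            "mean_sc": self.mean_sc.tolist(),
            "mask_fc": self.mask_fc.astype(int).tolist(),
            "mask_sc": self.mask_sc.astype(int).tolist(),
            "edge_mean": {k: v.tolist() for k, v in self.edge_mean.items()},
            "edge_sd": {k: v.tolist() for k, v in self.edge_sd.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "HealthyReference":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mean_fc=np.asarray(d["mean_fc"]),
            mean_sc=np.asarray(d["mean_sc"]),
            mask_fc=np.asarray(d["mask_fc"], dtype=bool),
            mask_sc=np.asarray(d["mask_sc"], dtype=bool),
            edge_mean={k: np.asarray(v) for k, v in d["edge_mean"].items()},
            edge_sd={k: np.asarray(v) for k, v in d["edge_sd"].items()},
            pooled_sd=d["pooled_sd"],
            thr=d["thr"],
            percentile_cutoff=d["percentile_cutoff"],
            sd_multiplier=d["sd_multiplier"],
        )


@dataclass
class AnomalyResult:
    """Per-subject masked normalized difference matrices and impaired flags."""

    subject_id: str
    diff: dict[str, np.ndarray]
    parcel_scores: dict[str, np.ndarray]
    impaired: dict[str, np.ndarray]


def percentile_mask(mean_matrix: np.ndarray, cutoff: float) -> np.ndarray:
    """Upper-triangle mask of entries strictly above the linear-interpolation
    percentile of all upper-triangle entries."""
    mean_matrix = np.asarray(mean_matrix, dtype=float)
    p = mean_matrix.shape[0]
    if not 0 < cutoff < 100:
        raise ValueError("cutoff must be in (0, 100)")
    iu = np.triu_indices(p, k=1)
    vals = mean_matrix[iu]
    threshold = np.percentile(vals, cutoff)
    mask = np.zeros((p, p), dtype=bool)
    mask[iu] = vals > threshold
    if not mask.any():
        warnings.warn("degenerate matrix: percentile mask is empty")
    return mask


def difference_matrix(orig: np.ndarray, recon: np.ndarray,
                      mask: np.ndarray) -> np.ndarray:
    """|orig - recon| on mask-retained edges, zero elsewhere."""
    orig = np.asarray(orig, dtype=float)
    recon = np.asarray(recon, dtype=float)
    if orig.shape != recon.shape or orig.shape != mask.shape:
        raise ValueError("shape mismatch")
    return np.where(mask, np.abs(orig - recon), 0.0)


def normalize_difference(diff: np.ndarray, edge_mean: np.ndarray,
                         edge_sd: np.ndarray, mask: np.ndarray,
                         pooled_sd: float) -> np.ndarray:
    """Per-edge z-score of a masked difference matrix against healthy
    statistics; near-constant edges fall back to the pooled modality SD."""
    if np.any(mask & ~np.isfinite(edge_mean)):
        raise ValueError("healthy statistics missing for a masked edge")
    sd = np.where(edge_sd < 1e-12, pooled_sd, edge_sd)
    out = np.zeros_like(np.asarray(diff, dtype=float))
    out[mask] = (diff[mask] - edge_mean[mask]) / sd[mask]
    return out


def integrate_modalities(norm_diff_fc: np.ndarray,
                         norm_diff_sc: np.ndarray) -> np.ndarray:
    """Elementwise sum; the support is the union of the two masks."""
    if norm_diff_fc.shape != norm_diff_sc.shape:
        raise ValueError("shape mismatch")
    return norm_diff_fc + norm_diff_sc


def parcel_scores(norm_diff: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean normalized difference over each parcel's mask-retained edges.

    ``mask`` is upper-triangular; each parcel's row support is the symmetrized
    mask.  Parcels without retained edges score NaN and are excluded downstream.
    """
    full_mask = mask | mask.T
    sym = np.where(full_mask, norm_diff + norm_diff.T, 0.0)
    counts = full_mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        scores = np.where(counts > 0, sym.sum(axis=1) / np.maximum(counts, 1), np.nan)
    return scores


def threshold_mean_3sd(scores: np.ndarray, multiplier: float = 3.0) -> float:
    """Pooled anomaly threshold: mean + multiplier x sample SD of the scores."""
    scores = np.asarray(scores, dtype=float).ravel()
    scores = scores[np.isfinite(scores)]
    if scores.size < 2:
        raise ValueError("need at least 2 finite scores")
    return float(scores.mean() + multiplier * scores.std(ddof=1))


def flag_impaired(scores: np.ndarray, thr: float) -> np.ndarray:
    """Strict exceedance; NaN (sentinel) scores are never flagged."""
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(scores), scores > thr, False).astype(bool)


def stack_cohort(impaired_vectors: list[np.ndarray]) -> np.ndarray:
    """Parcel x subject boolean matrix, column order following the manifest."""
    lengths = {len(v) for v in impaired_vectors}
    if len(lengths) != 1:
        raise ValueError("impaired vectors have differing lengths")
    return np.column_stack([np.asarray(v, dtype=bool) for v in impaired_vectors])


def _norm_diffs_subject(fc, fc_recon, zsc, sc_recon, ref: HealthyReference
                        ) -> dict[str, np.ndarray]:
    diff_fc = difference_matrix(fc, fc_recon, ref.mask_fc)
    diff_sc = difference_matrix(zsc, sc_recon, ref.mask_sc)
    nd_fc = normalize_difference(diff_fc, ref.edge_mean["FC"], ref.edge_sd["FC"],
                                 ref.mask_fc, ref.pooled_sd["FC"])
    nd_sc = normalize_difference(diff_sc, ref.edge_mean["SC"], ref.edge_sd["SC"],
                                 ref.mask_sc, ref.pooled_sd["SC"])
    return {"FC": nd_fc, "SC": nd_sc, "FCSC": integrate_modalities(nd_fc, nd_sc)}


def build_healthy_reference(
    originals: list[tuple[np.ndarray, np.ndarray]],
    reconstructions: list[tuple[np.ndarray, np.ndarray]],
    percentile_cutoff: float = 80.0,
    sd_multiplier: float = 3.0,
) -> HealthyReference:
    """Build masks, edge statistics, and thresholds from the healthy test split.

    ``originals``/``reconstructions`` are per-subject (FC, transformed-SC)
    pairs, index-aligned.
    """
    if len(originals) != len(reconstructions) or len(originals) < 2:
        raise ValueError("need >= 2 aligned healthy test subjects")
    fcs = np.stack([o[0] for o in originals])
    scs = np.stack([o[1] for o in originals])
    mean_fc = fcs.mean(axis=0)
    mean_sc = scs.mean(axis=0)
    ref = HealthyReference(
        mean_fc=mean_fc, mean_sc=mean_sc,
        mask_fc=percentile_mask(mean_fc, percentile_cutoff),
        mask_sc=percentile_mask(mean_sc, percentile_cutoff),
        percentile_cutoff=percentile_cutoff, sd_multiplier=sd_multiplier,
    )
    diffs = {
        "FC": np.stack([difference_matrix(o[0], r[0], ref.mask_fc)
                        for o, r in zip(originals, reconstructions)]),
        "SC": np.stack([difference_matrix(o[1], r[1], ref.mask_sc)
                        for o, r in zip(originals, reconstructions)]),
    }
    masks = {"FC": ref.mask_fc, "SC": ref.mask_sc}
    for key in ("FC", "SC"):
        ref.edge_mean[key] = diffs[key].mean(axis=0)
        ref.edge_sd[key] = diffs[key].std(axis=0, ddof=1)
        sds = ref.edge_sd[key][masks[key]]
        usable = sds[sds >= 1e-12]
        ref.pooled_sd[key] = float(usable.mean()) if usable.size else 1.0

    # thresholds from the pooled healthy parcel scores per modality
    pooled: dict[str, list[np.ndarray]] = {k: [] for k in MODALITY_KEYS}
    for o, r in zip(originals, reconstructions):
        nds = _norm_diffs_subject(o[0], r[0], o[1], r[1], ref)
        pooled["FC"].append(parcel_scores(nds["FC"], ref.mask_fc))
        pooled["SC"].append(parcel_scores(nds["SC"], ref.mask_sc))
        pooled["FCSC"].append(parcel_scores(nds["FCSC"], ref.mask_fcsc))
    for key in MODALITY_KEYS:
        ref.thr[key] = threshold_mean_3sd(np.concatenate(pooled[key]), sd_multiplier)
    return ref


def detect_subject(fc: ConnectivityMatrix | np.ndarray,
                   fc_recon: ConnectivityMatrix | np.ndarray,
                   zsc: ConnectivityMatrix | np.ndarray,
                   sc_recon: ConnectivityMatrix | np.ndarray,
                   ref: HealthyReference,
                   subject_id: str = "subject") -> AnomalyResult:
    """Score one subject against the healthy reference and flag parcels."""
    def arr(x):
        return x.values if isinstance(x, ConnectivityMatrix) else np.asarray(x)

    nds = _norm_diffs_subject(arr(fc), arr(fc_recon), arr(zsc), arr(sc_recon), ref)
    masks = {"FC": ref.mask_fc, "SC": ref.mask_sc, "FCSC": ref.mask_fcsc}
    scores = {k: parcel_scores(nds[k], masks[k]) for k in MODALITY_KEYS}
    impaired = {k: flag_impaired(scores[k], ref.thr[k]) for k in MODALITY_KEYS}
    return AnomalyResult(subject_id=subject_id, diff=nds,
                         parcel_scores=scores, impaired=impaired)
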