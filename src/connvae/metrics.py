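"""Network-level alteration statistics.

For each hemisphere-specific network n with K parcels, the network alteration
degree is the percentage of its parcels flagged impaired::

    NAD_n = 100 / K * sum_k impaired(k)

The global disruption GD of a subject is the number of networks with
NAD > 0, one value per modality (FC, SC, FC+SC).  The overlap index compares
a single modality with the integrated one::

    OI_FC = 100 * |altered_FC ∩ altered_FC+SC| / |altered_FC|

(and analogously for SC), undefined when the single-modality altered set is
empty.  Altered networks are stratified by the lesion tissue they overlap
(tumor > edema > healthy precedence) and associated with tumor/lesion volume
by Pearson (GD) or Spearman (OI) correlation with Benjamini-Hochberg
correction across the family of tests run together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SubjectRecord
from .parcellation import ParcellationScheme

#: Exclusive modality combinations; FC_SC (without the integrated modality)
#: completes the partition of non-empty subsets of {FC, SC, FC+SC}.
COMBINATIONS = (
    "FC_only", "SC_only", "FCSC_only", "FC_and_FCSC", "SC_and_FCSC",
    "FC_and_SC", "FC_SC_FCSC",
)

TISSUE_CLASSES = ("tumor", "edema", "healthy")


def nad(impaired: np.ndarray, scheme: ParcellationScheme) -> np.ndarray:
    """Per-network percentage of impaired parcels (length ``n_networks``)."""
    impaired = np.asarray(impaired, dtype=bool)
    if impaired.shape != (scheme.n_parcels,):
        raise ValueError("impaired vector length does not match scheme")
    counts = np.bincount(scheme.network_index, weights=impaired.astype(float),
                         minlength=scheme.n_networks)
    sizes = scheme.network_sizes()
    return 100.0 * counts / sizes


def altered_networks(impaired: np.ndarray, scheme: ParcellationScheme) -> set[int]:
    """Networks with NAD > 0, decided on the exact parcel count."""
    impaired = np.asarray(impaired, dtype=bool)
    return {
        idx for idx in range(scheme.n_networks)
        if Fraction(int(impaired[scheme.parcels_in_network(idx)].sum())) > 0
    }


def gd(nad_values: np.ndarray) -> int:
    """Number of networks with strictly positive alteration degree."""
    return int(np.sum(np.asarray(nad_values) > 0))


def overlap_index(single: set[int], integrated: set[int]) -> float:
    """Percentage of single-modality altered networks also altered in the
    integrated modality; NaN when the single set is empty."""
    if not single:
        return float("nan")
    return 100.0 * len(single & integrated) / len(single)


def stratify_by_tissue(scheme: ParcellationScheme, record: SubjectRecord,
                       overlap_threshold: float = 0.0) -> list[str]:
    """Tissue class per network: tumor if any parcel's tumor fraction exceeds
    the overlap threshold, else edema by the same rule, else healthy."""
    tumor = np.asarray(record.tumor_fraction, dtype=float)
    edema = np.asarray(record.edema_fraction, dtype=float)
    classes = []
    for idx in range(scheme.n_networks):
        members = scheme.parcels_in_network(idx)
        if np.any(tumor[members] > overlap_threshold):
            classes.append("tumor")
        elif np.any(edema[members] > overlap_threshold):
            classes.append("edema")
        else:
            classes.append("healthy")
    return classes


@dataclass
class NetworkMetrics:
    """One subject's network-level statistics."""

    subject_id: str
    nad: dict[str, np.ndarray]
    gd: dict[str, int]
    oi_fc: float
    oi_sc: float
    altered: dict[str, set[int]] = field(default_factory=dict)
    tissue_class: list[str] = field(default_factory=list)


def subject_metrics(impaired: dict[str, np.ndarray], scheme: ParcellationScheme,
                    record: SubjectRecord, overlap_threshold: float = 0.0,
                    ) -> NetworkMetrics:
    nads = {k: nad(v, scheme) for k, v in impaired.items()}
    altered = {k: altered_networks(v, scheme) for k, v in impaired.items()}
    return NetworkMetrics(
        subject_id=record.subject_id,
        nad=nads,
        gd={k: gd(v) for k, v in nads.items()},
        oi_fc=overlap_index(altered["FC"], altered["FCSC"]),
        oi_sc=overlap_index(altered["SC"], altered["FCSC"]),
        altered=altered,
        tissue_class=stratify_by_tissue(scheme, record, overlap_threshold),
    )


def _combination(in_fc: bool, in_sc: bool, in_fcsc: bool) -> str | None:
    key = (in_fc, in_sc, in_fcsc)
    return {
        (True, False, False): "FC_only",
        (False, True, False): "SC_only",
        (False, False, True): "FCSC_only",
        (True, False, True): "FC_and_FCSC",
        (False, True, True): "SC_and_FCSC",
        (True, True, False): "FC_and_SC",
        (True, True, True): "FC_SC_FCSC",
    }.get(key)


def cohort_summary(metrics: list[NetworkMetrics], scheme: ParcellationScheme,
                   group_by_hemisphere: bool = False) -> pd.DataFrame:
    """Percentage of subjects with altered connectivity per (network, tissue
    class, exclusive modality combination).

    Each altered network occurrence of a subject falls in exactly one
    combination, so per (network, tissue) the combination cells sum to the
    percentage of subjects with any alteration there.
    """
    if not metrics:
        raise ValueError("empty metrics list")
    rows = []
    for m in metrics:
        for idx in range(scheme.n_networks):
            combo = _combination(idx in m.altered["FC"], idx in m.altered["SC"],
                                 idx in m.altered["FCSC"])
            if combo is None:
                continue
            hemi, net = scheme.networks[idx]
            rows.append({
                "subject_id": m.subject_id,
                "network": net,
                "hemisphere": hemi,
                "tissue": m.tissue_class[idx] if m.tissue_class else "healthy",
                "combination": combo,
            })
    n_subjects = len(metrics)
    base = pd.DataFrame(rows, columns=["subject_id", "network", "hemisphere",
                                       "tissue", "combination"])
    counts = (base.groupby(["network", "hemisphere", "tissue", "combination"])
              ["subject_id"].nunique().reset_index(name="n_subjects"))
    counts["percent_subjects"] = 100.0 * counts["n_subjects"] / n_subjects
    return counts


def associate_with_volume(values: np.ndarray, volumes: np.ndarray,
                          method: str = "pearson") -> tuple[float, float]:
    """Correlation between a per-subject index and a volume; NaN pairs are
    excluded pairwise, constant inputs give the NaN sentinel."""
    values = np.asarray(values, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    keep = np.isfinite(values) & np.isfinite(volumes)
    v, w = values[keep], volumes[keep]
    if v.size < 3:
        raise ValueError("need >= 3 paired finite observations")
    if np.all(v == v[0]) or np.all(w == w[0]):
        return float("nan"), float("nan")
    if method == "pearson":
        res = stats.pearsonr(v, w)
    elif method == "spearman":
        res = stats.spearmanr(v, w)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def association_table(tests: list[tuple[str, np.ndarray, np.ndarray, str]],
                      alpha: float = 0.05) -> pd.DataFrame:
    """Run a family of volume-association tests and BH-adjust across it.

    ``tests`` rows are (name, values, volumes, method).  Tests whose
    coefficient is the NaN sentinel are excluded from the correction.
    """
    rows = []
    for name, values, volumes, method in tests:
        try:
            coef, p = associate_with_volume(values, volumes, method)
        except ValueError:
            # too few finite pairs (e.g., OI undefined for most subjects):
            # report the sentinel and leave the test out of the correction
            coef, p = float("nan"), float("nan")
        rows.append({"test": name, "method": method, "coefficient": coef, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = np.nan
    ok = df["p_raw"].notna()
    if ok.any():
        _, adj, _, _ = multipletests(df.loc[ok, "p_raw"], alpha=alpha, method="fdr_bh")
        df.loc[ok, "p_adjusted"] = adj
    df["significant"] = df["p_adjusted"] < alpha
    return df
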