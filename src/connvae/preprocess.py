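"""Model-input construction: FC from time series, streamline-count
normalization, power-law harmonization of SC, inverse-hyperbolic-tangent
normalization, and upper-triangle vectorization.

The power-law step maps structural weights ``(sc / sc_max) ** alpha *
sc_scale`` with ``alpha`` chosen by grid search so the transformed-SC
distribution best matches (minimum Kolmogorov-Smirnov distance) the |FC|
distribution of the healthy training split.  Both modalities then share the
artanh codomain, so one normalization serves the concatenated input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ConnectivityMatrix, FormatError

#: Sentinel for parcels with no usable signal (e.g., necrosis-excluded).
MISSING = np.nan

ALPHA_GRID = np.round(np.arange(0.01, 1.001, 0.01), 2)


@dataclass
class NormalizationParams:
    """Fitted once on the healthy training split, frozen for all subjects."""

    alpha: float
    sc_max: float
    epsilon_clip: float = 1e-6

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise FormatError("alpha must be > 0")
        if not 0 < self.epsilon_clip < 1e-2:
            raise FormatError("epsilon_clip out of range")

    @property
    def sc_scale(self) -> float:
        # transformed SC max maps to 1 - epsilon_clip
        return 1.0 - self.epsilon_clip

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "sc_max": self.sc_max,
                "epsilon_clip": self.epsilon_clip}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(alpha=d["alpha"], sc_max=d["sc_max"],
                   epsilon_clip=d.get("epsilon_clip", 1e-6))


def fc_from_timeseries(series: np.ndarray, exclude: np.ndarray | None = None,
                       subject_id: str = "subject") -> ConnectivityMatrix:
    """Pearson-correlation FC from a (parcels x timepoints) series table.

    Excluded parcels (e.g., overlapping necrotic tissue) and constant series
    yield rows of the missing-value sentinel; the diagonal is zero.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] < 3:
        raise FormatError("need a 2-D series table with >= 3 time points")
    p = series.shape[0]
    sd = series.std(axis=1)
    bad = sd == 0
    if exclude is not None:
        bad = bad | np.asarray(exclude, dtype=bool)
    if np.any(sd == 0):
        warnings.warn("constant time series: correlations set to missing sentinel")
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(series)
    fc = np.clip(fc, -1.0, 1.0)
    fc = np.where(np.isnan(fc), 0.0, fc)
    # validate/symmetrize on the finite version, then restore the sentinel
    m = ConnectivityMatrix(subject_id, "FC", fc)
    out = m.values
    out[bad, :] = MISSING
    out[:, bad] = MISSING
    np.fill_diagonal(out, 0.0)
    m.values = out
    return m


def normalize_sc_counts(counts: np.ndarray, total_streamlines: float = 1e7,
                        subject_id: str = "subject") -> ConnectivityMatrix:
    """Streamline counts -> normalized weights; singleton streamlines zeroed."""
    counts = np.asarray(counts, dtype=float)
    if counts.min() < 0:
        raise FormatError("negative streamline count")
    values = counts / float(total_streamlines)
    values[counts == 1] = 0.0
    return ConnectivityMatrix(subject_id, "SC", values)


def _ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def fit_civier_exponent(sc_weights: np.ndarray, fc_weights: np.ndarray,
                        epsilon_clip: float = 1e-6) -> NormalizationParams:
    """Grid-search the power-law exponent matching transformed SC to |FC|.

    ``sc_weights`` is the pooled sample of nonzero structural weights of the
    healthy training split; ``fc_weights`` the pooled functional weights.
    """
    sc = np.asarray(sc_weights, dtype=float).ravel()
    fc = np.abs(np.asarray(fc_weights, dtype=float).ravel())
    sc = sc[np.isfinite(sc)]
    fc = fc[np.isfinite(fc)]
    if sc.size == 0 or fc.size == 0:
        raise FormatError("empty weight sample")
    if sc.min() <= 0:
        raise FormatError("SC weight sample must be strictly positive")
    sc_max = float(sc.max())
    if np.all(sc == sc[0]):
        warnings.warn("degenerate SC sample (all weights identical): alpha = 1")
        return NormalizationParams(alpha=1.0, sc_max=sc_max, epsilon_clip=epsilon_clip)
    base = sc / sc_max
    scale = 1.0 - epsilon_clip
    dists = [_ks_distance(base ** a * scale, fc) for a in ALPHA_GRID]
    alpha = float(ALPHA_GRID[int(np.argmin(dists))])
    return NormalizationParams(alpha=alpha, sc_max=sc_max, epsilon_clip=epsilon_clip)


def apply_power_transform(sc: ConnectivityMatrix,
                          params: NormalizationParams) -> ConnectivityMatrix:
    """Map SC weights into (0, 1 - epsilon]; zeros stay zero, order preserved."""
    v = sc.values
    out = np.zeros_like(v)
    nz = v > 0
    out[nz] = (v[nz] / params.sc_max) ** params.alpha * params.sc_scale
    # weights above the training max would map past the artanh clip point
    out = np.minimum(out, params.sc_scale)
    return ConnectivityMatrix(sc.subject_id, "zSC", out)


def artanh_normalize(values: np.ndarray, epsilon_clip: float = 1e-6) -> np.ndarray:
    """Elementwise inverse hyperbolic tangent with domain clipping."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise FormatError("non-finite input to artanh normalization")
    clipped = np.clip(values, -(1.0 - epsilon_clip), 1.0 - epsilon_clip)
    return np.arctanh(clipped)


def tanh_denormalize(values: np.ndarray) -> np.ndarray:
    return np.tanh(np.asarray(values, dtype=float))


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Strict upper triangle in row-major (i < j) order."""
    matrix = np.asarray(matrix)
    p = matrix.shape[0]
    if matrix.shape != (p, p):
        raise FormatError("matrix must be square")
    return matrix[np.triu_indices(p, k=1)]


def devectorize_upper(vector: np.ndarray, p: int) -> np.ndarray:
    vector = np.asarray(vector, dtype=float)
    expected = p * (p - 1) // 2
    if vector.shape != (expected,):
        raise FormatError(f"expected vector of length {expected}, got {vector.shape}")
    out = np.zeros((p, p))
    out[np.triu_indices(p, k=1)] = vector
    return out + out.T


@dataclass
class ModelVector:
    """Concatenated zFC (first) and transformed zSC (second) upper triangles."""

    subject_id: str
    values: np.ndarray
    n_parcels: int

    def __post_init__(self) -> None:
        expected = self.n_parcels * (self.n_parcels - 1)
        if self.values.shape != (expected,):
            raise FormatError(
                f"model vector length {self.values.shape} != {expected}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("model vector contains non-finite entries")

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        half = self.values.size // 2
        return self.values[:half], self.values[half:]


def build_model_vector(zfc: ConnectivityMatrix, zsc: ConnectivityMatrix) -> ModelVector:
    if zfc.n_parcels != zsc.n_parcels:
        raise FormatError("zFC and zSC parcel counts differ")
    if {zfc.modality, zsc.modality} & {"SC", "FC"} == {"SC", "FC"}:
        raise FormatError("expected normalized matrices, got raw modalities")
    vec = np.concatenate([vectorize_upper(zfc.values), vectorize_upper(zsc.values)])
    return ModelVector(zfc.subject_id, vec, zfc.n_parcels)


def subject_model_vector(fc: ConnectivityMatrix, sc: ConnectivityMatrix,
                         params: NormalizationParams) -> ModelVector:
    """Full forward chain for one subject: Civier transform, artanh both
    modalities, vectorize and concatenate.  Missing-sentinel FC entries are
    filled with zero (the artanh fixed point)."""
    fc_vals = np.where(np.isfinite(fc.values), fc.values, 0.0)
    zfc = ConnectivityMatrix(fc.subject_id, "zFC",
                             artanh_normalize(fc_vals, params.epsilon_clip))
    zsc_t = apply_power_transform(sc, params)
    zsc = ConnectivityMatrix(sc.subject_id, "zSC",
                             artanh_normalize(zsc_t.values, params.epsilon_clip))
    return build_model_vector(zfc, zsc)
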