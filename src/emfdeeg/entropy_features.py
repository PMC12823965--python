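"""Entropy measures on decomposed modes and feature-matrix assembly.

Five complexity/irregularity measures are computed per (channel, mode):

* approximate entropy (Pincus; Chebyshev distance, self-matches counted)
* fuzzy entropy (Chen; baseline-removed templates, Gaussian-like
  exponential membership, self-matches excluded)
* differential entropy under a Gaussian density, ``0.5*ln(2*pi*e*sigma^2)``
* quadratic Renyi entropy via the Gaussian-kernel information potential,
  reported as ``h2 = -ln(IP)``
* fractal-dimension entropy: base-2 Shannon entropy of the distribution
  of per-sub-window Higuchi fractal dimensions

Natural logs everywhere except the fractal-dimension entropy, which is in
bits.  Feature rows are one per segment; columns are named
``<channel>__imf<k>__<entropy>``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import (chebyshev_match_counts, fuzzy_mean_membership,
                       gaussian_information_potential, higuchi_curve_lengths)
from .emfd import EMFD, ModeSet
from .io_preprocess import Segment

ENTROPY_NAMES = ("apen", "fuzzen", "diffen", "renyi", "fde")
META_COLUMNS = ("condition", "subject_id")


@dataclass(frozen=True)
class EntropyParams:
    """Tunable parameters of the five entropy estimators.

    ``r_coeff`` scales the sample SD to the template tolerance for the
    approximate and fuzzy entropies; ``fuzzy_exponent`` is the membership
    steepness.  The fractal-dimension entropy slides ``fd_subwindow_s``
    windows with fractional overlap ``fd_overlap``, estimates Higuchi FD
    (scales up to ``fd_kmax``) in each, and histograms the values into
    ``hist_bins_M`` bins spanning [1, 2].
    """

    embed_m: int = 2
    r_coeff: float = 0.2
    fuzzy_exponent: float = 2.0
    renyi_sigma_rule: str = "silverman"
    fd_subwindow_s: float = 0.5
    fd_overlap: float = 0.5
    fd_kmax: int = 10
    hist_bins_M: int = 10
    variance_floor: float = 1e-30

    def __post_init__(self):
        if self.embed_m < 1:
            raise ValueError("embed_m must be >= 1")
        if self.r_coeff <= 0 or self.fuzzy_exponent <= 0:
            raise ValueError("r_coeff and fuzzy_exponent must be positive")
        if self.hist_bins_M < 2:
            raise ValueError("hist_bins_M must be >= 2")


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                        r_coeff: float = 0.2) -> float:
    """Approximate entropy, classical Pincus definition (nats).

    ``Phi_m(r) - Phi_{m+1}(r)`` with Chebyshev template distance; each
    template's self-match is included in the count, so the statistic is
    always finite.  Default tolerance ``r = r_coeff * SD(x)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {x.size}")
    if r is None:
        r = r_coeff * x.std()
    if r <= 0:
        # constant input: every template matches every other exactly
        if np.ptp(x) == 0:
            return 0.0
        raise ValueError("tolerance r must be positive")

    def phi(mm: int) -> float:
        counts = chebyshev_match_counts(x, mm, r)
        return float(np.mean(np.log(counts / counts.size)))

    return phi(m) - phi(m + 1)


def fuzzy_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                  nexp: float = 2.0, r_coeff: float = 0.2) -> float:
    """Fuzzy entropy after Chen (nats).

    Templates are baseline-removed (their own mean subtracted) which makes
    the measure exactly invariant to constant offsets; the hard Heaviside
    match is replaced by the smooth membership ``exp(-(d/r)^nexp)``, and
    self-matches are excluded.  Both dimensions use N-m templates.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {x.size}")
    if r is None:
        r = r_coeff * x.std()
    if r <= 0:
        if np.ptp(x) == 0:
            return 0.0
        raise ValueError("tolerance r must be positive")

    n_t = x.size - m  # same template count for both dimensions
    phi_m = fuzzy_mean_membership(x, m, n_t, r, nexp)
    phi_m1 = fuzzy_mean_membership(x, m + 1, n_t, r, nexp)
    return float(np.log(phi_m) - np.log(phi_m1))


def differential_entropy(x: np.ndarray, variance_floor: float | None = None) -> float:
    """Gaussian-closed-form differential entropy ``0.5*ln(2*pi*e*sigma^2)``.

    Valid under a Gaussian density assumption; ``sigma`` is the sample
    standard deviation (ddof=1).  Zero variance sends the entropy to
    minus infinity, so it raises unless a ``variance_floor`` is supplied.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    var = float(np.var(x, ddof=1))
    if variance_floor is not None:
        var = max(var, variance_floor)
    if var <= 0:
        raise ValueError("zero variance: differential entropy is -inf "
                         "(pass variance_floor to clamp)")
    return 0.5 * float(np.log(2.0 * np.pi * np.e * var))


def _silverman_bandwidth(x: np.ndarray) -> float:
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return 1.0  # degenerate sample; kernel width is arbitrary but finite
    return 1.06 * sd * x.size ** (-1.0 / 5.0)


def renyi_entropy(x: np.ndarray, sigma: float | None = None) -> tuple[float, float]:
    """Quadratic Renyi entropy via the information potential.

    ``IP = (1/P^2) * sum_jk B_sigma(y_k - y_j)`` with the Gaussian kernel
    ``B_sigma(u) = exp(-u^2 / (2 sigma^2)) / (sigma * sqrt(2 pi))``; the
    entropy is ``h2 = -ln(IP)``.  Default kernel width by Silverman's rule
    on the sample itself.

    Returns ``(IP, h2)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if sigma is None:
        sigma = _silverman_bandwidth(x)
    if sigma <= 0:
        raise ValueError("kernel width sigma must be positive")
    ip = float(gaussian_information_potential(x, sigma))
    return ip, -float(np.log(ip))


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension of a 1-D series."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * kmax:
        kmax = max(2, n // 2)
    lk = higuchi_curve_lengths(x, kmax)
    ln_k = np.log(1.0 / np.arange(1, kmax + 1))
    valid = np.isfinite(lk) & (lk > 0)
    if valid.sum() < 2:
        return 1.0  # flat/degenerate series: curve fills no extra dimension
    a, b = ln_k[valid], np.log(lk[valid])
    slope = float(np.sum((a - a.mean()) * (b - b.mean())) / np.sum((a - a.mean()) ** 2))
    return slope


def fractal_dimension_entropy(x: np.ndarray, fs: float,
                              params: EntropyParams | None = None) -> float:
    """Shannon entropy (bits) of per-sub-window Higuchi FD values.

    Sub-windows of ``fd_subwindow_s`` seconds slide with overlap
    ``fd_overlap``; their FD estimates are clipped into [1, 2] and
    histogrammed into ``hist_bins_M`` equal bins, and the base-2 entropy
    of the normalized occupancy is returned.
    """
    params = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    win = int(round(params.fd_subwindow_s * fs))
    if win < 4:
        raise ValueError("sub-window too short for FD estimation")
    step = max(1, int(round(win * (1.0 - params.fd_overlap))))
    starts = range(0, x.size - win + 1, step)
    fds = [higuchi_fd(x[s:s + win], params.fd_kmax) for s in starts]
    if len(fds) < 2:
        raise ValueError("need at least 2 sub-windows for an FD distribution")
    return fd_distribution_entropy(np.asarray(fds), params.hist_bins_M)


def fd_distribution_entropy(fd_values: np.ndarray, n_bins: int = 10) -> float:
    """Base-2 entropy of FD values histogrammed over [1, 2]."""
    fd_values = np.clip(np.asarray(fd_values, float), 1.0, 2.0)
    counts, _ = np.histogram(fd_values, bins=n_bins, range=(1.0, 2.0))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum() + 0.0)  # avoid -0.0


def compute_entropies(x: np.ndarray, fs: float,
                      params: EntropyParams | None = None) -> dict[str, float]:
    """All five entropy measures of one mode, keyed by canonical name."""
    params = params or EntropyParams()
    ip, h2 = renyi_entropy(x)
    return {
        "apen": approximate_entropy(x, params.embed_m, r_coeff=params.r_coeff),
        "fuzzen": fuzzy_entropy(x, params.embed_m, nexp=params.fuzzy_exponent,
                                r_coeff=params.r_coeff),
        "diffen": differential_entropy(x, variance_floor=params.variance_floor),
        "renyi": h2,
        "fde": fractal_dimension_entropy(x, fs, params),
    }


def feature_column(channel: str, mode_index: int, entropy: str) -> str:
    return f"{channel}__imf{mode_index + 1}__{entropy}"


def features_from_modes(modesets: dict[str, ModeSet], fs: float,
                        params: EntropyParams | None = None) -> pd.Series:
    """One feature row from per-channel mode sets of a single segment.

    Column order is deterministic: channel (input order), then mode,
    then entropy name.
    """
    params = params or EntropyParams()
    counts = {ch: ms.n_modes for ch, ms in modesets.items()}
    if len(set(counts.values())) > 1:
        raise ValueError(f"inconsistent mode counts across channels: {counts}")
    values, names = [], []
    for ch, ms in modesets.items():
        for k in range(ms.n_modes):
            ent = compute_entropies(ms.modes[k], fs, params)
            for name in ENTROPY_NAMES:
                names.append(feature_column(ch, k, name))
                values.append(ent[name])
    return pd.Series(values, index=names)


class EntropyFeaturizer:
    """Segments -> entropy feature matrix, scikit-learn transformer style.

    Each segment's channels are decomposed with :class:`~emfdeeg.emfd.EMFD`
    and the five entropies are computed per mode.  ``transform`` returns a
    DataFrame with one row per segment; ``condition`` and ``subject_id``
    metadata columns are appended.

    Stateless: ``fit`` only validates parameters.
    """

    def __init__(self, n_modes: int = 10, params: EntropyParams | None = None):
        self.n_modes = n_modes
        self.params = params

    def get_params(self, deep: bool = True) -> dict:
        return {"n_modes": self.n_modes, "params": self.params}

    def set_params(self, **kw) -> "EntropyFeaturizer":
        for key, value in kw.items():
            if key not in ("n_modes", "params"):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X=None, y=None) -> "EntropyFeaturizer":
        self.params_ = self.params or EntropyParams()
        self.n_modes_ = int(self.n_modes)
        if self.n_modes_ < 1:
            raise ValueError("n_modes must be >= 1")
        return self

    def transform(self, segments: list[Segment]) -> pd.DataFrame:
        if not hasattr(self, "params_"):
            self.fit()
        rows, meta = [], []
        for seg in segments:
            decomposer = EMFD(self.n_modes_, seg.fs).fit()
            modesets = {lab: decomposer.decompose(seg.data[i])
                        for i, lab in enumerate(seg.labels)}
            rows.append(features_from_modes(modesets, seg.fs, self.params_))
            meta.append((seg.condition, seg.subject_id))
        matrix = pd.DataFrame(rows).reset_index(drop=True)
        matrix["condition"] = [m[0] for m in meta]
        matrix["subject_id"] = [m[1] for m in meta]
        return matrix

    def fit_transform(self, segments: list[Segment], y=None) -> pd.DataFrame:
        return self.fit().transform(segments)


def split_features_meta(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    meta_cols = [c for c in META_COLUMNS if c in matrix.columns]
    return matrix.drop(columns=meta_cols), matrix[meta_cols]


class MinMaxNormalizer:
    """Per-column min-max scaling with train-fold statistics only.

    ``(x - min) / (max - min)``; a column constant in training maps to 0.5
    everywhere, and out-of-range values at apply time are left unclipped
    so test folds cannot leak into the fitted statistics.  Metadata
    columns pass through untouched.
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **kw) -> "MinMaxNormalizer":
        if kw:
            raise ValueError("MinMaxNormalizer takes no parameters")
        return self

    def fit(self, matrix: pd.DataFrame, y=None) -> "MinMaxNormalizer":
        feats, _ = split_features_meta(matrix)
        self.columns_ = list(feats.columns)
        self.min_ = feats.min(axis=0)
        self.range_ = feats.max(axis=0) - self.min_
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        missing = set(matrix.columns) - set(self.columns_) - set(META_COLUMNS)
        if missing:
            raise ValueError(f"columns absent from training matrix: {sorted(missing)}")
        out = matrix.copy()
        for col in self.columns_:
            if col not in out.columns:
                continue
            rng = self.range_[col]
            if rng == 0:
                out[col] = 0.5
            else:
                out[col] = (out[col] - self.min_[col]) / rng
        return out

    def fit_transform(self, matrix: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(matrix).transform(matrix)


def fit_apply_minmax(train: pd.DataFrame, apply_to: pd.DataFrame) -> pd.DataFrame:
    """Scale ``apply_to`` with min/max statistics fitted on ``train``."""
    return MinMaxNormalizer().fit(train).transform(apply_to)


class FeatureReducer:
    """Variance floor then greedy correlation pruning.

    Columns with variance <= ``variance_floor`` are dropped first; then,
    scanning columns left to right, any column whose absolute Pearson
    correlation with an already-kept column reaches ``corr_cap`` is
    dropped (the earlier column wins).  At least one column is always
    retained.  Dropped names are recorded on ``dropped_``.
    """

    def __init__(self, variance_floor: float = 1e-12, corr_cap: float = 0.98):
        if variance_floor < 0:
            raise ValueError("variance_floor must be >= 0")
        if not 0 < corr_cap <= 1:
            raise ValueError("corr_cap must lie in (0, 1]")
        self.variance_floor = variance_floor
        self.corr_cap = corr_cap

    def get_params(self, deep: bool = True) -> dict:
        return {"variance_floor": self.variance_floor, "corr_cap": self.corr_cap}

    def set_params(self, **kw) -> "FeatureReducer":
        for key, value in kw.items():
            if key not in ("variance_floor", "corr_cap"):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, matrix: pd.DataFrame, y=None) -> "FeatureReducer":
        feats, _ = split_features_meta(matrix)
        variances = feats.var(axis=0, ddof=0)
        survivors = [c for c in feats.columns if variances[c] > self.variance_floor]
        dropped = [c for c in feats.columns if c not in survivors]
        if not survivors:  # never drop everything
            best = variances.idxmax()
            survivors = [best]
            dropped = [c for c in dropped if c != best]
        kept: list[str] = []
        data = feats[survivors].to_numpy(dtype=float)
        std = data.std(axis=0)
        centered = (data - data.mean(axis=0)) / np.where(std == 0, 1.0, std)
        for j, col in enumerate(survivors):
            redundant = False
            for i_kept in kept:
                i = survivors.index(i_kept)
                r = abs(float(centered[:, i] @ centered[:, j]) / len(centered))
                if r >= self.corr_cap:
                    redundant = True
                    dropped.append(col)
                    break
            if not redundant:
                kept.append(col)
        self.kept_ = kept
        self.dropped_ = dropped
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        meta_cols = [c for c in META_COLUMNS if c in matrix.columns]
        return matrix[self.kept_ + meta_cols]

    def fit_transform(self, matrix: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(matrix).transform(matrix)


def reduce_features(matrix: pd.DataFrame, variance_floor: float = 1e-12,
                    corr_cap: float = 0.98) -> pd.DataFrame:
    """Functional wrapper over :class:`FeatureReducer`."""
    return FeatureReducer(variance_floor, corr_cap).fit_transform(matrix)
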