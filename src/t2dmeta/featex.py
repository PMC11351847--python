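"""Feature extraction: 22,960 genes per patient down to 2,870 features.

All three extractors share one block layout: the standardized gene vector of
a patient is cut into consecutive non-overlapping blocks of 8 values
(22,960 = 2,870 x 8), and each block is summarized by one method-specific
scalar:

* STFT  -- magnitude of one discrete-Fourier coefficient of the block,
  by default the largest-magnitude non-DC bin (the dominant frequency);
* RR    -- ridge-regression slope of the block on a fixed standardized
  linear design (distributed ridge: one local fit per block, combinable
  by a weighted one-shot sum);
* PCC   -- Pearson correlation of the block with a per-block template,
  by default the across-patient mean block of the training patients.

The module also houses the descriptive statistics used to characterize the
extracted features (moments, Shannon/sample entropy, Higuchi fractal
dimension, canonical correlation) and the Welch t-test p-value screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .syndata import ExpressionMatrix

BLOCK_LEN = 8


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined for a constant input."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class STFTConfig:
    """Short-time Fourier transform settings.

    ``window`` is a taper array of length ``window_len`` (rectangular when
    None).  ``freq_bin`` selects which magnitude coefficient becomes the
    block feature; None keeps the largest-magnitude non-DC bin.
    """

    window_len: int = BLOCK_LEN
    window: np.ndarray | None = None
    hop: int | None = None  # defaults to window_len (non-overlapping)
    freq_bin: int | None = None
    pad: bool = True

    def taper(self) -> np.ndarray:
        if self.window is None:
            return np.ones(self.window_len)
        w = np.asarray(self.window, dtype=float)
        if len(w) != self.window_len:
            raise ValueError("window taper length must equal window_len")
        return w


@dataclass(frozen=True)
class RidgeConfig:
    """Per-block ridge regression settings.

    ``lam`` is the regularization strength lambda (>= 0); the local solve
    uses the n_i * lambda * I penalty.  ``weights`` (summing to 1) combine
    local estimators in the distributed one-shot sum; uniform by default.
    """

    lam: float = 0.1
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class FeatureMatrix:
    """d x n_patients extracted features, tagged with the method that made them."""

    values: np.ndarray
    method: str
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count must match patient columns")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class StatsRecord:
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    shannon_entropy: float
    sample_entropy: float
    higuchi_fd: float


# ---------------------------------------------------------------------------
# STFT


def stft(x: np.ndarray, cfg: STFTConfig = STFTConfig()) -> np.ndarray:
    """Windowed DFT X(m, w) = sum_n x_n w(n - m) e^{-iwn}.

    Returns a complex (n_windows, window_len) array; row m holds the
    coefficients of the window starting at sample m*hop on the frequency
    grid w_k = 2*pi*k/window_len.  The phase reference is the absolute
    sample index n, matching the analysis form above.  The tail is
    zero-padded when hop does not tile the signal exactly.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    L = cfg.window_len
    hop = cfg.hop if cfg.hop is not None else L
    if hop <= 0 or L <= 0:
        raise ValueError("window_len and hop must be positive")

    n_windows = max(1, -(-(max(x.size - L, 0)) // hop) + 1)
    needed = (n_windows - 1) * hop + L
    if needed > x.size:
        if not cfg.pad:
            raise ValueError("signal length not divisible by hop and padding disabled")
        x = np.concatenate([x, np.zeros(needed - x.size)])

    starts = np.arange(n_windows) * hop
    segments = x[starts[:, None] + np.arange(L)[None, :]] * cfg.taper()[None, :]
    spec = np.fft.fft(segments, axis=1)
    # shift phase reference from window-local j to absolute n = start + j
    k = np.arange(L)
    phase = np.exp(-2j * np.pi * np.outer(starts, k) / L)
    return spec * phase


def _block_view(m: ExpressionMatrix, block_len: int) -> np.ndarray:
    g = m.n_genes
    if g % block_len:
        raise ValueError(
            f"gene count {g} is not divisible by the block length {block_len}"
        )
    # (n_blocks, block_len, n_patients)
    return m.values.reshape(g // block_len, block_len, m.n_patients)


def stft_extract(m: ExpressionMatrix, cfg: STFTConfig = STFTConfig()) -> FeatureMatrix:
    """Per patient: one spectral magnitude per non-overlapping length-8 block."""
    blocks = _block_view(m, cfg.window_len)
    spec = np.fft.fft(blocks * cfg.taper()[None, :, None], axis=1)
    mag = np.abs(spec)
    if cfg.freq_bin is None:
        feats = mag[:, 1:, :].max(axis=1)  # dominant non-DC frequency
    else:
        if not 0 <= cfg.freq_bin < cfg.window_len:
            raise ValueError("freq_bin must be < window_len")
        feats = mag[:, cfg.freq_bin, :]
    return FeatureMatrix(values=feats, method="STFT", labels=m.labels)


# ---------------------------------------------------------------------------
# distributed ridge regression


def ridge_local_fit(Xi: np.ndarray, Yi: np.ndarray, lam: float, ni: int | None = None) -> np.ndarray:
    """Local ridge estimator beta = (Xi'Xi + ni*lam*I)^-1 Xi'Yi."""
    Xi = np.asarray(Xi, dtype=float)
    Yi = np.asarray(Yi, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if ni is None:
        ni = Xi.shape[0]
    gram = Xi.T @ Xi + ni * lam * np.eye(Xi.shape[1])
    try:
        return np.linalg.solve(gram, Xi.T @ Yi)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular ridge system (lambda={lam}): {exc}")


def ridge_combine(betas, weights=None) -> np.ndarray:
    """Weighted one-shot distributed estimator: beta_dist = sum_i w_i beta_i."""
    betas = [np.asarray(b, dtype=float) for b in betas]
    if not betas:
        raise ValueError("no local estimators to combine")
    p = betas[0].shape
    if any(b.shape != p for b in betas):
        raise ValueError("local estimators must have equal length")
    if weights is None:
        weights = np.full(len(betas), 1.0 / len(betas))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(betas):
        raise ValueError("one weight per local estimator required")
    if abs(weights.sum() - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    return np.tensordot(weights, np.stack(betas), axes=1)


def block_design(block_len: int = BLOCK_LEN) -> np.ndarray:
    """Fixed within-block design: intercept + standardized linear index."""
    t = np.arange(block_len, dtype=float)
    z = (t - t.mean()) / t.std(ddof=1)
    return np.column_stack([np.ones(block_len), z])


def ridge_extract(m: ExpressionMatrix, cfg: RidgeConfig = RidgeConfig()) -> FeatureMatrix:
    """Per patient: the ridge slope of each length-8 block on the linear design."""
    blocks = _block_view(m, BLOCK_LEN)  # (q, 8, n)
    X = block_design(BLOCK_LEN)
    gram = X.T @ X + BLOCK_LEN * cfg.lam * np.eye(2)
    # beta = gram^-1 X' y for every block and patient at once
    proj = np.linalg.solve(gram, X.T)  # (2, 8)
    betas = np.einsum("pb,qbn->qpn", proj, blocks)
    return FeatureMatrix(values=betas[:, 1, :], method="RR", labels=m.labels)


# ---------------------------------------------------------------------------
# Pearson correlation


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with the (n-1)-denominator covariance/SD forms."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    xc, yc = x - x.mean(), y - y.mean()
    sx = np.sqrt((xc**2).sum() / (x.size - 1))
    sy = np.sqrt((yc**2).sum() / (y.size - 1))
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    cov = (xc * yc).sum() / (x.size - 1)
    return float(np.clip(cov / (sx * sy), -1.0, 1.0))


def block_templates(m: ExpressionMatrix, columns=None, block_len: int = BLOCK_LEN) -> np.ndarray:
    """Across-patient mean block, one template per block.

    ``columns`` restricts the average to a subset of patients (the training
    fold inside cross-validation, so the template never sees test data).
    """
    blocks = _block_view(m, block_len)
    if columns is not None:
        blocks = blocks[:, :, np.asarray(columns, dtype=int)]
    return blocks.mean(axis=2)


def pcc_extract(m: ExpressionMatrix, template: np.ndarray | None = None) -> FeatureMatrix:
    """Per patient: correlation of each length-8 block with its template.

    Blocks (or templates) with zero variance get feature 0 with a warning.
    """
    blocks = _block_view(m, BLOCK_LEN)  # (q, 8, n)
    if template is None:
        template = block_templates(m)
    template = np.asarray(template, dtype=float)
    if template.shape != blocks.shape[:2]:
        raise ValueError("template must be (n_blocks, block_len)")

    bc = blocks - blocks.mean(axis=1, keepdims=True)
    tc = template - template.mean(axis=1, keepdims=True)
    bn = np.sqrt((bc**2).sum(axis=1))  # (q, n)
    tn = np.sqrt((tc**2).sum(axis=1))  # (q,)
    num = np.einsum("qbn,qb->qn", bc, tc)
    denom = bn * tn[:, None]
    feats = np.zeros_like(num)
    ok = denom > 0
    feats[ok] = num[ok] / denom[ok]
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} constant block/template pair(s): feature set to 0",
            stacklevel=2,
        )
    return FeatureMatrix(values=np.clip(feats, -1.0, 1.0), method="PCC", labels=m.labels)


def corr_matrix(f: FeatureMatrix, subset=None) -> np.ndarray:
    """Pairwise Pearson correlation over feature rows; constant rows flagged."""
    values = f.values if subset is None else f.values[np.asarray(subset, dtype=int)]
    if values.shape[1] < 2:
        raise ValueError("need at least two patients")
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature row(s): correlations set to 0",
            stacklevel=2,
        )
    safe = values.copy()
    safe[constant] = 0.0
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(safe)
    c = np.atleast_2d(c)
    c[np.isnan(c)] = 0.0
    c[constant, :] = 0.0
    c[:, constant] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


# ---------------------------------------------------------------------------
# descriptive statistics


def _shannon_entropy(x: np.ndarray, bins: int) -> float:
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _sample_entropy(x: np.ndarray, m_emb: int, r: float) -> float:
    """SampEn(m, r): -ln(A/B) with Chebyshev-distance template matching."""
    n = x.size
    if n <= m_emb + 1:
        return 0.0

    def count_matches(m: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, m)
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        within = d <= r
        np.fill_diagonal(within, False)
        return int(within.sum()) // 2

    b = count_matches(m_emb)
    a = count_matches(m_emb + 1)
    if a == 0 or b == 0:
        return 0.0
    return float(-np.log(a / b))


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi's fractal dimension via the curve-length slope over k=1..kmax."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2 * kmax:
        raise ValueError("series too short for the requested kmax")
    lengths = []
    for k in range(1, kmax + 1):
        lk = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lk.append(dist * norm / k)
        lengths.append(np.mean(lk))
    lengths = np.asarray(lengths)
    if np.any(lengths <= 0):
        return 1.0  # flat segments: treat as a smooth curve
    k = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / k), np.log(lengths), 1)[0]
    return float(slope)


def signal_stats(
    x: np.ndarray,
    shannon_bins: int = 16,
    m_emb: int = 2,
    r_factor: float = 0.2,
    kmax: int = 8,
) -> StatsRecord:
    """Moments, entropies and fractal dimension of a 1-D feature series.

    Skewness/kurtosis are the standardized third/fourth moments (excess
    kurtosis); Shannon entropy is in bits over a ``shannon_bins``-bin
    histogram; sample entropy uses embedding ``m_emb`` and tolerance
    ``r_factor * SD``; Higuchi FD fits curve lengths over k = 1..kmax.
    Constant series get zero entropies and FD 1 (smooth-curve limit).
    """
    x = np.asarray(x, dtype=float).ravel()
    mean = float(x.mean())
    var = float(x.var(ddof=1)) if x.size > 1 else 0.0
    if var == 0:
        return StatsRecord(mean, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0)
    return StatsRecord(
        mean=mean,
        variance=var,
        skewness=float(sps.skew(x)),
        kurtosis=float(sps.kurtosis(x)),  # excess
        shannon_entropy=_shannon_entropy(x, shannon_bins),
        sample_entropy=_sample_entropy(x, m_emb, r_factor * x.std(ddof=1)),
        higuchi_fd=higuchi_fd(x, kmax=kmax) if x.size >= 2 * kmax else 1.0,
    )


def stats_table(f: FeatureMatrix, **stat_params):
    """Per-class descriptive statistics of a feature matrix as a DataFrame.

    One column per class (diabetic / non-diabetic), rows: mean, variance,
    skewness, kurtosis, entropies, Higuchi FD, plus the first canonical
    correlation between the class feature blocks on the final row.  The
    quadratic-cost statistics (sample entropy) are computed on an evenly
    subsampled series capped at 2,000 values, and the CCA uses at most the
    first 50 feature rows, so the report stays cheap at full scale.
    """
    import pandas as pd

    columns = {}
    per_class = {}
    for label in ("dia", "nondia"):
        cols = np.flatnonzero(f.labels == label)
        series = f.values[:, cols].ravel()
        if series.size > 2000:
            series = series[:: series.size // 2000 + 1]
        per_class[label] = f.values[: min(f.n_features, 50), cols]
        rec = signal_stats(series, **stat_params)
        columns[label] = {
            "mean": rec.mean,
            "variance": rec.variance,
            "skewness": rec.skewness,
            "kurtosis": rec.kurtosis,
            "sample_entropy": rec.sample_entropy,
            "shannon_entropy": rec.shannon_entropy,
            "higuchi_fd": rec.higuchi_fd,
        }
    n_shared = min(v.shape[1] for v in per_class.values())
    cca = cca_corr(per_class["dia"][:, :n_shared].T, per_class["nondia"][:, :n_shared].T)
    for label in columns:
        columns[label]["cca"] = cca
    return pd.DataFrame(columns)


def cca_corr(X: np.ndarray, Y: np.ndarray, eps: float = 1e-6) -> float:
    """First canonical correlation between two feature blocks.

    Standard generalized-eigenvalue formulation with a ridge ``eps`` on the
    within-set covariance blocks for numerical stability.  Rows are shared
    patients; columns are features.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1:
        X = X.T
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    n = X.shape[0]
    if n < 2 or Y.shape[0] != n:
        raise ValueError("need >= 2 shared patients in both blocks")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = Xc.T @ Xc / (n - 1) + eps * np.eye(X.shape[1])
    syy = Yc.T @ Yc / (n - 1) + eps * np.eye(Y.shape[1])
    sxy = Xc.T @ Yc / (n - 1)
    m = np.linalg.solve(sxx, sxy) @ np.linalg.solve(syy, sxy.T)
    rho2 = np.max(np.linalg.eigvals(m).real)
    return float(np.clip(np.sqrt(max(rho2, 0.0)), 0.0, 1.0))


def welch_t_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value for a difference in group means."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 1.0
        raise ValueError("degenerate variances: Welch statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)
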