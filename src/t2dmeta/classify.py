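"""Seven target-coded classifiers for diabetic / non-diabetic discrimination.

Instead of class indicators, the regressors are trained onto fixed class
targets -- 0.1 for non-diabetic and 0.85 for diabetic -- and every model
exposes one continuous output per patient on that [0, 1] scale; a patient
is called diabetic when the output is at or above the midpoint threshold
0.475.  Mean squared error against the coded targets is the shared training
criterion.

Kinds:

* NLR     -- non-linear regression: a 3-parameter logistic curve on a fixed
  uniform projection of the features (weight 0.4 per coordinate), fit by
  iterative least squares;
* LR      -- linear regression by ordinary least squares on coded targets;
* GMM     -- one Gaussian per class (a single-component mixture), classify
  by class-conditional likelihood;
* EM      -- a two-component diagonal Gaussian mixture per class fit by
  expectation-maximization;
* LoR     -- ridge-penalized logistic regression (penalty ||v||^2 / (2 tau^2));
* SDC     -- softmax discriminant: per-class log-sum-exp of
  exp(-lambda ||v - v_ji||^2) over the class training samples;
* SVM-RBF -- soft-margin SVM with the kernel exp(-||xi-xj||^2 / (2 sigma)^2)
  (equivalently gamma = 1/(2 sigma)^2; defaults C=1, gamma=100, diabetic
  class weight 0.86).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as spo
from scipy.special import expit, logsumexp
from sklearn.svm import SVC

from .syndata import DIA, NONDIA

CLASSIFIER_KINDS = ("NLR", "LR", "GMM", "EM", "LoR", "SDC", "SVM-RBF")


@dataclass(frozen=True)
class TargetCoding:
    """Fixed regression targets per class and the decision threshold.

    The class targets must be at least ``min_separation`` apart; the
    decision threshold is their midpoint, with ties (output exactly at the
    threshold) resolved as diabetic.
    """

    t_nondia: float = 0.1
    t_dia: float = 0.85
    min_separation: float = 0.5

    def __post_init__(self):
        if abs(self.t_dia - self.t_nondia) < self.min_separation:
            raise ValueError(
                f"|t_dia - t_nondia| must be >= {self.min_separation}"
            )

    @property
    def threshold(self) -> float:
        return 0.5 * (self.t_dia + self.t_nondia)

    def decode(self, outputs: np.ndarray) -> np.ndarray:
        outputs = np.asarray(outputs, dtype=float)
        return np.where(outputs >= self.threshold, DIA, NONDIA).astype(object)

    def from_probability(self, p_dia: np.ndarray) -> np.ndarray:
        """Map P(diabetic) in [0,1] onto the coded-target output scale."""
        return self.t_nondia + (self.t_dia - self.t_nondia) * np.asarray(p_dia, dtype=float)


def encode_targets(labels, coding: TargetCoding = TargetCoding()) -> np.ndarray:
    """Map class labels onto the coded targets (nondia -> 0.1, dia -> 0.85)."""
    labels = np.asarray(labels, dtype=object)
    out = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(labels):
        if lab == DIA:
            out[i] = coding.t_dia
        elif lab == NONDIA:
            out[i] = coding.t_nondia
        else:
            raise ValueError(f"unknown label {lab!r}")
    return out


def check_target_feasibility(features_by_class: dict, coding: TargetCoding) -> None:
    """Warn when class feature means exceed their coded targets.

    The coding assumes each target sits above the mean feature level of its
    class; a violation does not invalidate the fit but is worth surfacing.
    """
    for label, target in ((NONDIA, coding.t_nondia), (DIA, coding.t_dia)):
        x = features_by_class.get(label)
        if x is not None and len(x) and float(np.mean(x)) > target:
            warnings.warn(
                f"mean feature level of class {label!r} exceeds its target {target}"
            )


# ---------------------------------------------------------------------------
# regression models


@dataclass
class LinearModel:
    intercept: float
    slope: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + np.atleast_2d(x) @ self.slope


def linreg_fit(x: np.ndarray, targets: np.ndarray) -> LinearModel:
    """Ordinary least squares on coded targets (ridge 1e-8 fallback if singular)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    design = np.column_stack([np.ones(x.shape[0]), x])
    try:
        beta, *_ = np.linalg.lstsq(design, targets, rcond=None)
    except np.linalg.LinAlgError:
        warnings.warn("singular least squares: falling back to ridge 1e-8")
        gram = design.T @ design + 1e-8 * np.eye(design.shape[1])
        beta = np.linalg.solve(gram, design.T @ targets)
    return LinearModel(intercept=float(beta[0]), slope=beta[1:])


@dataclass
class NLRModel:
    """3-parameter logistic expectation function on a fixed projection.

    output = theta1 + theta2 / (1 + exp(-(w . a + theta3))) with the uniform
    projection weight w_j = ``proj_weight`` for every feature.
    """

    theta: np.ndarray
    proj_weight: float = 0.4

    def project(self, x: np.ndarray) -> np.ndarray:
        return self.proj_weight * np.atleast_2d(x).sum(axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        t1, t2, t3 = self.theta
        return t1 + t2 * expit(self.project(x) + t3)


def nlr_fit(x: np.ndarray, targets: np.ndarray, proj_weight: float = 0.4) -> NLRModel:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    targets = np.asarray(targets, dtype=float)
    model = NLRModel(theta=np.zeros(3), proj_weight=proj_weight)
    z = model.project(x)
    lo, hi = float(targets.min()), float(targets.max())
    theta0 = np.array([lo, max(hi - lo, 1e-3), -float(np.median(z))])

    def residuals(theta):
        t1, t2, t3 = theta
        return t1 + t2 * expit(z + t3) - targets

    sol = spo.least_squares(residuals, theta0, method="lm", max_nfev=2000)
    model.theta = sol.x
    return model


# ---------------------------------------------------------------------------
# logistic regression (ridge-penalized likelihood)


@dataclass
class LogisticModel:
    intercept: float
    coef: np.ndarray
    tau: float

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return expit(self.intercept + np.atleast_2d(x) @ self.coef)


def _logistic_objective(params, x, y, tau):
    v0, v = params[0], params[1:]
    eta = v0 + x @ v
    # negative penalized log-likelihood and its gradient
    nll = float(np.sum(np.logaddexp(0.0, eta)) - y @ eta) + v @ v / (2 * tau**2)
    p = expit(eta)
    grad = np.concatenate([[np.sum(p - y)], x.T @ (p - y) + v / tau**2])
    return nll, grad


def logistic_fit(x: np.ndarray, y: np.ndarray, tau: float = 1.0, max_iter: int = 500) -> LogisticModel:
    """Maximize the ridge-penalized log-likelihood (intercept unpenalized).

    ``y`` holds binary class indicators (diabetic = 1).  The penalty keeps
    coefficients finite even on perfectly separated data.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    res = spo.minimize(
        _logistic_objective,
        np.zeros(x.shape[1] + 1),
        args=(x, y, tau),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success:
        warnings.warn(f"logistic fit did not converge: {res.message}")
    return LogisticModel(intercept=float(res.x[0]), coef=res.x[1:], tau=tau)


def logistic_gradient(model: LogisticModel, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient of the penalized negative log-likelihood at the model's estimate."""
    params = np.concatenate([[model.intercept], model.coef])
    return _logistic_objective(params, np.atleast_2d(x), np.asarray(y, float), model.tau)[1]


# ---------------------------------------------------------------------------
# Gaussian mixtures


@dataclass
class GMMModel:
    """Gaussian mixture with full or diagonal covariances.

    ``covariances`` is (k, d, d) for full and (k, d) for diagonal models;
    ``loglik_trace`` records the per-iteration training log-likelihood.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    covariance_type: str = "full"
    loglik_trace: list = field(default_factory=list)

    def log_density(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        parts = np.stack(
            [
                np.log(w) + _gauss_logpdf(x, mu, cov, self.covariance_type)
                for w, mu, cov in zip(self.weights, self.means, self.covariances)
            ]
        )
        return logsumexp(parts, axis=0)


def _gauss_logpdf(x, mu, cov, covariance_type):
    d = x.shape[1]
    diff = x - mu
    if covariance_type == "diag":
        var = np.asarray(cov, dtype=float)
        return -0.5 * (
            d * np.log(2 * np.pi) + np.log(var).sum() + ((diff**2) / var).sum(axis=1)
        )
    cov = np.asarray(cov, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    solved = np.linalg.solve(chol, diff.T)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2 * np.pi) + logdet + (solved**2).sum(axis=0))


def gmm_pdf(a: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Multivariate normal density (full covariance, as a standalone primitive)."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    return float(np.exp(_gauss_logpdf(a[None, :], mu, sigma, "full"))[0])


VAR_FLOOR = 1e-6


def em_fit(
    data: np.ndarray,
    n_components: int,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int | None = None,
    covariance_type: str = "full",
) -> GMMModel:
    """Fit a Gaussian mixture by expectation-maximization.

    Responsibilities (E) alternate with weighted re-estimation (M) until the
    mean log-likelihood gain drops below ``tol``.  Component variances are
    floored at 1e-6 (with a warning) to prevent collapse; the log-likelihood
    trace is non-decreasing up to that floor.
    """
    data = np.asarray(data, dtype=float)
    x = data[:, None] if data.ndim == 1 else data
    n, d = x.shape
    if n < n_components:
        raise ValueError("need at least one sample per component")
    rng = np.random.default_rng(seed)
    means = x[rng.choice(n, size=n_components, replace=False)].astype(float)
    base_var = x.var(axis=0) + VAR_FLOOR
    if covariance_type == "diag":
        covs = np.tile(base_var, (n_components, 1))
    else:
        base = np.cov(x.T) if n > 1 else np.eye(d)
        base = np.atleast_2d(base) + VAR_FLOOR * np.eye(d)
        covs = np.tile(base, (n_components, 1, 1))
    weights = np.full(n_components, 1.0 / n_components)

    trace: list[float] = []
    for _ in range(max_iter):
        log_parts = np.stack(
            [
                np.log(w) + _gauss_logpdf(x, mu, cov, covariance_type)
                for w, mu, cov in zip(weights, means, covs)
            ]
        )  # (k, n)
        log_norm = logsumexp(log_parts, axis=0)
        loglik = float(log_norm.sum())
        resp = np.exp(log_parts - log_norm)  # responsibilities

        nk = resp.sum(axis=1) + 1e-12
        weights = nk / n
        means = (resp @ x) / nk[:, None]
        floored = False
        for k in range(n_components):
            diff = x - means[k]
            if covariance_type == "diag":
                var = (resp[k][:, None] * diff**2).sum(axis=0) / nk[k]
                if np.any(var < VAR_FLOOR):
                    floored = True
                covs[k] = np.maximum(var, VAR_FLOOR)
            else:
                cov = (resp[k][:, None] * diff).T @ diff / nk[k]
                eig = np.linalg.eigvalsh(cov)
                if eig.min() < VAR_FLOOR:
                    floored = True
                    cov = cov + (VAR_FLOOR - min(eig.min(), 0.0)) * np.eye(d)
                covs[k] = cov
        if floored:
            warnings.warn("component variance floored at 1e-6")
        if trace and loglik - trace[-1] < tol:
            trace.append(loglik)
            break
        trace.append(loglik)
    return GMMModel(
        weights=weights,
        means=means,
        covariances=covs,
        covariance_type=covariance_type,
        loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# softmax discriminant


@dataclass
class SDCModel:
    """Per-class training samples and the distance scale lambda (Gamma = 0.5)."""

    samples: dict  # label -> (d_i, p) array
    lam: float = 0.5

    def score(self, v: np.ndarray) -> dict:
        """Per-class score log sum_j exp(-lambda ||v - v_ji||^2)."""
        v = np.asarray(v, dtype=float).ravel()
        out = {}
        for label, s in self.samples.items():
            d2 = ((s - v[None, :]) ** 2).sum(axis=1)
            out[label] = float(logsumexp(-self.lam * d2))
        return out


def sdc_fit(x: np.ndarray, labels, lam: float = 0.5) -> SDCModel:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.asarray(labels, dtype=object)
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    samples = {}
    for label in (DIA, NONDIA):
        rows = x[labels == label]
        if len(rows) == 0:
            raise ValueError(f"class {label!r} has no training samples")
        samples[label] = rows
    return SDCModel(samples=samples, lam=lam)


def sdc_score(model: SDCModel, v: np.ndarray) -> dict:
    return model.score(v)


def sdc_classify(model: SDCModel, v: np.ndarray) -> str:
    s = model.score(v)
    # argmax with a deterministic tie rule (diabetic first)
    return DIA if s[DIA] >= s[NONDIA] else NONDIA


# ---------------------------------------------------------------------------
# SVM with the printed RBF kernel


@dataclass(frozen=True)
class RBFConfig:
    """SVM settings: C, kernel coefficient and the diabetic-class weight.

    ``gamma`` may be a positive float (the exp(-gamma ||.||^2) coefficient,
    = 1/(2 sigma)^2 in the sigma form) or "scale" for the variance-adaptive
    sklearn convention 1 / (d * Var(X)), appropriate for scaled-down runs.
    """

    C: float = 1.0
    gamma: float | str = 100.0
    class_weight_dia: float = 0.86

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if not isinstance(self.gamma, str) and self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def rbf_kernel(xi: np.ndarray, xj: np.ndarray, sigma: float) -> float:
    """k(xi, xj) = exp(-||xi - xj||^2 / (2 sigma)^2), in (0, 1]."""
    if sigma == 0:
        raise ValueError("sigma must be nonzero")
    xi = np.asarray(xi, dtype=float).ravel()
    xj = np.asarray(xj, dtype=float).ravel()
    if xi.shape != xj.shape:
        raise ValueError("vectors must have equal length")
    return float(np.exp(-((xi - xj) ** 2).sum() / (2 * sigma) ** 2))


def gamma_from_sigma(sigma: float) -> float:
    """Kernel-coefficient equivalence: gamma = 1 / (2 sigma)^2."""
    return 1.0 / (2.0 * sigma) ** 2


@dataclass
class SVMModel:
    svc: SVC

    def decision(self, x: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(np.atleast_2d(x))


def svm_rbf_fit(x: np.ndarray, labels, cfg: RBFConfig = RBFConfig()) -> SVMModel:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.asarray(labels, dtype=object)
    y = (labels == DIA).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    svc = SVC(
        C=cfg.C,
        kernel="rbf",
        gamma=cfg.gamma,
        class_weight={1: cfg.class_weight_dia, 0: 1.0},
    )
    svc.fit(x, y)
    return SVMModel(svc=svc)


# ---------------------------------------------------------------------------
# unified fit / predict contract


@dataclass
class TrainedClassifier:
    kind: str
    model: object
    coding: TargetCoding
    training_mse: float = float("nan")

    def predict_continuous(self, x: np.ndarray) -> np.ndarray:
        return _predict_continuous(self.kind, self.model, x, self.coding)


def _class_conditional_outputs(log_dia, log_non, prior_dia, coding):
    # posterior P(dia | x) from class-conditional log-likelihoods + priors
    a = log_dia + np.log(prior_dia)
    b = log_non + np.log1p(-prior_dia)
    p = np.exp(a - np.logaddexp(a, b))
    return coding.from_probability(p)


def _predict_continuous(kind, model, x, coding):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if kind in ("LR",):
        return model.predict(x)
    if kind == "NLR":
        return model.predict(x)
    if kind == "LoR":
        return coding.from_probability(model.predict_proba(x))
    if kind in ("GMM", "EM"):
        mix_dia, mix_non, prior_dia = model
        return _class_conditional_outputs(
            mix_dia.log_density(x), mix_non.log_density(x), prior_dia, coding
        )
    if kind == "SDC":
        scores = np.array([[model.score(v)[DIA], model.score(v)[NONDIA]] for v in x])
        p = np.exp(scores[:, 0] - logsumexp(scores, axis=1))
        return coding.from_probability(p)
    if kind == "SVM-RBF":
        return coding.from_probability(expit(model.decision(x)))
    raise ValueError(f"unknown classifier kind {kind!r}")


def train_classifier(
    kind: str,
    x: np.ndarray,
    labels,
    coding: TargetCoding = TargetCoding(),
    cfg=None,
    seed: int | None = None,
) -> TrainedClassifier:
    """Fit one of the seven classifier kinds on (n_samples, d) features.

    Regression kinds fit the coded targets directly; GMM/EM/SDC are
    class-conditional and mapped back to the coded output scale; the
    decision rule for every kind is output >= 0.475 -> diabetic.
    """
    kind = normalize_kind(kind)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.asarray(labels, dtype=object)
    targets = encode_targets(labels, coding)
    y_bin = (labels == DIA).astype(float)

    if kind == "LR":
        model = linreg_fit(x, targets)
    elif kind == "NLR":
        model = nlr_fit(x, targets, proj_weight=0.4 if cfg is None else cfg.get("proj_weight", 0.4))
    elif kind == "LoR":
        tau = 1.0 if cfg is None else cfg.get("tau", 1.0)
        model = logistic_fit(x, y_bin, tau=tau)
    elif kind in ("GMM", "EM"):
        n_comp = 1 if kind == "GMM" else 2
        cov_type = "diag"
        mixes = {}
        for label in (DIA, NONDIA):
            rows = x[labels == label]
            k = min(n_comp, len(rows))
            mixes[label] = em_fit(rows, k, seed=seed, covariance_type=cov_type)
        prior_dia = float(np.mean(labels == DIA))
        model = (mixes[DIA], mixes[NONDIA], prior_dia)
    elif kind == "SDC":
        lam = 0.5 if cfg is None else cfg.get("lam", 0.5)
        model = sdc_fit(x, labels, lam=lam)
    elif kind == "SVM-RBF":
        model = svm_rbf_fit(x, labels, cfg if isinstance(cfg, RBFConfig) else RBFConfig())
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")

    trained = TrainedClassifier(kind=kind, model=model, coding=coding)
    outputs = trained.predict_continuous(x)
    trained.training_mse = float(np.mean((outputs - targets) ** 2))
    return trained


def normalize_kind(kind: str) -> str:
    k = kind.strip().upper().replace("_", "-")
    aliases = {"SVM": "SVM-RBF", "SVMRBF": "SVM-RBF", "SVM-RBF": "SVM-RBF", "LOR": "LoR"}
    if k in aliases:
        return aliases[k]
    for known in CLASSIFIER_KINDS:
        if k == known.upper():
            return known
    raise ValueError(f"unknown classifier kind {kind!r}")


def classify(trained: TrainedClassifier, x: np.ndarray) -> np.ndarray:
    """Continuous outputs thresholded at the coding midpoint (>= -> diabetic)."""
    return trained.coding.decode(trained.predict_continuous(x))
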