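"""Synthetic microarray expression data with the structure the analysis assumes.

The real study population is 20 diabetic and 50 non-diabetic pancreatic-islet
donors with ~22,960 probed genes per patient.  The generator here emulates
that shape with a deliberately simple statistical model: log10 intensities
are i.i.d. Gaussian per gene around a gene-specific baseline, and a
configurable minority of "informative" genes carries an additive class-mean
shift.  This is a stand-in for islet biology, not a model of it -- it gives
the downstream feature extraction, selection and classification stages a
known ground truth to recover.

Preprocessing mirrors the study protocol: keep the highest-peak-intensity
record per duplicated gene id, log10-transform, and standardize each gene to
mean 0 / variance 1 across patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DIA = "dia"
NONDIA = "nondia"
VALID_LABELS = (DIA, NONDIA)


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


class ParseError(ValueError):
    """Malformed expression-matrix or label file."""


@dataclass(frozen=True)
class SynthConfig:
    """Conditions for one synthetic cohort.

    Defaults reproduce the study's shape: 22,960 genes for 20 diabetic and
    50 non-diabetic patients.  ``effect_size`` is the class-mean shift on
    informative genes in units of ``noise_sd``, applied on the log10 scale
    before standardization.
    """

    n_genes: int = 22_960
    n_dia: int = 20
    n_nondia: int = 50
    n_informative: int = 200
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_dia <= 0 or self.n_nondia <= 0:
            raise ConfigError("class sizes must be positive")
        if self.n_dia + self.n_nondia < 2:
            raise ConfigError("need at least two patients")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ConfigError("n_informative must be in [0, n_genes]")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")


@dataclass
class ExpressionMatrix:
    """Genes x patients expression values with per-patient class labels.

    ``informative`` holds the synthetic ground-truth indices of genes that
    carry a class signal (empty for real data).  ``is_log`` and
    ``is_standardized`` record which preprocessing steps have been applied.
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    informative: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    is_log: bool = False
    is_standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x patients matrix")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count must match patient columns")
        if not self.gene_ids:
            self.gene_ids = [f"G{i:06d}" for i in range(self.values.shape[0])]
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length must match gene rows")
        self.informative = np.asarray(self.informative, dtype=int)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]

    def class_columns(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def generate_dataset(config: SynthConfig) -> ExpressionMatrix:
    """Draw one synthetic cohort of raw (linear-scale) intensities.

    Each gene g has a baseline log10 intensity b_g ~ U(6, 12); patient
    values are 10**(b_g + s_g + eps) with eps ~ N(0, noise_sd) and a shift
    s_g = +/- effect_size * noise_sd on informative genes for the diabetic
    class (random sign per gene).  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g, n = config.n_genes, config.n_dia + config.n_nondia

    labels = np.array([DIA] * config.n_dia + [NONDIA] * config.n_nondia, dtype=object)
    baseline = rng.uniform(6.0, 12.0, size=g)
    log_expr = baseline[:, None] + config.noise_sd * rng.standard_normal((g, n))

    informative = np.sort(
        rng.choice(g, size=config.n_informative, replace=False)
    ).astype(int)
    if config.n_informative:
        signs = rng.choice([-1.0, 1.0], size=config.n_informative)
        shift = signs * config.effect_size * config.noise_sd
        log_expr[informative, : config.n_dia] += shift[:, None]

    return ExpressionMatrix(
        values=10.0**log_expr,
        labels=labels,
        informative=informative,
    )


def _deduplicate(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep, per duplicated gene id, the record with the highest peak intensity."""
    ids = np.asarray(m.gene_ids, dtype=object)
    if len(set(ids)) == len(ids):
        return m
    peak = m.values.max(axis=1)
    best: dict[str, int] = {}
    for row, gid in enumerate(ids):
        if gid not in best or peak[row] > peak[best[gid]]:
            best[gid] = row
    keep = np.array(sorted(best.values()), dtype=int)
    return _subset_rows(m, keep)


def _subset_rows(m: ExpressionMatrix, keep: np.ndarray) -> ExpressionMatrix:
    old_to_new = {int(o): i for i, o in enumerate(keep)}
    informative = np.array(
        sorted(old_to_new[int(i)] for i in m.informative if int(i) in old_to_new),
        dtype=int,
    )
    return ExpressionMatrix(
        values=m.values[keep],
        labels=m.labels.copy(),
        gene_ids=[m.gene_ids[int(i)] for i in keep],
        informative=informative,
        is_log=m.is_log,
        is_standardized=m.is_standardized,
    )


def preprocess(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Deduplicate, log10-transform and per-gene standardize a matrix.

    Zero-variance genes cannot be standardized and are dropped with a
    warning.  Idempotent: the log step is skipped on already-log data and
    re-standardizing standardized rows is a no-op.
    """
    m = _deduplicate(raw)
    values = m.values
    if not m.is_log:
        if np.any(values <= 0):
            raise ValueError("non-positive intensity: log10 transform undefined")
        values = np.log10(values)

    sd = values.std(axis=1, ddof=1)
    keep = np.flatnonzero(sd > 0)
    if len(keep) < values.shape[0]:
        warnings.warn(
            f"dropping {values.shape[0] - len(keep)} zero-variance gene(s)",
            stacklevel=2,
        )
        m = _subset_rows(m, keep)
        values = values[keep]
        sd = sd[keep]

    mean = values.mean(axis=1)
    standardized = (values - mean[:, None]) / sd[:, None]
    return ExpressionMatrix(
        values=standardized,
        labels=m.labels.copy(),
        gene_ids=list(m.gene_ids),
        informative=m.informative.copy(),
        is_log=True,
        is_standardized=True,
    )


_SEPS = {"csv": ",", "tsv": "\t"}


def write_matrix(m: ExpressionMatrix, path, labels_path=None, dialect: str = "csv") -> None:
    """Write genes x patients values (header = patient ids) plus a label sidecar."""
    sep = _SEPS[dialect]
    patient_ids = [f"P{i:03d}" for i in range(m.n_patients)]
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=patient_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep)
    if labels_path is not None:
        pd.DataFrame({"patient_id": patient_ids, "label": m.labels}).to_csv(
            labels_path, sep=sep, index=False
        )


def read_matrix(path, labels_path=None, dialect: str = "csv") -> ExpressionMatrix:
    """Read a delimited genes x patients matrix and its label sidecar.

    Ragged rows and unknown labels raise :class:`ParseError` naming the
    offending line.
    """
    sep = _SEPS[dialect]
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # pandas message carries the line number
        raise ParseError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        bad = int(np.flatnonzero(df.isna().any(axis=1))[0]) + 2
        raise ParseError(f"{path}: missing value at line {bad}")

    values = df.to_numpy(dtype=float)
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, sep=sep)
        if list(ldf.columns) != ["patient_id", "label"]:
            raise ParseError(f"{labels_path}: expected header patient_id,label")
        for row, lab in enumerate(ldf["label"]):
            if lab not in VALID_LABELS:
                raise ParseError(f"{labels_path}: unknown label {lab!r} at line {row + 2}")
        order = {pid: i for i, pid in enumerate(ldf["patient_id"])}
        try:
            labels = np.array(
                [ldf["label"].iloc[order[c]] for c in df.columns], dtype=object
            )
        except KeyError as exc:
            raise ParseError(f"{labels_path}: no label for patient {exc}") from exc
    else:
        labels = np.array([NONDIA] * values.shape[1], dtype=object)

    return ExpressionMatrix(values=values, labels=labels, gene_ids=[str(i) for i in df.index])
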