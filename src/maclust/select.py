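"""Gene selection and standardization.

Five unsupervised selections — STD (highest standard deviation), M (highest
absolute mean log2-ratio), T1 (highest moderated one-sample t), PC (top-k
principal-component scores) and NONE — plus two supervised, class-using
selections, T2 (moderated two-sample t) and Mdiff (largest between-class
mean difference).  The moderated variance shrinks each gene's sample
variance toward a local prior sigma0² estimated from genes of similar mean
expression:

    sigma²_mod = (nu0 * sigma0² + (n - 1) * s²) / (nu0 + n - 2)

with ``nu0 = 0`` giving back the plain sample variance s² (so T1/T2 reduce
to the classical one-sample and Welch t statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .structures import FeatureMatrix, MValueMatrix

__all__ = [
    "SELECTION_METHODS",
    "SelectionSpec",
    "ModeratedVarianceConfig",
    "moderated_variance",
    "score_std",
    "score_m",
    "score_t1",
    "score_t2",
    "score_mdiff",
    "select_top",
    "select_pc",
    "standardize",
    "select_features",
]

SELECTION_METHODS = ("STD", "M", "T1", "T2", "Mdiff", "PC", "NONE")
SUPERVISED_METHODS = ("T2", "Mdiff")


@dataclass(frozen=True)
class SelectionSpec:
    """One gene selection: a method and its size (N genes or k components)."""

    method: str
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.method not in SELECTION_METHODS:
            raise ValueError(f"unknown selection method {self.method!r}")
        if self.method == "NONE":
            if self.n is not None:
                raise ValueError("NONE takes no size")
        elif self.n is None or self.n < 1:
            raise ValueError(f"{self.method} requires a size n >= 1")

    @property
    def supervised(self) -> bool:
        return self.method in SUPERVISED_METHODS

    @property
    def label(self) -> str:
        return self.method if self.method == "NONE" else f"{self.method} {self.n}"

    def max_features(self, n_genes: Optional[int] = None) -> Optional[int]:
        """Upper bound on the feature count this selection can yield."""
        if self.method == "NONE":
            return n_genes
        return self.n


@dataclass(frozen=True)
class ModeratedVarianceConfig:
    """Hyperparameters of the moderated (shrunken) variance.

    nu0: prior strength in pseudo-observations; 0 disables shrinkage.
    window: odd count of mean-expression-ranked neighbor genes whose sample
        variances average into the prior sigma0² ("window" mode); in
        "global" mode sigma0² is the mean sample variance of all genes.
    """

    nu0: float = 10.0
    window: int = 101
    mode: str = "window"

    def __post_init__(self) -> None:
        if self.nu0 < 0:
            raise ValueError("nu0 must be >= 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.mode not in ("window", "global"):
            raise ValueError("mode must be 'window' or 'global'")


def moderated_variance(
    values: np.ndarray,
    cfg: ModeratedVarianceConfig = ModeratedVarianceConfig(),
    sigma0: Optional[float] = None,
) -> np.ndarray:
    """Per-gene moderated variance for a genes × samples value matrix.

    ``sigma0`` fixes the prior variance sigma0² directly instead of
    estimating it from the matrix (useful when the prior comes from an
    external gene context).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    n = values.shape[1]
    if n < 2:
        raise ValueError("moderated_variance: need >= 2 observations per gene")
    s2 = values.var(axis=1, ddof=1)
    if cfg.nu0 == 0:
        return s2
    if cfg.nu0 + n - 2 <= 0:
        raise ValueError("moderated_variance: nu0 + n - 2 must be positive")
    if sigma0 is not None:
        sigma0 = np.full_like(s2, float(sigma0))
    elif cfg.mode == "global" or values.shape[0] == 1:
        sigma0 = np.full_like(s2, s2.mean())
    else:
        order = np.argsort(values.mean(axis=1), kind="stable")
        rolled = (pd.Series(s2[order])
                  .rolling(cfg.window, center=True, min_periods=1)
                  .mean().to_numpy())
        sigma0 = np.empty_like(s2)
        sigma0[order] = rolled
    return (cfg.nu0 * sigma0 + (n - 1) * s2) / (cfg.nu0 + n - 2)


def score_std(m: MValueMatrix) -> np.ndarray:
    """Per-gene sample standard deviation (denominator n − 1)."""
    _check_imputed(m)
    return m.values.std(axis=1, ddof=1)


def score_m(m: MValueMatrix) -> np.ndarray:
    """Per-gene absolute mean log2-ratio."""
    _check_imputed(m)
    return np.abs(m.values.mean(axis=1))


def score_t1(
    m: MValueMatrix,
    cfg: ModeratedVarianceConfig = ModeratedVarianceConfig(),
) -> np.ndarray:
    """Moderated one-sample t: |mean M| / sqrt(sigma²_mod / n)."""
    _check_imputed(m)
    n = m.n_samples
    var = moderated_variance(m.values, cfg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m.values.mean(axis=1)) / np.sqrt(var / n)
    return np.where(np.isfinite(t), t, 0.0)


def _class_split(m: MValueMatrix, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"supervised selection needs exactly 2 classes, "
                         f"got {len(classes)}")
    return (m.values[:, labels == classes[0]], m.values[:, labels == classes[1]])


def score_t2(
    m: MValueMatrix,
    labels: np.ndarray,
    cfg: ModeratedVarianceConfig = ModeratedVarianceConfig(),
) -> np.ndarray:
    """Moderated two-sample (Welch-style) t comparing the two classes."""
    _check_imputed(m)
    xa, xb = _class_split(m, labels)
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise ValueError("score_t2: each class needs >= 2 samples")
    va = moderated_variance(xa, cfg)
    vb = moderated_variance(xb, cfg)
    se = np.sqrt(va / xa.shape[1] + vb / xb.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(xa.mean(axis=1) - xb.mean(axis=1)) / se
    return np.where(np.isfinite(t), t, 0.0)


def score_mdiff(m: MValueMatrix, labels: np.ndarray) -> np.ndarray:
    """Absolute between-class difference of per-gene mean M."""
    _check_imputed(m)
    xa, xb = _class_split(m, labels)
    if xa.shape[1] < 1 or xb.shape[1] < 1:
        raise ValueError("score_mdiff: empty class")
    return np.abs(xa.mean(axis=1) - xb.mean(axis=1))


def select_top(m: MValueMatrix, scores: np.ndarray, n: int) -> FeatureMatrix:
    """Keep the n highest-scoring genes, transposed to samples × genes.

    Ties at the cutoff are broken deterministically by ascending gene ID, so
    top-n sets are nested in n.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (m.n_genes,):
        raise ValueError("select_top: one score per gene required")
    if not 1 <= n <= m.n_genes:
        raise ValueError(f"select_top: n={n} outside 1..{m.n_genes}")
    order = np.lexsort((m.gene_ids.astype(str), -scores))
    idx = np.sort(order[:n])  # keep original row order among the selected
    return FeatureMatrix(m.values[idx].T, m.sample_ids, m.gene_ids[idx],
                         kind="genes")


def select_pc(m: MValueMatrix, k: int) -> FeatureMatrix:
    """Project samples onto the top-k principal axes of the gene-centered
    matrix (eigengene scores).

    Components are ordered by decreasing explained variance; each
    component's sign is fixed so its largest-magnitude gene loading is
    positive, making the output bit-reproducible.
    """
    if not 1 <= k <= min(m.n_genes, m.n_samples):
        raise ValueError(f"select_pc: k={k} outside 1..{min(m.values.shape)}")
    _check_imputed(m)
    centered = m.values - m.values.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    flip = np.sign(u[np.abs(u).argmax(axis=0), np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    scores = (vt * flip[:, None]).T * s  # samples × components
    return FeatureMatrix(scores[:, :k], m.sample_ids,
                         np.array([f"PC{i + 1}" for i in range(k)], dtype=object),
                         kind="components")


def standardize(fm: FeatureMatrix, on: bool = True) -> FeatureMatrix:
    """Z-transform each gene feature across samples (mean 0, SD 1).

    ``on=False`` is the identity.  Constant features map to all-zero with a
    warning rather than dividing by zero.
    """
    if not on:
        return fm
    mean = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"standardize: {int(const.sum())} constant feature(s) "
                      "mapped to zero")
    sd = np.where(const, 1.0, sd)
    return FeatureMatrix((fm.values - mean) / sd, fm.sample_ids,
                         fm.feature_ids, fm.kind)


def select_features(
    m: MValueMatrix,
    spec: SelectionSpec,
    labels: Optional[np.ndarray] = None,
    cfg: ModeratedVarianceConfig = ModeratedVarianceConfig(),
) -> FeatureMatrix:
    """Dispatch a SelectionSpec to the matching scorer/projection."""
    if spec.method == "NONE":
        return FeatureMatrix(m.values.T, m.sample_ids, m.gene_ids, kind="genes")
    if spec.method == "PC":
        return select_pc(m, spec.n)
    if spec.method == "STD":
        scores = score_std(m)
    elif spec.method == "M":
        scores = score_m(m)
    elif spec.method == "T1":
        scores = score_t1(m, cfg)
    elif spec.method == "T2":
        if labels is None:
            raise ValueError("T2 selection requires class labels")
        scores = score_t2(m, labels, cfg)
    elif spec.method == "Mdiff":
        if labels is None:
            raise ValueError("Mdiff selection requires class labels")
        scores = score_mdiff(m, labels)
    else:  # pragma: no cover
        raise ValueError(spec.method)
    return select_top(m, scores, spec.n)


def _check_imputed(m: MValueMatrix) -> None:
    if m.missing.any():
        raise ValueError("gene selection requires an imputed (complete) matrix")
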