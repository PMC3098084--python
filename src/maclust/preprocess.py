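"""Building the genes × samples M-value matrix.

Pipeline order: assemble per-sample M/A vectors into a spot × sample matrix,
filter samples and genes by missingness (single pass, both criteria evaluated
on the input mask), impute the remaining missing values (row median or
iterative SVD), collapse duplicate spots of a gene to their mean, and drop
samples without a class label.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structures import MASpots, MValueMatrix

__all__ = [
    "assemble_matrix",
    "filter_matrix",
    "impute_row",
    "impute_svd",
    "collapse_duplicates",
    "drop_unlabeled",
    "preprocess_scans",
]


def assemble_matrix(
    ma_per_sample: Sequence[MASpots],
    gene_ids: Sequence[str],
    sample_ids: Sequence[str],
) -> MValueMatrix:
    """Stack per-sample M vectors into one spot × sample matrix.

    One row per spot (duplicate gene spots are still separate rows at this
    stage); the missingness mask is carried through.
    """
    if len(ma_per_sample) == 0:
        raise ValueError("assemble_matrix: empty sample list")
    if len(ma_per_sample) != len(sample_ids):
        raise ValueError("assemble_matrix: one MASpots per sample_id required")
    n_spots = len(gene_ids)
    for sid, ma in zip(sample_ids, ma_per_sample):
        if ma.M.shape != (n_spots,):
            raise ValueError(
                f"sample {sid!r} has {ma.M.shape[0]} spots, expected {n_spots}")
    values = np.column_stack([ma.M for ma in ma_per_sample])
    missing = np.column_stack([ma.missing for ma in ma_per_sample])
    values = values.copy()
    values[missing] = np.nan
    return MValueMatrix(values, missing, np.asarray(gene_ids, dtype=object),
                        np.asarray(sample_ids, dtype=object))


def filter_matrix(
    m: MValueMatrix,
    max_sample_missing: float = 0.5,
    max_gene_missing: float = 0.3,
    *,
    iterate: bool = False,
) -> MValueMatrix:
    """Filter samples and genes by missing fraction, simultaneously.

    Keeps exactly the samples whose missing fraction on the *input* mask is
    strictly below ``max_sample_missing`` and the genes strictly below
    ``max_gene_missing``; both criteria are evaluated on the original matrix
    in one pass.  ``iterate=True`` instead repeats the pass until a fixed
    point (alternative reading, off by default).
    """
    if not (0 < max_sample_missing <= 1 and 0 < max_gene_missing <= 1):
        raise ValueError("missingness thresholds must lie in (0, 1]")
    cur = m
    while True:
        sample_frac = cur.missing.mean(axis=0)
        gene_frac = cur.missing.mean(axis=1)
        keep_s = sample_frac < max_sample_missing
        keep_g = gene_frac < max_gene_missing
        if keep_g.sum() == 0 or keep_s.sum() == 0:
            raise ValueError(
                "filter_matrix: no genes or samples survive the missingness "
                f"thresholds ({keep_g.sum()} genes, {keep_s.sum()} samples)")
        out = MValueMatrix(cur.values[np.ix_(keep_g, keep_s)],
                           cur.missing[np.ix_(keep_g, keep_s)],
                           cur.gene_ids[keep_g], cur.sample_ids[keep_s],
                           dict(cur.provenance))
        if not iterate or (keep_s.all() and keep_g.all()):
            return out
        cur = out


def impute_row(m: MValueMatrix) -> MValueMatrix:
    """Replace each missing cell by the median of its gene's observed values."""
    if np.any(m.missing.all(axis=1)):
        bad = m.gene_ids[m.missing.all(axis=1)][:5]
        raise ValueError(f"impute_row: all-missing genes present (e.g. {list(bad)}); "
                         "filter the matrix first")
    values = m.values.copy()
    rows = np.where(m.missing.any(axis=1))[0]
    for i in rows:
        med = np.nanmedian(np.where(m.missing[i], np.nan, values[i]))
        values[i, m.missing[i]] = med
    prov = dict(m.provenance)
    prov["imputation"] = {"method": "ROW"}
    return MValueMatrix(values, np.zeros_like(m.missing), m.gene_ids,
                        m.sample_ids, prov)


def impute_svd(
    m: MValueMatrix,
    k: int = 10,
    tol: float = 0.01,
    max_iter: int = 100,
) -> MValueMatrix:
    """Iterative SVD imputation via the top-k eigengenes.

    Missing cells start at 0; each round takes the singular value
    decomposition of the completed matrix, regresses every incomplete gene's
    observed values on the top-k eigengenes restricted to the observed
    positions, and re-estimates the missing cells from the fit.  Stops when
    the relative Frobenius change of the completed matrix drops below
    ``tol`` (or at ``max_iter``, recording a warning in provenance).
    Observed cells are never modified.
    """
    if k < 1:
        raise ValueError("impute_svd: k must be >= 1")
    if tol <= 0:
        raise ValueError("impute_svd: tol must be > 0")
    if np.any(m.missing.all(axis=1)):
        raise ValueError("impute_svd: all-missing genes present; filter first")
    k = min(k, min(m.values.shape) - 1)

    prov = dict(m.provenance)
    if not m.missing.any():
        prov["imputation"] = {"method": "SVD", "k": k, "iterations": 0,
                              "converged": True, "history": []}
        return MValueMatrix(m.values.copy(), np.zeros_like(m.missing),
                            m.gene_ids, m.sample_ids, prov)

    X = m.values.copy()
    X[m.missing] = 0.0
    miss_rows = np.where(m.missing.any(axis=1))[0]
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # eigengenes: top-k right singular vectors (length n_samples)
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        V = vt[:k]  # k × samples
        X_new = X.copy()
        for i in miss_rows:
            obs = ~m.missing[i]
            coef, *_ = np.linalg.lstsq(V[:, obs].T, X[i, obs], rcond=None)
            X_new[i, ~obs] = coef @ V[:, ~obs]
        change = float(np.linalg.norm(X_new - X) / max(np.linalg.norm(X), 1e-12))
        history.append(change)
        X = X_new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"impute_svd: no convergence in {max_iter} iterations "
            f"(last relative change {history[-1]:.3g}); returning last iterate")
    prov["imputation"] = {"method": "SVD", "k": k, "iterations": it,
                          "converged": converged, "history": history}
    return MValueMatrix(X, np.zeros_like(m.missing), m.gene_ids,
                        m.sample_ids, prov)


def collapse_duplicates(m: MValueMatrix) -> MValueMatrix:
    """Average rows sharing a gene ID (first-occurrence row order)."""
    if m.missing.any():
        raise ValueError("collapse_duplicates expects an imputed matrix")
    df = pd.DataFrame(m.values)
    grouped = df.groupby(pd.Series(m.gene_ids), sort=False).mean()
    return MValueMatrix(grouped.to_numpy(),
                        np.zeros((grouped.shape[0], m.n_samples), dtype=bool),
                        grouped.index.to_numpy(dtype=object),
                        m.sample_ids, dict(m.provenance))


def drop_unlabeled(
    m: MValueMatrix,
    labels: Mapping[str, str],
) -> tuple[MValueMatrix, np.ndarray]:
    """Remove samples without a class label; return (matrix, label vector).

    Sample order is preserved.  Errors if fewer than two labeled classes
    remain.
    """
    keep = np.array([sid in labels for sid in m.sample_ids])
    kept_labels = np.array([labels[sid] for sid in m.sample_ids[keep]],
                           dtype=object)
    if len(set(kept_labels)) < 2:
        raise ValueError(
            f"drop_unlabeled: {len(set(kept_labels))} labeled class(es) remain; "
            "need at least 2")
    out = MValueMatrix(m.values[:, keep], m.missing[:, keep], m.gene_ids,
                       m.sample_ids[keep], dict(m.provenance))
    return out, kept_labels


def preprocess_scans(
    scans,
    labels: Mapping[str, str],
    normalization: str,
    imputation: str,
    *,
    svd_k: int = 10,
    svd_tol: float = 0.01,
    svd_max_iter: int = 100,
) -> tuple[MValueMatrix, np.ndarray]:
    """Full pre-processing: normalize each scan, assemble, filter, impute,
    collapse duplicates and drop unlabeled samples.

    Convenience wrapper used by the grid runner; each step is also public.
    """
    from .normalize import apply_normalization

    layouts = {scan.layout_signature() for scan in scans}
    if len(layouts) > 1:
        raise ValueError("preprocess_scans: scans have differing spot layouts")
    ma = [apply_normalization(s, normalization) for s in scans]
    m = assemble_matrix(ma, scans[0].gene_ids, [s.sample_id for s in scans])
    m = filter_matrix(m)
    if imputation == "ROW":
        m = impute_row(m)
    elif imputation == "SVD":
        m = impute_svd(m, k=svd_k, tol=svd_tol, max_iter=svd_max_iter)
    else:
        raise ValueError(f"unknown imputation method {imputation!r}")
    m = collapse_duplicates(m)
    return drop_unlabeled(m, labels)
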