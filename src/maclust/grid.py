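"""Factorial benchmarking: the method grid, its execution, variance
decomposition of the scores, and iterative method elimination.

A *cluster analysis* is one point in the cross product

    normalization (5) × imputation (2) × standardization (2)
      × gene selection (13 unsupervised, +6 supervised) × clustering (11)

minus the combinations where Gaussian-mixture clustering would see more than
500 features.  This yields 2780 unsupervised analyses (plus 1280 supervised
ones); the survivor subset after elimination has 288.  Each analysis is run
end-to-end on each dataset and scored by merge-optimized adjusted Rand;
shared upstream stages (normalization + imputation, then selection) are
cached so downstream variants reuse them.

The meta-analysis fits a linear model of aRand on the sub-process factors
plus all second-order interactions (sequential Type I sums of squares) and
iteratively removes methods shown inferior by Bonferroni-corrected paired
Wilcoxon signed-rank tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import CLUSTERING_METHODS, InvalidMethodError, cluster
from .evaluate import optimal_merge
from .io import provenance_record
from .preprocess import preprocess_scans
from .select import SelectionSpec, select_features, standardize
from .simulate import SyntheticExperiment

__all__ = [
    "AnalysisSpec",
    "EliminationTrace",
    "enumerate_specs",
    "run_grid",
    "variance_decomposition",
    "eliminate",
    "pairwise_comparison_counts",
    "summarize",
]

NORMALIZATIONS = ("no.norm", "norm.pt", "norm.pt.bkg", "norm.glob",
                  "norm.glob.bkg")
IMPUTATIONS = ("ROW", "SVD")

#: method sets surviving the elimination reported for the original cohorts
REDUCED_NORMALIZATIONS = ("norm.pt", "norm.pt.bkg", "norm.glob",
                          "norm.glob.bkg")
REDUCED_SELECTIONS = (("NONE", None), ("STD", 100), ("STD", 1000), ("PC", 15))
REDUCED_CLUSTERINGS = ("hclust.corr.ward", "hclust.eucl.ward",
                       "hclust.manh.ward", "kmeans", "mclust")

_MCLUST_MAX = 500


@dataclass(frozen=True)
class AnalysisSpec:
    """One point in the method grid."""

    normalization: str
    imputation: str
    standardization: bool
    selection: SelectionSpec
    clustering: str

    @property
    def valid(self) -> bool:
        """mclust is only valid when the selection yields <= 500 features
        (so not with N = 1000/1500 nor with NONE)."""
        if self.clustering != "mclust":
            return True
        if self.selection.method == "NONE":
            return False
        if self.selection.method == "PC":
            return self.selection.n <= _MCLUST_MAX
        return self.selection.n <= _MCLUST_MAX

    @property
    def key(self) -> str:
        return (f"{self.normalization}|{self.imputation}|"
                f"{'std' if self.standardization else 'notstd'}|"
                f"{self.selection.label}|{self.clustering}")


def _unsupervised_selections(extra_std_sizes: Iterable[int] = ()) -> List[SelectionSpec]:
    sels = [SelectionSpec(m, n) for m in ("STD", "M", "T1")
            for n in (15, 100, 1000)]
    sels += [SelectionSpec("PC", k) for k in (3, 5, 15)]
    sels.append(SelectionSpec("NONE"))
    sels += [SelectionSpec("STD", n) for n in sorted(extra_std_sizes)]
    return sels


def _supervised_selections() -> List[SelectionSpec]:
    return [SelectionSpec(m, n) for m in ("T2", "Mdiff")
            for n in (15, 100, 1000)]


def enumerate_specs(
    include_supervised: bool = False,
    reduced: bool = False,
    extra_std_sizes: Iterable[int] = (),
) -> List[AnalysisSpec]:
    """Enumerate the valid method grid.

    The full unsupervised grid has 2780 specs; ``include_supervised`` adds
    1280 more; ``reduced`` restricts every sub-process to the elimination
    survivors (288 specs); ``extra_std_sizes`` adds STD selections at the
    given sizes.
    """
    if reduced:
        norms: Sequence[str] = REDUCED_NORMALIZATIONS
        selections = [SelectionSpec(m, n) for m, n in REDUCED_SELECTIONS]
        clusterings: Sequence[str] = REDUCED_CLUSTERINGS
    else:
        norms = NORMALIZATIONS
        selections = _unsupervised_selections(extra_std_sizes)
        clusterings = CLUSTERING_METHODS
    if include_supervised:
        selections = selections + _supervised_selections()
    specs = [
        AnalysisSpec(norm, imp, std, sel, cl)
        for norm in norms
        for imp in IMPUTATIONS
        for std in (False, True)
        for sel in selections
        for cl in clusterings
    ]
    return [s for s in specs if s.valid]


def pairwise_comparison_counts(
    method_sets: Mapping[str, Sequence],
) -> Dict[str, int]:
    """Number of unordered pairwise comparisons per sub-process, C(m, 2)."""
    return {name: comb(len(set(methods)), 2)
            for name, methods in method_sets.items()}


def _derive_seed(master_seed: int, *parts) -> int:
    text = ":".join(str(p) for p in (master_seed, *parts))
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def _as_dataset(obj) -> Tuple[list, Mapping[str, str]]:
    if isinstance(obj, SyntheticExperiment):
        return obj.scans, obj.labels_mapping()
    scans, labels = obj
    return list(scans), dict(labels)


def run_grid(
    datasets: Mapping[str, object],
    specs: Sequence[AnalysisSpec],
    master_seed: int = 0,
    *,
    n_clusters: int = 10,
    cache: bool = True,
) -> Tuple[pd.DataFrame, dict]:
    """Run every (dataset, spec) combination and score it.

    ``datasets`` maps a name to a :class:`SyntheticExperiment` or a
    ``(scans, labels)`` pair.  For each valid spec the pipeline is
    normalize → filter/impute → collapse/drop → select → standardize →
    cluster into ``n_clusters`` → optimal-merge aRand against truth.
    Upstream stages are cached per (normalization, imputation) and
    (…, selection); caching never changes any number.  Per-run seeds derive
    deterministically from ``master_seed``; failures are recorded as rows
    with a reason, never aborting the grid.

    Returns the long-format result table and a provenance record.
    """
    records = []
    for ds_name in datasets:
        scans, labels = _as_dataset(datasets[ds_name])
        pre_cache: dict = {}
        sel_cache: dict = {}
        for spec in specs:
            row = {
                "dataset": ds_name,
                "normalization": spec.normalization,
                "imputation": spec.imputation,
                "standardization": spec.standardization,
                "selection": spec.selection.label,
                "clustering": spec.clustering,
                "arand": np.nan,
                "error": "",
            }
            try:
                if not spec.valid:
                    raise InvalidMethodError(
                        f"{spec.clustering} incompatible with selection "
                        f"{spec.selection.label}")
                pk = (spec.normalization, spec.imputation)
                if pk not in pre_cache or not cache:
                    pre_cache[pk] = preprocess_scans(
                        scans, labels, spec.normalization, spec.imputation)
                matrix, truth = pre_cache[pk]
                sk = pk + (spec.selection.label,)
                if sk not in sel_cache or not cache:
                    sel_cache[sk] = select_features(
                        matrix, spec.selection,
                        labels=truth if spec.selection.supervised else None)
                feats = standardize(sel_cache[sk], spec.standardization)
                seed = _derive_seed(master_seed, ds_name, spec.key)
                part = cluster(feats, spec.clustering,
                               n_clusters=n_clusters, seed=seed)
                row["arand"] = optimal_merge(part, truth).arand
            except InvalidMethodError as exc:
                row["error"] = f"invalid: {exc.reason}"
            except Exception as exc:  # noqa: BLE001 - recorded, not raised
                row["error"] = f"{type(exc).__name__}: {exc}"
            records.append(row)
    table = pd.DataFrame.from_records(records)
    prov = provenance_record(
        {"datasets": sorted(datasets), "n_specs": len(specs),
         "n_clusters": n_clusters}, master_seed)
    return table, prov


DEFAULT_FACTOR_ORDER = ("dataset", "normalization", "standardization",
                        "imputation", "selection", "clustering")


def variance_decomposition(
    rt: pd.DataFrame,
    *,
    order: Sequence[str] = DEFAULT_FACTOR_ORDER,
    alpha: float = 0.001,
    interactions: bool = True,
) -> pd.DataFrame:
    """Sequential (Type I) ANOVA of aRand on the sub-process factors.

    Fits a linear model of aRand on the categorical factors in ``order``
    plus (optionally) all second-order interactions, in the induced order,
    and reports each term's percent of the total sum of squares with a
    significance flag at ``alpha``.  The incremental projection handles
    rank-deficient designs (structurally missing grid cells) by attributing
    only estimable variation to each term; inestimable interaction cells
    simply contribute no rank.  Factors with fewer than two levels in the
    table are dropped with a note in the returned frame's ``attrs``.
    """
    df = rt.dropna(subset=["arand"]).copy()
    if df.empty:
        raise ValueError("variance_decomposition: no scored records")
    dropped = [f for f in order if df[f].nunique() < 2]
    factors = [f for f in order if f not in dropped]
    if not factors:
        raise ValueError("variance_decomposition: no factor has >= 2 levels")

    y = df["arand"].to_numpy(dtype=float)
    n = len(y)
    total_ss = float(((y - y.mean()) ** 2).sum())
    if total_ss == 0:
        raise ValueError("variance_decomposition: response is constant")

    dummies = {f: pd.get_dummies(df[f].astype(str), dtype=float).to_numpy()
               for f in factors}
    terms: List[Tuple[str, np.ndarray]] = [(f, dummies[f]) for f in factors]
    if interactions:
        for f1, f2 in combinations(factors, 2):
            d1, d2 = dummies[f1], dummies[f2]
            block = (d1[:, :, None] * d2[:, None, :]).reshape(n, -1)
            terms.append((f"{f1}:{f2}", block))

    X = np.ones((n, 1))
    rss_prev = total_ss
    rank_prev = 1
    rows = []
    for name, block in terms:
        X = np.hstack([X, block])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        rows.append({"term": name, "ss": max(rss_prev - rss, 0.0),
                     "df": max(rank - rank_prev, 0)})
        rss_prev, rank_prev = rss, rank

    df_resid = n - rank_prev
    resid_ms = rss_prev / df_resid if df_resid > 0 else np.nan
    for row in rows:
        if row["df"] > 0 and df_resid > 0 and resid_ms > 0:
            f_stat = (row["ss"] / row["df"]) / resid_ms
            row["F"] = f_stat
            row["p"] = float(stats.f.sf(f_stat, row["df"], df_resid))
        else:
            row["F"] = np.nan
            row["p"] = np.nan
        row["percent"] = 100.0 * row["ss"] / total_ss
        row["significant"] = bool(row["p"] < alpha) if np.isfinite(row["p"]) else False
    rows.append({"term": "residual", "ss": rss_prev, "df": df_resid,
                 "F": np.nan, "p": np.nan,
                 "percent": 100.0 * rss_prev / total_ss, "significant": False})
    out = pd.DataFrame(rows, columns=["term", "ss", "df", "F", "p",
                                      "percent", "significant"])
    out.attrs["dropped_factors"] = dropped
    out.attrs["alpha"] = alpha
    return out


@dataclass
class EliminationTrace:
    """Removal order of the iterative pairwise-Wilcoxon elimination."""

    steps: pd.DataFrame  # iteration, subprocess, removed, p_value, superior
    survivors: Dict[str, List[str]]
    skipped: List[str]


def eliminate(
    rt: pd.DataFrame,
    subprocesses: Sequence[str] = ("normalization", "selection", "clustering"),
    alpha: float = 0.001,
    *,
    bonferroni: str = "iteration",
    min_pairs: int = 3,
) -> EliminationTrace:
    """Iteratively remove sub-process methods dominated by a competitor.

    Each iteration compares every unordered pair of surviving methods within
    each sub-process by a two-sided Wilcoxon signed-rank test on aRand
    values paired on (dataset + all other sub-process settings), restricted
    to settings where both methods produced a score.  P-values are
    Bonferroni-corrected by the number of tests in the current iteration
    (``bonferroni="cumulative"`` corrects by the running total instead); if
    the minimum corrected p-value falls below ``alpha`` the pair's method
    with the lower paired median is removed together with all its analyses,
    and the process repeats until no removal is made.
    """
    if bonferroni not in ("iteration", "cumulative"):
        raise ValueError("bonferroni must be 'iteration' or 'cumulative'")
    df = rt.dropna(subset=["arand"]).copy()
    spec_cols = ["normalization", "imputation", "standardization",
                 "selection", "clustering"]
    for col in subprocesses:
        if col not in spec_cols:
            raise ValueError(f"unknown sub-process column {col!r}")

    steps = []
    skipped: List[str] = []
    iteration = 0
    cumulative_tests = 0
    while True:
        iteration += 1
        tests = []
        for sp in subprocesses:
            levels = sorted(df[sp].unique())
            others = ["dataset"] + [c for c in spec_cols if c != sp]
            by_level = {
                lev: df[df[sp] == lev].set_index(others)["arand"]
                for lev in levels
            }
            for x, y_ in combinations(levels, 2):
                sx, sy = by_level[x], by_level[y_]
                common = sx.index.intersection(sy.index)
                if len(common) < min_pairs:
                    skipped.append(
                        f"iter {iteration}: {sp} {x} vs {y_}: only "
                        f"{len(common)} paired settings")
                    continue
                diffs = (sx.loc[common] - sy.loc[common]).to_numpy()
                if np.allclose(diffs, 0):
                    skipped.append(
                        f"iter {iteration}: {sp} {x} vs {y_}: identical scores")
                    continue
                p = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
                tests.append({
                    "subprocess": sp, "x": x, "y": y_, "p": p,
                    "median_x": float(np.median(sx.loc[common])),
                    "median_y": float(np.median(sy.loc[common])),
                })
        if not tests:
            break
        cumulative_tests += len(tests)
        factor = len(tests) if bonferroni == "iteration" else cumulative_tests
        best = min(tests, key=lambda t: t["p"])
        corrected = min(best["p"] * factor, 1.0)
        if corrected >= alpha:
            break
        if best["median_x"] <= best["median_y"]:
            removed, superior = best["x"], best["y"]
        else:
            removed, superior = best["y"], best["x"]
        steps.append({"iteration": iteration, "subprocess": best["subprocess"],
                      "removed": removed, "p_value": corrected,
                      "superior": superior})
        df = df[df[best["subprocess"]] != removed]

    survivors = {sp: sorted(df[sp].unique()) for sp in subprocesses}
    steps_df = pd.DataFrame(
        steps, columns=["iteration", "subprocess", "removed", "p_value",
                        "superior"])
    return EliminationTrace(steps=steps_df, survivors=survivors,
                            skipped=skipped)


def summarize(
    rt: pd.DataFrame,
    by: str = "selection",
) -> pd.DataFrame:
    """Distribution of dataset-mean aRand per level of one sub-process.

    Each parameter combination's aRand is first averaged over datasets;
    the returned frame summarizes those means per ``by`` level.
    """
    df = rt.dropna(subset=["arand"])
    if df.empty:
        raise ValueError("summarize: empty result table")
    spec_cols = ["normalization", "imputation", "standardization",
                 "selection", "clustering"]
    means = (df.groupby(spec_cols, observed=True)["arand"]
             .mean().reset_index(name="mean_arand"))
    out = (means.groupby(by, observed=True)["mean_arand"]
           .agg(n="size", mean="mean", median="median", min="min", max="max")
           .reset_index())
    return out.sort_values("mean", ascending=False).reset_index(drop=True)
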