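"""Synthetic two-channel common-reference experiments with known two-class
structure.

The generator emulates the structure of the cancer cohorts the benchmark is
designed for: tens of samples in two classes, thousands of spots laid out in
print-tip blocks, a subset of genes differentially expressed between the
classes, an intensity-dependent dye bias (a smooth curved M-vs-A offset plus
a linear trend — exactly the pattern MA-loess removes), per-block offsets,
additive background, flagged spots, missing values, and a fraction of genes
printed in duplicate.

Generative model, per gene g and sample j:

* reference (green) intensity  G0_g = 2**x,  x ~ N(9, 1.5) — one draw per gene;
* true log2-ratio  m_gj = m0_g + s_g * de/2 * (+1 if class A else -1) + eps,
  with baseline m0_g ~ N(0, 0.3), random DE sign s_g, eps ~ N(0, noise_sd);
* red channel  R0_gj = G0_g * 2**(m_gj + b(A_gj) + block offset), where
  b(A) = amp*sin(2*pi*(A - Amin)/range) + 0.3*amp*(2*(A - Amin)/range - 1);
* measured foreground = channel + additive background (gamma-distributed,
  mean ``background_mean``); the written background column is a noisy
  estimate of that background, so background correction recovers the signal
  up to estimation noise.

Flags are Bernoulli(flag_rate); missing-completely-at-random spots
(Bernoulli(missing_rate)) are written with zero foreground in both channels,
which the M/A computation marks missing.  Everything is reproducible
bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .structures import ArrayScan

__all__ = ["SimConfig", "SyntheticExperiment", "generate_experiment",
           "write_scans", "synthetic_result_table"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror a mid-sized cohort from the designs the benchmark
    targets: 60 samples in two balanced classes, 2000 genes of which 200
    discriminate the classes with a 1.5 log2-unit shift, 16 print-tip
    blocks, and a few percent of flagged/missing spots.
    """

    n_samples_per_class: tuple[int, int] = (30, 30)
    n_genes: int = 2000
    n_de_genes: int = 200
    de_effect: float = 1.5  # mean log2-ratio shift between classes
    dye_bias_amplitude: float = 0.5  # log2 units
    n_printtip_blocks: int = 16
    block_offset_sd: float = 0.2  # log2 units
    background_mean: float = 80.0  # intensity units
    noise_sd: float = 0.4  # spot-level M noise
    flag_rate: float = 0.02
    missing_rate: float = 0.02
    duplicate_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples_per_class) < 1:
            raise ValueError("each class needs >= 1 sample")
        if self.n_genes < 1 or self.n_printtip_blocks < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ValueError("n_de_genes must lie in [0, n_genes]")
        if self.de_effect < 0:
            raise ValueError("de_effect must be >= 0")
        for name in ("flag_rate", "missing_rate", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        expected_missing = self.missing_rate + (1 - self.missing_rate) * self.flag_rate
        if expected_missing >= 0.5:
            raise ValueError(
                "config rejected: expected per-sample missing fraction "
                f"{expected_missing:.2f} >= 0.5, so sample filtration would "
                "remove every sample; lower missing_rate/flag_rate")


@dataclass
class SyntheticExperiment:
    """Generated scans plus the ground truth they encode."""

    scans: List[ArrayScan]
    true_labels: np.ndarray  # class per sample, aligned with scans
    de_genes: np.ndarray  # gene IDs of the differentially expressed genes
    config: SimConfig = field(repr=False, default=None)

    def labels_mapping(self) -> Dict[str, str]:
        return {s.sample_id: lab
                for s, lab in zip(self.scans, self.true_labels)}


def _layout(cfg: SimConfig, rng: np.random.Generator):
    """Spot layout shared by all arrays: gene per spot, block/row/column."""
    n_dup = int(round(cfg.duplicate_fraction * cfg.n_genes))
    dup_genes = rng.choice(cfg.n_genes, size=n_dup, replace=False)
    spot_gene = np.concatenate([np.arange(cfg.n_genes), dup_genes]).astype(int)
    rng.shuffle(spot_gene)
    n_spots = len(spot_gene)
    block = np.minimum(np.arange(n_spots) * cfg.n_printtip_blocks // n_spots,
                       cfg.n_printtip_blocks - 1) + 1
    per_block = int(np.ceil(n_spots / cfg.n_printtip_blocks))
    ncol = max(int(np.ceil(np.sqrt(per_block))), 1)
    within = np.concatenate([np.arange((block == b).sum())
                             for b in range(1, cfg.n_printtip_blocks + 1)])
    row = within // ncol + 1
    col = within % ncol + 1
    return spot_gene, block, row, col


def generate_experiment(config: SimConfig) -> SyntheticExperiment:
    """Generate a full synthetic experiment; bit-identical for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    spot_gene, block, row, col = _layout(cfg, rng)
    n_spots = len(spot_gene)
    width = len(str(cfg.n_genes))
    gene_names = np.array([f"G{i:0{width}d}" for i in range(cfg.n_genes)],
                          dtype=object)

    log_ref = rng.normal(9.0, 1.5, size=cfg.n_genes)
    m0 = rng.normal(0.0, 0.3, size=cfg.n_genes)
    de_idx = rng.choice(cfg.n_genes, size=cfg.n_de_genes, replace=False)
    de_sign = np.zeros(cfg.n_genes)
    de_sign[de_idx] = rng.choice([-1.0, 1.0], size=cfg.n_de_genes)

    n_a, n_b = cfg.n_samples_per_class
    n_samples = n_a + n_b
    class_of = np.array(["A"] * n_a + ["B"] * n_b, dtype=object)
    sample_ids = np.array([f"S{j + 1:03d}" for j in range(n_samples)],
                          dtype=object)

    scans: List[ArrayScan] = []
    for j in range(n_samples):
        half = cfg.de_effect / 2.0
        class_shift = de_sign * (half if class_of[j] == "A" else -half)
        m_true = (m0 + class_shift)[spot_gene] \
            + rng.normal(0.0, cfg.noise_sd, size=n_spots)

        g0 = 2.0 ** log_ref[spot_gene]
        r0 = g0 * 2.0 ** m_true
        a0 = 0.5 * (np.log2(r0) + np.log2(g0))
        rng_a = np.ptp(a0)
        rel = (a0 - a0.min()) / (rng_a if rng_a > 0 else 1.0)
        bias = cfg.dye_bias_amplitude * (np.sin(2 * np.pi * rel)
                                         + 0.3 * (2 * rel - 1))
        offsets = rng.normal(0.0, cfg.block_offset_sd,
                             size=cfg.n_printtip_blocks)
        r = r0 * 2.0 ** (bias + offsets[block - 1])

        bg_r = rng.gamma(4.0, cfg.background_mean / 4.0, size=n_spots)
        bg_g = rng.gamma(4.0, cfg.background_mean / 4.0, size=n_spots)
        fg_r = r + bg_r
        fg_g = g0 + bg_g
        bg_r_est = bg_r * rng.uniform(0.9, 1.1, size=n_spots)
        bg_g_est = bg_g * rng.uniform(0.9, 1.1, size=n_spots)

        flagged = rng.random(n_spots) < cfg.flag_rate
        mcar = rng.random(n_spots) < cfg.missing_rate
        fg_r = np.where(mcar, 0.0, fg_r)
        fg_g = np.where(mcar, 0.0, fg_g)

        scans.append(ArrayScan(
            sample_id=str(sample_ids[j]),
            gene_ids=gene_names[spot_gene],
            block=block.copy(), row=row.copy(), column=col.copy(),
            fg_red=fg_r, bg_red=bg_r_est, fg_green=fg_g, bg_green=bg_g_est,
            flagged=flagged,
        ))

    return SyntheticExperiment(scans=scans, true_labels=class_of,
                               de_genes=np.sort(gene_names[de_idx]),
                               config=cfg)


def write_scans(experiment: SyntheticExperiment, directory) -> List[Path]:
    """Write one GPR-like TSV per sample plus a two-column labels file.

    Round-trips losslessly through :func:`maclust.io.read_gpr` /
    :func:`maclust.io.read_labels`.
    """
    if not experiment.scans:
        raise ValueError("write_scans: empty experiment")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    for scan in experiment.scans:
        path = directory / f"{scan.sample_id}.gpr"
        df = pd.DataFrame({
            "Block": scan.block, "Row": scan.row, "Column": scan.column,
            "ID": scan.gene_ids,
            "F635": scan.fg_red, "B635": scan.bg_red,
            "F532": scan.fg_green, "B532": scan.bg_green,
            "Flags": np.where(scan.flagged, -50, 0),
        })
        # default float formatting is repr-shortest: lossless for float64
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    labels_path = directory / "labels.tsv"
    with open(labels_path, "w") as fh:
        fh.write("sample_id\tclass\n")
        for scan, lab in zip(experiment.scans, experiment.true_labels):
            fh.write(f"{scan.sample_id}\t{lab}\n")
    paths.append(labels_path)
    return paths


def synthetic_result_table(
    effects: Dict,
    noise_sd: float = 0.05,
    n_datasets: int = 4,
    seed: int = 0,
    norms=("no.norm", "norm.glob"),
    sels=("STD 100", "PC 15"),
    clusts=("kmeans", "som", "hclust.eucl.ward"),
):
    """Factorial benchmark result table with a known additive generating model.

    Builds a long-format table over datasets x normalizations x imputations
    x standardizations x selections x clusterings whose aRand is a 0.5
    baseline plus ``effects[(column, level)]`` shifts plus Gaussian noise.
    Used to test the meta-analysis layer (variance decomposition and method
    elimination) against planted ground truth.
    """
    import pandas as pd
    from itertools import product

    rng = np.random.default_rng(seed)
    rows = []
    for ds, norm, imp, std, sel, cl in product(
            [f"D{i}" for i in range(n_datasets)], norms, ("ROW", "SVD"),
            (False, True), sels, clusts):
        y = 0.5 + rng.normal(0, noise_sd)
        for col, lev in [("dataset", ds), ("normalization", norm),
                         ("imputation", imp), ("standardization", std),
                         ("selection", sel), ("clustering", cl)]:
            y += effects.get((col, lev), 0.0)
        rows.append({"dataset": ds, "normalization": norm, "imputation": imp,
                     "standardization": std, "selection": sel,
                     "clustering": cl, "arand": y, "error": ""})
    return pd.DataFrame(rows)
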