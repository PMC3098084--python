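import numpy as np
import pytest

import maclust as mc


@pytest.fixture(scope="session")
def small_experiment():
    """A small but fully featured synthetic experiment (24 samples x 400 genes)."""
    cfg = mc.SimConfig(
        n_samples_per_class=(12, 12), n_genes=400, n_de_genes=60,
        de_effect=1.5, n_printtip_blocks=4, seed=11)
    return mc.generate_experiment(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_experiment):
    """Preprocessed M-value matrix + truth labels for the small experiment."""
    exp = small_experiment
    return mc.preprocess_scans(exp.scans, exp.labels_mapping(),
                               "no.norm", "ROW")


def scan_from_ma(M, A, sample_id="S1", n_blocks=1, flagged=None):
    """Build an ArrayScan whose foreground-only M/A equal the given values."""
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    n = len(M)
    fg_red = 2.0 ** (A + M / 2)
    fg_green = 2.0 ** (A - M / 2)
    block = np.minimum(np.arange(n) * n_blocks // n, n_blocks - 1) + 1
    return mc.ArrayScan(
        sample_id=sample_id,
        gene_ids=np.array([f"G{i:05d}" for i in range(n)], dtype=object),
        block=block, row=np.ones(n, dtype=int),
        column=np.arange(n) + 1,
        fg_red=fg_red, bg_red=np.zeros(n),
        fg_green=fg_green, bg_green=np.zeros(n),
        flagged=np.zeros(n, dtype=bool) if flagged is None else np.asarray(flagged),
    )


@pytest.fixture
def make_scan():
    return scan_from_ma
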