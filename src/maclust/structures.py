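"""Core containers shared across the pipeline.

All containers are thin dataclasses over numpy arrays; they validate shape
consistency on construction and are deliberately free of behaviour beyond
simple views, so every stage of the pipeline stays a pure function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArrayScan", "MASpots", "MValueMatrix", "FeatureMatrix"]


@dataclass
class ArrayScan:
    """One sample's raw two-channel scan.

    Spots are stored in array (print) order.  ``block`` is the 1-based
    print-tip block index; ``row``/``column`` locate the spot within its
    block.  Intensities follow the GenePix convention: the red channel is
    the sample (F635/B635), the green channel the common reference
    (F532/B532).  ``flagged`` marks spots flagged by the scanner or the
    experimentalist.
    """

    sample_id: str
    gene_ids: np.ndarray  # str per spot; duplicate spots share an ID
    block: np.ndarray  # int, 1-based
    row: np.ndarray
    column: np.ndarray
    fg_red: np.ndarray
    bg_red: np.ndarray
    fg_green: np.ndarray
    bg_green: np.ndarray
    flagged: np.ndarray  # bool

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("block", "row", "column", "fg_red", "bg_red",
                     "fg_green", "bg_green", "flagged"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(
                    f"ArrayScan field {name!r} has shape {arr.shape}, "
                    f"expected ({n},)")
            setattr(self, name, arr)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.flagged = self.flagged.astype(bool)
        for name in ("fg_red", "bg_red", "fg_green", "bg_green"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"negative intensities in {name}")

    @property
    def n_spots(self) -> int:
        return len(self.gene_ids)

    def layout_signature(self) -> tuple:
        """Hashable summary of the spot layout, for cross-sample checks."""
        return (tuple(self.gene_ids), tuple(self.block.tolist()))


@dataclass
class MASpots:
    """Per-spot M (log2 ratio) and A (mean log2 intensity) values.

    ``missing`` is True wherever M or A is undefined (flagged spot or
    non-positive intensity in either channel); M and A hold NaN there.
    """

    M: np.ndarray
    A: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (self.M.shape == self.A.shape == self.missing.shape):
            raise ValueError("M, A and missing must share one shape")
        ok = ~self.missing
        if not (np.all(np.isfinite(self.M[ok])) and np.all(np.isfinite(self.A[ok]))):
            raise ValueError("non-finite M/A outside the missing mask")


@dataclass
class MValueMatrix:
    """Genes × samples log2-ratio matrix with an explicit missingness mask."""

    values: np.ndarray
    missing: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        g, s = self.values.shape
        if self.missing.shape != (g, s):
            raise ValueError("missing mask shape mismatch")
        if len(self.gene_ids) != g or len(self.sample_ids) != s:
            raise ValueError("identifier length mismatch")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MValueMatrix":
        return MValueMatrix(self.values.copy(), self.missing.copy(),
                            self.gene_ids.copy(), self.sample_ids.copy(),
                            dict(self.provenance))


@dataclass
class FeatureMatrix:
    """Samples × features input to clustering.

    Features are either selected genes (``feature_ids`` = gene IDs) or
    principal-component scores (``feature_ids`` = "PC1", ...).
    """

    values: np.ndarray
    sample_ids: np.ndarray
    feature_ids: np.ndarray
    kind: str = "genes"  # "genes" or "components"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        s, f = self.values.shape
        if len(self.sample_ids) != s or len(self.feature_ids) != f:
            raise ValueError("identifier length mismatch")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("FeatureMatrix must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]
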