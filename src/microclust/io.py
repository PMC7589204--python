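"""Reading, writing and pre-processing of OTU count tables and companion artifacts.

The central container is :class:`OtuCountTable`, a thin validated wrapper around
an integer ``samples x OTUs`` matrix.  Trees are held as scikit-bio ``TreeNode``
objects, distance matrices as scikit-bio ``DistanceMatrix`` (read/written in the
labelled square TSV "lsmat" dialect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix


class TableValidationError(ValueError):
    """Raised when a count table violates its structural invariants."""


@dataclass
class OtuCountTable:
    """Integer OTU count matrix, one row per sample, one column per OTU."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_ids),
            len(self.otu_ids),
        ):
            raise TableValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableValidationError("duplicate sample identifiers")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise TableValidationError("duplicate OTU identifiers")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise TableValidationError("non-integer counts")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise TableValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        """Per-sample read totals N_i (row sums)."""
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class RelativeAbundanceTable:
    """Row-normalised proportions sharing identifiers with a source count table."""

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray
    zero_total_samples: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class LabelVector:
    """Integer class labels aligned with a table's samples."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.sample_ids):
            raise TableValidationError("labels and sample_ids differ in length")


def read_count_table(path, orientation: str = "samples_as_rows") -> OtuCountTable:
    """Read a delimited count table (header row + leading identifier column).

    ``orientation="otus_as_rows"`` transposes the common biom-TSV layout in
    which OTUs are rows and samples are columns.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    arr = df.to_numpy()
    if arr.size == 0:
        raise TableValidationError(f"{path}: empty table")
    flat = pd.to_numeric(pd.Series(arr.ravel()), errors="coerce")
    if flat.isna().any():
        bad = np.unravel_index(int(flat.isna().idxmax()), arr.shape)
        raise TableValidationError(
            f"{path}: cell at row {df.index[bad[0]]!r}, column "
            f"{df.columns[bad[1]]!r} does not parse as a count"
        )
    vals = flat.to_numpy(dtype=float).reshape(arr.shape)
    if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
        bad = np.argwhere((vals < 0) | (vals != np.round(vals)))[0]
        raise TableValidationError(
            f"{path}: cell at row {df.index[bad[0]]!r}, column "
            f"{df.columns[bad[1]]!r} is not a non-negative integer"
        )
    counts = vals.astype(np.int64)
    if orientation == "otus_as_rows":
        return OtuCountTable(list(map(str, df.columns)), list(map(str, df.index)), counts.T)
    return OtuCountTable(list(map(str, df.index)), list(map(str, df.columns)), counts)


def write_count_table(table: OtuCountTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t")


def to_relative_abundance(table: OtuCountTable) -> RelativeAbundanceTable:
    """Divide each row by its total; all-zero rows stay zero and are flagged."""
    totals = table.sample_totals.astype(float)
    zero_rows = totals == 0
    safe = np.where(zero_rows, 1.0, totals)
    values = table.counts / safe[:, None]
    flagged = [s for s, z in zip(table.sample_ids, zero_rows) if z]
    if flagged:
        warnings.warn(
            f"{len(flagged)} sample(s) with zero total reads left as all-zero rows",
            stacklevel=2,
        )
    return RelativeAbundanceTable(
        list(table.sample_ids), list(table.otu_ids), values, flagged
    )


def filter_by_zero_proportion(
    table: OtuCountTable, max_zero_fraction: float = 0.8
) -> OtuCountTable:
    """Drop OTUs whose fraction of zero entries is *strictly above* the threshold.

    A count of zero is equivalent to a relative abundance of zero, so the
    filter is computed directly on counts.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must lie in [0, 1]")
    zero_frac = (table.counts == 0).mean(axis=0)
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        raise TableValidationError(
            "zero-proportion filter removed every OTU; raise the threshold"
        )
    kept_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    return OtuCountTable(list(table.sample_ids), kept_ids, table.counts[:, keep])


def read_newick(path) -> TreeNode:
    """Parse a rooted newick tree with branch lengths."""
    return TreeNode.read(str(path), format="newick")


def check_tree_covers_otus(tree: TreeNode, otu_ids) -> None:
    """Raise if any OTU is missing from the tree's leaf set."""
    leaves = {t.name for t in tree.tips()}
    missing = [o for o in otu_ids if o not in leaves]
    if missing:
        raise TableValidationError(f"missing leaves for OTUs: {missing}")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Write a labelled square TSV (lsmat) distance matrix."""
    dm.write(str(path))


def read_distance_matrix(path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path))


def read_labels(path) -> LabelVector:
    """Read a two-column TSV of (sample_id, integer label)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise TableValidationError(f"{path}: expected two columns (sample_id, label)")
    try:
        labels = df.iloc[:, 1].astype(int).to_numpy()
    except ValueError as exc:
        raise TableValidationError(f"{path}: non-integer label: {exc}") from exc
    return LabelVector(list(df.iloc[:, 0]), labels)


def write_labels(labels: LabelVector, path) -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep="\t", header=False, index=False
    )
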