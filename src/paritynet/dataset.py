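"""Two-group expression dataset container.

The universal input of the pipeline: a probes x samples matrix of continuous
(normalized, log-like) expression values together with a sample sheet that
assigns each sample to one of exactly two groups.  By convention group 1 is
the reference group ("nulliparous" in the motivating study) and group 2 the
contrast group ("parous"); every "delta" downstream is group 2 minus group 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REFERENCE_GROUP = "nulliparous"
CONTRAST_GROUP = "parous"


class DatasetError(ValueError):
    """Raised when an expression matrix / sample sheet pair is inconsistent."""


@dataclass
class ExpressionDataset:
    """Probes x samples expression matrix with a two-group sample assignment.

    Parameters
    ----------
    values
        DataFrame indexed by unique probe identifiers, one column per sample.
        All entries must be finite.
    sample_groups
        Series mapping each sample identifier (the matrix columns) to one of
        exactly two group labels.
    group_order
        The (reference, contrast) pair.  If omitted it is inferred: the labels
        ``nulliparous``/``parous`` are ordered that way, otherwise the two
        labels are taken in sorted order.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    group_order: tuple[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DatasetError(f"duplicate probe id {dup!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.values.to_numpy()))[0]
            raise DatasetError(
                f"non-finite value at probe {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.sample_groups.index]
        if missing:
            raise DatasetError(f"samples without a group label: {missing[:5]}")
        self.sample_groups = self.sample_groups.loc[self.values.columns]
        labels = pd.unique(self.sample_groups)
        if len(labels) != 2:
            raise DatasetError(f"expected exactly 2 groups, found {list(labels)}")
        if self.group_order is None:
            if set(labels) == {REFERENCE_GROUP, CONTRAST_GROUP}:
                self.group_order = (REFERENCE_GROUP, CONTRAST_GROUP)
            else:
                self.group_order = tuple(sorted(labels))  # type: ignore[assignment]
        if set(self.group_order) != set(labels):
            raise DatasetError(
                f"group_order {self.group_order} does not match labels {list(labels)}"
            )
        for g in self.group_order:
            if (self.sample_groups == g).sum() < 2:
                raise DatasetError(f"group {g!r} has fewer than 2 samples")

    # -- basic accessors ---------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def group1(self) -> str:
        """Reference group label."""
        return self.group_order[0]

    @property
    def group2(self) -> str:
        """Contrast group label."""
        return self.group_order[1]

    def samples_of(self, group: str) -> pd.Index:
        if group not in self.group_order:
            raise DatasetError(f"unknown group {group!r}")
        return self.sample_groups.index[self.sample_groups == group]

    def group_size(self, group: str) -> int:
        return len(self.samples_of(group))

    def group_matrix(self, group: str) -> pd.DataFrame:
        """Probes x samples sub-matrix of one group."""
        return self.values[self.samples_of(group)]

    def group_values(self, group: str) -> np.ndarray:
        """Plain ndarray view of one group's sub-matrix."""
        return self.group_matrix(group).to_numpy()

    def subset_probes(self, probes) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.loc[probes], self.sample_groups, self.group_order
        )
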