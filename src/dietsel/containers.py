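"""In-memory containers shared by every stage.

The pipeline's universal currency is the :class:`SampleTable`: a samples x
variables numeric matrix with a group label per sample and a block/segment
annotation per variable.  qPCR input arrives as a :class:`CtTable` of raw
cycle-threshold values and is converted to relative expression by the
``expression`` module.

Both are thin wrappers over :class:`pandas.DataFrame` that validate their
invariants on construction and know how to round-trip through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

#: Intestinal segments used as variable annotations: duodenum, jejunum,
#: ileum, ascending/descending colon, plus plasma and "none" for variables
#: without an anatomical location.
SEGMENTS = ("D", "J", "I", "AC", "DC", "plasma", "none")


@dataclass
class SampleTable:
    """Samples x variables table with group labels and variable annotations.

    Parameters
    ----------
    data
        Numeric values, index = sample ids, columns = variable ids.
        Missing values (NaN) are allowed.
    groups
        Group label per sample, aligned with ``data.index``.
    annotations
        One row per variable (index = variable id) with columns
        ``block`` and ``segment``.
    """

    data: pd.DataFrame
    groups: pd.Series
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            raise DataError("group labels must be indexed by the sample ids of `data`")
        missing_ann = [v for v in self.data.columns if v not in self.annotations.index]
        if missing_ann:
            raise DataError(
                f"variables missing from annotations: {missing_ann[:5]}"
            )
        extra_ann = [v for v in self.annotations.index if v not in self.data.columns]
        if extra_ann:
            raise DataError(f"annotated variables absent from table: {extra_ann[:5]}")
        bad_seg = set(self.annotations["segment"]) - set(SEGMENTS)
        if bad_seg:
            raise DataError(f"unknown segment annotations: {sorted(bad_seg)}")
        # keep annotation rows in table column order: downstream stages rely
        # on this order being deterministic
        self.annotations = self.annotations.loc[list(self.data.columns)]

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def subset_groups(self, labels: list[str]) -> "SampleTable":
        """Rows restricted to the given group labels (order preserved)."""
        unknown = set(labels) - set(self.groups)
        if unknown:
            raise DataError(f"unknown group label(s): {sorted(unknown)}")
        mask = self.groups.isin(labels)
        return SampleTable(
            data=self.data.loc[mask].copy(),
            groups=self.groups.loc[mask].copy(),
            annotations=self.annotations.copy(),
        )

    def block_variables(self, block: str) -> list[str]:
        return list(self.annotations.index[self.annotations["block"] == block])

    # ---- CSV round trip -------------------------------------------------
    def to_csv(self, data_path: str | Path, annotations_path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(data_path, index_label="sample")
        self.annotations.to_csv(annotations_path, index_label="variable")

    @classmethod
    def from_csv(
        cls, data_path: str | Path, annotations_path: str | Path
    ) -> "SampleTable":
        raw = pd.read_csv(data_path, index_col="sample")
        if "group" not in raw.columns:
            raise DataError(f"{data_path}: no 'group' column")
        groups = raw.pop("group")
        ann = pd.read_csv(annotations_path, index_col="variable")
        return cls(data=raw.astype(float), groups=groups, annotations=ann)


@dataclass
class CtTable:
    """Raw qPCR cycle-threshold values per sample x gene.

    ``reference_gene`` is the endogenous control (cyclophilin in the study
    this emulates) and ``control_group`` the calibrator group for the
    comparative-Ct method.
    """

    data: pd.DataFrame
    groups: pd.Series
    reference_gene: str
    control_group: str

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            raise DataError("group labels must be indexed by the sample ids of `data`")
        if self.reference_gene not in self.data.columns:
            raise DataError(f"reference gene {self.reference_gene!r} not in Ct table")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = self.data.index[~np.isfinite(vals).all(axis=1)][:3].tolist()
            raise DataError(f"non-finite Ct values, e.g. sample(s) {bad}")
        if (vals <= 0).any():
            raise DataError("Ct values must be positive cycle counts")

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.data.columns if g != self.reference_gene]

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, index_label="sample")

    @classmethod
    def from_csv(
        cls, path: str | Path, reference_gene: str, control_group: str
    ) -> "CtTable":
        raw = pd.read_csv(path, index_col="sample")
        groups = raw.pop("group")
        return cls(
            data=raw.astype(float),
            groups=groups,
            reference_gene=reference_gene,
            control_group=control_group,
        )


@dataclass
class Comparison:
    """A two-group contrast: ``test`` vs ``reference``, tagged by scenario."""

    test: str
    reference: str
    scenario: str = "healthy"

    def __post_init__(self) -> None:
        if self.test == self.reference:
            raise DataError("comparison groups must be distinct")

    @property
    def label(self) -> str:
        return f"{self.test}_vs_{self.reference}"


#: The study's comparison scheme: insect-supplemented groups against Control
#: in the healthy scenario; Control and Tenebrio+LPS against LPS under
#: inflammation (the reference group is the fold-change denominator).
DEFAULT_COMPARISONS: tuple[Comparison, ...] = (
    Comparison("Tenebrio", "Control", "healthy"),
    Comparison("Buffalo", "Control", "healthy"),
    Comparison("Control", "LPS", "inflammation"),
    Comparison("TenebrioLPS", "LPS", "inflammation"),
)
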