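"""Relative gene expression by the comparative-Ct (2^-ddCt) method.

For a target gene g in sample s, with reference gene r and a designated
control (calibrator) group::

    dCt(g, s)  = Ct(g, s) - Ct(r, s)
    ddCt(g, s) = dCt(g, s) - mean{ dCt(g, c) : c in control group }
    RE(g, s)   = 2 ** -ddCt(g, s)

Using the arithmetic control-group mean of dCt as the calibrator makes the
geometric mean of RE over the control group exactly 1 for every gene — the
identity the tests assert.  Fold changes between groups are ratios of
arithmetic group means of RE (or of any other variable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CtTable, SampleTable
from .errors import ConfigurationError, DataError


@dataclass
class ExpressionMatrix:
    """Relative expression (dimensionless, > 0) per sample x gene."""

    data: pd.DataFrame
    groups: pd.Series
    control_group: str

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, index_label="sample")


@dataclass(frozen=True)
class FoldChangeRecord:
    """FC = mean(A) / mean(B) for one variable and one group pair."""

    variable: str
    group_a: str
    group_b: str
    fc: float

    @property
    def log2fc(self) -> float:
        return float(np.log2(self.fc))


def relative_expression(ct: CtTable) -> ExpressionMatrix:
    """Convert a Ct table to relative expression via 2^-ddCt.

    Raises
    ------
    DataError
        If any sample lacks a reference-gene Ct.
    ConfigurationError
        If the designated control group has no samples.
    """
    ref = ct.data[ct.reference_gene]
    bad = ref.index[ref.isna()].tolist()
    if bad:
        raise DataError(f"missing reference Ct for sample(s): {bad[:5]}")
    control_mask = ct.groups == ct.control_group
    if not control_mask.any():
        raise ConfigurationError(
            f"control group {ct.control_group!r} has no samples"
        )
    dct = ct.data[ct.target_genes].sub(ref, axis=0)
    ddct = dct - dct.loc[control_mask].mean(axis=0)
    re = np.power(2.0, -ddct)
    return ExpressionMatrix(
        data=re, groups=ct.groups.copy(), control_group=ct.control_group
    )


def fold_change(
    table: SampleTable | ExpressionMatrix,
    variable: str,
    group_a: str,
    group_b: str,
) -> FoldChangeRecord:
    """Ratio of arithmetic group means, A over B.

    By the study's convention the denominator B is the scenario's reference
    group: Control in the healthy scenario, LPS under inflammation.
    Missing values are dropped before averaging.
    """
    if variable not in table.data.columns:
        raise DataError(f"unknown variable {variable!r}")
    values = table.data[variable]
    means = {}
    for grp in (group_a, group_b):
        mask = table.groups == grp
        if not mask.any():
            raise DataError(f"group {grp!r} has no samples")
        obs = values[mask].dropna()
        if obs.empty:
            raise DataError(f"group {grp!r} has no observed values for {variable!r}")
        means[grp] = float(obs.mean())
    if means[group_b] == 0.0:
        raise DataError(
            f"fold change undefined: mean of {variable!r} in {group_b!r} is zero"
        )
    return FoldChangeRecord(
        variable=variable,
        group_a=group_a,
        group_b=group_b,
        fc=means[group_a] / means[group_b],
    )
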