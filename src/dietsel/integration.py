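"""Integration across comparisons: Venn overlap, fold-change heatmap
matrices, and Spearman correlation maps.

The two per-scenario selections are combined with plain set algebra (the
Venn diagram of the two selected-variable lists); variables common to both
comparisons are laid out as a fold-change matrix against the scenario's
reference group, each cell carrying its univariate significance flag.
Associations between taste-receptor expression and every other variable are
scored with Spearman's rho, starred at p < 0.05 / 0.01 / 0.001 without
multiple-testing correction (matching the study's figures); a
Benjamini-Hochberg column is attached for users who want it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consensus import SelectionResult
from .containers import Comparison, SampleTable
from .errors import AlignmentError, DataError, DegenerateSampleError
from .expression import fold_change
from .univariate import flag_for_p


@dataclass(frozen=True)
class VennResult:
    """Two-set overlap of selected variables from two comparisons."""

    set_a: frozenset[str]
    set_b: frozenset[str]
    label_a: str = "A"
    label_b: str = "B"

    @property
    def intersection(self) -> frozenset[str]:
        return self.set_a & self.set_b

    @property
    def union(self) -> frozenset[str]:
        return self.set_a | self.set_b

    @property
    def counts(self) -> dict[str, int]:
        return {
            "A": len(self.set_a),
            "B": len(self.set_b),
            "intersection": len(self.intersection),
            "union": len(self.union),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "label_a": self.label_a,
                    "label_b": self.label_b,
                    "A": sorted(self.set_a),
                    "B": sorted(self.set_b),
                    "intersection": sorted(self.intersection),
                    "counts": self.counts,
                },
                fh,
                indent=2,
            )


def venn(selection_a: SelectionResult, selection_b: SelectionResult) -> VennResult:
    """Set algebra on the selected variables of two comparisons."""
    universe_a = set(selection_a.ranking.variables)
    universe_b = set(selection_b.ranking.variables)
    if not universe_a & universe_b:
        raise AlignmentError("selections come from disjoint variable universes")
    return VennResult(
        set_a=frozenset(selection_a.selected),
        set_b=frozenset(selection_b.selected),
        label_a=selection_a.comparison.label,
        label_b=selection_b.comparison.label,
    )


def foldchange_heatmap(
    table: SampleTable,
    common_vars: list[str],
    comparisons: list[Comparison],
    screen: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-form fold-change matrix for the variables shared by comparisons.

    ``table`` should be on the original measurement scale (imputed but not
    z-scored), since a fold change of standardized data is meaningless.
    If a univariate ``screen`` frame is supplied, its significance flags are
    attached per cell.  Returns a tidy frame (variable x comparison rows with
    fc, log2fc, flag); pivot on (variable, comparison) for the matrix view.
    """
    unknown = [v for v in common_vars if v not in table.data.columns]
    if unknown:
        raise DataError(f"common variables absent from table: {unknown[:5]}")
    if not common_vars:
        import warnings

        warnings.warn("empty common-variable set: empty heatmap", stacklevel=2)
    rows = []
    for cmp_ in comparisons:
        for var in common_vars:
            rec = fold_change(table, var, cmp_.test, cmp_.reference)
            flag = ""
            if screen is not None:
                hit = screen[
                    (screen["variable"] == var) & (screen["comparison"] == cmp_.label)
                ]
                if len(hit):
                    flag = str(hit["flag"].iloc[0])
            rows.append(
                {
                    "variable": var,
                    "comparison": cmp_.label,
                    "scenario": cmp_.scenario,
                    "fc": rec.fc,
                    "log2fc": rec.log2fc,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows, columns=["variable", "comparison", "scenario", "fc", "log2fc", "flag"])


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (Pearson on mid-ranks) and two-sided t-approximation p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise DataError("x and y must have equal length")
    if xa.size < 4:
        raise DataError(f"Spearman correlation requires n >= 4, got {xa.size}")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise DataError("Spearman correlation requires finite values")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        raise DegenerateSampleError("constant vector: correlation undefined")
    rho, p = stats.spearmanr(xa, ya)
    return float(rho), float(p)


def star_for_p(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrMatrix:
    """Spearman rho / p / stars for receptor x other-variable pairs."""

    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    bh_significant: pd.DataFrame  # BH-FDR at 5%, extra column for users

    def to_csv(self, prefix) -> None:
        self.rho.to_csv(f"{prefix}_rho.csv", index_label="receptor")
        self.p.to_csv(f"{prefix}_p.csv", index_label="receptor")
        self.stars.to_csv(f"{prefix}_stars.csv", index_label="receptor")
        self.bh_significant.to_csv(f"{prefix}_bh05.csv", index_label="receptor")


def correlation_heatmap(
    table: SampleTable,
    scenario_groups: list[str],
    receptor_block: str = "tasr_expression",
) -> CorrMatrix:
    """Spearman map of receptor expression against all other variables.

    Rows are the receptor-block variables, columns every non-receptor
    variable; samples are pooled over ``scenario_groups`` (the study pools
    the control group into each scenario).  Stars follow the raw
    0.05/0.01/0.001 convention; the BH matrix marks pairs that survive a 5%
    FDR across the whole matrix.
    """
    receptors = table.block_variables(receptor_block)
    if not receptors:
        raise DataError(f"receptor block {receptor_block!r} is empty")
    others = [v for v in table.variables if v not in set(receptors)]
    sub = table.subset_groups(scenario_groups)
    rho = pd.DataFrame(index=receptors, columns=others, dtype=float)
    pmat = pd.DataFrame(index=receptors, columns=others, dtype=float)
    for r in receptors:
        xr = sub.data[r]
        for c in others:
            xc = sub.data[c]
            mask = xr.notna() & xc.notna()
            rho.loc[r, c], pmat.loc[r, c] = spearman(xr[mask], xc[mask])
    stars = pmat.map(star_for_p)
    flat = pmat.to_numpy().ravel()
    reject = multipletests(flat, alpha=0.05, method="fdr_bh")[0]
    bh = pd.DataFrame(
        reject.reshape(pmat.shape), index=receptors, columns=others
    )
    return CorrMatrix(rho=rho, p=pmat, stars=stars, bh_significant=bh)
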