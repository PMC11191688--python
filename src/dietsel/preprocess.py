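"""Preprocessing: median imputation, redundancy pruning, scaling, PCA check.

Fixed stage order: ``impute_median`` -> ``drop_redundant`` -> ``scale`` ->
``pca_outliers``.  Each stage returns both the transformed table and a
serializable report fragment so the whole run can be audited.

Missing cells are replaced by the within-group median (global medians would
shrink exactly the group differences the selection stage must detect).
Redundant variables are pruned greedily in annotation order: scanning
variables left to right, a variable whose absolute Spearman correlation with
an already-kept variable reaches the threshold is dropped.  Scaling is a
z-score over the full sample set; comparisons subset rows afterwards.
PCA outlier flagging (Mahalanobis distance in the leading component space)
is advisory — the emulated study excluded no animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import SampleTable
from .errors import ConfigurationError, DataError, DegenerateVariableError


@dataclass
class PreprocessReport:
    """Audit trail of one preprocessing run."""

    imputed_cells: int = 0
    imputed_index: list[tuple[str, str]] = field(default_factory=list)
    dropped: list[dict] = field(default_factory=list)
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    pca_explained_variance: list[float] = field(default_factory=list)
    pca_scores: pd.DataFrame | None = None
    outlier_samples: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "imputed_cells": self.imputed_cells,
            "imputed_index": [list(t) for t in self.imputed_index],
            "dropped": self.dropped,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "pca_explained_variance": self.pca_explained_variance,
            "outlier_samples": self.outlier_samples,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def impute_median(
    table: SampleTable, report: PreprocessReport | None = None
) -> tuple[SampleTable, PreprocessReport]:
    """Replace missing cells by the within-group median of the variable."""
    report = report or PreprocessReport()
    data = table.data.copy()
    for grp in table.group_labels:
        mask = table.groups == grp
        block = data.loc[mask]
        missing = block.isna()
        if not missing.to_numpy().any():
            continue
        fully_missing = [v for v in block.columns if block[v].isna().all()]
        if fully_missing:
            raise DataError(
                f"variable(s) entirely missing within group {grp!r}: {fully_missing[:5]}"
            )
        medians = block.median(axis=0)
        for var in block.columns:
            idx = missing.index[missing[var]]
            if len(idx):
                data.loc[idx, var] = medians[var]
                report.imputed_cells += len(idx)
                report.imputed_index.extend((s, var) for s in idx)
    return (
        SampleTable(data=data, groups=table.groups.copy(), annotations=table.annotations.copy()),
        report,
    )


def drop_redundant(
    table: SampleTable,
    rho_threshold: float = 0.95,
    report: PreprocessReport | None = None,
) -> tuple[SampleTable, PreprocessReport]:
    """Greedy Spearman-based pruning of near-duplicate variables.

    Variables are scanned in annotation order; when ``|rho|`` with an
    already-kept variable reaches the threshold, the later variable is
    dropped and the triggering partner recorded.
    """
    if not (0.0 < rho_threshold <= 1.0):
        raise ConfigurationError(f"rho_threshold must be in (0, 1], got {rho_threshold}")
    report = report or PreprocessReport()
    corr = table.data.corr(method="spearman").abs()
    kept: list[str] = []
    for var in table.variables:
        partner = None
        for other in kept:
            if corr.loc[var, other] >= rho_threshold:
                partner = other
                break
        if partner is None:
            kept.append(var)
        else:
            report.dropped.append(
                {
                    "variable": var,
                    "partner": partner,
                    "abs_spearman_rho": float(corr.loc[var, partner]),
                }
            )
    return (
        SampleTable(
            data=table.data[kept].copy(),
            groups=table.groups.copy(),
            annotations=table.annotations.loc[kept].copy(),
        ),
        report,
    )


def scale(
    table: SampleTable, report: PreprocessReport | None = None
) -> tuple[SampleTable, PreprocessReport]:
    """Z-score each variable over all samples (sample SD, ddof=1)."""
    report = report or PreprocessReport()
    data = table.data.copy()
    for var in table.variables:
        col = data[var]
        center = float(col.mean())
        spread = float(col.std(ddof=1))
        if not np.isfinite(spread) or spread == 0.0:
            raise DegenerateVariableError(f"zero-variance variable: {var!r}")
        data[var] = (col - center) / spread
        report.scaling[var] = (center, spread)
    return (
        SampleTable(data=data, groups=table.groups.copy(), annotations=table.annotations.copy()),
        report,
    )


def pca_outliers(
    table: SampleTable,
    n_components: int = 2,
    z_cut: float = 3.0,
    report: PreprocessReport | None = None,
) -> PreprocessReport:
    """PCA sanity check: scores, explained variance, Mahalanobis flags.

    Samples whose Mahalanobis distance in the leading ``n_components`` score
    space exceeds ``z_cut`` are flagged as candidate outliers.  Flagging is
    advisory; exclusion is a pipeline config switch (default off).
    """
    report = report or PreprocessReport()
    max_comp = min(len(table.data), len(table.variables))
    if not (1 <= n_components <= max_comp):
        raise ConfigurationError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(table.data.to_numpy())
    report.pca_explained_variance = [float(v) for v in pca.explained_variance_ratio_]
    report.pca_scores = pd.DataFrame(
        scores,
        index=table.data.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0.0] = np.inf  # degenerate component carries no distance
    maha = np.sqrt(((scores / sd) ** 2).sum(axis=1))
    report.outlier_samples = list(table.data.index[maha > z_cut])
    return report


def preprocess(
    table: SampleTable,
    rho_threshold: float = 0.95,
    n_components: int = 2,
    z_cut: float = 3.0,
    exclude_outliers: bool = False,
) -> tuple[SampleTable, PreprocessReport]:
    """Run the full fixed-order preprocessing pipeline.

    Returns the imputed/pruned/scaled table and the combined report.  With
    ``exclude_outliers`` the flagged samples are removed from the returned
    table (after flagging, so the report always lists them).
    """
    report = PreprocessReport()
    table, report = impute_median(table, report)
    table, report = drop_redundant(table, rho_threshold, report)
    table, report = scale(table, report)
    report = pca_outliers(table, n_components=n_components, z_cut=z_cut, report=report)
    if exclude_outliers and report.outlier_samples:
        keep = ~table.data.index.isin(report.outlier_samples)
        table = SampleTable(
            data=table.data.loc[keep].copy(),
            groups=table.groups.loc[keep].copy(),
            annotations=table.annotations.copy(),
        )
    return table, report
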