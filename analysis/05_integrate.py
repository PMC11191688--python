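#!/usr/bin/env python
"""Integrate the per-comparison selections: Venn, fold changes, correlations.

Per scenario (healthy, inflammation): overlap the two selected-variable sets
(Venn), lay the common variables out as a fold-change matrix against the
scenario's reference group with univariate flags, and map Spearman
correlations between taste-receptor expression and every other variable.

Outputs under results/integration/: venn_<scenario>.json,
fc_heatmap_<scenario>.csv, corr_<scenario>_{rho,p,stars,bh05}.csv.
"""

import json
from pathlib import Path

import pandas as pd

from dietsel import (
    Comparison,
    DEFAULT_COMPARISONS,
    SampleTable,
    correlation_heatmap,
    foldchange_heatmap,
    impute_median,
    pairwise_screen,
    venn,
)
from dietsel.consensus import ConsensusRanking, SelectionResult

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_selection(cmp_: Comparison) -> SelectionResult:
    frame = pd.read_csv(ROOT / "selection" / f"selection_{cmp_.label}.csv",
                        index_col="variable")
    return SelectionResult(
        comparison=cmp_,
        ranking=ConsensusRanking(table=frame.drop(columns=["selected"])),
        knee_index=int(frame["selected"].sum()),
        selected=list(frame.index[frame["selected"]]),
    )


def main() -> None:
    table = SampleTable.from_csv(ROOT / "data" / "samples.csv",
                                 ROOT / "data" / "annotations.csv")
    imputed, _ = impute_median(table)
    screen = pairwise_screen(imputed)
    out = ROOT / "integration"
    out.mkdir(parents=True, exist_ok=True)

    scenarios: dict[str, list[Comparison]] = {}
    for cmp_ in DEFAULT_COMPARISONS:
        scenarios.setdefault(cmp_.scenario, []).append(cmp_)
    for scenario, cmps in scenarios.items():
        sel_a, sel_b = (load_selection(c) for c in cmps)
        v = venn(sel_a, sel_b)
        v.to_json(out / f"venn_{scenario}.json")
        c = v.counts
        print(f"{scenario}: |{cmps[0].label}|={c['A']}, |{cmps[1].label}|={c['B']}, "
              f"common={c['intersection']}, union={c['union']}")
        common = sorted(v.intersection)
        fch = foldchange_heatmap(imputed, common, cmps, screen=screen)
        fch.to_csv(out / f"fc_heatmap_{scenario}.csv", index=False)
        if not fch.empty:
            signif = fch[fch["flag"] == "*"]
            concord = (
                fch.pivot(index="variable", columns="comparison", values="log2fc")
                .apply(lambda r: (r > 0).all() or (r < 0).all(), axis=1)
            )
            print(f"  fold-change matrix: {len(common)} common variables, "
                  f"{signif['variable'].nunique()} starred, "
                  f"{int(concord.sum())} change in the same direction in both comparisons")
        groups = sorted({g for cmp_ in cmps for g in (cmp_.test, cmp_.reference)})
        corr = correlation_heatmap(imputed, groups)
        corr.to_csv(str(out / f"corr_{scenario}"))
        n_star = (corr.p.to_numpy() < 0.05).sum()
        n_bh = int(corr.bh_significant.to_numpy().sum())
        print(f"  receptor correlation map {corr.rho.shape[0]}x{corr.rho.shape[1]}: "
              f"{n_star} raw-starred pairs, {n_bh} survive BH-FDR 5%")


if __name__ == "__main__":
    main()
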