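# dietsel

Consensus variable selection and integrative analysis for small-n,
multi-block dietary intervention studies.

## The problem

Feeding trials in rodents routinely measure dozens of heterogeneous
variables — metabolic and biochemical panels, intestinal morphometry,
inflammatory markers, and qPCR expression of intestinal taste receptors
(TAS1R/TAS2R families) across gut segments — on only 7–8 animals per arm.
The scientific question is which of those ~90 variables best *discriminate*
a treatment group (e.g. insect-protein supplementation, or LPS-induced
inflammation) from its reference group, when no single statistical method
can be trusted at that sample size.

`dietsel` implements the full analysis chain for a five-arm design
(Control, Tenebrio, Buffalo, LPS, Tenebrio+LPS):

1. **Relative expression** — comparative-Ct: ΔCt = Ct_target − Ct_ref,
   ΔΔCt = ΔCt − mean(ΔCt | control), RE = 2^−ΔΔCt. The control-group
   geometric mean of RE is exactly 1 per gene.
2. **Univariate screen** — Shapiro–Wilk normality per group (informational),
   two-sided Mann–Whitney U per variable per comparison (exact null
   distribution for tie-free n ≤ 8 per group), fold change FC = mean(A)/mean(B),
   flags `*` (p < 0.05) and `#` (0.05 ≤ p < 0.1).
3. **Preprocessing** — within-group median imputation, greedy Spearman
   redundancy pruning (|ρ| ≥ 0.95), z-scoring over all samples, and a PCA
   Mahalanobis outlier check (advisory).
4. **Consensus selection** — per two-group comparison, three importance
   scores per variable: |coefficient| of a CV-tuned binomial elastic net,
   PLS-DA VIP (VIP_j = √(p·Σ_a w²_ja·SSY_a / Σ_a SSY_a), so mean VIP² = 1),
   and random-forest mean decrease in Gini. Each score vector is min-max
   normalized to [0, 1]; the **total score** ∈ [0, 3] ranks the variables
   and the **Kneedle** algorithm cuts the sorted curve at its knee.
5. **Integration** — Venn overlap of the two selections per scenario,
   a fold-change matrix for the common variables (reference = Control in
   the healthy scenario, LPS under inflammation), and Spearman correlation
   maps of receptor expression against all other variables with raw
   0.05/0.01/0.001 stars plus a BH-FDR column.

Because studies of this design rarely deposit raw animal data, the package
ships a first-class synthetic-study generator (`dietsel.synthetic`) with
block-correlated noise, lognormal expression marginals and *planted*
standardized group effects, so the entire pipeline is testable against
known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
replica with 8 planted discriminators (4 insect-responsive at d = 2 SD up,
4 LPS-responsive at d = 2 SD down) and 2% missing cells:

```bash
python analysis/01_simulate.py
python analysis/02_expression.py
python analysis/03_univariate_screen.py
python analysis/04_select_variables.py
python analysis/05_integrate.py
```

prints, among other lines:

```
wrote 40 samples x 89 variables (60 missing cells) and a Ct table with 8 genes
control geometric-mean identity: max |geomean - 1| = 3.33e-16
Tas1r1 Tenebrio vs Control: means 1.93 / 1.02, FC = 1.88 (planted Ct shift implies 1.7x)
30/356 tests significant at p<0.05 (12 borderline '#')
planted discriminators flagged '*': 8/8 across comparisons
Tenebrio_vs_Control: knee at 11/89; recovered 4/4 planted discriminators
healthy: |Tenebrio_vs_Control|=11, |Buffalo_vs_Control|=9, common=4, union=16
  fold-change matrix: 4 common variables, 4 starred, 4 change in the same direction in both comparisons
```

Reading this: the ΔΔCt identity holds to machine precision; the univariate
screen flags all 8 planted effects while the overall significant fraction
(30/356 ≈ 8%) sits above the 5% null rate exactly because of those planted
effects; the consensus knee keeps 11 of 89 variables for Tenebrio vs
Control and recovers every planted insect discriminator; and the 4
variables common to both insect comparisons all change in the same
direction — the behaviour expected of a true diet effect.

The same pipeline runs from a YAML config via the CLI:

```bash
dietsel simulate --seed 1 --out study/
dietsel run --config config.yaml
dietsel validate --data study/samples.csv --annotations study/annotations.csv
dietsel report --bundle results/run --figures
```

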