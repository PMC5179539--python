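# beacongrn

Supervised gene regulatory network (GRN) inference for developmental
time-course expression data, built around the regulatory program of seed
maturation in *Arabidopsis thaliana* embryos (the LAFL regulators ABI3,
FUS3 and LEC1), and applicable to any system with a short ordered
expression series plus prior TF→target knowledge.

## What it does

Given a gene × timepoint expression matrix (FPKM-like), replicate-level raw
counts, and regulons of experimentally confirmed targets per transcription
factor, the package:

1. **Compares inference methods** — soft-margin SVMs (C = 1000) in two
   formulations against the unsupervised CLR baseline, by three-fold
   cross-validated ROC AUC:
   - *global*: one classifier over concatenated pair features
     x = (e(r₁)…e(r_k), e(t₁)…e(t_k));
   - *local*: one classifier per regulator over target-only log fold-change
     features x_j = log₂((e(t_{j+1})+ε)/(e(t_j)+ε)), with linear
     (xᵀx′ + c) or RBF (exp(−γ‖x−x′‖²), γ = 1/n_features) kernels;
   - *CLR*: mutual information M_ij of discretised profiles, z-scored
     against each gene's background (positive part), combined as
     w_ij = √(z_ij² + z_ji²).
2. **Finds differentially expressed (DE) genes** between consecutive
   timepoints with a voom-style log2-CPM + precision-weights normalisation
   and empirical-Bayes moderated t-statistics, Benjamini–Hochberg adjusted
   (gene is DE if adjusted p < 0.05 in any consecutive contrast).
3. **Predicts targets** per regulator over all DE genes (decision value
   f(x) = Σ y_i α_i k(x_i, x) + b > 0), excluding training positives.
4. **Post-processes**: Pearson-correlation filter (keep r ≥ 0.6 with the
   regulator), k-means clustering of target profiles (Lloyd iterations,
   seeded restarts, clusters ordered by peak time), Venn overlap counts,
   and a report of strongly anti-correlated targets (r ≤ −0.6).
5. **Classifies direct vs indirect targets** by scanning promoters
   (3000 bp upstream or up to the next gene) with MEME-format PWMs using
   log-odds scores and *exact* p-values (dynamic programming over a
   1/1000-resolution score grid), threshold p < 10⁻⁴; direct targets that
   are themselves TFs with known motifs are cascaded one level to explain
   indirect targets.

A seeded synthetic-data module generates every input the pipeline consumes
(7-timepoint profiles with a planted regulon, negative-binomial counts,
promoters with planted binding sites) so the whole chain is testable
without access to any private dataset.

## Worked example

```python
from beacongrn import SimulationConfig, simulate_expression, compare_methods

cfg = SimulationConfig(n_genes=120, regulon_size=30, seed=17)
expr, regulons, signs = simulate_expression(cfg)
report = compare_methods(expr, {"TF1": regulons.targets("TF1")},
                         de_genes=set(expr.gene_ids), seed=17)
print(report.groupby(["method", "kernel"])["mean_auc"].mean().round(3))
```

```
method  kernel
clr     -         0.861
global  linear    0.977
        rbf       1.000
local   linear    0.947
        rbf       0.957
```

Every row is a mean held-out AUC over three cross-validation folds (the
probability that a randomly chosen true target outranks a randomly chosen
non-target); the supervised models clearly beat the unsupervised CLR
baseline on this planted single-regulator fixture, and all are far above
the 0.5 chance floor.  With a single positively coupled regulator the
global and local formulations are both easy; the local models' advantage
appears when regulators differ in their mode of regulation (see
`tests/test_evaluation.py`).

The same steps are available as a CLI (`beacon-grn simulate / de / clr /
evaluate / predict / cluster / scan / run`); `beacon-grn run --config
pipeline.yaml` executes all five phases and writes `report.tsv`,
`edges.tsv`, `clusters.tsv`, `hits.tsv`, `network.tsv` and a JSON manifest.

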