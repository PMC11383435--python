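# kodep — knockout-depletion analysis of essential-protein overabundance

Most essential bacterial proteins are expressed far above the minimum level
required for growth. `kodep` implements the analysis pipeline for
*knockout-depletion* experiments, which measure this **overabundance**
directly: an essential gene is deleted (in a naturally competent bacterium
such as *Acinetobacter baylyi* ADP1), synthesis of its product stops, and
the pre-existing protein pool is diluted by continued growth until function
fails and the lineage arrests.

The central quantities:

- **Dilution law.** With no synthesis after knockout, the mean
  concentration over the progeny of a progenitor cell is
  `C(t) = C0 · V0 / V(t)`, where `V(t)` is the total progeny volume
  (segmented cell area is used as the volume proxy, with the areal growth
  rate `k(t) = d ln A/dt`).
- **Overabundance.** `o ≡ C0 / C_A`, the ratio of wild-type concentration
  to the concentration at growth arrest. Because growth is exponential at
  rate `k0` until arrest, a measured arrest time `T` converts as
  `o = exp(k0 · T)`.
- **Trajectory classification.** In a transposon knockout library (TFNseq)
  read out by sequencing timed culture fractions, each mutant's log
  relative abundance `y(t)` follows one of three models —
  *no-effect* (`y = c`), *sufficient* (`y = c − s·t`, an immediate growth
  deficit) or *overabundant* (`y = c` until `T`, then declining at `−k0`).
  Two successive F-tests (no-effect vs. the best alternative, then
  sufficiency vs. overabundance) assign the class, with
  Benjamini–Hochberg correction across the library.
- **RLTO model.** The Robustness-Load Trade-Off model predicts the optimal
  overabundance from the message number `µ_m` (transcripts per gene per
  cell cycle): expression noise is gamma-distributed with `CV² = 1/µ_m`,
  arrest below the functional threshold is (nearly) lethal, and expression
  carries a metabolic load `ε·o`. Maximizing
  `F(o) = (1 − ε·o)·(1 − P_arrest(o, µ_m))` yields `o*(µ_m)`: low-expression
  genes should be strongly overabundant, high-expression genes barely so.

The package is aimed at microbial systems biologists analysing
knockout-depletion imaging or Tn-seq-style depletion time courses, and at
modellers exploring expression-noise optimality. Because the raw
experimental data are not packaged, a first-class synthetic-data module
generates single-cell lineages, library count matrices and RNA-seq tables
with the statistical structure each stage assumes, so the entire pipeline
is testable end to end.

## Worked example

Simulate a 60-gene knockout library (40 neutral, 10 sufficient,
10 overabundant), classify every trajectory, and query the optimality
model:

```python
import numpy as np
import kodep as kd

cfg = kd.TfnseqSimConfig(
    n_genes_per_class={"no_effect": 40, "sufficient": 10, "overabundant": 10},
    depth=100_000, seed=42)
counts, truth = kd.simulate_tfnseq_library(cfg)

result = kd.classify_library(counts, k0=np.log(2))
print(result["class"].value_counts().to_string())

ov = result[result["class"] == "overabundant"].head(3)
print(ov[["gene_id", "arrest_time_h", "log10_o", "se_log10_o"]]
      .round(3).to_string(index=False))

pred = kd.optimal_overabundance(kd.RltoParams(mu_m=2.0))
print(f"RLTO at mu_m=2: o* = {pred.o_star:.1f} "
      f"(log10 = {pred.log10_o_star:.2f}), "
      f"P(arrest) = {pred.p_arrest_at_opt:.3f}")
```

Output:

```
class
no_effect       40
sufficient      10
overabundant    10
   gene_id  arrest_time_h  log10_o  se_log10_o
gene_00050          4.130    1.243       0.020
gene_00051          7.753    2.334       0.011
gene_00052          5.935    1.787       0.007
RLTO at mu_m=2: o* = 15.2 (log10 = 1.18), P(arrest) = 0.008
```

All 60 genes land in their true class. `gene_00050` stopped growing
4.13 h after knockout; at a wild-type rate of ln 2 per hour that arrest
time converts to a 10^1.24 ≈ 17-fold protein overabundance, with the
standard error propagated from the local curvature of the breakpoint fit.
The RLTO prediction says a gene transcribed twice per cell cycle should
hold a ~15-fold reserve, and that even at that optimum ~0.8% of cells
still fall below threshold.

The same steps are available from the shell:

```bash
kodep simulate tfnseq --out lib/ --seed 42
kodep tfnseq classify --counts lib/counts.tsv --k0 0.693 --out cls/
kodep rlto predict --mu-min 0.3 --mu-max 1000 --out rlto.tsv
kodep summarize --classes cls/classification.tsv --expression mu.tsv \
    --annotation annotation.tsv --rlto rlto.tsv --out summary/
```

`kodep lineage analyze` runs the single-cell branch (arrest time,
elongation/septation overabundance, fitness landscape) on a cell-tracking
CSV, and `kodep expression message-number` converts RNA-seq counts to
message numbers.

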