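# meltforms

Detection of **functional proteoform groups** from deep thermal proteome
profiling (TPP) data, with the downstream statistics needed to interpret
them: differential melting across cell lines, differential
proteoform–proteoform co-aggregation, and association of proteoform thermal
stability with drug sensitivity.

## The scientific problem

Bottom-up proteomics quantifies peptides, but one gene can produce several
distinct protein species — splice variants, proteolytic cleavage products,
PTM states, or interaction states. In a TPP experiment, aliquots of each
cell line are heated across a temperature gradient and the soluble fraction
of every peptide is quantified by multiplexed MS, giving a *melting curve*
per peptide and cell line. Peptides belonging to different proteoforms of
the same gene can melt differently, so clustering peptides by melting
behavior across many cell lines separates co-existing proteoforms without
relying on annotation.

`meltforms` is aimed at proteomics groups analyzing peptide-level TPP/
meltome screens over multiple samples or cell lines.

## The method

For a gene's peptides *i*, *j* with fold-change curves
*x<sub>i</sub><sup>nk</sup>* (cell line *n*, temperature *k*, normalized to
the lowest temperature), the detector builds a complete weighted graph with
edge weights

&nbsp;&nbsp;&nbsp;&nbsp;*S<sub>ij</sub>* = 1 / (1 + *d<sub>ij</sub>*),&nbsp;&nbsp;
*d<sub>ij</sub>* = √( Σ<sub>valid&nbsp;(n,k)</sub> (*x<sub>i</sub>* − *x<sub>j</sub>*)² · *v*/(*NK*) ),

where *v* counts grid positions quantified in both peptides. Communities
are found with the Leiden algorithm (modularity objective) and accepted as
proteoform groups when the gene has ≥ 10 peptides with ≥ 2 per covered cell
line and an ambiguity ratio < 0.5, the partition modularity satisfies
*Q* > 10⁻¹³, and each community holds ≥ 3 peptides — an operating point
calibrated on a simulated benchmark to keep the false discovery rate at or
below 10%. Accepted groups are summarized (raw-signal summation, per-
temperature normalization, fold changes) and fed to:

- **Differential melting (NPARC-style F-test):** per-cell-line sigmoids
  *f(T)* = (1−*p*)/(1+exp(*b* − *a*/*T*)) + *p* versus one shared sigmoid;
  *F* = (RSS⁽⁰⁾ − RSS⁽¹⁾)/RSS⁽⁰⁾ · *d₂*/*d₁*; hits above the 90th
  percentile of *F*.
- **Differential co-aggregation:** for annotated proteoform pairs,
  per-line curve distance RSS*ₙ*; robust order-statistic
  *F* = (RSS₍ₙ₋₁₎ − RSS₍₂₎)/RSS₍₂₎.
- **Drug association:** OLS of selective drug sensitivity scores (sDSS) on
  per-line melting AUC, Benjamini–Hochberg adjusted jointly.
- **Simulation benchmark:** ground-truth generator (1,000 negative /
  200 positive proteins, ΔTm ∈ {1,2,3,4} °C, stated noise levels) with
  FDR/ROC evaluation and modularity-threshold calibration.

## Worked example

`examples/01_detect_proteoforms.py` builds a synthetic gene whose eleven
peptides come from two proteoforms melting at 48 °C and 56 °C and runs the
detector:

```
modularity Q = 0.2082
GENE1_1: 6 peptides -> ['pepA0', 'pepA1', 'pepA2', 'pepA3', 'pepA4', 'pepA5']
GENE1_2: 5 peptides -> ['pepB0', 'pepB1', 'pepB2', 'pepB3', 'pepB4']
```

The clearly positive modularity and two accepted groups mean the gene shows
evidence for two co-existing proteoforms, with every peptide assigned to
the correct one. `examples/06_benchmark_fdr.py` runs a reduced benchmark:

```
TP 19, FP 0, FN 21  ->  FDR 0.000, sensitivity 0.47
sensitivity by deltaTm: {1.0: 0.0, 2.0: 0.0, 3.0: 0.9, 4.0: 1.0}
ROC AUC (ranking proteins by modularity Q): 0.740
```

No negative protein is falsely split (FDR ≤ 10%), and sensitivity rises
steeply with the melting-point separation of the two simulated proteoforms.
The other examples cover sigmoid fitting (`02`), the differential-melting
F-test (`03`), robust co-aggregation scoring (`04`) and the drug screen
(`05`). A thin CLI wraps the same library calls:

```bash
meltforms init                 # write the default config block
meltforms simulate --seed 1 --out sim/
meltforms detect --input sim/peptides.tsv --seed 1 --out out/
meltforms benchmark --seed 1 --out bench/
```

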