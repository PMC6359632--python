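# nsafde

Label-free spectral-counting differential expression for shotgun
proteomics, built around the normalized spectral abundance factor (NSAF)
and an abundance-tiered significance scheme.

## The problem

In sperm proteomics, whole (neat) semen is usually frozen before analysis,
so the extracted protein mixture contains not just spermatozoa but also
"round cells" — immature germ cells, epithelial cells, and leukocytes.  Do
those contaminating proteins distort the sperm proteome that LC-MS/MS
identifies?  The analysis this package implements answers that with three
instruments:

1. **Differential expression between conditions** (e.g. semen with high vs
   low round-cell content) by spectral counting: proteins are quantified by
   NSAF, and calls are made with p-value and fold-change cutoffs stratified
   by abundance.
2. **Technical-replicate QC**: the coefficient of variation (CV) of the
   protein totals across triplicate injections measures intra-assay
   variability.  If the fraction of proteins called differential does not
   exceed that CV, the difference between conditions is within what
   repeated measurement of the *same* sample produces — i.e. the
   contaminant proteins do not interfere.
3. **Control-proteome subtraction**: each called protein is looked up in a
   pure leukocyte proteome; a protein absent or underexpressed there cannot
   have been contributed by leukocytes.

Everything is general-purpose: any two groups of technical-replicate runs
with a protein-length table can be analyzed the same way.

## The model

For protein *i* with spectral count SC\_i and length L\_i in one run,

```
NSAF_i = (SC_i / L_i) / Σ_j (SC_j / L_j)
```

computed per run and averaged over each group's replicates.  A comparison
is then: NSAF ratio R = mean NSAF(comparison) / mean NSAF(reference), and a
two-sided pooled-variance t-test on the per-run NSAF values.  The cutoffs
depend on the protein's abundance tier — the higher tier of its two group
means governs:

| tier | mean SC | p ≤ | overexpressed R ≥ | underexpressed R ≤ |
|------|---------|-----|-------------------|--------------------|
| very low | 0 < SC < 8 | 0.001 | 2.5 | 0.4 |
| low | 8 ≤ SC < 20 | 0.01 | 2.5 | 0.4 |
| medium | 20 ≤ SC < 80 | 0.05 | 2.0 | 0.5 |
| high | SC ≥ 80 | 0.05 | 1.5 | 2/3 |

Proteins detected in only one group are "unique to" that group; see
`docs/methods.md` for the full rules, degenerate cases, and limitations.

## Worked example

The package bundles reference tables from a published sperm-proteome
comparison (`nsafde.datasets`).  Re-analyzing the neat-semen contrast —
group1 (round cells/leukocytes ≥ 1×10⁶/mL) vs group3 (round cells <
1×10⁶/mL), as a means-as-pseudo-replicates matrix plus 100 background
proteins:

```python
from nsafde import DifferentialExpression
from nsafde.datasets import fixture_matrix, neat_semen_comparison

matrix, ratios = fixture_matrix(neat_semen_comparison())
res = DifferentialExpression(matrix, "group1", "group3", nsaf_ratios=ratios).fit()
print(res.summary())
```

```
NSAF differential expression
============================================
reference group:        group1
comparison group:       group3
proteins in comparison: 126
differentially expressed: 26 (20.63%)
  overexpressed:        16
  underexpressed:       10
  unique to one group:  0
============================================
```

26 proteins are differential — 16 up and 10 down in the low-round-cell
group — and every background protein comes out not significant.  (The
20.63% is a property of this 126-protein fixture; against the ~2,200
proteins of the full experiment the same 26 DEPs are 1.18%, below the
2.01%/1.74% replicate CVs, hence "no interference".)  The per-protein
report mirrors the published layout:

```python
print(res.report().head(4).to_string(index=False))
```

```
accession    gene                 description  SC_ref Abun_ref  SC_cmp Abun_cmp NSAF_ratio  p_value Expression
   P15289    ARSA             Arylsulfatase A    34.0        M     1.7       VL       0.05      0.0         UE
   P00352 ALDH1A1     Retinal dehydrogenase 1    26.3        M     2.7       VL       0.09      0.0         UE
   Q6PEW0  PRSS54 Inactive serine protease 54    18.0        L     4.7       VL       0.22      0.0         UE
   Q76KD6  SPATC1                   Speriolin     8.3        L     2.3       VL       0.26      0.0         UE
```

The interference verdict and leukocyte-control annotation:

```python
from nsafde import annotate_with_control, interference_assessment
from nsafde.datasets import control_fixture_matrix

print(interference_assessment(1.18, {"group1": 2.01, "group3": 1.74}).value)
# within_technical_variability

control_matrix, control_ratios = control_fixture_matrix()
ann = annotate_with_control(res.dep_call_records(), control_matrix,
                            nsaf_ratios=control_ratios)
print(ann.n_shared_all_three)   # 11 of the 26 DEPs detected in the control at all
print(ann.status_counts())
# {'absent_in_control': 15, 'underexpressed_in_control': 9,
#  'not_significant': 1, 'overexpressed_in_control': 1}
```

15 of the 26 DEPs are entirely absent from the pure leukocyte culture and
9 more are underexpressed there — the called proteins are sperm proteins,
not leukocyte carry-over.

## Command line

```sh
nsafde run --counts counts.tsv --design design.tsv \
           --ref group1 --cmp group3 --out results/
nsafde simulate --seed 7 --out sim/          # synthetic dataset + truth
nsafde qc --counts counts.tsv --design design.tsv --out qc.tsv
nsafde report --dep-report results/dep_report.tsv
```

`run` writes `dep_report.tsv`, `qc_report.tsv`, `summary.json` (and
`control_report.tsv` when a control matrix is given); logs go to stderr.
A seeded simulator (`nsafde.simulate`) generates count matrices with
planted fold changes and scores recovery, so the whole pipeline is testable
without any mass-spectrometry data.

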