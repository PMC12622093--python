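# locuskit

Locus-resolution analyses for long-read cohort callsets: tandem-repeat
allele characterization and candidate-locus nomination, CYP2D6–CYP2D7
structural haplotyping with star-allele and metabolizer inference, and
the filtering/QC machinery around a multi-caller structural-variant (SV)
callset. It is written for researchers working with haplotype-resolved
assemblies and cohort SV tables who need the analysis layer *between*
variant calling and interpretation — the part that turns sequences and
call tables into clinically meaningful categories — with every stage
testable offline against seeded synthetic data with planted truth.

## What it computes

**Tandem repeats.** An allele sequence is decomposed into motif units;
the longest pure run, interruptions (e.g. AGG units inside an FMR1 CGG
tract) and the total unit count feed rule-based classification at the
established clinical boundaries — FMR1 premutation ≥ 55 units, HTT
intermediate 27–35 and reduced-penetrance ≥ 36, ATXN3 pathogenic > 55,
and FMR1 instability tiers on the uninterrupted 3′ CGG run (25–33
moderate, ≥ 34 high). Catalog-level variability per locus is summarized
by the MAD of allele length and the 50th/99th percentiles of the longest
pure run; loci whose excess statistic p99 − median reaches the minimum
excess of the known pathogenic loci are nominated as candidates.

**CYP2D6–CYP2D7.** Haplotypes are painted in 100 bp tiles labeled by
best-matching reference gene (CYP2D6 / CYP2D7 / spacer); run-length
segmentation of the labels calls the structural configuration —
canonical, duplication, full-gene deletion, or hybrid fusions like
`CYP2D6::7` — with breakpoints resolved to one tile. Non-CNV haplotypes
get star alleles by global alignment, requiring **all** defining variants
of a candidate definition; diplotypes sum CPIC activity values
(0 → PM, (0,1] → IM, (1,2.25] → NM, >2.25 → UM), and multi-caller calls
are reconciled by majority (minimum 2).

**SV filtering/QC.** `SVCallFilter` is a scikit-learn-style estimator
(XGBoost over allele depth, allele balance, variant length, caller
support) whose `fit` also selects lenient/strict thresholds as the most
specific score cuts meeting TPR targets 0.9 and 0.7. Alongside it:
truth-set labeling, Mendelian trio discordance, the four reference-panel
postfilter rules, the imputed-cohort QC rules (mean GP, exact HWE test,
AF fold-change, carrier concordance, minimum carriers).

## Worked example

```python
from locuskit.repeats import RepeatAllele, classify_allele, fmr1_instability_tier
from locuskit.synthetic import RepeatSpec, gen_repeat_allele

# an FMR1-style allele: 60 CGG units with AGG interruptions at 10 and 20
spec = RepeatSpec("FMR1", "CGG", 60, ((10, "AGG"), (20, "AGG")))
sequence, truth = gen_repeat_allele(spec)
allele = RepeatAllele.from_sequence("FMR1", "hap1", sequence, "CGG")
print(allele.total_units, allele.longest_pure_run,
      classify_allele("FMR1", allele), fmr1_instability_tier(allele))
```

prints

```
60 39 premutation high
```

— 60 units total (interruptions included in the count) puts the allele in
the premutation range; the 3′-terminal pure CGG run of 39 units (no AGG
after index 20) lands in the high-instability tier. The same pipeline on
an SV table:

```python
from locuskit.svfilter import train_filter, apply_filter
from locuskit.synthetic import SvSimSpec, gen_sv_feature_table

table = gen_sv_feature_table(SvSimSpec(n_calls=10_000, seed=4242))
model = train_filter(table, seed=4242)
print({t: round(a["tpr"], 3) for t, a in model.achieved_.items()})
print(len(apply_filter(table, model, "lenient")), len(apply_filter(table, model, "strict")))
```

```
{'lenient': 0.9, 'strict': 0.7}
5607 4215
```

— the lenient cut keeps 90% of true calls (5,607 records survive), the
strict cut 70% (4,215 records, always a subset of the lenient set).

A `locuskit` CLI wraps the same functions
(`locuskit simulate|repeats|cyp|star|sv ...`; see `--help`).

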