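# Methods

`locuskit` implements the locus-resolution analyses that sit downstream of
long-read variant calling in a population cohort: tandem-repeat allele
characterization and candidate-locus nomination, CYP2D6–CYP2D7 structural
haplotyping with star-allele and metabolizer inference, and the
classifier/QC machinery around a multi-caller SV callset. Cohort sequence
data of this kind is controlled-access, so every stage is paired with a
seeded synthetic generator that plants known truth; the test suite and the
acceptance script run entirely on those generators.

## Tandem-repeat characterization

A repeat allele (the repeat region only, flanks stripped) is windowed into
motif-length units in the register that maximizes exact motif matches;
remainders shorter than one motif are dropped and recorded. The choice of
register on non-multiple lengths is a declared convention — nothing in the
underlying biology fixes it — and ties resolve to the smallest offset.
From the unit list we compute:

- **total length** in units (FMR1 counts include AGG interruption units);
- **longest pure run**: the maximal contiguous run of exact motif copies;
- **interruptions**: every non-motif unit, flagged canonical when it is in
  the motif's canonical set (AGG for CGG tracts; CAA for CAG tracts, the
  CAACAG cassette being read unit-wise as CAA then CAG).

Classification uses the clinically established unit-count boundaries,
packaged as a `ClassificationRuleSet`: FMR1 premutation ≥ 55 (full
mutation > 200), HTT normal < 27 / intermediate 27–35 / reduced penetrance
≥ 36, ATXN3 pathogenic > 55. FMR1 instability tiers are read off the
uninterrupted 3′ CGG run (after the last AGG, or the whole tract):
25–33 moderate, ≥ 34 high. All boundaries are inclusive as stated.
HTT counting follows the clinical CAG-count convention: the supplied
repeat region must be the pure CAG tract (plus internal interruptions),
excluding the downstream CAA-CAG/CCG cassette, because that is the
convention the 27/36 thresholds assume.

Per-locus variability over n ≥ 2 alleles reports the median absolute
deviation of total length (total length, not pure-segment length, is the
default and is configurable — the alternative reading is defensible) and
the 50th/99th percentiles of the longest pure run using type-7 linear
interpolation between order statistics; the quantile convention is
recorded because no standard exists for it in this context. Candidate
unstable loci are nominated by an explicit rule replacing what is
otherwise a visual judgement: the excess statistic p99 − median must reach
the minimum excess among the known pathogenic loci present in the same
table. The threshold is therefore data-relative, reported with the
output, and undefined (an error) without known loci.

## CYP2D6–CYP2D7 structural haplotyping

Assembled haplotypes over the locus are divided into non-overlapping
100 bp tiles (overlapping 100-mers would multiply the work ~100-fold with
no labeling benefit; the stride is a parameter). Each tile is aligned to
the full-length CYP2D6, CYP2D7 and spacer references by infix
(semi-global) edit-distance alignment via edlib, scored
`tile_len − 2·distance`; the label is the argmax, a mapq-like confidence
is `min(60, 2·(best − second))`, and tiles are AMBIGUOUS below a margin of
5 or UNALIGNED below a score floor of 40. Edit-distance infix scoring was
chosen over an affine-gap local aligner because the divergence between
the paralogs in scope is substitutional, where the two scoring schemes
induce the same argmax, and the edit-distance kernel is orders of
magnitude faster; the test suite checks painted labels against an
independent exhaustive sliding-window match-count oracle.

Segmentation run-length encodes the labels. AMBIGUOUS runs never split a
gene copy — with ~94% inter-paralog identity, some 100 bp windows are
nearly identical between the genes and ambiguity inside a gene body is
unavoidable — instead each ambiguous run is divided between its flanking
labels, which also centers hybrid breakpoints within the ambiguous zone.
Remaining runs shorter than `min_run_tiles` (default 3, i.e. 300 bp,
suppressing paralog-homology flicker) are absorbed into their longer
neighbor in place, preserving tile indices. Spacer and long unaligned
runs separate gene copies; a copy with exactly one internal label switch
becomes a hybrid `X::Y` with the breakpoint at the first tile of the 3′
label (resolution is inherently one tile; recovery is tested to ±2
tiles). Hybrids count in their own tally, not toward either pure gene's
copy number, matching how hybrids are reported separately from
duplications and deletions. Configuration classes: canonical (one D6,
≥ 1 D7), duplication (≥ 2 D6), deletion (no D6, D7 present), hybrid (any
hybrid copy), other.

The synthetic generator builds a surrogate D6 at random, derives D7 by
i.i.d. per-base substitution at divergence 0.05 (the real CYP2D6/2D7
identity is ≈ 94%), and concatenates segments for seven structure
classes; hybrid segments switch source gene at a planted breakpoint
fraction. It emits clean sequences; real assemblies add consensus errors
that this generator does not model, so structure-recovery results here
bound the clean-sequence behavior only.

## Star alleles, diplotypes, consensus

Haplotypes are globally aligned to the gene reference (match +1,
mismatch −1, gap open −2, extend −1) and their variants derived from the
alignment, then normalized to parsimonious left-aligned form so indel
representation can never defeat a set comparison. A definition is a
candidate only when **all** of its defining variants are present; the
best candidate maximizes matched defining count, then alignment score,
then fewest extra variants. The precedence between variant matches and
alignment score is not externally fixed; defining-variant count first is
the declared order and is configurable in spirit (the keys are explicit
in the code). Exact ties are surfaced as ambiguous with every tied name,
never silently resolved. Suballeles (e.g. *4.013) are reported when they
win, but aggregate to the core star for activity scoring.

Novel variants are the set difference between haplotype and best
definition. Protein-level comparison projects supplied exon intervals
through the alignment (an external gene predictor is deliberately not in
scope; supplied intervals keep the operation hermetic), translates with
the standard code, and reports missense/nonsense per codon plus a single
frameshift flag when the CDS length change is not a multiple of 3.

Diplotype activity is the sum of the two allele activities from the
packaged CPIC-derived table (*1 and *2 = 1.0; *3/*4/*5/*6 = 0; *9, *17,
*29, *41 = 0.5; *10 = 0.25), binned 0 → PM, (0, 1] → IM, (1, 2.25] → NM,
> 2.25 → UM. Any unresolved haplotype (NO_CALL, ambiguous, star missing
from the table) makes the phenotype indeterminate with the reason
recorded. Multi-caller consensus takes the most frequent identical call
string when its count reaches `min_agree` (default 2) and is uniquely
maximal; otherwise INDETERMINATE.

The packaged gene reference and definition table are synthetic
surrogates generated with a fixed seed (real PharmVar definition data and
the T2T gene sequence are not redistributed); they preserve the
structural properties the algorithms depend on — a reference allele with
zero defining variants, SNV- and indel-defined alleles, and a suballele
that is a strict superset of its core allele.

## SV filtering and QC

**Labeling.** Candidates are labeled TP against a truth set when a
same-type record lies within 500 bp with size similarity ≥ 0.7 (the
defaults of the merging tool this replaces), assigned greedily
nearest-first with each truth record consumed once. Greedy assignment is
compared against optimal bipartite matching in the tests (≥ 99%
agreement on randomized sets).

**Scorer.** `SVCallFilter` is a scikit-learn estimator wrapping an
XGBoost classifier over allele depth, allele balance, variant length and
caller support (200 trees, depth 3, learning rate 0.1, single-threaded,
seeded — deterministic). `fit` also selects both tier thresholds on the
training labels: the threshold rule is *the largest score cut whose TPR
still meets the target* (the most specific operating point meeting it),
verified against an exhaustive sweep. Lenient targets TPR 0.9, strict
0.7; the strict threshold is clamped to be ≥ the lenient one so the
strict callset always nests inside the lenient one.

**Mendelian discordance** is the fraction of complete biallelic sites
where the child's genotype cannot be formed from one allele of each
parent; missing genotypes are excluded from numerator and denominator
(a flag counts them as discordant instead). The consistency predicate is
tested against enumeration of all 27 genotype triplets.

**Panel postfilters**, applied in order with a per-rule removal log:
(1) singletons (AC = 1); (2) SV/short-variant duplicates (the
short-variant copy is removed); (3) short variants with AF < 0.5% more
than 25 kbp from any SV; (4) positionally conflicting calls — overlapping
intervals carried on a common haplotype when a haplotype matrix is
supplied, identical positions otherwise; the lower-AF call is removed.

**Cohort (PheWAS) QC** retains a variant iff mean GP ≥ 0.7, exact-test
HWE p ≥ 1e-5, symmetric AF fold-change < 1.5 (infinite when exactly one
cohort has AF 0), carrier concordance ≥ 0.70, and ≥ 10 carriers —
passing boundaries inclusive exactly as the removal inequalities imply.
The exact biallelic HWE test enumerates all heterozygote counts
compatible with the observed allele counts (no mid-p correction); it is
written in-package because no installed library provides it, and is
tested against a rational-arithmetic enumeration oracle.

## Synthetic data: what it does and does not emulate

All generators are pure functions of their spec including the seed.
The SV feature simulator plants a label-conditional model (Gaussian
latent per feature shifted by the standardized effect size; lengths
log-normal; support 1 + Binomial(2, p) with label-shifted log-odds) —
the feature names are real, the generative model is a modeling choice,
as none is externally specified. Default conditions used by the
acceptance run: 10,000 calls, prevalence 0.6, standardized effects 1.5.
Trio errors substitute a uniformly random different genotype, the
simplest model whose detectable fraction is enumerable. Repeat cohorts
draw per-locus lengths log-normally around the template median
(dispersion 0 collapses to the median exactly). None of the generators
model sequencing error, mosaicism, or read-level artifacts; passing
tests demonstrate algorithmic correctness on clean planted inputs, not
robustness to real assembly noise.

## Problem sizes and numerical conventions

The packaged test and acceptance runs use: 210 synthetic CYP loci
(30 per structure class) for structure recovery; 10,000 simulated SV
calls for ROC targeting and null calibration (held-out split 50/50);
10,000 trio sites for the planted-error check; 1,000 random alleles for
the pure-run oracle. These sizes put Monte-Carlo error comfortably
inside the asserted tolerances while keeping the default suite fast.
Thresholds use inclusive boundaries as printed throughout; quantiles are
type-7; the tile tie margin, score floor and `min_run_tiles` defaults
are declared knobs rather than derived constants.

## Known limitations

Haplotig extraction, read alignment/assembly, primary variant calling,
merging-engine internals, phasing/imputation engines and association
testing are out of scope — inputs are taken at the sequence/table level.
Hybrid detection assumes at most one breakpoint per copy; copies with
multiple internal switches fall into the "other" class. Star-allele
calling addresses non-CNV haplotypes only; activity scoring of
CNV-bearing diplotypes is not attempted. The candidate-locus rule is a
declared operationalization of a visual segregation judgement and should
be treated as a screen, not a significance test.
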