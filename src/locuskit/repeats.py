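"""Tandem-repeat allele characterization and catalog-level variability.

Decomposes a repeat allele (repeat region only, flanks stripped) into
motif-sized units, measures the longest pure tract and interruptions,
classifies disease-relevant alleles (FMR1 CGG, HTT CAG, ATXN3 CAG), and
computes per-locus variability statistics used to nominate candidate
unstable loci.

Coordinates are 0-based throughout; run lengths and allele lengths are
measured in repeat units, not base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

DNA_ALPHABET = set("ACGT")

#: Canonical interruption units per repeat motif.  The FMR1 CGG tract is
#: canonically interrupted by AGG; the HTT CAG tract by CAA (the CAACAG
#: cassette read unit-wise is CAA then CAG, and CAG is the motif itself).
CANONICAL_INTERRUPTIONS: dict[str, frozenset[str]] = {
    "CGG": frozenset({"AGG"}),
    "CAG": frozenset({"CAA"}),
}


class Decomposition(NamedTuple):
    """Result of windowing a repeat sequence into motif-sized units."""

    units: list[str]
    register: int
    leading: str
    trailing: str


@dataclass(frozen=True)
class ClassificationRuleSet:
    """Repeat-count category boundaries, in repeat units.

    Defaults are the clinically established thresholds: FMR1 premutation
    at >=55 units (full mutation above 200); HTT normal <27, intermediate
    27-35, reduced penetrance >=36; ATXN3 pathogenic strictly above 55.
    FMR1 instability tiers are defined on the uninterrupted 3' CGG run:
    moderate 25-33 units, high >=34.
    """

    fmr1_premutation_min: int = 55
    fmr1_full_mutation_gt: int = 200
    htt_intermediate_min: int = 27
    htt_reduced_penetrance_min: int = 36
    atxn3_pathogenic_gt: int = 55
    fmr1_tier_moderate_min: int = 25
    fmr1_tier_high_min: int = 34

    def __post_init__(self) -> None:
        if not (
            self.fmr1_premutation_min <= self.fmr1_full_mutation_gt
            and self.htt_intermediate_min < self.htt_reduced_penetrance_min
            and self.fmr1_tier_moderate_min < self.fmr1_tier_high_min
        ):
            raise ValueError("category boundaries must be ordered and disjoint")


DEFAULT_RULES = ClassificationRuleSet()


@dataclass
class RepeatAllele:
    """One haplotype's repeat allele decomposed into motif units."""

    locus_id: str
    haplotype_id: str
    sequence: str
    motif: str
    units: list[str]
    total_units: int
    longest_pure_run: int
    interruptions: list[tuple[int, str]]

    @classmethod
    def from_sequence(
        cls, locus_id: str, haplotype_id: str, sequence: str, motif: str
    ) -> "RepeatAllele":
        units = decompose_units(sequence, motif)
        return cls(
            locus_id=locus_id,
            haplotype_id=haplotype_id,
            sequence=sequence,
            motif=motif,
            units=units,
            total_units=len(units),
            longest_pure_run=longest_pure_run(units, motif),
            interruptions=[(i, u) for i, u in enumerate(units) if u != motif],
        )


@dataclass
class LocusVariability:
    locus_id: str
    n_alleles: int
    length_mad: float
    median_pure: float
    p99_pure: float


def _check_motif(motif: str) -> None:
    if not (1 <= len(motif) <= 6) or set(motif) - DNA_ALPHABET:
        raise ValueError(f"motif must be 1-6 bases over ACGT, got {motif!r}")


def decompose(sequence: str, motif: str) -> Decomposition:
    """Window ``sequence`` into motif-length units, choosing the register
    (0..len(motif)-1) that maximizes exact motif matches.

    When the region length is not a multiple of the motif length, the
    leading/trailing remainders shorter than one motif are dropped and
    recorded.  Ties between registers resolve to the smallest offset.
    """
    _check_motif(motif)
    sequence = sequence.upper()
    m = len(motif)
    if len(sequence) < m:
        return Decomposition([], 0, "", sequence)
    best_register, best_matches = 0, -1
    for r in range(m):
        n_win = (len(sequence) - r) // m
        matches = sum(
            1 for k in range(n_win) if sequence[r + k * m : r + (k + 1) * m] == motif
        )
        if matches > best_matches:
            best_register, best_matches = r, matches
    r = best_register
    n_win = (len(sequence) - r) // m
    units = [sequence[r + k * m : r + (k + 1) * m] for k in range(n_win)]
    return Decomposition(units, r, sequence[:r], sequence[r + n_win * m :])


def decompose_units(sequence: str, motif: str) -> list[str]:
    """Ordered motif-length unit list for a repeat region (see :func:`decompose`)."""
    return decompose(sequence, motif).units


def longest_pure_run(units: Sequence[str], motif: str) -> int:
    """Length in units of the maximal contiguous run of exact motif copies."""
    best = cur = 0
    for u in units:
        cur = cur + 1 if u == motif else 0
        best = max(best, cur)
    return best


def detect_interruptions(
    units: Sequence[str], motif: str, canonical: frozenset[str] | None = None
) -> list[tuple[int, str, bool]]:
    """Report every non-motif unit as ``(unit_index, unit, canonical_flag)``.

    ``canonical`` defaults to the packaged per-motif set (AGG for CGG
    tracts, CAA for CAG tracts); unknown motifs default to the empty set,
    so every interruption is flagged non-canonical.
    """
    if canonical is None:
        canonical = CANONICAL_INTERRUPTIONS.get(motif, frozenset())
    return [(i, u, u in canonical) for i, u in enumerate(units) if u != motif]


def classify_allele(
    gene: str,
    allele: "RepeatAllele | int",
    rules: ClassificationRuleSet = DEFAULT_RULES,
) -> str:
    """Categorize a repeat allele by total unit count.

    FMR1 counts include AGG interruption units.  Returns exactly one
    category per (gene, count); boundaries are inclusive as packaged.
    """
    n = allele.total_units if isinstance(allele, RepeatAllele) else int(allele)
    gene = gene.upper()
    if gene == "FMR1":
        if n > rules.fmr1_full_mutation_gt:
            return "full_mutation"
        if n >= rules.fmr1_premutation_min:
            return "premutation"
        return "normal"
    if gene == "HTT":
        if n >= rules.htt_reduced_penetrance_min:
            return "reduced_penetrance"
        if n >= rules.htt_intermediate_min:
            return "intermediate"
        return "normal"
    if gene == "ATXN3":
        return "pathogenic" if n > rules.atxn3_pathogenic_gt else "normal"
    raise ValueError(f"no classification rules for gene {gene!r}")


def three_prime_pure_run(allele: RepeatAllele) -> int:
    """Uninterrupted motif run at the 3' end (after the last interruption,
    or the whole tract if the allele is pure)."""
    run = 0
    for u in reversed(allele.units):
        if u != allele.motif:
            break
        run += 1
    return run


def fmr1_instability_tier(
    allele: RepeatAllele, rules: ClassificationRuleSet = DEFAULT_RULES
) -> str:
    """Instability tier from the 3'-terminal pure CGG run.

    Loss of the 3' AGG interruption lengthens this run and predicts
    expansion instability: 25-33 units -> "moderate", >=34 -> "high",
    otherwise "none".
    """
    run = three_prime_pure_run(allele)
    if run >= rules.fmr1_tier_high_min:
        return "high"
    if run >= rules.fmr1_tier_moderate_min:
        return "moderate"
    return "none"


def locus_variability(alleles: Iterable[RepeatAllele]) -> LocusVariability:
    """Per-locus variability statistics over >=2 alleles.

    length_mad is the median absolute deviation of total unit counts;
    median_pure / p99_pure are the 50th / 99th percentiles of the longest
    pure run (linear interpolation between order statistics).
    """
    alleles = list(alleles)
    if len(alleles) < 2:
        raise ValueError("locus variability is undefined for fewer than 2 alleles")
    loci = {a.locus_id for a in alleles}
    if len(loci) != 1:
        raise ValueError(f"alleles span multiple loci: {sorted(loci)}")
    lengths = np.array([a.total_units for a in alleles], dtype=float)
    pure = np.array([a.longest_pure_run for a in alleles], dtype=float)
    return LocusVariability(
        locus_id=alleles[0].locus_id,
        n_alleles=len(alleles),
        length_mad=float(np.median(np.abs(lengths - np.median(lengths)))),
        median_pure=float(np.percentile(pure, 50)),
        p99_pure=float(np.percentile(pure, 99)),
    )


def variability_table(alleles: Iterable[RepeatAllele]) -> pd.DataFrame:
    """Locus-by-locus variability table over a cohort of alleles."""
    by_locus: dict[str, list[RepeatAllele]] = {}
    for a in alleles:
        by_locus.setdefault(a.locus_id, []).append(a)
    rows = []
    for locus_id in sorted(by_locus):
        v = locus_variability(by_locus[locus_id])
        rows.append(
            {
                "locus_id": v.locus_id,
                "n_alleles": v.n_alleles,
                "length_mad": v.length_mad,
                "median_pure": v.median_pure,
                "p99_pure": v.p99_pure,
            }
        )
    return pd.DataFrame(rows)


def flag_candidates(
    variability: pd.DataFrame,
    known_pathogenic_ids: set[str],
    motif_class: str | None = None,
    region_class: str | None = None,
) -> pd.DataFrame:
    """Nominate candidate unstable loci by the excess-length statistic.

    The excess statistic is p99_pure - median_pure.  A locus is a
    candidate iff it is not a known pathogenic locus and its excess is at
    least the minimum excess among the known pathogenic loci present in
    the table (the known loci segregate to the right tail; the threshold
    is the left edge of that tail).  Optional motif/region filters
    restrict the table to one catalog class before thresholding.
    """
    df = variability.copy()
    if motif_class is not None and "motif" in df.columns:
        df = df[df["motif"] == motif_class]
    if region_class is not None and "region" in df.columns:
        df = df[df["region"] == region_class]
    df = df.assign(excess=df["p99_pure"] - df["median_pure"])
    known = df[df["locus_id"].isin(known_pathogenic_ids)]
    if known.empty:
        raise ValueError("no known pathogenic loci present; threshold undefined")
    threshold = float(known["excess"].min())
    out = df[(~df["locus_id"].isin(known_pathogenic_ids)) & (df["excess"] >= threshold)]
    out = out.copy()
    out.attrs["excess_threshold"] = threshold
    return out.reset_index(drop=True)


def carrier_frequency(n_carriers: int, n_haplotypes: int) -> float:
    """Carrier allele frequency, as a fraction of haplotypes."""
    if n_haplotypes <= 0:
        raise ValueError("n_haplotypes must be positive")
    return n_carriers / n_haplotypes


def characterize_table(
    records: Iterable[tuple[str, str, str, str]],
    genes: dict[str, str] | None = None,
    rules: ClassificationRuleSet = DEFAULT_RULES,
) -> pd.DataFrame:
    """Per-allele characterization table.

    ``records`` yields (locus_id, haplotype_id, sequence, motif).  If
    ``genes`` maps a locus_id to a rule-set gene name, category (and the
    FMR1 tier) are filled in; otherwise left empty.
    """
    genes = genes or {}
    rows = []
    for locus_id, hap_id, seq, motif in records:
        a = RepeatAllele.from_sequence(locus_id, hap_id, seq, motif)
        gene = genes.get(locus_id, "")
        row = {
            "locus_id": a.locus_id,
            "haplotype_id": a.haplotype_id,
            "motif": a.motif,
            "total_units": a.total_units,
            "longest_pure_run": a.longest_pure_run,
            "n_interruptions": len(a.interruptions),
            "interruptions": ";".join(f"{i}:{u}" for i, u in a.interruptions),
            "category": classify_allele(gene, a, rules) if gene else "",
            "fmr1_tier": fmr1_instability_tier(a, rules) if gene == "FMR1" else "",
        }
        rows.append(row)
    return pd.DataFrame(rows)
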