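"""Star-allele assignment, diplotype/metabolizer phenotyping, consensus.

A star allele is a named haplotype of a pharmacogene defined by a set of
variants on the gene reference.  Haplotypes are assigned by global
alignment against the reference: the candidate set is the definitions
whose defining variants are ALL present in the haplotype, and the best
candidate maximizes (matched defining count, alignment score, fewest
extra variants).  Variants are normalized (parsimonious, left-aligned)
before any set comparison so indel representation cannot break the
all-variants requirement.

Diplotypes sum CPIC activity values and map to metabolizer phenotype
(PM/IM/NM/UM); multi-caller calls are reconciled by majority agreement
with a configurable minimum (default 2).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Seq import Seq

NO_CALL = "NO_CALL"
INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True, order=True)
class Variant:
    """Normalized variant on the gene reference (0-based position)."""

    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class AlleleDefinition:
    star_name: str
    defining_variants: tuple[Variant, ...]
    suballele: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        prev_end = -1
        for v in sorted(self.defining_variants):
            if v.pos < prev_end:
                raise ValueError(f"overlapping defining variants in {self.name}")
            prev_end = v.pos + len(v.ref)

    @property
    def name(self) -> str:
        return self.suballele or self.star_name


@dataclass
class HaplotypeCall:
    haplotype_id: str
    best_star: str
    suballele: str | None
    score: int
    matched_defining: int
    missing_defining: int
    novel_variants: list[Variant]
    ambiguous: bool = False
    tied: tuple[str, ...] = ()


@dataclass
class ActivityTable:
    """Star-allele activity values and metabolizer phenotype bins.

    Bins partition [0, inf): score 0 -> PM, (0, 1] -> IM, (1, 2.25] -> NM,
    > 2.25 -> UM (CPIC-derived defaults, shipped as a versioned TSV).
    """

    activities: dict[str, float]
    im_max: float = 1.0
    nm_max: float = 2.25
    version: str = "unversioned"

    @classmethod
    def default(cls) -> "ActivityTable":
        text = resources.files("locuskit.data").joinpath("activity_scores.tsv").read_text()
        activities, version = {}, "unversioned"
        for line in text.splitlines():
            if line.startswith("#"):
                if "version=" in line:
                    version = line.split("version=", 1)[1].strip()
                continue
            if not line.strip() or line.startswith("star"):
                continue
            star, value = line.split("\t")[:2]
            activities[star] = float(value)
        return cls(activities=activities, version=version)

    def phenotype(self, score: float) -> str:
        if score == 0:
            return "PM"
        if score <= self.im_max:
            return "IM"
        if score <= self.nm_max:
            return "NM"
        return "UM"


@dataclass
class Diplotype:
    call_a: HaplotypeCall
    call_b: HaplotypeCall
    activity_score: float | None
    phenotype: str
    reason: str = ""

    @property
    def name(self) -> str:
        stars = sorted([self.call_a.best_star, self.call_b.best_star])
        return f"{stars[0]}/{stars[1]}"


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def normalize_variant(pos: int, ref: str, alt: str, sequence: str) -> Variant:
    """Parsimonious, left-aligned representation against ``sequence``."""
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if (not ref or not alt) and pos > 0:
            base = sequence[pos - 1]
            ref, alt, pos = base + ref, base + alt, pos - 1
            continue
        break
    # left-shift indels through repeated context
    while (
        len(ref) != len(alt)
        and len(ref) >= 1
        and len(alt) >= 1
        and ref[-1] == alt[-1]
        and pos > 0
    ):
        base = sequence[pos - 1]
        ref, alt, pos = base + ref[:-1], base + alt[:-1], pos - 1
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return Variant(pos, ref, alt)


def derive_variants(haplotype: str, reference: str) -> tuple[list[Variant], int]:
    """Variants of ``haplotype`` vs ``reference`` from a global alignment.

    Returns (normalized variants, alignment score).  Raises if the
    alignment degenerates (score below -len(reference), i.e. effectively
    unalignable).
    """
    aligner = _aligner()
    score = aligner.score(reference, haplotype)
    if score < -len(reference):
        raise ValueError("haplotype is not alignable to the gene reference")
    alignment = next(iter(aligner.align(reference, haplotype)))
    ref_blocks, hap_blocks = alignment.aligned
    variants: list[Variant] = []
    prev_r_end = prev_h_end = 0
    for (r0, r1), (h0, h1) in zip(ref_blocks, hap_blocks):
        if r0 > prev_r_end or h0 > prev_h_end:
            # gap region: deletion of ref[prev_r_end:r0] and/or insertion
            # of hap[prev_h_end:h0]; represent as one anchored substitution
            a = max(prev_r_end - 1, 0)
            ref_seg = reference[a:r0]
            alt_seg = reference[a:prev_r_end] + haplotype[prev_h_end:h0]
            variants.append(normalize_variant(a, ref_seg, alt_seg, reference))
        for k in range(r1 - r0):
            if reference[r0 + k] != haplotype[h0 + k]:
                variants.append(
                    Variant(r0 + k, reference[r0 + k], haplotype[h0 + k])
                )
        prev_r_end, prev_h_end = r1, h1
    if prev_r_end < len(reference) or prev_h_end < len(haplotype):
        a = max(prev_r_end - 1, 0)
        ref_seg = reference[a:]
        alt_seg = reference[a:prev_r_end] + haplotype[prev_h_end:]
        if ref_seg != alt_seg:
            variants.append(normalize_variant(a, ref_seg, alt_seg, reference))
    return sorted(set(variants)), int(score)


def call_star_allele(
    haplotype: str,
    gene_reference: str,
    definitions: Sequence[AlleleDefinition],
    haplotype_id: str = "",
) -> HaplotypeCall:
    """Best-matching star allele, requiring all defining variants.

    Candidates are definitions whose defining variants are all present in
    the haplotype's normalized variant set; ranking is by matched
    defining count, then alignment score (identical across candidates for
    one haplotype, kept for the declared contract), then fewest extra
    variants.  Exact ties surface as ambiguous with every tied name
    reported.  With no candidate, a zero-variant (reference) definition
    is the fallback; absent that, NO_CALL.
    """
    if not definitions:
        raise ValueError("definitions must be non-empty")
    hap_variants, score = derive_variants(haplotype, gene_reference)
    hap_set = set(hap_variants)
    candidates = []
    for d in definitions:
        defining = set(d.defining_variants)
        if defining <= hap_set:
            extras = len(hap_set - defining)
            candidates.append((len(defining), -extras, d))
    if not candidates:
        return HaplotypeCall(
            haplotype_id=haplotype_id,
            best_star=NO_CALL,
            suballele=None,
            score=score,
            matched_defining=0,
            missing_defining=min(
                (len(set(d.defining_variants) - hap_set) for d in definitions),
                default=0,
            ),
            novel_variants=hap_variants,
        )
    best_key = max(candidates, key=lambda c: (c[0], c[1]))[:2]
    tied = [d for n, e, d in candidates if (n, e) == best_key]
    best = tied[0]
    return HaplotypeCall(
        haplotype_id=haplotype_id,
        best_star=best.star_name,
        suballele=best.suballele,
        score=score,
        matched_defining=len(best.defining_variants),
        missing_defining=0,
        novel_variants=find_novel_variants(hap_variants, best),
        ambiguous=len(tied) > 1,
        tied=tuple(d.name for d in tied) if len(tied) > 1 else (),
    )


def find_novel_variants(
    haplotype_variants: Iterable[Variant], definition: AlleleDefinition
) -> list[Variant]:
    """Haplotype variants not among the definition's defining variants."""
    return sorted(set(haplotype_variants) - set(definition.defining_variants))


def call_diplotype(
    call_a: HaplotypeCall, call_b: HaplotypeCall, activity: ActivityTable
) -> Diplotype:
    """CPIC diplotype: summed allele activities binned to phenotype.

    Symmetric in its two calls.  Ambiguous or NO_CALL haplotypes, or a
    star absent from the activity table, yield an indeterminate
    phenotype with the reason recorded.
    """
    for call in (call_a, call_b):
        if call.best_star == NO_CALL or call.ambiguous:
            return Diplotype(call_a, call_b, None, "indeterminate", "unresolved haplotype call")
        if call.best_star not in activity.activities:
            return Diplotype(
                call_a, call_b, None, "indeterminate",
                f"{call.best_star} absent from activity table",
            )
    score = activity.activities[call_a.best_star] + activity.activities[call_b.best_star]
    return Diplotype(call_a, call_b, score, activity.phenotype(score))


def consensus_call(inputs: Mapping[str, str], min_agree: int = 2) -> str:
    """Majority consensus over per-caller call strings.

    The most frequent identical string wins if its count reaches
    ``min_agree`` and is uniquely maximal; otherwise INDETERMINATE.
    """
    if len(inputs) < 2:
        raise ValueError("consensus requires calls from at least 2 callers")
    counts = Counter(inputs.values())
    (top, n), *rest = counts.most_common()
    if n < min_agree or (rest and rest[0][1] == n):
        return INDETERMINATE
    return top


@dataclass
class ProteinChange:
    kind: str  # missense | nonsense | frameshift | synonymous_boundary
    position: int  # 1-based codon
    ref_aa: str
    alt_aa: str

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


def translate_and_diff(
    haplotype: str,
    gene_reference: str,
    exon_intervals: Sequence[tuple[int, int]],
    strand: str = "+",
    reference_protein: str | None = None,
) -> list[ProteinChange]:
    """Project exons through the alignment, translate, and diff proteins.

    Exon intervals are 0-based half-open on the gene reference; the
    reference CDS must be a multiple of 3.  The haplotype CDS takes the
    aligned haplotype bases over each exon, including insertions strictly
    inside it.  A CDS length change not divisible by 3 is reported as a
    single frameshift at the first affected codon; premature stops are
    reported as nonsense.
    """
    for start, end in exon_intervals:
        if not (0 <= start < end <= len(gene_reference)):
            raise ValueError("exon interval outside the gene reference")
    aligner = _aligner()
    alignment = next(iter(aligner.align(gene_reference, haplotype)))
    ref_blocks, hap_blocks = alignment.aligned
    # map each reference position to its aligned haplotype base (or "")
    # and record insertions keyed by the reference position they precede
    aligned_base = [""] * len(gene_reference)
    insertions: dict[int, str] = {}
    prev_r = prev_h = 0
    for (r0, r1), (h0, h1) in zip(ref_blocks, hap_blocks):
        if h0 > prev_h:
            insertions[r0] = haplotype[prev_h:h0]
        for k in range(r1 - r0):
            aligned_base[r0 + k] = haplotype[h0 + k]
        prev_r, prev_h = r1, h1
    if prev_h < len(haplotype):
        insertions[len(gene_reference)] = haplotype[prev_h:]

    ref_cds_parts, hap_cds_parts = [], []
    for start, end in exon_intervals:
        ref_cds_parts.append(gene_reference[start:end])
        hap_exon = []
        for p in range(start, end):
            if p > start and p in insertions:
                hap_exon.append(insertions[p])
            hap_exon.append(aligned_base[p])
        hap_cds_parts.append("".join(hap_exon))
    ref_cds, hap_cds = "".join(ref_cds_parts), "".join(hap_cds_parts)
    if strand == "-":
        ref_cds = str(Seq(ref_cds).reverse_complement())
        hap_cds = str(Seq(hap_cds).reverse_complement())
    if len(ref_cds) % 3:
        raise ValueError("reference CDS length is not a multiple of 3")
    if not ref_cds.startswith("ATG"):
        import warnings

        warnings.warn("start codon absent; translating from interval start", stacklevel=2)
    ref_protein = reference_protein or str(Seq(ref_cds).translate())
    changes: list[ProteinChange] = []
    if len(hap_cds) % 3:
        shift_at = _first_difference(ref_cds, hap_cds) // 3 + 1
        changes.append(ProteinChange("frameshift", shift_at, "", "fs"))
        return changes
    hap_protein = str(Seq(hap_cds).translate())
    for i in range(min(len(ref_protein), len(hap_protein))):
        r, h = ref_protein[i], hap_protein[i]
        if r != h:
            kind = "nonsense" if h == "*" else "missense"
            changes.append(ProteinChange(kind, i + 1, r, h))
            if h == "*":
                break
    return changes


def _first_difference(a: str, b: str) -> int:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i
    return min(len(a), len(b))


def load_default_definitions() -> tuple[str, list[AlleleDefinition], list[tuple[int, int]]]:
    """Packaged synthetic CYP2D6 surrogate: (reference, definitions, exons).

    The reference sequence and the star-allele definition table are
    synthetic surrogates generated with a fixed seed (the real gene
    sequence and PharmVar definition data are not redistributed here);
    star names and activity values mirror the field's conventions.
    """
    data = json.loads(
        resources.files("locuskit.data")
        .joinpath("cyp2d6_synthetic_star_definitions.json")
        .read_text()
    )
    reference = data["reference"]
    definitions = [
        AlleleDefinition(
            star_name=d["star"],
            suballele=d.get("suballele"),
            defining_variants=tuple(
                Variant(v["pos"], v["ref"], v["alt"]) for v in d["variants"]
            ),
            source=data.get("source", "synthetic"),
        )
        for d in data["definitions"]
    ]
    exons = [tuple(iv) for iv in data["exons"]]
    return reference, definitions, exons
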