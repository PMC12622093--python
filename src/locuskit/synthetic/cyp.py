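"""Synthetic CYP2D6-CYP2D7 locus generator.

Builds surrogate paralog references (a random "D6" gene, a "D7" paralog
derived from it by i.i.d. per-base substitution at the chosen divergence,
and an unrelated spacer), then concatenates segments into haplotypes for
canonical, duplicated, deleted and hybrid configurations, carrying the
planted structure as ground truth.  Default divergence is 0.05,
mirroring the ~94% real CYP2D6/CYP2D7 identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..cyp import GeneCopy, GeneReferenceSet, StructuralConfiguration

_BASES = np.array(list("ACGT"))

SegmentSpec = str | tuple[str, str, float]  # "D6" | "D7" | "SPACER" | (g5, g3, fraction)


@dataclass(frozen=True)
class CypConfigSpec:
    """Planted locus structure: ordered segments, paralog divergence, seed."""

    structure: tuple[SegmentSpec, ...]
    divergence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.structure:
            raise ValueError("structure must be non-empty")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")
        for seg in self.structure:
            if isinstance(seg, tuple):
                g5, g3, frac = seg
                if g5 not in ("D6", "D7") or g3 not in ("D6", "D7") or g5 == g3:
                    raise ValueError(f"invalid hybrid descriptor {seg!r}")
                if not (0.0 < frac < 1.0):
                    raise ValueError("breakpoint fraction must be strictly inside (0, 1)")
            elif seg not in ("D6", "D7", "SPACER"):
                raise ValueError(f"unknown segment label {seg!r}")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. per-base substitution (always to a different base) at ``rate``."""
    arr = np.array(list(sequence))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def make_gene_references(
    seed: int = 0,
    gene_length: int = 1500,
    spacer_length: int = 600,
    divergence: float = 0.05,
) -> GeneReferenceSet:
    """Surrogate reference set: D7 is D6 mutated at ``divergence``."""
    rng = np.random.default_rng(seed)
    d6 = _random_seq(gene_length, rng)
    d7 = mutate(d6, divergence, rng) if divergence > 0 else d6 + "A"
    spacer = _random_seq(spacer_length, rng)
    return GeneReferenceSet({"D6": d6, "D7": d7, "SPACER": spacer})


def gen_cyp_locus(
    spec: CypConfigSpec, refs: GeneReferenceSet
) -> tuple[str, StructuralConfiguration]:
    """Concatenate segments per the planted structure.

    A hybrid (g5, g3, fraction) segment takes the 5' gene up to
    round(fraction * gene_length) and the positionally homologous 3' gene
    from there on.  Truth copies carry haplotype offsets and, for
    hybrids, the breakpoint tile at the default 100 bp tile size.
    """
    if spec.divergence == 0:
        warnings.warn("divergence 0: paralog painting will be ambiguous", stacklevel=2)
    parts: list[str] = []
    copies: list[GeneCopy] = []
    offset = 0
    for seg in spec.structure:
        if isinstance(seg, tuple):
            g5, g3, frac = seg
            bp = round(frac * len(refs[g5]))
            seq = refs[g5][:bp] + refs[g3][bp:]
            copies.append(
                GeneCopy(
                    f"{g5}::{g3}",
                    offset,
                    offset + len(seq),
                    breakpoint_tile=(offset + bp) // 100,
                )
            )
        else:
            seq = refs[seg]
            if seg != "SPACER":
                copies.append(GeneCopy(seg, offset, offset + len(seq)))
        parts.append(seq)
        offset += len(seq)
    copy_number = {
        "D6": sum(1 for c in copies if c.label == "D6"),
        "D7": sum(1 for c in copies if c.label == "D7"),
        "hybrid": sum(1 for c in copies if c.is_hybrid),
    }
    if copy_number["hybrid"] > 0:
        config_class = "hybrid"
    elif copy_number["D6"] == 0:
        config_class = "deletion" if copy_number["D7"] > 0 else "other"
    elif copy_number["D6"] >= 2:
        config_class = "duplication"
    elif copy_number["D7"] >= 1:
        config_class = "canonical"
    else:
        config_class = "other"
    truth = StructuralConfiguration(copies, copy_number, config_class)
    return "".join(parts), truth


#: The seven configuration classes surveyed by the structure-recovery
#: suite: canonical, duplication, full-gene deletion, and the four
#: observed hybrid arrangements.
STRUCTURE_CLASSES: dict[str, tuple[SegmentSpec, ...]] = {
    "canonical": ("D6", "SPACER", "D7"),
    "duplication": ("D6", "SPACER", "D6", "SPACER", "D7"),
    "deletion": ("SPACER", "D7"),
    "hybrid_d6_d76": ("D6", "SPACER", ("D7", "D6", 0.5)),
    "hybrid_d6_d76_d7": ("D6", "SPACER", ("D7", "D6", 0.5), "SPACER", "D7"),
    "hybrid_d67": (("D6", "D7", 0.5), "SPACER"),
    "hybrid_d76_d7": (("D7", "D6", 0.5), "SPACER", "D7"),
}


def gen_structure_survey(
    n_loci: int,
    seed: int = 0,
    divergence: float = 0.05,
    refs: GeneReferenceSet | None = None,
) -> list[tuple[str, StructuralConfiguration, str]]:
    """n_loci synthetic haplotypes cycling over all structure classes,
    with randomized hybrid breakpoint fractions.

    Returns (haplotype, truth, class_name) triples; deterministic by seed.
    """
    rng = np.random.default_rng(seed)
    if refs is None:
        refs = make_gene_references(seed=seed, divergence=divergence)
    names = list(STRUCTURE_CLASSES)
    out = []
    for i in range(n_loci):
        name = names[i % len(names)]
        structure: list[SegmentSpec] = []
        for seg in STRUCTURE_CLASSES[name]:
            if isinstance(seg, tuple):
                g5, g3, _ = seg
                structure.append((g5, g3, float(rng.uniform(0.25, 0.75))))
            else:
                structure.append(seg)
        spec = CypConfigSpec(
            structure=tuple(structure), divergence=divergence, seed=seed + i
        )
        hap, truth = gen_cyp_locus(spec, refs)
        out.append((hap, truth, name))
    return out
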