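"""Synthetic star-allele haplotypes: apply defining + extra variants to a
gene reference, right-to-left, recording the planted truth."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from ..star import AlleleDefinition, Variant


def apply_variants(reference: str, variants: Iterable[Variant]) -> str:
    """Apply non-overlapping variants to ``reference`` right-to-left by
    position, so earlier edits do not shift later coordinates."""
    ordered = sorted(variants, key=lambda v: v.pos, reverse=True)
    prev_start = len(reference) + 1
    seq = reference
    for v in ordered:
        if not (0 <= v.pos <= len(reference) - len(v.ref)):
            raise ValueError(f"variant {v} outside reference bounds")
        if v.pos + len(v.ref) > prev_start:
            raise ValueError(f"overlapping variants at {v.pos}")
        if reference[v.pos : v.pos + len(v.ref)] != v.ref:
            raise ValueError(f"variant {v} ref allele mismatches the reference")
        seq = seq[: v.pos] + v.alt + seq[v.pos + len(v.ref) :]
        prev_start = v.pos
    return seq


def gen_star_haplotype(
    definition: AlleleDefinition,
    extra_variants: Sequence[Variant] = (),
    reference: str = "",
    seed: int = 0,
) -> tuple[str, dict]:
    """Haplotype carrying a definition's variants plus planted extras.

    Returns (haplotype, truth) where truth records the definition name
    and the planted extra variants; seed is accepted for interface
    symmetry with the other generators (the construction itself is
    deterministic).
    """
    del seed  # deterministic construction
    variants = list(definition.defining_variants) + list(extra_variants)
    haplotype = apply_variants(reference, variants)
    return haplotype, {
        "star": definition.star_name,
        "suballele": definition.suballele,
        "extra_variants": sorted(extra_variants),
    }


def random_snv(
    reference: str,
    rng: np.random.Generator,
    exclude_positions: set[int] | None = None,
) -> Variant:
    """A random SNV at a position not in ``exclude_positions``."""
    exclude = exclude_positions or set()
    while True:
        pos = int(rng.integers(1, len(reference) - 1))
        if pos in exclude:
            continue
        ref = reference[pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return Variant(pos, ref, str(alt))
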