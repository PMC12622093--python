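"""Seeded generators for tandem-repeat alleles and cohorts.

These stand in for the controlled-access cohort: every generated allele
carries its ground truth (unit labels, longest pure run, interruption
positions) so downstream characterization can be scored exactly.
Generated sequences are clean consensus sequences; an optional
substitution-noise knob exists but defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..repeats import DNA_ALPHABET, RepeatAllele, longest_pure_run

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RepeatSpec:
    """Template for one repeat allele.

    interruption_schedule lists (0-based unit index, interruption motif)
    pairs with strictly increasing indices below n_units; the
    interruption motif must have the motif's length and differ from it.
    """

    locus_id: str
    motif: str
    n_units: int
    interruption_schedule: tuple[tuple[int, str], ...] = ()
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        if set(self.motif) - DNA_ALPHABET or not (1 <= len(self.motif) <= 6):
            raise ValueError(f"invalid motif {self.motif!r}")
        if self.n_units < 1:
            raise ValueError("n_units must be positive")
        prev = -1
        for idx, imotif in self.interruption_schedule:
            if not (prev < idx < self.n_units):
                raise ValueError("interruption indices must be strictly increasing and < n_units")
            if len(imotif) != len(self.motif) or set(imotif) - DNA_ALPHABET:
                raise ValueError("interruption motif must match motif length over ACGT")
            if imotif == self.motif:
                raise ValueError("interruption motif must differ from the repeat motif")
            prev = idx
        for flank in (self.flank5, self.flank3):
            if set(flank) - DNA_ALPHABET:
                raise ValueError("flanks must be over ACGT")


def make_flank(length: int, motif: str, rng: np.random.Generator) -> str:
    """Random flank sequence guaranteed not to contain the repeat motif."""
    while True:
        flank = "".join(rng.choice(_BASES, size=length))
        if motif not in flank:
            return flank


def gen_repeat_allele(
    spec: RepeatSpec, haplotype_id: str = "hap1"
) -> tuple[str, RepeatAllele]:
    """Build flank5 + repeat tract + flank3 and its truth annotation.

    Scheduled unit indices carry the interruption motif; all other units
    are exact motif copies.
    """
    units = [spec.motif] * spec.n_units
    for idx, imotif in spec.interruption_schedule:
        units[idx] = imotif
    tract = "".join(units)
    sequence = spec.flank5 + tract + spec.flank3
    truth = RepeatAllele(
        locus_id=spec.locus_id,
        haplotype_id=haplotype_id,
        sequence=tract,
        motif=spec.motif,
        units=units,
        total_units=len(units),
        longest_pure_run=longest_pure_run(units, spec.motif),
        interruptions=[(i, u) for i, u in enumerate(units) if u != spec.motif],
    )
    return sequence, truth


def gen_repeat_cohort(
    catalog: list[RepeatSpec],
    n_haplotypes: int,
    dispersion: float = 0.15,
    seed: int = 0,
    locus_dispersion: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort of repeat alleles across a catalog of locus templates.

    Per-locus allele lengths are drawn log-normally around the template's
    n_units (the locus median): n = round(n_units * exp(dispersion * z)),
    z ~ N(0,1), floored at 1 unit.  dispersion 0 puts every allele at the
    median.  ``locus_dispersion`` overrides the dispersion per locus (a
    large value plants a heavy right tail).  Interruption schedules are
    inherited from the template, keeping entries that fit the drawn
    length.  Deterministic for a fixed seed.
    """
    if not catalog:
        raise ValueError("catalog must not be empty")
    if n_haplotypes < 2:
        raise ValueError("n_haplotypes must be >= 2")
    locus_dispersion = locus_dispersion or {}
    rng = np.random.default_rng(seed)
    allele_rows, truth_rows = [], []
    for spec in catalog:
        disp = locus_dispersion.get(spec.locus_id, dispersion)
        z = rng.standard_normal(n_haplotypes)
        lengths = np.maximum(1, np.round(spec.n_units * np.exp(disp * z))).astype(int)
        for h, n in enumerate(lengths):
            schedule = tuple((i, m) for i, m in spec.interruption_schedule if i < n)
            draw = RepeatSpec(
                locus_id=spec.locus_id,
                motif=spec.motif,
                n_units=int(n),
                interruption_schedule=schedule,
                flank5=spec.flank5,
                flank3=spec.flank3,
            )
            hap_id = f"hap{h}"
            sequence, truth = gen_repeat_allele(draw, hap_id)
            allele_rows.append(
                {
                    "locus_id": spec.locus_id,
                    "haplotype_id": hap_id,
                    "motif": spec.motif,
                    "sequence": sequence,
                }
            )
            truth_rows.append(
                {
                    "locus_id": spec.locus_id,
                    "haplotype_id": hap_id,
                    "motif": spec.motif,
                    "total_units": truth.total_units,
                    "longest_pure_run": truth.longest_pure_run,
                    "n_interruptions": len(truth.interruptions),
                }
            )
    return pd.DataFrame(allele_rows), pd.DataFrame(truth_rows)
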