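"""Trio genotype simulator with a planted Mendelian error rate.

Parents are drawn at Hardy-Weinberg equilibrium from the site allele
frequency; the child receives one allele from each parent.  A planted
fraction of child genotypes is then replaced by a uniformly random
different genotype (the simplest planted-error model with an enumerable
detectability oracle: only substitutions inconsistent with the parents
are detectable downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENOTYPES = ["0/0", "0/1", "1/1"]


@dataclass(frozen=True)
class TrioSimSpec:
    n_sites: int
    allele_frequency: float = 0.3
    planted_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if not (0.0 < self.allele_frequency < 1.0):
            raise ValueError("allele_frequency must be strictly inside (0, 1)")
        if not (0.0 <= self.planted_error_rate < 1.0):
            raise ValueError("planted_error_rate must be in [0, 1)")


def _hwe_probs(q: float) -> np.ndarray:
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def gen_trio_genotypes(spec: TrioSimSpec) -> pd.DataFrame:
    """Per-site father/mother/child genotypes with a truth error flag."""
    rng = np.random.default_rng(spec.seed)
    probs = _hwe_probs(spec.allele_frequency)
    father = rng.choice(3, size=spec.n_sites, p=probs)
    mother = rng.choice(3, size=spec.n_sites, p=probs)

    # transmitted allele: genotype 0 -> allele 0, 2 -> allele 1, 1 -> coin flip
    def transmit(gt: np.ndarray) -> np.ndarray:
        allele = (gt == 2).astype(int)
        het = gt == 1
        allele[het] = rng.integers(0, 2, size=het.sum())
        return allele

    child = transmit(father) + transmit(mother)

    err = rng.random(spec.n_sites) < spec.planted_error_rate
    for i in np.flatnonzero(err):
        others = [g for g in range(3) if g != child[i]]
        child[i] = others[rng.integers(2)]

    return pd.DataFrame(
        {
            "father": [GENOTYPES[g] for g in father],
            "mother": [GENOTYPES[g] for g in mother],
            "child": [GENOTYPES[g] for g in child],
            "truth_error": err,
        }
    )
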