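"""Labeled SV feature-table simulator.

Emulates a per-participant candidate callset with a planted score-label
relationship over the four genotyping features the filter consumes:
allele depth, allele balance, variant length and multi-caller support.
Labels are drawn at the requested prevalence; each feature separates the
classes by its standardized effect size (label-conditional Gaussians for
depth/balance, log-normal for length, binomial support counts in
{1,2,3}).  Effect sizes of zero give a non-separable null table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURES = ["allele_depth", "allele_balance", "length", "caller_support"]


@dataclass(frozen=True)
class SvSimSpec:
    n_calls: int
    prevalence_true: float = 0.6
    effect_allele_depth: float = 1.5
    effect_allele_balance: float = 1.5
    effect_length: float = 1.5
    effect_caller_support: float = 1.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_calls < 1:
            raise ValueError("n_calls must be positive")
        if not (0.0 < self.prevalence_true < 1.0):
            raise ValueError("prevalence must be strictly inside (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def separable(self) -> bool:
        return any(
            e != 0
            for e in (
                self.effect_allele_depth,
                self.effect_allele_balance,
                self.effect_length,
                self.effect_caller_support,
            )
        )


def gen_sv_feature_table(spec: SvSimSpec) -> pd.DataFrame:
    """Labeled callset table with columns chrom, pos, end, svtype, svlen,
    the four features, and label ("TP"/"FP").  Deterministic by seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_calls
    y = (rng.random(n) < spec.prevalence_true).astype(int)
    sd = spec.noise_sd

    z_depth = rng.normal(spec.effect_allele_depth * y, sd)
    z_bal = rng.normal(spec.effect_allele_balance * y, sd)
    z_len = rng.normal(spec.effect_length * y, sd)
    allele_depth = np.maximum(0.0, 4.0 + 2.0 * z_depth)
    allele_balance = np.clip(0.5 + 0.15 * z_bal, 0.0, 1.0)
    length = np.maximum(50, np.round(np.exp(5.0 + 0.8 * z_len))).astype(int)

    # support in {1,2,3}: 1 + Binomial(2, p) with a label-shifted log-odds
    logit = -0.3 + spec.effect_caller_support * y
    p = 1.0 / (1.0 + np.exp(-logit))
    caller_support = 1 + rng.binomial(2, p)

    svtype = np.where(rng.random(n) < 0.5, "INS", "DEL")
    pos = np.sort(rng.integers(0, 50_000_000, size=n))
    end = np.where(svtype == "DEL", pos + length, pos)
    svlen = np.where(svtype == "DEL", -length, length)

    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "end": end,
            "svtype": svtype,
            "svlen": svlen,
            "allele_depth": allele_depth,
            "allele_balance": allele_balance,
            "length": length,
            "caller_support": caller_support,
            "label": np.where(y == 1, "TP", "FP"),
        }
    )
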