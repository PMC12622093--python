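"""Imputed-cohort QC table simulator with planted rule violations.

Generates per-variant imputation QC metrics (mean genotype posterior,
HWE p-value, panel/imputed allele frequencies, carrier concordance,
carrier count) that all pass by construction, then plants exact numbers
of violations per rule in disjoint rows, marked in truth columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

QC_RULES = ["gp", "hwe", "af_fold", "concordance", "min_carriers"]


def gen_cohort_qc_table(
    n_variants: int,
    planted_violations: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """QC metric table with exactly the planted violation counts.

    ``planted_violations`` maps rule name (gp, hwe, af_fold, concordance,
    min_carriers) to a count; rows are assigned disjointly, so the sum of
    counts must not exceed n_variants (a variant cannot be forced to both
    pass and fail).  Truth columns viol_<rule> and viol_any mark the
    plantings.
    """
    planted = dict(planted_violations or {})
    unknown = set(planted) - set(QC_RULES)
    if unknown:
        raise ValueError(f"unknown QC rules: {sorted(unknown)}")
    if any(v < 0 for v in planted.values()):
        raise ValueError("violation counts must be non-negative")
    if sum(planted.values()) > n_variants:
        raise ValueError("planted violations exceed n_variants (contradictory planting)")

    rng = np.random.default_rng(seed)
    af_panel = rng.uniform(0.05, 0.5, size=n_variants)
    df = pd.DataFrame(
        {
            "variant_id": [f"sv{i}" for i in range(n_variants)],
            "mean_gp": rng.uniform(0.75, 1.0, size=n_variants),
            "hwe_p": rng.uniform(1e-3, 1.0, size=n_variants),
            "af_panel": af_panel,
            "af_imputed": af_panel * rng.uniform(1 / 1.4, 1.4, size=n_variants),
            "carrier_concordance": rng.uniform(0.75, 1.0, size=n_variants),
            "n_carriers": rng.integers(10, 200, size=n_variants),
        }
    )
    for rule in QC_RULES:
        df[f"viol_{rule}"] = False

    rows = rng.permutation(n_variants)
    cursor = 0
    for rule in QC_RULES:
        count = planted.get(rule, 0)
        idx = rows[cursor : cursor + count]
        cursor += count
        if count == 0:
            continue
        if rule == "gp":
            df.loc[idx, "mean_gp"] = rng.uniform(0.3, 0.699, size=count)
        elif rule == "hwe":
            df.loc[idx, "hwe_p"] = rng.uniform(0, 0.99e-5, size=count)
        elif rule == "af_fold":
            df.loc[idx, "af_imputed"] = df.loc[idx, "af_panel"] * rng.uniform(
                1.5, 3.0, size=count
            )
        elif rule == "concordance":
            df.loc[idx, "carrier_concordance"] = rng.uniform(0.0, 0.699, size=count)
        elif rule == "min_carriers":
            df.loc[idx, "n_carriers"] = rng.integers(1, 10, size=count)
        df.loc[idx, f"viol_{rule}"] = True

    df["viol_any"] = df[[f"viol_{r}" for r in QC_RULES]].any(axis=1)
    return df
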