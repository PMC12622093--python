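"""SV callset filtering and quality control.

Covers the harmonization filter layer: truth-matched labeling of
candidate calls, a supervised probabilistic scorer over the four
genotyping features (allele depth, allele balance, variant length,
multi-caller support), ROC-targeted threshold selection for lenient
(TPR ~ 0.9) and stringent (TPR ~ 0.7) callsets, Mendelian trio
discordance, the reference-panel postfilters, and the imputed-cohort
(PheWAS) QC rules.

The scorer (:class:`SVCallFilter`) is a scikit-learn-style estimator
wrapping a gradient-boosted-tree classifier, deterministic for a fixed
random_state on a single thread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

FEATURES = ["allele_depth", "allele_balance", "length", "caller_support"]

GENOTYPES = ("0/0", "0/1", "1/1")
MISSING = "./."


@dataclass
class SVRecord:
    """One SV call with its genotyping features (positions 0-based)."""

    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int
    allele_depth: float = 0.0
    allele_balance: float = 0.0
    caller_support: int = 1
    genotype: str = MISSING
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.svtype == "DEL" and self.end <= self.pos:
            raise ValueError("DEL requires end > pos")
        if self.svtype == "INS" and self.end != self.pos:
            raise ValueError("INS requires end == pos")
        if self.caller_support < 1:
            raise ValueError("caller_support must be >= 1")

    @property
    def length(self) -> int:
        return abs(self.svlen)


def _check_sorted(df: pd.DataFrame, name: str) -> None:
    key = df[["chrom", "pos"]]
    if not key.equals(key.sort_values(["chrom", "pos"]).reset_index(drop=True)):
        raise ValueError(f"{name} must be sorted by (chrom, pos)")


def size_similarity(len_a: int, len_b: int) -> float:
    a, b = abs(len_a), abs(len_b)
    if a == 0 or b == 0:
        return 0.0
    return min(a, b) / max(a, b)


def label_calls(
    candidates: pd.DataFrame,
    truth: pd.DataFrame,
    max_dist: int = 500,
    min_size_sim: float = 0.7,
) -> pd.DataFrame:
    """Label candidates TP/FP against a truth set.

    A candidate may match a same-chromosome, same-type truth record
    within ``max_dist`` bp whose size similarity (min/max of absolute
    lengths) reaches ``min_size_sim``; matches are assigned greedily
    nearest-first and each truth record is consumed at most once.  Both
    tables must be sorted by (chrom, pos).
    """
    _check_sorted(candidates.reset_index(drop=True), "candidates")
    _check_sorted(truth.reset_index(drop=True), "truth")
    cand = candidates.reset_index(drop=True)
    tru = truth.reset_index(drop=True)
    pairs = []  # (distance, cand_idx, truth_idx)
    for (chrom, svtype), tgroup in tru.groupby(["chrom", "svtype"], sort=False):
        cgroup = cand[(cand["chrom"] == chrom) & (cand["svtype"] == svtype)]
        if cgroup.empty:
            continue
        tpos = tgroup["pos"].to_numpy()
        for ci, cpos, clen in zip(
            cgroup.index, cgroup["pos"].to_numpy(), cgroup["svlen"].to_numpy()
        ):
            near = np.flatnonzero(np.abs(tpos - cpos) <= max_dist)
            for j in near:
                ti = tgroup.index[j]
                if size_similarity(clen, tgroup["svlen"].iloc[j]) >= min_size_sim:
                    pairs.append((abs(int(tpos[j]) - int(cpos)), ci, ti))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    for _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
    out = cand.copy()
    out["label"] = ["TP" if i in used_c else "FP" for i in out.index]
    return out


class SVCallFilter(BaseEstimator, ClassifierMixin):
    """Probabilistic SV-call scorer with ROC-targeted tier thresholds.

    A gradient-boosted-tree classifier over the four genotyping
    features; ``fit`` trains the scorer and selects the lenient and
    strict thresholds as the most specific score cuts whose training
    TPR still meets each target.  Scores are probabilities of being a
    true call; deterministic given ``random_state``.

    Parameters follow the scikit-learn contract; fitted attributes carry
    a trailing underscore (``model_``, ``thresholds_``, ``achieved_``).
    """

    def __init__(
        self,
        n_estimators: int = 200,
        max_depth: int = 3,
        learning_rate: float = 0.1,
        target_tpr_lenient: float = 0.9,
        target_tpr_strict: float = 0.7,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.target_tpr_lenient = target_tpr_lenient
        self.target_tpr_strict = target_tpr_strict
        self.random_state = random_state

    @staticmethod
    def _matrix(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[FEATURES].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURES):
            raise ValueError(f"expected {len(FEATURES)} feature columns")
        return X

    def fit(self, X, y):
        y = np.asarray([1 if v in (1, "TP", True) else 0 for v in y])
        if len(set(y)) < 2:
            raise ValueError("both classes (TP and FP) must be present")
        Xm = self._matrix(X)
        if len(Xm) < 100:
            raise ValueError("need at least 100 labeled calls to train")
        self.model_ = XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
        )
        self.model_.fit(Xm, y)
        self.classes_ = np.array([0, 1])
        scores = self.model_.predict_proba(Xm)[:, 1]
        self.thresholds_ = {}
        self.achieved_ = {}
        for tier, target in (
            ("lenient", self.target_tpr_lenient),
            ("strict", self.target_tpr_strict),
        ):
            thr, tpr, fpr = select_threshold(scores, y, target)
            self.thresholds_[tier] = thr
            self.achieved_[tier] = {"tpr": tpr, "fpr": fpr}
        if self.thresholds_["strict"] < self.thresholds_["lenient"]:
            # monotone repair: a strict tier may never be more permissive
            self.thresholds_["strict"] = self.thresholds_["lenient"]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._matrix(X))

    def score_samples(self, X) -> np.ndarray:
        """Probability-like score of being a true call."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X, tier: str = "lenient") -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        return (self.score_samples(X) >= self.thresholds_[tier]).astype(int)


def train_filter(labeled: pd.DataFrame, seed: int = 0, **params) -> SVCallFilter:
    """Fit an :class:`SVCallFilter` on a labeled callset table."""
    model = SVCallFilter(random_state=seed, **params)
    return model.fit(labeled[FEATURES], labeled["label"])


def select_threshold(
    scores: Sequence[float], labels, target_tpr: float
) -> tuple[float, float, float]:
    """Largest score cut whose TPR still reaches ``target_tpr``.

    Keeping records with score >= threshold, the selected operating
    point is the most specific one meeting the target; returns
    (threshold, achieved_tpr, achieved_fpr) on the supplied labels.
    """
    if not (0.0 < target_tpr <= 1.0):
        raise ValueError("target TPR must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if v in (1, "TP", True) else 0 for v in labels])
    tp_scores = scores[y == 1]
    if tp_scores.size == 0:
        raise ValueError("labels contain no true positives")
    k = math.ceil(target_tpr * tp_scores.size)
    threshold = float(np.sort(tp_scores)[::-1][k - 1])
    kept = scores >= threshold
    tpr = float(kept[y == 1].mean())
    fpr = float(kept[y == 0].mean()) if (y == 0).any() else 0.0
    return threshold, tpr, fpr


def apply_filter(records: pd.DataFrame, model: SVCallFilter, tier: str) -> pd.DataFrame:
    """Keep records whose score reaches the tier threshold.

    The strict output is always a subset of the lenient output for the
    same model.
    """
    if tier not in model.thresholds_:
        raise ValueError(f"unknown tier {tier!r}")
    scores = model.score_samples(records)
    return records[scores >= model.thresholds_[tier]].copy()


# ---------------------------------------------------------------- Mendelian QC


def _alleles(gt: str) -> tuple[int, int]:
    a, b = gt.split("/")
    return int(a), int(b)


def mendelian_consistent(father: str, mother: str, child: str) -> bool:
    """Whether the child's genotype can be formed from one allele of each
    parent (biallelic, unphased)."""
    fa, mo, (c1, c2) = _alleles(father), _alleles(mother), _alleles(child)
    return (c1 in fa and c2 in mo) or (c2 in fa and c1 in mo)


def mendelian_discordance(
    trios: pd.DataFrame, count_missing_as_discordant: bool = False
) -> float:
    """Fraction of complete sites whose trio genotypes are inconsistent.

    Sites with any missing genotype ("./.") are excluded from both
    numerator and denominator unless ``count_missing_as_discordant``.
    """
    complete = ~trios[["father", "mother", "child"]].isin([MISSING]).any(axis=1)
    if count_missing_as_discordant:
        n_sites = len(trios)
        if n_sites == 0:
            raise ValueError("no sites supplied")
        inconsistent = (~complete).sum()
    else:
        n_sites = int(complete.sum())
        if n_sites == 0:
            raise ValueError("no complete sites; discordance undefined")
        inconsistent = 0
    sub = trios[complete]
    inconsistent += sum(
        not mendelian_consistent(f, m, c)
        for f, m, c in zip(sub["father"], sub["mother"], sub["child"])
    )
    return inconsistent / n_sites


# ------------------------------------------------------------ panel postfilter


def panel_postfilter(
    variants: pd.DataFrame,
    haplotypes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference-panel postfilters, applied in order.

    (1) singleton variants (allele count 1); (2) duplicate variants
    between the SV and short-variant callsets (same chrom/pos/ref/alt in
    both; the short-variant copy is removed); (3) short variants with
    AF < 0.5% lying more than 25 kbp from any SV; (4) positionally
    conflicting calls (overlapping reference intervals carried on a
    common haplotype — or at identical positions when no haplotype
    matrix is supplied; the lower-AF call is removed).

    ``variants`` needs columns variant_id, chrom, pos, end, ref, alt,
    is_sv, ac, af, position-sorted.  ``haplotypes`` is an optional 0/1
    matrix indexed by variant_id (columns = haplotypes).  Returns the
    filtered table and a removal log (variant_id, rule).
    """
    df = variants.reset_index(drop=True).copy()
    _check_sorted(df, "variants")
    removals: list[tuple[str, int]] = []

    def drop(ids: list[str], rule: int) -> None:
        nonlocal df
        removals.extend((vid, rule) for vid in ids)
        df = df[~df["variant_id"].isin(ids)]

    # rule 1: singletons
    drop(df.loc[df["ac"] == 1, "variant_id"].tolist(), 1)

    # rule 2: SV/short-variant duplicates -> remove the short-variant copy
    key = df[["chrom", "pos", "ref", "alt"]].astype(str).agg("|".join, axis=1)
    dup_keys = set(key[df["is_sv"]]) & set(key[~df["is_sv"]])
    drop(df.loc[key.isin(dup_keys) & ~df["is_sv"], "variant_id"].tolist(), 2)

    # rule 3: rare short variants far from every SV
    sv_pos = df.loc[df["is_sv"]].groupby("chrom")["pos"]
    sv_by_chrom = {c: np.sort(g.to_numpy()) for c, g in sv_pos}
    far_ids = []
    short = df[~df["is_sv"] & (df["af"] < 0.005)]
    for vid, chrom, pos in zip(short["variant_id"], short["chrom"], short["pos"]):
        positions = sv_by_chrom.get(chrom)
        if positions is None or positions.size == 0:
            far_ids.append(vid)
            continue
        i = np.searchsorted(positions, pos)
        dist = min(
            abs(pos - positions[i - 1]) if i > 0 else np.inf,
            abs(positions[i] - pos) if i < positions.size else np.inf,
        )
        if dist > 25_000:
            far_ids.append(vid)
    drop(far_ids, 3)

    # rule 4: positionally conflicting calls
    conflict_ids: set[str] = set()
    for chrom, group in df.groupby("chrom", sort=False):
        g = group.sort_values(["pos", "end"]).reset_index(drop=True)
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                if g.loc[j, "pos"] >= g.loc[i, "end"] and g.loc[j, "pos"] != g.loc[i, "pos"]:
                    break
                a, b = g.loc[i], g.loc[j]
                overlap = (b["pos"] < a["end"] and a["pos"] < b["end"]) or (
                    a["pos"] == b["pos"]
                )
                if not overlap:
                    continue
                if haplotypes is not None:
                    if (
                        a["variant_id"] in haplotypes.index
                        and b["variant_id"] in haplotypes.index
                        and not bool(
                            (
                                (haplotypes.loc[a["variant_id"]] == 1)
                                & (haplotypes.loc[b["variant_id"]] == 1)
                            ).any()
                        )
                    ):
                        continue
                elif a["pos"] != b["pos"]:
                    continue
                loser = a if a["af"] <= b["af"] else b
                conflict_ids.add(loser["variant_id"])
    drop(sorted(conflict_ids), 4)

    log = pd.DataFrame(removals, columns=["variant_id", "rule"])
    return df.reset_index(drop=True), log


# --------------------------------------------------------------- PheWAS cohort QC


@dataclass(frozen=True)
class PhewasThresholds:
    """Imputed-cohort QC cuts; passing boundaries are inclusive exactly as
    the removal inequalities imply (removed when GP < 0.7, HWE p < 1e-5,
    AF fold-change >= 1.5, concordance < 0.70, carriers < 10)."""

    min_mean_gp: float = 0.7
    min_hwe_p: float = 1e-5
    max_af_fold: float = 1.5
    min_concordance: float = 0.70
    min_carriers: int = 10


def af_fold_change(af_a: float, af_b: float) -> float:
    """Symmetric allele-frequency fold change; infinite when exactly one
    side is zero, 1.0 when both are zero."""
    if af_a == 0 and af_b == 0:
        return 1.0
    if af_a == 0 or af_b == 0:
        return math.inf
    return max(af_a / af_b, af_b / af_a)


def apply_phewas_qc(
    table: pd.DataFrame, thresholds: PhewasThresholds = PhewasThresholds()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain variants passing every cohort QC rule.

    Returns (retained table, per-rule removal counts).  A variant failing
    several rules is counted under each.
    """
    t = thresholds
    fold = np.array(
        [af_fold_change(a, b) for a, b in zip(table["af_panel"], table["af_imputed"])]
    )
    fails = {
        "gp": table["mean_gp"] < t.min_mean_gp,
        "hwe": table["hwe_p"] < t.min_hwe_p,
        "af_fold": pd.Series(fold >= t.max_af_fold, index=table.index),
        "concordance": table["carrier_concordance"] < t.min_concordance,
        "min_carriers": table["n_carriers"] < t.min_carriers,
    }
    counts = {rule: int(mask.sum()) for rule, mask in fails.items()}
    keep = ~pd.concat(fails, axis=1).any(axis=1)
    return table[keep].copy(), counts


# ------------------------------------------------------------------- exact HWE


def hwe_exact_p(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact biallelic Hardy-Weinberg test p-value.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the probabilities of configurations no more
    likely than the observed one (two-sided, no mid-p correction).
    """
    if min(n_het, n_hom_ref, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = n_het + 2 * min(n_hom_ref, n_hom_alt)

    def log_prob(het: int) -> float:
        hom_rare = (n_rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            gammaln(n + 1)
            - gammaln(het + 1)
            - gammaln(hom_rare + 1)
            - gammaln(hom_common + 1)
            + het * math.log(2)
            + gammaln(n_rare + 1)
            + gammaln(2 * n - n_rare + 1)
            - gammaln(2 * n + 1)
        )

    hets = [h for h in range(n_rare % 2, n_rare + 1, 2) if (n - h - (n_rare - h) // 2) >= 0]
    logps = {h: log_prob(h) for h in hets}
    obs = logps[n_het]
    total = sum(math.exp(lp) for lp in logps.values())
    p = sum(math.exp(lp) for lp in logps.values() if lp <= obs + 1e-12)
    return min(1.0, p / total)
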