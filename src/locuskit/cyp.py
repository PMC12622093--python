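"""CYP2D6-CYP2D7 structural haplotyping by tile painting.

An assembled haplotype over the CYP2D6-CYP2D7 region is divided into
non-overlapping 100 bp tiles; each tile is labeled by its best-matching
reference gene (CYP2D6, CYP2D7, or the CYP2D7 spacer), and the run-length
structure of the labels is segmented into gene copies to call the
structural configuration: canonical, duplication, full-gene deletion, or
hybrid fusion alleles (notation X::Y, 5' gene before the breakpoint).

Tile scoring uses infix (semi-global) edit-distance alignment of the tile
against each full-length reference, with score = tile_len - 2*distance
(one unit for a lost match plus one penalty per edit).  The mapq proxy is
min(60, 2 * (best - second best)); a tile whose margin falls below the
configured minimum is AMBIGUOUS, and one whose best score falls below the
floor is UNALIGNED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

AMBIGUOUS = "AMBIGUOUS"
UNALIGNED = "UNALIGNED"

_GENE_NAMES = {"D6": "CYP2D6", "D7": "CYP2D7"}


@dataclass
class GeneReferenceSet:
    """Labeled full-length reference sequences for D6, D7 and SPACER."""

    refs: dict[str, str]

    def __post_init__(self) -> None:
        for key in ("D6", "D7", "SPACER"):
            if key not in self.refs or not self.refs[key]:
                raise ValueError(f"reference set must contain a non-empty {key} sequence")
        if len({self.refs[k] for k in self.refs}) != len(self.refs):
            raise ValueError("reference sequences must be pairwise distinct")

    def __getitem__(self, key: str) -> str:
        return self.refs[key]

    def items(self):
        return self.refs.items()


@dataclass
class GeneCopy:
    """One gene copy in a segmented haplotype.

    label is "D6", "D7" or a hybrid "X::Y"; offsets are 0-based haplotype
    coordinates; breakpoint_tile is the first tile of the 3' gene for
    hybrids, else None.
    """

    label: str
    start: int
    end: int
    breakpoint_tile: int | None = None

    @property
    def is_hybrid(self) -> bool:
        return "::" in self.label


@dataclass
class StructuralConfiguration:
    copies: list[GeneCopy]
    copy_number: dict[str, int]
    configuration_class: str


def tile_haplotype(haplotype: str, tile_size: int = 100) -> tuple[list[str], int]:
    """Consecutive non-overlapping tiles; returns (tiles, remainder_bp).

    The final remainder shorter than one tile is dropped and its length
    reported.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be positive")
    if len(haplotype) < tile_size:
        raise ValueError("haplotype shorter than one tile")
    n = len(haplotype) // tile_size
    tiles = [haplotype[i * tile_size : (i + 1) * tile_size] for i in range(n)]
    return tiles, len(haplotype) - n * tile_size


def _tile_scores(tile: str, refs: GeneReferenceSet) -> dict[str, tuple[int, int]]:
    """(score, ref_start) of the best infix hit of ``tile`` in each reference."""
    out = {}
    for label, ref in refs.items():
        res = edlib.align(tile, ref, mode="HW", task="locations")
        dist = res["editDistance"]
        start = res["locations"][0][0] if res["locations"] else -1
        out[label] = (len(tile) - 2 * dist, start if start is not None else -1)
    return out


def paint_tiles(
    tiles: list[str],
    refs: GeneReferenceSet,
    min_score_margin: int = 5,
    min_score_floor: int = 40,
    tile_size: int | None = None,
) -> pd.DataFrame:
    """Label every tile by its best-matching reference.

    Returns a painting table (tile_index, haplotype_offset, label, score,
    mapq_proxy, ref_coordinate).  Deterministic given tiles, references
    and scoring parameters; swapping the D6/D7 reference labels swaps the
    painted labels exactly (ties always fall below the margin and become
    AMBIGUOUS, so no label-order tie-break exists).
    """
    if tile_size is None:
        tile_size = len(tiles[0]) if tiles else 100
    rows = []
    for i, tile in enumerate(tiles):
        scores = _tile_scores(tile, refs)
        ordered = sorted(scores.items(), key=lambda kv: -kv[1][0])
        (best_label, (best_score, best_start)) = ordered[0]
        second_score = ordered[1][1][0] if len(ordered) > 1 else -len(tile)
        margin = best_score - second_score
        if best_score < min_score_floor:
            label, mapq = UNALIGNED, 0
        elif margin < min_score_margin:
            label, mapq = AMBIGUOUS, 0
        else:
            label, mapq = best_label, min(60, 2 * margin)
        rows.append(
            {
                "tile_index": i,
                "haplotype_offset": i * tile_size,
                "label": label,
                "score": best_score,
                "mapq_proxy": mapq,
                "ref_coordinate": best_start,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["tile_size"] = tile_size
    return df


def _runs(labels: list[str]) -> list[tuple[str, int, int]]:
    """Run-length encoding as (label, start_tile, end_tile_exclusive)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            start = i
    return runs


def segment_structure(
    painting: pd.DataFrame, min_run_tiles: int = 3
) -> StructuralConfiguration:
    """Segment a tile painting into gene copies and classify the structure.

    Short AMBIGUOUS/UNALIGNED runs (< min_run_tiles) are absorbed into
    their surroundings, as are short gene-label runs (paralog-homology
    flicker).  SPACER runs separate gene copies.  A copy whose tiles
    switch gene label once mid-body (>= min_run_tiles on both sides)
    becomes a hybrid "X::Y" with the breakpoint at the first tile of the
    3' label.  Hybrids count toward their own tally, not toward either
    pure gene's copy number.
    """
    if painting.empty:
        raise ValueError("painting must be non-empty")
    tile_size = painting.attrs.get("tile_size", 100)
    labels = list(painting["label"])
    if all(lab in (AMBIGUOUS, UNALIGNED) for lab in labels):
        return StructuralConfiguration([], {"D6": 0, "D7": 0, "hybrid": 0}, "other")

    # AMBIGUOUS runs never separate gene copies (paralog homology makes
    # near-identical windows unavoidable): split each between its flanking
    # labels, which also centers a hybrid breakpoint in the ambiguous zone.
    for lab, s, e in _runs(labels):
        if lab != AMBIGUOUS:
            continue
        left = labels[s - 1] if s > 0 else None
        right = labels[e] if e < len(labels) else None
        if left is None and right is None:
            continue
        mid = (s + e + 1) // 2
        for i in range(s, e):
            if left is None:
                labels[i] = right
            elif right is None:
                labels[i] = left
            else:
                labels[i] = left if i < mid else right

    # Absorb sub-threshold runs into their longer neighbor, in place, so
    # tile indices (and hence breakpoint positions) are preserved.
    runs = [list(r) for r in _runs(labels)]
    while len(runs) > 1:
        short = [
            (e - s, i)
            for i, (lab, s, e) in enumerate(runs)
            if e - s < min_run_tiles
        ]
        if not short:
            break
        _, i = min(short)
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i + 1 < len(runs) else None
        if left is not None and (
            right is None or (left[2] - left[1]) >= (right[2] - right[1])
        ):
            runs[i][0] = left[0]
        else:
            runs[i][0] = right[0]
        merged: list[list] = []
        for run in runs:
            if merged and merged[-1][0] == run[0]:
                merged[-1][2] = run[2]
            else:
                merged.append(run)
        runs = merged

    gene_runs: list[list[tuple[str, int, int]]] = [[]]
    for lab, s, e in runs:
        if lab == "SPACER" or lab in (AMBIGUOUS, UNALIGNED):
            if gene_runs[-1]:
                gene_runs.append([])
        else:
            gene_runs[-1].append((lab, s, e))
    if not gene_runs[-1]:
        gene_runs.pop()

    copies: list[GeneCopy] = []
    complex_copy = False
    for group in gene_runs:
        if len(group) == 1:
            lab, s, e = group[0]
            copies.append(GeneCopy(lab, s * tile_size, e * tile_size))
        elif len(group) == 2 and group[0][0] != group[1][0]:
            (lab5, s5, _), (lab3, s3, e3) = group
            copies.append(
                GeneCopy(
                    f"{lab5}::{lab3}",
                    s5 * tile_size,
                    e3 * tile_size,
                    breakpoint_tile=s3,
                )
            )
        else:
            lab5 = group[0][0]
            lab3 = group[-1][0]
            copies.append(
                GeneCopy(f"{lab5}::{lab3}", group[0][1] * tile_size, group[-1][2] * tile_size)
            )
            complex_copy = True

    copy_number = {
        "D6": sum(1 for c in copies if c.label == "D6"),
        "D7": sum(1 for c in copies if c.label == "D7"),
        "hybrid": sum(1 for c in copies if c.is_hybrid),
    }
    config_class = _configuration_class(copy_number, complex_copy, bool(copies))
    return StructuralConfiguration(copies, copy_number, config_class)


def _configuration_class(
    copy_number: dict[str, int], complex_copy: bool, any_copies: bool
) -> str:
    if not any_copies or complex_copy:
        return "other"
    if copy_number["hybrid"] > 0:
        return "hybrid"
    if copy_number["D6"] == 0:
        return "deletion" if copy_number["D7"] > 0 else "other"
    if copy_number["D6"] >= 2:
        return "duplication"
    if copy_number["D7"] >= 1:
        return "canonical"
    return "other"


def classify_configuration(config: StructuralConfiguration) -> str:
    """Canonical label string in the field's notation.

    Gene copies joined by "-"; hybrids written X::Y with the 3' gene
    abbreviated to its digit (e.g. "CYP2D6::7", "CYP2D7::6").  An empty
    copy list yields "none".
    """
    parts = []
    for copy in config.copies:
        if copy.is_hybrid:
            g5, g3 = copy.label.split("::")
            parts.append(f"{_GENE_NAMES[g5]}::{g3[-1]}")
        else:
            parts.append(_GENE_NAMES[copy.label])
    return "-".join(parts) if parts else "none"
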