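"""Five-criterion genetic prioritization score and top-quantile selection.

Each target accumulates partial scores over all of its collected variants
(the hits plus their QTL proxies); per criterion the best qualifying value
is awarded:

1. Association strength: any hit with p < 5e-8 scores 5 outside the MHC,
   2 inside it; weaker hits score 0.
2. Effect size with LD support: a hit with OR > 1.2 scores by the LD of
   its best gene-level QTL proxy (>=0.99 -> 4; [0.95, 0.99) -> 3;
   [0.90, 0.95) -> 2; [0.80, 0.90) -> 1; below 0.80 -> 0).
3. eQTL availability: 10, plus 5 more if any eQTL acts in the brain.
4. Hit-to-eQTL LD: best LD between a hit and an eQTL evidence variant
   (>=0.99 -> 5; [0.95, 0.99) -> 3; [0.90, 0.95) -> 2; [0.80, 0.90) -> 1).
5. Non-expression QTL in near-perfect LD (>= 0.99) with a hit: 3.

The total is the plain sum (maximum attainable 32 = 5+4+15+5+3). Targets
in the top quantile of totals (default top 25%) are prioritized; ties with
the boundary score are kept, and the realized score threshold is reported.

Bin boundaries are half-open [lo, hi) with the top bin closed at >= 0.99.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_model import GwasHit, PathwaySet, in_mhc, pathway_union
from .target_mapper import GeneTarget

__all__ = ["TargetScore", "ScoreConfig", "overlap_targets", "score_target", "select_top", "Selection"]


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring constants. Defaults are the published criterion values."""

    gw_sig_p: float = 5e-8
    or_threshold: float = 1.2
    # (lower bound, points) pairs, highest bin first; lower bounds are
    # inclusive, the next bin's lower bound is the exclusive upper bound
    ld_bins_c2: tuple[tuple[float, int], ...] = ((0.99, 4), (0.95, 3), (0.90, 2), (0.80, 1))
    ld_bins_c4: tuple[tuple[float, int], ...] = ((0.99, 5), (0.95, 3), (0.90, 2), (0.80, 1))
    c5_ld_min: float = 0.99
    top_fraction: float = 0.25
    score_threshold: int = 20

    def __post_init__(self):
        for bins in (self.ld_bins_c2, self.ld_bins_c4):
            lows = [lo for lo, _ in bins]
            if lows != sorted(lows, reverse=True):
                raise ValueError("LD bins must be ordered highest lower-bound first")


def _ld_bin(ld: float, bins: tuple[tuple[float, int], ...]) -> int:
    for lo, points in bins:
        if ld >= lo:
            return points
    return 0


@dataclass(frozen=True)
class TargetScore:
    """Per-criterion partial scores and their total for one gene."""

    gene: str
    c1: int
    c2: int
    c3: int
    c4: int
    c5: int

    @property
    def total(self) -> int:
        return self.c1 + self.c2 + self.c3 + self.c4 + self.c5

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.c1, self.c2, self.c3, self.c4, self.c5)


def overlap_targets(
    targets: Iterable[GeneTarget], pathways: Iterable[PathwaySet]
) -> list[GeneTarget]:
    """Keep targets whose gene belongs to the union of pathway members."""
    members = pathway_union(pathways)
    return [t for t in targets if t.gene in members]


def score_target(target: GeneTarget, cfg: ScoreConfig = ScoreConfig()) -> TargetScore:
    """Score one gene target against the five genetic criteria.

    Per criterion the maximum applicable value over the target's collected
    variants is awarded, realizing "met by at least one variant" with the
    best qualifying evidence.
    """
    evs = target.evidences

    # criterion 1: association strength of the best hit
    c1 = 0
    for e in evs:
        if e.hit.p_value < cfg.gw_sig_p:
            c1 = max(c1, 2 if in_mhc(e.hit.variant) else 5)

    # criterion 2: high-OR hit, scored by LD of its best gene-level QTL proxy
    c2 = 0
    for e in evs:
        if e.is_qtl and e.hit.odds_ratio > cfg.or_threshold:
            c2 = max(c2, _ld_bin(e.ld_to_hit, cfg.ld_bins_c2))

    # criterion 3: eQTL availability, with the brain bonus
    has_eqtl = any(e.is_qtl and e.qtl_ref.qtl_type == "eQTL" for e in evs)
    has_brain_eqtl = any(
        e.is_qtl and e.qtl_ref.qtl_type == "eQTL" and e.qtl_ref.tissue == "brain"
        for e in evs
    )
    c3 = (10 + (5 if has_brain_eqtl else 0)) if has_eqtl else 0

    # criterion 4: LD between the hit and the eQTL variant
    c4 = 0
    for e in evs:
        if e.is_qtl and e.qtl_ref.qtl_type == "eQTL":
            c4 = max(c4, _ld_bin(e.ld_to_hit, cfg.ld_bins_c4))

    # criterion 5: non-expression QTL in near-perfect LD with the hit
    c5 = 0
    for e in evs:
        if e.is_qtl and e.qtl_ref.qtl_type != "eQTL" and e.ld_to_hit >= cfg.c5_ld_min:
            c5 = 3

    return TargetScore(gene=target.gene, c1=c1, c2=c2, c3=c3, c4=c4, c5=c5)


@dataclass
class Selection:
    """Prioritized scores plus the realized boundary."""

    selected: list[TargetScore]
    threshold: int  # minimum total among the selected
    n_quantile: int  # floor(top_fraction * N) before tie extension

    def genes(self) -> list[str]:
        return [s.gene for s in self.selected]


def select_top(scores: Sequence[TargetScore], cfg: ScoreConfig = ScoreConfig()) -> Selection:
    """Retain the top quantile of targets by total score.

    The top ``floor(top_fraction * N)`` scores are kept (at least one), then
    extended to include every target tied with the boundary score. The
    realized threshold (minimum selected total) is reported for
    comparability with a fixed score cut.
    """
    if not scores:
        raise ValueError("scores must be non-empty")
    ranked = sorted(scores, key=lambda s: (-s.total, s.gene))
    k = max(1, math.floor(cfg.top_fraction * len(ranked)))
    boundary = ranked[k - 1].total
    selected = [s for s in ranked if s.total >= boundary]
    return Selection(selected=selected, threshold=boundary, n_quantile=k)


def write_scores(path, scores: Sequence[TargetScore], selected_genes: Iterable[str]) -> None:
    from .core_model import _write_tsv

    chosen = set(selected_genes)
    rows = [
        {
            "gene": s.gene,
            "c1": s.c1,
            "c2": s.c2,
            "c3": s.c3,
            "c4": s.c4,
            "c5": s.c5,
            "total": s.total,
            "selected_flag": str(s.gene in chosen).lower(),
        }
        for s in sorted(scores, key=lambda s: (-s.total, s.gene))
    ]
    _write_tsv(path, rows, build=None, cols=["gene", "c1", "c2", "c3", "c4", "c5", "total", "selected_flag"])
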