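"""Direction-of-effect calls: from risk allele to required drug modulation.

The disease risk allele observed at a GWAS hit is carried over to the
QTL variant through the LD coupling (the allele of the QTL variant that
rides on the same haplotype). If the coupled allele is the QTL's effect
allele, the risk allele moves the molecular trait in the direction of the
QTL's effect sign; otherwise in the opposite direction.

A risk allele that *raises* the gene product (direction +1) calls for an
*inhibitor*; one that lowers it (-1) calls for an *activator*.

Directions are called per tissue. By default only expression- and
protein-level QTLs (eQTL, pQTL) are used — splicing, polyadenylation and
methylation QTLs describe transcript form rather than product abundance,
so their sign does not translate into an inhibit/activate instruction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .core_model import GwasHit, QtlRecord
from .ld_engine import LDPair
from .target_mapper import Evidence, GeneTarget

__all__ = ["DirectionCall", "couple_risk_allele", "call_directions"]

#: QTL types whose effect sign orients therapeutic modulation
DEFAULT_DIRECTION_QTL_TYPES = ("eQTL", "pQTL")

_MODULATION = {1: "inhibit", -1: "activate"}


class DegenerateLDError(ValueError):
    """The LD pair cannot orient alleles (phase-degenerate or undefined)."""


@dataclass(frozen=True)
class DirectionCall:
    """Resolved direction of the risk-allele effect on one gene in one tissue.

    ``direction`` is +1 when the risk allele raises the molecular trait
    (modulation = inhibit) and -1 when it lowers it (modulation =
    activate). ``conflict`` marks calls where equally-ranked evidence
    disagreed; such calls are excluded from drug matching.
    """

    gene: str
    tissue: str
    direction: int
    modulation: str
    supporting: Evidence
    coupled_allele: str
    conflict: bool = False

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.modulation != _MODULATION[self.direction]:
            raise ValueError("modulation must be inhibit for +1 and activate for -1")
        if not self.supporting.is_qtl:
            raise ValueError("supporting evidence must be QTL-kind")


def couple_risk_allele(hit: GwasHit, qtl: QtlRecord, ld: Optional[LDPair]) -> str:
    """Carry the hit's risk allele over to the QTL variant through LD phase.

    When hit and QTL share the variant the risk allele is returned
    unchanged; otherwise the LD pair's coupling map is applied. Degenerate
    or undefined LD raises :class:`DegenerateLDError` — no direction can be
    called from it.
    """
    if hit.variant.pos_key == qtl.variant.pos_key:
        return hit.risk_allele
    if ld is None or ld.coupled is None:
        raise DegenerateLDError(
            f"cannot couple {hit.variant.label} to {qtl.variant.label}: "
            "LD phase is degenerate or undefined"
        )
    pair = {ld.var_a.pos_key: ld.var_b.pos_key, ld.var_b.pos_key: ld.var_a.pos_key}
    if pair.get(hit.variant.pos_key) != qtl.variant.pos_key:
        raise ValueError("LD pair does not relate the hit and QTL variants")
    if ld.var_a.pos_key == hit.variant.pos_key:
        coupled = ld.coupled
    else:  # coupling is a bijection; invert for the other orientation
        coupled = {v: k for k, v in ld.coupled.items()}
    return coupled[hit.risk_allele]


def _direction_from(evidence: Evidence, ld_lookup) -> tuple[int, str]:
    """(direction, coupled allele) for one QTL evidence."""
    qtl = evidence.qtl_ref
    hit = evidence.hit
    if hit.variant.pos_key == qtl.variant.pos_key:
        coupled = hit.risk_allele
    else:
        ld = ld_lookup(hit.variant, qtl.variant) if ld_lookup else None
        coupled = couple_risk_allele(hit, qtl, ld)
    sign = qtl.effect_sign if coupled == qtl.effect_allele else -qtl.effect_sign
    return sign, coupled


def _rank(evidence: Evidence) -> tuple:
    """Evidence priority: highest LD, then eQTL first, then variant label."""
    qtl_type_rank = 0 if evidence.qtl_ref.qtl_type == "eQTL" else 1
    return (-evidence.ld_to_hit, qtl_type_rank, evidence.via_variant.label)


def call_directions(
    targets: Iterable[GeneTarget],
    ld_lookup=None,
    tissue_filter: str = "brain",
    qtl_types: Sequence[str] = DEFAULT_DIRECTION_QTL_TYPES,
) -> list[DirectionCall]:
    """Call one modulation direction per (gene, tissue).

    Parameters
    ----------
    targets
        Gene targets with their evidence trails.
    ld_lookup
        ``callable(var_a, var_b) -> LDPair`` used when a hit and its QTL
        evidence sit at different variants; ``None`` restricts calls to
        same-variant evidence (degenerate couplings are skipped either way).
    tissue_filter
        Only QTL evidence from this tissue is used (default ``"brain"``,
        the tissue that feeds drug selection).
    qtl_types
        QTL types whose sign orients modulation (default eQTL + pQTL).

    Notes
    -----
    Per gene, evidence is ranked by LD to the hit, then eQTL before other
    types, then variant label. The top-ranked evidence makes the call; if
    other evidence of equal rank disagrees on direction, the call is
    emitted with ``conflict=True`` and drug matching ignores it.
    """
    calls: list[DirectionCall] = []
    for target in targets:
        usable = [
            e
            for e in target.evidences
            if e.is_qtl
            and e.qtl_ref.tissue == tissue_filter
            and e.qtl_ref.qtl_type in qtl_types
        ]
        if not usable:
            continue
        resolved: list[tuple[tuple, int, str, Evidence]] = []
        for e in sorted(usable, key=_rank):
            try:
                sign, coupled = _direction_from(e, ld_lookup)
            except DegenerateLDError:
                continue
            resolved.append((_rank(e), sign, coupled, e))
        if not resolved:
            continue
        top_key = resolved[0][0][:2]  # (LD, type-priority) of the best evidence
        top_group = [r for r in resolved if r[0][:2] == top_key]
        directions = {r[1] for r in top_group}
        _, sign, coupled, evidence = resolved[0]
        calls.append(
            DirectionCall(
                gene=target.gene,
                tissue=tissue_filter,
                direction=sign,
                modulation=_MODULATION[sign],
                supporting=evidence,
                coupled_allele=coupled,
                conflict=len(directions) > 1,
            )
        )
    return calls


def write_directions(path, calls: Sequence[DirectionCall]) -> None:
    from .core_model import _write_tsv

    rows = [
        {
            "gene": c.gene,
            "tissue": c.tissue,
            "direction": c.direction,
            "modulation": c.modulation,
            "coupled_allele": c.coupled_allele,
            "conflict_flag": str(c.conflict).lower(),
        }
        for c in calls
    ]
    _write_tsv(
        path, rows, build=None,
        cols=["gene", "tissue", "direction", "modulation", "coupled_allele", "conflict_flag"],
    )
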