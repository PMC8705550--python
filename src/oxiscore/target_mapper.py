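"""Map GWAS hits to gene targets through QTLs and functional annotations.

A gene becomes a *target* when a hit variant — or one of its LD proxies —
either regulates the gene at a molecular level (any QTL type) or tags it
through a functionally relevant coding variant (missense or more severe,
CADD-Phred above threshold). Each supporting link is kept as an
:class:`Evidence` record carrying the hit, the mediating variant and its LD
to the hit, so downstream scoring and direction calling can weigh evidence
by LD strength.

MHC handling: genes on a configurable MHC gene list are excluded outright,
and genes whose evidence lies entirely inside the MHC interval
(chr6:27-33 Mb) are excluded as well; MHC-located variants remain usable
evidence for genes outside the region (the prioritizer down-weights them).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .core_model import (
    ConsequenceRecord,
    GwasHit,
    QtlRecord,
    Variant,
    in_mhc,
    is_missense_or_worse,
)

__all__ = ["Evidence", "GeneTarget", "MappingResult", "consequence_filter", "map_targets"]

#: CADD-Phred threshold above which a missense-or-worse variant is
#: considered functionally relevant (strict inequality)
DEFAULT_CADD_MIN = 15.0


@dataclass(frozen=True)
class Evidence:
    """One hit -> variant -> gene support link.

    ``kind`` is ``"qtl:<type>:<tissue>"`` for molecular-QTL evidence or
    ``"consequence"`` for a functional coding annotation. Exactly one of
    ``qtl_ref``/``consequence_ref`` is populated.
    """

    gene: str
    hit: GwasHit
    via_variant: Variant
    kind: str
    ld_to_hit: float
    qtl_ref: Optional[QtlRecord] = None
    consequence_ref: Optional[ConsequenceRecord] = None

    def __post_init__(self):
        if (self.qtl_ref is None) == (self.consequence_ref is None):
            raise ValueError("exactly one of qtl_ref/consequence_ref must be set")
        if not (0 < self.ld_to_hit <= 1):
            raise ValueError(f"ld_to_hit must be in (0, 1], got {self.ld_to_hit}")

    @property
    def is_qtl(self) -> bool:
        return self.qtl_ref is not None


@dataclass
class GeneTarget:
    """A gene plus the evidence trail connecting it to disease loci."""

    gene: str
    evidences: list[Evidence]
    is_mhc_gene: bool = False

    def __post_init__(self):
        if not self.evidences:
            raise ValueError(f"gene target {self.gene} has no evidence")
        if any(e.gene != self.gene for e in self.evidences):
            raise ValueError("all evidences must share the target's gene symbol")

    @property
    def best_ld(self) -> float:
        return max(e.ld_to_hit for e in self.evidences)

    @property
    def hits(self) -> list[GwasHit]:
        seen: dict = {}
        for e in self.evidences:
            seen.setdefault(id(e.hit), e.hit)
        return list(seen.values())


@dataclass
class MappingResult:
    """Targets plus bookkeeping on MHC exclusions."""

    targets: list[GeneTarget]
    n_excluded_mhc: int = 0
    excluded_genes: list[str] = None

    def __post_init__(self):
        if self.excluded_genes is None:
            self.excluded_genes = []

    def __iter__(self):
        return iter(self.targets)

    def __len__(self):
        return len(self.targets)


def consequence_filter(
    records: Iterable[ConsequenceRecord], cadd_min: float = DEFAULT_CADD_MIN
) -> list[ConsequenceRecord]:
    """Keep functionally relevant annotations only.

    Retained iff the consequence class is missense or more severe AND
    CADD-Phred strictly exceeds ``cadd_min``.
    """
    if cadd_min < 0:
        raise ValueError(f"cadd_min must be >= 0, got {cadd_min}")
    return [
        r
        for r in records
        if is_missense_or_worse(r.consequence_class) and r.cadd_phred > cadd_min
    ]


ProxyMap = Mapping[GwasHit, Sequence[tuple[Variant, float]]]


def map_targets(
    hits: Sequence[GwasHit],
    proxy_map: ProxyMap,
    qtls: Sequence[QtlRecord],
    consequences: Sequence[ConsequenceRecord] = (),
    mhc_gene_list: Iterable[str] = (),
) -> MappingResult:
    """Assemble gene targets from hits, proxies, QTLs and annotations.

    Parameters
    ----------
    hits
        GWAS index variants (already intake-filtered).
    proxy_map
        For each hit, its proxies as ``(variant, r2)`` pairs including the
        hit itself at r2 = 1 (the output of
        :func:`oxiscore.ld_engine.expand_proxies`).
    qtls
        Molecular-QTL catalogue; matched to proxies by variant position.
    consequences
        Functional annotations, typically pre-filtered with
        :func:`consequence_filter`.
    mhc_gene_list
        Gene symbols excluded as MHC genes regardless of evidence location.

    Returns
    -------
    MappingResult
        One :class:`GeneTarget` per unique gene with at least one evidence,
        sorted by gene symbol; MHC-excluded genes are counted and listed.
        A gene is excluded when its symbol is on ``mhc_gene_list`` or when
        every one of its evidence variants lies in the MHC interval.
    """
    missing = [h for h in hits if h not in proxy_map]
    if missing:
        raise ValueError(
            f"proxy_map must cover every hit; missing {missing[0].variant.label}"
        )
    mhc_genes = {g.upper() for g in mhc_gene_list}

    qtl_by_variant: dict[str, list[QtlRecord]] = defaultdict(list)
    for q in qtls:
        qtl_by_variant[q.variant.pos_key].append(q)
    csq_by_variant: dict[str, list[ConsequenceRecord]] = defaultdict(list)
    for c in consequences:
        csq_by_variant[c.variant.pos_key].append(c)

    by_gene: dict[str, list[Evidence]] = defaultdict(list)
    for hit in hits:
        for via, r2 in proxy_map[hit]:
            for q in qtl_by_variant.get(via.pos_key, ()):
                by_gene[q.gene].append(
                    Evidence(
                        gene=q.gene,
                        hit=hit,
                        via_variant=q.variant,
                        kind=f"qtl:{q.qtl_type}:{q.tissue}",
                        ld_to_hit=r2,
                        qtl_ref=q,
                    )
                )
            for c in csq_by_variant.get(via.pos_key, ()):
                by_gene[c.gene].append(
                    Evidence(
                        gene=c.gene,
                        hit=hit,
                        via_variant=c.variant,
                        kind="consequence",
                        ld_to_hit=r2,
                        consequence_ref=c,
                    )
                )

    targets: list[GeneTarget] = []
    excluded: list[str] = []
    for gene in sorted(by_gene):
        evs = by_gene[gene]
        listed_mhc = gene in mhc_genes
        all_in_mhc = all(in_mhc(e.via_variant) for e in evs)
        if listed_mhc or all_in_mhc:
            excluded.append(gene)
            continue
        targets.append(GeneTarget(gene=gene, evidences=evs, is_mhc_gene=False))
    return MappingResult(
        targets=targets, n_excluded_mhc=len(excluded), excluded_genes=excluded
    )


def write_targets(path, result: MappingResult) -> None:
    """Write the target table (gene, evidence summary) as TSV."""
    from .core_model import _write_tsv  # shared low-level writer

    rows = [
        {
            "gene": t.gene,
            "n_evidence": len(t.evidences),
            "best_ld": repr(t.best_ld),
            "evidence_kinds": ",".join(sorted({e.kind for e in t.evidences})),
            "mhc_flag": str(t.is_mhc_gene).lower(),
        }
        for t in result.targets
    ]
    _write_tsv(path, rows, build=None, cols=["gene", "n_evidence", "best_ld", "evidence_kinds", "mhc_flag"])
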