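"""Synthetic pipeline inputs with planted, machine-checkable ground truth.

The generator emits all seven pipeline inputs — GWAS hits, QTL catalogue,
consequence annotations, genotype panel, pathway GMT, drug table and ADME
table — from a declarative plan, together with a ground-truth record
(targets, directions, scores, selected genes, qualifying drugs) computed
by a straight-line restatement of the scoring and selection rules that is
deliberately independent of the pipeline modules it is used to test.

Panel construction
------------------
Variants are planted at allele frequency 0.5. A hit and its QTL proxy
form a two-locus haplotype block built to an exact haplotype-level r^2:
with n diploid samples (n even) the 2n haplotypes contain f discordant
copies (f even), giving r = 1 - f/n exactly. Diploids are formed either
by random haplotype pairing (``pairing="random"``, the generic panel
behaviour) or by *balanced* pairing that pairs identical haplotypes so no
double heterozygote exists at the planted pair (``pairing="balanced"``,
used inside bundles): without double heterozygotes the EM phase step has
nothing to resolve and the genotype-level r^2 equals the haplotype-pool
value exactly, which is what makes exact parameter recovery — including
LD-bin-sensitive score criteria — possible.

Realized (not requested) r^2 values are stored in the ground truth; the
score oracle bins those, so generator and pipeline always see the same
numbers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    AdmeProfile,
    DrugRecord,
    GenotypePanel,
    GwasHit,
    PathwaySet,
    QtlRecord,
    Variant,
    write_adme_profiles,
    write_consequences,
    write_drugs,
    write_gwas_hits,
    write_panel_tsv,
    write_pathways_gmt,
    write_qtls,
)

__all__ = [
    "PlantedQtl",
    "PlantedTarget",
    "PlannedDrug",
    "LDBlock",
    "GeneratorConfig",
    "GroundTruth",
    "simulate_panel",
    "generate_bundle",
    "build_reference_fixture",
]

BRAIN = "brain"


@dataclass(frozen=True)
class PlantedQtl:
    """One molecular-QTL association to plant for a gene.

    ``proxy_r2`` is the haplotype r^2 between the gene's GWAS hit and the
    QTL variant; 1.0 places the QTL on the hit variant itself. At most one
    QTL per gene may have ``proxy_r2 < 1`` (it gets its own exact two-locus
    block; additional QTLs share the hit variant).
    """

    qtl_type: str = "eQTL"
    tissue: str = BRAIN
    direction: int = 1  # planted effect of the RISK allele on the trait
    proxy_r2: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.proxy_r2 <= 1.0):
            raise ValueError(f"proxy_r2 must be in [0, 1], got {self.proxy_r2}")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass(frozen=True)
class PlantedTarget:
    """A gene with its planted association and molecular evidence."""

    gene: str
    p_value: float = 1e-9
    odds_ratio: float = 1.3
    qtls: tuple[PlantedQtl, ...] = (PlantedQtl(),)
    in_mhc: bool = False
    consequence: Optional[tuple[str, float]] = None  # (class, CADD-Phred)

    def __post_init__(self):
        if not (0 < self.p_value < 1e-5):
            raise ValueError(
                f"planted p-values must be below the intake gate 1e-5, got {self.p_value}"
            )
        sub = [q for q in self.qtls if q.proxy_r2 < 1.0]
        if len(sub) > 1:
            raise ValueError(
                f"{self.gene}: at most one planted QTL may have proxy_r2 < 1"
            )
        object.__setattr__(self, "gene", self.gene.upper())
        object.__setattr__(self, "qtls", tuple(self.qtls))


@dataclass(frozen=True)
class PlannedDrug:
    """A drug-table row plus the intended ADME outcome."""

    name: str
    gene: str
    mechanism: str  # inhibit | activate | other
    status: str
    interaction_score: float = 0.9
    direct_action: bool = True
    validated_transcriptional_modulator: bool = False
    adme_ok: bool = True
    source_db: str = "synthetic"


@dataclass(frozen=True)
class LDBlock:
    """A generic haplotype block: members' target r^2 to the lead variant."""

    size: int
    target_r2: tuple[float, ...]

    def __post_init__(self):
        if self.size < 2 or len(self.target_r2) != self.size - 1:
            raise ValueError("LDBlock needs size >= 2 and size-1 target r^2 values")
        if any(not (0.0 <= t <= 1.0) for t in self.target_r2):
            raise ValueError("target_r2 values must lie in [0, 1]")


@dataclass
class GeneratorConfig:
    """Declarative plan for one synthetic input bundle."""

    seed: int = 0
    n_samples: int = 400
    n_noise_loci: int = 5
    blocks: tuple[LDBlock, ...] = ()
    planted_targets: tuple[PlantedTarget, ...] = ()
    drug_plan: tuple[PlannedDrug, ...] = ()
    pathway_fraction: float = 1.0
    n_pathways: int = 22
    extra_pathway_genes: tuple[str, ...] = ()
    build: str = "GRCh37"

    def __post_init__(self):
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        if self.n_samples % 2:
            raise ValueError("n_samples must be even")
        if not (0.0 <= self.pathway_fraction <= 1.0):
            raise ValueError("pathway_fraction must be in [0, 1]")
        genes = [t.gene for t in self.planted_targets]
        if len(genes) != len(set(genes)):
            raise ValueError("planted target genes must be unique")


@dataclass
class GroundTruth:
    """What a correct pipeline must recover from a generated bundle."""

    seed: int
    true_targets: list[str] = field(default_factory=list)
    in_pathway: list[str] = field(default_factory=list)
    true_directions: dict = field(default_factory=dict)  # gene -> {direction, modulation}
    true_scores: dict = field(default_factory=dict)  # gene -> {c1..c5, total}
    selected_genes: list[str] = field(default_factory=list)
    score_threshold: int = 0
    true_candidates: dict = field(default_factory=dict)  # track -> [drug names]
    realized_r2: dict = field(default_factory=dict)  # gene -> [r2 per planted QTL]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# haplotype-block machinery
# ---------------------------------------------------------------------------


def _exact_flip_count(n: int, r2: float) -> int:
    """Even number of discordant haplotypes realizing r = 1 - f/n ~ sqrt(r2)."""
    f = 2 * round(n * (1.0 - math.sqrt(r2)) / 2.0)
    return int(min(max(f, 0), n - (n % 2)))


def _pair_block_genotypes(n: int, f: int, rng: np.random.Generator, balanced: bool) -> np.ndarray:
    """Genotypes (2 x n) for a two-locus block with exact haplotype r = 1 - f/n.

    Haplotype counts: (1,1) and (0,0) each n - f/2; (1,0) and (0,1) each
    f/2. Balanced pairing mates identical haplotypes (any leftovers are
    mated within the same first-locus allele), so the planted pair has no
    double heterozygotes; random pairing shuffles haplotypes freely.
    """
    half = f // 2
    haps = (
        [(1, 1)] * (n - half)
        + [(0, 0)] * (n - half)
        + [(1, 0)] * half
        + [(0, 1)] * half
    )
    haps = np.array(haps, dtype=np.int8)  # (2n, 2)
    if balanced:
        pairs = []
        for pattern in ((1, 1), (0, 0), (1, 0), (0, 1)):
            cnt = int(((haps == pattern).all(axis=1)).sum())
            pairs += [(pattern, pattern)] * (cnt // 2)
        leftovers = []
        for pattern in ((1, 1), (0, 0), (1, 0), (0, 1)):
            cnt = int(((haps == pattern).all(axis=1)).sum())
            if cnt % 2:
                leftovers.append(pattern)
        # leftovers come in {(1,1),(1,0)} x {(0,0),(0,1)} — mate within the
        # same first-locus allele so neither locus pair is double-het
        ones = [p for p in leftovers if p[0] == 1]
        zeros = [p for p in leftovers if p[0] == 0]
        for grp in (ones, zeros):
            while len(grp) >= 2:
                pairs.append((grp.pop(), grp.pop()))
        geno = np.array([[a[0] + b[0], a[1] + b[1]] for a, b in pairs], dtype=np.int8).T
    else:
        perm = rng.permutation(len(haps))
        h = haps[perm]
        geno = (h[0::2] + h[1::2]).T.astype(np.int8)
    # random sample order, so block membership carries no positional signal
    order = rng.permutation(n)
    return geno[:, order]


def _chain_block_genotypes(
    n: int, targets: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Genotypes (size x n) for a lead + members block, random pairing."""
    two_n = 2 * n
    lead = np.zeros(two_n, dtype=np.int8)
    lead[rng.permutation(two_n)[:n]] = 1
    cols = [lead]
    for t in targets:
        f = _exact_flip_count(n, t)
        member = lead.copy()
        ones = np.flatnonzero(lead == 1)
        zeros = np.flatnonzero(lead == 0)
        flip = np.concatenate(
            [rng.choice(ones, f // 2, replace=False), rng.choice(zeros, f // 2, replace=False)]
        ).astype(np.intp)
        member[flip] ^= 1
        cols.append(member)
    haps = np.stack(cols, axis=1)  # (2n, size)
    perm = rng.permutation(two_n)
    h = haps[perm]
    return (h[0::2] + h[1::2]).T.astype(np.int8)


class _Layout:
    """Doles out non-interfering genomic positions for planted blocks."""

    def __init__(self, spacing: int = 3_000_000):
        self.spacing = spacing
        self._next: dict[str, int] = {}
        self._mhc_cursor = 27_200_000
        self._autosomes = [str(c) for c in range(1, 23) if c != 6]
        self._round = 0

    def next_block(self, n_var: int, in_mhc: bool = False) -> list[tuple[str, int]]:
        if in_mhc:
            # hit inside the MHC, proxy just outside (still within the
            # 1 Mb search window) so the gene keeps non-MHC evidence
            base = self._mhc_cursor
            self._mhc_cursor += 50_000
            out = [("6", base)]
            for k in range(1, n_var):
                out.append(("6", 26_900_000 - 50_000 * (self._mhc_cursor // 50_000 % 50) - 10_000 * k))
            return out
        chrom = self._autosomes[self._round % len(self._autosomes)]
        self._round += 1
        base = self._next.get(chrom, 1_000_000)
        self._next[chrom] = base + self.spacing
        return [(chrom, base + 50_000 * k) for k in range(n_var)]


def simulate_panel(
    cfg: GeneratorConfig,
    seed: Optional[int] = None,
    pairing: str = "random",
    _layout: Optional[_Layout] = None,
) -> GenotypePanel:
    """Simulate a genotype reference panel from the config's LD blocks.

    Haplotypes are drawn from block-structured pools (allele frequency
    0.5) so that realized pairwise r^2 tracks each block's target —
    within about +-0.1 of the target at n_samples >= 500 under random
    pairing, and exactly for two-locus blocks under balanced pairing.
    Reproducible given the seed.
    """
    if pairing not in ("random", "balanced"):
        raise ValueError("pairing must be 'random' or 'balanced'")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    layout = _Layout() if _layout is None else _layout
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    serial = 0

    def add_variant(chrom: str, pos: int, geno: np.ndarray):
        nonlocal serial
        serial += 1
        variants.append(
            Variant(chrom=chrom, pos=pos, allele_a="A", allele_b="G", rsid=f"rs9{serial:05d}")
        )
        rows.append(geno)

    for block in cfg.blocks:
        coords = layout.next_block(block.size)
        if pairing == "balanced" and block.size == 2:
            f = _exact_flip_count(cfg.n_samples, block.target_r2[0])
            geno = _pair_block_genotypes(cfg.n_samples, f, rng, balanced=True)
        else:
            geno = _chain_block_genotypes(cfg.n_samples, block.target_r2, rng)
        for (chrom, pos), row in zip(coords, geno):
            add_variant(chrom, pos, row)

    for _ in range(cfg.n_noise_loci):
        (chrom, pos), = layout.next_block(1)
        geno = _chain_block_genotypes(cfg.n_samples, [], rng)[0]
        add_variant(chrom, pos, geno)

    samples = [f"S{j + 1:04d}" for j in range(cfg.n_samples)]
    genotypes = (
        np.stack(rows, axis=0) if rows else np.zeros((0, cfg.n_samples), dtype=np.int8)
    )
    return GenotypePanel(samples=samples, variants=variants, genotypes=genotypes)


# ---------------------------------------------------------------------------
# the independent scoring/selection oracle (straight-line restatement)
# ---------------------------------------------------------------------------


def _oracle_score(plant: PlantedTarget, realized: Sequence[float]) -> dict:
    """Score a planted gene directly from the plan and realized r^2 values.

    This restates the five criteria in open code, independent of the
    prioritizer implementation, so tests can compare the two routes.
    """
    c1 = 0
    if plant.p_value < 5e-8:
        c1 = 2 if plant.in_mhc else 5

    def bin4(ld):
        if ld >= 0.99:
            return 4
        if ld >= 0.95:
            return 3
        if ld >= 0.90:
            return 2
        if ld >= 0.80:
            return 1
        return 0

    def bin5(ld):
        if ld >= 0.99:
            return 5
        if ld >= 0.95:
            return 3
        if ld >= 0.90:
            return 2
        if ld >= 0.80:
            return 1
        return 0

    c2 = 0
    if plant.odds_ratio > 1.2:
        for q, ld in zip(plant.qtls, realized):
            c2 = max(c2, bin4(ld))
    has_eqtl = any(q.qtl_type == "eQTL" for q in plant.qtls)
    has_brain_eqtl = any(q.qtl_type == "eQTL" and q.tissue == BRAIN for q in plant.qtls)
    c3 = (15 if has_brain_eqtl else 10) if has_eqtl else 0
    c4 = 0
    c5 = 0
    for q, ld in zip(plant.qtls, realized):
        if q.qtl_type == "eQTL":
            c4 = max(c4, bin5(ld))
        elif ld >= 0.99:
            c5 = 3
    total = c1 + c2 + c3 + c4 + c5
    return {"c1": c1, "c2": c2, "c3": c3, "c4": c4, "c5": c5, "total": total}


def _oracle_direction(plant: PlantedTarget) -> Optional[dict]:
    """Planted brain direction: best expression/protein QTL in the brain."""
    usable = [
        (q, i)
        for i, q in enumerate(plant.qtls)
        if q.tissue == BRAIN and q.qtl_type in ("eQTL", "pQTL")
    ]
    if not usable:
        return None
    usable.sort(key=lambda t: (-t[0].proxy_r2, 0 if t[0].qtl_type == "eQTL" else 1))
    q = usable[0][0]
    return {
        "direction": q.direction,
        "modulation": "inhibit" if q.direction == 1 else "activate",
        "tissue": BRAIN,
    }


def _oracle_select(totals: dict[str, int], top_fraction: float = 0.25) -> tuple[list[str], int]:
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    k = max(1, math.floor(top_fraction * len(ranked)))
    boundary = ranked[k - 1][1]
    return [g for g, t in ranked if t >= boundary], boundary


def _oracle_candidates(
    plan: Sequence[PlannedDrug],
    selected: Sequence[str],
    directions: dict,
) -> dict[str, list[str]]:
    """Drug survivors per track, restated in open code."""
    chosen = set(selected)
    out = {"repurposable": [], "experimental": []}
    for d in plan:
        gene = d.gene.upper()
        if gene not in chosen:
            continue
        credible = (
            d.direct_action
            or d.interaction_score > 0.50
            or d.validated_transcriptional_modulator
        )
        if not credible:
            continue
        call = directions.get(gene)
        if call is not None and d.mechanism != call["modulation"]:
            continue
        if not d.adme_ok:
            continue
        track = "experimental" if d.status == "experimental" else "repurposable"
        out[track].append(d.name)
    return out


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------

_ADME_PASS = dict(
    cns_activity=1, log_bb=0.2, mdck_perm=600.0, caco2_perm=500.0,
    human_oral_absorption=3, pct_human_absorption=92.0,
)
_ADME_FAIL = dict(
    cns_activity=-2, log_bb=-3.0, mdck_perm=10.0, caco2_perm=10.0,
    human_oral_absorption=1, pct_human_absorption=40.0,
)


def generate_bundle(cfg: GeneratorConfig, out_dir) -> tuple[dict, GroundTruth]:
    """Write the seven input files plus ground truth; return paths and truth.

    The same seed always produces byte-identical files. Every table
    records the seed in a header comment.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    layout = _Layout()
    n = cfg.n_samples

    hits: list[GwasHit] = []
    qtls: list[QtlRecord] = []
    consequences = []
    variants: list[Variant] = []
    geno_rows: list[np.ndarray] = []
    truth = GroundTruth(seed=cfg.seed)
    serial = 0

    def new_variant(chrom: str, pos: int, geno: np.ndarray) -> Variant:
        nonlocal serial
        serial += 1
        v = Variant(chrom=chrom, pos=pos, allele_a="A", allele_b="G", rsid=f"rs{serial:06d}")
        variants.append(v)
        geno_rows.append(geno)
        return v

    for plant in cfg.planted_targets:
        sub = [(i, q) for i, q in enumerate(plant.qtls) if q.proxy_r2 < 1.0]
        n_var = 2 if sub else 1
        coords = layout.next_block(n_var, in_mhc=plant.in_mhc)
        if sub:
            f = _exact_flip_count(n, sub[0][1].proxy_r2)
            geno = _pair_block_genotypes(n, f, rng, balanced=True)
            realized_proxy = (1.0 - f / n) ** 2
        else:
            geno = _chain_block_genotypes(n, [], rng)
            realized_proxy = 1.0
        hit_var = new_variant(coords[0][0], coords[0][1], geno[0])
        proxy_var = (
            new_variant(coords[1][0], coords[1][1], geno[1]) if sub else hit_var
        )

        # random allele orientation; effect signs are then set so the
        # realized risk-allele direction equals the planted one
        risk = hit_var.allele_b if rng.random() < 0.5 else hit_var.allele_a
        hits.append(
            GwasHit(
                variant=hit_var,
                risk_allele=risk,
                p_value=plant.p_value,
                odds_ratio=plant.odds_ratio,
                study_id="SYNTH1",
            )
        )
        realized = []
        for i, q in enumerate(plant.qtls):
            qv = proxy_var if q.proxy_r2 < 1.0 else hit_var
            r2_i = realized_proxy if q.proxy_r2 < 1.0 else 1.0
            realized.append(r2_i)
            effect = qv.allele_b if rng.random() < 0.5 else qv.allele_a
            if qv is hit_var:
                coupled = risk
            else:
                # positive D couples allele_b with allele_b by construction
                coupled = (
                    qv.allele_b if risk == hit_var.allele_b else qv.allele_a
                )
            sign = q.direction if coupled == effect else -q.direction
            qtls.append(
                QtlRecord(
                    variant=qv,
                    effect_allele=effect,
                    gene=plant.gene,
                    qtl_type=q.qtl_type,
                    tissue=q.tissue,
                    effect_sign=sign,
                )
            )
        truth.realized_r2[plant.gene] = realized
        if plant.consequence is not None:
            from .core_model import ConsequenceRecord

            consequences.append(
                ConsequenceRecord(
                    variant=hit_var,
                    gene=plant.gene,
                    consequence_class=plant.consequence[0],
                    cadd_phred=plant.consequence[1],
                )
            )

    # generic blocks and noise loci ride along in the panel
    aux = simulate_panel(
        GeneratorConfig(
            seed=cfg.seed + 1,
            n_samples=n,
            n_noise_loci=cfg.n_noise_loci,
            blocks=cfg.blocks,
        ),
        _layout=layout,  # continue the same coordinate layout: no collisions
    )
    panel = GenotypePanel(
        samples=[f"S{j + 1:04d}" for j in range(n)],
        variants=variants + aux.variants,
        genotypes=(
            np.vstack([np.stack(geno_rows), aux.genotypes])
            if geno_rows
            else aux.genotypes
        ),
    )

    # ground truth: targets, pathways, scores, directions, selection, drugs
    genes = [p.gene for p in cfg.planted_targets]
    truth.true_targets = sorted(g for p, g in zip(cfg.planted_targets, genes)
                                if any(q.proxy_r2 > 0.7 for q in p.qtls) or p.consequence)
    n_in = math.ceil(cfg.pathway_fraction * len(genes)) if genes else 0
    in_pathway = genes[:n_in]
    truth.in_pathway = sorted(in_pathway)

    totals = {}
    for plant in cfg.planted_targets:
        if plant.gene not in in_pathway:
            continue
        score = _oracle_score(plant, truth.realized_r2[plant.gene])
        truth.true_scores[plant.gene] = score
        totals[plant.gene] = score["total"]
        direction = _oracle_direction(plant)
        if direction is not None:
            truth.true_directions[plant.gene] = direction
    if totals:
        truth.selected_genes, truth.score_threshold = _oracle_select(totals)
    truth.true_candidates = _oracle_candidates(
        cfg.drug_plan, truth.selected_genes, truth.true_directions
    )

    # pathway sets: planted members round-robin over n_pathways, plus extras
    members_pool = list(in_pathway) + list(cfg.extra_pathway_genes)
    pathway_sets = []
    if members_pool:
        k = max(1, min(cfg.n_pathways, len(members_pool)))
        buckets: list[list[str]] = [[] for _ in range(k)]
        for i, g in enumerate(members_pool):
            buckets[i % k].append(g)
        pathway_sets = [
            PathwaySet(name=f"OSPATH{i + 1:02d}", members=frozenset(b))
            for i, b in enumerate(buckets)
            if b
        ]

    drugs = [
        DrugRecord(
            name=d.name,
            target_gene=d.gene,
            mechanism=d.mechanism,
            status=d.status,
            interaction_score=d.interaction_score,
            direct_action=d.direct_action,
            validated_transcriptional_modulator=d.validated_transcriptional_modulator,
            source_db=d.source_db,
        )
        for d in cfg.drug_plan
    ]
    profiles = [
        AdmeProfile(compound=d.name, **(_ADME_PASS if d.adme_ok else _ADME_FAIL))
        for d in cfg.drug_plan
    ]

    paths = {
        "gwas": out / "gwas.tsv",
        "qtls": out / "qtls.tsv",
        "consequences": out / "consequences.tsv",
        "panel": out / "panel.tsv",
        "pathways": out / "pathways.gmt",
        "drugs": out / "drugs.tsv",
        "adme": out / "adme.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_gwas_hits(paths["gwas"], hits, build=cfg.build)
    write_qtls(paths["qtls"], qtls, build=cfg.build)
    write_consequences(paths["consequences"], consequences, build=cfg.build)
    write_panel_tsv(paths["panel"], panel, build=cfg.build, extra_meta={"seed": cfg.seed})
    write_pathways_gmt(paths["pathways"], pathway_sets)
    write_drugs(paths["drugs"], drugs)
    write_adme_profiles(paths["adme"], profiles)
    truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}, truth


# ---------------------------------------------------------------------------
# curated reference fixture
# ---------------------------------------------------------------------------

# the ten brain-direction genes: risk allele raises (+1) or lowers (-1)
# brain expression of the target
_DIRECTION_GENES = {
    "ASF1A": 1, "CAPN1": 1, "CARM1": 1, "CHAC1": 1, "NUP85": 1,
    "POM121C": 1, "TRMT112": 1,
    "BBC3": -1, "MAPK1": -1, "PSMB9": -1,
}

# brain-eQTL-directed genes that also rank in the top quantile
_TOP_DIRECTION_GENES = ("ASF1A", "BBC3", "CAPN1", "CARM1", "MAPK1", "NUP85", "TRMT112")

# further top-quantile targets without a brain direction
_TOP_OTHER_GENES = (
    "CDK4", "STAT3", "FOS", "NR1D1", "MAPK3", "HVCN1", "YWHAQ", "HDAC1", "NCF4",
    # synthetic placeholders standing in for unnamed top-quantile members
    "OSTOP01", "OSTOP02", "OSTOP03", "OSTOP04",
)

# brain-supported (non-expression) targets outside the top quantile;
# KEAP1 is brain-supported too but ranks in the top quantile via an
# additional non-brain eQTL
_BRAIN_OTHER_GENES = (
    "ATP6V1G2", "BCL2L11", "CRTC3", "CSNK2B", "DNM2", "FOXO3", "HSPA1L",
)

_N_FIXTURE_GENES = 85
_N_DECOYS = _N_FIXTURE_GENES - (
    len(_DIRECTION_GENES) + len(_TOP_OTHER_GENES) + len(_BRAIN_OTHER_GENES) + 1  # KEAP1
)


def _fixture_config(seed: int = 0) -> GeneratorConfig:
    plants: list[PlantedTarget] = []
    strong = dict(p_value=1e-9, odds_ratio=1.3)
    weak = dict(p_value=1e-6, odds_ratio=1.1)

    for gene in _TOP_DIRECTION_GENES:
        plants.append(
            PlantedTarget(
                gene=gene,
                **strong,
                qtls=(PlantedQtl("eQTL", BRAIN, _DIRECTION_GENES[gene], 1.0),),
            )
        )
    for gene in ("CHAC1", "POM121C", "PSMB9"):
        plants.append(
            PlantedTarget(
                gene=gene,
                **weak,
                qtls=(PlantedQtl("eQTL", BRAIN, _DIRECTION_GENES[gene], 0.85),),
            )
        )
    for gene in _TOP_OTHER_GENES:
        plants.append(
            PlantedTarget(gene=gene, **strong, qtls=(PlantedQtl("eQTL", "blood", 1, 1.0),))
        )
    plants.append(
        PlantedTarget(
            gene="KEAP1",
            **strong,
            qtls=(PlantedQtl("eQTL", "blood", 1, 1.0), PlantedQtl("sQTL", BRAIN, 1, 1.0)),
        )
    )
    for gene in _BRAIN_OTHER_GENES:
        plants.append(
            PlantedTarget(gene=gene, **weak, qtls=(PlantedQtl("sQTL", BRAIN, 1, 0.85),))
        )
    for i in range(_N_DECOYS):
        plants.append(
            PlantedTarget(
                gene=f"OSDECOY{i + 1:02d}",
                p_value=1e-6,
                odds_ratio=1.05,
                qtls=(PlantedQtl("mQTL", "blood", 1, 0.85),),
            )
        )

    inhib = dict(mechanism="inhibit")
    drugs: list[PlannedDrug] = [
        PlannedDrug("BIIB021", "CARM1", "inhibit", "phase2", source_db="DGIdb"),
        PlannedDrug("PEITC", "MAPK1", "activate", "phase2", source_db="SuperTarget"),
        PlannedDrug("ABEMACICLIB", "CDK4", "inhibit", "approved", source_db="DGIdb;DrugBank;OpenTarget"),
        PlannedDrug("ALVOCIDIB", "CDK4", "inhibit", "phase2", source_db="DGIdb;DrugBank;OpenTarget"),
        PlannedDrug("MILCICLIB", "CDK4", "inhibit", "phase2", source_db="DGIdb;OpenTarget"),
        PlannedDrug("PHA-793887", "CDK4", "inhibit", "phase1", source_db="DGIdb"),
        PlannedDrug("ATIPRIMOD", "STAT3", "inhibit", "phase2", source_db="DGIdb"),
        PlannedDrug("ENMD1198", "STAT3", "inhibit", "phase1", source_db="DrugBank"),
        PlannedDrug("ERLOTINIB", "STAT3", "other", "approved", source_db="SuperTarget;DGIdb"),
        PlannedDrug("PILOCARPINE", "FOS", "activate", "approved", source_db="DGIdb"),
        # direction-inconsistent MAPK1 inhibitors — removed by the filter
        PlannedDrug("MK8353", "MAPK1", "inhibit", "phase1", source_db="DGIdb"),
        PlannedDrug("LY3214996", "MAPK1", "inhibit", "phase1", source_db="DGIdb"),
    ]
    # synthetic database fillers completing the 35-candidate repurposable
    # track; all fail the ADME gate
    filler_targets = ("MAPK3", "CDK4", "STAT3", "FOS")
    for i in range(23):
        drugs.append(
            PlannedDrug(
                f"DBFILL{i + 1:02d}", filler_targets[i % 4], "inhibit"
                if filler_targets[i % 4] != "FOS" else "other",
                "phase2", adme_ok=False,
            )
        )
    # experimental track: named survivors plus synthetic ADME failures
    for name in ("MS049", "MS023", "TP064"):
        drugs.append(PlannedDrug(name, "CARM1", "inhibit", "experimental"))
    for name, mech in (
        ("GSK4112", "activate"), ("SR9009", "activate"), ("SR9011", "activate"),
        ("SR8278", "inhibit"),
    ):
        drugs.append(PlannedDrug(name, "NR1D1", mech, "experimental"))
    for i in range(2):
        drugs.append(
            PlannedDrug(f"EXPFILL{i + 1:02d}", "CARM1", "inhibit", "experimental", adme_ok=False)
        )
    for i in range(2, 8):
        drugs.append(
            PlannedDrug(f"EXPFILL{i + 1:02d}", "CAPN1", "inhibit", "experimental", adme_ok=False)
        )

    return GeneratorConfig(
        seed=seed,
        n_samples=400,
        n_noise_loci=4,
        planted_targets=tuple(plants),
        drug_plan=tuple(drugs),
        pathway_fraction=1.0,
        n_pathways=22,
        extra_pathway_genes=tuple(f"OSPROT{i + 1:02d}" for i in range(10)),
    )


def build_reference_fixture(out_dir, seed: int = 0) -> tuple[dict, GroundTruth]:
    """Build the curated MS / oxidative-stress demonstration bundle.

    Encodes the known name-level result lists of the MS-to-oxidative-stress
    repurposing analysis this package reproduces: 18 brain-QTL-supported
    targets, ten brain direction calls (seven up-regulated, three
    down-regulated), the ten repurposable drugs over five targets, the
    seven surviving experimental compounds, and the two MAPK1 inhibitors
    removed for direction inconsistency. Rows the source lists leave
    unnamed are filled with synthetic placeholders (gene symbols
    ``OSTOP``/``OSDECOY``, drug names ``DBFILL``/``EXPFILL``) so that the
    funnel counts (85 targets -> 21 prioritized -> 35 + 15 candidates ->
    10 + 7 survivors) are reproduced end to end.
    """
    return generate_bundle(_fixture_config(seed), out_dir)
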