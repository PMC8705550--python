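"""Domain types, table readers/writers and shared genomic conventions.

Every stage of the pipeline speaks in terms of the types defined here:
variants, GWAS hits, molecular-QTL records, consequence annotations, a
genotype reference panel, pathway sets, drug records and ADME profiles.

Conventions
-----------
* Coordinates are 1-based on a single genome build (GRCh37 by default).
  Every table file may carry a ``#build=<name>`` header comment; readers
  surface it and :func:`check_builds` enforces equality across inputs.
* Gene identity is the uppercased symbol string; alias resolution is out
  of scope.
* The MHC region is the closed interval chr6:27,000,000-33,000,000
  (GRCh37 convention).
* Variant-consequence severity follows the standard ordered ontology,
  most severe first; "missense or more deleterious" means severity rank
  at or above ``missense_variant``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "GwasHit",
    "QtlRecord",
    "ConsequenceRecord",
    "GenotypePanel",
    "PathwaySet",
    "DrugRecord",
    "AdmeProfile",
    "ReadResult",
    "SchemaError",
    "RowError",
    "BuildMismatchError",
    "DEFAULT_BUILD",
    "GWAS_P_THRESHOLD",
    "QTL_TYPES",
    "DRUG_STATUSES",
    "MHC_CHROM",
    "MHC_START",
    "MHC_END",
    "CONSEQUENCE_SEVERITY_ORDER",
    "consequence_rank",
    "is_missense_or_worse",
    "in_mhc",
    "check_builds",
    "read_gwas_hits",
    "write_gwas_hits",
    "read_qtls",
    "write_qtls",
    "read_consequences",
    "write_consequences",
    "read_pathways_gmt",
    "write_pathways_gmt",
    "read_panel",
    "read_panel_tsv",
    "write_panel_tsv",
    "read_panel_vcf",
    "write_panel_vcf",
    "read_drugs",
    "write_drugs",
    "read_adme_profiles",
    "write_adme_profiles",
]

DEFAULT_BUILD = "GRCh37"

#: intake significance gate for GWAS index variants
GWAS_P_THRESHOLD = 1e-5

QTL_TYPES = ("eQTL", "pQTL", "sQTL", "polyQTL", "mQTL")

DRUG_STATUSES = ("approved", "phase1", "phase2", "phase3", "experimental")
DRUG_MECHANISMS = ("inhibit", "activate", "other")

MHC_CHROM = "6"
MHC_START = 27_000_000
MHC_END = 33_000_000

# Standard variant-consequence ontology terms ordered most severe first.
# Rank 0 is the most deleterious class; "missense or more deleterious"
# therefore means rank <= rank of "missense_variant".
CONSEQUENCE_SEVERITY_ORDER = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "feature_elongation",
    "feature_truncation",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_donor_5th_base_variant",
    "splice_region_variant",
    "splice_donor_region_variant",
    "splice_polypyrimidine_tract_variant",
    "incomplete_terminal_codon_variant",
    "start_retained_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "TFBS_ablation",
    "TFBS_amplification",
    "TF_binding_site_variant",
    "regulatory_region_ablation",
    "regulatory_region_amplification",
    "regulatory_region_variant",
    "intergenic_variant",
    "sequence_variant",
)

_SEVERITY_RANK = {term: i for i, term in enumerate(CONSEQUENCE_SEVERITY_ORDER)}
_MISSENSE_RANK = _SEVERITY_RANK["missense_variant"]


class SchemaError(ValueError):
    """A table is missing a required column or has an invalid header."""


class RowError(ValueError):
    """A data row could not be parsed; carries the 1-based file line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class BuildMismatchError(ValueError):
    """Input files declare different genome builds."""


def consequence_rank(term: str) -> int:
    """Severity rank of a consequence term (0 = most severe).

    Raises ``KeyError``-style ``ValueError`` for terms outside the embedded
    ontology so that typos never silently pass a severity filter.
    """
    try:
        return _SEVERITY_RANK[term]
    except KeyError:
        raise ValueError(f"unknown consequence class: {term!r}") from None


def is_missense_or_worse(term: str) -> bool:
    return consequence_rank(term) <= _MISSENSE_RANK


def _norm_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class Variant:
    """A biallelic genetic variant at a 1-based genomic position."""

    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    rsid: Optional[str] = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"alleles must differ, got {self.allele_a!r} twice")
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    @property
    def pos_key(self) -> str:
        """Position-based identity key used for cross-table joins."""
        a, b = sorted((self.allele_a, self.allele_b))
        return f"{self.chrom}:{self.pos}:{a}:{b}"

    @property
    def label(self) -> str:
        """Display label: rsID when available, else the positional key."""
        return self.rsid if self.rsid else self.pos_key


def in_mhc(variant: Variant) -> bool:
    """True iff the variant lies in the MHC region, chr6:27-33 Mb (closed)."""
    return variant.chrom == MHC_CHROM and MHC_START <= variant.pos <= MHC_END


@dataclass(frozen=True)
class GwasHit:
    """An index (top) disease-association signal for one locus."""

    variant: Variant
    risk_allele: str
    p_value: float
    odds_ratio: float
    study_id: str = ""

    def __post_init__(self):
        if self.risk_allele not in self.variant.alleles:
            raise ValueError(
                f"risk allele {self.risk_allele!r} is not an allele of "
                f"{self.variant.label}"
            )
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if self.odds_ratio <= 0:
            raise ValueError(f"odds_ratio must be > 0, got {self.odds_ratio}")


@dataclass(frozen=True)
class QtlRecord:
    """A variant -> gene molecular-regulation record (one QTL association)."""

    variant: Variant
    effect_allele: str
    gene: str
    qtl_type: str
    tissue: str
    effect_sign: int

    def __post_init__(self):
        if self.effect_allele not in self.variant.alleles:
            raise ValueError(
                f"effect allele {self.effect_allele!r} is not an allele of "
                f"{self.variant.label}"
            )
        if self.qtl_type not in QTL_TYPES:
            raise ValueError(f"qtl_type must be one of {QTL_TYPES}, got {self.qtl_type!r}")
        if self.effect_sign not in (-1, 1):
            raise ValueError(f"effect_sign must be +1 or -1, got {self.effect_sign}")
        object.__setattr__(self, "gene", self.gene.upper())


@dataclass(frozen=True)
class ConsequenceRecord:
    """A functional (coding) consequence annotation for a variant in a gene."""

    variant: Variant
    gene: str
    consequence_class: str
    cadd_phred: float

    def __post_init__(self):
        consequence_rank(self.consequence_class)  # validates the term
        if self.cadd_phred < 0:
            raise ValueError(f"cadd_phred must be >= 0, got {self.cadd_phred}")
        object.__setattr__(self, "gene", self.gene.upper())


MISSING_GENOTYPE = -1


@dataclass
class GenotypePanel:
    """Unphased diploid genotypes for a set of variants and samples.

    ``genotypes[i, j]`` counts copies of ``variants[i].allele_b`` carried by
    sample ``j`` (0, 1 or 2); missing calls are ``-1``.
    """

    samples: list[str]
    variants: list[Variant]
    genotypes: np.ndarray  # shape (n_variants, n_samples), int8

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING_GENOTYPE))
        if bad.any():
            raise ValueError("genotypes must be 0, 1, 2 or -1 (missing)")
        self._index = {v.pos_key: i for i, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValueError("panel contains duplicate variants (same position and alleles)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __contains__(self, variant: Variant) -> bool:
        return variant.pos_key in self._index

    def index_of(self, variant: Variant) -> int:
        try:
            return self._index[variant.pos_key]
        except KeyError:
            raise KeyError(f"variant {variant.label} not in panel") from None

    def genotype_row(self, variant: Variant) -> np.ndarray:
        return self.genotypes[self.index_of(variant)]


@dataclass(frozen=True)
class PathwaySet:
    """A named pathway and its member gene symbols (uppercased)."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(m.upper() for m in self.members))


@dataclass(frozen=True)
class DrugRecord:
    """A candidate modulator of a gene target."""

    name: str
    target_gene: str
    mechanism: str  # inhibit | activate | other
    status: str  # approved | phase1..3 | experimental
    interaction_score: Optional[float] = None
    direct_action: bool = False
    validated_transcriptional_modulator: bool = False
    source_db: str = ""

    def __post_init__(self):
        if self.mechanism not in DRUG_MECHANISMS:
            raise ValueError(f"mechanism must be one of {DRUG_MECHANISMS}")
        if self.status not in DRUG_STATUSES:
            raise ValueError(f"status must be one of {DRUG_STATUSES}")
        if self.interaction_score is not None and self.interaction_score < 0:
            raise ValueError("interaction_score must be >= 0 when present")
        object.__setattr__(self, "target_gene", self.target_gene.upper())


@dataclass(frozen=True)
class AdmeProfile:
    """Predicted pharmacokinetic descriptors for one compound.

    ``None`` marks a missing descriptor; the ADME gate fails the
    corresponding rule with reason "missing".
    """

    compound: str
    cns_activity: Optional[int] = None  # -2 (inactive) .. +2 (active)
    log_bb: Optional[float] = None  # log blood-brain partition coefficient
    mdck_perm: Optional[float] = None  # nm/sec
    caco2_perm: Optional[float] = None  # nm/sec
    human_oral_absorption: Optional[int] = None  # ordinal class 1-3
    pct_human_absorption: Optional[float] = None  # 0-100

    def __post_init__(self):
        if self.cns_activity is not None and not (-2 <= self.cns_activity <= 2):
            raise ValueError("cns_activity must be in [-2, 2]")
        if self.human_oral_absorption is not None and not (
            1 <= self.human_oral_absorption <= 3
        ):
            raise ValueError("human_oral_absorption must be an ordinal class 1-3")
        if self.pct_human_absorption is not None and not (
            0 <= self.pct_human_absorption <= 100
        ):
            raise ValueError("pct_human_absorption must be in [0, 100]")


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


@dataclass
class ReadResult:
    """Records parsed from a table plus intake bookkeeping.

    ``n_dropped`` counts data rows removed by an intake filter (e.g. the
    GWAS significance gate); parsed + dropped always equals the number of
    data rows in the file.
    """

    records: list
    n_dropped: int = 0
    build: Optional[str] = None
    path: Optional[str] = None

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def check_builds(*results: ReadResult) -> Optional[str]:
    """Assert all inputs declare the same genome build.

    Files without a ``#build=`` header are treated as unlabelled and do not
    conflict. Returns the common declared build, if any.
    """
    builds = {r.build for r in results if r.build is not None}
    if len(builds) > 1:
        detail = ", ".join(
            f"{r.path or '<table>'}={r.build}" for r in results if r.build is not None
        )
        raise BuildMismatchError(f"inputs declare different genome builds: {detail}")
    return next(iter(builds), None)


def _read_header_and_table(path, required: Sequence[str]):
    """Read a TSV with optional leading '#key=value' comments.

    Returns (dataframe, metadata dict, line number of the first data row).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    n_comment = 0
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#"):
                n_comment += 1
                body = raw[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=n_comment, dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    return df, meta, n_comment + 2  # +1 header line, +1 to 1-based


def _parse_float(value, name: str, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowError(f"cannot parse {name}={value!r} as a number", line) from None


def _parse_int(value, name: str, line: int) -> int:
    try:
        return int(str(value))
    except (TypeError, ValueError):
        raise RowError(f"cannot parse {name}={value!r} as an integer", line) from None


def _parse_alleles(value, line: int) -> tuple[str, str]:
    parts = str(value).split("/")
    if len(parts) != 2 or not all(parts):
        raise RowError(f"alleles must be 'A/B', got {value!r}", line)
    return parts[0], parts[1]


def _opt_str(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return str(value)


def _opt_rsid(row) -> Optional[str]:
    rsid = row.get("rsid")
    if rsid is None or (isinstance(rsid, float) and math.isnan(rsid)) or rsid == "":
        return None
    return str(rsid)


def _variant_from_row(row, line: int) -> Variant:
    a, b = _parse_alleles(row["alleles"], line)
    try:
        return Variant(
            chrom=str(row["chrom"]),
            pos=_parse_int(row["pos"], "pos", line),
            allele_a=a,
            allele_b=b,
            rsid=_opt_rsid(row),
        )
    except ValueError as exc:
        raise RowError(str(exc), line) from None


def _build_header_lines(build: Optional[str], extra: Optional[dict] = None) -> str:
    lines = []
    if build:
        lines.append(f"#build={build}")
    for k, v in (extra or {}).items():
        lines.append(f"#{k}={v}")
    return "".join(line + "\n" for line in lines)


def read_gwas_hits(path, p_threshold: float = GWAS_P_THRESHOLD) -> ReadResult:
    """Read GWAS index associations, applying the intake significance gate.

    Rows with ``p_value >= p_threshold`` (default 1e-5) are dropped and
    counted in ``n_dropped``. Malformed rows raise :class:`RowError` with
    the file line number.
    """
    df, meta, first_line = _read_header_and_table(
        path, ["chrom", "pos", "alleles", "risk_allele", "p_value", "odds_ratio", "study_id"]
    )
    hits: list[GwasHit] = []
    n_dropped = 0
    for i, row in enumerate(df.to_dict("records")):
        line = first_line + i
        variant = _variant_from_row(row, line)
        p = _parse_float(row["p_value"], "p_value", line)
        if p >= p_threshold:
            n_dropped += 1
            continue
        try:
            hits.append(
                GwasHit(
                    variant=variant,
                    risk_allele=str(row["risk_allele"]),
                    p_value=p,
                    odds_ratio=_parse_float(row["odds_ratio"], "odds_ratio", line),
                    study_id=str(row["study_id"]),
                )
            )
        except ValueError as exc:
            raise RowError(str(exc), line) from None
    return ReadResult(hits, n_dropped=n_dropped, build=meta.get("build"), path=str(path))


def write_gwas_hits(path, hits: Iterable[GwasHit], build: str = DEFAULT_BUILD) -> None:
    rows = [
        {
            "chrom": h.variant.chrom,
            "pos": h.variant.pos,
            "alleles": f"{h.variant.allele_a}/{h.variant.allele_b}",
            "rsid": h.variant.rsid or "",
            "risk_allele": h.risk_allele,
            "p_value": repr(h.p_value),
            "odds_ratio": repr(h.odds_ratio),
            "study_id": h.study_id,
        }
        for h in hits
    ]
    _write_tsv(path, rows, build, cols=["chrom", "pos", "alleles", "rsid", "risk_allele", "p_value", "odds_ratio", "study_id"])


def read_qtls(path) -> ReadResult:
    """Read the molecular-QTL catalogue (variant -> gene regulation records)."""
    df, meta, first_line = _read_header_and_table(
        path, ["chrom", "pos", "alleles", "effect_allele", "gene", "qtl_type", "tissue", "effect_sign"]
    )
    records: list[QtlRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        line = first_line + i
        variant = _variant_from_row(row, line)
        try:
            records.append(
                QtlRecord(
                    variant=variant,
                    effect_allele=str(row["effect_allele"]),
                    gene=str(row["gene"]),
                    qtl_type=str(row["qtl_type"]),
                    tissue=str(row["tissue"]),
                    effect_sign=_parse_int(row["effect_sign"], "effect_sign", line),
                )
            )
        except ValueError as exc:
            raise RowError(str(exc), line) from None
    return ReadResult(records, build=meta.get("build"), path=str(path))


def write_qtls(path, qtls: Iterable[QtlRecord], build: str = DEFAULT_BUILD) -> None:
    rows = [
        {
            "chrom": q.variant.chrom,
            "pos": q.variant.pos,
            "alleles": f"{q.variant.allele_a}/{q.variant.allele_b}",
            "rsid": q.variant.rsid or "",
            "effect_allele": q.effect_allele,
            "gene": q.gene,
            "qtl_type": q.qtl_type,
            "tissue": q.tissue,
            "effect_sign": q.effect_sign,
        }
        for q in qtls
    ]
    _write_tsv(path, rows, build, cols=["chrom", "pos", "alleles", "rsid", "effect_allele", "gene", "qtl_type", "tissue", "effect_sign"])


def read_consequences(path) -> ReadResult:
    """Read functional consequence annotations (consequence class + CADD)."""
    df, meta, first_line = _read_header_and_table(
        path, ["chrom", "pos", "alleles", "gene", "consequence", "cadd_phred"]
    )
    records: list[ConsequenceRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        line = first_line + i
        variant = _variant_from_row(row, line)
        try:
            records.append(
                ConsequenceRecord(
                    variant=variant,
                    gene=str(row["gene"]),
                    consequence_class=str(row["consequence"]),
                    cadd_phred=_parse_float(row["cadd_phred"], "cadd_phred", line),
                )
            )
        except ValueError as exc:
            raise RowError(str(exc), line) from None
    return ReadResult(records, build=meta.get("build"), path=str(path))


def write_consequences(path, records: Iterable[ConsequenceRecord], build: str = DEFAULT_BUILD) -> None:
    rows = [
        {
            "chrom": r.variant.chrom,
            "pos": r.variant.pos,
            "alleles": f"{r.variant.allele_a}/{r.variant.allele_b}",
            "rsid": r.variant.rsid or "",
            "gene": r.gene,
            "consequence": r.consequence_class,
            "cadd_phred": repr(r.cadd_phred),
        }
        for r in records
    ]
    _write_tsv(path, rows, build, cols=["chrom", "pos", "alleles", "rsid", "gene", "consequence", "cadd_phred"])


def read_pathways_gmt(path) -> ReadResult:
    """Read pathway membership in GMT format (name, description, members...).

    Member symbols are uppercased and de-duplicated within each set.
    """
    sets: list[PathwaySet] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RowError(
                    f"GMT line needs >= 3 tab-separated fields, got {len(fields)}", line_no
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise RowError(f"pathway {name!r} has no members", line_no)
            sets.append(PathwaySet(name=name, members=frozenset(members)))
    return ReadResult(sets, path=str(path))


def write_pathways_gmt(path, sets: Iterable[PathwaySet]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.members)]) + "\n")


def pathway_union(sets: Iterable[PathwaySet]) -> frozenset[str]:
    out: set[str] = set()
    for s in sets:
        out |= s.members
    return frozenset(out)


def read_panel(path) -> ReadResult:
    """Read a genotype panel from matrix TSV or VCF, dispatching on suffix."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_panel_vcf(path)
    return read_panel_tsv(path)


def read_panel_tsv(path) -> ReadResult:
    """Read a genotype panel from a matrix TSV.

    Columns: chrom, pos, alleles, rsid, then one column per sample holding
    0/1/2 counts of allele_b, or '.' for missing.
    """
    df, meta, first_line = _read_header_and_table(path, ["chrom", "pos", "alleles"])
    fixed = [c for c in ("chrom", "pos", "alleles", "rsid") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in fixed]
    if not sample_cols:
        raise SchemaError(f"{Path(path).name}: panel has no sample columns")
    variants: list[Variant] = []
    rows: list[list[int]] = []
    for i, row in enumerate(df.to_dict("records")):
        line = first_line + i
        variants.append(_variant_from_row(row, line))
        geno = []
        for c in sample_cols:
            v = row[c]
            if v in (".", "", None) or (isinstance(v, float) and math.isnan(v)):
                geno.append(MISSING_GENOTYPE)
            else:
                g = _parse_int(v, f"genotype[{c}]", line)
                if g not in (0, 1, 2):
                    raise RowError(f"genotype must be 0/1/2/., got {v!r}", line)
                geno.append(g)
        rows.append(geno)
    panel = GenotypePanel(
        samples=list(sample_cols),
        variants=variants,
        genotypes=np.array(rows, dtype=np.int8).reshape(len(variants), len(sample_cols)),
    )
    return ReadResult([panel], build=meta.get("build"), path=str(path))


def write_panel_tsv(path, panel: GenotypePanel, build: str = DEFAULT_BUILD, extra_meta: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_build_header_lines(build, extra_meta))
        fh.write("\t".join(["chrom", "pos", "alleles", "rsid", *panel.samples]) + "\n")
        for i, v in enumerate(panel.variants):
            geno = [
                "." if g == MISSING_GENOTYPE else str(int(g)) for g in panel.genotypes[i]
            ]
            fh.write(
                "\t".join(
                    [v.chrom, str(v.pos), f"{v.allele_a}/{v.allele_b}", v.rsid or "", *geno]
                )
                + "\n"
            )


def read_panel_vcf(path) -> ReadResult:
    """Read a genotype panel from a (minimal, diploid, GT-only) VCF via pysam."""
    import pysam

    variants: list[Variant] = []
    rows: list[list[int]] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"panel VCF must be biallelic; offending record at "
                    f"{rec.chrom}:{rec.pos}"
                )
            variants.append(
                Variant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    allele_a=rec.ref,
                    allele_b=rec.alts[0],
                    rsid=rec.id,
                )
            )
            geno = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    geno.append(MISSING_GENOTYPE)
                else:
                    geno.append(int(sum(gt)))
            rows.append(geno)
    panel = GenotypePanel(
        samples=samples,
        variants=variants,
        genotypes=np.array(rows, dtype=np.int8).reshape(len(variants), len(samples)),
    )
    return ReadResult([panel], path=str(path))


def write_panel_vcf(path, panel: GenotypePanel, build: str = DEFAULT_BUILD) -> None:
    """Write the panel as a minimal VCF v4.2 (GT only, unphased) via pysam."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##reference={build}")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(v.chrom for v in panel.variants):
        header.add_line(f"##contig=<ID={chrom}>")
    for s in panel.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, v in enumerate(panel.variants):
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.allele_a),
                alleles=(v.allele_a, v.allele_b),
                id=v.rsid,
            )
            for j, s in enumerate(panel.samples):
                g = int(panel.genotypes[i, j])
                if g == MISSING_GENOTYPE:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1))
            out.write(rec)


_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


def _parse_bool(value, name: str, line: int) -> bool:
    s = str(value).strip().lower()
    if s in ("nan", "none"):
        s = ""
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise RowError(f"cannot parse {name}={value!r} as a boolean", line)


def read_drugs(path) -> ReadResult:
    """Read the drug-target interaction table."""
    df, meta, first_line = _read_header_and_table(
        path, ["name", "target_gene", "mechanism", "status"]
    )
    records: list[DrugRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        line = first_line + i
        score = row.get("interaction_score")
        if score is None or score == "" or (isinstance(score, float) and math.isnan(score)):
            score_val = None
        else:
            score_val = _parse_float(score, "interaction_score", line)
        try:
            records.append(
                DrugRecord(
                    name=str(row["name"]),
                    target_gene=str(row["target_gene"]),
                    mechanism=str(row["mechanism"]),
                    status=str(row["status"]),
                    interaction_score=score_val,
                    direct_action=_parse_bool(
                        row.get("direct_action", False), "direct_action", line
                    ),
                    validated_transcriptional_modulator=_parse_bool(
                        row.get("validated_transcriptional_modulator", False),
                        "validated_transcriptional_modulator",
                        line,
                    ),
                    source_db=_opt_str(row.get("source_db")),
                )
            )
        except ValueError as exc:
            if isinstance(exc, RowError):
                raise
            raise RowError(str(exc), line) from None
    return ReadResult(records, build=meta.get("build"), path=str(path))


def write_drugs(path, drugs: Iterable[DrugRecord]) -> None:
    rows = [
        {
            "name": d.name,
            "target_gene": d.target_gene,
            "mechanism": d.mechanism,
            "status": d.status,
            "interaction_score": "" if d.interaction_score is None else repr(d.interaction_score),
            "direct_action": str(d.direct_action).lower(),
            "validated_transcriptional_modulator": str(
                d.validated_transcriptional_modulator
            ).lower(),
            "source_db": d.source_db,
        }
        for d in drugs
    ]
    _write_tsv(path, rows, build=None, cols=["name", "target_gene", "mechanism", "status", "interaction_score", "direct_action", "validated_transcriptional_modulator", "source_db"])


_ADME_FIELDS = (
    "cns_activity",
    "log_bb",
    "mdck_perm",
    "caco2_perm",
    "human_oral_absorption",
    "pct_human_absorption",
)


def read_adme_profiles(path) -> ReadResult:
    """Read the ADME descriptor table; blank cells become missing descriptors."""
    df, meta, first_line = _read_header_and_table(path, ["compound", *_ADME_FIELDS])
    records: list[AdmeProfile] = []
    for i, row in enumerate(df.to_dict("records")):
        line = first_line + i
        vals = {}
        for f in _ADME_FIELDS:
            v = row[f]
            if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
                vals[f] = None
            elif f in ("cns_activity", "human_oral_absorption"):
                vals[f] = _parse_int(v, f, line)
            else:
                vals[f] = _parse_float(v, f, line)
        try:
            records.append(AdmeProfile(compound=str(row["compound"]), **vals))
        except ValueError as exc:
            raise RowError(str(exc), line) from None
    return ReadResult(records, build=meta.get("build"), path=str(path))


def write_adme_profiles(path, profiles: Iterable[AdmeProfile]) -> None:
    def fmt(v):
        if v is None:
            return ""
        return repr(v) if isinstance(v, float) else str(v)

    rows = [
        {"compound": p.compound, **{f: fmt(getattr(p, f)) for f in _ADME_FIELDS}}
        for p in profiles
    ]
    _write_tsv(path, rows, build=None, cols=["compound", *_ADME_FIELDS])


def _write_tsv(path, rows: list[dict], build: Optional[str], cols: Optional[list[str]] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_build_header_lines(build))
        if cols is None:
            cols = list(rows[0].keys()) if rows else []
        if not cols:
            return
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
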