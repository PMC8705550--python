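"""End-to-end orchestration: files in, funnel report and stage tables out.

``run_pipeline`` executes target mapping -> pathway overlap -> scoring ->
top-quantile selection -> direction calling -> drug filtering (repurposable
and experimental tracks) -> ADME gating, writing every intermediate table
and a JSON run report whose stage counts are self-audited against the
files it wrote. Deterministic given identical inputs.

All tunable constants live in :class:`PipelineConfig` with the published
defaults (intake p < 1e-5, genome-wide significance 5e-8, proxy r^2 > 0.7,
CADD > 15, OR > 1.2, top 25%, MHC chr6:27-33 Mb, the ADME bands).
"""

from __future__ import annotations

import dataclasses
import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import core_model as cm
from .core_model import check_builds
from .direction_engine import call_directions, write_directions
from .drug_adme import (
    AdmeThresholds,
    REPURPOSABLE_STATUSES,
    adme_gate,
    filter_drugs,
    write_drug_verdicts,
)
from .ld_engine import expand_proxies, ld_pair
from .prioritizer import ScoreConfig, overlap_targets, score_target, select_top, write_scores
from .target_mapper import consequence_filter, map_targets, write_targets

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Input paths plus every stage constant, with published defaults."""

    # inputs
    gwas: str = ""
    qtls: str = ""
    consequences: str = ""
    panel: str = ""
    pathways: str = ""
    drugs: str = ""
    adme: str = ""
    out_dir: str = "oxiscore_out"
    # intake / mapping
    p_intake: float = cm.GWAS_P_THRESHOLD
    r2_min: float = 0.7
    window_bp: int = 1_000_000
    cadd_min: float = 15.0
    mhc_gene_list: tuple[str, ...] = ()
    # scoring / selection
    gw_sig_p: float = 5e-8
    or_threshold: float = 1.2
    top_fraction: float = 0.25
    score_threshold: int = 20
    # directions
    tissue: str = "brain"
    direction_qtl_types: tuple[str, ...] = ("eQTL", "pQTL")
    # drugs
    interaction_score_min: float = 0.50
    repurposable_statuses: tuple[str, ...] = REPURPOSABLE_STATUSES
    experimental_statuses: tuple[str, ...] = ("experimental",)
    # ADME
    cns_min: int = 0
    logbb_range: tuple[float, float] = (-1.0, 1.2)
    mdck_min: float = 100.0
    caco2_min: float = 100.0
    hoa_min_class: int = 3
    pct_hoa_min: float = 80.0

    def score_config(self) -> ScoreConfig:
        return ScoreConfig(
            gw_sig_p=self.gw_sig_p,
            or_threshold=self.or_threshold,
            top_fraction=self.top_fraction,
            score_threshold=self.score_threshold,
        )

    def adme_thresholds(self) -> AdmeThresholds:
        return AdmeThresholds(
            cns_min=self.cns_min,
            logbb_range=tuple(self.logbb_range),
            mdck_min=self.mdck_min,
            caco2_min=self.caco2_min,
            hoa_min_class=self.hoa_min_class,
            pct_hoa_min=self.pct_hoa_min,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):  # per-stage blocks are flattened
                flat.update(value)
            else:
                flat[key] = value
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - names
        if unknown:
            raise cm.SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for k, v in flat.items():
            if isinstance(v, list):
                flat[k] = tuple(v)
        return cls(**flat)


@dataclass
class RunReport:
    """Funnel counts, realized thresholds, output paths and warnings."""

    counts: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    output_paths: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    audit_ok: bool = False

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _count_tsv_rows(path) -> int:
    with open(path) as fh:
        rows = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    return max(0, len(rows) - 1)  # minus header


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage in order and write tables plus the JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")

        gwas = cm.read_gwas_hits(config.gwas, p_threshold=config.p_intake)
        qtls = cm.read_qtls(config.qtls)
        consequences = (
            cm.read_consequences(config.consequences) if config.consequences else cm.ReadResult([])
        )
        panel_res = cm.read_panel(config.panel)
        panel = panel_res[0]
        pathways = cm.read_pathways_gmt(config.pathways)
        drugs = cm.read_drugs(config.drugs) if config.drugs else cm.ReadResult([])
        adme = cm.read_adme_profiles(config.adme) if config.adme else cm.ReadResult([])
        check_builds(gwas, qtls, consequences, panel_res)

        report.counts["gwas_hits"] = len(gwas)
        report.counts["gwas_dropped_by_intake"] = gwas.n_dropped

        proxy_map = expand_proxies(
            panel, gwas.records, r2_min=config.r2_min, window_bp=config.window_bp
        )
        report.counts["proxy_pairs"] = sum(len(v) for v in proxy_map.values())

        kept_csq = consequence_filter(consequences.records, cadd_min=config.cadd_min)
        report.counts["consequences_kept"] = len(kept_csq)

        mapping = map_targets(
            gwas.records, proxy_map, qtls.records, kept_csq, config.mhc_gene_list
        )
        report.counts["gene_targets"] = len(mapping.targets)
        report.counts["mhc_excluded_genes"] = mapping.n_excluded_mhc

        shared = overlap_targets(mapping.targets, pathways.records)
        report.counts["shared_targets"] = len(shared)

        scfg = config.score_config()
        scores = [score_target(t, scfg) for t in shared]
        if scores:
            selection = select_top(scores, scfg)
            selected_genes = selection.genes()
            report.thresholds["realized_score_threshold"] = selection.threshold
            report.thresholds["n_top_quantile"] = selection.n_quantile
        else:
            selection = None
            selected_genes = []
        report.counts["prioritized_targets"] = len(selected_genes)

        lookup = lambda a, b: ld_pair(panel, a, b)  # noqa: E731
        directions = call_directions(
            shared,
            ld_lookup=lookup,
            tissue_filter=config.tissue,
            qtl_types=config.direction_qtl_types,
        )
        report.counts["direction_calls"] = len(directions)
        report.counts["direction_conflicts"] = sum(1 for d in directions if d.conflict)

        tracks = {}
        for track, statuses in (
            ("repurposable", config.repurposable_statuses),
            ("experimental", config.experimental_statuses),
        ):
            candidates = [d for d in drugs.records if d.status in statuses]
            filt = filter_drugs(
                candidates,
                selected_genes,
                directions,
                allowed_statuses=statuses,
                interaction_score_min=config.interaction_score_min,
            )
            survivors, verdicts = adme_gate(filt.retained, adme.records, config.adme_thresholds())
            tracks[track] = (filt, survivors, verdicts)
            report.counts[f"{track}_candidates"] = len(candidates)
            report.counts[f"{track}_after_drug_filter"] = len(filt.retained)
            report.counts[f"{track}_after_adme"] = len(survivors)
            report.counts[f"{track}_targets_after_adme"] = len(
                {d.target_gene for d in survivors}
            )
            report.warnings.extend(filt.warnings)

        report.warnings.extend(str(w.message) for w in caught)

    # ---- outputs -----------------------------------------------------------
    paths = {
        "proxies": out / "proxies.tsv",
        "targets": out / "targets.tsv",
        "scores": out / "scores.tsv",
        "directions": out / "directions.tsv",
        "drugs_repurposable": out / "drugs_repurposable.tsv",
        "drugs_experimental": out / "drugs_experimental.tsv",
        "survivors_repurposable": out / "survivors_repurposable.tsv",
        "survivors_experimental": out / "survivors_experimental.tsv",
        "report": out / "report.json",
    }
    _write_proxies(paths["proxies"], proxy_map)
    write_targets(paths["targets"], mapping)
    write_scores(paths["scores"], scores, selected_genes)
    write_directions(paths["directions"], directions)
    for track in ("repurposable", "experimental"):
        filt, survivors, verdicts = tracks[track]
        write_drug_verdicts(paths[f"drugs_{track}"], filt, verdicts)
        cm.write_drugs(paths[f"survivors_{track}"], survivors)

    report.thresholds.update(
        p_intake=config.p_intake,
        gw_sig_p=config.gw_sig_p,
        r2_min=config.r2_min,
        cadd_min=config.cadd_min,
        or_threshold=config.or_threshold,
        top_fraction=config.top_fraction,
        interaction_score_min=config.interaction_score_min,
    )
    report.output_paths = {k: str(v) for k, v in paths.items()}

    # self-audit: stage counts must match the tables written for them
    audit = {
        "proxy_pairs": _count_tsv_rows(paths["proxies"]),
        "gene_targets": _count_tsv_rows(paths["targets"]),
        "shared_targets": _count_tsv_rows(paths["scores"]),
        "direction_calls": _count_tsv_rows(paths["directions"]),
        "repurposable_after_adme": _count_tsv_rows(paths["survivors_repurposable"]),
        "experimental_after_adme": _count_tsv_rows(paths["survivors_experimental"]),
    }
    report.audit_ok = all(report.counts[k] == v for k, v in audit.items())
    if not report.audit_ok:
        report.warnings.append(f"self-audit mismatch: {audit} vs counts")
    report.to_json(paths["report"])
    return report


def _write_proxies(path, proxy_map) -> None:
    from .core_model import _write_tsv

    rows = []
    for hit, proxies in proxy_map.items():
        for var, r2 in proxies:
            rows.append(
                {
                    "hit": hit.variant.label,
                    "proxy": var.label,
                    "r2": repr(float(r2)),
                }
            )
    _write_tsv(path, rows, build=None, cols=["hit", "proxy", "r2"])
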