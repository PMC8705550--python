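"""Drug selection against prioritized targets, and the ADME-Tox gate.

Drug filtering retains a candidate modulator iff

* its target gene is in the prioritized set;
* its development status is allowed (approved / phase 1-3 by default;
  experimental compounds go through a separate track);
* its interaction evidence is credible: direct action on the target, a
  database interaction score strictly above 0.50, or published
  experimental validation as a transcriptional modulator;
* its mechanism is consistent with the required modulation whenever a
  brain direction call exists for the gene (no call -> no constraint;
  conflicted calls impose no constraint either, they are unresolved).

The ADME gate then demands CNS activity and oral bioavailability: every
rule must pass, and per-rule verdicts (including "missing" descriptors)
are always reported. The default numeric thresholds realize the
qualitative medium-good bands of the QikProp descriptor conventions and
are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core_model import AdmeProfile, DrugRecord
from .direction_engine import DirectionCall

__all__ = [
    "AdmeThresholds",
    "AdmeVerdict",
    "DrugVerdict",
    "FilterResult",
    "filter_drugs",
    "adme_pass",
    "adme_gate",
]

#: development statuses eligible for the repurposable track
REPURPOSABLE_STATUSES = ("approved", "phase1", "phase2", "phase3")

#: strict lower bound on the database interaction score
INTERACTION_SCORE_MIN = 0.50


@dataclass(frozen=True)
class AdmeThresholds:
    """Numeric ADME cut-offs (defaults: medium-good descriptor bands).

    * ``cns_min`` 0: predicted CNS activity at least neutral.
    * ``logbb_range`` [-1.0, 1.2]: medium-good blood-brain partition.
    * ``mdck_min``/``caco2_min`` 100 nm/sec: medium-good apparent
      permeability (below 25 is poor, above 500 great).
    * ``hoa_min_class`` 3: high qualitative human oral absorption.
    * ``pct_hoa_min`` 80%: high percent human oral absorption.
    """

    cns_min: int = 0
    logbb_range: tuple[float, float] = (-1.0, 1.2)
    mdck_min: float = 100.0
    caco2_min: float = 100.0
    hoa_min_class: int = 3
    pct_hoa_min: float = 80.0

    def __post_init__(self):
        if self.logbb_range[0] > self.logbb_range[1]:
            raise ValueError("logbb_range must be (low, high) with low <= high")


@dataclass
class AdmeVerdict:
    """Overall pass/fail plus per-rule booleans and failure reasons."""

    compound: str
    passed: bool
    rules: dict[str, bool]
    reasons: dict[str, str] = field(default_factory=dict)


def adme_pass(profile: AdmeProfile, th: AdmeThresholds = AdmeThresholds()) -> AdmeVerdict:
    """Apply the ADME rules to one compound profile.

    A missing descriptor fails its rule with reason ``"missing"``; overall
    pass requires every rule to pass.
    """
    checks = {
        "cns_activity": (profile.cns_activity, lambda v: v >= th.cns_min),
        "log_bb": (
            profile.log_bb,
            lambda v: th.logbb_range[0] <= v <= th.logbb_range[1],
        ),
        "mdck_perm": (profile.mdck_perm, lambda v: v >= th.mdck_min),
        "caco2_perm": (profile.caco2_perm, lambda v: v >= th.caco2_min),
        "human_oral_absorption": (
            profile.human_oral_absorption,
            lambda v: v >= th.hoa_min_class,
        ),
        "pct_human_absorption": (
            profile.pct_human_absorption,
            lambda v: v >= th.pct_hoa_min,
        ),
    }
    rules: dict[str, bool] = {}
    reasons: dict[str, str] = {}
    for name, (value, ok) in checks.items():
        if value is None:
            rules[name] = False
            reasons[name] = "missing"
        else:
            rules[name] = bool(ok(value))
            if not rules[name]:
                reasons[name] = "below threshold" if name != "log_bb" else "outside range"
    return AdmeVerdict(
        compound=profile.compound,
        passed=all(rules.values()),
        rules=rules,
        reasons=reasons,
    )


@dataclass
class DrugVerdict:
    drug: DrugRecord
    retained: bool
    reason: str = ""  # empty when retained


@dataclass
class FilterResult:
    retained: list[DrugRecord]
    verdicts: list[DrugVerdict]
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.retained)

    def __len__(self):
        return len(self.retained)


def _direction_index(
    directions: Iterable[DirectionCall],
) -> dict[str, DirectionCall]:
    """Gene -> unconflicted direction call (conflicts are unresolved)."""
    idx: dict[str, DirectionCall] = {}
    for call in directions:
        if not call.conflict:
            idx[call.gene] = call
    return idx


def filter_drugs(
    drugs: Sequence[DrugRecord],
    prioritized_genes: Iterable[str],
    directions: Iterable[DirectionCall] = (),
    allowed_statuses: Sequence[str] = REPURPOSABLE_STATUSES,
    interaction_score_min: float = INTERACTION_SCORE_MIN,
    known_genes: Optional[Iterable[str]] = None,
) -> FilterResult:
    """Select candidate drugs for the prioritized targets.

    Parameters
    ----------
    drugs
        Candidate drug-target records.
    prioritized_genes
        Genes that survived score-based prioritization.
    directions
        Direction calls for the drug-selection tissue; a drug whose
        mechanism contradicts its target's required modulation is removed.
    allowed_statuses
        Development statuses admitted to this track (default: approved +
        clinical phases; pass ``("experimental",)`` for the experimental
        track).
    known_genes
        The full gene universe; drugs referencing genes outside it are
        dropped with a warning (default: the prioritized set plus genes
        with direction calls).

    The filter is idempotent and independent of input row order.
    """
    prioritized = {g.upper() for g in prioritized_genes}
    dir_idx = _direction_index(directions)
    universe = (
        {g.upper() for g in known_genes}
        if known_genes is not None
        else prioritized | set(dir_idx)
    )
    retained: list[DrugRecord] = []
    verdicts: list[DrugVerdict] = []
    warns: list[str] = []
    for d in drugs:
        if d.target_gene not in universe:
            warns.append(f"drug {d.name}: unknown target gene {d.target_gene}; dropped")
            verdicts.append(DrugVerdict(d, False, "unknown gene"))
            continue
        if d.target_gene not in prioritized:
            verdicts.append(DrugVerdict(d, False, "target not prioritized"))
            continue
        if d.status not in allowed_statuses:
            verdicts.append(DrugVerdict(d, False, f"status {d.status} not allowed"))
            continue
        credible = (
            d.direct_action
            or (d.interaction_score is not None and d.interaction_score > interaction_score_min)
            or d.validated_transcriptional_modulator
        )
        if not credible:
            verdicts.append(DrugVerdict(d, False, "insufficient interaction evidence"))
            continue
        call = dir_idx.get(d.target_gene)
        if call is not None and d.mechanism != call.modulation:
            verdicts.append(
                DrugVerdict(
                    d, False, f"mechanism {d.mechanism} inconsistent with required {call.modulation}"
                )
            )
            continue
        retained.append(d)
        verdicts.append(DrugVerdict(d, True))
    return FilterResult(retained=retained, verdicts=verdicts, warnings=warns)


def adme_gate(
    drugs: Iterable[DrugRecord],
    profiles: Iterable[AdmeProfile],
    th: AdmeThresholds = AdmeThresholds(),
) -> tuple[list[DrugRecord], dict[str, AdmeVerdict]]:
    """Gate filtered drugs by their ADME profiles.

    Returns the surviving drugs and every compound's verdict. A drug with
    no profile fails with all rules marked missing.
    """
    by_compound = {p.compound: p for p in profiles}
    survivors: list[DrugRecord] = []
    verdicts: dict[str, AdmeVerdict] = {}
    for d in drugs:
        profile = by_compound.get(d.name, AdmeProfile(compound=d.name))
        verdict = adme_pass(profile, th)
        verdicts[d.name] = verdict
        if verdict.passed:
            survivors.append(d)
    return survivors, verdicts


def write_drug_verdicts(path, result: FilterResult, adme_verdicts: Mapping[str, AdmeVerdict] = ()) -> None:
    from .core_model import _write_tsv

    adme_verdicts = dict(adme_verdicts)
    rows = []
    for v in result.verdicts:
        av = adme_verdicts.get(v.drug.name)
        rows.append(
            {
                "name": v.drug.name,
                "target_gene": v.drug.target_gene,
                "mechanism": v.drug.mechanism,
                "status": v.drug.status,
                "drug_filter": "pass" if v.retained else "fail",
                "drug_filter_reason": v.reason,
                "adme": "" if av is None else ("pass" if av.passed else "fail"),
                "adme_failed_rules": ""
                if av is None
                else ",".join(sorted(k for k, ok in av.rules.items() if not ok)),
            }
        )
    _write_tsv(
        path, rows, build=None,
        cols=[
            "name", "target_gene", "mechanism", "status", "drug_filter",
            "drug_filter_reason", "adme", "adme_failed_rules",
        ],
    )
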