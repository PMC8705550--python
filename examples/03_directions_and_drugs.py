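"""Direction-of-effect calls and direction-consistent drug selection.

A risk allele that raises brain expression of its target calls for an
inhibitor; one that lowers it calls for an activator. Drugs whose
mechanism contradicts the required modulation are removed before the
ADME gate.
"""

from oxiscore import (
    AdmeProfile,
    DrugRecord,
    GwasHit,
    QtlRecord,
    Variant,
    adme_gate,
    call_directions,
    filter_drugs,
)
from oxiscore.target_mapper import Evidence, GeneTarget

v = Variant(chrom="22", pos=21_800_000, allele_a="A", allele_b="G", rsid="rs1001")
hit = GwasHit(variant=v, risk_allele="G", p_value=1e-9, odds_ratio=1.3)
# the risk allele G lowers MAPK1 expression in brain (effect allele G, sign -1)
qtl = QtlRecord(variant=v, effect_allele="G", gene="MAPK1", qtl_type="eQTL",
                tissue="brain", effect_sign=-1)
target = GeneTarget(gene="MAPK1", evidences=[
    Evidence(gene="MAPK1", hit=hit, via_variant=v, kind="qtl:eQTL:brain",
             ld_to_hit=1.0, qtl_ref=qtl)])

(call,) = call_directions([target])
print(f"{call.gene}: risk allele {call.coupled_allele} direction "
      f"{call.direction:+d} -> required modulation: {call.modulation}")

drugs = [
    DrugRecord("PEITC", "MAPK1", "activate", "phase2", 0.9, True, False, "SuperTarget"),
    DrugRecord("MK8353", "MAPK1", "inhibit", "phase1", 0.9, True, False, "DGIdb"),
    DrugRecord("LY3214996", "MAPK1", "inhibit", "phase1", 0.9, True, False, "DGIdb"),
]
kept = filter_drugs(drugs, prioritized_genes=["MAPK1"], directions=[call])
print("after direction-consistency filter:", [d.name for d in kept])
for verdict in kept.verdicts:
    if not verdict.retained:
        print(f"  removed {verdict.drug.name}: {verdict.reason}")

profiles = [AdmeProfile("PEITC", cns_activity=1, log_bb=0.1, mdck_perm=900,
                        caco2_perm=700, human_oral_absorption=3,
                        pct_human_absorption=95)]
survivors, verdicts = adme_gate(kept.retained, profiles)
print("after ADME gate (CNS + oral bioavailability):", [d.name for d in survivors])
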