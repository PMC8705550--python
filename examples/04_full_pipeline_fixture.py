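"""The complete funnel on the curated MS/oxidative-stress bundle.

Builds the demonstration bundle encoding the known name-level result
lists, runs every stage, and prints the funnel: targets -> pathway
overlap -> prioritized -> drug candidates -> ADME survivors.
"""

import tempfile
from pathlib import Path

from oxiscore import PipelineConfig, build_reference_fixture, run_pipeline

with tempfile.TemporaryDirectory() as work:
    paths, truth = build_reference_fixture(Path(work) / "bundle", seed=0)
    report = run_pipeline(PipelineConfig(
        gwas=paths["gwas"], qtls=paths["qtls"], consequences=paths["consequences"],
        panel=paths["panel"], pathways=paths["pathways"], drugs=paths["drugs"],
        adme=paths["adme"], out_dir=str(Path(work) / "out"),
    ))

c = report.counts
print("disease gene targets:          ", c["gene_targets"])
print("in oxidative-stress pathways:  ", c["shared_targets"])
print("prioritized (top 25% by score):", c["prioritized_targets"])
print("brain direction calls:         ", c["direction_calls"])
print("repurposable candidates:       ", c["repurposable_candidates"])
print("  after drug-selection filter: ", c["repurposable_after_drug_filter"])
print("  after ADME gate:             ", c["repurposable_after_adme"],
      f"(over {c['repurposable_targets_after_adme']} targets)")
print("experimental candidates:       ", c["experimental_candidates"])
print("  after ADME gate:             ", c["experimental_after_adme"])
# 10 repurposable drugs over 5 targets and 7 experimental compounds
# survive; the two MAPK1 inhibitors fall to the direction filter.
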