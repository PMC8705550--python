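# oxiscore

Genetics-driven target prioritization and drug repositioning for
oxidative-stress (OS) pathways in multiple sclerosis (MS) — as a reusable,
testable pipeline.

Unchecked oxidative stress drives the neurodegenerative component of MS, yet
antioxidant therapies chosen without genetic support have repeatedly failed
in the clinic. This package implements the in-silico route from disease
genetics to candidate drugs: GWAS index variants are expanded to their
linkage-disequilibrium (LD) proxies in a genotype reference panel, mapped to
gene targets through molecular QTLs (eQTL, pQTL, sQTL, polyQTL, mQTL) and
deleterious coding annotations, intersected with OS pathway membership,
ranked by a five-criterion genetic score, and matched to drugs whose
mechanism agrees with the *direction* the risk allele pushes the target in
brain — finally gated by ADME rules for CNS penetration and oral
bioavailability. It is written for computational geneticists and drug
repositioning groups who want this logic on their own hit tables and
catalogues rather than behind one-off database queries.

## The model

**LD and allele coupling.** For two biallelic loci with haplotype frequency
p_AB and allele frequencies p_A, p_B, the package estimates haplotype
frequencies from unphased genotypes by EM (the double heterozygote is the
only ambiguous genotype) and reports

    D = p_AB − p_A·p_B,   D′ = D / D_max,   r² = D² / (p_A(1−p_A) p_B(1−p_B))

plus the *coupled allele*: the allele of the second variant riding on the
same haplotype as a given allele of the first (the sign of D). Proxies are
panel variants with r² > 0.7 to an index variant.

**Direction of effect.** The disease risk allele is carried to the QTL
variant through the coupling; if it lands on the QTL effect allele the risk
allele moves the molecular trait with the QTL's sign, otherwise against it.
Risk allele raises the product → the therapeutic instruction is *inhibit*;
lowers it → *activate*.

**Prioritization score** (sum over five criteria, awarded by the best
qualifying variant collected for the gene; maximum 32):

| criterion | points |
|---|---|
| hit with p < 5×10⁻⁸ (outside MHC / inside MHC) | 5 / 2 |
| hit with OR > 1.2, by LD to a gene-level QTL: ≥0.99 / [0.95,0.99) / [0.90,0.95) / [0.80,0.90) | 4 / 3 / 2 / 1 |
| eQTL available (+5 if in brain) | 10 (+5) |
| LD between hit and eQTL: ≥0.99 / [0.95,0.99) / [0.90,0.95) / [0.80,0.90) | 5 / 3 / 2 / 1 |
| non-eQTL QTL with LD ≥ 0.99 to the hit | 3 |

The top 25% of targets by total are prioritized (ties at the boundary are
kept, and the realized threshold is reported). Drugs for prioritized targets
must be approved or in clinical trials (an experimental track is kept
separately), have credible interaction evidence (direct action, database
interaction score > 0.50, or validated transcriptional modulation) and a
mechanism consistent with the brain direction call when one exists; ADME
gating then requires CNS activity ≥ 0, logBB in [−1.0, 1.2], MDCK and Caco2
apparent permeability ≥ 100 nm/s, high human oral absorption, and percent
absorption ≥ 80.

## Worked example

`examples/04_full_pipeline_fixture.py` builds the curated demonstration
bundle — the known name-level MS/OS result lists plus synthetic placeholder
rows for unnamed entries — and runs every stage:

```
disease gene targets:           85
in oxidative-stress pathways:   85
prioritized (top 25% by score): 21
brain direction calls:          10
repurposable candidates:        35
  after drug-selection filter:  33
  after ADME gate:              10 (over 5 targets)
experimental candidates:        15
  after ADME gate:              7
```

Reading the funnel: 85 OS-pathway gene targets are scored and 21 survive the
top-quantile cut; ten genes have a resolvable brain direction (seven
up-regulated by the risk allele → inhibit, three down-regulated → activate);
of 35 repurposable candidate drugs, two MAPK1 inhibitors (MK8353,
LY3214996) fall to the direction-consistency rule — MAPK1 must be
*activated* — and the ADME gate leaves ten drugs over five targets
(CARM1, MAPK1, CDK4, STAT3, FOS) plus seven experimental compounds (three
CARM1 inhibitors, four NR1D1 modulators).

The other examples are smaller, single-capability walkthroughs: LD/proxy
expansion (`01`), target mapping and scoring (`02`), direction calls and
drug filtering (`03`).

A thin CLI wraps the same library calls:

```bash
oxiscore fixture --out bundle/          # write the demonstration bundle
oxiscore run --config pipeline.yaml     # run the full pipeline
oxiscore ld --panel bundle/panel.tsv --var-a rs000001 --var-b rs000002
oxiscore adme-gate --adme bundle/adme.tsv
```

## Layout

- `src/oxiscore/core_model.py` — domain types, TSV/GMT/VCF readers and writers, genomic conventions (MHC interval, consequence-severity order)
- `src/oxiscore/ld_engine.py` — EM haplotype frequencies, D/D′/r², allele coupling, proxy expansion
- `src/oxiscore/target_mapper.py` — hits + proxies + QTLs + annotations → gene targets with evidence trails
- `src/oxiscore/direction_engine.py` — risk-allele coupling → inhibit/activate calls per tissue
- `src/oxiscore/prioritizer.py` — pathway overlap, five-criterion score, top-quantile selection
- `src/oxiscore/drug_adme.py` — drug-selection rules and the ADME gate
- `src/oxiscore/synthetic_data.py` — bundle generator with planted ground truth; curated demonstration bundle
- `src/oxiscore/pipeline.py`, `cli.py` — orchestration, run report, thin CLI

See `docs/methods.md` for the modelling choices, defaults and limitations.
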