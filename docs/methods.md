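# Methods

This note records the models, conventions and design choices behind
oxiscore, in the order the pipeline applies them.

## Coordinates, identities, conventions

All genomic coordinates are 1-based on a single build (GRCh37 by
convention). Table files may declare their build in a `#build=` header
comment; the pipeline requires all declared builds to agree and treats a
mismatch as a hard error — coordinate liftover is deliberately out of
scope. Genes are identified by uppercased symbol strings; alias resolution
is not attempted because every list the pipeline consumes and produces is
symbol-level. Variants are joined across tables by position and allele pair
(rsIDs are display labels only). The MHC is the closed interval
chr6:27,000,000–33,000,000; boundary membership is a convention this
package fixes, since "27–33 Mb" does not state it. Consequence severity
follows the standard variant-consequence ontology ordering embedded in
`core_model.CONSEQUENCE_SEVERITY_ORDER` (most severe first); "missense or
more deleterious" means rank ≤ rank(missense_variant), and the functional
filter additionally requires CADD-Phred strictly above 15.

GWAS intake keeps index variants with p < 1×10⁻⁵ and counts what it drops.
The gate is applied uniformly to all studies; whether sub-genome-wide hits
should be study-specific is not decidable from symbol-level inputs, so the
uniform gate is the contract.

## Two-locus EM and LD

Haplotype frequencies for a variant pair are estimated from the 3×3 joint
genotype table by EM under random union of gametes. Every genotype pair
except the double heterozygote contributes its two gametes deterministically;
the double-het count is split between cis (AB/ab) and trans (Ab/aB) phase in
proportion to their current expected products. Numerical contract:

- **Initialisation** at linkage equilibrium (product of observed allele
  frequencies). This is deterministic and keeps observed allele frequencies
  fixed through every iteration (they are the MLE for this model).
- **Convergence** when the largest frequency change falls below 1e-10, or
  after 1000 iterations. The log-likelihood is non-decreasing per iteration
  (property-tested). A small family of flat-likelihood tables converges
  sublinearly and stops at the iteration cap within ~1e-5 log-likelihood
  units of the optimum; the oracle-agreement suite therefore compares
  likelihoods at 1e-4 and frequencies at 1e-3.
- **Monomorphic loci** make every LD statistic undefined; this is flagged
  (`undefined`), never raised.
- **Phase degeneracy**: when double heterozygotes are present and the
  converged cis and trans products are equal (the symmetric fixed point,
  e.g. an all-double-het table), the coupling cannot be oriented. The
  result is flagged `degenerate`, no coupled-allele map is emitted, and
  direction calling skips such pairs. The symmetric fixed point is *not*
  the likelihood maximum of such tables; accepting it (rather than breaking
  the tie arbitrarily) keeps the estimator deterministic and honest about
  unidentifiable phase.

From converged frequencies: D = p_AB − p_A·p_B, D′ = D/D_max, r² =
D²/(p_A(1−p_A)p_B(1−p_B)). The coupled-allele map follows the sign of D
and is a bijection between the two variants' alleles. Missing genotypes are
deleted pairwise and the retained sample count reported (`n_eff`).

Proxy expansion returns, for each index variant, itself at r² = 1 plus all
panel variants within a window whose r² *strictly* exceeds the threshold
(default 0.7). The window default is 1 Mb — the source procedure does not
state a window; 1 Mb matches common proxy-search practice and bounds
compute — and is configurable.

An independent oracle for the EM exists in the test suite: the profile
multinomial likelihood is a function of the single free cis-haplotype
frequency once allele frequencies are fixed at their observed values, and a
dense grid search maximises it directly. The EM agrees with this oracle on
all 3×3 tables with total ≤ 7 (exhaustive) and on seeded larger tables.

## Target mapping and MHC handling

A gene becomes a target when a hit or one of its proxies is a QTL for it
(any of eQTL, pQTL, sQTL, polyQTL, mQTL) or tags it through a filtered
coding annotation. Each link is kept as evidence carrying the hit, the
mediating variant and its LD to the hit. Two MHC statements are reconciled
as follows: genes on a configurable MHC gene list are excluded outright;
genes whose evidence lies entirely inside the MHC interval are excluded;
but MHC-located variants remain usable evidence for genes outside the
region and are down-weighted by the score (criterion 1 awards 2 instead of
5). A gene supported only by a consequence record is still a target.

## Direction of effect

The risk allele is carried to the QTL variant through the coupled-allele
map (identity when hit and QTL share a variant). Landing on the effect
allele gives the QTL's sign; otherwise the negated sign. Direction +1
(risk allele raises the product) maps to *inhibit*, −1 to *activate* —
swapping the QTL record's allele labels (effect allele ↔ other, sign
negated) leaves calls invariant, which is property-tested.

Directions are called per tissue, and only the configured tissue (default
"brain") feeds drug selection. Two design choices here were genuinely open:

- **QTL types.** Only expression- and protein-level QTLs (eQTL, pQTL)
  orient modulation by default. Splicing, polyadenylation and methylation
  QTLs describe transcript form or regulatory state rather than product
  abundance, so their sign does not translate into an inhibit/activate
  instruction; they still support targets and criterion 5. Configurable via
  `direction_qtl_types`.
- **Conflicts.** Evidence is ranked by LD to the hit, then eQTL before
  other types, then variant label — deterministic, favouring the evidence
  class the score itself privileges. If equally-ranked evidence disagrees
  on sign, the call is emitted with a `conflict` flag and drug matching
  ignores it, making unresolvable cases explicit instead of guessing.

## Score and selection

Per criterion the maximum applicable value over the gene's collected
variants is awarded ("met by at least one variant", realised with the best
qualifying evidence). LD bins are half-open `[lo, hi)` with the top bin
closed at ≥ 0.99 — the printed ranges do not state boundary membership, so
the package fixes lower-inclusive bins. Odds ratios are used as reported on
the risk-allele scale, without folding protective effects. Criterion 2
ranges over all QTL types while criterion 4 ranges over eQTLs only; the
same proxy can therefore legitimately contribute to both. The total is
bounded by 32 = 5+4+15+5+3 and is monotone: adding evidence or raising any
evidence LD never lowers it (property-tested).

Selection keeps the top floor(0.25·N) targets by total, extended to include
all ties with the boundary score, and reports the realized threshold for
comparability with a fixed score cut. For N < 4 the floor would be zero; at
least one target is always retained. The quantile, not the threshold, is
the primary selector.

## Drug selection and ADME gate

A drug survives iff its target is prioritized, its status is allowed for
the track (approved/phase 1–3 on the repurposable track; experimental
compounds are reported separately), its interaction evidence is credible
(direct action, interaction score strictly above 0.50, or validated
transcriptional modulation), and — when an unconflicted brain direction
call exists for the target — its mechanism equals the required modulation.
The filter is idempotent and order-independent.

The ADME gate evaluates six rules, always reporting per-rule verdicts:
CNS activity ≥ 0; logBB within [−1.0, 1.2]; MDCK ≥ 100 nm/s; Caco2 ≥ 100
nm/s; human oral absorption at the highest qualitative class (3); percent
human absorption ≥ 80. The source criteria are qualitative ("medium–good",
"high"); the numeric realizations follow the descriptor tool's published
poor/medium/great conventions (permeability < 25 poor, > 500 great; logBB
range −3..1.2) and every one is configurable. A missing descriptor fails
its rule with reason "missing". Tightening any threshold can only shrink
the pass set (property-tested).

## Synthetic data and the demonstration bundle

The generator emits all seven inputs from a declarative plan and computes
ground truth (targets, directions, scores, selection, drug survivors) by a
straight-line restatement of the rules that deliberately shares no code
with the pipeline modules.

Panel construction plants variants at allele frequency 0.5. A hit/proxy
pair is a two-locus haplotype block with exactly f discordant haplotypes
among 2n, giving haplotype r = 1 − f/n. Diploids are formed by random
haplotype pairing for generic panels; inside bundles, *balanced* pairing
mates identical haplotypes so the planted pair has no double heterozygotes.
With nothing for the EM phase step to resolve, genotype-level r² equals the
haplotype-pool value exactly — this is what makes parameter recovery exact,
including the LD-bin-sensitive score criteria, rather than merely close.
The realized (not requested) r² is stored in the ground truth and is what
the oracle bins, so generator and pipeline always see the same number.
Allele orientations (which allele is the risk allele, which the effect
allele) are randomised per seed, with effect signs set so the realized
risk-allele direction equals the planted one. Defaults: 400 diploid
samples (600 in the recovery suite), one GWAS hit per planted gene, blocks
spaced 3 Mb apart so proxy windows never overlap.

What the generator does **not** emulate: realistic allele-frequency
spectra, multi-variant LD decay, population structure, overlapping loci,
multi-hit genes, or the external-database scale of a real analysis
(hundreds of hits, thousands of targets). Passing recovery tests therefore
demonstrates the correctness of the pipeline's logic under clean, planted
conditions — not robustness to the noise and redundancy of real catalogues.

The curated demonstration bundle encodes the known name-level MS/OS result
lists exactly — the 18 brain-QTL-supported targets, the ten brain direction
calls (seven up, three down), the ten repurposable drugs over five targets,
the seven surviving experimental compounds, and the two MAPK1 inhibitors
removed for direction inconsistency — and fills the unnamed remainder of
the funnel (85 targets, 21 prioritized, 35 repurposable and 15 experimental
candidates) with clearly-labelled synthetic placeholders (`OSTOP`/`OSDECOY`
genes, `DBFILL`/`EXPFILL` compounds) whose planted scores and ADME profiles
put them on the intended side of each gate. One bookkeeping discrepancy in
the source counts (35 database drugs + 5 + 11 experimental compounds = 51
named, against a stated final list of 50 split 35 + 15) is resolved in
favour of the 35 + 15 accounting.

## Known limitations

- Biallelic autosomal variants only; no X-chromosome ploidy handling, no
  phased input, no multi-allelic sites.
- Direction calling assumes a single causal orientation per (gene, tissue);
  colocalization testing and multi-tissue meta-analysis are out of scope.
- The EM iteration cap (1000) leaves rare flat-likelihood tables a hair
  short of the optimum (see above); raise `max_iter` where exactness at
  the 1e-10 level matters.
- Enrichment analysis, live database clients, liftover and descriptor
  prediction are out of scope by design; all external resources enter as
  files.
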