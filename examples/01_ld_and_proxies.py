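"""Two-locus LD from unphased genotypes, and proxy expansion.

Builds a small simulated reference panel with a planted haplotype block,
estimates haplotype frequencies by EM, and expands a GWAS index variant
to its LD proxies.
"""

from oxiscore import GwasHit, em_haplotype_freqs, expand_proxies, ld_pair
from oxiscore.synthetic_data import GeneratorConfig, LDBlock, simulate_panel

# a 3x3 joint genotype table (rows: copies of the counted allele at locus
# 1; columns: locus 2) with phase ambiguity in the double-het cell
counts = [[20, 3, 0], [4, 10, 2], [0, 5, 16]]
em = em_haplotype_freqs(counts)
print("haplotype frequencies (0/0, 0/1, 1/0, 1/1):",
      [round(float(f), 4) for f in em.freqs.ravel()])
print(f"converged in {em.n_iter} iterations, log-likelihood {em.log_likelihood:.3f}")

# a panel with a planted block: two proxies at r^2 ~ 0.95 and ~ 0.5
cfg = GeneratorConfig(seed=11, n_samples=1000, n_noise_loci=2,
                      blocks=(LDBlock(size=3, target_r2=(0.95, 0.5)),))
panel = simulate_panel(cfg)
lead, near, far = panel.variants[:3]

pair = ld_pair(panel, lead, near)
print(f"\n{lead.label} vs {near.label}: r2={pair.r2:.3f}  D'={pair.d_prime:.3f} "
      f"coupled={pair.coupled}")

hit = GwasHit(variant=lead, risk_allele=lead.allele_b, p_value=1e-9, odds_ratio=1.3)
proxies = expand_proxies(panel, [hit], r2_min=0.7)[hit]
print(f"proxies of {lead.label} at r2 > 0.7:",
      [(v.label, round(r2, 3)) for v, r2 in proxies])
# the r^2 ~ 0.5 variant is excluded: it no longer carries the same signal
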