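"""EM haplotype estimation and LD statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxiscore.core_model import GwasHit, Variant
from oxiscore.ld_engine import em_haplotype_freqs, expand_proxies, ld_pair
from oxiscore.synthetic_data import GeneratorConfig, LDBlock, simulate_panel
from conftest import grid_oracle, make_panel


def table(strategy_total=30):
    return st.lists(st.integers(0, 6), min_size=9, max_size=9).map(
        lambda xs: np.array(xs).reshape(3, 3)
    ).filter(lambda t: t.sum() >= 1)


class TestEm:
    def test_no_double_hets_is_closed_form_gamete_counting(self):
        n = np.array([[3, 1, 0], [2, 0, 1], [0, 2, 4]])
        r = em_haplotype_freqs(n)
        two_n = 2 * n.sum()
        expected = np.array(
            [
                [2 * n[0, 0] + n[1, 0] + n[0, 1], 2 * n[0, 2] + n[1, 2] + n[0, 1]],
                [2 * n[2, 0] + n[2, 1] + n[1, 0], 2 * n[2, 2] + n[2, 1] + n[1, 2]],
            ]
        ) / two_n
        assert np.allclose(r.freqs, expected, atol=1e-12)
        assert not r.degenerate

    def test_all_double_het_symmetric_fixed_point_flagged(self):
        r = em_haplotype_freqs([[0, 0, 0], [0, 10, 0], [0, 0, 0]])
        assert np.allclose(r.freqs, 0.25)
        assert r.degenerate

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.multinomial(25, rng.dirichlet(np.ones(9))).reshape(3, 3)
            r = em_haplotype_freqs(n)
            assert abs(r.freqs.sum() - 1.0) < 1e-12

    def test_random_20_sample_table_matches_grid_search(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 10:
            n = rng.multinomial(20, rng.dirichlet(np.ones(9))).reshape(3, 3)
            r = em_haplotype_freqs(n)
            if r.undefined or r.degenerate:
                continue
            p11, ll = grid_oracle(n, res=20001)
            assert r.freqs[1, 1] == pytest.approx(p11, abs=1e-4)
            assert r.log_likelihood >= ll - 1e-6
            checked += 1

    def test_monomorphic_locus_is_undefined_not_error(self):
        r = em_haplotype_freqs([[5, 3, 2], [0, 0, 0], [0, 0, 0]])
        assert r.undefined

    @settings(max_examples=200, derandomize=True)
    @given(table())
    def test_loglik_monotone_non_decreasing(self, n):
        r = em_haplotype_freqs(n)
        trace = r.loglik_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))


class TestLdPair:
    def test_identical_columns_perfect_ld(self):
        panel = make_panel([[0, 1, 2, 1, 0, 2], [0, 1, 2, 1, 0, 2]])
        pair = ld_pair(panel, panel.variants[0], panel.variants[1])
        assert pair.r2 == pytest.approx(1.0, abs=1e-9)
        assert pair.coupled["G"] == "G" and pair.coupled["A"] == "A"

    def test_r2_symmetric_in_argument_order(self):
        panel = make_panel([[0, 1, 2, 1, 0, 2, 1, 1], [0, 1, 1, 1, 0, 2, 0, 1]])
        a, b = panel.variants
        assert ld_pair(panel, a, b).r2 == pytest.approx(ld_pair(panel, b, a).r2, abs=1e-12)

    def test_allele_label_swap_flips_d_preserves_r2_and_coupling(self):
        geno = [[0, 1, 2, 1, 0, 2, 1, 1], [0, 1, 1, 1, 0, 2, 0, 1]]
        panel = make_panel(geno)
        pair = ld_pair(panel, panel.variants[0], panel.variants[1])

        # swap the labels at the second locus: counts flip 0<->2, 1 stays
        swapped = [geno[0], [2 - g for g in geno[1]]]
        panel2 = make_panel(swapped)
        # rebuild second variant with swapped allele labels
        v1 = panel2.variants[1]
        pair2 = ld_pair(panel2, panel2.variants[0], v1)
        assert pair2.r2 == pytest.approx(pair.r2, abs=1e-9)
        assert pair2.d == pytest.approx(-pair.d, abs=1e-9)
        # the counted allele at locus 2 is now the former other allele, so
        # the coupling in terms of genotype codes flips while the physical
        # phase is unchanged: coupled[G at locus 1] moves from G to A
        assert pair.coupled["G"] == "G" and pair2.coupled["G"] == "A"

    def test_hand_built_6_sample_panel_matches_oracle(self):
        geno = [[2, 2, 1, 1, 0, 0], [2, 1, 1, 0, 1, 0]]
        panel = make_panel(geno)
        pair = ld_pair(panel, panel.variants[0], panel.variants[1])
        counts = np.zeros((3, 3), dtype=int)
        for a, b in zip(*geno):
            counts[a, b] += 1
        p11, _ = grid_oracle(counts, res=200001)
        pa = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * counts.sum())
        pb = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * counts.sum())
        d = p11 - pa * pb
        r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
        assert pair.r2 == pytest.approx(r2, abs=1e-4)

    def test_independent_loci_have_near_zero_r2(self):
        cfg = GeneratorConfig(seed=7, n_samples=2000, n_noise_loci=0,
                              blocks=(LDBlock(size=2, target_r2=(0.0,)),))
        panel = simulate_panel(cfg)
        pair = ld_pair(panel, panel.variants[0], panel.variants[1])
        assert pair.r2 < 0.01

    def test_monomorphic_variant_propagates_undefined(self):
        panel = make_panel([[1, 1, 2, 0], [0, 0, 0, 0]])
        pair = ld_pair(panel, panel.variants[0], panel.variants[1])
        assert pair.undefined and pair.coupled is None

    def test_pairwise_deletion_recorded_in_n_eff(self):
        panel = make_panel([[0, 1, -1, 2], [0, -1, 1, 2]])
        pair = ld_pair(panel, panel.variants[0], panel.variants[1])
        assert pair.n_eff == 2


class TestExpandProxies:
    def _hit(self, variant):
        return GwasHit(variant=variant, risk_allele=variant.allele_b,
                       p_value=1e-9, odds_ratio=1.3)

    def test_no_neighbours_above_threshold_keeps_self_only(self):
        panel = make_panel([[0, 1, 2, 1, 0, 2], [1, 0, 1, 2, 2, 0]])
        hit = self._hit(panel.variants[0])
        out = expand_proxies(panel, [hit])
        assert out[hit] == [(panel.variants[0], 1.0)]

    def test_threshold_is_strict(self):
        panel = make_panel([[0, 1, 2, 1, 0, 2, 1, 1], [0, 1, 1, 1, 0, 2, 1, 1]])
        a, b = panel.variants
        r2 = ld_pair(panel, a, b).r2
        hit = self._hit(a)
        at = expand_proxies(panel, [hit], r2_min=r2)
        assert all(v.pos_key != b.pos_key for v, _ in at[hit])
        below = expand_proxies(panel, [hit], r2_min=r2 - 1e-9)
        assert any(v.pos_key == b.pos_key for v, _ in below[hit])

    def test_planted_block_recovers_strong_proxies_only(self):
        cfg = GeneratorConfig(
            seed=5, n_samples=2000, n_noise_loci=0,
            blocks=(LDBlock(size=4, target_r2=(0.95, 0.8, 0.5)),),
        )
        panel = simulate_panel(cfg)
        hit = self._hit(panel.variants[0])
        proxies = expand_proxies(panel, [hit], r2_min=0.7)[hit]
        keys = {v.pos_key for v, _ in proxies}
        assert panel.variants[1].pos_key in keys
        assert panel.variants[2].pos_key in keys
        assert panel.variants[3].pos_key not in keys

    def test_sorted_by_descending_r2(self):
        cfg = GeneratorConfig(
            seed=5, n_samples=1000, n_noise_loci=0,
            blocks=(LDBlock(size=3, target_r2=(0.8, 0.95)),),
        )
        panel = simulate_panel(cfg)
        hit = self._hit(panel.variants[0])
        proxies = expand_proxies(panel, [hit], r2_min=0.5)[hit]
        r2s = [r for _, r in proxies]
        assert r2s == sorted(r2s, reverse=True)
        assert proxies[0][0].pos_key == hit.variant.pos_key

    def test_hit_absent_from_panel_warns_and_keeps_self(self):
        panel = make_panel([[0, 1, 2, 1]])
        stray = Variant(chrom="9", pos=123, allele_a="A", allele_b="G")
        hit = self._hit(stray)
        with pytest.warns(UserWarning, match="absent from reference panel"):
            out = expand_proxies(panel, [hit])
        assert out[hit] == [(stray, 1.0)]

    def test_invalid_threshold_rejected(self):
        panel = make_panel([[0, 1, 2, 1]])
        with pytest.raises(ValueError):
            expand_proxies(panel, [], r2_min=0.0)
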