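"""Pathway overlap, five-criterion scoring and top-quantile selection."""

import pytest
from hypothesis import given, settings, strategies as st

from oxiscore.core_model import GwasHit, PathwaySet, QtlRecord, Variant
from oxiscore.prioritizer import (
    ScoreConfig,
    TargetScore,
    overlap_targets,
    score_target,
    select_top,
)
from oxiscore.target_mapper import Evidence, GeneTarget


def var(pos=1_000_000, chrom="1"):
    return Variant(chrom=chrom, pos=pos, allele_a="A", allele_b="G")


def make_target(gene="GENE1", hit_p=1e-9, hit_or=1.3, hit_in_mhc=False,
                qtl_specs=(), consequence_only=False):
    """qtl_specs: iterable of (qtl_type, tissue, ld)."""
    v = var(pos=28_000_000, chrom="6") if hit_in_mhc else var()
    h = GwasHit(variant=v, risk_allele="G", p_value=hit_p, odds_ratio=hit_or)
    evs = []
    for qtl_type, tissue, ld in qtl_specs:
        q = QtlRecord(variant=v, effect_allele="G", gene=gene,
                      qtl_type=qtl_type, tissue=tissue, effect_sign=1)
        evs.append(Evidence(gene=gene, hit=h, via_variant=v,
                            kind=f"qtl:{qtl_type}:{tissue}", ld_to_hit=ld, qtl_ref=q))
    if consequence_only or not evs:
        from oxiscore.core_model import ConsequenceRecord

        c = ConsequenceRecord(variant=v, gene=gene,
                              consequence_class="missense_variant", cadd_phred=22)
        evs.append(Evidence(gene=gene, hit=h, via_variant=v, kind="consequence",
                            ld_to_hit=1.0, consequence_ref=c))
    return GeneTarget(gene=gene, evidences=evs)


class TestOverlap:
    def test_gene_in_no_pathway_dropped(self):
        t = make_target("LONELY")
        assert overlap_targets([t], [PathwaySet("OS1", frozenset({"OTHER"}))]) == []

    def test_shared_gene_retained(self):
        t = make_target("KEAP1")
        kept = overlap_targets([t], [PathwaySet("OS1", frozenset({"KEAP1", "HDAC1"}))])
        assert [x.gene for x in kept] == ["KEAP1"]

    def test_hand_counted_overlap(self):
        targets = [make_target(f"G{i}") for i in range(7)]
        pathways = [PathwaySet("OS1", frozenset({"G0", "G3"})),
                    PathwaySet("OS2", frozenset({"G5", "NOT_A_TARGET"}))]
        kept = overlap_targets(targets, pathways)
        assert sorted(t.gene for t in kept) == ["G0", "G3", "G5"]


class TestScoreTarget:
    def test_maximal_evidence_reaches_32(self):
        t = make_target(
            hit_p=1e-9, hit_or=1.3,
            qtl_specs=[("eQTL", "brain", 1.0), ("pQTL", "brain", 1.0)],
        )
        s = score_target(t)
        assert s.as_tuple() == (5, 4, 15, 5, 3)
        assert s.total == 32

    def test_mhc_hit_consequence_only_scores_2(self):
        t = make_target(hit_p=1e-10, hit_in_mhc=True, consequence_only=True)
        s = score_target(t)
        assert s.as_tuple() == (2, 0, 0, 0, 0)
        assert s.total == 2

    def test_nonbrain_eqtl_mid_ld_weak_or(self):
        t = make_target(hit_p=1e-9, hit_or=1.1, qtl_specs=[("eQTL", "blood", 0.96)])
        s = score_target(t)
        assert s.as_tuple() == (5, 0, 10, 3, 0)

    @pytest.mark.parametrize(
        "ld,expected_c2,expected_c4",
        [
            (1.0, 4, 5),
            (0.99, 4, 5),     # top bin closed at 0.99
            (0.989, 3, 3),
            (0.95, 3, 3),     # half-open lower bound included
            (0.949, 2, 2),
            (0.90, 2, 2),
            (0.899, 1, 1),
            (0.80, 1, 1),
            (0.799, 0, 0),
        ],
    )
    def test_ld_bin_boundaries(self, ld, expected_c2, expected_c4):
        t = make_target(hit_or=1.3, qtl_specs=[("eQTL", "brain", ld)])
        s = score_target(t)
        assert s.c2 == expected_c2
        assert s.c4 == expected_c4

    def test_c5_requires_near_perfect_ld_and_non_expression_qtl(self):
        near = make_target(qtl_specs=[("pQTL", "blood", 0.99)])
        far = make_target(qtl_specs=[("pQTL", "blood", 0.98)])
        eqtl = make_target(qtl_specs=[("eQTL", "blood", 1.0)])
        assert score_target(near).c5 == 3
        assert score_target(far).c5 == 0
        assert score_target(eqtl).c5 == 0

    def test_brain_bonus_needs_eqtl_not_other_brain_qtl(self):
        t = make_target(qtl_specs=[("sQTL", "brain", 1.0), ("eQTL", "blood", 1.0)])
        assert score_target(t).c3 == 10

    def test_or_below_threshold_zeroes_c2_only(self):
        t = make_target(hit_or=1.2, qtl_specs=[("eQTL", "brain", 1.0)])  # strict
        s = score_target(t)
        assert s.c2 == 0 and s.c4 == 5

    @settings(max_examples=100, derandomize=True)
    @given(
        p=st.sampled_from([1e-9, 1e-6]),
        odds=st.sampled_from([1.1, 1.3]),
        mhc=st.booleans(),
        specs=st.lists(
            st.tuples(
                st.sampled_from(["eQTL", "pQTL", "sQTL", "mQTL", "polyQTL"]),
                st.sampled_from(["brain", "blood"]),
                st.floats(0.05, 1.0),
            ),
            max_size=4,
        ),
        extra_ld=st.floats(0.05, 1.0),
    )
    def test_score_monotone_under_more_and_stronger_evidence(
        self, p, odds, mhc, specs, extra_ld
    ):
        base = make_target(hit_p=p, hit_or=odds, hit_in_mhc=mhc, qtl_specs=specs)
        total = score_target(base).total
        assert 0 <= total <= 32

        if specs:
            # raising any evidence LD never decreases the total
            boosted_specs = [(t, ti, min(1.0, ld + 0.05)) for t, ti, ld in specs]
            boosted = make_target(hit_p=p, hit_or=odds, hit_in_mhc=mhc,
                                  qtl_specs=boosted_specs)
            assert score_target(boosted).total >= total

        # adding evidence never decreases the total
        widened = make_target(hit_p=p, hit_or=odds, hit_in_mhc=mhc,
                              qtl_specs=list(specs) + [("eQTL", "brain", extra_ld)])
        assert score_target(widened).total >= total

    def test_partials_within_declared_sets(self):
        t = make_target(qtl_specs=[("eQTL", "brain", 0.93), ("mQTL", "brain", 1.0)])
        s = score_target(t)
        assert s.c1 in {0, 2, 5} and s.c2 in range(5) and s.c3 in {0, 10, 15}
        assert s.c4 in {0, 1, 2, 3, 5} and s.c5 in {0, 3}


def ts(gene, total):
    """TargetScore with the given total, greedily packed into partials."""
    c3 = 15 if total >= 15 else (10 if total >= 10 else 0)
    rem = total - c3
    c1 = 5 if rem >= 5 else (2 if rem == 2 else 0)
    rem -= c1
    c4 = 5 if rem >= 5 else (rem if rem in (1, 2, 3) else 0)
    rem -= c4
    c5 = 3 if rem >= 3 else 0
    rem -= c5
    assert rem in range(5), f"cannot encode total {total}"
    return TargetScore(gene=gene, c1=c1, c2=rem, c3=c3, c4=c4, c5=c5)


class TestSelectTop:
    def test_85_targets_give_21_before_tie_extension(self):
        scores = [ts(f"G{i:03d}", 25 - (i % 2)) for i in range(21)]
        scores += [ts(f"H{i:03d}", 10) for i in range(64)]
        sel = select_top(scores)
        assert sel.n_quantile == 21
        assert len(sel.selected) == 21

    def test_equal_totals_all_retained_by_tie_extension(self):
        scores = [ts(f"G{i}", 15) for i in range(4)]
        sel = select_top(scores)
        assert len(sel.selected) == 4
        assert sel.threshold == 15

    def test_eight_distinct_totals_keep_exactly_two(self):
        scores = [ts(f"G{i}", t) for i, t in enumerate([22, 20, 18, 17, 15, 12, 10, 5])]
        sel = select_top(scores)
        assert [s.gene for s in sel.selected] == ["G0", "G1"]

    def test_tiny_input_keeps_at_least_one(self):
        sel = select_top([ts("G1", 12), ts("G2", 10)])
        assert [s.gene for s in sel.selected] == ["G1"]

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            select_top([])
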