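"""Anchor chaining DP, block significance, and layer classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from karyoevo.collinearity import (
    Anchor,
    Background,
    ChainingParams,
    CollinearBlock,
    PositionIndex,
    block_significance,
    chain_blocks,
    classify_homology_layer,
    _best_chain,
    _gap_penalty,
)
from karyoevo.homology import HomologPair

from conftest import make_genome


def diagonal_pairs(n, chrom_a="X", chrom_b="Y", log10e=-60.0, offset=0):
    """n consecutive-gene anchor pairs along the main diagonal."""
    return [
        HomologPair(f"{chrom_a}g{i + offset:04d}", f"{chrom_b}g{i + offset:04d}", log10e)
        for i in range(n)
    ]


@pytest.fixture
def two_chrom_positions():
    g = make_genome({"X": 200, "Y": 200})
    return PositionIndex.from_genomes(g)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class TestChainScoring:
    def test_hand_computed_diagonal_score(self, two_chrom_positions):
        # 6 anchors at E=1e-60 (capped at 50), genes 12 kb apart start to
        # start: per step the summed two-chromosome distance is 24 kb
        # -> penalty 2.4; score = 6*50 - 5*2.4 = 288
        pairs = diagonal_pairs(6)
        blocks = chain_blocks(pairs, two_chrom_positions,
                              ChainingParams(min_anchors=2))
        assert len(blocks) == 1
        assert blocks[0].score == pytest.approx(6 * 50 - 5 * 2.4)
        assert blocks[0].orientation == "forward"

    def test_ten_kb_spacing_example(self):
        # genes laid exactly 10 kb apart: score = 6*50 - 5*(20/10) = 290
        g = make_genome({"X": 200, "Y": 200})
        for chrom in g.chromosomes:
            for i, loc in enumerate(chrom.loci):
                loc.start_bp = 1 + i * 10_000
                loc.end_bp = loc.start_bp + 1999
        pos = PositionIndex.from_genomes(g)
        blocks = chain_blocks(diagonal_pairs(6), pos, ChainingParams(min_anchors=2))
        assert blocks[0].score == pytest.approx(290.0)

    def test_match_cap_applies(self, two_chrom_positions):
        strong = chain_blocks(diagonal_pairs(6, log10e=-200.0),
                              two_chrom_positions, ChainingParams(min_anchors=2))
        weak = chain_blocks(diagonal_pairs(6, log10e=-60.0),
                            two_chrom_positions, ChainingParams(min_anchors=2))
        assert strong[0].score == weak[0].score  # both capped at 50/anchor

    def test_single_pair_rejected_by_min_anchors(self, two_chrom_positions):
        assert chain_blocks(diagonal_pairs(1), two_chrom_positions,
                            ChainingParams()) == []

    def test_mg_constraint_splits_blocks(self, two_chrom_positions):
        # two runs separated by 41 intervening genes on both chromosomes can
        # never share a block at mg=40
        pairs = diagonal_pairs(10) + diagonal_pairs(10, offset=52)
        params = ChainingParams(min_anchors=5, block_evalue_threshold=1.0)
        blocks = chain_blocks(pairs, two_chrom_positions, params)
        assert len(blocks) == 2
        # at a permissive mg they merge
        merged = chain_blocks(pairs, two_chrom_positions,
                              ChainingParams(mg=50, min_anchors=5,
                                             block_evalue_threshold=1.0))
        assert len(merged) == 1

    def test_antidiagonal_symmetry(self, two_chrom_positions):
        g = make_genome({"X": 50, "Y": 50})
        pos = PositionIndex.from_genomes(g)
        fwd_pairs = diagonal_pairs(8)
        rev_pairs = [
            HomologPair(f"Xg{i:04d}", f"Yg{49 - i:04d}", -60.0) for i in range(8)
        ]
        params = ChainingParams(min_anchors=2, block_evalue_threshold=1.0)
        fwd = chain_blocks(fwd_pairs, pos, params)
        rev = chain_blocks(rev_pairs, pos, params)
        assert fwd[0].orientation == "forward"
        assert rev[0].orientation == "reverse"
        assert len(rev[0].anchors) == len(fwd[0].anchors)

    def test_filtering_monotone_in_threshold(self, two_chrom_positions):
        pairs = diagonal_pairs(30) + diagonal_pairs(6, offset=60)
        strict = chain_blocks(pairs, two_chrom_positions,
                              ChainingParams(block_evalue_threshold=1e-30))
        loose = chain_blocks(pairs, two_chrom_positions,
                             ChainingParams(block_evalue_threshold=1e-5))
        strict_keys = {(b.chrom_a, b.chrom_b, b.ord_span_a) for b in strict}
        loose_keys = {(b.chrom_a, b.chrom_b, b.ord_span_a) for b in loose}
        assert strict_keys <= loose_keys


# ---------------------------------------------------------------------------
# DP optimality against exhaustive enumeration
# ---------------------------------------------------------------------------

def oracle_best_score(anchors, params):
    """Best chain score over all anchor subsets and both orientations,
    by brute force."""
    best = 0.0
    for r in range(1, len(anchors) + 1):
        for subset in itertools.combinations(anchors, r):
            for sign in (1, -1):
                chain = sorted(subset, key=lambda a: (a.ord_a, sign * a.ord_b))
                ok = True
                for u, v in zip(chain, chain[1:]):
                    if v.ord_a <= u.ord_a or sign * (v.ord_b - u.ord_b) <= 0:
                        ok = False
                        break
                    if (v.ord_a - u.ord_a - 1 > params.mg
                            or abs(v.ord_b - u.ord_b) - 1 > params.mg):
                        ok = False
                        break
                if not ok:
                    continue
                score = sum(a.weight for a in chain) - sum(
                    _gap_penalty(u, v, params) for u, v in zip(chain, chain[1:])
                )
                best = max(best, score)
    return best


@st.composite
def anchor_sets(draw):
    n = draw(st.integers(min_value=1, max_value=8))
    anchors = []
    for i in range(n):
        oa = draw(st.integers(min_value=0, max_value=12))
        ob = draw(st.integers(min_value=0, max_value=12))
        w = draw(st.integers(min_value=5, max_value=50))
        anchors.append(Anchor(
            gene_a=f"a{i}", gene_b=f"b{i}", ord_a=oa, ord_b=ob,
            bp_a=1 + oa * 12_000, bp_b=1 + ob * 12_000,
            end_bp_a=oa * 12_000 + 2_000, end_bp_b=ob * 12_000 + 2_000,
            weight=float(w),
        ))
    return anchors


@settings(max_examples=250, deadline=None, derandomize=True)
@given(anchor_sets(), st.sampled_from([2, 5, 40]))
def test_dp_matches_exhaustive_enumeration(anchors, mg):
    params = ChainingParams(mg=mg)
    sf, _ = _best_chain(anchors, params, "forward")
    sr, _ = _best_chain(anchors, params, "reverse")
    assert max(sf, sr) == pytest.approx(oracle_best_score(anchors, params))


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def _diag_block(m, na=200, nb=200):
    anchors = [
        Anchor(f"a{i}", f"b{i}", i, i, 1 + i * 12_000, 1 + i * 12_000,
               i * 12_000 + 2_000, i * 12_000 + 2_000, 50.0)
        for i in range(m)
    ]
    return CollinearBlock("X", "Y", anchors, "forward",
                          score=sum(a.weight for a in anchors))


class TestSignificance:
    def test_zero_anchor_convention(self):
        b = CollinearBlock("X", "Y", [], "forward", 0.0)
        assert block_significance(b, Background(10, 200, 200)) == 1.0

    def test_monotone_decreasing_in_anchor_count(self):
        bg = Background(60, 200, 200)
        evals = [block_significance(_diag_block(m), bg) for m in range(2, 30)]
        assert all(e2 <= e1 for e1, e2 in zip(evals, evals[1:]))

    def test_dense_random_background_not_significant(self):
        # a 20-anchor chain is expected by chance among 400 uniform pairs in
        # a 200 x 200 grid at mg=40, and the E-value says so
        rng = np.random.default_rng(0)
        block = _diag_block(20)
        # a genuinely diffuse chance chain spans much more than 20 ordinals
        for i, a in enumerate(block.anchors):
            object.__setattr__(a, "ord_a", i * 10)
            object.__setattr__(a, "ord_b", i * 10)
        assert block_significance(block, Background(400, 200, 200)) > 1e-10

    def test_tight_block_in_sparse_background_significant(self):
        # 20-anchor gap-free diagonal with a handful of stray background
        # pairs: far below the 1e-10 reporting threshold
        assert block_significance(_diag_block(20), Background(24, 200, 200)) < 1e-10

    def test_permutation_oracle_agrees_on_sparse_fixture(self):
        rng = np.random.default_rng(7)
        anchors = list(_diag_block(20).anchors)
        for j in range(4):  # 4 stray background pairs (~1% of genes)
            oa, ob = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            anchors.append(Anchor(
                f"n{j}", f"m{j}", oa, ob, 1 + oa * 12_000, 1 + ob * 12_000,
                oa * 12_000 + 2_000, ob * 12_000 + 2_000, 8.0))
        block = _diag_block(20)
        bg = Background(len(anchors), 200, 200, anchors)
        params = ChainingParams(permutation_reps=2000, permutation_seed=1)
        e_perm = block_significance(block, bg, params, method="permutation")
        assert e_perm < 1e-10

    def test_empty_background_raises(self):
        with pytest.raises(ValueError):
            block_significance(_diag_block(5), Background(5, 0, 0))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassification:
    def test_sole_block_is_primary(self):
        b = _diag_block(10)
        classify_homology_layer([b])
        assert b.homology_class == "primary"

    def test_overlapping_lower_scorer_secondary(self):
        hi = _diag_block(20)
        lo = _diag_block(12)
        lo.chrom_b = "Z"
        classify_homology_layer([hi, lo])
        assert hi.homology_class == "primary"
        assert lo.homology_class == "secondary"

    def test_equal_score_tie_breaks_by_subject_id_deterministically(self):
        a = _diag_block(10)
        b = _diag_block(10)
        b.chrom_b = "W"
        for _ in range(3):
            classify_homology_layer([a, b])
            assert b.homology_class == "primary"  # "W" < "Y"
            assert a.homology_class == "secondary"

    def test_self_comparison_always_secondary(self):
        b = _diag_block(10)
        classify_homology_layer([b], self_comparison=True)
        assert b.homology_class == "secondary"
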