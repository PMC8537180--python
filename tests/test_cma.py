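"""Correlation statistic, co-evolution network, and position selection."""

import numpy as np
import pytest

from specmap import (
    Alignment,
    CorrelationResult,
    build_network,
    cma_matrix,
    column_pair_score,
    henikoff_weights,
    select_positions,
)
from specmap.errors import DegenerateInputError

from _oracles import henikoff_oracle, nmi_oracle
from conftest import random_alignment

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestHenikoffWeights:
    def test_identical_rows_equal_weights(self):
        aln = Alignment(ids=("a", "b", "c"), rows=("ACD",) * 3)
        w = henikoff_weights(aln)
        assert np.allclose(w.values, 1.0)

    def test_duplicate_downweighted(self):
        aln = Alignment(ids=("a1", "a2", "b"), rows=("ACDE", "ACDE", "KLMN"))
        w = henikoff_weights(aln)
        assert w.weight("b") > w.weight("a1")
        assert w.weight("a1") == pytest.approx(w.weight("a2"))

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(17)
        aln = random_alignment(rng, 10, 15, gap_rate=0.1)
        w = henikoff_weights(aln)
        expected = henikoff_oracle(list(aln.rows))
        assert np.allclose(w.values, expected, atol=1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(23)
        aln = random_alignment(rng, 8, 12)
        w1 = dict(zip(aln.ids, henikoff_weights(aln).values))
        perm = rng.permutation(8)
        aln2 = Alignment(
            ids=tuple(aln.ids[i] for i in perm),
            rows=tuple(aln.rows[i] for i in perm),
        )
        w2 = dict(zip(aln2.ids, henikoff_weights(aln2).values))
        for sid in aln.ids:
            assert w1[sid] == pytest.approx(w2[sid], abs=1e-12)

    def test_all_gap_alignment_degenerate(self):
        aln = Alignment(ids=("a", "b"), rows=("--", "--"))
        with pytest.raises(DegenerateInputError):
            henikoff_weights(aln)


class TestColumnPairScore:
    def test_perfect_bijection_scores_one(self):
        # two equiprobable states per column, perfectly coupled
        aln = Alignment(
            ids=tuple(f"s{i}" for i in range(40)),
            rows=tuple("AC" if i % 2 else "DE" for i in range(40)),
        )
        w = henikoff_weights(aln)
        assert column_pair_score(aln, 1, 2, w, min_pairs=10) == pytest.approx(1.0)

    def test_independent_columns_score_near_zero(self):
        rng = np.random.default_rng(100)
        aln = random_alignment(rng, 2000, 2)
        w = henikoff_weights(aln)
        assert column_pair_score(aln, 1, 2, w) < 0.05

    def test_matches_brute_force_oracle_on_toys(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            aln = random_alignment(rng, 8, 4, gap_rate=0.15)
            try:
                w = henikoff_weights(aln)
            except DegenerateInputError:
                continue
            for (i, j) in [(1, 2), (2, 4), (1, 4)]:
                got = column_pair_score(aln, i, j, w, min_pairs=2, h_min=0.0)
                exp = nmi_oracle(aln.column(i), aln.column(j), list(w.values))
                if np.isnan(got):
                    continue
                assert got == pytest.approx(min(max(exp, 0), 1), abs=1e-12)

    def test_constant_column_masked(self):
        aln = Alignment(
            ids=tuple(f"s{i}" for i in range(30)),
            rows=tuple("A" + AA[i % 20] for i in range(30)),
        )
        w = henikoff_weights(aln)
        assert np.isnan(column_pair_score(aln, 1, 2, w, min_pairs=5))

    def test_too_few_complete_pairs_masked(self):
        aln = Alignment(
            ids=tuple(f"s{i}" for i in range(30)),
            rows=tuple(("AC" if i < 5 else "-C") for i in range(30)),
        )
        w = henikoff_weights(aln)
        assert np.isnan(column_pair_score(aln, 1, 2, w, min_pairs=20))

    def test_same_column_rejected(self):
        aln = Alignment(ids=("a",), rows=("AC",))
        with pytest.raises(ValueError):
            column_pair_score(aln, 1, 1, henikoff_weights(aln))


@pytest.fixture(scope="module")
def toys():
    rng = np.random.default_rng(77)
    return [random_alignment(rng, 6, 5) for _ in range(100)], rng


class TestMatrixInvariances:
    def test_symmetry_range_and_permutation_invariance(self, toys):
        alns, rng = toys
        for aln in alns:
            w = henikoff_weights(aln)
            cr = cma_matrix(aln, w, min_pairs=2, h_min=0.0)
            finite = np.isfinite(cr.scores)
            assert np.array_equal(cr.scores[finite], cr.scores.T[finite])
            assert np.all(cr.scores[finite] >= 0) and np.all(cr.scores[finite] <= 1)
            assert np.all(np.isnan(np.diag(cr.scores)))
            perm = rng.permutation(aln.n_sequences)
            aln2 = Alignment(
                ids=tuple(aln.ids[i] for i in perm),
                rows=tuple(aln.rows[i] for i in perm),
            )
            cr2 = cma_matrix(aln2, henikoff_weights(aln2), min_pairs=2, h_min=0.0)
            assert np.allclose(cr.scores[finite], cr2.scores[finite], atol=1e-12)

    def test_alphabet_relabeling_invariance(self, toys):
        alns, rng = toys
        for aln in alns[:30]:
            w = henikoff_weights(aln)
            base = cma_matrix(aln, w, min_pairs=2, h_min=0.0)
            # bijective relabeling of column 1 only; reuse the same weights
            # (relabeling one column perturbs Henikoff weights, which is a
            # property of the weighting, not of the MI statistic)
            perm = rng.permutation(list(AA))
            table = str.maketrans(AA, "".join(perm))
            rows = tuple(r[0].translate(table) + r[1:] for r in aln.rows)
            aln2 = Alignment(ids=aln.ids, rows=rows)
            cr2 = cma_matrix(aln2, w, min_pairs=2, h_min=0.0)
            finite = np.isfinite(base.scores)
            assert np.allclose(base.scores[finite], cr2.scores[finite], atol=1e-12)

    def test_five_column_matrix_combinatorics(self):
        rng = np.random.default_rng(55)
        aln = random_alignment(rng, 30, 5)
        cr = cma_matrix(aln, henikoff_weights(aln), min_pairs=2, h_min=0.0)
        off_diag = ~np.eye(5, dtype=bool)
        # 20 ordered = 10 unordered entries, defined or masked, symmetric
        assert cr.scores.shape == (5, 5)
        assert np.isnan(cr.scores[np.eye(5, dtype=bool)]).all()
        vals = cr.scores[off_diag]
        assert vals.size == 20


def _matrix_from_edges(labels, edges):
    m = len(labels)
    idx = {p: i for i, p in enumerate(labels)}
    scores = np.full((m, m), 0.1)
    np.fill_diagonal(scores, np.nan)
    for i, j, s in edges:
        scores[idx[i], idx[j]] = scores[idx[j], idx[i]] = s
    return CorrelationResult(scores=scores, columns=tuple(labels))


class TestNetworkAndSelection:
    def test_all_below_threshold_gives_empty_network(self):
        cr = _matrix_from_edges([1, 2, 3], [])
        assert build_network(cr, 0.8).edges == []

    def test_manual_degree_count(self):
        cr = _matrix_from_edges(
            [1, 2, 3, 4], [(1, 2, 0.9), (1, 3, 0.85), (2, 3, 0.82)]
        )
        net = build_network(cr, 0.8)
        assert net.degrees() == {1: 2, 2: 2, 3: 2}
        assert 4 not in net.nodes

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        labels = list(range(1, 13))
        edges = [
            (i, j, float(rng.uniform(0.5, 1.0)))
            for k, i in enumerate(labels) for j in labels[k + 1:]
            if rng.random() < 0.4
        ]
        cr = _matrix_from_edges(labels, edges)
        e1 = set((i, j) for i, j, _ in build_network(cr, 0.7).edges)
        e2 = set((i, j) for i, j, _ in build_network(cr, 0.85).edges)
        assert e2 <= e1

    def test_selection_on_constructed_benchmark_matrix(self):
        # exactly {64, 392, 394, 402, 416, 585} satisfy both criteria
        strong = [64, 392, 394, 402, 416, 585]
        weak = [56, 62, 63]
        labels = strong + weak
        edges = []
        for k, i in enumerate(strong):
            for j in strong[k + 1:]:
                edges.append((i, j, 0.95))
        edges += [(56, 62, 0.85), (62, 63, 0.85)]
        cr = _matrix_from_edges(labels, edges)
        net = build_network(cr, 0.8)
        sel = select_positions(net, cr, 0.9, 2)
        assert sel.positions == strong

    def test_empty_network_empty_selection(self):
        cr = _matrix_from_edges([1, 2], [])
        sel = select_positions(build_network(cr, 0.8), cr)
        assert sel.positions == []

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(12)
        labels = list(range(1, 13))
        edges = [
            (i, j, float(rng.uniform(0.6, 1.0)))
            for k, i in enumerate(labels) for j in labels[k + 1:]
            if rng.random() < 0.5
        ]
        cr = _matrix_from_edges(labels, edges)
        net = build_network(cr, 0.8)
        sel = select_positions(net, cr, 0.9, 2)
        # brute force over the score matrix
        expected = []
        for a, p in enumerate(labels):
            row = cr.scores[a]
            mx = np.nanmax(row)
            deg = sum(
                1 for i, j, s in edges if p in (i, j) and s >= 0.8
            )
            if mx > 0.9 and deg >= 2:
                expected.append(p)
        assert sel.positions == sorted(expected)

    def test_inconsistent_thresholds_rejected(self):
        cr = _matrix_from_edges([1, 2], [(1, 2, 0.9)])
        net = build_network(cr, 0.8)
        with pytest.raises(ValueError):
            select_positions(net, cr, strong_threshold=0.7)
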