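"""Alignment route: seeding, chaining (vs exhaustive oracle), gap fill
(vs hand-computed DP), netting, windows, and boundary detection."""

import itertools

import numpy as np
import pytest

from msypipe.divergence import (
    MATCH,
    MISMATCH,
    Q_GAP,
    T_GAP,
    AlignmentChain,
    Anchor,
    Block,
    ChainSkeleton,
    WindowDivergence,
    align_chromosomes,
    chain_anchors,
    detect_boundary,
    fill_chain_gaps,
    net_chains,
    read_paf,
    revcomp,
    seed_anchors,
    window_divergence,
    write_paf,
)

RNG = np.random.default_rng(20_240_501)


def _random_seq(n, rng=RNG):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _mk_window(start, end, div, covered=1.0):
    aligned = end - start
    return WindowDivergence(
        "Y", start, end, aligned, 0, 0, div, covered, covered < 0.25
    )


class TestSeeding:
    def test_identical_sequences_single_full_anchor(self):
        s = _random_seq(10_000, np.random.default_rng(1))
        anchors = seed_anchors(s, s, k=15)
        assert len(anchors) == 1
        a = anchors[0]
        assert (a.q_start, a.t_start, a.length, a.strand) == (0, 0, 10_000, "+")

    def test_reverse_complement_query_gives_minus_anchors(self):
        rng = np.random.default_rng(2)
        x = _random_seq(5_000, rng)
        y = x[:2_000] + _random_seq(1_000, rng) + x[3_000:]
        fwd = seed_anchors(x, y, k=15)
        rev = seed_anchors(revcomp(x), y, k=15)
        assert {(a.t_start, a.length) for a in fwd} == {
            (a.t_start, a.length) for a in rev
        }
        assert all(a.strand == "-" for a in rev)

    def test_planted_unique_kmers_found_exactly(self):
        rng = np.random.default_rng(3)
        probes = [_random_seq(25, rng) for _ in range(3)]
        x = _random_seq(3_000, rng)
        y = _random_seq(3_000, rng)
        xpos, ypos = [200, 1_500, 2_700], [400, 1_100, 2_500]
        for p, xp, yp in zip(probes, xpos, ypos):
            x = x[:xp] + p + x[xp + 25 :]
            y = y[:yp] + p + y[yp + 25 :]
        anchors = seed_anchors(x, y, k=15)
        plus = [a for a in anchors if a.strand == "+"]
        # exactly one maximal anchor per planted probe, each containing its
        # probe on the right diagonal (chance flanking matches may extend it)
        assert len(plus) == 3
        for a, xp, yp in zip(plus, xpos, ypos):
            assert a.t_start - a.q_start == yp - xp
            assert a.q_start <= xp and a.q_end >= xp + 25

    def test_k_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            seed_anchors("ACGT" * 10, "ACGT" * 10, k=9)


def _brute_force_best_chain(anchors, gap_open=2.0, gap_extend=1.0):
    """Exhaustive maximum over all co-linear anchor subsets."""

    def score(subset):
        s = sum(a.length for a in subset)
        for p, q in zip(subset, subset[1:]):
            dt = q.t_start - p.t_end
            dq = q.q_start - p.q_end
            if dt < 0 or dq < 0:
                return None
            g = abs(dt - dq)
            if g:
                s -= gap_open + gap_extend * g
        return s

    best = 0.0
    ordered = sorted(anchors, key=lambda a: (a.t_start, a.q_start))
    for r in range(1, len(ordered) + 1):
        for subset in itertools.combinations(ordered, r):
            sc = score(list(subset))
            if sc is not None and sc > best:
                best = sc
    return best


class TestChaining:
    def test_colinear_anchors_form_one_chain(self):
        anchors = [Anchor(0, 0, 20), Anchor(30, 30, 20)]
        chains = chain_anchors(anchors)
        assert len(chains[0].anchors) == 2
        assert chains[0].score == 40  # co-diagonal gap costs nothing

    def test_off_diagonal_anchor_excluded_from_best_chain(self):
        anchors = [Anchor(0, 0, 20), Anchor(30, 30, 20), Anchor(100, 25, 20)]
        chains = chain_anchors(anchors)
        best = chains[0]
        assert {(a.q_start, a.t_start) for a in best.anchors} == {(0, 0), (30, 30)}

    @pytest.mark.parametrize("trial", range(10))
    def test_chain_score_matches_exhaustive_optimum(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(6, 13))
        anchors = [
            Anchor(int(rng.integers(0, 400)), int(rng.integers(0, 400)),
                   int(rng.integers(10, 40)))
            for _ in range(n)
        ]
        chains = chain_anchors(anchors, lookback=64)
        assert chains[0].score == pytest.approx(_brute_force_best_chain(anchors))

    def test_empty_input_empty_output(self):
        assert chain_anchors([]) == []


def _fill_fixture(x_gap, y_gap):
    """Two 20 bp anchors around one gap; returns the filled column counts."""
    rng = np.random.default_rng(42)
    pre, post = _random_seq(20, rng), _random_seq(20, rng)
    x = pre + x_gap + post
    y = pre + y_gap + post
    sk = ChainSkeleton(
        anchors=[Anchor(0, 0, 20), Anchor(20 + len(x_gap), 20 + len(y_gap), 20)],
        score=40.0,
    )
    chain = fill_chain_gaps(sk, x, y)
    return chain.column_counts(), chain


class TestGapFill:
    def test_identical_gap_all_matches(self):
        counts, _ = _fill_fixture("ACGT", "ACGT")
        assert counts == {"match": 44, "mismatch": 0, "t_gap": 0, "q_gap": 0}

    def test_single_substitution_gap(self):
        # hand DP on the 4x4 matrix (match +1, mismatch -1, open -2,
        # extend -1): diagonal path, 3 matches + 1 mismatch, segment score 2
        counts, chain = _fill_fixture("ACGT", "AGGT")
        assert counts == {"match": 43, "mismatch": 1, "t_gap": 0, "q_gap": 0}
        assert chain.score == 43 - 1

    def test_deletion_on_target_side(self):
        # hand DP: X="ACGT" vs Y="AC" -> 2 matches + 2 target-gap columns
        counts, _ = _fill_fixture("ACGT", "AC")
        assert counts["match"] == 42
        assert counts["t_gap"] == 2
        assert counts["q_gap"] == 0

    def test_column_conservation(self):
        _, chain = _fill_fixture("ACGTAC", "AGT")
        counts = chain.column_counts()
        total = sum(len(b.cols) for b in chain.blocks)
        assert sum(counts.values()) == total
        # consumed bases account for the full extent on both sequences
        assert counts["match"] + counts["mismatch"] + counts["q_gap"] == chain.blocks[-1].t_end
        assert counts["match"] + counts["mismatch"] + counts["t_gap"] == 46


class TestNetting:
    def _chain(self, t0, n_cols, score):
        return AlignmentChain(
            blocks=[Block(t0, t0, np.full(n_cols, MATCH, dtype=np.uint8))],
            score=score,
        )

    def test_single_chain_unchanged(self):
        c = self._chain(0, 100, 50)
        netted = net_chains([c])
        assert len(netted) == 1
        assert netted[0].column_counts()["match"] == 100

    def test_disjoint_chains_both_kept(self):
        netted = net_chains([self._chain(0, 100, 50), self._chain(500, 100, 40)])
        assert len(netted) == 2

    def test_overlap_trimmed_from_lower_scoring_chain(self):
        # chains span [0, 2000) and [1000, 3000); the weaker one loses
        # exactly the 1000 bp overlap
        a = self._chain(0, 2_000, 500)
        b = self._chain(1_000, 2_000, 300)
        netted = net_chains([a, b])
        spans = sorted((c.t_start, c.t_end) for c in netted)
        assert spans == [(0, 2_000), (2_000, 3_000)]
        trimmed = [c for c in netted if c.t_start == 2_000][0]
        assert trimmed.column_counts()["match"] == 1_000


class TestWindows:
    def test_hand_counted_window(self):
        # 100 aligned columns: 94 match, 4 mismatch, 2 gap -> 6.0000 %
        cols = np.array(
            [MATCH] * 94 + [MISMATCH] * 4 + [T_GAP, Q_GAP], dtype=np.uint8
        )
        chain = AlignmentChain(blocks=[Block(0, 0, cols)], score=0)
        windows = window_divergence([chain], window_bp=200, chrom_length=200)
        assert windows[0].divergence_pct == pytest.approx(6.0, abs=1e-12)
        assert windows[0].n_snp == 4
        assert windows[0].n_indel_cols == 2

    def test_identical_alignment_zero_everywhere(self):
        chain = AlignmentChain(
            blocks=[Block(0, 0, np.full(5_000, MATCH, dtype=np.uint8))], score=0
        )
        windows = window_divergence([chain], window_bp=1_000, chrom_length=5_000)
        assert all(w.divergence_pct == 0.0 for w in windows)
        assert all(w.covered_fraction == 1.0 for w in windows)

    def test_window_counts_sum_to_chain_totals(self, small_netted, small_scenario):
        _, _, y, _ = small_scenario
        windows = window_divergence(small_netted, window_bp=1_000, chrom_length=len(y))
        totals = {"match": 0, "mismatch": 0, "t_gap": 0, "q_gap": 0}
        for c in small_netted:
            for k, v in c.column_counts().items():
                totals[k] += v
        assert sum(w.aligned_cols for w in windows) == sum(totals.values())
        assert sum(w.n_snp for w in windows) == totals["mismatch"]
        assert sum(w.n_indel_cols for w in windows) == totals["t_gap"] + totals["q_gap"]

    def test_indel_event_mode_counts_runs(self):
        cols = np.array([MATCH] * 5 + [T_GAP] * 3 + [MATCH] * 5, dtype=np.uint8)
        chain = AlignmentChain(blocks=[Block(0, 0, cols)], score=0)
        w_cols = window_divergence([chain], window_bp=100, chrom_length=100)[0]
        w_events = window_divergence(
            [chain], window_bp=100, chrom_length=100, indel_events=True
        )[0]
        assert w_cols.n_indel_cols == 3
        assert w_events.n_indel_cols == 1


class TestBoundary:
    def test_step_series_split_before_jump(self):
        divs = [1, 1, 1, 1, 6, 6, 6]
        windows = [_mk_window(i * 10, (i + 1) * 10, d) for i, d in enumerate(divs)]
        call = detect_boundary(windows, min_windows_per_side=1)
        assert call.changepoint_bp == 40
        assert call.mean_before == pytest.approx(1.0)
        assert call.mean_after == pytest.approx(6.0)
        assert call.fold == pytest.approx(6.0)
        assert not call.no_transition

    def test_constant_series_flags_no_transition(self):
        windows = [_mk_window(i * 10, (i + 1) * 10, 2.0) for i in range(12)]
        call = detect_boundary(windows, min_windows_per_side=2)
        assert call.fold == pytest.approx(1.0)
        assert call.no_transition
        # SSE is tied everywhere; tie broken to the rightmost edge
        assert call.changepoint_bp == 100

    def test_too_few_windows_rejected(self):
        windows = [_mk_window(i * 10, (i + 1) * 10, 1.0) for i in range(6)]
        with pytest.raises(ValueError):
            detect_boundary(windows, min_windows_per_side=5)

    def test_low_confidence_windows_excluded(self):
        divs = [1, 1, 1, 1, 6, 6, 6]
        windows = [_mk_window(i * 10, (i + 1) * 10, d) for i, d in enumerate(divs)]
        windows.insert(0, _mk_window(-10, 0, 50.0, covered=0.1))
        call = detect_boundary(windows, min_windows_per_side=1)
        assert call.n_windows_used == 7
        assert call.changepoint_bp == 40


class TestPafRoundTrip:
    def test_windows_identical_after_paf_round_trip(
        self, tmp_path, small_netted, small_scenario
    ):
        _, x, y, _ = small_scenario
        paf = tmp_path / "chains.paf"
        write_paf(small_netted, paf, "X", "Y", len(x), len(y))
        reloaded = read_paf(paf)
        w0 = window_divergence(small_netted, window_bp=1_000, chrom_length=len(y))
        w1 = window_divergence(reloaded, window_bp=1_000, chrom_length=len(y))
        assert w0 == w1


class TestEndToEnd:
    def test_scenario_boundary_recovered(self, small_scenario, small_netted):
        cfg, _, y, truth = small_scenario
        windows = window_divergence(
            small_netted, window_bp=cfg.bp(10_000), chrom_length=len(y)
        )
        call = detect_boundary(windows)
        assert abs(call.changepoint_bp - truth.boundary_y) <= 2 * cfg.bp(10_000)
        assert call.fold > 4
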