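"""Gene-evidence synthesis: support scoring, clustering, selection,
terminal-exon rescue, ab initio recruitment, idempotence, GFF3 I/O."""

import pytest

from msypipe.genes import (
    GeneModel,
    cluster_models,
    compute_support,
    merge_annotation,
    read_gff3,
    recruit_abinitio,
    rescue_terminal_exons,
    select_representative,
    write_gff3,
)


def _gm(mid, exons, strand="+", source="homology", chrom="Y"):
    return GeneModel(mid, source, chrom, strand, tuple(exons))


def _full_cover(models):
    return [x for m in models for x in m.exons]


def _all_junctions(models):
    return [(s, e, m.strand) for m in models for s, e in m.introns]


class TestSupport:
    def test_full_coverage_and_junctions_score_one(self):
        m = _gm("a", [(0, 100), (200, 300)])
        prof, score = compute_support(m, [(0, 100), (200, 300)], [(100, 200, "+")])
        assert prof.exon_cover == (1.0, 1.0)
        assert prof.junction_match == (True,)
        assert score == 1.0

    def test_partial_coverage_weighted_half_half(self):
        # two 100 bp exons with 150 bp covered, junction matched:
        # 0.5 * 0.75 + 0.5 * 1.0 = 0.875
        m = _gm("a", [(0, 100), (200, 300)])
        prof, score = compute_support(m, [(0, 100), (200, 250)], [(100, 200, "+")])
        assert sum(prof.exon_cover) / 2 == pytest.approx(0.75)
        assert score == pytest.approx(0.875)

    def test_no_transcript_data_scores_zero(self):
        m = _gm("a", [(0, 100), (200, 300)])
        prof, score = compute_support(m, [], [])
        assert score == 0.0
        assert prof.junction_match == (False,)

    def test_single_exon_uses_exon_term_only(self):
        m = _gm("a", [(0, 100)])
        _, score = compute_support(m, [(0, 50)], [])
        assert score == pytest.approx(0.5)


class TestClustering:
    def test_one_base_exonic_overlap_joins(self):
        a = _gm("a", [(0, 100)])
        b = _gm("b", [(99, 200)])
        assert len(cluster_models([a, b])) == 1

    def test_opposite_strands_stay_apart(self):
        a = _gm("a", [(0, 100)], strand="+")
        b = _gm("b", [(0, 100)], strand="-")
        assert len(cluster_models([a, b])) == 2

    def test_intronic_overlap_does_not_join(self):
        a = _gm("a", [(0, 100), (500, 600)])
        b = _gm("b", [(200, 300)])  # inside a's intron
        assert len(cluster_models([a, b])) == 2

    def test_transitive_chain_single_component(self):
        a = _gm("a", [(0, 100)])
        b = _gm("b", [(50, 150)])
        c = _gm("c", [(140, 240)])  # overlaps b, not a
        clusters = cluster_models([a, b, c])
        assert len(clusters) == 1
        assert len(clusters[0]) == 3


class TestSelection:
    def test_highest_score_kept(self):
        a, b = _gm("a", [(0, 100)]), _gm("b", [(50, 150)])
        kept, elim = select_representative([a, b], {"a": 0.9, "b": 0.4})
        assert kept.model_id == "a" and [m.model_id for m in elim] == ["b"]

    def test_tie_broken_by_longer_cds(self):
        a = _gm("a", [(0, 600)])
        b = _gm("b", [(0, 900)])
        kept, _ = select_representative([a, b], {"a": 0.8, "b": 0.8})
        assert kept.model_id == "b"

    def test_singleton_kept_unchanged(self):
        a = _gm("a", [(0, 100)])
        kept, elim = select_representative([a], {"a": 0.1})
        assert kept is a and elim == []


class TestRescue:
    # truth structure: exons (0,100), (200,300), (400,500) on "+"
    TRUTH = [(0, 100), (200, 300), (400, 500)]

    def _profiles(self, models, cover, juncs):
        return {m.model_id: compute_support(m, cover, juncs)[0] for m in models}

    def test_poorly_supported_terminal_exon_replaced(self):
        truth = _gm("t", self.TRUTH)
        kept = _gm("k", [(-200, 100), (200, 300), (400, 500)])  # bad left exon
        donor = _gm("d", [(0, 100), (200, 300), (400, 900)])  # bad right exon
        cover = _full_cover([truth])
        juncs = _all_junctions([truth])
        profiles = self._profiles([kept, donor], cover, juncs)
        assert profiles["k"].exon_cover[0] < 0.5
        new, rescued = rescue_terminal_exons(kept, [donor], profiles)
        assert rescued
        assert new.exons == truth.exons

    def test_well_supported_terminal_exon_untouched(self):
        kept = _gm("k", self.TRUTH)
        donor = _gm("d", [(-50, 100), (200, 300), (400, 500)])
        cover = _full_cover([kept])
        juncs = _all_junctions([kept])
        profiles = self._profiles([kept, donor], cover, juncs)
        new, rescued = rescue_terminal_exons(kept, [donor], profiles)
        assert not rescued and new.exons == kept.exons

    def test_incompatible_internal_junctions_block_rescue(self):
        truth = _gm("t", self.TRUTH)
        kept = _gm("k", [(-200, 100), (200, 300), (400, 500)])
        # donor's middle exon differs -> internal junction mismatch
        donor = _gm("d", [(0, 100), (210, 300), (400, 500)])
        cover = _full_cover([truth])
        juncs = _all_junctions([truth])
        profiles = self._profiles([kept, donor], cover, juncs)
        new, rescued = rescue_terminal_exons(kept, [donor], profiles)
        assert not rescued and new.exons == kept.exons

    def test_overlapping_replacement_rejected(self):
        kept = _gm("k", [(-200, 100), (200, 300)])
        # single-exon donor whose exon would run past kept's second exon
        donor = _gm("d", [(0, 250)])
        cover = [(0, 250), (200, 300)]
        juncs = [(100, 200, "+")]
        profiles = self._profiles([kept, donor], cover, juncs)
        new, rescued = rescue_terminal_exons(kept, [donor], profiles)
        assert not rescued and new.exons == kept.exons


class TestRecruitment:
    def test_fully_supported_isolated_model_recruited(self):
        ab = _gm("ab", [(1000, 1100), (1200, 1300)], source="abinitio")
        profiles = {
            "ab": compute_support(
                ab, _full_cover([ab]), _all_junctions([ab])
            )[0]
        }
        assert recruit_abinitio([ab], [], profiles) == [ab]

    def test_almost_full_coverage_not_recruited(self):
        ab = _gm("ab", [(1000, 1100)], source="abinitio")
        profiles = {"ab": compute_support(ab, [(1000, 1099)], [])[0]}
        assert recruit_abinitio([ab], [], profiles) == []

    def test_overlap_with_homology_cluster_blocks_recruitment(self):
        ab = _gm("ab", [(1000, 1100)], source="abinitio")
        hom = _gm("h", [(1050, 1200)])
        profiles = {"ab": compute_support(ab, [(1000, 1100)], [])[0]}
        assert recruit_abinitio([ab], [[hom]], profiles) == []


class TestMerge:
    def test_counts_conserved(self):
        h1 = _gm("h1", [(0, 100), (200, 300)])
        h2 = _gm("h2", [(50, 120), (200, 300)])
        h3 = _gm("h3", [(5_000, 5_100)])
        ab = _gm("ab", [(9_000, 9_100)], source="abinitio")
        merged = merge_annotation(
            [h1, h2, h3], [ab],
            _full_cover([h1, h3, ab]), _all_junctions([h1, ab]),
        )
        assert len(merged.kept) == 2  # one per cluster
        assert len(merged.final_models) == len(merged.kept) + len(merged.recruited)
        assert merged.provenance["ab"] == "recruited"

    def test_merge_is_idempotent(self):
        h1 = _gm("h1", [(0, 100), (200, 300)])
        h2 = _gm("h2", [(-300, 100), (200, 300)])
        ab = _gm("ab", [(9_000, 9_100)], source="abinitio")
        cover = _full_cover([h1, ab])
        juncs = _all_junctions([h1, ab])
        first = merge_annotation([h1, h2], [ab], cover, juncs)
        again = merge_annotation(first.kept, first.recruited, cover, juncs)
        assert {(m.strand, m.exons) for m in again.final_models} == {
            (m.strand, m.exons) for m in first.final_models
        }


class TestGff3:
    def test_round_trip(self, tmp_path):
        models = [
            _gm("g1", [(0, 100), (200, 300)]),
            _gm("g2", [(1_000, 1_500)], strand="-", source="abinitio"),
        ]
        path = tmp_path / "models.gff3"
        write_gff3(models, path, {"g1": "selected", "g2": "recruited"})
        back = read_gff3(path)
        assert [(m.model_id, m.strand, m.source, m.exons) for m in back] == [
            (m.model_id, m.strand, m.source, m.exons) for m in models
        ]
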