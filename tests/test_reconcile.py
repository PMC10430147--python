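import numpy as np
import pandas as pd
import pytest

from annomerge import (
    Annotation,
    BlastHit,
    FixtureSpec,
    GeneModel,
    HitSet,
    MatchComponent,
    ReconcileParams,
    ReconcileReport,
    decide_component,
    detect_fusion_fragmentation,
    make_annotation_pair,
    reconcile,
)

from conftest import load_pair


def _hit(q, s, qstart, qend, sstart=1, send=None, evalue=1e-30, bitscore=500.0):
    return BlastHit(q, s, 95.0, qend - qstart + 1, qstart, qend, sstart,
                    send if send is not None else sstart + (qend - qstart),
                    evalue, bitscore)


def _hs(q, qlen, *hits):
    return HitSet(q, qlen, sorted(hits, key=lambda h: -h.bitscore))


PARAMS = ReconcileParams()


class TestDecideComponent:
    def test_ref_only_always_kept(self):
        c = MatchComponent(ref_genes=["rA"], pipe_genes=[])
        d = decide_component(c, 0, {}, {}, PARAMS)
        assert d.kept_ref == ["rA"] and not d.kept_pipe
        assert "always kept" in d.reason

    def test_pipe_only_without_hit_discarded(self):
        c = MatchComponent(ref_genes=[], pipe_genes=["pB"])
        d = decide_component(c, 0, {}, {"pB": _hs("pB", 100)}, PARAMS)
        assert d.kept == []

    def test_pipe_only_with_weak_hit_discarded(self):
        c = MatchComponent(ref_genes=[], pipe_genes=["pB"])
        hits = {"pB": _hs("pB", 100, _hit("pB", "s", 1, 50, evalue=10.0))}
        d = decide_component(c, 0, {}, hits, PARAMS)
        assert d.kept == []

    def test_pipe_only_with_significant_hit_kept(self):
        c = MatchComponent(ref_genes=[], pipe_genes=["pB"])
        hits = {"pB": _hs("pB", 100, _hit("pB", "s", 1, 90))}
        d = decide_component(c, 0, {}, hits, PARAMS)
        assert d.kept_pipe == ["pB"]

    def test_one_to_one_keeps_reference_structure(self):
        c = MatchComponent(ref_genes=["rA"], pipe_genes=["pA"])
        d = decide_component(c, 0, {}, {}, PARAMS)
        assert d.kept_ref == ["rA"] and not d.kept_pipe

    def test_one_to_many_coverage_arbitration_ref_wins(self):
        c = MatchComponent(ref_genes=["rA"], pipe_genes=["p1", "p2"])
        ref_hits = {"rA": _hs("rA", 100, _hit("rA", "sR", 1, 90))}  # cov 0.9
        pipe_hits = {
            "p1": _hs("p1", 100, _hit("p1", "s1", 1, 60)),  # cov 0.6
            "p2": _hs("p2", 100, _hit("p2", "s2", 1, 60)),
        }
        d = decide_component(c, 0, ref_hits, pipe_hits, PARAMS)
        assert d.kept_ref == ["rA"] and not d.kept_pipe

    def test_one_to_many_coverage_arbitration_pipe_wins(self):
        c = MatchComponent(ref_genes=["rA"], pipe_genes=["p1", "p2"])
        ref_hits = {"rA": _hs("rA", 100, _hit("rA", "sR", 1, 40))}
        pipe_hits = {
            "p1": _hs("p1", 100, _hit("p1", "s1", 1, 95)),
            "p2": _hs("p2", 100, _hit("p2", "s2", 1, 95)),
        }
        d = decide_component(c, 0, ref_hits, pipe_hits, PARAMS)
        assert not d.kept_ref and d.kept_pipe == ["p1", "p2"]

    def test_no_hit_genes_dropped_before_arbitration(self):
        c = MatchComponent(ref_genes=["rA"], pipe_genes=["p1", "p2"])
        ref_hits = {"rA": _hs("rA", 100, _hit("rA", "sR", 1, 50))}
        pipe_hits = {"p1": _hs("p1", 100)}  # empty; p2 missing entirely
        d = decide_component(c, 0, ref_hits, pipe_hits, PARAMS)
        assert d.kept_ref == ["rA"]

    def test_all_sides_empty_component_contributes_nothing(self):
        c = MatchComponent(ref_genes=["rA"], pipe_genes=["p1"])
        # one_to_one would keep ref; force a many-type by two pipe genes
        c = MatchComponent(ref_genes=["rA"], pipe_genes=["p1", "p2"])
        d = decide_component(c, 0, {}, {}, PARAMS)
        assert d.kept == []

    def test_coverage_tie_respects_policy(self):
        c = MatchComponent(ref_genes=["rA"], pipe_genes=["p1", "p2"])
        ref_hits = {"rA": _hs("rA", 100, _hit("rA", "sR", 1, 80))}
        pipe_hits = {
            "p1": _hs("p1", 100, _hit("p1", "s1", 1, 80)),
            "p2": _hs("p2", 100, _hit("p2", "s2", 1, 80)),
        }
        d = decide_component(c, 0, ref_hits, pipe_hits, PARAMS)
        assert d.kept_ref == ["rA"]
        flipped = ReconcileParams(coverage_tie_policy="prefer_pipeline")
        d = decide_component(c, 0, ref_hits, pipe_hits, flipped)
        assert d.kept_pipe == ["p1", "p2"]

    def test_unknown_category_rejected(self):
        class Fake(MatchComponent):
            category = "bogus"

        with pytest.raises(ValueError, match="bogus"):
            decide_component(Fake(ref_genes=["r"], pipe_genes=[]), 0, {}, {},
                             PARAMS)


class TestFusionFragmentation:
    def test_adjacent_same_subject_hits_flag_fragmentation(self):
        # p1 covers subject residues 1-140, p2 covers 150-300: gap 9
        c = MatchComponent(ref_genes=["rA"], pipe_genes=["p1", "p2"])
        hits = {
            "rA": _hs("rA", 300, _hit("rA", "S", 1, 300, sstart=1, send=300)),
            "p1": _hs("p1", 140, _hit("p1", "S", 1, 140, sstart=1, send=140)),
            "p2": _hs("p2", 151, _hit("p2", "S", 1, 151, sstart=150, send=300)),
        }
        events = detect_fusion_fragmentation(c, hits, PARAMS)
        frag = [e for e in events if e.type == "fragmentation"]
        assert len(frag) == 1
        assert frag[0].gene_ids == ["p1", "p2"]
        assert frag[0].subject_id == "S" and frag[0].side == "pipe"

    def test_large_subject_gap_is_not_fragmentation(self):
        c = MatchComponent(ref_genes=[], pipe_genes=["p1", "p2"])
        hits = {
            "p1": _hs("p1", 140, _hit("p1", "S", 1, 140, sstart=1, send=140)),
            "p2": _hs("p2", 100, _hit("p2", "S", 1, 100, sstart=300, send=399)),
        }
        assert detect_fusion_fragmentation(c, hits, PARAMS) == []

    def test_overlapping_subject_intervals_are_not_fragmentation(self):
        c = MatchComponent(ref_genes=[], pipe_genes=["p1", "p2"])
        hits = {
            "p1": _hs("p1", 140, _hit("p1", "S", 1, 140, sstart=1, send=140)),
            "p2": _hs("p2", 140, _hit("p2", "S", 1, 140, sstart=1, send=140)),
        }
        assert detect_fusion_fragmentation(c, hits, PARAMS) == []

    def test_disjoint_two_subject_hits_flag_fusion(self):
        # qlen 500: S1 on 1-200, S2 on 260-500 -> disjoint 441/500 = 0.882
        c = MatchComponent(ref_genes=["rA"], pipe_genes=["p1", "p2"])
        hits = {
            "rA": _hs(
                "rA", 500,
                _hit("rA", "S1", 1, 200),
                _hit("rA", "S2", 260, 500),
            )
        }
        events = detect_fusion_fragmentation(c, hits, PARAMS)
        fus = [e for e in events if e.type == "fusion"]
        assert len(fus) == 1
        assert fus[0].gene_ids == ["rA"] and fus[0].side == "ref"

    def test_heavily_overlapping_subjects_are_not_fusion(self):
        c = MatchComponent(ref_genes=["rA"], pipe_genes=["p1", "p2"])
        hits = {
            "rA": _hs(
                "rA", 500,
                _hit("rA", "S1", 1, 400),
                _hit("rA", "S2", 50, 450),
            )
        }
        assert detect_fusion_fragmentation(c, hits, PARAMS) == []

    def test_empty_hit_sets_yield_no_events(self):
        c = MatchComponent(ref_genes=["rA"], pipe_genes=["p1", "p2"])
        assert detect_fusion_fragmentation(c, {}, PARAMS) == []

    def test_events_override_coverage(self):
        """Fragmented pipe side loses even with higher mean coverage."""
        c = MatchComponent(ref_genes=["rA"], pipe_genes=["p1", "p2"])
        ref_hits = {
            "rA": _hs("rA", 300, _hit("rA", "S", 1, 250, sstart=1, send=250))
        }  # cov 0.83
        pipe_hits = {
            "p1": _hs("p1", 140, _hit("p1", "S", 1, 140, sstart=1, send=140)),
            "p2": _hs("p2", 151, _hit("p2", "S", 1, 151, sstart=150, send=300)),
        }  # cov 1.0 each
        d = decide_component(c, 0, ref_hits, pipe_hits, PARAMS)
        assert d.kept_ref == ["rA"]
        assert any(e.type == "fragmentation" for e in d.events)


class TestReconcile:
    def test_idempotent_on_identical_annotations(self):
        genes = [
            GeneModel(f"g{i}", "chr1", "+", 1000 * i + 1, 1000 * i + 600,
                      protein_length=200)
            for i in range(10)
        ]
        ref = Annotation([GeneModel(g.gene_id, g.seqid, g.strand, g.start,
                                    g.end, "reference",
                                    protein_length=g.protein_length)
                          for g in genes])
        pipe = Annotation([GeneModel(g.gene_id + "_p", g.seqid, g.strand,
                                     g.start, g.end, "pipeline",
                                     protein_length=g.protein_length)
                           for g in genes])
        hits = {
            g.gene_id: _hs(g.gene_id, 200, _hit(g.gene_id, "s", 1, 200))
            for g in ref
        }
        merged, rep = reconcile(ref, pipe, hits, {}, PARAMS)
        assert list(merged) == list(ref)
        assert rep.n_added_pipe == 0 and rep.n_removed_ref == 0
        assert rep.n_merged == 10

    def test_pipe_only_bookkeeping(self):
        ref = Annotation(
            [GeneModel(f"r{i}", "chr1", "+", 10_000 * i + 1, 10_000 * i + 500,
                       "reference") for i in range(10)]
        )
        pipe = Annotation(
            [
                GeneModel("pA", "chr2", "+", 1, 500, "pipeline"),
                GeneModel("pB", "chr2", "+", 10_001, 10_500, "pipeline"),
                GeneModel("pC", "chr2", "+", 20_001, 20_500, "pipeline"),
            ]
        )
        pipe_hits = {
            "pA": _hs("pA", 100, _hit("pA", "s", 1, 90)),
            "pB": _hs("pB", 100, _hit("pB", "s", 1, 90)),
            "pC": _hs("pC", 100, _hit("pC", "s", 1, 50, evalue=10.0)),
        }
        merged, rep = reconcile(ref, pipe, {}, pipe_hits, PARAMS)
        assert rep.n_ref_total == 10
        assert rep.n_added_pipe == 2
        assert rep.n_merged == 12
        assert "pC" not in merged

    @pytest.mark.parametrize("seed", range(10))
    def test_ground_truth_recovery_on_planted_fixtures(self, tmp_path, seed):
        """Every planted component's decision matches its intended outcome."""
        spec = FixtureSpec(seed=200 + seed)
        paths = make_annotation_pair(spec, str(tmp_path / f"s{seed}"))
        ref, pipe, ref_hits, pipe_hits = load_pair(paths)
        merged, rep = reconcile(ref, pipe, ref_hits, pipe_hits, PARAMS)

        truth = pd.read_csv(paths["truth"], sep="\t").fillna("")
        kept = {g.gene_id for g in merged}
        n_match = 0
        for _, row in truth.iterrows():
            expected = {
                x
                for col in ("expected_kept_ref", "expected_kept_pipe")
                for x in str(row[col]).split(",")
                if x
            }
            members = {
                x
                for col in ("ref_ids", "pipe_ids")
                for x in str(row[col]).split(",")
                if x
            }
            n_match += (kept & members) == expected
        assert n_match == len(truth)
        # planted event counts surface in the report
        n_fusion_truth = (truth["expected_event"] == "fusion").sum()
        n_frag_truth = (truth["expected_event"] == "fragmentation").sum()
        assert rep.n_fusion_events == n_fusion_truth
        assert rep.n_fragmentation_events == n_frag_truth

    @pytest.mark.parametrize("seed", range(6))
    def test_conservation_invariant(self, tmp_path, seed):
        """n_merged = n_ref_total - n_removed_ref + n_added_pipe, always."""
        spec = FixtureSpec(seed=300 + seed)
        paths = make_annotation_pair(spec, str(tmp_path / f"s{seed}"))
        ref, pipe, ref_hits, pipe_hits = load_pair(paths)
        merged, rep = reconcile(ref, pipe, ref_hits, pipe_hits, PARAMS)
        assert rep.n_merged == rep.n_ref_total - rep.n_removed_ref + rep.n_added_pipe
        assert rep.n_kept_common == rep.n_ref_total - rep.n_removed_ref
        assert rep.n_merged == len(merged)
        # traceability: every merged gene comes from exactly one input
        for g in merged:
            src = ref.get(g.gene_id) or pipe.get(g.gene_id)
            assert src is not None and (g.start, g.end) == (src.start, src.end)

    def test_raising_evalue_max_never_decreases_added_genes(self, planted):
        added = []
        for emax in (1e-40, 1e-10, 1e-3, 1.0, 20.0):
            _, rep = reconcile(
                planted["ref"], planted["pipe"], planted["ref_hits"],
                planted["pipe_hits"], ReconcileParams(evalue_max=emax),
            )
            added.append(rep.n_added_pipe)
        assert added == sorted(added)

    def test_deterministic_given_identical_inputs(self, planted):
        run = lambda: reconcile(planted["ref"], planted["pipe"],
                                planted["ref_hits"], planted["pipe_hits"],
                                PARAMS)
        m1, r1 = run()
        m2, r2 = run()
        assert list(m1) == list(m2)
        assert [(d.component_id, d.kept, d.reason)
                for d in r1.per_component_decisions] == [
            (d.component_id, d.kept, d.reason)
            for d in r2.per_component_decisions
        ]


def test_report_arithmetic_identities():
    """The report's derived counts are pure bookkeeping arithmetic."""
    rep = ReconcileReport(n_ref_total=100, n_removed_ref=30, n_added_pipe=12)
    assert rep.n_kept_common == 70
    assert rep.n_merged == 82


def test_params_validation():
    with pytest.raises(ValueError):
        ReconcileParams(evalue_max=0)
    with pytest.raises(ValueError):
        ReconcileParams(coverage_tie_policy="prefer_chaos")
    with pytest.raises(ValueError):
        ReconcileParams(fusion_min_disjoint_fraction=1.5)
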