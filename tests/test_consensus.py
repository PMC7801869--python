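import itertools

import numpy as np
import pytest

import tmtopo.pipeline as pl
from tmtopo import PipelineConfig, run_family_pipeline
from tmtopo.consensus import (
    CandidateRegion,
    ColumnVoteMatrix,
    TopologyConstraints,
    TopologyError,
    assign_loop_sides,
    call_candidate_regions,
    cross_family_discrepancies,
    project_segments_to_columns,
    reconcile,
    required_parity,
)
from tmtopo.formats import Alignment, AnnotationTrack, Sequence
from tmtopo.hydropathy import PredictorOutput, TMSegment
from tmtopo.synthetic import FamilySimConfig, evolve_family, spec_for_n_tm


def votes_from(per_pred: np.ndarray, max_gap=0.5, gap_frac=None) -> ColumnVoteMatrix:
    n_pred, n_cols = per_pred.shape
    gap = np.zeros(n_cols) if gap_frac is None else np.asarray(gap_frac)
    return ColumnVoteMatrix(
        predictor_ids=[f"p{i}" for i in range(n_pred)],
        per_predictor=per_pred,
        aggregate=per_pred.mean(axis=0),
        gap_fraction=gap,
        callable_mask=gap <= max_gap,
        max_gap_fraction=max_gap,
    )


def brute_regions(votes, min_support, core_min, min_width, min_gap):
    """Direct scan implementing the candidate-region rule."""
    supported = [
        votes.callable_mask[c] and votes.aggregate[c] >= min_support
        for c in range(votes.n_columns)
    ]
    runs, cur = [], None
    for c, ok in enumerate(supported):
        if ok:
            cur = [c + 1, c + 1] if cur is None else [cur[0], c + 1]
        else:
            if cur:
                runs.append(tuple(cur))
            cur = None
    if cur:
        runs.append(tuple(cur))
    merged = []
    for run in runs:
        if merged:
            prev = merged[-1]
            between = range(prev[1] + 1, run[0])
            if (len(between) < min_gap
                    and all(votes.callable_mask[c - 1] for c in between)):
                merged[-1] = (prev[0], run[1])
                continue
        merged.append(run)
    out = []
    for span in merged:
        if span[1] - span[0] + 1 < min_width:
            continue
        strong = [
            c for c in range(span[0], span[1] + 1)
            if (votes.per_predictor[:, c - 1] >= min_support).sum() >= core_min
        ]
        cores, cur = [], None
        for c in strong:
            if cur and c == cur[-1] + 1:
                cur.append(c)
            else:
                if cur:
                    cores.append(cur)
                cur = [c]
        if cur:
            cores.append(cur)
        core = None
        if cores:
            best = max(cores, key=lambda r: (len(r), -r[0]))
            core = (best[0], best[-1])
        out.append((span, core))
    return out


def make_candidates(supports, width=10, gap=5):
    """Equal-width candidates laid left to right with the given supports."""
    cands = []
    col = 1
    for i, sup in enumerate(supports, start=1):
        span = (col, col + width - 1)
        cands.append(CandidateRegion(index=i, span=span, core=span, support=sup))
        col += width + gap
    return cands


def oracle_reconcile(cands, eligible, parity, must_include):
    """Exhaustive subset search under the documented deterministic tie rule."""
    best = None
    for r in range(len(eligible) + 1):
        for combo in itertools.combinations(sorted(eligible), r):
            if parity is not None and len(combo) % 2 != (1 if parity == "odd" else 0):
                continue
            if must_include is not None and must_include not in combo:
                continue
            key = (sum(cands[i].support for i in combo), -len(combo),
                   tuple(-i for i in combo))
            if best is None or key > best[0]:
                best = (key, combo)
    return list(best[1]) if best else None


class TestProjection:
    def test_single_ungapped_row_is_indicator(self):
        aln = Alignment(rows=[("s", "LLLLLDDDDD")])
        out = PredictorOutput("p", {"s": [TMSegment("s", 1, 5)]})
        votes = project_segments_to_columns(aln, [out])
        np.testing.assert_allclose(votes.per_predictor[0],
                                   [1] * 5 + [0] * 5)

    def test_gap_column_not_covered(self):
        aln = Alignment(rows=[("s", "A-CD")])
        out = PredictorOutput("p", {"s": [TMSegment("s", 2, 3)]})
        votes = project_segments_to_columns(aln, [out])
        np.testing.assert_allclose(votes.per_predictor[0], [0, 0, 1, 1])
        assert not votes.callable_mask[1]  # all-gap column is uncallable

    def test_row_duplication_leaves_support_unchanged(self, family11, family11_result):
        aln = family11.alignment
        outputs = pl.predict_tm_stage(family11.sequences, PipelineConfig())
        votes = project_segments_to_columns(aln, outputs)
        dup_rows = aln.rows + [(sid + "_dup", g) for sid, g in aln.rows]
        dup_outputs = []
        for out in outputs:
            segs = dict(out.segments)
            segs.update({
                sid + "_dup": [TMSegment(sid + "_dup", s.start, s.end, s.score,
                                         s.confidence, s.source)
                               for s in out.segments[sid]]
                for sid, _ in aln.rows
            })
            dup_outputs.append(PredictorOutput(out.predictor_id, segs))
        votes_dup = project_segments_to_columns(Alignment(rows=dup_rows), dup_outputs)
        np.testing.assert_allclose(votes.aggregate, votes_dup.aggregate, atol=1e-12)

    def test_segment_beyond_degapped_length_is_error(self):
        aln = Alignment(rows=[("s", "AC-D")])
        out = PredictorOutput("p", {"s": [TMSegment("s", 2, 4)]})
        with pytest.raises(ValueError, match="beyond degapped length"):
            project_segments_to_columns(aln, [out])


class TestCandidateRegions:
    def test_zero_votes_give_nothing(self):
        votes = votes_from(np.zeros((3, 40)))
        assert call_candidate_regions(votes) == []

    def test_two_plateaus_match_brute_force(self):
        per = np.zeros((4, 30))
        per[:, 2:12] = 1.0
        per[:2, 17:27] = 1.0
        per[2, 17:27] = 0.6
        votes = votes_from(per)
        regions = call_candidate_regions(votes, min_support=0.5,
                                         core_min_predictors=3, min_width=5)
        expected = brute_regions(votes, 0.5, 3, 5, 3)
        assert [(r.span, r.core) for r in regions] == expected
        assert len(regions) == 2

    @pytest.mark.parametrize("seed", range(40))
    def test_random_matrices_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_cols = int(rng.integers(20, 80))
        per = (rng.random((5, n_cols)) < 0.45).astype(float)
        per *= rng.random((5, n_cols)) * 0.5 + 0.5
        gaps = rng.random(n_cols) * (rng.random(n_cols) < 0.15)
        votes = votes_from(per, max_gap=0.3, gap_frac=gaps)
        min_width = int(rng.integers(2, 8))
        regions = call_candidate_regions(votes, min_support=0.4,
                                         core_min_predictors=3,
                                         min_width=min_width, min_gap=3)
        assert [(r.span, r.core) for r in regions] == \
            brute_regions(votes, 0.4, 3, min_width, 3)

    def test_lowering_support_never_loses_width(self, rng):
        per = rng.random((5, 60))
        votes = votes_from(per)
        def total_width(ms):
            regs = call_candidate_regions(votes, min_support=ms, min_width=1,
                                          min_gap=1)
            return sum(r.span[1] - r.span[0] + 1 for r in regs)
        assert total_width(0.3) >= total_width(0.6)


class TestParity:
    def test_opposite_sides_need_odd(self):
        assert required_parity("cytoplasmic", "lumenal") == "odd"
        assert required_parity("lumenal", "cytoplasmic") == "odd"

    def test_same_side_needs_even(self):
        assert required_parity("cytoplasmic", "cytoplasmic") == "even"

    def test_unknown_side_is_error(self):
        with pytest.raises(ValueError):
            required_parity("cytoplasmic", "unknown")


class TestReconcile:
    def test_twelve_candidates_one_masked_gives_eleven(self):
        # 12 equal-support candidates laid on a single ungapped reference
        # row; the 8th lies inside a lumenal-annotation mask (the classic
        # false-positive hydrophobic helix inside a long lumenal loop)
        cands = make_candidates([0.8] * 12)
        n_res = 12 * 15 + 10
        aln = Alignment(rows=[("ref", "L" * n_res)])
        for c in cands:
            c.span_by_seq["ref"] = c.span
            c.core_by_seq["ref"] = c.core
        m1, m2 = cands[7].span
        masks = AnnotationTrack(intervals=[("ref", m1 - 3, m2 + 3, "lumenal-helix")])
        constraints = TopologyConstraints(
            n_term_side="cytoplasmic", c_term_side="lumenal", masks=masks
        )
        model, report = reconcile(cands, constraints, aln)
        assert model.n_tm == 11
        assert cands[7].status == "masked"
        assert "mask-overlap" in report.classes()
        assert model.parity_ok

    def test_single_candidate_loop_sides(self):
        cands = make_candidates([0.9])
        constraints = TopologyConstraints(n_term_side="cytoplasmic",
                                          c_term_side="lumenal")
        model, _ = reconcile(cands, constraints)
        assert model.n_tm == 1
        assert model.loops[0].side == "cytoplasmic"
        assert model.loops[-1].side == "lumenal"

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_subset_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        cands = make_candidates(np.round(rng.random(n), 3).tolist())
        parity = "odd" if rng.random() < 0.5 else "even"
        anchors = (("cytoplasmic", "lumenal") if parity == "odd"
                   else ("cytoplasmic", "cytoplasmic"))
        constraints = TopologyConstraints(
            n_term_side=anchors[0], c_term_side=anchors[1],
            first_segment_signal_anchor=False,
        )
        expected = oracle_reconcile(cands, list(range(n)), parity, None)
        if expected is None:
            with pytest.raises(TopologyError):
                reconcile(cands, constraints)
            return
        model, _ = reconcile(cands, constraints)
        got = [cands.index(r) for r in model.tms]
        assert got == expected

    def test_signal_anchor_pins_first_candidate(self):
        # first candidate weakest: dropped without the pin, kept with it
        cands = make_candidates([0.1, 0.9, 0.9, 0.9])
        constraints = TopologyConstraints(
            n_term_side="cytoplasmic", c_term_side="lumenal",
            first_segment_signal_anchor=True,
        )
        model, report = reconcile(cands, constraints)
        assert cands[0].status == "accepted"
        assert model.n_tm == 3
        assert "signal-anchor-ambiguity" in report.classes()

    def test_unsatisfiable_parity_raises_with_report(self):
        constraints = TopologyConstraints(n_term_side="cytoplasmic",
                                          c_term_side="lumenal")
        with pytest.raises(TopologyError) as err:
            reconcile([], constraints)
        assert err.value.report is not None

    def test_accepted_regions_never_intersect_mask(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = int(r.integers(2, 12))
            cands = make_candidates(np.round(r.random(n), 3).tolist())
            aln = Alignment(rows=[("ref", "L" * (n * 15 + 10))])
            for c in cands:
                c.span_by_seq["ref"] = c.span
                c.core_by_seq["ref"] = c.core
            masked_idx = int(r.integers(n))
            m = cands[masked_idx].span
            masks = AnnotationTrack(intervals=[("ref", m[0], m[1], "mask")])
            constraints = TopologyConstraints(
                n_term_side="cytoplasmic",
                c_term_side="lumenal" if (n - 1) % 2 else "cytoplasmic",
                masks=masks, first_segment_signal_anchor=False,
            )
            try:
                model, _ = reconcile(cands, constraints, aln)
            except TopologyError:
                continue
            assert cands[masked_idx] not in model.tms


class TestLoopSides:
    def test_eleven_tm_layout(self):
        cands = make_candidates([0.8] * 11)
        constraints = TopologyConstraints(n_term_side="cytoplasmic",
                                          c_term_side="lumenal")
        model, _ = reconcile(cands, constraints)
        lumenal = [(lp.name, lp.after_tm) for lp in model.lumenal_loops()]
        assert lumenal == [("EL1", 1), ("EL2", 3), ("EL3", 5), ("EL4", 7),
                           ("EL5", 9)]
        assert model.c_term_side == "lumenal"

    def test_sides_strictly_alternate(self, family11_result):
        sides = [lp.side for lp in family11_result.model.loops]
        for a, b in zip(sides, sides[1:]):
            assert a != b

    def test_flipping_anchor_flips_every_label(self):
        cands = make_candidates([0.8] * 5)
        constraints = TopologyConstraints(n_term_side="cytoplasmic",
                                          c_term_side="lumenal")
        model, _ = reconcile(cands, constraints)
        before = [lp.side for lp in model.loops]
        assign_loop_sides(model, ("n", "lumenal"))
        after = [lp.side for lp in model.loops]
        assert all(a != b for a, b in zip(before, after))

    def test_parity_violation_is_error(self):
        cands = make_candidates([0.8] * 2)
        model, _ = reconcile(cands, TopologyConstraints(
            n_term_side="cytoplasmic", c_term_side="cytoplasmic"))
        model.parity_ok = False
        with pytest.raises(TopologyError):
            assign_loop_sides(model, ("n", "cytoplasmic"))


class TestCrossFamily:
    @staticmethod
    def _family(seed=7, n=4):
        cfg = FamilySimConfig(n_sequences=n, substitution_prob=0.0,
                              sprinkle_prob=0.0, indel_rate=0.0, seed=seed)
        return evolve_family(spec_for_n_tm(5), cfg)

    @staticmethod
    def _patch_member(fam, sid, start, end, replacement):
        """Overwrite residues [start, end] of one member in place (the
        family is ungapped, so alignment columns equal positions)."""
        idx = [s.id for s in fam.sequences].index(sid)
        seq = fam.sequences[idx]
        res = list(seq.residues)
        res[start - 1:end] = replacement
        new = "".join(res)
        fam.sequences[idx] = Sequence(id=sid, residues=new)
        fam.alignment.rows[idx] = (sid, new)

    def test_identical_members_report_nothing(self):
        fam = self._family()
        outputs = pl.predict_tm_stage(fam.sequences, PipelineConfig())
        votes, regions = pl.consensus_stage(fam.alignment, outputs, PipelineConfig())
        report = cross_family_discrepancies(fam.alignment, outputs, regions)
        assert report.items == []

    def test_deleted_tm_is_missing_in_sequence(self):
        fam = self._family()
        s, e = fam.root_truth.tm_intervals[2]
        # replace the whole TM with loop-like residues in one member
        self._patch_member(fam, "seq02", s, e,
                           ("DRNESQKTGP" * 3)[:e - s + 1])
        outputs = pl.predict_tm_stage(fam.sequences, PipelineConfig())
        votes, regions = pl.consensus_stage(fam.alignment, outputs, PipelineConfig())
        report = cross_family_discrepancies(fam.alignment, outputs, regions)
        missing = [d for d in report.items if d.klass == "missing-in-sequence"]
        assert any(d.subject == "seq02" for d in missing)

    def test_polar_substitutions_give_subthreshold(self):
        fam = self._family()
        s, e = fam.root_truth.tm_intervals[2]
        mid = (s + e) // 2
        # a polar stretch weakens the helix enough that most predictors
        # drop it in this member while the consensus region survives
        self._patch_member(fam, "seq02", mid - 6, mid + 5, "DSSDSSDSSDSS")
        outputs = pl.predict_tm_stage(fam.sequences, PipelineConfig())
        votes, regions = pl.consensus_stage(fam.alignment, outputs, PipelineConfig())
        report = cross_family_discrepancies(fam.alignment, outputs, regions)
        region3 = [r for r in regions
                   if r.span_by_seq["seq00"][0] <= s <= r.span_by_seq["seq00"][1]]
        assert region3
        flagged = [d for d in report.items
                   if d.region_index == region3[0].index and d.subject == "seq02"]
        assert flagged and flagged[0].klass in ("subthreshold",
                                                "missing-in-sequence")

    def test_signal_anchor_flag_marks_region_one(self):
        fam = self._family()
        outputs = pl.predict_tm_stage(fam.sequences, PipelineConfig())
        votes, regions = pl.consensus_stage(fam.alignment, outputs, PipelineConfig())
        report = cross_family_discrepancies(
            fam.alignment, outputs, regions, first_segment_signal_anchor=True
        )
        assert any(d.klass == "signal-anchor-ambiguity" and d.region_index == 1
                   for d in report.items)

    def test_requires_two_rows(self):
        aln = Alignment(rows=[("s", "LLLL")])
        with pytest.raises(ValueError):
            cross_family_discrepancies(aln, [], [])
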