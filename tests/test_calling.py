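"""Pooled calling threshold, replicate intersection, background filtering."""

import numpy as np
import pytest

from mutamosaic.calling import (
    BackgroundModel,
    PlaquePoolSample,
    call_mutations,
    calling_threshold,
)
from mutamosaic.pileup import BaseCountMatrix

REF = "GATTACAGCT" * 3


def _sample(n_plaques=300, **kw):
    base = dict(
        sample_id="s1", animal_id="a1", tissue="bone_marrow", dose=20.0,
        n_plaques=n_plaques, library_ids=("l1", "l2"),
    )
    base.update(kw)
    return PlaquePoolSample(**base)


def _lib(lib_id, depth=10_000, events=()):
    """Uniform-depth library with (pos, alt, count) events on top of ref."""
    m = BaseCountMatrix.empty(lib_id, REF)
    m.depth[:] = depth
    for i, b in enumerate(REF):
        m.base_counts[i, "ACGT".index(b)] = depth
    for pos, alt, count in events:
        if alt in "ACGT":
            m.base_counts[pos - 1, "ACGT".index(alt)] += count
            m.base_counts[pos - 1, "ACGT".index(REF[pos - 1])] -= count
        else:
            m.indels[(pos, alt)] = count
    m.validate()
    return m


class TestThreshold:
    def test_one_over_n_plaques(self):
        assert calling_threshold(_sample(300)) == pytest.approx(1 / 300)
        assert calling_threshold(_sample(500)) == 0.002
        assert calling_threshold(_sample(1)) == 1.0

    def test_zero_plaques_rejected(self):
        with pytest.raises(ValueError):
            calling_threshold(0)
        with pytest.raises(ValueError):
            _sample(0)

    def test_two_libraries_required(self):
        with pytest.raises(ValueError, match="two technical-replicate"):
            _sample(library_ids=("only_one",))


class TestBackground:
    def test_median_across_libraries(self):
        libs = [
            _lib("a", events=[(2, "C", 10)]),       # proportion 0.001
            _lib("b", events=[(2, "C", 10)]),
            _lib("c", events=[(2, "C", 500)]),      # one clonal sample: 0.05
        ]
        bg = BackgroundModel.from_libraries(libs)
        assert bg.rate(2, "C") == pytest.approx(0.001)

    def test_absent_class_has_zero_rate(self):
        bg = BackgroundModel.from_libraries([_lib("a"), _lib("b")])
        assert bg.rate(5, "T") == 0.0
        assert bg.rate(5, "INS") == 0.0

    def test_requires_two_libraries(self):
        with pytest.raises(ValueError):
            BackgroundModel.from_libraries([_lib("a")])


class TestCallMutations:
    def test_strict_threshold_in_both_replicates(self):
        s = _sample(300)  # threshold 1/300 ~ 0.00333
        rep1 = _lib("l1", events=[(2, "T", 40)])   # 0.004
        rep2 = _lib("l2", events=[(2, "T", 31)])   # 0.0031 < threshold
        assert call_mutations(s, rep1, rep2) == []
        rep2b = _lib("l2", events=[(2, "T", 50)])  # 0.005
        calls = call_mutations(s, rep1, rep2b)
        assert [c.position for c in calls] == [2]
        assert calls[0].mean_proportion == pytest.approx(0.0045)

    def test_background_filter_removes_systematic_sites(self):
        s = _sample(300)
        rep1 = _lib("l1", events=[(2, "T", 40)])
        rep2 = _lib("l2", events=[(2, "T", 50)])
        libs = [_lib(f"x{i}", events=[(2, "T", 400)]) for i in range(6)]
        bg = BackgroundModel.from_libraries(libs + [rep1, rep2])  # median 4%
        assert call_mutations(s, rep1, rep2, bg=bg) == []
        # exactly at the cutoff is also excluded ("must be < 2%")
        libs2 = [_lib(f"x{i}", events=[(2, "T", 200)]) for i in range(8)]
        bg2 = BackgroundModel.from_libraries(libs2)
        assert bg2.rate(2, "T") == pytest.approx(0.02)
        assert call_mutations(s, rep1, rep2, bg=bg2) == []

    def test_indels_intersect_by_anchor_and_sequence(self):
        s = _sample(100)
        rep1 = _lib("l1", events=[(6, "+AG", 300), (9, "-C", 300)])
        rep2 = _lib("l2", events=[(6, "+AG", 300), (9, "-G", 300)])
        calls = call_mutations(s, rep1, rep2)
        assert [(c.position, c.alt) for c in calls] == [(6, "+AG")]

    def test_two_alts_at_one_position_are_two_calls(self):
        s = _sample(100)
        events = [(2, "T", 300), (2, "C", 300)]
        calls = call_mutations(s, _lib("l1", events=events), _lib("l2", events=events))
        assert [(c.position, c.alt) for c in calls] == [(2, "C"), (2, "T")]

    def test_no_coverage_is_an_error(self):
        s = _sample(100)
        empty = BaseCountMatrix.empty("l1", REF)
        with pytest.raises(ValueError, match="no usable coverage"):
            call_mutations(s, empty, _lib("l2"))

    def test_monotone_in_n_plaques_and_background_cutoff(self):
        """Raising n_plaques or the background cutoff never removes a call."""
        events = [(2, "T", 80), (7, "C", 200), (15, "+A", 35)]
        rep1 = _lib("l1", events=events)
        rep2 = _lib("l2", events=[(p, a, c - 10) for p, a, c in events])
        bg = BackgroundModel.from_libraries([rep1, rep2])
        prev: set = set()
        for n in (50, 100, 300, 1000, 5000):
            got = {
                (c.position, c.alt)
                for c in call_mutations(_sample(n), rep1, rep2, bg=bg)
            }
            assert prev <= got
            prev = got
        prev = set()
        for cutoff in (0.001, 0.005, 0.02, 0.1, 1.0):
            got = {
                (c.position, c.alt)
                for c in call_mutations(
                    _sample(300), rep1, rep2, bg=bg, background_cutoff=cutoff
                )
            }
            assert prev <= got
            prev = got


class TestSimulatedRecovery:
    def test_all_injected_mutations_called_no_false_positives(self, small_experiment):
        exp = small_experiment
        bg = BackgroundModel.from_libraries(exp.libraries.values())
        truth_keys, called_keys = set(), set()
        for s in exp.samples:
            calls = call_mutations(
                s, exp.libraries[s.library_ids[0]], exp.libraries[s.library_ids[1]], bg=bg
            )
            called_keys |= {(s.sample_id, c.position, c.alt) for c in calls}
            t = exp.truth_mutations[exp.truth_mutations.sample_id == s.sample_id]
            truth_keys |= set(zip(t.sample_id, t.position, t.alt))
        assert truth_keys == called_keys

    def test_systematic_artifact_rejected_by_background_filter(self, small_experiment):
        exp = small_experiment
        pos = exp.artifact_position
        bg = BackgroundModel.from_libraries(exp.libraries.values())
        assert bg.rate(pos, "T") == pytest.approx(0.04, abs=0.01)
        s = exp.samples[0]
        rep1 = exp.libraries[s.library_ids[0]]
        rep2 = exp.libraries[s.library_ids[1]]
        # visible in both replicates, yet filtered by the 2% background rule
        assert rep1.proportion(pos, "T") > calling_threshold(s)
        assert rep2.proportion(pos, "T") > calling_threshold(s)
        calls = call_mutations(s, rep1, rep2, bg=bg)
        assert (pos, "T") not in {(c.position, c.alt) for c in calls}
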