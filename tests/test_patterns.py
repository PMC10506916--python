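"""Pattern analysis: matching, signatures, occurrence counts and
convergence detection."""

import pytest
from hypothesis import given, settings, strategies as st

from cortemf.patterns import (
    BaselineReference,
    SessionRecord,
    aggregate_baseline,
    cluster_frequencies,
    detect_convergence,
    interval_signature,
    match_peaks,
    occurrence_counts,
    optimal_match_count,
    signature_similarity,
    similarity_report,
)
from cortemf.spectral import SpectralFeatures


def features(peaks=(), valleys=()):
    return SpectralFeatures(
        peaks=tuple((f, 1.0) for f in peaks),
        valleys=tuple((f, 0.1) for f in valleys),
    )


def record(day, peaks=(), valleys=(), phase="post_stim"):
    return SessionRecord(day, phase, "B319", features(peaks, valleys))


# -- match_peaks ----------------------------------------------------------


def test_identical_sets_have_jaccard_one():
    pairs, j = match_peaks([2.5, 5.5, 6.7], [2.5, 5.5, 6.7], 0.2)
    assert j == 1.0
    assert len(pairs) == 3


def test_partial_overlap_jaccard_one_third():
    pairs, j = match_peaks([2.5, 5.5], [2.5, 10.5], tolerance=0.2)
    assert pairs == [(2.5, 2.5)]
    assert j == pytest.approx(1.0 / 3.0)


def test_two_empty_sets_are_identical_by_convention():
    _, j = match_peaks([], [], 0.2)
    assert j == 1.0


def test_tolerance_boundary_match_is_inclusive():
    pairs, _ = match_peaks([5.0], [5.2], tolerance=0.2)
    assert pairs == [(5.0, 5.2)]


small_sets = st.lists(
    st.floats(1.0, 12.0).map(lambda x: round(x, 1)), min_size=0, max_size=6, unique=True
)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(small_sets, small_sets)
def test_greedy_matching_equals_brute_force_optimum(a, b):
    pairs, j = match_peaks(a, b, 0.2)
    assert len(pairs) == optimal_match_count(a, b, 0.2)
    assert 0.0 <= j <= 1.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(small_sets, small_sets)
def test_similarity_scores_symmetric_and_bounded(a, b):
    _, j_ab = match_peaks(a, b, 0.2)
    _, j_ba = match_peaks(b, a, 0.2)
    assert j_ab == pytest.approx(j_ba)
    s_ab = signature_similarity(interval_signature(a), interval_signature(b))
    s_ba = signature_similarity(interval_signature(b), interval_signature(a))
    assert s_ab == pytest.approx(s_ba)
    assert 0.0 <= s_ab <= 1.0


# -- interval signatures --------------------------------------------------


def test_interval_signature_of_sorted_peaks():
    assert interval_signature([5.5, 2.5, 10.5]) == (3.0, 5.0)
    assert interval_signature([4.0]) == ()


def test_identical_signatures_have_similarity_one():
    assert signature_similarity((1.0, 2.1, 0.5), (1.0, 2.1, 0.5)) == 1.0


def test_single_substitution_on_two_intervals_scores_half():
    # {1,2,3} vs {1,2,4}: signatures (1,1) vs (1,2), edit distance 1 of 2
    a = interval_signature([1.0, 2.0, 3.0])
    b = interval_signature([1.0, 2.0, 4.0])
    assert signature_similarity(a, b) == pytest.approx(0.5)


def test_empty_signature_conventions():
    assert signature_similarity((), ()) == 1.0
    assert signature_similarity((), (1.0,)) == 0.0


# -- occurrence counts ----------------------------------------------------


def test_no_sessions_gives_empty_mapping():
    assert occurrence_counts([]) == {}


def test_occurrence_counts_manual_three_sessions():
    sessions = [record(0, [2.5]), record(1, [2.5, 5.5]), record(2, [5.5])]
    counts = occurrence_counts(sessions, tolerance=0.2)
    assert counts == {2.5: 2, 5.5: 2}


def test_occurrence_counts_permutation_invariant():
    sessions = [record(0, [2.5, 3.9]), record(1, [2.5]), record(2, [10.5, 3.9])]
    a = occurrence_counts(sessions)
    b = occurrence_counts(sessions[::-1])
    assert a == b


def test_cluster_frequencies_single_linkage_splits_at_gaps():
    clusters = cluster_frequencies([1.0, 1.1, 1.25, 2.0, 2.1], tolerance=0.2)
    assert clusters == [[1.0, 1.1, 1.25], [2.0, 2.1]]


# -- baseline aggregation and similarity ----------------------------------


def test_aggregate_baseline_unions_session_features():
    sessions = [
        record(0, [2.5, 5.5], [1.8], "preop"),
        record(1, [2.5, 3.9], [1.8, 3.2], "preop"),
    ]
    ref = aggregate_baseline(sessions, 0.2)
    assert ref.peak_frequencies == (2.5, 3.9, 5.5)
    assert ref.valley_frequencies == (1.8, 3.2)
    assert ref.n_sessions == 2


def test_aggregate_baseline_requires_sessions():
    with pytest.raises(ValueError):
        aggregate_baseline([])


def test_similarity_report_components_in_unit_interval(default_result):
    ref = default_result.baseline_reference
    for rec in default_result.post_stim_sessions:
        rep = similarity_report(rec.features, ref)
        for value in (rep.peak_jaccard, rep.valley_jaccard, rep.interval_similarity,
                      rep.valley_interval_similarity, rep.combined):
            assert 0.0 <= value <= 1.0
        assert rep.combined == pytest.approx(
            (rep.peak_jaccard + rep.valley_jaccard + rep.interval_similarity) / 3.0
        )


# -- convergence ----------------------------------------------------------


def _exhaustive_convergence(scores, days, threshold, sustain):
    """Oracle: brute-force scan over all suffixes."""
    for i, (d, s) in enumerate(zip(days, scores)):
        if s >= threshold and (not sustain or all(x >= threshold for x in scores[i:])):
            return d
    return None


def test_series_identical_to_baseline_converges_on_first_day():
    ref = BaselineReference((2.5, 5.5, 6.7), (1.8, 3.2), 1)
    series = [record(d, [2.5, 5.5, 6.7], [1.8, 3.2]) for d in range(3, 8)]
    assert detect_convergence(series, ref, threshold=0.7, sustain=True) == 3


def test_sustained_convergence_skips_transient_crossing():
    """Crossing at day 8, dip at day 9, sustained from day 12: the
    sustained detector must return 12 (oracle: exhaustive scan)."""
    ref = BaselineReference((2.0, 4.0, 6.0, 8.0), (3.0, 5.0), 1)
    good = [2.0, 4.0, 6.0, 8.0]
    bad = [2.9, 4.7, 7.3]
    by_day = {7: bad, 8: good, 9: bad, 10: bad, 11: bad, 12: good, 13: good, 14: good}
    series = [record(d, peaks) for d, peaks in sorted(by_day.items())]
    scores = [
        similarity_report(r.features, ref).score("peaks") for r in series
    ]
    oracle = _exhaustive_convergence(scores, sorted(by_day), 0.7, sustain=True)
    assert oracle == 12
    assert detect_convergence(series, ref, 0.7, sustain=True, mode="peaks") == 12
    assert detect_convergence(series, ref, 0.7, sustain=False, mode="peaks") == 8


def test_empty_series_returns_none():
    ref = BaselineReference((2.5,), (), 1)
    assert detect_convergence([], ref) is None


def test_never_crossing_returns_none():
    ref = BaselineReference((2.5, 5.5, 7.5, 9.5), (), 1)
    series = [record(d, [1.3, 4.4, 6.1]) for d in range(5)]
    assert detect_convergence(series, ref, threshold=0.7) is None


def test_unordered_series_rejected():
    ref = BaselineReference((2.5,), (), 1)
    series = [record(5, [2.5]), record(3, [2.5])]
    with pytest.raises(ValueError, match="ordered"):
        detect_convergence(series, ref)


def test_unknown_mode_rejected():
    ref = BaselineReference((2.5,), (), 1)
    with pytest.raises(ValueError, match="mode"):
        detect_convergence([record(0, [2.5])], ref, mode="slopes")


# -- packaged-scenario behaviour ------------------------------------------


def test_conserved_frequencies_present_in_both_data_sets(default_result):
    """10.5 and 3.9 Hz recur pre-operatively and post-stimulation: both
    are matched between the baseline reference and a late post-stimulation
    session's peak set."""
    ref = default_result.baseline_reference
    late = [r for r in default_result.post_stim_sessions if r.day_index >= 17]
    matched = set()
    for rec in late:
        pairs, _ = match_peaks(rec.features.peak_frequencies(), ref.peak_frequencies, 0.2)
        matched |= {b for _, b in pairs}
    assert any(abs(f - 10.5) <= 0.2 for f in matched)
    assert any(abs(f - 3.9) <= 0.2 for f in matched)


def test_10p5_hz_is_most_frequent_peak_across_all_sessions(default_result):
    counts = default_result.occurrence_table
    top_freq, top_count = max(counts.items(), key=lambda kv: kv[1])
    assert abs(top_freq - 10.5) <= 0.2
    runners = [c for f, c in counts.items() if abs(f - 10.5) > 0.2]
    assert top_count > max(runners)


def test_signature_similarity_rises_toward_convergence(default_result):
    """Post-stimulation sessions near convergence match the baseline
    interval signature better than the immediate post-injury session."""
    ref = default_result.baseline_reference
    def sig_sim(rec):
        return signature_similarity(
            interval_signature(rec.features.peak_frequencies()), ref.peak_signature
        )
    early = sig_sim(default_result.post_cci_session)
    late = [sig_sim(r) for r in default_result.post_stim_sessions if r.day_index >= 10]
    assert min(late) > early
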