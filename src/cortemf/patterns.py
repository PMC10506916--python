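"""Deterministic cross-session pattern analysis.

Replaces the manual/large-language-model pattern reading of daily
peak/valley lists with three explicit criteria: repeated values
(tolerance-matched peak sets and their Jaccard index), intervals between
peaks (interval signatures), and similar sequences (normalised edit
distance between interval signatures).  A session series "converges"
when its combined similarity to the pre-operative baseline first crosses
a threshold -- optionally sustained through every later session.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from statistics import fmean
from typing import Iterable, Optional, Sequence

import numpy as np

from .spectral import SpectralFeatures

DEFAULT_TOLERANCE = 0.2  # Hz; one 0.1 Hz reporting-grid step each side
DEFAULT_THRESHOLD = 0.7
MODES = ("peaks", "valleys", "combined")


@dataclass(frozen=True)
class SessionRecord:
    """Feature set of one daily measurement."""

    day_index: int
    phase_label: str
    sensor_id: str
    features: SpectralFeatures

    def __post_init__(self) -> None:
        if self.day_index < 0:
            raise ValueError("day_index must be >= 0")


@dataclass(frozen=True)
class SimilarityReport:
    """Similarity of one session's features to a baseline reference.

    All components lie in [0, 1]; ``combined`` is the unweighted mean of
    the peak Jaccard, valley Jaccard and peak-interval similarity.
    """

    peak_jaccard: float
    valley_jaccard: float
    interval_similarity: float
    valley_interval_similarity: float
    combined: float

    def score(self, mode: str) -> float:
        if mode == "peaks":
            return 0.5 * (self.peak_jaccard + self.interval_similarity)
        if mode == "valleys":
            return 0.5 * (self.valley_jaccard + self.valley_interval_similarity)
        if mode == "combined":
            return self.combined
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def match_peaks(
    set_a: Sequence[float],
    set_b: Sequence[float],
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[list[tuple[float, float]], float]:
    """Greedy nearest-frequency matching of two peak (or valley) sets.

    Pairs are formed in order of increasing frequency difference, each
    element used at most once, and only within ``tolerance``.  Returns the
    matched pairs and the Jaccard index |M| / (|A| + |B| - |M|); two empty
    sets are identical by convention (Jaccard 1).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    a = sorted(set_a)
    b = sorted(set_b)
    if not a and not b:
        return [], 1.0
    candidates = sorted(
        ((abs(fa - fb), i, j) for i, fa in enumerate(a) for j, fb in enumerate(b)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[float, float]] = []
    for d, i, j in candidates:
        if d > tolerance + 1e-9:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((a[i], b[j]))
    m = len(pairs)
    jaccard = m / (len(a) + len(b) - m)
    return sorted(pairs), jaccard


def optimal_match_count(
    set_a: Sequence[float], set_b: Sequence[float], tolerance: float = DEFAULT_TOLERANCE
) -> int:
    """Exhaustive maximum matching size (oracle for small sets)."""
    a, b = list(set_a), list(set_b)
    if len(a) > len(b):
        a, b = b, a
    best = 0
    for perm in permutations(range(len(b)), len(a)):
        best = max(
            best, sum(1 for i, j in enumerate(perm) if abs(a[i] - b[j]) <= tolerance + 1e-9)
        )
    return best


def interval_signature(peaks: Sequence[float]) -> tuple[float, ...]:
    """Ordered inter-peak intervals of the frequency-sorted peak list."""
    freqs = sorted(peaks)
    return tuple(round(b - a, 6) for a, b in zip(freqs, freqs[1:]))


def _edit_distance(a: Sequence[int], b: Sequence[int], match_within: int = 0) -> int:
    # Levenshtein distance on small quantized-interval sequences; tokens
    # within `match_within` quanta of each other count as equal
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            sub = prev[j - 1] + (abs(ca - cb) > match_within)
            cur.append(min(prev[j] + 1, cur[-1] + 1, sub))
        prev = cur
    return prev[-1]


def signature_similarity(
    sig_a: Sequence[float],
    sig_b: Sequence[float],
    quantum: float = 0.1,
    tolerance: float = 0.1,
) -> float:
    """1 minus the normalised edit distance between interval signatures.

    Intervals are quantized to ``quantum`` Hz before comparison; two
    quantized intervals differing by no more than ``tolerance`` (default
    one reporting-grid step) count as the same token.  Two empty
    signatures are identical (similarity 1); an empty versus a non-empty
    signature scores 0.
    """
    if not sig_a and not sig_b:
        return 1.0
    if not sig_a or not sig_b:
        return 0.0
    qa = [int(round(x / quantum)) for x in sig_a]
    qb = [int(round(x / quantum)) for x in sig_b]
    within = int(round(tolerance / quantum))
    dist = _edit_distance(qa, qb, match_within=within)
    return 1.0 - dist / max(len(qa), len(qb))


def cluster_frequencies(
    values: Iterable[float], tolerance: float = DEFAULT_TOLERANCE
) -> list[list[float]]:
    """Single-linkage 1-D clustering: split sorted values at gaps > tolerance."""
    vals = sorted(values)
    if not vals:
        return []
    clusters = [[vals[0]]]
    for v in vals[1:]:
        if v - clusters[-1][-1] <= tolerance:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return clusters


def occurrence_counts(
    sessions: Sequence[SessionRecord],
    tolerance: float = DEFAULT_TOLERANCE,
    kind: str = "peaks",
) -> dict[float, int]:
    """How many sessions exhibit each (tolerance-clustered) frequency.

    Frequencies from all sessions are pooled and single-linkage clustered;
    each cluster is keyed by the mean of its members and counted once per
    session that contributes at least one member.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    tagged: list[tuple[float, int]] = []
    for s_idx, rec in enumerate(sessions):
        freqs = rec.features.peak_frequencies() if kind == "peaks" else rec.features.valley_frequencies()
        tagged.extend((f, s_idx) for f in freqs)
    if not tagged:
        return {}
    tagged.sort()
    clusters: list[list[tuple[float, int]]] = [[tagged[0]]]
    for item in tagged[1:]:
        if item[0] - clusters[-1][-1][0] <= tolerance:
            clusters[-1].append(item)
        else:
            clusters.append([item])
    out: dict[float, int] = {}
    for cl in clusters:
        centre = round(fmean(f for f, _ in cl), 6)
        out[centre] = len({s for _, s in cl})
    return out


@dataclass(frozen=True)
class BaselineReference:
    """Tolerance-clustered union of the pre-operative sessions' features."""

    peak_frequencies: tuple[float, ...]
    valley_frequencies: tuple[float, ...]
    n_sessions: int

    @property
    def peak_signature(self) -> tuple[float, ...]:
        return interval_signature(self.peak_frequencies)

    @property
    def valley_signature(self) -> tuple[float, ...]:
        return interval_signature(self.valley_frequencies)


def aggregate_baseline(
    sessions: Sequence[SessionRecord],
    tolerance: float = DEFAULT_TOLERANCE,
    grid: float = 0.1,
) -> BaselineReference:
    """Build the pre-operative reference from >= 1 baseline session.

    Cluster centres are snapped back to the feature-reporting grid so the
    reference lives on the same frequency lattice as the per-session
    feature lists it is compared against.
    """
    if not sessions:
        raise ValueError("baseline reference requires at least one session")
    peak_clusters = cluster_frequencies(
        (f for rec in sessions for f in rec.features.peak_frequencies()), tolerance
    )
    valley_clusters = cluster_frequencies(
        (f for rec in sessions for f in rec.features.valley_frequencies()), tolerance
    )

    def centre(cluster: list[float]) -> float:
        return round(round(fmean(cluster) / grid) * grid, 6)

    return BaselineReference(
        peak_frequencies=tuple(centre(c) for c in peak_clusters),
        valley_frequencies=tuple(centre(c) for c in valley_clusters),
        n_sessions=len(sessions),
    )


def similarity_report(
    features: SpectralFeatures,
    reference: BaselineReference,
    tolerance: float = DEFAULT_TOLERANCE,
) -> SimilarityReport:
    """Score one session's features against the baseline reference."""
    peaks = features.peak_frequencies()
    valleys = features.valley_frequencies()
    _, p_j = match_peaks(peaks, reference.peak_frequencies, tolerance)
    _, v_j = match_peaks(valleys, reference.valley_frequencies, tolerance)
    i_sim = signature_similarity(interval_signature(peaks), reference.peak_signature)
    vi_sim = signature_similarity(interval_signature(valleys), reference.valley_signature)
    return SimilarityReport(
        peak_jaccard=p_j,
        valley_jaccard=v_j,
        interval_similarity=i_sim,
        valley_interval_similarity=vi_sim,
        combined=(p_j + v_j + i_sim) / 3.0,
    )


def detect_convergence(
    series: Sequence[SessionRecord],
    baseline_reference: BaselineReference,
    threshold: float = DEFAULT_THRESHOLD,
    sustain: bool = True,
    mode: str = "peaks",
    tolerance: float = DEFAULT_TOLERANCE,
) -> Optional[int]:
    """First day the series resembles the pre-operative baseline.

    Sessions must be ordered by day.  Returns the day index of the first
    session whose similarity score (in the given mode) reaches
    ``threshold``; with ``sustain`` set, every subsequent session must
    also stay at or above the threshold.  ``None`` when the criterion is
    never met (including for an empty series).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if not series:
        return None
    days = [rec.day_index for rec in series]
    if days != sorted(days):
        raise ValueError("series must be ordered by day")
    scores = [
        similarity_report(rec.features, baseline_reference, tolerance).score(mode)
        for rec in series
    ]
    if sustain:
        ok_from = len(scores)
        for i in range(len(scores) - 1, -1, -1):
            if scores[i] >= threshold:
                ok_from = i
            else:
                break
        return series[ok_from].day_index if ok_from < len(scores) else None
    for rec, s in zip(series, scores):
        if s >= threshold:
            return rec.day_index
    return None
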