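"""T-cell splicing distance and per-sample splicing similarity scores.

The *splicing distance* between two cell subtypes is the Euclidean
distance of logit-transformed PSI profiles over events expressed in
both subtypes, after linearly rescaling each event's PSI values across
the compared subtypes onto [0.01, 0.99] (which keeps the logit finite
at boundary PSIs).

The *similarity score* places a sample's pooled PSI on the axis
between two anchor subtypes A and B: per event l it is 0 at or below
the A anchor, 1 at or above the B anchor, and linear in between; when
PSI_A > PSI_B the anchors swap roles. The per-sample score S_t is the
mean over axis events with at least ``min_reads`` junction reads in
that sample; samples where more than ``max_missing_fraction`` of axis
events fall under the read floor are excluded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

MIN_READS = 5
MAX_MISSING_FRACTION = 1.0 / 3.0
SCALE_LO = 0.01
SCALE_HI = 0.99


@dataclass(frozen=True)
class SplicingDistance:
    subtype_a: str
    subtype_b: str
    distance: float
    n_shared_events: int


@dataclass(frozen=True)
class SimilarityScore:
    sample_id: str
    axis: tuple[str, str]
    score: float | None
    n_events_used: int
    excluded: bool
    reason: str | None = None


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _rescale(values: np.ndarray) -> np.ndarray:
    """Fixed affine map sending PSI in [0, 1] onto [0.01, 0.99].

    A fixed map (rather than a per-event min/max stretch) keeps the
    logit finite at boundary PSIs while leaving the transform identical
    for every subtype pair, so pairwise distances form a true Euclidean
    metric."""
    return SCALE_LO + (SCALE_HI - SCALE_LO) * values


def splicing_distance(
    psi_profiles: Mapping[str, Mapping[str, float]],
) -> list[SplicingDistance]:
    """Pairwise splicing distances between subtypes.

    ``psi_profiles`` maps subtype -> {event_id -> PSI}; only events
    present (expressed) in both subtypes of a pair enter that pair's
    distance. Per event, PSIs are affinely rescaled onto [0.01, 0.99],
    logit-transformed, and the Euclidean norm of the difference vector
    is the distance.
    """
    subtypes = sorted(psi_profiles)
    if len(subtypes) < 2:
        raise ValueError("need at least two subtypes")
    out = []
    for a, b in itertools.combinations(subtypes, 2):
        shared = sorted(set(psi_profiles[a]) & set(psi_profiles[b]))
        if not shared:
            raise ValueError(f"no shared events between {a} and {b}")
        sq = 0.0
        for ev in shared:
            pair = _rescale(
                np.array([psi_profiles[a][ev], psi_profiles[b][ev]], dtype=float)
            )
            sq += (_logit(pair[0]) - _logit(pair[1])) ** 2
        out.append(
            SplicingDistance(
                subtype_a=a,
                subtype_b=b,
                distance=math.sqrt(sq),
                n_shared_events=len(shared),
            )
        )
    return out


def event_similarity(psi_t: float, psi_a: float, psi_b: float) -> float:
    """Piecewise-linear position of psi_t between the anchors.

    0 at or below anchor A, 1 at or above anchor B, linear in between;
    anchors swap when psi_a > psi_b. Anchors must differ.
    """
    if psi_a == psi_b:
        raise ValueError("anchor PSIs must differ")
    if psi_a > psi_b:
        psi_a, psi_b = psi_b, psi_a
        return 1.0 - event_similarity(psi_t, psi_a, psi_b)
    if psi_t <= psi_a:
        return 0.0
    if psi_t >= psi_b:
        return 1.0
    return (psi_t - psi_a) / (psi_b - psi_a)


def similarity_score(
    sample_id: str,
    axis: tuple[str, str],
    events: Sequence[dict],
    min_reads: int = MIN_READS,
    max_missing_fraction: float = MAX_MISSING_FRACTION,
) -> SimilarityScore:
    """Per-sample similarity score along a subtype axis.

    ``events`` rows need keys psi_a, psi_b (anchor PSIs), psi_t
    (sample pooled PSI, may be None) and reads (junction reads in the
    sample). Events with equal anchors are skipped; events under the
    read floor are not averaged, and the sample is excluded when more
    than ``max_missing_fraction`` of axis events are under the floor.
    """
    usable = [e for e in events if e["psi_a"] != e["psi_b"]]
    if not usable:
        raise ValueError("no axis events with distinct anchors")
    low = [e for e in usable if e.get("reads", 0) < min_reads]
    if len(low) / len(usable) > max_missing_fraction:
        return SimilarityScore(
            sample_id=sample_id,
            axis=axis,
            score=None,
            n_events_used=0,
            excluded=True,
            reason=f"{len(low)}/{len(usable)} axis events with <{min_reads} reads",
        )
    used = [e for e in usable if e.get("reads", 0) >= min_reads]
    scores = [
        event_similarity(e["psi_t"], e["psi_a"], e["psi_b"]) for e in used
    ]
    return SimilarityScore(
        sample_id=sample_id,
        axis=axis,
        score=float(np.mean(scores)),
        n_events_used=len(used),
        excluded=False,
    )
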