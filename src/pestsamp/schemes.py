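"""Sampling-scheme trajectories: random, collection-order, belt transect.

A trajectory is an ordered sequence of tree indices into a site's
pre-sample; the evaluation module turns trajectories into estimate and
error curves.  Random trajectories draw with replacement (the pre-sample is
itself a sample of the stand); ordered and transect trajectories are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .site_data import SiteSample

__all__ = [
    "TransectSpec",
    "Trajectory",
    "random_trajectory",
    "ordered_trajectory",
    "transect_membership",
    "transect_trajectory",
]


@dataclass(frozen=True)
class TransectSpec:
    """A belt-transect set: centre line from start to end, width w, jitter j.

    The set expands into three parallel transects: the centre line, then a
    copy displaced ``jitter_j`` metres to the left of the direction of
    travel, then one to the right.  "Left" is +90 degrees counter-clockwise
    from the travel direction in the east-north plane.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    width_w: float
    jitter_j: float = 0.0

    def __post_init__(self) -> None:
        if self.width_w <= 0:
            raise ValueError("width_w must be positive")
        if self.jitter_j < 0:
            raise ValueError("jitter_j must be non-negative")
        if tuple(self.start) == tuple(self.end):
            raise ValueError("start and end must differ")


@dataclass
class Trajectory:
    """An ordered sequence of tree indices produced by a sampling scheme."""

    scheme: str
    indices: np.ndarray
    replicate_id: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise ValueError("empty trajectory")

    def __len__(self) -> int:
        return int(self.indices.size)


def random_trajectory(
    site: SiteSample, n_max: int, seed: int, replicate_id: int = 0
) -> Trajectory:
    """Draw ``n_max`` trees uniformly, independently, with replacement.

    The random stream is derived from ``(seed, replicate_id)`` so that every
    replicate of a simulation is individually reproducible.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rng = np.random.default_rng([seed, replicate_id])
    idx = rng.integers(0, site.n_trees, size=n_max)
    return Trajectory(scheme="random", indices=idx, replicate_id=replicate_id,
                      metadata={"seed": seed})


def ordered_trajectory(site: SiteSample, reverse: bool = False) -> Trajectory:
    """All trees in field-collection order (or its exact reversal)."""
    order = np.array([t.collection_index for t in site.trees])
    if len(set(order.tolist())) != order.size:
        raise ValueError("duplicate collection_index")
    idx = np.argsort(order, kind="stable")
    if reverse:
        idx = idx[::-1]
    return Trajectory(scheme="ordered_reverse" if reverse else "ordered",
                      indices=idx)


def transect_membership(
    site: SiteSample,
    start: tuple[float, float],
    end: tuple[float, float],
    width_w: float,
) -> np.ndarray:
    """Trees inside a belt transect, ordered along the direction of travel.

    A tree is included iff its along-track projection lies in the closed
    segment [0, L] and its cross-track distance is at most ``width_w / 2``
    (closed boundaries).  Ties in along-track position break by tree_id.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    axis = end - start
    length = float(np.linalg.norm(axis))
    if length == 0:
        raise ValueError("start and end must differ")
    d = axis / length

    v = site.coords() - start
    t = v @ d
    cross = v[:, 0] * d[1] - v[:, 1] * d[0]  # signed cross-track offset
    inside = (t >= 0) & (t <= length) & (np.abs(cross) <= width_w / 2.0)

    ids = np.array([tr.tree_id for tr in site.trees])
    cand = np.nonzero(inside)[0]
    order = np.lexsort((ids[cand], t[cand]))
    return cand[order]


def _expand_set(spec: TransectSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    start = np.asarray(spec.start, dtype=float)
    end = np.asarray(spec.end, dtype=float)
    axis = end - start
    d = axis / np.linalg.norm(axis)
    left = np.array([-d[1], d[0]])  # +90 deg counter-clockwise
    j = spec.jitter_j
    return [
        (start, end),
        (start + j * left, end + j * left),
        (start - j * left, end - j * left),
    ]


def transect_trajectory(
    site: SiteSample,
    sets: TransectSpec | list[TransectSpec],
    reverse: bool = False,
) -> Trajectory:
    """Belt-transect trajectory over one or two transect sets.

    Each set expands into centre, left-jittered and right-jittered
    transects; with two sets the transects interleave A1, B1, A2, B2, A3,
    B3.  A tree reachable from several transects is kept at its first
    occurrence only, preserving the order in which trees are encountered.
    """
    if isinstance(sets, TransectSpec):
        sets = [sets]
    if not 1 <= len(sets) <= 2:
        raise ValueError("one or two transect sets supported")

    expanded = [_expand_set(s) for s in sets]
    # interleave: A1, B1, A2, B2, A3, B3
    lines = [expanded[s][rank] for rank in range(3) for s in range(len(sets))]

    seen: set[int] = set()
    seq: list[int] = []
    for (a, b), spec in zip(lines, [s for _ in range(3) for s in sets]):
        for idx in transect_membership(site, a, b, spec.width_w):
            if int(idx) not in seen:
                seen.add(int(idx))
                seq.append(int(idx))
    if not seq:
        raise ValueError("no trees fall in any transect")
    if reverse:
        seq = seq[::-1]
    return Trajectory(
        scheme="transect_reverse" if reverse else "transect",
        indices=np.array(seq),
        metadata={
            "n_sets": len(sets),
            "width_w": [s.width_w for s in sets],
            "jitter_j": [s.jitter_j for s in sets],
            "handedness": "left = +90 deg counter-clockwise from travel",
        },
    )
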