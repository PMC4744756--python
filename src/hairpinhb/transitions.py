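"""Population change maps and greedy folding-pathway extraction.

Transitions are counted between consecutive saved frames within each run;
pairs spanning run boundaries are never counted, since independent
production runs share no dynamics. Row-normalizing the count matrix gives a
population change map: entry (i, j) is the percentage of frames in pattern
i whose successor frame is in pattern j.

The most probable folding pathway from the fully open ``oooo`` state to the
fully closed ``cccc`` state follows, from each state, the destination with
the highest off-diagonal percentage. Already-visited states are never
re-entered (the raw greedy rule can cycle); ties prefer the destination
with more closed bonds, then the lexicographically smaller label. At each
step the second-best destination is recorded as the alternative branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import PathwayError, ValidationError
from .patterns import ALL_PATTERNS, n_closed

__all__ = [
    "TransitionMap",
    "PathStep",
    "FoldingPathway",
    "count_transitions",
    "normalize_map",
    "extract_pathway",
    "restrict_map",
]


@dataclass
class TransitionMap:
    """Pattern-to-pattern transition counts and row percentages.

    ``counts[i, j]`` is the number of within-run frame pairs going from
    ``states[i]`` to ``states[j]``; ``percentages`` is the row-normalized
    map (×100), with rows of all-zero counts flagged undefined (NaN).
    Either matrix may be absent (``None``) depending on provenance — a map
    transcribed from a published table carries percentages only.
    """

    states: list[str]
    counts: np.ndarray | None = None
    percentages: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.states)
        if len(set(self.states)) != n:
            raise ValidationError("duplicate state labels in transition map")
        for name in ("counts", "percentages"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, float)
                if m.shape != (n, n):
                    raise ValidationError(f"{name} must be {n}x{n}, got {m.shape}")
                setattr(self, name, m)
        if self.counts is not None:
            if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
                raise ValidationError("counts must be non-negative integers")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index_of(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValidationError(f"state {state!r} not in transition map") from None

    def defined_rows(self) -> np.ndarray:
        """Boolean mask of rows whose percentages are defined."""
        if self.percentages is None:
            raise ValidationError("percentages not filled")
        return ~np.isnan(self.percentages).all(axis=1)


def count_transitions(
    pattern_runs: Iterable[Sequence[str]], states: Sequence[str] | None = None
) -> TransitionMap:
    """Count frame-to-frame pattern transitions over one or more runs.

    Each element of ``pattern_runs`` is the ordered pattern sequence of one
    run; consecutive pairs within a run increment the count matrix
    (self-pairs land on the diagonal). Pairs across run boundaries are not
    counted.
    """
    states = list(states) if states is not None else list(ALL_PATTERNS)
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)), dtype=np.int64)
    any_frames = False
    for run in pattern_runs:
        run = list(run)
        if not run:
            continue
        any_frames = True
        try:
            codes = np.array([index[p] for p in run], dtype=np.intp)
        except KeyError as exc:
            raise ValidationError(f"pattern {exc.args[0]!r} not in state list") from None
        if len(codes) > 1:
            np.add.at(counts, (codes[:-1], codes[1:]), 1)
    if not any_frames:
        raise ValidationError("no frames given")
    return TransitionMap(states=states, counts=counts.astype(float))


def normalize_map(tmap: TransitionMap) -> TransitionMap:
    """Fill row percentages: 100 × counts / row sum; all-zero rows → NaN."""
    if tmap.counts is None:
        raise ValidationError("counts not filled")
    rowsum = tmap.counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(rowsum > 0, 100.0 * tmap.counts / rowsum, np.nan)
    return TransitionMap(states=list(tmap.states), counts=tmap.counts.copy(), percentages=pct)


@dataclass(frozen=True)
class PathStep:
    """One step of a folding pathway with its alternative branch."""

    source: str
    destination: str
    percent: float
    alt_destination: str | None = None
    alt_percent: float | None = None


@dataclass
class FoldingPathway:
    """Ordered pattern sequence from start to end with per-step percentages."""

    states: list[str]
    steps: list[PathStep] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise ValidationError("pathway revisits a state")
        for a, b, step in zip(self.states, self.states[1:], self.steps):
            if step.source != a or step.destination != b:
                raise ValidationError("pathway steps inconsistent with state sequence")

    @property
    def start(self) -> str:
        return self.states[0]

    @property
    def end(self) -> str:
        return self.states[-1]


def _candidate_order(tmap: TransitionMap, row: int, excluded: set[int]) -> list[int]:
    """Column indices of row sorted by descending percentage; ties prefer
    more closed bonds, then the lexicographically smaller label."""
    pct = tmap.percentages[row]
    candidates = [
        j
        for j in range(tmap.n_states)
        if j != row and j not in excluded and not np.isnan(pct[j]) and pct[j] > 0
    ]
    return sorted(
        candidates,
        key=lambda j: (-pct[j], -n_closed(tmap.states[j]), tmap.states[j]),
    )


def extract_pathway(
    tmap: TransitionMap, start: str = "oooo", end: str = "cccc"
) -> FoldingPathway:
    """Greedy most-probable pathway from ``start`` to ``end``.

    From each state, move to the not-yet-visited destination with the
    highest off-diagonal percentage; record the runner-up as the
    alternative branch. Raise :class:`PathwayError` (carrying the partial
    path) when no admissible destination remains before reaching ``end``.
    """
    if tmap.percentages is None:
        raise ValidationError("percentages not filled; call normalize_map first")
    i_start = tmap.index_of(start)
    tmap.index_of(end)

    path = [start]
    steps: list[PathStep] = []
    visited = {i_start}
    current = i_start
    while tmap.states[current] != end:
        if not tmap.defined_rows()[current]:
            raise PathwayError(
                f"row {tmap.states[current]!r} has no observed transitions", path
            )
        order = _candidate_order(tmap, current, visited)
        if not order:
            raise PathwayError(
                f"no unvisited destination with positive probability from "
                f"{tmap.states[current]!r}",
                path,
            )
        best = order[0]
        # the branch annotation may point at any state, including visited ones
        branch_order = _candidate_order(tmap, current, {current, best})
        alt = branch_order[0] if branch_order else None
        steps.append(
            PathStep(
                source=tmap.states[current],
                destination=tmap.states[best],
                percent=float(tmap.percentages[current, best]),
                alt_destination=tmap.states[alt] if alt is not None else None,
                alt_percent=float(tmap.percentages[current, alt]) if alt is not None else None,
            )
        )
        path.append(tmap.states[best])
        visited.add(best)
        current = best
    return FoldingPathway(states=path, steps=steps)


def restrict_map(tmap: TransitionMap, keep: Sequence[str], other_label: str = "other") -> TransitionMap:
    """Aggregate all states outside ``keep`` into a single row/column.

    Mirrors reporting only the prominently populated patterns while folding
    the remaining ones into an "other" aggregate. Requires counts; the
    restricted map is re-normalized from the aggregated counts.
    """
    if tmap.counts is None:
        raise ValidationError("restriction requires raw counts")
    keep = list(keep)
    for s in keep:
        tmap.index_of(s)
    others = [i for i, s in enumerate(tmap.states) if s not in keep]
    idx_keep = [tmap.index_of(s) for s in keep]
    n = len(keep) + (1 if others else 0)
    counts = np.zeros((n, n))
    groups = [[i] for i in idx_keep] + ([others] if others else [])
    for a, ga in enumerate(groups):
        for b, gb in enumerate(groups):
            counts[a, b] = tmap.counts[np.ix_(ga, gb)].sum()
    states = keep + ([other_label] if others else [])
    return normalize_map(TransitionMap(states=states, counts=counts))
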