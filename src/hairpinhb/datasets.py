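"""Bundled reference data: two closely related cyclic β-hairpin decapeptides.

The peptides differ by a single side chain at position 3 — serine
(peptide ``"ser3"``) versus aminobutyric acid (peptide ``"abu3"``) — which
enables or removes an interstrand side-chain hydrogen bond. For each
peptide the dataset carries the published MD-derived statistics of the six
prominently populated hydrogen-bond fingerprint patterns: pattern
populations (% of frames), per-bond mean H···A distances (Å), the overall
mean, the folded/unfolded call, and the 6×6 population change map
(row percentages of frame-to-frame pattern transitions at a 2 ps stride,
4.4 µs of simulation per peptide in DMSO).

These tables serve as worked-example inputs for pathway extraction and as
ground truth for the folded-classification rule; they are not recomputed by
this package (the underlying trajectories are not distributed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import MarkovSpec
from .transitions import TransitionMap

__all__ = [
    "PEPTIDES",
    "TABLE_STATES",
    "reference_pattern_stats",
    "reference_transition_map",
    "example_markov_spec",
]

PEPTIDES = ("ser3", "abu3")

#: The six prominently populated patterns, in published row order.
TABLE_STATES = ("oooo", "oooc", "cooc", "cocc", "ccoc", "cccc")

# pattern -> (population %, HB1..HB4 mean distances Å, overall mean Å, folded?)
_PATTERN_STATS = {
    "ser3": {
        "oooo": (7, (5.87, 9.67, 8.06, 5.00), 7.15, "u"),
        "oooc": (3, (4.14, 5.56, 4.40, 2.30), 4.10, "u"),
        "cooc": (22, (2.29, 3.77, 3.82, 2.18), 3.01, "u"),
        "cocc": (47, (2.40, 3.70, 2.17, 2.13), 2.60, "f"),
        "ccoc": (4, (2.21, 2.50, 3.70, 2.19), 2.65, "f"),
        "cccc": (9, (2.25, 2.42, 2.18, 2.16), 2.25, "f"),
    },
    "abu3": {
        "oooo": (14, (5.92, 8.87, 6.95, 4.09), 6.46, "u"),
        "oooc": (7, (5.31, 7.60, 5.14, 2.45), 5.13, "u"),
        "cooc": (28, (2.26, 3.72, 3.83, 2.19), 3.00, "u"),
        "cocc": (29, (2.37, 3.59, 2.26, 2.13), 2.59, "f"),
        "ccoc": (6, (2.17, 2.49, 3.74, 2.23), 2.66, "f"),
        "cccc": (8, (2.23, 2.37, 2.24, 2.18), 2.25, "f"),
    },
}

# Row percentages of the published population change maps (from-row,
# to-column over TABLE_STATES). Rows need not sum to exactly 100: the maps
# were computed over the full 16-state space and sub-selected for display.
_TRANSITION_PCT = {
    "ser3": [
        [94, 4, 0, 0, 0, 0],
        [9, 49, 23, 8, 3, 1],
        [0, 3, 72, 14, 7, 2],
        [0, 1, 6, 79, 1, 8],
        [0, 2, 39, 8, 37, 9],
        [0, 0, 6, 39, 3, 46],
    ],
    "abu3": [
        [87, 10, 0, 0, 0, 0],
        [21, 65, 8, 2, 1, 0],
        [0, 2, 75, 11, 8, 2],
        [0, 1, 11, 73, 1, 9],
        [0, 1, 39, 6, 40, 7],
        [0, 0, 8, 34, 5, 47],
    ],
}

#: Published overall folding ratios (% of frames in folded patterns).
REFERENCE_FOLDING_RATIO = {"ser3": 66.0, "abu3": 43.0}


def _check_peptide(peptide: str) -> str:
    if peptide not in PEPTIDES:
        raise KeyError(f"unknown peptide {peptide!r}; choose from {PEPTIDES}")
    return peptide


def reference_pattern_stats(peptide: str) -> pd.DataFrame:
    """Published pattern statistics for one peptide.

    Returns a DataFrame indexed by pattern with columns ``population``,
    ``mean_HB1`` .. ``mean_HB4``, ``overall_mean`` and ``folded``
    ('f'/'u').
    """
    stats = _PATTERN_STATS[_check_peptide(peptide)]
    rows = []
    for pattern, (pop, dists, overall, folded) in stats.items():
        row = {"pattern": pattern, "population": float(pop)}
        for i, d in enumerate(dists, start=1):
            row[f"mean_HB{i}"] = d
        row["overall_mean"] = overall
        row["folded"] = folded
        rows.append(row)
    return pd.DataFrame(rows).set_index("pattern")


def reference_transition_map(peptide: str) -> TransitionMap:
    """Published 6-state population change map (percentages only)."""
    pct = np.asarray(_TRANSITION_PCT[_check_peptide(peptide)], float)
    return TransitionMap(states=list(TABLE_STATES), percentages=pct)


def example_markov_spec(
    peptide: str = "ser3",
    n_runs: int = 1,
    n_frames_per_run: int = 50_000,
    seed: int = 0,
) -> MarkovSpec:
    """A Markov chain whose matrix is the published map, rows renormalized.

    Published rows do not all sum to exactly 100 (the originals were
    computed over the full 16-state space); each row is rescaled to a
    proper probability vector. The resulting 6-state chain is the packaged
    example generator for synthetic trajectories.
    """
    from .synthetic import stationary_distribution

    pct = np.asarray(_TRANSITION_PCT[_check_peptide(peptide)], float)
    P = pct / pct.sum(axis=1, keepdims=True)
    return MarkovSpec(
        states=list(TABLE_STATES),
        transition_matrix=P,
        initial_distribution=stationary_distribution(P),
        n_runs=n_runs,
        n_frames_per_run=n_frames_per_run,
        seed=seed,
    )
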