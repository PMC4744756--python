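"""Open/closed hydrogen-bond fingerprints and pattern population statistics.

Each trajectory frame is assigned a 4-character fingerprint over the
interstrand backbone hydrogen bonds HB1..HB4: a bond is *closed* (``c``)
when its H···A distance is at or below the detection cutoff (default 3 Å)
and its D–H–A angle is at or above the lower limit (default 120°),
otherwise *open* (``o``). Four bonds give 2**4 = 16 possible patterns.

A pattern is *folded* when the arithmetic mean of its four per-bond average
distances falls strictly below the folded threshold (default 3 Å); the
overall folding ratio is the summed population of the folded patterns
(pattern-level mode) or the fraction of frames whose own four-distance mean
is below the threshold (frame-level mode).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .trajectory import GeometrySeries

__all__ = [
    "HBCriteria",
    "PatternTable",
    "FoldingSummary",
    "ALL_PATTERNS",
    "OPEN",
    "CLOSED",
    "classify_hbond",
    "classify_hbonds",
    "assign_pattern",
    "pattern_series",
    "pattern_table",
    "classify_folded",
    "overall_folding_ratio",
    "auxiliary_cooccurrence",
    "n_closed",
]

OPEN = "o"
CLOSED = "c"
N_BONDS = 4

#: All 16 patterns in binary order (o = 0, c = 1; HB1 most significant):
#: "oooo", "oooc", ..., "cccc".
ALL_PATTERNS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(OPEN + CLOSED, repeat=N_BONDS)
)

DEFAULT_DISTANCE_CUTOFF = 3.0
DEFAULT_ANGLE_MIN = 120.0
DEFAULT_FOLDED_THRESHOLD = 3.0


@dataclass(frozen=True)
class HBCriteria:
    """Geometric hydrogen-bond detection criteria.

    ``distance_cutoff`` is the maximum H···A distance in Å (inclusive);
    ``angle_min`` the minimum D–H–A angle in degrees (inclusive).
    """

    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF
    angle_min: float = DEFAULT_ANGLE_MIN

    def __post_init__(self):
        if not (self.distance_cutoff > 0 and math.isfinite(self.distance_cutoff)):
            raise ValidationError("distance_cutoff must be positive and finite")
        if not (0 <= self.angle_min <= 180):
            raise ValidationError("angle_min must lie in [0, 180] degrees")


def n_closed(pattern: str) -> int:
    """Number of closed bonds in a pattern label."""
    return pattern.count(CLOSED)


def classify_hbond(distance: float, angle: float, criteria: HBCriteria | None = None) -> str:
    """Classify a single bond observation as ``'c'`` (closed) or ``'o'``.

    Closed iff ``distance <= cutoff`` and ``angle >= angle_min`` (both
    boundaries inclusive).
    """
    criteria = criteria or HBCriteria()
    if not (math.isfinite(distance) and math.isfinite(angle)):
        raise ValidationError("distance and angle must be finite")
    if distance <= 0:
        raise ValidationError("distance must be positive")
    if not 0 <= angle <= 180:
        raise ValidationError("angle must lie in [0, 180] degrees")
    closed = distance <= criteria.distance_cutoff and angle >= criteria.angle_min
    return CLOSED if closed else OPEN


def classify_hbonds(
    distances: np.ndarray, angles: np.ndarray, criteria: HBCriteria | None = None
) -> np.ndarray:
    """Vectorized closed-bond mask for matching distance/angle arrays."""
    criteria = criteria or HBCriteria()
    distances = np.asarray(distances, float)
    angles = np.asarray(angles, float)
    if not (np.all(np.isfinite(distances)) and np.all(np.isfinite(angles))):
        raise ValidationError("distances and angles must be finite")
    return (distances <= criteria.distance_cutoff) & (angles >= criteria.angle_min)


def assign_pattern(states: Sequence[str]) -> str:
    """Join four per-bond states (``'o'``/``'c'``, HB1..HB4 order) into a label."""
    if len(states) != N_BONDS:
        raise ValidationError(f"expected {N_BONDS} bond states, got {len(states)}")
    for s in states:
        if s not in (OPEN, CLOSED):
            raise ValidationError(f"invalid bond state {s!r}")
    return "".join(states)


def pattern_series(
    series: GeometrySeries, criteria: HBCriteria | None = None
) -> pd.Series:
    """Per-frame pattern labels for the four fingerprint bonds.

    Returns a Series aligned with ``series.data`` rows.
    """
    criteria = criteria or HBCriteria()
    if len(series.bond_labels) != N_BONDS:
        raise ValidationError(
            f"fingerprint requires exactly {N_BONDS} bonds, got {len(series.bond_labels)}"
        )
    closed = classify_hbonds(series.distances(), series.angles(), criteria)
    codes = closed @ (1 << np.arange(N_BONDS - 1, -1, -1))
    lookup = np.array(ALL_PATTERNS)
    return pd.Series(lookup[codes], index=series.data.index, name="pattern")


@dataclass
class PatternTable:
    """Population and distance statistics per fingerprint pattern.

    ``table`` is indexed by all 16 pattern labels (binary order) with
    columns ``n_frames``, ``population`` (%), one mean-distance column per
    bond label, ``overall_mean`` (Å), ``folded`` (nullable boolean) and
    ``significant`` (rounded population >= 1%). Patterns with no frames have
    NaN distances and a missing folded flag.
    """

    table: pd.DataFrame
    bond_labels: list[str]
    criteria: HBCriteria = field(default_factory=HBCriteria)
    folded_threshold: float = DEFAULT_FOLDED_THRESHOLD

    @property
    def n_frames(self) -> int:
        return int(self.table["n_frames"].sum())

    def populated(self) -> pd.DataFrame:
        """Rows of patterns observed at least once."""
        return self.table[self.table["n_frames"] > 0]


def classify_folded(
    mean_distances: Sequence[float], threshold: float = DEFAULT_FOLDED_THRESHOLD
) -> tuple[bool, float]:
    """Folded flag and overall mean for four per-bond mean distances.

    The overall mean is the plain arithmetic mean; a structure is folded iff
    that mean is *strictly* below the threshold, so a mean exactly at the
    threshold counts as unfolded.
    """
    values = np.asarray(mean_distances, float)
    if values.shape != (N_BONDS,):
        raise ValidationError(f"expected {N_BONDS} mean distances, got shape {values.shape}")
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValidationError("mean distances must be positive and finite")
    overall = float(values.mean())
    return overall < threshold, overall


def pattern_table(
    series: GeometrySeries,
    criteria: HBCriteria | None = None,
    folded_threshold: float = DEFAULT_FOLDED_THRESHOLD,
) -> PatternTable:
    """Classify every frame and tabulate per-pattern statistics.

    Populations are percentages of all frames and sum to 100 exactly before
    rounding. Per-bond mean distances are computed over the frames of each
    pattern only; the folded flag applies the strict-mean rule to those
    means. All 16 patterns appear in the output, empty ones with NaN
    distance cells and a missing folded flag.
    """
    criteria = criteria or HBCriteria()
    labels = pattern_series(series, criteria)
    dist = series.distances()
    n_total = len(labels)

    rows = []
    for pattern in ALL_PATTERNS:
        mask = (labels == pattern).to_numpy()
        n = int(mask.sum())
        row: dict[str, object] = {"pattern": pattern, "n_frames": n}
        row["population"] = 100.0 * n / n_total
        if n > 0:
            means = dist[mask].mean(axis=0)
            folded, overall = classify_folded(means, folded_threshold)
            for b, m in zip(series.bond_labels, means):
                row[f"mean_{b}"] = float(m)
            row["overall_mean"] = overall
            row["folded"] = folded
        else:
            for b in series.bond_labels:
                row[f"mean_{b}"] = np.nan
            row["overall_mean"] = np.nan
            row["folded"] = pd.NA
        rows.append(row)
    df = pd.DataFrame(rows).set_index("pattern")
    df["folded"] = df["folded"].astype("boolean")
    df["significant"] = df["population"].round() >= 1.0
    return PatternTable(
        table=df,
        bond_labels=list(series.bond_labels),
        criteria=criteria,
        folded_threshold=folded_threshold,
    )


@dataclass
class FoldingSummary:
    """Overall folding ratio in percent.

    ``folded_fraction`` follows the requested mode; both modes are reported
    when computable. Pattern-level sums the populations of folded patterns;
    frame-level classifies each frame by its own four-distance mean.
    """

    folded_fraction: float
    mode: str
    pattern_level: float
    frame_level: float | None = None

    def __post_init__(self):
        if not 0 <= self.folded_fraction <= 100:
            raise ValidationError("folded_fraction must lie in [0, 100]")


def overall_folding_ratio(
    table: PatternTable,
    series: GeometrySeries | None = None,
    mode: str = "pattern",
) -> FoldingSummary:
    """Overall folding ratio from a pattern table (and optionally frames).

    ``mode='pattern'`` (default) sums populations of folded patterns.
    ``mode='frame'`` requires the geometry series and counts frames whose
    own mean distance over the four bonds is strictly below the threshold.
    """
    if mode not in ("pattern", "frame"):
        raise ValidationError(f"unknown classification mode {mode!r}")
    folded_mask = table.table["folded"].fillna(False).astype(bool)
    pattern_level = float(table.table.loc[folded_mask, "population"].sum())
    frame_level: float | None = None
    if series is not None:
        frame_means = series.distances().mean(axis=1)
        frame_level = float(100.0 * np.mean(frame_means < table.folded_threshold))
    if mode == "frame":
        if frame_level is None:
            raise ValidationError("frame-level mode requires the geometry series")
        fraction = frame_level
    else:
        fraction = pattern_level
    return FoldingSummary(
        folded_fraction=fraction, mode=mode, pattern_level=pattern_level, frame_level=frame_level
    )


def auxiliary_cooccurrence(
    series: GeometrySeries,
    criteria: HBCriteria | None = None,
    aux_labels: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Closed-state frequency of auxiliary bonds, overall and per pattern.

    Auxiliary bonds (e.g. a serine side-chain OH donating to a backbone
    carbonyl within the same strand) ride along in the geometry series,
    frame-aligned with the fingerprint bonds.

    Returns
    -------
    conditional : DataFrame
        Rows = auxiliary bond labels, columns = 16 patterns; entry = % of
        that pattern's frames with the auxiliary bond closed (NaN for empty
        patterns).
    overall : Series
        Per auxiliary bond, % of all frames with the bond closed.
    """
    criteria = criteria or HBCriteria()
    aux_labels = list(aux_labels) if aux_labels is not None else list(series.aux_labels)
    if not aux_labels:
        raise ValidationError("no auxiliary bonds in the series")
    missing = [l for l in aux_labels if f"{l}_dist" not in series.data.columns]
    if missing:
        raise AlignmentError(f"auxiliary bonds absent from the geometry series: {missing}")
    labels = pattern_series(series, criteria)
    closed = classify_hbonds(
        series.distances(aux_labels), series.angles(aux_labels), criteria
    )  # (n_frames, n_aux)
    overall = pd.Series(100.0 * closed.mean(axis=0), index=aux_labels, name="overall")
    cond = pd.DataFrame(index=aux_labels, columns=list(ALL_PATTERNS), dtype=float)
    for pattern in ALL_PATTERNS:
        mask = (labels == pattern).to_numpy()
        if mask.any():
            cond[pattern] = 100.0 * closed[mask].mean(axis=0)
        else:
            cond[pattern] = np.nan
    return cond, overall
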