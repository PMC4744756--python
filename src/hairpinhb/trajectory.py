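"""Trajectory input and reduction to per-frame hydrogen-bond geometry.

A trajectory is reduced to a :class:`GeometrySeries`: for every saved frame
and every defined hydrogen bond, the hydrogen-to-acceptor distance (Å) and
the donor–hydrogen–acceptor angle (degrees, 180° = collinear). These two
numbers are the only structural information the downstream pattern analysis
consumes.

File parsing is delegated to MDAnalysis; this module owns atom resolution,
the geometry math, and the tabular geometry interchange format.

Conventions
-----------
* Distances are hydrogen···acceptor, in Å (MDAnalysis positions are Å).
* Angles are measured at the hydrogen between the directions to donor and
  acceptor; a perfectly linear D–H···A bond gives 180°.
* Atom identifiers are ``"RESNAME RESID ATOMNAME"`` triplets, matched
  exactly but case-insensitively.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    AtomLookupError,
    ConfigurationError,
    TrajectoryError,
    ValidationError,
)

__all__ = [
    "HBondDefinition",
    "TrajectoryBundle",
    "GeometrySeries",
    "read_trajectory",
    "read_hbond_config",
    "extract_geometries",
    "hbond_geometry",
]

N_FINGERPRINT_BONDS = 4


@dataclass(frozen=True)
class HBondDefinition:
    """One labelled hydrogen bond: donor heavy atom, its hydrogen, acceptor.

    Atom identifiers are ``"RESNAME RESID ATOMNAME"`` strings, e.g.
    ``"VAL 9 O"`` for the backbone carbonyl oxygen of valine 9.
    """

    label: str
    donor_atom: str
    hydrogen_atom: str
    acceptor_atom: str
    auxiliary: bool = False

    def __post_init__(self):
        norm = [
            tuple(self.donor_atom.upper().split()),
            tuple(self.hydrogen_atom.upper().split()),
            tuple(self.acceptor_atom.upper().split()),
        ]
        if len(set(norm)) != 3:
            raise ConfigurationError(
                f"bond {self.label!r}: donor, hydrogen and acceptor must be three distinct atoms"
            )


@dataclass
class TrajectoryBundle:
    """Coordinates of one or more independent runs over a shared topology.

    ``atoms`` carries per-atom resname / resid / name; ``runs`` is a list of
    ``(n_frames, n_atoms, 3)`` coordinate arrays in Å, one per run.
    """

    atoms: pd.DataFrame
    runs: list[np.ndarray]
    frame_interval_ps: float | None = None

    def __post_init__(self):
        if not self.runs:
            raise TrajectoryError("a trajectory bundle needs at least one run")
        n_atoms = len(self.atoms)
        for r, coords in enumerate(self.runs):
            coords = np.asarray(coords, dtype=float)
            if coords.ndim != 3 or coords.shape[2] != 3:
                raise TrajectoryError(f"run {r}: coordinates must have shape (frames, atoms, 3)")
            if coords.shape[0] < 1:
                raise TrajectoryError(f"run {r}: at least one frame required")
            if coords.shape[1] != n_atoms:
                raise TrajectoryError(
                    f"run {r}: {coords.shape[1]} atoms per frame, topology has {n_atoms}"
                )
            self.runs[r] = coords

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_frames(self) -> int:
        return sum(c.shape[0] for c in self.runs)


@dataclass
class GeometrySeries:
    """Per-frame, per-bond hydrogen-bond geometry.

    ``data`` has columns ``run``, ``frame``, then ``<label>_dist`` (Å) and
    ``<label>_ang`` (degrees) for every bond label. ``bond_labels`` names the
    four fingerprint bonds in HB1..HB4 order; ``aux_labels`` any auxiliary
    bonds carried alongside.
    """

    data: pd.DataFrame
    bond_labels: list[str]
    aux_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.data.empty:
            raise ValidationError("geometry series must contain at least one frame")
        for label in list(self.bond_labels) + list(self.aux_labels):
            for suffix in ("dist", "ang"):
                col = f"{label}_{suffix}"
                if col not in self.data.columns:
                    raise ValidationError(f"geometry series missing column {col!r}")
        dist_cols = [f"{l}_dist" for l in self.bond_labels + self.aux_labels]
        ang_cols = [f"{l}_ang" for l in self.bond_labels + self.aux_labels]
        d = self.data[dist_cols].to_numpy(float)
        a = self.data[ang_cols].to_numpy(float)
        if not np.all(np.isfinite(d)) or not np.all(np.isfinite(a)):
            raise ValidationError("geometry series contains non-finite values")
        if np.any(d <= 0):
            raise ValidationError("distances must be strictly positive")
        if np.any(a < 0) or np.any(a > 180):
            raise ValidationError("angles must lie in [0, 180] degrees")
        for run, grp in self.data.groupby("run"):
            f = grp["frame"].to_numpy()
            if np.any(np.diff(f) <= 0):
                raise ValidationError(f"frame indices in run {run} must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def distances(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Distance matrix, shape (n_frames, n_bonds), for the given labels."""
        labels = list(labels) if labels is not None else self.bond_labels
        return self.data[[f"{l}_dist" for l in labels]].to_numpy(float)

    def angles(self, labels: Sequence[str] | None = None) -> np.ndarray:
        labels = list(labels) if labels is not None else self.bond_labels
        return self.data[[f"{l}_ang" for l in labels]].to_numpy(float)

    def to_tsv(self, path: str | Path) -> None:
        """Write the interchange table: two comment lines naming the bond
        groups, then a tab-separated table with a header row."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("# fingerprint: " + ",".join(self.bond_labels) + "\n")
            fh.write("# auxiliary: " + ",".join(self.aux_labels) + "\n")
            self.data.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeometrySeries":
        path = Path(path)
        if not path.exists():
            raise TrajectoryError(f"geometry table not found: {path}")
        with path.open() as fh:
            header = [fh.readline(), fh.readline()]
            labels: dict[str, list[str]] = {"fingerprint": [], "auxiliary": []}
            for line in header:
                if not line.startswith("#"):
                    raise TrajectoryError(f"{path}: missing bond-group comment header")
                key, _, value = line.lstrip("# ").partition(":")
                names = [v for v in value.strip().split(",") if v]
                labels[key.strip()] = names
            data = pd.read_csv(fh, sep="\t")
        return cls(data=data, bond_labels=labels["fingerprint"], aux_labels=labels["auxiliary"])


# ---------------------------------------------------------------------------
# Reading


def read_trajectory(
    paths: str | Path | Sequence[str | Path],
    format: str = "pdb",
    topology: str | Path | None = None,
) -> TrajectoryBundle:
    """Read one or more trajectory files; each file becomes one run.

    Parameters
    ----------
    paths
        A single path or an ordered sequence; run order follows argument
        order. Multi-model PDB is the reference format; ``xtc``/``dcd``
        require a ``topology`` file (PDB or GRO) and are converted from nm
        to Å by MDAnalysis automatically.
    """
    import MDAnalysis as mda

    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if not paths:
        raise TrajectoryError("no trajectory files given")
    fmt = format.lower()
    if fmt not in {"pdb", "xtc", "dcd"}:
        raise ConfigurationError(f"unsupported trajectory format: {format!r}")
    if fmt in {"xtc", "dcd"} and topology is None:
        raise ConfigurationError(f"{fmt} trajectories require a topology file")

    atoms_df: pd.DataFrame | None = None
    runs: list[np.ndarray] = []
    interval: float | None = None
    for path in paths:
        if not path.exists():
            raise TrajectoryError(f"trajectory file not found: {path}")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if fmt == "pdb":
                    u = mda.Universe(str(path))
                else:
                    u = mda.Universe(str(topology), str(path))
                frames = [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
                if len(u.trajectory) > 1 and u.trajectory.dt:
                    interval = float(u.trajectory.dt)
        except TrajectoryError:
            raise
        except Exception as exc:  # MDAnalysis raises format-specific errors
            raise TrajectoryError(f"could not read {path}: {exc}") from exc
        df = pd.DataFrame(
            {
                "resname": [a.resname.upper() for a in u.atoms],
                "resid": [int(a.resid) for a in u.atoms],
                "name": [a.name.upper() for a in u.atoms],
            }
        )
        if atoms_df is None:
            atoms_df = df
        elif not atoms_df.equals(df):
            raise TrajectoryError(f"{path}: topology differs from the first file")
        runs.append(np.stack(frames))
    assert atoms_df is not None
    return TrajectoryBundle(atoms=atoms_df, runs=runs, frame_interval_ps=interval)


def read_hbond_config(path: str | Path) -> list[HBondDefinition]:
    """Read a YAML hydrogen-bond config.

    The file holds a ``bonds`` list; each entry has ``label``, ``donor``,
    ``hydrogen``, ``acceptor`` and an optional ``auxiliary`` flag. Bonds are
    returned in declared order; the first four non-auxiliary bonds define the
    fingerprint.
    """
    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"hydrogen-bond config not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict) or "bonds" not in raw:
        raise ConfigurationError(f"{path}: expected a mapping with a 'bonds' list")
    defs: list[HBondDefinition] = []
    seen: set[str] = set()
    for i, entry in enumerate(raw["bonds"]):
        try:
            d = HBondDefinition(
                label=str(entry["label"]),
                donor_atom=str(entry["donor"]),
                hydrogen_atom=str(entry["hydrogen"]),
                acceptor_atom=str(entry["acceptor"]),
                auxiliary=bool(entry.get("auxiliary", False)),
            )
        except KeyError as exc:
            raise ConfigurationError(f"{path}: bond entry {i} missing field {exc}") from exc
        if d.label in seen:
            raise ConfigurationError(f"{path}: duplicate bond label {d.label!r}")
        seen.add(d.label)
        defs.append(d)
    n_fingerprint = sum(not d.auxiliary for d in defs)
    if n_fingerprint < N_FINGERPRINT_BONDS:
        raise ConfigurationError(
            f"{path}: {n_fingerprint} fingerprint bonds declared, "
            f"{N_FINGERPRINT_BONDS} required for the hairpin analysis"
        )
    return defs


# ---------------------------------------------------------------------------
# Geometry


def hbond_geometry(
    donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hydrogen···acceptor distance and D–H–A angle for coordinate arrays.

    Accepts single points or stacked ``(..., 3)`` arrays; returns distance
    in the input length unit and the angle at the hydrogen in degrees.
    """
    donor = np.asarray(donor, float)
    hydrogen = np.asarray(hydrogen, float)
    acceptor = np.asarray(acceptor, float)
    ha = acceptor - hydrogen
    hd = donor - hydrogen
    dist = np.linalg.norm(ha, axis=-1)
    cosang = np.sum(ha * hd, axis=-1) / (dist * np.linalg.norm(hd, axis=-1))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return dist, angle


def _resolve_atom(atoms: pd.DataFrame, identifier: str) -> int:
    parts = identifier.upper().split()
    if len(parts) != 3:
        raise AtomLookupError(identifier, 0)
    resname, resid_s, name = parts
    try:
        resid = int(resid_s)
    except ValueError:
        raise AtomLookupError(identifier, 0) from None
    mask = (
        (atoms["resname"].str.upper() == resname)
        & (atoms["resid"] == resid)
        & (atoms["name"].str.upper() == name)
    )
    idx = np.flatnonzero(mask.to_numpy())
    if len(idx) != 1:
        raise AtomLookupError(identifier, len(idx))
    return int(idx[0])


def extract_geometries(
    bundle: TrajectoryBundle, defs: Sequence[HBondDefinition]
) -> GeometrySeries:
    """Reduce a trajectory bundle to per-frame hydrogen-bond geometry.

    Every atom identifier must resolve to exactly one atom in the topology.
    """
    if not defs:
        raise ConfigurationError("no hydrogen-bond definitions given")
    indices = [
        (
            _resolve_atom(bundle.atoms, d.donor_atom),
            _resolve_atom(bundle.atoms, d.hydrogen_atom),
            _resolve_atom(bundle.atoms, d.acceptor_atom),
        )
        for d in defs
    ]
    rows: list[pd.DataFrame] = []
    for r, coords in enumerate(bundle.runs):
        block: dict[str, np.ndarray] = {
            "run": np.full(coords.shape[0], r, dtype=int),
            "frame": np.arange(coords.shape[0], dtype=int),
        }
        for d, (i_d, i_h, i_a) in zip(defs, indices):
            dist, ang = hbond_geometry(coords[:, i_d], coords[:, i_h], coords[:, i_a])
            block[f"{d.label}_dist"] = dist
            block[f"{d.label}_ang"] = ang
        rows.append(pd.DataFrame(block))
    data = pd.concat(rows, ignore_index=True)
    fingerprint = [d.label for d in defs if not d.auxiliary]
    aux = [d.label for d in defs if d.auxiliary]
    # any non-auxiliary bonds beyond the first four are carried as auxiliary
    aux = fingerprint[N_FINGERPRINT_BONDS:] + aux
    return GeometrySeries(
        data=data,
        bond_labels=fingerprint[:N_FINGERPRINT_BONDS],
        aux_labels=aux,
    )
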