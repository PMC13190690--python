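"""Trajectory, topology and relaxation-table I/O plus residue-region selection.

All coordinates are held in nanometres internally; Angstrom-based formats
(PDB, MDAnalysis) are converted at the boundary.  Residue numbers follow the
author numbering of the studied construct (339-725); zero-based indices are
used only for atoms and frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

A_PER_NM = 10.0

#: Observables a relaxation table may contain.
OBSERVABLES = ("R1", "R2", "NOE", "eta_xy", "methyl_R1", "methyl_G2")

RELAXATION_COLUMNS = [
    "residue", "observable", "value", "uncertainty", "field_mhz", "probe", "group",
]


class AtomTable:
    """Per-atom metadata table (name, residue number/name, chain).

    Wraps a pandas DataFrame indexed by the contiguous 0-based atom index.
    """

    REQUIRED = ("atom_name", "residue_number", "residue_name", "chain_id")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        df = df.reset_index(drop=True)
        df.index.name = "atom_index"
        key = df[["residue_number", "atom_name", "chain_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate atom identity: {tuple(dup)}")
        self.df = df

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "AtomTable":
        return cls(pd.DataFrame(records, columns=list(cls.REQUIRED)))

    @property
    def n_atoms(self) -> int:
        return len(self.df)

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.df["residue_number"].to_numpy()

    @property
    def atom_names(self) -> np.ndarray:
        return self.df["atom_name"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, AtomTable) and self.df.equals(other.df)


@dataclass
class TrajectoryRecord:
    """Time-stamped coordinate frames with an atom table.

    coordinates: (n_frames, n_atoms, 3) in nm; frame_times strictly increasing, ns.
    """

    frame_times: np.ndarray
    coordinates: np.ndarray
    atom_table: AtomTable

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.n_frames < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coordinates.shape[0] != len(self.frame_times):
            raise ValueError("frame_times length does not match coordinate frames")
        if self.coordinates.shape[1] != self.atom_table.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} does not match "
                f"atom table ({self.atom_table.n_atoms} atoms)"
            )
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def duration_ns(self) -> float:
        return float(self.frame_times[-1] - self.frame_times[0])

    def spacing_ns(self) -> float:
        """Native frame spacing; raises if non-uniform (tolerance 1e-6 ns)."""
        if self.n_frames < 2:
            raise ValueError("spacing undefined for a single frame")
        dt = np.diff(self.frame_times)
        if np.ptp(dt) > 1e-6:
            raise ValueError("frame spacing is not uniform")
        return float(dt.mean())

    def slice_frames(self, idx) -> "TrajectoryRecord":
        return TrajectoryRecord(self.frame_times[idx], self.coordinates[idx], self.atom_table)

    def slice_time(self, t0_ns: float, t1_ns: float) -> "TrajectoryRecord":
        """Frames with t0 <= t < t1 (half-open, matching the windowing convention)."""
        mask = (self.frame_times >= t0_ns) & (self.frame_times < t1_ns)
        if not mask.any():
            raise ValueError(f"no frames in time range [{t0_ns}, {t1_ns}) ns")
        return self.slice_frames(mask)


@dataclass(frozen=True)
class RegionSpec:
    """Residue-range selection in author numbering with an atom-name filter."""

    name: str
    residue_ranges: tuple
    atom_filter: frozenset = frozenset({"CA"})

    def __post_init__(self):
        ranges = tuple(tuple(int(x) for x in r) for r in self.residue_ranges)
        object.__setattr__(self, "residue_ranges", ranges)
        object.__setattr__(self, "atom_filter", frozenset(self.atom_filter))
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"range [{lo},{hi}] has lo > hi")
            if lo < 339 or hi > 725:
                raise ValueError(f"range [{lo},{hi}] outside construct span [339, 725]")
        spans = sorted(ranges)
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ValueError(f"overlapping ranges [{lo1},{hi1}] and [{lo2},{hi2}]")

    def contains(self, residue_number: int) -> bool:
        return any(lo <= residue_number <= hi for lo, hi in self.residue_ranges)


# Regions used throughout: Reg1 = structured regions; Reg2 = everything except the
# termini (339-341 and 718-725); loop definitions of the paracaspase domain.
REG1 = RegionSpec("Reg1", ((342, 467), (484, 491), (509, 562), (572, 717)))
REG2 = RegionSpec("Reg2", ((342, 717),))
BETA3_HAIRPIN = RegionSpec("beta3_hairpin", ((416, 425),))
LOOP2 = RegionSpec("loop2", ((464, 485),))
LOOP3 = RegionSpec("loop3", ((491, 509),))
#: Alternative loop-3 bounds (496-510) quoted in the relaxation-discrepancy analysis.
LOOP3_ALT = RegionSpec("loop3_alt", ((496, 510),))

NAMED_REGIONS = {r.name: r for r in (REG1, REG2, BETA3_HAIRPIN, LOOP2, LOOP3, LOOP3_ALT)}


def resolve_region(region: RegionSpec, atoms: AtomTable) -> np.ndarray:
    """Resolve a region into sorted 0-based atom indices.

    One index per (residue, atom name in the filter) present in the table.
    Raises if any range lies wholly outside the table's residue span or if the
    selection comes up empty.
    """
    res = atoms.residue_numbers
    lo_all, hi_all = int(res.min()), int(res.max())
    for lo, hi in region.residue_ranges:
        if hi < lo_all or lo > hi_all:
            raise ValueError(
                f"range [{lo},{hi}] outside the model's residue span [{lo_all},{hi_all}]"
            )
    in_range = np.zeros(len(atoms), dtype=bool)
    for lo, hi in region.residue_ranges:
        in_range |= (res >= lo) & (res <= hi)
    in_filter = np.isin(atoms.atom_names, list(region.atom_filter))
    idx = np.nonzero(in_range & in_filter)[0]
    if idx.size == 0:
        raise ValueError(f"region {region.name!r} selects no atoms")
    return idx


def _atoms_from_universe(u) -> AtomTable:
    ag = u.atoms
    try:
        chains = ag.chainIDs
    except Exception:
        try:
            chains = ag.segids
        except Exception:
            chains = np.full(len(ag), "A")
    chains = ["A" if str(c).strip() in ("", "SYSTEM") else str(c).strip() for c in chains]
    return AtomTable(pd.DataFrame({
        "atom_name": [a.name for a in ag],
        "residue_number": [int(a.resid) for a in ag],
        "residue_name": [a.resname for a in ag],
        "chain_id": chains,
    }))


def read_trajectory(
    topology_path,
    trajectory_paths: Sequence | str | Path | None = None,
    stride_ns: float = 1.0,
) -> TrajectoryRecord:
    """Read a topology (PDB/GRO) plus trajectory (XTC/DCD/multi-model PDB).

    With no trajectory paths the topology's own frames are used (multi-model
    PDB).  Coordinates are converted to nm.  Frame times are taken from the
    file when present and non-degenerate, otherwise synthesized at
    ``stride_ns`` spacing starting from 0.
    """
    import MDAnalysis as mda

    topology_path = str(topology_path)
    if trajectory_paths is None:
        paths = []
    elif isinstance(trajectory_paths, (str, Path)):
        paths = [str(trajectory_paths)]
    else:
        paths = [str(p) for p in trajectory_paths]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(topology_path, *paths) if paths else mda.Universe(topology_path)
        except ValueError as exc:
            # MDAnalysis raises ValueError on topology/trajectory atom-count mismatch
            if "atoms" in str(exc):
                raise ValueError(f"atom-count mismatch between topology and trajectory: {exc}")
            raise
        n_frames = len(u.trajectory)
        if n_frames == 0:
            raise ValueError("trajectory contains zero frames")
        coords = np.empty((n_frames, len(u.atoms), 3))
        times_ps = np.empty(n_frames)
        for i, ts in enumerate(u.trajectory):
            coords[i] = u.atoms.positions / A_PER_NM  # Angstrom -> nm
            times_ps[i] = ts.time

    times_ns = times_ps / 1000.0
    # multi-model PDB carries no time stamps (MDAnalysis invents 1-ps steps)
    sources = paths if paths else [topology_path]
    pdb_only = all(str(p).lower().endswith((".pdb", ".ent")) for p in sources)
    if n_frames == 1:
        times_ns = np.zeros(1)
    elif pdb_only or np.any(np.diff(times_ns) <= 0) or np.allclose(np.ptp(times_ns), 0):
        times_ns = np.arange(n_frames, dtype=float) * stride_ns
    return TrajectoryRecord(times_ns, coords, _atoms_from_universe(u))


def downsample_uniform(traj: TrajectoryRecord, interval_ns: float) -> TrajectoryRecord:
    """Down-sample to uniform ``interval_ns`` spacing (frames at 0, T, 2T, ...).

    The interval must be an integer multiple of the native spacing; e.g. a
    3000 ns trajectory sampled at 1 ns intervals yields 3000 frames.
    """
    native = traj.spacing_ns() if traj.n_frames > 1 else interval_ns
    ratio = interval_ns / native
    if ratio < 1 - 1e-9:
        raise ValueError(f"interval {interval_ns} ns below native spacing {native} ns")
    step = int(round(ratio))
    if abs(ratio - step) > 1e-6:
        raise ValueError(
            f"interval {interval_ns} ns is not an integer multiple of native spacing {native} ns"
        )
    out = traj.slice_frames(slice(None, None, step))
    return out


def read_relaxation_table(path) -> "RelaxationTable":
    """Read a CSV/TSV relaxation table with the documented header."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    return RelaxationTable(df)


class RelaxationTable:
    """Per-residue experimental/back-calculated relaxation observables.

    Columns: residue, observable, value, uncertainty, field_mhz, probe, group.
    Rates in 1/s (NOE dimensionless); uncertainty strictly positive.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in RELAXATION_COLUMNS[:6] if c not in df.columns]
        if missing:
            raise ValueError(f"relaxation table missing columns: {missing}")
        df = df.copy()
        if "group" not in df.columns:
            df["group"] = ""
        df["group"] = df["group"].fillna("")
        bad = ~df["observable"].isin(OBSERVABLES)
        if bad.any():
            raise ValueError(f"unknown observables: {sorted(df.loc[bad, 'observable'].unique())}")
        if (df["uncertainty"] <= 0).any():
            raise ValueError("uncertainty must be strictly positive")
        key = df[["residue", "observable", "probe", "group"]]
        if key.duplicated().any():
            raise ValueError("duplicate (residue, observable, probe) rows")
        self.df = df[RELAXATION_COLUMNS].reset_index(drop=True)

    def select(self, observable: str, probe: str = "backbone_NH") -> pd.DataFrame:
        sub = self.df[(self.df["observable"] == observable) & (self.df["probe"] == probe)]
        return sub.sort_values("residue").reset_index(drop=True)

    def write(self, path) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        self.df.to_csv(path, sep=sep, index=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RelaxationTable):
            return NotImplemented
        return self.df.equals(other.df)


def write_relaxation_table(table: RelaxationTable, path) -> None:
    table.write(path)


def write_ensemble(pdb_path, traj: TrajectoryRecord) -> None:
    """Write frames as a MODEL/ENDMDL multi-model PDB (coordinates nm -> A)."""
    if traj.n_atoms > 99999:
        raise ValueError("PDB format supports at most 99,999 atoms")
    at = traj.atom_table.df
    lines = []
    for m in range(traj.n_frames):
        lines.append(f"MODEL     {m + 1:4d}")
        xyz = traj.coordinates[m] * A_PER_NM
        for i in range(traj.n_atoms):
            name = str(at.at[i, "atom_name"])
            # PDB atom-name column convention: 1-letter elements start in col 14
            name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
            lines.append(
                "ATOM  {serial:5d} {name} {res:<3s} {chain:1s}{resnum:4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}".format(
                    serial=i + 1, name=name_f,
                    res=str(at.at[i, "residue_name"])[:3],
                    chain=str(at.at[i, "chain_id"])[:1] or "A",
                    resnum=int(at.at[i, "residue_number"]),
                    x=xyz[i, 0], y=xyz[i, 1], z=xyz[i, 2], occ=1.0, b=0.0,
                )
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(pdb_path).write_text("\n".join(lines) + "\n")
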