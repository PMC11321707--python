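"""Structural and tabular I/O for coarse-grained bead assemblies.

The universal structural record is :class:`AssemblyFrame`: one bead per
peptide residue (plus counterion beads), with chain, residue, mass and
optional orthorhombic box bookkeeping.  Coordinates are Cartesian ångström,
0-origin, residue numbering 1-based.

File dialects
-------------
PDB
    Multi-model (``MODEL``/``ENDMDL``), ``CRYST1`` when a box is present,
    ``HETATM`` for counterion beads.  Two non-standard conventions, both
    round-tripped by this module: the per-bead mass (Da) is stored in the
    B-factor column, and chain labels beyond ``Z`` use two characters in
    columns 21-22.
XYZ
    Standard multi-frame XYZ plus a CSV *topology sidecar* carrying chain,
    residue, name, mass and bead class (XYZ itself has no bookkeeping).
CSV tables
    Peak lists, DOSY series and kinetic traces, validated against a named
    schema.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AssemblyFrame",
    "Trajectory",
    "ParseError",
    "SchemaError",
    "read_coordinates",
    "write_coordinates",
    "read_table",
    "write_table",
    "TABLE_SCHEMAS",
]

PEPTIDE_BEAD = "peptide"
COUNTERION_BEAD = "counterion"


class ParseError(ValueError):
    """Malformed coordinate file (message carries the offending line number)."""


class SchemaError(ValueError):
    """Tabular input does not match the declared schema."""


@dataclass
class AssemblyFrame:
    """One frame of a bead assembly.

    Attributes
    ----------
    positions : (n, 3) float array, Å
    chain : (n,) str array — peptide chain label per bead
    resid : (n,) int array — 1-based residue index within the chain
    resname : (n,) str array — residue / counterion name
    mass : (n,) float array, Da
    bead_class : (n,) str array — ``"peptide"`` or ``"counterion"``
    box : optional (3,) float array, orthorhombic edge lengths in Å
    time : frame time label (arbitrary units, used for trajectory ordering)
    """

    positions: np.ndarray
    chain: np.ndarray
    resid: np.ndarray
    resname: np.ndarray
    mass: np.ndarray
    bead_class: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.chain = np.asarray(self.chain, dtype=object)
        self.resid = np.asarray(self.resid, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        self.mass = np.asarray(self.mass, dtype=float)
        self.bead_class = np.asarray(self.bead_class, dtype=object)
        for name in ("chain", "resid", "resname", "mass", "bead_class"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch with positions")
        if np.any(self.resid < 1):
            raise ValueError("residue indices must be 1-based positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box edges must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def chains(self) -> list[str]:
        """Distinct peptide chain labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for c, k in zip(self.chain, self.bead_class):
            if k == PEPTIDE_BEAD and c not in seen:
                seen[c] = None
        return list(seen)

    def peptide_mask(self) -> np.ndarray:
        return np.asarray([k == PEPTIDE_BEAD for k in self.bead_class], dtype=bool)

    def select_chains(self, chains: Iterable[str]) -> "AssemblyFrame":
        wanted = set(chains)
        mask = np.asarray([c in wanted for c in self.chain], dtype=bool)
        return self.subset(mask)

    def subset(self, mask: np.ndarray) -> "AssemblyFrame":
        return AssemblyFrame(
            positions=self.positions[mask],
            chain=self.chain[mask],
            resid=self.resid[mask],
            resname=self.resname[mask],
            mass=self.mass[mask],
            bead_class=self.bead_class[mask],
            box=None if self.box is None else self.box.copy(),
            time=self.time,
        )

    def translated(self, shift: np.ndarray) -> "AssemblyFrame":
        out = replace(self)
        out.positions = self.positions + np.asarray(shift, dtype=float)
        return out

    def topology_signature(self) -> tuple:
        return (
            tuple(self.chain),
            tuple(int(r) for r in self.resid),
            tuple(self.resname),
            tuple(np.round(self.mass, 6)),
            tuple(self.bead_class),
        )


@dataclass
class Trajectory:
    """Ordered frames sharing one topology (times strictly increasing)."""

    frames: list[AssemblyFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        sig = self.frames[0].topology_signature()
        for i, f in enumerate(self.frames[1:], start=1):
            if f.topology_signature() != sig:
                raise ValueError(f"frame {i} topology differs from frame 0")
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> AssemblyFrame:
        return self.frames[i]


# ---------------------------------------------------------------------------
# PDB dialect
# ---------------------------------------------------------------------------

def _format_chain(label: str) -> str:
    if len(label) > 2:
        raise ValueError(f"chain label {label!r} exceeds two characters")
    return f"{label:>2s}"


def _pdb_atom_line(i: int, f: AssemblyFrame, k: int) -> str:
    record = "HETATM" if f.bead_class[k] == COUNTERION_BEAD else "ATOM  "
    name = " CA " if f.bead_class[k] == PEPTIDE_BEAD else " X  "
    x, y, z = f.positions[k]
    # chain occupies cols 21-22 (two-character extension), resseq 23-26
    return (
        f"{record}{i:5d} {name} {str(f.resname[k])[:3]:>3s}"
        f"{_format_chain(str(f.chain[k]))}{int(f.resid[k]):4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{f.mass[k]:6.2f}          "
        f"{'C' if f.bead_class[k] == PEPTIDE_BEAD else 'P':>2s}"
    )


def _write_pdb(traj: Trajectory, path: Path) -> None:
    lines: list[str] = []
    first = traj[0]
    if first.box is not None:
        bx, by, bz = first.box
        lines.append(
            f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    multi = len(traj) > 1
    for m, frame in enumerate(traj, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for k in range(frame.n_beads):
            lines.append(_pdb_atom_line(k + 1, frame, k))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _parse_pdb(text: str, path: str) -> Trajectory:
    frames: list[AssemblyFrame] = []
    box = None
    cur: list[tuple] | None = None
    seen_model = False

    def flush(t: float) -> None:
        nonlocal cur
        if cur:
            pos, ch, rid, rn, ms, cls = zip(*cur)
            frames.append(
                AssemblyFrame(
                    positions=np.asarray(pos),
                    chain=np.asarray(ch, dtype=object),
                    resid=np.asarray(rid),
                    resname=np.asarray(rn, dtype=object),
                    mass=np.asarray(ms),
                    bead_class=np.asarray(cls, dtype=object),
                    box=box,
                    time=t,
                )
            )
        cur = None

    for ln, raw in enumerate(text.splitlines(), start=1):
        rec = raw[:6]
        try:
            if rec == "CRYST1":
                box = np.asarray([float(raw[6:15]), float(raw[15:24]), float(raw[24:33])])
            elif rec.startswith("MODEL"):
                seen_model = True
                flush(float(len(frames)))
                cur = []
            elif rec == "ENDMDL":
                flush(float(len(frames)))
            elif rec in ("ATOM  ", "HETATM"):
                if cur is None:
                    cur = []
                chain = raw[20:22].strip()
                cur.append(
                    (
                        (float(raw[30:38]), float(raw[38:46]), float(raw[46:54])),
                        chain,
                        int(raw[22:26]),
                        raw[17:20].strip(),
                        float(raw[60:66]),
                        COUNTERION_BEAD if rec == "HETATM" else PEPTIDE_BEAD,
                    )
                )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: malformed PDB record at line {ln}: {raw!r}") from exc
    flush(float(len(frames)))
    if not frames:
        raise ParseError(f"{path}: no coordinate records found")
    if seen_model:
        for i, f in enumerate(frames):
            f.time = float(i)
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# XYZ dialect + sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".topology.csv")


def _write_xyz(traj: Trajectory, path: Path) -> None:
    buf = io.StringIO()
    for frame in traj:
        buf.write(f"{frame.n_beads}\n")
        boxpart = (
            " box=" + ",".join(f"{b:.6f}" for b in frame.box) if frame.box is not None else ""
        )
        buf.write(f"time={frame.time:.6f}{boxpart}\n")
        for k in range(frame.n_beads):
            el = "C" if frame.bead_class[k] == PEPTIDE_BEAD else "P"
            x, y, z = frame.positions[k]
            buf.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
    path.write_text(buf.getvalue())
    f0 = traj[0]
    pd.DataFrame(
        {
            "chain": f0.chain,
            "resid": f0.resid,
            "resname": f0.resname,
            "mass": f0.mass,
            "bead_class": f0.bead_class,
        }
    ).to_csv(_sidecar_path(path), index=False)


def _parse_xyz(text: str, path: Path) -> Trajectory:
    side = _sidecar_path(path)
    if not side.exists():
        raise ParseError(
            f"{path}: XYZ input requires a topology sidecar at {side} "
            "(chain/resid/resname/mass/bead_class per bead)"
        )
    topo = pd.read_csv(side)
    lines = text.splitlines()
    if not any(l.strip() for l in lines):
        raise ParseError(f"{path}: empty file")
    frames: list[AssemblyFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: expected atom count at line {i + 1}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        time = float(len(frames))
        box = None
        for tok in comment.split():
            if tok.startswith("time="):
                time = float(tok[5:])
            elif tok.startswith("box="):
                box = np.asarray([float(v) for v in tok[4:].split(",")])
        pos = np.empty((n, 3))
        for k in range(n):
            ln = i + 2 + k
            try:
                parts = lines[ln].split()
                pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: malformed XYZ atom at line {ln + 1}") from exc
        if n != len(topo):
            raise ParseError(f"{path}: frame size {n} != sidecar topology size {len(topo)}")
        frames.append(
            AssemblyFrame(
                positions=pos,
                chain=topo["chain"].astype(str).to_numpy(dtype=object),
                resid=topo["resid"].to_numpy(),
                resname=topo["resname"].astype(str).to_numpy(dtype=object),
                mass=topo["mass"].to_numpy(dtype=float),
                bead_class=topo["bead_class"].astype(str).to_numpy(dtype=object),
                box=box,
                time=time,
            )
        )
        i += 2 + n
    return Trajectory(frames)


def read_coordinates(path: str | os.PathLike, format: str | None = None) -> Trajectory:
    """Read a PDB or multi-frame XYZ file into a :class:`Trajectory`.

    ``format`` defaults to the file suffix.  XYZ requires the topology
    sidecar written by :func:`write_coordinates`.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    fmt = (format or p.suffix.lstrip(".")).lower()
    text = p.read_text()
    if not text.strip():
        raise ParseError(f"{p}: empty file")
    if fmt == "pdb":
        return _parse_pdb(text, str(p))
    if fmt == "xyz":
        return _parse_xyz(text, p)
    raise ValueError(f"unknown coordinate format {fmt!r} (expected pdb or xyz)")


def write_coordinates(
    traj: Trajectory | AssemblyFrame, path: str | os.PathLike, format: str | None = None
) -> Path:
    """Write a trajectory (or single frame) to PDB or XYZ (+ sidecar)."""
    if isinstance(traj, AssemblyFrame):
        traj = Trajectory([traj])
    p = Path(path)
    fmt = (format or p.suffix.lstrip(".")).lower()
    p.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "pdb":
        _write_pdb(traj, p)
    elif fmt == "xyz":
        _write_xyz(traj, p)
    else:
        raise ValueError(f"unknown coordinate format {fmt!r} (expected pdb or xyz)")
    return p


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

TABLE_SCHEMAS: dict[str, list[str]] = {
    # residue id, two chemical shifts (ppm), intensity
    "peaks": ["resid", "resname", "shift_a", "shift_b", "intensity"],
    # gradient strength (T/m) vs integral
    "dosy": ["gradient", "integral"],
    # long format: time (s), residue, normalized intensity
    "kinetics": ["time", "resid", "intensity"],
}

_NUMERIC_COLS = {
    "peaks": ["resid", "shift_a", "shift_b", "intensity"],
    "dosy": ["gradient", "integral"],
    "kinetics": ["time", "resid", "intensity"],
}


def read_table(path: str | os.PathLike, schema: str) -> pd.DataFrame:
    """Read a CSV table and validate it against a named schema.

    Raises :class:`SchemaError` naming the missing column or the first row
    with a non-numeric cell.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(TABLE_SCHEMAS)}")
    df = pd.read_csv(path)
    for col in TABLE_SCHEMAS[schema]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r} for schema {schema!r}")
    for col in _NUMERIC_COLS[schema]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at row {int(bad[0]) + 2}"
            )
        df[col] = coerced
    return df[TABLE_SCHEMAS[schema]].copy()


def write_table(df: pd.DataFrame, path: str | os.PathLike, schema: str) -> Path:
    """Write a schema-conformant CSV (header row, no index)."""
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    missing = [c for c in TABLE_SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {schema!r} table: missing columns {missing}")
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    df[TABLE_SCHEMAS[schema]].to_csv(p, index=False)
    return p
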