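"""Structure-ensemble and energy-table I/O.

Two families of input feed the pipeline: multi-model PDB files holding an
ordered structural ensemble (one MODEL per snapshot), and long-format
delimited tables holding per-frame MM-GBSA energy components for the
complex, the receptor (protein) and the ligand (DNA).

The PDB dialect accepted here is a strict fixed-width v3.3 subset: ATOM /
HETATM coordinate records inside MODEL/ENDMDL blocks (or a single implicit
model).  Alternate locations and insertion codes are rejected — ensembles
exported from a trajectory never carry them, and silently picking one
altloc would corrupt atom correspondence across frames.  Author residue
numbering is preserved exactly; nothing is renumbered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, PDBParseError, SchemaError, ValidationError

SPECIES = ("complex", "receptor", "ligand")

_ELEMENT_FALLBACK = {"C": "C", "N": "N", "O": "O", "S": "S", "P": "P", "H": "H"}


@dataclass(frozen=True)
class Atom:
    """One atom of a snapshot; coordinates in Å, author residue numbering."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.xyz)):
            raise ValidationError(f"non-finite coordinates for atom {self.serial} {self.name}")

    @property
    def ref(self) -> tuple[str, int, str]:
        """(chain, res_seq, atom name) — the reference triple used across modules."""
        return (self.chain, self.res_seq, self.name)


@dataclass
class StructureFrame:
    """A single snapshot: ordered atoms plus its position in the trajectory."""

    frame_index: int
    time_ps: float
    atoms: list[Atom]

    def coord_array(self) -> np.ndarray:
        return np.asarray([a.xyz for a in self.atoms], dtype=float)

    def signature(self) -> tuple:
        """Atom identity tuple used to check frame-to-frame consistency."""
        return tuple((a.name, a.res_name, a.res_seq, a.chain) for a in self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)


class Trajectory:
    """Ordered list of frames with identical atom order.

    Invariants checked at construction: strictly increasing frame_index and
    an identical atom signature (name, residue, chain) in every frame.
    """

    def __init__(self, frames: Sequence[StructureFrame]):
        frames = list(frames)
        if frames:
            sig = frames[0].signature()
            prev = None
            for fr in frames:
                if prev is not None and fr.frame_index <= prev:
                    raise IntegrityError(
                        f"frame_index not strictly increasing at frame {fr.frame_index}"
                    )
                prev = fr.frame_index
                if fr.signature() != sig:
                    raise IntegrityError(
                        f"atom order/identity differs in frame {fr.frame_index}"
                    )
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[StructureFrame]:
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.frames[i])
        return self.frames[i]

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0]) if self.frames else 0


@dataclass(frozen=True)
class EnergyRecord:
    """MM-GBSA components of one species in one frame (kcal/mol).

    ``e_gas`` is the gas-phase molecular-mechanics energy, ``g_sol`` the
    Generalized-Born solvation free energy, ``ts_entropy`` the optional
    TΔS term (absent when entropy was not computed).
    """

    frame_index: int
    species: str
    e_gas: float
    g_sol: float
    ts_entropy: float | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(
                f"species must be one of {SPECIES}, got {self.species!r}"
            )


def _guess_element(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            return _ELEMENT_FALLBACK.get(ch.upper(), ch.upper())
    return "X"


def read_multimodel_pdb(path: str | Path, dt_ps: float = 10.0) -> Trajectory:
    """Parse a multi-model PDB ensemble into a Trajectory.

    ``dt_ps`` assigns ``time_ps = dt_ps * frame_index`` (snapshots at a
    fixed stride); the PDB format itself carries no time information.
    """
    path = Path(path)
    frames: list[StructureFrame] = []
    atoms: list[Atom] = []
    in_model = False
    saw_model_records = False
    model_no = 0

    def close_model() -> None:
        nonlocal atoms
        if not atoms:
            raise PDBParseError(f"model {model_no} contains no atoms in {path}")
        if frames and len(atoms) != len(frames[0].atoms):
            raise PDBParseError(
                f"model {model_no} has {len(atoms)} atoms, expected "
                f"{len(frames[0].atoms)} (model 1) in {path}"
            )
        idx = len(frames)
        frames.append(StructureFrame(frame_index=idx, time_ps=dt_ps * idx, atoms=atoms))
        atoms = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_records = True
                in_model = True
                model_no += 1
                if atoms:
                    raise PDBParseError(f"line {lineno}: MODEL opened before previous ENDMDL")
            elif rec == "ENDMDL":
                close_model()
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                if saw_model_records and not in_model:
                    raise PDBParseError(f"line {lineno}: atom record outside MODEL block")
                if line[16] not in (" ", ""):
                    raise PDBParseError(
                        f"line {lineno}: alternate location indicator {line[16]!r} not supported"
                    )
                if len(line) > 26 and line[26] not in (" ", "\n", ""):
                    raise PDBParseError(
                        f"line {lineno}: insertion code {line[26]!r} not supported"
                    )
                try:
                    serial = int(line[6:11])
                    res_seq = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise PDBParseError(f"line {lineno}: malformed numeric field ({exc})") from None
                name = line[12:16].strip()
                element = line[76:78].strip() if len(line) >= 78 else ""
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=element or _guess_element(name),
                        res_name=line[17:20].strip(),
                        res_seq=res_seq,
                        chain=line[21].strip() or "A",
                        xyz=(x, y, z),
                    )
                )
    if atoms:
        # single implicit model (no MODEL/ENDMDL records)
        model_no = max(model_no, 1)
        close_model()
    if not frames:
        raise PDBParseError(f"no atoms found in {path}")
    return Trajectory(frames)


def _format_atom_name(name: str, element: str) -> str:
    """PDB column-13..16 convention: 1-char elements start at column 14."""
    if len(name) > 4:
        raise ValidationError(f"atom name {name!r} longer than 4 characters")
    if len(name) >= 4 or len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as fixed-width multi-model PDB (coordinates at 3 dp)."""
    if len(traj) == 0:
        raise ValidationError("cannot write an empty trajectory")
    path = Path(path)
    with open(path, "w") as fh:
        for model_no, frame in enumerate(traj, start=1):
            fh.write(f"MODEL     {model_no:4d}\n")
            for atom in frame.atoms:
                name = _format_atom_name(atom.name, atom.element)
                x, y, z = atom.xyz
                fh.write(
                    f"ATOM  {atom.serial:5d} {name} {atom.res_name:>3s} "
                    f"{atom.chain:1s}{atom.res_seq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# energy tables

_REQUIRED_COLUMNS = ("frame", "species", "e_gas", "g_sol")


def read_energy_table(path: str | Path) -> list[EnergyRecord]:
    """Read a long-format delimited energy table (comma default, tab accepted).

    Columns: frame, species, e_gas, g_sol, optional ts_entropy.  Rows must
    be sorted by frame within each species; duplicate (frame, species)
    pairs are rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"energy table {path} missing column(s): {', '.join(missing)}")
    bad = set(df["species"]) - set(SPECIES)
    if bad:
        raise SchemaError(f"unknown species label(s) {sorted(bad)} in {path}")
    if df.duplicated(subset=["frame", "species"]).any():
        dup = df[df.duplicated(subset=["frame", "species"])].iloc[0]
        raise IntegrityError(
            f"duplicate record for frame {int(dup['frame'])} species {dup['species']!r}"
        )
    for sp, grp in df.groupby("species"):
        if not grp["frame"].is_monotonic_increasing:
            raise IntegrityError(f"frames for species {sp!r} are not sorted ascending")
    has_entropy = "ts_entropy" in df.columns
    records = []
    for row in df.itertuples(index=False):
        ts = getattr(row, "ts_entropy", None) if has_entropy else None
        if ts is not None and pd.isna(ts):
            ts = None
        records.append(
            EnergyRecord(
                frame_index=int(row.frame),
                species=str(row.species),
                e_gas=float(row.e_gas),
                g_sol=float(row.g_sol),
                ts_entropy=None if ts is None else float(ts),
            )
        )
    return records


def write_energy_table(records: Sequence[EnergyRecord], path: str | Path, sep: str = ",") -> None:
    """Write EnergyRecords in the long format that :func:`read_energy_table` reads."""
    rows = []
    any_entropy = any(r.ts_entropy is not None for r in records)
    for r in records:
        row = {"frame": r.frame_index, "species": r.species, "e_gas": r.e_gas, "g_sol": r.g_sol}
        if any_entropy:
            row["ts_entropy"] = r.ts_entropy
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.10g")
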