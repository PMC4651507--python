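"""Geometric hydrogen-bond detection, interface counting and occupancy.

A hydrogen bond D–H···A is recorded when the donor-heavy-atom to
acceptor-heavy-atom distance is at most ``max_da_distance`` (default 3.0 Å)
and the angle at the hydrogen, ∠(D,H,A), is at least ``min_dha_angle``
(default 135°); both boundaries inclusive.  These are the cpptraj-style
cutoffs used throughout the p53–DNA analysis.

The interface H-bond count k of a frame counts the detected bonds whose
protein-side residue belongs to the eight-residue DNA-binding interface
(LYS 120, SER 241, ARG 248, ARG 273, ALA 276, CYS 277, ARG 280, ARG 283 in
crystal numbering) and whose partner atom sits on a DNA chain; each
distinct (donor, acceptor) pair counts once per frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .trajectory_io import Atom, StructureFrame, Trajectory

AtomRef = tuple[str, int, str]  # (chain, res_seq, atom name)

INTERFACE_RESIDUES = frozenset({120, 241, 248, 273, 276, 277, 280, 283})

#: max donor–hydrogen covalent distance; beyond this the pair is not a real
#: donor group and is skipped with a warning.
MAX_DH_COVALENT = 1.5


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric cutoffs: heavy-atom D–A distance (Å) and D-H···A angle (deg)."""

    max_da_distance: float = 3.0
    min_dha_angle: float = 135.0

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValidationError("max_da_distance must be positive")
        if not (0.0 < self.min_dha_angle <= 180.0):
            raise ValidationError("min_dha_angle must lie in (0, 180]")


@dataclass(frozen=True)
class InterfaceSpec:
    """Which protein residues and which partner (DNA) chains define the interface."""

    protein_residues: frozenset[int] = INTERFACE_RESIDUES
    partner_chains: frozenset[str] = frozenset({"B", "C"})

    def __post_init__(self) -> None:
        if not self.protein_residues or not self.partner_chains:
            raise ValidationError("interface residue set and partner chains must be non-empty")


@dataclass(frozen=True)
class HBondEvent:
    frame_index: int
    donor: AtomRef
    hydrogen: AtomRef
    acceptor: AtomRef
    da_distance: float
    dha_angle: float


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _index_frame(frame: StructureFrame) -> dict[AtomRef, int]:
    return {atom.ref: i for i, atom in enumerate(frame.atoms)}


def default_donors_acceptors(
    frame: StructureFrame, max_dh: float = 1.2
) -> tuple[list[tuple[AtomRef, AtomRef]], list[AtomRef]]:
    """Chemistry-table donor/acceptor assignment from atom names and elements.

    Donors: N or O heavy atoms with a hydrogen of the same residue within
    ``max_dh`` Å.  Acceptors: all N and O atoms.  Override by passing
    explicit lists to :func:`detect_hbonds` when a system needs more.
    """
    coords = frame.coord_array()
    donors: list[tuple[AtomRef, AtomRef]] = []
    acceptors: list[AtomRef] = []
    by_residue: dict[tuple[str, int], list[int]] = {}
    for i, atom in enumerate(frame.atoms):
        by_residue.setdefault((atom.chain, atom.res_seq), []).append(i)
    for i, atom in enumerate(frame.atoms):
        if atom.element not in ("N", "O"):
            continue
        acceptors.append(atom.ref)
        for j in by_residue[(atom.chain, atom.res_seq)]:
            other = frame.atoms[j]
            if other.element != "H":
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= max_dh:
                donors.append((atom.ref, other.ref))
    return donors, acceptors


def detect_hbonds(
    frame: StructureFrame,
    donors: list[tuple[AtomRef, AtomRef]],
    acceptors: list[AtomRef],
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondEvent]:
    """All D–H···A events of one frame satisfying the geometric criteria."""
    index = _index_frame(frame)
    coords = frame.coord_array()
    events: list[HBondEvent] = []
    for donor_ref, hydrogen_ref in donors:
        try:
            di = index[donor_ref]
            hi = index[hydrogen_ref]
        except KeyError as exc:
            raise ValidationError(f"donor pair references missing atom {exc}") from None
        if np.linalg.norm(coords[di] - coords[hi]) > MAX_DH_COVALENT:
            warnings.warn(
                f"hydrogen {hydrogen_ref} is {np.linalg.norm(coords[di] - coords[hi]):.2f} Å "
                f"from donor {donor_ref} (> {MAX_DH_COVALENT} Å); pair skipped",
                stacklevel=2,
            )
            continue
        for acc_ref in acceptors:
            if acc_ref == donor_ref:
                continue
            try:
                ai = index[acc_ref]
            except KeyError as exc:
                raise ValidationError(f"acceptor references missing atom {exc}") from None
            da = float(np.linalg.norm(coords[di] - coords[ai]))
            if da > criteria.max_da_distance:
                continue
            angle = _angle_deg(coords[di], coords[hi], coords[ai])
            if angle < criteria.min_dha_angle:
                continue
            events.append(
                HBondEvent(
                    frame_index=frame.frame_index,
                    donor=donor_ref,
                    hydrogen=hydrogen_ref,
                    acceptor=acc_ref,
                    da_distance=da,
                    dha_angle=angle,
                )
            )
    return events


def interface_hbond_count(events: list[HBondEvent], spec: InterfaceSpec = InterfaceSpec()) -> int:
    """k: number of distinct interface protein–DNA bonds among one frame's events."""
    seen: set[tuple[AtomRef, AtomRef]] = set()
    for ev in events:
        donor_chain = ev.donor[0]
        acc_chain = ev.acceptor[0]
        if acc_chain in spec.partner_chains and donor_chain not in spec.partner_chains:
            protein_res = ev.donor[1]
        elif donor_chain in spec.partner_chains and acc_chain not in spec.partner_chains:
            protein_res = ev.acceptor[1]
        else:
            continue  # protein-protein or DNA-DNA contact
        if protein_res in spec.protein_residues:
            seen.add((ev.donor, ev.acceptor))
    return len(seen)


def interface_hbond_series(
    traj: Trajectory,
    spec: InterfaceSpec = InterfaceSpec(),
    criteria: HBondCriteria = HBondCriteria(),
    donors: list[tuple[AtomRef, AtomRef]] | None = None,
    acceptors: list[AtomRef] | None = None,
) -> tuple[list[int], list[int]]:
    """(frame_index list, per-frame k list) over a trajectory.

    Donors/acceptors default to the chemistry-table assignment computed on
    the first frame (atom identity is constant across frames).
    """
    if len(traj) == 0:
        raise ValidationError("empty trajectory")
    if donors is None or acceptors is None:
        auto_d, auto_a = default_donors_acceptors(traj[0])
        donors = donors if donors is not None else auto_d
        acceptors = acceptors if acceptors is not None else auto_a
    frames, ks = [], []
    for frame in traj:
        events = detect_hbonds(frame, donors, acceptors, criteria)
        frames.append(frame.frame_index)
        ks.append(interface_hbond_count(events, spec))
    return frames, ks


def bond_occupancy(
    traj: Trajectory,
    donor_pair: tuple[AtomRef, AtomRef],
    acceptor: AtomRef,
    criteria: HBondCriteria = HBondCriteria(),
) -> float:
    """Percent of frames in which one specific D–H···A bond is present (0–100)."""
    if len(traj) == 0:
        raise ValidationError("occupancy undefined for an empty trajectory")
    donor_ref, hydrogen_ref = donor_pair
    hits = 0
    for frame in traj:
        events = detect_hbonds(frame, [donor_pair], [acceptor], criteria)
        hits += any(
            ev.donor == donor_ref and ev.acceptor == acceptor for ev in events
        )
    return 100.0 * hits / len(traj)
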