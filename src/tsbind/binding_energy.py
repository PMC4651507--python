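"""Per-frame MM-GBSA free energies and binding free energy.

For each species s ∈ {complex, receptor, ligand} the frame free energy is

    ΔG_s = ΔE_gas(s) + ΔG_sol(s) − TΔS(s)

where the entropy term is optional (it is routinely skipped because
normal-mode entropy is expensive and rarely changes the trend).  The
binding free energy of a frame follows the standard thermodynamic cycle

    ΔΔG_bind = ΔG_complex − ΔG_receptor − ΔG_ligand

so that a more negative ΔΔG_bind means stronger predicted binding.  A
``legacy_sign`` switch reproduces the alternative printed combination
ΔG_complex − ΔG_receptor + ΔG_ligand for reproduction studies.

The receptor-only series ΔG_protein (the p53 molecule alone) doubles as a
whole-protein stability proxy and feeds the population analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, IntegrityError, ValidationError
from .trajectory_io import EnergyRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrameBindingEnergy:
    """One frame's binding free energy and the three species terms (kcal/mol)."""

    frame_index: int
    ddg_bind: float
    dg_complex: float
    dg_receptor: float
    dg_ligand: float
    entropy_included: bool


@dataclass
class ProteinStabilitySeries:
    """Per-frame free energy of the protein alone (ΔG_protein, kcal/mol)."""

    frame_index: list[int]
    dg_protein: np.ndarray

    def __post_init__(self) -> None:
        self.dg_protein = np.asarray(self.dg_protein, dtype=float)
        if len(self.frame_index) != len(self.dg_protein):
            raise ValidationError("frame_index and dg_protein lengths differ")
        if len(self.dg_protein) and not np.all(np.isfinite(self.dg_protein)):
            raise ValidationError("non-finite ΔG_protein value")

    def __len__(self) -> int:
        return len(self.dg_protein)


def species_free_energy(record: EnergyRecord, include_entropy: bool = False) -> float:
    """ΔG for one species in one frame: e_gas + g_sol (− ts_entropy if included)."""
    if include_entropy:
        if record.ts_entropy is None:
            raise ConfigurationError(
                f"entropy requested but absent for frame {record.frame_index} "
                f"species {record.species!r}"
            )
        return record.e_gas + record.g_sol - record.ts_entropy
    return record.e_gas + record.g_sol


def frame_binding_energy(
    complex_rec: EnergyRecord,
    receptor: EnergyRecord,
    ligand: EnergyRecord,
    include_entropy: bool = False,
    legacy_sign: bool = False,
) -> FrameBindingEnergy:
    """Combine the three species free energies of one frame into ΔΔG_bind."""
    for rec, sp in ((complex_rec, "complex"), (receptor, "receptor"), (ligand, "ligand")):
        if rec.species != sp:
            raise IntegrityError(f"expected species {sp!r}, got {rec.species!r}")
    if not (complex_rec.frame_index == receptor.frame_index == ligand.frame_index):
        raise IntegrityError(
            f"frame indices differ: complex={complex_rec.frame_index}, "
            f"receptor={receptor.frame_index}, ligand={ligand.frame_index}"
        )
    dgc = species_free_energy(complex_rec, include_entropy)
    dgr = species_free_energy(receptor, include_entropy)
    dgl = species_free_energy(ligand, include_entropy)
    ddg = dgc - dgr + dgl if legacy_sign else dgc - dgr - dgl
    return FrameBindingEnergy(
        frame_index=complex_rec.frame_index,
        ddg_bind=ddg,
        dg_complex=dgc,
        dg_receptor=dgr,
        dg_ligand=dgl,
        entropy_included=include_entropy,
    )


def binding_energy_series(
    records: list[EnergyRecord],
    include_entropy: bool = False,
    legacy_sign: bool = False,
) -> tuple[list[FrameBindingEnergy], list[int]]:
    """ΔΔG_bind for every frame with a complete complex/receptor/ligand triple.

    Returns ``(series, skipped_frames)``.  Frames missing one or more
    species are skipped with a logged warning, never silently dropped: the
    skipped frame indices come back to the caller for the run report.
    """
    by_frame: dict[int, dict[str, EnergyRecord]] = {}
    for rec in records:
        slot = by_frame.setdefault(rec.frame_index, {})
        if rec.species in slot:
            raise IntegrityError(
                f"duplicate record for frame {rec.frame_index} species {rec.species!r}"
            )
        slot[rec.species] = rec
    series: list[FrameBindingEnergy] = []
    skipped: list[int] = []
    for frame in sorted(by_frame):
        slot = by_frame[frame]
        if len(slot) < 3:
            skipped.append(frame)
            continue
        series.append(
            frame_binding_energy(
                slot["complex"], slot["receptor"], slot["ligand"],
                include_entropy=include_entropy, legacy_sign=legacy_sign,
            )
        )
    if skipped:
        logger.warning(
            "skipped %d frame(s) with incomplete species triples: %s%s",
            len(skipped), skipped[:10], "..." if len(skipped) > 10 else "",
        )
    return series, skipped


def protein_free_energy_series(
    receptor_records: list[EnergyRecord],
    include_entropy: bool = False,
) -> ProteinStabilitySeries:
    """ΔG_protein per frame from receptor-only records (sorted by frame)."""
    frames: list[int] = []
    values: list[float] = []
    prev = None
    for rec in receptor_records:
        if rec.species != "receptor":
            raise IntegrityError(
                f"non-receptor record (species {rec.species!r}) in protein series input"
            )
        if prev is not None and rec.frame_index <= prev:
            raise IntegrityError("receptor records not sorted by frame_index")
        prev = rec.frame_index
        frames.append(rec.frame_index)
        values.append(species_free_energy(rec, include_entropy))
    return ProteinStabilitySeries(frame_index=frames, dg_protein=np.asarray(values))
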