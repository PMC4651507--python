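"""Seeded generators emulating the statistical structure of the p53–DNA study.

No trajectories are deposited for the original QM-MM simulations, so every
analysis stage is exercised against synthetic data with the features the
method assumes:

* per-frame binding energies linearly coupled to the interface H-bond
  count k (ΔΔG | k ~ Normal(β0 + β1·k, σ), k from independent Bernoulli
  draws of the eight interface bonds);
* condition presets contrasting 300 K and 310 K — higher bond
  probabilities and lower β0 in the cold condition — including a
  V143A-like preset that out-binds wild type at 300 K;
* a toy p53–DNA interface ensemble whose bonds, when formed, satisfy the
  geometric criteria by construction, with occluder pseudo-atoms whose
  proximity (burial_factor) buries the interface side chains;
* wrapped cis (~0°) / trans (~180°) dihedral mixtures.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64,
integer state), so a fixed seed reproduces every artifact bit-for-bit on
any platform.  Ground truth is returned alongside each artifact so
downstream expected values are computable in closed form in the noiseless
limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .trajectory_io import Atom, EnergyRecord, StructureFrame, Trajectory
from .dihedral_pca import DihedralSeries, wrap_degrees

#: interface residues in crystal numbering with the donor group used for each
#: (residue name, donor heavy atom, donor hydrogen); ALA/CYS donate via the
#: backbone amide.
INTERFACE_DONORS = (
    (120, "LYS", "NZ", "HZ1"),
    (241, "SER", "OG", "HG"),
    (248, "ARG", "NH1", "HH11"),
    (273, "ARG", "NH1", "HH11"),
    (276, "ALA", "N", "H"),
    (277, "CYS", "N", "H"),
    (280, "ARG", "NH1", "HH11"),
    (283, "ARG", "NH1", "HH11"),
)

# fixed energy baselines for the species decomposition (kcal/mol)
_RECEPTOR_GSOL = -105.0
_LIGAND_EGAS = -80.0
_LIGAND_GSOL = -15.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic ensemble.

    Defaults mirror the analysed simulations: 3000 frames (30 ns at 10 ps
    snapshots), binding noise σ = 3 kcal/mol, coupling β1 = −2 kcal/mol per
    interface bond.  ``hbond_probs`` holds one Bernoulli probability per
    interface bond; ``burial_factor`` ∈ [0, 1] moves occluder pseudo-atoms
    toward the interface side chains (1 = most buried).
    """

    seed: int = 0
    n_frames: int = 3000
    condition: str = "T300"
    variant: str = "WT"
    hbond_probs: tuple[float, ...] = (0.65,) * 8
    ddg_intercept: float = -4.0
    ddg_slope: float = -2.0
    noise_sd: float = 3.0
    dihedral_clusters: tuple[tuple[float, float, float], ...] = (
        (180.0, 8.0, 0.8),
        (0.0, 8.0, 0.2),
    )
    burial_factor: float = 0.3
    dg_protein_mean: float = -2500.0
    dg_protein_sd: float = 30.0
    include_entropy: bool = True

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be positive")
        if self.condition not in ("T300", "T310"):
            raise ValidationError(f"condition must be 'T300' or 'T310', got {self.condition!r}")
        if not self.hbond_probs or any(not (0.0 <= p <= 1.0) for p in self.hbond_probs):
            raise ValidationError("hbond_probs must be non-empty probabilities in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not (0.0 <= self.burial_factor <= 1.0):
            raise ValidationError("burial_factor must lie in [0, 1]")
        weights = [w for _, _, w in self.dihedral_clusters]
        if not weights or any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError("dihedral cluster weights must be non-negative and sum to 1")
        if any(kappa <= 0 for _, kappa, _ in self.dihedral_clusters):
            raise ValidationError("dihedral cluster concentrations must be positive")


#: Condition presets: the cold condition binds more bonds at lower ΔΔG; the
#: warm condition loses bonds, shifts β0 up by 4.5 kcal/mol and raises
#: ΔG_protein by ~150 kcal/mol.  V143A out-binds WT at 300 K only.
_PRESETS: dict[tuple[str, str], dict] = {
    ("WT", "T300"): dict(hbond_probs=(0.65,) * 8, ddg_intercept=-4.0,
                         dg_protein_mean=-2500.0, burial_factor=0.3,
                         dihedral_clusters=((180.0, 8.0, 0.8), (0.0, 8.0, 0.2))),
    ("WT", "T310"): dict(hbond_probs=(0.45,) * 8, ddg_intercept=0.5,
                         dg_protein_mean=-2350.0, burial_factor=0.5,
                         dihedral_clusters=((180.0, 8.0, 0.55), (0.0, 8.0, 0.45))),
    ("V143A", "T300"): dict(hbond_probs=(0.75,) * 8, ddg_intercept=-6.0,
                            dg_protein_mean=-2520.0, burial_factor=0.25,
                            dihedral_clusters=((180.0, 8.0, 0.85), (0.0, 8.0, 0.15))),
    ("V143A", "T310"): dict(hbond_probs=(0.40,) * 8, ddg_intercept=-1.5,
                            dg_protein_mean=-2380.0, burial_factor=0.55,
                            dihedral_clusters=((180.0, 8.0, 0.5), (0.0, 8.0, 0.5))),
    ("R249S", "T300"): dict(hbond_probs=(0.50,) * 8, ddg_intercept=-2.0,
                            dg_protein_mean=-2420.0, burial_factor=0.45,
                            dihedral_clusters=((180.0, 8.0, 0.6), (0.0, 8.0, 0.4))),
    ("R249S", "T310"): dict(hbond_probs=(0.35,) * 8, ddg_intercept=2.5,
                            dg_protein_mean=-2360.0, burial_factor=0.6,
                            dihedral_clusters=((180.0, 8.0, 0.45), (0.0, 8.0, 0.55))),
    ("R175H", "T300"): dict(hbond_probs=(0.50,) * 8, ddg_intercept=-1.5,
                            dg_protein_mean=-2410.0, burial_factor=0.5,
                            dihedral_clusters=((180.0, 8.0, 0.55), (0.0, 8.0, 0.45))),
    ("R175H", "T310"): dict(hbond_probs=(0.35,) * 8, ddg_intercept=3.0,
                            dg_protein_mean=-2355.0, burial_factor=0.6,
                            dihedral_clusters=((180.0, 8.0, 0.45), (0.0, 8.0, 0.55))),
}


def preset(variant: str = "WT", condition: str = "T300", seed: int = 0,
           n_frames: int = 3000, **overrides) -> GeneratorConfig:
    """GeneratorConfig for a named variant/temperature study condition."""
    key = (variant, condition)
    if key not in _PRESETS:
        raise ValidationError(
            f"no preset for {variant!r} at {condition!r}; "
            f"known: {sorted(set(v for v, _ in _PRESETS))} × ('T300', 'T310')"
        )
    params = dict(_PRESETS[key])
    params.update(overrides)
    return GeneratorConfig(seed=seed, n_frames=n_frames, condition=condition,
                           variant=variant, **params)


@dataclass
class GroundTruth:
    """Planted parameters and latent draws behind one synthetic ensemble."""

    bond_matrix: np.ndarray      # frames × bonds boolean
    k: np.ndarray                # per-frame interface bond count
    ddg: np.ndarray              # per-frame drawn ΔΔG_bind
    dg_protein: np.ndarray       # per-frame drawn ΔG_protein
    beta0: float
    beta1: float
    noise_sd: float


def generate_energy_tables(cfg: GeneratorConfig) -> tuple[list[EnergyRecord], GroundTruth]:
    """Per-frame energy records whose combination reproduces the drawn ΔΔG exactly.

    The receptor carries the ΔG_protein series (constant solvation term),
    the ligand is a fixed baseline, and the complex is receptor + ligand +
    ΔΔG, so ``frame_binding_energy`` recovers the planted value to
    round-off.  Optional TΔS columns are small per-species draws.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    probs = np.asarray(cfg.hbond_probs)
    bonds = rng.random((n, len(probs))) < probs
    k = bonds.sum(axis=1)
    ddg = cfg.ddg_intercept + cfg.ddg_slope * k + rng.normal(0.0, cfg.noise_sd, n)
    dg_protein = rng.normal(cfg.dg_protein_mean, cfg.dg_protein_sd, n)
    if cfg.include_entropy:
        ts_rec = rng.normal(-20.0, 1.0, n)
        ts_lig = rng.normal(-8.0, 0.5, n)
        ts_com = ts_rec + ts_lig + rng.normal(-2.0, 0.5, n)
    records: list[EnergyRecord] = []
    for sp in ("complex", "receptor", "ligand"):
        for i in range(n):
            e_gas_rec = dg_protein[i] - _RECEPTOR_GSOL
            if sp == "receptor":
                e_gas, g_sol = e_gas_rec, _RECEPTOR_GSOL
                ts = ts_rec[i] if cfg.include_entropy else None
            elif sp == "ligand":
                e_gas, g_sol = _LIGAND_EGAS, _LIGAND_GSOL
                ts = ts_lig[i] if cfg.include_entropy else None
            else:
                e_gas = e_gas_rec + _LIGAND_EGAS + ddg[i]
                g_sol = _RECEPTOR_GSOL + _LIGAND_GSOL
                ts = ts_com[i] if cfg.include_entropy else None
            records.append(EnergyRecord(frame_index=i, species=sp, e_gas=e_gas,
                                        g_sol=g_sol, ts_entropy=ts))
    truth = GroundTruth(bond_matrix=bonds, k=k, ddg=ddg, dg_protein=dg_protein,
                        beta0=cfg.ddg_intercept, beta1=cfg.ddg_slope, noise_sd=cfg.noise_sd)
    return records, truth


def _interface_residue_atoms(
    slot: int, res_seq: int, res_name: str, donor_name: str, h_name: str,
    bonded: bool, burial_factor: float, serial_start: int,
) -> list[Atom]:
    """Atoms of one interface residue, its DNA acceptor, and its occluders.

    Residues sit 14 Å apart along x so neighbouring groups never interact.
    The donor heavy atom is at the origin of the slot, the hydrogen 1 Å
    along +y, and the acceptor on the same axis: 2.8 Å in bond frames
    (collinear, angle 180°), 4.5 Å otherwise.  Occluders are carbon
    pseudo-atoms on fixed directions around CB at distance 8 − 5·burial.
    """
    x0 = 14.0 * slot
    base = np.array([x0, 0.0, 0.0])
    serial = serial_start
    atoms: list[Atom] = []

    def add(name, element, res_nm, res_id, chain, pos):
        nonlocal serial
        atoms.append(Atom(serial=serial, name=name, element=element, res_name=res_nm,
                          res_seq=res_id, chain=chain, xyz=tuple(pos)))
        serial += 1

    donor_is_backbone = donor_name == "N"
    # backbone (N placed at the donor site when it donates; otherwise kept
    # > 1.2 Å from the side-chain donor group so donor assignment stays clean)
    n_pos = base if donor_is_backbone else base + np.array([0.0, -1.5, 1.2])
    add("N", "N", res_name, res_seq, "A", n_pos)
    add("H", "H", res_name, res_seq, "A", n_pos + np.array([0.0, 1.0, 0.0]))
    add("CA", "C", res_name, res_seq, "A", base + np.array([0.3, -1.8, 0.0]))
    add("C", "C", res_name, res_seq, "A", base + np.array([0.0, -3.0, -0.6]))
    add("O", "O", res_name, res_seq, "A", base + np.array([0.0, -3.8, 0.2]))
    cb = base + np.array([1.2, -1.6, -1.2])
    add("CB", "C", res_name, res_seq, "A", cb)
    if not donor_is_backbone:
        add(donor_name, donor_name[0], res_name, res_seq, "A", base)
        add(h_name, "H", res_name, res_seq, "A", base + np.array([0.0, 1.0, 0.0]))
    # DNA acceptor opposite the donor
    acc_dist = 2.8 if bonded else 4.5
    add("N7", "N", "DG", 500 + slot, "B", base + np.array([0.0, acc_dist, 0.0]))
    # occluders around CB: closer when burial_factor is higher
    d = 8.0 - 5.0 * burial_factor
    for direction in (np.array([1.0, 0.0, 0.0]), np.array([-0.5, 0.0, -0.87]),
                      np.array([0.3, -0.6, 0.74])):
        add("C", "C", "OCC", 900 + slot, "X", cb + d * direction)
    return atoms


def generate_interface_frames(
    cfg: GeneratorConfig, return_truth: bool = False
) -> Trajectory | tuple[Trajectory, np.ndarray]:
    """Toy p53–DNA interface ensemble with planted per-frame bonds.

    Bond draws reuse the config's per-bond probabilities; a formed bond is
    collinear D–H···A at 2.8 Å (detected under the default criteria by
    construction), an absent bond parks the acceptor at 4.5 Å.
    """
    rng = np.random.default_rng(cfg.seed)
    probs = np.asarray(cfg.hbond_probs)
    n_bonds = min(len(probs), len(INTERFACE_DONORS))
    bonds = rng.random((cfg.n_frames, n_bonds)) < probs[:n_bonds]
    frames = []
    for fi in range(cfg.n_frames):
        atoms: list[Atom] = []
        for slot in range(n_bonds):
            res_seq, res_name, donor, hyd = INTERFACE_DONORS[slot]
            atoms.extend(
                _interface_residue_atoms(
                    slot, res_seq, res_name, donor, hyd,
                    bonded=bool(bonds[fi, slot]),
                    burial_factor=cfg.burial_factor,
                    serial_start=len(atoms) + 1,
                )
            )
        frames.append(StructureFrame(frame_index=fi, time_ps=10.0 * fi, atoms=atoms))
    traj = Trajectory(frames)
    return (traj, bonds) if return_truth else traj


def generate_dihedral_series(
    cfg: GeneratorConfig, n_residues: int = 10, angle_kind: str = "phi"
) -> tuple[DihedralSeries, np.ndarray]:
    """Wrapped-mixture torsion series; returns (series, cluster assignments).

    One reporter residue (the last) flips between the mixture clusters with
    the configured weights; the remaining residues fluctuate tightly about
    trans, so the reporter's cis/trans transition is the dominant mode.
    """
    rng = np.random.default_rng(cfg.seed)
    weights = np.array([w for _, _, w in cfg.dihedral_clusters])
    centers = np.array([c for c, _, _ in cfg.dihedral_clusters])
    kappas = np.array([kp for _, kp, _ in cfg.dihedral_clusters])
    n = cfg.n_frames
    assignments = rng.choice(len(weights), size=n, p=weights)
    values = np.empty((n, n_residues))
    for j in range(n_residues - 1):
        values[:, j] = np.degrees(rng.vonmises(np.pi, 50.0, n))  # tight trans baseline
    reporter = np.degrees(
        rng.vonmises(np.radians(centers[assignments]), kappas[assignments])
    )
    values[:, n_residues - 1] = reporter
    values = wrap_degrees(values)
    values[values <= -180.0] = 180.0
    residues = list(range(240, 240 + n_residues))
    return DihedralSeries(angle_kind=angle_kind, residues=residues, values=values), assignments


def generate_population_points(
    n: int, p_less_stable: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """(rel_sasa, rel_dg) draws with a planted (+, +) quadrant probability.

    Each frame lands in the less-stable quadrant with probability
    ``p_less_stable``; the remainder spreads evenly over the other three
    quadrants.  Magnitudes are folded normals bounded away from zero.
    """
    if not (0.0 <= p_less_stable <= 1.0):
        raise ValidationError("p_less_stable must lie in [0, 1]")
    if n < 1:
        raise ValidationError("n must be positive")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    rest = (1.0 - p_less_stable) / 3.0
    # quadrant signs: (+,+), (-,-), (+,-), (-,+)
    signs = np.array([(1, 1), (-1, -1), (1, -1), (-1, 1)], dtype=float)
    idx = np.digitize(u, np.cumsum([p_less_stable, rest, rest]))
    mag_sasa = np.abs(rng.normal(50.0, 20.0, n)) + 1.0
    mag_dg = np.abs(rng.normal(30.0, 10.0, n)) + 1.0
    return signs[idx, 0] * mag_sasa, signs[idx, 1] * mag_dg
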