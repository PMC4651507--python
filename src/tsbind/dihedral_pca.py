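"""Backbone φ/ψ extraction and circular-aware principal component analysis.

Backbone torsions are the standard definitions

    φ(i) = torsion C(i−1)–N(i)–CA(i)–C(i)
    ψ(i) = torsion N(i)–CA(i)–C(i)–N(i+1)

reported in degrees on the principal interval (−180, 180].  Because a
torsion is a circular variable, PCA is performed on the (sin θ, cos θ)
embedding of each angle rather than on raw degrees: this makes the
analysis exactly invariant under ±360° rewrapping and avoids the
cis (~0°) / trans (~180°) populations being split by the branch cut.

Component scores are therefore linear scores in the embedded space, not
angles; cluster topology (e.g. a cis and a trans basin separating along a
component) is the comparable structure.  The dominant mode of each
component is back-projected to an angle for interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, IntegrityError, ValidationError
from .binding_energy import ProteinStabilitySeries
from .trajectory_io import Trajectory


def wrap_degrees(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (degrees) to the principal interval (−180, 180]."""
    w = np.mod(x, 360.0)
    return np.where(w > 180.0, w - 360.0, w) if isinstance(w, np.ndarray) else (
        w - 360.0 if w > 180.0 else w
    )


@dataclass
class DihedralSeries:
    """frames × residues matrix of one backbone torsion kind, degrees in (−180, 180]."""

    angle_kind: str  # "phi" or "psi"
    residues: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.angle_kind not in ("phi", "psi"):
            raise ValidationError(f"angle_kind must be 'phi' or 'psi', got {self.angle_kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.residues):
            raise ValidationError("values must be a frames × residues matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("missing/non-finite dihedral values")
        if np.any(self.values <= -180.0) or np.any(self.values > 180.0):
            raise ValidationError("dihedral values outside (−180, 180]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class PCAResult:
    component_scores: np.ndarray       # frames × components
    variance_explained: np.ndarray     # per-component fraction of total variance
    loadings: np.ndarray               # 2·residues (sin block, cos block) × components
    mode_angles_deg: np.ndarray        # dominant-residue back-projected angle per component


def torsion_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion of four points, degrees in (−180, 180] (IUPAC sign)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(wrap_degrees(np.degrees(np.arctan2(y, x))))


def compute_backbone_dihedrals(
    traj: Trajectory, angle_kind: str, chain: str | None = None
) -> DihedralSeries:
    """φ or ψ time series for every residue of one chain with complete backbone.

    Residues missing a backbone atom (or the neighbouring residue needed
    for the torsion) are omitted with a warning.  Consecutiveness is judged
    on author numbering: residue i−1/i+1 must literally be res_seq ± 1.
    """
    if angle_kind not in ("phi", "psi"):
        raise ValidationError(f"angle_kind must be 'phi' or 'psi', got {angle_kind!r}")
    if len(traj) == 0:
        raise ValidationError("empty trajectory")
    frame0 = traj[0]
    chains = {a.chain for a in frame0.atoms}
    if chain is None:
        chain = sorted(chains)[0]
    backbone: dict[int, dict[str, int]] = {}
    for i, atom in enumerate(frame0.atoms):
        if atom.chain == chain and atom.name in ("N", "CA", "C"):
            backbone.setdefault(atom.res_seq, {})[atom.name] = i

    quads: list[tuple[int, tuple[int, int, int, int]]] = []
    for res in sorted(backbone):
        this = backbone[res]
        if angle_kind == "phi":
            prev = backbone.get(res - 1, {})
            needed = [("C", prev), ("N", this), ("CA", this), ("C", this)]
        else:
            nxt = backbone.get(res + 1, {})
            needed = [("N", this), ("CA", this), ("C", this), ("N", nxt)]
        if all(name in d for name, d in needed):
            quads.append((res, tuple(d[name] for name, d in needed)))
        else:
            missing_neighbor = (angle_kind == "phi" and res - 1 not in backbone) or (
                angle_kind == "psi" and res + 1 not in backbone
            )
            if not missing_neighbor:  # terminal omissions are expected, stay quiet
                warnings.warn(
                    f"residue {res} chain {chain} lacks a backbone atom for {angle_kind}; omitted",
                    stacklevel=2,
                )
    if not quads:
        raise ValidationError(f"no residue of chain {chain!r} has a complete {angle_kind} quadruple")

    residues = [res for res, _ in quads]
    values = np.empty((len(traj), len(quads)))
    for fi, frame in enumerate(traj):
        coords = frame.coord_array()
        for qi, (_, (a, b, c, d)) in enumerate(quads):
            values[fi, qi] = torsion_angle(coords[a], coords[b], coords[c], coords[d])
    return DihedralSeries(angle_kind=angle_kind, residues=residues, values=values)


def circular_pca(series: DihedralSeries, n_components: int = 2) -> PCAResult:
    """PCA on the (sin, cos) embedding of each torsion.

    Columns are mean-centered; the covariance matrix is eigendecomposed
    and the leading ``n_components`` scores returned.  An all-constant
    dataset (zero total variance) raises DegenerateDataError.
    """
    if series.n_frames < 2:
        raise ValidationError("circular PCA needs at least 2 frames")
    theta = np.radians(series.values)
    X = np.hstack([np.sin(theta), np.cos(theta)])
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (series.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total < 1e-12:
        raise DegenerateDataError("all dihedrals constant: zero total variance")
    n_components = min(n_components, len(evals))
    scores = Xc @ evecs[:, :n_components]
    loadings = evecs[:, :n_components]
    n_res = len(series.residues)
    mode_angles = np.empty(n_components)
    for j in range(n_components):
        ls, lc = loadings[:n_res, j], loadings[n_res:, j]
        dominant = int(np.argmax(np.hypot(ls, lc)))
        mode_angles[j] = wrap_degrees(np.degrees(np.arctan2(ls[dominant], lc[dominant])))
    return PCAResult(
        component_scores=scores,
        variance_explained=evals[:n_components] / total,
        loadings=loadings,
        mode_angles_deg=mode_angles,
    )


@dataclass
class StabilityLandscape:
    """(PC2, ΔG_protein) pairs and their 2-D histogram summary."""

    pairs: pd.DataFrame          # columns frame_index, pc2, dg_protein
    counts: np.ndarray           # 2-D histogram, pc2 × dg bins
    pc2_edges: np.ndarray
    dg_edges: np.ndarray


def stability_landscape(
    scores_pc2: np.ndarray,
    dg_series: ProteinStabilitySeries,
    frame_index: list[int] | None = None,
    bins: int | tuple[int, int] = 40,
) -> StabilityLandscape:
    """Population map of whole-protein free energy along component 2.

    ``frame_index`` (defaults to the stability series' frames) must align
    one-to-one with the score vector.
    """
    scores_pc2 = np.asarray(scores_pc2, dtype=float)
    if frame_index is None:
        frame_index = list(dg_series.frame_index)
    if len(scores_pc2) != len(dg_series) or list(frame_index) != list(dg_series.frame_index):
        raise IntegrityError("PC2 scores and ΔG_protein series are not frame-aligned")
    pairs = pd.DataFrame(
        {"frame_index": frame_index, "pc2": scores_pc2, "dg_protein": dg_series.dg_protein}
    )
    counts, pc2_edges, dg_edges = np.histogram2d(
        pairs["pc2"], pairs["dg_protein"], bins=bins
    )
    return StabilityLandscape(pairs=pairs, counts=counts, pc2_edges=pc2_edges, dg_edges=dg_edges)
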