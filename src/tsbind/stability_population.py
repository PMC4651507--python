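"""Relative-stability population classification against the native reference.

Each frame of a variant simulation is reduced to two coordinates relative
to the wild-type 300 K reference window:

    Relative SASA       = frame total SASA − mean reference total SASA
    Relative ΔG_protein = frame ΔG_protein − mean reference ΔG_protein

Conformers in the (+, +) quadrant (larger exposure AND higher free energy
than the native ensemble) are classified less stable; (−, −) conformers
are more stable; the two mixed quadrants are kept separate.  Boundary
values (exact zero on either axis) are assigned away from the less-stable
quadrant; under continuous inputs they have measure zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IntegrityError, ValidationError

QUADRANTS = ("less_stable", "more_stable", "mixed_sasa_up", "mixed_sasa_down")


@dataclass(frozen=True)
class PopulationPoint:
    frame_index: int
    rel_sasa: float
    rel_dg: float
    quadrant: str


@dataclass
class PopulationSummary:
    points: list[PopulationPoint]
    counts: dict
    percent_less_stable: float
    percent_by_quadrant: dict

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": [p.frame_index for p in self.points],
                "rel_sasa": [p.rel_sasa for p in self.points],
                "rel_dg": [p.rel_dg for p in self.points],
                "quadrant": [p.quadrant for p in self.points],
            }
        )


def relative_series(
    variant_series: np.ndarray, reference_series: np.ndarray
) -> tuple[np.ndarray, float]:
    """Variant values minus the scalar reference mean; returns (series, ref_mean)."""
    reference_series = np.asarray(reference_series, dtype=float)
    if reference_series.size == 0:
        raise ValidationError("reference series is empty")
    ref_mean = float(reference_series.mean())
    return np.asarray(variant_series, dtype=float) - ref_mean, ref_mean


def classify_point(rel_sasa: float, rel_dg: float) -> str:
    if rel_sasa > 0 and rel_dg > 0:
        return "less_stable"
    if rel_sasa > 0:
        return "mixed_sasa_up"
    if rel_dg > 0:
        return "mixed_sasa_down"
    return "more_stable"


def classify_population(
    rel_sasa: np.ndarray,
    rel_dg: np.ndarray,
    frame_index: list[int] | None = None,
) -> PopulationSummary:
    """Quadrant labels and percent-less-stable summary for a variant ensemble."""
    rel_sasa = np.asarray(rel_sasa, dtype=float)
    rel_dg = np.asarray(rel_dg, dtype=float)
    if rel_sasa.shape != rel_dg.shape:
        raise IntegrityError("rel_sasa and rel_dg lengths differ")
    if rel_sasa.size == 0:
        raise ValidationError("population classification needs at least one point")
    if frame_index is None:
        frame_index = list(range(len(rel_sasa)))
    elif len(frame_index) != len(rel_sasa):
        raise IntegrityError("frame_index does not align with the relative series")
    points = [
        PopulationPoint(fi, float(s), float(g), classify_point(float(s), float(g)))
        for fi, s, g in zip(frame_index, rel_sasa, rel_dg)
    ]
    counts = {q: 0 for q in QUADRANTS}
    for p in points:
        counts[p.quadrant] += 1
    total = len(points)
    percent = {q: 100.0 * c / total for q, c in counts.items()}
    return PopulationSummary(
        points=points,
        counts=counts,
        percent_less_stable=percent["less_stable"],
        percent_by_quadrant=percent,
    )
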