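"""Maximum-likelihood optimal estimate of ΔΔG_bind per interface H-bond count.

Frames are partitioned by their interface hydrogen-bond count k.  Within a
bin the uncertainty of each sample is taken as the bin's own spread,

    δ²x_k = ⟨x_n²⟩ − ⟨x_n⟩²        (population variance),

and the inverse-variance (maximum-likelihood) weighted estimate

    X̂_k = Σ_n (x_n / δ²x_k) / Σ_n (1 / δ²x_k)

reduces, with a bin-constant weight, to the arithmetic bin mean.  The
weighting becomes informative when combining estimates across independent
runs or blocks, where the per-run δ² differ.

A profile {(k, X̂_k)} summarises a whole simulation; comparing profiles of
two conditions (e.g. 300 K vs 310 K, mutant vs wild type) is the headline
binding-affinity comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import IntegrityError, ValidationError
from .binding_energy import FrameBindingEnergy


@dataclass
class HBondBin:
    """All ΔΔG_bind samples (kcal/mol) of frames sharing one k."""

    k: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class BinnedEstimate:
    """Optimal estimate X̂_k with uncertainty δ²x_k and sample count."""

    k: int
    estimate: float
    uncertainty: float  # δ²x_k, (kcal/mol)²
    n: int
    unreliable: bool = False
    run_label: str | None = None


def bin_by_hbond_count(
    ddg_series: Sequence[FrameBindingEnergy] | Sequence[float],
    k_series: Sequence[int],
    k_frames: Sequence[int] | None = None,
) -> list[HBondBin]:
    """Partition frames by interface H-bond count k (bins sorted ascending).

    ``ddg_series`` may hold FrameBindingEnergy objects or raw ΔΔG values
    positionally aligned with ``k_series``.  When ``k_frames`` is given the
    frame indices of both series must match exactly.
    """
    if len(ddg_series) != len(k_series):
        raise IntegrityError(
            f"ddg_series ({len(ddg_series)}) and k_series ({len(k_series)}) lengths differ"
        )
    if len(ddg_series) and isinstance(ddg_series[0], FrameBindingEnergy):
        ddg_frames = [fbe.frame_index for fbe in ddg_series]
        values = np.asarray([fbe.ddg_bind for fbe in ddg_series], dtype=float)
        if k_frames is not None and list(k_frames) != ddg_frames:
            raise IntegrityError("k_series frame indices do not align with ddg_series")
    else:
        values = np.asarray(ddg_series, dtype=float)
    ks = np.asarray(k_series, dtype=int)
    if len(ks) and ks.min() < 0:
        raise ValidationError("negative H-bond count")
    return [HBondBin(k=int(k), samples=values[ks == k]) for k in np.unique(ks)]


def optimal_bin_estimate(
    hbin: HBondBin, min_samples: int = 2, variance_ddof: int = 0
) -> BinnedEstimate:
    """X̂_k and δ²x_k for one bin.

    ``variance_ddof=0`` is the population form; 1 gives the sample variance
    for sensitivity checks.  A zero-variance bin returns the common value
    with zero uncertainty.  Bins with fewer than ``min_samples`` samples
    are flagged unreliable (their spread estimate is meaningless).
    """
    if hbin.n == 0:
        raise ValidationError(f"empty bin k={hbin.k}")
    x = hbin.samples
    var = float(x.var(ddof=variance_ddof)) if hbin.n > variance_ddof else 0.0
    # bin-constant weights cancel: the ML estimate is the bin mean
    return BinnedEstimate(
        k=hbin.k,
        estimate=float(x.mean()),
        uncertainty=var,
        n=hbin.n,
        unreliable=hbin.n < min_samples,
    )


def combine_runs(
    estimates: Sequence[BinnedEstimate], mode: str = "inverse_variance"
) -> BinnedEstimate:
    """Combine per-run estimates of the same k into one.

    mode="inverse_variance": X̂ = Σ(X̂_r/δ²_r)/Σ(1/δ²_r), combined
    δ² = 1/Σ(1/δ²_r) — the ML combination treating each run's δ² as its
    estimate's uncertainty.  mode="pooled": exact moment pooling using
    (X̂_r, δ²_r, n_r); identical to computing the estimate on the
    concatenated samples of all runs.
    """
    if not estimates:
        raise ValidationError("no estimates to combine")
    k = estimates[0].k
    if any(e.k != k for e in estimates):
        raise IntegrityError(f"mixed k values in combine_runs: {sorted({e.k for e in estimates})}")
    if len(estimates) == 1:
        return estimates[0]
    means = np.array([e.estimate for e in estimates])
    variances = np.array([e.uncertainty for e in estimates])
    ns = np.array([e.n for e in estimates])
    n_total = int(ns.sum())
    if mode == "inverse_variance":
        if np.any(variances == 0.0):
            if np.allclose(means, means[0]):
                return replace(estimates[0], n=n_total, unreliable=False, run_label=None)
            raise IntegrityError(
                "zero-uncertainty run with a conflicting estimate cannot be combined"
            )
        w = 1.0 / variances
        est = float((means * w).sum() / w.sum())
        var = float(1.0 / w.sum())
    elif mode == "pooled":
        est = float((ns * means).sum() / n_total)
        second_moment = float((ns * (variances + means**2)).sum() / n_total)
        var = max(second_moment - est**2, 0.0)
    else:
        raise ValidationError(f"unknown combine mode {mode!r}")
    return BinnedEstimate(k=k, estimate=est, uncertainty=var, n=n_total)


def estimate_profile(
    ddg_series: Sequence[FrameBindingEnergy] | Sequence[float],
    k_series: Sequence[int],
    min_samples: int = 2,
    variance_ddof: int = 0,
    run_label: str | None = None,
) -> list[BinnedEstimate]:
    """One BinnedEstimate per observed k: the X̂_k-vs-k binding profile."""
    bins = bin_by_hbond_count(ddg_series, k_series)
    return [
        replace(
            optimal_bin_estimate(b, min_samples=min_samples, variance_ddof=variance_ddof),
            run_label=run_label,
        )
        for b in bins
    ]


def profile_slope(
    profile: Sequence[BinnedEstimate], include_unreliable: bool = False
) -> float:
    """Least-squares slope of X̂_k against k, weighted by bin sample count.

    Used for parameter-recovery checks against a known linear coupling
    E[ΔΔG|k] = β0 + β1·k.
    """
    pts = [e for e in profile if include_unreliable or not e.unreliable]
    if len(pts) < 2:
        raise ValidationError("need at least two (reliable) bins for a slope")
    k = np.array([e.k for e in pts], dtype=float)
    y = np.array([e.estimate for e in pts])
    w = np.array([e.n for e in pts], dtype=float)
    kbar = (w * k).sum() / w.sum()
    ybar = (w * y).sum() / w.sum()
    denom = (w * (k - kbar) ** 2).sum()
    if denom == 0.0:
        raise ValidationError("all bins share one k; slope undefined")
    return float((w * (k - kbar) * (y - ybar)).sum() / denom)
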