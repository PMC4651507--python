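"""End-to-end orchestration: generate or ingest → analyze → report.

A run processes one or more datasets (variant × temperature).  For each
dataset the pipeline produces delimited tables for every analysis stage
(binding energies, interface H-bond counts, optimal-estimate profiles,
dihedral-PCA scores and landscape, side-chain SASA, stability population
vs the reference dataset) plus a JSON manifest listing every output file
with its SHA-256 checksum, the seed, a config echo and collected warnings.
Identical config + seed yields byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, TsbindError
from .trajectory_io import read_energy_table, write_energy_table, write_multimodel_pdb
from .binding_energy import binding_energy_series, protein_free_energy_series
from .hbond import HBondCriteria, InterfaceSpec, interface_hbond_series, INTERFACE_RESIDUES
from .optimal_estimate import estimate_profile
from .dihedral_pca import circular_pca, stability_landscape
from .sasa import RadiiTable, sidechain_sasa_series, total_sasa_series, sasa_significance
from .stability_population import classify_population, relative_series
from . import synthetic

logger = logging.getLogger(__name__)

ALL_STAGES = ("binding", "hbond", "estimate", "dpca", "sasa", "population")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    seed: int = 0
    outdir: str = "tsbind_out"
    datasets: list = field(default_factory=lambda: [
        {"variant": "WT", "condition": "T300"},
        {"variant": "WT", "condition": "T310"},
    ])
    reference: str = "WT_T300"
    n_frames: int = 600
    structure_frames: int = 60
    window_start: int = 0
    window_stop: int | None = None          # exclusive; None = end
    max_da_distance: float = 3.0
    min_dha_angle: float = 135.0
    interface_residues: list = field(default_factory=lambda: sorted(INTERFACE_RESIDUES))
    partner_chains: list = field(default_factory=lambda: ["B"])
    min_samples: int = 2
    sasa_points: int = 960
    n_components: int = 2
    include_entropy: bool = False
    stages: list = field(default_factory=lambda: list(ALL_STAGES))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    outdir: Path
    tables: dict            # name -> path
    checksums: dict         # relative path -> sha256
    warnings: list
    seed: int


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _dataset_label(ds: dict) -> str:
    return f"{ds['variant']}_{ds['condition']}"


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all configured stages; write tables + manifest under outdir."""
    outdir = Path(config.outdir)
    tables_dir = outdir / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)
    run_warnings: list[str] = []
    tables: dict[str, Path] = {}

    bad_stages = set(config.stages) - set(ALL_STAGES)
    if bad_stages:
        raise ConfigurationError(f"unknown stage(s): {sorted(bad_stages)}")
    labels = [_dataset_label(ds) for ds in config.datasets]
    if config.reference not in labels:
        raise ConfigurationError(
            f"reference {config.reference!r} is not among datasets {labels}"
        )

    criteria = HBondCriteria(config.max_da_distance, config.min_dha_angle)
    spec = InterfaceSpec(frozenset(config.interface_residues), frozenset(config.partner_chains))
    radii = RadiiTable()

    def emit(name: str, df: pd.DataFrame) -> None:
        path = tables_dir / f"{name}.csv"
        _write(df, path)
        tables[name] = path

    try:
        per_dataset: dict[str, dict] = {}
        for idx, ds in enumerate(config.datasets):
            label = _dataset_label(ds)
            ds_seed = np.random.SeedSequence(entropy=config.seed, spawn_key=(idx,))
            gen_seed = int(ds_seed.generate_state(1)[0] % (2**31))
            cfg = synthetic.preset(ds["variant"], ds["condition"], seed=gen_seed,
                                   n_frames=config.n_frames)
            records, truth = synthetic.generate_energy_tables(cfg)
            table_path = tables_dir / f"energies_{label}.csv"
            write_energy_table(records, table_path)
            tables[f"energies_{label}"] = table_path
            records = read_energy_table(table_path)  # exercise the reader path

            series, skipped = binding_energy_series(records, config.include_entropy)
            if skipped:
                run_warnings.append(f"{label}: skipped {len(skipped)} incomplete frame(s)")
            w0, w1 = config.window_start, config.window_stop
            series = [s for s in series if s.frame_index >= w0
                      and (w1 is None or s.frame_index < w1)]
            if not series:
                raise ConfigurationError(
                    f"window [{w0}, {w1}) selects zero frames for {label}"
                )
            k_cfg = synthetic.preset(ds["variant"], ds["condition"], seed=gen_seed,
                                     n_frames=config.structure_frames)
            traj = synthetic.generate_interface_frames(k_cfg)
            pdb_path = tables_dir / f"frames_{label}.pdb"
            write_multimodel_pdb(traj, pdb_path)
            tables[f"frames_{label}"] = pdb_path

            receptor = [r for r in records if r.species == "receptor"]
            dg_series = protein_free_energy_series(receptor, config.include_entropy)
            per_dataset[label] = dict(cfg=cfg, truth=truth, series=series,
                                      traj=traj, dg_series=dg_series)

            if "binding" in config.stages:
                emit(f"binding_{label}", pd.DataFrame({
                    "frame_index": [s.frame_index for s in series],
                    "dg_complex": [s.dg_complex for s in series],
                    "dg_receptor": [s.dg_receptor for s in series],
                    "dg_ligand": [s.dg_ligand for s in series],
                    "ddg_bind": [s.ddg_bind for s in series],
                }))

            if "hbond" in config.stages or "estimate" in config.stages:
                frames_idx, ks = interface_hbond_series(traj, spec, criteria)
                per_dataset[label]["k_structural"] = (frames_idx, ks)
                if "hbond" in config.stages:
                    emit(f"hbond_counts_{label}",
                         pd.DataFrame({"frame_index": frames_idx, "k": ks}))

            if "estimate" in config.stages:
                # statistical profile uses the planted per-frame k aligned with
                # the energy frames (structural ensembles are kept smaller)
                frames_in = [s.frame_index for s in series]
                k_energy = truth.k[frames_in]
                profile = estimate_profile([s.ddg_bind for s in series], k_energy,
                                           min_samples=config.min_samples,
                                           run_label=label)
                per_dataset[label]["profile"] = profile
                n_unreliable = sum(e.unreliable for e in profile)
                if n_unreliable:
                    run_warnings.append(f"{label}: {n_unreliable} unreliable bin(s)")
                emit(f"estimate_{label}", pd.DataFrame({
                    "k": [e.k for e in profile],
                    "estimate": [e.estimate for e in profile],
                    "uncertainty": [e.uncertainty for e in profile],
                    "n": [e.n for e in profile],
                    "unreliable": [e.unreliable for e in profile],
                    "run_label": [e.run_label for e in profile],
                }))

            if "dpca" in config.stages:
                dser, _assign = synthetic.generate_dihedral_series(cfg)
                pca = circular_pca(dser, config.n_components)
                emit(f"dpca_scores_{label}", pd.DataFrame(
                    {"frame_index": np.arange(dser.n_frames)}
                    | {f"PC{j+1}": pca.component_scores[:, j]
                       for j in range(pca.component_scores.shape[1])}
                ))
                emit(f"dpca_variance_{label}", pd.DataFrame({
                    "component": [f"PC{j+1}" for j in range(len(pca.variance_explained))],
                    "variance_explained": pca.variance_explained,
                    "mode_angle_deg": pca.mode_angles_deg,
                }))
                pc2 = pca.component_scores[:, 1] if pca.component_scores.shape[1] > 1 \
                    else pca.component_scores[:, 0]
                land = stability_landscape(pc2[[s.frame_index for s in series]],
                                           _subset_series(per_dataset[label]["dg_series"],
                                                          [s.frame_index for s in series]))
                hist = _landscape_long(land)
                emit(f"dpca_landscape_{label}", hist)

            if "sasa" in config.stages or "population" in config.stages:
                sc_table = sidechain_sasa_series(traj, set(config.interface_residues),
                                                 radii, config.sasa_points, chain="A")
                per_dataset[label]["sidechain"] = sc_table
                per_dataset[label]["total_sasa"] = total_sasa_series(
                    traj, radii, config.sasa_points)
                if "sasa" in config.stages:
                    emit(f"sasa_sidechain_{label}", sc_table)

        ref = per_dataset[config.reference]

        if "sasa" in config.stages:
            ref_means = ref["sidechain"].groupby("res_id")["sidechain_sasa"].mean()
            for label, data in per_dataset.items():
                rows = []
                for res_id, grp in data["sidechain"].groupby("res_id"):
                    mean, sd, sig = sasa_significance(grp["sidechain_sasa"].to_numpy(),
                                                      float(ref_means[res_id]))
                    rows.append({"res_id": res_id, "mean": mean, "sd": sd,
                                 "reference_mean": float(ref_means[res_id]),
                                 "significant_vs_reference": sig})
                emit(f"sasa_summary_{label}", pd.DataFrame(rows))

        if "population" in config.stages:
            n_struct = len(ref["total_sasa"])
            summary_rows = []
            for label, data in per_dataset.items():
                rel_sasa, _ = relative_series(data["total_sasa"], ref["total_sasa"])
                dg = data["dg_series"].dg_protein[:n_struct]
                rel_dg, _ = relative_series(dg, ref["dg_series"].dg_protein[:n_struct])
                summary = classify_population(rel_sasa, rel_dg)
                emit(f"population_{label}", summary.as_frame())
                ds = config.datasets[[_dataset_label(d) for d in config.datasets].index(label)]
                summary_rows.append({"variant": ds["variant"], "temperature": ds["condition"],
                                     "percent_less_stable": summary.percent_less_stable})
            emit("population_summary", pd.DataFrame(summary_rows))

        if "estimate" in config.stages and len(per_dataset) >= 2:
            rows = []
            ref_prof = {e.k: e for e in ref.get("profile", [])}
            for label, data in per_dataset.items():
                if label == config.reference:
                    continue
                for e in data.get("profile", []):
                    if e.k in ref_prof:
                        rows.append({"k": e.k, "dataset": label,
                                     "reference": config.reference,
                                     "estimate_diff": e.estimate - ref_prof[e.k].estimate})
            if rows:
                emit("estimate_difference", pd.DataFrame(rows))

        checksums = {str(p.relative_to(outdir)): _sha256(p) for p in sorted(tables.values())}
        manifest = {
            "tsbind_version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "warnings": run_warnings,
            "files": checksums,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return RunReport(outdir=outdir, tables=tables, checksums=checksums,
                         warnings=run_warnings, seed=config.seed)
    except TsbindError:
        shutil.rmtree(tables_dir, ignore_errors=True)  # no partial outputs
        raise


def _subset_series(dg_series, frame_indices):
    from .binding_energy import ProteinStabilitySeries

    index = {f: i for i, f in enumerate(dg_series.frame_index)}
    rows = [index[f] for f in frame_indices]
    return ProteinStabilitySeries(frame_index=list(frame_indices),
                                  dg_protein=dg_series.dg_protein[rows])


def _landscape_long(land) -> pd.DataFrame:
    rows = []
    counts = land.counts
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            c = counts[i, j]
            if c > 0:
                rows.append({
                    "pc2_bin": 0.5 * (land.pc2_edges[i] + land.pc2_edges[i + 1]),
                    "dg_bin": 0.5 * (land.dg_edges[j] + land.dg_edges[j + 1]),
                    "count": int(c),
                })
    return pd.DataFrame(rows)
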