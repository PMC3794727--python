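"""End-to-end study orchestration from one declarative config.

Stages: build (model + contact tables) -> simulate (replica-exchange DMD) ->
thermo (Cv, Tm, WHAM free-energy profile and basins) -> analyze (fixed-T
ensemble, clustering, populations, SASA, contact ratios) -> pca (essential
dynamics).  Each stage persists tab-separated tables into the output
directory; a manifest records versions, parameters and seeds so a run can be
reproduced exactly.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    build_ensemble,
    cluster_kmeans,
    contact_ratio_map,
    macrostate_populations,
    peptide_omega,
    radius_of_gyration,
    sasa_ratio_profile,
    superpose_rmsd,
)
from .engine import EngineParams, build_pair_tables, initialize_state, run_dmd
from .essential import covariance_matrix, principal_modes, rmsf_along_modes
from .replica import TemperatureLadder, run_replica_exchange
from .structure import SegmentMap, StructureModel, segment_contact_counts, write_contacts_tsv
from .synthetic import make_minifold
from .thermo import find_basins_1d, free_energy_landscape, heat_capacity, melting_temperature, wham_fit, wham_frame_weights

__all__ = ["load_config", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "structure": {"fixture": "minifold", "n_beads": 12, "chain": "A"},
    "model": {"alpha": 0.80, "lam": 1.6, "b0": 0.9, "b1": 1.1},
    "simulation": {
        # ladder spanning the minifold's folding transition (Cv peak ~ 1.43)
        "temperatures": [1.10, 1.25, 1.40, 1.55, 1.70, 1.85],
        "exchange_interval": 10_000,
        "n_sweeps": 80,
        "thermostat_rate": 0.2,
    },
    "analysis": {
        "cluster_radius": 3.0,
        "stride": 1,
        "fixed_t_events": 600_000,
        "sample_every": 5_000,
        "omega_bond": None,
    },
    "pca": {"n_modes": 5},
    "seed": 1,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (cfg or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _build_model(cfg: dict) -> StructureModel:
    scfg = cfg["structure"]
    alpha = cfg["model"]["alpha"]
    lam = cfg["model"]["lam"]
    if scfg.get("fixture") == "minifold":
        return make_minifold(scfg.get("n_beads", 10), seed=cfg["seed"]).model
    path = Path(scfg["path"])
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    return StructureModel.from_pdb(path.read_text(), chain=scfg.get("chain"),
                                   alpha=alpha, lam=lam)


def _default_segments(model: StructureModel) -> SegmentMap:
    """Fallback decomposition into N-terminal / core / C-terminal thirds."""
    res = sorted({a.residue_index for a in model.atoms})
    third = max(len(res) // 3, 1)
    return SegmentMap({
        "Nterm": (res[0], res[third - 1]),
        "core": (res[third], res[min(2 * third, len(res)) - 1]),
        "Cterm": (res[min(2 * third, len(res) - 1)] + 1, res[-1]),
    })


def stage_build(cfg: dict, outdir: Path) -> StructureModel:
    model = _build_model(cfg)
    write_contacts_tsv(model.contacts, str(outdir / "contacts.tsv"))
    seg_cfg = cfg.get("segments")
    segments = SegmentMap({k: tuple(v) for k, v in seg_cfg.items()}) if seg_cfg \
        else _default_segments(model)
    counts = segment_contact_counts(model.contacts, model.atoms, segments)
    pd.DataFrame(
        [{"segment": k, **v} for k, v in counts.items()]
    ).to_csv(outdir / "segment_counts.tsv", sep="\t", index=False)
    return model


def stage_simulate(cfg: dict, outdir: Path, model: StructureModel):
    sim = cfg["simulation"]
    tables = build_pair_tables(model.atoms, model.bonds, model.contacts,
                               b0=cfg["model"]["b0"], b1=cfg["model"]["b1"])
    ladder = TemperatureLadder(sim["temperatures"], sim["exchange_interval"])
    params = EngineParams(thermostat_rate=sim["thermostat_rate"],
                          alpha=cfg["model"]["alpha"], lam=cfg["model"]["lam"],
                          b0=cfg["model"]["b0"], b1=cfg["model"]["b1"])
    result = run_replica_exchange(tables, model.positions, ladder,
                                  n_sweeps=sim["n_sweeps"], params=params,
                                  seed=cfg["seed"] + 1)
    rows = [
        {"temperature": T, "energy": e}
        for T, energies in sorted(result.energy_by_temperature.items())
        for e in energies
    ]
    pd.DataFrame(rows).to_csv(outdir / "energy_samples.tsv", sep="\t", index=False,
                              float_format="%.8g")
    pd.DataFrame(result.swap_record,
                 columns=["sweep", "slot_i", "slot_j", "accepted"]
                 ).to_csv(outdir / "swap_record.tsv", sep="\t", index=False)
    return result, tables


def stage_thermo(cfg: dict, outdir: Path):
    df = pd.read_csv(outdir / "energy_samples.tsv", sep="\t")
    samples = {T: g["energy"].to_numpy() for T, g in df.groupby("temperature")}
    cv_direct = {T: heat_capacity(E, T) for T, E in samples.items() if E.size > 1}
    dos = wham_fit(samples, bin_width=cfg.get("wham_bin_width", 2.0))
    temps = np.array(sorted(samples))
    grid = np.linspace(temps.min(), temps.max(), 101)
    cv_grid = np.array([dos.reweight(T)[1] for T in grid])
    tm = melting_temperature(grid, cv_grid)
    pd.DataFrame({"temperature": grid, "cv_wham": cv_grid}).to_csv(
        outdir / "cv_curve.tsv", sep="\t", index=False, float_format="%.8g")
    pd.DataFrame({"temperature": list(cv_direct), "cv_fluct": list(cv_direct.values())}
                 ).to_csv(outdir / "cv_direct.tsv", sep="\t", index=False,
                          float_format="%.8g")
    # free-energy profile over E at Tm, WHAM-reweighted
    E_all = df["energy"].to_numpy()
    T_all = df["temperature"].to_numpy()
    w = wham_frame_weights(E_all, T_all, dos, tm)
    landscape = free_energy_landscape(E_all, tm, bins=dos.bin_edges,
                                      coordinates=("E",), weights=w)
    basins = find_basins_1d(landscape, min_barrier=cfg.get("min_basin_barrier", 1.0))
    centers = 0.5 * (landscape.bin_edges[0][:-1] + landscape.bin_edges[0][1:])
    pd.DataFrame({"E": centers, "F": landscape.F}).to_csv(
        outdir / "fe_profile.tsv", sep="\t", index=False, float_format="%.8g")
    (outdir / "thermo.json").write_text(json.dumps({
        "melting_temperature": tm,
        "basins": {k: list(v) for k, v in basins.windows.items()},
        "wham_converged": bool(dos.converged),
        "wham_iterations": int(dos.n_iter),
    }, indent=2))
    return tm, basins, dos


def stage_analyze(cfg: dict, outdir: Path, model: StructureModel, tables, tm: float,
                  basins):
    ana = cfg["analysis"]
    params = EngineParams(temperature=tm,
                          thermostat_rate=cfg["simulation"]["thermostat_rate"],
                          seed=cfg["seed"] + 2,
                          alpha=cfg["model"]["alpha"], lam=cfg["model"]["lam"])
    state = initialize_state(tables, model.positions, tm, seed=cfg["seed"] + 3)
    traj = run_dmd(state, ana["fixed_t_events"], params, tables,
                   sample_every=ana["sample_every"],
                   native_positions=model.positions, collect_frames=True)
    from .engine import write_trajectory_tsv
    write_trajectory_tsv(traj, str(outdir / "trajectory.tsv"))
    # equilibration rule: first sample at/below the native-basin upper edge
    native_window = min(basins.windows.values(), key=lambda w: w[0])
    ensemble = build_ensemble([traj], stride=ana["stride"],
                              folded_energy_threshold=native_window[1],
                              temperature=tm)
    np.savez(outdir / "ensemble.npz", frames=ensemble.frames,
             energy=np.array(traj.energy), rg=np.array(traj.rg),
             rmsd=np.array(traj.rmsd))
    clusters = cluster_kmeans(ensemble, ana["cluster_radius"], seed=cfg["seed"] + 4)
    pd.DataFrame({"frame": np.arange(len(ensemble)), "cluster": clusters.labels}
                 ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    pops = macrostate_populations(np.array(traj.energy), basins)
    # cross-check: populations via cluster membership, each cluster assigned
    # to the basin holding its representative's energy
    from .engine import total_potential_energy
    frame_E = np.array([total_potential_energy(fr, model.contacts)
                        for fr in ensemble.frames])
    cluster_pops = {k: 0.0 for k in basins.windows}
    for c in range(clusters.k):
        rep_E = frame_E[clusters.representatives[c]]
        frac = float(np.mean(clusters.labels == c))
        for name, (lo, hi) in basins.windows.items():
            if lo <= rep_E < hi:
                cluster_pops[name] += frac
                break
    pd.DataFrame([
        {"basin": k, "population": pops[k], "cluster_population": cluster_pops[k]}
        for k in pops
    ]).to_csv(outdir / "populations.tsv", sep="\t", index=False,
              float_format="%.8g")
    stats = {
        "mean_energy": float(np.mean(traj.energy)),
        "mean_rg": float(np.mean(traj.rg)),
        "mean_rmsd": float(np.mean(traj.rmsd)),
        "native_energy": model.native_energy,
        "n_frames": len(ensemble),
        "n_clusters": clusters.k,
    }
    if ana.get("omega_bond"):
        ri, rj = ana["omega_bond"]
        stats["omega_deg"] = [
            peptide_omega(model.atoms, fr, ri, rj) for fr in ensemble.frames
        ]
    sasa = sasa_ratio_profile(ensemble, model.positions, model.atoms)
    pd.DataFrame([{"residue": r, **v} for r, v in sasa.items()]
                 ).to_csv(outdir / "sasa_ratio.tsv", sep="\t", index=False,
                          float_format="%.8g")
    cmap = contact_ratio_map(ensemble, model.contacts, model.atoms)
    pd.DataFrame([{"res_i": i, "res_j": j, "ratio": v} for (i, j), v in cmap.items()]
                 ).to_csv(outdir / "contact_ratio.tsv", sep="\t", index=False,
                          float_format="%.8g")
    (outdir / "intermediate_stats.json").write_text(json.dumps(stats, indent=2))
    return ensemble, clusters, pops, cluster_pops


def stage_pca(cfg: dict, outdir: Path, model: StructureModel, ensemble):
    ca = model.ca_indices()
    cov = covariance_matrix(ensemble, model.positions, selection=ca)
    k = min(cfg["pca"]["n_modes"], cov.eigenvalues.size)
    evals, _, fraction = principal_modes(cov, k)
    rmsf = rmsf_along_modes(cov, k)
    pd.DataFrame({"mode": np.arange(1, cov.eigenvalues.size + 1),
                  "eigenvalue": cov.eigenvalues}
                 ).to_csv(outdir / "pca_eigenvalues.tsv", sep="\t", index=False,
                          float_format="%.8g")
    pd.DataFrame({"ca_atom": ca, "rmsf": rmsf}).to_csv(
        outdir / "rmsf.tsv", sep="\t", index=False, float_format="%.8g")
    np.savetxt(outdir / "covariance.tsv", cov.matrix, delimiter="\t", fmt="%.6g")
    return {"total_msf": cov.total_msf, "top_k": k, "msf_fraction_top_k": fraction}


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Run every stage in order; returns the report bundle as a dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    model = stage_build(cfg, outdir)
    timings["build"] = time.perf_counter() - t0
    report["n_contacts"] = len(model.contacts)
    report["native_energy"] = model.native_energy

    t0 = time.perf_counter()
    re_result, tables = stage_simulate(cfg, outdir, model)
    timings["simulate"] = time.perf_counter() - t0
    report["swap_acceptance"] = re_result.acceptance_rate

    t0 = time.perf_counter()
    tm, basins, dos = stage_thermo(cfg, outdir)
    timings["thermo"] = time.perf_counter() - t0
    report["melting_temperature"] = tm
    report["basins"] = {k: list(v) for k, v in basins.windows.items()}

    t0 = time.perf_counter()
    ensemble, clusters, pops, cluster_pops = stage_analyze(cfg, outdir, model, tables, tm, basins)
    timings["analyze"] = time.perf_counter() - t0
    report["populations"] = pops
    report["cluster_populations"] = cluster_pops
    report["n_clusters"] = clusters.k

    t0 = time.perf_counter()
    report["pca"] = stage_pca(cfg, outdir, model, ensemble)
    timings["pca"] = time.perf_counter() - t0

    manifest = {
        "gofold_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
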