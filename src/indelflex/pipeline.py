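"""End-to-end pipeline driver over synthetic or provided inputs.

Stages run in order variants → conservation → trajectories → compare → PCA →
scan; every stage writes plain TSV/JSON under the output directory and the
run finishes with a manifest (seeds, config hash, aggregate simulated time).
Identical config + seed gives byte-identical numeric outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .conservation import conservation_profile
from .indel_scan import additive_hydropathy_scorer, classify, run_scan
from .synthetic_data import (AlleleSimSpec, MsaSimSpec, TrajectorySpec,
                             generate_alleles, generate_msa,
                             generate_trajectories, random_cds)
from .traj_compare import compare_systems, loop_flexibility_test
from .traj_core import (aggregate_rmsf, rg_series, rmsd_series, sem_of_max_dif,
                        trim_equilibration)
from .traj_pca import flag_outlier_replicates, pooled_pca
from .variants import allele_frequency, call_allele_set


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, ensemble=None, alleles=None,
                 msa=None, scan_sequence=None) -> dict:
    """Execute the configured stages and return the manifest dict.

    Any input left as None is generated synthetically from the demo sizing in
    the config (seeded), so a bare config gives a complete demonstration run.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config_hash": config.digest(), "stages": []}

    if config.run_variants:
        if alleles is None:
            cds = random_cds(200, seed=config.seed,
                             protein_constraints={153: "N", 155: "V"})
            spec = AlleleSimSpec(reference_cds=cds,
                                 populations=[("popA", 16, 0.5), ("popB", 20, 0.1),
                                              ("popC", 10, 0.0)],
                                 deletion=(153, 155), seed=config.seed)
            alleles = generate_alleles(spec)
        calls = call_allele_set(alleles)
        freq = allele_frequency(alleles, calls)
        freq.per_population.to_csv(outdir / "allele_frequencies.tsv", sep="\t",
                                   index=False)
        freq.per_indel.to_csv(outdir / "indel_summary.tsv", sep="\t", index=False)
        unique_calls = sorted({(c.hgvs, c.nt_start, c.nt_end, c.aa_start, c.aa_end,
                                c.in_frame, c.nt_length)
                               for cl in calls.values() for c in cl})
        with open(outdir / "indel_calls.tsv", "w") as fh:
            fh.write("# coordinates are 1-based inclusive\n")
            fh.write("hgvs\tnt_start\tnt_end\taa_start\taa_end\tin_frame\tnt_length\n")
            for row in unique_calls:
                fh.write("\t".join(str(x) for x in row) + "\n")
        manifest["stages"].append("variants")

    if config.run_conservation:
        if msa is None:
            rng = np.random.default_rng(config.seed)
            targets = rng.uniform(0.0, 1.0, size=60)
            msa = generate_msa(MsaSimSpec(n_sequences=80, length=60,
                                          conservation_profile=targets,
                                          gap_rate=0.05, seed=config.seed))
        profile = conservation_profile(msa, tau=config.conservation_tau)
        with open(outdir / "conservation.tsv", "w") as fh:
            fh.write("# positions are 1-based in the reference sequence\n")
            fh.write("position\tscore\tgap_fraction\tconserved\n")
            for pos, s, g in zip(profile.positions, profile.scores,
                                 profile.gap_fractions):
                fh.write(f"{pos}\t{s:.6f}\t{g:.6f}\t"
                         f"{int(s >= config.conservation_tau)}\n")
        _write_json(outdir / "conservation_summary.json", {
            "dops": profile.dops,
            "high_diversity": profile.dops > config.dops_diversity_cut,
            "n_conserved": int(len(profile.conserved_positions)),
            "tau": config.conservation_tau})
        manifest["stages"].append("conservation")

    profiles = None
    if config.run_trajectories or config.run_compare or config.run_pca:
        if ensemble is None:
            n_res = config.demo_n_residues
            sigma = np.full(n_res, 0.6)
            all_ids = np.arange(1, n_res + 1)
            deleted = np.asarray(config.demo_deleted_residues, dtype=int)
            del_ids = all_ids[~np.isin(all_ids, deleted)]
            spec = TrajectorySpec(
                n_residues=n_res, duration_ns=config.demo_n_frames / 10.0,
                frame_interval_ps=100.0, n_replicates=config.demo_n_replicates,
                amplitude_profile={s: sigma for s in config.demo_systems},
                residue_ids_per_system={s: del_ids for s in config.demo_systems
                                        if s.startswith("del")},
                seed=config.seed)
            ensemble = generate_trajectories(spec)
        manifest["total_simulated_time_us"] = ensemble.total_simulated_time_us()
        manifest["per_system_time_us"] = ensemble.per_system_time_us()

    if config.run_trajectories:
        trimmed = {}
        profiles = {}
        rmsd_means = {}
        summary: dict = {"per_system": {}}
        for system, reps in ensemble.systems.items():
            kept = []
            for rep in reps:
                if rep.duration_ns > config.burn_in_ns:
                    rep = trim_equilibration(rep, config.burn_in_ns)
                kept.append(rep)
            trimmed[system] = kept
            profiles[system] = aggregate_rmsf(kept)
            series = [rmsd_series(r) for r in kept]
            rg = [rg_series(r) for r in kept]
            rmsd_means[system] = np.mean([s.values for s in series], axis=0)
            per_rep_rmsd = [s.mean() for s in series]
            summary["per_system"][system] = {
                "rmsd_mean": float(np.mean(per_rep_rmsd)),
                "rmsd_sem": float(np.std(per_rep_rmsd, ddof=1)
                                  / np.sqrt(len(per_rep_rmsd)))
                if len(per_rep_rmsd) > 1 else 0.0,
                "rg_mean": float(np.mean([g.mean() for g in rg])),
                "rmsf_mean": float(profiles[system].mean.mean()),
            }
        shared = ensemble.shared_residue_ids()
        rmsf_means = {s: profiles[s].select(shared).mean for s in profiles}
        if len(profiles) >= 2:
            loc, sem = sem_of_max_dif(rmsf_means, axis=shared)
            summary["rmsf_sem_of_max_dif"] = {"residue": int(loc), "sem": sem}
            loc, sem = sem_of_max_dif(rmsd_means)
            summary["rmsd_sem_of_max_dif"] = {"frame": int(loc), "sem": sem}
        _write_json(outdir / "trajectory_summary.json", summary)
        with open(outdir / "rmsf_profiles.tsv", "w") as fh:
            fh.write("# residue IDs are 1-based reference numbering\n")
            fh.write("system\tresidue\tmean\tsd\tsem\n")
            for system, prof in profiles.items():
                for rid, m, sd, se in zip(prof.residue_ids, prof.mean, prof.sd,
                                          prof.sem):
                    fh.write(f"{system}\t{rid}\t{m:.6f}\t{sd:.6f}\t{se:.6f}\n")
        manifest["stages"].append("trajectories")

    if config.run_compare:
        if profiles is None:
            profiles = {s: aggregate_rmsf(reps)
                        for s, reps in ensemble.systems.items()}
        labels = list(profiles)
        if {"wt", "del", "wtg", "delg"} <= set(labels):
            comparisons = None
        else:
            comparisons = [(labels[i], labels[j]) for i in range(len(labels))
                           for j in range(i + 1, len(labels))][:2]
        peaks = compare_systems(profiles, comparisons=comparisons,
                                window=config.window, step=config.step,
                                alpha=config.alpha, resolution=config.resolution)
        peaks.table.to_csv(outdir / "peak_table.tsv", sep="\t", index=False)
        _write_json(outdir / "consistency.json", {
            "consistent_windows": [list(w) for w in peaks.consistent_windows],
            "direction_concordance": {f"{w[0]}-{w[1]}": bool(v) for w, v in
                                      peaks.direction_concordance.items()},
            "conclusion": peaks.conclusion})
        manifest["stages"].append("compare")

    if config.run_pca:
        pca = pooled_pca(ensemble, n_components=min(10, 3 * len(
            ensemble.shared_residue_ids()) - 1))
        _write_json(outdir / "pca_explained_variance.json", {
            "ratios": [float(x) for x in pca.explained_variance_ratio]})
        pca.projections.to_csv(outdir / "pca_projections.tsv", sep="\t",
                               index=False)
        flags = flag_outlier_replicates(pca)
        flags.to_csv(outdir / "pca_outlier_flags.tsv", sep="\t", index=False)
        manifest["stages"].append("pca")

    if config.run_scan:
        if scan_sequence is None:
            rng = np.random.default_rng(config.seed)
            aa = "ACDEFGHIKLMNPQRSTVWY"
            scan_sequence = "".join(aa[i] for i in rng.integers(0, 20, size=120))
        result = run_scan(scan_sequence, additive_hydropathy_scorer,
                          window=config.scan_window)
        result.table.to_csv(outdir / "scan_table.tsv", sep="\t", index=False)
        query = (1, config.scan_window)
        _write_json(outdir / "scan_summary.json",
                    classify(result, query, rule="above_mean"))
        manifest["stages"].append("scan")

    _write_json(outdir / "manifest.json", manifest)
    return manifest
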