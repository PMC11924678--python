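"""Study-level orchestration: run configured stages from a manifest.

A study manifest is a YAML (or plain dict) description of which stages to
run and with what inputs — simulated (seeded) or read from files::

    seed: 1
    output_dir: results/run1
    stages:
      splice:
        simulate: {psi: 0.945, depth_per_junction: 10000}
        min_reads: 3
      tfl:
        simulate: {groups: {WT: 1.06, HOM: 0.96}, n_profiles_per_group: 4}
        mask_fraction: 0.5
      mech:
        simulate:
          groups:
            WT:  {p0min: 2.0, p0max: 20.0, fhalf: 45.0, k: 8.0}
            HOM: {p0min: 2.0, p0max: 12.0, fhalf: 50.0, k: 8.0}
          n_per_group: 4
          noise_sd: 0.3
      morph:
        simulate: {n_per_sample: 150, n_samples: 4,
                   groups: {WT: {feret_mean: 40.0}, HOM: {feret_mean: 32.0}}}
        edges: [0, 10, 20, 30, 40, 50, 60, 80]
      survival:
        records: survival.csv   # animal_id, genotype, time_days, event

Each stage writes its tables under the output directory, failures are
isolated per stage, and a machine-readable ``summary.json`` plus a parameter
log are emitted. Identical manifest + seed produce identical outputs: every
stochastic stage derives its RNG seed from the manifest seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, mech, morph, splice, stats, tfl
from .locus import annotate_pseudoexon, build_fixture_locus

__all__ = ["load_manifest", "run_pipeline"]

GENOTYPES = ("WT", "HET", "HOM")
TISSUES = ("TA", "EDL", "SOL", "gastroc", "quad", "plantaris", "diaphragm", "hindlimb")

# fixed per-stage seed offsets so stages are independent but reproducible
_STAGE_SEED = {"splice": 11, "tfl": 23, "mech": 37, "morph": 47, "survival": 53}


def load_manifest(path: str | Path) -> dict:
    with Path(path).open() as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "stages" not in manifest:
        raise ValueError("manifest must be a mapping with a 'stages' section")
    return manifest


def _stage_seed(manifest: dict, stage: str) -> int:
    return (int(manifest.get("seed", 0)) * 101 + _STAGE_SEED[stage]) % (2**31 - 1)


def _stage_splice(config: dict, seed: int, out_dir: Path) -> dict:
    fixture = build_fixture_locus(0)["dExon55"]
    annotation = annotate_pseudoexon(fixture.locus, fixture.junctions)
    exon54 = fixture.locus.exon("exon54")
    exon56 = fixture.locus.exon("exon56")

    if "simulate" in config:
        sim = config["simulate"]
        table = splice.simulate_junction_reads(
            psi=float(sim["psi"]),
            n_transcripts=int(sim.get("n_transcripts", 10_000)),
            depth_per_junction=float(sim.get("depth_per_junction", 10_000)),
            seed=seed,
            annotation=annotation,
            exon_up=exon54,
            exon_down=exon56,
        )
    else:
        table = splice.read_junctions(config["junctions"])
    filtered = splice.filter_junctions(table, int(config.get("min_reads", 3)))
    estimate = splice.estimate_inclusion(filtered, annotation, exon54, exon56)
    splice.write_junctions(filtered, out_dir / "splice_junctions.tsv")
    return {
        "psi_hat": estimate.psi_hat,
        "psi_percent": 100.0 * estimate.psi_hat,
        "j_up": estimate.j_up,
        "j_down": estimate.j_down,
        "j_skip": estimate.j_skip,
        "pseudoexon_length_bp": annotation.length_bp,
        "ptc_count": annotation.ptc_count,
    }


def _stage_tfl(config: dict, seed: int, out_dir: Path) -> dict:
    mask_fraction = float(config.get("mask_fraction", 0.5))
    sl_window = tuple(config.get("sl_window", tfl.SL_WINDOW))
    profiles: list[tfl.IntensityProfile] = []
    if "simulate" in config:
        sim = config["simulate"]
        n_per_group = int(sim.get("n_profiles_per_group", 4))
        for g_index, (genotype, true_tfl) in enumerate(sim["groups"].items()):
            for i in range(n_per_group):
                profiles.append(
                    tfl.generate_profile(
                        true_tfl=float(true_tfl),
                        sl=float(sim.get("sl", 2.6)),
                        sigma=float(sim.get("sigma", 0.15)),
                        n_sarcomeres=int(sim.get("n_sarcomeres", 8)),
                        bump_rel_amp=float(sim.get("bump_rel_amp", 0.15)),
                        noise_sd=float(sim.get("noise_sd", 0.0)),
                        seed=seed + 1000 * g_index + i,
                        source={
                            "genotype": genotype,
                            "animal": f"{genotype}_a{i // 2}",
                            "bundle": f"b{i % 2}",
                        },
                    )
                )
    else:
        manifest_df = pd.read_csv(config["manifest"])
        base = Path(config["manifest"]).parent
        for row in manifest_df.itertuples():
            profile = tfl.read_profile(base / row.file)
            profile.source.update(
                genotype=row.genotype, animal=str(row.animal), bundle=str(row.bundle)
            )
            profiles.append(profile)

    all_results = []
    for profile in profiles:
        fits = tfl.fit_profile(profile, mask_fraction=mask_fraction)
        all_results.extend(tfl.extract_tfl_sl(fits, sl_window=sl_window, source=profile.source))
    frame = tfl.results_to_frame(all_results)
    frame.to_csv(out_dir / "tfl_units.csv", index=False)
    summary = tfl.aggregate_tfl(frame)
    summary["per_genotype"].to_csv(out_dir / "tfl_by_genotype.csv", index=False)
    out = {
        "group_means": {
            str(r.genotype): float(r.mean) for r in summary["per_genotype"].itertuples()
        },
        "n_units_kept": int(frame["kept"].sum()),
    }
    if "t_test" in summary:
        out["t_test"] = summary["t_test"]
    return out


def _stage_mech(config: dict, seed: int, out_dir: Path) -> dict:
    frequencies = (
        mech.EDL_FREQUENCIES
        if config.get("simulate", {}).get("muscle", "edl").lower() == "edl"
        else mech.SOL_FREQUENCIES
    )
    curves: dict[str, list] = {}
    if "simulate" in config:
        sim = config["simulate"]
        n_per_group = int(sim.get("n_per_group", 4))
        noise_sd = float(sim.get("noise_sd", 0.0))
        for g_index, (genotype, p) in enumerate(sim["groups"].items()):
            params = mech.SigmoidParams(
                p0min=float(p["p0min"]), p0max=float(p["p0max"]),
                fhalf=float(p["fhalf"]), k=float(p["k"]),
            )
            curves[genotype] = [
                mech.simulate_force_frequency(
                    params, frequencies, noise_sd=noise_sd,
                    seed=seed + 500 * g_index + i,
                )
                for i in range(n_per_group)
            ]
    else:
        for genotype, paths in config["curves"].items():
            curves[genotype] = []
            for path in paths:
                df = pd.read_csv(path)
                curves[genotype].append(
                    (df["frequency_hz"].to_numpy(), df["force_mn"].to_numpy())
                )

    rows, out = [], {"fits": {}}
    for genotype, group in curves.items():
        for i, (freqs, forces) in enumerate(group):
            fit = mech.fit_force_frequency(freqs, forces)
            rows.append(
                {
                    "genotype": genotype, "curve": i,
                    "p0min": fit.params.p0min, "p0max": fit.params.p0max,
                    "fhalf": fit.params.fhalf, "k": fit.params.k,
                    "rss": fit.rss, "converged": fit.converged,
                }
            )
        fits_df = pd.DataFrame([r for r in rows if r["genotype"] == genotype])
        out["fits"][genotype] = {
            "p0max_mean": float(fits_df["p0max"].mean()),
            "fhalf_mean": float(fits_df["fhalf"].mean()),
        }
    pd.DataFrame(rows).to_csv(out_dir / "mech_sigmoid_fits.csv", index=False)

    genotypes = list(curves)
    if len(genotypes) == 2:
        ftest = mech.compare_curves_f_test(curves[genotypes[0]], curves[genotypes[1]])
        out["f_test"] = {
            "groups": genotypes,
            "F": ftest.f_statistic,
            "df": [ftest.df_num, ftest.df_den],
            "p": ftest.p_value,
        }
    if "fatigue" in config:
        fatigue_out = {}
        for genotype, path in config["fatigue"].items():
            series = pd.read_csv(path)["force_mn"].to_numpy()
            fatigue_out[genotype] = mech.fatigue_index(series)
        out["fatigue_index"] = fatigue_out
    return out


def _stage_morph(config: dict, seed: int, out_dir: Path) -> dict:
    edges = config.get("edges", list(np.arange(0.0, 90.0, 10.0)))
    min_area = float(config.get("min_area", 300.0))
    groups: dict[str, list] = {}
    if "simulate" in config:
        sim = config["simulate"]
        n_samples = int(sim.get("n_samples", 4))
        n_per_sample = int(sim.get("n_per_sample", 150))
        for g_index, (genotype, p) in enumerate(sim["groups"].items()):
            fibers = []
            for s in range(n_samples):
                fibers.extend(
                    morph.generate_fibers(
                        n=n_per_sample,
                        feret_mean=float(p.get("feret_mean", 40.0)),
                        feret_sd=float(p.get("feret_sd", 8.0)),
                        type_probs=tuple(p.get("type_probs", (0.0, 0.12, 0.24, 0.64))),
                        seed=seed + 300 * g_index + s,
                        sample_id=f"{genotype}_s{s}",
                    )
                )
            groups[genotype] = fibers
    else:
        for genotype, path in config["fibers"].items():
            groups[genotype] = morph.read_fibers(path)

    out = {}
    for genotype, fibers in groups.items():
        kept = morph.filter_by_area(fibers, min_area=min_area)
        dist = morph.bin_by_feret(kept, edges)
        comp = morph.type_composition([f.label for f in kept])
        out[genotype] = {
            "n_fibers": len(fibers),
            "n_after_area_filter": len(kept),
            "feret_bin_counts": list(dist.counts),
            "feret_overflow": dist.overflow,
            "type_percent": comp.percent,
        }
    pd.DataFrame(
        [
            {"genotype": g, "bin_lo": lo, "bin_hi": hi, "count": c}
            for g, info in out.items()
            for lo, hi, c in zip(edges[:-1], edges[1:], info["feret_bin_counts"])
        ]
    ).to_csv(out_dir / "morph_feret_bins.csv", index=False)
    return out


def _stage_survival(config: dict, seed: int, out_dir: Path) -> dict:
    if "records" in config and isinstance(config["records"], str):
        df = pd.read_csv(config["records"])
    else:
        df = pd.DataFrame(config["records"])
    records = [
        stats.SurvivalRecord(
            animal_id=str(r.animal_id),
            genotype=str(r.genotype),
            time_days=float(r.time_days),
            event=bool(r.event),
        )
        for r in df.itertuples()
    ]
    medians = stats.km_median_by_group(records)
    pd.DataFrame(
        [{"genotype": g, "median_survival_days": m} for g, m in medians.items()]
    ).to_csv(out_dir / "survival_medians.csv", index=False)
    return {"median_survival_days": medians}


_STAGE_RUNNERS = {
    "splice": _stage_splice,
    "tfl": _stage_tfl,
    "mech": _stage_mech,
    "morph": _stage_morph,
    "survival": _stage_survival,
}


def run_pipeline(manifest: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute every configured stage; failures are isolated per stage.

    Returns the report dict (also written as ``summary.json``). The report's
    ``errors`` mapping is empty on full success; callers wanting a process
    exit code should treat a non-empty mapping as failure.
    """
    if not isinstance(manifest, dict):
        manifest = load_manifest(manifest)
    out_dir = Path(output_dir or manifest.get("output_dir", "results/pipeline"))
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {"stages": {}, "errors": {}, "seed": int(manifest.get("seed", 0))}
    for stage, config in manifest["stages"].items():
        if stage not in _STAGE_RUNNERS:
            report["errors"][stage] = f"unknown stage {stage!r}"
            continue
        try:
            report["stages"][stage] = _STAGE_RUNNERS[stage](
                config or {}, _stage_seed(manifest, stage), out_dir
            )
        except Exception as exc:
            report["errors"][stage] = f"{type(exc).__name__}: {exc}"

    with (out_dir / "summary.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with (out_dir / "run.log").open("w") as fh:
        fh.write(f"sarcophen {__version__}\n")
        fh.write(f"seed: {report['seed']}\n")
        fh.write(f"stages: {', '.join(manifest['stages'])}\n")
        fh.write(yaml.safe_dump(manifest, sort_keys=True))
    return report
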