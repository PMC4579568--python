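"""Pipeline driver: simulate -> select -> measure -> mechanics -> kinetics.

Each stage reads and writes files under one output directory, so any
suffix of the chain can be re-run on saved intermediates and produce the
same numbers as a full run.  A JSON manifest records the package version,
the seed, the full parameter set and the files each invocation produced.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import measure_particle_table
from .io import (
    PipelineConfig,
    read_particle_table,
    write_particle_table,
    write_report,
    write_run_table,
)
from .kinetics import kinetics_report
from .mechanics import mechanics_report
from .selection import assign_roles, classify_head_count, isolate
from .synthgen import (
    sample_offset_dimers,
    sample_superposed_dimers,
    simulate_runs,
    to_particle_table,
)

__all__ = ["PipelineError", "ALL_STAGES", "run_pipeline"]

ALL_STAGES = ("simulate", "select", "measure", "mechanics", "kinetics")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, n)]


def _stage_simulate(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    gen, geom, mech = config.generation, config.motor, config.mechanical
    seeds = _child_seeds(config.seed, 8)
    rng = np.random.default_rng(seeds[0])

    n_sup = int(round(gen.n_dimers * gen.superposed_fraction))
    n_off = gen.n_dimers - n_sup
    seps = sorted(gen.separation_weights)
    probs = np.array([gen.separation_weights[s] for s in seps])
    counts = rng.multinomial(n_off, probs) if n_off > 0 else np.zeros(len(seps), int)

    # anchor (trailing-stalkhead) positions: uniform along enough MTs to
    # realise the requested crowding density
    n_mol = gen.n_dimers
    exp_per_mt = max(gen.crowding_density * gen.mt_length / 100.0, 1.0)
    n_mts = max(1, int(round(n_mol / exp_per_mt)))
    mol_mt = rng.integers(0, n_mts, n_mol)
    mol_x = rng.uniform(0.0, gen.mt_length, n_mol)

    frames: list[pd.DataFrame] = []
    next_particle = 0
    next_molecule = 0
    cursor = 0

    def take_anchor(k: int) -> tuple[np.ndarray, np.ndarray]:
        nonlocal cursor
        sel = slice(cursor, cursor + k)
        cursor += k
        return mol_mt[sel], mol_x[sel]

    if n_sup > 0:
        theta = sample_superposed_dimers(mech, geom, n_sup, seeds[1])["theta_deg"]
        mts, xs = take_anchor(n_sup)
        tbl = to_particle_table(
            theta.to_numpy(), geom, xs,
            noise_sd=gen.measurement_noise_sd, seed=seeds[2],
            start_id=next_particle, n_rings_visible=2, pixel_sum=2.0,
        )
        tbl["mt_id"] = mts
        tbl["molecule_id"] = np.arange(next_molecule, next_molecule + n_sup)
        tbl["true_class"] = "superposed"
        tbl["true_sep_nm"] = 0.9
        tbl["true_role"] = "both"
        frames.append(tbl)
        next_particle += n_sup
        next_molecule += n_sup

    for i, (sep, k) in enumerate(zip(seps, counts)):
        if k == 0:
            continue
        pairs = sample_offset_dimers(mech, geom, float(sep), int(k), seeds[3] + i)
        mts, xs = take_anchor(int(k))
        mol_ids = np.arange(next_molecule, next_molecule + k)
        for role, theta_col, shift in (
            ("trailing", "theta_trailing_deg", 0.0),
            ("leading", "theta_leading_deg", float(sep)),
        ):
            tbl = to_particle_table(
                pairs[theta_col].to_numpy(), geom, xs + shift,
                noise_sd=gen.measurement_noise_sd,
                seed=seeds[4] + 2 * i + (role == "leading"),
                start_id=next_particle, n_rings_visible=1, pixel_sum=1.0,
            )
            tbl["mt_id"] = mts
            tbl["molecule_id"] = mol_ids
            tbl["true_class"] = "offset"
            tbl["true_sep_nm"] = float(sep)
            tbl["true_role"] = role
            frames.append(tbl)
            next_particle += int(k)
        next_molecule += int(k)

    particles = pd.concat(frames, ignore_index=True)
    particles = particles.sort_values(
        ["mt_id", "axial_x_nm"], kind="stable"
    ).reset_index(drop=True)
    write_particle_table(particles, outdir / "particles.tsv")
    return particles


def _stage_select(config: PipelineConfig, outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    particles = read_particle_table(outdir / "particles.tsv")
    rep = config.report
    pair_rows, single_rows = [], []
    for mt_id, group in particles.groupby("mt_id"):
        pairs, singles = isolate(group, rep.pair_window_nm, rep.exclusion_nm)
        for a, b in pairs:
            pair_rows.append({"mt_id": mt_id, "particle_id_a": a, "particle_id_b": b})
        by_id = group.set_index("particle_id")
        for pid in singles:
            ratio = float(by_id.loc[pid, "pixel_sum"])
            label = (
                classify_head_count(ratio, monomer_reference=1.0)
                if int(by_id.loc[pid, "n_rings_visible"]) >= 1
                else "unknown"
            )
            single_rows.append({"mt_id": mt_id, "particle_id": pid, "class_label": label})
    pairs_df = pd.DataFrame(pair_rows, columns=["mt_id", "particle_id_a", "particle_id_b"])
    singles_df = pd.DataFrame(single_rows, columns=["mt_id", "particle_id", "class_label"])
    pairs_df.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    singles_df.to_csv(outdir / "singles.tsv", sep="\t", index=False)
    return pairs_df, singles_df


def _stage_measure(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    particles = read_particle_table(outdir / "particles.tsv")
    pairs = pd.read_csv(outdir / "pairs.tsv", sep="\t")
    measured = measure_particle_table(particles, config.motor, on_invalid="drop")
    measured.to_csv(outdir / "particles_measured.tsv", sep="\t", index=False)

    by_id = measured.set_index("particle_id")
    rows = []
    for r in pairs.itertuples(index=False):
        if r.particle_id_a not in by_id.index or r.particle_id_b not in by_id.index:
            continue  # a member was unmeasurable (height outside rigid-body range)
        a = by_id.loc[r.particle_id_a]
        b = by_id.loc[r.particle_id_b]
        motors = [
            {
                "particle_id": pid,
                "stalkhead_x": row["stalkhead_x_nm"],
                "ring_x": row["axial_x_nm"],
                "theta_deg": row["theta_deg"],
            }
            for pid, row in ((r.particle_id_a, a), (r.particle_id_b, b))
        ]
        roles = assign_roles(motors[0], motors[1])
        lead, trail = roles.leading, roles.trailing
        rows.append(
            {
                "mt_id": r.mt_id,
                "particle_id_leading": lead["particle_id"],
                "particle_id_trailing": trail["particle_id"],
                "theta_leading_deg": lead["theta_deg"],
                "theta_trailing_deg": trail["theta_deg"],
                "stalkhead_separation_nm": lead["stalkhead_x"] - trail["stalkhead_x"],
                "ring_separation_nm": lead["ring_x"] - trail["ring_x"],
                "crossed": bool(roles.crossed),
                "ambiguous": roles.ambiguous,
            }
        )
    dimers = pd.DataFrame(
        rows,
        columns=[
            "mt_id", "particle_id_leading", "particle_id_trailing",
            "theta_leading_deg", "theta_trailing_deg",
            "stalkhead_separation_nm", "ring_separation_nm",
            "crossed", "ambiguous",
        ],
    )
    dimers.to_csv(outdir / "dimers.tsv", sep="\t", index=False)
    return dimers


def _stage_mechanics(config: PipelineConfig, outdir: Path) -> dict:
    dimers = pd.read_csv(outdir / "dimers.tsv", sep="\t")
    singles = pd.read_csv(outdir / "singles.tsv", sep="\t")
    measured = pd.read_csv(outdir / "particles_measured.tsv", sep="\t")
    sup_ids = singles.loc[singles["class_label"] == "superposed_dimer", "particle_id"]
    by_id = measured.set_index("particle_id")
    # particles dropped as unmeasurable at the measure stage carry no angle
    sup_ids = sup_ids[sup_ids.isin(by_id.index)]
    sup_theta = by_id.loc[sup_ids, "theta_deg"].to_numpy() if len(sup_ids) else None
    # molecules with superposed stalkheads but offset rings: stalkhead
    # separation below half a lattice repeat
    half_repeat = config.lattice.axial_repeat / 2.0
    n_off_sup = int((dimers["stalkhead_separation_nm"] < half_repeat).sum())
    report = mechanics_report(
        dimers,
        sup_theta,
        geom=config.motor,
        thermal_energy=config.mechanical.thermal_energy,
        mode=config.report.mode,
        window=config.report.window,
        n_superposed_rings=int(len(sup_ids)),
        n_offset_rings_superposed_stalkheads=n_off_sup if n_off_sup > 0 else None,
    )
    report["n_dimers"] = int(len(dimers))
    write_report(report, outdir / "mechanics_report.json")
    return report


def _stage_kinetics(config: PipelineConfig, outdir: Path) -> dict:
    kin = config.kinetics
    seeds = _child_seeds(config.seed + 1, 2)
    runs = simulate_runs(kin.duty_ratio, kin.step_nm, kin.n_runs, seeds[0])
    rng = np.random.default_rng(seeds[1])
    velocities = rng.normal(kin.velocity_mean, kin.velocity_sd, kin.n_runs)
    velocities = np.clip(velocities, 1.0, None)
    durations = runs / velocities
    table = pd.DataFrame(
        {
            "molecule_id": np.arange(kin.n_runs),
            "run_length_nm": runs,
            "duration_s": durations,
            "velocity_nm_per_s": velocities,
        }
    )
    write_run_table(table, outdir / "runs.tsv")
    report = kinetics_report(
        run_lengths=runs[runs > 0],
        velocities=velocities,
        step_sizes=kin.step_sizes,
        criterion=kin.criterion,
        atp_check={
            # imaging-mix conditions: 330 nM dimer (0.66 uM heads), 3.7 uM
            # MT, up to 46 s between ATP addition and freezing, 3.6 mM ATP
            "dynein_heads_uM": 0.66,
            "mt_uM": 3.7,
            "time_s": 46.0,
            "atp0_mM": 3.6,
        },
    )
    write_report(report, outdir / "kinetics_report.json")
    return report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "select": _stage_select,
    "measure": _stage_measure,
    "mechanics": _stage_mechanics,
    "kinetics": _stage_kinetics,
}


def run_pipeline(
    config: PipelineConfig | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
    outdir: str | Path = "dyneinflex_out",
) -> dict:
    """Execute the requested stages in canonical order.

    Stages not requested are skipped; later stages read their inputs from
    files already present in ``outdir`` (so ``stages=("mechanics",)`` on a
    saved dimer table reproduces the numbers of a full run).  Returns the
    manifest, which is also written to ``manifest.json``.
    """
    config = config if config is not None else PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")

    ran = []
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:  # noqa: BLE001 - manifest must name the stage
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        ran.append(stage)

    manifest = {
        "package": "dyneinflex",
        "version": __version__,
        "seed": config.seed,
        "stages": ran,
        "config": config.to_dict(),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    write_report(manifest, outdir / "manifest.json")
    return manifest
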