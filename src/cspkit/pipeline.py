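"""End-to-end desk-scale workflow: generate → nmer → al → relax → qha → rank.

Every stage persists its intermediates under the output root and appends a
record (counts, seed, wall time) to the run manifest.  All randomness flows
from the single global seed through named substreams, so a rerun with the
same configuration reproduces every output.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .active_learning import ALConfig, run_al
from .fixtures import Fixture, FixtureSpec, make_fixture
from .generation import (
    ContactCriterion,
    GenerationConfig,
    GenerationFailure,
    generate_candidate,
)
from .nmer_sampling import ShellSpec, TetherSettings, enumerate_nmers, tethered_sampling
from .optimization import MatchTolerances, RelaxSettings, deduplicate, relax
from .phonons import qha
from .potentials import LabeledSample
from .ranking import landscape_table
from .structures import Molecule, NMer, write_cif, write_xyz

STAGES = ("generate", "nmer", "al", "relax", "qha", "rank")


@dataclass
class PipelineConfig:
    stages: list[str] = field(default_factory=lambda: ["generate", "relax", "rank"])
    seed: int = 0
    out: str = "pipeline_out"
    n_structures: int = 10
    space_groups: list[str] = field(default_factory=lambda: ["P1", "P-1"])
    Z_values: list[int] = field(default_factory=lambda: [1, 2])
    s_r: float = 0.75
    n_max_order: int = 3
    per_order_counts: int = 4
    tether_steps: int = 200
    qha_volume_factors: tuple = (0.95, 0.975, 1.0, 1.025, 1.05, 1.075, 1.1, 1.125, 1.15)
    qha_temperatures: tuple = (0.0, 150.0, 300.0)
    qha_mesh: tuple = (3, 3, 3)
    fixture: FixtureSpec = field(
        default_factory=lambda: FixtureSpec("rigid_diatomic_crystal"))

    def __post_init__(self):
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")


def _substream(seed: int, stage: str) -> int:
    """Named substream seed (stable, below 2^31)."""
    return int(np.random.default_rng([seed, sum(map(ord, stage))])
               .integers(0, 2**31 - 1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    fixture: Fixture = make_fixture(config.fixture)
    teacher = fixture.calculator
    molecule: Molecule = fixture.reference.get("molecule") or Molecule(
        list(fixture.structure.species[:1]),
        fixture.structure.cart_coords[:1])
    criterion = ContactCriterion(config.s_r)
    manifest = {"seed": config.seed, "stages": [], "failed": False}
    structures = []
    energies = []

    for stage in config.stages:
        t0 = time.perf_counter()
        rec = {"stage": stage, "seed": _substream(config.seed, stage)}
        try:
            if stage == "generate":
                gen_cfg = GenerationConfig(space_groups=config.space_groups,
                                           Z_values=config.Z_values,
                                           seed=rec["seed"])
                rng = np.random.default_rng(rec["seed"])
                made = 0
                attempts_total = 0
                gdir = out / "generated"
                gdir.mkdir(exist_ok=True)
                while made < config.n_structures:
                    sg = config.space_groups[rng.integers(len(config.space_groups))]
                    from .generation import SPACE_GROUP_WHITELIST
                    import gemmi as _gemmi
                    mult = len(list(_gemmi.SpaceGroup(
                        SPACE_GROUP_WHITELIST[sg][0]).operations()))
                    z_opts = [z for z in config.Z_values if z % mult == 0]
                    if not z_opts:
                        z = mult
                    else:
                        z = z_opts[rng.integers(len(z_opts))]
                    try:
                        s = generate_candidate(molecule, sg, z, criterion,
                                               gen_cfg,
                                               seed=int(rng.integers(2**31 - 1)))
                    except GenerationFailure:
                        attempts_total += gen_cfg.max_attempts
                        continue
                    structures.append(s)
                    (gdir / f"{made:04d}.cif").write_text(
                        write_cif(s, f"gen{made:04d}"))
                    made += 1
                rec["n_generated"] = made
            elif stage == "nmer":
                src = structures[0] if structures else fixture.structure
                nmers = enumerate_nmers(src, config.n_max_order,
                                        config.per_order_counts,
                                        seed=rec["seed"],
                                        shell=ShellSpec(0, 6.0))
                frames = []
                for k, nm in enumerate(nmers):
                    frames.append(write_xyz(
                        nm, f"order={nm.order} id={k} seed={rec['seed']}"))
                (out / "nmers.xyz").write_text("".join(frames))
                rec["n_nmers"] = len(nmers)
                manifest["_nmers"] = nmers
            elif stage == "al":
                nmers = manifest.get("_nmers")
                if nmers is None:
                    src = structures[0] if structures else fixture.structure
                    nmers = enumerate_nmers(src, config.n_max_order,
                                            config.per_order_counts,
                                            seed=rec["seed"])
                monomers = [n for n in nmers if n.order == 1]
                rng = np.random.default_rng(rec["seed"])
                seeds_mono: list[LabeledSample] = []
                for k, nm in enumerate(monomers):
                    frames = tethered_sampling(
                        nm, teacher,
                        TetherSettings(n_steps=config.tether_steps,
                                       stride=max(1, config.tether_steps // 10),
                                       seed=int(rng.integers(2**31 - 1))))
                    for fr in [nm.positions] + frames:
                        geom = Molecule(nm.symbols, fr,
                                        bonds=nm.as_molecule_graph().bonds)
                        e, f = teacher.energy_forces(geom)
                        seeds_mono.append(LabeledSample(geom, e, f))
                pools = {}
                for nm in nmers:
                    if nm.order >= 2:
                        pools.setdefault(nm.order, []).append(nm)
                state = run_al(teacher, seeds_mono, pools,
                               ALConfig(), seed=rec["seed"])
                rec["history"] = state.history
                rec["n_labelled_total"] = len(state.training_pool)
                (out / "al_history.json").write_text(
                    json.dumps(state.history, indent=1))
            elif stage == "relax":
                pool = structures or [fixture.structure]
                rdir = out / "relaxed"
                rdir.mkdir(exist_ok=True)
                relaxed = []
                energies.clear()
                logs = []
                for k, s in enumerate(pool):
                    res = relax(s, teacher, RelaxSettings(mode="variable_cell"))
                    relaxed.append(res.structure)
                    energies.append(res.energy)
                    (rdir / f"{k:04d}.cif").write_text(
                        write_cif(res.structure, f"rel{k:04d}"))
                    logs.append({"id": k, "steps": res.n_steps,
                                 "converged": res.converged,
                                 "E": res.energy,
                                 "rms_force": res.rms_force})
                structures[:] = relaxed
                (rdir / "relax_log.json").write_text(json.dumps(logs, indent=1))
                rec["n_relaxed"] = len(relaxed)
                rec["n_converged"] = sum(l["converged"] for l in logs)
            elif stage == "qha":
                pool = structures or [fixture.structure]
                idx = int(np.argmin(energies)) if energies else 0
                curve = qha(pool[idx], teacher,
                            volume_factors=config.qha_volume_factors,
                            T_list=config.qha_temperatures,
                            mesh=config.qha_mesh,
                            min_supercell_length=8.0)
                table = {
                    "T": curve.temperatures.tolist(),
                    "G": curve.G_of_T.tolist(),
                    "V": curve.V_of_T.tolist(),
                    "volumes": curve.volumes.tolist(),
                }
                (out / "thermo.json").write_text(json.dumps(table, indent=1))
                rec["n_volumes"] = len(curve.volumes)
            elif stage == "rank":
                pool = structures or [fixture.structure]
                ee = energies or [0.0] * len(pool)
                zvals = [s.Z or 1 for s in pool]
                per_mol = [e / z for e, z in zip(ee, zvals)]
                reps, cmap = deduplicate(pool, MatchTolerances(), ee)
                entries = landscape_table(pool, per_mol)
                rows = ["id,density_g_cm3,E_rel_kJ_mol,rank,space_group"]
                rows += [f"{t.structure_id},{t.density:.4f},{t.E_rel:.4f},"
                         f"{t.rank},{t.space_group}" for t in entries]
                (out / "landscape.csv").write_text("\n".join(rows) + "\n")
                rec["n_unique"] = len(reps)
                rec["clusters"] = cmap
        except Exception as exc:
            rec["error"] = f"{type(exc).__name__}: {exc}"
            rec["wall_time_s"] = time.perf_counter() - t0
            manifest["stages"].append(rec)
            manifest["failed"] = True
            break
        rec["wall_time_s"] = time.perf_counter() - t0
        manifest["stages"].append(rec)

    manifest.pop("_nmers", None)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
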