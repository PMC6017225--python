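"""End-to-end orchestration: build -> map -> structure -> analyses.

A pipeline run is fully described by a JSON-serializable configuration
(molecule spec, system or fixture selection, analysis parameters and
explicit seeds).  Every run writes its artifacts plus a manifest listing
files, SHA-256 checksums and the configuration, so identical configs
produce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from .analysis import (aggregate_metrics, bilayer_thickness, cluster_aggregates,
                       core_thickness, density_profile, interdigitation_ratio,
                       monomer_length)
from .builder import (RunConfig, SimulationBox, SystemSpec, concentration,
                      emit_run_config, emit_topology_stub, random_pack)
from .cgmap import assign_bonded_params, map_to_cg, write_itp
from .grammar import (DendronSpec, FocalPoint, JanusSpec, Terminal, build_janus,
                      molecule_report)
from .groio import write_gro
from .structures import get_fixture

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    """Reference configuration: default molecule, reference patch analyses."""
    return {
        "molecule": {
            "hydrophilic_generation": 2,
            "hydrophobic_generation": 2,
            "tail_carbons": 13,
        },
        "adducts": {"Na": 2},
        "system": None,              # or {"n_molecules":, "box":, "seed":}
        "fixture": "reference_patch",
        "fixture_seed": 42,
        "analyses": {
            "density": {"bin_width": 0.1},
            "thickness": True,
            "cluster": None,          # or {"cutoff": 0.6}
        },
        "run_config": {},
        "seed": 42,
    }


def janus_spec_from_config(mol: dict) -> JanusSpec:
    return JanusSpec(
        hydrophilic=DendronSpec(mol.get("hydrophilic_generation", 2),
                                Terminal.HYDROXYL, FocalPoint.LINKER),
        hydrophobic=DendronSpec(mol.get("hydrophobic_generation", 2),
                                Terminal.MYRISTOYL, FocalPoint.LINKER),
        tail_carbons=mol.get("tail_carbons", 13),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> Path:
        p = outdir / name
        p.write_text(text)
        written.append(p)
        return p

    stage = "build_molecule"
    try:
        spec = janus_spec_from_config(config.get("molecule", {}))
        tree = build_janus(spec)
        emit("molecule.json",
             json.dumps(molecule_report(tree, config.get("adducts")), indent=1))

        stage = "map_cg"
        top = assign_bonded_params(map_to_cg(tree))
        emit("molecule.itp", write_itp(top))

        stage = "run_config"
        rc = RunConfig(**config.get("run_config", {}))
        emit("run.mdp", emit_run_config(rc, seed=config.get("seed", 42)))

        frame = None
        if config.get("system"):
            stage = "build_system"
            sysc = config["system"]
            sspec = SystemSpec(
                n_molecules=sysc["n_molecules"],
                box=SimulationBox(tuple(sysc["box"])),
                min_separation=sysc.get("min_separation", 0.5),
                seed=sysc.get("seed", config.get("seed", 42)),
            )
            frame = random_pack(top, sspec)
            emit("system.gro", write_gro(frame, "packed system"))
            emit("system.top", emit_topology_stub(
                top.molecule_name, sspec.n_molecules, "molecule.itp"))
            emit("system.json", json.dumps({
                "n_molecules": sspec.n_molecules,
                "concentration_mM": concentration(sspec.n_molecules, sspec.box),
            }, indent=1))
        elif config.get("fixture"):
            stage = "fixture"
            frame = get_fixture(config["fixture"], seed=config.get("fixture_seed"))
            emit("fixture.gro", write_gro(frame, config["fixture"]))

        analyses = config.get("analyses") or {}
        results: dict = {}
        if frame is not None and analyses:
            if analyses.get("density"):
                stage = "density"
                prof = density_profile(
                    frame, bin_width=analyses["density"].get("bin_width", 0.1))
                rows = ["z_nm," + ",".join(prof.densities)]
                for i, zc in enumerate(prof.centers):
                    rows.append(f"{zc:.4f}," + ",".join(
                        f"{prof.densities[g][i]:.6f}" for g in prof.densities))
                emit("density_profile.csv", "\n".join(rows) + "\n")
                if analyses.get("thickness"):
                    stage = "thickness"
                    d = bilayer_thickness(prof)
                    core = core_thickness(prof)
                    L, lt = monomer_length(frame)
                    ratio, label = interdigitation_ratio(d, L)
                    results["thickness"] = {
                        "bilayer_thickness_nm": d,
                        "core_thickness_nm": core,
                        "monomer_length_nm": L,
                        "tail_length_nm": lt,
                        "interdigitation_ratio": ratio,
                        "classification": label,
                    }
            if analyses.get("cluster"):
                stage = "cluster"
                rep = aggregate_metrics(
                    cluster_aggregates(frame, **analyses["cluster"]), frame)
                results["clusters"] = {
                    "aggregation_numbers": rep.aggregation_numbers,
                    "metrics": rep.metrics,
                }
        if results:
            emit("analysis.json", json.dumps(results, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": config,
        "files": {p.name: _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
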