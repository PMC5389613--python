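"""End-to-end pipeline: peaks → frequencies → pseudo-individuals →
(diversity, distances, NJ, PCoA) and K-scan → ΔK → assignment →
sub-structure, driven by a flat YAML config with per-stage blocks.

Every run writes its artifacts plus a ``manifest.json`` listing each output
file with a SHA-256 content hash, and a ``run.log``. Re-running the same
config and seed reproduces the manifest hashes bit for bit (all stochastic
stages are seeded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .admixture import (
    assign_groups,
    consensus_q,
    evanno_delta_k,
    hierarchical_substructure,
    k_scan,
)
from .distance import distance_extremes, distance_matrix
from .diversity import diversity_table
from .nj import neighbor_joining
from .ordination import PCoA
from .peaks import PeakFilterParams, peaks_to_frequencies
from .pseudo import SimulationParams, simulate_individuals
from .synth import GeneratorConfig, generate_dataset

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

logger = logging.getLogger("bulkpop")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "bulkpop_out",
    "stages": {
        "synth": True,
        "freqs": True,
        "individuals": True,
        "distance": True,
        "nj": True,
        "pcoa": True,
        "structure": True,
        "diversity": True,
        "substructure": False,
    },
    "inputs": {"peaks": None, "loci": None, "freqs": None},
    "synth": {"k_true": 3, "n_populations": 12, "n_loci": 8},
    "peaks": {"stutter_ratio": 0.2, "noise_floor": 0.05},
    "individuals": {"n_individuals": 15, "het_tolerance": 0.05},
    "structure": {
        "k_min": 1,
        "k_max": 4,
        "n_runs": 3,
        "burn_in": 2000,
        "n_reps": 2000,
        "unit": "individual",
        "cutoff": 0.51,
        "strong_cutoff": 0.80,
    },
}


def load_config(path) -> dict:
    """Load a YAML config, filling unspecified blocks from the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the enabled stages in order and return the manifest.

    A stage failure aborts with the stage named in the raised error;
    artifacts written by completed stages are retained.
    """
    cfg = load_config(config) if not isinstance(config, dict) else _merge(DEFAULT_CONFIG, config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    artifacts: dict[str, Path] = {}

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("bulkpop %s, seed %d, config %s", __version__, seed, json.dumps(cfg, default=str))

    stage = "init"
    try:
        locus_defs = None
        table = None
        peaks = None

        if stages.get("synth"):
            stage = "synth"
            gcfg = GeneratorConfig(**{**cfg["synth"], "seed": seed})
            ds = generate_dataset(gcfg)
            locus_defs, peaks = ds.locus_defs, ds.peaks
            io.write_locus_defs(locus_defs, outdir / "loci.csv")
            io.write_peak_table(peaks, outdir / "peaks.csv")
            ds.true_q.to_csv(outdir / "truth_q.csv", float_format="%.9f")
            artifacts["loci"] = outdir / "loci.csv"
            artifacts["peaks"] = outdir / "peaks.csv"
            artifacts["truth_q"] = outdir / "truth_q.csv"
        else:
            inputs = cfg["inputs"]
            if inputs.get("loci"):
                locus_defs = io.read_locus_defs(inputs["loci"])
            if inputs.get("peaks"):
                peaks = io.read_peak_table(inputs["peaks"], locus_defs)
            if inputs.get("freqs"):
                table = io.read_frequency_table(inputs["freqs"], locus_defs)

        if stages.get("freqs") and table is None:
            stage = "freqs"
            if peaks is None or locus_defs is None:
                raise ValueError("freqs stage needs peak and locus inputs")
            table = peaks_to_frequencies(peaks, locus_defs, PeakFilterParams(**cfg["peaks"]))
            io.write_frequency_table(table, outdir / "freqs.csv")
            artifacts["freqs"] = outdir / "freqs.csv"
        if table is None:
            raise ValueError("no frequency table available for downstream stages")

        genotypes = None
        if stages.get("individuals"):
            stage = "individuals"
            genotypes = simulate_individuals(
                table, SimulationParams(seed=seed, **cfg["individuals"])
            )
            io.write_genotypes(genotypes, outdir / "genotypes.csv")
            artifacts["genotypes"] = outdir / "genotypes.csv"

        if stages.get("distance"):
            stage = "distance"
            dm = distance_matrix(table)
            io.write_distance_matrix(dm, outdir / "dist.csv")
            artifacts["dist"] = outdir / "dist.csv"
            ext = distance_extremes(dm)
            logger.info("distance extremes: %s", ext)
            if stages.get("nj"):
                stage = "nj"
                io.write_newick(neighbor_joining(dm), outdir / "tree.nwk")
                artifacts["tree"] = outdir / "tree.nwk"
            if stages.get("pcoa"):
                stage = "pcoa"
                ord_ = PCoA().fit(dm)
                ord_.coordinates_.to_csv(outdir / "pcoa.csv", float_format="%.9f")
                pd.DataFrame(
                    {
                        "eigenvalue": ord_.eigenvalues_,
                        "proportion_explained": ord_.proportion_explained_,
                    }
                ).to_csv(outdir / "pcoa_eigenvalues.csv", float_format="%.9f", index=False)
                artifacts["pcoa"] = outdir / "pcoa.csv"
                artifacts["pcoa_eigenvalues"] = outdir / "pcoa_eigenvalues.csv"

        assignment = None
        if stages.get("structure"):
            stage = "structure"
            if genotypes is None:
                raise ValueError("structure stage needs the individuals stage")
            scfg = cfg["structure"]
            ks = list(range(int(scfg["k_min"]), int(scfg["k_max"]) + 1))
            results, lnpd = k_scan(
                genotypes,
                ks,
                n_runs=int(scfg["n_runs"]),
                seed=seed,
                unit=scfg["unit"],
                burn_in=int(scfg["burn_in"]),
                n_reps=int(scfg["n_reps"]),
            )
            lnpd.rename_axis("run").to_csv(outdir / "lnpd.csv", float_format="%.6f")
            artifacts["lnpd"] = outdir / "lnpd.csv"
            table_dk = evanno_delta_k(lnpd)
            table_dk.to_csv(outdir / "deltak.csv", float_format="%.6f")
            artifacts["deltak"] = outdir / "deltak.csv"
            selected = table_dk.attrs["selected_k"]
            logger.info("ΔK selects K = %s", selected)
            if selected is not None:
                qbar = consensus_q([results[(selected, r)] for r in range(int(scfg["n_runs"]))])
                io.write_q_matrix(qbar, outdir / f"q_k{selected}.csv")
                artifacts["q_selected"] = outdir / f"q_k{selected}.csv"
                assignment = assign_groups(
                    qbar, cutoff=float(scfg["cutoff"]), strong_cutoff=float(scfg["strong_cutoff"])
                )
                assignment.to_csv(outdir / "assignments.csv", float_format="%.6f")
                artifacts["assignments"] = outdir / "assignments.csv"
                if stages.get("substructure"):
                    stage = "substructure"
                    sub = hierarchical_substructure(
                        genotypes,
                        assignment,
                        ks,
                        n_runs=int(scfg["n_runs"]),
                        seed=seed,
                        cutoff=float(scfg["cutoff"]),
                        unit=scfg["unit"],
                        burn_in=int(scfg["burn_in"]),
                        n_reps=int(scfg["n_reps"]),
                    )
                    frames = [
                        e["assignment"]
                        for e in sub.values()
                        if not e.get("skipped") and "assignment" in e
                    ]
                    if frames:
                        pd.concat(frames).to_csv(
                            outdir / "sub_assignments.csv", float_format="%.6f"
                        )
                        artifacts["sub_assignments"] = outdir / "sub_assignments.csv"

        if stages.get("diversity"):
            stage = "diversity"
            if assignment is not None:
                groups: dict[str, list[str]] = {}
                for pop, row in assignment.iterrows():
                    groups.setdefault(str(row["group"]), []).append(str(pop))
            else:
                groups = {"all": list(table.populations)}
            diversity_table(table, groups).to_csv(
                outdir / "diversity.csv", float_format="%.6f", index=False
            )
            artifacts["diversity"] = outdir / "diversity.csv"
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest = {
        "version": __version__,
        "seed": seed,
        "artifacts": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in artifacts.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
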