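"""End-to-end pipeline orchestration from a plain-text (YAML) config.

Stages run in a fixed order — probe stats, triplet caller, permutation
FDR, TSS assignment, then the optional overlap and motif stages and the
TSS profile — each logged to stderr with its timing.  The run emits a
machine-readable ``report.json`` plus the standard output files of each
stage; on a stage failure the partial outputs are retained and the report
is marked incomplete.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import genes as ga
from . import io as cio
from . import motifs as mf
from . import overlap as ov
from . import simulate as sim
from . import triplets as tc
from . import tssprofile
from .model import BindingModel

log = logging.getLogger("chipscan")

_TOP_KEYS = {"simulate", "inputs", "caller", "assign", "overlap", "profile", "motif"}


def _validate_config(config: dict) -> None:
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    if ("simulate" in config) == ("inputs" in config):
        raise ValueError("config needs exactly one of 'simulate' or 'inputs'")


def _require_file(path: str | Path, what: str) -> Path:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"missing {what} file: {p}")
    return p


class _Stage:
    """Context manager logging a stage's wall time."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("[%s] start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        status = "done" if exc_type is None else f"FAILED ({exc})"
        log.info("[%s] %s in %.2fs", self.name, status, time.perf_counter() - self.t0)
        return False


def run_pipeline(config: dict, outdir: str | Path, seed: int = 0) -> dict:
    """Run the configured pipeline into `outdir`; returns the run report."""
    _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"incomplete": True, "stages": []}
    truth = None

    try:
        with _Stage("input"):
            if "simulate" in config:
                sim_cfg = sim.SimulationConfig(**{**config["simulate"], "seed": config["simulate"].get("seed", seed)})
                probes, genes, truth = sim.simulate_array(sim_cfg, outdir=outdir)
            else:
                inputs = config["inputs"]
                probes = cio.read_probe_table(_require_file(inputs["probes"], "probe table"))
                genes = (
                    cio.read_gene_bed(_require_file(inputs["genes"], "gene BED"))
                    if "genes" in inputs
                    else None
                )
            report["stages"].append("input")

        caller_cfg = dict(config.get("caller", {}))
        n_perm = int(caller_cfg.pop("n_permutations", 10))
        assign_cfg = config.get("assign", {})
        model = BindingModel(
            probes,
            genes,
            config=tc.CallerConfig(**caller_cfg),
            max_tss_distance=int(assign_cfg.get("max_distance", ga.MAX_TSS_DISTANCE)),
        )

        with _Stage("call"):
            results = model.fit(n_permutations=n_perm, seed=seed)
            results.save(outdir)
            report.update(results.report())
            report["stages"] += ["probe_stats", "triplet_caller", "estimate_fdr", "gene_assignment"]

        if truth is not None and results.assignments is not None:
            from .evaluate import region_recovery

            rec = region_recovery(results.regions, truth.true_regions)
            report["recovery_vs_truth"] = {
                "sensitivity": rec.sensitivity,
                "precision": rec.precision,
                "mean_boundary_error_bp": rec.mean_boundary_error,
            }

        if "overlap" in config and results.assignments is not None:
            with _Stage("overlap"):
                universe = list(genes["gene_id"])
                targets = set(results.assignments["gene_id"])
                rows = {}
                for ref in config["overlap"].get("reference_sets", []):
                    ref_set = ov.read_gene_set(_require_file(ref["path"], "gene set"))
                    res = ov.test_overlap(targets, ref_set, universe)
                    rows[ref["name"]] = res.__dict__
                report["overlap"] = rows
                report["stages"].append("overlap_enrichment")

        if results.assignments is not None:
            with _Stage("profile"):
                pc = config.get("profile", {})
                edges = np.arange(
                    int(pc.get("bin_start", -5500)),
                    int(pc.get("bin_end", 2500)) + 1,
                    int(pc.get("bin_width", 250)),
                )
                profile = results.tss_profile(edges)
                tssprofile.write_profile(profile, outdir / "tss_profile.tsv")
                if pc.get("plot"):
                    tssprofile.plot_profile(profile, outdir / "tss_profile.png")
                peak = (
                    None
                    if profile.empty
                    else int((profile.bin_edges[:-1] + profile.bin_edges[1:])[np.argmax(profile.counts)] // 2)
                )
                report["tss_profile"] = {"n_assigned": profile.n_assigned, "peak_bin_center": peak}
                report["stages"].append("tss_profile")

        if "motif" in config:
            with _Stage("motif"):
                mc = config["motif"]
                seqs = cio.read_fasta(_require_file(mc["fasta"], "FASTA"))
                k = int(mc.get("k", 8))
                m = int(mc.get("max_mismatches", 1))
                ranked = mf.find_motifs(seqs, k=k, max_mismatches=m)
                ranked.to_csv(outdir / "motifs.tsv", sep="\t", index=False)
                top = ranked.iloc[0]
                report["motif"] = {
                    "consensus": top["consensus"],
                    "fraction": float(top["fraction"]),
                    "enrichment_z": float(top["enrichment_z"]),
                }
                if "pwm_library" in mc:
                    lib = cio.read_pwm_library(_require_file(mc["pwm_library"], "PWM library"))
                    query = mf.build_query_pwm(seqs, top["consensus"], m)
                    matches = mf.match_library(query, lib, n_null=int(mc.get("n_null", 1000)), seed=seed)
                    mf.matches_to_frame(matches).to_csv(outdir / "pwm_matches.tsv", sep="\t", index=False)
                    best = matches[0]
                    report["motif"]["best_pwm_match"] = {
                        "library_name": best.library_name,
                        "similarity": best.similarity,
                        "p_value": best.p_value,
                    }
                report["stages"].append("motif_finder")
    except Exception as err:
        report["error"] = f"{type(err).__name__}: {err}"
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        raise

    report["incomplete"] = False
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
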