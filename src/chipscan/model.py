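"""Model/Results interface over the ChIP-chip calling pipeline.

`BindingModel` bundles a probe table, an optional gene annotation and the
caller thresholds; `fit()` runs probe statistics, the triplet caller, the
permutation FDR and (when genes are given) TSS assignment, returning a
`BindingResults` that carries every intermediate table, a `summary()`
report and serialization helpers.

>>> probes, genes, truth = simulate.simulate_array()
>>> res = BindingModel(probes, genes).fit(seed=1)
>>> res.regions.shape[0]            # number of bound regions called
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import genes as ga
from . import io as cio
from . import probe_stats as ps
from . import triplets as tc
from . import tssprofile


class BindingModel:
    """Two-color promoter-array binding model.

    Parameters
    ----------
    probes : DataFrame
        Probe table (probe_id, chrom, start, end, rep{k}_ip, rep{k}_ctl);
        sorted internally by (chrom, start).
    genes : DataFrame, optional
        Gene annotation (gene_id, chrom, tss, strand, biotype); enables
        target assignment and TSS profiles.
    config : CallerConfig
        Triplet-rule thresholds; defaults are the published values.
    max_tss_distance : int
        Strict upper bound on region-to-TSS assignment distance (bp).
    """

    def __init__(
        self,
        probes: pd.DataFrame,
        genes: pd.DataFrame | None = None,
        config: tc.CallerConfig = tc.CallerConfig(),
        max_tss_distance: int = ga.MAX_TSS_DISTANCE,
    ) -> None:
        n_rep = probes.attrs.get("n_replicates")
        self.probes = probes.sort_values(["chrom", "start"], kind="stable", ignore_index=True)
        if n_rep is not None:
            self.probes.attrs["n_replicates"] = n_rep
        self.genes = genes
        self.config = config
        self.max_tss_distance = max_tss_distance

    @classmethod
    def from_files(
        cls,
        probe_path: str | Path,
        gene_bed: str | Path | None = None,
        **kwargs,
    ) -> "BindingModel":
        probes = cio.read_probe_table(probe_path)
        genes = cio.read_gene_bed(gene_bed) if gene_bed is not None else None
        return cls(probes, genes, **kwargs)

    def fit(self, n_permutations: int = 10, seed: int = 0) -> "BindingResults":
        """Run the pipeline: probe stats → triplet caller → FDR → assignment.

        `n_permutations = 0` skips the (comparatively slow) empirical FDR.
        """
        stats = ps.compute_probe_stats(self.probes)
        triplets, regions = tc.call_regions(stats, self.config)
        fdr = (
            tc.estimate_fdr(self.probes, self.config, n_permutations, seed)
            if n_permutations >= 1
            else None
        )
        assignments = target_summary = None
        if self.genes is not None:
            assignments = ga.assign_regions(regions, self.genes, self.max_tss_distance)
            n_pc = int((self.genes["biotype"] == "protein_coding").sum())
            target_summary = ga.summarize_targets(assignments, self.genes, n_pc)
        return BindingResults(
            model=self,
            probe_stats=stats,
            triplets=triplets,
            regions=regions,
            fdr=fdr,
            assignments=assignments,
            target_summary=target_summary,
            seed=seed,
        )


class BindingResults:
    """Fitted results: called regions, FDR, target genes and reports."""

    def __init__(
        self,
        model: BindingModel,
        probe_stats: pd.DataFrame,
        triplets: pd.DataFrame,
        regions: pd.DataFrame,
        fdr: tc.FdrEstimate | None,
        assignments: pd.DataFrame | None,
        target_summary: ga.TargetSummary | None,
        seed: int,
    ) -> None:
        self.model = model
        self.probe_stats = probe_stats
        self.triplets = triplets
        self.regions = regions
        self.fdr = fdr
        self.assignments = assignments
        self.target_summary = target_summary
        self.seed = seed

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_significant_triplets(self) -> int:
        return int(self.triplets["significant"].sum()) if len(self.triplets) else 0

    def tss_profile(self, bin_edges: np.ndarray = tssprofile.DEFAULT_BIN_EDGES) -> tssprofile.TssProfile:
        if self.assignments is None:
            raise ValueError("no gene annotation: fit the model with genes to profile")
        return tssprofile.compute_profile(self.regions, self.assignments, self.model.genes, bin_edges)

    def report(self) -> dict:
        """Machine-readable run report (the JSON the pipeline emits)."""
        rep: dict = {
            "tool": "chipscan",
            "version": __version__,
            "seed": self.seed,
            "config": {**asdict(self.model.config), "max_tss_distance": self.model.max_tss_distance},
            "n_probes": int(len(self.model.probes)),
            "n_replicates": int(self.model.probes.attrs.get("n_replicates", 0)),
            "n_triplets": int(len(self.triplets)),
            "n_significant_triplets": self.n_significant_triplets,
            "n_regions": self.n_regions,
        }
        if self.fdr is not None:
            rep["fdr"] = {
                "observed_regions": self.fdr.observed_regions,
                "mean_null_regions": self.fdr.mean_null_regions,
                "fdr": self.fdr.fdr,
                "n_permutations": self.fdr.n_permutations,
                "zero_observed": self.fdr.zero_observed,
            }
        if self.target_summary is not None:
            ts = self.target_summary
            rep["targets"] = {
                "n_assigned_regions": ts.n_regions_assigned,
                "unique_gene_counts": ts.unique_genes,
                "array_gene_total": ts.array_gene_total,
                "fraction_of_array": ts.fraction_of_array,
                "percent_of_array": ts.percent_of_array,
            }
        return rep

    def summary(self) -> str:
        """Human-readable fit summary."""
        cfg = self.model.config
        lines = [
            "ChIP-chip triplet-caller results",
            "=" * 44,
            f"{'probes':<28}{len(self.model.probes):>16}",
            f"{'replicates':<28}{self.model.probes.attrs.get('n_replicates', '?'):>16}",
            f"{'triplet thresholds':<28}{f'{cfg.p_probe}/{cfg.p_center}/{cfg.p_flank}':>16}",
            f"{'max triplet span (bp)':<28}{cfg.max_span:>16}",
            f"{'significant triplets':<28}{self.n_significant_triplets:>16}",
            f"{'bound regions':<28}{self.n_regions:>16}",
        ]
        if self.fdr is not None:
            lines.append(f"{'empirical FDR':<28}{self.fdr.fdr:>16.4f}")
            lines.append(f"{'  mean null regions':<28}{self.fdr.mean_null_regions:>16.1f}")
        if self.target_summary is not None:
            ts = self.target_summary
            lines.append(f"{'regions assigned to a TSS':<28}{ts.n_regions_assigned:>16}")
            for bt, n in sorted(ts.unique_genes.items()):
                lines.append(f"{'  unique ' + bt:<28}{n:>16}")
            lines.append(f"{'fraction of array bound':<28}{ts.percent_of_array:>15.1f}%")
        lines.append("=" * 44)
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write regions.bed, probe_stats.tsv, targets.tsv and report.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_regions_bed(self.regions, outdir / "regions.bed")
        ps.write_probe_stats(
            self.probe_stats[["probe_id", "chrom", "start", "end", "combined_z", "p_value"]],
            outdir / "probe_stats.tsv",
        )
        if self.assignments is not None:
            ga.write_target_table(self.assignments, self.model.genes, outdir / "targets.tsv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.report(), fh, indent=1, sort_keys=True)
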