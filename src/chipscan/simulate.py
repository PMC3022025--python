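"""Synthetic promoter-array, sequence and gene-set generators with ground truth.

The array generator emulates a two-color promoter tiling design: every
gene carries probes covering −5.5 kb to +2.5 kb around its TSS (60-mer
probes every 200 bp), hybridized in two replicate IP/control channel
pairs.  Intensities are log-normal; a chosen fraction of genes receives
one truly bound region downstream of the TSS whose probes have their IP
channel multiplied by 2^effect_size.  Every generator is a pure function
of its configuration and seed.

Defaults are desk-scale: 2000 genes rather than the 17089 of a real
244k promoter array; the full-scale design is reachable by configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio

GENES_PER_CHROM = 100


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic promoter array."""

    n_genes: int = 2000
    window: tuple[int, int] = (-5500, 2500)   # bp relative to TSS, array design
    probe_length: int = 60
    probe_spacing: int = 200
    n_replicates: int = 2
    bound_fraction: float = 0.05              # fraction of genes with a true region
    region_width: int = 1000                  # bp width of each true region
    effect_size: float = 2.0                  # Δlog2 IP enrichment inside true regions
    noise_sd: float = 0.5                     # s.d. of log-intensity noise
    intensity_baseline: float = 7.0           # mean log intensity (~1100 fluorescence units)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.probe_length <= 0 or self.probe_spacing <= 0:
            raise ValueError("n_genes, probe_length, probe_spacing must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.bound_fraction < 1:
            raise ValueError("bound_fraction must be in (0, 1)")
        if self.region_width <= 0 or self.noise_sd <= 0:
            raise ValueError("region_width and noise_sd must be positive")
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be an increasing (lo, hi) pair")

    @property
    def window_span(self) -> int:
        return self.window[1] - self.window[0]


@dataclass
class GroundTruth:
    """Truth channel emitted alongside every synthetic dataset."""

    bound_gene_ids: list[str] = field(default_factory=list)
    true_regions: pd.DataFrame | None = None       # chrom, start, end, gene_id
    planted_motif: dict | None = None              # consensus + per-sequence positions
    reference_overlap: dict | None = None          # designed set sizes/overlap
    seed: int | None = None

    def to_dict(self) -> dict:
        d: dict = {"seed": self.seed, "bound_gene_ids": sorted(self.bound_gene_ids)}
        if self.true_regions is not None:
            d["true_regions"] = self.true_regions.to_dict(orient="records")
        if self.planted_motif is not None:
            d["planted_motif"] = self.planted_motif
        if self.reference_overlap is not None:
            d["reference_overlap"] = self.reference_overlap
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def simulate_array(
    config: SimulationConfig = SimulationConfig(),
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a synthetic promoter array: probes, gene annotation, truth.

    Genes are packed non-overlapping onto synthetic chromosomes (100 per
    chromosome) with random strands; a ``bound_fraction`` of genes gets one
    true bound region of ``region_width`` bp at a uniform offset within
    +1…+2500 downstream of its TSS (strand-oriented).  Probes whose midpoint
    falls inside a true region have their IP channel scaled by
    2^effect_size.  With ``outdir`` set, writes ``probes.tsv``,
    ``genes.bed`` and ``truth.json`` (byte-identical for a fixed seed).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.window
    span = config.window_span
    gap = 4000  # bp between gene windows: keeps neighbours > array window apart
    pitch = span + gap

    gene_rows = []
    for g in range(config.n_genes):
        chrom = f"chrS{g // GENES_PER_CHROM + 1:02d}"
        w0 = gap + (g % GENES_PER_CHROM) * pitch
        strand = "+" if rng.random() < 0.5 else "-"
        tss = w0 - lo if strand == "+" else w0 + hi  # window covers rel [lo, hi)
        biotype = "miRNA" if rng.random() < 0.01 else "protein_coding"
        gene_rows.append((f"g{g + 1:05d}", chrom, int(tss), strand, biotype, w0))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand", "biotype", "w0"])

    # one true region per bound gene, uniform offset in +1 .. hi - width downstream
    n_bound = int(round(config.bound_fraction * config.n_genes))
    hi_off = hi - config.region_width
    if hi_off < 1:
        raise ValueError("region_width does not fit in the downstream window")
    bound_idx = np.sort(rng.choice(config.n_genes, size=n_bound, replace=False))
    offsets = rng.integers(1, hi_off + 1, size=n_bound)
    true_rows = []
    for gi, off in zip(bound_idx, offsets):
        g = genes.iloc[gi]
        if g.strand == "+":
            rstart, rend = g.tss + off, g.tss + off + config.region_width
        else:
            rstart, rend = g.tss - off - config.region_width + 1, g.tss - off + 1
        true_rows.append((g.chrom, int(rstart), int(rend), g.gene_id))
    true_regions = pd.DataFrame(true_rows, columns=["chrom", "start", "end", "gene_id"])

    # probe layout: tile each gene window
    n_per_gene = (span - config.probe_length) // config.probe_spacing + 1
    probe_rows = []
    for g in genes.itertuples(index=False):
        for j in range(n_per_gene):
            s = g.w0 + j * config.probe_spacing
            probe_rows.append((g.chrom, int(s), int(s + config.probe_length)))
    probes = pd.DataFrame(probe_rows, columns=["chrom", "start", "end"])
    probes = probes.sort_values(["chrom", "start"], kind="stable", ignore_index=True)
    probes.insert(0, "probe_id", [f"P{i + 1:06d}" for i in range(len(probes))])

    # effect per probe: midpoint inside a true region
    mid = probes["start"].to_numpy() + config.probe_length // 2
    enriched = np.zeros(len(probes), dtype=bool)
    by_chrom = {c: d for c, d in true_regions.groupby("chrom", sort=False)}
    for chrom, idx in probes.groupby("chrom", sort=False).indices.items():
        tr = by_chrom.get(chrom)
        if tr is None:
            continue
        m = mid[idx]
        hit = np.zeros(len(idx), dtype=bool)
        for r in tr.itertuples(index=False):
            hit |= (m >= r.start) & (m < r.end)
        enriched[idx] = hit

    scale = np.exp2(np.where(enriched, config.effect_size, 0.0))
    for k in range(1, config.n_replicates + 1):
        ip = np.exp(config.intensity_baseline + rng.normal(0, config.noise_sd, len(probes))) * scale
        ctl = np.exp(config.intensity_baseline + rng.normal(0, config.noise_sd, len(probes)))
        probes[f"rep{k}_ip"] = ip
        probes[f"rep{k}_ctl"] = ctl
    probes.attrs["n_replicates"] = config.n_replicates

    genes = genes.drop(columns="w0")
    truth = GroundTruth(
        bound_gene_ids=[genes["gene_id"].iloc[i] for i in bound_idx],
        true_regions=true_regions.sort_values(["chrom", "start"], ignore_index=True),
        seed=config.seed,
    )
    truth.config = dataclasses.asdict(config)  # type: ignore[attr-defined]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_probe_table(probes, outdir / "probes.tsv")
        cio.write_gene_bed(genes, outdir / "genes.bed")
        truth.to_json(outdir / "truth.json")
    return probes, genes, truth


def simulate_sequences(
    n: int,
    length: int,
    gc: float,
    consensus: str = "CACCAGGG",
    plant_fraction: float = 0.5,
    seed: int = 1,
    outdir: str | Path | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """I.i.d. background sequences with a consensus planted in a fraction of them.

    The consensus is inserted once, at a uniform position, on a uniform
    strand, in ``round(plant_fraction * n)`` randomly chosen sequences.
    """
    if not 0 <= plant_fraction <= 1:
        raise ValueError("plant_fraction must be in [0, 1]")
    if len(consensus) > length:
        raise ValueError("consensus longer than sequence length")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    k = len(consensus)

    n_plant = int(round(plant_fraction * n))
    planted_in = set(rng.choice(n, size=n_plant, replace=False).tolist())
    seqs: dict[str, str] = {}
    planted: dict[str, dict] = {}
    from .motifs import revcomp

    for i in range(n):
        name = f"seq{i + 1:05d}"
        s = "".join(bases[rng.choice(4, size=length, p=probs)])
        if i in planted_in:
            pos = int(rng.integers(0, length - k + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            ins = consensus if strand == "+" else revcomp(consensus)
            s = s[:pos] + ins + s[pos + k :]
            planted[name] = {"position": pos, "strand": strand}
        seqs[name] = s

    truth = GroundTruth(
        planted_motif={
            "consensus": consensus,
            "plant_fraction": plant_fraction,
            "n_planted": n_plant,
            "hits": planted,
        },
        seed=seed,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_fasta(seqs, outdir / "sequences.fa")
        truth.to_json(outdir / "truth.json")
    return seqs, truth


def simulate_reference_sets(
    genes: pd.DataFrame | list[str],
    n_setA_only: int,
    n_setB_only: int,
    n_both: int,
    seed: int = 1,
    outdir: str | Path | None = None,
) -> tuple[set[str], set[str], GroundTruth]:
    """Two gene sets with an exactly designed overlap, sampled from a universe."""
    universe = list(genes["gene_id"]) if isinstance(genes, pd.DataFrame) else list(genes)
    total = n_setA_only + n_setB_only + n_both
    if min(n_setA_only, n_setB_only, n_both) < 0 or total > len(universe):
        raise ValueError("designed set sizes infeasible for the universe")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(universe), size=total, replace=False)
    a_only = {universe[i] for i in picked[:n_setA_only]}
    b_only = {universe[i] for i in picked[n_setA_only : n_setA_only + n_setB_only]}
    both = {universe[i] for i in picked[n_setA_only + n_setB_only :]}
    setA, setB = a_only | both, b_only | both
    truth = GroundTruth(
        reference_overlap={
            "n_universe": len(universe),
            "n_setA": len(setA),
            "n_setB": len(setB),
            "n_overlap": n_both,
        },
        seed=seed,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .overlap import write_gene_set

        write_gene_set(setA, outdir / "setA.txt")
        write_gene_set(setB, outdir / "setB.txt")
        truth.to_json(outdir / "truth.json")
    return setA, setB, truth


#: NRSE-style 21-bp consensus carrying the CACCAGGG core; the basis of the
#: synthetic REST-like PWM shipped for library-matching tests.
REST_LIKE_CONSENSUS = "TTCAGCACCAGGGACAGCGCC"


def synthetic_rest_pwm(dominant: float = 0.85) -> np.ndarray:
    """Synthetic REST/NRSE-like PWM (stand-in built from the public
    21-bp NRSE-style consensus; not derived from any licensed library).

    Each position puts `dominant` probability on the consensus base and
    splits the rest evenly.
    """
    from .motifs import _LOOKUP

    k = len(REST_LIKE_CONSENSUS)
    mat = np.full((k, 4), (1 - dominant) / 3)
    for i, ch in enumerate(REST_LIKE_CONSENSUS):
        mat[i, _LOOKUP[ord(ch)]] = dominant
    return mat


def decoy_pwm_library(n_decoys: int = 20, length: int = 12, seed: int = 0) -> dict[str, np.ndarray]:
    """Random Dirichlet(1,1,1,1) decoy PWMs plus the synthetic REST-like PWM."""
    rng = np.random.default_rng(seed)
    lib = {"REST_like_synthetic": synthetic_rest_pwm()}
    for i in range(n_decoys):
        lib[f"decoy{i + 1:02d}"] = rng.dirichlet(np.ones(4), size=length)
    return lib
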