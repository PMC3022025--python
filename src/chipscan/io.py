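"""Readers and writers for the external formats the pipeline touches.

All genomic intervals are 0-based half-open (BED-native). Every reader
validates strictly and every (write, read) pair is the identity.

Formats
-------
* probe table — tab-delimited with header
  ``probe_id  chrom  start  end  rep1_ip  rep1_ctl  ...  repR_ip  repR_ctl``;
  two columns per replicate hybridization (IP channel, control channel).
* gene BED — BED6 with an optional 7th biotype column
  (``protein_coding`` | ``miRNA`` | ``other``). The TSS of a ``+`` gene is
  the interval start; of a ``-`` gene the interval end − 1.
* regions BED — BED5; score is −log10 of the region's best probe p-value,
  capped at 300.
* FASTA — via Biopython; sequences restricted to A/C/G/T/N.
* PWM library — minimal text format: a ``>name`` line, then one line per
  motif position with 4 tab-separated non-negative frequencies (A C G T);
  rows are renormalized to sum to 1 on read.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BIOTYPES = ("protein_coding", "miRNA", "other")
_SEQ_ALPHABET = re.compile(r"^[ACGTN]+$")

PROBE_KEY_COLUMNS = ["probe_id", "chrom", "start", "end"]


class FormatError(ValueError):
    """A file violated the dialect this package reads or writes."""


def _replicate_columns(columns: list[str]) -> int:
    """Infer the replicate count R from rep{k}_ip / rep{k}_ctl columns."""
    extra = [c for c in columns if c not in PROBE_KEY_COLUMNS]
    r = 0
    while f"rep{r + 1}_ip" in extra and f"rep{r + 1}_ctl" in extra:
        r += 1
    expected = [f"rep{k}_{ch}" for k in range(1, r + 1) for ch in ("ip", "ctl")]
    if r == 0 or sorted(extra) != sorted(expected):
        raise FormatError(
            "probe table header must be probe_id, chrom, start, end followed "
            f"by rep{{k}}_ip, rep{{k}}_ctl pairs; got {columns}"
        )
    return r


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Read a probe table, validate it, and return probes sorted by (chrom, start).

    The returned frame carries ``attrs['n_replicates']``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = [c for c in PROBE_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"probe table missing columns {missing}")
    n_rep = _replicate_columns(list(df.columns))
    intensity_cols = [f"rep{k}_{ch}" for k in range(1, n_rep + 1) for ch in ("ip", "ctl")]

    for row, (start, end) in enumerate(zip(df["start"], df["end"]), start=2):
        if not start < end:
            raise FormatError(f"row {row}: start {start} is not < end {end}")
    bad = ~(df[intensity_cols] > 0).all(axis=1)
    if bad.any():
        row = int(bad.idxmax()) + 2  # +2: header line and 1-based file rows
        raise FormatError(f"row {row}: non-positive intensity")
    if df["probe_id"].duplicated().any():
        row = int(df["probe_id"].duplicated().idxmax()) + 2
        raise FormatError(f"row {row}: duplicate probe_id {df['probe_id'][row - 2]!r}")

    df = df.sort_values(["chrom", "start"], kind="stable", ignore_index=True)
    df.attrs["n_replicates"] = n_rep
    return df


def write_probe_table(probes: pd.DataFrame, path: str | Path) -> None:
    probes.to_csv(path, sep="\t", index=False)


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6(+biotype) gene annotation into (gene_id, chrom, tss, strand, biotype)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"line {lineno}: expected >= 6 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if start < 0 or start >= end:
                raise FormatError(f"line {lineno}: bad interval [{start}, {end})")
            if strand == "+":
                tss = start
            elif strand == "-":
                tss = end - 1
            else:
                raise FormatError(f"line {lineno}: unknown strand {strand!r}")
            biotype = fields[6] if len(fields) > 6 else "protein_coding"
            if biotype not in VALID_BIOTYPES:
                raise FormatError(f"line {lineno}: unknown biotype {biotype!r}")
            rows.append((name, chrom, tss, strand, biotype))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "biotype"])
    if genes["gene_id"].duplicated().any():
        dup = genes["gene_id"][genes["gene_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicated gene_id {dup!r}")
    return genes


def write_gene_bed(genes: pd.DataFrame, path: str | Path, gene_length: int = 1000) -> None:
    """Write gene annotations as BED6+biotype.

    Only the TSS-defining edge of the interval is meaningful; the other
    edge is a nominal `gene_length` downstream.
    """
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            if g.strand == "+":
                start, end = g.tss, g.tss + gene_length
            else:
                start, end = max(0, g.tss - gene_length + 1), g.tss + 1
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\t{g.biotype}\n")


def region_score(best_p: float) -> float:
    """BED score for a region: −log10 of its best probe p-value, capped at 300."""
    return float(min(300.0, -np.log10(best_p)))


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write bound regions as BED5 (chrom, start, end, region_id, score)."""
    with open(path, "w") as fh:
        for r in regions.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{region_score(r.best_p):g}\n")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED5 regions file back into a (region_id, chrom, start, end, score) frame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"line {lineno}: expected 5 BED fields")
            chrom, start, end, region_id, score = fields[:5]
            start, end = int(start), int(end)
            if start >= end:
                raise FormatError(f"line {lineno}: bad interval [{start}, {end})")
            rows.append((region_id, chrom, start, end, float(score)))
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "score"])


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {name: sequence} dict; alphabet restricted to ACGTN."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if not _SEQ_ALPHABET.match(s):
            raise FormatError(f"sequence {rec.id!r} contains characters outside A/C/G/T/N")
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence name {rec.id!r}")
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_pwm_library(path: str | Path) -> dict[str, np.ndarray]:
    """Read the minimal PWM text format; rows renormalized to sum to 1.

    Returns {name: (L, 4) array}, columns ordered A, C, G, T.
    """
    pwms: dict[str, np.ndarray] = {}
    name = None
    rows: list[list[float]] = []

    def flush() -> None:
        if name is None:
            return
        if not rows:
            raise FormatError(f"PWM {name!r} has no rows")
        mat = np.asarray(rows, dtype=float)
        if (mat < 0).any():
            raise FormatError(f"PWM {name!r} has a negative frequency")
        sums = mat.sum(axis=1)
        if (sums <= 0).any():
            raise FormatError(f"PWM {name!r} has a zero-sum row")
        pwms[name] = mat / sums[:, None]

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                if not name:
                    raise FormatError(f"line {lineno}: empty PWM name")
                if name in pwms:
                    raise FormatError(f"line {lineno}: duplicate PWM name {name!r}")
                rows = []
            else:
                if name is None:
                    raise FormatError(f"line {lineno}: PWM row before any >name line")
                vals = line.split("\t")
                if len(vals) != 4:
                    raise FormatError(f"line {lineno}: expected 4 tab-separated values")
                rows.append([float(v) for v in vals])
    flush()
    return pwms


def write_pwm_library(pwms: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, mat in pwms.items():
            fh.write(f">{name}\n")
            for row in np.asarray(mat, dtype=float):
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
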