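"""Gene-set overlap statistics.

The question "do the caller's targets overlap a reference target set (a
SUZ12 / H3K27me3 list, a functional annotation term) more than chance?" is
answered with the one-sided hypergeometric test: with a universe of N
array genes, |A| targets and |B| reference genes, the p-value is
P(X >= k) for X ~ Hypergeom(N, |A|, |B|) and k the observed overlap.
Fold enrichment is observed / expected with expected = |A|·|B|/N.

For many terms at once the p-values are Benjamini–Hochberg adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class OverlapResult:
    n_universe: int
    n_setA: int
    n_setB: int
    n_overlap: int
    p_value: float
    fold_enrichment: float


def test_overlap(setA: Iterable[str], setB: Iterable[str], universe: Iterable[str]) -> OverlapResult:
    """One-sided hypergeometric overlap test of two gene sets in a universe."""
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    a, b = set(setA), set(setB)
    for name, s in (("setA", a), ("setB", b)):
        stray = s - uni
        if stray:
            raise ValueError(f"{name} has {len(stray)} element(s) outside the universe, e.g. {sorted(stray)[0]!r}")
    k = len(a & b)
    n, ka, kb = len(uni), len(a), len(b)
    # upper tail P(X >= k); sf is P(X > k-1)
    p = float(min(1.0, hypergeom.sf(k - 1, n, ka, kb)))
    expected = ka * kb / n
    fold = k / expected if expected > 0 else float("nan")
    return OverlapResult(
        n_universe=n, n_setA=ka, n_setB=kb, n_overlap=k,
        p_value=max(p, 5e-324), fold_enrichment=float(fold),
    )


def enrich_annotation(
    targets: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of a target set against every annotation term.

    Returns one row per term (term, n_universe, n_targets, n_term,
    n_overlap, fold_enrichment, p_value, q_value) sorted by ascending p;
    q-values are Benjamini–Hochberg adjusted over the terms tested.
    """
    uni = set(universe)
    tgt = set(targets)
    rows = []
    for term, members in annotation.items():
        res = test_overlap(tgt, members, uni)
        rows.append(
            (term, res.n_universe, res.n_setA, res.n_setB, res.n_overlap,
             res.fold_enrichment, res.p_value)
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "n_universe", "n_targets", "n_term", "n_overlap", "fold_enrichment", "p_value"],
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values(["p_value", "term"], ignore_index=True)
    else:
        df["q_value"] = []
    return df


def read_gene_set(path) -> set[str]:
    """Read a gene-set file: one gene id per line, '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_gene_set(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def read_annotation(path) -> dict[str, set[str]]:
    """Read a two-column (term, gene) tab-delimited annotation."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            term, gene = line.split("\t")[:2]
            ann.setdefault(term, set()).add(gene)
    return ann
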