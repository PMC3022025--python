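"""Probe-triplet peak calling with an empirical, permutation-based FDR.

The genome is scanned three consecutive probes at a time.  A triplet is
significant when its three probes span at most 1000 bp and either

* at least 2 of the 3 probe p-values are below 0.05, or
* the center probe p-value is below 0.01 and both flanking p-values are
  below 0.1.

All threshold comparisons are strict.  Significant triplets sharing at
least one probe are merged transitively into bound regions, the unit the
downstream modules consume.  The empirical FDR is the mean number of
regions called on position-permuted log-ratios (same permutation applied
to every replicate, within each chromosome) divided by the observed
region count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import probe_stats as ps

RULE_NONE = "none"
RULE_TWO_OF_THREE = "two_of_three"
RULE_CENTER = "center"


@dataclass(frozen=True)
class CallerConfig:
    """Significance thresholds of the triplet rule (defaults as published)."""

    p_probe: float = 0.05   # per-probe threshold of the 2-of-3 rule
    p_center: float = 0.01  # center-probe threshold of the center rule
    p_flank: float = 0.1    # flanking-probe threshold of the center rule
    max_span: int = 1000    # bp, end of third probe − start of first

    def __post_init__(self) -> None:
        for name in ("p_probe", "p_center", "p_flank"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.max_span <= 0:
            raise ValueError("max_span must be positive")


@dataclass(frozen=True)
class FdrEstimate:
    """Empirical FDR of a region set from permuted-null recalls."""

    observed_regions: int
    mean_null_regions: float
    fdr: float
    n_permutations: int
    seed: int
    null_region_counts: tuple[int, ...] = field(default=(), repr=False)
    zero_observed: bool = False  # warning flag: no regions observed, fdr forced to 0


def _check_sorted(stats: pd.DataFrame) -> None:
    key = list(zip(stats["chrom"], stats["start"]))
    if key != sorted(key):
        raise ValueError("probe stats must be sorted by (chrom, start)")


def scan_triplets(stats: pd.DataFrame, config: CallerConfig = CallerConfig()) -> pd.DataFrame:
    """Score every consecutive-probe triplet per chromosome.

    Returns one row per triplet: ``chrom``, ``first`` (positional index of
    the triplet's first probe in `stats`), ``span`` (bp), ``rule`` (which
    p-value rule matched, independent of the span gate) and ``significant``
    (rule matched AND span <= max_span).
    """
    _check_sorted(stats)
    if ((stats["p_value"] <= 0) | (stats["p_value"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")

    chrom = stats["chrom"].to_numpy()
    start = stats["start"].to_numpy()
    end = stats["end"].to_numpy()
    p = stats["p_value"].to_numpy(dtype=float)
    n = len(stats)

    if n < 3:
        return pd.DataFrame(columns=["chrom", "first", "span", "rule", "significant"])

    same_chrom = (chrom[:-2] == chrom[1:-1]) & (chrom[1:-1] == chrom[2:])
    span = end[2:] - start[:-2]
    below = p < config.p_probe
    two_of_three = (below[:-2].astype(int) + below[1:-1] + below[2:]) >= 2
    center = (p[1:-1] < config.p_center) & (p[:-2] < config.p_flank) & (p[2:] < config.p_flank)

    idx = np.flatnonzero(same_chrom)
    rule = np.where(
        two_of_three[idx], RULE_TWO_OF_THREE, np.where(center[idx], RULE_CENTER, RULE_NONE)
    )
    significant = (rule != RULE_NONE) & (span[idx] <= config.max_span)
    return pd.DataFrame(
        {
            "chrom": chrom[idx],
            "first": idx.astype(int),
            "span": span[idx].astype(int),
            "rule": rule,
            "significant": significant,
        }
    )


def merge_triplets(triplets: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Merge significant triplets sharing >= 1 probe into bound regions.

    Consecutive significant triplets whose first indices differ by at most 2
    (i.e. sharing a probe) join the same region; region intervals are the
    union of member-probe intervals.  Region ids are assigned in genomic
    order as R000001, R000002, ...
    """
    sig = triplets.loc[triplets["significant"], "first"].to_numpy(dtype=int)
    sig.sort()
    start = stats["start"].to_numpy()
    end = stats["end"].to_numpy()
    chrom = stats["chrom"].to_numpy()
    p = stats["p_value"].to_numpy(dtype=float)

    rows = []
    i = 0
    while i < len(sig):
        j = i
        while j + 1 < len(sig) and sig[j + 1] - sig[j] <= 2:
            j += 1
        first_probe, last_probe = sig[i], sig[j] + 2
        members = slice(first_probe, last_probe + 1)
        rows.append(
            (
                chrom[first_probe],
                int(start[members].min()),
                int(end[members].max()),
                last_probe - first_probe + 1,
                j - i + 1,
                float(p[members].min()),
                int(first_probe),
                int(last_probe),
            )
        )
        i = j + 1

    regions = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_probes", "n_triplets", "best_p", "first_probe", "last_probe"],
    )
    regions.insert(0, "region_id", [f"R{k + 1:06d}" for k in range(len(regions))])
    return regions


def call_regions(stats: pd.DataFrame, config: CallerConfig = CallerConfig()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: scan triplets then merge into regions."""
    triplets = scan_triplets(stats, config)
    return triplets, merge_triplets(triplets, stats)


def _permute_within_chrom(lr: np.ndarray, chrom: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute log-ratio rows uniformly within each chromosome.

    One permutation per chromosome, shared across replicate columns so the
    replicate structure of each probe measurement is preserved.
    """
    out = lr.copy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        out[idx] = lr[idx[rng.permutation(len(idx))]]
    return out


def estimate_fdr(
    probes: pd.DataFrame,
    config: CallerConfig = CallerConfig(),
    n_permutations: int = 10,
    seed: int = 0,
) -> FdrEstimate:
    """Empirical FDR: mean permuted-null region count over observed count.

    Runs the full caller (probe statistics included) on the observed array,
    then `n_permutations` times on arrays whose log-ratios were permuted
    uniformly at random across probe positions within each chromosome.
    Reproducible for a fixed seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    lr = ps.compute_log_ratios(probes)
    nulls = [ps.fit_null_model(lr[:, k]) for k in range(lr.shape[1])]
    stats = ps.probe_pvalues(probes, lr, nulls)
    _, regions = call_regions(stats, config)
    observed = len(regions)

    rng = np.random.default_rng(seed)
    chrom = probes["chrom"].to_numpy()
    null_counts = []
    for _ in range(n_permutations):
        lr_perm = _permute_within_chrom(lr, chrom, rng)
        perm_nulls = [ps.fit_null_model(lr_perm[:, k]) for k in range(lr_perm.shape[1])]
        perm_stats = ps.probe_pvalues(probes, lr_perm, perm_nulls)
        _, perm_regions = call_regions(perm_stats, config)
        null_counts.append(len(perm_regions))

    mean_null = float(np.mean(null_counts))
    if observed == 0:
        fdr, zero_observed = 0.0, True
    else:
        fdr, zero_observed = mean_null / observed, False
    return FdrEstimate(
        observed_regions=observed,
        mean_null_regions=mean_null,
        fdr=float(fdr),
        n_permutations=n_permutations,
        seed=seed,
        null_region_counts=tuple(null_counts),
        zero_observed=zero_observed,
    )
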