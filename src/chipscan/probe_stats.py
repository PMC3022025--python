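"""Per-probe enrichment statistics for two-color ChIP-chip arrays.

The enrichment signal of a probe is the log2 ratio of the IP channel
(Cy5, ChIP material) to the control channel (Cy3, IgG mock), median-centered
per replicate array.  A robust null — median location, 1.4826·MAD scale — is
fitted per replicate across all probes on the array; per-probe z-scores are
averaged across replicates as z = Σ z_k / √R and converted to a one-sided
upper-tail standard-normal p-value.  Only enrichment (IP above control) can
be significant; depletion maps to p > 0.5.

Under pure-null data this construction is calibrated: the fraction of
probes with p < α is α for any α.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

MIN_PROBES = 10
#: consistency factor making MAD estimate the s.d. of a normal sample
MAD_SCALE = 1.4826

_P_FLOOR = 1e-300  # p-values live in (0, 1]


@dataclass(frozen=True)
class NullModel:
    """Robust location/scale of one replicate's per-probe log-ratios."""

    center: float
    spread: float

    def __post_init__(self) -> None:
        if not self.spread > 0:
            raise ValueError(f"spread must be > 0, got {self.spread}")

    def z(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center) / self.spread


def replicate_channel_columns(probes: pd.DataFrame) -> list[tuple[str, str]]:
    """(ip, ctl) column-name pairs, one per replicate, in replicate order."""
    pairs = []
    k = 1
    while f"rep{k}_ip" in probes.columns:
        pairs.append((f"rep{k}_ip", f"rep{k}_ctl"))
        k += 1
    if not pairs:
        raise ValueError("probe frame has no rep{k}_ip / rep{k}_ctl columns")
    return pairs


def compute_log_ratios(probes: pd.DataFrame) -> np.ndarray:
    """Median-centered log2(IP/control), one column per replicate.

    Row order matches the input probe order.  Refuses fewer than 10 probes:
    the per-array median normalization is unstable below that.
    """
    if len(probes) < MIN_PROBES:
        raise ValueError(f"need >= {MIN_PROBES} probes, got {len(probes)}")
    pairs = replicate_channel_columns(probes)
    out = np.empty((len(probes), len(pairs)), dtype=float)
    for j, (ip, ctl) in enumerate(pairs):
        ip_v = probes[ip].to_numpy(dtype=float)
        ctl_v = probes[ctl].to_numpy(dtype=float)
        if (ip_v <= 0).any() or (ctl_v <= 0).any():
            raise ValueError("intensities must be positive")
        lr = np.log2(ip_v / ctl_v)
        out[:, j] = lr - np.median(lr)
    return out


def fit_null_model(log_ratios: np.ndarray) -> NullModel:
    """Fit the robust null (median, 1.4826·MAD) to one replicate's log-ratios."""
    v = np.asarray(log_ratios, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < MIN_PROBES:
        raise ValueError(f"need >= {MIN_PROBES} finite values, got {v.size}")
    center = float(np.median(v))
    spread = float(MAD_SCALE * np.median(np.abs(v - center)))
    if spread == 0.0:
        raise ValueError("degenerate input: robust spread is zero")
    return NullModel(center=center, spread=spread)


def probe_pvalues(
    probes: pd.DataFrame,
    log_ratios: np.ndarray,
    nulls: list[NullModel],
) -> pd.DataFrame:
    """Per-probe combined z and one-sided enrichment p-value.

    Returns a ProbeStat frame: probe_id, chrom, start, end, per-replicate
    log-ratio columns ``lr_rep{k}``, ``combined_z`` and ``p_value``; row
    order matches the input.
    """
    lr = np.asarray(log_ratios, dtype=float)
    if lr.ndim != 2 or lr.shape[0] != len(probes):
        raise ValueError("log_ratios must be (n_probes, n_replicates)")
    if lr.shape[1] != len(nulls):
        raise ValueError(
            f"replicate count mismatch: {lr.shape[1]} log-ratio columns, {len(nulls)} null models"
        )
    z = np.column_stack([null.z(lr[:, k]) for k, null in enumerate(nulls)])
    combined = z.sum(axis=1) / np.sqrt(z.shape[1])
    p = norm.sf(combined)
    p = np.clip(p, _P_FLOOR, 1.0)

    stats = probes[["probe_id", "chrom", "start", "end"]].copy()
    for k in range(lr.shape[1]):
        stats[f"lr_rep{k + 1}"] = lr[:, k]
    stats["combined_z"] = combined
    stats["p_value"] = p
    return stats


def compute_probe_stats(probes: pd.DataFrame) -> pd.DataFrame:
    """Full probe-level pipeline: log-ratios → per-replicate nulls → p-values."""
    lr = compute_log_ratios(probes)
    nulls = [fit_null_model(lr[:, k]) for k in range(lr.shape[1])]
    return probe_pvalues(probes, lr, nulls)


def write_probe_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False)
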