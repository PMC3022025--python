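"""Comparison of called regions against simulated ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RecoveryStats:
    """Region-level agreement between a call set and the simulated truth."""

    n_true: int
    n_called: int
    n_true_recovered: int        # true regions overlapped by >= 1 called region
    n_called_matching: int       # called regions overlapping >= 1 true region
    sensitivity: float
    precision: float
    boundary_errors: tuple[int, ...]   # max(|Δstart|, |Δend|) per recovered true region
    mean_boundary_error: float

    def boundary_within(self, tol: int) -> float:
        """Fraction of recovered true regions with both boundaries within `tol` bp."""
        if not self.boundary_errors:
            return float("nan")
        return float(np.mean(np.asarray(self.boundary_errors) <= tol))


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def region_recovery(called: pd.DataFrame, truth: pd.DataFrame) -> RecoveryStats:
    """Match called regions (chrom/start/end) against true regions by overlap.

    A true region is recovered when any called region overlaps it; its
    boundary error is taken from the called region with the largest
    overlap.  Precision is the fraction of called regions overlapping any
    true region.
    """
    called_by_chrom = {c: d for c, d in called.groupby("chrom", sort=False)}
    n_true_recovered = 0
    boundary_errors: list[int] = []
    matching_called: set[int] = set()

    for t in truth.itertuples(index=False):
        cand = called_by_chrom.get(t.chrom)
        if cand is None:
            continue
        s = cand["start"].to_numpy()
        e = cand["end"].to_numpy()
        ov = np.minimum(e, t.end) - np.maximum(s, t.start)
        hit = ov > 0
        if not hit.any():
            continue
        n_true_recovered += 1
        matching_called.update(cand.index[hit])
        j = int(np.argmax(np.where(hit, ov, -1)))
        boundary_errors.append(int(max(abs(s[j] - t.start), abs(e[j] - t.end))))

    n_true, n_called = len(truth), len(called)
    return RecoveryStats(
        n_true=n_true,
        n_called=n_called,
        n_true_recovered=n_true_recovered,
        n_called_matching=len(matching_called),
        sensitivity=n_true_recovered / n_true if n_true else float("nan"),
        precision=len(matching_called) / n_called if n_called else float("nan"),
        boundary_errors=tuple(boundary_errors),
        mean_boundary_error=float(np.mean(boundary_errors)) if boundary_errors else float("nan"),
    )
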