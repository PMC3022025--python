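"""Exhaustive consensus-motif enrichment and PWM library matching.

Motif discovery enumerates every k-mer (4 <= k <= 12, canonicalized over
reverse complement so both strands count) and scores it by the number of
sequences containing a hit within ``max_mismatches`` Hamming distance,
against the expectation under an order-0 background model.  With one
hit-or-not event per sequence the null is binomial, and the enrichment
score is z = (obs − exp) / sqrt(var).  This is the same search space a
suffix-tree consensus finder explores at small k; brute force is exact
and cheap at this scale.

The best-per-sequence hit instances of a chosen consensus are stacked into
a position-frequency matrix (pseudocount 0.5), which can then be matched
against a PWM library: best mean per-column Pearson correlation over all
alignment offsets with >= 4 overlapping columns and both orientations,
with an empirical p-value from column-shuffled library matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_LOOKUP = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LOOKUP[ord(_b)] = _i
    _LOOKUP[ord(_b.lower())] = _i

MIN_K, MAX_K = 4, 12
MAX_MISMATCHES = 2
MIN_ALIGNED_COLUMNS = 4


@dataclass(frozen=True)
class Motif:
    """A consensus k-mer with its per-sequence occurrence statistics."""

    consensus: str
    max_mismatches: int
    n_seqs_with_hit: int
    n_seqs_total: int
    enrichment_z: float

    @property
    def fraction(self) -> float:
        return self.n_seqs_with_hit / self.n_seqs_total

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


@dataclass(frozen=True)
class PwmMatch:
    library_name: str
    similarity: float       # mean per-column Pearson r over the best alignment
    offset: int             # library column aligned with query column 0
    orientation: str        # forward | reverse-complement
    n_aligned: int
    p_value: float


# ---------------------------------------------------------------------------
# k-mer encoding


def encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        v = _LOOKUP[ord(ch)]
        if v > 3:
            raise ValueError(f"invalid base {ch!r} in k-mer")
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    return "".join(BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of 2-bit-encoded k-mers, vectorized."""
    codes = np.asarray(codes)
    rc = np.zeros_like(codes)
    for t in range(k):
        digit = (codes >> (2 * t)) & 3
        rc |= (digit ^ 3) << (2 * (k - 1 - t))
    return rc


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def window_codes(seq: str, k: int) -> np.ndarray:
    """Codes of all k-windows of `seq` (forward strand); windows with N dropped."""
    arr = _LOOKUP[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    if len(arr) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win <= 3).all(axis=1)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win[valid] @ weights


def hamming_ball(codes: np.ndarray, k: int, m: int) -> np.ndarray:
    """All codes within Hamming distance <= m of each input code.

    Returns an (n, B) matrix; duplicates are allowed (callers take unique).
    """
    codes = np.asarray(codes, dtype=np.int64)
    cols = [codes]
    if m >= 1:
        for i in range(k):
            clear = codes & ~np.int64(3 << (2 * i))
            for b in range(4):
                cols.append(clear | (b << (2 * i)))
    if m >= 2:
        for i in range(k):
            for j in range(i + 1, k):
                clear = codes & ~np.int64((3 << (2 * i)) | (3 << (2 * j)))
                for b1 in range(4):
                    for b2 in range(4):
                        cols.append(clear | (b1 << (2 * i)) | (b2 << (2 * j)))
    if m > MAX_MISMATCHES:
        raise ValueError(f"max_mismatches must be <= {MAX_MISMATCHES}")
    return np.stack(cols, axis=1)


def hamming_distance_to(codes: np.ndarray, target: int, k: int) -> np.ndarray:
    """Hamming distance of each encoded k-mer to a fixed target code."""
    x = np.asarray(codes, dtype=np.int64) ^ np.int64(target)
    d = np.zeros(len(x), dtype=np.int64)
    for i in range(k):
        d += ((x >> (2 * i)) & 3) != 0
    return d


# ---------------------------------------------------------------------------
# background model


def background_frequencies(sequences: Iterable[str]) -> np.ndarray:
    """Strand-symmetrized order-0 base frequencies of a sequence set.

    Symmetrization (A with T, C with G) makes motif ranking exactly
    invariant under reverse-complementing the input.
    """
    counts = np.zeros(4, dtype=float)
    for s in sequences:
        arr = _LOOKUP[np.frombuffer(s.encode(), dtype=np.uint8)]
        counts += np.bincount(arr[arr <= 3], minlength=4)
    if counts.sum() == 0:
        raise ValueError("background sequences contain no A/C/G/T")
    pi = counts / counts.sum()
    at = (pi[0] + pi[3]) / 2
    cg = (pi[1] + pi[2]) / 2
    return np.array([at, cg, cg, at])


def _ball_probability(codes: np.ndarray, k: int, m: int, pi: np.ndarray) -> np.ndarray:
    """P(random order-0 k-mer lies within Hamming distance m of each code)."""
    codes = np.asarray(codes, dtype=np.int64)
    coef = np.zeros((m + 1, len(codes)))
    coef[0] = 1.0
    for i in range(k):
        p_match = pi[(codes >> (2 * (k - 1 - i))) & 3]
        nxt = np.zeros_like(coef)
        for j in range(m + 1):
            nxt[j] = coef[j] * p_match
            if j > 0:
                nxt[j] += coef[j - 1] * (1.0 - p_match)
        coef = nxt
    return coef.sum(axis=0)


# ---------------------------------------------------------------------------
# discovery


def _validate_k_m(sequences: Mapping[str, str] | Sequence[str], k: int, m: int) -> list[str]:
    seqs = list(sequences.values()) if isinstance(sequences, Mapping) else list(sequences)
    if not seqs:
        raise ValueError("no sequences given")
    if not MIN_K <= k <= MAX_K:
        raise ValueError(f"k must be in [{MIN_K}, {MAX_K}]")
    if not 0 <= m <= MAX_MISMATCHES:
        raise ValueError(f"max_mismatches must be in [0, {MAX_MISMATCHES}]")
    if min(len(s) for s in seqs) < k:
        raise ValueError("k longer than the shortest sequence")
    return seqs


def find_motifs(
    sequences: Mapping[str, str] | Sequence[str],
    k: int = 8,
    max_mismatches: int = 1,
    background: Mapping[str, str] | Sequence[str] | np.ndarray | None = None,
    top: int | None = 50,
) -> pd.DataFrame:
    """Rank every canonical k-mer by per-sequence hit enrichment.

    A sequence "has" a motif when any window on either strand lies within
    `max_mismatches` of the consensus; each sequence counts at most once.
    The expected per-sequence hit probability under the order-0 background
    is 1 − (1 − q)^W for W valid windows, with q the Hamming-ball
    probability of the consensus and of its reverse complement (summed,
    capped at 1).  Deterministic; invariant to sequence order and to
    reverse-complementing every input.

    Returns a frame (consensus, n_seqs_with_hit, n_seqs_total, fraction,
    expected_fraction, enrichment_z) sorted by descending z; `top` rows
    (all when None).
    """
    seqs = _validate_k_m(sequences, k, max_mismatches)
    if background is None:
        pi = background_frequencies(seqs)
    elif isinstance(background, np.ndarray) or (
        isinstance(background, Sequence) and len(background) == 4 and not isinstance(background[0], str)
    ):
        pi = np.asarray(background, dtype=float)
        pi = pi / pi.sum()
    else:
        bg = list(background.values()) if isinstance(background, Mapping) else list(background)
        pi = background_frequencies(bg)

    n_codes = 4**k
    all_codes = np.arange(n_codes, dtype=np.int64)
    rc_table = revcomp_codes(all_codes, k)
    canon_table = np.minimum(all_codes, rc_table)

    # observed: sequences containing each canonical class within m mismatches
    hit_counts = np.zeros(n_codes, dtype=np.int64)
    window_totals: list[int] = []
    for s in seqs:
        codes = window_codes(s, k)
        window_totals.append(len(codes))
        if len(codes) == 0:
            continue
        ball = canon_table[hamming_ball(codes, k, max_mismatches)]
        hit_counts[np.unique(ball)] += 1

    # expected per-class per-sequence hit probability
    q_fwd = _ball_probability(all_codes, k, max_mismatches, pi)
    q_class = np.where(rc_table == all_codes, q_fwd, np.minimum(1.0, q_fwd + q_fwd[rc_table]))

    canonical = all_codes[all_codes <= rc_table]
    q = q_class[canonical]
    expected = np.zeros(len(canonical))
    variance = np.zeros(len(canonical))
    for w, n_w in zip(*np.unique(window_totals, return_counts=True)):
        p_seq = 1.0 - (1.0 - q) ** int(w)
        expected += n_w * p_seq
        variance += n_w * p_seq * (1.0 - p_seq)
    obs = hit_counts[canonical]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(variance > 0, (obs - expected) / np.sqrt(variance), 0.0)

    n_seqs = len(seqs)
    df = pd.DataFrame(
        {
            "consensus": [decode_kmer(int(c), k) for c in canonical],
            "n_seqs_with_hit": obs,
            "n_seqs_total": n_seqs,
            "fraction": obs / n_seqs,
            "expected_fraction": expected / n_seqs,
            "enrichment_z": z,
        }
    )
    df = df.sort_values(["enrichment_z", "consensus"], ascending=[False, True], ignore_index=True)
    return df.head(top) if top is not None else df


def sequence_hits(
    sequences: Mapping[str, str] | Sequence[str], consensus: str, max_mismatches: int = 0
) -> np.ndarray:
    """Boolean per-sequence flags: does the sequence hit the consensus (both strands)?"""
    k = len(consensus)
    seqs = _validate_k_m(sequences, k, max_mismatches)
    target = encode_kmer(consensus)
    target_rc = int(revcomp_codes(np.array([target]), k)[0])
    flags = np.zeros(len(seqs), dtype=bool)
    for i, s in enumerate(seqs):
        codes = window_codes(s, k)
        if len(codes) == 0:
            continue
        d = hamming_distance_to(codes, target, k)
        if target_rc != target:
            d = np.minimum(d, hamming_distance_to(codes, target_rc, k))
        flags[i] = bool((d <= max_mismatches).any())
    return flags


def count_fraction(
    sequences: Mapping[str, str] | Sequence[str], consensus: str, max_mismatches: int = 0
) -> Motif:
    """Exact fraction of sequences containing the consensus on either strand."""
    seqs = list(sequences.values()) if isinstance(sequences, Mapping) else list(sequences)
    flags = sequence_hits(seqs, consensus, max_mismatches)
    n_hit, n_tot = int(flags.sum()), len(flags)

    # enrichment z of this single consensus under the input's own background
    k = len(consensus)
    pi = background_frequencies(seqs)
    code = encode_kmer(consensus)
    code_rc = int(revcomp_codes(np.array([code]), k)[0])
    q = float(_ball_probability(np.array([code]), k, max_mismatches, pi)[0])
    if code_rc != code:
        q = min(1.0, q + float(_ball_probability(np.array([code_rc]), k, max_mismatches, pi)[0]))
    exp = var = 0.0
    for s in seqs:
        w = len(window_codes(s, k))
        p_seq = 1.0 - (1.0 - q) ** w
        exp += p_seq
        var += p_seq * (1.0 - p_seq)
    z = (n_hit - exp) / np.sqrt(var) if var > 0 else 0.0
    return Motif(
        consensus=consensus,
        max_mismatches=max_mismatches,
        n_seqs_with_hit=n_hit,
        n_seqs_total=n_tot,
        enrichment_z=float(z),
    )


# ---------------------------------------------------------------------------
# query PWM from hit instances


def best_hit_instances(
    sequences: Mapping[str, str] | Sequence[str], consensus: str, max_mismatches: int = 0
) -> list[str]:
    """Best hit per sequence, oriented to the consensus strand.

    "Best" = fewest mismatches; ties break forward strand first, then
    leftmost.  Sequences without a hit contribute nothing.
    """
    k = len(consensus)
    seqs = _validate_k_m(sequences, k, max_mismatches)
    target = encode_kmer(consensus)
    instances: list[str] = []
    for s in seqs:
        best: tuple[int, int, int] | None = None  # (mismatches, strand, pos)
        for strand, seq_oriented in enumerate((s, revcomp(s))):
            codes = window_codes(seq_oriented, k)
            if len(codes) == 0:
                continue
            d = hamming_distance_to(codes, target, k)
            ok = np.flatnonzero(d <= max_mismatches)
            if len(ok):
                # window_codes drops N windows; recover positions via a scan
                pos_map = _valid_positions(seq_oriented, k)
                j = ok[np.argmin(d[ok])]
                cand = (int(d[j]), strand, int(pos_map[j]))
                if best is None or cand < best:
                    best = cand
        if best is not None:
            _, strand, pos = best
            src = s if strand == 0 else revcomp(s)
            instances.append(src[pos : pos + k])
    return instances


def _valid_positions(seq: str, k: int) -> np.ndarray:
    arr = _LOOKUP[np.frombuffer(seq.encode(), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    return np.flatnonzero((win <= 3).all(axis=1))


def build_query_pwm(
    sequences: Mapping[str, str] | Sequence[str],
    consensus: str,
    max_mismatches: int = 0,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Position-frequency matrix over the best hit instance of each sequence.

    Rows (positions) are normalized to sum 1 after adding `pseudocount`
    to every cell.
    """
    instances = best_hit_instances(sequences, consensus, max_mismatches)
    if not instances:
        raise ValueError("no hits: cannot build a query PWM")
    k = len(consensus)
    counts = np.full((k, 4), pseudocount, dtype=float)
    for inst in instances:
        for i, ch in enumerate(inst):
            counts[i, _LOOKUP[ord(ch)]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# PWM library matching


def pwm_reverse_complement(pwm: np.ndarray) -> np.ndarray:
    return np.asarray(pwm)[::-1, ::-1]


def _standardize_rows(pwm: np.ndarray) -> np.ndarray:
    """Center and L2-normalize each row; zero-variance rows become zero vectors.

    Mean per-column Pearson correlation between two PWMs then reduces to
    mean dot products of aligned standardized rows (a zero-variance column
    contributes correlation 0 by convention).
    """
    m = np.asarray(pwm, dtype=float)
    c = m - m.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 1e-12, c / norm, 0.0)
    return out


def _best_alignment(dot: np.ndarray) -> tuple[float, int, int]:
    """Best (mean-diagonal, offset, n_aligned) of a query×library dot matrix."""
    lq, ll = dot.shape
    best = (-np.inf, 0, 0)
    for off in range(-(lq - MIN_ALIGNED_COLUMNS), ll - MIN_ALIGNED_COLUMNS + 1):
        diag = np.diagonal(dot, offset=off)
        if len(diag) < MIN_ALIGNED_COLUMNS:
            continue
        sim = float(diag.mean())
        if sim > best[0]:
            best = (sim, off, len(diag))
    return best


def match_library(
    query: np.ndarray,
    library: Mapping[str, np.ndarray],
    n_null: int = 1000,
    seed: int = 0,
) -> list[PwmMatch]:
    """Match a query PWM against a library, ranked by column-correlation similarity.

    For each library PWM the similarity is the best mean per-column Pearson
    correlation over all offsets with >= 4 aligned columns, in both the
    forward and reverse-complement orientation.  The p-value is empirical:
    the add-one-corrected fraction of `n_null` column(position)-shuffled
    library PWMs scoring at least the observed similarity.
    """
    if not library:
        raise ValueError("empty PWM library")
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    q_std = _standardize_rows(query)
    rng = np.random.default_rng(seed)
    matches = []
    for name, pwm in library.items():
        pwm = np.asarray(pwm, dtype=float)
        dots = {
            "forward": q_std @ _standardize_rows(pwm).T,
            "reverse-complement": q_std @ _standardize_rows(pwm_reverse_complement(pwm)).T,
        }
        scored = {o: _best_alignment(d) for o, d in dots.items()}
        orientation = max(scored, key=lambda o: scored[o][0])
        sim, off, n_aligned = scored[orientation]

        n_pos = pwm.shape[0]
        exceed = 0
        for _ in range(n_null):
            perm = rng.permutation(n_pos)
            null_sim = max(_best_alignment(d[:, perm])[0] for d in dots.values())
            if null_sim >= sim:
                exceed += 1
        p = (exceed + 1) / (n_null + 1)
        matches.append(
            PwmMatch(
                library_name=name, similarity=sim, offset=off,
                orientation=orientation, n_aligned=n_aligned, p_value=p,
            )
        )
    matches.sort(key=lambda m: (-m.similarity, m.library_name))
    return matches


def matches_to_frame(matches: Sequence[PwmMatch]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in matches])
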