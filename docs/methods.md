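# Methods

## Scope and model

`chipscan` analyzes two-color promoter tiling arrays in which each probe
carries a pair of fluorescence intensities per replicate hybridization:
the immunoprecipitated chromatin (IP channel) and a mock-antibody control.
The analysis unit chain is probe → triplet → bound region → target gene.
All genomic intervals are 0-based half-open throughout; the convention is
fixed here because upstream array formats do not agree on one.

### Probe error model

The enrichment signal of probe *i* in replicate *k* is
`m_ik = log2(IP_ik / control_ik) − median_i(log2 IP/control)`, the
per-array median centering absorbing global labeling and loading
differences. A robust null is fitted per replicate across all probes:
location = median, scale = 1.4826 × median absolute deviation (the
consistency factor making the MAD estimate a normal s.d.). Probe z-scores
are combined across R replicates as `z = Σ_k z_ik / √R` and converted to a
one-sided upper-tail standard-normal p-value — one-sided because the
question is only where the IP exceeds the control; depletion maps to
p > 0.5 and can never call a region.

Assumptions: log-ratios of unbound probes are approximately symmetric and
unimodal (the robust fit then ignores the enriched minority); replicate
noise is independent; no dye-swap structure (the design keeps IP on one
channel). Spatial artifacts, loess normalization and per-probe variance
shrinkage are deliberately out of scope. Under these assumptions the null
p-values are calibrated: on simulated effect-free arrays the fraction of
probes with p < α matches α for α ∈ {0.01, 0.05, 0.1} (tested).

### Triplet caller

The probe list, sorted by (chromosome, start), is scanned three
consecutive probes at a time. A triplet is significant iff its span (end
of third probe − start of first) is ≤ 1000 bp and either (a) at least 2 of
the 3 probe p-values are < 0.05 or (b) the center p-value is < 0.01 and
both flanks are < 0.1. All comparisons are strict, matching the "lower
than" phrasing of the rule's published form. Design choices where the rule
is under-specified: the span is measured first-probe-start to
third-probe-end; triplets are consecutive probes only (no gapped
combinations); significant triplets sharing at least one probe merge
transitively into bound regions whose interval is the union of member
probe intervals. Region ids are assigned in genomic order. An exhaustive
window-enumeration + union-find oracle in the test suite confirms the
merge on random instances.

### Empirical FDR

For each of B permutations (default 10), log-ratio rows are permuted
uniformly at random across probe positions within each chromosome, with
the *same* permutation applied to every replicate column so the
replicate structure of a measurement is preserved; the entire caller
(null refit included) is re-run and the region count recorded. The FDR is
the mean null count divided by the observed count; with zero observed
regions it is reported as 0 with a warning flag. Fixed seeds make the
estimate bit-reproducible.

**Known property worth stating plainly:** at the published thresholds and
with calibrated probe p-values, the null rate per triplet is
3·0.05²·0.95 + 0.05³ ≈ 0.73%. A 2000-gene array (40 probes per gene)
contains ~74 000 null triplets and therefore produces hundreds of false
regions; the empirical FDR of the default synthetic spike-in run is ≈ 0.8
and region-level precision ≈ 0.23, even while sensitivity for true
regions is 1.0 and most recovered boundaries are within one probe spacing
(mean boundary error ≈ 203 bp at 200 bp spacing, inflated by false-probe
neighbours merging into true regions; the geometric bound of the design
itself is ≤ 170 bp). Historical ChIP-chip pipelines reported FDRs of
~0.005 at these same thresholds because their single-array error models
were strongly *conservative* at the probe level, not calibrated. This
package keeps the calibrated model (it is the honest, testable choice and
the caller consumes only p-values, isolating it); users wanting that
specificity should tighten the thresholds (e.g. `p_probe=0.005`) rather
than rely on the published ones.

### Target assignment

Distance between a region [s, e) and a TSS t is 0 when s ≤ t < e and
min(|t − s|, |t − (e−1)|) otherwise; the TSS is a strand-resolved point
(interval start for +, end − 1 for −) and strand is otherwise ignored for
distance. Each region is assigned to its single closest gene when the
distance is strictly < 10 000 bp (ties → lexicographically smallest gene
id); many regions may share a gene, and target genes are counted
uniquely per biotype. The "fraction of the array bound" is unique
protein-coding targets over protein-coding genes represented on the
array.

### Overlap statistics

Set overlap against a reference list uses the one-sided hypergeometric
upper tail P(X ≥ k) with the array's gene complement as the universe;
fold enrichment is observed/expected with expected = |A||B|/N. The
multi-term variant adds Benjamini–Hochberg q-values. Fisher's one-sided
exact test on the equivalent 2×2 table is used as an independent
cross-check in the tests, never as the implementation. Whether a
genome-wide or array universe is appropriate is a user decision; the
array universe is the default because targets can only be detected among
arrayed genes.

### TSS profile

Every gene is centered at its TSS and oriented so transcription points in
the positive direction; each assigned region is represented by its
midpoint, mapped to r = m − t (+ strand) or t − m (− strand) and binned
over the array design window (−5500 … +2500, 250 bp bins by default).
Counts normalize to a density summing to 1; an empty profile is flagged
rather than silently NaN. The midpoint representation and the bin width
are package choices (the representative point of a region and the plot
binning are not standardized in this assay); density is structurally zero
beyond the design window because no probe can fall there.

### Motif discovery and PWM matching

Discovery enumerates all 4^k k-mers (default k = 8), canonicalized over
reverse complement so both strands count and a sequence contributes at
most one hit per motif. Observed per-sequence hits are counted exactly
via Hamming-ball expansion of every sequence window (mismatch tolerance
m ≤ 2; default m = 1, with m = 0 used when an exact-occurrence fraction
is wanted). At k ≤ 8, m ≤ 2 this brute force covers the same search space
as suffix-tree consensus finders at negligible cost. The expectation uses
an order-0 background fitted on the input (strand-symmetrized, which
makes the ranking exactly invariant under reverse-complementing the
input; an explicit background sequence set or base-frequency vector
overrides). With q the background probability that one window hits the
motif class and W the window count of a sequence, the per-sequence hit
probability is 1 − (1 − q)^W and the enrichment score is the binomial
z = (obs − exp)/√var. For near-palindromic motifs the forward and
reverse-complement ball probabilities are summed without subtracting
their (tiny) intersection — a slight overestimate of the expectation,
i.e. conservative for enrichment.

The query PWM stacks the best hit instance per sequence (fewest
mismatches; ties → forward strand, then leftmost), adds a pseudocount of
0.5 per cell and normalizes rows. Library matching scores each library
PWM by the best mean per-column Pearson correlation over all alignment
offsets with ≥ 4 overlapping columns, in both orientations; columns with
zero variance contribute correlation 0 by convention. The p-value is
empirical: the add-one-corrected fraction of n_null (≥ 100, default
1000) position-shuffled library matrices scoring at least the observed
similarity — a library-free null chosen because curated score
distributions for commercial motif libraries are not redistributable.
The shipped `REST_like_synthetic` PWM is a constructed stand-in: an
NRSE-style 21-bp consensus carrying the CACCAGGG core with 0.85 weight on
the consensus base per position; it is not extracted from any licensed
database.

## Synthetic data: what it emulates, what it does not

`simulate_array` reproduces the promoter-array geometry (−5.5 kb/+2.5 kb
windows, 60-mer probes every 200 bp, two replicate channel pairs),
log-normal intensity noise (σ = 0.5 on the natural-log scale,
baseline e^7 ≈ 1100 fluorescence units) and multiplicative enrichment
(Δlog2 = 2 by default) on one 1-kb region downstream of the TSS
(uniform offset in +1…+2500, echoing the downstream-biased occupancy this
assay family reports) in 5% of genes. Defaults are desk-scale — 2000
genes rather than 17 089 — so the full pipeline runs in seconds; the full
scale is one config field away. Genes sit on synthetic chromosomes 12 kb
apart, so cross-gene assignment ambiguity is rare by construction.

Not emulated: dye bias and dye swaps, spatial array artifacts, probe
cross-hybridization and sequence-dependent affinity, correlated
fragment-length smearing of enrichment across neighbouring probes, and
real promoter sequence composition (motif backgrounds are i.i.d. order-0).
Passing the recovery tests therefore demonstrates the correctness of the
statistics and bookkeeping under the stated noise model — not performance
on real arrays, where the error model's calibration assumptions can fail
in all the ways above.

`simulate_sequences` plants a consensus once per selected sequence at a
uniform position and strand in i.i.d. background of chosen GC;
`simulate_reference_sets` draws two gene sets with an exactly designed
overlap. Every generator is a pure function of (config, seed) and its
emitted files round-trip through the package's own readers byte-stably.

## Numerical choices and degenerate inputs

* p-values are clipped to [1e-300, 1] so downstream −log10 scores stay
  finite; BED region scores cap at 300.
* Probe-statistic computation refuses arrays with fewer than 10 probes
  (median normalization unstable) and degenerate log-ratio vectors with
  zero MAD.
* Thresholds compare strictly everywhere (`<`, never `≤`).
* Assignment ties break to the lexicographically smallest gene id;
  motif-rank ties break alphabetically on the consensus; PWM-match ties
  break alphabetically on the library name. All outputs are deterministic
  given seeds.
* The permutation FDR with zero observed regions reports 0 with a
  `zero_observed` flag instead of dividing by zero.

## Problem sizes used in validation

The shipped validation suite runs the caller-vs-oracle equivalence on 100
random instances of up to 1000 probes, calibration on a 500-gene null
array (20 000 probes), spike-in recovery on the default 2000-gene array
(80 000 probes, 10 permutations), motif recovery on 500 sequences of
500 bp, and library matching against 21 PWMs with 200–1000 shuffles —
sizes chosen so the whole suite completes in well under a minute of
compute per component while keeping Monte-Carlo standard errors small
relative to the tested tolerances.

## Known limitations

* The exact probe-level error model behind the historical "2205 regions /
  FDR 0.005" result is not public; with the calibrated stand-in model the
  published thresholds are permissive (see the FDR discussion above), so
  absolute region counts from real arrays will not be comparable without
  threshold tightening.
* One gene per region and one region width per simulation; no multi-gene
  assignment, no promoter/gene-body partitioning, no per-gene metagene
  scaling.
* The motif module is a consensus-based finder: it will not discover
  motifs better described by a soft PWM than by a k-mer with ≤ 2
  mismatches, and its library p-values are relative to a column-shuffle
  null, not comparable to E-values of dedicated motif-comparison tools.
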