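# Methods

## Coordinate model

All gene models are converted to *coding orientation* at read time: for a
minus-strand gene on a contig of length `L`, contig coordinate `c` becomes
`L − c + 1` on the reverse-complemented contig. Downstream code never sees
strand. Intervals are 1-based inclusive (GFF3 convention). Each intron
carries the pair `(x, y)`: `x` is the last exonic base before the intron,
`y` the first exonic base after it, both in coding orientation; the intron
interior is `x+1 … y−1`. Probes are stored with a 1-based start on the
spliced CDS; the distance from the 3′ end is `d = cds_length − cds_start + 1`.
A probe may match either the spliced CDS (its genomic footprint then jumps
over introns) or the contiguous unspliced coding strand (a probe designed
on a mispredicted model, possibly running into an intron); `map_probe`
distinguishes the two by exact string match at the stated start.

## Cross-hybridization search

The internal search finds ungapped probe-vs-CDS hits: exact 7-mer words
seed diagonals; each seeded run is extended in both directions under
+2/−3 match/mismatch scoring with an X-drop of 20 and trimmed to the
maximal-scoring extent; hits are kept when they are ≥ 20 nt long and
contain a 20-nt sub-window of ≥ 70% identity. Because max-score trimming
can shrink a cluster of scattered matches below 20 nt, a qualifying 20-nt
window that itself contains an exact 7-mer run is additionally reported as
a hit in its own right — this makes the stated sensitivity floor (70% over
20 contiguous bases) hold whenever a seed exists, by construction. Hit
significance is *not* modelled by search-space e-values; the explicit
window rule is the contract. Percent identity is matches/length over the
reported hit. CHI is the maximum percent identity over non-target hits,
zero when none exist; externally supplied (possibly gapped) tabular hits
are used as-is.

Two consequences of this rule are worth knowing. First, against a few
hundred kb of unrelated sequence, almost every 60-mer has some chance
61–84% window (median best non-target identity ≈ 78% on random fixtures),
so a CHI band-1 score is the *baseline* for clean probes when CHI comes
from the internal search, and roughly one probe in ten crosses 85% by
chance; planted 90%-identity windows are still cleanly detected (all
report ≥ 88%). Second, chance windows almost never contain an exact 7-mer
run, so a word-seeded search cannot find them — the oracle-equivalence
test therefore counts a disagreement with the exhaustive sliding-window
aligner as *explained* when every brute-force-only window provably lacks a
7-mer, and requires zero spurious hits and zero seeded misses.

## Hairpin model

Self-folding is evaluated as the minimum free energy over all *single*
hairpins: a contiguous Watson–Crick stem of ≥ 3 bp and a loop of ≥ 3 nt.
The energy is the sum of unified nearest-neighbor DNA/DNA stack terms at
37 °C plus a tabulated hairpin-loop initiation penalty (linear
interpolation between tabulated loop sizes; Jacobson–Stockmayer
extrapolation beyond 30 nt). Bulges, internal loops, multiloops, terminal
mismatches and dangling ends are out of scope: for flagging 60-mers with a
stable fold against a −8 kcal/mol cutoff, the single-hairpin term is the
dominant one, and the restricted model is exactly enumerable, which is what
makes the implementation oracle-testable (the fast inward-extension search
provably visits every structure the exhaustive enumeration does).
Sequences admitting no hairpin return +∞.

## Scoring and selection

Criterion scores follow the table in the README. Boundary conventions:
CHI exactly 60 scores 0 and exactly 85 scores 4 (the scoring table
governs), while the round-2 exclusion is strictly `CHI > 85` (the
admission rule governs); a distance of exactly 500 takes the better bin;
the class-2 "immediately downstream" window is configurable and defaults
to 10 nt from `y` (intron 3′ boundaries vary little, so only a narrow band
is suspect), with a probe starting exactly at `y` in class 2. Round-2
"scores up to 8" is inclusive. Class-3 probes are round-2-admissible only
when *every* intron they overlap is EST-confirmed; no adjacency exemption
is granted for EST-confirmed introns (class 2 stays penalized). The
re-annotation match score is a fifth addend (0 or 20); 20 exceeds every
admission cutoff, so a mismatched probe can never survive selection.
Ties in panel assembly are broken by probe id after distance, making every
selection total and deterministic. Round 2 does not re-apply the 100-nt
3′-proximity exclusion (it is a round-1 rule); CDS whose panel is empty
after both rounds are electable by an in silico rescue (lowest final
score, then distance) mirroring the supervised rescue of the experimental
stage, since re-running an external design service is out of scope.

## Experimental QC

Normalization: per array × channel, background-subtract (`max(fg − bg, 1)`),
log2, median-center; the stored normalized value is back-transformed to the
linear scale so that CVs are scale-free linear-intensity CVs. Technical
replicate spots are collapsed to their median per probe × array × channel
before any filter. Arrays with fewer than 10 spots per channel are a hard
error (degenerate median).

* **SSR/SBR.** `ssr = (fg − bg)/bg_sd`, `sbr = fg/bg` (standard definitions
  of the two named ratios), computed per spot, medianed over technical
  replicates. A "sample" is one array's sample channel. A probe fails when
  `ssr < 10` and `sbr < 2` together in ≥ n−1 of the n samples. Zero
  denominators yield +∞ with a warning.
* **CV.** Sample standard deviation (n−1) over mean of the linear
  normalized intensities across the biological replicates of one
  condition. Strictly greater than 0.75 in any condition fails the probe
  unless an expert rescue list (probe id + mandatory justification, a
  file, never interactive) retains it.
* **M_probe / IQR.** M_probe is the median reference-channel normalized
  intensity of a probe across arrays; quartiles of the member M_probe
  values use linear interpolation between order statistics, and rejection
  is strictly outside `[q1, q3]` (bounds inclusive). Single-probe CDS are
  exempt. Note the mechanism: with four distinct members the interpolated
  quartiles always lie strictly inside the extremes, so the minimum and
  maximum member are always rejected — this filter is intentionally the
  most selective of the cascade. The IQR is computed over member medians,
  not pooled spot intensities.
* **M_array ± 1.5 CI.** Per array, the mean of the CDS's member
  sample-channel intensities and a normal-approximation 95% CI of that
  mean (`1.96·sd/√n`; a t-based interval is available via config,
  but with n = 4 members a t interval can never flag anything — the
  maximum attainable deviation is `1.5·sd` against a `2.39·sd` band).
  "± 1.5 CI" is read as 1.5 × the half-width. A probe fails only when it
  is outside the band on *every* array. With an include-self mean and
  n = 4, a lone extreme outlier sits at `1.5·sd` against a `1.47·sd`
  threshold — a structural 2% margin, so this filter only catches gross,
  systematic outliers, which is its purpose.

Flags are computed independently (never sequential eliminations), so
filter order cannot change any verdict. Election: per CDS, the qualified
probe (no fail flags; a rescued high-CV probe counts as qualified) closest
to the 3′ end, ties by probe id. Probe-deficient CDS get the least-bad
rejected probe (fewest failed filters, then lowest final score, then
distance), flagged as rescued, unless an expert override file names one.
Probes marked `bypass_experimental` are elected on in silico standing
alone.

## Synthetic data

The generator emulates the target study design: ~200 genes (about half
with 1–3 introns, ~30% of introns EST-confirmed), CDS lengths 1300–2400 nt
on both strands of multi-gene contigs, four 60-mer candidates per CDS at
160/260/360/460 nt from the 3′ end, five conditions × four biological
replicates hybridized against a common reference, four replicate spots per
probe. Intensities are multiplicative log-normal:
`value = latent(CDS) · condition · bio(CDS, array) · efficiency(probe) · spot`,
with σ_bio = 0.12 **shared across probes of a CDS on one array** (it is
the same mRNA), σ_probe = 0.10 constant across arrays, σ_spot = 0.05, over
a log-normal background (mean 100, sd field 10). These defaults put clean
per-condition CVs around 0.11 (median), in the range reported for
production two-channel platforms, and were verified by direct simulation
to separate every planted defect from clean probes by a wide margin under
the exact filter definitions above — in particular, a 20× efficiency
outlier in a 4-probe CDS clears the structural 2% CI margin on every
array, while clean-probe excursions decorrelate across arrays and are
essentially never universal. Planted defects are disjoint by gene;
unexpressed (LOW_SNR) genes are planted at the gene level because a single
background-level probe among bright siblings would itself be a true
intensity outlier, confounding per-filter ground truth.

What the generator does **not** emulate: sequence-dependent probe
affinity, dye bias and dye swaps, spatial array artifacts, compositional
realism of genomic sequence (iid uniform bases), condition-correlated
biology beyond a shared per-(gene, condition) factor, and paralogy (high
CHI arises only by planting or by chance windows). Passing the recovery
tests therefore demonstrates that each filter isolates its intended defect
under the stated noise model, not that the thresholds are optimal for any
particular real platform.

## Problem sizes and runtime choices

The bundled study runs at 200 genes × 4 probes (800 probes, 128,000 spot
rows), which exercises every rule while keeping a full pipeline run at a
few seconds; oracle comparisons use 1,000 random probe/subject pairs for
the alignment search and 200 random 30-mers for the hairpin enumeration —
sizes at which the exhaustive oracles are exact and fast. Determinism is
verified byte-for-byte on complete re-runs; all randomness flows from a
single integer seed through `numpy` generators.

## Known limitations

* The hairpin model ignores non-hairpin self-structure (homodimers,
  bulged stems); a probe with a strong bulged fold can evade the −8
  kcal/mol flag.
* CHI from the internal search saturates the 61–84% band on unrelated
  sequence (chance windows), so score 0 on that criterion is effectively
  reserved for probes screened against an empty or curated hit set.
* The M_array filter is structurally insensitive with 4-probe panels
  (2% margin); it exists to catch systematic outliers only.
* One gene model per CDS; no isoforms, no GenBank/EMBL input, no de novo
  probe design.
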