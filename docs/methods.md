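# Methods

This note documents the models and procedures implemented in `cageforge`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Data model

A CTSS table is a sparse map (chromosome, 1-based position, strand) →
per-sample signal. Raw counts are integers; normalized signal is real.
Library sizes are fixed at load time as the per-sample raw totals and are
not recomputed after normalization. All in-memory coordinates are 1-based
inclusive; exported bedGraph/BED12 tracks use 0-based half-open
coordinates, and minus-strand bedGraph values are negated for mirrored
browser display (disable with `negate_minus=False`).

## 5′ G-addition correction

The CAGE protocol's reverse transcriptase frequently adds a template-free G
to the tag's 5′ end, so a fraction ρ of tags map one base upstream (in
transcription direction) of the true TSS.

*Simple mode* shifts a read one base downstream when its first
(transcription-strand) base is a G that does not match the genome — these
additions are certain. The operation is idempotent: a shifted read no
longer starts with a mismatching G.

*Systematic mode* works on per-position counts split into three classes:
first-base G mismatching the genome (`firstG_mismatch`), first-base G
matching (`firstG_match`), and non-G starts (`non_G`).

1. All mismatch-G counts move one base downstream.
2. ρ̂ = Σ mismatch / (Σ mismatch + Σ non-G), using only unambiguous reads.
   If no non-G starts exist the estimate degenerates; it is then clamped to
   m/(m+1) to stay below 1.
3. Positions whose genomic (transcription-strand) base is G are ambiguous:
   a read starting there may be a true TSS or an upstream-shifted addition.
   Sweeping 3′→5′ along each strand, position p donates
   m(p) = min(firstG_match(p), round(ρ̂/(1−ρ̂) · corrected_total(p+1)))
   counts to its downstream neighbour, whose total is already corrected
   when p is visited. Rounding is half-to-even.

Both modes conserve the total tag count exactly. Only single-G additions
are modelled; multi-G cascades are not. The estimator is unbiased when the
base composition one base upstream of observed starts matches that at the
starts themselves; with tags stacked on a handful of promoters this
composition is lumpy (a few fixed upstream bases carry most of the weight)
and ρ̂ acquires a composition-sampling error that more sequencing depth
does not reduce — the benchmark therefore estimates the rate from
dispersed single tags, where the assumption holds.

## Power-law normalization

For each sample, the reverse cumulative r(v) = #{TSS with count ≥ v} is
computed with one entry per distinct count value, and a line is fitted by
OLS to (log10 v, log10 r) for v in the fit range, default [10, 1000]
(the range is a parameter and is logged; using one point per distinct value
keeps long plateaus of identical low counts from dominating the fit).
α_s = −slope, β_s = intercept.

The reference law takes α_ref as the median of per-sample slopes and total
T as the power of ten nearest the median library size on the log scale.
Since the reference distribution must hold T tags,
Σ_{x≥1} 10^β x^(−α) = 10^β ζ(α) = T, so β_ref = log10(T/ζ(α_ref)); this
needs α_ref > 1 (an α ≤ 1 law has infinite mass and is rejected with an
explicit error — sparse datasets whose per-TSS tail is too flat surface
this error rather than producing a bogus reference). Note that a numeric
check of this identity must include the series tail: for α = 1.05 the
terms beyond 10^7 still carry ~43% of ζ(α).

Counts map onto the reference by matching tail counts,
x′ = 10^{(β_s − β_ref)/α_ref} · x^{α_s/α_ref}, a strictly increasing
transform, so within-sample ranks and ties are preserved. tpm
(count/library size × 10^6) and raw pass-through are provided for
workflows that delegate count modelling elsewhere.

## TSS clustering

`distclu` merges same-chromosome, same-strand CTSSs transitively while
neighbour distance ≤ `max_dist` (default 20 bp, the conventional choice of
roughly one tag length). `max_dist = 0` yields one cluster per position.

`paraclu` segments each chromosome strand recursively: for a segment, the
weakest prefix density is min over proper prefixes of (prefix total /
prefix genomic span) and likewise for suffixes; the segment's max density
is the smaller of the two, the segment splits at the minimizing boundary
(prefix preferred on exact ties), and children inherit the parent's max
density as their min density. The root has min density 0; unsplittable
singletons get max density +∞. All visited segments are candidates; those
with max/min density ≥ `min_stability` (default 2), genomic length ≤
`max_length` (default 500 bp) and total ≥ `min_total` survive. Because the
density uses the segment's genomic span, a child can be *less* dense than
the split that produced it; such segments fail the stability filter and
are never reported. Survivors form a laminar family, flattened by keeping
the outermost members (or the densest, behind a flag); `keep_nested=True`
returns the filtered hierarchy for inspection.

`custom` assigns each CTSS to every user window containing it (windows may
overlap; unstranded windows collect both strands); empty windows drop.

Every cluster records its dominant TSS: argmax signal, ties resolved
toward the signal-weighted cluster centre, remaining ties to the 5′-most
position.

## Promoter width

Walking the cluster 5′→3′ in transcription direction, pos_low/pos_up are
the first positions where cumulative signal reaches q_low/q_up of the
total ("reaches" is ≥; this resolves the boundary convention). The
interquantile width |pos_up − pos_low| + 1 with defaults (0.1, 0.9) is
invariant to uniform scaling of the signal, bounded by the full span, and
non-decreasing in the quantile span. Promoters with width ≤
`sharp_max_width` (default 10 bp, exposed and echoed in output metadata —
the sharp/broad boundary is a convention, not a measured constant) are
classified sharp, otherwise broad.

PWM scans use JASPAR count matrices (parsed with Bio.motifs), converted to
probabilities with a total pseudocount of 0.8 split by background and
scored as log2-odds. The default window is −35…−22 bp upstream of the
dominant TSS (the TATA position), scanned in transcription orientation;
the report is 100·(best − min)/(max − min), the best match as a percent of
the attainable score range. Dinucleotide profiles report the frequency of
a class (e.g. WW = AA/AT/TA/TT) at each TSS-relative offset in
transcription orientation, averaged over anchors — downstream WW
periodicity of ~10 bp in broad promoters reflects nucleosome positioning.

## Consensus promoters and expression profiles

Per-sample tag clusters with total ≥ `tpm_threshold` (default 5 tpm) are
projected per strand and merged transitively when separated by ≤ `max_gap`
(default 100 bp; both defaults are conventions for promoter-scale
aggregation). Per-sample totals and dominant TSSs are then recomputed from
the CTSS signal inside the consensus span, including samples whose own
clusters fell below threshold. Consensus building requires normalized
input so cluster totals and spans live on one scale.

Expression profiles are log2(x+1)-transformed and row-standardized
(mean 0, sd 1); rows with max signal below `min_signal` or zero variance
drop. Row-max scaling is available as an alternative. k-means is Lloyd's
algorithm, best of `n_init` seeded random initializations, with the
within-class sum of squares recorded per iteration (non-increasing by
construction). The SOM is an online rectangular-grid map: codebook
initialized from random data rows, Gaussian neighbourhood, learning rate
and radius decaying linearly over 200·n_rows updates from lr0 = 0.1 and
max(xdim, ydim)/2, floored at 10⁻³ and 0.05. Shorter schedules with a
smaller initial learning rate (e.g. lr0 = 0.05 over 100·n_rows updates)
were observed to collapse pairs of well-separated profile groups onto one
unit of a 2×4 grid; the chosen schedule separates eight stage-specific
groups reliably. Given a seed, both algorithms are deterministic; results
carry a digest of the scaled matrix for provenance.

## Promoter shifting

For a consensus promoter and two disjoint sample groups, per-group signal
is summed per position and accumulated 5′→3′. With L the group of smaller
total (ties → group 1) and H the other, the score is
max over scan directions of max_i (F_L(i) − F_H(i)) / total_L,
where the 3′→5′ cumulative is rebuilt from per-position increments. Both
directions are evaluated because initiation can move upstream *or*
downstream of the stronger group's region; the score is ≤ 1, invariant
under group exchange and under uniform rescaling of both groups, and can
be negative when L's region nests inside H's. Promoters where the
lower-total group has no signal are skipped (the ratio is undefined) and
logged.

Significance: the cumulatives are scaled to [0,1] and compared by the
two-sample Kolmogorov–Smirnov statistic D, with the asymptotic tail
p = 2 Σ_{j≥1} (−1)^{j−1} e^{−2j²λ²},
λ = (√n_e + 0.12 + 0.11/√n_e)·D, n_e = n₁n₂/(n₁+n₂), evaluated via
`scipy.special.kolmogorov`. Sample sizes are the groups' raw tag totals in
the promoter when a raw table is supplied, otherwise rounded normalized
totals (K–S sample sizes must be counts). With coarse position support
(heavy ties) the test is conservative — p-values shift toward 1, never
toward 0 — so FDR control is preserved; null calibration is benchmarked in
the near-continuous regime (wide multinomial support) where the asymptotic
formula is calibrated. Benjamini–Hochberg adjustment
(`scipy.stats.false_discovery_control`) runs across promoters; a promoter
is called *shifting* when score ≥ `score_min` (default 0.6; 0.4 is a
lenient preset matching the score's "at least 40% independent
transcription" reading) and FDR ≤ `fdr_max` (default 0.01). Promoters
significant by K–S but below the score threshold are tagged `complex` —
narrowing/broadening patterns rather than clean positional shifts.

## Synthetic data

The generator is seeded once; fixed offsets derive per-stage child
generators so stages are independently reproducible. It emulates exactly
the structures the package measures:

- genomes as i.i.d. base sequences with a set GC content;
- promoter expression magnitudes from a discrete power law
  (P(X ≥ v) = v^(−α), default α = 1.25, the slope regime of real CAGE
  libraries), so the simulated per-TSS reverse cumulative is log-log
  linear;
- sharp promoters (1–3 bp support, ≥ 80% of mass on the anchor) and broad
  promoters (flat-topped, 30–80 bp, tapered edges, a doubled centre so
  the dominant TSS is unambiguous);
- per-sample tag counts multinomial over promoters and then over each
  promoter's profile; uniform background noise at a set fraction of depth;
- planted shifts: a chosen fraction of promoters displace their profile by
  `shift_offset` bp in the second half of the samples;
- 5′ G addition: each tag moves one base upstream with probability ρ, with
  genome-aware bookkeeping of whether the added G matches the genome —
  producing exactly the class counts the systematic correction consumes;
- simulated alignments (perfect-match reads at known 5′ ends, text SAM)
  for the ingestion path.

It does **not** emulate sequence-dependent initiation preferences, real
chromatin or CpG context, mapping errors, or multi-mapping reads. Passing
benchmarks therefore demonstrate the correctness and calibration of the
algorithms under their stated models, not performance on the full
complexity of experimental CAGE libraries.

## Benchmark scales and numerical conventions

Benchmarks use 10⁵ TSSs for slope recovery (fit tolerance ±0.05), 500
promoters × 2 samples at ~500 tags/promoter for shift detection
(sensitivity ≥ 0.9 at 40-bp shifts, ≤ 1 false call), 2000 null replicates
for K–S calibration, 240 profiles for the 2×4 SOM (unit purity ≥ 0.9),
and 10⁴ reads for G-rate recovery (±0.03) — sizes chosen to make the
statistical assertions sharp at desk scale. Ties and degenerate cases:
quantile walks use ≥ with a 10⁻⁹ relative tolerance against float
accumulation; paraclu splits prefer the prefix on exact density ties;
dominant-TSS ties resolve centre-ward then 5′-most; empty inputs raise
errors naming the offending quantity; p-values are clamped into (0, 1].
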