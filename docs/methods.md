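# Methods

## Model and statistics

The compositional signature of a DNA segment is the deviation vector
`Δ_w = (C_w|obs − C_w|e) / C_w|0` over all 4^N words of length N
(default N = 4; N ≤ 6 enforced).  `C_w|0 = W · 4^(−N)` is the uniform
expectation, where `W` counts word positions made solely of A/C/G/T —
windows containing ambiguity codes are skipped and do not increment `W`.
Using `W` rather than sequence length in `C_w|0` keeps `Σ_w Δ_w = 0`
exactly under the un-normalised scheme even for sequences with ambiguous
bases; for clean sequences the two differ only by the `N − 1` edge
positions.

Expected counts follow the normalisation scheme:

* `none` — `C_w|e = C_w|0`;
* `gc_local` / `gc_generalized` — zero-order model
  `C_w|e = W · Π_i p(ξ_i)` with `p(G) = p(C) = gc/2`,
  `p(A) = p(T) = (1 − gc)/2`, gc taken from the window itself (local) or
  from a reference (generalised).  The zero-order form is the simplest
  model consistent with "normalised by GC content"; nothing finer is
  implied by the statistic's definition.
* `markov_k` (k ∈ {1, 2}, off by default) — the standard chain estimate
  `p(w) = p(w[0:k+1]) · Π_i p(w[i:i+k+1]) / p(w[i:i+k])` with sub-word
  frequencies obtained as position-specific marginals of the N-word
  counts.

Ranks are assigned by ascending Δ with ties broken by lexicographic word
order (a stable sort over the lexicographically ordered vector); since
the distance uses absolute rank differences, rank direction is
immaterial, and the tie-break only needs to be deterministic.

* **D(%)** `= 100 (Σ_w |rank_w,i − rank_w,j| − D_min)/(D_max − D_min)`
  with `D_min = 0`, `D_max = 4^N (4^N − 1)/2` (32,640 for N = 4).
* **PS** is D between the direct- and reverse-complement-strand patterns
  of the same segment, with `D_min = 4^N − 2^N` for even N (240 for
  N = 4; reverse-complement-palindromic words necessarily tie) and `4^N`
  for odd N.
* Neither D nor PS is clamped: the printed `D_max` lies below the
  combinatorial maximum of the rank sum (4^(2N)/2), so extreme rank
  reversals can exceed 100%, and perfectly strand-symmetric input gives
  the small negative floor PS = −100·240/32,400 ≈ −0.74.
* **V** `= Σ_w Δ_w² / ((4^N − 1) σ₀)` with `σ₀ = √(0.02 + 4^N/L_seq)`,
  `L_seq` the segment length in bp.  The 0.02 constant is used exactly as
  printed at every N.

**RV and GRV.**  RV is V of the window's pattern normalised by the
window's own GC; GRV the same normalised by the reference GC.  When the
two GCs coincide RV = GRV exactly.  The island-calling ratio is
**GRV/RV** (generalised over local): local normalisation absorbs a GC
shift that the reference model cannot, so the ratio rises above 1
precisely on windows whose composition deviates from the reference
beyond what their own GC explains, and stays at ≈ 1.00 on homogeneous
background.  The opposite orientation (RV/GRV) is mathematically ≤ ~1 on
GC-shifted windows and could never exceed a 1.5 cut-off; both values are
emitted in the stats track so either curve can be plotted.

## The two-tier scan

Reference frames of 300 kbp advance in 100-kbp steps; a chromosome
shorter than one frame is its own single frame, and a full-width terminal
frame anchored at `seq_len − ref_window` is appended when the last
stepped frame falls short of the end.  Each 8-kbp local window (step
2 kbp) is scored against the frame whose centre is nearest its own
(ties to the earlier frame — symmetric, and avoids edge bias).  One
truncated terminal window is evaluated when it adds coverage and spans at
least half the nominal width; anything shorter makes σ₀ unstable.
Windows with no countable word or with GC of exactly 0 or 1 are skipped.

A window is flagged when `D > 1.5`, `PS < 55` and `GRV/RV > 1.5`, all
strict inequalities.  On realistic (structured) backgrounds D and PS sit
well away from pathological values (D ≈ 15–30 against the local
reference, PS ≈ 20–40) and the GRV/RV condition is the discriminative
one; the PS condition vetoes strand-asymmetric loci such as rRNA operons,
which otherwise look compositionally alien.

**Island intervals.**  Runs of overlapping or abutting flagged windows
are merged (`merge_flagged` reports the raw union).  A window flags only
when foreign sequence contributes a substantial share of it, and the end
windows of a run flag with the least foreign content, so the raw union
overestimates the foreign segment by almost a window per side.
`predict_islands` therefore trims each merged run by
`(local_window + local_step)/2 per side` (never below one step of width)
— a conservative estimate of the supported extent — and then drops
islands shorter than `min_island` (default 5 kbp; exactly 5,000 bp
survives, "smaller than" being strict).  Without the trim the minimum-
length filter would be vacuous: no union of 8-kbp windows can be shorter
than 8 kbp.  Verified consequences: a 3-kbp foreign insert flags at most
a four-window run, whose trimmed extent (≤ 4 kbp) is always dropped,
while ≥ 10-kbp islands keep runs of six or more windows and survive.
Boundary refinement beyond window resolution is out of scope.

## Post-call filters and classification

* **Length**: islands < 5 kbp removed (reason `too_short`).
* **PS (rRNA) filter**: an island whose overlapping windows all have
  PS ≥ 55 is removed (reason `rrn_ps`).  Under the calling rule such
  windows cannot flag, so this is a safety net for islands assembled near
  rRNA loci and for externally supplied island lists.
* **External rRNA search**: a documented tabular contract — a standard
  12-column alignment hit file (query = island id, column 11 = e-value)
  is consumed and matched islands removed (reason `rrn_blast`).  The
  aligner itself is deliberately not run here, keeping the package
  download-free.
* **Coding classification**: a feature overlaps an island when their
  half-open intervals intersect by ≥ 1 bp; an island is *coding* when at
  least one overlapping feature is a CDS.  Partial overlap counts, so
  boundary-spanning genes are not missed; requiring full containment is a
  stricter alternative we did not adopt.

## Benchmark protocols

* **False negatives**: each donor island is inserted once (cycling
  forbidden; trials ≤ donors) at a position drawn uniformly from
  `[0, len]`, the caller re-run, and the insert counted as detected when
  the union of calls covers ≥ `overlap_frac` (default 0.5) of the truth
  interval.  The FN ratio is `100 · misses / trials`.
* **False positives**: per trial a fragment of fixed length (default
  28,173 bp, the published mean donor-island length) is copied from one
  chromosome and inserted into the other; with `exclude_existing` the
  source must not overlap a known island and the insertion point must not
  fall inside one (rejection sampling, 1,000 attempts).  Only detection
  of the transferred interval itself counts as a false positive; calls
  elsewhere are ignored.  Fragments are copied, not excised — excision of
  the donor cannot affect recipient scoring.
* The 50%-coverage detection criterion is a convention, exposed as
  `overlap_frac` (at → 0 it reduces to "any overlap", at 1.0 to full
  coverage).  One seeded generator drives each run, so results are
  bit-reproducible for a fixed seed.

## Synthetic chromosomes

A naive i.i.d. generator with near-equal word probabilities would make
rank statistics pure sampling noise (and PS meaninglessly high), so the
default background is a first-order Markov chain with

* exact target GC (stationary base distribution fixed to
  `p(G) = p(C) = gc/2`), default 0.45 (fungal-like);
* seeded "roughness" in the transitions: a log-normal perturbation
  symmetrised under reverse complementation and projected onto the GC
  marginals by iterative proportional fitting.  The dinucleotide joint
  distribution is then invariant under reverse complementation, so
  generated backbones are strand-symmetric (PS ≈ 20–40 at 8 kbp), as real
  chromosome backbones are away from rRNA operons.

Roughness (default **0.25**) sets the island-internal non-GC structure
`S = Σ Δ²` against which the GC-mismatch signal `G` must compete in the
GRV/RV ratio (flagging requires `G ≳ 0.5 S`).  Measured at 8 kbp,
`G ≈ 41–131` for GC contrasts of 0.10–0.15, while `S ≈ 50` at roughness
0.25 (vs ≈ 500 at 0.8).  The default therefore puts the detectability
threshold below a 0.10 GC contrast — the regime the recovery tests
exercise — while keeping the word spectrum several times the sampling
noise of an 8-kbp window.  Islands with GC contrast around 0.10 and
minimal length (10 kbp) sit at the detection boundary by construction;
the standard contrast suite (12/30/20 kbp at GC 0.30/0.55/0.60 against
0.45) is recovered essentially completely.

Other pieces: order-0 models (optionally with explicit base weights; the
purine-rich preset `strand_asymmetric_model` emulates rRNA-operon-like
loci with PS ≈ 90), order-2 models with generally strand-asymmetric rows
(a GC tilt solved by bisection on the stationary distribution keeps the
target GC), island planting at seeded positions with ≥ 50-kbp separation,
and synthetic CDS/rRNA features for the classification tests.

What the generator does **not** emulate: repeats, telomeres/centromeres,
isochore-scale GC gradients, codon structure, and donor DNA whose
atypicality is non-GC (e.g. dinucleotide-biased at identical GC).  The
GRV/RV statistic is by construction blind to the last class, so passing
recovery tests here says nothing about such islands in real data; on real
chromosomes the background S is also larger and more variable than the
synthetic default, which is why the published genome-scale error ratios
(FN ≈ 20%, FP ≈ 11%) are worse than the desk-scale analogues computed by
`scripts/acceptance.py` (FN ≈ 0–7%, FP ≈ 0% under the synthetic
conditions).

## Problem sizes and numerical choices

The acceptance script and test suite run at desk scale, chosen to keep a
full run in minutes on one CPU while preserving every protocol feature:
ten 1-Mbp chromosomes (30 islands) for recovery, 24 donor insertions of
10–30 kbp for the FN protocol, 50 transfer trials of 28,173 bp for the FP
protocol.  The scan itself is exact integer counting (a single encoded
pass with prefix sums; per-window `bincount` over word codes), so scan
results are bit-identical across runs and platforms; all stochastic
components derive from explicit seeds through `numpy` PCG64 generators.

Degenerate inputs are errors, not silent results: sequences shorter than
the word length or the local window, windows with no countable word, GC
of exactly 0/1 under a GC scheme, a zero variance in a requested ratio,
donor sets smaller than the requested trial count, and rejection-sampling
caps all raise typed exceptions.
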