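# Methods

## Scope and model

`tfbench` evaluates transcription-factor binding models — position weight
matrices (PWMs) — against three kinds of measurement: protein-binding
microarray (PBM) probe intensities, HT-SELEX per-cycle read samples, and
ChIP-seq peak sets. It does not *learn* models; matrices are consumed from
standard text formats and scored.

The central quantity is the **sum occupancy score**: for a sequence *s* and
a PWM Θ of length *k*,

    S(s; Θ) = Σ_j Π_{i=1..k} Θ_i(s[j+i]),

summed over every length-*k* window *j*. This is the expected number of
bound windows under an independent-sites, low-concentration approximation;
it is computed as a plain probability product (not in log space), which is
numerically safe because window products are summed, never chained. Since
probes, oligos and genomic DNA are double-stranded, the default
`strand_mode="both"` adds the score of the reverse complement; `"given"`
scores the literal strand only, and both conventions are exposed because the
right choice depends on how the upstream assay was read out. When several
PWMs are reported for one TF, a sequence receives the **maximum** score over
the set; members longer than the sequence are skipped.

Other conventions fixed here:

* **N bases** are rejected by default; in lenient mode (used for genomic
  FASTA) an N contributes the uniform 0.25 to its windows.
* **Trimming** to the *n* most informative positions takes the contiguous
  window maximising summed information content (2 − entropy, bits); a
  non-contiguous selection would not be a scannable PWM. Ties go to the
  leftmost window.
* **Consensus** is the per-column argmax with ties broken in A<C<G<T order.
  All tie-breaks in the package (top-k lists, top peaks, trimming) are
  deterministic so downstream results are exactly reproducible.

## PBM evaluation

A probe is called **positive** when its intensity exceeds the array median
by more than 4·(MAD/0.6745), where MAD is the raw median absolute deviation
and 0.6745 is the MAD of the standard normal (so MAD/0.6745 estimates σ).
The inequality is strict: boundary equality is negative, the conservative
reading. Metrics:

* **AUC** — the rank statistic (probability a random positive outscores a
  random negative, ties ½), identical to the trapezoidal area under the ROC.
* **Sensitivity at 1% FPR** — the TPR at the most permissive threshold with
  FPR ≤ 0.01 on the step-function ROC; tied scores enter the predicted set
  together; no interpolation.
* **Spearman on positives** — rank correlation restricted to positive
  probes; undefined (reported missing, never 0) with fewer than 3 positives
  or constant input.

**8-mer intensity scores**: the mean (or median) intensity over probes
containing the word on either strand; a probe contributes at most one
observation per word no matter how many times the word occurs, because a
probe's intensity is one measurement of everything it carries. Words and
their reverse complements are kept as separate keys; under both-strand
counting their scores coincide, so nothing is lost and directional analyses
remain possible.

## HT-SELEX statistics

k-mer counting is **read-strand only** by default: oligo synthesis and
sequencing are both strand-specific, so A/T (and C/G) frequencies need not
match, and collapsing strands would hide exactly the composition biases the
audit measures. Frequencies are normalised by total k-mer windows, making
each cycle's table a probability vector; with a fixed oligo length this
differs from a per-read denominator only by a constant and produces the same
ranking. Between-cycle **ratio** scores (freq in cycle *i* over cycle
*i*−1) drop words absent from the earlier cycle: the correlation analyses
need finite scores, and an infinity would capture top-k lists spuriously.
At the whole-oligo level the enrichment ratio of a previously unseen oligo
*is* reported as infinite — there it is the signature of interest.

## Cross-technology comparison

For each cell of the (cycle × top-list source × SELEX score kind) grid, the
top-100 8-mers of the source table are correlated (Pearson) across the two
technologies. Keys missing from the other table are dropped and counted,
not imputed zero — zero is meaningless on the ratio scale. Cells with fewer
than 3 shared keys, or a constant side, are undefined and omitted. The best
cell maximises correlation with deterministic tie-breaks (lowest cycle, PBM
source first, frequency first). Late cycles can be excluded from the grid
via `max_cycle` when their coverage is too sparse to be comparable — a
reporting decision, not hard-coded behaviour.

**Approximate 8-mer matching** (for "did SELEX find the PBM top word")
allows up to 2 mismatches under alignment offsets up to ±2; mismatches are
counted only inside the overlap, the only consistent reading of an offset
between equal-length words. The reverse complement of the second word is
tried as well by default (a word and its complement are the same
double-stranded site); the flag exists because either convention is
defensible.

A model set is called a **failure** against a reference panel when its AUC
trails the panel mean by at least 0.1 (boundary inclusive, with a 1e-9
tolerance so the inclusive boundary survives float rounding).

## ChIP evaluation

Coordinates are 0-based half-open (BED). The positives are the 500
smallest-p peaks, taking [c−125, c+125) around each center c (interval
midpoint; summit annotations are not assumed). Negatives are [c+300, c+550)
on the plus strand ("downstream"; an upstream mode mirrors it), so each
negative shares local GC and k-mer statistics with its positive. Pairs
whose windows run off the contig are dropped whole, keeping classes paired,
and the drop count is logged.

## Bias audit

8-mers are classified poly(A)/poly(C) (≥7 of the base), palindrome (equal
to own reverse complement), or other; for 8-mers the categories are provably
exclusive (a palindrome pairs A↔T and C↔G, capping any base at 4), and the
poly checks take precedence for other k. The census over all 65 536 8-mers
is 25 + 25 + 256 + 65 230.

The **uniform-null p-value** for a category's median frequency is
Monte-Carlo: only the joint distribution of the category's cells plus one
remainder cell is simulated (a margin of a multinomial is multinomial), with
the add-one estimator (1+exceedances)/(1+n_mc). A closed form for the
median of dependent multinomial cells is not practical; the seed is a
parameter so reported p-values are reproducible.

The **K–S rate-of-change test** compares palindromes' per-word frequency
ratios between two cycles against the ratios of `other`-category words
(poly categories excluded from both sides), asymptotic p by default with a
permutation option for small counts.

**False oligos**: among the 100 most frequent last-cycle oligos, those
containing no experiment seed on either strand within 1 mismatch. Their
characterisation: composition skew (top base ≥ 50% of the oligo) and
absence from the previous cycle, plus per-oligo enrichment ratios.

## Synthetic data generator

All three assays are generated from one hidden PWM so every pipeline stage
can be checked against known truth. Defaults were chosen once to mimic the
technologies at desk scale; they are study conditions, not fitting knobs.

* **Ground-truth PWM**: symmetric-Dirichlet columns, concentration 0.1
  (mean column information ≈ 1.5 bits, typical of strong published motifs).
  Each column is redrawn until the preferred base beats the runner-up by
  0.2 in probability, so the consensus is well defined at every position —
  as it is in published matrices for strong motifs.
* **PBM arm**: 40 000 random 36-bp probes (the coverage of a real
  all-10-mer array: each 8-mer lands on ~32 probes, which is what averages
  away the "hitchhiker" inflation of words sharing a probe with a strong
  site); intensity = (baseline 100 + gain 5000 × occupancy) × lognormal
  noise (σ = 0.25) — microarray noise is classically multiplicative.
* **SELEX arm**: a 100 000-molecule pool of 16-bp oligos, 4 cycles, 5 000
  sequenced reads per cycle (read depth far below the 65 536 8-mers, as in
  the real assay). Per cycle, each oligo's expected copy number is
  multiplied by `(occupancy + 1e-6)^0.3` times a per-base amplification
  factor, then the pool is multinomially resampled at fixed size and the
  reads are a further multinomial subsample — so drop-out, drift and
  overspecification all emerge from finite sampling. The exponent 0.3 is
  calibrated so the consensus enriches roughly two orders of magnitude per
  cycle (dominance by cycle 3–4, as observed in practice); the additive
  floor is the TF's non-specific background binding, which keeps unselected
  oligos surviving at a composition-independent rate — without it, the
  huge dynamic range of occupancy products imposes a spurious composition
  dependence on the background that has no biophysical counterpart. Pool
  size matters: far below ~10⁵ molecules, so few pool members carry the
  consensus that founder lineages distort k-mer ranks.
* **Bias knobs**: per-base amplification weights act multiplicatively on
  oligo composition (the minimal mechanism producing poly(C)-type
  enrichment without TF involvement); contaminant oligos amplify
  geometrically (factor 8 per cycle from roughly single-molecule abundance),
  matching the observed false-oligo signature of surging from a low or zero
  count. A helper generates contaminants guaranteed seed-free.
* **ChIP arm**: a random genome, 500 peaks laid out one per slot so
  evaluation windows can never collide; with probability `plant_prob` a
  site sampled from the PWM is written within ±50 bp of the peak center,
  and planted peaks get smaller p-values.

Every generator is bit-reproducible under (seed, config); each stage draws
from an independent seeded stream, so changing one knob never perturbs
another stage's random numbers.

### What the generator does *not* emulate

No PCR chemistry or polymerase errors, no read-quality model, no probe
design structure (real arrays are de Bruijn sequences, not i.i.d. random),
no chromatin or co-factor effects in the ChIP arm, and binding is strictly
PWM-additive (no dinucleotide or shape terms). Passing tests therefore
demonstrate that the *machinery* is correct and that the qualitative
phenomena (enrichment, overspecification, composition bias, false oligos)
follow from the modelled mechanisms — not that real experiments will show
them with the same magnitudes.

## Validation design and problem sizes

Tests validate every statistic against an independent brute-force
implementation on small instances (window-product enumeration, pair-counting
AUC, threshold-scan sensitivity, ECDF-gap K–S, pad-and-slide word matching,
exact binomial oracle for the uniform-null test), and the generators against
recovery experiments: consensus recovery from cycle-3 frequencies and from
PBM 8-mer averages (20 seeded runs each), the interior maximum of the
correlation-with-truth profile across cycles under limited reads (1 000
reads/cycle, 5 cycles — chosen to be clearly read-limited), the PBM-vs-SELEX
source reliability gap averaged over the comparison grid, poly(C)
growth under a C-favouring amplification bias (50 000 reads/cycle there,
because category medians from 5 000-read tables are depth-censored; the
dense early transitions are compared), contaminant recovery
(sensitivity/specificity of the false-oligo detector), and the ChIP
planted/unplanted AUC contrast (sharp, concentration-0.02 motif for the
planted case, where sampled sites are essentially consensus). The
correlation-with-truth profile imputes frequency 0 for unobserved words —
an observed frequency of an absent word is genuinely zero, and dropping
such words would mask exactly the overspecification being measured.

The idealized deep-coverage regime used for the strong-correlation check
(pool 500 000, 50 000 reads/cycle, 14-bp oligos, noise-free intensities,
median 8-mer statistic) exists because at realistic desk scale the best
cross-technology correlation sits near 0.6–0.9: hitchhiker words and
founder sampling bound it, in the same way real PBM/SELEX correlations
plateau well below 1.

## Known limitations

* Occupancy is a sum of products of probabilities; for very long PWMs
  (k ≳ 30) window products underflow toward 0 — irrelevant at motif scale
  but worth knowing.
* `kmer_intensity_scores` holds one observation list per word; for k ≫ 8 on
  large arrays memory grows accordingly.
* The uniform-null test models category cells as exchangeable multinomial
  cells; it does not condition on the observed total of the category.
* CLI `compare-kmers` recomputes PBM 8-mer scores from the probe table on
  every run; cache the k-mer table via the library API for repeated grids.
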