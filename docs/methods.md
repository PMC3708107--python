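# Methods

## Problem and model

A single-nucleotide substitution can reorganize the equilibrium ensemble of
RNA secondary structures and thereby disturb the function of a structured
element — a riboSNitch. `rnasnip` quantifies this effect without ever
committing to a single predicted structure: wild-type and mutant sequences
are folded into base-pair probability matrices `P` and `P*` under the
McCaskill partition function, and the two ensembles are compared.

Because substitutions preserve length, positions correspond one-to-one and
the comparison needs no alignment (indels are out of scope). The measures
are:

* Euclidean distance `d` and Pearson correlation `r`, applied to the full
  matrices, to the per-position pairing probabilities `pi_i = sum_j P_ij`,
  or to the upstream/downstream split `xi^< / xi^>` (matrix entries are
  summed once per unordered pair; the `xi` vector concatenates the two
  components and omits the redundant unpaired term).
* the ensemble distance `delta`, with
  `delta^2 = sum_psi (p_x(psi) - p_x*(psi))^2`, computed from partition
  functions with all energies doubled (equivalently, the Boltzmann constant
  halved) plus a cross term over structures formable by both sequences with
  pair energies averaged. `delta` is exposed for the builtin model only,
  where it is exact; it is retained chiefly because the correlation study
  (below) shows it measures something different from the `P`-derived
  distances.

## Localization

Structural effects of substitutions are predominantly local, and long-range
pair predictions are the least reliable part of any fold. The score of
record is therefore the restriction of `d` (or `r`) to the interval `[k, l]`
where the two ensembles differ most:

* `M[i, k]` (probability that `i` pairs within `[k, i-1]`) and `N[i, l]`
  (within `[i+1, l]`) satisfy one-step recursions and give any restricted
  marginal as `pi_i[k, l] = M[i,k] + N[i,l]` in O(1).
* Intervals must be self-contained: the expected number of pairs inside,
  `W_in`, must outweigh the expected number crossing the boundary,
  `W_cross`, i.e. `W_in >= alpha * W_cross` with `alpha = 1`, in the
  wild-type or the mutant. Pairs below `p_thr = 0.01` are ignored
  throughout — in the distances and in the self-containedness sums alike
  (one uniform filter; the alternative of filtering only the distances was
  rejected for simplicity and symmetry).
* `d_max` / `r_min` maximize/minimize over all admissible intervals of
  length >= 50. The search evaluates every interval at once: per-interval
  sums that depend on one bound reduce to prefix sums, and the coupled term
  `sum_i A[i,k] B[i,l]` over `k <= i <= l` reduces to three matrix products
  (`A^T B` minus the `i < k` and `i > l` shells), so the full O(n^2)
  interval scan costs a handful of BLAS calls. Agreement with exhaustive
  per-interval recomputation is part of the test suite.
* Ties go to the smallest `k`, then smallest `l`, for determinism. If every
  interval has an undefined correlation (featureless ensembles), the
  pipeline reports `r_min` as NaN with P = 1 rather than failing the run.

For screening-scale work the exact search is replaced by the scanning
measure `d#`: fold with a sliding window (W = 200) and maximal pair span
L = 120, integrate the squared difference of span-limited marginals over a
short window of h' = 20 positions (typical size of miRNA/protein binding
sites), slide by prefix sums, and re-optimize exactly only at the peak
position `k*`, with the right end capped at `k* + h'' + h'` (h'' = 120) so
the re-optimization never uses spans the scanning fold could not see. The
integration window is `[k, k + h' - 1]` (exactly h' positions).

## Folding backends

* **thermodynamic** — ViennaRNA's RNAfold/RNAplfold partition functions
  (Turner energies) through the scripting interface; this is the backend for
  real analyses and for the calibration results.
* **builtin** — an exact McCaskill inside/outside dynamic program over a
  pair-additive model: e(GC) = -3 RT, e(AU) = -2 RT, e(GU) = -1 RT, hairpin
  loops >= 3. The model is intentionally minimal: it has a nontrivial
  ensemble but admits exhaustive structure enumeration, so every derived
  quantity (P, marginals, restricted measures, delta) is verified against
  direct Boltzmann sums at n <= 12 to 1e-8. Partition values are rescaled
  per nucleotide (pair weights divided by kappa^2, unpaired positions by
  kappa, with kappa from a crude ground-state bound and automatic retry) to
  stay inside double precision; without stacking or loop penalties this
  model frays helix ends more than Turner energetics do.

The builtin scanning fold averages each pair over all fully contained
windows, with the window set simply truncated at the sequence ends (the
reference scanning implementation's end handling is not documented; this is
our choice). Window-averaged matrices can have per-position probability
sums slightly above 1 because each pair is normalized by its own window
count; the sum-to-one invariant is therefore enforced for global folds only.

## Empirical P-values

An observed `d_max` is meaningful only against the null distribution of the
same score for random substitutions in random sequences. Nulls are
simulated per condition — sequence length, GC content, substitution
position — through exactly the scoring path used for real variants, then
summarized parametrically:

* distances: `x = 1 - log d` is fitted by a Gumbel distribution (maximum
  likelihood); since the transform is decreasing,
  `P(D >= d) = F_Gumbel(1 - log d; mu, sigma)`. At `x = mu` this gives
  `P = exp(-1)`. Zero distances are excluded from fitting and assigned
  P = 1 (no structural change at all).
* correlations: `y = (r + 1)/2` is fitted by a beta distribution;
  `P = F_beta(y; a, b)`.

The fits are certified by the correlation between fitted and rank-based
P-values on a simulated null (the `fit_quality_study`), and a
Kolmogorov–Smirnov statistic is recorded per table cell as a warning — the
extreme upper tail of the distance distributions is known to fit
imperfectly, which affects only scores whose empirical P-values could not
be estimated accurately anyway.

Tables are JSON documents keyed by (length, GC bin, relative position bin).
GC bins follow the generation targets 0.2–0.8 in steps of 0.1; a query uses
the GC fraction of the exact folded window, clamped to [0.2, 0.8], and maps
to the nearest tabulated cell, as does the folded length and the relative
substitution position (deciles at full resolution; shipped defaults
collapse positions to one central bin). The full-scale grid of the original
tables (lengths 400–1600 by 100, per-nucleotide positions, thousands of
sequences per cell) is reproducible with the same code given compute; the
defaults here are desk-scale.

## Operating modes

1. **Mode 1** (short inputs): fold `[pos - winsizeFold, pos + winsizeFold]`
   (default 200, allowed 200–800 in steps of 50) globally for wild-type and
   mutant, report `d_max` and `r_min` with P-values. Windows are clipped at
   sequence ends, not re-centred; the P-value lookup uses the actual folded
   length and window GC. Multi-substitution variants are centred on their
   mean position.
2. **Mode 2** (long inputs): scanning fold, `d#` profile within h'' of the
   variant, exact re-optimization at the peak; P-value from the
   (d_max, scanning) table.
3. **Mode 3** (screening): for all `3n` substitutions, stage-1 P from `d#`
   against the (d#, scanning) table; candidates with P < t1 = 0.4 are
   re-scored through the mode-1 path (wild-type window folds are cached and
   shared) and reported when P(d_max) < t2 = 0.1. Reported intervals are
   merged into maximal overlapping regions with occurrence counts. Stage 1
   deliberately uses the `d#` score, not the re-optimized one — the
   re-optimized score is what stage 2 recomputes accurately.

Mode 1 and mode-3 stage 2 are one code path, as are the null sampler's
scoring routes, so P-values are calibrated against the identical
computation that scores a real variant. The default profile basis for
`d_max`/`r_min` is `pi` (the per-position pairing probabilities); the `P`
and `xi` bases are available through the library API and rank variants
nearly identically (see the correlation study).

## Synthetic data and what tests show

`fixtures.make_hairpin_fixture` builds a perfect GC stem (random G/C with
same-letter runs capped at two) around an A-loop inside random A/U context.
The A/U context insulates the stem: under the pair-additive builtin model a
GC stem in uniform-ACGU context frays at the ends because freed stem bases
re-pair with context G/C at zero energy cost. With insulation every
designed pair carries probability > 0.5 (builtin) or > 0.95 (Turner), so
"stem-breaking" and "loop" substitution labels are unambiguous. Real
riboSNitches live in thermodynamically marginal structures; passing the
fixture tests shows the machinery ranks designed disruptions correctly, not
that the method's sensitivity on natural sequences equals its sensitivity
here.

Random-sequence nulls are i.i.d. with Pr(G) = Pr(C) = gc/2; they reproduce
the composition, but not the dinucleotide correlations or selected
structure, of natural transcripts. Calibration results on these nulls
(uniform P-values, ~10% flagged at the 0.1 threshold) therefore certify
internal consistency of the P-value machinery.

## Simulation sizes and numerics

The published calibration used thousands of sequences per grid cell
(~156 CPU-years in total). The desk-scale defaults used by the test suite
and `scripts/acceptance.py` are: 500 null draws for the global-fold
fits/tables (250 in the test suite), 300 for the scanning-fold ones, and
three 400-nt sequences screened on staggered every-third-position subsets
(1200 pooled variants covering all positions) for the null screening rate;
these sizes keep a complete run within minutes on one core while leaving
the fit-quality correlations' sampling error well inside the tolerances
asserted.

A calibration fact worth knowing when interpreting screening output: on
unstructured null sequences the stage-1 and stage-2 P-values correlate
only moderately (Spearman ≈ 0.74 in our simulations), so the two-stage AND
rule flags ~5–6% of null variants rather than the nominal 10% implied by
the stage-2 threshold alone — the first stage is not lossless. Each stage
is individually calibrated (≈40% pass t1, ≈10% of all variants would pass
t2); on strongly structured inputs the two scores agree much more closely
and the flagged fraction approaches the stage-2 level.

Numerical choices: probabilities below 1e-5 are dropped when extracting
ViennaRNA matrices; variance terms below 1e-14 mark a correlation as
undefined (an explicit error, never NaN propagation, when either input is
constant); admissibility comparisons use a 1e-9 slack; `d^2` grids are
clipped at zero before the square root; beta fitting clips the transform
to (1e-9, 1 - 1e-9) to keep the likelihood finite.

## Known limitations

* The builtin energy model is for verification, not realism; energetics,
  and hence absolute scores, differ from the Turner model.
* Only substitutions are supported; indels would change coordinates and
  require alignment-aware comparison.
* The ensemble distance `delta` has no thermodynamic-backend and no
  localized implementation here.
* A correlation-based scanning measure is deliberately absent (it performs
  poorly as a screening statistic).
* Background tables shipped by tests are single-cell; genuinely
  heterogeneous inputs need tables built across the length/GC/position grid.
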