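# Methods

This note documents the models, the numerical choices, and the synthetic
study conditions behind `tripeak`, in the order the pipeline runs.

## Background count model

Unique-tag counts in non-overlapping windows of the maximum fragment size
*d* (default 250 bp) are modelled as a Gamma-Poisson mixture: each window's
Poisson rate is itself Gamma-distributed because the genome is not a
uniform substrate — nonspecific TF binding, chromatin accessibility, and
mappability all modulate the local rate. Marginally the count is negative
binomial, P(X = x) = C(x+r−1, x) p^r (1−p)^x with mean r(1−p)/p and
variance r(1−p)/p². Zero-count windows are excluded (zeros largely reflect
non-mappable sequence), so the model is fitted zero-truncated on support
x ≥ 1 with mass divided by 1 − p^r.

Maximum likelihood runs on the transformed parameters (log r, logit p) with
L-BFGS-B (function tolerance 1e-12), initialized from method of moments on
the truncated sample; the rare precision-loss stop of L-BFGS-B is accepted
as converged since it occurs at the optimum. A zero-truncated Poisson is
fitted alongside (its rate solves λ/(1−e^−λ) = sample mean by bisection)
and both log-likelihoods and AICs are reported, so a user can see how much
over-dispersion the data carry. When data are truly Poisson, the
Gamma-Poisson fit collapses onto it (log-likelihoods agree within ~2
units); this nested-limit behaviour is tested.

The empirical FDR of a count threshold k is
eFDR(k) = min(1, N_total · Pr(X > k) / N_obs(X > k)), with Pr taken under
the truncated fit (so Pr(X > 0) = 1; the untruncated-vs-truncated choice at
k = 0 is irrelevant in practice because eFDR is ~1 there anyway). The
selection threshold k\* is the smallest k with eFDR ≤ α; windows with count
> k\* merge into PBRs when adjacent. The final partial window of each
chromosome is kept — at 250 bp against megabase chromosomes the bias is
negligible and the bookkeeping stays simple.

## Strand profiles and the peak p-value

Each PBR is extended by *d* bp per side before profiling: a fragment's 5'
tag can lie a full fragment length away from the site, and without the
flanks the windowed counts at the PBR edges would be censored. F[s] and
R[s] count forward/reverse tags in [s, s+d) for every window start s in the
extended region. The peak used for the count p-value is the maximum of
F + R (one combined peak per PBR; p_c = Pr(X ≥ peak count) under the
truncated background). Argmax ties break leftmost. The binding-site
estimate is the rounded midpoint between the downstream edge of the
forward-peak window and the start of the reverse-peak window — the two
window edges that theoretically abut the site; window starts rather than
centers keep the estimate within ±(d/2) of either convention and the
planted-site tests show ±25 bp accuracy at realistic tag yields.

## Pattern matching

The reference pattern simulates an immunoprecipitation on a 1 kb region
with one central site: 3×10⁶ fragments, integer lengths uniform on
[150, 250] bp, starts uniform, retention probability 1e-3 for fragments
spanning the site and 5e-5 otherwise, one 5'-end tag per retained fragment
from a uniformly chosen end. S_R = F − R over width-d windows is smoothed
and normalized to max |S| = 1; its single positive lobe strictly precedes
its single negative lobe.

Smoothing uses the stationary (maximal-overlap) discrete wavelet transform
with the 8-tap least-asymmetric filter (`sym4` in PyWavelets), depth
min(4, ⌊log₂ n⌋) — deep enough to remove tag-level noise at the ~250 bp
scale of the signal — with hard thresholding at the universal threshold
σ̂·√(2 ln n), σ̂ = median|finest detail|/0.6745, and symmetric end padding
to the required dyadic multiple. The transform is shift-invariant, so
output length equals input length.

An observed pattern is amplitude-normalized, its global peak and trough
(leftmost ties) are mapped onto the reference extrema by the affine
position map, and the pattern is linearly resampled at the n reference
positions (constant extrapolation beyond its ends). The dissimilarity is
d_p = Σᵢ |S_obs′(i) − S_R(i)|, summed over the fixed n reference positions
so scores are comparable across PBRs of different sizes. Flat patterns and
patterns whose trough does not strictly follow their peak receive the
penalty 2n — the supremum of the sum when both signals are bounded by 1 —
because a wrong-orientation pattern carries no evidence of binding
geometry. Only the global extrema are aligned (the reference has exactly
one of each); dynamic alignment over all local extrema is deliberately out
of scope.

## Motif discovery and scanning

Candidate sequences are the ±20 bp (41 bp total) around the site estimates
of the high-quality PBRs — those ranked jointly best on p_c and d_p, taken
as the intersection of the two top-q lists with q grown until the requested
set size is reached (at most 500 sequences). At 41 bp a sequence is assumed
to contain either one motif occurrence or none (ZOOPS). The EM treats the
occurrence position and strand as latent, with a fixed 0-order background
estimated from the input, pseudocount 0.1 per matrix cell, and convergence
at |Δ objective| < 1e-6 or 200 iterations, best of 5 seeded restarts (each
seeded from a random w-mer at 0.7/0.1 base probabilities). Default width
9, configurable 6–15.

Maximum-likelihood ZOOPS on short sequences is degenerate: once the matrix
sharpens around the best-scoring random windows, every sequence owns one,
and the site prior γ drifts to 1 even on pure noise. The site prior
therefore carries a Beta(1, n+1) MAP prior — one pseudo-dataset of
site-free sequences — under which noise inputs settle at containment
fractions ~0.2 while a genuinely shared motif still reaches ≥0.6. The
monitored (and provably non-decreasing) objective is the penalized
log-likelihood: data log-likelihood plus the Dirichlet term of the
pseudocount and the Beta term of the prior. A motif is accepted only if
≥25 % (inclusive) of the input sequences contain it (posterior > 0.5).

Scanning computes natural-log odds against the scan set's own 0-order
background at every position on both strands. The best-hit p-value comes
from the exact null distribution of the integerized score (granularity
1e-3), built by convolving the per-column score distributions — so p-values
need no asymptotics and match exhaustive enumeration at small widths. The
region p-value is the best-of-m correction p_m = 1 − (1 − p₁)^m over the m
scanned (position, strand) pairs, clipped into (0, 1]. Ambiguous bases
score 0 (background-neutral). If no motif is accepted, all regions receive
p_m = 1 and the ranking falls back to count + pattern evidence, logged
prominently.

## Evidence integration and the two-step eFDR

The three scores enter as x_c = ln p_c, x_p = ln(d_p + ε) with ε = 1e-6
(d_p can be exactly 0), and x_m = ln p_m. Their natural ranges differ by
orders of magnitude (p_c can reach 1e-30; p_m is bounded below by roughly
4^−w·m), so x_p and x_m are rescaled onto the scale of x_c by
quantile-matching ordinary least squares: regress the sorted x_c vector on
the sorted x_p (resp. x_m) vector and apply the fitted affine map
per-region. Sorted-on-sorted regression always yields a non-negative
slope, so each score's own ranking is preserved, and the rescaled vectors
match the target's mean exactly and its spread up to the sorted-vectors
correlation (≈1 for continuous scores). The combined score is the plain
mean of the three; ranking is ascending with ties broken by p_c then
genomic order. The scheme is equivariant under affine maps of the log
scores — i.e. under power transforms c·p^a of the raw scores — which is
the family for which "rescale to a common level" is exactly meaningful; no
value-averaging scheme can be invariant under arbitrary monotone
transforms.

The significant set is the top (1−α)·N_PBR of the re-ranked list. Since
re-ranking permutes a set whose expected true-positive fraction the first
eFDR step fixed at (1−α), the set size — and the FDR guarantee — depends
only on N_PBR and α; the evidence decides which regions fill it. The
rounding rule is configurable (half-away-from-zero, the default, or floor)
because published worked examples of this arithmetic round both ways;
both rules are exposed and tested.

## Synthetic study conditions

The generator plants all four enrichment mechanisms. Defaults define the
canonical desk-scale fixture:

- **Genome**: 3 × 250 kb chromosomes plus a 250 kb decoy (uniform i.i.d.
  A/C/G/T), i.e. 4 000 windows at d = 250. Signal occupies <1 % of
  windows — the background-dominance regime the count model assumes; with
  markedly smaller chromosomes the background fit absorbs the signal and
  the eFDR never reaches α = 0.5.
- **Sites**: 10 planted TTCCGGGAA instances (per-base mutation rate 0.1,
  random strand), placed evenly within each chromosome's confounder-free
  stretch; occupancy strengths linspace(0.6, 1.0) model heterogeneous
  binding. Site pull-down probability 1.5e-2 × strength vs background
  5e-4: ten times the reference-simulation probabilities with their ~20:1
  enrichment preserved, so realistic yields (~36–60 tags/site, background
  ~2.5 tags/window) are reached with 2×10⁷ fragments instead of an
  intractable 1.5×10⁸. Every planted site is detectable by construction
  (worst case ~18 site tags in one window against thresholds around 12),
  which the end-to-end recall test asserts.
- **Focal amplifications**: two 1 kb intervals at fold 8 — high,
  strand-symmetric coverage; the pattern stage's designated confounder.
- **Nonspecific binding**: a per-segment Gamma(5, 1/5) rate multiplier
  (moderate over-dispersion, variance ≈ 1.5 × mean) plus hotspots — 1 % of
  250 bp segments at uniform 3–10× background. The Gamma component alone
  is exactly negative binomial and is absorbed by the fit; the hotspots
  inflate the observed tail beyond the fitted model, which is what lets
  the eFDR cross α at a realistic threshold and what populates the decoy
  chromosome with spurious enriched regions.
- **Decoy**: one chromosome receiving only background (Gamma + hotspot)
  fragments — the internal false-positive surrogate.

A second configuration (`pattern_benchmark_config`) plants 50 sites and 50
amplification intervals on disjoint chromosomes with homogeneous
background, for the pattern-discrimination benchmark (site vs
amplification d_p, rank-sum p < 0.01).

What the generator does *not* emulate: realistic base composition,
sequencing error, mappability structure, paired ends, or fragment-length
biases. Passing tests therefore demonstrate the algorithmic contracts —
threshold selection, site localization, confounder rejection, motif
recovery, FDR bookkeeping — not performance on real libraries.

## Pipeline defaults and determinism

d = 250 bp (the fixture's fragment size selection), α = 0.5 (large enough
to pool candidates for re-ranking, small enough to stay tractable),
motif-discovery set size 12 on the fixture (the desk-scale analogue of
selecting ~190 of 69 809 regions; the library default remains 200, capped
at 500), flank 20 bp, motif width 9, 5 EM restarts. All stages draw from
seeds derived from one configured seed; outputs are byte-identical across
reruns with the same inputs and seed, and the tests assert it.

## Known limitations

- At desk scale the decoy-chromosome comparison rests on ~4 decoy hotspot
  regions; the cumulative-curve advantage of the three-evidence ranking
  over count-only ranking is established at the default study seed but is
  statistically marginal per-seed at this size (ties occur), unlike at
  genome scale where thousands of regions enter the curves.
- The count model is global; local background variation beyond the Gamma
  mixing (e.g. large copy-number segments) is handled only through the
  pattern and motif evidence, not the threshold.
- Site p-values ignore the multiplicity of overlapping windows inside a
  PBR (one peak p-value per region), and the motif stage discovers a
  single motif (no multi-motif models, no higher-order backgrounds).
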