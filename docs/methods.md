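# Methods

## Model and assumptions

`cmapsig` treats a disease signature as an ordered list of signed genes
derived from several independent paired tumour/normal expression studies
over a shared gene universe of size N (the intersection of the platforms'
probe sets; identifiers are opaque strings). The statistical model behind
each per-cohort analysis is the classical paired design: for gene g and
subject j, the tumour−normal log2 difference d_gj is i.i.d. normal with
mean δ_g, and the paired t statistic t_g = mean(d_g)/(sd(d_g)/√n) has
n−1 degrees of freedom under δ_g = 0. Expression is assumed log2; a
`linear_input` flag log2-transforms on read, because the two-fold-change
filter and the effect sizes are defined on the log2 scale.

### Significance threshold and π₀

Genes are split into significant/non-significant groups at
p < 1/(π₀·N), which sets the expected count of false-positive genes to
one. π₀ (the fraction of non-differential genes) is estimated by the tail
estimator π̂₀ = #{p > λ}/((1−λ)·n) with λ = 0.5, clamped into (0, 1]:
above λ the p-value density is almost entirely null genes, so the
estimator is slightly conservative (biased up) when many genes are truly
differential, which only tightens the threshold. The estimator is
pluggable (`pi0_estimator=` callable, or `fixed_pi0(x)`), since more
elaborate estimators exist; λ = 0.5 keeps variance low at the few-thousand
gene scale used in tests.

### Signed normalized rank scores and combination

Within a cohort, significant genes ranked i = 1..M by ascending p (ties:
|t| descending, then gene id — a deterministic order is required because
the score is a function of i) get Score_i = (M−i+1)/M, signed by
regulation direction. Two biological-filter details are deliberate:

* the fold-change filter (|mean log2 diff| ≥ 1) is applied **after** rank
  assignment — filtered genes are zeroed but keep their rank positions, so
  surviving genes retain their original (M−i+1)/M values rather than being
  re-ranked (re-ranking would change every published-style fractional
  score downstream of a filtered gene);
* fold change is computed from the mean of per-pair log2 differences (the
  paired geometric-mean ratio), consistent with the paired test, not from
  the ratio of group means.

Totals are plain sums across cohorts; the combined ranking sorts by
|total| descending with ties broken by the number of contributing
datasets (descending) then gene id. Genes with total exactly 0 carry no
direction and are excluded from signature construction. The signature
sign of a gene is the sign of its total, not a majority vote.

## Connectivity engine

A reference profile stores each compound treatment as signed ranks: the
most perturbed gene has magnitude N, the least magnitude 1, and sign =
regulation direction. The connection score of an m-gene signature is the
signed-rank sum normalized by its maximum attainable value
(N + (N−1) + … + (N−m+1)), hence always in [−1, 1], antisymmetric under
sign flips, and invariant to genes outside the signature.

### Null model and p-values

The null draws random signatures: uniform m-subsets of the universe with
independent uniform signs, signature length preserved. P-values are
one-sided in the direction of the observed score. Two regimes:

* **exact** — when the state space C(N, m)·2^m is small (≤ 10⁶ for
  per-profile p-values; ≤ 2·10⁴ for compound-level queries, which covers
  every m = 1 query since that space is just 2N signed singletons), the
  null is enumerated exhaustively. Exact p-values need no seed and no
  pseudocount; they are bounded below by 1/n_states because the observed
  signature is itself one of the states.
* **Monte-Carlo** — otherwise, n_null draws (default 2000) with the
  (r+1)/(n+1) pseudocount so p is never 0. Every stochastic operation
  takes an explicit seed.

The exact small-m regime matters: the single-gene null is a coarse
lattice, and Monte-Carlo sampling there turns borderline compounds into
coin flips; enumeration makes the m = 1 step of the progression
deterministic.

A note on calibration: a one-sided p in the *observed* direction lives on
(0, ½] under a symmetric null — each tail carries half the mass. The
calibration tests therefore check uniformity of the null-CDF transform
u = p (negative scores) / 1 − p (positive scores), which is U(0, 1) under
the null. The expected-false-positive arithmetic is unaffected: at
threshold Efp/Nc, each tail contributes Efp/2·(…) and the two directions
together give Efp expected false compounds, of which the negative-direction
filter keeps half.

### Replicates

A compound with K replicate profiles is scored by the mean replicate
cscore; the null is the same mean computed for the null signatures scored
against all K replicates (one shared draw set per query, which is what
makes compound p-values comparable within a query). Averaging shrinks
null variance to the extent replicates are independent; for literally
identical replicate profiles the null means are perfectly correlated and
the z-score does not change — variance shrinkage is a property of
replicate diversity, not of the count alone.

## Progression and perturbation

The signature grows from m_start = 1 in steps of 1; at each m the engine
counts hits (negative cscore, p ≤ Efp/Nc) and the empirical FDR is
Efp/Ns (∞ at Ns = 0). First passage below the target FDR (default 0.10)
stops the loop; exhaustion of the non-zero-total genes returns the
visited state with maximal Ns, flagged `exhausted`. Per-m null seeds are
derived deterministically as SeedSequence(seed, spawn_key=(m,)), so the
trace is bit-reproducible and lengths are independent; Ns is recomputed
from scratch at each m.

Perturbation stability re-tests each hit under perturbed signatures:
exhaustive leave-one-out when n_remove = 1 and m ≤ 200 (deterministic,
seed-free), otherwise a fixed number of random removals. Stability is the
retained fraction under the unchanged Efp/Nc threshold and direction
filter. Stability is monotone under threshold tightening on a fixed
perturbation set. Caveat: leave-one-out from a 2-gene signature queries
single-gene signatures, which generally cannot clear a strict Efp/Nc
threshold at all — stability is only informative for signatures long
enough that each perturbed query remains well-posed, and the pipeline
skips it when final_m ≤ n_remove.

## Synthetic data: what it emulates, what it does not

`generate_study` draws, for each gene, a baseline ~ N(7, 2) log2 units;
each subject adds N(0, 0.5) to both samples of its pair (the pairing
structure that the paired t-test exploits); the tumour sample adds the
planted shift plus N(0, 0.6) residual noise. Defaults model the
five-cohort design the package is tested at: pairs (15, 19, 4, 18, 15)
with one deliberately under-powered 4-pair cohort, 2000 genes, 100
planted DEGs at ±2 log2 units, each present in a cohort with probability
0.8 and sign-flipped with probability 0.05 (exercising score
cancellation). The residual SD of 0.6 is typical paired-array
repeatability and gives near-complete power at 10+ pairs under the
1/(π₀N) threshold while leaving the 4-pair cohort powerless (t ≈ 6.7 at
df = 3 is still far above the threshold p) — exactly the asymmetry the
combination step is designed to absorb.

`generate_reference_db` plants inhibitors (and optionally mimics) against
a chosen query signature: the leading `strength` fraction of the
signature's genes is forced into the profile's top rank magnitudes with
reversed (matched) signs; replicates share the forced gene set but redraw
the magnitude assignment within it and the entire unforced remainder;
null compounds are uniform signed permutations. `strength` is therefore
directly interpretable: a strength-0.8 inhibitor reverses the top 80% of
the signature. In end-to-end runs the planted signature is the top 20
genes of the combined ranking actually obtained on the simulated study.

What the generator does **not** emulate: probe-level artifacts, batch and
platform effects, heavy-tailed noise, correlated genes, or compound
profiles with realistic pathway structure. Passing planted-truth tests
shows the pipeline's statistics and bookkeeping are correct under its own
model, not that the model captures microarray reality; with planted
inhibitors reversing the very top ranks, the progression legitimately
terminates at m = 1, whereas diffuse real-data signals yield long
progressions (hundreds of genes) before ten hits accumulate.

## Numerical choices and degenerate inputs

* Zero-variance difference vectors: t is undefined; set t = 0, p = 1,
  flagged `zero_variance`.
* π̂₀ is clamped to [1/n, 1]; thresholds with π₀ ≤ 0 are rejected.
* All orderings (significance ranks, combined ranking, hit tables) use
  stable sorts with documented tie-breaks; reruns are byte-identical.
* M = 0 cohorts produce an all-zero score vector and simply dilute
  nothing (they contribute no terms to any total).
* Monte-Carlo mode refuses n_null < 1000 for per-profile p-values; the
  pseudocount bounds p ≥ 1/(n_null+1).
* Sampling m-of-N without replacement uses random-key argpartition,
  O(n_null·N), exact uniformity.

## Problem sizes used in the tests

Unit tests run on universes of 4–60 genes with exhaustively enumerable
nulls; calibration tests use 2000 draws at n_null = 2000 (N = 100, m = 5);
the end-to-end planted-truth study runs the full default design (5
cohorts × 2000 genes, 200 compounds) with n_null = 2000. These sizes make
the whole suite run in well under a minute while keeping every statistical
assertion at conventional test power (KS at α = 0.01, 3·SE bounds).

## Known limitations

* The π₀ tail estimator is a simple default; users with very high
  differential fractions should supply their own estimator.
* Replicate aggregation is mean-of-scores with a shared-draw null; set
  statistics that weight replicates by quality are out of scope.
* The engine implements the signed-rank score only — not the original
  KS-statistic connectivity score — and does not parse CMap02/LINCS
  archives; reference databases must be provided in the long TSV format.
* Perturbation stability with non-unit removal counts uses random subsets;
  exact enumeration is implemented only for leave-one-out.
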