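# cmapsig

Combined gene signatures from multiple paired expression studies, and
signed-rank connectivity mapping to rank candidate drugs that reverse them.

## The problem

Differential-expression lists for the same disease rarely agree across
independent cohorts: a gene can be significant in one study, absent in
another, or even flip regulation direction. Simple intersection of
per-study gene lists throws away genes that are strong everywhere except
one cohort, and tends toward the empty set as studies accumulate. Yet
connectivity mapping — querying a disease gene signature against a database
of compound-induced expression profiles to find compounds that reverse it —
depends entirely on signature quality.

`cmapsig` implements a rank-based multi-cohort signature method for users
of connectivity mapping (computational biologists doing drug repurposing):

1. **Per-cohort scoring.** In each paired tumour/normal dataset, every gene
   gets a paired t-test; genes with p below the adaptive threshold
   1/(π₀·N) form the significant group (π₀ = estimated fraction of
   non-differential genes, N = genes analysed; the threshold caps the
   expected number of false positives at one). The i-th most significant
   gene scores

       Score_i = (M − i + 1) / M,

   signed + for up- and − for down-regulation, with genes under two-fold
   change zeroed. Dividing by M (the significant-group size) makes scores
   comparable between an under-powered 4-pair cohort and a 19-pair one.

2. **Combination.** Per-gene scores are summed across the D datasets into a
   total score in [−D, D] and genes are ranked by |total|. Consistent genes
   accumulate; conflicting ones cancel; under-powered cohorts fade out
   automatically.

3. **Connectivity mapping.** The top-m signature (genes + signs) is scored
   against each compound profile (signed ranks over the gene universe) as

       cscore = Σᵢ sᵢ · r(gᵢ) / (N + (N−1) + ⋯ + (N−m+1))  ∈ [−1, 1],

   with −1 meaning perfect reversal. P-values come from a null of random
   signed signatures (exact enumeration when the state space is small,
   Monte-Carlo otherwise); replicate profiles of a compound are aggregated
   by mean cscore. A connection is significant at p ≤ Efp/Nc.

4. **Signature-length progression.** m grows from 1 until the empirical
   false discovery rate Efp/Ns of the negative-score drug hits reaches the
   target (default 0.10, i.e. at least 10 hits at Efp = 1).

5. **Perturbation stability.** Each hit is re-tested under leave-one-out
   (or random-removal) perturbations of the final signature; the stability
   score is the fraction of perturbations under which it stays significant.

A synthetic-data module generates multi-cohort studies with planted
differentially expressed genes and reference databases with planted
inhibitor/mimic compounds, so the whole pipeline is testable offline.

## Worked example

The package ships a 15-gene worked example: the per-dataset score columns
of five colorectal-cancer sub-datasets (stage II–III and stage IV groups of
three GEO cohorts) for the top gene of each cohort and the top ten genes of
the combined ranking. Recombining the columns reproduces the published
totals:

```python
>>> from cmapsig.examples import worked_example_combined
>>> combo = worked_example_combined()
>>> print(combo.summary(5))
Combined signature over 5 datasets: 15 genes with non-zero total score
             GSE21510S2-3  GSE41258S2-3  GSE21510S4  GSE41258S4  GSE49355S4  total_score  n_nonzero_datasets  overall_rank
ProbeID
203908 at         -0.9933       -0.9847      0.0000     -0.9895     -0.9883      -3.9558                   4             1
207502 at         -0.9904       -0.9973      0.0000     -0.9797     -0.9826      -3.9500                   4             2
207003 at         -0.9627       -0.9989      0.0000     -0.9822     -0.9513      -3.8951                   4             3
205480 s at       -0.9912       -0.9732      0.0000     -0.9197     -0.9996      -3.8837                   4             4
205950 s at       -0.9974       -0.8872      0.0000     -0.9959     -0.9352      -3.8157                   4             5
```

Probe `203908 at` is SLC4A4, down-regulated in all four powered cohorts
(total −3.9558 out of a possible −5); the all-zero `GSE21510S4` column is
the 4-pair cohort whose 7 significant genes contribute nothing to the top
of the combined ranking. `combo.take_top(m)` turns the ranking into a
query signature.

An end-to-end run on synthetic data with known ground truth:

```python
>>> from cmapsig import full_synthetic_run
>>> run = full_synthetic_run(seed=1)   # 5 cohorts, 2000 genes, planted truth
>>> print(run.progression.summary())
Gene-signature progression
  status          FDR target met
  final length m  1
  drug hits Ns    14
  empirical FDR   0.07143  (target 0.1)
  ...
```

Here 12 of the 14 hits are the 12 planted inhibitor compounds (profiles
built to reverse the top of the combined signature); the empirical FDR
Efp/Ns = 1/14 met the 0.10 target. Because the planted inhibitors reverse
the very top of the ranking at full rank strength, the progression stops
immediately; diffuse real-data signals produce longer progressions.

The same pipeline is available from the shell:

```sh
cmapsig full-run --outdir out/ --seed 1
cmapsig simulate --outdir sim/ --seed 1
cmapsig diffexp --matrix sim/synth1_matrix.tsv --metadata sim/synth1_metadata.tsv --out de1.tsv
```

`full-run` writes per-stage TSVs (diffexp tables, combined signature,
progression trace, hits with a PerturbStability column) plus a JSON
manifest with the seed and config hash for bit-reproducible reruns.

## Scope

Working from real cohorts requires externally prepared inputs: normalized
expression matrices with sample metadata (TSV), and a compound
reference-profile database as signed ranks (TSV; e.g. derived from the
Broad CMap02 or LINCS archives, which this package does not download or
parse). Quantities that depend on those proprietary-scale inputs — a
148-gene clinical signature, specific drug names — are out of reach of the
synthetic tests, which instead verify every algorithmic step against exact
oracles and planted ground truth.
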