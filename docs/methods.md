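# Methods

## The question and the model

Circulating-miRNA case-control studies of one disease frequently report
non-overlapping signatures. `mirconverge` formalizes the convergence
hypothesis: the *targets* of those discordant signatures may coincide
even when the miRNAs do not. The analysis treats the pooled signature as
fixed and asks whether its targeting is unusually concentrated
(convergence) and whether the targeted genes are unusually
interconnected (functional coherence), against a null of
composition-matched random signatures.

### Targeting-frequency score

For each gene, the number of distinct elevated signature miRNAs with a
recorded interaction to it and the number of distinct decreased ones are
counted separately; their difference is the gene's score. Two choices
are deliberate:

* **Evidence multiplicity is ignored.** The interaction table is
  deduplicated to unique (miRNA, gene) pairs before counting, so a pair
  supported by many publications still contributes one vote — the score
  counts *miRNAs*, not evidence records.
* **Untargeted genes are absent**, not scored zero: the score table is
  a table of targeted genes, and downstream selections operate on it.

miRNA identifiers are compared case-insensitively after trimming; arm
variants (-5p/-3p) are distinct miRNAs and no alias collapsing is
attempted. Genes are bare symbols with no alias resolution. Species
filtering applies to both the miRNA and the target-gene species columns.

### Permutation null

Random signatures draw `n_high + n_low` distinct miRNAs uniformly
without replacement from all distinct miRNAs present in the interaction
table (the observed signature's members are not excluded: the null is
"any signature of this composition"). Each replicate is scored exactly
like the observed signature; the two statistics are the top-k score sum
and, per confidence threshold, the PPI edge count among each
replicate's *own* top-k genes. Ties at the top-k boundary are broken by
gene symbol so the statistic is a deterministic function of the draw;
the boundary-tie condition is flagged in results because the edge
statistic (not the sum) could differ under another tie convention.

Both empirical p-value conventions are reported: strict
`r / N` (r = null values strictly above observed) and add-one
`(r' + 1) / (N + 1)` (r' = null values ≥ observed). The strict
convention can reach exactly zero; the add-one one cannot and is the
honest summary when no null replicate reaches the observed value. The
randomness source is a seeded PCG64 generator; the test's validity
rests on the statistical behavior of the resampling, not on the
physical origin of the random numbers.

### Directed network and combined score

The curation chain over the selected (score ≥ 5 by default) genes:
drop undirected edges; split bidirectional edges into two opposite
directed edges with the same sign; cross-reference against the PPI
network at threshold 0.95 to list high-confidence pairs with no directed
edge (these go to manual curation, consumed as an annotation table whose
rows resolve direction and sign — `a_to_b`, `b_to_a`, `both`, `none`);
finally keep only unambiguous activating edges. Annotations never
overwrite an existing edge; a sign contradiction on the same ordered
pair is a hard error rather than a silent choice.

Katz centrality uses the incoming-edge convention
`x_v = beta + alpha * sum_{u->v} x_u` with `alpha = 0.1`, `beta = 1`,
solved exactly as a dense linear system after verifying
`alpha * rho(A) < 1` (the spectral radius is reported when the bound is
violated). The solution is left unnormalized so isolated genes score
exactly `beta` and hub genes exceed 1; selected genes that end up
isolated in the activating network are retained with `katz = beta`, so
every selected gene has a combined score `katz * frequency_score`.

### Influence score

Influence runs the activating network in reverse from each elevated
miRNA: `I_m = sum_g s_g * sum_p alpha^{l_p}` over *simple* directed
paths (no repeated node) of at most `max_path_len` edges, with `s_g`
the gene's combined score. Simple paths are the only finite reading of
"all unique paths" once the network contains cycles. The implementation
is a backtracking depth-first search that accumulates `alpha^depth` at
every node arrival (each prefix of a simple path is itself a simple
path, so each arrival corresponds to exactly one path); the test suite
checks it exactly against independent per-pair path enumeration. The
default cap `max_path_len = 8` makes any truncated path contribute at
most `alpha^9 = 1e-9` times a gene score — far below the two-decimal
precision at which influences are reported; the bound is logged.
Influence is computed for elevated miRNAs (the framing is suppression
of downstream genes); decreased miRNAs can be scored by passing the low
subset explicitly.

## Synthetic data: what it emulates and what it does not

The generators produce the combinatorial structure the analysis
consumes, nothing more. Targeting is independent Bernoulli: every
(miRNA, gene) cell has probability `p_background`, except the planted
block of (designated elevated miRNA, cluster gene) cells at
`p_cluster`. The PPI network is likewise Bernoulli with
within-cluster probability `q_cluster` vs `q_background`, confidences
drawn uniformly from configurable ranges (the statistics depend on
thresholds only, so the confidence distribution's shape is immaterial).
The signed directed generator assigns each present gene pair to
directed / bidirectional / undirected categories with configured
fractions and an inhibition probability, purely to exercise the
curation chain.

Default condition: a 300-miRNA x 1000-gene universe, 37 high + 19 low
signature, 60-gene cluster, `p_background = 0.02`, `p_cluster = 0.35`,
`q_background = 0.005`, `q_cluster = 0.5` — a strong planted effect
used for the power measurements; setting the cluster probabilities
equal to background gives the exchangeable null used for calibration.
Degree heterogeneity of real databases (hub miRNAs, hub genes),
literature ascertainment bias, expression levels and sequence features
are *not* modeled: passing calibration and power checks here shows the
statistical machinery is correct under the stated null and effect, not
that real databases satisfy that null.

## Numerical and design choices

* Ordering everywhere is deterministic: score descending, symbol (or
  miRNA id) ascending on ties; all outputs are byte-stable for fixed
  inputs and seed.
* The permutation engine works on a boolean miRNA x gene matrix with
  vectorized column sums, so the default problem sizes run in seconds;
  measured quantities in tests use 200 null datasets x 500 replicates
  (calibration) and 50 runs x 500 replicates (power) as the package's
  standard verification sizes.
* Katz is an exact solve, never a truncated series; the truncated walk
  series appears only as an independent oracle in tests.
* Self-loops in PPI input are dropped with a logged count (public dumps
  occasionally contain them); conflicting signature directions and
  annotation sign conflicts are hard errors, never silently resolved.
* Support-type / evidence-strength filtering of interaction records is
  not applied by default; the reader keeps any record of the requested
  species.
* The statsmodels-style split (`ConvergenceTest.fit()` returning a
  `PermutationResult` with `summary()`) marks the one genuinely
  statistical fit in the pipeline; the remaining stages are
  deterministic transformations exposed as functions.

## Known limitations

* Gene and miRNA identity is purely lexical; no ortholog, alias or
  miRBase-version reconciliation.
* The manual-curation step is consumed as a table; the package does not
  attempt direction/sign inference from literature.
* The null resamples miRNA identity only; it does not preserve the
  degree sequence of the targeting table. A degree-preserving null
  would be stricter and is out of scope.
* Whether the original edge-statistic convention capped path ties or
  boundary ties identically is unknowable from the published numbers;
  the tie flag surfaces every case where it could matter.
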