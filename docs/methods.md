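# Methods

## Generation model

The cohort is a binary matrix: one row per phased haplotype, one column per
biallelic SNP (0 = reference, 1 = alternate allele). Generation never
operates on genotypes; diploid output is produced only by pairing
consecutive synthetic haplotypes at write time.

**Clusters.** One overlapping cluster per cohort haplotype: the seed row
plus its *N*−1 nearest rows by Hamming distance, ties broken towards the
lower row index. This construction is deterministic given the matrix, keeps
every haplotype coverable as a seed, and realises "overlapping clusters of
size *N*" without any free parameter beyond *N* itself.

**Constraints.** For one synthetic haplotype, a cluster is drawn uniformly
and a pair universe is sampled: each of the C(*s*, 2) site pairs is kept
independently with probability 1−*L*. For every kept pair, the four joint
allele patterns are counted over the cluster and a threshold *z* is drawn
once per pair as ⌊Uniform[0, α+1)⌋ (so α = 0.5 gives *z* = 1 with
probability 1/3; integer α gives *z* uniform on {0, …, α}). Every pattern
with count ≤ *z* is forbidden by the 2-literal clause ¬(x_i = a ∧ x_j = b).
A pattern is forbidden exactly when its frequency is at or below *z*; this
is the only reading under which larger α is monotonically more suppressive,
which is the entire point of the parameter. If all four patterns of a pair
would be forbidden, the most frequent one (ties: lexicographically smallest
pattern) is left allowed so that no single pair is contradictory.

**Solving.** The formula is pure 2-SAT, so the package ships a complete
implication-closure solver (pick an unassigned literal, commit the closure
of its implications; if contradictory, the negation's closure is forced;
for a satisfiable formula this never backtracks). Free decisions are
randomized under the run seed in variable order and polarity, which is what
makes successive outputs diverse. Decision polarity is itself a modelling
choice exposed as `GenomatorParams.polarity`:

* `"frequency"` (default) tries the alternate allele with probability equal
  to its cluster frequency, so weakly constrained sites reproduce the
  cluster's marginal allele-frequency spectrum — the right setting for
  fidelity work;
* `"uniform"` tries each allele with probability 1/2, maximising solver
  diversity and the expression of rare admissible patterns — the right
  setting when probing memorisation, since rare in-cluster combinations are
  actually emitted at α = 0.

**Satisfiability and retries.** At α = 0 only frequency-0 patterns are
forbidden, so every cluster member is a model and the problem is always
satisfiable, for any pair universe. For α > 0 the randomized thresholds can
produce an unsatisfiable formula; generation retries with fresh randomness
(`max_retries`, default 10) and then halves α, terminating because α = 0 is
satisfiable. The per-haplotype provenance log records the cluster seed, the
retry count, and the effective α.

**Defaults.** *N* = 150, *L* = 0.99, α = 0.5. These are the generation
defaults for large cohorts, where excluding 99% of pairs still leaves
hundreds of constrained partners per site. On small simulated cohorts
(hundreds of sites) the same fraction would leave sites essentially
unconstrained, so the bundled experiments use *L* between 0 and 0.9, stated
per experiment.

## Reverse audit

Generation with *L* = 0 has one certain consequence: every pairwise pattern
of the output had frequency ≥ 1 in the source cluster. The audit therefore
asks, for subset size *M*: which size-*M* row subsets exhibit, for every
site pair, at least one member matching the target's pattern? This is a CNF
over one selection variable per cohort row — a positive support clause per
pair (deduplicated) plus an exactly-*M* cardinality constraint — solved by
a small DPLL with chronological backtracking. Cardinality is enforced by a
native counting propagator rather than a CNF encoding (sequential counter
or otherwise): the propagator is exact, adds no auxiliary variables, and is
substantially faster in pure Python at audit scale. The support threshold
is frequency ≥ 1, not > *z*, because the auditor does not know the *z*
draws; the audit is deliberately conservative, and it is defined only for
the *L* = 0 regime — with *L* > 0 no sound constraint exists and the API
says so.

Distinct reconstructions are enumerated by adding a blocking clause per
found subset, with re-randomized decision order/polarity for diversity; the
intersection of the sample estimates the backbone. `certify_exposure` gives
the exact answer (member forced false → unsatisfiable ⇔ member is in every
feasible subset) and always contains the sampled intersection on
exhaustively enumerable fixtures.

The exposure-risk experiment draws, per iteration, *G* sites and *M* rows,
generates one synthetic haplotype from exactly that row subset (cluster =
the sample, *L* = 0, given α), audits it against the whole cohort restricted
to the same sites, and scores whether the sampled backbone is non-empty.
Risk is the mean indicator with a Clopper–Pearson interval (default level
0.90). Auditing against the full cohort (rather than only the sampled *M*
rows) is a choice: it models an attacker holding the complete candidate
pool, the strongest realistic adversary; the pool is configurable by
passing a pre-subset cohort.

## Fidelity metrics

*Sliced Wasserstein distance* is the mean over random unit directions
(default 100, seeded) of the exact 1-D Wasserstein distance between the
projected point clouds. 100 directions stabilise the score to ~1% relative
jitter on the bundled fixtures. PCA is fitted on the real cohort only and
both cohorts are projected onto its first two components (`fit_on="pooled"`
exists for sensitivity checks). The raw-data score uses all site dimensions
and is reported as a percentage of the maximal possible displacement — the
sliced distance between the all-reference and all-alternate clouds under
the same directions — so identical cohorts score 0% and the bitwise
complement of a constant cohort scores exactly 100%. Normalising by the
site count instead would make the nominal 100% unreachable under random
projections (a unit direction maps the full flip to |Σθ| ≪ *s*), which is
why the yardstick form is used; the choice is recorded in the report
metadata.

*LD error.* On phased haplotypes the Rogers–Huff r² estimator reduces to
the squared Pearson correlation of the 0/1 allele indicators, which is how
it is computed. Pairs are restricted to the same chromosome within a
base-pair window; monomorphic sites yield undefined r² and are skipped.
The error between cohorts is the mean over in-window pairs of
(r²_real − r²_synth)², per window size (default grid 50–250 kb in five
equal steps; density is a parameter since any equal-increment grid is
defensible), with a percentile bootstrap over SNP pairs (1000 replicates,
95%) — the SNP pair being the averaging unit.

## Privacy metrics

*Attribute inference.* Rows are split into two random equal halves;
synthetic data is generated from each; every real row's nearest-neighbour
Hamming distance to its own half's synthetic set (in-data) and the other
half's (out-data) is computed, and leakage is the difference of the two
medians (medians taken over all real rows — the per-row-then-median order
is stated because it is not the only reading). The generator is injectable
so the probe can score any method; memorising and cohort-independent
reference generators bound the scale. Note the probe's resolution is one
Hamming unit (medians of integers): the α dose–response is only visible
when the synthetic sets are large enough to saturate the halves (every
row's neighbourhood seeded), which the bundled experiment conditions ensure.

*Quadruplet revelation.* Quadruplets are sampled uniformly: 4 distinct
sites and 16 allele patterns, rejection-sampled without duplicates until
the private (real count = 1) and fictitious (count = 0) quotas are met
(default quota 10 000 each; a cap returns a partial result with a warning).
"Occurrence" across repeated synthetic datasets is reported both ways —
fraction of quadruplets appearing in ≥ 1 dataset (headline likelihood) and
mean per-dataset rate — since either is a defensible reading of a
multi-dataset occurrence count.

## Cohort simulator

The simulator reproduces exactly the two structures the metrics measure.
Population structure: ancestral frequencies uniform on `maf_range`
(default 0.05–0.5), population frequencies from the Balding–Nichols Beta
construction at the given F_ST (default 0.15, two populations). LD: sites
are partitioned into blocks of geometric mean length (default 10 sites =
10 kb at the fixed 1 kb spacing, which maps the 50–250 kb window grid onto
50–250 sites); each population holds 4 founder block-haplotypes and every
haplotype copies one founder per block with a 1% per-allele copy error.
Founders are drawn from uniforms shared across populations and thresholded
at each population's frequency, so at F_ST = 0 the populations are exactly
exchangeable and differentiation grows continuously with F_ST. Block
copying yields high within-block and near-zero between-block r².

What the simulator does *not* emulate: recombination-map heterogeneity,
demographic history, selection, realistic site-frequency spectra, missing
data, or phasing error. Tests passing on it show the logic, the guarantees
and the metric machinery are correct at cohort scale; they do not certify
accuracy levels on real population data.

Planting helpers create auditable rare features: `plant_unique_quadruplet`
writes a previously absent 4-site combination into exactly one row (a
*private* quadruplet by construction); `plant_singleton_variant` makes one
site a singleton, whose pairwise patterns are uniquely supported by the
carrier — the sharpest identifying feature a pairwise audit can see (a
unique 4-site combination does not guarantee any unique *pair*, which is
why the singleton variant exists).

## Numerical and scale choices

MAF filtering compares allele counts, not float fractions, so threshold
boundaries (1 carrier in 100 rows at 0.01) are exact. All randomness flows
through `numpy.random.Generator`; fixed seeds give bit-identical matrices
and byte-identical CLI outputs (no timestamps are written). Bundled
experiments and the acceptance script run on cohorts of 40–200 haplotypes
and 50–300 sites with 5–120 synthetic haplotypes, 50 audit iterations and
40–500 reconstructions — sizes at which the exhaustive oracles in the test
suite remain tractable; every size is stated at the call site.

## Known limitations

The reverse audit is exact but exponential in the worst case; like any
complete search it is practical only for small site windows (the audit
experiments use ~12-site windows; the backbone certificate is cheap once
the support clauses are built). The generator's accuracy at default *L*
depends on constraint density and therefore on cohort width; very narrow
cohorts need smaller *L*. Multiallelic sites and indels are out of scope
throughout (skipped on read, with counts logged).
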