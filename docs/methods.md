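# Methods

This note documents the statistical models, algorithmic choices and known
limitations of `hlapop`, in the order a typical analysis runs.

## Ambiguity representation

A typing result at one locus is stored as a non-empty, duplicate-free set
of unordered allele pairs ("the list of allele pairs required to explain
the genotype").  Homozygotes are always written with explicit duplication
(`A*01:01+A*01:01`); a bare single allele is a syntax error, which removes
the homozygote-versus-blank reading ambiguity.  The canonical text dialect
is the genotype-list (GL) string delimiter set — `/` for allele-level
ambiguity, `+` between the two alleles of a genotype, `|` between
alternative whole-genotype explanations, `^` between loci — chosen because
it is an established grammar whose semantics match the pair-list
representation exactly: `a+b|c+d` denotes those two pairs and nothing
else, whereas the factored `a/c+b/d` denotes the four-pair cross-product.
Serialization offers both styles; the factored form is emitted only when
its expansion equals the candidate set, otherwise it falls back to the
explicit pair list, so serialization can never add spurious pairs.
Multi-locus candidates are stored unphased; phase enters only inside
haplotype estimation, because typing data carry no phase.

Abbreviation-code (MAC) expansion is implemented faithfully as the full
cross-product of the two expanded sides — this is precisely the artificial
inflation that makes codes unsuitable for population genetics, and
reproducing it exactly is what lets `count_spurious_pairs` measure the
information loss (|expansion| − |true pair list|).  The code table is
user-supplied; there is no live registry lookup, keeping runs reproducible
offline.

## Nomenclature and the common allele pool

Allele names follow the grammar `LOCUS*F1(:F2(:F3(:F4)))[NLSCAQ]`.
Serology-era names and G/P groups are rejected in this version.  Leading
zeros are preserved as text (round-trip fidelity) but fields compare
numerically, so `A*02:01 == A*2:1`.  Truncating a name below its current
resolution drops the expression suffix with a warning — specialised to a
null-allele-merge warning for `N` alleles, which must remain analysable
(e.g. `C*04:09N` merged into `C*04`) rather than be rejected.

Samples typed with different techniques resolve different allele splits.
The common pool of a collection is computed as the finest partition of
the union of observed alleles that no sample's reporting contradicts: two
alleles are merged whenever one observed name covers the other (its field
list is a prefix of the other's), and classes are the transitive closure
of this relation (union–find).  Each class is named by the longest common
field prefix of its members, which is non-empty by construction since
merges preserve the first field.  This is one consistent reading of
"setting the common allele pool"; no published algorithm exists for the
screening step, so the prefix-cover rule was fixed here as the package's
definition and is exercised against an independent exhaustive-merge oracle
in the tests.

## Kit interpretation

The forward reaction model is deterministic and dominant-positive: a probe
is positive iff it reacts with at least one of the two alleles carried.
No probe noise or failure model is included.  Interpretation enumerates
all k(k+1)/2 unordered pairs over the kit universe (with memoized
predicted patterns) and returns those matching the observed pattern; a
pattern matched by no pair raises an error carrying the nearest
interpretable patterns by Hamming distance.  Patterns explained only by
alleles outside the kit universe therefore surface as uninterpretable
rather than being absorbed by a catch-all "untyped" allele; blank-like
alleles are not modeled in this version.

## EM frequency estimation

Likelihood: `L(p) = Π_i Σ_{(a,b)∈C_i} g_ab(p)` with HWE genotype
probabilities inside each candidate.  Individuals with identical candidate
sets are aggregated into observation classes, so cost scales with the
number of distinct ambiguity patterns rather than N.  Defaults:

| parameter | default | rationale |
|---|---|---|
| starting points | 5 (1 uniform + 4 Dirichlet(1)) | multimodality is rare but must be surfaced |
| convergence | \|Δ log L\| < 1e−8 or L∞ freq change < 1e−9 | well below any reportable precision |
| max iterations | 5000 | ample for the flat likelihoods ambiguity induces |
| distinct-solution clustering | Δ log L ≤ 0.01 and L∞ ≤ 1e−4 | coarse enough to ignore numeric jitter |

The number of starting points, distinct solutions found, convergence
criterion, iteration count and seed are always reported in
`em_diagnostics`, because frequency reports should state the estimation
algorithm's initial conditions.  The per-iteration log-likelihood is
asserted non-decreasing (an EM guarantee); a decrease raises an error
carrying the trajectory.

Haplotype estimation expands each multi-locus candidate into its
2^(het−1) compatible phased diplotypes (capped at 10⁶ per individual;
exceeding the cap advises resolution reduction first) and runs the same
EM over diplotypes, `g_jk = h_j h_k`, doubled off-diagonal.  Haplotypes
below `1/(10·2N)` are zeroed between iterations to bound the state space
— never in a way that empties an individual's explanation set, and the
monotonicity assertion is suspended on pruning steps since removing mass
can lower the likelihood transiently.  With one locus the procedure
reduces exactly to allele EM (tested).

Linkage disequilibrium uses the standard definitions: `D_jk = h_jk −
p_j q_k`, `D′ = D/D_max` with the conventional sign-dependent bounds, and
`W_n = sqrt(Σ D²/(p q) / (min(k₁,k₂)−1))`, clipped to [0, 1] against
round-off.

## Hardy–Weinberg testing

The nested likelihood-ratio construction needs an explicit alternative;
the one-parameter inbreeding model is the default because it is the
canonical nested departure (df = 1) and yields an interpretable `f̂`,
with the saturated genotype-frequency model (df = k(k+1)/2 − k) as an
option.  Both likelihoods sum over candidate sets, so ambiguity is
handled identically to the estimator.  The inbreeding profile is
maximized by L-BFGS-B on an unconstrained parametrization (softmax for p;
f mapped into its admissible range `[−min_a p_a/(1−p_a), 1]`, which keeps
every genotype probability non-negative), started at the null optimum
(f = 0) plus positive- and negative-f perturbations.  An alternative
optimum below the null beyond 1e−6 log-units raises an internal
optimization error rather than reporting a negative statistic.  On
unambiguous data the saturated LR statistic equals the classical G
statistic exactly, and a classical chi-square on the genotype table can
be attached for comparison (`fallback=True`); contingency-table tests are
otherwise deliberately unavailable, as they require ambiguity-free data.

Calibration under the null was verified by simulation (1000 HWE datasets,
k = 5, N = 200): the rejection rate at α = 0.05 stays inside the binomial
99% envelope and the p-value ECDF inside the Kolmogorov 99% band; power
against f = 0.15 at N = 200 exceeds 50% by a wide margin.  These problem
sizes were chosen as representative of a typical single-locus population
sample.

## Ewens–Watterson neutrality test

θ̂ solves `E[K | θ, n] = Σ_{i<n} θ/(θ+i) = k` by bracketed root-finding.
The null of F conditional on (n, k) is sampled by rejection: Hoppe-urn
draws at θ̂ are kept when they contain exactly k types.  The conditional
configuration law is θ-free, so rejection is exact regardless of θ̂, which
only tunes the acceptance rate; an acceptance rate below 0.1% aborts with
advice to use the exact enumeration.  `k = 1` and `k = n` are degenerate
single-configuration cases handled without sampling.  Both tail
conventions are reported: inclusive tails `p_low = P(F ≤ F_obs)`,
`p_high = P(F ≥ F_obs)` (tie mass counted in both, so they sum to ≥ 1)
and mid-p variants with ties counted half.  F_obs is computed from the
point EM frequencies; the ambiguity uncertainty of those frequencies is
*not* propagated into the null, and the result says so in its notes.  By
default k counts all estimated alleles, with an option to restrict to
significant ones, since allele counts are sample-size sensitive.

The exact small-n oracle enumerates integer partitions of n into k parts;
a configuration with multiplicities a_j of part-size j has conditional
probability ∝ Π_j (1/j)^{a_j}/a_j!.  For (n=4, k=2) this gives
P(3+1) = 8/11, P(2+2) = 3/11, mean F = 6.5/11 — frozen in the tests and
matched by the resampler.

## Sample-size thresholds

Model I uses z = 2 exactly ("two standard deviations"), not 1.96, because
only z = 2 reproduces every printed two-tail cell (`6.25 = 4/64` at
N = 30, `3.85 ≈ 4/104` at N = 50, ...).  Model III is
`p* = 1 − α^{1/2N}`.  Two printed cells are known not to reproduce:
model I at N = 500 prints 0.39 where the closed form gives 0.3984% → 0.40,
and model III at N ∈ {30, 100, 150} differs by ≤ 0.02 — rounding
inconsistencies in the source table; the `thresholds` CLI marks such
cells against the packaged printed reference rather than silently
preferring either.  The one-tail column (model II) is *not* reproduced by
the one-tail z = 1.645 analogue (2.63 vs the printed 2.75 at N = 50) and
its exact construction is undocumented; the implementation provides the
analogue flagged as approximate and makes no reproduction claim for it.
Displayed thresholds are rounded half away from zero to two decimals; the
unrounded value is retained for computation.

## Synthetic data

The generator draws N independent individuals (the analyses assume
unrelated subjects, hence the first-degree-relative exclusion flag in the
metadata) from `P(aa) = p_a² + f p_a(1−p_a)`, `P(ab) = 2 p_a p_b(1−f)`
via an explicit genotype probability vector, with frequencies either
given or symmetric-Dirichlet.  Defaults (N = 100, k = 8, f = 0) mirror a
modest single-locus sample at the recommended minimal size.  Kit masking
reuses the interpretation module verbatim (predict → interpret), so
masked samples always contain the truth among candidates; the random
7-probe kit used in the recovery tests leaves roughly half the
individuals ambiguous.  A kit-free random-merge mode adds one random
extra pair per individual at a given rate for cheap EM stress tests.
All randomness flows from a single seed through `numpy.random.Generator`;
integer draws only, so results are platform-stable.

What the generator does **not** emulate: genotyping error, probe noise,
blank/untyped alleles, related individuals, population substructure, and
registry-scale heterogeneity.  Passing recovery tests therefore
demonstrate correctness of the estimators under their own assumptions,
not robustness to these real-data features.

## Problem sizes used in the checks

The automated checks run EM recovery at k = 8, N = 500 through a 7-probe
kit; HWE calibration on 1000 simulated datasets (k = 5, N = 200) plus 100
power datasets; and the Ewens–Watterson comparison at 10⁵ replicates for
(n = 4, k = 2) with exact enumeration up to n = 12.  These sizes are
representative of desk-scale population samples while keeping the full
suite quick to run.

## Known limitations

* No Bayesian/posterior uncertainty on frequencies; multi-start EM
  reports multimodality but not standard errors beyond the binomial
  approximation used for plotting whiskers.
* Ambiguity uncertainty is not propagated into the neutrality null.
* No IMGT/HLA database integration, nomenclature-version conversion, or
  G/P-group computation; no sequence-level input; no HML/XML exchange.
* The inbreeding-model generator accepts f ∈ [0, 1] only; negative-f
  (heterozygote-excess) data can be analysed but not generated.
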