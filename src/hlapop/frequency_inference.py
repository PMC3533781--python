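"""Maximum-likelihood allele and haplotype frequency estimation by EM over
ambiguity sets.

The likelihood assumes Hardy-Weinberg genotype proportions (p_a^2 for
homozygotes, 2 p_a p_b for heterozygotes) and treats each individual as the
sum over its candidate explanations::

    L(p) = prod_i  sum_{(a,b) in candidates_i}  g_ab(p)

The E-step gives each candidate pair posterior weight g_ab / sum g; the
M-step re-estimates p_a as the expected count of allele a over 2N gene
copies.  Haplotype estimation is the same algorithm over phased diplotypes:
each multi-locus candidate genotype expands to its compatible haplotype
pairs (2^(het-1) phase explanations), with low-frequency haplotypes pruned
between iterations.

Reports of frequencies should state the algorithm's initial conditions;
the estimate therefore carries the number of starting points, the number of
distinct solutions found, the convergence criteria and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from hlapop.errors import ConvergenceError
from hlapop.genotype_io import PopulationSample
from hlapop.sample_size import ThresholdQuery, frequency_threshold

NONSIGNIFICANT_NOTE = (
    "frequencies below the sample-size threshold are not significantly "
    "different from zero; avoid discussion on the 'number of alleles present' "
    "or 'the presence or absence of given alleles'"
)


@dataclass
class FrequencyEstimate:
    """Per-allele (or per-haplotype) ML frequencies with EM diagnostics.

    ``frequencies`` maps allele text (or a tuple of per-locus allele texts for
    haplotypes) to a proportion; it sums to 1.  ``flags`` maps the same keys
    to a set drawn from {significant, nonsignificant, common,
    well_documented}.
    """

    loci: list[str]
    frequencies: dict
    n_individuals: int
    log_likelihood: float
    em_diagnostics: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def n_gene_copies(self) -> int:
        return 2 * self.n_individuals

    @property
    def k(self) -> int:
        return len(self.frequencies)

    def sorted_items(self):
        return sorted(self.frequencies.items(), key=lambda kv: (-kv[1], str(kv[0])))


# ---------------------------------------------------------------------------
# shared EM core: individuals = classes of identical candidate sets over
# unordered item pairs (items are alleles, or phased haplotypes)


class _PairMixture:
    """Aggregated observation classes for the HWE-mixture EM."""

    def __init__(self, class_pairs: list[list[tuple[int, int]]],
                 class_counts: list[int], n_items: int):
        self.n_items = n_items
        self.n_individuals = int(sum(class_counts))
        flat_i, flat_j, flat_class = [], [], []
        for c, pairs in enumerate(class_pairs):
            for i, j in pairs:
                flat_i.append(i)
                flat_j.append(j)
                flat_class.append(c)
        self.i = np.asarray(flat_i, dtype=np.intp)
        self.j = np.asarray(flat_j, dtype=np.intp)
        self.cls = np.asarray(flat_class, dtype=np.intp)
        self.coef = np.where(self.i == self.j, 1.0, 2.0)
        self.counts = np.asarray(class_counts, dtype=float)
        self.n_classes = len(class_counts)

    def genotype_probs(self, p: np.ndarray) -> np.ndarray:
        return self.coef * p[self.i] * p[self.j]

    def log_likelihood(self, p: np.ndarray) -> float:
        g = self.genotype_probs(p)
        s = np.bincount(self.cls, weights=g, minlength=self.n_classes)
        with np.errstate(divide="ignore"):
            return float(np.dot(self.counts, np.log(s)))

    def em_step(self, p: np.ndarray) -> np.ndarray:
        g = self.genotype_probs(p)
        s = np.bincount(self.cls, weights=g, minlength=self.n_classes)
        w = g / s[self.cls] * self.counts[self.cls]
        acc = np.bincount(self.i, weights=w, minlength=self.n_items)
        acc += np.bincount(self.j, weights=w, minlength=self.n_items)
        return acc / (2.0 * self.n_individuals)


def _prune(mix: _PairMixture, p: np.ndarray, threshold: float) -> tuple[np.ndarray, bool]:
    """Zero frequencies below threshold, never emptying an observation
    class's explanation set; renormalize.  Returns (p, pruned_anything)."""
    low = (p > 0.0) & (p < threshold)
    if not low.any() or (p < threshold).all():
        return p, False
    keep = ~low
    cand_ok = keep[mix.i] & keep[mix.j]
    class_ok = np.bincount(mix.cls, weights=cand_ok.astype(float),
                           minlength=mix.n_classes) > 0
    if not class_ok.all():
        g = mix.genotype_probs(p)
        for c in np.nonzero(~class_ok)[0]:
            members = np.nonzero(mix.cls == c)[0]
            best = members[np.argmax(g[members])]
            keep[mix.i[best]] = keep[mix.j[best]] = True
    p = np.where(keep, p, 0.0)
    return p / p.sum(), bool((~keep).any())


def _run_em(mix: _PairMixture, p0: np.ndarray, tol_loglik: float,
            tol_freq: float, max_iter: int, prune_threshold: float | None = None):
    """One EM run; returns (p, loglik, n_iter, trajectory).  The trajectory is
    asserted non-decreasing (up to round-off) on every pure EM step — EM
    guarantees it; pruning steps may lower it and are exempt."""
    p = np.asarray(p0, dtype=float)
    p = p / p.sum()
    ll = mix.log_likelihood(p)
    trajectory = [ll]
    for it in range(1, max_iter + 1):
        p_new = mix.em_step(p)
        pruned = False
        if prune_threshold is not None:
            p_new, pruned = _prune(mix, p_new, prune_threshold)
        ll_new = mix.log_likelihood(p_new)
        trajectory.append(ll_new)
        if not pruned and ll_new < ll - 1e-9 * max(1.0, abs(ll)):
            raise ConvergenceError(
                f"log-likelihood decreased at iteration {it} "
                f"({ll} -> {ll_new})", trajectory)
        done = (not pruned
                and (abs(ll_new - ll) < tol_loglik
                     or np.max(np.abs(p_new - p)) < tol_freq))
        p, ll = p_new, ll_new
        if done:
            return p, ll, it, trajectory
    raise ConvergenceError(
        f"EM did not converge in {max_iter} iterations "
        f"(last |dlogL| = {abs(trajectory[-1] - trajectory[-2]):.3g})",
        trajectory)


def _multi_start(mix: _PairMixture, n_starts: int, tol_loglik: float,
                 tol_freq: float, max_iter: int, seed,
                 prune_threshold: float | None = None):
    rng = np.random.default_rng(seed)
    k = mix.n_items
    solutions = []
    for s in range(max(1, n_starts)):
        p0 = np.full(k, 1.0 / k) if s == 0 else rng.dirichlet(np.ones(k))
        p, ll, it, _ = _run_em(mix, p0, tol_loglik, tol_freq, max_iter,
                               prune_threshold)
        solutions.append((ll, p, it))
    # cluster optima: same solution if |dlogL| <= 0.01 and Linf(p) <= 1e-4
    distinct = []
    for ll, p, _ in solutions:
        if not any(abs(ll - ll2) <= 0.01 and np.max(np.abs(p - p2)) <= 1e-4
                   for ll2, p2 in distinct):
            distinct.append((ll, p))
    best_ll, best_p, best_it = max(solutions, key=lambda t: t[0])
    return best_p, best_ll, best_it, len(distinct)


def _build_allele_mixture(s: PopulationSample):
    """Index alleles and aggregate individuals by identical candidate sets."""
    allele_index: dict = {}
    alleles: list = []

    def idx(a):
        key = a.serialize()
        if key not in allele_index:
            allele_index[key] = len(alleles)
            alleles.append(key)
        return allele_index[key]

    class_map: dict[frozenset, int] = {}
    class_pairs: list[list[tuple[int, int]]] = []
    class_counts: list[int] = []
    for g in s.genotypes:
        pairs = []
        for c in g.candidates:
            if isinstance(c, tuple):
                raise ValueError(
                    "em_allele_frequencies requires a single-locus sample; "
                    "use estimate_haplotype_frequencies for multi-locus data")
            i, j = idx(c.allele1), idx(c.allele2)
            pairs.append((min(i, j), max(i, j)))
        key = frozenset(pairs)
        if key in class_map:
            class_counts[class_map[key]] += 1
        else:
            class_map[key] = len(class_pairs)
            class_pairs.append(sorted(set(pairs)))
            class_counts.append(1)
    return alleles, _PairMixture(class_pairs, class_counts, len(alleles))


def em_allele_frequencies(
    s: PopulationSample,
    n_starts: int = 5,
    tol_loglik: float = 1e-8,
    tol_freq: float = 1e-9,
    max_iter: int = 5000,
    seed: int | None = 0,
) -> FrequencyEstimate:
    """ML allele frequencies of a single-locus sample with any number and
    kind of ambiguities.

    Runs ``n_starts`` EM initializations (one uniform, the rest
    Dirichlet(1)-random from ``seed``) and returns the best optimum; the
    number of distinct optima found is reported in ``em_diagnostics``.  On
    fully unambiguous data the result equals the direct counting estimator.
    """
    if not s.genotypes:
        raise ValueError("empty sample")
    alleles, mix = _build_allele_mixture(s)
    p, ll, iters, n_distinct = _multi_start(
        mix, n_starts, tol_loglik, tol_freq, max_iter, seed)
    return FrequencyEstimate(
        loci=list(s.locus_set),
        frequencies={a: float(pi) for a, pi in zip(alleles, p)},
        n_individuals=s.n_individuals,
        log_likelihood=ll,
        em_diagnostics={
            "n_starting_points": max(1, n_starts),
            "n_distinct_solutions": n_distinct,
            "convergence_criterion": (
                f"|dlogL| < {tol_loglik:g} or Linf frequency change < {tol_freq:g}"
            ),
            "iterations": iters,
            "max_iter": max_iter,
            "seed": seed,
            "ambiguity_fraction": s.ambiguity_fraction(),
        },
    )


# ---------------------------------------------------------------------------
# haplotype estimation


def _phase_expansions(candidate, cap: int):
    """All unordered phased haplotype pairs compatible with one multi-locus
    candidate genotype (tuple of per-locus unordered pairs)."""
    pairs = candidate if isinstance(candidate, tuple) else (candidate,)
    het = [not p.homozygous for p in pairs]
    n_het = sum(het)
    if 2 ** max(0, n_het - 1) > cap:
        raise ValueError(
            f"diplotype expansion of {len(pairs)}-locus genotype exceeds cap "
            f"{cap}; reduce typing resolution (transliterate) first")
    out = set()
    for orient in product((0, 1), repeat=len(pairs)):
        h1, h2 = [], []
        for p, o in zip(pairs, orient):
            a, b = p.alleles()
            if o:
                a, b = b, a
            h1.append(a.serialize())
            h2.append(b.serialize())
        h1, h2 = tuple(h1), tuple(h2)
        out.add((h1, h2) if h1 <= h2 else (h2, h1))
    return out


def estimate_haplotype_frequencies(
    s: PopulationSample,
    n_starts: int = 5,
    tol_loglik: float = 1e-8,
    tol_freq: float = 1e-9,
    max_iter: int = 5000,
    seed: int | None = 0,
    prune_threshold: float | None = None,
    expansion_cap: int = 10 ** 6,
) -> FrequencyEstimate:
    """ML haplotype frequencies of an (unphased, possibly ambiguous)
    multi-locus sample.

    Every candidate genotype expands to its compatible phased diplotypes;
    the EM then runs exactly as for alleles, with diplotype probability
    h_j h_k (doubled when j != k).  Haplotypes estimated below
    ``prune_threshold`` (default 1/(10*2N)) are dropped between multi-start
    runs' final estimates, never in a way that empties an individual's
    explanation set.  With a single locus this reduces exactly to
    :func:`em_allele_frequencies`.
    """
    if not s.genotypes:
        raise ValueError("empty sample")
    if prune_threshold is None:
        prune_threshold = 1.0 / (10.0 * 2 * s.n_individuals)

    hap_index: dict = {}
    haplotypes: list = []

    def idx(h):
        if h not in hap_index:
            hap_index[h] = len(haplotypes)
            haplotypes.append(h)
        return hap_index[h]

    class_map: dict[frozenset, int] = {}
    class_pairs: list[list[tuple[int, int]]] = []
    class_counts: list[int] = []
    for g in s.genotypes:
        diplotypes = set()
        for c in g.candidates:
            for h1, h2 in _phase_expansions(c, expansion_cap):
                i, j = idx(h1), idx(h2)
                diplotypes.add((min(i, j), max(i, j)))
        key = frozenset(diplotypes)
        if key in class_map:
            class_counts[class_map[key]] += 1
        else:
            class_map[key] = len(class_pairs)
            class_pairs.append(sorted(diplotypes))
            class_counts.append(1)

    mix = _PairMixture(class_pairs, class_counts, len(haplotypes))
    p, ll, iters, n_distinct = _multi_start(
        mix, n_starts, tol_loglik, tol_freq, max_iter, seed,
        prune_threshold=prune_threshold)

    freqs = {}
    for h, pi in zip(haplotypes, p):
        if pi > 0.0:
            key = h if len(h) > 1 else h[0]
            freqs[key] = float(pi)
    return FrequencyEstimate(
        loci=list(s.locus_set),
        frequencies=freqs,
        n_individuals=s.n_individuals,
        log_likelihood=ll,
        em_diagnostics={
            "n_starting_points": max(1, n_starts),
            "n_distinct_solutions": n_distinct,
            "convergence_criterion": (
                f"|dlogL| < {tol_loglik:g} or Linf frequency change < {tol_freq:g}"
            ),
            "iterations": iters,
            "max_iter": max_iter,
            "seed": seed,
            "prune_threshold": prune_threshold,
            "ambiguity_fraction": s.ambiguity_fraction(),
        },
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium


@dataclass
class LDResult:
    """Two-locus linkage disequilibrium: raw D and normalized D' per
    haplotype, plus the overall normalized measure W_n in [0, 1]."""

    loci: tuple[str, str]
    D: dict          # haplotype tuple -> raw disequilibrium
    D_prime: dict    # haplotype tuple -> D / D_max
    W_n: float


def linkage_disequilibrium(est: FrequencyEstimate) -> LDResult:
    """D, D' and W_n from a two-locus haplotype frequency estimate.

    ``D_jk = h_jk - p_j q_k``; ``D' = D / D_max`` with the conventional
    bounds; ``W_n = sqrt(sum_jk D_jk^2/(p_j q_k) / (min(k1,k2)-1))``.
    """
    keys = list(est.frequencies)
    if not keys or not isinstance(keys[0], tuple) or len(keys[0]) != 2:
        raise ValueError("linkage_disequilibrium requires a 2-locus haplotype estimate")
    a1 = sorted({h[0] for h in keys})
    a2 = sorted({h[1] for h in keys})
    if len(a1) < 2 or len(a2) < 2:
        raise ValueError(
            "W_n undefined: a locus is monomorphic in the haplotype estimate")
    h = np.zeros((len(a1), len(a2)))
    for (x, y), f in est.frequencies.items():
        h[a1.index(x), a2.index(y)] = f
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    D = h - np.outer(p, q)
    D_dict, Dp_dict = {}, {}
    chi2_sum = 0.0
    for i, x in enumerate(a1):
        for j, y in enumerate(a2):
            d = D[i, j]
            if d >= 0:
                dmax = min(p[i] * (1 - q[j]), (1 - p[i]) * q[j])
            else:
                dmax = min(p[i] * q[j], (1 - p[i]) * (1 - q[j]))
            D_dict[(x, y)] = float(d)
            Dp_dict[(x, y)] = float(d / dmax) if dmax > 0 else 0.0
            chi2_sum += d * d / (p[i] * q[j])
    W_n = float(np.sqrt(chi2_sum / (min(len(a1), len(a2)) - 1)))
    return LDResult(loci=(est.loci[0], est.loci[1]), D=D_dict, D_prime=Dp_dict,
                    W_n=min(1.0, W_n))


# ---------------------------------------------------------------------------
# classification


def classify_cwd(freq: float, observed_count: int) -> set:
    """Common/well-documented classification: *common* iff frequency >
    0.0001 (strict), *well_documented* iff observed at least three times."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency {freq} outside [0,1]")
    if observed_count < 0:
        raise ValueError(f"negative observed count {observed_count}")
    labels = set()
    if freq > 0.0001:
        labels.add("common")
    if observed_count >= 3:
        labels.add("well_documented")
    return labels


def flag_nonsignificant(est: FrequencyEstimate, model: str = "I") -> FrequencyEstimate:
    """Flag every allele whose estimated frequency falls below the
    sample-size significance threshold: such estimates are not significantly
    different from zero.  Also applies the common/well-documented labels
    using the expected gene-copy count p * 2N.  Flags are set in place and
    the estimate is returned."""
    thr = frequency_threshold(ThresholdQuery(N=est.n_individuals, model=model))
    for key, p in est.frequencies.items():
        flags = est.flags.setdefault(key, set())
        flags.add("nonsignificant" if p < thr.proportion else "significant")
        flags |= classify_cwd(p, int(round(p * est.n_gene_copies)))
    est.em_diagnostics["significance_threshold_percent"] = thr.percent
    est.em_diagnostics["significance_model"] = thr.query.model
    if NONSIGNIFICANT_NOTE not in est.notes:
        est.notes.append(NONSIGNIFICANT_NOTE)
    return est


def significant_alleles(est: FrequencyEstimate) -> list:
    return [k for k, f in est.flags.items() if "significant" in f]
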