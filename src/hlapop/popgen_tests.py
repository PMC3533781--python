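"""Hardy-Weinberg and selective-neutrality testing on ambiguous samples.

Classical HWE tests (chi-square, G or exact tests on the genotype
contingency table) require unambiguous genotypes.  With ambiguity sets the
natural replacement is a nested likelihood-ratio test: the null is the
HWE-mixture likelihood used by the EM estimator, the alternative either a
one-parameter inbreeding model

    P(aa) = p_a^2 + f p_a (1 - p_a),      P(ab) = 2 p_a p_b (1 - f)

(df = 1, the canonical single-parameter departure inflating homozygosity)
or the saturated genotype-frequency model (df = k(k+1)/2 - k).  Both
likelihoods sum over each individual's candidate set, so any number and
kind of ambiguities is accommodated.

Selective neutrality is assessed by the Ewens-Watterson homozygosity test:
the observed F = sum p_a^2 is placed in its null distribution under the
Ewens sampling formula conditional on the sample size n = 2N and the number
of alleles k, obtained by resampling (the conditional law is free of theta,
so rejection sampling of the Hoppe-urn construction at theta_hat is exact);
an exact small-n enumeration over integer partitions serves as oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from hlapop.errors import ConvergenceError
from hlapop.frequency_inference import (
    FrequencyEstimate,
    _build_allele_mixture,
    _multi_start,
    significant_alleles,
)
from hlapop.genotype_io import PopulationSample

AMBIGUITY_ADVICE = (
    "chi-square, G or exact tests on contingency tables should only be used "
    "in the absence of ambiguities and blank-like alleles; otherwise use a "
    "method explicitly accommodating ambiguities such as this nested "
    "likelihood-ratio test"
)


@dataclass
class HWEResult:
    """Outcome of a Hardy-Weinberg equilibrium test."""

    method: str          # nested_LR_inbreeding | nested_LR_saturated | chi_square
    statistic: float
    df: int
    p_value: float
    f_hat: float | None = None
    ambiguity_fraction: float = 0.0
    log_likelihood_null: float = float("nan")
    log_likelihood_alt: float = float("nan")
    fallback: "HWEResult | None" = None
    warnings_: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "f_hat": self.f_hat,
            "ambiguity_fraction": self.ambiguity_fraction,
            "log_likelihood_null": self.log_likelihood_null,
            "log_likelihood_alt": self.log_likelihood_alt,
            "warnings": self.warnings_,
            "note": AMBIGUITY_ADVICE,
        }
        if self.fallback is not None:
            d["fallback"] = self.fallback.to_dict()
        return d


def _inbreeding_loglik(mix, p: np.ndarray, f: float) -> float:
    hom = mix.i == mix.j
    pa = p[mix.i]
    pb = p[mix.j]
    g = np.where(hom, pa * pa + f * pa * (1.0 - pa), 2.0 * pa * pb * (1.0 - f))
    s = np.bincount(mix.cls, weights=g, minlength=mix.n_classes)
    if np.any(s <= 0.0):
        return -np.inf
    return float(np.dot(mix.counts, np.log(s)))


def _fit_inbreeding(mix, p_null: np.ndarray, ll_null: float):
    """Profile the (p, f) likelihood by quasi-Newton search on an
    unconstrained parametrization: p = softmax(x), f mapped into its
    admissible range [-min p/(1-p), 1] so every genotype probability stays
    non-negative."""
    k = mix.n_items
    eps = 1e-10

    def unpack(theta):
        x = theta[:k]
        ex = np.exp(x - x.max())
        p = ex / ex.sum()
        fmin = -np.min(p / np.maximum(1.0 - p, eps))
        fmin = max(fmin, -1.0)
        t = 1.0 / (1.0 + np.exp(-theta[k]))
        f = fmin + t * (1.0 - fmin)
        return p, f

    def negloglik(theta):
        p, f = unpack(theta)
        ll = _inbreeding_loglik(mix, np.maximum(p, eps), f)
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.log(np.maximum(p_null, eps))
    fmin0 = max(-np.min(p_null / np.maximum(1.0 - p_null, eps)), -1.0)
    t_zero = np.clip((0.0 - fmin0) / (1.0 - fmin0), 1e-6, 1 - 1e-6)
    y_zero = math.log(t_zero / (1.0 - t_zero))
    starts = [
        np.concatenate([x0, [y_zero]]),          # f = 0 (the null optimum)
        np.concatenate([x0, [y_zero + 1.0]]),    # positive f
        np.concatenate([x0, [y_zero - 1.0]]),    # negative f
    ]
    best = None
    for s0 in starts:
        res = optimize.minimize(negloglik, s0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    p_hat, f_hat = unpack(best.x)
    ll_alt = -best.fun
    if ll_alt < ll_null - 1e-6:
        raise ConvergenceError(
            f"inbreeding alternative optimization fell below the null "
            f"likelihood ({ll_alt} < {ll_null})")
    return max(ll_alt, ll_null), float(f_hat)


def _fit_saturated(mix, tol: float = 1e-10, max_iter: int = 10000):
    """EM for the saturated genotype-frequency mixture: maximize
    prod_i sum_{g in cand_i} q_g over the simplex of genotype categories."""
    n_cand = len(mix.cls)
    cats: dict[tuple[int, int], int] = {}
    cat_of = np.empty(n_cand, dtype=np.intp)
    for idx in range(n_cand):
        key = (int(mix.i[idx]), int(mix.j[idx]))
        cat_of[idx] = cats.setdefault(key, len(cats))
    m = len(cats)
    q = np.full(m, 1.0 / m)
    N = mix.counts.sum()
    ll = -np.inf
    for _ in range(max_iter):
        g = q[cat_of]
        s = np.bincount(mix.cls, weights=g, minlength=mix.n_classes)
        ll_new = float(np.dot(mix.counts, np.log(s)))
        w = g / s[mix.cls] * mix.counts[mix.cls]
        q = np.bincount(cat_of, weights=w, minlength=m) / N
        if abs(ll_new - ll) < tol:
            return ll_new
        ll = ll_new
    return ll


def _classical_chi_square(mix, p_hat: np.ndarray) -> HWEResult:
    """Chi-square on the genotype contingency table (unambiguous data only)."""
    k = mix.n_items
    obs = {}
    for idx, c in enumerate(mix.cls):
        key = (int(mix.i[idx]), int(mix.j[idx]))
        obs[key] = obs.get(key, 0.0) + mix.counts[c]
    N = mix.counts.sum()
    stat = 0.0
    for i in range(k):
        for j in range(i, k):
            e = N * (p_hat[i] ** 2 if i == j else 2 * p_hat[i] * p_hat[j])
            o = obs.get((i, j), 0.0)
            if e > 0:
                stat += (o - e) ** 2 / e
    df = k * (k + 1) // 2 - k
    return HWEResult(
        method="chi_square", statistic=float(stat), df=df,
        p_value=float(stats.chi2.sf(stat, df)) if df > 0 else 1.0,
        ambiguity_fraction=0.0,
    )


def hwe_test(
    s: PopulationSample,
    alternative: str = "inbreeding",
    fallback: bool = False,
    n_starts: int = 3,
    seed: int | None = 0,
) -> HWEResult:
    """Nested likelihood-ratio test of Hardy-Weinberg equilibrium on a
    single-locus sample with arbitrary ambiguities.

    ``alternative='inbreeding'`` tests the one-parameter inbreeding departure
    (df = 1); ``'saturated'`` tests against free genotype frequencies
    (df = k(k+1)/2 - k).  With ``fallback=True`` and a fully unambiguous
    sample, the classical chi-square on the genotype table is also computed
    for comparison and attached as ``result.fallback``.
    """
    if alternative not in ("inbreeding", "saturated"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if not s.genotypes:
        raise ValueError("empty sample")
    alleles, mix = _build_allele_mixture(s)
    k = mix.n_items
    ambig = s.ambiguity_fraction()
    if k == 1:
        msg = "monomorphic sample: null and alternative models coincide"
        warnings.warn(msg, UserWarning, stacklevel=2)
        return HWEResult(
            method=f"nested_LR_{alternative}", statistic=0.0,
            df=0 if alternative == "saturated" else 1, p_value=1.0,
            f_hat=0.0 if alternative == "inbreeding" else None,
            ambiguity_fraction=ambig, log_likelihood_null=0.0,
            log_likelihood_alt=0.0, warnings_=[msg],
        )
    p_null, ll_null, _, _ = _multi_start(mix, n_starts, 1e-10, 1e-12, 10000, seed)
    f_hat = None
    if alternative == "inbreeding":
        ll_alt, f_hat = _fit_inbreeding(mix, p_null, ll_null)
        df = 1
    else:
        ll_alt = _fit_saturated(mix)
        if ll_alt < ll_null - 1e-6:
            raise ConvergenceError(
                f"saturated likelihood below null ({ll_alt} < {ll_null})")
        ll_alt = max(ll_alt, ll_null)
        df = k * (k + 1) // 2 - k
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    result = HWEResult(
        method=f"nested_LR_{alternative}", statistic=stat, df=df,
        p_value=float(stats.chi2.sf(stat, df)) if df > 0 else 1.0,
        f_hat=f_hat, ambiguity_fraction=ambig,
        log_likelihood_null=ll_null, log_likelihood_alt=ll_alt,
    )
    if fallback and ambig == 0.0:
        result.fallback = _classical_chi_square(mix, p_null)
    return result


# ---------------------------------------------------------------------------
# Ewens-Watterson selective-neutrality test


def observed_homozygosity(est: FrequencyEstimate) -> float:
    """F_obs = sum of squared allele frequencies (expected homozygosity
    under HWE at the estimated frequencies)."""
    total = sum(est.frequencies.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {total}, not 1")
    return float(sum(p * p for p in est.frequencies.values()))


def expected_k(theta: float, n: int) -> float:
    """Expected number of distinct alleles in a neutral sample of n gene
    copies: sum_{i=0}^{n-1} theta/(theta+i)."""
    i = np.arange(n, dtype=float)
    return float(np.sum(theta / (theta + i)))


def watterson_theta(k: int, n: int) -> float:
    """Solve E[K | theta, n] = k for theta (monotone in theta)."""
    if k >= n:
        raise ValueError("theta undefined for k >= n (all-singleton boundary)")
    if k <= 1:
        raise ValueError("theta undefined for k <= 1 (monomorphic boundary)")
    return float(optimize.brentq(
        lambda t: expected_k(t, n) - k, 1e-9, 1e9, xtol=1e-12, rtol=1e-12))


def sample_ewens_counts(
    n: int, theta: float, replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Hoppe-urn (sequential) construction of the Ewens sampling formula:
    returns a (replicates, n) integer array of type labels."""
    labels = np.zeros((replicates, n), dtype=np.int32)
    next_label = np.ones(replicates, dtype=np.int32)
    rows = np.arange(replicates)
    for i in range(1, n):
        is_new = rng.random(replicates) < theta / (theta + i)
        copy_idx = rng.integers(0, i, size=replicates)
        copied = labels[rows, copy_idx]
        labels[:, i] = np.where(is_new, next_label, copied)
        next_label += is_new
    return labels


def _labels_to_F_and_k(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = labels.shape[1]
    F = np.empty(labels.shape[0])
    K = np.empty(labels.shape[0], dtype=np.intp)
    for r in range(labels.shape[0]):
        counts = np.bincount(labels[r])
        counts = counts[counts > 0]
        K[r] = counts.size
        F[r] = float(np.sum((counts / n) ** 2))
    return F, K


@dataclass
class NeutralityResult:
    """Ewens-Watterson test outcome.

    ``p_low``/``p_high`` are the inclusive tail probabilities
    P(F_null <= F_obs) and P(F_null >= F_obs) — the tie mass is counted in
    both, so p_low + p_high >= 1.  ``p_low_mid``/``p_high_mid`` apply the
    mid-p convention (ties counted half).  A small p_low indicates excess
    heterozygosity relative to neutrality (balancing selection); a small
    p_high indicates excess homozygosity (directional selection).
    """

    F_obs: float
    F_null_mean: float
    F_null_sd: float
    p_low: float
    p_high: float
    p_low_mid: float
    p_high_mid: float
    k: int
    n: int
    replicates: int
    seed: int | None
    theta_hat: float
    acceptance_rate: float = 1.0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def ewens_watterson_test(
    est: FrequencyEstimate,
    replicates: int = 10000,
    seed: int | None = 0,
    restrict_to_significant: bool = False,
    max_attempt_factor: int = 2000,
) -> NeutralityResult:
    """Resampling Ewens-Watterson test of selective neutrality.

    The null distribution of F conditional on (n = 2N, k) is sampled by
    rejection: Hoppe-urn draws at theta_hat (the Watterson estimate solving
    E[K] = k) are kept when they produce exactly k alleles.  Because the
    conditional configuration law does not depend on theta, the rejection
    scheme is exact; theta_hat only tunes the acceptance rate.

    ``k`` defaults to the count of all estimated alleles;
    ``restrict_to_significant=True`` instead uses only alleles flagged
    significant (allele counts are sample-size sensitive, so both behaviours
    are available).  F_obs is computed from the point EM frequencies; the
    ambiguity uncertainty of those frequencies is not propagated into the
    null.
    """
    keys = list(est.frequencies)
    if restrict_to_significant:
        sig = set(significant_alleles(est))
        keys = [a for a in keys if a in sig]
    k = len(keys)
    n = est.n_gene_copies
    if k > n:
        raise ValueError(f"k={k} alleles exceed n={n} gene copies")
    if k < 1:
        raise ValueError("no alleles selected for the neutrality test")
    F_obs = float(sum(est.frequencies[a] ** 2 for a in keys)
                  / max(sum(est.frequencies[a] for a in keys), 1e-300) ** 2)
    notes = ["F_obs computed from point EM frequencies; ambiguity "
             "uncertainty not propagated into the null"]

    if k == 1 or k == n:
        # degenerate: a single configuration has positive probability
        F_const = 1.0 if k == 1 else 1.0 / n
        null = np.full(replicates, F_const)
        theta_hat = 0.0 if k == 1 else float("inf")
        acc = 1.0
    else:
        theta_hat = watterson_theta(k, n)
        rng = np.random.default_rng(seed)
        accepted: list[np.ndarray] = []
        n_acc = 0
        attempts = 0
        max_attempts = max_attempt_factor * replicates
        batch = max(1000, replicates)
        while n_acc < replicates and attempts < max_attempts:
            labels = sample_ewens_counts(n, theta_hat, batch, rng)
            F, K = _labels_to_F_and_k(labels)
            hit = F[K == k]
            accepted.append(hit)
            n_acc += hit.size
            attempts += batch
            if attempts >= 20 * batch and n_acc / attempts < 0.001:
                raise RuntimeError(
                    f"rejection acceptance rate {n_acc/attempts:.2e} below "
                    "0.1%; use exact_ewens_null (small n) instead")
        if n_acc < replicates:
            raise RuntimeError(
                f"only {n_acc}/{replicates} accepted configurations in "
                f"{attempts} attempts")
        null = np.concatenate(accepted)[:replicates]
        acc = n_acc / attempts

    tol = 1e-12
    below = float(np.mean(null < F_obs - tol))
    above = float(np.mean(null > F_obs + tol))
    ties = max(0.0, 1.0 - below - above)
    return NeutralityResult(
        F_obs=F_obs,
        F_null_mean=float(null.mean()),
        F_null_sd=float(null.std(ddof=1)) if null.size > 1 else 0.0,
        p_low=below + ties,
        p_high=above + ties,
        p_low_mid=below + 0.5 * ties,
        p_high_mid=above + 0.5 * ties,
        k=k, n=n, replicates=int(null.size), seed=seed,
        theta_hat=theta_hat, acceptance_rate=acc, notes=notes,
    )


# ---------------------------------------------------------------------------
# exact small-n null (oracle for the resampling test)


def _partitions_into(n: int, k: int, max_part: int | None = None):
    """All partitions of n into exactly k positive parts, non-increasing."""
    if max_part is None:
        max_part = n
    if k == 0:
        if n == 0:
            yield ()
        return
    if n < k:
        return
    for first in range(min(n - k + 1, max_part), 0, -1):
        for rest in _partitions_into(n - first, k - 1, first):
            yield (first,) + rest


@dataclass
class ExactEwensNull:
    """Exact null distribution of F conditional on (n, k): one entry per
    integer partition of n into k parts."""

    n: int
    k: int
    partitions: list          # list of (partition tuple, F, probability)

    @property
    def mean_F(self) -> float:
        return sum(F * p for _, F, p in self.partitions)

    @property
    def var_F(self) -> float:
        m = self.mean_F
        return sum((F - m) ** 2 * p for _, F, p in self.partitions)

    def f_distribution(self) -> dict:
        out: dict[float, float] = {}
        for _, F, p in self.partitions:
            out[F] = out.get(F, 0.0) + p
        return out

    def p_low(self, F_obs: float, tol: float = 1e-12) -> float:
        return sum(p for _, F, p in self.partitions if F <= F_obs + tol)


def exact_ewens_null(n: int, k: int, max_n: int = 30) -> ExactEwensNull:
    """Enumerate the exact conditional Ewens null of F for small n.

    Under the Ewens sampling formula conditional on K = k, an allele
    configuration with multiplicities a_j of part-size j has probability
    proportional to prod_j (1/j)^{a_j} / a_j! — independent of theta.
    """
    if n > max_n:
        raise ValueError(f"n={n} too large for exact enumeration (max {max_n})")
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    entries = []
    for part in _partitions_into(n, k):
        mult: dict[int, int] = {}
        for size in part:
            mult[size] = mult.get(size, 0) + 1
        weight = 1.0
        for size, a in mult.items():
            weight *= (1.0 / size) ** a / math.factorial(a)
        F = sum(s * s for s in part) / n ** 2
        entries.append((part, F, weight))
    total = sum(w for _, _, w in entries)
    entries = [(part, F, w / total) for part, F, w in entries]
    entries.sort(key=lambda t: -t[2])
    return ExactEwensNull(n=n, k=k, partitions=entries)
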