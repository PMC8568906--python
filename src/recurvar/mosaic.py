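"""Parental mosaicism and de novo support from allele read counts.

A parent who is somatically mosaic for a variant transmits it
constitutionally yet shows a variant allele fraction (VAF) well below the
heterozygous expectation of 0.5 in their own sequencing reads — e.g. 8 of 50
reads, or 1 of 32 on one platform and 2 of 110 on another.  This module
estimates VAF with exact binomial (Clopper-Pearson) intervals, classifies a
parent as absent / mosaic / heterozygous by a pair of exact binomial tests,
pools read evidence across platforms, and computes a simplified trio
posterior probability that a child's variant arose de novo (ppDNM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

DEFAULT_ERROR_RATE = 0.005
DEFAULT_ALPHA = 0.05
DEFAULT_MUTATION_RATE = 1e-8
DEFAULT_CONFIDENCE = 0.95

CLASSIFICATIONS = ("absent", "possible_mosaic", "mosaic", "heterozygous",
                   "ambiguous")


@dataclass(frozen=True)
class ReadCounts:
    alt: int
    depth: int

    def __post_init__(self) -> None:
        if self.alt < 0 or self.depth < self.alt:
            raise ValueError("need 0 <= alt <= depth")

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            raise ZeroDivisionError("VAF undefined at depth 0")
        return self.alt / self.depth


@dataclass(frozen=True)
class TrioReadCounts:
    proband: ReadCounts
    mother: ReadCounts
    father: ReadCounts


@dataclass(frozen=True)
class MosaicCall:
    vaf: float
    ci_low: float
    ci_high: float
    p_vs_het: float
    p_vs_error: float
    classification: str
    alt: int
    depth: int


@dataclass(frozen=True)
class DeNovoPosterior:
    ppDNM: float
    posteriors: dict  # (g_mother, g_father, g_child) -> posterior probability


# ---------------------------------------------------------------------------
# VAF estimation
# ---------------------------------------------------------------------------

def estimate_vaf(rc: ReadCounts,
                 confidence: float = DEFAULT_CONFIDENCE
                 ) -> tuple[float, float, float]:
    """Point estimate alt/depth with an exact Clopper-Pearson interval.

    The bounds invert the binomial tail via beta quantiles:
    lower = Beta(alpha/2; k, n-k+1), upper = Beta(1-alpha/2; k+1, n-k),
    with the conventional 0 / 1 endpoints at k = 0 / k = n.
    """
    if rc.depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0,1)")
    k, n = rc.alt, rc.depth
    a = 1 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a / 2, k + 1, n - k))
    return k / n, lo, hi


# ---------------------------------------------------------------------------
# Classification decision table
# ---------------------------------------------------------------------------

def _two_tests(rc: ReadCounts, error_rate: float) -> tuple[float, float]:
    # two-sided exact binomial against the heterozygous null p = 0.5,
    # one-sided (upper tail) against the sequencing-error null p = error_rate
    p_het = float(stats.binomtest(rc.alt, rc.depth, 0.5).pvalue)
    p_err = float(stats.binom.sf(rc.alt - 1, rc.depth, error_rate))
    return p_het, p_err


def classify_parent(rc: ReadCounts,
                    error_rate: float = DEFAULT_ERROR_RATE,
                    alpha: float = DEFAULT_ALPHA,
                    confidence: float = DEFAULT_CONFIDENCE) -> MosaicCall:
    """Classify a parent's carrier state from one set of read counts.

    Decision table on the two exact binomial tests:

    ========================  ==========================================
    rejected nulls            classification
    ========================  ==========================================
    het and error             mosaic if VAF < 0.5 (mosaicism is
                              sub-heterozygous by definition), else
                              ambiguous
    het only                  absent if VAF <= error rate, else
                              possible_mosaic
    error only                heterozygous (VAF compatible with 0.5)
    neither                   ambiguous
    ========================  ==========================================
    """
    if not 0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if rc.depth < 1:
        raise ValueError("depth must be >= 1")
    p_het, p_err = _two_tests(rc, error_rate)
    vaf, lo, hi = estimate_vaf(rc, confidence)
    reject_het = p_het <= alpha
    reject_err = p_err <= alpha
    if reject_het and reject_err:
        cls = "mosaic" if vaf < 0.5 else "ambiguous"
    elif reject_het:
        cls = "absent" if vaf <= error_rate else "possible_mosaic"
    elif reject_err:
        cls = "heterozygous"
    else:
        cls = "ambiguous"
    return MosaicCall(vaf, lo, hi, p_het, p_err, cls, rc.alt, rc.depth)


def combine_evidence(counts: Iterable[ReadCounts],
                     error_rate: float = DEFAULT_ERROR_RATE,
                     alpha: float = DEFAULT_ALPHA,
                     confidence: float = DEFAULT_CONFIDENCE) -> MosaicCall:
    """Pool independent platforms by summing counts, then classify.

    Pooling assumes a shared underlying cell fraction and no
    platform-specific overdispersion.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("need at least one read-count set")
    pooled = ReadCounts(sum(c.alt for c in counts),
                        sum(c.depth for c in counts))
    return classify_parent(pooled, error_rate, alpha, confidence)


# ---------------------------------------------------------------------------
# Simplified trio de novo posterior
# ---------------------------------------------------------------------------

def _genotype_prior(af: float) -> np.ndarray:
    # Hardy-Weinberg prior over alt-allele counts {0, 1, 2}
    return np.array([(1 - af) ** 2, 2 * af * (1 - af), af ** 2])


def _gamete_alt_prob(g: int, mu: float) -> float:
    # probability a transmitted gamete carries the alt allele, with a
    # per-gamete mutation rate mu acting symmetrically
    base = g / 2
    return base * (1 - mu) + (1 - base) * mu


def _read_lik(rc: ReadCounts, g: int, error_rate: float) -> float:
    f = (error_rate, 0.5, 1 - error_rate)[g]
    return float(stats.binom.pmf(rc.alt, rc.depth, f))


def de_novo_posterior(trio: TrioReadCounts,
                      population_af: float = 1e-5,
                      mutation_rate: float = DEFAULT_MUTATION_RATE,
                      error_rate: float = DEFAULT_ERROR_RATE
                      ) -> DeNovoPosterior:
    """Posterior over trio genotype configurations; ppDNM is the mass where
    the child carries an alt allele absent from both parental genotypes.

    This is a deliberately simplified stand-in for a full trio caller:
    Hardy-Weinberg parental priors, Mendelian transmission with a per-gamete
    mutation rate, and binomial read likelihoods with genotype alt fractions
    error_rate / 0.5 / 1 - error_rate.
    """
    for name, val in (("population_af", population_af),
                      ("mutation_rate", mutation_rate),
                      ("error_rate", error_rate)):
        if not 0 < val < 1:
            raise ValueError(f"{name} must be in (0,1)")
    for member in (trio.proband, trio.mother, trio.father):
        if member.depth < 1:
            raise ValueError("zero depth in a trio member")

    prior = _genotype_prior(population_af)
    joint: dict[tuple[int, int, int], float] = {}
    for gm in range(3):
        for gf in range(3):
            pm = _gamete_alt_prob(gm, mutation_rate)
            pf = _gamete_alt_prob(gf, mutation_rate)
            trans = {
                0: (1 - pm) * (1 - pf),
                1: pm * (1 - pf) + (1 - pm) * pf,
                2: pm * pf,
            }
            for gc in range(3):
                lik = (_read_lik(trio.mother, gm, error_rate)
                       * _read_lik(trio.father, gf, error_rate)
                       * _read_lik(trio.proband, gc, error_rate))
                joint[(gm, gf, gc)] = (prior[gm] * prior[gf]
                                       * trans[gc] * lik)
    z = sum(joint.values())
    if z == 0:
        raise FloatingPointError("all trio configurations have zero "
                                 "likelihood")
    post = {k: v / z for k, v in joint.items()}
    ppdnm = 0.0
    for (gm, gf, gc), p in post.items():
        # child carries an alt allele absent from both parents: either both
        # parents are ref/ref and the child has any alt, or the child is
        # hom-alt while some parent has no alt allele to give
        if gc >= 1 and gm == 0 and gf == 0:
            ppdnm += p
        elif gc == 2 and (gm == 0 or gf == 0):
            ppdnm += p
    return DeNovoPosterior(ppdnm, post)


# ---------------------------------------------------------------------------
# Simulation helpers (used by calibration tests and the acceptance script)
# ---------------------------------------------------------------------------

def het_rejection_rate(n_reps: int, depth: int, seed: int,
                       alpha: float = DEFAULT_ALPHA) -> float:
    """Empirical rate at which true heterozygotes reject the het null."""
    rng = np.random.default_rng(seed)
    pvals = np.array([stats.binomtest(k, depth, 0.5).pvalue
                      for k in range(depth + 1)])
    draws = rng.binomial(depth, 0.5, size=n_reps)
    return float(np.mean(pvals[draws] <= alpha))


def exact_het_test_size(depth: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Analytical size of the discrete exact test at the given depth."""
    pvals = np.array([stats.binomtest(k, depth, 0.5).pvalue
                      for k in range(depth + 1)])
    pmf = stats.binom.pmf(np.arange(depth + 1), depth, 0.5)
    return float(pmf[pvals <= alpha].sum())


def mosaic_detection_rate(n_reps: int, depth: int, fraction: float,
                          seed: int,
                          error_rate: float = DEFAULT_ERROR_RATE,
                          alpha: float = DEFAULT_ALPHA) -> float:
    """Fraction of simulated mosaic parents classified ``mosaic``."""
    rng = np.random.default_rng(seed)
    draws = rng.binomial(depth, fraction, size=n_reps)
    hits = 0
    cache: dict[int, str] = {}
    for k in draws:
        k = int(k)
        if k not in cache:
            cache[k] = classify_parent(ReadCounts(k, depth), error_rate,
                                       alpha).classification
        hits += cache[k] == "mosaic"
    return hits / n_reps
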