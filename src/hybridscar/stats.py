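"""Organism-level statistics for intercross breeding and stem-cell assays.

Covers: exact two-sided binomial tests of observed birth frequencies
against the Mendelian 1/16 double-knockout expectation, with Bonferroni
adjustment and exact (Clopper-Pearson) confidence intervals; chi-square /
Monte-Carlo goodness of fit of litter genotype classes to the Mendelian
{1,2,1} x {1,2,1} / 16 distribution; and the single-hit limiting-dilution
model P(no engraftment | dose d) = exp(-f d) with maximum-likelihood
frequency estimation and likelihood-ratio comparison between cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

#: Mendelian double-knockout fraction from a double-heterozygote intercross.
MENDELIAN_DKO_FRACTION = 0.25 * 0.25

#: The 9 two-locus genotype classes and their Mendelian probabilities
#: ({1,2,1}/4 at each locus, independent loci).
TWO_LOCUS_CLASSES = [(a, b) for a in ("+/+", "+/-", "-/-") for b in ("+/+", "+/-", "-/-")]
TWO_LOCUS_PROBS = np.outer([0.25, 0.5, 0.25], [0.25, 0.5, 0.25]).ravel()


def expected_dko_fraction() -> float:
    """P(-/- at both loci) for independently segregating loci = 1/16."""
    return MENDELIAN_DKO_FRACTION


# ---------------------------------------------------------------------------
# binomial proportion tests


@dataclass
class TestResult:
    p_value: float
    p_adjusted: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    method: str = ""


def exact_binomial_test(x: int, n: int, p0: float, alternative: str = "two-sided",
                        method: str = "exact") -> float:
    """Test a binomial proportion against the null value ``p0``.

    The default is the exact test: the two-sided p-value sums the
    Binomial(n, p0) pmf over all outcomes no more likely than the observed
    one (the minimum-likelihood convention).  ``method="normal"`` gives the
    continuity-corrected normal approximation for comparison.
    """
    if not 0 <= x <= n or n <= 0:
        raise ValueError("require 0 <= x <= n with n > 0")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if method == "exact":
        return float(stats.binomtest(x, n, p0, alternative=alternative).pvalue)
    if method != "normal":
        raise ValueError(f"unknown method {method!r}")
    se = np.sqrt(p0 * (1 - p0) / n)
    cc = 0.5 / n
    diff = x / n - p0
    z = (abs(diff) - cc) / se if abs(diff) > cc else 0.0
    if alternative == "two-sided":
        return float(2 * stats.norm.sf(z))
    z_signed = (diff + (cc if diff < 0 else -cc)) / se
    if alternative == "greater":
        return float(stats.norm.sf(z_signed))
    if alternative == "less":
        return float(stats.norm.cdf(z_signed))
    raise ValueError(f"unknown alternative {alternative!r}")


def clopper_pearson_ci(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) confidence interval for a binomial proportion."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("require 0 <= x <= n with n > 0")
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: multiply by the number of tests, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(p * m, 1.0)


@dataclass
class BreedCounts:
    """Weaned-pup counts for one double-heterozygote intercross breed."""

    breed: str
    n_weaned: int
    n_dko: int
    p0: float = MENDELIAN_DKO_FRACTION

    def __post_init__(self):
        if not 0 <= self.n_dko <= self.n_weaned:
            raise ValueError("require 0 <= n_dko <= n_weaned")
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0, 1)")


def breeding_frequency_tests(breeds: list[BreedCounts], alpha: float = 0.05,
                              method: str = "exact") -> pd.DataFrame:
    """Test each breed's DKO birth frequency against Mendelian expectation.

    Two-sided exact binomial test per breed, Bonferroni-adjusted across
    breeds, with exact 95% confidence intervals on the observed fraction.
    """
    raw = [exact_binomial_test(b.n_dko, b.n_weaned, b.p0, method=method)
           for b in breeds]
    adj = bonferroni(raw)
    rows = []
    for b, p, pa in zip(breeds, raw, adj):
        lo, hi = clopper_pearson_ci(b.n_dko, b.n_weaned, alpha)
        rows.append((b.breed, b.n_weaned, b.n_dko, b.n_dko / b.n_weaned,
                     b.p0, p, pa, lo, hi))
    return pd.DataFrame(rows, columns=["breed", "n_weaned", "n_dko", "fraction",
                                       "p0", "p_value", "p_adjusted",
                                       "ci_low", "ci_high"])


# ---------------------------------------------------------------------------
# Mendelian goodness of fit


@dataclass
class LitterClassCounts:
    """Counts over the 9 two-locus genotype classes of an intercross litter."""

    counts: np.ndarray
    expected_probs: np.ndarray = field(default_factory=lambda: TWO_LOCUS_PROBS.copy())

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.expected_probs = np.asarray(self.expected_probs, dtype=float)
        if self.counts.shape != self.expected_probs.shape:
            raise ValueError("counts and expected_probs must have the same length")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if not np.isclose(self.expected_probs.sum(), 1.0):
            raise ValueError("expected probabilities must sum to 1")


@dataclass
class GofResult:
    statistic: float
    p_value: float
    residuals: np.ndarray  # Pearson residuals per class
    method: str


def mendelian_gof(litter: LitterClassCounts, n_mc: int = 9999,
                  rng: np.random.Generator | None = None) -> GofResult:
    """Goodness of fit of litter genotype counts to Mendelian expectation.

    Chi-square with df = classes - 1 when every expected count is >= 5;
    otherwise (small litters) a seeded Monte-Carlo multinomial p-value on
    the same statistic, with the method tagged in the result.
    """
    total = int(litter.counts.sum())
    if total == 0:
        raise ValueError("litter has no embryos")
    expected = litter.expected_probs * total
    resid = (litter.counts - expected) / np.sqrt(expected)
    statistic = float((resid ** 2).sum())
    if (expected >= 5).all():
        p = float(stats.chi2.sf(statistic, df=len(expected) - 1))
        return GofResult(statistic, p, resid, "chi-square")
    if rng is None:
        rng = np.random.default_rng(0)
    sims = rng.multinomial(total, litter.expected_probs, size=n_mc)
    sim_stat = ((sims - expected) ** 2 / expected).sum(axis=1)
    p = float((1 + (sim_stat >= statistic - 1e-9).sum()) / (n_mc + 1))
    return GofResult(statistic, p, resid, "monte-carlo")


# ---------------------------------------------------------------------------
# single-hit limiting-dilution model


@dataclass
class LimitingDilutionAssay:
    """Dose-response rows of a limiting-dilution (competitive repopulation)
    assay: cells injected, mice tested, mice negative for engraftment."""

    group: str
    dose: np.ndarray
    n_tested: np.ndarray
    n_negative: np.ndarray

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        self.n_tested = np.asarray(self.n_tested, dtype=np.int64)
        self.n_negative = np.asarray(self.n_negative, dtype=np.int64)
        if not (self.dose >= 0).all():
            raise ValueError("doses must be >= 0")
        if ((self.n_negative < 0) | (self.n_negative > self.n_tested)).any():
            raise ValueError("require 0 <= n_negative <= n_tested")


@dataclass
class SingleHitFit:
    frequency: float           # active-cell frequency f
    log_likelihood: float
    ci_low: float | None       # Wald CI on log f, mapped back
    ci_high: float | None
    identifiable: bool


def _single_hit_loglik(log_f: float, assay: LimitingDilutionAssay) -> float:
    """Binomial log-likelihood of the single-hit model at log frequency."""
    f = np.exp(log_f)
    log_p_neg = -f * assay.dose                      # log P(negative)
    log_p_pos = np.log(-np.expm1(-np.maximum(f * assay.dose, 1e-300)))
    k = assay.n_negative
    n = assay.n_tested
    const = special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
    return float(np.sum(const + k * log_p_neg + (n - k) * log_p_pos))


def fit_single_hit(assay: LimitingDilutionAssay, alpha: float = 0.05) -> SingleHitFit:
    """Maximum-likelihood frequency under P(negative | dose d) = exp(-f d).

    One-dimensional optimization over log f.  With a single informative
    dose this reproduces the closed form f = -ln(k/n)/d.  All-negative or
    all-positive data give a boundary estimate flagged non-identifiable.
    """
    informative = (assay.dose > 0) & (assay.n_tested > 0)
    if not informative.any():
        raise ValueError("assay has no informative dose")
    k = assay.n_negative[informative]
    n = assay.n_tested[informative]
    d = assay.dose[informative]
    if (k == n).all():
        return SingleHitFit(0.0, 0.0, None, None, False)
    if (k == 0).all():
        return SingleHitFit(np.inf, 0.0, None, None, False)
    # crude moment start: pooled fraction negative
    frac = max(min(k.sum() / n.sum(), 1 - 1e-9), 1e-9)
    x0 = np.log(-np.log(frac) / np.average(d, weights=n))
    res = optimize.minimize_scalar(
        lambda lf: -_single_hit_loglik(lf, assay),
        bracket=(x0 - 2, x0, x0 + 2) if np.isfinite(x0) else None,
        bounds=(x0 - 30, x0 + 30), method="bounded",
        options={"xatol": 1e-12})
    log_f = float(res.x)
    ll = -float(res.fun)
    # observed information on log f by central difference
    h = 1e-4
    info = -(_single_hit_loglik(log_f + h, assay)
             - 2 * ll + _single_hit_loglik(log_f - h, assay)) / h ** 2
    if info > 0:
        z = stats.norm.ppf(1 - alpha / 2)
        se = 1 / np.sqrt(info)
        ci = (float(np.exp(log_f - z * se)), float(np.exp(log_f + z * se)))
    else:
        ci = (None, None)
    return SingleHitFit(float(np.exp(log_f)), ll, ci[0], ci[1], True)


def _pooled(assays: list[LimitingDilutionAssay]) -> LimitingDilutionAssay:
    return LimitingDilutionAssay(
        "+".join(a.group for a in assays),
        np.concatenate([a.dose for a in assays]),
        np.concatenate([a.n_tested for a in assays]),
        np.concatenate([a.n_negative for a in assays]))


@dataclass
class LrtResult:
    statistic: float
    p_value: float
    fit_a: SingleHitFit
    fit_b: SingleHitFit
    fit_shared: SingleHitFit


def lrt_compare(assay_a: LimitingDilutionAssay, assay_b: LimitingDilutionAssay
                ) -> LrtResult:
    """Likelihood-ratio test of equal single-hit frequencies in two groups.

    statistic = 2 (l(f_a) + l(f_b) - l(f_shared)); p from the asymptotic
    chi-square with 1 df.  Non-identifiable component fits propagate their
    flag (the p-value is still reported from the boundary likelihoods).
    """
    fa = fit_single_hit(assay_a)
    fb = fit_single_hit(assay_b)
    fs = fit_single_hit(_pooled([assay_a, assay_b]))
    statistic = max(0.0, 2 * (fa.log_likelihood + fb.log_likelihood
                              - fs.log_likelihood))
    p = float(stats.chi2.sf(statistic, df=1))
    return LrtResult(statistic, p, fa, fb, fs)
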