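"""Expected-count reconstruction, count log-likelihoods, and the LRT.

Two likelihood models are used downstream: a multinomial model over channel
proportions (presence filtering) and an independent per-channel negative
binomial model with a shared dispersion (forward search).  Nested maximized
models are compared with a chi-square likelihood ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from sigattr.catalogs_spectra import Attribution, SignatureCatalog, Spectrum

__all__ = [
    "ExpectedCounts",
    "LrtResult",
    "expected_counts",
    "floor_means",
    "multinomial_loglik",
    "negbinom_loglik",
    "likelihood_ratio_test",
]

#: Relative floor applied to expected counts before forming probabilities
#: or negative-binomial means; keeps log-likelihoods finite when a model
#: puts zero mass on an observed channel, while preserving their ordering.
MEAN_FLOOR = 1e-10


def floor_means(values: np.ndarray) -> np.ndarray:
    """Floor expected counts at ``MEAN_FLOOR * max(1, sum(values))``."""
    values = np.asarray(values, dtype=float)
    floor = MEAN_FLOOR * max(1.0, float(values.sum()))
    return np.maximum(values, floor)


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected per-channel counts c = H x A and the derived proportions."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if (values < 0).any():
            raise ValueError("expected counts must be non-negative")
        object.__setattr__(self, "values", values)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    @property
    def pi(self) -> np.ndarray:
        """Multinomial parameter vector (floored, exactly normalized)."""
        floored = floor_means(self.values)
        return floored / floored.sum()


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test statistic, degrees of freedom, and p-value."""

    lam: float
    df: int
    p_value: float


def expected_counts(
    catalog: SignatureCatalog, attribution: Attribution
) -> ExpectedCounts:
    """Reconstruction H x A for the given activities.

    Signatures absent from the attribution contribute nothing; an empty
    attribution yields the all-zero reconstruction.
    """
    if not attribution.activities:
        return ExpectedCounts(np.zeros(catalog.scheme.k))
    names = sorted(attribution.activities)
    sub = catalog.restrict(names)  # raises KeyError on unknown names
    a = np.array([attribution.activities[n] for n in names])
    return ExpectedCounts(sub.matrix @ a)


def multinomial_loglik(spectrum: Spectrum, expected: ExpectedCounts) -> float:
    """Multinomial log-likelihood of the observed spectrum.

    Includes the multinomial coefficient, computed via log-gamma:
    ``log[(sum d)! / prod(d_i!)] + sum d_i log(pi_i)``.
    """
    d = spectrum.counts
    if expected.total <= 0:
        raise ValueError("expected counts sum to zero; likelihood undefined")
    if spectrum.total <= 0:
        raise ValueError("empty spectrum; multinomial likelihood undefined")
    pi = expected.pi
    coef = gammaln(d.sum() + 1) - gammaln(d + 1).sum()
    return float(coef + np.dot(d, np.log(pi)))


def negbinom_loglik(
    spectrum: Spectrum, expected: ExpectedCounts, dispersion: float
) -> float:
    """Sum over channels of log NB(d_i | mean=c_i, size=dispersion).

    Parameterization: size r and mean mu, variance mu + mu^2/r, so
    success probability p = r / (r + mu).
    """
    if dispersion <= 0:
        raise ValueError(f"dispersion must be positive, got {dispersion}")
    mu = floor_means(expected.values)
    p = dispersion / (dispersion + mu)
    return float(stats.nbinom.logpmf(spectrum.counts, dispersion, p).sum())


def likelihood_ratio_test(
    loglik_sub: float, loglik_full: float, df: int
) -> LrtResult:
    """Chi-square LRT of a sub-model against the nesting full model.

    lambda = -2 (loglik_sub - loglik_full), clamped at zero (negative
    values can only arise from optimizer noise in nested maximized fits).
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    lam = max(0.0, -2.0 * (loglik_sub - loglik_full))
    p_value = float(stats.chi2.sf(lam, df))
    return LrtResult(lam=lam, df=df, p_value=p_value)
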