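"""Fit non-negative activities for a fixed signature subset.

Two routes: exact non-negative least squares (convex, global optimum) and
maximum likelihood under the multinomial or negative-binomial count model.
The MLE route runs bounded L-BFGS-B over log-activities with analytic
gradients, initialized at the NNLS solution, so it is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from sigattr.catalogs_spectra import Attribution, SignatureCatalog, Spectrum
from sigattr.likelihood_models import floor_means

__all__ = ["FitResult", "nnls_fit", "mle_fit"]

_MAX_EVALS = 2000
_FTOL = 1e-8


@dataclass(frozen=True)
class FitResult:
    """Outcome of an activity fit for one signature subset."""

    attribution: Attribution
    #: residual L2 norm for NNLS; achieved log-likelihood for MLE
    objective: float
    converged: bool
    n_evals: int


def nnls_fit(spectrum: Spectrum, catalog: SignatureCatalog) -> FitResult:
    """Minimize ||D - H A||_2 subject to A >= 0 (global optimum)."""
    if catalog.g == 0:
        raise ValueError("signature subset is empty")
    d = spectrum.counts.astype(float)
    acts, _ = optimize.nnls(catalog.matrix, d)
    residual = float(np.linalg.norm(d - catalog.matrix @ acts))
    attribution = Attribution(
        spectrum.sample_id, dict(zip(catalog.names, acts))
    )
    return FitResult(
        attribution=attribution,
        objective=residual,
        converged=True,
        n_evals=1,
    )


def _neg_multinomial(t, H, d, M):
    a = np.exp(t)
    c = floor_means(H @ a)
    C = c.sum()
    ll = float(np.dot(d, np.log(c / C)))
    grad_a = H.T @ (d / c) - M * (H.sum(axis=0) / C)
    return -ll, -(grad_a * a)


def _neg_negbinom(t, H, d, r):
    a = np.exp(t)
    c = floor_means(H @ a)
    ll = float(
        np.sum(
            gammaln(d + r)
            - gammaln(r)
            - gammaln(d + 1)
            + r * np.log(r / (r + c))
            + d * np.log(c / (r + c))
        )
    )
    grad_a = H.T @ (d / c - (d + r) / (r + c))
    return -ll, -(grad_a * a)


def mle_fit(
    spectrum: Spectrum,
    catalog: SignatureCatalog,
    model: str = "multinomial",
    dispersion: float = 100.0,
) -> FitResult:
    """Maximize the chosen count log-likelihood over non-negative activities.

    Parameters
    ----------
    model:
        ``"multinomial"`` (the total activity is unidentifiable; the result
        is rescaled to sum to ``spectrum.total``) or ``"negbinom"``.
    dispersion:
        Negative-binomial size parameter (ignored for the multinomial).
    """
    if catalog.g == 0:
        raise ValueError("signature subset is empty")
    if spectrum.total <= 0:
        raise ValueError("empty spectrum")
    if model not in {"multinomial", "negbinom"}:
        raise ValueError(f"unknown model {model!r}")
    if dispersion <= 0:
        raise ValueError(f"dispersion must be positive, got {dispersion}")

    H = catalog.matrix
    d = spectrum.counts.astype(float)
    M = float(spectrum.total)

    if model == "multinomial":
        fun, args = _neg_multinomial, (H, d, M)
    else:
        fun, args = _neg_negbinom, (H, d, float(dispersion))

    # NNLS warm start; zeros lifted off the boundary of the log transform
    a0 = nnls_fit(spectrum, catalog).attribution.as_vector(catalog.names)
    a0 = np.maximum(a0, 1e-4 * M)
    lo, hi = np.log(1e-10 * M), np.log(10.0 * M)
    bounds = [(lo, hi)] * catalog.g

    def run(start: np.ndarray):
        return optimize.minimize(
            fun,
            np.clip(np.log(start), lo, hi),
            args=args,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxfun": _MAX_EVALS, "ftol": _FTOL, "gtol": 1e-10},
        )

    res = run(a0)
    n_evals = int(res.nfev)
    if not res.success:
        retry = run(a0 * 1.5 + 1e-3 * M)  # deterministic perturbed restart
        n_evals += int(retry.nfev)
        if retry.fun <= res.fun:
            res = retry

    acts = np.exp(res.x)
    if model == "multinomial":
        acts = acts * (M / acts.sum())
        objective = -_neg_multinomial(np.log(acts), H, d, M)[0] + _multinomial_coef(d)
    else:
        objective = -float(res.fun)

    attribution = Attribution(
        spectrum.sample_id, dict(zip(catalog.names, acts))
    )
    return FitResult(
        attribution=attribution,
        objective=float(objective),
        converged=bool(res.success),
        n_evals=n_evals,
    )


def _multinomial_coef(d: np.ndarray) -> float:
    return float(gammaln(d.sum() + 1) - gammaln(d + 1).sum())
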