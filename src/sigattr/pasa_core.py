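"""Two-step sparse signature attribution.

Step 1 runs a leave-one-out presence test for every offered signature under
the multinomial likelihood: a signature is retained only if removing it
significantly worsens the best achievable fit (chi-square LRT, df = 1).

Step 2 runs a greedy forward search over the survivors under the
negative-binomial likelihood, starting from the empty set: each iteration
adds the candidate giving the largest fitted log-likelihood, and stops the
first time the add-one LRT is non-significant.  The first addition is
unconditional (the empty model has no defined likelihood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from sigattr.activity_optimizers import mle_fit
from sigattr.catalogs_spectra import (
    Attribution,
    SignatureCatalog,
    Spectrum,
    cosine_similarity,
)
from sigattr.likelihood_models import (
    ExpectedCounts,
    LrtResult,
    expected_counts,
    likelihood_ratio_test,
)

__all__ = [
    "PasaConfig",
    "PresenceTestReport",
    "AttributionResult",
    "presence_filter",
    "forward_search",
    "attribute",
    "signature_presence_test",
]

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class PasaConfig:
    """Tunables for the two-step attribution.

    alpha is the significance level for both the presence tests and the
    forward-search stopping rule.  dispersion is the Step-2
    negative-binomial size parameter.
    """

    alpha: float = 0.01
    dispersion: float = 100.0
    max_signatures: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")


@dataclass(frozen=True)
class PresenceTestReport:
    signature: str
    lrt: LrtResult | None
    retained: bool


@dataclass(frozen=True)
class AttributionResult:
    attribution: Attribution
    step1_reports: tuple[PresenceTestReport, ...]
    addition_trace: tuple[tuple[str, float], ...]
    reconstruction: ExpectedCounts
    reconstruction_cosine: float
    final_loglik: float
    warnings: tuple[str, ...] = field(default_factory=tuple)


def presence_filter(
    spectrum: Spectrum, catalog: SignatureCatalog, config: PasaConfig
) -> tuple[list[str], list[PresenceTestReport]]:
    """Leave-one-out presence tests for every signature in the catalog.

    Returns the survivor name list V (catalog order) and per-signature
    reports.  Each test compares the best multinomial fit without the
    signature to the best fit with the full catalog (df = 1); the result
    does not depend on testing order.  A single-signature catalog is
    retained untested (the reduced model would be empty).
    """
    if catalog.g == 0:
        raise ValueError("catalog is empty")
    if spectrum.total <= 0:
        raise ValueError("empty spectrum")
    if catalog.g == 1:
        return list(catalog.names), [
            PresenceTestReport(catalog.names[0], None, True)
        ]

    full = mle_fit(spectrum, catalog, model="multinomial")
    reports = []
    for name in catalog.names:
        reduced = mle_fit(spectrum, catalog.drop(name), model="multinomial")
        lrt = likelihood_ratio_test(reduced.objective, full.objective, df=1)
        reports.append(
            PresenceTestReport(name, lrt, lrt.p_value < config.alpha)
        )
    survivors = [r.signature for r in reports if r.retained]
    return survivors, reports


def signature_presence_test(
    spectrum: Spectrum,
    catalog: SignatureCatalog,
    target: str,
    config: PasaConfig | None = None,
) -> PresenceTestReport:
    """Standalone presence test for one signature against the catalog."""
    config = config or PasaConfig()
    if target not in catalog.names:
        raise KeyError(f"unknown signature {target!r}")
    if catalog.g == 1:
        return PresenceTestReport(target, None, True)
    full = mle_fit(spectrum, catalog, model="multinomial")
    reduced = mle_fit(spectrum, catalog.drop(target), model="multinomial")
    lrt = likelihood_ratio_test(reduced.objective, full.objective, df=1)
    return PresenceTestReport(target, lrt, lrt.p_value < config.alpha)


def forward_search(
    spectrum: Spectrum,
    survivors: SignatureCatalog,
    config: PasaConfig,
    step1_reports: tuple[PresenceTestReport, ...] = (),
) -> AttributionResult:
    """Greedy forward search with LRT stopping over the survivor catalog."""
    if survivors.g == 0:
        raise ValueError("survivor catalog is empty")
    if spectrum.total <= 0:
        raise ValueError("empty spectrum")

    selected: list[str] = []
    trace: list[tuple[str, float]] = []
    current_ll = float("-inf")
    current_fit = None
    remaining = list(survivors.names)
    cap = config.max_signatures or survivors.g

    while remaining and len(selected) < cap:
        best_name, best_fit = None, None
        for name in sorted(remaining):  # lexicographic tie-break
            fit = mle_fit(
                spectrum,
                survivors.restrict(selected + [name]),
                model="negbinom",
                dispersion=config.dispersion,
            )
            if best_fit is None or fit.objective > best_fit.objective + _TIE_TOL:
                best_name, best_fit = name, fit
        assert best_name is not None and best_fit is not None

        if not selected:
            # unconditional first addition: the empty model has no likelihood
            p_value = 0.0
        else:
            p_value = likelihood_ratio_test(
                current_ll, best_fit.objective, df=1
            ).p_value
            if p_value > config.alpha:
                break
        selected.append(best_name)
        remaining.remove(best_name)
        trace.append((best_name, p_value))
        current_ll = best_fit.objective
        current_fit = best_fit

    assert current_fit is not None
    attribution = current_fit.attribution
    recon = expected_counts(survivors, attribution)
    return AttributionResult(
        attribution=attribution,
        step1_reports=tuple(step1_reports),
        addition_trace=tuple(trace),
        reconstruction=recon,
        reconstruction_cosine=cosine_similarity(
            spectrum.counts, recon.values
        ),
        final_loglik=current_ll,
    )


def attribute(
    spectrum: Spectrum,
    catalog: SignatureCatalog,
    config: PasaConfig | None = None,
) -> AttributionResult:
    """Full two-step attribution of one spectrum.

    If no signature survives Step 1 (possible for flat spectra), Step 2
    falls back to the full catalog.  A zero-count spectrum yields an empty
    attribution with a warning record.
    """
    config = config or PasaConfig()
    if spectrum.total == 0:
        msg = f"sample {spectrum.sample_id!r}: zero-count spectrum"
        warnings.warn(msg, stacklevel=2)
        return AttributionResult(
            attribution=Attribution(spectrum.sample_id, {}),
            step1_reports=(),
            addition_trace=(),
            reconstruction=expected_counts(
                catalog, Attribution(spectrum.sample_id, {})
            ),
            reconstruction_cosine=float("nan"),
            final_loglik=float("nan"),
            warnings=(msg,),
        )

    survivors, reports = presence_filter(spectrum, catalog, config)
    notes: tuple[str, ...] = ()
    if not survivors:
        notes = (
            f"sample {spectrum.sample_id!r}: no signature survived the "
            "presence filter; forward search ran on the full catalog",
        )
        survivor_catalog = catalog
    else:
        survivor_catalog = catalog.restrict(survivors)

    result = forward_search(
        spectrum, survivor_catalog, config, step1_reports=tuple(reports)
    )
    if notes:
        result = AttributionResult(
            attribution=result.attribution,
            step1_reports=result.step1_reports,
            addition_trace=result.addition_trace,
            reconstruction=result.reconstruction,
            reconstruction_cosine=result.reconstruction_cosine,
            final_loglik=result.final_loglik,
            warnings=notes,
        )
    return result
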