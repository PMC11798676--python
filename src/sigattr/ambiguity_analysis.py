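"""Exhaustive subset enumeration quantifying attribution ambiguity.

Every nonempty signature subset is refit by NNLS; attributions are counted
as distinct by their post-fit positive-activity support (two offered
subsets can collapse to the same support when NNLS zeroes extras).  An
attribution "passes" when its reconstruction cosine exceeds a threshold;
a second, optional filter requires every activity to account for at least
a minimum proportion of the sample's mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from sigattr.activity_optimizers import nnls_fit
from sigattr.catalogs_spectra import (
    Attribution,
    SignatureCatalog,
    Spectrum,
    cosine_similarity,
)

__all__ = [
    "EnumerationConfig",
    "PassingAttribution",
    "EnumerationResult",
    "BestVsTruthRow",
    "AmbiguityReport",
    "enumerate_attributions",
    "best_vs_truth",
]

#: NNLS support membership: activity > this fraction of the sample total
_SUPPORT_REL_TOL = 1e-6


@dataclass(frozen=True)
class EnumerationConfig:
    cosine_threshold: float = 0.969
    min_activity_proportion: float = 0.03
    max_signatures_for_enumeration: int = 22

    def __post_init__(self) -> None:
        if not 0.0 < self.cosine_threshold < 1.0:
            raise ValueError("cosine_threshold must be in (0,1)")
        if not 0.0 <= self.min_activity_proportion < 1.0:
            raise ValueError("min_activity_proportion must be in [0,1)")


@dataclass(frozen=True)
class PassingAttribution:
    support: frozenset[str]
    activities: dict[str, float]
    cosine: float
    passes_filter: bool  # every activity >= min proportion of mutations


@dataclass(frozen=True)
class EnumerationResult:
    sample_id: str
    n_subsets_tested: int
    passing: tuple[PassingAttribution, ...]
    n_passing_unfiltered: int
    n_passing_filtered: int
    best: PassingAttribution | None
    best_filtered: PassingAttribution | None
    #: best cosine over ALL enumerated supports, passing or not
    best_any_cosine: float
    #: cosine achieved by a given reference support, when requested
    truth_support_cosine: float | None = None


def _fit_support(
    spectrum: Spectrum, catalog: SignatureCatalog, names: Sequence[str]
) -> tuple[frozenset[str], dict[str, float], float]:
    fit = nnls_fit(spectrum, catalog.restrict(names))
    tol = _SUPPORT_REL_TOL * max(1, spectrum.total)
    acts = {n: a for n, a in fit.attribution.activities.items() if a > tol}
    support = frozenset(acts)
    if not support:
        return support, {}, 0.0
    recon = sum(
        a * catalog.column(n) for n, a in acts.items()
    )
    return support, acts, cosine_similarity(spectrum.counts, recon)


def enumerate_attributions(
    spectrum: Spectrum,
    catalog: SignatureCatalog,
    config: EnumerationConfig | None = None,
    truth_support: frozenset[str] | None = None,
) -> EnumerationResult:
    """NNLS-refit every nonempty signature subset of the catalog.

    Iterates subsets by increasing size then lexicographically; results
    are deduplicated by fitted support.  If *truth_support* is given, the
    cosine achievable by NNLS on exactly that support is also recorded.
    """
    config = config or EnumerationConfig()
    g = catalog.g
    if g > config.max_signatures_for_enumeration:
        raise ValueError(
            f"catalog has {g} signatures, above the enumeration cap "
            f"{config.max_signatures_for_enumeration}; raise "
            "max_signatures_for_enumeration deliberately if intended"
        )
    if spectrum.total == 0:
        raise ValueError("cannot enumerate attributions of a zero spectrum")

    names = sorted(catalog.names)
    seen: dict[frozenset[str], PassingAttribution] = {}
    n_tested = 0
    best_any_cosine = 0.0
    min_act = config.min_activity_proportion * spectrum.total
    for size in range(1, g + 1):
        for combo in combinations(names, size):
            n_tested += 1
            support, acts, cos = _fit_support(spectrum, catalog, combo)
            if not support or support in seen:
                continue
            best_any_cosine = max(best_any_cosine, cos)
            passes_filter = all(a >= min_act for a in acts.values())
            seen[support] = PassingAttribution(
                support=support,
                activities=acts,
                cosine=cos,
                passes_filter=passes_filter,
            )

    passing = tuple(
        pa for pa in seen.values() if pa.cosine > config.cosine_threshold
    )
    filtered = [pa for pa in passing if pa.passes_filter]
    best = max(passing, key=lambda pa: pa.cosine, default=None)
    best_filtered = max(filtered, key=lambda pa: pa.cosine, default=None)

    truth_cos = None
    if truth_support is not None:
        _, _, truth_cos = _fit_support(
            spectrum, catalog, sorted(truth_support)
        )
    return EnumerationResult(
        sample_id=spectrum.sample_id,
        n_subsets_tested=n_tested,
        passing=passing,
        n_passing_unfiltered=len(passing),
        n_passing_filtered=len(filtered),
        best=best,
        best_filtered=best_filtered,
        best_any_cosine=best_any_cosine,
        truth_support_cosine=truth_cos,
    )


@dataclass(frozen=True)
class BestVsTruthRow:
    sample_id: str
    truth_support: frozenset[str]
    truth_support_cosine: float
    best_any_cosine: float
    truth_beaten: bool  # some alternative support reconstructs better
    best_filtered_support: frozenset[str] | None
    best_equals_truth: bool
    fn: int  # in truth, missing from best filtered attribution
    fp: int  # in best filtered attribution, absent from truth


@dataclass(frozen=True)
class AmbiguityReport:
    rows: tuple[BestVsTruthRow, ...]
    mean_fn: float
    mean_fp: float
    n_truth_beaten: int
    n_best_equals_truth: int
    mean_passing_unfiltered: float
    mean_passing_filtered: float


def best_vs_truth(
    samples,
    catalog: SignatureCatalog,
    config: EnumerationConfig | None = None,
) -> AmbiguityReport:
    """Compare best enumerated attributions with ground truth per sample."""
    config = config or EnumerationConfig()
    rows = []
    n_unf, n_fil = [], []
    for gs in samples:
        truth_support = frozenset(gs.truth.signatures)
        res = enumerate_attributions(
            gs.spectrum, catalog, config, truth_support=truth_support
        )
        n_unf.append(res.n_passing_unfiltered)
        n_fil.append(res.n_passing_filtered)
        best_f = res.best_filtered
        bf_support = best_f.support if best_f is not None else None
        fn = len(truth_support - (bf_support or frozenset()))
        fp = len((bf_support or frozenset()) - truth_support)
        rows.append(
            BestVsTruthRow(
                sample_id=gs.spectrum.sample_id,
                truth_support=truth_support,
                truth_support_cosine=float(res.truth_support_cosine),
                best_any_cosine=res.best_any_cosine,
                truth_beaten=res.best_any_cosine
                > float(res.truth_support_cosine),
                best_filtered_support=bf_support,
                best_equals_truth=bf_support == truth_support,
                fn=fn,
                fp=fp,
            )
        )
    return AmbiguityReport(
        rows=tuple(rows),
        mean_fn=float(np.mean([r.fn for r in rows])),
        mean_fp=float(np.mean([r.fp for r in rows])),
        n_truth_beaten=sum(r.truth_beaten for r in rows),
        n_best_equals_truth=sum(r.best_equals_truth for r in rows),
        mean_passing_unfiltered=float(np.mean(n_unf)),
        mean_passing_filtered=float(np.mean(n_fil)),
    )
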