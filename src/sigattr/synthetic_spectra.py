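"""Synthetic tumor spectra with known ground-truth attributions.

Generation scheme, per sample: each signature of a cancer type is present
independently with its observed prevalence; present signatures draw a
positive activity from a per-signature negative binomial (size, mu); the
per-channel counts contributed by a signature are negative-binomial draws
centered on activity x channel probability, summed over signatures.

The negative binomial is parameterized throughout by (size, mu) with
variance mu + mu^2/size.  A shared per-channel dispersion can be
calibrated so the median cosine between spectra and their ground-truth
reconstructions hits a target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

from sigattr.catalogs_spectra import (
    Attribution,
    SignatureCatalog,
    Spectrum,
    cosine_similarity,
)
from sigattr.likelihood_models import expected_counts

__all__ = [
    "SignatureActivityModel",
    "GeneratorParams",
    "GroundTruthSample",
    "fit_generator_params",
    "sample_ground_truth",
    "sample_spectrum",
    "generate_dataset",
    "calibrate_dispersion",
]

_SIZE_UPPER = 1e6  # Poisson-like ceiling for the fitted size parameter
_SIZE_LOWER = 1e-3
_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class SignatureActivityModel:
    """Prevalence and activity distribution for one signature."""

    name: str
    prevalence: float
    activity_size: float | None = None
    activity_mu: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence outside [0,1]: {self.prevalence}")
        if self.prevalence > 0:
            if self.activity_size is None or self.activity_mu is None:
                raise ValueError(
                    f"{self.name}: active signature needs (size, mu)"
                )
            if self.activity_size <= 0 or self.activity_mu <= 0:
                raise ValueError(f"{self.name}: size and mu must be positive")


@dataclass(frozen=True)
class GeneratorParams:
    """Per-cancer-type generation parameters."""

    cancer_type: str
    signatures: tuple[SignatureActivityModel, ...]
    #: per-signature channel-sampling size parameter; a single float is
    #: shared across signatures
    channel_dispersion: float | Mapping[str, float] = 100.0

    def dispersion_for(self, name: str) -> float:
        if isinstance(self.channel_dispersion, Mapping):
            return float(self.channel_dispersion[name])
        return float(self.channel_dispersion)

    def with_dispersion(
        self, dispersion: float | Mapping[str, float]
    ) -> "GeneratorParams":
        return GeneratorParams(self.cancer_type, self.signatures, dispersion)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cancer_type": self.cancer_type,
            "channel_dispersion": (
                dict(self.channel_dispersion)
                if isinstance(self.channel_dispersion, Mapping)
                else self.channel_dispersion
            ),
            "signatures": [
                {
                    "name": s.name,
                    "prevalence": s.prevalence,
                    "activity_size": s.activity_size,
                    "activity_mu": s.activity_mu,
                }
                for s in self.signatures
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            cancer_type=payload["cancer_type"],
            signatures=tuple(
                SignatureActivityModel(**rec) for rec in payload["signatures"]
            ),
            channel_dispersion=payload["channel_dispersion"],
        )


@dataclass(frozen=True)
class GroundTruthSample:
    """A synthetic spectrum together with its generating truth."""

    spectrum: Spectrum
    truth: Attribution
    cancer_type: str
    seed_path: tuple[int, ...] = field(default_factory=tuple)
    truth_reconstruction_cosine: float = float("nan")


def _nb_negloglik(params: np.ndarray, x: np.ndarray) -> float:
    log_size, log_mu = params
    r, mu = np.exp(log_size), np.exp(log_mu)
    p = r / (r + mu)
    ll = (
        gammaln(x + r)
        - gammaln(r)
        - gammaln(x + 1)
        + r * np.log(p)
        + x * np.log1p(-p)
    )
    return -float(ll.sum())


def _fit_negbinom(x: np.ndarray) -> tuple[float, float]:
    """(size, mu) MLE with method-of-moments start; bounded fallback."""
    x = np.asarray(x, dtype=float)
    mu0 = float(x.mean())
    var = float(x.var(ddof=1)) if x.size > 1 else 0.0
    if x.size == 1:
        return 1.0, mu0
    if var <= mu0:  # under-dispersed: push toward the Poisson limit
        size0 = _SIZE_UPPER
    else:
        size0 = mu0**2 / (var - mu0)
    size0 = float(np.clip(size0, _SIZE_LOWER, _SIZE_UPPER))
    res = optimize.minimize(
        _nb_negloglik,
        np.log([size0, max(mu0, 1e-6)]),
        args=(x,),
        method="L-BFGS-B",
        bounds=[
            (np.log(_SIZE_LOWER), np.log(_SIZE_UPPER)),
            (np.log(1e-6), np.log(max(mu0 * 100, 1.0))),
        ],
    )
    if res.success:
        size, mu = np.exp(res.x)
    else:
        size, mu = size0, mu0
    return float(size), float(mu)


def fit_generator_params(
    activity_table: pd.DataFrame,
    cancer_type: str,
    channel_dispersion: float | Mapping[str, float] = 100.0,
) -> GeneratorParams:
    """Fit per-signature prevalence and NB activity models from a cohort.

    *activity_table* is signatures x samples, non-negative.  Prevalence is
    the fraction of samples with activity > 0; (size, mu) are fitted to
    the positive activities only.
    """
    if (activity_table.to_numpy() < 0).any():
        raise ValueError("negative activities in table")
    if activity_table.shape[1] < 2:
        raise ValueError("need >= 2 samples to fit generator parameters")
    models = []
    for name, row in activity_table.iterrows():
        vals = row.to_numpy(dtype=float)
        positive = vals[vals > 0]
        prevalence = positive.size / vals.size
        if positive.size == 0:
            models.append(SignatureActivityModel(str(name), 0.0))
            continue
        size, mu = _fit_negbinom(positive)
        models.append(
            SignatureActivityModel(str(name), prevalence, size, mu)
        )
    return GeneratorParams(cancer_type, tuple(models), channel_dispersion)


def _draw_positive_nb(
    rng: np.random.Generator, size: float, mu: float
) -> int:
    p = size / (size + mu)
    for _ in range(_MAX_REDRAWS):
        draw = int(rng.negative_binomial(size, p))
        if draw > 0:
            return draw
    raise RuntimeError(
        f"could not draw a positive NB(size={size}, mu={mu}) activity in "
        f"{_MAX_REDRAWS} attempts"
    )


def sample_ground_truth(
    params: GeneratorParams, rng: np.random.Generator
) -> Attribution:
    """Draw one ground-truth attribution (which signatures, what activity).

    Tumors with no drawn signature are redrawn (every real tumor carries at
    least one); bounded at 1000 attempts.
    """
    active = [s for s in params.signatures if s.prevalence > 0]
    if not active:
        raise ValueError("all prevalences are zero; nothing to draw")
    for _ in range(_MAX_REDRAWS):
        acts = {}
        for sig in active:
            if rng.random() < sig.prevalence:
                acts[sig.name] = float(
                    _draw_positive_nb(rng, sig.activity_size, sig.activity_mu)
                )
        if acts:
            return Attribution("synthetic", acts)
    raise RuntimeError("no non-empty attribution drawn in 1000 attempts")


def sample_spectrum(
    truth: Attribution,
    catalog: SignatureCatalog,
    channel_dispersion: float | Mapping[str, float],
    rng: np.random.Generator,
    sample_id: str = "synthetic",
) -> Spectrum:
    """Draw a spectrum: per-signature, per-channel NB counts, summed."""
    if not truth.activities:
        raise ValueError("empty ground-truth attribution")
    counts = np.zeros(catalog.scheme.k, dtype=np.int64)
    for name, activity in truth.activities.items():
        h = catalog.column(name)
        size = (
            float(channel_dispersion[name])
            if isinstance(channel_dispersion, Mapping)
            else float(channel_dispersion)
        )
        mu = activity * h
        positive = mu > 0
        p = size / (size + mu[positive])
        counts[positive] += rng.negative_binomial(size, p)
    return Spectrum(sample_id, catalog.scheme, counts)


def generate_dataset(
    params: GeneratorParams,
    catalog: SignatureCatalog,
    n: int,
    seed: int,
) -> list[GroundTruthSample]:
    """Generate *n* independent ground-truth samples, reproducibly.

    Each sample uses its own spawned random substream, so sample i is
    identical regardless of n >= i+1.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    known = set(catalog.names)
    missing = [
        s.name for s in params.signatures if s.prevalence > 0 and s.name not in known
    ]
    if missing:
        raise KeyError(f"params reference signatures not in catalog: {missing!r}")

    root = np.random.SeedSequence(seed)
    samples = []
    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        sid = f"{params.cancer_type}::S{i + 1}"
        truth = sample_ground_truth(params, rng)
        truth = Attribution(sid, truth.activities)
        spectrum = sample_spectrum(
            truth, catalog, params.channel_dispersion, rng, sample_id=sid
        )
        recon = expected_counts(catalog, truth)
        samples.append(
            GroundTruthSample(
                spectrum=spectrum,
                truth=truth,
                cancer_type=params.cancer_type,
                seed_path=(seed, i),
                truth_reconstruction_cosine=cosine_similarity(
                    spectrum.counts, recon.values
                ),
            )
        )
    return samples


def _median_cosine(
    params: GeneratorParams,
    catalog: SignatureCatalog,
    dispersion: float,
    n: int,
    seed: int,
) -> float:
    data = generate_dataset(
        params.with_dispersion(dispersion), catalog, n, seed
    )
    return float(
        np.median([s.truth_reconstruction_cosine for s in data])
    )


def calibrate_dispersion(
    params: GeneratorParams,
    catalog: SignatureCatalog,
    target_median_cosine: float,
    seed: int,
    n_probe: int = 500,
    tolerance: float = 0.005,
    bounds: tuple[float, float] = (1e-2, 1e6),
) -> float:
    """Find a shared channel dispersion hitting a target median cosine.

    Bisects log-dispersion, exploiting that the median reconstruction
    cosine is monotone non-decreasing in the size parameter.  Raises if
    the target lies outside the attainable range at the given bounds.
    """
    if not 0.0 < target_median_cosine < 1.0:
        raise ValueError("target median cosine must be in (0,1)")
    n_probe = max(n_probe, 500)
    lo, hi = bounds
    cos_lo = _median_cosine(params, catalog, lo, n_probe, seed)
    cos_hi = _median_cosine(params, catalog, hi, n_probe, seed)
    if not cos_lo <= target_median_cosine <= cos_hi:
        raise ValueError(
            f"target {target_median_cosine} outside attainable median-cosine "
            f"range [{cos_lo:.4f}, {cos_hi:.4f}] for dispersion in {bounds}"
        )
    for it in range(60):
        mid = float(np.sqrt(lo * hi))  # bisect in log space
        # fresh substream each probe so probe noise cannot repeat itself
        cos_mid = _median_cosine(params, catalog, mid, n_probe, seed + it)
        if abs(cos_mid - target_median_cosine) <= 0.5 * tolerance:
            # confirm on an independent, larger probe before accepting
            confirm = _median_cosine(
                params, catalog, mid, 2 * n_probe, seed + 1000 + it
            )
            pooled = (cos_mid + 2 * confirm) / 3
            if abs(pooled - target_median_cosine) <= tolerance:
                return mid
            cos_mid = pooled
        if cos_mid < target_median_cosine:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.0001:
            break
    return float(np.sqrt(lo * hi))
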