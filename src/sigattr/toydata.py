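"""Deterministic toy catalogs and generator parameters for tests and demos.

Six toy SBS96 signatures, each dominated by one of the six substitution
blocks with a small common background, so pairwise cosines are low and
attribution problems built from them are well-posed.  Everything here is
reproducible from fixed constants; no downloads.
"""

from __future__ import annotations

import numpy as np

from sigattr.catalogs_spectra import SBS96, SignatureCatalog
from sigattr.synthetic_spectra import GeneratorParams, SignatureActivityModel

__all__ = ["toy_catalog", "toy_generator_params", "TOY_SIGNATURE_NAMES"]

TOY_SIGNATURE_NAMES = ("TS1", "TS2", "TS3", "TS4", "TS5", "TS6")

_BLOCK = 16  # channels per substitution class in SBS96
_SEED = 20240917


def toy_catalog(g: int = 6) -> SignatureCatalog:
    """A catalog of up to six well-separated toy SBS96 signatures.

    Signature j concentrates 90% of its mass on substitution block j with
    an uneven but fixed within-block profile, plus a 10% uniform
    background.  Pairwise cosines are ~0.05.
    """
    if not 1 <= g <= 6:
        raise ValueError("toy catalog supports 1..6 signatures")
    rng = np.random.default_rng(_SEED)
    k = SBS96.k
    cols = []
    for j in range(6):
        profile = np.full(k, 0.10 / k)
        within = rng.dirichlet(np.full(_BLOCK, 0.5))
        profile[j * _BLOCK : (j + 1) * _BLOCK] += 0.90 * within
        cols.append(profile / profile.sum())
    matrix = np.column_stack(cols)[:, :g]
    return SignatureCatalog(SBS96, TOY_SIGNATURE_NAMES[:g], matrix)


_TOY_PARAMS = {
    "ToyTypeA": [
        ("TS1", 1.00, 3.0, 5000.0),
        ("TS2", 0.70, 2.0, 2000.0),
        ("TS3", 0.40, 2.0, 1200.0),
        ("TS4", 0.25, 1.5, 800.0),
        ("TS5", 0.30, 2.0, 600.0),
        ("TS6", 0.10, 1.0, 400.0),
    ],
    "ToyTypeB": [
        ("TS1", 0.60, 2.0, 3000.0),
        ("TS2", 0.90, 4.0, 4000.0),
        ("TS3", 0.20, 1.0, 500.0),
        ("TS4", 0.50, 2.5, 1500.0),
        ("TS5", 0.05, 1.0, 300.0),
        ("TS6", 0.35, 1.5, 900.0),
    ],
}


def toy_generator_params(
    cancer_type: str = "ToyTypeA", channel_dispersion: float = 100.0
) -> GeneratorParams:
    """Generator parameters for one of two pseudo cancer types."""
    try:
        rows = _TOY_PARAMS[cancer_type]
    except KeyError:
        raise KeyError(
            f"unknown toy cancer type {cancer_type!r}; "
            f"known: {sorted(_TOY_PARAMS)}"
        ) from None
    return GeneratorParams(
        cancer_type=cancer_type,
        signatures=tuple(
            SignatureActivityModel(name, prev, size, mu)
            for name, prev, size, mu in rows
        ),
        channel_dispersion=channel_dispersion,
    )
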