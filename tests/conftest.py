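import numpy as np
import pytest

from sigattr import toydata
from sigattr.catalogs_spectra import Spectrum


@pytest.fixture(scope="session")
def toy_catalog6():
    return toydata.toy_catalog(6)


@pytest.fixture(scope="session")
def toy_catalog4():
    return toydata.toy_catalog(4)


@pytest.fixture(scope="session")
def toy_params():
    return toydata.toy_generator_params("ToyTypeA", channel_dispersion=50.0)


def make_spectrum(catalog, activities, seed=None, total=None, sample_id="s"):
    """Spectrum from exact expected counts (rounded), or multinomial draws.

    With seed=None the expected counts H @ a are rounded deterministically;
    with a seed, `total` mutations are drawn from the mixture multinomial.
    """
    a = np.array([activities.get(n, 0.0) for n in catalog.names])
    mean = catalog.matrix @ a
    if seed is None:
        counts = np.rint(mean).astype(int)
    else:
        rng = np.random.default_rng(seed)
        pi = mean / mean.sum()
        counts = rng.multinomial(int(total or a.sum()), pi)
    return Spectrum(sample_id, catalog.scheme, counts)


@pytest.fixture
def spectra_tsv(tmp_path, toy_catalog6):
    """A 2-sample toy spectra TSV on disk."""
    from sigattr.catalogs_spectra import SpectrumSet, write_matrix_tsv

    s1 = make_spectrum(toy_catalog6, {"TS1": 5000, "TS3": 2000}, seed=11)
    s2 = make_spectrum(toy_catalog6, {"TS2": 3000, "TS4": 1500}, seed=12)
    ss = SpectrumSet(
        toy_catalog6.scheme,
        ("sampleA", "sampleB"),
        np.column_stack([s1.counts, s2.counts]),
    )
    path = tmp_path / "spectra.tsv"
    write_matrix_tsv(ss, path)
    return path


@pytest.fixture
def catalog_tsv(tmp_path, toy_catalog6):
    from sigattr.catalogs_spectra import write_matrix_tsv

    path = tmp_path / "catalog.tsv"
    write_matrix_tsv(toy_catalog6, path)
    return path
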