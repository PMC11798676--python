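import numpy as np
import pandas as pd
import pytest

from sigattr.catalogs_spectra import Attribution, cosine_similarity
from sigattr.likelihood_models import expected_counts
from sigattr.synthetic_spectra import (
    GeneratorParams,
    SignatureActivityModel,
    calibrate_dispersion,
    fit_generator_params,
    generate_dataset,
    sample_ground_truth,
    sample_spectrum,
)
from sigattr.toydata import toy_generator_params


class TestFitGeneratorParams:
    def test_prevalence_counting(self):
        table = pd.DataFrame(
            {"s1": [0.0], "s2": [0.0], "s3": [5.0], "s4": [5.0]},
            index=["SigX"],
        )
        params = fit_generator_params(table, "T")
        assert params.signatures[0].prevalence == pytest.approx(0.5)

    def test_nb_parameter_recovery(self):
        rng = np.random.default_rng(99)
        size, mu = 2.0, 500.0
        draws = rng.negative_binomial(size, size / (size + mu), 10_000)
        table = pd.DataFrame(
            [draws.astype(float)],
            index=["SigY"],
            columns=[f"c{i}" for i in range(10_000)],
        )
        params = fit_generator_params(table, "T")
        model = params.signatures[0]
        # prevalence < 1 because NB(2,500) has a little mass at zero
        positive = draws[draws > 0]
        assert model.prevalence == pytest.approx(
            positive.size / draws.size, abs=1e-9
        )
        assert model.activity_size == pytest.approx(size, rel=0.15)
        assert model.activity_mu == pytest.approx(positive.mean(), rel=0.15)

    def test_constant_activities_poisson_limit(self):
        table = pd.DataFrame(
            [[700.0] * 6], index=["SigZ"], columns=list("abcdef")
        )
        params = fit_generator_params(table, "T")
        model = params.signatures[0]
        assert model.activity_mu == pytest.approx(700.0, rel=0.01)
        assert model.activity_size == pytest.approx(1e6, rel=0.01)

    def test_never_active_signature(self):
        table = pd.DataFrame(
            [[0.0] * 4, [3.0, 4.0, 0.0, 5.0]],
            index=["dead", "alive"],
            columns=list("abcd"),
        )
        params = fit_generator_params(table, "T")
        dead = params.signatures[0]
        assert dead.prevalence == 0.0
        assert dead.activity_mu is None

    def test_single_active_sample_fallback(self):
        table = pd.DataFrame(
            [[0.0, 0.0, 123.0]], index=["rare"], columns=list("abc")
        )
        params = fit_generator_params(table, "T")
        model = params.signatures[0]
        assert model.activity_size == pytest.approx(1.0)
        assert model.activity_mu == pytest.approx(123.0)

    def test_rejects_bad_tables(self):
        neg = pd.DataFrame([[-1.0, 2.0]], index=["s"], columns=["a", "b"])
        with pytest.raises(ValueError, match="negative"):
            fit_generator_params(neg, "T")
        one = pd.DataFrame([[5.0]], index=["s"], columns=["a"])
        with pytest.raises(ValueError, match="2 samples"):
            fit_generator_params(one, "T")


class TestSampleGroundTruth:
    def test_forced_presence(self):
        params = GeneratorParams(
            "T", (SignatureActivityModel("S", 1.0, 2.0, 100.0),)
        )
        rng = np.random.default_rng(0)
        for _ in range(50):
            truth = sample_ground_truth(params, rng)
            assert truth.signatures == {"S"}
            assert truth.activities["S"] > 0

    def test_presence_fraction_matches_prevalence(self):
        # second signature at prevalence 1 so draws never need redrawing
        params = GeneratorParams(
            "T",
            (
                SignatureActivityModel("A", 0.3, 2.0, 100.0),
                SignatureActivityModel("B", 1.0, 2.0, 100.0),
            ),
        )
        rng = np.random.default_rng(1)
        hits = sum(
            "A" in sample_ground_truth(params, rng).signatures
            for _ in range(10_000)
        )
        assert hits / 10_000 == pytest.approx(0.3, abs=0.02)

    def test_conditioned_positive_mean(self):
        size, mu = 1.5, 50.0
        params = GeneratorParams(
            "T", (SignatureActivityModel("A", 1.0, size, mu),)
        )
        rng = np.random.default_rng(2)
        acts = [
            sample_ground_truth(params, rng).activities["A"]
            for _ in range(20_000)
        ]
        p0 = (size / (size + mu)) ** size
        expected = mu / (1.0 - p0)
        assert np.mean(acts) == pytest.approx(expected, rel=0.02)

    def test_all_zero_prevalence_errors(self):
        params = GeneratorParams("T", (SignatureActivityModel("A", 0.0),))
        with pytest.raises(ValueError, match="prevalences"):
            sample_ground_truth(params, np.random.default_rng(0))


class TestSampleSpectrum:
    def test_high_activity_matches_profile(self, toy_catalog4):
        truth = Attribution("s", {"TS1": 1_000_000.0})
        rng = np.random.default_rng(3)
        sp = sample_spectrum(truth, toy_catalog4, 1e6, rng)
        cos = cosine_similarity(sp.counts, toy_catalog4.column("TS1"))
        assert cos > 0.9999

    def test_channel_expectation(self, toy_catalog4):
        truth = Attribution("s", {"TS1": 500.0, "TS2": 300.0})
        rng = np.random.default_rng(4)
        n = 10_000
        acc = np.zeros(96)
        sq = np.zeros(96)
        for _ in range(n):
            c = sample_spectrum(truth, toy_catalog4, 20.0, rng).counts
            acc += c
            sq += c.astype(float) ** 2
        mean = acc / n
        se = np.sqrt((sq / n - mean**2) / n)
        expect = expected_counts(toy_catalog4, truth).values
        assert (np.abs(mean - expect) <= 3 * se + 1e-9).mean() > 0.98

    def test_empty_truth_rejected(self, toy_catalog4):
        with pytest.raises(ValueError, match="empty"):
            sample_spectrum(
                Attribution("s", {}), toy_catalog4, 10.0, np.random.default_rng(0)
            )


class TestGenerateDataset:
    def test_same_seed_identical(self, toy_catalog6, toy_params):
        d1 = generate_dataset(toy_params, toy_catalog6, 5, seed=7)
        d2 = generate_dataset(toy_params, toy_catalog6, 5, seed=7)
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.spectrum.counts, b.spectrum.counts)
            assert a.truth.activities == b.truth.activities

    def test_different_seeds_differ(self, toy_catalog6, toy_params):
        d1 = generate_dataset(toy_params, toy_catalog6, 5, seed=7)
        d2 = generate_dataset(toy_params, toy_catalog6, 5, seed=8)
        assert any(
            not np.array_equal(a.spectrum.counts, b.spectrum.counts)
            for a, b in zip(d1, d2)
        )

    def test_n_one_works(self, toy_catalog6, toy_params):
        d = generate_dataset(toy_params, toy_catalog6, 1, seed=0)
        assert len(d) == 1
        assert d[0].truth.activities

    def test_total_conservation_in_expectation(self, toy_catalog6, toy_params):
        data = generate_dataset(toy_params, toy_catalog6, 400, seed=11)
        totals = np.array([s.spectrum.total for s in data])
        truths = np.array([s.truth.total_activity for s in data])
        diff = totals - truths
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 4 * se + 1e-9

    def test_unknown_signature_in_params(self, toy_catalog4, toy_params):
        # toy_params references TS5/TS6 which toy_catalog4 lacks
        with pytest.raises(KeyError, match="TS5"):
            generate_dataset(toy_params, toy_catalog4, 1, seed=0)


class TestCalibrateDispersion:
    def test_monotone_in_dispersion(self, toy_catalog6):
        params = toy_generator_params("ToyTypeA")
        medians = []
        for disp in (1.0, 10.0, 100.0, 10_000.0):
            data = generate_dataset(
                params.with_dispersion(disp), toy_catalog6, 200, seed=13
            )
            medians.append(
                np.median([s.truth_reconstruction_cosine for s in data])
            )
        assert medians == sorted(medians)

    def test_unreachable_target_errors(self, toy_catalog6):
        params = toy_generator_params("ToyTypeA")
        with pytest.raises(ValueError, match="attainable"):
            calibrate_dispersion(
                params, toy_catalog6, 0.99999, seed=1, bounds=(1e-2, 1e2)
            )

    def test_closed_loop_small(self, toy_catalog6):
        # a light version of the full acceptance check
        params = toy_generator_params("ToyTypeA")
        disp = calibrate_dispersion(
            params, toy_catalog6, 0.97, seed=5, n_probe=500
        )
        data = generate_dataset(
            params.with_dispersion(disp), toy_catalog6, 500, seed=17
        )
        med = np.median([s.truth_reconstruction_cosine for s in data])
        assert med == pytest.approx(0.97, abs=0.01)


class TestParamsJson:
    def test_roundtrip(self, tmp_path, toy_params):
        path = tmp_path / "params.json"
        toy_params.to_json(path)
        back = GeneratorParams.from_json(path)
        assert back == toy_params
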