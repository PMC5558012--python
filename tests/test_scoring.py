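"""Aggregate score arithmetic, random-ensemble calibration, refitting."""

import numpy as np
import pytest

from solscreen.profiles import SolubilityProfile, intrinsic_profile
from solscreen.scoring import (
    DEFAULT_PARAMETERS,
    HUMAN_PROTEOME_FREQS,
    ParameterBounds,
    RandomEnsemble,
    ScoreParameters,
    calibrate,
    calibrated_score,
    combined_score,
    ensemble_raw_scores,
    generate_random_ensemble,
    raw_score,
    refit_objective,
    refit_parameters,
)
from solscreen.seqio import STANDARD_AA


def profile_of(values, chain_id="p"):
    seq = "A" * len(values)
    return SolubilityProfile(chain_id=chain_id, sequence=seq, values=np.asarray(values, float))


UNIT = ScoreParameters(th_up=1, th_low=-1, omega_up=1, omega_low=1, gamma=1, delta=1)


class TestRawScore:
    def test_neutral_band_contributes_zero(self):
        assert raw_score(profile_of([0.5, -1.0, 1.0, 0.0]), UNIT) == 0.0

    def test_single_residue_closed_form(self):
        p = profile_of([UNIT.th_up + 1.0])
        assert raw_score(p, UNIT) == pytest.approx(UNIT.omega_up / UNIT.gamma)

    def test_hand_evaluated_balance(self):
        # (1*(2-1) + 1*(-2-(-1))) / 3 = 0
        assert raw_score(profile_of([2.0, 0.0, -2.0]), UNIT) == pytest.approx(0.0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            raw_score(np.array([]), UNIT)

    def test_monotone_in_each_value(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1.5, 30)
        s0 = raw_score(profile_of(base), UNIT)
        for i in range(len(base)):
            bumped = base.copy()
            bumped[i] += 0.7
            assert raw_score(profile_of(bumped), UNIT) >= s0 - 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 2, 40)
        shuffled = rng.permutation(vals)
        assert raw_score(profile_of(vals), UNIT) == pytest.approx(
            raw_score(profile_of(shuffled), UNIT)
        )

    def test_duplication_limits(self):
        vals = np.array([2.0, -3.0, 0.5, 1.4])
        doubled = np.concatenate([vals, vals])
        # delta = 1: length-normalized, duplication leaves score unchanged
        assert raw_score(profile_of(doubled), UNIT) == pytest.approx(
            raw_score(profile_of(vals), UNIT)
        )
        # delta = 0: raw sum, duplication doubles it
        p0 = ScoreParameters(delta=0.0)
        assert raw_score(profile_of(doubled), p0) == pytest.approx(
            2 * raw_score(profile_of(vals), p0)
        )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ScoreParameters(th_up=-1, th_low=1)
        with pytest.raises(ValueError):
            ScoreParameters(gamma=0)
        with pytest.raises(ValueError):
            ScoreParameters(sigma_random=0)


class TestRandomEnsemble:
    def test_point_mass_gives_homopolymers(self):
        freqs = {aa: 0.0 for aa in STANDARD_AA}
        freqs["A"] = 1.0
        spec = RandomEnsemble(frequencies=freqs, n=5, seed=3)
        assert all(set(c.sequence) == {"A"} for c in generate_random_ensemble(spec))

    def test_same_seed_identical(self):
        spec = RandomEnsemble(n=10, seed=42)
        e1 = generate_random_ensemble(spec)
        e2 = generate_random_ensemble(spec)
        assert [c.sequence for c in e1] == [c.sequence for c in e2]

    def test_empirical_frequencies_match_spec(self):
        spec = RandomEnsemble(n=400, seed=5)
        ens = generate_random_ensemble(spec)
        joined = "".join(c.sequence for c in ens)
        total = len(joined)
        for aa in STANDARD_AA:
            p = HUMAN_PROTEOME_FREQS[aa]
            observed = joined.count(aa) / total
            se = np.sqrt(p * (1 - p) / total)
            assert abs(observed - p) < 3 * se + 1e-4

    def test_invalid_frequencies_rejected(self):
        bad = dict(HUMAN_PROTEOME_FREQS)
        bad["A"] += 0.5
        with pytest.raises(ValueError):
            RandomEnsemble(frequencies=bad, n=10, seed=0)


@pytest.fixture(scope="module")
def small_ensemble():
    return generate_random_ensemble(RandomEnsemble(n=300, seed=11))


@pytest.fixture(scope="module")
def training():
    rng = np.random.default_rng(21)
    truth = ScoreParameters(th_up=0.8, th_low=-0.8, omega_up=2.0,
                            omega_low=1.0, gamma=1.0, delta=1.0)
    ens = generate_random_ensemble(
        RandomEnsemble(n=40, seed=13, length_min=50, length_max=120)
    )
    profiles = [intrinsic_profile(c) for c in ens]
    scores = np.array([raw_score(p, truth) for p in profiles])
    measurements = -scores + rng.normal(0, 0.001, len(scores))
    labels = (scores > np.median(scores)).astype(int)
    return truth, profiles, measurements, labels


class TestCalibration:
    def test_same_ensemble_mean_zero_sd_one(self, small_ensemble):
        params = calibrate(DEFAULT_PARAMETERS, small_ensemble)
        raws = ensemble_raw_scores(small_ensemble, params)
        calibrated = (raws - params.mu_random) / params.sigma_random
        assert calibrated.mean() == pytest.approx(0.0, abs=1e-12)
        assert calibrated.std() == pytest.approx(1.0, abs=1e-12)

    def test_fresh_ensemble_mean_within_clt_bound(self, small_ensemble):
        params = calibrate(DEFAULT_PARAMETERS, small_ensemble)
        fresh = generate_random_ensemble(RandomEnsemble(n=300, seed=99))
        raws = ensemble_raw_scores(fresh, params)
        calibrated = (raws - params.mu_random) / params.sigma_random
        assert abs(calibrated.mean()) < 4 / np.sqrt(len(fresh))

    def test_calibration_is_affine_preserves_ranking(self, small_ensemble):
        params = calibrate(DEFAULT_PARAMETERS, small_ensemble)
        seqs = ["KDEKRDE" * 8, "LLIVFWY" * 8, "ASGTNQP" * 8]
        raws = [raw_score(intrinsic_profile(s), params) for s in seqs]
        cals = [
            calibrated_score(intrinsic_profile(s), params).calibrated for s in seqs
        ]
        assert np.argsort(raws).tolist() == np.argsort(cals).tolist()

    def test_degenerate_ensemble_rejected(self):
        from solscreen.seqio import Chain

        same = [Chain(id=f"c{i}", sequence="AAAA") for i in range(5)]
        with pytest.raises(ValueError, match="degenerate"):
            calibrate(DEFAULT_PARAMETERS, same)


class TestCombinedScore:
    def test_order_invariance_exact(self):
        vh = intrinsic_profile("EVQLVESGGGLVQPGGSLRLSCAAS")
        vl = intrinsic_profile("DIQMTQSPSSLSASVGDRVTITCRAS")
        s1 = combined_score([vh, vl])
        s2 = combined_score([vl, vh])
        assert s1.raw == s2.raw
        assert s1.calibrated == s2.calibrated

    def test_single_chain_equals_chain_score(self):
        p = intrinsic_profile("KDELLLKRR")
        assert combined_score([p]).raw == pytest.approx(
            calibrated_score(p).raw
        )

    def test_all_neutral_profiles_score_zero(self):
        a = profile_of([0.2, -0.5, 0.9])
        b = profile_of([-0.9, 0.0])
        assert combined_score([a, b]).raw == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combined_score([])


class TestRefit:
    def test_zero_iterations_returns_initial(self, training):
        truth, profiles, meas, labels = training
        out = refit_parameters(
            DEFAULT_PARAMETERS, profiles, meas, profiles, labels, iterations=0
        )
        assert out == DEFAULT_PARAMETERS

    def test_same_seed_deterministic(self, training):
        truth, profiles, meas, labels = training
        kwargs = dict(iterations=30, seed=5)
        a = refit_parameters(DEFAULT_PARAMETERS, profiles, meas, profiles, labels, **kwargs)
        b = refit_parameters(DEFAULT_PARAMETERS, profiles, meas, profiles, labels, **kwargs)
        assert a == b

    def test_objective_at_least_generating_parameters(self, training):
        truth, profiles, meas, labels = training
        best = refit_parameters(
            truth, profiles, meas, profiles, labels, iterations=50, seed=2
        )
        obj_best = refit_objective(best, profiles, meas, profiles, labels)
        obj_truth = refit_objective(truth, profiles, meas, profiles, labels)
        assert obj_best >= obj_truth - 1e-12

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            refit_parameters(DEFAULT_PARAMETERS, [], [], [], [], iterations=1)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterBounds(th_up=(0.1, 0.2), th_low=(0.5, 0.9))


class TestParameterSerialization:
    def test_roundtrip(self, tmp_path):
        from solscreen.scoring import load_parameters, save_parameters

        params = ScoreParameters(
            th_up=0.9, th_low=-1.2, omega_up=1.5, omega_low=0.7,
            gamma=1.1, delta=0.8, mu_random=0.01, sigma_random=0.02,
            version="test-v1",
        )
        path = tmp_path / "params.cfg"
        save_parameters(params, path)
        assert load_parameters(path) == params
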