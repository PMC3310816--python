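"""Per-window energies, the MS log-sum-exp ensemble, and serialization."""

import json

import numpy as np
import pytest

from msbind.energy_models import (
    EnergyParams,
    MSModel,
    SSModel,
    model_from_dict,
    model_to_dict,
    ms_energy,
    load_model,
    save_model,
    ss_energy,
    window_energy,
)
from msbind.sequence_space import (
    AA_ALPHABET,
    SLOTS_PER_POSITION,
    Peptide,
    ReferenceProfile,
    Window,
    encode_window,
    enumerate_windows,
)


def make_params(S, rng=None, J0=0.0):
    profile = ReferenceProfile(("A",) * S)
    J = (
        np.zeros((S, SLOTS_PER_POSITION))
        if rng is None
        else rng.normal(size=(S, SLOTS_PER_POSITION))
    )
    return EnergyParams(profile, J, J0)


class TestWindowEnergy:
    def test_reference_window_scores_the_intercept(self):
        params = make_params(3, J0=1.25)
        assert window_energy(params, Window("p", 0, 3, "AAA")) == 1.25

    def test_single_substitution_term(self):
        params = make_params(2)
        params.J[0, 0] = -1.5  # slot 0 at position 1 is C (ref A)
        assert window_energy(params, Window("p", 0, 2, "CA")) == -1.5

    def test_equals_feature_dot_product(self, rng):
        """The additive expansion is linear in the indicator encoding."""
        params = make_params(4, rng=rng, J0=rng.normal())
        for _ in range(20):
            seq = "".join(rng.choice(list(AA_ALPHABET), size=4))
            w = Window("p", 0, 4, seq)
            vec = encode_window(w, params.profile)
            assert window_energy(params, w) == pytest.approx(
                float(vec @ params.flat()), rel=1e-12
            )

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            window_energy(make_params(2), Window("p", 0, 3, "ACD"))


class TestMSEnergy:
    def test_single_window_reduces_to_alpha_plus_g(self, rng):
        model = MSModel(make_params(3, rng=rng), alpha=1.7)
        pep = Peptide("p", "CDE")
        (w,) = enumerate_windows(pep, 3)
        g = window_energy(model.params, w)
        assert ms_energy(model, pep).total == pytest.approx(1.7 + g, abs=1e-12)

    def test_equal_energy_windows_shift_by_log_n(self):
        model = MSModel(make_params(1), alpha=0.5)  # all-zero J: every g = 0
        for n in (2, 3, 7):
            pep = Peptide("p", "A" * n)
            assert ms_energy(model, pep).total == pytest.approx(
                0.5 + 0.0 - np.log(n), abs=1e-12
            )

    def test_three_window_direct_summation(self):
        """Energies {0,1,2} at alpha=0: total is -ln(sum exp(-g)) by brute force."""
        params = make_params(1)
        params.J[0, :] = 0.0
        params.J[0, 0] = 1.0  # C
        params.J[0, 1] = 2.0  # D
        model = MSModel(params, alpha=0.0)
        pep = Peptide("p", "ACD")  # window energies 0, 1, 2
        oracle = -np.log(np.sum(np.exp(-np.array([0.0, 1.0, 2.0]))))
        total = ms_energy(model, pep).total
        assert total == pytest.approx(oracle, abs=1e-12)
        assert total == pytest.approx(-0.40760596, abs=1e-7)

    def test_numerical_stability_at_large_energies(self):
        """Window energies of ~1000 RT: log-sum-exp must not overflow."""
        params = make_params(1)
        params.J[0, 0] = 1000.0  # C
        params.J[0, 1] = 1001.0  # D
        model = MSModel(params, alpha=0.0)
        total = ms_energy(model, Peptide("p", "CD")).total
        closed = 1000.0 - np.log1p(np.exp(-1.0))
        assert np.isfinite(total)
        assert total == pytest.approx(closed, abs=1e-9)

    def test_shift_covariance(self, rng):
        """A uniform shift of every window energy shifts the total by the same."""
        base = make_params(2, rng=rng)
        c = 3.7
        # off-reference peptide: +c on every J entry adds S*c = 2c per window
        shifted = EnergyParams(base.profile, base.J + c, 0.0)
        pep = Peptide("p", "CDEFG")
        t0 = ms_energy(MSModel(base, 1.0), pep).total
        t1 = ms_energy(MSModel(shifted, 1.0), pep).total
        assert t1 - t0 == pytest.approx(2 * c, abs=1e-9)

    def test_appending_a_window_lowers_the_ensemble_energy(self, rng):
        params = make_params(1, rng=rng)
        t_short = ms_energy(MSModel(params, 0.0), Peptide("p", "CD")).total
        t_long = ms_energy(MSModel(params, 0.0), Peptide("p", "CDE")).total
        assert t_long < t_short

    def test_dominance_bound(self, random_ms_model, rng):
        """Total never exceeds alpha + the best (minimum) window energy."""
        for _ in range(10):
            seq = "".join(rng.choice(list(AA_ALPHABET), size=9))
            profile = ms_energy(random_ms_model, Peptide("p", seq))
            assert profile.total <= random_ms_model.alpha + profile.window_energies.min() + 1e-12

    def test_too_short_peptide_rejected(self):
        model = MSModel(make_params(4), alpha=0.0)
        with pytest.raises(ValueError, match="shorter"):
            ms_energy(model, Peptide("p", "ACD"))


class TestSSEnergy:
    def test_full_length_site(self, rng):
        params = make_params(3, rng=rng, J0=0.3)
        model = SSModel(params, site_offset=0)
        pep = Peptide("p", "CDE")
        assert ss_energy(model, pep) == window_energy(
            params, Window("p", 0, 3, "CDE")
        )

    def test_intercept_only_model_is_constant(self):
        model = SSModel(make_params(2, J0=4.2), site_offset=1)
        for seq in ("AAAA", "ACDE", "WYVK"):
            assert ss_energy(model, Peptide("p", seq)) == pytest.approx(
                4.2 + model.params.lookup(0, seq[1]) + model.params.lookup(1, seq[2])
            )

    def test_all_zero_params_give_intercept(self):
        model = SSModel(make_params(2, J0=4.2), site_offset=0)
        assert ss_energy(model, Peptide("p", "WY")) == 4.2

    def test_single_window_peptide_matches_ms_minus_alpha(self, rng):
        params = make_params(3, rng=rng)
        ms, ss = MSModel(params, alpha=1.1), SSModel(params, 0)
        pep = Peptide("p", "KLM")
        assert ss_energy(ss, pep) == pytest.approx(
            ms_energy(ms, pep).total - 1.1, abs=1e-12
        )

    def test_site_out_of_range_rejected(self):
        model = SSModel(make_params(3), site_offset=2)
        with pytest.raises(ValueError):
            ss_energy(model, Peptide("p", "ACDE"))  # 2 + 3 > 4


class TestModelInvariantsAndSerialization:
    def test_ms_model_requires_zero_intercept(self):
        with pytest.raises(ValueError, match="J0"):
            MSModel(make_params(2, J0=1.0), alpha=0.0)

    def test_json_round_trip_is_lossless(self, rng, tmp_path):
        for model in (
            MSModel(make_params(3, rng=rng), alpha=rng.normal()),
            SSModel(make_params(2, rng=rng, J0=rng.normal()), site_offset=1),
        ):
            blob = json.dumps(model_to_dict(model, provenance={"seed": 1}))
            back = model_from_dict(json.loads(blob))
            assert type(back) is type(model)
            np.testing.assert_array_equal(back.params.J, model.params.J)
            assert back.params.profile == model.params.profile
            path = tmp_path / "m.json"
            save_model(model, path)
            assert load_model(path) == model

    def test_reparameterization_preserves_energies(self, rng):
        """Changing the reference profile must not change predictions."""
        params = make_params(3, rng=rng)
        model = MSModel(params, alpha=0.9)
        new_profile = ReferenceProfile(("P", "G", "W"))
        model2 = model.reparameterized(new_profile)
        assert model2.params.profile == new_profile
        for _ in range(10):
            seq = "".join(rng.choice(list(AA_ALPHABET), size=7))
            pep = Peptide("p", seq)
            assert ms_energy(model2, pep).total == pytest.approx(
                ms_energy(model, pep).total, abs=1e-9
            )
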