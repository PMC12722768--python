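"""Functional forms, losses, training loop, checkpoints."""

import numpy as np
import pytest

from mpacdens.models import (
    ML2Model,
    MLS2Model,
    SystemData,
    compute_loss,
    prepare_one_electron_system,
    prepare_system,
)
from mpacdens.nn import MLP, lr_schedule
from mpacdens.reference import MoleculeSpec


@pytest.fixture(scope="module")
def he_system(he_ref):
    return prepare_system(he_ref, kappa=2.0, grid_level=0)


@pytest.fixture(scope="module")
def he_mls2_system(he_ref):
    from mpacdens.features import MLS2_FEATURES

    return prepare_system(he_ref, kappa=2.0, grid_level=0,
                          feature_spec=MLS2_FEATURES)


@pytest.fixture(scope="module")
def h_atom_system():
    return prepare_one_electron_system(
        MoleculeSpec(symbols=("H",), coords=((0, 0, 0),), label="H"),
        kappa=2.0, grid_level=0,
    )


def _fitted_stub(model_cls, system, **kw):
    """Model with architecture in place but weights forced, no training."""
    m = model_cls(epochs=1, **kw)
    spec = m._spec(len(system.columns))
    m.net_ = MLP(spec, np.random.default_rng(0))
    m.spec_ = spec
    m.feature_columns_ = system.columns
    m.kappa_ = system.kappa
    m.loss_history_ = np.zeros(1)
    m.validation_history_ = []
    return m


class TestML2Form:
    def test_zero_network_gives_zero_field(self, he_system):
        m = _fitted_stub(ML2Model, he_system)
        m.net_.force_constant_output(0.0)
        assert np.abs(m.predict(he_system)).max() == 0.0

    def test_saturated_weight_recovers_carrier(self, he_system):
        m = _fitted_stub(ML2Model, he_system)
        m.net_.force_constant_output(1.0)
        np.testing.assert_allclose(m.predict(he_system), he_system.carrier,
                                   rtol=1e-12)

    def test_feature_spec_mismatch_rejected(self, he_mls2_system):
        m = ML2Model(epochs=1)
        with pytest.raises(ValueError, match="feature columns"):
            m.fit([he_mls2_system])


class TestMLS2Form:
    def test_identity_weights_recover_regularized_mp2(self, he_mls2_system):
        m = _fitted_stub(MLS2Model, he_mls2_system)
        m.net_.force_constant_output(1.0)
        e_ml = m.predict(he_mls2_system)
        np.testing.assert_allclose(
            e_ml, he_mls2_system.e_os + he_mls2_system.e_ss, atol=1e-12)

    def test_zero_weights_give_zero(self, he_mls2_system):
        m = _fitted_stub(MLS2Model, he_mls2_system)
        m.net_.force_constant_output(0.0)
        # sigmoid never reaches exactly 0; the driven-to-zero limit is
        # indistinguishable from zero at any physical scale
        assert np.abs(m.predict(he_mls2_system)).max() < 1e-200

    def test_one_electron_exactness_for_random_weights(self, h_atom_system):
        """E_c^{MLS2}(H atom) = 0 for arbitrary network weights."""
        m = _fitted_stub(MLS2Model, h_atom_system)
        n = m.net_.get_flat().size
        rng = np.random.default_rng(7)
        for _ in range(100):
            m.net_.set_flat(rng.normal(scale=2.0, size=n))
            assert abs(m.predict_energy(h_atom_system)) < 1e-12


class TestLosses:
    def _toy(self, e_ref, rho=None, w=None):
        n = len(e_ref)
        rho = np.ones(n) if rho is None else rho
        w = np.ones(n) if w is None else w
        return SystemData(
            label="toy", features=np.zeros((n, 5)),
            columns=("s", "q", "alpha", "f1", "f2"),
            weights=w, rho=rho, e_ref=np.asarray(e_ref, float),
            carrier=np.ones(n), e_os=np.zeros(n), e_ss=np.zeros(n),
            kappa=2.0, n_elec=int(rho.sum() if rho is not None else n),
        )

    def test_exact_match_zeroes_every_mode(self):
        sd = self._toy([0.1, -0.2, 0.3])
        pred = sd.e_ref.copy()
        for mode in ("les", "les2", "ges"):
            assert compute_loss(mode, [pred], [sd]) == 0.0
        assert compute_loss("direct", [sd.rho * sd.e_ref], [sd]) == 0.0

    def test_constant_offset_equates_les_and_ges(self):
        """A uniform per-particle shift delta: LES = GES = delta * N."""
        sd = self._toy([0.1, 0.1, 0.1, 0.1])
        delta = 0.05
        pred = sd.e_ref + delta
        n_elec = float(sd.wrho.sum())
        assert compute_loss("les", [pred], [sd]) == pytest.approx(delta * n_elec)
        assert compute_loss("ges", [pred], [sd]) == pytest.approx(delta * n_elec)

    def test_sign_alternating_error_invisible_to_ges(self):
        """Zero-integral pointwise error: GES = 0 but LES > 0."""
        sd = self._toy([0.1, 0.1])
        pred = sd.e_ref + np.array([0.05, -0.05])
        assert compute_loss("ges", [pred], [sd]) == pytest.approx(0.0, abs=1e-15)
        assert compute_loss("les", [pred], [sd]) > 0.05

    def test_multi_system_loss_is_arithmetic_mean(self):
        s1, s2 = self._toy([0.1]), self._toy([0.3])
        p1, p2 = s1.e_ref + 0.1, s2.e_ref + 0.3
        l1 = compute_loss("les", [p1], [s1])
        l2 = compute_loss("les", [p2], [s2])
        both = compute_loss("les", [p1, p2], [s1, s2])
        assert both == pytest.approx(0.5 * (l1 + l2))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            compute_loss("nope", [], [])


class TestTraining:
    def test_loss_decreases_and_is_deterministic(self, he_system):
        m1 = ML2Model(loss="les", epochs=150, seed=3).fit([he_system])
        assert m1.loss_history_[-1] < 0.2 * m1.loss_history_[0]
        m2 = ML2Model(loss="les", epochs=150, seed=3).fit([he_system])
        assert np.array_equal(m1.loss_history_, m2.loss_history_)
        assert np.array_equal(m1.net_.get_flat(), m2.net_.get_flat())

    def test_different_seeds_differ(self, he_system):
        m1 = ML2Model(loss="les", epochs=30, seed=0).fit([he_system])
        m2 = ML2Model(loss="les", epochs=30, seed=1).fit([he_system])
        assert not np.array_equal(m1.net_.get_flat(), m2.net_.get_flat())

    def test_validation_history_recorded(self, he_system):
        m = ML2Model(loss="les", epochs=60, seed=0).fit(
            [he_system], validation_systems=[he_system])
        assert len(m.validation_history_) >= 1
        assert all(v >= 0 for _, v in m.validation_history_)

    def test_warmup_and_decay_schedule_shape(self):
        lrs = [lr_schedule(e, 100, 0.1, 0.1, 0.01) for e in range(100)]
        assert lrs[0] < lrs[9] == pytest.approx(0.1)  # warm-up peak
        assert lrs[-1] == pytest.approx(0.001, rel=0.1)  # decayed
        assert np.all(np.diff(lrs[10:]) < 0)

    def test_sklearn_params_roundtrip(self):
        m = ML2Model(loss="ges", epochs=42, seed=9)
        params = m.get_params()
        assert params["loss"] == "ges" and params["epochs"] == 42
        m2 = ML2Model().set_params(**params)
        assert m2.get_params() == params


class TestCheckpoint:
    def test_roundtrip_bitwise(self, he_system, tmp_path):
        from mpacdens.io import load_checkpoint, save_checkpoint

        m = ML2Model(loss="les", epochs=40, seed=5).fit([he_system])
        save_checkpoint(m, tmp_path / "ckpt")
        m2 = load_checkpoint(tmp_path / "ckpt")
        assert np.array_equal(m.net_.get_flat(), m2.net_.get_flat())
        np.testing.assert_array_equal(m.predict(he_system), m2.predict(he_system))
        assert m2.feature_columns_ == m.feature_columns_
        assert m2.kappa_ == m.kappa_


class TestMLS2Training:
    def test_fit_toward_ci_reference_and_combined_loss(self, he_ref):
        """MLS2 trains toward a beyond-MP2 correlation target; the combined
        total+interaction loss path also converges."""
        from mpacdens.features import MLS2_FEATURES
        from mpacdens.models import InteractionData
        from mpacdens.oracles import ci_reference

        ci = ci_reference(he_ref)
        assert ci.e_corr < 0
        sd = prepare_system(he_ref, kappa=2.0, grid_level=0,
                            feature_spec=MLS2_FEATURES, e_ref_scalar=ci.e_corr)
        m = MLS2Model(epochs=60, seed=0).fit([sd])
        assert m.loss_history_[-1] < 0.1 * m.loss_history_[0]
        # artificial interaction datum exercises the combined gradient path
        job = InteractionData(label="toy", complex=sd, fragments=[],
                              de_ref=ci.e_corr)
        m2 = MLS2Model(epochs=40, seed=0).fit([sd], interactions=[job])
        assert np.isfinite(m2.loss_history_).all()
        assert m2.loss_history_[-1] < m2.loss_history_[0]
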