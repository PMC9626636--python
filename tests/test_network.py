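import copy

import numpy as np
import pandas as pd
import pytest

from dfikit.harmonize import (
    FEATURES,
    FeatureMatrix,
    assemble_matrix,
    derive_granulocytes,
    strain_center,
)
from dfikit.network import (
    AEARModel,
    NetworkConfig,
    age_adjust_dfi,
    autocorrelation,
    build_model,
    compute_losses,
    evaluate_reconstruction,
    fit_growth_exponent,
    make_pairs,
    score_dfi,
    train,
)


class TestBuildModel:
    def test_shape_contract(self):
        model = build_model(NetworkConfig(seed=0))
        y = model.encode(np.zeros((3, 12)))
        assert y.shape == (3, 4)
        x = model.decode(y)
        assert x.shape == (3, 12)

    def test_seed_determinism(self):
        a = build_model(NetworkConfig(seed=7))
        b = build_model(NetworkConfig(seed=7))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_resnet_block_zeroed_is_identity(self):
        model = build_model(NetworkConfig(seed=0))
        block = model.encoder[1]
        for p in block.params():
            p.data[...] = 0.0
        x = np.random.default_rng(0).standard_normal((5, model.config.hidden_width))
        np.testing.assert_array_equal(block.forward_np(x), x)

    def test_nonstandard_latent_warns(self):
        with pytest.warns(RuntimeWarning, match="latent_dim"):
            NetworkConfig(latent_dim=3)

    def test_latent_must_be_compressive(self):
        with pytest.raises(ValueError):
            NetworkConfig(latent_dim=12)


class TestMakePairs:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["animal_id", "age_weeks"])

    def test_exact_gap(self):
        t = self._table([("a", 26.0), ("a", 52.0)])
        i_n, i_n1 = make_pairs(t, 26.0, 4.0)
        assert len(i_n) == 1

    def test_different_animals_never_pair(self):
        t = self._table([("a", 26.0), ("b", 52.0)])
        with pytest.warns(RuntimeWarning, match="no longitudinal pairs"):
            i_n, _ = make_pairs(t, 26.0, 4.0)
        assert len(i_n) == 0

    def test_gap_out_of_tolerance(self):
        t = self._table([("a", 26.0), ("a", 60.0)])
        with pytest.warns(RuntimeWarning):
            i_n, _ = make_pairs(t, 26.0, 4.0)
        assert len(i_n) == 0

    def test_age_window_restriction(self):
        t = self._table([("a", 104.0), ("a", 130.0)])
        with pytest.warns(RuntimeWarning):
            i_n, _ = make_pairs(t, 26.0, 4.0)
        assert len(i_n) == 0


def _identity_toy_model():
    """phi(x) = x0 on data of the form (v, 0); exact AR with r=1.3, z'=0.25."""
    with pytest.warns(RuntimeWarning):
        cfg = NetworkConfig(input_dim=2, latent_dim=1, hidden_width=2,
                            n_resnet_blocks=0, seed=0)
    model = build_model(cfg)
    enc1, enc2 = model.encoder
    dec1, dec2 = model.decoder
    enc1.W.data = np.eye(2)
    enc1.b.data[...] = 0.0
    enc2.W.data = np.array([[1.0], [0.0]])
    enc2.b.data[...] = 0.0
    dec1.W.data = np.array([[1.0, 0.0]])
    dec1.b.data[...] = 0.0
    dec2.W.data = np.eye(2)
    dec2.b.data[...] = 0.0
    model.A.data = np.array([[1.0]])
    model.B.data = np.array([[1.0]])
    model.r.data[...] = 1.3
    model.shift.data[...] = 0.25
    return model


class TestComputeLosses:
    def test_zero_residual_linear_system(self):
        model = _identity_toy_model()
        v = np.linspace(-1, 1, 6)
        xn = np.stack([v, np.zeros(6)], axis=1)
        xn1 = np.stack([1.3 * v + 0.25, np.zeros(6)], axis=1)
        losses = compute_losses(model, xn, (xn, xn1))
        assert losses["L_AE"].item() == pytest.approx(0.0, abs=1e-24)
        assert losses["L_pred"].item() == pytest.approx(0.0, abs=1e-24)
        assert losses["L_AR"].item() == pytest.approx(0.0, abs=1e-24)
        assert losses["L_C"].item() == pytest.approx(0.0, abs=1e-24)
        assert losses["L2"].item() > 0.0

    def test_constraint_loss_direct_values(self):
        model = build_model(NetworkConfig(seed=0))
        model.A.data = np.array([[1.0], [0.0], [0.0], [0.0]])
        model.B.data = np.array([[1.0, 0.0, 0.0, 0.0]])
        l_c = compute_losses(model, np.zeros((2, 12)))["L_C"]
        assert l_c.item() == pytest.approx(0.0)
        model.B.data = np.array([[0.0, 1.0, 0.0, 0.0]])  # A.B = 0, |B| = 1
        l_c = compute_losses(model, np.zeros((2, 12)))["L_C"]
        assert l_c.item() == pytest.approx(1.0)

    def test_hand_computed_against_numpy_forward(self):
        # independent reimplementation of the loss formulas in plain numpy
        cfg = NetworkConfig(hidden_width=8, n_resnet_blocks=1, seed=3)
        model = build_model(cfg)
        rng = np.random.default_rng(0)
        xc = rng.standard_normal((5, 12))
        xn = rng.standard_normal((4, 12))
        xn1 = rng.standard_normal((4, 12))
        losses = compute_losses(model, xc, (xn, xn1))

        enc = model.encode
        dec = model.decode
        A, B = model.A.data, model.B.data
        r, s = model.ar_r, model.ar_shift
        l_ae = ((xc - dec(enc(xc))) ** 2).mean()
        zn = enc(xn) @ A
        zn1 = enc(xn1) @ A
        znext = r * zn + s
        l_ar = ((zn1 - znext) ** 2).mean()
        l_pred = ((xn1 - dec(znext @ B)) ** 2).mean()
        ab = (B @ A).item()
        l_c = (ab - 1.0) ** 2 + ((B**2).sum() - 1.0) ** 2
        l2 = sum((w.data**2).sum() for w in model.weight_matrices())

        assert losses["L_AE"].item() == pytest.approx(l_ae, rel=1e-12)
        assert losses["L_AR"].item() == pytest.approx(l_ar, rel=1e-12)
        assert losses["L_pred"].item() == pytest.approx(l_pred, rel=1e-12)
        assert losses["L_C"].item() == pytest.approx(l_c, rel=1e-12)
        assert losses["L2"].item() == pytest.approx(l2, rel=1e-12)

    def test_nonfinite_loss_aborts(self):
        model = build_model(NetworkConfig(seed=0))
        with pytest.raises(FloatingPointError):
            compute_losses(model, np.full((2, 12), np.inf))


class TestAgeAdjust:
    def _scores(self, dfi, sex=None, age=None):
        n = len(dfi)
        return pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(n)],
                "sex": sex if sex is not None else ["M"] * n,
                "age_weeks": age if age is not None else [26.0] * n,
                "dfi": dfi,
            }
        )

    def test_identical_values_adjust_to_zero(self):
        out = age_adjust_dfi(self._scores([2.0, 2.0, 2.0, 2.0]))
        np.testing.assert_allclose(out["dfi_age_adjusted"], 0.0)

    def test_hand_computed_two_groups(self):
        scores = self._scores(
            [1.0, 3.0, 10.0, 20.0],
            sex=["M", "M", "F", "F"],
            age=[26.0, 26.0, 26.0, 26.0],
        )
        out = age_adjust_dfi(scores)
        np.testing.assert_allclose(
            out["dfi_age_adjusted"], [-1.0, 1.0, -5.0, 5.0]
        )

    def test_group_sums_exactly_zero(self):
        rng = np.random.default_rng(0)
        scores = self._scores(
            rng.standard_normal(40),
            sex=list(np.repeat(["M", "F"], 20)),
            age=list(np.tile([26.0, 52.0], 20)),
        )
        out = age_adjust_dfi(scores)
        for _, grp in out.groupby(["sex", "age_weeks"]):
            assert grp["dfi_age_adjusted"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_singleton_group_warns(self):
        scores = self._scores([1.0, 2.0], sex=["M", "F"])
        with pytest.warns(RuntimeWarning, match="singleton"):
            out = age_adjust_dfi(scores)
        np.testing.assert_allclose(out["dfi_age_adjusted"], 0.0)


class TestEvaluateReconstruction:
    class _Stub:
        """Model stand-in with a fixed reconstruction map."""

        def __init__(self, delta):
            self.delta = delta

        def reconstruct(self, X):
            return X + self.delta

    def _matrix(self, col0):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((len(col0), 12))
        X[:, 0] = col0
        return FeatureMatrix(
            values=X,
            row_keys=pd.DataFrame({"animal_id": [f"a{i}" for i in range(len(col0))],
                                   "age_weeks": 26.0}),
        )

    def test_perfect_reconstruction(self):
        fm = self._matrix([1.0, 2.0, 3.0])
        res = evaluate_reconstruction(self._Stub(np.zeros(12)), fm)
        assert (res.loc[res["feature"] != "average", "rmse"] == 0).all()
        assert (res.loc[res["feature"] != "average", "r2"] == 1).all()

    def test_hand_computed_rmse_r2(self):
        # feature 0: y=(1,2,3), yhat=(1,2,4) -> SSres 1, SStot 2, R2 0.5
        fm = self._matrix([1.0, 2.0, 3.0])
        delta = np.zeros((3, 12))
        delta[2, 0] = 1.0
        res = evaluate_reconstruction(self._Stub(delta), fm)
        row = res[res["feature"] == "GR%"].iloc[0]
        assert row["r2"] == pytest.approx(0.5)
        assert row["rmse"] == pytest.approx(np.sqrt(1.0 / 3.0))

    def test_mean_prediction_gives_zero_r2(self):
        fm = self._matrix([1.0, 2.0, 3.0])

        class MeanStub:
            def reconstruct(self, X):
                return np.tile(X.mean(axis=0), (X.shape[0], 1))

        res = evaluate_reconstruction(MeanStub(), fm)
        row = res[res["feature"] == "GR%"].iloc[0]
        assert row["r2"] == pytest.approx(0.0, abs=1e-12)


class TestFitGrowthExponent:
    def test_exact_recovery(self):
        t = np.array([26.0, 40.0, 52.0, 66.0, 78.0, 90.0])
        y = 0.5 * np.exp(0.02 * t) + 0.1
        res = fit_growth_exponent(t, y, np.full(t.size, 0.01), lifespan_cutoff=100.0)
        assert res["alpha"] == pytest.approx(0.02, abs=1e-6)
        assert res["zbar"] == pytest.approx(0.5, abs=1e-5)
        assert res["z0"] == pytest.approx(0.1, abs=1e-4)

    def test_flat_data_ci_covers_zero(self):
        t = np.array([26.0, 40.0, 52.0, 66.0, 78.0])
        y = np.full(t.size, 1.0) + np.array([1e-6, -1e-6, 0.0, 1e-6, -1e-6])
        res = fit_growth_exponent(t, y, np.full(t.size, 0.01), lifespan_cutoff=100.0)
        lo, hi = res["alpha_ci"]
        assert lo <= 0.0 <= hi

    def test_cutoff_excludes_late_groups(self):
        t = np.array([26.0, 40.0, 52.0, 66.0, 120.0])
        y = 0.5 * np.exp(0.025 * t)
        y[-1] = 0.0  # corrupted late point must not matter
        res = fit_growth_exponent(t, y, np.full(t.size, 0.01), lifespan_cutoff=100.0)
        assert res["alpha"] == pytest.approx(0.025, abs=1e-6)
        assert res["n_groups"] == 4

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            fit_growth_exponent(
                np.array([26.0, 52.0, 120.0]),
                np.ones(3), np.ones(3), lifespan_cutoff=100.0,
            )

    def test_monte_carlo_coverage(self):
        # 95% CI covers the true exponent in >= 90% of replicates
        rng = np.random.default_rng(6)
        t = np.array([26.0, 40.0, 52.0, 66.0, 78.0, 90.0])
        sem = np.full(t.size, 0.05)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            y = 0.5 * np.exp(0.025 * t) + 0.1 + rng.standard_normal(t.size) * sem
            res = fit_growth_exponent(t, y, sem, lifespan_cutoff=100.0)
            lo, hi = res["alpha_ci"]
            hits += lo <= 0.025 <= hi
        assert hits / n_rep >= 0.85


class TestAutocorrelation:
    def _scores(self, values):
        rows = []
        for animal, series in values.items():
            for age, v in series:
                rows.append({"animal_id": animal, "sex": "M",
                             "age_weeks": age, "dfi": v})
        return pd.DataFrame(rows)

    def test_perfect_persistence(self):
        vals = {f"a{i}": [(26.0, float(i)), (52.0, float(i))] for i in range(8)}
        out = autocorrelation(self._scores(vals), lags=[26.0])
        assert out.loc[0, "pearson_r"] == pytest.approx(1.0)

    def test_white_noise_uncorrelated(self):
        rng = np.random.default_rng(0)
        vals = {
            f"a{i}": [(26.0, rng.standard_normal()), (52.0, rng.standard_normal())]
            for i in range(300)
        }
        out = autocorrelation(self._scores(vals), lags=[26.0])
        assert abs(out.loc[0, "pearson_r"]) < 0.15

    def test_sparse_lag_skipped(self):
        vals = {"a0": [(26.0, 1.0), (52.0, 2.0)]}
        with pytest.warns(RuntimeWarning, match="fewer than 3"):
            out = autocorrelation(self._scores(vals), lags=[26.0])
        assert out.empty


@pytest.fixture(scope="module")
def trained_setup():
    """Small trained model on a linear synthetic cohort."""
    from dfikit.core_model import LangevinParams
    from dfikit.synthetic import (
        CohortConfig, DEFAULT_BASELINE, DEFAULT_NOISE_SD, generate_cohort,
    )

    cfg = CohortConfig(
        n_per_strain_sex=250,
        strains=[("S1", DEFAULT_BASELINE.copy())],
        feature_noise_sd=DEFAULT_NOISE_SD / 2,
        visit_ages=(26.0, 52.0, 78.0, 104.0),
        seed=23,
    )
    cohort, _, latent = generate_cohort(cfg)
    fm = assemble_matrix(strain_center(derive_granulocytes(cohort)))
    table = fm.to_frame()
    i_n, i_n1 = make_pairs(table, 26.0, 4.0)
    pos = {idx: k for k, idx in enumerate(table.index)}
    X = fm.values
    pairs = (X[[pos[i] for i in i_n]], X[[pos[i] for i in i_n1]])
    ncfg = NetworkConfig(hidden_width=48, n_resnet_blocks=2, epochs=60,
                         lr_switch_epoch=40, alpha2_ramp_epochs=30,
                         batch_size=256, seed=1)
    model = build_model(ncfg)
    train(model, X, pairs,
          ages_cross=fm.row_keys["age_weeks"].to_numpy(dtype=float))
    return model, fm, latent, cohort


class TestTraining:
    def test_constraints_after_training(self, trained_setup):
        model, *_ = trained_setup
        res_ab, res_b = model.constraint_residuals()
        assert res_ab < 1e-2
        assert res_b < 1e-2

    def test_ar_exponent_recovery(self, trained_setup):
        model, *_ = trained_setup
        alpha_hat = np.log(model.ar_r) / 26.0
        assert abs(alpha_hat - 0.03) / 0.03 < 0.4  # strict 0.2 in acceptance

    def test_dfi_tracks_latent(self, trained_setup):
        model, fm, latent, _ = trained_setup
        scores = score_dfi(model, fm)
        m = scores.merge(latent, on=["animal_id", "age_weeks"])
        assert abs(np.corrcoef(m["dfi"], m["z_true"])[0, 1]) > 0.85

    def test_dfi_sign_positive_with_age(self, trained_setup):
        model, fm, *_ = trained_setup
        scores = score_dfi(model, fm)
        ages = fm.row_keys["age_weeks"].to_numpy(dtype=float)
        assert np.corrcoef(scores["dfi"], ages)[0, 1] > 0

    def test_mean_dfi_increases_across_age_groups(self, trained_setup):
        model, fm, *_ = trained_setup
        scores = score_dfi(model, fm)
        means = scores.groupby("age_weeks")["dfi"].mean()
        assert means.loc[26.0] < means.loc[52.0] < means.loc[78.0]

    def test_scoring_deterministic(self, trained_setup):
        model, fm, *_ = trained_setup
        a = score_dfi(model, fm)["dfi"].to_numpy()
        b = score_dfi(model, fm)["dfi"].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_affine_rescaling_invariance(self, trained_setup):
        model, fm, *_ = trained_setup
        base = score_dfi(model, fm)["dfi"].to_numpy()
        df = fm.to_frame()
        df["HB"] = 2.0 * df["HB"] + 5.0
        model2 = copy.deepcopy(model)
        X2 = df[FEATURES].to_numpy(dtype=float)
        model2.fit_scaler(X2)  # refit absorbs the affine map exactly
        rescored = model2.dfi(X2)
        np.testing.assert_allclose(rescored, base, atol=1e-6)

    def test_checkpoint_roundtrip_bit_exact(self, trained_setup, tmp_path):
        model, fm, *_ = trained_setup
        model.save(tmp_path / "ckpt")
        back = AEARModel.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(model.dfi(fm.values), back.dfi(fm.values))

    def test_missing_feature_records_skipped(self, trained_setup):
        model, fm, *_ = trained_setup
        df = fm.to_frame()
        df.loc[df.index[0], "HB"] = np.nan
        with pytest.warns(RuntimeWarning, match="skipped"):
            scores = score_dfi(model, df)
        assert len(scores) == len(df) - 1

    def test_empty_cross_data_rejected(self):
        model = build_model(NetworkConfig(seed=0))
        with pytest.raises(ValueError):
            train(model, np.empty((0, 12)), (np.ones((1, 12)), np.ones((1, 12))))


class TestWarpedCohort:
    def test_latent_recovered_through_monotone_warp(self):
        from dfikit.synthetic import (
            CohortConfig, DEFAULT_BASELINE, DEFAULT_NOISE_SD, cubic_warp,
            generate_cohort,
        )

        cfg = CohortConfig(
            n_per_strain_sex=200,
            strains=[("S1", DEFAULT_BASELINE.copy())],
            feature_noise_sd=DEFAULT_NOISE_SD / 2,
            warp=cubic_warp(1.0),
            visit_ages=(26.0, 52.0, 78.0, 104.0),
            seed=31,
        )
        cohort, _, latent = generate_cohort(cfg)
        fm = assemble_matrix(strain_center(derive_granulocytes(cohort)))
        table = fm.to_frame()
        i_n, i_n1 = make_pairs(table, 26.0, 4.0)
        pos = {idx: k for k, idx in enumerate(table.index)}
        X = fm.values
        pairs = (X[[pos[i] for i in i_n]], X[[pos[i] for i in i_n1]])
        ncfg = NetworkConfig(hidden_width=48, n_resnet_blocks=2, epochs=60,
                             lr_switch_epoch=40, alpha2_ramp_epochs=30,
                             batch_size=256, seed=2)
        model = build_model(ncfg)
        train(model, X, pairs,
              ages_cross=fm.row_keys["age_weeks"].to_numpy(dtype=float))
        scores = score_dfi(model, fm)
        m = scores.merge(latent, on=["animal_id", "age_weeks"])
        assert abs(np.corrcoef(m["dfi"], m["z_true"])[0, 1]) > 0.85
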