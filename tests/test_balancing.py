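"""Oversampling: interpolation formulas, exact balance, geometry, determinism."""
import numpy as np
import pandas as pd
import pytest

import bdcfgp as b
from bdcfgp.balancing import AS_PRINTED, CONVENTIONAL, OversamplerConfig


class TestInterpolation:
    def test_smote_r_zero_is_identity_both_directions(self):
        for d in (CONVENTIONAL, AS_PRINTED):
            np.testing.assert_array_equal(
                b.interpolate_smote((2, 2), (4, 4), 0.0, d), [2, 2]
            )

    def test_smote_conventional_midpoint(self):
        np.testing.assert_allclose(
            b.interpolate_smote((2, 2), (4, 4), 0.5, CONVENTIONAL), [3, 3]
        )

    def test_smote_as_printed_extrapolates(self):
        np.testing.assert_allclose(
            b.interpolate_smote((2, 2), (4, 4), 0.5, AS_PRINTED), [1, 1]
        )

    def test_adasyn_endpoints_and_quarter(self):
        np.testing.assert_allclose(b.interpolate_adasyn((0, 4), (4, 0), 0.0), [0, 4])
        np.testing.assert_allclose(b.interpolate_adasyn((0, 4), (4, 0), 1.0), [4, 0])
        np.testing.assert_allclose(b.interpolate_adasyn((0, 4), (4, 0), 0.25), [1, 3])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            b.interpolate_smote((1, 2), (1, 2, 3), 0.5)
        with pytest.raises(ValueError):
            b.interpolate_adasyn((1,), (1, 2), 0.5)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            b.interpolate_smote((1,), (2,), 1.5)


def _study_features(fgp_frame):
    X = fgp_frame[list(b.TARGET_COLUMNS)]
    y = fgp_frame["PT"].to_numpy()
    return X, y


class TestOversample:
    @pytest.mark.parametrize("method", ["smote", "adasyn"])
    def test_study_distribution_balances_to_majority(self, fgp_frame, method):
        X, y = _study_features(fgp_frame)
        cfg = OversamplerConfig(method=method, seed=5, value_range=(0, 5))
        Xb, yb, flags = b.oversample(X, y, cfg)
        _, counts = np.unique(yb, return_counts=True)
        assert counts.tolist() == [360] * 6
        assert len(Xb) == 2160
        # originals preserved, in order, before all synthetic rows
        assert not flags[: len(X)].any() and flags[len(X):].all()
        np.testing.assert_array_equal(np.asarray(Xb)[: len(X)], np.asarray(X, float))

    def test_already_balanced_unchanged(self, rng):
        X = rng.integers(0, 5, size=(40, 3)).astype(float)
        y = np.repeat([0, 1], 20)
        Xb, yb, flags = b.oversample(X, y, OversamplerConfig(seed=1))
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)
        assert not flags.any()

    @pytest.mark.parametrize("method", ["smote", "adasyn"])
    def test_determinism_byte_identical(self, fgp_frame, method):
        X, y = _study_features(fgp_frame)
        cfg = OversamplerConfig(method=method, seed=11, value_range=(0, 5))
        a = b.oversample(X, y, cfg)
        c = b.oversample(X, y, cfg)
        assert np.asarray(a[0]).tobytes() == np.asarray(c[0]).tobytes()
        assert a[1].tobytes() == c[1].tobytes()

    def test_conventional_synthetics_between_minority_points(self, rng):
        # 2-class toy: 5 minority points on a line vs 20 majority points.
        minority = np.linspace(0, 4, 5)[:, None] * np.ones((1, 2))
        majority = rng.normal(20, 1, size=(20, 2))
        X = np.vstack([minority, majority])
        y = np.array([1] * 5 + [0] * 20)
        cfg = OversamplerConfig(method="smote", seed=2, snap_to_grid=False)
        with pytest.warns(UserWarning):  # minority class of 5 < k+1
            Xb, yb, flags = b.oversample(X, y, cfg)
        synth = np.asarray(Xb)[flags]
        assert (yb[flags] == 1).all()
        # brute force: every synthetic point must lie on a segment between
        # two original minority points (betweenness + collinearity).
        for s in synth:
            on_some_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    p, q = minority[i], minority[j]
                    u, v = q - p, s - p
                    cross = u[0] * v[1] - u[1] * v[0]
                    within = np.all(s >= np.minimum(p, q) - 1e-9) and np.all(
                        s <= np.maximum(p, q) + 1e-9
                    )
                    if abs(float(cross)) < 1e-9 and within:
                        on_some_segment = True
            assert on_some_segment

    def test_as_printed_synthetics_collinear(self, rng):
        minority = np.array([[0.0, 0.0], [2.0, 2.0], [4.0, 4.0], [6.0, 6.0]])
        majority = rng.normal(30, 1, size=(12, 2))
        X = np.vstack([minority, majority])
        y = np.array([1] * 4 + [0] * 12)
        cfg = OversamplerConfig(
            method="smote", seed=3, direction=AS_PRINTED, snap_to_grid=False
        )
        with pytest.warns(UserWarning):
            Xb, _, flags = b.oversample(X, y, cfg)
        for s in np.asarray(Xb)[flags]:
            # all minority points lie on y = x; extrapolation stays on it
            assert abs(s[0] - s[1]) < 1e-9

    def test_snap_to_grid_keeps_ordinal_values(self, fgp_frame):
        X, y = _study_features(fgp_frame)
        cfg = OversamplerConfig(method="smote", seed=7, value_range=(0, 5))
        Xb, _, _ = b.oversample(X, y, cfg)
        vals = np.asarray(Xb)
        assert np.array_equal(vals, np.rint(vals))
        assert vals.min() >= 0 and vals.max() <= 5

    def test_single_member_class_replicates(self):
        X = np.array([[0.0], [10.0], [11.0], [12.0]])
        y = np.array([1, 0, 0, 0])
        with pytest.warns(UserWarning, match="single member"):
            Xb, yb, flags = b.oversample(X, y, OversamplerConfig(seed=0))
        synth = np.asarray(Xb)[flags]
        assert (synth == 0.0).all() and (yb[flags] == 1).all()

    def test_adasyn_quotas_sum_to_deficit(self, rng):
        from bdcfgp.balancing import _adasyn_ratios, _allocate_quotas

        X = rng.normal(size=(60, 2))
        y = np.array([0] * 45 + [1] * 15)
        ratios = _adasyn_ratios(X, y, 1, k=5)
        quotas = _allocate_quotas(ratios, 30)
        assert quotas.sum() == 30 and (quotas >= 0).all()

    def test_empty_and_single_class_errors(self):
        with pytest.raises(ValueError):
            b.oversample(np.empty((0, 2)), [], OversamplerConfig())
        with pytest.raises(ValueError):
            b.oversample(np.ones((3, 2)), [1, 1, 1], OversamplerConfig())

    def test_dataframe_columns_preserved(self, fgp_frame):
        X, y = _study_features(fgp_frame)
        Xb, _, _ = b.oversample(X, y, OversamplerConfig(seed=1, value_range=(0, 5)))
        assert isinstance(Xb, pd.DataFrame)
        assert list(Xb.columns) == list(b.TARGET_COLUMNS)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OversamplerConfig(method="borderline")
        with pytest.raises(ValueError):
            OversamplerConfig(k=0)
        with pytest.raises(ValueError):
            OversamplerConfig(direction="sideways")
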