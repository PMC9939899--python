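"""Dynamic transforms: hand-derived values, invariances, oracle agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynrad import (
    PhaseSeries,
    build_dynamic_matrix,
    dc_feature,
    poly_features,
    racr_features,
    rcr_features,
    sd_feature,
)
from oracles import dc_naive, poly_naive, racr_naive, rcr_naive, sd_naive

series_strategy = st.lists(
    st.floats(min_value=-1e3, max_value=1e3, allow_nan=False, width=64), min_size=2, max_size=6
)
positive_series = st.lists(
    st.floats(min_value=1e-3, max_value=1e3, allow_nan=False, width=64), min_size=2, max_size=6
)


@pytest.mark.parametrize(
    "values, expected",
    [
        ((1, 2, 3, 4), 1.0),  # fbar=2.5, deviations (1.5,0.5,0.5,1.5)
        ((5, 5, 5, 5), 0.0),
        ((2, 4), 1.0),
    ],
)
def test_sd_hand_values(values, expected):
    assert sd_feature(values) == pytest.approx(expected, abs=1e-12)


def test_dc_hand_value_and_scale_invariance():
    assert dc_feature((1, 2, 3, 4)) == pytest.approx(0.4, abs=1e-12)
    assert dc_feature((3, 3, 3)) == 0.0
    for c in (0.5, 7.0, 1234.5):
        assert dc_feature((c * 1, c * 2, c * 3, c * 4)) == pytest.approx(0.4, rel=1e-12)


def test_rcr_pair_convention():
    out = rcr_features((2, 4))
    assert out == {(1, 2): pytest.approx(0.5)}
    # later-phase denominator as defined; switch flips it
    assert rcr_features((2, 4), denominator="earlier")[(1, 2)] == pytest.approx(1.0)
    k4 = rcr_features((1, 2, 3, 4))
    assert set(k4) == {(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)}


def test_racr_hand_value_and_numerator_identity():
    assert racr_features((2, 4))[(1, 2)] == pytest.approx(2 / 3, rel=1e-12)
    vals = (3.0, 1.5, 4.0, 2.5)
    fbar = abs(np.mean(vals))
    rcr = rcr_features(vals)
    racr = racr_features(vals)
    for (j, i), v in racr.items():
        num = rcr[(j, i)] * abs(vals[i - 1])
        assert v == pytest.approx(num / fbar, rel=1e-9)


def test_poly_exact_line_and_saturated_fit():
    fit = poly_features(PhaseSeries([1, 2, 3, 4]), degree=1)
    assert fit.coefficients == pytest.approx((0.0, 1.0), abs=1e-9)
    assert fit.rss == 0.0
    const = poly_features([7, 7, 7, 7], degree=1)
    assert const.coefficients[1] == 0.0
    assert const.coefficients[0] == pytest.approx(7.0)
    # degree k-1 interpolates
    assert poly_features([1.0, -2.0, 5.0, 0.3]).rss == 0.0


def test_poly_rejects_bad_degree_and_repeated_times():
    with pytest.raises(ValueError):
        poly_features([1, 2, 3], degree=3)
    with pytest.raises(ValueError):
        PhaseSeries([1, 2, 3], times=[1, 1, 2])


@settings(max_examples=50, deadline=None)
@given(series_strategy)
def test_transforms_match_naive_translation(values):
    assert sd_feature(values) == pytest.approx(sd_naive(values), abs=1e-12, rel=1e-12)
    assert dc_feature(values) == pytest.approx(dc_naive(values), abs=1e-12, rel=1e-12)
    for key, v in rcr_features(values).items():
        assert v == pytest.approx(rcr_naive(values)[key], abs=1e-12, rel=1e-12)
    for key, v in racr_features(values).items():
        assert v == pytest.approx(racr_naive(values)[key], abs=1e-12, rel=1e-12)


@settings(max_examples=30, deadline=None)
@given(positive_series, st.floats(min_value=1e-2, max_value=1e3))
def test_rcr_racr_scale_invariance(values, c):
    base_rcr = rcr_features(values)
    base_racr = racr_features(values)
    scaled = [c * v for v in values]
    for key in base_rcr:
        assert rcr_features(scaled)[key] == pytest.approx(base_rcr[key], rel=1e-9)
        assert racr_features(scaled)[key] == pytest.approx(base_racr[key], rel=1e-9)


@settings(max_examples=30, deadline=None)
@given(series_strategy)
def test_sign_flip_invariance(values):
    neg = [-v for v in values]
    assert sd_feature(neg) == pytest.approx(sd_feature(values), abs=1e-12)
    for key, v in rcr_features(values).items():
        assert rcr_features(neg)[key] == pytest.approx(v, abs=1e-12)
    for key, v in racr_features(values).items():
        assert racr_features(neg)[key] == pytest.approx(v, abs=1e-12)


def test_constant_series_yields_exact_zero():
    c = (3.7, 3.7, 3.7, 3.7)
    assert sd_feature(c) == 0.0
    assert dc_feature(c) == 0.0
    assert all(v == 0.0 for v in rcr_features(c).values())
    assert all(v == 0.0 for v in racr_features(c).values())
    fit = poly_features(c, degree=2)
    assert fit.coefficients[1] == 0.0 and fit.coefficients[2] == 0.0


def _phase_frames(data, patients, features, phases=("PP", "AP", "PVP", "DP")):
    return {
        ph: pd.DataFrame(data[:, :, pi], index=patients, columns=features)
        for pi, ph in enumerate(phases[: data.shape[2]])
    }


class TestBuildDynamicMatrix:
    def test_column_counts_and_names(self, rng):
        data = rng.lognormal(size=(5, 3, 4))
        frames = _phase_frames(data, [f"p{i}" for i in range(5)], list("abc"))
        dyn = build_dynamic_matrix(frames, kinds=["SD", "DC", "RCR", "RACR", "P"])
        # per base: 1 + 1 + 6 + 6 + 4 = 18
        assert dyn.data.shape == (5, 3 * 18)
        assert "a__SD" in dyn.data.columns
        assert "b__RCR_1to2" in dyn.data.columns and "b__RCR_3to4" in dyn.data.columns
        assert "c__P_a3" in dyn.data.columns
        assert list(dyn.meta.index) == list(dyn.data.columns)

    def test_matches_per_series_functions(self, rng):
        data = rng.normal(size=(8, 4, 4)) * 10
        patients = [f"p{i}" for i in range(8)]
        feats = list("wxyz")
        dyn = build_dynamic_matrix(_phase_frames(data, patients, feats))
        for pi, pid in enumerate(patients):
            for fi, f in enumerate(feats):
                series = data[pi, fi, :]
                assert dyn.data.loc[pid, f"{f}__SD"] == pytest.approx(sd_naive(series), rel=1e-12, abs=1e-12)
                assert dyn.data.loc[pid, f"{f}__DC"] == pytest.approx(dc_naive(series), rel=1e-12, abs=1e-12)
                for (j, i), v in rcr_naive(series).items():
                    assert dyn.data.loc[pid, f"{f}__RCR_{j}to{i}"] == pytest.approx(v, rel=1e-12, abs=1e-12)
                coef, _ = poly_naive(series, [1, 2, 3, 4], 3)
                for m in range(4):
                    assert dyn.data.loc[pid, f"{f}__P_a{m}"] == pytest.approx(coef[m], rel=1e-6, abs=1e-8)

    def test_three_phases_gives_three_pairs(self, rng):
        data = rng.lognormal(size=(4, 2, 3))
        frames = _phase_frames(data, list("abcd"), ["f1", "f2"], phases=("PP", "AP", "PVP"))
        dyn = build_dynamic_matrix(frames, kinds=["RCR"])
        assert dyn.data.shape[1] == 2 * 3

    def test_missing_patient_is_reported(self, rng):
        data = rng.lognormal(size=(4, 2, 4))
        frames = _phase_frames(data, list("abcd"), ["f1", "f2"])
        frames["PVP"] = frames["PVP"].drop(index="c")
        with pytest.raises(ValueError, match="PVP"):
            build_dynamic_matrix(frames)

    def test_row_equivariance_under_patient_permutation(self, rng):
        data = rng.lognormal(size=(6, 3, 4))
        patients = [f"p{i}" for i in range(6)]
        frames = _phase_frames(data, patients, list("abc"))
        dyn = build_dynamic_matrix(frames, kinds=["RCR"])
        perm = [3, 0, 5, 1, 4, 2]
        frames_perm = {ph: df.iloc[perm] for ph, df in frames.items()}
        dyn_perm = build_dynamic_matrix(frames_perm, kinds=["RCR"])
        pd.testing.assert_frame_equal(dyn.data.iloc[perm], dyn_perm.data)

    def test_eps_guard_flags_not_drops(self):
        frames = {
            "PP": pd.DataFrame({"f": [0.0, 1.0]}, index=["a", "b"]),
            "AP": pd.DataFrame({"f": [0.0, 2.0]}, index=["a", "b"]),
        }
        dyn = build_dynamic_matrix(frames, kinds=["RCR", "DC"])
        assert dyn.data.loc["a", "f__RCR_1to2"] == 0.0
        assert dyn.meta.loc["f__RCR_1to2", "eps_guarded"]
        assert dyn.n_guarded_cells >= 2  # DC mean-zero cell and the RCR cell
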