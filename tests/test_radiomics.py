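"""Radiomics feature extraction: census, crops, and brute-force agreement."""

import numpy as np
import pytest

from epidfluence.radiomics_features import (
    DiscretizationConfig,
    center_crop,
    discretize,
    extract_features,
    feature_names,
    select_ml_columns,
)

from . import oracles

GLRLM_TO_SHARED = {
    "ShortRunEmphasis": "SmallEmphasis",
    "LongRunEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity": "SizeNonUniformity",
    "RunLengthNonUniformityNormalized": "SizeNonUniformityNormalized",
    "RunPercentage": "Percentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "RunVariance": "SizeVariance",
    "RunEntropy": "Entropy",
    "LowGrayLevelRunEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelRunEmphasis": "HighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}
GLSZM_TO_SHARED = {
    "SmallAreaEmphasis": "SmallEmphasis",
    "LargeAreaEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity": "SizeNonUniformity",
    "SizeZoneNonUniformityNormalized": "SizeNonUniformityNormalized",
    "ZonePercentage": "Percentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "ZoneVariance": "SizeVariance",
    "ZoneEntropy": "Entropy",
    "LowGrayLevelZoneEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelZoneEmphasis": "HighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}
GLDM_TO_SHARED = {
    "SmallDependenceEmphasis": "SmallEmphasis",
    "LargeDependenceEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "DependenceNonUniformity": "SizeNonUniformity",
    "DependenceNonUniformityNormalized": "SizeNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "DependenceVariance": "SizeVariance",
    "DependenceEntropy": "Entropy",
    "LowGrayLevelEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}


@pytest.fixture(scope="module")
def small_maps():
    """Deterministic small matrices exercising all texture families."""
    rng = np.random.default_rng(11)
    return {
        "random6": rng.integers(0, 60, size=(6, 6)).astype(float),
        "random8": rng.integers(0, 120, size=(8, 8)).astype(float),
        "smooth8": np.add.outer(np.arange(8.0), np.arange(8.0)) * 3.7,
        "blocky": np.kron(rng.integers(0, 4, (4, 4)), np.ones((2, 2))).astype(float),
    }


def test_census_is_94_with_expected_family_sizes():
    names = feature_names()
    assert len(names) == len(set(names)) == 94
    by_family = {}
    for n in names:
        by_family.setdefault(n.split("_")[0], []).append(n)
    assert {k: len(v) for k, v in by_family.items()} == {
        "firstorder": 19, "glcm": 24, "gldm": 14,
        "glrlm": 16, "glszm": 16, "ngtdm": 5,
    }
    assert not any("shape" in n.lower() for n in names)


def test_extract_features_returns_all_94_finite(small_maps):
    f = extract_features(small_maps["random8"])
    assert list(f) == feature_names()
    assert all(np.isfinite(v) for v in f.values())


@pytest.mark.parametrize(
    "shape, side, offset",
    [((1190, 1190), 512, 339), ((512, 512), 512, 0), ((600, 600), 512, 44)],
)
def test_center_crop_offsets(shape, side, offset):
    x = np.zeros(shape, dtype=np.float32)
    x[offset, offset] = 1.0
    crop = center_crop(x, side)
    assert crop.shape == (side, side)
    assert crop[0, 0] == 1.0


def test_center_crop_rejects_small_maps():
    with pytest.raises(ValueError, match="smaller"):
        center_crop(np.zeros((100, 100)), 512)


def test_constant_map_degenerate_values_not_nan():
    f = extract_features(np.full((32, 32), 5.0))
    assert all(np.isfinite(v) for v in f.values())
    assert f["firstorder_Variance"] == 0.0
    assert f["glcm_Contrast"] == 0.0
    assert f["glcm_Correlation"] == 1.0
    # axis-aligned lines hold one full-width run (length 32); diagonal
    # lines hold runs of length 1..32 -> direction-averaged enumeration
    axis_lre = 32.0**2
    diag_lre = (2 * sum(j * j for j in range(1, 32)) + 32**2) / 63
    assert f["glrlm_LongRunEmphasis"] == pytest.approx(
        (2 * axis_lre + 2 * diag_lre) / 4
    )
    assert f["glszm_SmallAreaEmphasis"] == pytest.approx(1 / 32.0**4)


def test_checkerboard_glcm_contrast_and_entropy():
    # horizontal/vertical neighbours always differ by one level (contrast 1),
    # diagonal neighbours never differ (contrast 0) -> direction mean 0.5;
    # two equally likely values -> first-order entropy exactly 1 bit
    cb = (np.add.outer(np.arange(4), np.arange(4)) % 2).astype(float) * 10
    f = extract_features(cb, DiscretizationConfig("count", bin_count=2))
    assert f["glcm_Contrast"] == pytest.approx(0.5)
    assert f["firstorder_Entropy"] == pytest.approx(1.0)


def test_fixed_width_discretization_shift_invariant(small_maps):
    cfg = DiscretizationConfig("width", bin_width=10.0)
    x = small_maps["random8"]
    f0 = extract_features(x, cfg)
    f1 = extract_features(x + 500.0, cfg)
    # anchored at the map minimum: difference-based features are unchanged
    for name in ("glcm_Contrast", "glcm_DifferenceAverage", "glcm_JointEntropy",
                 "glrlm_RunPercentage", "ngtdm_Contrast"):
        assert f0[name] == pytest.approx(f1[name], abs=1e-12), name


def test_discretize_bin_count_bounds():
    x = np.array([[0.0, 1.0], [2.0, 10.0]])
    lv = discretize(x, DiscretizationConfig("count", bin_count=4))
    assert lv.min() == 1 and lv.max() == 4


@pytest.mark.parametrize("key", ["random6", "random8", "smooth8", "blocky"])
def test_every_texture_feature_matches_bruteforce(small_maps, key):
    """All 75 texture features vs independent enumeration, tol 1e-9."""
    x = small_maps[key]
    cfg = DiscretizationConfig("count", bin_count=4)
    lv = discretize(x, cfg)
    ng = int(lv.max())
    f = extract_features(x, cfg)

    for name, val in oracles.glcm_features(lv, ng).items():
        assert f[f"glcm_{name}"] == pytest.approx(val, abs=1e-9), name
    ref = oracles.glrlm_features(lv, ng)
    for name, shared in GLRLM_TO_SHARED.items():
        assert f[f"glrlm_{name}"] == pytest.approx(ref[shared], abs=1e-9), name
    ref = oracles.glszm_features(lv, ng)
    for name, shared in GLSZM_TO_SHARED.items():
        assert f[f"glszm_{name}"] == pytest.approx(ref[shared], abs=1e-9), name
    ref = oracles.gldm_features(lv, ng)
    for name, shared in GLDM_TO_SHARED.items():
        assert f[f"gldm_{name}"] == pytest.approx(ref[shared], abs=1e-9), name
    for name, val in oracles.ngtdm_features(lv, ng).items():
        assert f[f"ngtdm_{name}"] == pytest.approx(val, abs=1e-9), name


def test_firstorder_against_direct_formulas(small_maps):
    x = small_maps["random8"]
    f = extract_features(x, DiscretizationConfig("count", bin_count=8))
    flat = x.ravel()
    assert f["firstorder_Mean"] == pytest.approx(flat.mean())
    assert f["firstorder_Variance"] == pytest.approx(flat.var())
    assert f["firstorder_Energy"] == pytest.approx((flat**2).sum())
    assert f["firstorder_RootMeanSquared"] == pytest.approx(
        np.sqrt((flat**2).mean())
    )
    d = flat - flat.mean()
    assert f["firstorder_Skewness"] == pytest.approx(
        (d**3).mean() / flat.var() ** 1.5
    )
    assert f["firstorder_Kurtosis"] == pytest.approx(
        (d**4).mean() / flat.var() ** 2
    )


def test_ml_config_column_selection():
    cols = [f"{src}_{n}" for src in ("dd", "luminance", "contrast", "structure")
            for n in feature_names()]
    assert len(select_ml_columns(cols, "ml1")) == 94
    assert len(select_ml_columns(cols, "ml2")) == 282
    assert len(select_ml_columns(cols, "ml3")) == 376


def test_non_finite_map_rejected():
    bad = np.ones((8, 8))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        extract_features(bad)
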