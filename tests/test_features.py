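"""GLCM texture, pixel statistics, and attenuation estimation.

Each operation is checked against an independent brute-force or closed-form
oracle rather than against frozen numbers.
"""

import numpy as np
import pytest

from octava import features, patching, pipeline, synthgen
from octava.features import (attenuation_map, glcm_features, glcm_matrix,
                             optical_features, pixel_statistics)
from octava.volume_io import Label

# --------------------------------------------------------------------------
# brute-force oracles


def glcm_oracle(pixels, offset, levels=32):
    """Exhaustive pair counting + direct Haralick formulas."""
    quant = (pixels.astype(int) * levels) // 256
    P = np.zeros((levels, levels))
    dr, dc = offset
    h, w = quant.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                P[quant[r, c], quant[r2, c2]] += 1
                P[quant[r2, c2], quant[r, c]] += 1  # symmetrize
    P /= P.sum()
    i = np.arange(levels)
    mu_i = sum(i[a] * P[a, b] for a in i for b in i)
    mu_j = sum(i[b] * P[a, b] for a in i for b in i)
    var_i = sum((a - mu_i) ** 2 * P[a, b] for a in i for b in i)
    var_j = sum((b - mu_j) ** 2 * P[a, b] for a in i for b in i)
    energy = sum(P[a, b] ** 2 for a in i for b in i)
    contrast = sum((a - b) ** 2 * P[a, b] for a in i for b in i)
    homog = sum(P[a, b] / (1 + abs(a - b)) for a in i for b in i)
    if var_i * var_j > 0:
        corr = sum((a - mu_i) * (b - mu_j) * P[a, b] for a in i for b in i) \
            / np.sqrt(var_i * var_j)
    else:
        corr = 0.0
    return corr, energy, contrast, homog


def stats_oracle(pixels):
    x = pixels.astype(float).ravel()
    n = x.size
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    kurt = m4 / m2 ** 2 - 3 if m2 > 0 else 0.0
    counts = {}
    for v in pixels.ravel():
        counts[v] = counts.get(v, 0) + 1
    ent = -sum((c / n) * np.log2(c / n) for c in counts.values())
    return mean, m2, skew, kurt, ent


# --------------------------------------------------------------------------
# GLCM


def test_constant_patch_conventions():
    flat = np.full((16, 16), 42, dtype=np.uint8)
    f = glcm_features(flat)
    assert f["energy"] == pytest.approx(1.0)
    assert f["contrast"] == pytest.approx(0.0)
    assert f["homogeneity"] == pytest.approx(1.0)
    assert f["correlation"] == 0.0  # degenerate variance -> 0 by convention


def test_stripe_patch_contrast_by_pair_counting():
    """2-level vertical stripes, offset (0,1): every horizontal pair crosses."""
    patch = np.zeros((8, 8), dtype=np.uint8)
    patch[:, 1::2] = 255  # quantizes to level 31 at 32 levels
    P = glcm_matrix(patch, offset=(0, 1))
    # contrast = (31-0)^2 * (fraction of cross-level pairs) = 31^2 * 1.0
    contrast = sum((a - b) ** 2 * P[a, b] for a in range(32) for b in range(32))
    assert contrast == pytest.approx(31 ** 2)
    # vertical offset sees no level changes at all
    P_v = glcm_matrix(patch, offset=(1, 0))
    contrast_v = sum((a - b) ** 2 * P_v[a, b] for a in range(32) for b in range(32))
    assert contrast_v == pytest.approx(0.0)


def test_glcm_features_match_brute_force_oracle(rng):
    """20 random 8x8 patches: all four features equal the double-loop oracle."""
    for _ in range(20):
        patch = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        got = glcm_features(patch)
        per_offset = np.array([glcm_oracle(patch, off) for off in ((0, 1), (1, 0))])
        corr, energy, contrast, homog = per_offset.mean(axis=0)
        assert got["correlation"] == pytest.approx(corr, abs=1e-10)
        assert got["energy"] == pytest.approx(energy, abs=1e-10)
        assert got["contrast"] == pytest.approx(contrast, abs=1e-10)
        assert got["homogeneity"] == pytest.approx(homog, abs=1e-10)


def test_glcm_invariant_under_transposition(rng):
    """Symmetric offset set {(0,1),(1,0)}: transposing swaps the offsets."""
    patch = rng.integers(0, 256, size=(12, 20), dtype=np.uint8)
    a = glcm_features(patch)
    b = glcm_features(patch.T.copy())
    for k in a:
        assert a[k] == pytest.approx(b[k], abs=1e-12)


def test_energy_decreases_with_dispersion():
    """More evenly spread gray levels -> weakly smaller GLCM energy."""
    last = np.inf
    for n_levels in (1, 2, 4, 8):
        vals = np.linspace(0, 255, n_levels).astype(np.uint8)
        patch = np.tile(np.repeat(vals, 32 // n_levels), (16, 1))
        e = glcm_features(patch)["energy"]
        assert e <= last + 1e-12
        last = e


# --------------------------------------------------------------------------
# pixel statistics


def test_pixel_statistics_degenerate_and_two_bin():
    s = pixel_statistics(np.full((4, 4), 7, dtype=np.uint8))
    assert (s["mean"], s["variance"], s["entropy"]) == (7.0, 0.0, 0.0)
    assert (s["skewness"], s["kurtosis"]) == (0.0, 0.0)

    half = np.zeros((4, 4), dtype=np.uint8)
    half[:2] = 255
    assert pixel_statistics(half)["entropy"] == pytest.approx(1.0)


def test_pixel_statistics_match_direct_summation(rng):
    for _ in range(20):
        patch = rng.integers(0, 256, size=(6, 7), dtype=np.uint8)
        got = pixel_statistics(patch)
        mean, var, skew, kurt, ent = stats_oracle(patch)
        assert got["mean"] == pytest.approx(mean, abs=1e-10)
        assert got["variance"] == pytest.approx(var, abs=1e-9)
        assert got["skewness"] == pytest.approx(skew, abs=1e-10)
        assert got["kurtosis"] == pytest.approx(kurt, abs=1e-9)
        assert got["entropy"] == pytest.approx(ent, abs=1e-10)


# --------------------------------------------------------------------------
# attenuation


def test_attenuation_geometric_series_closed_form():
    """Deep noiseless exponential: mu_hat = (1-r)/(2 dz r), r = e^(-2 mu dz)."""
    mu, dz, depth = 0.6042, 0.00367, 2000
    I = np.exp(-2 * mu * np.arange(depth) * dz)[:, None]
    m = attenuation_map(I, dz, tail_exclude=200)
    r = np.exp(-2 * mu * dz)
    expected = (1 - r) / (2 * dz * r)
    # residual truncation of the geometric tail at depth 2000 is ~r^2000
    np.testing.assert_allclose(m[:50, 0], expected, rtol=5e-4)
    assert expected == pytest.approx(mu, rel=0.005)


def test_attenuation_scale_invariance(rng):
    I = rng.random((64, 16)) + 0.01
    m1 = attenuation_map(I, 0.00367)
    m2 = attenuation_map(1234.5 * I, 0.00367)
    np.testing.assert_allclose(m1, m2, rtol=1e-12)


def test_attenuation_two_segment_decay_matches_formula_oracle():
    """A gain step mid A-line produces a mu_hat discontinuity exactly where
    the direct-formula oracle places it."""
    mu, dz, depth, boundary = 0.6, 0.00367, 256, 100
    amp = np.where(np.arange(depth) < boundary, 4.0, 1.0)
    I = (amp * np.exp(-2 * mu * np.arange(depth) * dz))[:, None]
    got = attenuation_map(I, dz, tail_exclude=8)
    # direct per-pixel evaluation of the estimator
    for i in [0, 50, boundary - 1, boundary, boundary + 1, 200]:
        tail = I[i + 1:, 0].sum()
        expect = I[i, 0] / (2 * dz * tail)
        assert got[i, 0] == pytest.approx(expect, rel=1e-10)
    d = np.diff(got[:, 0])
    assert np.argmax(np.abs(d)) in (boundary - 1, boundary)


def test_attenuation_invalid_pixels_and_tail():
    I = np.zeros((64, 4))
    I[:32, :] = 1.0  # zero tail below row 31
    m = attenuation_map(I, 0.00367, tail_exclude=8)
    assert m.shape == (56, 4)
    assert np.isnan(m[31, 0])  # zero denominator -> invalid


def test_optical_features_summaries():
    uniform = np.full((10, 5), 0.5227)
    f = optical_features(uniform)
    assert f == {"attenuation": pytest.approx(0.5227), "attenuation_sd": pytest.approx(0.0)}
    two = np.array([[0.4, 0.6]] * 5).ravel().reshape(5, 2)
    f2 = optical_features(two)
    assert f2["attenuation"] == pytest.approx(0.5)
    assert f2["attenuation_sd"] == pytest.approx(0.1)
    assert optical_features(np.full((3, 3), np.nan)) is None


def test_la_attenuation_higher_than_pv_on_noiseless_phantoms():
    """Mean patch attenuation ordering matches the underlying optics."""
    cfg = synthgen.PhantomConfig(grid_nx=512, grid_ny=8, speckle=False, seed=3)
    ph = synthgen.generate_volume(cfg)
    accepted, _ = pipeline.volume_to_patches(
        ph.as_volume("log8bit", "j0"), ph.as_volume("linear", "j0"), ph.labels)
    table = features.compute_feature_table(accepted)
    la = table.loc[table.label == "LA", "attenuation"]
    pv = table.loc[table.label == "PV", "attenuation"]
    assert len(la) and len(pv)
    assert la.mean() > pv.mean()


def test_feature_table_has_no_missing_values(small_cohort):
    _, table, _ = small_cohort
    assert not table[features.FEATURE_NAMES].isna().any().any()
    assert list(table.columns[:11]) == features.FEATURE_NAMES
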