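import numpy as np
import pytest

from rimsift import (BinaryMask, StandardScale, Volume, apply_template,
                     load_template, save_template, train_template)
from rimsift.normalize import DEFAULT_PERCENTILES, _piecewise_map


def _vol(data):
    return Volume(np.asarray(data, dtype=float), np.diag([0.5, 0.5, 0.5, 1.0]))


def _full_mask(shape):
    return BinaryMask(np.ones(shape, dtype=np.uint8), np.diag([0.5, 0.5, 0.5, 1.0]))


@pytest.fixture
def cohort(rng):
    vols = [_vol(rng.normal(60, 15, (12, 12, 12))) for _ in range(3)]
    masks = [_full_mask(v.shape) for v in vols]
    return vols, masks


def test_single_image_template_is_own_mapped_landmarks(rng):
    v = _vol(rng.normal(0, 1, (10, 10, 10)))
    m = _full_mask(v.shape)
    tmpl = train_template([v], [m])
    lm = np.percentile(v.data, DEFAULT_PERCENTILES)
    expected = (lm - lm[0]) / (lm[-1] - lm[0]) * 100
    np.testing.assert_allclose(tmpl.standard_values, expected, atol=1e-12)


def test_training_affine_invariance(rng):
    """An image and its affine transform a*x+b contribute identically."""
    v = _vol(rng.normal(50, 10, (10, 10, 10)))
    w = _vol(2.5 * v.data - 7.0)
    m = _full_mask(v.shape)
    t1 = train_template([v], [m])
    t2 = train_template([v, w], [m, m])
    np.testing.assert_allclose(t1.standard_values, t2.standard_values, rtol=1e-10)


def test_apply_affine_invariance(rng, cohort):
    vols, masks = cohort
    tmpl = train_template(vols, masks)
    v, m = vols[0], masks[0]
    out1 = apply_template(v, m, tmpl)
    out2 = apply_template(_vol(3.0 * v.data + 11.0), m, tmpl)
    np.testing.assert_allclose(out1.data, out2.data, rtol=1e-9, atol=1e-9)


def test_landmark_percentiles_hit_standard_values_after_apply(rng, cohort):
    """With landmark values coinciding with order statistics (n-1 divisible
    by 100) the mapped landmarks equal the template values to float
    precision."""
    vols, masks = cohort
    tmpl = train_template(vols, masks)
    vals = np.sort(rng.normal(60, 15, 201))
    v = _vol(np.pad(vals, (0, 1000 - 201), mode="edge").reshape(10, 10, 10))
    # use exactly 201 in-mask voxels
    mask_arr = np.zeros(1000, dtype=np.uint8)
    mask_arr[:201] = 1
    m = BinaryMask(mask_arr.reshape(10, 10, 10), v.affine)
    out = apply_template(v, m, tmpl)
    got = np.percentile(out.data[m.data > 0], DEFAULT_PERCENTILES)
    np.testing.assert_allclose(got, tmpl.standard_values, atol=1e-6)


def test_mapping_is_monotone(rng, cohort):
    vols, masks = cohort
    tmpl = train_template(vols, masks)
    out = apply_template(vols[0], masks[0], tmpl)
    x = vols[0].data.ravel()
    y = out.data.ravel()
    order = np.argsort(x)
    assert np.all(np.diff(y[order]) >= -1e-12)


def test_idempotence_on_normalized_image(rng, cohort):
    """Re-normalizing an already-normalized image moves the landmarks by
    less than 1e-6 (landmarks on exact order statistics: 201 voxels)."""
    vols, masks = cohort
    tmpl = train_template(vols, masks)
    vals = np.sort(rng.normal(60, 15, 201))
    v = _vol(np.pad(vals, (0, 1000 - 201), mode="edge").reshape(10, 10, 10))
    mask_arr = np.zeros(1000, dtype=np.uint8)
    mask_arr[:201] = 1
    m = BinaryMask(mask_arr.reshape(10, 10, 10), v.affine)
    once = apply_template(v, m, tmpl)
    twice = apply_template(once, m, tmpl)
    lm1 = np.percentile(once.data[m.data > 0], DEFAULT_PERCENTILES)
    lm2 = np.percentile(twice.data[m.data > 0], DEFAULT_PERCENTILES)
    np.testing.assert_allclose(lm1, lm2, atol=1e-6)


def test_tails_are_extrapolated_not_clipped():
    xp = np.array([0.0, 1.0, 2.0])
    fp = np.array([0.0, 50.0, 100.0])
    y = _piecewise_map(np.array([-1.0, 3.0]), xp, fp)
    assert y[0] == pytest.approx(-50.0)
    assert y[1] == pytest.approx(150.0)


def test_matched_image_maps_to_itself(rng):
    """An image whose landmarks already equal the standard values is left
    unchanged (identity mapping) within the landmark span."""
    v = _vol(rng.uniform(0, 100, (12, 12, 12)))
    m = _full_mask(v.shape)
    tmpl = train_template([v], [m])
    lm = np.percentile(v.data, DEFAULT_PERCENTILES)
    rescaled = _vol((v.data - lm[0]) / (lm[-1] - lm[0]) * 100)
    out = apply_template(rescaled, m, tmpl)
    np.testing.assert_allclose(out.data, rescaled.data, atol=1e-9)


def test_constant_image_rejected():
    v = _vol(np.full((8, 8, 8), 5.0))
    m = _full_mask(v.shape)
    with pytest.raises(ValueError, match="distinct"):
        train_template([v], [m])


def test_template_round_trip(tmp_path, cohort):
    vols, masks = cohort
    tmpl = train_template(vols, masks, contrast_tag="post")
    path = tmp_path / "template_post.txt"
    save_template(tmpl, path)
    back = load_template(path)
    assert back.contrast_tag == "post"
    assert back.scale_range == tmpl.scale_range
    np.testing.assert_allclose(back.standard_values, tmpl.standard_values)
    np.testing.assert_allclose(back.landmark_percentiles, tmpl.landmark_percentiles)


def test_load_handwritten_template(tmp_path):
    path = tmp_path / "tiny.txt"
    path.write_text(
        "version: 1\ncontrast_tag: pre\nscale_range: 0 100\n"
        "percentiles: 1 50 99\nstandard_values: 0 40 100\n"
    )
    t = load_template(path)
    assert t.standard_values == (0.0, 40.0, 100.0)
    assert t.landmark_percentiles == (1.0, 50.0, 99.0)


def test_load_malformed_template(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("version: 1\njunk without colon goes here")
    with pytest.raises(ValueError):
        load_template(path)


def test_standard_scale_invariants():
    with pytest.raises(ValueError, match="increasing"):
        StandardScale((1, 50, 99), (0.0, 100.0, 40.0))
    with pytest.raises(ValueError, match="span"):
        StandardScale((1, 50, 99), (5.0, 40.0, 100.0))
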