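import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shapebias import geometry as G
from shapebias.synth import gen_shape_class, sample_mask


def _blob_mask(seed):
    spec = gen_shape_class(seed, "blob")
    return sample_mask(spec, seed=seed + 1)


def test_disk_contour_length_within_one_percent(disk_mask):
    v = G.extract_contour(disk_mask)
    expected = 2 * np.pi * 50.0
    assert abs(G.contour_length(v) - expected) / expected < 0.01


def test_disk_signed_area_ccw(disk_mask):
    v = G.extract_contour(disk_mask)
    area = G.signed_area(v)
    assert area > 0  # CCW orientation enforced
    assert abs(area - np.pi * 50.0 ** 2) / (np.pi * 50.0 ** 2) < 0.02


def test_resample_preserves_length_and_count(disk_mask):
    v = G.extract_contour(disk_mask)
    r = G.resample_arclength(v, 256)
    assert r.shape == (256, 2)
    assert abs(G.contour_length(r) - G.contour_length(v)) / G.contour_length(v) < 0.01


@pytest.mark.parametrize("seed", [0, 3, 7])
def test_turning_number_exact_on_raw_profile(seed):
    """Sum of turning angles of a simple closed CCW contour is exactly 2*pi
    when no profile smoothing is applied."""
    v = G.extract_contour(_blob_mask(seed))
    p = G.curvature_profile(v, profile_smooth_px=0.0)
    assert abs(np.sum(p.kappa * p.ds) - 2 * np.pi) < 1e-9


def test_disk_curvature_concentrates_in_one_default_bin(disk_mask):
    bins = G.default_curvature_bins()
    h = G.mask_curvature_histogram(disk_mask, bins=bins)
    assert h.sum() == pytest.approx(1.0)
    assert h.max() > 0.99  # 1/50 rad/px falls in a single default-width bin


def test_efd_translation_and_scale_invariance():
    v = G.extract_contour(_blob_mask(2)).astype(float)
    d0 = G.elliptic_fourier(v)
    d_shift = G.elliptic_fourier(v + np.array([13.5, -7.25]))
    d_scale = G.elliptic_fourier(v * 2.75)
    assert G.global_shape_distance(d0, d_shift) < 1e-6
    assert G.global_shape_distance(d0, d_scale) < 1e-6


def test_efd_distance_zero_iff_same_and_symmetric():
    da = G.elliptic_fourier(G.extract_contour(_blob_mask(1)))
    db = G.elliptic_fourier(G.extract_contour(_blob_mask(4)))
    assert G.global_shape_distance(da, da) == 0.0
    assert G.global_shape_distance(da, db) == G.global_shape_distance(db, da) > 0


def test_gauge_flip_is_involution():
    d = G.elliptic_fourier(G.extract_contour(_blob_mask(5)))
    flipped = G.gauge_flip(d.harmonics)
    assert not np.allclose(flipped, d.harmonics)
    assert np.allclose(G.gauge_flip(flipped), d.harmonics)


def test_start_point_gauge_quotient():
    """Tracing the same curve from the antipodal start gives distance 0."""
    v = G.resample_arclength(G.extract_contour(_blob_mask(6)), 512)
    rolled = np.roll(v, len(v) // 2, axis=0)
    d1 = G.elliptic_fourier(v)
    d2 = G.elliptic_fourier(rolled)
    assert G.global_shape_distance(d1, d2) < 1e-6


def test_rasterize_extract_round_trip_raw_is_exact():
    """Marching squares at 0.5 + polygon fill are mutually inverse when no
    smoothing is applied on either side."""
    mask = _blob_mask(8)
    v = G.extract_contour(mask, smooth_px=0.0)
    back = G.rasterize(v, *mask.shape)
    v2 = G.extract_contour(back, smooth_px=0.0)
    d = G.global_shape_distance(G.elliptic_fourier(v), G.elliptic_fourier(v2))
    assert d == 0.0


def test_local_feature_distance_properties():
    h1 = np.array([0.5, 0.5, 0.0])
    h2 = np.array([0.0, 0.5, 0.5])
    h3 = np.array([1.0, 0.0, 0.0])
    assert G.local_feature_distance(h1, h1) == 0.0
    assert G.local_feature_distance(h1, h2) == G.local_feature_distance(h2, h1)
    assert G.local_feature_distance(h3, np.array([0.0, 1.0, 0.0])) == pytest.approx(1.0)


def test_log_curvature_bins_shape_and_validation():
    b = G.log_curvature_bins(0.012, 0.35, 10)
    assert len(b) == 22 and np.all(np.diff(b) > 0)
    assert b[0] == -0.35 and b[-1] == 0.35
    with pytest.raises(ValueError):
        G.log_curvature_bins(0.5, 0.1)
    with pytest.raises(ValueError):
        G.log_curvature_bins(0.0, 0.1)


def test_mask_curvature_histogram_spike_excision_removes_corner_mass():
    """A square's curvature mass sits entirely in its 4 corners; spike
    excision must remove (nearly) all of it."""
    sq = np.zeros((120, 120), dtype=np.uint8)
    sq[30:90, 30:90] = 1
    bins = G.log_curvature_bins()
    h_plain = G.mask_curvature_histogram(sq, bins=bins)
    h_excised = G.mask_curvature_histogram(sq, bins=bins, spike_thresh=0.35,
                                           spike_win_px=5.0, allow_empty=True)
    assert h_plain.sum() == pytest.approx(1.0)
    # curved mass = everything outside the central straight band; a square
    # has it only at corners, which excision should mostly remove
    center = (len(bins) - 1) // 2
    curved = np.ones(len(bins) - 1, dtype=bool)
    curved[center] = False
    assert h_plain[curved].sum() > 0.2
    assert h_excised[curved].sum() < 0.5 * h_plain[curved].sum()


def test_mask_curvature_histogram_validates_input():
    with pytest.raises(ValueError):
        G.mask_curvature_histogram(np.zeros((10, 10), dtype=np.uint8))
    with pytest.raises(ValueError):
        G.mask_curvature_histogram(np.zeros((4, 4, 3), dtype=np.uint8))


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_turning_number_property_over_seeds(seed):
    spec = gen_shape_class(seed % 997, "blob")
    mask = sample_mask(spec, seed=seed)
    p = G.curvature_profile(G.extract_contour(mask), profile_smooth_px=0.0)
    assert abs(np.sum(p.kappa * p.ds) - 2 * np.pi) < 1e-9
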