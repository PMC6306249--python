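import numpy as np
import pytest

from shapebias import stimuli as S


def _mask(small_catalog, i=0, j=0):
    label = small_catalog.vocabulary[i]
    return small_catalog.test[label][j]


def test_place_mask_scales_and_centers(disk_mask):
    out = S.place_mask(disk_mask, out_size=(224, 224), fill_fraction=0.8)
    rows = np.any(out, axis=1).nonzero()[0]
    cols = np.any(out, axis=0).nonzero()[0]
    extent = max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
    assert abs(extent - 0.8 * 224) <= 2
    center = ((rows[0] + rows[-1]) / 2, (cols[0] + cols[-1]) / 2)
    assert abs(center[0] - 111.5) <= 1 and abs(center[1] - 111.5) <= 1
    assert set(np.unique(out)) <= {0, 1}


def test_place_mask_empty_error():
    with pytest.raises(ValueError):
        S.place_mask(np.zeros((10, 10), dtype=np.uint8))


def test_render_silhouette_colors(disk_mask):
    stim = S.render_silhouette(disk_mask, colorway=S.RED_ON_WHITE)
    px = stim.pixels
    assert px.shape == (224, 224, 3) and px.dtype == np.uint8
    colors = {tuple(c) for c in np.unique(px.reshape(-1, 3), axis=0)}
    assert colors == {(255, 0, 0), (255, 255, 255)}


def test_render_outline_only_contour_contrast(disk_mask):
    stim = S.render_outline(disk_mask, stroke_px=2)
    px = stim.pixels
    # interior center and exterior corner share the same background color
    assert tuple(px[112, 112]) == tuple(px[2, 2]) == (255, 255, 255)
    assert (px.reshape(-1, 3) == 0).all(axis=1).any()  # some stroke pixels


def test_render_chimera_texture_inside_only(disk_mask):
    tex = np.zeros((224, 224, 3), dtype=np.uint8)
    tex[..., 0] = 200  # uniform dark red texture
    stim = S.render_texture_chimera(disk_mask, tex)
    px = stim.pixels
    assert tuple(px[2, 2]) == (255, 255, 255)        # background untouched
    assert tuple(px[112, 112]) == (200, 0, 0)        # interior textured


def test_colorway_validation():
    with pytest.raises(ValueError):
        S.Colorway(fg=(0, 0, 0), bg=(0, 0, 0))


def test_record_invariants():
    with pytest.raises(ValueError):
        S.StimulusRecord(shape_label="a", manipulation="chimera")  # no texture
    with pytest.raises(ValueError):
        S.StimulusRecord(shape_label="a", manipulation="silhouette",
                         texture_label="b")
    with pytest.raises(ValueError):
        S.StimulusRecord(shape_label="a", manipulation="part_scramble")  # no seed


def test_record_round_trip():
    rec = S.StimulusRecord(shape_label="a", manipulation="chimera",
                           texture_label="b", params={"x": 1}, item_id="a/000")
    assert S.StimulusRecord.from_dict(rec.to_dict()) == rec


def test_part_scramble_preserves_area_exactly(small_catalog):
    m = _mask(small_catalog)
    scr, report = S.part_scramble(m, n_parts=3, seed=4)
    assert scr.sum() == m.sum()
    assert report.area_ratio == pytest.approx(1.0)


def test_part_scramble_deterministic(small_catalog):
    m = _mask(small_catalog, 1)
    a, _ = S.part_scramble(m, n_parts=3, seed=9)
    b, _ = S.part_scramble(m, n_parts=3, seed=9)
    c, _ = S.part_scramble(m, n_parts=3, seed=10)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_part_scramble_changes_global_more_than_local(small_catalog):
    m = _mask(small_catalog, 2)
    _, report = S.part_scramble(m, n_parts=3, seed=2)
    assert report.global_distance > report.local_distance


def test_serrate_changes_local_more_than_global(small_catalog):
    m = _mask(small_catalog, 3)
    ser, report = S.serrate(m)
    assert report.local_distance > report.global_distance
    assert 0.95 <= report.area_ratio <= 1.05
    assert not np.array_equal(ser, m)


def test_serrate_deterministic(small_catalog):
    m = _mask(small_catalog)
    a, _ = S.serrate(m)
    b, _ = S.serrate(m)
    assert np.array_equal(a, b)


def test_save_load_round_trip(tmp_path, disk_mask):
    rec = S.StimulusRecord(shape_label="disk", manipulation="silhouette",
                           item_id="disk/000")
    stim = S.render_silhouette(disk_mask, record=rec)
    S.save_stimulus(stim, tmp_path / "s.png")
    back = S.load_stimulus(tmp_path / "s.png")
    assert np.array_equal(back.pixels, stim.pixels)
    assert back.record == rec


def test_manifest_round_trip_columns(tmp_path):
    recs = [S.StimulusRecord(shape_label="a", manipulation="silhouette",
                             item_id=f"a/{i:03d}") for i in range(3)]
    S.write_manifest(recs, tmp_path / "m.csv")
    import csv
    with open(tmp_path / "m.csv") as fh:
        rows = list(csv.DictReader(fh))
    assert len(rows) == 3
    assert rows[0]["shape_label"] == "a"
    assert rows[0]["manipulation"] == "silhouette"
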