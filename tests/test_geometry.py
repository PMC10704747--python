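"""Cross-section synthesis, mask pipeline, electrode and extrusion tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from cuffsim import geometry as geo


# ---------------------------------------------------------------------------
# Endoneurium segmentation
# ---------------------------------------------------------------------------


class TestSegmentEndoneurium:
    def test_default_synthetic_slice_yields_17_fascicles(self):
        cs = geo.synthesize_cross_section(seed=0)
        masks = geo.segment_endoneurium(cs.to_grayscale(), cs.pixel_pitch)
        assert len(masks) == 17

    def test_uniform_image_raises_no_threshold(self):
        with pytest.raises(geo.NoThresholdError):
            geo.segment_endoneurium(np.full((64, 64), 80, dtype=np.uint8), 0.01)

    def test_drawn_ellipses_recovered_within_two_percent(self):
        """Three bright ellipses above min_area and one sub-threshold speck."""
        img = np.full((300, 300), 40, dtype=np.uint8)
        yy, xx = np.mgrid[:300, :300]
        drawn = []
        for cy, cx, a, b in [(70, 80, 30, 20), (200, 90, 25, 25), (150, 220, 35, 18)]:
            mask = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1
            img[mask] = 220
            drawn.append(mask)
        img[20:22, 270:272] = 220  # speck below min_area
        masks = geo.segment_endoneurium(img, pixel_pitch=0.01, min_area=0.01)
        assert len(masks) == 3
        total = np.zeros_like(masks[0])
        for m in masks:
            total |= m
        for d in drawn:
            overlap = max((m & d).sum() / d.sum() for m in masks)
            assert overlap > 0.98
            matched = max(masks, key=lambda m: (m & d).sum())
            assert abs(matched.sum() - d.sum()) / d.sum() < 0.02

    def test_idempotent_on_rendered_output(self):
        cs = geo.synthesize_cross_section(seed=2, n_fascicles=5, pixel_pitch=0.05)
        masks = geo.segment_endoneurium(cs.to_grayscale(), cs.pixel_pitch)
        rendered = np.where(np.any(masks, axis=0), 220, 30).astype(np.uint8)
        masks2 = geo.segment_endoneurium(rendered, cs.pixel_pitch)
        assert len(masks2) == len(masks)
        union1 = np.any(masks, axis=0)
        union2 = np.any(masks2, axis=0)
        # re-segmentation reproduces the union up to the smoothing boundary
        assert (union1 ^ union2).sum() / union1.sum() < 0.05


# ---------------------------------------------------------------------------
# Perineurium / epineurium masks
# ---------------------------------------------------------------------------


class TestTissueMasks:
    def test_perineurium_annulus_radius_matches_distance_transform(self):
        yy, xx = np.mgrid[:300, :300]
        circle = (yy - 150) ** 2 + (xx - 150) ** 2 <= 100**2
        peri = geo.grow_perineurium([circle], dilation_fraction=0.03)
        # equivalent diameter 200 px -> dilation radius 6 px
        dist = ndimage.distance_transform_edt(~circle)
        outer_r = dist[peri].max()
        assert abs(outer_r - 6.0) <= 1.0
        assert not np.any(peri & circle)

    def test_empty_fascicle_set_gives_empty_perineurium(self):
        assert geo.grow_perineurium([]).size == 0

    def test_bad_dilation_fraction_rejected(self):
        with pytest.raises(geo.GeometryError):
            geo.grow_perineurium([np.ones((5, 5), bool)], dilation_fraction=0.0)

    def test_epineurium_pixel_arithmetic_and_disjointness(self):
        yy, xx = np.mgrid[:200, :200]
        f1 = (yy - 80) ** 2 + (xx - 70) ** 2 <= 20**2
        f2 = (yy - 120) ** 2 + (xx - 140) ** 2 <= 15**2
        peri = geo.grow_perineurium([f1, f2], 0.05)
        outline = (yy - 100) ** 2 + (xx - 100) ** 2 <= 90**2
        epi = geo.fill_epineurium(peri, [f1, f2], outline)
        endo = f1 | f2
        assert epi.sum() == outline.sum() - (endo | peri).sum()
        assert not np.any(epi & peri) and not np.any(epi & endo)
        assert not np.any(peri & endo)

    def test_outline_must_enclose_fascicles(self):
        yy, xx = np.mgrid[:100, :100]
        f1 = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2
        outline = (yy - 70) ** 2 + (xx - 70) ** 2 <= 20**2
        with pytest.raises(geo.GeometryError):
            geo.fill_epineurium(np.zeros((100, 100), bool), [f1], outline)

    def test_label_precedence_in_synthetic_slice(self):
        """Combined mask layering: saline < epi < peri < endo < electrode."""
        cs = geo.synthesize_cross_section(seed=0, pixel_pitch=0.05)
        labels = cs.label_image
        # mutually exclusive by construction: each pixel exactly one code
        assert set(np.unique(labels)) <= {0, 1, 2, 3, 4}
        # electrode wins everywhere the cuff wall is
        emask = geo.electrode_mask(labels.shape, 0.05, geo.build_fine_electrode())
        assert np.all(labels[emask] == geo.LABEL_ELECTRODE)
        # every endoneurium pixel carries a fascicle id
        assert np.all(cs.fascicle_ids[labels == geo.LABEL_ENDONEURIUM] > 0)


# ---------------------------------------------------------------------------
# Electrode layout
# ---------------------------------------------------------------------------


class TestElectrode:
    def test_default_layout_has_56_contacts(self, layout):
        assert layout.n_contacts == 56
        assert layout.n_layers == 7
        counts = np.bincount(layout.layer_index)
        assert np.all(counts == 8)

    def test_minimal_configuration(self):
        lay = geo.build_fine_electrode(n_layers=1, contacts_per_edge=1)
        assert lay.n_contacts == 2

    def test_contact_pitches(self, layout):
        pos = layout.contact_positions
        for k in range(7):
            for e in range(2):
                sel = (layout.layer_index == k) & (layout.edge_index == e)
                xs = np.sort(pos[sel, 0])
                assert np.allclose(np.diff(xs), 2.25)
        for e in range(2):
            for w in range(4):
                sel = (layout.edge_index == e) & (layout.within_edge_index == w)
                zs = np.sort(pos[sel, 2])
                assert np.allclose(np.diff(zs), 2.86)

    def test_mirror_symmetry(self, layout):
        """Contact cloud is symmetric under the cuff's two mirror planes."""
        pos = layout.contact_positions
        as_set = {tuple(np.round(p, 9)) for p in pos}
        for flipped in (pos * [-1, 1, 1], pos * [1, -1, 1], pos * [1, 1, -1]):
            assert {tuple(np.round(p, 9)) for p in flipped} == as_set

    def test_nerve_too_large_rejected(self):
        with pytest.raises(geo.GeometryError, match="too large"):
            geo.build_fine_electrode(nerve_bbox_mm=(10.0, 4.0))


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


class TestSynthesizeCrossSection:
    def test_deterministic_under_seed(self):
        a = geo.synthesize_cross_section(seed=7, pixel_pitch=0.1)
        b = geo.synthesize_cross_section(seed=7, pixel_pitch=0.1)
        assert np.array_equal(a.label_image, b.label_image)
        assert np.array_equal(a.fascicle_ids, b.fascicle_ids)

    def test_segmentation_roundtrip_recovers_17(self):
        cs = geo.synthesize_cross_section(seed=5)
        masks = geo.segment_endoneurium(cs.to_grayscale(), cs.pixel_pitch)
        assert len(masks) == 17

    def test_centroid_separation_floor_across_seeds(self):
        floor = 1.0
        for seed in range(100):
            cs = geo.synthesize_cross_section(seed=seed, pixel_pitch=0.15)
            c = np.array(cs.fascicle_centroids)
            d = np.hypot(c[:, None, 0] - c[None, :, 0], c[:, None, 1] - c[None, :, 1])
            np.fill_diagonal(d, np.inf)
            assert d.min() >= floor

    def test_infeasible_packing_signals(self):
        with pytest.raises(geo.PackingError):
            geo.synthesize_cross_section(
                seed=0, n_fascicles=100, pixel_pitch=0.1
            )


# ---------------------------------------------------------------------------
# Extrusion
# ---------------------------------------------------------------------------


class TestExtrudeVolume:
    def test_slices_inside_cuff_identical(self, tiny_volume):
        z = tiny_volume.z_coords
        inside = np.flatnonzero(np.abs(z) <= tiny_volume.layout.height / 2)
        ref = tiny_volume.label_grid[:, :, inside[0]]
        for iz in inside[1:]:
            assert np.array_equal(tiny_volume.label_grid[:, :, iz], ref)

    def test_electrode_only_within_cuff_span(self, layout):
        cs = geo.synthesize_cross_section(
            seed=3,
            n_fascicles=3,
            pixel_pitch=0.3,
            fascicle_radius_range=(0.35, 0.45),
            min_centroid_separation=2.0,
        )
        vol = geo.extrude_volume(cs, layout, axial_length=30.0, axial_pitch=2.0)
        z = vol.z_coords
        has_cuff = (vol.label_grid == geo.LABEL_ELECTRODE).any(axis=(0, 1))
        assert np.array_equal(has_cuff, np.abs(z) <= layout.height / 2)

    def test_tissue_volume_fractions_match_area_fractions(self, tiny_cross_section, layout):
        vol = geo.extrude_volume(
            tiny_cross_section, layout, axial_length=20.0, axial_pitch=2.0
        )
        # within the cuff span, each slice is the cross-section with the
        # saline cylinder cut out; nerve tissue is untouched by the cut
        mid = vol.label_grid[:, :, vol.shape[2] // 2]
        for code in (geo.LABEL_ENDONEURIUM, geo.LABEL_PERINEURIUM, geo.LABEL_EPINEURIUM):
            assert (mid == code).sum() == (tiny_cross_section.label_image == code).sum()

    def test_short_extent_rejected(self, tiny_cross_section, layout):
        with pytest.raises(geo.GeometryError):
            geo.extrude_volume(tiny_cross_section, layout, axial_length=10.0)

    def test_broken_perineurium_rejected(self, layout):
        cs = geo.synthesize_cross_section(
            seed=3,
            n_fascicles=3,
            pixel_pitch=0.3,
            fascicle_radius_range=(0.35, 0.45),
            min_centroid_separation=2.0,
        )
        bad = geo.CrossSectionModel(
            label_image=cs.label_image.copy(),
            fascicle_ids=cs.fascicle_ids.copy(),
            pixel_pitch=cs.pixel_pitch,
            fascicle_centroids=cs.fascicle_centroids,
        )
        endo = bad.label_image == geo.LABEL_ENDONEURIUM
        ring = ndimage.binary_dilation(
            endo, structure=ndimage.generate_binary_structure(2, 1)
        ) & ~endo
        bad.label_image[tuple(np.argwhere(ring)[0])] = geo.LABEL_EPINEURIUM
        with pytest.raises(geo.ResolutionError):
            geo.extrude_volume(bad, layout, axial_length=20.0, axial_pitch=2.0)
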