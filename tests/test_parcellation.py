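import numpy as np
import pytest

from ccparc import evaluation as ev
from ccparc import parcellation as pc
from ccparc import phantoms, slic
from ccparc.cc_isolation import CCMask


def first_columns(pm):
    """Leftmost column of each parcel 1..5."""
    return [int(np.nonzero((pm.labels == p).any(axis=0))[0].min()) for p in range(1, 6)]


class TestAxis:
    def test_horizontal_rectangle(self, rectangle_mask):
        (ar, ac), (anterior, posterior) = pc.anterior_posterior_axis(rectangle_mask)
        assert abs(ar) < 1e-12 and abs(ac - 1.0) < 1e-12
        assert anterior[1] == 5 and posterior[1] == 64

    def test_vertical_rectangle_rotates_axis(self, rectangle_mask):
        axis, _ = pc.anterior_posterior_axis(rectangle_mask.T)
        assert abs(abs(axis[0]) - 1.0) < 1e-12 and abs(axis[1]) < 1e-12

    def test_flip_anterior_inverts(self, rectangle_mask):
        axis, (ant, post) = pc.anterior_posterior_axis(rectangle_mask, flip_anterior=True)
        assert axis[1] == -1.0
        assert ant[1] == 64 and post[1] == 5

    def test_arch_axis_near_horizontal(self, small_bundle):
        axis, _ = pc.anterior_posterior_axis(small_bundle.cc_mask)
        angle = np.degrees(np.arctan2(abs(axis[0]), abs(axis[1])))
        assert angle < 10

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            pc.anterior_posterior_axis(np.zeros((8, 8), dtype=bool))


class TestGeometric:
    def test_witelson_cut_columns(self, rectangle_mask):
        pm = pc.geometric_parcellate(rectangle_mask, pc.WITELSON)
        assert first_columns(pm) == [5, 25, 35, 45, 53]  # cuts at 20/30/40/48

    def test_hofer_cut_columns(self, rectangle_mask):
        pm = pc.geometric_parcellate(rectangle_mask, pc.HOFER)
        assert first_columns(pm) == [5, 15, 35, 45, 50]  # cuts at 10/30/40/45

    @pytest.mark.parametrize(
        "scheme, fractions",
        [(pc.WITELSON, (1 / 3, 1 / 2, 2 / 3, 4 / 5)), (pc.HOFER, (1 / 6, 1 / 2, 2 / 3, 3 / 4))],
    )
    def test_cuts_equal_floor_of_fraction_times_extent(self, rectangle_mask, scheme, fractions):
        pm = pc.geometric_parcellate(rectangle_mask, scheme)
        cuts = [c - 5 for c in first_columns(pm)[1:]]
        assert cuts == [int(np.floor(f * 60)) for f in fractions]

    def test_boundary_tie_goes_posterior(self):
        # 10x60 rectangle: column offset 20 has t = 20/59 > 1/3, but the exact
        # Witelson cut pixel (ceil(59/3) = 20) belongs to parcel 2, i.e. the
        # posterior side of the 1/3 boundary.
        m = np.zeros((12, 66), dtype=bool)
        m[1:11, 3:63] = True
        pm = pc.geometric_parcellate(m, pc.WITELSON)
        assert pm.labels[5, 3 + 20] == 2 and pm.labels[5, 3 + 19] == 1

    def test_partition_and_order(self, rectangle_mask):
        pm = pc.geometric_parcellate(rectangle_mask, pc.WITELSON)
        assert ((pm.labels > 0) == rectangle_mask).all()
        means = [np.nonzero(pm.labels == p)[1].mean() for p in range(1, 6)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_short_mask_rejected(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2:6, 2:5] = True
        with pytest.raises(ValueError, match="extent"):
            pc.geometric_parcellate(m, pc.WITELSON)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            pc.GeometricScheme("bad", (0.5, 0.4, 0.6, 0.8))


class TestSlicParcellate:
    def test_uniform_rectangle_gives_five_even_bands(self):
        m = np.zeros((24, 84), dtype=bool)
        m[4:20, 4:80] = True
        cm = CCMask.from_mask(m)
        sp = slic.slic_segment(np.full((24, 84), 0.6), slic.SlicParams(n_superpixels=48), roi=cm)
        pm = pc.slic_parcellate(sp, cm)
        assert ((pm.labels > 0) == m).all()
        for p in range(1, 6):
            cols = np.nonzero((pm.labels == p).any(axis=0))[0]
            extent = cols.max() - cols.min() + 1
            assert abs(extent - 76 / 5) <= 1.5 * sp.grid_size

    def test_distinct_intensity_parcels_recovered(self):
        b = phantoms.make_phantom(
            phantoms.PhantomSpec(
                size=(128, 128), seed=3, noise_sigma=0.02,
                parcel_offsets=(0.0, -0.05, 0.05, -0.08, 0.08),
            )
        )
        sp = slic.slic_segment(b.image, slic.SlicParams(n_superpixels=60), roi=b.cc_mask)
        pm = pc.slic_parcellate(sp, b.cc_mask)
        for p in range(1, 6):
            assert ev.dice(ev.confusion(pm, b.parcels_gt, p)) >= 0.7

    def test_too_few_superpixels_rejected(self, rectangle_ccmask):
        m = rectangle_ccmask.mask
        labels = np.zeros(m.shape, dtype=int)
        quarters = np.array_split(np.nonzero(m.any(axis=0))[0], 4)
        centers = []
        for i, cols in enumerate(quarters):
            sel = m & np.isin(np.arange(m.shape[1]), cols)[None, :]
            labels[sel] = i + 1
            rr, cc = np.nonzero(sel)
            centers.append((rr.mean(), cc.mean(), 0.5))
        fake = slic.SuperpixelMap(labels=labels, centers=np.array(centers), grid_size=5.0)
        with pytest.raises(ValueError, match="superpixel"):
            pc.slic_parcellate(fake, rectangle_ccmask)

    def test_order_of_parcel_projections(self, small_bundle):
        sp = slic.slic_segment(
            small_bundle.image, slic.SlicParams(n_superpixels=60), roi=small_bundle.cc_mask
        )
        pm = pc.slic_parcellate(sp, small_bundle.cc_mask)
        axis = np.asarray(pm.axis)
        means = []
        for p in range(1, 6):
            rr, cc = np.nonzero(pm.labels == p)
            means.append((np.column_stack([rr, cc]) @ axis).mean())
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_parcels_partition_mask(self, small_bundle):
        sp = slic.slic_segment(
            small_bundle.image, slic.SlicParams(n_superpixels=60), roi=small_bundle.cc_mask
        )
        pm = pc.slic_parcellate(sp, small_bundle.cc_mask)
        assert ((pm.labels > 0) == small_bundle.cc_mask.mask).all()
        assert set(np.unique(pm.labels[small_bundle.cc_mask.mask])) == {1, 2, 3, 4, 5}
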