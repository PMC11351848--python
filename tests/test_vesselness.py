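"""Hessian analysis and the Frangi vesselness discriminant."""

import math

import numpy as np
import pytest

from coroseg.phantoms import make_blob, make_plate, make_tube
from coroseg.vesselness import (
    VesselnessParams,
    enhance_with_vesselness,
    eigen_ordered,
    hessian_at_scale,
    multiscale_vesselness,
    vesselness_response,
)
from coroseg.volume import Volume


def reference_vesselness(
    l1, l2, l3, S, alpha, beta, c, rb_sqrt=True, zero="or", s_squared=True
):
    """Independent scalar transcription of the discriminant (test oracle)."""
    if zero == "or":
        if l2 >= 0 or l3 >= 0:
            return 0.0
    else:
        if l2 >= 0 and l3 >= 0:
            return 0.0
    if l3 == 0:
        return 0.0
    ra = abs(l2) / abs(l3)
    denom = math.sqrt(abs(l2 * l3)) if rb_sqrt else abs(l2 * l3)
    rb = abs(l1) / denom if denom > 0 else float("inf")
    s_factor = (
        1.0 - math.exp(-(S**2) / (2 * c * c))
        if s_squared
        else 1.0 - math.exp(-(S**2) / c)
    )
    return (
        (1.0 - math.exp(-(ra**2) / (2 * alpha**2)))
        * math.exp(-(rb**2) / (2 * beta**2))
        * s_factor
    )


class TestHessian:
    def test_constant_volume_all_zero(self):
        h = hessian_at_scale(Volume(data=np.ones((20, 20, 20))), 2.0)
        for comp in (h.zz, h.yy, h.xx, h.zy, h.zx, h.yx):
            np.testing.assert_allclose(comp, 0.0, atol=1e-10)

    def test_quadratic_has_known_second_derivative(self):
        # I = x^2: d2/dx2 = 2, scale-normalized to 2*sigma^2; others vanish
        _, _, xx = np.meshgrid(*[np.arange(48.0)] * 3, indexing="ij")
        h = hessian_at_scale(Volume(data=xx**2), 2.0)
        centre = (24, 24, 24)
        assert h.xx[centre] == pytest.approx(2 * 4.0, rel=0.01)
        assert abs(h.zz[centre]) < 0.01 * 8
        assert abs(h.zy[centre]) < 0.01 * 8

    def test_gaussian_blob_centre_is_isotropic(self):
        # symmetric Gaussian: Hessian at the centre is a multiple of I
        z, y, x = np.meshgrid(*[np.arange(40.0)] * 3, indexing="ij")
        s = 4.0
        blob = np.exp(-((z - 20) ** 2 + (y - 20) ** 2 + (x - 20) ** 2) / (2 * s * s))
        h = hessian_at_scale(Volume(data=blob), 3.0)
        c = (20, 20, 20)
        diag = [h.zz[c], h.yy[c], h.xx[c]]
        assert np.allclose(diag, diag[0], rtol=1e-6)
        assert abs(h.zy[c]) < 1e-8
        assert diag[0] < 0  # bright blob: negative curvature

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            hessian_at_scale(Volume(data=np.zeros((4, 4, 4))), -1.0)


class TestEigenOrdered:
    def test_magnitude_ordering_on_diagonal_matrix(self):
        from coroseg.vesselness import HessianField

        shape = (1, 1, 1)
        h = HessianField(
            zz=np.full(shape, 1.0),
            yy=np.full(shape, -2.0),
            xx=np.full(shape, -5.0),
            zy=np.zeros(shape),
            zx=np.zeros(shape),
            yx=np.zeros(shape),
        )
        eigs = eigen_ordered(h)[0, 0, 0]
        np.testing.assert_allclose(eigs, [1.0, -2.0, -5.0])

    def test_trace_identity_on_random_symmetric_fields(self, rng):
        from coroseg.vesselness import HessianField

        shape = (5, 6, 7)
        comps = {k: rng.normal(size=shape) for k in ("zz", "yy", "xx", "zy", "zx", "yx")}
        h = HessianField(**comps)
        eigs = eigen_ordered(h)
        trace = comps["zz"] + comps["yy"] + comps["xx"]
        np.testing.assert_allclose(eigs.sum(axis=-1), trace, atol=1e-8)
        mags = np.abs(eigs)
        assert (mags[..., 0] <= mags[..., 1] + 1e-12).all()
        assert (mags[..., 1] <= mags[..., 2] + 1e-12).all()


class TestResponse:
    def test_matches_independent_transcription_on_random_triples(self, rng):
        params = VesselnessParams()
        for _ in range(100):
            l1, l2, l3 = rng.normal(0, 2, 3)
            eigs = np.array(sorted([l1, l2, l3], key=abs))
            S = abs(rng.normal(0, 3))
            c = abs(rng.normal(0, 2)) + 0.1
            got = float(vesselness_response(eigs, S, params, c=c))
            want = reference_vesselness(*eigs, S, 0.5, 0.5, c)
            assert got == pytest.approx(want, abs=1e-12)

    def test_literal_product_rb_variant_matches_oracle(self, rng):
        params = VesselnessParams(rb_sqrt=False)
        for _ in range(100):
            eigs = np.array(sorted(rng.normal(0, 2, 3), key=abs))
            S, c = abs(rng.normal(0, 3)), 0.5
            got = float(vesselness_response(eigs, S, params, c=c))
            want = reference_vesselness(*eigs, S, 0.5, 0.5, c, rb_sqrt=False)
            assert got == pytest.approx(want, abs=1e-12)

    def test_literal_s_term_variant_matches_oracle(self, rng):
        params = VesselnessParams(s_term="literal")
        for _ in range(100):
            eigs = np.array(sorted(rng.normal(0, 2, 3), key=abs))
            S, c = abs(rng.normal(0, 3)), 0.5
            got = float(vesselness_response(eigs, S, params, c=c))
            want = reference_vesselness(*eigs, S, 0.5, 0.5, c, s_squared=False)
            assert got == pytest.approx(want, abs=1e-12)

    def test_bright_vessel_suppression(self):
        # positive lambda2/lambda3: not a bright tube, response is zero
        v = vesselness_response(np.array([0.1, 2.0, 3.0]), 10.0, c=1.0)
        assert v == 0.0

    def test_ideal_tube_limit(self):
        v = float(
            vesselness_response(np.array([0.0, -5.0, -5.0]), 1e6, c=1.0)
        )
        assert v == pytest.approx(1.0 - math.exp(-2.0), abs=1e-3)

    def test_ideal_blob_limit(self):
        v = float(
            vesselness_response(np.array([-5.0, -5.0, -5.0]), 1e6, c=1.0)
        )
        assert v == pytest.approx((1.0 - math.exp(-2.0)) * math.exp(-2.0), abs=1e-3)

    def test_bounded_to_unit_interval(self, rng):
        eigs = np.sort(rng.normal(0, 5, (200, 3)), axis=-1)
        order = np.argsort(np.abs(eigs), axis=-1)
        eigs = np.take_along_axis(eigs, order, axis=-1)
        v = vesselness_response(eigs, np.abs(rng.normal(0, 5, 200)), c=1.0)
        assert (v >= 0).all() and (v <= 1).all()


class TestMultiscale:
    def test_constant_volume_zero_response(self):
        out = multiscale_vesselness(Volume(data=np.full((24, 24, 24), 0.5)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_single_scale_equals_multiscale_of_one(self, noisy_cylinder):
        noisy, _, _ = noisy_cylinder
        p1 = VesselnessParams(scales=(3.0,))
        out = multiscale_vesselness(noisy, p1)
        assert out.data.max() > 0
        out2 = multiscale_vesselness(noisy, VesselnessParams(scales=(3.0,)))
        np.testing.assert_array_equal(out.data, out2.data)

    def test_scale_selection_matches_radius(self):
        vol, _ = make_tube(48, axis=0, radius=3.0, contrast=1.0)
        _, argmax = multiscale_vesselness(
            vol, VesselnessParams(scales=(2, 3, 4, 5, 6, 7, 8)), return_scales=True
        )
        centreline = argmax[10:-10, 24, 24]
        assert set(np.unique(centreline)) <= {2.0, 3.0, 4.0}

    def test_rotational_robustness(self):
        p = VesselnessParams(scales=(2, 3, 4))
        vz, _ = make_tube(40, axis=0, radius=3.0, contrast=1.0)
        vx, _ = make_tube(40, axis=2, radius=3.0, contrast=1.0)
        rz = multiscale_vesselness(vz, p).data[8:-8, 20, 20].mean()
        rx = multiscale_vesselness(vx, p).data[20, 20, 8:-8].mean()
        assert abs(rz - rx) / max(rz, rx) < 0.10

    def test_tube_beats_blob_and_plate(self):
        p = VesselnessParams(scales=(2, 3, 4, 5))
        tube, _ = make_tube(40, axis=0, radius=3.0, contrast=1.0)
        blob, _ = make_blob(40, radius=3.0, contrast=1.0)
        plate, _ = make_plate(40, axis=0, thickness=6, contrast=1.0)
        r_tube = multiscale_vesselness(tube, p).data[8:-8, 20, 20].mean()
        r_blob = multiscale_vesselness(blob, p).data[20, 20, 20]
        r_plate = multiscale_vesselness(plate, p).data[20, 8:-8, 8:-8].mean()
        assert r_tube > 2 * r_blob
        assert r_tube > 2 * r_plate

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            VesselnessParams(scales=())


class TestEnhance:
    def test_zero_weight_is_identity(self, noisy_cylinder):
        noisy, _, _ = noisy_cylinder
        vol = Volume(data=np.clip(noisy.data, 0, 1))
        v = multiscale_vesselness(vol, VesselnessParams(scales=(3.0,)))
        out = enhance_with_vesselness(vol, v, weight=0.0)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_zero_vesselness_is_identity(self, random_volume):
        v = random_volume.with_data(np.zeros(random_volume.shape))
        vol = random_volume.with_data(np.clip(random_volume.data, 0, 1))
        out = enhance_with_vesselness(vol, v)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_brightens_tube_leaves_background(self):
        vol, mask = make_tube(32, axis=0, radius=3.0, contrast=0.6)
        v = multiscale_vesselness(vol, VesselnessParams(scales=(2, 3, 4)))
        out = enhance_with_vesselness(vol, v, weight=1.0)
        inside = mask.data.astype(bool)
        assert out.data[inside].mean() > vol.data[inside].mean()
        untouched = (~inside) & (v.data == 0)
        np.testing.assert_allclose(out.data[untouched], vol.data[untouched], atol=1e-6)

    def test_shape_mismatch_rejected(self, random_volume):
        v = Volume(data=np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="shape"):
            enhance_with_vesselness(random_volume, v)
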