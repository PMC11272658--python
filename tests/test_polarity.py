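"""Tests of the EC polarity image pipeline: segmentation, object
identification, pairing, angle classification and polarity metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm
from skimage import draw

from hemoshear.errors import DomainError
from hemoshear.polarity import (
    CellOrientation,
    EndotheliumImage,
    LabeledOrganelle,
    analyze_image,
    angle_to_flow,
    classify_orientation,
    despeckle,
    estimate_background,
    gaussian_background_threshold,
    identify_objects,
    orientation_summary,
    pair_nucleus_to_golgi,
    polarity_metrics,
)


def brute_force_median3x3(mask: np.ndarray) -> np.ndarray:
    """Oracle: 3x3 median (majority of 9) with zero padding."""
    padded = np.pad(mask.astype(int), 1)
    out = np.zeros_like(mask, dtype=bool)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            out[i, j] = padded[i : i + 3, j : j + 3].sum() >= 5
    return out


def make_organelle(oid, x, y, major=10.0, minor=5.0, channel="nucleus", area=40.0):
    return LabeledOrganelle(
        id=oid, channel=channel, centroid_um=(x, y),
        major_axis_um=major, minor_axis_um=minor, area_um2=area,
    )


class TestBackgroundThreshold:
    def test_pure_noise_tail_fraction(self, rng):
        img = rng.normal(40.0, 6.0, (512, 512))
        frac = gaussian_background_threshold(img, k=3.89).mean()
        # expected tail 5.0e-5 of 262144 pixels -> ~13 +- 3.6 counts
        assert frac < 1.5e-4
        assert 1.0 - frac >= 0.9999

    def test_estimator_ignores_sparse_bright_foreground(self, rng):
        img = rng.normal(20.0, 5.0, (512, 512))
        img[:40, :40] = 220.0  # ~0.6% bright foreground
        mu, sd = estimate_background(img)
        assert mu == pytest.approx(20.0, abs=0.15)
        assert sd == pytest.approx(5.0, abs=0.15)

    def test_quantized_noise_retention(self, rng):
        img = np.clip(np.rint(rng.normal(20, 5, (1024, 1024))), 0, 255).astype(np.uint8)
        mask = gaussian_background_threshold(img)
        assert 1.0 - mask.mean() >= 0.9999

    def test_all_zero_image(self):
        assert gaussian_background_threshold(np.zeros((32, 32))).sum() == 0

    def test_bright_ellipses_fully_recovered(self, rng):
        img = rng.normal(20.0, 5.0, (256, 256))
        truth = np.zeros((256, 256), dtype=bool)
        for cy, cx in [(64, 64), (180, 120)]:
            rr, cc = draw.ellipse(cy, cx, 20, 10, shape=img.shape)
            truth[rr, cc] = True
        img[truth] = 220.0
        mask = gaussian_background_threshold(img)
        assert (mask & truth).sum() >= 0.99 * truth.sum()

    def test_invalid_k(self):
        with pytest.raises(DomainError):
            gaussian_background_threshold(np.zeros((4, 4)), k=0.0)

    def test_analytic_retention_at_default_k(self):
        assert round(100 * norm.cdf(3.89), 3) == 99.995


class TestDespeckle:
    def test_isolated_voxel_removed(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert despeckle(mask).sum() == 0

    def test_solid_block_interior_preserved(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        out = despeckle(mask)
        assert out[3:11, 3:11].all()

    @pytest.mark.parametrize("offset", [0, 1])
    def test_checkerboard_matches_oracle(self, offset):
        i, j = np.indices((16, 16))
        mask = (i + j + offset) % 2 == 0
        assert np.array_equal(despeckle(mask), brute_force_median3x3(mask))

    def test_random_masks_match_oracle(self, rng):
        for density in (0.1, 0.5, 0.9):
            mask = rng.random((32, 32)) < density
            assert np.array_equal(despeckle(mask), brute_force_median3x3(mask))


class TestIdentifyObjects:
    def test_single_ellipse_geometry(self):
        px = 0.2  # um
        mask = np.zeros((256, 256), dtype=bool)
        # half-axes 25 and 12.7 px -> area ~ pi*25*12.7*0.04 = 39.9 um^2
        rr, cc = draw.ellipse(128, 100, 25, 12.7, shape=mask.shape, rotation=0.4)
        mask[rr, cc] = True
        objs = identify_objects(mask, px, "nucleus")
        assert len(objs) == 1
        obj = objs[0]
        assert obj.centroid_um[0] == pytest.approx(100 * px, abs=px)
        assert obj.centroid_um[1] == pytest.approx(128 * px, abs=px)
        assert obj.major_axis_um == pytest.approx(2 * 25 * px, rel=0.1)
        assert obj.minor_axis_um == pytest.approx(2 * 12.7 * px, rel=0.1)
        assert obj.area_um2 == pytest.approx(math.pi * 25 * 12.7 * px**2, rel=0.05)

    def test_size_segmentation_thresholds(self):
        px = 0.5
        mask = np.zeros((64, 64), dtype=bool)
        rr, cc = draw.disk((32, 32), 3.2, shape=mask.shape)  # ~8 um^2 at 0.25 um^2/px
        mask[rr, cc] = True
        assert identify_objects(mask, px, "nucleus") == []  # below 10 um^2
        golgi = identify_objects(mask, px, "golgi")  # above 2 um^2
        assert len(golgi) == 1

    def test_touching_ellipses_form_one_object(self):
        mask = np.zeros((128, 128), dtype=bool)
        for cx in (50, 70):
            rr, cc = draw.ellipse(64, cx, 15, 12, shape=mask.shape)
            mask[rr, cc] = True
        assert len(identify_objects(mask, 0.5, "nucleus")) == 1

    def test_empty_mask(self):
        assert identify_objects(np.zeros((16, 16), dtype=bool), 0.5, "golgi") == []

    def test_unknown_channel(self):
        with pytest.raises(DomainError):
            identify_objects(np.zeros((4, 4), dtype=bool), 0.5, "mitochondria")


class TestPairing:
    def test_three_four_five(self):
        nuclei = [make_organelle(1, 0.0, 0.0)]
        golgis = [make_organelle(1, 3.0, 4.0, channel="golgi")]
        (cell,) = pair_nucleus_to_golgi(nuclei, golgis)
        assert cell.ng_vector_um == pytest.approx((3.0, 4.0))
        assert cell.ng_length_um == pytest.approx(5.0)

    def test_tie_break_lowest_golgi_id(self):
        nuclei = [make_organelle(1, 0.0, 0.0)]
        golgis = [
            make_organelle(7, 2.0, 0.0, channel="golgi"),
            make_organelle(3, -2.0, 0.0, channel="golgi"),
        ]
        (cell,) = pair_nucleus_to_golgi(nuclei, golgis)
        assert cell.golgi_id == 3

    def test_nearest_selection_and_reuse(self):
        nuclei = [make_organelle(1, 0.0, 0.0), make_organelle(2, 1.0, 0.0)]
        golgis = [
            make_organelle(1, 0.4, 0.0, channel="golgi"),
            make_organelle(2, 50.0, 0.0, channel="golgi"),
        ]
        cells = pair_nucleus_to_golgi(nuclei, golgis)
        assert [c.golgi_id for c in cells] == [1, 1]

    def test_empty_golgi_list(self):
        assert pair_nucleus_to_golgi([make_organelle(1, 0, 0)], []) == []

    def test_coincident_centroids_flagged(self):
        nuclei = [make_organelle(1, 1.0, 1.0)]
        golgis = [make_organelle(1, 1.0, 1.0, channel="golgi")]
        (cell,) = pair_nucleus_to_golgi(nuclei, golgis)
        assert cell.orientation_class is None
        assert math.isnan(cell.angle_deg)

    def test_elongation_carried_from_nucleus(self):
        nuclei = [make_organelle(1, 0, 0, major=12.0, minor=6.0)]
        golgis = [make_organelle(1, 5, 0, channel="golgi")]
        (cell,) = pair_nucleus_to_golgi(nuclei, golgis)
        assert cell.nucleus_elongation == pytest.approx(2.0)


class TestAngles:
    def test_cardinal_angles(self):
        assert angle_to_flow((1, 0), (1, 0)) == pytest.approx(0.0)
        assert angle_to_flow((-1, 0), (1, 0)) == pytest.approx(180.0)
        assert angle_to_flow((1, math.sqrt(3)), (1, 0)) == pytest.approx(60.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(DomainError):
            angle_to_flow((0, 0), (1, 0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        vx=st.floats(-5, 5), vy=st.floats(-5, 5),
        phi=st.floats(0, 2 * math.pi),
    )
    def test_rotation_invariance(self, vx, vy, phi):
        if math.hypot(vx, vy) < 1e-3:
            return
        c, s = math.cos(phi), math.sin(phi)
        rot = lambda x, y: (c * x - s * y, s * x + c * y)
        flow = (1.0, 0.0)
        assert angle_to_flow(rot(vx, vy), rot(*flow)) == pytest.approx(
            angle_to_flow((vx, vy), flow), abs=1e-6
        )


class TestClassification:
    @pytest.mark.parametrize(
        "angle,expected",
        [
            (0.0, "dromic"),
            (59.999, "dromic"),
            (60.0, "lateral"),
            (119.999, "lateral"),
            (120.0, "antidromic"),
            (150.0, "antidromic"),
            (180.0, "antidromic"),
        ],
    )
    def test_boundaries(self, angle, expected):
        assert classify_orientation(angle) == expected

    @pytest.mark.parametrize("angle", [-1.0, 180.001])
    def test_out_of_range(self, angle):
        with pytest.raises(DomainError):
            classify_orientation(angle)


def orientation_from_angle(angle, oid=1, length=5.0, elongation=2.0):
    return CellOrientation(
        nucleus_id=oid, golgi_id=oid,
        ng_vector_um=(length * math.cos(math.radians(angle)),
                      length * math.sin(math.radians(angle))),
        ng_length_um=length, angle_deg=angle,
        orientation_class=classify_orientation(angle),
        nucleus_elongation=elongation,
    )


class TestSummaries:
    def test_uniform_angles_near_equipartition(self, rng):
        angles = rng.uniform(0, 180, 3000)
        cells = [orientation_from_angle(a, i) for i, a in enumerate(angles)]
        summary = orientation_summary(cells)
        assert summary["n_cells"] == 3000
        for pct in summary["percentages"].values():
            assert pct == pytest.approx(100 / 3, abs=3.0)
        assert sum(summary["percentages"].values()) == pytest.approx(100.0)
        assert sum(summary["counts"].values()) == 3000

    def test_all_antidromic(self):
        cells = [orientation_from_angle(150.0, i) for i in range(5)]
        assert orientation_summary(cells)["percentages"]["antidromic"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            orientation_summary([])

    def test_polarity_metrics_known_values(self):
        cells = [
            orientation_from_angle(10.0, 1, length=4.0, elongation=1.0),
            orientation_from_angle(100.0, 2, length=6.0, elongation=1.0),
        ]
        metrics = polarity_metrics(cells)
        assert metrics["ng_length_um"]["mean"] == pytest.approx(5.0)
        assert metrics["nucleus_elongation"]["mean"] == pytest.approx(1.0)
        assert metrics["ng_length_um"]["sem"] == pytest.approx(1.0)

    def test_polarity_metrics_empty(self):
        with pytest.raises(DomainError):
            polarity_metrics([])


class TestEndToEnd:
    def test_ground_truth_recovery(self, synthetic_field, fast_image_spec):
        image, truth = synthetic_field
        result = analyze_image(image)
        n = fast_image_spec.n_cells
        assert len(result.nuclei) == n
        assert len(result.orientations) == n
        summary = result.summary()
        pct = summary["orientation"]["percentages"]
        truth_counts = truth["orientation_class"].value_counts()
        for cls in ("dromic", "lateral", "antidromic"):
            assert pct[cls] == pytest.approx(100 * truth_counts[cls] / n, abs=4.5)
        assert summary["polarity"]["ng_length_um"]["mean"] == pytest.approx(
            truth["ng_length_um"].mean(), rel=0.10
        )
        assert summary["polarity"]["nucleus_elongation"]["mean"] == pytest.approx(
            truth["nucleus_elongation"].mean(), rel=0.10
        )

    def test_rotated_field_same_classes(self, synthetic_field):
        image, _ = synthetic_field
        base = analyze_image(image).summary()["orientation"]["counts"]
        fx, fy = image.flow_direction
        rotated = EndotheliumImage(
            nucleus_channel=np.rot90(image.nucleus_channel).copy(),
            golgi_channel=np.rot90(image.golgi_channel).copy(),
            pixel_size_um=image.pixel_size_um,
            # rot90 maps (row, col) -> (n-1-col, row): (x, y) -> (y, -x)
            flow_direction=(fy, -fx),
        )
        counts = analyze_image(rotated).summary()["orientation"]["counts"]
        assert counts == base

    def test_noise_only_image_yields_no_cells(self, rng):
        noise = np.clip(np.rint(rng.normal(20, 5, (512, 512))), 0, 255).astype(np.uint8)
        image = EndotheliumImage(
            nucleus_channel=noise, golgi_channel=noise.copy(), pixel_size_um=0.234
        )
        result = analyze_image(image)
        assert result.nuclei == [] and result.orientations == []
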