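import math

import numpy as np
import pytest

from kinarch.classify import (
    AngleThresholds,
    ResolutionModel,
    apply_resolution,
    classify_attachment_mode,
    classify_configuration,
    classify_fiber_topology,
    detect_cohesion_state,
    identify_univalents,
    is_at_pole,
    is_split,
    predict_segregation_outcome,
    score_rotation,
    score_twist,
    univalent_biorientation,
)
from kinarch.core import (
    Bivalent,
    Homolog,
    KFiber,
    KinetochoreSpot,
    Oocyte,
    Point3,
    SisterPair,
    Spindle,
    Univalent,
    ValidationError,
)

SPINDLE = Spindle(pole_positions=(Point3(-6, 0, 0), Point3(6, 0, 0)))


def spot(sid, x, y, z, biv="b1", homolog=1, merged=False, radius=0.25):
    return KinetochoreSpot(
        spot_id=sid, oocyte_id="oo1", bivalent_id=biv, homolog_id=homolog,
        position=Point3(x, y, z), radius=radius, merged=merged,
    )


def pair_at(centroid, axis, d, radius=0.25, prefix="p"):
    c = np.asarray(centroid, float)
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    s1 = spot(f"{prefix}1", *(c - 0.5 * d * u), radius=radius)
    s2 = spot(f"{prefix}2", *(c + 0.5 * d * u), radius=radius)
    return SisterPair(spots=(s1, s2))


def merged_pair(centroid, prefix="m"):
    s = spot(f"{prefix}1", *centroid, merged=True)
    return SisterPair(spots=(s,))


def make_bivalent(center, biv_dir, pair_axes, pair_sep=3.0, pair_d=(1.0, 1.0),
                  extents=(1.1, 1.1), chrom_sep=None, biv_id="b1"):
    c = np.asarray(center, float)
    b = np.asarray(biv_dir, float)
    b = b / np.linalg.norm(b)
    if chrom_sep is None:
        chrom_sep = 0.9 * sum(extents)
    homologs = []
    for k, sign in enumerate((-1, 1)):
        pc = c + sign * 0.5 * pair_sep * b
        cc = c + sign * 0.5 * chrom_sep * b
        if pair_axes[k] is None:
            p = merged_pair(pc, prefix=f"{biv_id}m{k}")
        else:
            p = pair_at(pc, pair_axes[k], pair_d[k], prefix=f"{biv_id}h{k}")
        homologs.append(
            Homolog(sister_pair=p, chromatin_centroid=Point3(*cc),
                    chromatin_extent=extents[k])
        )
    return Bivalent(bivalent_id=biv_id, homologs=tuple(homologs))


class TestApplyResolution:
    def test_lateral_merge(self):
        model = ResolutionModel(merge_distance_lateral=0.25)
        spots = [spot("s1", 0, 0, 0), spot("s2", 0.1, 0, 0)]
        out, id_map = apply_resolution(spots, model)
        assert len(out) == 1 and out[0].merged
        assert id_map["s1"] == id_map["s2"] == out[0].spot_id

    def test_far_spots_pass_through(self):
        out, id_map = apply_resolution(
            [spot("s1", 0, 0, 0), spot("s2", 1.0, 0, 0)], ResolutionModel()
        )
        assert len(out) == 2 and not any(s.merged for s in out)
        assert id_map == {"s1": "s1", "s2": "s2"}

    def test_axial_merge_direction_weighted(self):
        # purely axial 0.5 µm separation: (0.5/0.65)^2 = 0.59 < 1 -> merged,
        # while laterally 0.5 µm would not merge
        model = ResolutionModel(merge_distance_lateral=0.30, merge_distance_axial=0.65)
        out, _ = apply_resolution(
            [spot("s1", 0, 0, 0), spot("s2", 0, 0, 0.5)], model
        )
        assert len(out) == 1
        out, _ = apply_resolution(
            [spot("s1", 0, 0, 0), spot("s2", 0.5, 0, 0)], model
        )
        assert len(out) == 2

    def test_merged_position_is_midpoint_for_equal_radii(self):
        out, _ = apply_resolution(
            [spot("s1", 0, 0, 0), spot("s2", 0.2, 0, 0)], ResolutionModel()
        )
        assert out[0].position.x == pytest.approx(0.1)

    def test_different_homologs_never_merge(self):
        out, _ = apply_resolution(
            [spot("s1", 0, 0, 0, homolog=1), spot("s2", 0.05, 0, 0, homolog=2)],
            ResolutionModel(),
        )
        assert len(out) == 2


class TestClassifyConfiguration:
    def test_merged_is_indistinguishable_with_zero_distance(self, resolution):
        p = merged_pair((0, 0, 0))
        assert classify_configuration(p, resolution) == "indistinguishable"
        assert p.distance == 0.0

    def test_separated_beyond_touching(self, resolution):
        p = pair_at((0, 0, 0), (1, 0, 0), 0.6, radius=0.25)
        assert classify_configuration(p, resolution) == "separated"

    def test_distinct_band(self, resolution):
        # r1+r2 = 0.5, overlap_factor 0.6: 0.30 <= d <= 0.50 -> distinct
        p = pair_at((0, 0, 0), (1, 0, 0), 0.35, radius=0.25)
        assert classify_configuration(p, resolution) == "distinct"

    def test_overlapping_band(self, resolution):
        p = pair_at((0, 0, 0), (1, 0, 0), 0.25, radius=0.25)
        assert classify_configuration(p, resolution) == "overlapping"

    def test_monotone_in_distance(self, resolution):
        order = ["overlapping", "distinct", "separated"]
        last = 0
        for d in np.linspace(0.05, 2.0, 80):
            cat = classify_configuration(
                pair_at((0, 0, 0), (1, 0, 0), d, radius=0.25), resolution
            )
            idx = order.index(cat)
            assert idx >= last
            last = idx


class TestIsSplit:
    @pytest.mark.parametrize(
        "cat,expected",
        [
            ("indistinguishable", False),
            ("overlapping", False),
            ("distinct", True),
            ("separated", True),
        ],
    )
    def test_definition(self, cat, expected):
        assert is_split(cat) is expected

    def test_unknown_rejected(self):
        with pytest.raises(ValidationError):
            is_split("weird")


def fiber(fid, kin, pole, endpoint, geometry="end_on", trunk=None):
    return KFiber(fiber_id=fid, kinetochore_id=kin, pole_index=pole,
                  pole_endpoint=Point3(*endpoint), contact_geometry=geometry,
                  trunk_group=trunk)


class TestFiberTopology:
    def _pair(self):
        return pair_at((0, 0, 0), (0, 1, 0), 1.0, prefix="p")

    def test_no_fibers(self):
        assert classify_fiber_topology(self._pair(), []) == (0, "none")

    def test_single(self):
        p = self._pair()
        f = fiber("f1", "p1", 0, (-6, 0, 0))
        assert classify_fiber_topology(p, [f]) == (1, "single")

    def test_shared_trunk_is_type_c(self):
        p = self._pair()
        fs = [
            fiber("f1", "p1", 0, (-6, 0.1, 0), trunk="t1"),
            fiber("f2", "p2", 0, (-6, 0.1, 0), trunk="t1"),
        ]
        assert classify_fiber_topology(p, fs) == (2, "C")

    def test_parallel_adjacent_is_type_a(self):
        p = self._pair()
        fs = [
            fiber("f1", "p1", 0, (-6, 0.2, 0)),
            fiber("f2", "p2", 0, (-6, -0.2, 0)),
        ]
        assert classify_fiber_topology(p, fs) == (2, "A")

    def test_distant_endpoints_is_type_b(self):
        # endpoints 5 µm apart at the same pole
        p = self._pair()
        fs = [
            fiber("f1", "p1", 0, (-6, 2.5, 0)),
            fiber("f2", "p2", 0, (-6, -2.5, 0)),
        ]
        assert classify_fiber_topology(p, fs) == (2, "B")

    def test_opposite_poles_is_type_b(self):
        p = self._pair()
        fs = [fiber("f1", "p1", 0, (-6, 0, 0)), fiber("f2", "p2", 1, (6, 0, 0))]
        assert classify_fiber_topology(p, fs) == (2, "B")


class TestAttachmentMode:
    def _pair(self):
        return pair_at((0, 0, 0), (0, 1, 0), 1.0, prefix="p")

    def test_amphitelic(self):
        p = self._pair()
        fs = [fiber("f1", "p1", 0, (-6, 0.2, 0)), fiber("f2", "p2", 0, (-6, -0.2, 0))]
        assert classify_attachment_mode(p, fs, SPINDLE).mode == "amphitelic"

    def test_merotelic_requires_opposite_end_on(self):
        p = self._pair()
        fs = [fiber("f1", "p1", 0, (-6, 0, 0)), fiber("f2", "p2", 1, (6, 0, 0))]
        assert classify_attachment_mode(p, fs, SPINDLE).mode == "merotelic"

    def test_lateral_merotelic_folds_into_lateral(self):
        p = self._pair()
        fs = [
            fiber("f1", "p1", 0, (-6, 0, 0)),
            fiber("f2", "p2", 1, (6, 0, 0), geometry="lateral"),
        ]
        assert classify_attachment_mode(p, fs, SPINDLE).mode == "lateral"

    def test_unattached(self):
        assert classify_attachment_mode(self._pair(), [], SPINDLE).mode == "unattached"

    def test_unknown_kinetochore_rejected(self):
        p = self._pair()
        f = fiber("f1", "nope", 0, (-6, 0, 0))
        with pytest.raises(ValidationError):
            classify_attachment_mode(p, [f], SPINDLE)


class TestRotation:
    def test_in_axis(self, thresholds):
        biv = make_bivalent((0, 0, 0), (1, 0, 0), [(0, 1, 0), (0, 1, 0)])
        call = score_rotation(biv, SPINDLE, thresholds)
        assert call.label == "in_axis"
        assert call.bivalent_axis_angle == pytest.approx(0.0, abs=1e-9)

    def test_fully_inverted(self, thresholds):
        # bivalent rotated 90 degrees: axis perpendicular, both pairs facing poles
        biv = make_bivalent((0, 0, 0), (0, 1, 0), [(1, 0, 0), (1, 0, 0)])
        assert score_rotation(biv, SPINDLE, thresholds).label == "fully_inverted"

    def test_half_inverted(self, thresholds):
        biv = make_bivalent((0, 0, 0), (1, 0, 0), [(1, 0, 0), (0, 1, 0)],
                            pair_sep=3.6)
        assert score_rotation(biv, SPINDLE, thresholds).label == "half_inverted"

    def test_merged_pair_low_confidence(self, thresholds):
        biv = make_bivalent((0, 0, 0), (1, 0, 0), [None, (0, 1, 0)])
        call = score_rotation(biv, SPINDLE, thresholds)
        assert call.label == "in_axis"
        assert call.low_confidence
        assert call.pair_axis_angles[0] is None

    def test_at_pole_rejected(self, thresholds):
        biv = make_bivalent((0, 0, 0), (1, 0, 0), [(0, 1, 0), (0, 1, 0)])
        biv.at_pole = True
        with pytest.raises(ValidationError):
            score_rotation(biv, SPINDLE, thresholds)

    def test_rigid_motion_invariance(self, thresholds, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(10):
            biv = make_bivalent((0.5, -1, 0.3), (1, 0, 0), [(0, 1, 0), (0, 0.2, 1)])
            base = score_rotation(biv, SPINDLE, thresholds)
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(size=3)

            def move(p):
                return Point3(*(R @ p.as_array() + t))

            homs = []
            for h in biv.homologs:
                sp = tuple(
                    KinetochoreSpot(
                        spot_id=s.spot_id, oocyte_id=s.oocyte_id,
                        bivalent_id=s.bivalent_id, homolog_id=s.homolog_id,
                        position=move(s.position), radius=s.radius, merged=s.merged,
                    )
                    for s in h.sister_pair.spots
                )
                homs.append(
                    Homolog(sister_pair=SisterPair(spots=sp),
                            chromatin_centroid=move(h.chromatin_centroid),
                            chromatin_extent=h.chromatin_extent)
                )
            biv2 = Bivalent(bivalent_id="b1", homologs=tuple(homs))
            sp2 = Spindle(pole_positions=tuple(move(p) for p in SPINDLE.pole_positions))
            moved = score_rotation(biv2, sp2, thresholds)
            assert moved.label == base.label
            assert moved.bivalent_axis_angle == pytest.approx(
                base.bivalent_axis_angle, abs=1e-6
            )

    def test_spindle_axis_sign_flip_invariance(self, thresholds):
        biv = make_bivalent((0, 0, 0), (1, 0, 0), [(0, 1, 0), (0, 1, 0)])
        flipped = Spindle(pole_positions=(SPINDLE.pole_positions[1],
                                          SPINDLE.pole_positions[0]))
        assert (
            score_rotation(biv, SPINDLE, thresholds).label
            == score_rotation(biv, flipped, thresholds).label
        )


class TestTwist:
    def _with_configs(self, biv, cats=("separated", "separated")):
        for h, c in zip(biv.homologs, cats):
            h.sister_pair.configuration = c
        return biv

    def test_parallel_pairs_undistorted(self, thresholds):
        biv = self._with_configs(
            make_bivalent((0, 0, 0), (1, 0, 0), [(0, 1, 0), (0, 1, 0)])
        )
        call = score_twist(biv, thresholds)
        assert call.label == "undistorted" and not call.ambiguous

    def test_perpendicular_pairs_twisted(self, thresholds):
        biv = self._with_configs(
            make_bivalent((0, 0, 0), (1, 0, 0), [(0, 1, 0), (0, 0, 1)])
        )
        call = score_twist(biv, thresholds)
        assert call.label == "twisted"
        assert call.pair_axis_angle == pytest.approx(90.0)

    def test_seventy_degree_rotation_twisted(self, thresholds):
        a = math.radians(70)
        biv = self._with_configs(
            make_bivalent((0, 0, 0), (1, 0, 0),
                          [(0, 1, 0), (0, math.cos(a), math.sin(a))])
        )
        assert score_twist(biv, thresholds).label == "twisted"

    def test_unsplit_pair_not_scorable(self, thresholds):
        biv = self._with_configs(
            make_bivalent((0, 0, 0), (1, 0, 0), [(0, 1, 0), (0, 1, 0)]),
            cats=("indistinguishable", "separated"),
        )
        assert score_twist(biv, thresholds).label == "not_scorable"

    def test_intermediate_angle_ambiguous_undistorted(self, thresholds):
        a = math.radians(40)  # between parallel_max 30 and twist_min 50
        biv = self._with_configs(
            make_bivalent((0, 0, 0), (1, 0, 0),
                          [(0, 1, 0), (0, math.cos(a), math.sin(a))])
        )
        call = score_twist(biv, thresholds)
        assert call.label == "undistorted" and call.ambiguous


class TestCohesion:
    def test_touching_is_intact(self):
        biv = make_bivalent((0, 0, 0), (1, 0, 0), [(0, 1, 0), (0, 1, 0)],
                            extents=(1.2, 1.0), chrom_sep=2.0)
        assert detect_cohesion_state(biv) == ("intact", 0.0)

    def test_large_gap(self):
        biv = make_bivalent((0, 0, 0), (1, 0, 0), [(0, 1, 0), (0, 1, 0)],
                            extents=(1.0, 1.0), chrom_sep=5.2, pair_sep=6.4)
        state, gap = detect_cohesion_state(biv)
        assert state == "weak_gap"
        assert gap == pytest.approx(3.2)

    def test_small_gap(self):
        biv = make_bivalent((0, 0, 0), (1, 0, 0), [(0, 1, 0), (0, 1, 0)],
                            extents=(1.0, 1.0), chrom_sep=2.3, pair_sep=3.5)
        state, gap = detect_cohesion_state(biv)
        assert state == "weak_gap"
        assert gap == pytest.approx(0.3)


def _oocyte_with(n_biv, n_uni):
    oo = Oocyte(oocyte_id="oo1", donor_age=38.0, spindle=SPINDLE)
    for k in range(n_biv):
        oo.bivalents.append(
            make_bivalent((0, 1.6 * (k + 1), 0), (1, 0, 0),
                          [(0, 1, 0), (0, 1, 0)], biv_id=f"b{k:02d}")
        )
    for k in range(n_uni):
        origin = f"b{90 + k // 2:02d}"
        pair = pair_at((2.0 + 2.5 * (k % 2), -2, 0), (1, 0, 0), 1.0,
                       prefix=f"u{k}")
        hom = Homolog(sister_pair=pair, chromatin_centroid=Point3(2, -2, 0),
                      chromatin_extent=1.0)
        oo.univalents.append(
            Univalent(univalent_id=f"{origin}-u{k % 2 + 1}", homolog=hom,
                      origin_bivalent_id=origin)
        )
    return oo


class TestIdentifyUnivalents:
    def test_all_bivalents(self):
        oo = _oocyte_with(23, 0)
        univalents, report = identify_univalents(oo)
        assert univalents == []
        assert report["n_units"] == 23 and not report["excess_units"]

    def test_one_disintegrated(self):
        oo = _oocyte_with(22, 2)
        univalents, report = identify_univalents(oo)
        assert len(univalents) == 2
        assert report["n_units"] == 24 and report["excess_units"]
        assert report["n_chromosomes"] == 46
        assert {u.position for u in univalents} == {"proximal", "distal"}

    def test_proximal_is_nearer_plate_center(self):
        oo = _oocyte_with(22, 2)
        univalents, _ = identify_univalents(oo)
        by_pos = {u.position: u for u in univalents}
        from kinarch.core import distance

        assert distance(by_pos["proximal"].sister_pair.centroid,
                        SPINDLE.plate_center) < distance(
            by_pos["distal"].sister_pair.centroid, SPINDLE.plate_center)

    def test_accounting_failure(self):
        oo = _oocyte_with(23, 1)
        with pytest.raises(ValidationError, match="47"):
            identify_univalents(oo)


class TestUnivalentBiorientation:
    def _uni(self, axis):
        pair = pair_at((0, 0, 0), axis, 1.0, prefix="u")
        hom = Homolog(sister_pair=pair, chromatin_centroid=Point3(0, 0, 0),
                      chromatin_extent=1.0)
        return Univalent(univalent_id="u1", homolog=hom)

    def _both_pole_fibers(self):
        return [fiber("f1", "u1", 0, (-6, 0, 0)), fiber("f2", "u2", 1, (6, 0, 0))]

    def test_bioriented(self, thresholds):
        uni = self._uni((1, 0, 0))
        assert bool(univalent_biorientation(uni, SPINDLE, self._both_pole_fibers(),
                                            thresholds))

    def test_perpendicular_not_bioriented(self, thresholds):
        uni = self._uni((0, 1, 0))
        assert not univalent_biorientation(uni, SPINDLE, self._both_pole_fibers(),
                                           thresholds)

    def test_boundary_inclusive(self, thresholds):
        a = math.radians(thresholds.parallel_max)
        uni = self._uni((math.cos(a), math.sin(a), 0))
        call = univalent_biorientation(uni, SPINDLE, self._both_pole_fibers(),
                                       thresholds)
        assert bool(call)

    def test_one_pole_only_not_bioriented(self, thresholds):
        uni = self._uni((1, 0, 0))
        fs = [fiber("f1", "u1", 0, (-6, 0, 0)), fiber("f2", "u2", 0, (-6, 0.5, 0))]
        assert not univalent_biorientation(uni, SPINDLE, fs, thresholds)

    def test_merged_pair_low_confidence(self, thresholds):
        pair = merged_pair((0, 0, 0))
        hom = Homolog(sister_pair=pair, chromatin_centroid=Point3(0, 0, 0),
                      chromatin_extent=1.0)
        uni = Univalent(univalent_id="u1", homolog=hom)
        call = univalent_biorientation(uni, SPINDLE, [], thresholds)
        assert not call.bioriented and call.low_confidence


class TestSegregationOutcome:
    def test_in_axis_normal(self):
        out = predict_segregation_outcome("in_axis", ("intact", "intact"))
        assert out.predicted_event == "normal_disjunction"
        assert out.chromatid_count == 4

    def test_inverted_intact_lags(self):
        out = predict_segregation_outcome("fully_inverted", ("intact", "intact"))
        assert out.predicted_event == "lagging"

    def test_inverted_one_compromised(self):
        out = predict_segregation_outcome("fully_inverted", ("intact", "compromised"))
        assert out.predicted_event == "univalent_plus_chromatids"
        assert sorted(out.predicted_products) == ["chromatid", "chromatid", "chromosome"]

    def test_inverted_both_compromised_reverse(self):
        out = predict_segregation_outcome("fully_inverted",
                                          ("compromised", "compromised"))
        assert out.predicted_event == "reverse_segregation"
        assert out.predicted_products == ("chromatid",) * 4

    @pytest.mark.parametrize("orientation", ["in_axis", "half_inverted", "fully_inverted"])
    @pytest.mark.parametrize("c1", ["intact", "compromised"])
    @pytest.mark.parametrize("c2", ["intact", "compromised"])
    def test_chromatid_conservation(self, orientation, c1, c2):
        assert predict_segregation_outcome(orientation, (c1, c2)).chromatid_count == 4

    def test_unknown_orientation_rejected(self):
        with pytest.raises(ValidationError):
            predict_segregation_outcome("sideways", ("intact", "intact"))


class TestAtPole:
    def test_centered_bivalent_not_at_pole(self):
        biv = make_bivalent((0, 0, 0), (1, 0, 0), [(0, 1, 0), (0, 1, 0)])
        assert not is_at_pole(biv, SPINDLE)

    def test_pole_proximal_bivalent(self):
        biv = make_bivalent((-5.0, 0, 0), (1, 0, 0), [(0, 1, 0), (0, 1, 0)])
        assert is_at_pole(biv, SPINDLE)
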