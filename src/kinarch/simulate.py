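"""Seeded generator of synthetic meiosis-I oocyte cohorts.

Each oocyte carries a bipolar spindle (poles ~12 µm apart), 23 chromosome
pairs and optional cold-stable k-fibers.  Per-unit labels (configuration,
attachment mode, rotation, twist, cohesion state, biorientation) are first
sampled from the profile's rates and then *entailed geometrically*: spots,
chromatin bodies and fibers are placed so that the classifiers recover the
sampled labels exactly in the noise-free limit.  Localization noise and
optical merging are applied afterwards, so a noisy cohort exercises the
full detect → pair → classify path.

Determinism: identical (profile, seed) yields byte-identical tables;
per-oocyte generators are derived from ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import ResolutionModel, apply_resolution
from .core import (
    KinetochoreSpot,
    Point3,
    ValidationError,
    severity_from_misaligned,
)

__all__ = [
    "CohortProfile",
    "CohortTables",
    "InfeasibleProfileError",
    "simulate_oocyte",
    "simulate_cohort",
    "simulate_timelapse_cohort",
    "get_profile",
    "PROFILES",
]

CONFIG_CATEGORIES = ("indistinguishable", "overlapping", "distinct", "separated")
SPLIT_CATEGORIES = ("distinct", "separated")

#: Clearance kept between sampled distances and every classification
#: boundary so that localization noise rarely flips a category.
BAND_MARGIN = 0.03


class InfeasibleProfileError(ValueError):
    """Profile parameters admit no geometry consistent with the labels."""


@dataclass(frozen=True)
class CohortProfile:
    """All generator parameters for one cohort/age group."""

    name: str = "custom"
    seed: int = 0
    n_oocytes: int = 23
    age_range: Tuple[float, float] = (23.0, 30.0)
    stage: str = "MI"
    cold_treated: bool = True

    # sister-pair configuration mixture and per-category separation limits
    config_mixture: Dict[str, float] = field(
        default_factory=lambda: {
            "indistinguishable": 0.25,
            "overlapping": 0.15,
            "distinct": 0.35,
            "separated": 0.25,
        }
    )
    max_separation: float = 1.7
    irresolvable_rate: float = 0.02

    # attachment conditionals (per detected-category stratum)
    merotelic_given_config: Dict[str, float] = field(
        default_factory=lambda: {
            "indistinguishable": 0.12,
            "overlapping": 0.12,
            "distinct": 0.17,
            "separated": 0.28,
        }
    )
    lateral_rate: float = 0.10
    unattached_rate: float = 0.03
    two_fiber_rate_split: float = 0.90
    two_fiber_rate_unified: float = 0.40
    fiber_type_mixture: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.45, "B": 0.35, "C": 0.20}
    )

    # bivalent architecture rates
    p_fully_inverted: float = 0.018
    p_half_inverted: float = 0.018
    p_twisted_given_split: float = 0.20
    p_weak_gap: float = 0.10
    p_disintegrate: float = 0.012
    p_univalent_bioriented: float = 0.95
    p_at_pole: float = 0.01
    gap_range: Tuple[float, float] = (0.1, 3.2)

    # imaging model
    noise_sigma_um: Tuple[float, float, float] = (0.012, 0.012, 0.025)
    resolution: ResolutionModel = field(default_factory=ResolutionModel)
    spot_radius_um: float = 0.4
    spindle_length_um: Tuple[float, float] = (12.0, 0.5)  # mean, sd

    # optional linear age effect on sampled sister distances (µm / year),
    # anchored at the age-range midpoint
    age_distance_slope: float = 0.0

    # time-lapse parameters (times in hours relative to NEBD)
    severity_mixture: Dict[str, float] = field(
        default_factory=lambda: {"none": 0.5, "mild": 0.3, "severe": 0.2}
    )
    progression_by_severity: Dict[str, float] = field(
        default_factory=lambda: {"none": 1.0, "mild": 1.0, "severe": 0.92}
    )
    lagging_rate_by_severity: Dict[str, float] = field(
        default_factory=lambda: {"none": 0.05, "mild": 0.30, "severe": 0.60}
    )
    anaphase_onset_h: Tuple[float, float] = (16.3, 2.3)  # mean, sd
    congression_lead_h: Tuple[float, float] = (1.5, 0.5)  # onset minus congression

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, mix in (
            ("config_mixture", self.config_mixture),
            ("fiber_type_mixture", self.fiber_type_mixture),
            ("severity_mixture", self.severity_mixture),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1")
            if any(p < 0 for p in mix.values()):
                raise ValidationError(f"{name} has negative probability")
        probs = [
            self.lateral_rate,
            self.unattached_rate,
            self.two_fiber_rate_split,
            self.two_fiber_rate_unified,
            self.p_fully_inverted,
            self.p_half_inverted,
            self.p_twisted_given_split,
            self.p_weak_gap,
            self.p_disintegrate,
            self.p_univalent_bioriented,
            self.p_at_pole,
            self.irresolvable_rate,
            *self.merotelic_given_config.values(),
            *self.progression_by_severity.values(),
            *self.lagging_rate_by_severity.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if self.p_fully_inverted + self.p_half_inverted > 1.0:
            raise ValidationError("inversion probabilities exceed 1")
        if self.n_oocytes < 1:
            raise ValidationError("n_oocytes must be >= 1")
        self._check_feasible()

    def _check_feasible(self) -> None:
        r2 = 2.0 * self.spot_radius_um
        touch = r2
        overlap_thr = self.resolution.overlap_factor * r2
        if self.max_separation <= touch + 2 * BAND_MARGIN:
            raise InfeasibleProfileError(
                f"max_separation {self.max_separation} leaves no room above the "
                f"touching threshold {touch}"
            )
        # widest merge distance for the pair-axis orientations the generator
        # uses for sub-resolution categories (|z-component| <= sin(40 deg))
        m_worst = _worst_merge_distance(self.resolution)
        if m_worst + 2 * BAND_MARGIN >= overlap_thr:
            raise InfeasibleProfileError(
                f"overlapping band is empty: effective merge distance up to "
                f"{m_worst:.3f} µm vs overlap threshold {overlap_thr:.3f} µm"
            )
        if overlap_thr + 2 * BAND_MARGIN >= touch:
            raise InfeasibleProfileError("distinct band is empty")
        s = sum(self.config_mixture[c] for c in SPLIT_CATEGORIES)
        if self.p_fully_inverted > s * s + 1e-12 or self.p_half_inverted > s + 1e-12:
            raise InfeasibleProfileError(
                "inversion probabilities exceed the split-configuration mass "
                f"(split mass {s:.3f}); rotated bivalents need split pairs"
            )

    def replace(self, **overrides) -> "CohortProfile":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["resolution"] = dataclasses.asdict(self.resolution)
        return d

    @staticmethod
    def from_dict(d: dict) -> "CohortProfile":
        d = dict(d)
        if "resolution" in d and isinstance(d["resolution"], dict):
            d["resolution"] = ResolutionModel(**d["resolution"])
        for key in (
            "age_range",
            "noise_sigma_um",
            "gap_range",
            "spindle_length_um",
            "anaphase_onset_h",
            "congression_lead_h",
        ):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return CohortProfile(**d)


_MAX_Z_FRACTION = math.sin(math.radians(40.0))


def _worst_merge_distance(model: ResolutionModel) -> float:
    u = np.array(
        [math.sqrt(1 - _MAX_Z_FRACTION**2), 0.0, _MAX_Z_FRACTION]
    )
    return model.effective_merge_distance(u)


# ---------------------------------------------------------------------------
# geometry helpers


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_direction(axis: np.ndarray, e1: np.ndarray, e2: np.ndarray, rng,
                    max_z_deg: float = 30.0) -> np.ndarray:
    """Direction perpendicular to the spindle axis with a bounded
    z-component (keeps sub-resolution pairs inside the lateral merge
    regime)."""
    psi = math.radians(rng.uniform(-max_z_deg, max_z_deg))
    return _unit(math.cos(psi) * e1 + math.sin(psi) * e2)


def _tilted_from_axis(axis: np.ndarray, e1: np.ndarray, e2: np.ndarray,
                      rng, max_tilt_deg: float = 15.0) -> np.ndarray:
    """Direction within ``max_tilt_deg`` of the spindle axis."""
    tilt = math.radians(rng.uniform(0.0, max_tilt_deg))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    perp = math.cos(phi) * e1 + math.sin(phi) * e2
    return _unit(math.cos(tilt) * axis + math.sin(tilt) * perp)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    th = math.radians(angle_deg)
    k = _unit(axis)
    return (
        v * math.cos(th)
        + np.cross(k, v) * math.sin(th)
        + k * float(np.dot(k, v)) * (1.0 - math.cos(th))
    )


def _sample_distance(category: str, axis_dir: np.ndarray, profile: CohortProfile,
                     rng) -> float:
    """Sister separation consistent with the category for this pair axis,
    kept BAND_MARGIN away from every classification boundary."""
    res = profile.resolution
    r2 = 2.0 * profile.spot_radius_um
    overlap_thr = res.overlap_factor * r2
    m_eff = res.effective_merge_distance(axis_dir)
    if category == "indistinguishable":
        hi = min(0.20, res.merge_distance_lateral - BAND_MARGIN)
        return rng.uniform(0.03, hi)
    if category == "overlapping":
        lo = m_eff + BAND_MARGIN
        hi = overlap_thr - BAND_MARGIN
        if lo >= hi:
            raise InfeasibleProfileError(
                f"overlapping band empty for axis direction {axis_dir} "
                f"(merge distance {m_eff:.3f}, overlap threshold {overlap_thr:.3f})"
            )
        return rng.uniform(lo, hi)
    if category == "distinct":
        # lower bound also clears the direction-dependent merge distance
        # (near-axial pair axes have a coarser resolution limit)
        lo = max(overlap_thr, m_eff) + BAND_MARGIN
        hi = r2 - BAND_MARGIN
        if lo >= hi:
            raise InfeasibleProfileError(
                f"distinct band empty for axis direction {axis_dir}"
            )
        return rng.uniform(lo, hi)
    if category == "separated":
        lo = max(r2, m_eff) + BAND_MARGIN
        hi = profile.max_separation
        # truncated gamma above the touching threshold
        for _ in range(1000):
            x = rng.gamma(shape=2.0, scale=0.25)
            if lo + x <= hi:
                return lo + x
        return rng.uniform(lo, hi)
    raise ValidationError(f"unknown category {category!r}")


def _apply_age_shift(d: float, category: str, age: float, profile: CohortProfile,
                     rng) -> float:
    if profile.age_distance_slope == 0.0 or category not in SPLIT_CATEGORIES:
        return d
    ref = 0.5 * (profile.age_range[0] + profile.age_range[1])
    shift = profile.age_distance_slope * (age - ref)
    r2 = 2.0 * profile.spot_radius_um
    if category == "distinct":
        lo = profile.resolution.overlap_factor * r2 + BAND_MARGIN
        hi = r2 - BAND_MARGIN
    else:
        lo = r2 + BAND_MARGIN
        hi = profile.max_separation
    return float(np.clip(d + shift, lo, hi))


# ---------------------------------------------------------------------------
# per-oocyte simulation


@dataclass
class CohortTables:
    """Tidy per-cohort outputs of the generator."""

    oocytes: pd.DataFrame
    spots: pd.DataFrame
    fibers: pd.DataFrame
    chromatin: pd.DataFrame
    truth_pairs: pd.DataFrame
    truth_units: pd.DataFrame


class _OocyteBuilder:
    """Accumulates one oocyte's rows while sampling unit geometries."""

    def __init__(self, profile: CohortProfile, oocyte_id: str, rng) -> None:
        self.profile = profile
        self.oocyte_id = oocyte_id
        self.rng = rng
        self.spot_rows: List[dict] = []
        self.fiber_rows: List[dict] = []
        self.chromatin_rows: List[dict] = []
        self.truth_pair_rows: List[dict] = []
        self.truth_unit_rows: List[dict] = []
        self._fiber_counter = 0
        self._trunk_counter = 0

        mean, sd = profile.spindle_length_um
        length = max(8.0, rng.normal(mean, sd))
        phi = rng.uniform(0.0, 2.0 * math.pi)
        self.axis = np.array([math.cos(phi), math.sin(phi), 0.0])
        self.e1 = np.array([-math.sin(phi), math.cos(phi), 0.0])
        self.e2 = np.array([0.0, 0.0, 1.0])
        self.length = length
        self.pole0 = -0.5 * length * self.axis
        self.pole1 = 0.5 * length * self.axis
        self.age = float(rng.uniform(*profile.age_range))

        # lateral plate sites with a 1.5 µm spacing floor
        cells = [(i, j) for i in range(-2, 3) for j in range(-2, 3)]
        order = rng.permutation(len(cells))
        self.sites = []
        for k in order[:23]:
            ci, cj = cells[k]
            u = ci * 2.2 + rng.uniform(-0.3, 0.3)
            v = cj * 2.2 + rng.uniform(-0.3, 0.3)
            self.sites.append(u * self.e1 + v * self.e2)

    # -- low-level row emitters -------------------------------------------

    def _add_spot(self, spot_id: str, unit_id: str, homolog: int,
                  pos: np.ndarray) -> str:
        self.spot_rows.append(
            {
                "oocyte_id": self.oocyte_id,
                "spot_id": spot_id,
                "unit_id": unit_id,
                "homolog_id": homolog,
                "x_um": pos[0],
                "y_um": pos[1],
                "z_um": pos[2],
                "radius_um": self.profile.spot_radius_um,
                "merged": False,
            }
        )
        return spot_id

    def _add_chromatin(self, unit_id: str, homolog: int, pos: np.ndarray,
                       extent: float) -> None:
        self.chromatin_rows.append(
            {
                "oocyte_id": self.oocyte_id,
                "unit_id": unit_id,
                "homolog_id": homolog,
                "x_um": pos[0],
                "y_um": pos[1],
                "z_um": pos[2],
                "extent_um": extent,
            }
        )

    def _add_fiber(self, kin_id: str, pole_index: int, endpoint: np.ndarray,
                   geometry: str = "end_on", trunk: Optional[str] = None) -> None:
        self._fiber_counter += 1
        self.fiber_rows.append(
            {
                "oocyte_id": self.oocyte_id,
                "fiber_id": f"{self.oocyte_id}-f{self._fiber_counter:04d}",
                "kinetochore_spot_id": kin_id,
                "pole_index": pole_index,
                "x_um": endpoint[0],
                "y_um": endpoint[1],
                "z_um": endpoint[2],
                "contact_geometry": geometry,
                "trunk_group": trunk if trunk is not None else "",
            }
        )

    def _pole_point(self, pole_index: int, offset: np.ndarray) -> np.ndarray:
        pole = self.pole0 if pole_index == 0 else self.pole1
        return pole + offset

    # -- sampling ----------------------------------------------------------

    def _sample_category(self, rng, force_split: bool = False) -> str:
        mix = self.profile.config_mixture
        if force_split:
            tot = sum(mix[c] for c in SPLIT_CATEGORIES)
            if tot <= 0:
                # profile has no split mass; fall back to an even split
                probs = {c: 0.5 for c in SPLIT_CATEGORIES}
            else:
                probs = {c: mix[c] / tot for c in SPLIT_CATEGORIES}
            cats = SPLIT_CATEGORIES
        else:
            cats = CONFIG_CATEGORIES
            probs = mix
        u = rng.random()
        acc = 0.0
        for c in cats:
            acc += probs.get(c, 0.0)
            if u < acc:
                return c
        return cats[-1]

    def _place_pair(self, unit_id: str, homolog: int, centroid: np.ndarray,
                    axis_dir: np.ndarray, category: str) -> Tuple[List[str], float]:
        """Emit the 2 true sister spots of a pair; returns ids and distance."""
        rng = self.rng
        d = _sample_distance(category, axis_dir, self.profile, rng)
        d = _apply_age_shift(d, category, self.age, self.profile, rng)
        ids = []
        for s, sign in ((1, -0.5), (2, 0.5)):
            pos = centroid + sign * d * axis_dir
            ids.append(
                self._add_spot(f"{unit_id}-h{homolog}-s{s}", unit_id, homolog, pos)
            )
        return ids, d

    def _facing_pole(self, centroid: np.ndarray) -> int:
        return 0 if float(np.dot(centroid, self.axis)) < 0 else 1

    def _sample_attachment_mode(self, category: str, rng) -> str:
        p = self.profile
        m = p.merotelic_given_config[category]
        u = rng.random()
        if u < m:
            return "merotelic"
        if u < m + p.lateral_rate:
            return "lateral"
        if u < m + p.lateral_rate + p.unattached_rate:
            return "unattached"
        return "amphitelic"

    def _two_fiber_prob(self, category: str) -> float:
        """Non-merotelic two-fiber probability, calibrated so the overall
        two-fiber rate among split pairs matches the configured target
        (merotelic pairs always carry two fibers)."""
        p = self.profile
        if category in SPLIT_CATEGORIES:
            mix = p.config_mixture
            tot = sum(mix[c] for c in SPLIT_CATEGORIES)
            if tot > 0:
                mero_split = (
                    sum(mix[c] * p.merotelic_given_config[c] for c in SPLIT_CATEGORIES)
                    / tot
                )
            else:
                mero_split = 0.0
            u = p.unattached_rate
            if mero_split + u >= 1.0:
                return 1.0
            # calibrated so the two-fiber rate among *attached* split pairs
            # matches the configured target (merotelic pairs always carry 2)
            return float(
                np.clip(
                    (p.two_fiber_rate_split * (1.0 - u) - mero_split)
                    / (1.0 - mero_split - u),
                    0.0, 1.0,
                )
            )
        return p.two_fiber_rate_unified

    def _emit_fibers(self, pair_ids: Sequence[str], centroid: np.ndarray,
                     mode: str, category: str) -> Tuple[int, str]:
        """Fibers entailing the sampled attachment mode; returns the truth
        (n_fibers, fiber_type)."""
        rng = self.rng
        facing = self._facing_pole(centroid)
        other = 1 - facing
        two = mode == "merotelic" or rng.random() < self._two_fiber_prob(category)

        def small_offset() -> np.ndarray:
            v = rng.normal(0.0, 0.25, size=3)
            return v - self.axis * float(np.dot(v, self.axis))

        if mode == "unattached":
            return 0, "none"
        if mode == "lateral":
            # lateral contact toward the opposite pole; optionally one
            # end-on fiber to the facing pole (lateral-merotelic folds here)
            self._add_fiber(pair_ids[0], other,
                            self._pole_point(other, small_offset()), "lateral")
            if two:
                self._add_fiber(pair_ids[-1], facing,
                                self._pole_point(facing, small_offset()), "end_on")
                return 2, "B"
            return 1, "single"
        if mode == "merotelic":
            self._add_fiber(pair_ids[0], facing,
                            self._pole_point(facing, small_offset()), "end_on")
            self._add_fiber(pair_ids[-1], other,
                            self._pole_point(other, small_offset()), "end_on")
            return 2, "B"
        # amphitelic
        if not two:
            self._add_fiber(pair_ids[0], facing,
                            self._pole_point(facing, small_offset()), "end_on")
            return 1, "single"
        u = rng.random()
        fm = self.profile.fiber_type_mixture
        if u < fm["C"]:
            self._trunk_counter += 1
            trunk = f"{self.oocyte_id}-t{self._trunk_counter:03d}"
            end = self._pole_point(facing, small_offset())
            self._add_fiber(pair_ids[0], facing, end, "end_on", trunk)
            self._add_fiber(pair_ids[-1], facing, end, "end_on", trunk)
            return 2, "C"
        if u < fm["C"] + fm["A"]:
            base = small_offset()
            sep = _unit(self.e1 + rng.normal(0, 0.1, 3)) * 0.2
            self._add_fiber(pair_ids[0], facing,
                            self._pole_point(facing, base + sep), "end_on")
            self._add_fiber(pair_ids[-1], facing,
                            self._pole_point(facing, base - sep), "end_on")
            return 2, "A"
        # type B: endpoints at distant locations at the same pole
        off = _unit(math.cos(a := rng.uniform(0, 2 * math.pi)) * self.e1
                    + math.sin(a) * self.e2) * rng.uniform(1.8, 2.4)
        self._add_fiber(pair_ids[0], facing,
                        self._pole_point(facing, off), "end_on")
        self._add_fiber(pair_ids[-1], facing,
                        self._pole_point(facing, -off), "end_on")
        return 2, "B"

    # -- units -------------------------------------------------------------

    def build_bivalent(self, index: int, site: np.ndarray, at_pole: bool) -> None:
        rng = self.rng
        p = self.profile
        unit_id = f"{self.oocyte_id}-b{index:02d}"

        # configurations come straight from the mixture; rotation is then
        # sampled conditionally on split-ness (rescaled so the marginal
        # inversion rates match the configured probabilities without
        # distorting the configuration mixture)
        categories = [self._sample_category(rng), self._sample_category(rng)]
        splitness = [c in SPLIT_CATEGORIES for c in categories]
        s = sum(p.config_mixture[c] for c in SPLIT_CATEGORIES)
        inverted_first = rng.random() < 0.5
        rotation = "in_axis"
        weak, gap = False, 0.0
        if not at_pole:
            if all(splitness) and rng.random() < p.p_fully_inverted / max(s * s, 1e-12):
                rotation = "fully_inverted"
            elif (
                splitness[0 if inverted_first else 1]
                and rng.random() < p.p_half_inverted / max(s, 1e-12)
            ):
                rotation = "half_inverted"
            weak = rng.random() < p.p_weak_gap
            gap = float(rng.uniform(*p.gap_range)) if weak else 0.0

        twisted = False
        if (
            rotation == "in_axis"
            and not at_pole
            and all(c in SPLIT_CATEGORIES for c in categories)
        ):
            twisted = rng.random() < p.p_twisted_given_split

        extents = rng.uniform(0.9, 1.3, size=2)
        if weak:
            chrom_sep = float(extents.sum()) + gap
        else:
            chrom_sep = 0.9 * float(extents.sum())
        pair_sep = chrom_sep + 1.2
        if rotation == "half_inverted":
            pair_sep = max(pair_sep, 3.4 + rng.uniform(0.0, 0.6))

        if rotation == "fully_inverted":
            a = rng.uniform(0, 2 * math.pi)
            biv_dir = _unit(math.cos(a) * self.e1 + math.sin(a) * self.e2)
        else:
            biv_dir = self.axis

        if at_pole:
            pole_index = int(rng.integers(0, 2))
            inward = self.axis if pole_index == 0 else -self.axis
            pole = self.pole0 if pole_index == 0 else self.pole1
            center = pole + inward * (0.05 * self.length) + 0.3 * site / max(
                1.0, np.linalg.norm(site)
            )
        else:
            center = site

        pair_centroids = [center - 0.5 * pair_sep * biv_dir,
                          center + 0.5 * pair_sep * biv_dir]
        chrom_centroids = [center - 0.5 * chrom_sep * biv_dir,
                           center + 0.5 * chrom_sep * biv_dir]

        # pair axes entailed by rotation/twist labels
        if rotation == "fully_inverted":
            axes = [_tilted_from_axis(self.axis, self.e1, self.e2, rng),
                    _tilted_from_axis(self.axis, self.e1, self.e2, rng)]
        elif rotation == "half_inverted":
            ax_inv = _tilted_from_axis(self.axis, self.e1, self.e2, rng)
            ax_norm = _perp_direction(self.axis, self.e1, self.e2, rng)
            axes = [ax_inv, ax_norm] if inverted_first else [ax_norm, ax_inv]
        else:
            ax1 = _perp_direction(self.axis, self.e1, self.e2, rng)
            if twisted:
                ax2 = _rotate_about(ax1, biv_dir, 70.0)
            else:
                ax2 = _rotate_about(ax1, biv_dir, rng.uniform(-10.0, 10.0))
            axes = [ax1, _unit(ax2)]

        pair_info = []
        for h, (cat, axis_dir, pc) in enumerate(
            zip(categories, axes, pair_centroids), start=1
        ):
            ids, d = self._place_pair(unit_id, h, pc, axis_dir, cat)
            self._add_chromatin(unit_id, h, chrom_centroids[h - 1], float(extents[h - 1]))
            irresolvable = rng.random() < p.irresolvable_rate
            mode, n_fibers, fiber_type = "", 0, ""
            if p.cold_treated and not at_pole:
                mode = self._sample_attachment_mode(cat, rng)
                n_fibers, fiber_type = self._emit_fibers(ids, pc, mode, cat)
            self.truth_pair_rows.append(
                {
                    "oocyte_id": self.oocyte_id,
                    "unit_id": unit_id,
                    "pair_index": h,
                    "unit_type": "bivalent",
                    "configuration": cat,
                    "distance_um": d,
                    "attachment_mode": mode,
                    "n_fibers": n_fibers,
                    "fiber_type": fiber_type,
                    "at_pole": at_pole,
                    "irresolvable": irresolvable,
                }
            )
            pair_info.append((cat, irresolvable))

        twist_label = "not_scorable"
        if all(c in SPLIT_CATEGORIES for c, _ in pair_info):
            twist_label = "twisted" if twisted else "undistorted"
        self.truth_unit_rows.append(
            {
                "oocyte_id": self.oocyte_id,
                "unit_id": unit_id,
                "unit_type": "bivalent",
                "rotation": rotation if not at_pole else "",
                "twist": twist_label if rotation == "in_axis" and not at_pole else "not_scorable",
                "cohesion_state": "weak_gap" if weak else "intact",
                "gap_um": gap,
                "at_pole": at_pole,
                "origin_bivalent_id": "",
                "univalent_position": "",
                "bioriented": "",
            }
        )

    def build_univalent_pair(self, index: int, site: np.ndarray) -> None:
        rng = self.rng
        p = self.profile
        origin = f"{self.oocyte_id}-b{index:02d}"
        # one univalent stays near the plate (proximal), the partner drifts
        # poleward (distal)
        pole_sign = 1.0 if rng.random() < 0.5 else -1.0
        offsets = [rng.uniform(-0.4, 0.4), pole_sign * rng.uniform(2.0, 3.5)]
        order = ("proximal", "distal")
        for k, (off, posname) in enumerate(zip(offsets, order), start=1):
            unit_id = f"{origin}-u{k}"
            centroid = site + off * self.axis
            bioriented = rng.random() < p.p_univalent_bioriented
            if bioriented:
                axis_dir = _tilted_from_axis(self.axis, self.e1, self.e2, rng, 12.0)
            else:
                perp = _perp_direction(self.axis, self.e1, self.e2, rng)
                axis_dir = _unit(
                    math.sin(math.radians(t := rng.uniform(0.0, 8.0))) * self.axis
                    + math.cos(math.radians(t)) * perp
                )
            cat = self._sample_category(rng, force_split=True)
            ids, d = self._place_pair(unit_id, 1, centroid, axis_dir, cat)
            self._add_chromatin(unit_id, 1, centroid, float(rng.uniform(0.9, 1.3)))
            mode, n_fibers, fiber_type = "", 0, ""
            if p.cold_treated:
                def off3() -> np.ndarray:
                    v = rng.normal(0.0, 0.25, size=3)
                    return v - self.axis * float(np.dot(v, self.axis))

                if bioriented:
                    # one sister end-on to each pole
                    self._add_fiber(ids[0], 0, self._pole_point(0, off3()), "end_on")
                    self._add_fiber(ids[1], 1, self._pole_point(1, off3()), "end_on")
                    mode, n_fibers, fiber_type = "merotelic", 2, "B"
                else:
                    facing = self._facing_pole(centroid)
                    self._add_fiber(ids[0], facing,
                                    self._pole_point(facing, off3()), "end_on")
                    self._add_fiber(ids[1], facing,
                                    self._pole_point(facing, off3()), "end_on")
                    mode, n_fibers, fiber_type = "amphitelic", 2, "A"
            self.truth_pair_rows.append(
                {
                    "oocyte_id": self.oocyte_id,
                    "unit_id": unit_id,
                    "pair_index": 1,
                    "unit_type": "univalent",
                    "configuration": cat,
                    "distance_um": d,
                    "attachment_mode": mode,
                    "n_fibers": n_fibers,
                    "fiber_type": fiber_type,
                    "at_pole": False,
                    "irresolvable": rng.random() < p.irresolvable_rate,
                }
            )
            self.truth_unit_rows.append(
                {
                    "oocyte_id": self.oocyte_id,
                    "unit_id": unit_id,
                    "unit_type": "univalent",
                    "rotation": "",
                    "twist": "",
                    "cohesion_state": "disintegrated",
                    "gap_um": 0.0,
                    "at_pole": False,
                    "origin_bivalent_id": origin,
                    "univalent_position": posname,
                    "bioriented": bool(bioriented),
                }
            )

    # -- assembly ----------------------------------------------------------

    def build(self) -> None:
        rng = self.rng
        p = self.profile
        for i in range(23):
            site = self.sites[i]
            if rng.random() < p.p_disintegrate:
                self.build_univalent_pair(i + 1, site)
            else:
                at_pole = rng.random() < p.p_at_pole
                self.build_bivalent(i + 1, site, at_pole)

    def finish(self) -> dict:
        """Apply localization noise, merge sub-resolution detections and
        remap fiber references; returns this oocyte's table rows."""
        p = self.profile
        rng = self.rng
        sigma = np.asarray(p.noise_sigma_um, dtype=float)

        true_spots = []
        for row in self.spot_rows:
            pos = np.array([row["x_um"], row["y_um"], row["z_um"]])
            if sigma.any():
                pos = pos + rng.normal(0.0, 1.0, size=3) * sigma
            true_spots.append(
                KinetochoreSpot(
                    spot_id=row["spot_id"],
                    oocyte_id=row["oocyte_id"],
                    bivalent_id=row["unit_id"],
                    homolog_id=row["homolog_id"],
                    position=Point3.from_array(pos),
                    radius=row["radius_um"],
                )
            )
        detected, id_map = apply_resolution(true_spots, p.resolution)

        irr_pairs = {
            (r["unit_id"], r["pair_index"])
            for r in self.truth_pair_rows
            if r["irresolvable"]
        }
        spot_rows = []
        for s in detected:
            # pair_index equals the generated homolog id for bivalents and 1
            # for univalents
            key = (s.bivalent_id, s.homolog_id)
            spot_rows.append(
                {
                    "oocyte_id": s.oocyte_id,
                    "spot_id": s.spot_id,
                    "unit_id": s.bivalent_id,
                    "homolog_id": s.homolog_id,
                    "x_um": s.position.x,
                    "y_um": s.position.y,
                    "z_um": s.position.z,
                    "radius_um": s.radius,
                    "merged": s.merged,
                    "resolved_confident": key not in irr_pairs,
                }
            )
        for row in self.fiber_rows:
            row["kinetochore_spot_id"] = id_map[row["kinetochore_spot_id"]]

        oocyte_row = {
            "oocyte_id": self.oocyte_id,
            "donor_age_years": self.age,
            "stage": p.stage,
            "cold_treated": p.cold_treated,
            "pole0_x_um": self.pole0[0],
            "pole0_y_um": self.pole0[1],
            "pole0_z_um": self.pole0[2],
            "pole1_x_um": self.pole1[0],
            "pole1_y_um": self.pole1[1],
            "pole1_z_um": self.pole1[2],
        }
        return {
            "oocyte": oocyte_row,
            "spots": spot_rows,
            "fibers": self.fiber_rows,
            "chromatin": self.chromatin_rows,
            "truth_pairs": self.truth_pair_rows,
            "truth_units": self.truth_unit_rows,
        }


def simulate_oocyte(profile: CohortProfile, seed, oocyte_id: str = "oo001"):
    """Simulate one oocyte; returns its table rows (dict of lists).

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    builder = _OocyteBuilder(profile, oocyte_id, rng)
    builder.build()
    return builder.finish()


def simulate_cohort(profile: CohortProfile) -> CohortTables:
    """Simulate ``profile.n_oocytes`` oocytes with per-oocyte seeds derived
    deterministically from ``profile.seed``."""
    if profile.n_oocytes < 1:
        raise ValidationError("n_oocytes must be >= 1")
    oocyte_rows, spot_rows, fiber_rows = [], [], []
    chromatin_rows, tp_rows, tu_rows = [], [], []
    for i in range(profile.n_oocytes):
        ss = np.random.SeedSequence(entropy=profile.seed, spawn_key=(i,))
        out = simulate_oocyte(profile, ss, oocyte_id=f"{profile.name}-oo{i + 1:03d}")
        oocyte_rows.append(out["oocyte"])
        spot_rows.extend(out["spots"])
        fiber_rows.extend(out["fibers"])
        chromatin_rows.extend(out["chromatin"])
        tp_rows.extend(out["truth_pairs"])
        tu_rows.extend(out["truth_units"])

    fiber_cols = [
        "oocyte_id", "fiber_id", "kinetochore_spot_id", "pole_index",
        "x_um", "y_um", "z_um", "contact_geometry", "trunk_group",
    ]
    return CohortTables(
        oocytes=pd.DataFrame(oocyte_rows),
        spots=pd.DataFrame(spot_rows),
        fibers=pd.DataFrame(fiber_rows, columns=fiber_cols),
        chromatin=pd.DataFrame(chromatin_rows),
        truth_pairs=pd.DataFrame(tp_rows),
        truth_units=pd.DataFrame(tu_rows),
    )


def simulate_timelapse_cohort(profile: CohortProfile,
                              n_records: Optional[int] = None) -> pd.DataFrame:
    """Simulate per-oocyte live-imaging event records.

    Times are hours relative to NEBD; anaphase onset (10 min before first
    chromosome separation) is sampled from the profile's normal model and
    left empty for oocytes that failed to progress.
    """
    n = profile.n_oocytes if n_records is None else int(n_records)
    if n < 1:
        raise ValidationError("need at least one time-lapse record")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=profile.seed, spawn_key=(9999,))
    )
    sevs = list(profile.severity_mixture)
    probs = np.array([profile.severity_mixture[s] for s in sevs])
    rows = []
    mean, sd = profile.anaphase_onset_h
    lead_m, lead_s = profile.congression_lead_h
    for i in range(n):
        sev = sevs[int(rng.choice(len(sevs), p=probs))]
        if sev == "none":
            n_mis = 0
        elif sev == "mild":
            n_mis = int(rng.integers(1, 4))
        else:
            n_mis = int(rng.integers(4, 9))
        assert severity_from_misaligned(n_mis) == sev
        progressed = rng.random() < profile.progression_by_severity[sev]
        lagging = progressed and rng.random() < profile.lagging_rate_by_severity[sev]
        onset = max(2.0, rng.normal(mean, sd))
        congression = max(1.0, onset - abs(rng.normal(lead_m, lead_s)))
        rows.append(
            {
                "oocyte_id": f"{profile.name}-tl{i + 1:05d}",
                "t_nebd_h": 0.0,
                "t_congression_h": congression,
                "t_anaphase_onset_h": onset if progressed else np.nan,
                "n_misaligned": n_mis,
                "severity": sev,
                "lagging": lagging,
                "progressed": progressed,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged profiles


def _young_baseline() -> CohortProfile:
    return CohortProfile(name="young_baseline", n_oocytes=23, age_range=(23.0, 30.0))


def _mid_baseline() -> CohortProfile:
    return CohortProfile(
        name="from30to35_baseline",
        n_oocytes=20,
        age_range=(30.0, 35.0),
        config_mixture={
            "indistinguishable": 0.15,
            "overlapping": 0.10,
            "distinct": 0.42,
            "separated": 0.33,
        },
        p_weak_gap=0.09,
        p_disintegrate=0.02,
    )


def _over35_baseline() -> CohortProfile:
    # mixture chosen so that split = 87% and the configuration-conditional
    # merotelic rates imply an overall merotelic rate of ~21%
    return CohortProfile(
        name="over35_baseline",
        n_oocytes=20,
        age_range=(36.0, 44.0),
        config_mixture={
            "indistinguishable": 0.08,
            "overlapping": 0.05,
            "distinct": 0.45,
            "separated": 0.42,
        },
        p_weak_gap=0.075,
        p_disintegrate=0.035,
    )


PROFILES = {
    "young_baseline": _young_baseline,
    "from30to35_baseline": _mid_baseline,
    "over35_baseline": _over35_baseline,
}


def get_profile(name: str, **overrides) -> CohortProfile:
    """Fetch a packaged cohort profile, optionally overriding fields."""
    try:
        prof = PROFILES[name]()
    except KeyError:
        raise ValidationError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}"
        ) from None
    return prof.replace(**overrides) if overrides else prof
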