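"""Classification of kinetochore configurations, attachments and bivalent geometry.

Implements the full set of per-unit calls: optical-resolution merging,
four-category sister-pair configuration, k-fiber topology (types A/B/C),
attachment mode (amphitelic / merotelic / lateral / unattached), bivalent
rotation and twist relative to the spindle axis, cohesion-state and
univalent identification, and the deterministic segregation-outcome table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    Bivalent,
    KFiber,
    KinetochoreSpot,
    MI_CHROMOSOME_COUNT,
    Oocyte,
    Point3,
    SisterPair,
    Spindle,
    Univalent,
    ValidationError,
    axis_angle,
    distance,
)

__all__ = [
    "ResolutionModel",
    "AngleThresholds",
    "AttachmentCall",
    "RotationCall",
    "TwistCall",
    "BiorientationCall",
    "OutcomePrediction",
    "apply_resolution",
    "classify_configuration",
    "is_split",
    "classify_fiber_topology",
    "classify_attachment_mode",
    "score_rotation",
    "score_twist",
    "detect_cohesion_state",
    "identify_univalents",
    "univalent_biorientation",
    "predict_segregation_outcome",
    "is_at_pole",
]


@dataclass(frozen=True)
class ResolutionModel:
    """Optical resolution limits governing spot merging and touching.

    Two sister spots collapse into a single detection when the
    direction-weighted separation metric

        (dx/m_lat)^2 + (dy/m_lat)^2 + (dz/m_ax)^2 < 1

    falls below one (ellipsoidal resolution volume; the axial limit is
    coarser than the lateral one).
    """

    merge_distance_lateral: float = 0.30
    merge_distance_axial: float = 0.65
    overlap_factor: float = 0.6

    def __post_init__(self) -> None:
        if self.merge_distance_lateral <= 0 or self.merge_distance_axial <= 0:
            raise ValidationError("merge distances must be > 0")
        if not (0.0 < self.overlap_factor < 1.0):
            raise ValidationError("overlap_factor must lie in (0, 1)")

    def merge_metric(self, delta: Sequence[float]) -> float:
        dx, dy, dz = (float(c) for c in delta)
        ml, ma = self.merge_distance_lateral, self.merge_distance_axial
        return (dx / ml) ** 2 + (dy / ml) ** 2 + (dz / ma) ** 2

    def merges(self, p: Point3, q: Point3) -> bool:
        return self.merge_metric(q.as_array() - p.as_array()) < 1.0

    def effective_merge_distance(self, direction: Sequence[float]) -> float:
        """Centre separation below which spots along ``direction`` merge."""
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        m = self.merge_metric(u)
        return 1.0 / math.sqrt(m)


@dataclass(frozen=True)
class AngleThresholds:
    """Angular cutoffs (degrees) for rotation/twist/biorientation calls.

    ``parallel_max`` bounds "parallel to the spindle axis";
    ``perpendicular_min`` bounds "perpendicular"; angles between the two
    are an ambiguity band.
    """

    parallel_max: float = 30.0
    perpendicular_min: float = 60.0
    twist_min: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 < self.parallel_max < self.perpendicular_min <= 90.0):
            raise ValidationError("need 0 < parallel_max < perpendicular_min <= 90")
        if not (self.parallel_max < self.twist_min <= 90.0):
            raise ValidationError("twist_min must lie in (parallel_max, 90]")


def apply_resolution(
    spots: Sequence[KinetochoreSpot], model: ResolutionModel
) -> Tuple[List[KinetochoreSpot], Dict[str, str]]:
    """Collapse sub-resolution sister spots into single merged detections.

    Candidate merges are the two spots sharing (oocyte, bivalent, homolog).
    A merged detection sits at the intensity-weighted midpoint (intensity
    taken proportional to radius cubed) with the volume-combined radius.

    Returns the detected spot list plus a map from original spot_id to the
    id of the detection that now represents it (identity for pass-through
    spots); fiber records should be remapped through it.
    """
    groups: Dict[tuple, List[KinetochoreSpot]] = {}
    for s in spots:
        groups.setdefault((s.oocyte_id, s.bivalent_id, s.homolog_id), []).append(s)

    detected: List[KinetochoreSpot] = []
    id_map: Dict[str, str] = {}
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda s: s.spot_id)
        if len(members) == 2 and model.merges(members[0].position, members[1].position):
            a, b = members
            wa, wb = a.radius**3, b.radius**3
            pos = (wa * a.position.as_array() + wb * b.position.as_array()) / (wa + wb)
            merged = KinetochoreSpot(
                spot_id=f"{a.spot_id}+{b.spot_id}",
                oocyte_id=a.oocyte_id,
                bivalent_id=a.bivalent_id,
                homolog_id=a.homolog_id,
                position=Point3.from_array(pos),
                radius=(wa + wb) ** (1.0 / 3.0),
                merged=True,
            )
            detected.append(merged)
            id_map[a.spot_id] = merged.spot_id
            id_map[b.spot_id] = merged.spot_id
        else:
            for s in members:
                detected.append(s)
                id_map[s.spot_id] = s.spot_id
    return detected, id_map


def classify_configuration(pair: SisterPair, model: ResolutionModel) -> str:
    """Four-category sister-pair configuration from detections and radii.

    A single merged detection is ``indistinguishable`` (distance recorded
    as 0 µm).  With two detections at centre distance d and radii r1, r2:
    d below ``overlap_factor*(r1+r2)`` is ``overlapping``, d up to the sum
    of radii (touching) is ``distinct``, beyond that ``separated``.
    """
    if len(pair.spots) == 1:
        return "indistinguishable"
    if len(pair.spots) > 2:
        raise ValidationError("a sister pair cannot have more than 2 detections")
    r_sum = pair.spots[0].radius + pair.spots[1].radius
    d = pair.distance
    if d < model.overlap_factor * r_sum:
        return "overlapping"
    if d <= r_sum:
        return "distinct"
    return "separated"


def is_split(category: str) -> bool:
    """True when the pair shows two discrete spots (distinct or separated)."""
    if category not in ("indistinguishable", "overlapping", "distinct", "separated"):
        raise ValidationError(f"unknown configuration category {category!r}")
    return category in ("distinct", "separated")


def _fiber_directions(
    pair: SisterPair, fibers: Sequence[KFiber]
) -> Dict[str, np.ndarray]:
    pos_by_id = {s.spot_id: s.position.as_array() for s in pair.spots}
    dirs = {}
    for f in fibers:
        if f.kinetochore_id not in pos_by_id:
            raise ValidationError(
                f"fiber {f.fiber_id} references unknown kinetochore "
                f"{f.kinetochore_id!r}"
            )
        dirs[f.fiber_id] = f.pole_endpoint.as_array() - pos_by_id[f.kinetochore_id]
    return dirs


def classify_fiber_topology(
    pair: SisterPair,
    fibers: Sequence[KFiber],
    thresholds: AngleThresholds = AngleThresholds(),
    pole_neighborhood: float = 2.0,
) -> Tuple[int, str]:
    """Count discrete k-fibers on a sister pair and type multi-fiber attachments.

    Type C: branches of one trunk (shared ``trunk_group``).  Type A: separate
    fibers running in parallel to neighbouring endpoints at the same pole.
    Type B: separate fibers from distant locations on the spindle.
    """
    fibers = list(fibers)
    n = len(fibers)
    if n == 0:
        return 0, "none"
    dirs = _fiber_directions(pair, fibers)
    if n == 1:
        return 1, "single"

    trunks = [f.trunk_group for f in fibers]
    if any(t is not None for t in trunks) and len(set(trunks)) == 1:
        return n, "C"

    same_pole = len({f.pole_index for f in fibers}) == 1
    endpoints = [f.pole_endpoint.as_array() for f in fibers]
    max_sep = max(
        float(np.linalg.norm(a - b))
        for i, a in enumerate(endpoints)
        for b in endpoints[i + 1 :]
    )
    max_angle = 0.0
    flist = list(dirs.values())
    for i in range(len(flist)):
        for j in range(i + 1, len(flist)):
            max_angle = max(max_angle, axis_angle(flist[i], flist[j]))
    if same_pole and max_sep <= pole_neighborhood and max_angle <= thresholds.parallel_max:
        return n, "A"
    return n, "B"


@dataclass
class AttachmentCall:
    pair_id: str
    n_fibers: int
    fiber_type: str  # A | B | C | single | none
    mode: str  # amphitelic | merotelic | lateral | unattached


def classify_attachment_mode(
    pair: SisterPair,
    fibers: Sequence[KFiber],
    spindle: Spindle,
    thresholds: AngleThresholds = AngleThresholds(),
    pair_id: str = "",
) -> AttachmentCall:
    """Attachment mode of one sister pair from its k-fiber records.

    Only end-on fibers reaching opposite spindle poles count as merotelic;
    lateral-merotelic contacts are folded into the lateral group.
    """
    fibers = list(fibers)
    _fiber_directions(pair, fibers)  # validates kinetochore references
    n_fibers, fiber_type = classify_fiber_topology(pair, fibers, thresholds)

    end_on_poles = {f.pole_index for f in fibers if f.contact_geometry == "end_on"}
    has_lateral = any(f.contact_geometry == "lateral" for f in fibers)
    if len(end_on_poles) == 2:
        mode = "merotelic"
    elif has_lateral:
        mode = "lateral"
    elif len(end_on_poles) == 1:
        mode = "amphitelic"
    else:
        mode = "unattached"
    return AttachmentCall(
        pair_id=pair_id, n_fibers=n_fibers, fiber_type=fiber_type, mode=mode
    )


@dataclass
class RotationCall:
    bivalent_id: str
    label: str  # in_axis | half_inverted | fully_inverted | ambiguous
    bivalent_axis_angle: float
    pair_axis_angles: Tuple[Optional[float], Optional[float]]
    low_confidence: bool = False


def score_rotation(
    bivalent: Bivalent,
    spindle: Spindle,
    thresholds: AngleThresholds = AngleThresholds(),
) -> RotationCall:
    """Rotation state of a bivalent relative to the spindle axis.

    Uses the bivalent-axis angle beta and the two pair-axis angles.  A pair
    with a merged detection contributes no angle; the call then falls back
    on the bivalent axis plus the remaining pair and is flagged
    low-confidence.
    """
    if bivalent.at_pole:
        raise ValidationError(
            f"bivalent {bivalent.bivalent_id} is at a spindle pole (not under "
            "tension); rotation is not scored"
        )
    baxis = bivalent.bivalent_axis
    if baxis is None:
        raise ValidationError(
            f"bivalent {bivalent.bivalent_id}: coincident pair centroids"
        )
    beta = axis_angle(baxis, spindle.axis)
    angles: List[Optional[float]] = []
    for h in bivalent.homologs:
        ax = h.sister_pair.pair_axis
        angles.append(None if ax is None else axis_angle(ax, spindle.axis))

    par, perp = thresholds.parallel_max, thresholds.perpendicular_min
    defined = [a for a in angles if a is not None]
    low_confidence = len(defined) < 2

    if len(defined) == 2:
        p1, p2 = defined
        if beta >= perp and p1 <= par and p2 <= par:
            label = "fully_inverted"
        elif (p1 <= par and p2 >= perp) or (p2 <= par and p1 >= perp):
            label = "half_inverted"
        elif beta <= par and p1 >= perp and p2 >= perp:
            label = "in_axis"
        else:
            label = "ambiguous"
    elif len(defined) == 1:
        p = defined[0]
        if beta >= perp and p <= par:
            label = "fully_inverted"
        elif beta <= par and p >= perp:
            label = "in_axis"
        elif beta <= par and p <= par:
            label = "half_inverted"
        else:
            label = "ambiguous"
    else:
        if beta <= par:
            label = "in_axis"
        elif beta >= perp:
            label = "fully_inverted"
        else:
            label = "ambiguous"
    return RotationCall(
        bivalent_id=bivalent.bivalent_id,
        label=label,
        bivalent_axis_angle=beta,
        pair_axis_angles=(angles[0], angles[1]),
        low_confidence=low_confidence,
    )


@dataclass
class TwistCall:
    bivalent_id: str
    label: str  # undistorted | twisted | not_scorable
    pair_axis_angle: Optional[float] = None
    ambiguous: bool = False


def score_twist(
    bivalent: Bivalent, thresholds: AngleThresholds = AngleThresholds()
) -> TwistCall:
    """Twist state from the angle between the two sister-pair axes.

    Scorable only when both pairs show a split configuration (pair axes
    determinable); the angle between the pair axes at or above
    ``twist_min`` is twisted, at or below ``parallel_max`` undistorted,
    in between recorded as ambiguous-undistorted.
    """
    pairs = [h.sister_pair for h in bivalent.homologs]
    confs = [p.configuration for p in pairs]
    if any(c is None or not is_split(c) for c in confs):
        return TwistCall(bivalent_id=bivalent.bivalent_id, label="not_scorable")
    ax1, ax2 = pairs[0].pair_axis, pairs[1].pair_axis
    if ax1 is None or ax2 is None:
        return TwistCall(bivalent_id=bivalent.bivalent_id, label="not_scorable")
    tau = axis_angle(ax1, ax2)
    if tau >= thresholds.twist_min:
        return TwistCall(bivalent.bivalent_id, "twisted", tau)
    if tau <= thresholds.parallel_max:
        return TwistCall(bivalent.bivalent_id, "undistorted", tau)
    return TwistCall(bivalent.bivalent_id, "undistorted", tau, ambiguous=True)


def detect_cohesion_state(bivalent: Bivalent) -> Tuple[str, float]:
    """Cohesion state from the chromatin surface gap between homologs.

    The surface gap is the centroid distance minus the two chromatin
    extents; non-positive gaps mean the homolog bodies touch (intact).
    """
    h1, h2 = bivalent.homologs
    g = distance(h1.chromatin_centroid, h2.chromatin_centroid) - (
        h1.chromatin_extent + h2.chromatin_extent
    )
    if g <= 1e-9:
        return "intact", 0.0
    return "weak_gap", float(g)


def identify_univalents(oocyte: Oocyte) -> Tuple[List[Univalent], dict]:
    """Verify chromosome/kinetochore accounting and annotate univalents.

    Checks 2*(#bivalents) + (#univalents) = 46 and flags oocytes whose
    segregation-unit count exceeds 23.  Univalents sharing an origin
    bivalent are annotated proximal/distal by distance to the spindle
    plate centre.
    """
    oocyte.check_accounting()
    univalents = list(oocyte.univalents)
    center = oocyte.spindle.plate_center

    by_origin: Dict[str, List[Univalent]] = {}
    for u in univalents:
        if u.origin_bivalent_id is not None:
            by_origin.setdefault(u.origin_bivalent_id, []).append(u)
    for members in by_origin.values():
        if len(members) == 2:
            d = [distance(m.sister_pair.centroid, center) for m in members]
            order = np.argsort(d)
            members[int(order[0])].position = "proximal"
            members[int(order[1])].position = "distal"

    report = {
        "oocyte_id": oocyte.oocyte_id,
        "n_bivalents": len(oocyte.bivalents),
        "n_univalents": len(univalents),
        "n_units": oocyte.n_units,
        "n_chromosomes": oocyte.n_chromosomes,
        "excess_units": oocyte.n_units > 23,
    }
    return univalents, report


@dataclass
class BiorientationCall:
    bioriented: bool
    low_confidence: bool = False

    def __bool__(self) -> bool:
        return self.bioriented


def univalent_biorientation(
    univalent: Univalent,
    spindle: Spindle,
    fibers: Sequence[KFiber],
    thresholds: AngleThresholds = AngleThresholds(),
) -> BiorientationCall:
    """True when the univalent's sister pair biorients on the spindle.

    Requires the pair axis within ``parallel_max`` of the spindle axis
    (boundary inclusive) and end-on fibers reaching both poles.  A merged
    pair cannot be assessed and returns false, flagged low-confidence.
    """
    pair = univalent.sister_pair
    ax = pair.pair_axis
    if ax is None:
        return BiorientationCall(bioriented=False, low_confidence=True)
    angle = axis_angle(ax, spindle.axis)
    end_on_poles = {f.pole_index for f in fibers if f.contact_geometry == "end_on"}
    ok = angle <= thresholds.parallel_max and end_on_poles == {0, 1}
    return BiorientationCall(bioriented=ok)


@dataclass
class OutcomePrediction:
    bivalent_id: str
    orientation: str
    centromeric_cohesion: Tuple[str, str]
    predicted_products: Tuple[str, ...]  # multiset of chromosome | chromatid
    predicted_event: str

    @property
    def chromatid_count(self) -> int:
        return sum(2 if p == "chromosome" else 1 for p in self.predicted_products)


_ORIENTATIONS = ("in_axis", "half_inverted", "fully_inverted")
_COHESION = ("intact", "compromised")


def predict_segregation_outcome(
    orientation: str,
    cohesion_states: Tuple[str, str],
    bivalent_id: str = "",
) -> OutcomePrediction:
    """Deterministic anaphase-I outcome table for one bivalent.

    In-axis bivalents disjoin normally regardless of centromeric cohesion.
    Rotated (half- or fully-inverted) bivalents: both centromeres intact ->
    the bivalent lags; one compromised -> one univalent plus two sister
    chromatids; both compromised -> four individual chromatids and reverse
    segregation.  Products always total four chromatids.
    """
    if orientation not in _ORIENTATIONS:
        raise ValidationError(f"unknown orientation {orientation!r}")
    cohesion_states = tuple(cohesion_states)
    if len(cohesion_states) != 2 or any(c not in _COHESION for c in cohesion_states):
        raise ValidationError(f"bad centromeric cohesion states {cohesion_states!r}")

    n_comp = sum(c == "compromised" for c in cohesion_states)
    if orientation == "in_axis":
        products = ("chromosome", "chromosome")
        event = "normal_disjunction"
    elif n_comp == 0:
        products = ("chromosome", "chromosome")
        event = "lagging"
    elif n_comp == 1:
        products = ("chromosome", "chromatid", "chromatid")
        event = "univalent_plus_chromatids"
    else:
        products = ("chromatid",) * 4
        event = "reverse_segregation"
    return OutcomePrediction(
        bivalent_id=bivalent_id,
        orientation=orientation,
        centromeric_cohesion=cohesion_states,
        predicted_products=products,
        predicted_event=event,
    )


def is_at_pole(bivalent: Bivalent, spindle: Spindle, fraction: float = 0.1) -> bool:
    """Pole proximity: any pair centroid within ``fraction`` of the spindle
    length from a pole (such bivalents are not under tension and are
    excluded from configuration statistics)."""
    limit = fraction * spindle.length
    for h in bivalent.homologs:
        c = h.sister_pair.centroid
        if min(distance(c, p) for p in spindle.pole_positions) <= limit:
            return True
    return False
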