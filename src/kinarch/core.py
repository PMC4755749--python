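"""Domain model and 3D geometry primitives.

All coordinates are world coordinates in micrometres (µm); all angles are
reported in degrees.  Directions ("axes") are undirected: every angle
between axes lies in [0, 90].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "Point3",
    "KinetochoreSpot",
    "SisterPair",
    "Bivalent",
    "Homolog",
    "Univalent",
    "KFiber",
    "Spindle",
    "Oocyte",
    "TimelapseRecord",
    "distance",
    "axis_angle",
    "assign_sister_pairs",
    "severity_from_misaligned",
    "MI_CHROMOSOME_COUNT",
]

#: Chromosome count of a human oocyte in meiosis I.
MI_CHROMOSOME_COUNT = 46

#: Tolerance used when breaking distance ties in sister-pair assignment.
PAIRING_TIE_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when model invariants or operation preconditions are violated."""


@dataclass(frozen=True)
class Point3:
    """A point in 3D world coordinates (µm)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for c in (self.x, self.y, self.z):
            if not math.isfinite(c):
                raise ValidationError(f"non-finite coordinate in Point3: {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a: Sequence[float]) -> "Point3":
        a = np.asarray(a, dtype=float)
        return Point3(float(a[0]), float(a[1]), float(a[2]))


def distance(p: Point3, q: Point3) -> float:
    """Euclidean distance between two points, in µm.

    Uses ``math.dist`` (scaled algorithm: no under/overflow of squared
    terms).
    """
    return math.dist((p.x, p.y, p.z), (q.x, q.y, q.z))


def axis_angle(u: Sequence[float], v: Sequence[float]) -> float:
    """Angle between two undirected axes, in degrees within [0, 90].

    Sign-invariant: ``axis_angle(u, v) == axis_angle(-u, v)``.

    Raises
    ------
    ValidationError
        If either vector is (numerically) zero or non-finite.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValidationError("non-finite direction vector")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValidationError("zero direction vector has no axis angle")
    c = abs(float(np.dot(u, v))) / (nu * nv)
    c = min(1.0, c)
    return math.degrees(math.acos(c))


@dataclass
class KinetochoreSpot:
    """A detected kinetochore centroid.

    ``merged`` marks a single detection standing in for two sub-resolution
    sister kinetochores; merged spots carry no within-homolog sister
    distinction.
    """

    spot_id: str
    oocyte_id: str
    bivalent_id: str
    homolog_id: int
    position: Point3
    radius: float = 0.4
    merged: bool = False

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValidationError(f"spot {self.spot_id}: radius must be > 0")
        if self.homolog_id not in (1, 2):
            raise ValidationError(f"spot {self.spot_id}: homolog_id must be 1 or 2")


# Configuration categories, ordered by increasing separation.
CONFIGURATIONS = ("indistinguishable", "overlapping", "distinct", "separated")


@dataclass
class SisterPair:
    """One or two sister-kinetochore detections and their geometry.

    A single (merged) detection means the pair is optically unresolvable:
    its configuration is ``indistinguishable`` and its distance is recorded
    as 0 µm.  For two detections the distance is the Euclidean distance of
    the centres and ``pair_axis`` is the unit direction joining them.
    """

    spots: tuple
    configuration: Optional[str] = None

    def __post_init__(self) -> None:
        n = len(self.spots)
        if n not in (1, 2):
            raise ValidationError(f"SisterPair needs 1 or 2 spots, got {n}")
        if n == 1 and not self.spots[0].merged:
            raise ValidationError("single-spot pair requires a merged detection")

    @property
    def distance(self) -> float:
        if len(self.spots) == 1:
            return 0.0
        return distance(self.spots[0].position, self.spots[1].position)

    @property
    def pair_axis(self) -> Optional[np.ndarray]:
        """Unit direction joining the two spots; None for a merged pair."""
        if len(self.spots) == 1:
            return None
        d = self.spots[1].position.as_array() - self.spots[0].position.as_array()
        n = np.linalg.norm(d)
        if n == 0.0:
            return None
        return d / n

    @property
    def centroid(self) -> Point3:
        arr = np.mean([s.position.as_array() for s in self.spots], axis=0)
        return Point3.from_array(arr)

    @property
    def is_merged(self) -> bool:
        return len(self.spots) == 1


@dataclass
class Homolog:
    """One homologous chromosome of a bivalent (or the body of a univalent)."""

    sister_pair: SisterPair
    chromatin_centroid: Point3
    chromatin_extent: float

    def __post_init__(self) -> None:
        if not (self.chromatin_extent > 0):
            raise ValidationError("chromatin_extent must be > 0")


@dataclass
class Bivalent:
    """Two homologs linked by cohesion, carrying two sister-kinetochore pairs."""

    bivalent_id: str
    homologs: tuple  # (Homolog, Homolog)
    cohesion_state: str = "intact"  # intact | weak_gap | disintegrated
    gap: float = 0.0
    at_pole: bool = False

    def __post_init__(self) -> None:
        if len(self.homologs) != 2:
            raise ValidationError("Bivalent requires exactly 2 homologs")
        if (self.gap == 0.0) != (self.cohesion_state == "intact"):
            raise ValidationError(
                f"bivalent {self.bivalent_id}: gap={self.gap} inconsistent with "
                f"cohesion_state={self.cohesion_state!r}"
            )

    @property
    def bivalent_axis(self) -> Optional[np.ndarray]:
        """Unit direction joining the two sister-pair centroids."""
        c0 = self.homologs[0].sister_pair.centroid.as_array()
        c1 = self.homologs[1].sister_pair.centroid.as_array()
        d = c1 - c0
        n = np.linalg.norm(d)
        if n == 0.0:
            return None
        return d / n

    @property
    def centroid(self) -> Point3:
        c0 = self.homologs[0].sister_pair.centroid.as_array()
        c1 = self.homologs[1].sister_pair.centroid.as_array()
        return Point3.from_array((c0 + c1) / 2.0)


@dataclass
class Univalent:
    """A single chromosome produced by precocious bivalent disintegration."""

    univalent_id: str
    homolog: Homolog
    origin_bivalent_id: Optional[str] = None
    position: Optional[str] = None  # proximal | distal (relative to partner)
    bioriented: Optional[bool] = None

    @property
    def sister_pair(self) -> SisterPair:
        return self.homolog.sister_pair


@dataclass
class KFiber:
    """A cold-stable microtubule bundle linking a kinetochore to a pole region.

    Branches of a single trunk share ``trunk_group``.
    """

    fiber_id: str
    kinetochore_id: str
    pole_index: int
    pole_endpoint: Point3
    contact_geometry: str = "end_on"  # end_on | lateral
    trunk_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pole_index not in (0, 1):
            raise ValidationError(f"fiber {self.fiber_id}: pole_index must be 0 or 1")
        if self.contact_geometry not in ("end_on", "lateral"):
            raise ValidationError(
                f"fiber {self.fiber_id}: bad contact_geometry {self.contact_geometry!r}"
            )


@dataclass
class Spindle:
    pole_positions: tuple  # (Point3, Point3)

    def __post_init__(self) -> None:
        if len(self.pole_positions) != 2:
            raise ValidationError("Spindle requires exactly 2 poles")
        if distance(*self.pole_positions) == 0.0:
            raise ValidationError("spindle poles must be distinct")

    @property
    def axis(self) -> np.ndarray:
        d = self.pole_positions[1].as_array() - self.pole_positions[0].as_array()
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return distance(*self.pole_positions)

    @property
    def plate_center(self) -> Point3:
        a = self.pole_positions[0].as_array()
        b = self.pole_positions[1].as_array()
        return Point3.from_array((a + b) / 2.0)


@dataclass
class Oocyte:
    oocyte_id: str
    donor_age: float
    spindle: Spindle
    bivalents: list = field(default_factory=list)
    univalents: list = field(default_factory=list)
    fibers: list = field(default_factory=list)
    stage: str = "MI"
    cold_treated: bool = False

    @property
    def n_chromosomes(self) -> int:
        return 2 * len(self.bivalents) + len(self.univalents)

    @property
    def n_units(self) -> int:
        """Number of segregation units (bivalents + univalents)."""
        return len(self.bivalents) + len(self.univalents)

    def check_accounting(self) -> None:
        """Verify the MI chromosome-count invariant (46 chromosomes)."""
        if self.stage != "MI":
            return
        if self.n_chromosomes != MI_CHROMOSOME_COUNT:
            raise ValidationError(
                f"oocyte {self.oocyte_id}: 2*{len(self.bivalents)} bivalents + "
                f"{len(self.univalents)} univalents = {self.n_chromosomes} "
                f"chromosomes, expected {MI_CHROMOSOME_COUNT}"
            )

    def all_pairs(self) -> list:
        pairs = [h.sister_pair for b in self.bivalents for h in b.homologs]
        pairs.extend(u.sister_pair for u in self.univalents)
        return pairs


def severity_from_misaligned(n_misaligned: int) -> str:
    """Severity category from the misaligned-chromosome count at anaphase onset."""
    if n_misaligned < 0:
        raise ValidationError("misaligned count cannot be negative")
    if n_misaligned == 0:
        return "none"
    if n_misaligned <= 3:
        return "mild"
    return "severe"


@dataclass
class TimelapseRecord:
    """Per-oocyte live-imaging event record; times are hours relative to NEBD.

    Anaphase onset is the time point 10 min before the first observed
    chromosome separation; it is absent for oocytes that never progressed.
    """

    oocyte_id: str
    t_nebd: float = 0.0
    t_congression: Optional[float] = None
    t_anaphase_onset: Optional[float] = None
    n_misaligned_at_anaphase: int = 0
    lagging: bool = False
    progressed: bool = True

    @property
    def severity(self) -> str:
        return severity_from_misaligned(self.n_misaligned_at_anaphase)


def _pair_from_spots(a: KinetochoreSpot, b: KinetochoreSpot) -> SisterPair:
    return SisterPair(spots=(a, b))


def assign_sister_pairs(spots: Sequence[KinetochoreSpot]):
    """Group the kinetochore spots of one bivalent into two sister pairs.

    The two most proximal spots form the first sister pair; the remaining
    two form the second.  Ties (within 1e-9 µm) are broken toward the
    lexicographically smallest ``(spot_id, spot_id)`` tuple for determinism.
    Homolog labels on the returned spots are reassigned so that the first
    pair is homolog 1 and the second homolog 2.

    With merged detections (fewer than 4 spots) pairs are formed from the
    merged spots directly.

    Raises
    ------
    ValidationError
        If spots span multiple bivalents, more than 4 spots are given, or
        an unmerged set does not contain exactly 4 spots.
    """
    spots = list(spots)
    if not spots:
        raise ValidationError("no spots to pair")
    biv_ids = {s.bivalent_id for s in spots}
    if len(biv_ids) != 1:
        raise ValidationError(f"spots span multiple bivalents: {sorted(biv_ids)}")
    if len(spots) > 4:
        raise ValidationError(f"expected at most 4 spots per bivalent, got {len(spots)}")

    merged = [s for s in spots if s.merged]
    unmerged = [s for s in spots if not s.merged]

    if merged:
        # Each merged detection is a whole pair; leftover unmerged spots
        # (if any) form the other pair.
        if len(merged) == 2 and not unmerged:
            pairs = (SisterPair(spots=(merged[0],)), SisterPair(spots=(merged[1],)))
        elif len(merged) == 1 and len(unmerged) == 2:
            pairs = (SisterPair(spots=(merged[0],)), _pair_from_spots(*unmerged))
        else:
            raise ValidationError(
                f"cannot pair {len(merged)} merged + {len(unmerged)} unmerged spots"
            )
        _relabel_homologs(pairs)
        return pairs

    if len(spots) != 4:
        raise ValidationError(f"expected 4 unmerged spots, got {len(spots)}")

    best = None
    for i, j in combinations(range(4), 2):
        d = distance(spots[i].position, spots[j].position)
        key_ids = tuple(sorted((spots[i].spot_id, spots[j].spot_id)))
        if best is None or d < best[0] - PAIRING_TIE_TOL or (
            abs(d - best[0]) <= PAIRING_TIE_TOL and key_ids < best[1]
        ):
            best = (d, key_ids, (i, j))
    i, j = best[2]
    rest = [k for k in range(4) if k not in (i, j)]
    pairs = (
        _pair_from_spots(spots[i], spots[j]),
        _pair_from_spots(spots[rest[0]], spots[rest[1]]),
    )
    _relabel_homologs(pairs)
    return pairs


def _relabel_homologs(pairs: Iterable[SisterPair]) -> None:
    for label, pair in zip((1, 2), pairs):
        for s in pair.spots:
            s.homolog_id = label
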