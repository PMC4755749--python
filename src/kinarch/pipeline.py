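"""Cohort-level classification: tables -> oocyte models -> per-unit calls.

The entry points consume the tidy tables produced by the generator (or read
from disk) and emit one result row per sister pair and per segregation
unit, plus the figure-level summary tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .classify import (
    AngleThresholds,
    ResolutionModel,
    classify_attachment_mode,
    classify_configuration,
    detect_cohesion_state,
    identify_univalents,
    is_at_pole,
    is_split,
    score_rotation,
    score_twist,
    univalent_biorientation,
)
from .core import (
    Bivalent,
    Homolog,
    KFiber,
    KinetochoreSpot,
    Oocyte,
    Point3,
    SisterPair,
    Spindle,
    ValidationError,
    assign_sister_pairs,
    distance,
)
from .stats import assign_age_group, frequency_table

logger = logging.getLogger("kinarch")

__all__ = ["classify_cohort", "summarize_cohort", "render_report"]

_UNIVALENT_ID = re.compile(r"^(?P<origin>.+-b\d+)-u\d+$")


def _spot_from_row(row) -> KinetochoreSpot:
    return KinetochoreSpot(
        spot_id=row.spot_id,
        oocyte_id=row.oocyte_id,
        bivalent_id=row.unit_id,
        homolog_id=int(row.homolog_id),
        position=Point3(float(row.x_um), float(row.y_um), float(row.z_um)),
        radius=float(row.radius_um),
        merged=bool(row.merged),
    )


def _build_oocyte(
    oo_row,
    spots: pd.DataFrame,
    fibers: pd.DataFrame,
    chromatin: pd.DataFrame,
) -> Tuple[Oocyte, Dict[str, int], Dict[str, bool]]:
    """Reconstruct one oocyte; also returns per-spot original homolog labels
    and per-spot resolution-confidence flags."""
    spindle = Spindle(
        pole_positions=(
            Point3(oo_row.pole0_x_um, oo_row.pole0_y_um, oo_row.pole0_z_um),
            Point3(oo_row.pole1_x_um, oo_row.pole1_y_um, oo_row.pole1_z_um),
        )
    )
    oocyte = Oocyte(
        oocyte_id=oo_row.oocyte_id,
        donor_age=float(oo_row.donor_age_years),
        spindle=spindle,
        stage=str(oo_row.stage),
        cold_treated=bool(oo_row.cold_treated),
    )

    orig_homolog: Dict[str, int] = {}
    confident: Dict[str, bool] = {}
    spot_objs: Dict[str, List[KinetochoreSpot]] = {}
    for row in spots.itertuples(index=False):
        s = _spot_from_row(row)
        orig_homolog[s.spot_id] = s.homolog_id
        confident[s.spot_id] = bool(getattr(row, "resolved_confident", True))
        spot_objs.setdefault(row.unit_id, []).append(s)

    chrom_by_unit: Dict[str, list] = {}
    for row in chromatin.itertuples(index=False):
        chrom_by_unit.setdefault(row.unit_id, []).append(row)

    for unit_id in sorted(chrom_by_unit):
        chroms = chrom_by_unit[unit_id]
        unit_spots = spot_objs.get(unit_id, [])
        if not unit_spots:
            raise ValidationError(f"unit {unit_id}: chromatin without spots")
        if len(chroms) == 2:
            pairs = assign_sister_pairs(unit_spots)
            homologs = _match_homologs(pairs, chroms)
            biv = Bivalent(bivalent_id=unit_id, homologs=homologs)
            state, gap = detect_cohesion_state(biv)
            biv.cohesion_state, biv.gap = state, gap
            biv.at_pole = is_at_pole(biv, spindle)
            oocyte.bivalents.append(biv)
        elif len(chroms) == 1:
            if len(unit_spots) == 2:
                pair = SisterPair(spots=tuple(sorted(unit_spots, key=lambda s: s.spot_id)))
            elif len(unit_spots) == 1:
                pair = SisterPair(spots=(unit_spots[0],))
            else:
                raise ValidationError(
                    f"univalent {unit_id} has {len(unit_spots)} spots"
                )
            ch = chroms[0]
            hom = Homolog(
                sister_pair=pair,
                chromatin_centroid=Point3(ch.x_um, ch.y_um, ch.z_um),
                chromatin_extent=float(ch.extent_um),
            )
            m = _UNIVALENT_ID.match(unit_id)
            from .core import Univalent

            oocyte.univalents.append(
                Univalent(
                    univalent_id=unit_id,
                    homolog=hom,
                    origin_bivalent_id=m.group("origin") if m else None,
                )
            )
        else:
            raise ValidationError(
                f"unit {unit_id}: {len(chroms)} chromatin bodies (expected 1 or 2)"
            )

    fiber_objs = []
    known_ids = set(orig_homolog)
    for row in fibers.itertuples(index=False):
        if row.kinetochore_spot_id not in known_ids:
            raise ValidationError(
                f"fiber {row.fiber_id} references unknown kinetochore "
                f"{row.kinetochore_spot_id!r}"
            )
        trunk = row.trunk_group if isinstance(row.trunk_group, str) and row.trunk_group else None
        fiber_objs.append(
            KFiber(
                fiber_id=row.fiber_id,
                kinetochore_id=row.kinetochore_spot_id,
                pole_index=int(row.pole_index),
                pole_endpoint=Point3(row.x_um, row.y_um, row.z_um),
                contact_geometry=row.contact_geometry,
                trunk_group=trunk,
            )
        )
    oocyte.fibers = fiber_objs
    return oocyte, orig_homolog, confident


def _match_homologs(pairs, chroms) -> tuple:
    """Pair each sister pair with the chromatin body on its side."""
    c0 = np.array([chroms[0].x_um, chroms[0].y_um, chroms[0].z_um])
    c1 = np.array([chroms[1].x_um, chroms[1].y_um, chroms[1].z_um])
    p0 = pairs[0].centroid.as_array()
    p1 = pairs[1].centroid.as_array()
    straight = np.linalg.norm(p0 - c0) + np.linalg.norm(p1 - c1)
    crossed = np.linalg.norm(p0 - c1) + np.linalg.norm(p1 - c0)
    order = (chroms[0], chroms[1]) if straight <= crossed else (chroms[1], chroms[0])
    return tuple(
        Homolog(
            sister_pair=pair,
            chromatin_centroid=Point3(ch.x_um, ch.y_um, ch.z_um),
            chromatin_extent=float(ch.extent_um),
        )
        for pair, ch in zip(pairs, order)
    )


def classify_cohort(
    oocytes: pd.DataFrame,
    spots: pd.DataFrame,
    fibers: pd.DataFrame,
    chromatin: pd.DataFrame,
    thresholds: AngleThresholds = AngleThresholds(),
    resolution: ResolutionModel = ResolutionModel(),
    at_pole_fraction: float = 0.1,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every oocyte in the cohort tables.

    Returns (pair_results, unit_results).  ``pair_index`` preserves the
    input homolog labels so results stay joinable to a generator truth
    table; pairing itself uses only geometry within each labelled unit.
    """
    pair_rows: List[dict] = []
    unit_rows: List[dict] = []
    empty = pd.DataFrame(
        columns=["oocyte_id", "fiber_id", "kinetochore_spot_id", "pole_index",
                 "x_um", "y_um", "z_um", "contact_geometry", "trunk_group"]
    )
    for oo_row in oocytes.itertuples(index=False):
        oid = oo_row.oocyte_id
        osp = spots[spots["oocyte_id"] == oid]
        ofb = fibers[fibers["oocyte_id"] == oid] if len(fibers) else empty
        och = chromatin[chromatin["oocyte_id"] == oid]
        oocyte, orig_homolog, confident = _build_oocyte(oo_row, osp, ofb, och)
        oocyte.check_accounting()

        fibers_by_spot: Dict[str, list] = {}
        for f in oocyte.fibers:
            fibers_by_spot.setdefault(f.kinetochore_id, []).append(f)

        univalents, account = identify_univalents(oocyte)
        n_in, n_excluded = 0, 0

        def pair_fibers(pair) -> list:
            out = []
            for s in pair.spots:
                out.extend(fibers_by_spot.get(s.spot_id, []))
            return out

        def emit_pair(pair, unit_id, unit_type, at_pole) -> dict:
            cat = classify_configuration(pair, resolution)
            pair.configuration = cat
            pf = pair_fibers(pair)
            mode, n_f, f_type = "", 0, ""
            if oocyte.cold_treated and not at_pole:
                call = classify_attachment_mode(
                    pair, pf, oocyte.spindle, thresholds, pair_id=unit_id
                )
                mode, n_f, f_type = call.mode, call.n_fibers, call.fiber_type
            res_conf = all(confident.get(s.spot_id, True) for s in pair.spots)
            row = {
                "oocyte_id": oid,
                "unit_id": unit_id,
                "pair_index": orig_homolog[pair.spots[0].spot_id],
                "unit_type": unit_type,
                "configuration": cat,
                "distance_um": pair.distance,
                "split": is_split(cat),
                "attachment_mode": mode,
                "n_fibers": n_f,
                "fiber_type": f_type,
                "at_pole": at_pole,
                "resolved_confident": res_conf,
                "excluded": at_pole or not res_conf,
            }
            pair_rows.append(row)
            return row

        for biv in oocyte.bivalents:
            biv.at_pole = is_at_pole(biv, oocyte.spindle, at_pole_fraction)
            for pair in (h.sister_pair for h in biv.homologs):
                r = emit_pair(pair, biv.bivalent_id, "bivalent", biv.at_pole)
                n_excluded += r["excluded"]
                n_in += 1
            rot_label, beta, p_angles, low_conf = "", np.nan, (np.nan, np.nan), False
            twist_label, tau = "not_scorable", np.nan
            if not biv.at_pole:
                rot = score_rotation(biv, oocyte.spindle, thresholds)
                rot_label, beta, low_conf = rot.label, rot.bivalent_axis_angle, rot.low_confidence
                p_angles = tuple(
                    np.nan if a is None else a for a in rot.pair_axis_angles
                )
                if rot_label == "in_axis":
                    tw = score_twist(biv, thresholds)
                    twist_label = tw.label
                    tau = np.nan if tw.pair_axis_angle is None else tw.pair_axis_angle
            unit_rows.append(
                {
                    "oocyte_id": oid,
                    "unit_id": biv.bivalent_id,
                    "unit_type": "bivalent",
                    "at_pole": biv.at_pole,
                    "rotation": rot_label,
                    "bivalent_axis_angle_deg": beta,
                    "pair1_axis_angle_deg": p_angles[0],
                    "pair2_axis_angle_deg": p_angles[1],
                    "rotation_low_confidence": low_conf,
                    "twist": twist_label,
                    "twist_angle_deg": tau,
                    "cohesion_state": biv.cohesion_state,
                    "gap_um": biv.gap,
                    "origin_bivalent_id": "",
                    "univalent_position": "",
                    "bioriented": "",
                }
            )

        for uni in univalents:
            emit_pair(uni.sister_pair, uni.univalent_id, "univalent", False)
            call = univalent_biorientation(
                uni, oocyte.spindle, pair_fibers(uni.sister_pair), thresholds
            )
            uni.bioriented = bool(call)
            unit_rows.append(
                {
                    "oocyte_id": oid,
                    "unit_id": uni.univalent_id,
                    "unit_type": "univalent",
                    "at_pole": False,
                    "rotation": "",
                    "bivalent_axis_angle_deg": np.nan,
                    "pair1_axis_angle_deg": np.nan,
                    "pair2_axis_angle_deg": np.nan,
                    "rotation_low_confidence": False,
                    "twist": "",
                    "twist_angle_deg": np.nan,
                    "cohesion_state": "disintegrated",
                    "gap_um": 0.0,
                    "origin_bivalent_id": uni.origin_bivalent_id or "",
                    "univalent_position": uni.position or "",
                    "bioriented": bool(uni.bioriented),
                }
            )
        logger.info(
            "oocyte %s: %d units (%d bivalents, %d univalents), "
            "%d pairs in, %d excluded (at-pole or unresolved)",
            oid, account["n_units"], account["n_bivalents"],
            account["n_univalents"], n_in, n_excluded,
        )
    return pd.DataFrame(pair_rows), pd.DataFrame(unit_rows)


# ---------------------------------------------------------------------------
# summaries


def _unified_stratum(cat: str) -> str:
    return "unified" if cat in ("indistinguishable", "overlapping") else cat


def summarize_cohort(
    pair_results: pd.DataFrame,
    unit_results: pd.DataFrame,
    oocytes: pd.DataFrame,
) -> Dict[str, pd.DataFrame]:
    """Figure-level summary tables, each carrying integer counts.

    Configuration/attachment statistics cover bivalent sister pairs that
    are neither at a spindle pole nor flagged unresolvable; twist
    frequencies cover in-axis bivalents scorable for twist; disintegration
    is reported per bivalent slot (a univalent pair occupies one slot).
    """
    ages = oocytes.set_index("oocyte_id")["donor_age_years"]
    groups = ages.map(assign_age_group)

    pr = pair_results.copy()
    pr["age_group"] = pr["oocyte_id"].map(groups)
    ur = unit_results.copy()
    ur["age_group"] = ur["oocyte_id"].map(groups)

    incl = pr[(pr["unit_type"] == "bivalent") & ~pr["excluded"]]

    out: Dict[str, pd.DataFrame] = {}
    out["configuration_freq"] = frequency_table(incl["configuration"], incl["age_group"])

    split_rows = []
    for g, sub in incl.groupby("age_group"):
        split_rows.append(
            {
                "age_group": g,
                "n_split": int(sub["split"].sum()),
                "n_total": len(sub),
                "split_pct": 100.0 * sub["split"].mean() if len(sub) else np.nan,
                "mean_distance_um": sub["distance_um"].mean(),
            }
        )
    split_rows.append(
        {
            "age_group": "all",
            "n_split": int(incl["split"].sum()),
            "n_total": len(incl),
            "split_pct": 100.0 * incl["split"].mean() if len(incl) else np.nan,
            "mean_distance_um": incl["distance_um"].mean(),
        }
    )
    out["split_summary"] = pd.DataFrame(split_rows)

    att = incl[incl["attachment_mode"] != ""]
    if len(att):
        strata = att["configuration"].map(_unified_stratum)
        out["attachment_by_configuration"] = frequency_table(
            att["attachment_mode"], strata
        )
        out["attachment_by_age"] = frequency_table(
            att["attachment_mode"], att["age_group"]
        )
        split_att = att[att["split"] & (att["n_fibers"] >= 1)]
        out["fiber_count_split"] = frequency_table(
            (split_att["n_fibers"] >= 2).map({True: "two_fibers", False: "one_fiber"})
        )

    biv_units = ur[(ur["unit_type"] == "bivalent") & ~ur["at_pole"]]
    if len(biv_units):
        rot = biv_units[biv_units["rotation"] != ""]
        out["rotation_freq"] = frequency_table(rot["rotation"])
        inv = rot["rotation"].isin(["half_inverted", "fully_inverted"])
        per_oo = rot.assign(inverted=inv).groupby("oocyte_id")["inverted"].any()
        out["inverted_oocytes"] = pd.DataFrame(
            [
                {
                    "n_oocytes_with_inverted": int(per_oo.sum()),
                    "n_oocytes": len(per_oo),
                    "pct": 100.0 * per_oo.mean(),
                }
            ]
        )
        scorable = biv_units[biv_units["twist"].isin(["twisted", "undistorted"])]
        out["twist_freq"] = frequency_table(scorable["twist"])

    # cohesion per bivalent slot: a univalent pair occupies one slot
    n_biv = int((ur["unit_type"] == "bivalent").sum())
    n_uni = int((ur["unit_type"] == "univalent").sum())
    n_weak = int((ur["cohesion_state"] == "weak_gap").sum())
    n_slots = n_biv + n_uni // 2
    out["cohesion_freq"] = pd.DataFrame(
        [
            {"state": "intact", "count": n_biv - n_weak, "total": n_slots},
            {"state": "weak_gap", "count": n_weak, "total": n_slots},
            {"state": "disintegrated", "count": n_uni // 2, "total": n_slots},
        ]
    ).assign(pct=lambda d: 100.0 * d["count"] / d["total"])

    uni = ur[ur["unit_type"] == "univalent"]
    if len(uni):
        bio = uni["bioriented"].astype(bool)
        out["univalent_biorientation"] = pd.DataFrame(
            [
                {
                    "n_bioriented": int(bio.sum()),
                    "n_univalents": len(uni),
                    "pct": 100.0 * bio.mean(),
                }
            ]
        )
    per_oo_uni = ur.assign(u=ur["unit_type"] == "univalent").groupby(
        ["age_group", "oocyte_id"]
    )["u"].any().reset_index()
    rows = []
    for g, sub in per_oo_uni.groupby("age_group"):
        rows.append(
            {
                "age_group": g,
                "n_with_univalents": int(sub["u"].sum()),
                "n_oocytes": len(sub),
                "pct": 100.0 * sub["u"].mean(),
            }
        )
    out["univalent_oocytes"] = pd.DataFrame(rows)
    return out


def render_report(tables: Dict[str, pd.DataFrame]) -> str:
    """Human-readable text report; every percentage sits beside its
    integer numerator/denominator."""
    lines = []
    for name in sorted(tables):
        lines.append(f"== {name} ==")
        lines.append(tables[name].to_string(index=False))
        lines.append("")
    return "\n".join(lines)
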