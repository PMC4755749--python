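"""Frequency tables, exact and t tests, age-trend regression and
anaphase-timing summaries.

All percentages in the summary report are backed by integer numerators and
denominators carried in the same table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError

__all__ = [
    "AGE_GROUPS",
    "assign_age_group",
    "ContingencyTable2x2",
    "frequency_table",
    "fisher_exact_2x2",
    "t_test_two_tailed",
    "age_trend",
    "anaphase_summary",
    "benjamini_hochberg",
]

# Age bins: the boundary at exactly 35 belongs to the middle bin.
AGE_GROUPS = (
    ("under30", 0.0, 30.0),      # [0, 30)
    ("from30to35", 30.0, 35.0),  # [30, 35]
    ("over35", 35.0, math.inf),  # (35, inf)
)


def assign_age_group(age: float) -> str:
    if age < 30.0:
        return "under30"
    if age <= 35.0:
        return "from30to35"
    return "over35"


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValidationError("contingency counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def frequency_table(
    labels: Sequence, group_by: Optional[Sequence] = None
) -> pd.DataFrame:
    """Counts and proportions of labels, optionally per group.

    Proportions sum to 1 within each group; empty groups get count 0 and a
    NaN proportion (flagged ``undefined``).
    """
    df = pd.DataFrame({"label": list(labels)})
    df["group"] = list(group_by) if group_by is not None else "all"
    rows = []
    all_labels = sorted(df["label"].unique(), key=str)
    for g, sub in df.groupby("group", sort=True):
        n = len(sub)
        for lab in all_labels:
            k = int((sub["label"] == lab).sum())
            rows.append(
                {
                    "group": g,
                    "label": lab,
                    "count": k,
                    "total": n,
                    "proportion": k / n if n else float("nan"),
                    "undefined": n == 0,
                }
            )
    return pd.DataFrame(rows)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Sums hypergeometric probabilities (margins fixed) of every table at
    most as probable as the observed one, with 1e-12 relative slack on the
    comparison.
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=float)
        if arr.shape != (2, 2) or np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValidationError("need a 2x2 table of non-negative integers")
        arr = arr.astype(int)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0:
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = float(sps.hypergeom.pmf(a, n, c1, r1))
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, p)


def t_test_two_tailed(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    welch: bool = False,
) -> Tuple[float, float, float]:
    """Two-sample t test, two-tailed; pooled variance by default (Student),
    Welch behind a flag.  Returns (t, dof, p).

    Degenerate zero-variance input: equal means give p = 1; unequal means
    give the p -> 0 limit.
    """
    x = np.asarray(sample_a, dtype=float)
    y = np.asarray(sample_b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    dm = x.mean() - y.mean()
    if vx == 0.0 and vy == 0.0:
        if dm == 0.0:
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return math.copysign(math.inf, dm), float(len(x) + len(y) - 2), 0.0
    if welch:
        se2x, se2y = vx / len(x), vy / len(y)
        t = dm / math.sqrt(se2x + se2y)
        dof = (se2x + se2y) ** 2 / (
            se2x**2 / (len(x) - 1) + se2y**2 / (len(y) - 1)
        )
    else:
        dof = len(x) + len(y) - 2
        sp2 = ((len(x) - 1) * vx + (len(y) - 1) * vy) / dof
        t = dm / math.sqrt(sp2 * (1.0 / len(x) + 1.0 / len(y)))
    p = 2.0 * float(sps.t.sf(abs(t), dof))
    return float(t), float(dof), min(1.0, p)


def age_trend(
    mean_distances: Sequence[float], ages: Sequence[float]
) -> Tuple[float, float, float]:
    """OLS of per-oocyte mean sister distance on donor age.

    Returns (slope µm/year, intercept µm, Pearson r).
    """
    d = np.asarray(mean_distances, dtype=float)
    a = np.asarray(ages, dtype=float)
    if len(d) != len(a) or len(d) < 3:
        raise ValidationError("need >= 3 paired (age, distance) observations")
    if np.ptp(a) == 0.0:
        raise ValidationError("constant age: trend is not identifiable")
    res = sps.linregress(a, d)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted p values (optional; off by default in reports)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


def anaphase_summary(records: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Per-severity progression efficiency and NEBD-relative onset timing.

    ``records`` follows the time-lapse table schema.  Records without a
    NEBD time are excluded (counted in the report).
    """
    req = {"severity", "progressed", "t_anaphase_onset_h", "t_nebd_h", "lagging",
           "t_congression_h"}
    missing = req - set(records.columns)
    if missing:
        raise ValidationError(f"time-lapse table lacks columns: {sorted(missing)}")
    valid = records[records["t_nebd_h"].notna()].copy()
    n_excluded = len(records) - len(valid)

    eff_rows = []
    for sev in ("none", "mild", "severe"):
        sub = valid[valid["severity"] == sev]
        n = len(sub)
        k = int(sub["progressed"].sum())
        eff_rows.append(
            {
                "severity": sev,
                "n_progressed": k,
                "n_total": n,
                "efficiency": k / n if n else float("nan"),
            }
        )
    efficiency = pd.DataFrame(eff_rows)

    prog = valid[valid["progressed"] & valid["t_anaphase_onset_h"].notna()]
    timing_rows = []
    for sev in ("none", "mild", "severe"):
        t = prog.loc[prog["severity"] == sev, "t_anaphase_onset_h"]
        timing_rows.append(
            {
                "stratum": f"severity={sev}",
                "n": len(t),
                "onset_mean_h": t.mean() if len(t) else float("nan"),
                "onset_sd_h": t.std(ddof=1) if len(t) > 1 else float("nan"),
            }
        )
    for flag in (False, True):
        t = prog.loc[prog["lagging"] == flag, "t_anaphase_onset_h"]
        timing_rows.append(
            {
                "stratum": f"lagging={flag}",
                "n": len(t),
                "onset_mean_h": t.mean() if len(t) else float("nan"),
                "onset_sd_h": t.std(ddof=1) if len(t) > 1 else float("nan"),
            }
        )
    timing = pd.DataFrame(timing_rows)

    cong = valid["t_congression_h"].dropna()
    congression = pd.DataFrame(
        [
            {
                "n": len(cong),
                "congression_mean_h": cong.mean() if len(cong) else float("nan"),
                "congression_sd_h": cong.std(ddof=1) if len(cong) > 1 else float("nan"),
                "n_excluded_missing_nebd": n_excluded,
            }
        ]
    )
    return {"efficiency": efficiency, "timing": timing, "congression": congression}
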