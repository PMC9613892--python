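"""Medication adjustment and progressor / non-progressor labelling.

MDS-UPDRS subpart scores of treated subjects are masked by symptomatic
medication; the adjustment adds back, to every visit of every treated
subject, the training-cohort mean difference between untreated and treated
subpart values (reference values from the study: +0.67 / +1.5 / +3.67 for
parts I / II / III).  A subject is a *progressor* for a given subpart and
horizon when the annualized two-endpoint slope of the adjusted value is
strictly positive; a slope <= 0 is a non-progressor.  Because the offset is
applied uniformly across timepoints it never changes a label — the
adjustment matters for downstream uses of the slope values, not for the
binary classifications.

Targets: {I, II, III, Total} x {12, 24, 36 months} = 12 labels per subject
with complete endpoint data.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import PART_NAMES, LongitudinalCohort

log = logging.getLogger(__name__)

__all__ = [
    "AdjustmentOffsets", "estimate_offsets", "apply_adjustment",
    "label_progression", "annualized_trajectory", "jaccard_overlap",
    "TARGETS", "HORIZONS",
]

HORIZONS = (12, 24, 36)
PARTS = ("i", "ii", "iii", "total")
TARGETS = tuple((p, h) for p in PARTS for h in HORIZONS)

_SCORE_COL = {"i": "mds_updrs_i_summary_score",
              "ii": "mds_updrs_ii_summary_score",
              "iii": "mds_updrs_iii_summary_score",
              "total": "mds_updrs_total_score"}


@dataclass(frozen=True)
class AdjustmentOffsets:
    """Score-scale offsets added to treated subjects' subpart values.

    Estimated on the training cohort only and frozen for reuse on any
    external cohort.
    """

    delta_i: float
    delta_ii: float
    delta_iii: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.delta_i, self.delta_ii, self.delta_iii)


def estimate_offsets(train: LongitudinalCohort) -> AdjustmentOffsets:
    """Delta_part = mean(untreated) - mean(treated), pooled over all visits.

    "Treated" means treated at any point during follow-up (the per-subject
    summary flag).  Raises if either group is empty.
    """
    treated_ids = set(train.subjects.loc[train.subjects["treated_any"] == 1,
                                         "participant_id"])
    untreated_ids = set(train.subjects["participant_id"]) - treated_ids
    if not treated_ids or not untreated_ids:
        raise ValueError("need both treated and untreated subjects")
    is_treated = train.visits["participant_id"].isin(treated_ids).values
    deltas = []
    for p in PART_NAMES:
        col = train.visits[_SCORE_COL[p]].values.astype(float)
        deltas.append(float(np.nanmean(col[~is_treated])
                            - np.nanmean(col[is_treated])))
    return AdjustmentOffsets(*deltas)


def apply_adjustment(cohort: LongitudinalCohort,
                     offsets: AdjustmentOffsets) -> LongitudinalCohort:
    """Add the per-subpart offset to treated subjects at every visit and
    recompute Total as adjusted I+II+III.  Untreated subjects unchanged.

    Item responses are left untouched; the adjustment is defined on subpart
    summary scores (so adjusted summaries no longer equal item sums for
    treated subjects — by design, labels derive from summaries).
    """
    out = cohort.copy()
    treated_ids = set(out.subjects.loc[out.subjects["treated_any"] == 1,
                                       "participant_id"])
    mask = out.visits["participant_id"].isin(treated_ids).values
    for p, d in zip(PART_NAMES, offsets.as_tuple()):
        col = _SCORE_COL[p]
        vals = out.visits[col].values.astype(float)
        vals[mask] = vals[mask] + d
        out.visits[col] = vals
    out.visits["mds_updrs_total_score"] = sum(
        out.visits[_SCORE_COL[p]] for p in PART_NAMES)
    return out


def _endpoint_values(visits: pd.DataFrame, col: str, month: int,
                     window: int = 3) -> pd.Series:
    """Per-subject value at the visit nearest ``month`` within +-window."""
    v = visits[["participant_id", "visit_month", col]].dropna(subset=[col])
    near = v[(v["visit_month"] - month).abs() <= window].copy()
    near["dist"] = (near["visit_month"] - month).abs()
    near = near.sort_values(["participant_id", "dist"], kind="stable")
    return near.groupby("participant_id", sort=False)[col].first()


def label_progression(cohort: LongitudinalCohort,
                      horizons: tuple[int, ...] = HORIZONS,
                      window: int = 3) -> pd.DataFrame:
    """Two-endpoint annualized slopes and binary progressor status.

    Returns a long table (participant_id, part, horizon, slope, progressor);
    ``progressor`` is 1 iff slope > 0.  Subjects missing the baseline or the
    horizon endpoint (nearest visit within +-``window`` months) are omitted
    from that target only.
    """
    rows = []
    for p in PARTS:
        col = _SCORE_COL[p]
        base = _endpoint_values(cohort.visits, col, 0, window=0)
        for h in horizons:
            end = _endpoint_values(cohort.visits, col, h, window=window)
            common = base.index.intersection(end.index)
            n_drop = len(base.index.union(end.index)) - len(common)
            if n_drop:
                log.info("target (%s, %d mo): %d subjects lack an endpoint",
                         p, h, n_drop)
            slope = (end.loc[common] - base.loc[common]) / (h / 12.0)
            # tolerance absorbs float residue from the medication offsets so
            # an exactly-flat trajectory stays a non-progressor
            rows.append(pd.DataFrame({
                "participant_id": common, "part": p, "horizon": h,
                "slope": slope.values,
                "progressor": (slope.values > 1e-9).astype(int)}))
    return pd.concat(rows, ignore_index=True)


def labels_wide(labels: pd.DataFrame, part: str, horizon: int) -> pd.Series:
    """Per-subject binary label series for one (part, horizon) target."""
    sel = labels[(labels["part"] == part) & (labels["horizon"] == horizon)]
    return sel.set_index("participant_id")["progressor"]


def annualized_trajectory(cohort: LongitudinalCohort, part: str
                          ) -> pd.DataFrame:
    """12-month-lag slope series: at visit month m >= 12 the value is
    score(m) - score(m-12) (points/year).  Missing lagged visits omit the
    point."""
    col = _SCORE_COL[part]
    v = cohort.visits[["participant_id", "visit_month", col]].dropna()
    wide = v.pivot(index="participant_id", columns="visit_month", values=col)
    rows = []
    for m in sorted(wide.columns):
        if m < 12 or (m - 12) not in wide.columns:
            continue
        diff = wide[m] - wide[m - 12]
        ok = diff.dropna()
        rows.append(pd.DataFrame({"participant_id": ok.index,
                                  "visit_month": m,
                                  "lag_slope": ok.values}))
    if not rows:
        return pd.DataFrame(columns=["participant_id", "visit_month",
                                     "lag_slope"])
    return pd.concat(rows, ignore_index=True)


def jaccard_overlap(labels: pd.DataFrame, horizon: int) -> pd.DataFrame:
    """4x4 Jaccard similarity matrix of progressor sets across
    {I, II, III, Total} at one horizon: J(A,B) = |A&B| / |A|B|.

    Symmetric with unit diagonal.  If both sets are empty J is defined as 1
    (with a warning).
    """
    sets = {}
    for p in PARTS:
        lab = labels_wide(labels, p, horizon)
        sets[p] = set(lab.index[lab == 1])
    mat = pd.DataFrame(np.eye(len(PARTS)), index=PARTS, columns=PARTS)
    for a, b in itertools.combinations(PARTS, 2):
        union = sets[a] | sets[b]
        if not union:
            warnings.warn(f"Jaccard({a},{b}): both progressor sets empty; "
                          "defining J=1")
            j = 1.0
        else:
            j = len(sets[a] & sets[b]) / len(union)
        mat.loc[a, b] = mat.loc[b, a] = j
    return mat
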