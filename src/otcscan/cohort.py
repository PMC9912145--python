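"""Cohort assembly: eligibility exclusions, 2:1 nearest-age matching with
replacement within loyalty-card strata, and diagnosis-anchored alignment of
24-month purchase windows.

Matching follows the design of retrospective loyalty-card case-control
studies: each case is matched to ``ratio`` controls holding exactly the same
card combination, choosing the controls closest in age, sampling with
replacement so the same control may serve several cases (each appearance is
an independent stratum member downstream).
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from . import months

VALID_PREVIOUS_CANCER = {"none", "nonmelanoma_skin", "other"}
VALID_CARDS = {"HSR1", "HSR2", "both"}


def flow_percentage(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, rounded half away from zero.

    Matches the convention of participant-flow tables where e.g. 13.75%
    prints as 13.8.
    """
    if denominator == 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must satisfy 0 <= n <= denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def apply_exclusions(roster: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply eligibility exclusions and return the eligible roster plus a
    CONSORT-style flow report.

    Exclusion steps, in order: withdrawn; insufficient consent; loyalty-card
    details not matched by the retailer; previous cancer other than
    nonmelanoma skin cancer. Participants with a previous nonmelanoma skin
    cancer are retained.
    """
    bad = set(roster["previous_cancer"].dropna()) - VALID_PREVIOUS_CANCER
    if bad:
        raise ValueError(f"unknown previous_cancer codes: {sorted(bad)}")

    report: dict = {"steps": []}
    current = roster

    def count_arms(df: pd.DataFrame) -> dict:
        return {"total": int(len(df)),
                "cases": int((df["arm"] == "case").sum()),
                "controls": int((df["arm"] == "control").sum())}

    report["steps"].append({"step": "input", **count_arms(current)})

    rules = [
        ("withdrawn", "withdrawn",
         lambda df: ~df["withdrawn"].fillna(False).astype(bool)),
        ("insufficient_consent", "sufficient_consent",
         lambda df: df["sufficient_consent"].fillna(True).astype(bool)),
        ("card_details_unmatched", "card_details_matched",
         lambda df: df["card_details_matched"].fillna(True).astype(bool)),
        ("previous_cancer", "previous_cancer",
         lambda df: df["previous_cancer"].fillna("none") != "other"),
    ]
    for name, col, keep_fn in rules:
        if col not in current.columns:
            continue
        keep = keep_fn(current)
        removed = current[~keep]
        current = current[keep]
        report["steps"].append({
            "step": f"excluded_{name}",
            "removed_cases": int((removed["arm"] == "case").sum()),
            "removed_controls": int((removed["arm"] == "control").sum()),
            **count_arms(current),
        })

    report["eligible"] = count_arms(current)
    return current.reset_index(drop=True), report


@dataclass
class MatchedSet:
    """One case with its matched controls and (once aligned) the calendar
    window each member's relative months −24…−1 map onto."""

    set_id: str
    case_id: str
    control_ids: list[str]
    cards: str
    case_age: float
    control_ages: list[float]
    #: per-member alignment, filled by :func:`align_timeline`:
    #: {"case": {"window_start": ord, "rule": str},
    #:  "controls": [{...}, {...}]}
    alignment: dict | None = dc_field(default=None)

    def relative_month(self, member: str, calendar_month: str | int) -> int:
        """Calendar month → relative month −24…−1 for 'case' or control slot int."""
        if self.alignment is None:
            raise ValueError("set not aligned yet")
        a = (self.alignment["case"] if member == "case"
             else self.alignment["controls"][int(member)])
        cal = (months.to_ordinal(calendar_month)
               if isinstance(calendar_month, str) else int(calendar_month))
        rel = cal - a["window_start"] - 24
        if not (-24 <= rel <= -1):
            raise ValueError(f"month {calendar_month} outside aligned window")
        return rel


def match(eligible: pd.DataFrame, ratio: int = 2,
          caliper: float | None = None) -> tuple[list[MatchedSet], dict]:
    """Nearest-age matching with replacement within exact card strata.

    For each case, the ``ratio`` controls with smallest |age difference|
    within the case's exact loyalty-card stratum are selected (ties broken by
    smaller control id; a control pool smaller than ``ratio`` is reused
    within the set). Controls are sampled with replacement across sets.
    Returns the matched sets and a report with the median and IQR of signed
    age differences (control − case) and the unique-control count.
    """
    cases = eligible[eligible["arm"] == "case"].sort_values("participant_id")
    controls = eligible[eligible["arm"] == "control"]
    pools: dict[str, pd.DataFrame] = {
        cards: grp.sort_values("participant_id").reset_index(drop=True)
        for cards, grp in controls.groupby("cards")
    }

    sets: list[MatchedSet] = []
    diffs: list[float] = []
    for i, (_, case) in enumerate(cases.iterrows(), start=1):
        stratum = case["cards"]
        pool = pools.get(stratum)
        if pool is None or len(pool) == 0:
            raise ValueError(
                f"no eligible controls in loyalty-card stratum {stratum!r} "
                f"needed by case {case['participant_id']}")
        gap = (pool["age_years"] - case["age_years"]).abs()
        order = np.lexsort((pool["participant_id"].to_numpy(), gap.to_numpy()))
        if caliper is not None:
            order = [j for j in order if gap.iloc[j] <= caliper]
            if len(order) == 0:
                raise ValueError(
                    f"no control within caliper {caliper} for case "
                    f"{case['participant_id']}")
        chosen = [order[j % len(order)] for j in range(ratio)]
        ctrl = pool.iloc[chosen]
        sets.append(MatchedSet(
            set_id=f"set_{i:04d}",
            case_id=case["participant_id"],
            control_ids=list(ctrl["participant_id"]),
            cards=stratum,
            case_age=float(case["age_years"]),
            control_ages=[float(a) for a in ctrl["age_years"]],
        ))
        diffs += list(ctrl["age_years"] - case["age_years"])

    diffs_arr = np.array(diffs) if diffs else np.array([np.nan])
    report = {
        "n_sets": len(sets),
        "n_control_slots": sum(len(s.control_ids) for s in sets),
        "n_unique_controls": len({c for s in sets for c in s.control_ids}),
        "age_diff_median": float(np.median(diffs_arr)),
        "age_diff_iqr": [float(np.percentile(diffs_arr, 25)),
                         float(np.percentile(diffs_arr, 75))],
        "tie_break": "smallest participant_id",
        "order": "cases processed in participant_id order",
    }
    return sets, report


def availability_from_roster(roster: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Per-participant (first, last) available calendar month ordinals."""
    return {
        row["participant_id"]: (months.to_ordinal(row["data_start_month"]),
                                months.to_ordinal(row["data_end_month"]))
        for _, row in roster.iterrows()
    }


def availability_from_transactions(log: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Availability inferred from each participant's first and last purchase."""
    ords = pd.PeriodIndex(pd.to_datetime(log["date"]), freq="M").asi8
    grouped = pd.DataFrame({"participant_id": log["participant_id"],
                            "ord": ords}).groupby("participant_id")["ord"]
    return {pid: (int(lo), int(hi))
            for pid, (lo, hi) in grouped.agg(["min", "max"]).iterrows()}


def align_timeline(matched_set: MatchedSet, diagnosis_month: str | int,
                   availability: dict[str, tuple[int, int]],
                   truncate: bool = False) -> MatchedSet:
    """Fill in each member's 24-month calendar window.

    The case's relative month −m is the m-th calendar month before the
    diagnosis month (the diagnosis month itself excluded). Each control uses
    the case's calendar window when its own availability fully covers it;
    otherwise its latest 24 available months. The rule applied is recorded
    per control.
    """
    diag = (months.to_ordinal(diagnosis_month)
            if isinstance(diagnosis_month, str) else int(diagnosis_month))
    case_start = diag - 24  # window covers [diag-24, diag-1]
    alignment = {"case": {"window_start": case_start, "rule": "diagnosis"},
                 "controls": []}
    for cid in matched_set.control_ids:
        if cid not in availability:
            raise ValueError(f"no availability window for control {cid}")
        lo, hi = availability[cid]
        if hi - lo + 1 < 24 and not truncate:
            raise ValueError(
                f"control {cid} has only {hi - lo + 1} months of data "
                "(24 required); pass truncate=True to keep it")
        if lo <= case_start and hi >= diag - 1:
            alignment["controls"].append(
                {"window_start": case_start, "rule": "case_window"})
        else:
            alignment["controls"].append(
                {"window_start": hi - 23, "rule": "own_latest"})
    matched_set.alignment = alignment
    return matched_set


def align_all(sets: list[MatchedSet], roster: pd.DataFrame,
              availability: dict[str, tuple[int, int]] | None = None,
              truncate: bool = False) -> list[MatchedSet]:
    """Align every matched set using diagnosis months from the roster."""
    if availability is None:
        availability = availability_from_roster(roster)
    diag = roster.set_index("participant_id")["diagnosis_month"]
    for s in sets:
        align_timeline(s, diag[s.case_id], availability, truncate=truncate)
    return sets


def matched_sets_frame(sets: list[MatchedSet]) -> pd.DataFrame:
    """Long-format matched-set table (one row per member appearance)."""
    rows = []
    for s in sets:
        al = s.alignment or {"case": {"window_start": None, "rule": None},
                             "controls": [{"window_start": None, "rule": None}]
                             * len(s.control_ids)}
        rows.append({"set_id": s.set_id, "participant_id": s.case_id,
                     "role": "case", "slot": 0, "cards": s.cards,
                     "applied_alignment_rule": al["case"]["rule"],
                     "calendar_window_start":
                         None if al["case"]["window_start"] is None
                         else months.to_str(al["case"]["window_start"])})
        for k, cid in enumerate(s.control_ids):
            a = al["controls"][k]
            rows.append({"set_id": s.set_id, "participant_id": cid,
                         "role": "control", "slot": k + 1, "cards": s.cards,
                         "applied_alignment_rule": a["rule"],
                         "calendar_window_start":
                             None if a["window_start"] is None
                             else months.to_str(a["window_start"])})
    return pd.DataFrame(rows)
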