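"""Monthly binning of aligned purchase histories.

The central container is :class:`AlignedPanel`: one row per matched-set
member *appearance* (a control reused across sets appears once per set) with
a dense (category × relative month) count array over months −24…−1. All
downstream scans — Fisher enrichment, conditional logistic regression, ROC —
operate on this panel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import months
from .cohort import MatchedSet

REL_MONTHS = np.arange(-24, 0)  # −24 … −1


def rel_index(m: int) -> int:
    """Relative month −24…−1 → array index 0…23."""
    if not (-24 <= m <= -1):
        raise ValueError(f"relative month must be in -24..-1, got {m}")
    return m + 24


def window_months(m: int, style: str = "centered") -> list[int]:
    """Relative months in the sliding 3-month window at ``m``.

    Centered windows are {m−1, m, m+1} truncated at the −24/−1 boundaries
    (so a window of 2 at the ends); trailing windows are {m−2, m−1, m}
    truncated at −24.
    """
    rel_index(m)  # validates range
    if style == "centered":
        cand = [m - 1, m, m + 1]
    elif style == "trailing":
        cand = [m - 2, m - 1, m]
    else:
        raise ValueError(f"unknown window style {style!r}")
    return [x for x in cand if -24 <= x <= -1]


@dataclass
class AlignedPanel:
    """Binned counts for every matched-set member appearance.

    counts[i, c, t] is member i's purchase count of category c in relative
    month REL_MONTHS[t].
    """

    members: pd.DataFrame     # set_id, participant_id, role, slot, window_start
    counts: np.ndarray        # (n_members, n_categories, 24) int
    categories: list[str]
    discard_report: dict

    def __post_init__(self) -> None:
        assert self.counts.shape == (len(self.members), len(self.categories), 24)

    def category_index(self, categories: str | list[str] | tuple[str, ...]) -> list[int]:
        if isinstance(categories, str):
            categories = [categories]
        missing = [c for c in categories if c not in self.categories]
        if missing:
            raise KeyError(f"unknown categories: {missing}")
        return [self.categories.index(c) for c in categories]

    @property
    def is_case(self) -> np.ndarray:
        return (self.members["role"] == "case").to_numpy()

    def series(self, i: int) -> pd.DataFrame:
        """Member i's counts as a (relative month × category) frame."""
        return pd.DataFrame(self.counts[i].T, index=REL_MONTHS,
                            columns=self.categories)

    def window_sum(self, m: int, categories=None,
                   style: str = "centered") -> np.ndarray:
        """Per-member summed counts over the 3-month window at month ``m``.

        Returns an (n_members,) vector (summed over the selected categories;
        all categories if None).
        """
        win = [rel_index(x) for x in window_months(m, style)]
        if categories is None:
            idx = list(range(len(self.categories)))
        else:
            idx = self.category_index(categories)
        return self.counts[:, idx][:, :, win].sum(axis=(1, 2))

    def total(self, categories=None) -> np.ndarray:
        """Per-member total count over the whole 24-month window."""
        if categories is None:
            idx = list(range(len(self.categories)))
        else:
            idx = self.category_index(categories)
        return self.counts[:, idx, :].sum(axis=(1, 2))

    def calendar_month(self, m: int) -> np.ndarray:
        """Per-member calendar ordinal of relative month ``m``."""
        ws = self.members["window_start"].to_numpy(int)
        return ws + rel_index(m)


def bin_monthly(log: pd.DataFrame, sets: list[MatchedSet],
                categories: list[str] | None = None,
                known_participants: set[str] | None = None) -> AlignedPanel:
    """Bin the transaction log into each member appearance's aligned window.

    Rows outside a member's −24…−1 window are dropped and counted in the
    panel's discard report. A transaction whose participant is not in
    ``known_participants`` (defaults to the union of participants in the
    matched sets plus those in the log's roster) raises.
    """
    if any(s.alignment is None for s in sets):
        raise ValueError("matched sets must be aligned before binning")

    member_rows = []
    for s in sets:
        member_rows.append((s.set_id, s.case_id, "case", 0,
                            s.alignment["case"]["window_start"],
                            s.alignment["case"]["rule"]))
        for k, cid in enumerate(s.control_ids):
            a = s.alignment["controls"][k]
            member_rows.append((s.set_id, cid, "control", k + 1,
                                a["window_start"], a["rule"]))
    members = pd.DataFrame(member_rows, columns=[
        "set_id", "participant_id", "role", "slot", "window_start", "rule"])

    if known_participants is not None:
        unknown = set(log["participant_id"]) - set(known_participants)
        if unknown:
            raise ValueError(
                f"transactions for unknown participants: {sorted(unknown)[:5]}")

    if categories is None:
        categories = sorted(log["category"].unique()) if len(log) else []
    cat_idx = {c: j for j, c in enumerate(categories)}

    counts = np.zeros((len(members), len(categories), 24), dtype=int)
    discarded = 0
    if len(log) and len(members):
        pid_list = sorted(set(members["participant_id"]))
        pid_idx = {p: i for i, p in enumerate(pid_list)}
        ws_arr = members["window_start"].to_numpy(int)
        lo = int(ws_arr.min())
        hi = int(ws_arr.max()) + 23

        ords = pd.PeriodIndex(pd.to_datetime(log["date"]), freq="M").asi8
        p = log["participant_id"].map(pid_idx).to_numpy()
        c = log["category"].map(cat_idx).to_numpy()
        n_items = log["n_items"].to_numpy(int)
        ok = (~pd.isna(p)) & (~pd.isna(c)) & (ords >= lo) & (ords <= hi)
        dense = np.zeros((len(pid_list), len(categories), hi - lo + 1), dtype=int)
        np.add.at(dense,
                  (p[ok].astype(int), c[ok].astype(int), ords[ok] - lo),
                  n_items[ok])
        # per-participant totals over categories of interest (for discards)
        totals = np.zeros(len(pid_list), dtype=int)
        ok_cat = ~pd.isna(c)
        np.add.at(totals, p[ok_cat & ~pd.isna(p)].astype(int),
                  n_items[ok_cat & ~pd.isna(p)])

        member_p = members["participant_id"].map(pid_idx).to_numpy(int)
        offsets = ws_arr - lo
        t_idx = offsets[:, None] + np.arange(24)[None, :]     # (n_members, 24)
        sel = dense[member_p]                                 # (n, C, T)
        counts = np.take_along_axis(
            sel, np.broadcast_to(t_idx[:, None, :],
                                 (len(members), len(categories), 24)),
            axis=2)
        binned_per_member = counts.sum(axis=(1, 2))
        discarded = int((totals[member_p] - binned_per_member).sum())

    total_items = int(log["n_items"].sum()) if len(log) else 0
    panel = AlignedPanel(
        members=members, counts=counts, categories=list(categories),
        discard_report={
            "items_in_log": total_items,
            "items_binned": int(counts.sum()),
            "items_discarded_per_appearance": discarded,
            "note": ("a participant appearing in several sets is binned once "
                     "per appearance, so binned+discarded can exceed the log "
                     "total"),
        })
    return panel


def cumulative_curve(panel: AlignedPanel, categories=None,
                     group_by: str = "role") -> pd.DataFrame:
    """Mean cumulative purchase count per relative month, by group.

    Running sums start at month −24; the value at month m is the mean over
    the group's members of their total purchases from −24 through m.
    """
    if categories is None:
        idx = list(range(len(panel.categories)))
    else:
        idx = panel.category_index(categories)
    per_member = panel.counts[:, idx, :].sum(axis=1)       # (n, 24)
    cum = per_member.cumsum(axis=1)
    out = {}
    groups = panel.members[group_by]
    for g in sorted(groups.unique()):
        sel = (groups == g).to_numpy()
        if not sel.any():
            continue
        out[g] = cum[sel].mean(axis=0)
    return pd.DataFrame(out, index=pd.Index(REL_MONTHS, name="month"))
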