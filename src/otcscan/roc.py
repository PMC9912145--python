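"""Month-wise ROC/AUC scans of purchase scores.

AUC is the Mann–Whitney estimate — the probability a random case's score
exceeds a random control's, plus half the tie probability — computed with
midranks. Confidence intervals use the DeLong structural-component variance
with a normal approximation (stratified bootstrap available as a fallback).
Scans restrict to participants who purchased the category at all during the
24-month window, and can stratify cases by stage at diagnosis (stages 1–2
early, 3–4 late) against the identical control pool.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AlignedPanel, REL_MONTHS, rel_index

_Z975 = stats.norm.ppf(0.975)


def auc_mann_whitney(case_scores, control_scores) -> float:
    """AUC with midrank tie handling: P(case > control) + ½·P(tie)."""
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[:len(x)].sum() - len(x) * (len(x) + 1) / 2
    return float(u / (len(x) * len(y)))


def _delong_components(x: np.ndarray, y: np.ndarray):
    """Midrank structural components V10 (cases) and V01 (controls)."""
    m, n = len(x), len(y)
    allv = np.concatenate([x, y])
    rank_all = stats.rankdata(allv)
    rank_x = stats.rankdata(x)
    rank_y = stats.rankdata(y)
    v10 = (rank_all[:m] - rank_x) / n
    v01 = 1.0 - (rank_all[m:] - rank_y) / m
    return v10, v01


def auc_ci(case_scores, control_scores, alpha: float = 0.05,
           method: str = "delong", n_boot: int = 2000,
           rng: np.random.Generator | None = None
           ) -> tuple[float, float, dict]:
    """(lo, hi) CI for the AUC, truncated to [0, 1].

    DeLong variance by default; ``method='bootstrap'`` draws a stratified
    bootstrap (seeded via ``rng``). A degenerate (zero) variance — all ties,
    or perfect separation — collapses the CI at the point estimate and is
    flagged.
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 scores per group")
    auc = auc_mann_whitney(x, y)
    flags: dict = {"method": method, "degenerate": False}
    z = stats.norm.ppf(1 - alpha / 2)
    if method == "delong":
        v10, v01 = _delong_components(x, y)
        var = v10.var(ddof=1) / len(x) + v01.var(ddof=1) / len(y)
        if var <= 0:
            flags["degenerate"] = True
            return auc, auc, flags
        half = z * np.sqrt(var)
        return max(0.0, auc - half), min(1.0, auc + half), flags
    if method == "bootstrap":
        if rng is None:
            rng = np.random.default_rng(0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            xb = x[rng.integers(0, len(x), len(x))]
            yb = y[rng.integers(0, len(y), len(y))]
            aucs[b] = auc_mann_whitney(xb, yb)
        lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        if lo == hi:
            flags["degenerate"] = True
        return float(lo), float(hi), flags
    raise ValueError(f"unknown CI method {method!r}")


def restrict_purchasers(panel: AlignedPanel, category) -> np.ndarray:
    """Boolean member mask: total purchases of ``category`` over −24…−1 > 0."""
    keep = panel.total(category) > 0
    if not keep.any():
        raise ValueError(f"no member purchased {category!r} in the window")
    return keep


@dataclass
class ROCScanResults:
    table: pd.DataFrame  # month, category, stratum, auc, ci_lo, ci_hi, n_cases, n_controls
    argmax: dict         # stratum -> month of maximum AUC
    flags: dict

    def summary(self) -> str:
        lines = [f"ROC scan ({self.flags.get('score_form')} score, "
                 f"purchaser-restricted)"]
        for stratum, m in self.argmax.items():
            row = self.table[(self.table["stratum"] == stratum)
                             & (self.table["month"] == m)].iloc[0]
            lines.append(f"  {stratum}: max AUC {row['auc']:.3f} "
                         f"(95% CI {row['ci_lo']:.3f}-{row['ci_hi']:.3f}) "
                         f"at month {m}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        colors = {"all": "black", "early_stage": "firebrick",
                  "late_stage": "steelblue"}
        for stratum, grp in self.table.groupby("stratum"):
            ax.plot(grp["month"], grp["auc"], "o-", label=stratum,
                    color=colors.get(stratum))
            ax.fill_between(grp["month"], grp["ci_lo"], grp["ci_hi"],
                            alpha=0.15, color=colors.get(stratum))
        ax.axhline(0.5, color="grey", lw=0.8)
        ax.set_xlabel("months before diagnosis")
        ax.set_ylabel("AUC")
        ax.legend()
        return ax


class ROCScan:
    """Month-wise ROC analysis of one purchase category.

    The score at month m is the cumulative count from −24 through m by
    default (``score='single_month'`` and ``'window'`` are variants).
    Strata: 'all', plus 'early_stage' (stage 1–2 cases) and 'late_stage'
    (stage 3–4 cases), each against the identical restricted control pool.
    Controls have no stage, so stratification subsets cases only.
    """

    def __init__(self, panel: AlignedPanel, roster: pd.DataFrame,
                 category: str = "pain", score: str = "cumulative",
                 strata: tuple[str, ...] = ("all", "early_stage", "late_stage"),
                 window_style: str = "centered", ci_method: str = "delong",
                 rng: np.random.Generator | None = None):
        if score not in ("cumulative", "single_month", "window"):
            raise ValueError(f"unknown score form {score!r}")
        unknown = set(strata) - {"all", "early_stage", "late_stage"}
        if unknown:
            raise ValueError(f"unknown strata: {sorted(unknown)}")
        self.panel = panel
        self.roster = roster
        self.category = category
        self.score = score
        self.strata = tuple(strata)
        self.window_style = window_style
        self.ci_method = ci_method
        self.rng = rng

    def _scores_at(self, m: int) -> np.ndarray:
        idx = self.panel.category_index(self.category)
        if self.score == "cumulative":
            return self.panel.counts[:, idx, :rel_index(m) + 1].sum(
                axis=(1, 2)).astype(float)
        if self.score == "single_month":
            return self.panel.counts[:, idx, rel_index(m)].sum(axis=1).astype(float)
        return self.panel.window_sum(m, [self.category],
                                     style=self.window_style).astype(float)

    def fit(self) -> ROCScanResults:
        keep = restrict_purchasers(self.panel, self.category)
        is_case = self.panel.is_case
        stage = (self.roster.set_index("participant_id")["stage"]
                 .reindex(self.panel.members["participant_id"])
                 .to_numpy(object))
        stage_num = pd.to_numeric(pd.Series(stage), errors="coerce").to_numpy()
        masks = {}
        for stratum in self.strata:
            if stratum == "all":
                cmask = is_case & keep
            elif stratum == "early_stage":
                cmask = is_case & keep & np.isin(stage_num, [1, 2])
            else:
                cmask = is_case & keep & np.isin(stage_num, [3, 4])
            masks[stratum] = cmask
        ctrl_mask = (~is_case) & keep

        rows = []
        flagged = []
        for m in REL_MONTHS:
            scores = self._scores_at(int(m))
            for stratum, cmask in masks.items():
                n_cases = int(cmask.sum())
                n_ctrl = int(ctrl_mask.sum())
                if n_cases < 2:
                    flagged.append({"month": int(m), "stratum": stratum,
                                    "reason": "fewer than 2 cases"})
                    continue
                auc = auc_mann_whitney(scores[cmask], scores[ctrl_mask])
                lo, hi, fl = auc_ci(scores[cmask], scores[ctrl_mask],
                                    method=self.ci_method, rng=self.rng)
                rows.append({"month": int(m), "category": self.category,
                             "stratum": stratum, "auc": auc,
                             "ci_lo": lo, "ci_hi": hi,
                             "n_cases": n_cases, "n_controls": n_ctrl,
                             "degenerate_ci": fl["degenerate"]})
        table = pd.DataFrame(rows)
        argmax = {}
        for stratum, grp in table.groupby("stratum"):
            argmax[stratum] = int(grp.loc[grp["auc"].idxmax(), "month"])
        return ROCScanResults(table=table, argmax=argmax,
                              flags={"score_form": self.score,
                                     "ci_method": self.ci_method,
                                     "skipped": flagged})


def monthly_roc_scan(panel, roster, category="pain", **kwargs) -> ROCScanResults:
    """Functional shorthand for ``ROCScan(…).fit()``."""
    return ROCScan(panel, roster, category, **kwargs).fit()
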