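"""Synthetic cohort and transaction-log generator.

Generates (a) a participant roster with case/control status, demographics,
loyalty-card ownership, questionnaire covariates and diagnosis metadata, and
(b) an item-level purchase log whose monthly per-category counts follow a
Poisson or negative-binomial model with seasonality, household-size effects
and — in cases — an elevated pain/indigestion purchase rate beginning a
configurable number of months before diagnosis.

Ground truth (true rates, true covariates before masking, the injected onset
and ratio) is returned alongside so that recovery experiments can score the
downstream analyses against what was actually simulated.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import months
from .config import RISK_FACTORS, SimConfig

ROSTER_META_COLS = [
    "participant_id", "arm", "age_years", "cards", "diagnosis_month",
    "recruitment_month", "stage", "previous_cancer", "withdrawn",
    "sufficient_consent", "card_details_matched",
    "data_start_month", "data_end_month",
]

EXTRA_COVARIATES = [
    "household_size", "gp_visits", "hrt_ever",
    "symptom_abdominal_pain", "symptom_bloating", "symptom_indigestion",
    "symptom_urinary",
]


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery scoring.

    ``rates`` holds the true mean purchase count per participant, calendar
    month and category (the Poisson/NB mean before sampling).
    """

    participant_ids: list[str]
    month_ordinals: np.ndarray            # calendar months simulated
    categories: list[str]
    rates: np.ndarray                     # (n_participants, n_months, n_categories)
    signal_onset: int
    signal_ratio: float
    true_covariates: pd.DataFrame         # roster before missingness masking
    masked_cells: list[tuple[str, str]]   # (participant_id, field)

    def rate(self, participant_id: str, month: str | int, category: str) -> float:
        i = self.participant_ids.index(participant_id)
        t = months.to_ordinal(month) if isinstance(month, str) else int(month)
        j = int(np.searchsorted(self.month_ordinals, t))
        if j >= len(self.month_ordinals) or self.month_ordinals[j] != t:
            raise KeyError(f"month {month} not simulated")
        return float(self.rates[i, j, self.categories.index(category)])

    def to_jsonable(self) -> dict:
        return {
            "participant_ids": self.participant_ids,
            "month_ordinals": self.month_ordinals.tolist(),
            "months": [months.to_str(m) for m in self.month_ordinals],
            "categories": self.categories,
            "rates": self.rates.tolist(),
            "signal_onset": self.signal_onset,
            "signal_ratio": self.signal_ratio,
            "true_covariates": self.true_covariates.to_dict(orient="list"),
            "masked_cells": [list(c) for c in self.masked_cells],
        }


def _draw_binary(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    return (rng.random(n) < p).astype(int)


def _draw_roster_arm(rng: np.random.Generator, config: SimConfig, arm: str,
                     n: int) -> pd.DataFrame:
    """Draw one arm's worth of participants with correlated questionnaire
    covariates (parity cluster, OC pair, age-linked menopause)."""
    prev = config.covariate_prevalences
    mean, sd = config.age_distributions[arm]
    age = np.maximum(18.0, rng.normal(mean, sd, n)).round(1)

    cards_levels = list(config.cards_probs[arm])
    cards = rng.choice(cards_levels, size=n, p=[config.cards_probs[arm][c]
                                                for c in cards_levels])

    p_other = prev.get("previous_cancer_other", 0.0)
    p_nonmel = prev.get("previous_cancer_nonmelanoma", 0.0)
    u = rng.random(n)
    previous_cancer = np.where(u < p_other, "other",
                               np.where(u < p_other + p_nonmel,
                                        "nonmelanoma_skin", "none"))

    fullterm = rng.poisson(1.8, n)
    nonfullterm = rng.poisson(0.4, n)
    any_preg = (fullterm + nonfullterm) > 0
    breastfed = ((rng.random(n) < (0.15 + 0.55 * (fullterm > 0)))
                 & (fullterm > 0)).astype(int)
    months_bf = np.where(breastfed == 1,
                         np.round(rng.gamma(2.0, (3.0 + 2.0 * fullterm) / 2.0), 1),
                         0.0)
    age_end_preg = np.where(any_preg,
                            np.clip(rng.normal(24 + 2.5 * fullterm, 4.0), 16, 45),
                            0.0).round(1)
    oc_ever = _draw_binary(rng, prev.get("oc_ever", 0.5), n)
    oc_years = np.where(oc_ever == 1, np.round(rng.gamma(2.0, 3.0), 1), 0.0)
    menop_age = rng.normal(50.5, 2.5, n)
    postmenopausal = (age > menop_age).astype(int)
    hrt = (_draw_binary(rng, prev.get("hrt_ever", 0.3), n)
           * postmenopausal)
    hyster = _draw_binary(rng, prev.get("hysterectomy_no_hrt", 0.08), n)
    hyster_no_hrt = (hyster * (1 - hrt)).astype(int)

    hh_sizes = np.array([1, 2, 3, 4, 5])
    household = rng.choice(hh_sizes, size=n, p=[0.20, 0.45, 0.20, 0.10, 0.05])

    df = pd.DataFrame({
        "arm": arm,
        "age_years": age,
        "cards": cards,
        "previous_cancer": previous_cancer,
        "withdrawn": False,
        "sufficient_consent": True,
        "card_details_matched": True,
        "household_size": household,
        "gp_visits": rng.poisson(2.0, n),
        "hrt_ever": hrt,
        "aspirin_use": _draw_binary(rng, prev.get("aspirin_use", 0.15), n),
        "bmi": np.round(rng.normal(27.0, 4.5, n), 1),
        "breastfed_ever": breastfed,
        "months_breastfeeding": months_bf,
        "endometriosis": _draw_binary(rng, prev.get("endometriosis", 0.05), n),
        "famhist_breast": _draw_binary(rng, prev.get("famhist_breast", 0.12), n),
        "famhist_ovarian": _draw_binary(rng, prev.get("famhist_ovarian", 0.04), n),
        "hysterectomy_no_hrt": hyster_no_hrt,
        "age_end_last_pregnancy": age_end_preg,
        "age_menarche": np.round(rng.normal(13.0, 1.5, n), 1),
        "postmenopausal": postmenopausal,
        "oc_ever": oc_ever,
        "oc_years": oc_years,
        "nonfullterm_pregnancies": nonfullterm,
        "fullterm_pregnancies": fullterm,
        "tubal_ligation": _draw_binary(rng, prev.get("tubal_ligation", 0.10), n),
    })
    for s in ("symptom_abdominal_pain", "symptom_bloating",
              "symptom_indigestion", "symptom_urinary"):
        df[s] = _draw_binary(rng, prev.get(s, 0.2), n)
    return df


def generate_roster(config: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the participant roster and its ground truth.

    Cases carry a diagnosis month (with at least 24 months of purchase data
    before it) and a stage drawn from ``config.stage_probs``; controls carry
    a recruitment month only. Requested missingness is applied after the
    true covariate table is recorded.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    start = months.to_ordinal(config.start_month)
    end = start + config.months_span - 1  # last simulated month, inclusive

    frames = []
    for arm, n in (("case", config.n_cases), ("control", config.n_controls)):
        if n == 0:
            continue
        df = _draw_roster_arm(rng, config, arm, n)
        prefix = "case" if arm == "case" else "ctrl"
        df.insert(0, "participant_id",
                  [f"{prefix}_{i:04d}" for i in range(1, n + 1)])
        if config.entry_stagger_months > 0:
            stagger = rng.integers(0, config.entry_stagger_months + 1, n)
        else:
            stagger = np.zeros(n, dtype=int)
        df["data_start_month"] = [months.to_str(start + int(s)) for s in stagger]
        df["data_end_month"] = months.to_str(end)
        if arm == "case":
            lo = start + stagger + 24
            if np.any(lo > end):
                raise ValueError(
                    "months_span too short for 24 months of pre-diagnosis data")
            diag = np.array([rng.integers(l, end + 1) for l in lo])
            df["diagnosis_month"] = [months.to_str(d) for d in diag]
            df["recruitment_month"] = [months.to_str(d + int(r)) for d, r in
                                       zip(diag, rng.integers(0, 4, n))]
            stages = list(config.stage_probs)
            df["stage"] = rng.choice(
                stages, size=n,
                p=[config.stage_probs[s] for s in stages]).astype(int)
        else:
            df["diagnosis_month"] = pd.NA
            df["recruitment_month"] = [
                months.to_str(int(m)) for m in
                rng.integers(max(start, end - 11), end + 1, n)]
            df["stage"] = pd.NA
        frames.append(df)

    if frames:
        roster = pd.concat(frames, ignore_index=True)
    else:
        roster = pd.DataFrame(columns=ROSTER_META_COLS
                              + EXTRA_COVARIATES + list(RISK_FACTORS))
    roster = roster.reindex(columns=ROSTER_META_COLS + EXTRA_COVARIATES
                            + [c for c in RISK_FACTORS if c not in EXTRA_COVARIATES])

    true_covariates = roster.copy()
    masked_cells: list[tuple[str, str]] = []
    maskable = set(roster.columns) - {"participant_id", "arm",
                                      "diagnosis_month", "data_start_month",
                                      "data_end_month"}
    for fld, p in config.missingness.items():
        if p == 0 or len(roster) == 0:
            continue
        if fld not in maskable:
            raise ValueError(f"missingness requested for unknown field {fld!r}")
        if config.missing_mechanism == "MAR_age":
            # older participants more likely missing (questionnaire amendments
            # reached late recruits; emulates age-linked nonresponse)
            age = roster["age_years"].to_numpy(float)
            z = (age - age.mean()) / max(age.std(), 1e-9)
            pvec = 1.0 / (1.0 + np.exp(-(np.log(p / (1 - p) + 1e-12) + z)))
        else:
            pvec = np.full(len(roster), p)
        mask = rng.random(len(roster)) < pvec
        if mask.any():
            roster.loc[mask, fld] = np.nan
            masked_cells += [(pid, fld) for pid in
                             roster.loc[mask, "participant_id"]]

    gt = GroundTruth(
        participant_ids=list(true_covariates["participant_id"]),
        month_ordinals=np.arange(start, end + 1),
        categories=list(config.baseline_rate),
        rates=np.zeros((len(true_covariates), config.months_span,
                        len(config.baseline_rate))),
        signal_onset=config.signal_onset,
        signal_ratio=config.signal_ratio,
        true_covariates=true_covariates,
        masked_cells=masked_cells,
    )
    gt.rates = _rate_matrix(true_covariates, config)
    return roster, gt


def _rate_matrix(roster: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """True mean purchase counts per (participant, calendar month, category)."""
    start = months.to_ordinal(config.start_month)
    n = len(roster)
    cats = list(config.baseline_rate)
    month_ord = np.arange(start, start + config.months_span)

    base = np.array([config.baseline_rate[c] for c in cats])  # (C,)
    moy = month_ord % 12 + 1
    seas = 1.0 + config.seasonal_amplitude * np.cos(
        2 * np.pi * (moy - config.seasonal_peak_month) / 12.0)  # (T,)
    hh = roster["household_size"].to_numpy(float)
    hh = np.where(np.isfinite(hh), hh, 2.0)  # masked household → typical size
    hh_mult = config.household_effect ** np.maximum(hh - 1, 0)  # (N,)

    rates = (hh_mult[:, None, None] * seas[None, :, None] * base[None, None, :])

    sig_idx = [cats.index(c) for c in config.signal_categories if c in cats]
    is_case = (roster["arm"] == "case").to_numpy()
    if sig_idx and is_case.any() and config.signal_ratio != 1.0 or \
            (config.stage_signal_ratio and is_case.any()):
        diag = np.array([months.to_ordinal(m) if isinstance(m, str) else -1
                         for m in roster["diagnosis_month"]])
        for i in np.where(is_case)[0]:
            ratio = config.signal_ratio
            if config.stage_signal_ratio:
                ratio = config.stage_signal_ratio.get(
                    int(roster["stage"].iloc[i]), ratio)
            if ratio == 1.0:
                continue
            lo = diag[i] - config.signal_onset
            hi = diag[i] - 1
            tmask = (month_ord >= lo) & (month_ord <= hi)
            if config.signal_shape == "peaked":
                # maximal elevation at the onset month, decaying linearly
                # toward diagnosis: r(m) = 1 + (R-1)·(diag − m)/onset
                u = (diag[i] - month_ord[tmask]) / config.signal_onset
                mult = 1.0 + (ratio - 1.0) * u
            else:
                mult = ratio
            for j in sig_idx:
                rates[i, tmask, j] *= mult
    return rates


def generate_purchases(roster: pd.DataFrame, config: SimConfig,
                       rng: np.random.Generator | None = None,
                       ground_truth: GroundTruth | None = None) -> pd.DataFrame:
    """Draw the transaction log implied by the roster and config.

    Counts are drawn per participant × calendar month × category from a
    Poisson (default) or negative-binomial model and expanded to dated item
    rows (columns: participant_id, date, category, n_items), with dates
    uniform within the month.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    start = months.to_ordinal(config.start_month)
    end = start + config.months_span - 1

    is_case = roster["arm"] == "case"
    if is_case.any():
        diag = roster.loc[is_case, "diagnosis_month"].map(months.to_ordinal)
        dstart = roster.loc[is_case, "data_start_month"].map(months.to_ordinal)
        bad = roster.loc[is_case].loc[(diag - 24) < dstart, "participant_id"]
        if len(bad):
            raise ValueError(
                "purchase span shorter than 24 months before diagnosis for "
                f"cases: {sorted(bad)}")

    if ground_truth is not None:
        rates = ground_truth.rates
        cats = ground_truth.categories
    else:
        rates = _rate_matrix(roster, config)
        cats = list(config.baseline_rate)
    n, n_months, n_cats = rates.shape

    # zero out months before each participant's data start
    month_ord = np.arange(start, end + 1)
    dstart_all = roster["data_start_month"].map(months.to_ordinal).to_numpy()
    avail = month_ord[None, :] >= dstart_all[:, None]
    mu = rates * avail[:, :, None]

    if config.dispersion == "poisson":
        counts = rng.poisson(mu)
    else:
        size = float(config.dispersion)
        p = size / (size + np.where(mu > 0, mu, 1.0))
        counts = np.where(mu > 0, rng.negative_binomial(size, p), 0)

    idx = np.nonzero(counts)
    k = counts[idx]
    part_rep = np.repeat(roster["participant_id"].to_numpy()[idx[0]], k)
    month_rep = np.repeat(month_ord[idx[1]], k)
    cat_rep = np.repeat(np.array(cats, dtype=object)[idx[2]], k)
    dim = np.array([months.days_in_month(m) for m in month_ord])
    day_rep = rng.integers(1, np.repeat(dim[idx[1]], k) + 1)

    log = pd.DataFrame({
        "participant_id": part_rep,
        "month_ordinal": month_rep,
        "day": day_rep,
        "category": cat_rep,
    })
    if len(log) == 0:
        return pd.DataFrame(columns=["participant_id", "date", "category",
                                     "n_items"])
    grouped = (log.groupby(["participant_id", "month_ordinal", "day",
                            "category"], sort=False)
               .size().rename("n_items").reset_index())
    period = pd.PeriodIndex.from_ordinals(grouped["month_ordinal"], freq="M")
    ts = pd.Series(period.to_timestamp()) + pd.to_timedelta(
        grouped["day"].to_numpy() - 1, unit="D")
    grouped["date"] = ts.dt.strftime("%Y-%m-%d")
    out = grouped[["participant_id", "date", "category", "n_items"]]
    return (out.sort_values(["participant_id", "date", "category"])
            .reset_index(drop=True))


def simulate_cohort(config: SimConfig, seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Roster + transactions + ground truth in one call.

    ``seed`` overrides ``config.seed``; roster and purchase draws use
    independent child streams of the one root seed.
    """
    root = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    r1, r2 = [np.random.default_rng(s) for s in ss.spawn(2)]
    roster, gt = generate_roster(config, rng=r1)
    log = generate_purchases(roster, config, rng=r2, ground_truth=gt)
    return roster, log, gt
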