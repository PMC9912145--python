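"""Configuration objects for simulation and pipeline runs.

The simulator emulates loyalty-card purchase histories of a matched
case-control cohort: monthly per-category purchase counts with seasonality
and household-size effects, and an elevated pain/indigestion purchase rate
in cases beginning a configurable number of months before diagnosis.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

#: The 16 risk factors entering the additive ovarian-cancer risk score.
#: Binary factors are coded 1/0; numeric factors enter as-is.
RISK_FACTORS: dict[str, str] = {
    "aspirin_use": "binary",
    "bmi": "numeric",
    "breastfed_ever": "binary",
    "months_breastfeeding": "numeric",
    "endometriosis": "binary",
    "famhist_breast": "binary",
    "famhist_ovarian": "binary",
    "hysterectomy_no_hrt": "binary",
    "age_end_last_pregnancy": "numeric",
    "age_menarche": "numeric",
    "postmenopausal": "binary",
    "oc_ever": "binary",
    "oc_years": "numeric",
    "nonfullterm_pregnancies": "numeric",
    "fullterm_pregnancies": "numeric",
    "tubal_ligation": "binary",
}

#: Illustrative per-unit median log odds ratios for the additive risk score,
#: stratified at age 50. These are placeholders with plausible signs and
#: magnitudes, NOT calibrated estimates; supply your own via YAML for real use.
DEFAULT_RISK_COEFFICIENTS: dict[str, dict[str, float]] = {
    "under_50": {
        "aspirin_use": -0.10, "bmi": 0.02, "breastfed_ever": -0.15,
        "months_breastfeeding": -0.010, "endometriosis": 0.65,
        "famhist_breast": 0.15, "famhist_ovarian": 0.95,
        "hysterectomy_no_hrt": -0.20, "age_end_last_pregnancy": -0.010,
        "age_menarche": -0.05, "postmenopausal": 0.20, "oc_ever": -0.35,
        "oc_years": -0.040, "nonfullterm_pregnancies": -0.05,
        "fullterm_pregnancies": -0.18, "tubal_ligation": -0.30,
    },
    "over_50": {
        "aspirin_use": -0.08, "bmi": 0.015, "breastfed_ever": -0.12,
        "months_breastfeeding": -0.008, "endometriosis": 0.55,
        "famhist_breast": 0.12, "famhist_ovarian": 0.85,
        "hysterectomy_no_hrt": -0.15, "age_end_last_pregnancy": -0.008,
        "age_menarche": -0.04, "postmenopausal": 0.25, "oc_ever": -0.30,
        "oc_years": -0.035, "nonfullterm_pregnancies": -0.04,
        "fullterm_pregnancies": -0.15, "tubal_ligation": -0.25,
    },
}

#: Purchase categories and their mean purchases per participant-month.
#: Illustrative baseline frequencies (retailer category rates are not public);
#: the two signal categories are a minority of all purchases, as in real
#: health-and-beauty retail baskets.
DEFAULT_BASELINE_RATE: dict[str, float] = {
    "pain": 0.50,
    "indigestion": 0.35,
    "cold_flu": 0.40,
    "vitamins": 0.60,
    "skincare": 0.80,
    "other": 6.00,
}

SIGNAL_CATEGORIES = ("pain", "indigestion")

CARD_LEVELS = ("HSR1", "HSR2", "both")


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= float(p) <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {p!r}")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort and transaction generator.

    Defaults describe a cohort of 150 cases and 300 controls observed over
    40 calendar months, Poisson purchase counts, a mild winter seasonality,
    and a three-fold pain/indigestion rate increase in cases starting
    8 months before diagnosis.
    """

    n_cases: int = 150
    n_controls: int = 300
    months_span: int = 40
    start_month: str = "2018-06"
    baseline_rate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RATE))
    signal_onset: int = 8
    signal_ratio: float = 3.0
    #: "constant": rate ratio applied uniformly from onset to diagnosis;
    #: "peaked": ratio maximal at the onset month, decaying linearly toward
    #: diagnosis — emulates a discrimination hump at the onset month.
    signal_shape: str = "constant"
    signal_categories: tuple[str, ...] = SIGNAL_CATEGORIES
    seasonal_amplitude: float = 0.2
    seasonal_peak_month: int = 1
    household_effect: float = 1.15
    dispersion: float | str = "poisson"
    age_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"case": (64.7, 10.9), "control": (51.6, 13.7)})
    cards_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "case": {"HSR1": 0.27, "HSR2": 0.25, "both": 0.48},
            "control": {"HSR1": 0.40, "HSR2": 0.27, "both": 0.33},
        })
    stage_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.08, 2: 0.11, 3: 0.45, 4: 0.36})
    stage_signal_ratio: dict[int, float] | None = None
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: {
            "aspirin_use": 0.15, "breastfed_ever": 0.60, "endometriosis": 0.05,
            "famhist_breast": 0.12, "famhist_ovarian": 0.04,
            "hysterectomy_no_hrt": 0.08, "oc_ever": 0.55, "tubal_ligation": 0.10,
            "hrt_ever": 0.30, "previous_cancer_other": 0.10,
            "previous_cancer_nonmelanoma": 0.03,
            "symptom_abdominal_pain": 0.20, "symptom_bloating": 0.25,
            "symptom_indigestion": 0.20, "symptom_urinary": 0.15,
        })
    missingness: dict[str, float] = field(default_factory=dict)
    missing_mechanism: str = "MCAR"  # or "MAR_age"
    entry_stagger_months: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.months_span < 24:
            raise ValueError("months_span must be at least 24")
        for cat, rate in self.baseline_rate.items():
            if rate < 0:
                raise ValueError(
                    f"baseline_rate[{cat!r}] must be non-negative, got {rate}")
        if not (1 <= self.signal_onset <= 24):
            raise ValueError("signal_onset must be in 1..24 months")
        if self.signal_onset > self.months_span:
            raise ValueError("signal_onset cannot exceed months_span")
        if self.signal_ratio < 1:
            raise ValueError("signal_ratio must be >= 1")
        if self.signal_shape not in ("constant", "peaked"):
            raise ValueError('signal_shape must be "constant" or "peaked"')
        if not (0.0 <= self.seasonal_amplitude < 1.0):
            raise ValueError("seasonal_amplitude must be in [0, 1)")
        if self.household_effect < 1:
            raise ValueError("household_effect must be >= 1")
        if self.dispersion != "poisson" and float(self.dispersion) <= 0:
            raise ValueError('dispersion must be positive or "poisson"')
        for arm, probs in self.cards_probs.items():
            tot = sum(probs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"cards_probs[{arm!r}] must sum to 1, got {tot}")
        for name, p in self.covariate_prevalences.items():
            _check_prob(f"covariate_prevalences[{name!r}]", p)
        for name, p in self.missingness.items():
            _check_prob(f"missingness[{name!r}]", p)
        if self.missing_mechanism not in ("MCAR", "MAR_age"):
            raise ValueError("missing_mechanism must be 'MCAR' or 'MAR_age'")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load a SimConfig from YAML or JSON."""
        raw = Path(path).read_text()
        data = yaml.safe_load(raw)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        data = dict(data)
        if "stage_probs" in data:
            data["stage_probs"] = {int(k): v for k, v in data["stage_probs"].items()}
        if "age_distributions" in data:
            data["age_distributions"] = {
                k: tuple(v) for k, v in data["age_distributions"].items()}
        if "signal_categories" in data:
            data["signal_categories"] = tuple(data["signal_categories"])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["signal_categories"] = list(self.signal_categories)
        d["age_distributions"] = {k: list(v) for k, v in
                                  self.age_distributions.items()}
        return d


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Either ``sim`` (generate a cohort) or ``roster_path``/``transactions_path``
    (load one) must be provided. Analysis flags select the variants documented
    in each analysis module.
    """

    sim: SimConfig | None = None
    roster_path: str | None = None
    transactions_path: str | None = None
    target_categories: tuple[str, ...] = SIGNAL_CATEGORIES
    match_ratio: int = 2
    window_style: str = "centered"          # or "trailing"
    table_variant: str = "events"           # or "participants"
    or_variant: str = "conditional"         # or "sample"
    target_variant: str = "union"           # or "co_occurrence"
    clr_exposure: str = "window"            # or "single_month", "binary"
    roc_score: str = "cumulative"           # or "single_month", "window"
    adjustment_sets: tuple[tuple[str, ...], ...] = (
        ("oc_ever", "household_size"),
    )
    bonferroni: bool = False
    seed: int = 0
    out_dir: str = "otcscan_out"

    def __post_init__(self) -> None:
        vocab = {
            "window_style": ("centered", "trailing"),
            "table_variant": ("events", "participants"),
            "or_variant": ("conditional", "sample"),
            "target_variant": ("union", "co_occurrence"),
            "clr_exposure": ("window", "single_month", "binary"),
            "roc_score": ("cumulative", "single_month", "window"),
        }
        for name, allowed in vocab.items():
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {allowed}")
        if self.sim is None and (self.roster_path is None
                                 or self.transactions_path is None):
            raise ValueError(
                "provide either sim config or roster_path + transactions_path")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "sim" in data and data["sim"] is not None:
            data["sim"] = SimConfig.from_dict(data["sim"])
        for key in ("target_categories",):
            if key in data:
                data[key] = tuple(data[key])
        if "adjustment_sets" in data:
            data["adjustment_sets"] = tuple(tuple(s) for s in data["adjustment_sets"])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict() if self.sim is not None else None
        d["target_categories"] = list(self.target_categories)
        d["adjustment_sets"] = [list(s) for s in self.adjustment_sets]
        return d


def load_risk_coefficients(path: str | Path | None = None) -> dict[str, dict[str, float]]:
    """Load per-age-stratum risk coefficients from YAML, or the illustrative defaults.

    The file must map stratum names ``under_50``/``over_50`` to
    factor → median-log-OR maps covering all 16 risk factors.
    """
    if path is None:
        return {s: dict(v) for s, v in DEFAULT_RISK_COEFFICIENTS.items()}
    data = yaml.safe_load(Path(path).read_text())
    for stratum in ("under_50", "over_50"):
        if stratum not in data:
            raise ValueError(f"risk coefficient file missing stratum {stratum!r}")
        missing = set(RISK_FACTORS) - set(data[stratum])
        if missing:
            raise ValueError(
                f"stratum {stratum!r} missing factors: {sorted(missing)}")
        bad = {k: v for k, v in data[stratum].items()
               if not isinstance(v, (int, float)) or not abs(v) < float("inf")}
        if bad:
            raise ValueError(f"non-finite coefficients in {stratum!r}: {bad}")
    return {s: {k: float(v) for k, v in data[s].items()} for s in data}


def dump_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
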