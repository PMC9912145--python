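"""Additive ovarian-cancer risk score with mixed-type kNN imputation.

The score for a participant is Σ_f coef[stratum][f] × value_f over 16 risk
factors, where the per-unit coefficients are median log odds ratios supplied
via configuration, stratified at age 50. Missing factors are imputed with a
k-nearest-neighbours scheme under the Gower distance (numeric: |Δ|/range;
categorical: 0/1 mismatch; averaged over fields observed in both records),
with donors required to observe the target field: numeric cells take the
donor median, categorical cells the donor mode (distance ties broken by
record order, mode ties by the nearest donor's value). Scores are grouped
into low/medium/high using tertile cutpoints computed among controls only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RISK_FACTORS


def gower_distance(record_a: pd.Series | dict, record_b: pd.Series | dict,
                   schema: dict[str, str],
                   ranges: dict[str, float]) -> float:
    """Gower dissimilarity in [0, 1] between two mixed-type records.

    Mean over the fields observed in both records of the per-field
    dissimilarity; ``ranges`` gives the observed range of each numeric field
    (a zero range makes any two observed values identical).
    """
    a = pd.Series(record_a)
    b = pd.Series(record_b)
    total = 0.0
    n = 0
    for fld, kind in schema.items():
        va, vb = a.get(fld), b.get(fld)
        if pd.isna(va) or pd.isna(vb):
            continue
        if kind == "numeric":
            rng = ranges.get(fld, 0.0)
            d = 0.0 if rng == 0 else abs(float(va) - float(vb)) / rng
        else:
            d = 0.0 if va == vb else 1.0
        total += d
        n += 1
    if n == 0:
        raise ValueError("records share no commonly observed field")
    return total / n


def _gower_matrix(X: pd.DataFrame, schema: dict[str, str]) -> np.ndarray:
    """Pairwise Gower distances; NaN where two records share no field."""
    fields = [f for f in schema if f in X.columns]
    n = len(X)
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for fld in fields:
        v = X[fld].to_numpy(float if schema[fld] == "numeric" else object)
        obs = ~pd.isna(X[fld]).to_numpy()
        both = obs[:, None] & obs[None, :]
        if schema[fld] == "numeric":
            vv = X[fld].to_numpy(float)
            rng = np.nanmax(vv) - np.nanmin(vv) if obs.any() else 0.0
            if rng > 0:
                with np.errstate(invalid="ignore"):
                    d = np.abs(vv[:, None] - vv[None, :]) / rng
            else:
                d = np.zeros((n, n))
        else:
            d = (v[:, None] != v[None, :]).astype(float)
        d = np.where(both, np.nan_to_num(d), 0.0)
        num += d
        cnt += both
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / cnt
    return out


def knn_impute(records: pd.DataFrame, schema: dict[str, str] | None = None,
               k: int = 5) -> tuple[pd.DataFrame, list[dict]]:
    """Impute missing cells by k nearest donors under Gower distance.

    Donors must observe the target field; distances are computed on the
    commonly observed fields. Numeric cells take the median of the k donor
    values; categorical/binary cells the mode, with mode ties resolved by the
    nearest donor's value. Deterministic: distance ties break by row order.
    Observed cells are never modified.
    """
    if schema is None:
        schema = {f: RISK_FACTORS[f] for f in RISK_FACTORS
                  if f in records.columns}
    fields = [f for f in schema if f in records.columns]
    out = records.copy()
    n = len(records)
    for fld in fields:
        obs = ~pd.isna(records[fld])
        if obs.sum() < min(k, 1):
            raise ValueError(f"field {fld!r} observed in fewer than k records")
    if n == 0 or not records[fields].isna().any().any():
        return out, []

    D = _gower_matrix(records[fields], schema)
    log: list[dict] = []
    for i in range(n):
        missing = [f for f in fields if pd.isna(records[f].iloc[i])]
        if not missing:
            continue
        d = D[i].copy()
        # a pair sharing no observed field has undefined distance; treat as
        # maximally dissimilar so such donors rank last but remain usable
        d[np.isnan(d)] = 1.0
        d[i] = np.inf
        for fld in missing:
            donors = np.where(~pd.isna(records[fld]).to_numpy()
                              & np.isfinite(d))[0]
            if len(donors) == 0:
                raise ValueError(f"no donor observes field {fld!r}")
            order = donors[np.lexsort((donors, d[donors]))]
            chosen = order[:k]
            vals = records[fld].iloc[chosen]
            if schema[fld] == "numeric":
                imputed = float(np.median(vals.to_numpy(float)))
            else:
                counts = vals.value_counts()
                top = counts[counts == counts.max()].index
                if len(top) == 1:
                    imputed = top[0]
                else:
                    imputed = next(v for v in vals if v in set(top))
            out.loc[out.index[i], fld] = imputed
            log.append({"row": int(i), "id": str(records.index[i]),
                        "field": fld, "value": imputed,
                        "n_donors": int(len(chosen))})
    return out, log


@dataclass
class RiskScoreResult:
    participant_id: str
    score: float
    contributions: dict[str, float]
    imputed: set[str]
    tertile: str | None = None


def compute_score(record: pd.Series | dict,
                  coefficients: dict[str, dict[str, float]],
                  age: float | None = None,
                  imputed: set[str] | None = None) -> RiskScoreResult:
    """Additive risk score for one completed record.

    The age stratum is <50 vs ≥50; binary factors are coded 1/0 and
    continuous factors enter as-is. Raises if any factor is still missing.
    """
    rec = pd.Series(record)
    if age is None:
        age = float(rec["age_years"])
    stratum = "under_50" if age < 50 else "over_50"
    coefs = coefficients[stratum]
    contributions = {}
    for fld in RISK_FACTORS:
        v = rec.get(fld)
        if pd.isna(v):
            raise ValueError(f"factor {fld!r} missing after imputation")
        contributions[fld] = coefs[fld] * float(v)
    pid = str(rec.get("participant_id", rec.name if hasattr(rec, "name") else ""))
    return RiskScoreResult(participant_id=pid,
                           score=float(sum(contributions.values())),
                           contributions=contributions,
                           imputed=set(imputed or ()))


def assign_tertiles(scores: pd.Series, control_ids) -> pd.Series:
    """Low/medium/high labels from control-only tertile cutpoints.

    Cutpoints are the 1/3 and 2/3 empirical quantiles (linear interpolation)
    of the controls' scores; intervals are (−∞, q1], (q1, q2], (q2, ∞).
    """
    ctrl = scores.loc[scores.index.intersection(pd.Index(control_ids))]
    if len(ctrl) < 3:
        raise ValueError("need at least 3 controls for tertiles")
    q1, q2 = np.quantile(ctrl.to_numpy(float), [1 / 3, 2 / 3])
    if q1 == q2:
        import warnings
        warnings.warn("degenerate control scores: single tertile cutpoint")
    labels = pd.Series(
        np.where(scores <= q1, "low",
                 np.where(scores <= q2, "medium", "high")),
        index=scores.index, name="tertile")
    labels.attrs["cutpoints"] = (float(q1), float(q2))
    return labels


def risk_scores(roster: pd.DataFrame,
                coefficients: dict[str, dict[str, float]],
                k: int = 5) -> pd.DataFrame:
    """Impute, score and tertile-group every participant in a roster.

    Returns a frame indexed by participant_id with score, tertile and the
    imputed field list per participant.
    """
    factors = [f for f in RISK_FACTORS if f in roster.columns]
    sub = roster.set_index("participant_id")[["arm", "age_years"] + factors]
    completed, log = knn_impute(sub[factors], k=k)
    imputed_by_id: dict[str, set[str]] = {}
    for entry in log:
        imputed_by_id.setdefault(entry["id"], set()).add(entry["field"])

    results = []
    for pid, row in completed.iterrows():
        rec = row.copy()
        res = compute_score(rec, coefficients, age=float(sub.loc[pid, "age_years"]),
                            imputed=imputed_by_id.get(pid, set()))
        results.append({"participant_id": pid, "score": res.score,
                        "imputed_fields": ";".join(sorted(res.imputed))})
    out = pd.DataFrame(results).set_index("participant_id")
    control_ids = sub.index[sub["arm"] == "control"]
    out["tertile"] = assign_tertiles(out["score"], control_ids)
    return out
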