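"""Conditional logistic regression for matched case-control sets.

For a stratum s with one case and m controls the conditional likelihood of
the case being the member it is, given that exactly one member is a case, is
exp(x_case·β) / Σ_{j∈s} exp(x_j·β); the model maximises

    ℓ(β) = Σ_s [ x_case·β − log Σ_{j∈s} exp(x_j·β) ]

by Newton–Raphson with analytic gradient and Hessian and a log-sum-exp
stabilised objective. Stratum-specific intercepts cancel, so any covariate
constant within every stratum is unidentifiable; such columns are detected,
pinned at zero and flagged rather than fitted.

The month-wise scans refit the model at every relative month with the
3-month-window purchase count as the exposure, optionally adjusted for
oral-contraceptive use, household size, season, a COVID-era indicator, GP
attendance, symptom report or the additive risk score.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import months
from .panel import AlignedPanel, REL_MONTHS

_Z975 = stats.norm.ppf(0.975)


def _group_structure(groups: np.ndarray):
    """Sort rows by group; return order, group start indices, sizes."""
    order = np.argsort(groups, kind="stable")
    g = np.asarray(groups)[order]
    starts = np.r_[0, np.nonzero(g[1:] != g[:-1])[0] + 1]
    sizes = np.diff(np.r_[starts, len(g)])
    return order, starts, sizes


class ConditionalLogit:
    """Conditional logistic regression model for 1:m matched strata.

    Parameters
    ----------
    endog : array of 0/1, one 1 per group (the case)
    exog : (n, k) covariate matrix, exposure first by convention
    groups : stratum labels
    exog_names : optional column names for reporting
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        endog = np.asarray(endog, dtype=float)
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if exog.shape[0] != len(endog):
            exog = exog.T
        if not np.all(np.isfinite(exog)):
            raise ValueError("non-finite covariate values")
        if not np.all((endog == 0) | (endog == 1)):
            raise ValueError("endog must be 0/1")
        groups = np.asarray(groups)
        order, starts, sizes = _group_structure(groups)
        self.endog = endog[order]
        self.exog = exog[order]
        self.groups = groups[order]
        self._starts = starts
        self._sizes = sizes
        ones_per = np.add.reduceat(self.endog, starts)
        if not np.all(ones_per == 1):
            raise ValueError("each stratum must contain exactly one case")
        self.n_strata = len(starts)
        self.k = self.exog.shape[1]
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(self.k)])
        # identifiability: a covariate constant within every stratum cancels
        rep = np.repeat(starts, sizes)
        within_dev = self.exog - self.exog[rep]  # deviation from group's 1st row
        dev_ptp = np.abs(within_dev).max(axis=0) if len(self.exog) else \
            np.zeros(self.k)
        self.identified = dev_ptp > 1e-12
        self._case_idx = np.nonzero(self.endog == 1)[0]

    # -- likelihood ---------------------------------------------------------
    def _eta_terms(self, params):
        eta = self.exog @ params
        gmax = np.maximum.reduceat(eta, self._starts)
        z = np.exp(eta - np.repeat(gmax, self._sizes))
        denom = np.add.reduceat(z, self._starts)
        return eta, gmax, z, denom

    def loglike(self, params) -> float:
        params = np.asarray(params, dtype=float)
        eta, gmax, z, denom = self._eta_terms(params)
        return float(np.sum(eta[self._case_idx] - gmax - np.log(denom)))

    def score(self, params) -> np.ndarray:
        params = np.asarray(params, dtype=float)
        _, _, z, denom = self._eta_terms(params)
        p = z / np.repeat(denom, self._sizes)
        xbar = np.add.reduceat(p[:, None] * self.exog, self._starts, axis=0)
        return (self.exog[self._case_idx] - xbar).sum(axis=0)

    def hessian(self, params) -> np.ndarray:
        params = np.asarray(params, dtype=float)
        _, _, z, denom = self._eta_terms(params)
        p = z / np.repeat(denom, self._sizes)
        xw = p[:, None] * self.exog
        xbar = np.add.reduceat(xw, self._starts, axis=0)      # (S, k)
        sxx = np.add.reduceat(xw[:, :, None] * self.exog[:, None, :],
                              self._starts, axis=0)            # (S, k, k)
        cov = sxx - xbar[:, :, None] * xbar[:, None, :]
        return -cov.sum(axis=0)

    def fit(self, start_params=None, maxiter: int = 50, gtol: float = 1e-8,
            ltol: float = 1e-10, bound: float = 15.0) -> "CLRFit":
        """Newton–Raphson with step-halving from β=0.

        Convergence when max |∇ℓ| < gtol or the relative change in ℓ is
        below ltol; a coefficient wandering past ``bound`` on the log-OR
        scale is flagged as (quasi-)complete separation.
        """
        free = np.nonzero(self.identified)[0]
        beta = np.zeros(self.k)
        if start_params is not None:
            beta = np.asarray(start_params, dtype=float).copy()
            beta[~self.identified] = 0.0
        converged = False
        separation = False
        ll = self.loglike(beta)
        if len(free) == 0:
            converged = True
        for _ in range(maxiter):
            if converged or separation:
                break
            g = self.score(beta)[free]
            if np.max(np.abs(g)) < gtol:
                converged = True
                break
            H = self.hessian(beta)[np.ix_(free, free)]
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-H, g, rcond=None)[0]
            lam = 1.0
            for _half in range(30):
                cand = beta.copy()
                cand[free] += lam * step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                lam *= 0.5
            beta, ll_prev, ll = cand, ll, ll_new
            if np.max(np.abs(beta[free])) > bound:
                separation = True
                break
            if abs(ll - ll_prev) < ltol * (abs(ll_prev) + 1e-12) and \
                    np.max(np.abs(self.score(beta)[free])) < 1e-6:
                converged = True
                break
        # a conditional likelihood approaching its supremum of 0 means the
        # case is predicted perfectly in every stratum: complete separation
        if len(free) and ll > -1e-6 * max(self.n_strata, 1):
            separation = True
            converged = False

        se = np.full(self.k, np.nan)
        if len(free) and not separation:
            H = self.hessian(beta)[np.ix_(free, free)]
            try:
                cov = np.linalg.inv(-H)
                se_free = np.sqrt(np.clip(np.diag(cov), 0, None))
                se[free] = se_free
            except np.linalg.LinAlgError:
                pass
        return CLRFit(model=self, params=beta, bse=se, llf=ll,
                      converged=bool(converged), separation=bool(separation),
                      nonidentified=[self.exog_names[j] for j in
                                     np.nonzero(~self.identified)[0]],
                      n_strata=self.n_strata)


@dataclass
class CLRFit:
    """Fitted conditional logistic regression."""

    model: ConditionalLogit
    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    separation: bool
    nonidentified: list[str]
    n_strata: int
    alpha: float = field(default=0.05)

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return np.column_stack([lo, hi])

    def or_table(self) -> pd.DataFrame:
        with np.errstate(over="ignore"):
            ci = np.exp(self.conf_int())
        return pd.DataFrame({
            "term": self.model.exog_names,
            "beta": self.params, "se": self.bse, "or": self.or_,
            "ci_lo": ci[:, 0], "ci_hi": ci[:, 1],
        })

    def summary(self) -> str:
        head = (f"Conditional logistic regression  "
                f"(strata: {self.n_strata}, loglik: {self.llf:.3f}, "
                f"converged: {self.converged})")
        notes = []
        if self.separation:
            notes.append("WARNING: separation detected; estimates unreliable")
        if self.nonidentified:
            notes.append("not identifiable (constant within strata): "
                         + ", ".join(self.nonidentified))
        tbl = self.or_table().to_string(
            index=False, float_format=lambda v: f"{v: .4f}")
        return "\n".join([head, tbl] + notes)


def fit_clr(endog, exog, groups, exog_names=None, **fit_kws) -> CLRFit:
    """One-call fit of a conditional logistic regression."""
    return ConditionalLogit(endog, exog, groups, exog_names).fit(**fit_kws)


# -- covariate assembly for scans ------------------------------------------

KNOWN_ADJUSTMENTS = ("oc_ever", "household_size", "gp_visits", "symptom_any",
                     "season", "covid_era", "risk_score")


def _member_covariates(panel: AlignedPanel, roster: pd.DataFrame,
                       adjustments, m: int,
                       risk_scores: pd.Series | None) -> tuple[np.ndarray, list[str]]:
    """Build the adjustment design matrix for month ``m``.

    Roster covariates attach per participant appearance; season and COVID-era
    indicators derive from each member's own calendar month at ``m``. Missing
    roster values are filled with the column median (impute upstream for
    anything better).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    ros = roster.set_index("participant_id")
    pids = panel.members["participant_id"]
    for adj in adjustments:
        if adj in ("oc_ever", "household_size", "gp_visits"):
            v = ros[adj].reindex(pids).to_numpy(float)
            med = np.nanmedian(v)
            cols.append(np.where(np.isfinite(v), v, med))
            names.append(adj)
        elif adj == "symptom_any":
            sym = [c for c in ros.columns if c.startswith("symptom_")]
            v = (ros[sym].reindex(pids).fillna(0).to_numpy(float)
                 .max(axis=1))
            cols.append(v)
            names.append(adj)
        elif adj == "season":
            cal = panel.calendar_month(m)
            seas = np.array([months.season(o) for o in cal])
            for s in ("spring", "summer", "autumn"):  # winter is baseline
                cols.append((seas == s).astype(float))
                names.append(f"season_{s}")
        elif adj == "covid_era":
            cal = panel.calendar_month(m)
            cols.append((cal >= months.COVID_START).astype(float))
            names.append(adj)
        elif adj == "risk_score":
            if risk_scores is None:
                raise ValueError("risk_score adjustment requires scores")
            cols.append(risk_scores.reindex(pids).to_numpy(float))
            names.append(adj)
        else:
            raise ValueError(f"unknown adjustment {adj!r}; "
                             f"known: {KNOWN_ADJUSTMENTS}")
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(pids), 0)), names


@dataclass
class CLRScanResults:
    """Per-month conditional-logistic fits for one exposure definition."""

    table: pd.DataFrame   # month, term, beta, se, or, ci_lo, ci_hi, n_strata, converged
    category: tuple[str, ...]
    flags: dict

    def exposure_table(self) -> pd.DataFrame:
        return (self.table[self.table["term"] == "exposure"]
                .reset_index(drop=True))

    def summary(self) -> str:
        t = self.exposure_table()
        lines = [f"CLR scan, exposure: {'+'.join(self.category)} "
                 f"({self.flags.get('exposure_form')}), adjustments: "
                 f"{self.flags.get('adjustments')}"]
        lines.append(t.to_string(index=False,
                                 float_format=lambda v: f"{v:.4g}"))
        sig = t[(t["ci_lo"] > 1) & t["converged"]]
        if len(sig):
            lines.append("months with CI excluding OR=1 (increase): "
                         + ", ".join(str(int(m)) for m in sig["month"]))
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        t = self.exposure_table()
        ax.plot(t["month"], t["or"], "o-", color="steelblue")
        ax.fill_between(t["month"], t["ci_lo"], t["ci_hi"], alpha=0.2,
                        color="steelblue")
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xlabel("months before diagnosis")
        ax.set_ylabel("adjusted odds ratio")
        return ax


class MonthlyCLRScan:
    """Month-wise conditional logistic regression scan.

    The exposure at month m is the member's 3-month-window purchase count of
    the chosen categories (``exposure='window'``), the single-month count
    (``'single_month'``) or any-purchase indicator (``'binary'``).
    """

    def __init__(self, panel: AlignedPanel, roster: pd.DataFrame,
                 category=("pain", "indigestion"),
                 adjustments: tuple[str, ...] = (),
                 exposure: str = "window", window_style: str = "centered",
                 risk_scores: pd.Series | None = None):
        if exposure not in ("window", "single_month", "binary"):
            raise ValueError(f"unknown exposure form {exposure!r}")
        self.panel = panel
        self.roster = roster
        self.category = (category,) if isinstance(category, str) else tuple(category)
        self.adjustments = tuple(adjustments)
        self.exposure = exposure
        self.window_style = window_style
        self.risk_scores = risk_scores

    def _exposure_at(self, m: int) -> np.ndarray:
        if self.exposure == "window":
            return self.panel.window_sum(m, list(self.category),
                                         style=self.window_style).astype(float)
        from .panel import rel_index
        idx = self.panel.category_index(list(self.category))
        x = self.panel.counts[:, idx, rel_index(m)].sum(axis=1).astype(float)
        if self.exposure == "binary":
            win = self.panel.window_sum(m, list(self.category),
                                        style=self.window_style)
            return (win > 0).astype(float)
        return x

    def fit(self) -> CLRScanResults:
        rows = []
        groups = self.panel.members["set_id"].to_numpy()
        endog = self.panel.is_case.astype(float)
        for m in REL_MONTHS:
            x = self._exposure_at(int(m))
            adj, names = _member_covariates(self.panel, self.roster,
                                            self.adjustments, int(m),
                                            self.risk_scores)
            exog = np.column_stack([x, adj]) if adj.shape[1] else x[:, None]
            fit = fit_clr(endog, exog, groups,
                          exog_names=["exposure"] + names)
            tab = fit.or_table()
            tab.insert(0, "month", int(m))
            tab["n_strata"] = fit.n_strata
            tab["converged"] = fit.converged and not fit.separation
            tab["separation"] = fit.separation
            rows.append(tab)
        table = pd.concat(rows, ignore_index=True)
        return CLRScanResults(table=table, category=self.category,
                              flags={"exposure_form": self.exposure,
                                     "adjustments": list(self.adjustments),
                                     "window_style": self.window_style})


def monthly_clr_scan(panel, roster, category=("pain", "indigestion"),
                     adjustments=(), **kwargs) -> CLRScanResults:
    """Functional shorthand for ``MonthlyCLRScan(…).fit()``."""
    return MonthlyCLRScan(panel, roster, category, adjustments,
                          **kwargs).fit()


def cumulative_clr(panel: AlignedPanel, roster: pd.DataFrame,
                   category=("pain", "indigestion"),
                   adjustments: tuple[str, ...] = (),
                   horizons: tuple[int, ...] = (6, 12, 24),
                   risk_scores: pd.Series | None = None) -> pd.DataFrame:
    """CLR of mean monthly purchases over the last h months, per horizon.

    The exposure for horizon h is the member's mean monthly purchase count of
    the chosen categories over relative months −h…−1.
    """
    category = (category,) if isinstance(category, str) else tuple(category)
    idx = panel.category_index(list(category))
    groups = panel.members["set_id"].to_numpy()
    endog = panel.is_case.astype(float)
    out = []
    for h in horizons:
        if not (1 <= h <= 24):
            raise ValueError("horizon must be in 1..24")
        x = panel.counts[:, idx, 24 - h:].sum(axis=(1, 2)) / h
        adj, names = _member_covariates(panel, roster, adjustments, -1,
                                        risk_scores)
        exog = np.column_stack([x, adj]) if adj.shape[1] else x[:, None]
        fit = fit_clr(endog, exog, groups, exog_names=["exposure"] + names)
        tab = fit.or_table()
        tab.insert(0, "horizon_months", h)
        tab["converged"] = fit.converged and not fit.separation
        tab["separation"] = fit.separation
        out.append(tab[tab["term"] == "exposure"])
    return pd.concat(out, ignore_index=True)


def unconditional_logistic(roster: pd.DataFrame, covariates: list[str],
                           outcome: str = "arm"):
    """Standard (unmatched) ML logistic regression of case status.

    A generic utility for risk tables on the full roster; rows with missing
    covariates are dropped. Returns a statsmodels results object.
    """
    import statsmodels.api as sm
    df = roster[[outcome] + covariates].dropna()
    y = (df[outcome] == "case").astype(float) if outcome == "arm" \
        else df[outcome].astype(float)
    X = df[covariates].astype(float)
    keep = [c for c in covariates if X[c].nunique() > 1]
    X = sm.add_constant(X[keep], has_constant="add")
    res = sm.Logit(y, X).fit(disp=0)
    res.dropped_constant_covariates = [c for c in covariates if c not in keep]
    return res
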