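"""Concentration–response fitting: 3-parameter logistic and the
operational model of allosterism.

The operational model of allosterism describes the response of a receptor
to an orthosteric agonist A in the presence of an allosteric modulator B:

    E = Em * num^n / (den^n + num^n)
    num = tau_A*[A]*(K_B + alpha*beta*[B]) + tau_B*[B]*K_A
    den = [A]*K_B + K_A*K_B + K_A*[B] + alpha*[A]*[B]

with Em the maximal system response, n the transducer slope, tau_A/tau_B
the operational efficacies of agonist and modulator, K_A/K_B their
equilibrium dissociation constants (M), alpha the affinity cooperativity
and beta the efficacy cooperativity.  At [B] = 0 this reduces exactly to
the operational model of agonism.  The headline quantity is the composite
cooperativity Logαβ = log10(alpha*beta): with functional data alone alpha
and beta are only jointly identifiable, so the default constraint set
fixes alpha = 1 and carries all cooperativity in a single log10(αβ)
parameter; (alpha, beta) are reported separately only under user-supplied
constraints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

from .io import DoseResponseDataset

logger = logging.getLogger(__name__)

__all__ = [
    "OperationalParams",
    "LogisticFit",
    "AllosteryFit",
    "ComparisonResult",
    "FitError",
    "logistic3",
    "operational_response",
    "operational_agonism",
    "fit_logistic3",
    "fit_operational_allosterism",
    "logab",
    "compare_conditions",
]


class FitError(RuntimeError):
    """Raised when a fit is unidentifiable or fails to converge."""


@dataclass(frozen=True)
class OperationalParams:
    """Parameter set of the operational model of allosterism."""

    em: float  # maximal system response (assay units)
    tau_a: float  # operational efficacy of the agonist
    tau_b: float  # operational efficacy of the modulator
    k_a: float  # agonist dissociation constant, M
    k_b: float  # modulator dissociation constant, M
    alpha: float = 1.0  # affinity cooperativity
    beta: float = 1.0  # efficacy cooperativity
    n: float = 1.0  # transducer slope

    def __post_init__(self) -> None:
        for name in ("tau_a", "k_a", "k_b", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tau_b < 0:
            raise ValueError("tau_b must be >= 0")

    @property
    def logab(self) -> float:
        """log10 of the composite cooperativity alpha*beta."""
        return math.log10(self.alpha * self.beta)

    @property
    def pec50_vehicle(self) -> float:
        """Vehicle potency implied by the agonism reduction (n = 1 only)."""
        return -math.log10(self.k_a / (1.0 + self.tau_a))


def logistic3(log_conc: np.ndarray, bottom: float, top: float, pec50: float) -> np.ndarray:
    """Unit-slope 3-parameter logistic on log10 molar concentration."""
    log_conc = np.asarray(log_conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (-pec50 - log_conc))


def operational_response(
    conc_a: np.ndarray, conc_b: np.ndarray, params: OperationalParams
) -> np.ndarray:
    """Response surface of the operational model of allosterism."""
    a = np.asarray(conc_a, dtype=float)
    b = np.asarray(conc_b, dtype=float)
    p = params
    ab = p.alpha * p.beta
    num = p.tau_a * a * (p.k_b + ab * b) + p.tau_b * b * p.k_a
    den = a * p.k_b + p.k_a * p.k_b + p.k_a * b + p.alpha * a * b
    return p.em * num**p.n / (den**p.n + num**p.n)


def operational_agonism(conc_a: np.ndarray, params: OperationalParams) -> np.ndarray:
    """Operational model of agonism (no modulator)."""
    a = np.asarray(conc_a, dtype=float)
    p = params
    num = p.tau_a * a
    den = a + p.k_a
    return p.em * num**p.n / (den**p.n + num**p.n)


# ---------------------------------------------------------------------------
# 3-parameter logistic fitting


@dataclass
class LogisticFit:
    """Per-group logistic fit with per-replicate estimates."""

    group: tuple
    pec50: float
    pec50_sem: float
    top: float
    bottom: float
    per_replicate: pd.DataFrame  # columns: replicate, pec50, top, bottom, converged
    ec50_in_span: bool
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return f"{self.pec50:.2f} ± {self.pec50_sem:.2f}"


def _fit_logistic_once(log_conc: np.ndarray, response: np.ndarray) -> lmfit.minimizer.MinimizerResult:
    span = response.max() - response.min()
    if span <= 1e-12 * max(1.0, abs(response).max()):
        raise FitError("responses are constant: top and bottom are unidentifiable")
    model = lmfit.Model(logistic3, independent_vars=["log_conc"])
    half = response.min() + span / 2.0
    guess = -log_conc[np.argmin(np.abs(response - half))]
    params = model.make_params(
        bottom=dict(value=float(response.min())),
        top=dict(value=float(response.max())),
        pec50=dict(value=float(guess), min=-log_conc.max() - 6, max=-log_conc.min() + 6),
    )
    return model.fit(response, params, log_conc=log_conc)


def fit_logistic3(
    dataset: DoseResponseDataset,
    grouping: Sequence[str] = ("agonist", "modulator_concentration"),
) -> list[LogisticFit]:
    """Fit the unit-slope 3-parameter logistic per group, replicate-wise.

    Each replicate curve is fitted independently; the group estimate is
    the mean ± SEM across replicates, the convention used when potencies
    are tabulated per assay plate.
    """
    fits: list[LogisticFit] = []
    for key, grp in dataset.table.groupby(list(grouping)):
        key = key if isinstance(key, tuple) else (key,)
        if grp["agonist_concentration"].nunique() < 4:
            raise FitError(f"group {key}: need >= 4 distinct agonist concentrations")
        rows = []
        flags: list[str] = []
        for rep, sub in grp.groupby("replicate"):
            log_conc = np.log10(sub["agonist_concentration"].to_numpy())
            resp = sub["response"].to_numpy()
            try:
                res = _fit_logistic_once(log_conc, resp)
                rows.append(
                    dict(
                        replicate=rep,
                        pec50=res.params["pec50"].value,
                        top=res.params["top"].value,
                        bottom=res.params["bottom"].value,
                        converged=bool(res.success),
                    )
                )
                if not res.success:
                    flags.append(f"replicate {rep}: fit did not converge")
            except FitError:
                raise
            if np.any(np.diff(pd.Series(resp).groupby(log_conc).mean().to_numpy()) < -0.5 * np.ptp(resp)):
                flags.append(f"replicate {rep}: non-monotonic response profile")
        per_rep = pd.DataFrame(rows)
        ok = per_rep[per_rep["converged"]]
        if ok.empty:
            raise FitError(f"group {key}: no replicate converged")
        pec50 = float(ok["pec50"].mean())
        sem = float(ok["pec50"].std(ddof=1) / math.sqrt(len(ok))) if len(ok) > 1 else float("nan")
        span_lo = -math.log10(grp["agonist_concentration"].max())
        span_hi = -math.log10(grp["agonist_concentration"].min())
        in_span = span_lo <= pec50 <= span_hi
        if not in_span:
            flags.append("EC50 outside tested concentration span")
        fits.append(
            LogisticFit(
                group=key,
                pec50=pec50,
                pec50_sem=sem,
                top=float(ok["top"].mean()),
                bottom=float(ok["bottom"].mean()),
                per_replicate=per_rep,
                ec50_in_span=in_span,
                flags=flags,
            )
        )
    return fits


# ---------------------------------------------------------------------------
# Operational model of allosterism: global surface fit


@dataclass
class AllosteryFit:
    """Global operational-model fit across modulator concentrations."""

    params: OperationalParams
    logab: float
    logab_se: float
    constraints: dict
    result: lmfit.minimizer.MinimizerResult
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        se = "n/a" if not np.isfinite(self.logab_se) else f"{self.logab_se:.2f}"
        return f"Logαβ = {self.logab:.2f} ± {se}"


#: Default constraint set: unit transducer slope, shared Em, alpha fixed to 1
#: (cooperativity carried entirely by log10(αβ)), K_A tied to the
#: vehicle-curve potency through K_A = EC50_vehicle * (1 + tau_A).
DEFAULT_CONSTRAINTS: dict = {"n": 1.0, "alpha": 1.0, "k_a": "vehicle"}


def _multistart_grid(log_kb_values: Sequence[float]) -> list[dict]:
    return [
        {"log_tau_a": log_tau_a, "log_kb": log_kb}
        for log_tau_a in (-0.5, 0.5, 1.5)
        for log_kb in log_kb_values
    ]


def fit_operational_allosterism(
    dataset: DoseResponseDataset,
    constraints: Mapping | None = None,
    agonist: str | None = None,
) -> AllosteryFit:
    """Globally fit the operational model of allosterism to a response surface.

    All curves (one per modulator concentration, replicates pooled as
    observations) are fitted simultaneously.  ``constraints`` maps
    parameter names (``n``, ``alpha``, ``beta``, ``em``, ``tau_a``,
    ``tau_b``, ``k_a``, ``k_b``) to fixed numeric values; ``k_a`` may be
    the string ``"vehicle"`` to tie it to the vehicle-fit potency via
    K_A = EC50_vehicle * (1 + tau_A).  Parameters not named are free.
    Freeing ``alpha`` and ``beta`` together without fixing either is
    rejected: with functional data they are aliased through their
    product.

    Multi-start initialisation over a fixed log-spaced grid guards
    against local minima; the start with the lowest residual wins.
    """
    constraints = dict(DEFAULT_CONSTRAINTS if constraints is None else constraints)
    table = dataset.table
    if agonist is not None:
        table = table[table["agonist"] == agonist]
    if table.empty:
        raise FitError("no data for requested agonist")
    if table["modulator_concentration"].nunique() < 3:
        raise FitError("need >= 3 modulator concentrations (including vehicle)")
    if not (table["modulator_concentration"] == 0).any():
        raise FitError("dataset must include vehicle (modulator = 0) curves")
    if "alpha" not in constraints and "beta" not in constraints:
        raise FitError(
            "alpha and beta are aliased (only their product is identifiable "
            "from functional data): fix one of them or fit log10(αβ) only"
        )

    conc_a = table["agonist_concentration"].to_numpy()
    conc_b = table["modulator_concentration"].to_numpy()
    y = table["response"].to_numpy()

    # vehicle potency for the K_A tie
    veh = DoseResponseDataset(
        table[table["modulator_concentration"] == 0].drop(columns=["vehicle"])
    )
    pec50_veh = fit_logistic3(veh, grouping=("modulator_concentration",))[0].pec50

    p = lmfit.Parameters()
    scale = max(float(np.max(y)), 1e-9)
    # concentration-scale-aware bounds keep the fit invariant to the
    # unit the table is expressed in (M vs nM only shifts pK values)
    mod_pos = conc_b[conc_b > 0]
    log_b_lo, log_b_hi = math.log10(mod_pos.min()), math.log10(mod_pos.max())
    log_a_lo, log_a_hi = math.log10(conc_a.min()), math.log10(conc_a.max())

    def add_log(name: str, value: float, lo: float, hi: float) -> None:
        if name in constraints and constraints[name] != "vehicle":
            p.add(f"log_{name}", value=math.log10(float(constraints[name])), vary=False)
        else:
            p.add(f"log_{name}", value=value, min=lo, max=hi)

    add_log("em", math.log10(scale) + 0.05, math.log10(scale) - 1.5, math.log10(scale) + 2.0)
    add_log("tau_a", 0.5, -2.5, 3.5)
    add_log("tau_b", -1.0, -6.0, 2.5)
    add_log("kb", (log_b_lo + log_b_hi) / 2, log_b_lo - 3.0, log_b_hi + 3.0)
    if constraints.get("k_a") == "vehicle":
        p.add("log_ka", expr=f"log10(1 + 10**log_tau_a) + ({-pec50_veh})")
    else:
        add_log("ka", (log_a_lo + log_a_hi) / 2, log_a_lo - 3.0, log_a_hi + 3.0)
    if "beta" not in constraints:
        # cooperativity carried by log_ab; alpha is fixed
        p.add("log_alpha", value=math.log10(float(constraints["alpha"])), vary=False)
        p.add("log_ab", value=0.3, min=-3.0, max=4.0)
    else:
        add_log("alpha", 0.0, -3.0, 4.0)
        p.add("log_beta", value=math.log10(float(constraints["beta"])), vary=False)
        p.add("log_ab", expr="log_alpha + log_beta")

    n_slope = float(constraints.get("n", 1.0))

    def residual(params: lmfit.Parameters) -> np.ndarray:
        v = params.valuesdict()
        op = OperationalParams(
            em=10 ** v["log_em"],
            tau_a=10 ** v["log_tau_a"],
            tau_b=10 ** v["log_tau_b"],
            k_a=10 ** v["log_ka"],
            k_b=10 ** v["log_kb"],
            alpha=10 ** v["log_alpha"],
            beta=10 ** (v["log_ab"] - v["log_alpha"]),
            n=n_slope,
        )
        return operational_response(conc_a, conc_b, op) - y

    best: lmfit.minimizer.MinimizerResult | None = None
    for start in _multistart_grid((log_b_lo, (log_b_lo + log_b_hi) / 2)):
        trial = p.copy()
        for name, val in start.items():
            if name in trial and trial[name].vary:
                trial[name].value = val
        try:
            res = lmfit.minimize(residual, trial, method="least_squares", ftol=1e-10, xtol=1e-12)
        except Exception:  # singular trial start; other starts may succeed
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError("operational-model fit failed from every start")

    v = best.params.valuesdict()
    fitted = OperationalParams(
        em=10 ** v["log_em"],
        tau_a=10 ** v["log_tau_a"],
        tau_b=10 ** v["log_tau_b"],
        k_a=10 ** v["log_ka"],
        k_b=10 ** v["log_kb"],
        alpha=10 ** v["log_alpha"],
        beta=10 ** (v["log_ab"] - v["log_alpha"]),
        n=n_slope,
    )
    se = best.params["log_ab"].stderr
    flags = []
    if not best.success:
        flags.append("optimizer reported non-convergence")
    return AllosteryFit(
        params=fitted,
        logab=float(v["log_ab"]),
        logab_se=float(se) if se is not None else float("nan"),
        constraints=constraints,
        result=best,
        flags=flags,
    )


def logab(
    alpha: float,
    beta: float,
    cov: np.ndarray | None = None,
) -> tuple[float, float]:
    """Composite cooperativity log10(alpha*beta) with a delta-method SE.

    ``cov`` is the 2x2 covariance of (alpha, beta) on the natural scale;
    when omitted the SE is NaN.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    value = math.log10(alpha * beta)
    if cov is None:
        return value, float("nan")
    grad = np.array([1.0 / (alpha * math.log(10)), 1.0 / (beta * math.log(10))])
    var = float(grad @ np.asarray(cov, dtype=float) @ grad)
    return value, math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# Condition comparison


@dataclass
class ComparisonResult:
    anova: pd.DataFrame
    dunnett: pd.DataFrame  # per (agonist, condition): estimate, p_raw, p_adj, stars
    control: str


def _stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_conditions(
    table: pd.DataFrame,
    control: str,
    value: str = "pec50",
    condition: str = "condition",
    agonist: str = "agonist",
) -> ComparisonResult:
    """Two-way ANOVA (agonist x condition) with Dunnett tests vs control.

    ``table`` holds one row per replicate with columns for the agonist,
    the condition label (e.g. modulator concentration) and the fitted
    per-replicate parameter.  Conditions with a single replicate are
    excluded with a warning.  The control compared with itself reports
    p = 1 by convention.
    """
    import scipy.stats as st
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if control not in set(table[condition].astype(str)):
        raise ValueError(f"control level {control!r} absent from {condition!r}")
    work = table.copy()
    work[condition] = work[condition].astype(str)
    counts = work.groupby([agonist, condition])[value].count()
    thin = counts[counts < 2]
    for key in thin.index:
        logger.warning("condition %s excluded: single replicate", key)
        work = work[~((work[agonist] == key[0]) & (work[condition] == key[1]))]

    data = work.rename(columns={value: "y", condition: "cond", agonist: "ago"})
    n_ago = data["ago"].nunique()
    formula = "y ~ C(ago) * C(cond)" if n_ago > 1 else "y ~ C(cond)"
    model = ols(formula, data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    rows = []
    for ago, sub in data.groupby("ago"):
        ctrl_vals = sub.loc[sub["cond"] == control, "y"].to_numpy()
        others = [c for c in sorted(sub["cond"].unique()) if c != control]
        if others and len(ctrl_vals) >= 2:
            samples = [sub.loc[sub["cond"] == c, "y"].to_numpy() for c in others]
            dn = st.dunnett(*samples, control=ctrl_vals)
            for c, samp, p_adj in zip(others, samples, dn.pvalue):
                p_raw = st.ttest_ind(samp, ctrl_vals).pvalue
                rows.append(
                    dict(
                        agonist=ago,
                        condition=c,
                        estimate=float(np.mean(samp)),
                        delta=float(np.mean(samp) - np.mean(ctrl_vals)),
                        p_raw=float(p_raw),
                        p_adj=float(max(p_adj, p_raw)),
                        stars=_stars(float(max(p_adj, p_raw))),
                    )
                )
        rows.append(
            dict(
                agonist=ago,
                condition=control,
                estimate=float(np.mean(ctrl_vals)),
                delta=0.0,
                p_raw=1.0,
                p_adj=1.0,
                stars="ns",
            )
        )
    return ComparisonResult(anova=anova, dunnett=pd.DataFrame(rows), control=control)
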