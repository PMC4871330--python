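"""Logistic lameness models, ROC analysis and frozen-model scoring.

The scoring convention follows the published model equations: the linear
predictor ``intercept + sum(coef * x)`` has negative coefficients for
variables that are lower in lame cows, so lame cows obtain *higher* scores
and a cow is classified lame when its score strictly exceeds the cutoff
(cows exactly on the cutoff are non-lame).  The ROC cutoff rule selects the
threshold maximising sensitivity + specificity, preferring the higher
specificity on ties.  Univariable thresholds operate on the natural variable
scale with the direction implied by the odds-ratio sign (OR < 1: lame if
below the cutoff).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .variables import BY_NAME

__all__ = [
    "LogisticModel", "RocResult", "FrozenModel", "FROZEN_MODELS",
    "fit_logistic", "roc_analysis", "build_multivariable", "SelectionResult",
    "score_frozen", "FrozenEvaluation", "threshold_classify",
    "univariable_table", "confusion_metrics",
]


# --------------------------------------------------------------------------
# confusion metrics


def confusion_metrics(predicted, labels) -> dict:
    """Sensitivity / specificity / proportion correct (percent) plus counts."""
    pred = np.asarray(predicted, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    pos, neg = lab, ~lab
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & neg))
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    return {
        "tp": tp, "fn": n_pos - tp, "tn": tn, "fp": n_neg - tn,
        "n_pos": n_pos, "n_neg": n_neg,
        "sensitivity": 100.0 * tp / n_pos if n_pos else float("nan"),
        "specificity": 100.0 * tn / n_neg if n_neg else float("nan"),
        "proportion_correct": 100.0 * (tp + tn) / (n_pos + n_neg),
    }


def threshold_classify(values, cutoff: float, direction: str, labels) -> dict:
    """Classify on a single variable at a fixed natural-scale cutoff.

    ``direction='below'`` predicts lame for values strictly below the cutoff
    (variables with OR < 1); ``'above'`` for values strictly above (lying
    time, stride duration, lying bout duration).  Ties sit on the non-lame
    side.  Rows with missing values are dropped and counted.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    ok = ~np.isnan(v)
    if direction == "below":
        pred = v[ok] < cutoff
    elif direction == "above":
        pred = v[ok] > cutoff
    else:
        raise ValidationError("direction must be 'below' or 'above'")
    out = confusion_metrics(pred, lab[ok])
    out["n_missing"] = int((~ok).sum())
    out["cutoff"] = float(cutoff)
    out["direction"] = direction
    return out


# --------------------------------------------------------------------------
# ROC analysis


@dataclass
class RocResult:
    table: pd.DataFrame          # threshold, sensitivity, specificity
    auc: float
    cutoff: float
    sensitivity: float           # percent, at the selected cutoff
    specificity: float
    proportion_correct: float


def roc_analysis(scores, labels) -> RocResult:
    """ROC sweep of a lame-high score with the max(sens+spec) cutoff rule.

    AUC uses the rank (Mann-Whitney) construction with midranks, so ties
    count one half.  Candidate cutoffs are midpoints between consecutive
    distinct scores plus open ends; classification is lame when
    score > cutoff, and cutoff ties are resolved toward higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if np.any(np.isnan(s)):
        raise ValidationError("scores contain missing values")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    uniq = np.unique(s)
    cands = np.concatenate(([uniq[0] - 1.0],
                            (uniq[:-1] + uniq[1:]) / 2.0,
                            [uniq[-1] + 1.0]))
    pos, neg = s[y], s[~y]
    sens = np.array([(pos > c).mean() for c in cands])
    spec = np.array([(neg <= c).mean() for c in cands])
    total = sens + spec
    best = np.flatnonzero(total >= total.max() - 1e-12)
    pick = best[np.argmax(spec[best])]        # tie -> higher specificity
    cutoff = float(cands[pick])
    correct = 100.0 * (sens[pick] * n_pos + spec[pick] * n_neg) / (n_pos + n_neg)
    return RocResult(
        table=pd.DataFrame({"threshold": cands, "sensitivity": sens,
                            "specificity": spec}),
        auc=float(auc), cutoff=cutoff,
        sensitivity=float(100.0 * sens[pick]),
        specificity=float(100.0 * spec[pick]),
        proportion_correct=float(correct),
    )


# --------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticModel:
    intercept: float
    coefficients: dict[str, float]
    se: dict[str, float]
    wald_p: dict[str, float]
    or_table: pd.DataFrame        # variable, increment, OR, ci_low, ci_high, p
    r2_mcfadden: float
    r2_nagelkerke: float
    converged: bool
    separation: bool
    n_obs: int
    note: str = ""

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(frame), self.intercept, dtype=float)
        for name, b in self.coefficients.items():
            lp += b * frame[name].to_numpy(float)
        return lp

    @property
    def variables(self) -> list[str]:
        return list(self.coefficients)


def fit_logistic(frame: pd.DataFrame, labels, variables: list[str] | None = None
                 ) -> LogisticModel:
    """Maximum-likelihood logistic fit with Wald statistics and scaled ORs.

    Perfect or quasi-perfect separation does not raise: the model is returned
    with ``separation=True`` and a diagnostic note, so callers can decide.
    Odds ratios are reported per the field-customary increments (30 min of
    time, 1000 chews, 10 boluses/bouts, 100 strides, 100 ms, 10 cm, 0.1 m/s).
    """
    import statsmodels.api as sm

    variables = list(variables if variables is not None else frame.columns)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValidationError("need at least 2 cows in each class")
    x = frame[variables].to_numpy(float)
    if np.any(np.isnan(x)):
        raise ValidationError("missing feature values; drop or impute first")
    exog = sm.add_constant(x, has_constant="add")
    separation, note, converged = False, "", False
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception as exc:                      # e.g. PerfectSeparationError
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, exog).fit(disp=0, maxiter=50, method="bfgs")
        separation, note = True, f"separation detected: {exc}"
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not separation and (not converged or np.any(np.abs(params[1:]) > 1e3)
                           or np.any(~np.isfinite(bse))):
        separation = True
        note = note or "fit did not converge cleanly; possible separation"
    pvals = np.asarray(res.pvalues, dtype=float)
    coefs = dict(zip(variables, params[1:]))
    ses = dict(zip(variables, bse[1:]))
    wald = dict(zip(variables, pvals[1:]))
    rows = []
    np_err = np.seterr(over="ignore")   # CI bounds may overflow on separation
    for name in variables:
        inc = BY_NAME[name].or_increment if name in BY_NAME else 1.0
        b, se = coefs[name], ses[name]
        rows.append({
            "variable": name, "increment": inc,
            "odds_ratio": float(np.exp(b * inc)),
            "ci_low": float(np.exp((b - 1.959963984540054 * se) * inc)),
            "ci_high": float(np.exp((b + 1.959963984540054 * se) * inc)),
            "wald_p": wald[name],
        })
    np.seterr(**np_err)
    llf, llnull, n = float(res.llf), float(res.llnull), len(y)
    cox_snell = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    max_cs = 1.0 - np.exp(2.0 * llnull / n)
    return LogisticModel(
        intercept=float(params[0]), coefficients=coefs, se=ses, wald_p=wald,
        or_table=pd.DataFrame(rows),
        r2_mcfadden=float(1.0 - llf / llnull) if llnull != 0 else float("nan"),
        r2_nagelkerke=float(cox_snell / max_cs) if max_cs > 0 else float("nan"),
        converged=converged or separation, separation=separation,
        n_obs=n, note=note)


def univariable_table(frame: pd.DataFrame, variables: list[str], labels
                      ) -> pd.DataFrame:
    """Per-variable logistic model + ROC at the optimal natural-scale cutoff.

    The ROC runs on the variable itself, oriented lame-high by the sign of
    the fitted coefficient; the selected cutoff is mapped back to the natural
    scale together with its direction.
    """
    y = np.asarray(labels, dtype=bool)
    rows = []
    for name in variables:
        v = frame[name].to_numpy(float)
        ok = ~np.isnan(v)
        model = fit_logistic(frame.loc[ok, [name]], y[ok], [name])
        b = model.coefficients[name]
        sign = 1.0 if b >= 0 else -1.0
        roc = roc_analysis(sign * v[ok], y[ok])
        r = model.or_table.iloc[0]
        rows.append({
            "variable": name, "odds_ratio": r["odds_ratio"],
            "ci_low": r["ci_low"], "ci_high": r["ci_high"],
            "wald_p": r["wald_p"], "auc": roc.auc,
            "r2_mcfadden": model.r2_mcfadden,
            "r2_nagelkerke": model.r2_nagelkerke,
            "cutoff": sign * roc.cutoff,
            "direction": "above" if b >= 0 else "below",
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
            "proportion_correct": roc.proportion_correct,
            "separation": model.separation,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# correlation-filtered backward selection


@dataclass
class SelectionResult:
    model: LogisticModel
    variables: list[str]
    auc: float
    pre_elimination: LogisticModel
    pre_elimination_auc: float
    trace: list[dict] = field(default_factory=list)
    note: str = ""


def _model_auc(model: LogisticModel, frame: pd.DataFrame, y) -> float:
    return roc_analysis(model.linear_predictor(frame), y).auc


def build_multivariable(frame: pd.DataFrame, candidates: list[str], labels,
                        alpha: float = 0.05, rho_limit: float = 0.5
                        ) -> SelectionResult:
    """Correlation-filtered stepwise-backward multivariable model.

    Candidate variables (those significant in the two-group comparisons) may
    only share a model when their pairwise Spearman correlation lies strictly
    inside (-rho_limit, rho_limit); the admissible variable sets are the
    maximal cliques of that compatibility graph.  Each maximal set is fitted
    and backward-eliminated (repeatedly dropping the largest Wald p >= alpha,
    recording the model AUC before and after every removal); the final model
    is the eliminated model with the highest ROC AUC (ties: fewer variables,
    then candidate order).  The pre-elimination fit of the winning set is
    returned alongside, since a retained-but-non-significant variable can
    still be of practical interest.
    """
    from .group_stats import spearman_matrix

    candidates = list(candidates)
    y = np.asarray(labels, dtype=bool)
    if not candidates:
        raise ValidationError("no candidate variables")
    rho = spearman_matrix(frame, candidates) if len(candidates) > 1 else None
    g = nx.Graph()
    g.add_nodes_from(candidates)
    for a, b in itertools.combinations(candidates, 2):
        r = rho.loc[a, b]
        if not np.isnan(r) and abs(r) < rho_limit:
            g.add_edge(a, b)
    cliques = [sorted(c, key=candidates.index) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: [candidates.index(v) for v in c])
    note = ""
    if all(len(c) == 1 for c in cliques):
        note = "no admissible variable pair; best univariable model returned"

    best: SelectionResult | None = None
    for clique in cliques:
        sub = frame[clique].dropna()
        yy = y[frame[clique].notna().all(axis=1).to_numpy()]
        pre = fit_logistic(sub, yy, clique)
        pre_auc = _model_auc(pre, sub, yy)
        model, model_auc, vars_now = pre, pre_auc, list(clique)
        trace = [{"set": list(clique), "action": "fit", "auc": pre_auc}]
        while len(vars_now) > 1:
            worst = max(vars_now, key=lambda v: model.wald_p[v])
            if model.wald_p[worst] < alpha:
                break
            reduced_vars = [v for v in vars_now if v != worst]
            reduced = fit_logistic(sub, yy, reduced_vars)
            reduced_auc = _model_auc(reduced, sub, yy)
            trace.append({"set": list(vars_now), "action": f"drop {worst}",
                          "wald_p": model.wald_p[worst],
                          "auc_before": model_auc, "auc_after": reduced_auc})
            model, model_auc, vars_now = reduced, reduced_auc, reduced_vars
        cand = SelectionResult(model=model, variables=vars_now, auc=model_auc,
                               pre_elimination=pre, pre_elimination_auc=pre_auc,
                               trace=trace, note=note)
        if best is None or _better(cand, best, candidates):
            best = cand
    assert best is not None
    return best


def _better(a: SelectionResult, b: SelectionResult, order: list[str]) -> bool:
    if abs(a.auc - b.auc) > 1e-12:
        return a.auc > b.auc
    if len(a.variables) != len(b.variables):
        return len(a.variables) < len(b.variables)
    return [order.index(v) for v in a.variables] < [order.index(v)
                                                    for v in b.variables]


# --------------------------------------------------------------------------
# frozen (published) models


@dataclass(frozen=True)
class FrozenModel:
    """A fixed linear scoring rule; scoring is pure arithmetic, no fitting."""

    model_id: str
    intercept: float
    coefficients: dict[str, float]
    cutoffs: tuple[float, ...]

    @property
    def default_cutoff(self) -> float:
        return self.cutoffs[0]

    def score(self, frame: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(frame), self.intercept, dtype=float)
        for name, b in self.coefficients.items():
            if name not in frame.columns:
                raise ValidationError(f"missing variable {name!r} for model "
                                      f"{self.model_id}")
            lp += b * frame[name].to_numpy(float)
        return lp


FROZEN_MODELS: dict[str, FrozenModel] = {
    "A": FrozenModel(
        model_id="A", intercept=25.6859,
        coefficients={"standing_bouts": -0.1143,
                      "walking_speed_calc": -20.9763},
        cutoffs=(-0.06, 1.77, -2.08)),
    "B": FrozenModel(
        model_id="B", intercept=26.3199,
        coefficients={"eating_time": -0.0091, "standing_bouts": -0.1043,
                      "walking_speed_calc": -18.8167},
        cutoffs=(-0.49, 2.09, -2.08)),
}


@dataclass
class FrozenEvaluation:
    model_id: str
    cutoff: float
    scores: np.ndarray
    predicted_lame: np.ndarray      # boolean; NaN-score rows excluded
    n_missing: int
    metrics: dict | None            # confusion metrics when labels provided
    auc: float | None


def score_frozen(model: str | FrozenModel, frame: pd.DataFrame,
                 cutoff: float | None = None, labels=None) -> FrozenEvaluation:
    """Apply a frozen scoring rule; lame when score > cutoff."""
    fm = FROZEN_MODELS[model] if isinstance(model, str) else model
    scores = fm.score(frame)
    c = fm.default_cutoff if cutoff is None else float(cutoff)
    ok = ~np.isnan(scores)
    predicted = scores[ok] > c
    metrics = auc = None
    if labels is not None:
        lab = np.asarray(labels, dtype=bool)[ok]
        metrics = confusion_metrics(predicted, lab)
        auc = roc_analysis(scores[ok], lab).auc
    return FrozenEvaluation(
        model_id=fm.model_id, cutoff=c, scores=scores,
        predicted_lame=predicted, n_missing=int((~ok).sum()),
        metrics=metrics, auc=auc)
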