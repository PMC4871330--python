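"""Two- and four-group comparisons with normality-based test routing.

Routing mirrors a classical biostatistics workflow: Shapiro-Wilk on each
group at alpha 0.05 decides normal vs rank-based; for normal data an F-ratio
test on the variances chooses between the equal-variance T-test and the
Aspin-Welch (unequal-variance) test, otherwise the Wilcoxon rank-sum test is
used (exact enumeration for small tie-free samples, normal approximation
with tie and continuity correction otherwise).  Four-group comparisons use
one-way ANOVA with Bonferroni-corrected pairwise T-tests on the normal
route and Kruskal-Wallis with Dunn's pairwise Z tests (Bonferroni-corrected
critical value) on the rank route; pairwise outcomes are condensed into a
compact letter display (groups sharing a letter do not differ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ComparisonResult", "descriptives", "wilcoxon_rank_sum",
    "route_two_group_test", "four_group_compare", "spearman_matrix",
    "letters_from_nonsig", "dunn_test", "two_group_table",
]

ROUTING_ALPHA = 0.05
EXACT_THRESHOLD = 10


def descriptives(values) -> dict:
    """Mean, SD (n-1), median and interpolated IQR of one group."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q1, q3 = np.percentile(v, [25, 75])
    return {"n": int(v.size), "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "median": float(np.median(v)), "iqr": float(q3 - q1)}


@dataclass
class ComparisonResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    groups: dict[str, dict] = field(default_factory=dict)   # label -> descriptives
    pairwise: pd.DataFrame | None = None
    letters: dict[str, str] | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def wilcoxon_rank_sum(x, y, exact_threshold: int = EXACT_THRESHOLD
                      ) -> tuple[float, float, str]:
    """Rank-sum statistic of the first sample and two-sided p.

    Exact enumeration (via the Mann-Whitney exact distribution) when the
    smaller sample has at most ``exact_threshold`` observations and the data
    are tie-free; the tie-corrected normal approximation with continuity
    correction otherwise (midranks force the approximation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = (min(x.size, y.size) <= exact_threshold) and not ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    w = float(res.statistic + x.size * (x.size + 1) / 2.0)   # U -> rank sum
    return w, float(res.pvalue), "exact" if exact else "normal_approx"


def route_two_group_test(x, y, alpha: float = 0.05,
                         variable: str = "") -> ComparisonResult:
    """Two-group comparison with normality/variance routing (see module doc)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValidationError("each group needs n >= 3 for test routing")
    normal = all(_shapiro_normal(v) for v in (x, y))
    if normal:
        f_equal = _variances_equal(x, y)
        res = stats.ttest_ind(x, y, equal_var=f_equal)
        test = "t_equal_var" if f_equal else "aspin_welch"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p, _method = wilcoxon_rank_sum(x, y)
        test = "wilcoxon"
    return ComparisonResult(
        variable=variable, test=test, statistic=stat, p_value=p,
        groups={"x": descriptives(x), "y": descriptives(y)})


def _shapiro_normal(v: np.ndarray, alpha: float = ROUTING_ALPHA) -> bool:
    if np.ptp(v) == 0:
        return True          # degenerate constant sample: t route, p = 1
    return stats.shapiro(v).pvalue >= alpha


def _variances_equal(x, y, alpha: float = ROUTING_ALPHA) -> bool:
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    if v1 == 0 and v2 == 0:
        return True
    (va, na), (vb, nb) = sorted([(v1, len(x)), (v2, len(y))], reverse=True)
    if vb == 0:
        return False
    f = va / vb
    p = 2.0 * stats.f.sf(f, na - 1, nb - 1)
    return min(p, 1.0) >= alpha


def dunn_test(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's rank-based pairwise Z tests after Kruskal-Wallis.

    Uses pooled midranks with tie correction; Bonferroni is applied to the
    critical Z over all pairwise comparisons, per the usual
    multiple-comparison Z-value procedure.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank, sizes, at = {}, {}, 0
    for g in labels:
        n = len(groups[g])
        mean_rank[g] = float(ranks[at:at + n].mean())
        sizes[g] = n
        at += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    z_crit = stats.norm.ppf(1.0 - alpha / (2.0 * m))
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            rows.append({"group_a": a, "group_b": b, "z": float(z),
                         "p_raw": float(2.0 * stats.norm.sf(abs(z))),
                         "significant": bool(abs(z) > z_crit)})
    return pd.DataFrame(rows)


def _pairwise_t_bonferroni(groups: dict[str, np.ndarray],
                           alpha: float) -> pd.DataFrame:
    labels = list(groups)
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            res = stats.ttest_ind(groups[a], groups[b], equal_var=True)
            p_corr = min(1.0, float(res.pvalue) * m)
            rows.append({"group_a": a, "group_b": b,
                         "statistic": float(res.statistic),
                         "p_raw": float(res.pvalue), "p_corrected": p_corr,
                         "significant": bool(p_corr < alpha)})
    return pd.DataFrame(rows)


def letters_from_nonsig(labels: list[str],
                        pairwise: pd.DataFrame) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly
    different (letters are the maximal cliques of the non-significance graph)."""
    g = nx.Graph()
    g.add_nodes_from(labels)
    for row in pairwise.itertuples(index=False):
        if not row.significant:
            g.add_edge(row.group_a, row.group_b)
    cliques = sorted((sorted(c, key=labels.index) for c in nx.find_cliques(g)),
                     key=lambda c: labels.index(c[0]))
    letters = {lab: "" for lab in labels}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for lab in clique:
            letters[lab] += ch
    return letters


def four_group_compare(groups: dict[str, list], alpha: float = 0.05,
                       variable: str = "") -> ComparisonResult:
    """Omnibus + pairwise comparison across the lameness groups.

    Normal route: one-way ANOVA, pairwise T-tests Bonferroni-corrected.
    Rank route: Kruskal-Wallis, Dunn's Z tests with Bonferroni-corrected
    critical Z.  Empty groups are dropped.  Returns the letter display.
    """
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()
              if len(v) > 0}
    if len(arrays) < 2:
        raise ValidationError("need at least 2 non-empty groups")
    labels = list(arrays)
    normal = all(_shapiro_normal(v) for v in arrays.values() if v.size >= 3)
    if normal:
        stat, p = stats.f_oneway(*arrays.values())
        pairwise = _pairwise_t_bonferroni(arrays, alpha)
        test = "anova_bonferroni"
    else:
        stat, p = stats.kruskal(*arrays.values())
        pairwise = dunn_test(arrays, alpha)
        test = "kruskal_wallis_dunn"
    return ComparisonResult(
        variable=variable, test=test, statistic=float(stat),
        p_value=float(p),
        groups={g: descriptives(v) for g, v in arrays.items()},
        pairwise=pairwise,
        letters=letters_from_nonsig(labels, pairwise))


def spearman_matrix(frame: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pairwise Spearman rho matrix (midranks for ties, NaN for constants)."""
    if len(frame) < 3:
        raise ValidationError("need at least 3 rows for a correlation matrix")
    data = frame[variables].to_numpy(float)
    import warnings
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(data).statistic
    if np.ndim(rho) == 0:            # scipy collapses the 2-variable case
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    for j, name in enumerate(variables):
        if np.ptp(data[~np.isnan(data[:, j]), j]) == 0:
            rho[j, :] = np.nan
            rho[:, j] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=variables, columns=variables)


def two_group_table(frame: pd.DataFrame, variables: list[str],
                    lame_col: str = "lame", alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable two-group comparison table (descriptives + routed test)."""
    rows = []
    lame = frame[frame[lame_col].astype(bool)]
    ctrl = frame[~frame[lame_col].astype(bool)]
    for name in variables:
        x = ctrl[name].dropna().to_numpy(float)
        y = lame[name].dropna().to_numpy(float)
        res = route_two_group_test(x, y, alpha=alpha, variable=name)
        dx, dy = descriptives(x), descriptives(y)
        rows.append({
            "variable": name,
            "c_mean": dx["mean"], "c_sd": dx["sd"],
            "c_median": dx["median"], "c_iqr": dx["iqr"],
            "l_mean": dy["mean"], "l_sd": dy["sd"],
            "l_median": dy["median"], "l_iqr": dy["iqr"],
            "test": res.test, "p_value": res.p_value,
            "significant": res.significant,
        })
    return pd.DataFrame(rows)
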