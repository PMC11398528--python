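"""Heteroscedasticity-aware multiple-comparison decision tree.

The workflow mirrors the standard bench protocol for per-cell /
per-experiment microscopy measurements:

1. Shapiro–Wilk normality per group.
2. If every group looks Gaussian, Brown–Forsythe (median-centred
   Levene) **and** Bartlett variance tests.
3. Both pass → Student's t (two groups) or one-way ANOVA with
   Šidák-adjusted pairwise comparisons, p_adj = 1 − (1 − p)^m.
4. Either fails → Welch's t (two groups) or Welch's ANOVA (primary
   omnibus) plus the Brown–Forsythe adjusted-df F* ANOVA, with
   Dunnett-T3 pairwise comparisons: Welch statistics referred to the
   studentized maximum modulus (SMM) distribution.
5. A Shapiro–Wilk failure routes to the robust Welch branch with a
   logged warning (no nonparametric branch is provided).

Stars follow the strict coding * p<0.05, ** p<0.01, *** p<0.001,
**** p<0.0001.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

__all__ = ["StatReport", "decide_and_test", "star_code", "sidak_adjust",
           "welch_anova", "brown_forsythe_anova", "smm_sf", "dunnett_t3"]

log = logging.getLogger(__name__)

PAIRWISE_COLUMNS = ["group_1", "group_2", "test", "statistic", "df",
                    "p_raw", "p_adj", "stars"]


def star_code(p: float) -> str:
    """Significance stars: strict inequalities at 0.05/0.01/0.001/0.0001."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return ""


def sidak_adjust(p: float, m: int) -> float:
    """Šidák multiplicity adjustment p_adj = 1 − (1 − p)^m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


# ---------------------------------------------------------------------------
# omnibus tests absent from scipy
# ---------------------------------------------------------------------------

def welch_anova(*groups: Sequence[float]) -> tuple:
    """Welch's heteroscedastic one-way ANOVA: returns (F, df1, df2, p)."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1.0 - w / np.sum(w)) ** 2 / (n - 1))
    b = 1.0 + 2.0 * (k - 2) / (k * k - 1.0) * lam
    f = a / b
    df1 = k - 1.0
    df2 = (k * k - 1.0) / (3.0 * lam)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, float(df2), p


def brown_forsythe_anova(*groups: Sequence[float]) -> tuple:
    """Brown–Forsythe adjusted-df F* ANOVA: returns (F*, df1, df2, p).

    F* = Σ nᵢ(ȳᵢ − ȳ)² / Σ (1 − nᵢ/N) sᵢ², with Satterthwaite
    denominator degrees of freedom.
    """
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    big_n = n.sum()
    grand = np.sum(n * m) / big_n
    num = np.sum(n * (m - grand) ** 2)
    c = (1.0 - n / big_n) * v
    den = np.sum(c)
    f = num / den
    g = c / den
    df2 = 1.0 / np.sum(g ** 2 / (n - 1))
    df1 = k - 1.0
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, float(df2), p


# ---------------------------------------------------------------------------
# studentized maximum modulus (Dunnett T3)
# ---------------------------------------------------------------------------

def smm_sf(q: float, df: float, k: int) -> float:
    """Survival function of the studentized maximum modulus distribution.

    SMM(k, ν) is the maximum of k independent |N(0,1)| variates
    studentized by a common χ_ν/√ν denominator:
    P(SMM ≤ q) = ∫ (2Φ(q·s) − 1)^k f_ν(s) ds, evaluated by adaptive
    quadrature.  k = 1 reduces to the two-sided t distribution.
    """
    if q <= 0:
        return 1.0
    if df <= 0:
        raise ValueError("df must be positive")

    # density of S = chi_df / sqrt(df)
    from scipy.special import gammaln

    log_c = (1.0 - df / 2.0) * np.log(2.0) + (df / 2.0) * np.log(df) - gammaln(df / 2.0)

    def integrand(s: float) -> float:
        if s <= 0:
            return 0.0
        log_f = log_c + (df - 1.0) * np.log(s) - df * s * s / 2.0
        core = 2.0 * sps.norm.cdf(q * s) - 1.0
        if core <= 0.0:
            return 0.0
        return float(np.exp(log_f + k * np.log(core)))

    cdf, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def _welch_pair(a: np.ndarray, b: np.ndarray) -> tuple:
    """Welch t statistic, Welch–Satterthwaite df and two-sided raw p."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = va / na + vb / nb
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), float(df), p


def dunnett_t3(groups: Mapping[str, np.ndarray],
               sidak_fallback: bool = False) -> List[dict]:
    """All-pairs Dunnett T3 comparisons on Welch statistics.

    Adjusted p-values refer each |t| to the SMM distribution with the
    pair's Welch df and k = number of comparisons.  With
    ``sidak_fallback`` the (slightly conservative) Šidák adjustment of
    the Welch p-value is used instead — a documented cross-check path.
    """
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for g1, g2 in pairs:
        t, df, p_raw = _welch_pair(np.asarray(groups[g1]), np.asarray(groups[g2]))
        if sidak_fallback:
            p_adj = sidak_adjust(p_raw, len(pairs))
        else:
            p_adj = smm_sf(abs(t), df, len(pairs))
        rows.append({"group_1": g1, "group_2": g2, "test": "welch_t_T3",
                     "statistic": t, "df": df, "p_raw": p_raw,
                     "p_adj": min(p_adj, 1.0), "stars": star_code(min(p_adj, 1.0))})
    return rows


# ---------------------------------------------------------------------------
# the decision tree
# ---------------------------------------------------------------------------

@dataclass
class StatReport:
    """Full record of the decision tree: every test run, in order."""

    path: str                        # student | welch | anova_sidak | welch_anova_T3
    alpha: float
    normality_p: Dict[str, float]
    variance_p: Dict[str, float]     # brown_forsythe / bartlett (empty if skipped)
    omnibus: Dict[str, float]        # omnibus statistics and p-values
    pairwise: pd.DataFrame
    trace: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "path": self.path,
            "alpha": self.alpha,
            "normality_p": self.normality_p,
            "variance_p": self.variance_p,
            "omnibus": self.omnibus,
            "pairwise": self.pairwise.to_dict(orient="records"),
            "trace": self.trace,
            "warnings": self.warnings,
        }


def _validate(groups: Mapping[str, Sequence[float]]) -> Dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or len(arr) < 3:
            raise ValueError(f"group '{name}' needs at least 3 finite values")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group '{name}' contains non-finite values")
        if np.var(arr, ddof=1) == 0:
            raise ValueError(f"group '{name}' has zero variance")
        out[str(name)] = arr
    return out


def decide_and_test(groups: Mapping[str, Sequence[float]],
                    alpha: float = 0.05,
                    t3_sidak_fallback: bool = False) -> StatReport:
    """Run the full decision tree on named measurement groups.

    Pairwise comparisons are always computed (they are not gated on the
    omnibus test); every comparison carries a raw p, an adjusted p and
    its star code.
    """
    data = _validate(groups)
    names = list(data)
    trace: List[str] = []
    warn: List[str] = []

    normality = {n: float(sps.shapiro(v).pvalue) for n, v in data.items()}
    trace.append(f"shapiro-wilk per group at alpha={alpha}")
    gaussian = all(p >= alpha for p in normality.values())
    if not gaussian:
        warn.append("Shapiro-Wilk failed for at least one group; routing to "
                    "the robust Welch branch")
        log.warning(warn[-1])

    variance_p: Dict[str, float] = {}
    equal_var = False
    if gaussian:
        bf = sps.levene(*data.values(), center="median")
        bt = sps.bartlett(*data.values())
        variance_p = {"brown_forsythe": float(bf.pvalue), "bartlett": float(bt.pvalue)}
        trace.append("brown-forsythe (median levene) and bartlett variance tests")
        equal_var = all(p >= alpha for p in variance_p.values())

    pairs = list(itertools.combinations(names, 2))
    omnibus: Dict[str, float] = {}
    rows: List[dict] = []

    if gaussian and equal_var:
        if len(names) == 2:
            path = "student"
            res = sps.ttest_ind(data[names[0]], data[names[1]], equal_var=True)
            trace.append("student t-test (two groups, equal variances)")
            omnibus = {"student_t": float(res.statistic), "p": float(res.pvalue)}
            rows.append({"group_1": names[0], "group_2": names[1],
                         "test": "student_t", "statistic": float(res.statistic),
                         "df": float(len(data[names[0]]) + len(data[names[1]]) - 2),
                         "p_raw": float(res.pvalue), "p_adj": float(res.pvalue),
                         "stars": star_code(float(res.pvalue))})
        else:
            path = "anova_sidak"
            f, p = sps.f_oneway(*data.values())
            trace.append("one-way ANOVA followed by sidak-adjusted pairwise t-tests")
            omnibus = {"anova_F": float(f), "p": float(p)}
            for g1, g2 in pairs:
                res = sps.ttest_ind(data[g1], data[g2], equal_var=True)
                p_adj = sidak_adjust(float(res.pvalue), len(pairs))
                rows.append({"group_1": g1, "group_2": g2, "test": "student_t_sidak",
                             "statistic": float(res.statistic),
                             "df": float(len(data[g1]) + len(data[g2]) - 2),
                             "p_raw": float(res.pvalue), "p_adj": p_adj,
                             "stars": star_code(p_adj)})
    else:
        if len(names) == 2:
            path = "welch"
            t, df, p = _welch_pair(data[names[0]], data[names[1]])
            trace.append("welch t-test (two groups, unequal variances)")
            omnibus = {"welch_t": t, "df": df, "p": p}
            rows.append({"group_1": names[0], "group_2": names[1],
                         "test": "welch_t", "statistic": t, "df": df,
                         "p_raw": p, "p_adj": p, "stars": star_code(p)})
        else:
            path = "welch_anova_T3"
            fw, d1, d2, pw = welch_anova(*data.values())
            fb, b1, b2, pb = brown_forsythe_anova(*data.values())
            trace.append("welch ANOVA (primary) + brown-forsythe F* ANOVA, "
                         "dunnett-T3 pairwise comparisons")
            omnibus = {"welch_F": fw, "welch_df1": d1, "welch_df2": d2, "p": pw,
                       "brown_forsythe_F": fb, "brown_forsythe_df1": b1,
                       "brown_forsythe_df2": b2, "brown_forsythe_p": pb}
            rows.extend(dunnett_t3(data, sidak_fallback=t3_sidak_fallback))

    pairwise = pd.DataFrame(rows, columns=PAIRWISE_COLUMNS)
    return StatReport(path=path, alpha=alpha, normality_p=normality,
                      variance_p=variance_p, omnibus=omnibus,
                      pairwise=pairwise, trace=trace, warnings=warn)
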