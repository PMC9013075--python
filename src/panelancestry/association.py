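"""Statistical battery for targetable-alteration cohorts.

Alteration-flag extraction from MAF-like records, first-sample selection,
pack-year binning, pairwise Fisher exact tests with exact conditional
confidence intervals, covariate-adjusted logistic regression (with a
Firth-penalised fallback under separation), Bonferroni adjustment reported
as q-values with significance at q < 0.1, cohort frequency summaries, and
TMB group comparisons.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio
import statsmodels.api as sm

from .simulate import ALTERATIONS, SMOKING_BINS

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "extract_alteration_flags",
    "first_sample_selection",
    "bin_pack_years",
    "fisher_exact",
    "logistic_fit",
    "bonferroni_adjust",
    "summarize_cohort",
    "compare_tmb",
]

Q_CUTOFF = 0.1


@dataclass
class AssociationResult:
    """Point estimate (odds ratio), 95% CI, p and multiplicity-adjusted q."""

    estimate: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    q: float | None = None
    n_tests: int | None = None
    estimate_cmle: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool | None:
        return None if self.q is None else bool(self.q < Q_CUTOFF)


# ======================================================================
# cohort preparation
# ======================================================================

_FUSION_GENES = {"ALK": "ALK_fus", "ROS1": "ROS1_fus", "RET": "RET_fus",
                 "NTRK": "NTRK_fus", "NTRK1": "NTRK_fus", "NTRK2": "NTRK_fus",
                 "NTRK3": "NTRK_fus"}
_KNOWN_CLASSES = {"SNV", "indel", "CNA", "fusion"}


def extract_alteration_flags(calls: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Derive the eight targetable-alteration flags from MAF-like records.

    Expected columns: ``sample``, ``gene``, ``class`` (SNV/indel/CNA/
    fusion), ``hgvs_p``, ``exon``, ``cna_type``, ``fusion_partner``.
    Rules: EGFR_sens = L858R or exon-19 deletion or exon-20 insertion;
    KRAS_G12C = p.G12C exactly; MET_alt = exon-14 skipping or
    amplification; BRAF_V600E = p.V600E exactly; fusion flags require the
    named gene (or an NTRK1/2/3 member) as a fusion partner.  Records of
    unknown class are skipped with a warning.
    """
    if samples is None:
        samples = list(pd.unique(calls["sample"]))
    flags = pd.DataFrame(False, index=pd.Index(samples, name="sample"),
                         columns=list(ALTERATIONS))
    for rd in calls.to_dict("records"):
        cls = rd.get("class")
        if cls not in _KNOWN_CLASSES:
            logger.warning("skipping record with unknown variant class %r", cls)
            continue
        sample, gene = rd.get("sample"), rd.get("gene")
        if sample not in flags.index:
            continue
        hgvs = str(rd.get("hgvs_p") or "")
        exon = rd.get("exon")
        exon = int(exon) if exon is not None and not pd.isna(exon) else None
        flag = None
        if gene == "EGFR":
            if cls == "SNV" and hgvs == "p.L858R":
                flag = "EGFR_sens"
            elif cls == "indel" and exon == 19 and "del" in hgvs:
                flag = "EGFR_sens"
            elif cls == "indel" and exon == 20 and "ins" in hgvs:
                flag = "EGFR_sens"
        elif gene == "KRAS" and cls == "SNV" and hgvs == "p.G12C":
            flag = "KRAS_G12C"
        elif gene == "MET":
            if cls == "CNA" and str(rd.get("cna_type")) == "amplification":
                flag = "MET_alt"
            elif cls in ("SNV", "indel") and exon == 14:
                flag = "MET_alt"
        elif gene == "BRAF" and cls == "SNV" and hgvs == "p.V600E":
            flag = "BRAF_V600E"
        if cls == "fusion":
            partner = str(rd.get("fusion_partner") or "")
            for g, fl in _FUSION_GENES.items():
                if gene == g or partner == g:
                    flag = fl
                    break
        if flag is not None:
            flags.loc[sample, flag] = True
    return flags


def first_sample_selection(samples: pd.DataFrame) -> pd.DataFrame:
    """Keep the minimum-age sample per patient (lexicographic tie-break).

    Requires columns ``patient_id``, ``sample_id``, ``sample_age``.
    Patients whose samples all lack an age are dropped with a warning.
    """
    df = samples.copy()
    has_age = df["sample_age"].notna()
    dropped = set(df["patient_id"]) - set(df.loc[has_age, "patient_id"])
    for pt in sorted(dropped):
        logger.warning("dropping patient %s: no sample has an age", pt)
    df = df[has_age]
    df = df.sort_values(["patient_id", "sample_age", "sample_id"], kind="mergesort")
    out = df.groupby("patient_id", as_index=False, sort=False).head(1)
    return out.reset_index(drop=True)


def bin_pack_years(pack_years):
    """Map pack-years to the six smoking-exposure bins.

    0 -> never; (0, 15] -> 1-15; (15, 30] -> 16-30; (30, 45] -> 31-45;
    (45, 60) -> 46-59; >= 60 -> 60+.  Missing stays missing; negative
    values raise.  Accepts a scalar or an array/Series.
    """
    def _one(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        if v < 0:
            raise ValueError(f"negative pack-years: {v}")
        if v == 0:
            return "never"
        if v <= 15:
            return "1-15"
        if v <= 30:
            return "16-30"
        if v <= 45:
            return "31-45"
        if v < 60:
            return "46-59"
        return "60+"

    if np.isscalar(pack_years) or pack_years is None:
        return _one(pack_years)
    vals = pd.Series(pack_years, dtype=float)
    return pd.Series([_one(v if not pd.isna(v) else None) for v in vals],
                     index=vals.index, dtype=object)


# ======================================================================
# tests
# ======================================================================

def fisher_exact(table) -> AssociationResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Rows are exposure groups, columns altered / not altered.  The primary
    point estimate is the sample odds ratio ad/bc (0 or inf with a zero
    cell); the conditional-MLE odds ratio and its exact conditional 95% CI
    are reported alongside.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("empty margin in 2x2 table")
    a, b = t[0]
    c, d = t[1]
    _, p = stats.fisher_exact(t, alternative="two-sided")
    if b * c > 0:
        sample_or = (a * d) / (b * c)
    elif a * d == 0:
        sample_or = np.nan
    else:
        sample_or = np.inf
    res = _cond_odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return AssociationResult(
        estimate=float(sample_or), ci_low=float(ci.low), ci_high=float(ci.high),
        p=float(p), method="fisher", estimate_cmle=float(res.statistic),
    )


def _firth_fit(y: np.ndarray, X: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Firth-penalised logistic regression (Jeffreys-prior score correction)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1.0 - p)
        XW = X * W[:, None]
        I = X.T @ XW
        Iinv = np.linalg.pinv(I)
        # hat-matrix diagonal
        h = np.einsum("ij,jk,ik->i", XW, Iinv, X)
        U = X.T @ (y - p + h * (0.5 - p))
        step = Iinv @ U
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = np.clip(X @ beta, -30.0, 30.0)
    p = 1.0 / (1.0 + np.exp(-eta))
    I = X.T @ (X * (p * (1 - p))[:, None])
    cov = np.linalg.pinv(I)
    return beta, cov


def logistic_fit(y, X: pd.DataFrame, *, firth_threshold: float = 15.0,
                 maxiter: int = 100) -> dict:
    """Covariate-adjusted logistic regression; per-covariate odds ratios.

    Maximum-likelihood Newton/IRLS fit with Wald 95% CIs and p-values;
    OR = exp(coefficient).  Separation (non-convergence or diverging
    coefficients) triggers a Firth-penalised refit, flagged via the
    result's ``method``.  Returns {column: AssociationResult}.
    """
    y = np.asarray(y, dtype=float)
    Xd = sm.add_constant(X.astype(float), has_constant="add")
    if len(y) <= Xd.shape[1]:
        raise ValueError("need more observations than model columns")
    method = "logistic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xd).fit(disp=0, maxiter=maxiter)
            params = fit.params
            bse = fit.bse
            converged = fit.mle_retvals.get("converged", True)
        except Exception:
            converged = False
            params = bse = None
    if params is None or not converged or np.abs(np.asarray(params)).max() > firth_threshold:
        logger.warning("separation or non-convergence detected; Firth fallback")
        beta, cov = _firth_fit(y, Xd.to_numpy())
        params = pd.Series(beta, index=Xd.columns)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=Xd.columns)
        method = "logistic_firth"
    z = 1.959963984540054
    out = {}
    for col in Xd.columns:  # includes the intercept under "const"
        est, se = float(params[col]), float(bse[col])
        if se == 0 or not np.isfinite(se):
            raise RuntimeError(f"non-convergence: no standard error for {col!r}")
        zval = est / se
        pval = 2.0 * stats.norm.sf(abs(zval))
        out[col] = AssociationResult(
            estimate=float(np.exp(est)),
            ci_low=float(np.exp(est - z * se)),
            ci_high=float(np.exp(est + z * se)),
            p=float(pval), method=method,
            extra={"coef": est, "se": se, "z": zval},
        )
    return out


def bonferroni_adjust(pvals, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values reported as q: q = min(1, p * n)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p) if n_tests is None else int(n_tests)
    if n < 1:
        raise ValueError("n_tests must be >= 1")
    return np.minimum(1.0, p * n)


# ======================================================================
# summaries
# ======================================================================

def summarize_cohort(cohort: pd.DataFrame, strata=None,
                     alterations=ALTERATIONS) -> pd.DataFrame:
    """Per-stratum frequency table for each alteration plus "any targetable".

    Returns long-format rows (stratum columns, alteration, count, denom,
    pct) with pct = 100 * count / denom at full precision (NaN for empty
    strata); display rounding is left to the caller.
    """
    alterations = [a for a in alterations if a in cohort.columns]
    work = cohort.copy()
    work["any_targetable"] = work[alterations].any(axis=1) if alterations else False
    targets = alterations + ["any_targetable"]
    if strata:
        groups = work.groupby(list(strata), dropna=False, observed=True)
    else:
        groups = [((), work)]
    rows = []
    for key, grp in groups:
        if strata and not isinstance(key, tuple):
            key = (key,)
        denom = len(grp)
        for alt in targets:
            count = int(grp[alt].sum())
            rows.append({
                **({} if not strata else dict(zip(strata, key))),
                "alteration": alt,
                "count": count,
                "denom": denom,
                "pct": 100.0 * count / denom if denom else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass
class TmbComparison:
    median_a: float
    median_b: float
    p: float
    p_adjusted: float | None = None


def compare_tmb(tmb_a, tmb_b, pack_years_a=None, pack_years_b=None) -> TmbComparison:
    """Median TMB per group with a two-sided Mann–Whitney p.

    If pack-years are supplied, also reports the group p from a linear
    model of log(TMB + 1) on group + pack-years (listwise-complete rows),
    the smoking-adjusted comparison.
    """
    a = np.asarray(tmb_a, dtype=float)
    b = np.asarray(tmb_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all TMB values tied; p set to 1")
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    p_adj = None
    if pack_years_a is not None and pack_years_b is not None:
        py = np.concatenate([np.asarray(pack_years_a, float),
                             np.asarray(pack_years_b, float)])
        grp = np.concatenate([np.ones(len(a)), np.zeros(len(b))])
        tmb = np.concatenate([a, b])
        ok = ~np.isnan(py) & ~np.isnan(tmb)
        X = sm.add_constant(np.column_stack([grp[ok], py[ok]]))
        ols = sm.OLS(np.log(tmb[ok] + 1.0), X).fit()
        p_adj = float(ols.pvalues[1])
    return TmbComparison(median_a=float(np.median(a)), median_b=float(np.median(b)),
                         p=p, p_adjusted=p_adj)
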