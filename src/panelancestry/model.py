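"""Model/Results interfaces tying the pipeline stages together.

:class:`AncestryModel` estimates quantitative ancestry indices from sparse
tumor-panel read counts and a phased reference panel; its
:meth:`~AncestryModel.fit` returns an :class:`AncestryResults` carrying the
imputed dosages, per-site INFO, trained SNP weights, rescaled scores,
thresholds and group calls.  :class:`AlterationAssociationModel` fits the
covariate-adjusted logistic battery relating ancestry indices to the eight
targetable-alteration flags and returns an :class:`AssociationResults`
with odds ratios, Wald CIs and Bonferroni q-values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ReferencePanel
from .impute import (HMMParams, ImputedDosages, PileupCounts,
                     dosage_and_info, filter_sites, genotype_likelihoods,
                     li_stephens_posterior)
from .projection import (SNPWeightSet, assign_groups, binary_auc,
                         four_sd_thresholds, project_scores, rescale_scores,
                         score_concordance, train_snp_weights)
from .association import AssociationResult, bonferroni_adjust, logistic_fit
from .simulate import ALTERATIONS, SimTruth

__all__ = ["AncestryModel", "AncestryResults",
           "AlterationAssociationModel", "AssociationResults",
           "anchors_from_truth"]


def anchors_from_truth(truth: SimTruth, axes=("african", "asian", "aj")) -> dict:
    """Anchor-group masks from simulated self-report labels.

    The analog of the study's anchoring on self-reported race: the zero
    group of each continental axis is the self-reported parent (European)
    population, the high group the self-reported target population; the AJ
    axis anchors the drifted-subpanel members against the remaining
    self-reported Europeans.
    """
    rep = truth.self_report
    eur = np.array([r == "EUR" for r in rep])
    anchors = {}
    for axis, pop in (("african", "AFR"), ("asian", "EAS")):
        if axis in axes:
            anchors[axis] = (eur & ~truth.subpop_flag,
                             np.array([r == pop for r in rep]))
    if "aj" in axes:
        anchors["aj"] = (eur & ~truth.subpop_flag, truth.subpop_flag)
    return anchors


# ======================================================================
# ancestry estimation
# ======================================================================

class AncestryModel:
    """Ancestry-index estimation from tumor-panel pileups.

    Parameters
    ----------
    pileup : PileupCounts
        Per-sample per-site ref/alt read counts aligned to ``panel``.
    panel : ReferencePanel
        Phased reference haplotypes with population labels.
    error_rate : float
        Per-read sequencing error used in the genotype likelihoods.
    hmm : HMMParams
        Li–Stephens switch/copying parameters and haplotype cap.
    info_min, af_min : float
        Strict post-imputation site filters (INFO > info_min, panel minor
        allele frequency > af_min).
    axes_spec : dict, optional
        Axis -> (target population, reference population); defaults to the
        African/Asian/AJ axes available in the panel.
    """

    def __init__(self, pileup: PileupCounts, panel: ReferencePanel, *,
                 error_rate: float = 0.01, hmm: HMMParams | None = None,
                 info_min: float = 0.4, af_min: float = 0.01,
                 axes_spec: dict | None = None, hmm_dtype=np.float32):
        if pileup.n_sites != panel.n_sites:
            raise ValueError("pileup and panel disagree on site count")
        self.pileup = pileup
        self.panel = panel
        self.error_rate = error_rate
        self.hmm = hmm or HMMParams()
        self.info_min = info_min
        self.af_min = af_min
        self.axes_spec = axes_spec
        # single-precision messages are renormalised per site; adequate at
        # cohort scale and roughly twice as fast as double precision
        self.hmm_dtype = hmm_dtype

    def fit(self, anchors: dict, seed: int = 0,
            thresholds: dict | None = None) -> "AncestryResults":
        """Run imputation, filtering, weight training, projection, rescaling.

        ``anchors`` maps each axis to (zero-group, high-group) boolean
        masks over the cohort (see :func:`anchors_from_truth`).
        ``thresholds`` may override the African/Asian/AJ group cutoffs
        (defaults 20 / 15 / 0.75).
        """
        gl = genotype_likelihoods(self.pileup, self.error_rate)
        post = li_stephens_posterior(gl, self.panel, self.hmm, seed=seed,
                                     dtype=self.hmm_dtype)
        dosages = dosage_and_info(post, self.panel.af)
        mask = filter_sites(dosages, self.info_min, self.af_min)
        if not mask.any():
            raise ValueError("no sites survive the INFO/AF filters")
        weights = train_snp_weights(self.panel, mask, self.axes_spec)
        raw = project_scores(dosages.dosage, weights)
        scores, rescale_params = rescale_scores(raw, anchors)
        thr = dict(african_max=20.0, asian_max=15.0, aj_min=0.75)
        if thresholds:
            thr.update(thresholds)
        groups = assign_groups(scores, **thr)
        cont = [c for c in ("african_pct", "asian_pct") if c in scores]
        anchor_zero = next(iter(anchors.values()))[0]
        four_sd = four_sd_thresholds(scores[cont], anchor_zero) if cont else {}
        return AncestryResults(
            model=self, scores=pd.concat([scores, groups], axis=1),
            raw_scores=raw, dosages=dosages, site_mask=mask, weights=weights,
            rescale_params=rescale_params, thresholds=thr,
            anchor_four_sd=four_sd, seed=seed,
        )


@dataclass
class AncestryResults:
    """Fitted ancestry indices and imputation diagnostics."""

    model: AncestryModel
    scores: pd.DataFrame
    raw_scores: pd.DataFrame
    dosages: ImputedDosages
    site_mask: np.ndarray
    weights: SNPWeightSet
    rescale_params: dict
    thresholds: dict
    anchor_four_sd: dict = field(default_factory=dict)
    seed: int = 0

    # -- derived quantities -------------------------------------------
    def project_genotypes(self, genotypes: np.ndarray) -> pd.DataFrame:
        """Score an external genotype/dosage matrix through the same
        weights and affine rescaling (e.g. true genotypes for validation)."""
        raw = project_scores(np.asarray(genotypes, dtype=float), self.weights)
        out = {}
        for axis in raw.columns:
            prm = self.rescale_params[axis]
            name = axis + ("_score" if axis == "aj" else "_pct")
            out[name] = (raw[axis].to_numpy() - prm["offset"]) * prm["slope"]
        return pd.DataFrame(out, index=raw.index)

    def concordance(self, truth_values, axis: str = "african_pct") -> float:
        """Pearson r between an axis score and ground-truth values."""
        return score_concordance(self.scores[axis].to_numpy(),
                                 np.asarray(truth_values, dtype=float))

    def auc(self, labels, axis: str = "aj_score") -> float:
        """Mann–Whitney AUC of an axis score against binary labels."""
        return binary_auc(self.scores[axis].to_numpy(), labels)

    @property
    def mean_info(self) -> float:
        return float(np.nanmean(self.dosages.info))

    def summary(self) -> str:
        n, m = self.dosages.dosage.shape
        kept = int(self.site_mask.sum())
        lines = [
            "Ancestry inference results",
            "==========================",
            f"individuals:            {n}",
            f"panel sites:            {m}",
            f"sites passing filters:  {kept} (INFO > {self.model.info_min}, "
            f"minor AF > {self.model.af_min})",
            f"mean INFO:              {self.mean_info:.3f}",
            f"axes:                   {', '.join(self.weights.axes)}",
        ]
        for axis, t in self.anchor_four_sd.items():
            lines.append(f"4-SD anchor threshold [{axis}]: {t:.2f}")
        if "is_european" in self.scores:
            ne = int(self.scores["is_european"].sum())
            na = int(self.scores["is_aj"].sum())
            lines.append(f"European group:         {ne} ({na} Ashkenazi Jewish)")
        return "\n".join(lines)


# ======================================================================
# association battery
# ======================================================================

class AlterationAssociationModel:
    """Covariate-adjusted logistic battery over alterations x ancestry axes.

    For each alteration flag, fits a logistic regression of the flag on
    the ancestry index columns plus age, pack-years (missing-indicator
    coded), sex and histology dummies, and Bonferroni-adjusts the ancestry
    p-values per axis over the number of alterations tested.
    """

    def __init__(self, cohort: pd.DataFrame, *,
                 alterations=ALTERATIONS,
                 ancestry_cols=("african_pct", "asian_pct", "aj_score"),
                 adjust_covariates: bool = True,
                 n_tests: int | None = None,
                 q_cut: float = 0.1):
        self.cohort = cohort.reset_index(drop=True)
        self.alterations = [a for a in alterations if a in cohort.columns]
        if not self.alterations:
            raise ValueError("cohort carries none of the requested alteration flags")
        self.ancestry_cols = [c for c in ancestry_cols if c in cohort.columns]
        if not self.ancestry_cols:
            raise ValueError("cohort carries none of the requested ancestry columns")
        self.adjust_covariates = adjust_covariates
        self.n_tests = n_tests or len(self.alterations)
        self.q_cut = q_cut

    def design_matrix(self) -> pd.DataFrame:
        X = self.cohort[self.ancestry_cols].astype(float).copy()
        if self.adjust_covariates:
            c = self.cohort
            if "sample_age" in c:
                X["sample_age"] = c["sample_age"].astype(float)
            if "pack_years" in c:
                py = c["pack_years"].astype(float)
                X["pack_years"] = py.fillna(0.0)
                if py.isna().any():
                    X["pack_years_missing"] = py.isna().astype(float)
            if "sex" in c:
                X["sex_male"] = (c["sex"] == "male").astype(float)
            if "histology" in c:
                hist = pd.get_dummies(c["histology"], prefix="hist", dtype=float)
                ref = "hist_LUAD" if "hist_LUAD" in hist else hist.columns[0]
                hist = hist.drop(columns=[ref])
                # dummies with fewer than 3 members are uninformative and
                # invite separation; fold them into the reference level
                hist = hist.loc[:, hist.sum() >= 3]
                X = pd.concat([X, hist], axis=1)
        # drop constant columns (cannot be estimated)
        return X.loc[:, X.nunique() > 1]

    def fit(self) -> "AssociationResults":
        X = self.design_matrix()
        rows = []
        results = {}
        for alt in self.alterations:
            y = self.cohort[alt].astype(float).to_numpy()
            if y.sum() == 0 or y.sum() == len(y):
                continue
            per_cov = logistic_fit(y, X)
            results[alt] = per_cov
            for axis in self.ancestry_cols:
                if axis not in per_cov:
                    continue
                r = per_cov[axis]
                rows.append({"alteration": alt, "term": axis,
                             "or": r.estimate, "ci_low": r.ci_low,
                             "ci_high": r.ci_high, "p": r.p,
                             "method": r.method})
        table = pd.DataFrame(rows)
        if len(table):
            qs = []
            for axis in self.ancestry_cols:
                sel = table["term"] == axis
                q = bonferroni_adjust(table.loc[sel, "p"].to_numpy(), self.n_tests)
                qs.append(pd.Series(q, index=table.index[sel]))
            table["q"] = pd.concat(qs).sort_index()
            table["significant"] = table["q"] < self.q_cut
        return AssociationResults(model=self, table=table, per_model=results)


@dataclass
class AssociationResults:
    """Ancestry-axis odds ratios per alteration with Bonferroni q-values."""

    model: AlterationAssociationModel
    table: pd.DataFrame
    per_model: dict

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def get(self, alteration: str, term: str) -> AssociationResult:
        per = self.per_model[alteration][term]
        sel = self.table[(self.table["alteration"] == alteration)
                         & (self.table["term"] == term)]
        if len(sel):
            per.q = float(sel["q"].iloc[0])
            per.n_tests = self.model.n_tests
        return per

    def summary(self) -> str:
        if not len(self.table):
            return "Association results: no estimable alterations"
        lines = ["Targetable-alteration association results",
                 "=========================================",
                 f"{'alteration':<12}{'term':<14}{'OR':>8}{'95% CI':>18}"
                 f"{'p':>10}{'q':>10}  sig"]
        for _, r in self.table.iterrows():
            ci = f"[{r['ci_low']:.2f}, {r['ci_high']:.2f}]"
            lines.append(
                f"{r['alteration']:<12}{r['term']:<14}{r['or']:>8.2f}{ci:>18}"
                f"{r['p']:>10.2g}{r['q']:>10.2g}  {'*' if r['significant'] else ''}")
        lines.append(f"(Bonferroni over {self.model.n_tests} tests per axis; "
                     f"significance q < {self.model.q_cut})")
        return "\n".join(lines)
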