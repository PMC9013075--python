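"""Ancestry SNP weights, linear projection, rescaling and group calls.

Weights are trained by PCA on frequency-standardised reference genotypes:
for each ancestry axis the principal component that best separates the
axis's contrast populations (two-sample t statistic on reference
individuals' component scores) provides the per-site loadings.  Cohort
dosages are projected as average standardised scores, affinely rescaled so
anchor-group means hit 0/100 (continental axes) or 0/1 (the Ashkenazi
Jewish axis), and binarised with the 20 % / 15 % / 0.75 threshold rules.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .panel import ReferencePanel

__all__ = [
    "SNPWeightSet",
    "train_snp_weights",
    "project_scores",
    "rescale_scores",
    "four_sd_thresholds",
    "assign_groups",
    "score_concordance",
    "binary_auc",
    "DEFAULT_AXES",
]

#: axis -> (target population, reference population); the target anchors
#: the high end of the axis (100 for continental axes, 1 for AJ).
DEFAULT_AXES = {"african": ("AFR", "EUR"), "asian": ("EAS", "EUR"), "aj": ("AJ", "EUR")}

#: affine rescaling target for the high-anchor group, per axis
AXIS_TARGET = {"african": 100.0, "asian": 100.0, "aj": 1.0}


@dataclass
class SNPWeightSet:
    """Per-site ancestry weights on the retained sites.

    site_index : indices of the retained sites in panel coordinates
    weights : DataFrame (retained sites x axes) of PC loadings
    p : panel alt-allele frequency per retained site, in (0, 1)
    """

    site_index: np.ndarray
    weights: pd.DataFrame
    p: np.ndarray

    @property
    def axes(self) -> list[str]:
        return list(self.weights.columns)

    @property
    def n_sites(self) -> int:
        return len(self.site_index)


def train_snp_weights(
    panel: ReferencePanel,
    site_mask: np.ndarray | None = None,
    axes_spec: dict | None = None,
    n_components: int = 10,
) -> SNPWeightSet:
    """Train per-axis SNP weights by PCA on the reference panel.

    For each axis ``name -> (target_pop, ref_pop)`` the PCA runs on all
    reference individuals, except when one contrast population is the
    panel's drifted subpanel (the AJ axis), in which case it runs within
    the contrast populations only (the European subset).

    Axis weights live in the span of the top ``n_components`` principal
    components.  For a two-population contrast (the AJ axis) the weight
    vector is the standardised centroid mean-difference projected onto
    that span.  For a continental axis the weight vector is the dual
    basis of *all* main-population contrasts against the reference: the
    direction along which the target population scores positive while
    every other main population scores exactly like the reference.  A
    single raw component would be an arbitrary rotation when top
    eigenvalues are close, and a lone mean-difference direction picks up
    the other populations' unequal divergences; the dual-basis contrast
    is rotation-stable and makes scores linear in the target admixture
    fraction alone.
    """
    if axes_spec is None:
        axes_spec = {k: v for k, v in DEFAULT_AXES.items()
                     if v[0] in panel.populations and v[1] in panel.populations}
    if not axes_spec:
        raise ValueError("no trainable axes for this panel")
    mask = np.ones(panel.n_sites, dtype=bool) if site_mask is None \
        else np.asarray(site_mask, dtype=bool)
    p_all = panel.af
    keep = mask & (p_all > 0) & (p_all < 1)
    idx = np.flatnonzero(keep)
    if idx.size < 10:
        raise ValueError(f"only {idx.size} retained sites; need at least 10")

    G, pops_ind = panel.diploid_genotypes()
    Gk = G[:, idx].astype(float)
    p = p_all[idx]
    sd = np.sqrt(2.0 * p * (1.0 - p))
    Z = (Gk - 2.0 * p) / sd

    weights = {}
    for axis, (target, ref) in axes_spec.items():
        for pop in (target, ref):
            if (pops_ind == pop).sum() < 2:
                raise ValueError(f"axis {axis!r}: population {pop!r} has < 2 reference individuals")
        if panel.subpop in (target, ref):
            rows = np.isin(pops_ind, (target, ref))
        else:
            rows = np.ones(len(pops_ind), dtype=bool)
        Zc = Z[rows] - Z[rows].mean(axis=0)
        U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
        if S[0] <= 1e-10:
            raise ValueError("degenerate panel: no genotypic variance")
        k = min(n_components, len(S))
        rpops = pops_ind[rows]
        ref_centroid = Zc[rpops == ref].mean(axis=0)
        if panel.subpop in (target, ref):
            others = [target]                 # single-contrast axis
        else:
            others = [p for p in panel.main_pops if p != ref]
        # contrasts of each population against the reference, in the
        # coordinates of the retained principal components
        C = np.vstack([
            (Zc[rpops == p].mean(axis=0) - ref_centroid) @ Vt[:k].T
            for p in others])
        gram = C @ C.T
        sel = np.zeros(len(others))
        sel[others.index(target)] = 1.0
        coords = np.linalg.solve(gram, sel) @ C
        w = coords @ Vt[:k]
        weights[axis] = w
    wdf = pd.DataFrame(weights, index=pd.RangeIndex(idx.size))
    return SNPWeightSet(site_index=idx, weights=wdf, p=p)


def project_scores(dosages: np.ndarray, weights: SNPWeightSet) -> pd.DataFrame:
    """Raw per-axis scores: average of w (d - 2p) / sqrt(2p(1-p)).

    ``dosages`` is (n_ind, n_sites) either already restricted to the weight
    set's sites or in full panel coordinates (subset taken via
    ``site_index``).  Missing (NaN) dosages contribute 0 (mean imputation
    at 2p) and are excluded from the per-individual averaging denominator.
    """
    D = np.asarray(dosages, dtype=float)
    if D.ndim != 2:
        raise ValueError("dosages must be 2-D")
    if D.shape[1] != weights.n_sites:
        if D.shape[1] > int(weights.site_index.max()):
            D = D[:, weights.site_index]
        else:
            raise ValueError("dosage matrix does not cover the weight set's sites")
    if weights.n_sites == 0:
        raise ValueError("empty site intersection between dosages and weights")
    sd = np.sqrt(2.0 * weights.p * (1.0 - weights.p))
    Z = (D - 2.0 * weights.p) / sd
    missing = np.isnan(Z)
    Z = np.where(missing, 0.0, Z)
    n_used = (~missing).sum(axis=1)
    if (n_used == 0).any():
        raise ValueError("individual with no non-missing sites")
    out = {}
    for axis in weights.axes:
        out[axis] = (Z @ weights.weights[axis].to_numpy()) / n_used
    return pd.DataFrame(out)


def rescale_scores(
    raw: pd.DataFrame,
    anchors: dict,
    targets: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Affinely rescale raw scores so anchor-group means are exact.

    ``anchors`` maps axis -> (zero_group, high_group) boolean masks; the
    zero group's mean maps to 0 and the high group's to the axis target
    (100 for continental axes, 1 for the AJ axis).  Returns the rescaled
    scores and the per-axis (offset, slope) applied.  The map is affine,
    so any affine pre-transform of the raw scores yields identical output.
    """
    out = {}
    params = {}
    for axis in raw.columns:
        if axis not in anchors:
            raise ValueError(f"no anchors supplied for axis {axis!r}")
        zero_ids, high_ids = anchors[axis]
        zero_ids = np.asarray(zero_ids)
        high_ids = np.asarray(high_ids)
        if zero_ids.dtype == bool and zero_ids.sum() == 0 or \
           high_ids.dtype == bool and high_ids.sum() == 0:
            raise ValueError(f"empty anchor group for axis {axis!r}")
        x = raw[axis].to_numpy()
        m0 = x[zero_ids].mean()
        m1 = x[high_ids].mean()
        if m1 == m0:
            raise ValueError(f"anchor means coincide on axis {axis!r}; zero slope")
        target = (targets or AXIS_TARGET).get(axis, 100.0)
        slope = target / (m1 - m0)
        out[axis + _suffix(axis)] = (x - m0) * slope
        params[axis] = {"offset": m0, "slope": slope, "target": target}
    return pd.DataFrame(out, index=raw.index), params


def _suffix(axis: str) -> str:
    return "_score" if axis == "aj" else "_pct"


def four_sd_thresholds(scores: pd.DataFrame, anchor_group: np.ndarray) -> dict:
    """Per-axis threshold = mean + 4 SD of the anchor group's scores.

    The SD is the population SD (ddof = 0).  A zero-variance anchor group
    yields threshold = mean and a degeneracy warning.
    """
    anchor_group = np.asarray(anchor_group)
    if (anchor_group.dtype == bool and anchor_group.sum() < 2) or \
       (anchor_group.dtype != bool and len(anchor_group) < 2):
        raise ValueError("anchor group must contain at least 2 individuals")
    out = {}
    for axis in scores.columns:
        x = scores[axis].to_numpy()[anchor_group]
        sd = x.std(ddof=0)
        if sd == 0:
            warnings.warn(f"degenerate anchor group on {axis!r}: zero variance")
            out[axis] = float(x.mean())
        else:
            out[axis] = float(x.mean() + 4.0 * sd)
    return out


def assign_groups(
    scores: pd.DataFrame,
    african_max: float = 20.0,
    asian_max: float = 15.0,
    aj_min: float = 0.75,
) -> pd.DataFrame:
    """European / AJ group flags from rescaled scores (strict inequalities).

    European iff african < african_max AND asian < asian_max; AJ iff
    European AND aj score > aj_min (the AJ rule is evaluated only within
    the European group).
    """
    for thr in (african_max, asian_max, aj_min):
        if not np.isfinite(thr):
            raise ValueError("thresholds must be finite")
    zeros = np.zeros(len(scores))
    afr = scores["african_pct"].to_numpy() if "african_pct" in scores else zeros
    asn = scores["asian_pct"].to_numpy() if "asian_pct" in scores else zeros
    eur = (afr < african_max) & (asn < asian_max)
    if "aj_score" in scores:
        aj = eur & (scores["aj_score"].to_numpy() > aj_min)
    else:
        aj = np.zeros(len(scores), dtype=bool)
    return pd.DataFrame({
        "is_european": eur,
        "is_aj": aj,
        "group": np.where(eur, "European", "non-European"),
    }, index=scores.index)


def score_concordance(x, y) -> float:
    """Pearson correlation between two per-individual score vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def binary_auc(score, label) -> float:
    """Rank-based (Mann–Whitney) AUC of a score against binary labels."""
    label = np.asarray(label, dtype=bool)
    score = np.asarray(score, dtype=float)
    if label.all() or not label.any():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(label, score))
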