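"""Reference validation benchmarks run at the study's default conditions.

Two simulation benchmarks mirror the validation strategy of the ancestry
method: (1) concordance of sparse-read-derived continental scores with
ground-truth admixture and with scores from the same individuals' true
genotypes; (2) classification of a weakly drifted Ashkenazi-Jewish-like
subpopulation within Europeans by the AJ-axis score.  Both run the full
pipeline (reads -> likelihoods -> HMM imputation -> filters -> projection
-> rescaling) at the default conditions: 3 continental populations, 2000
panel sites, depth 1x, 200 (or 300) individuals.
"""
from __future__ import annotations

import numpy as np

from .impute import HMMParams
from .model import AncestryModel, anchors_from_truth
from .projection import binary_auc, score_concordance
from .simulate import (simulate_admixed_cohort, simulate_reads,
                       simulate_reference_panel)

__all__ = ["ancestry_recovery_benchmark", "aj_classification_benchmark"]


def ancestry_recovery_benchmark(seed: int = 1, n_ind: int = 200,
                                m_sites: int = 2000, depth: float = 1.0) -> dict:
    """Continental-score recovery from sparse reads.

    Simulates a mostly-unadmixed cohort (Dirichlet alpha 0.1, 10 % AJ-like)
    and returns, per continental axis and as conservative minima:

    - ``r_truth``: Pearson r between the rescaled score and the 0-100
      encoding of the true ancestry fraction;
    - ``r_sparse_dense``: Pearson r between scores from imputed dosages
      and scores from the same individuals' true genotypes, through the
      same weights.
    """
    panel = simulate_reference_panel(m_sites=m_sites, seed=seed)
    truth = simulate_admixed_cohort(panel, n_ind, dirichlet_alpha=0.1,
                                    subpop_fraction=0.1, seed=seed + 1)
    reads = simulate_reads(truth, mean_depth=depth, error_rate=0.01,
                           seed=seed + 2)
    # benchmarks use the full panel (no haplotype subsampling): the exact
    # computation is affordable at this panel size and removes the one
    # approximation the default cap introduces
    model = AncestryModel(reads, panel,
                          hmm=HMMParams(n_hap_used=max(100, panel.n_hap)))
    res = model.fit(anchors_from_truth(truth), seed=seed + 3)
    dense = res.project_genotypes(truth.genotypes[:, res.weights.site_index])
    out = {"n": n_ind, "m_kept": int(res.site_mask.sum()),
           "mean_info": res.mean_info}
    r_truth, r_sd = [], []
    for axis, pop in (("african_pct", "AFR"), ("asian_pct", "EAS")):
        rt = score_concordance(res.scores[axis], 100.0 * truth.fraction(pop))
        rs = score_concordance(res.scores[axis], dense[axis])
        out[f"r_truth_{axis}"] = rt
        out[f"r_sparse_dense_{axis}"] = rs
        r_truth.append(rt)
        r_sd.append(rs)
    out["r_truth"] = min(r_truth)
    out["r_sparse_dense"] = min(r_sd)
    return out


def aj_classification_benchmark(seed: int = 1, n_ind: int = 300,
                                aj_fraction: float = 0.2,
                                m_sites: int = 2000, depth: float = 1.0) -> dict:
    """AUC of the AJ-axis score within a European cohort.

    Simulates ``n_ind`` European-ancestry individuals of whom
    ``aj_fraction`` come from the drifted AJ-like subpanel, runs the sparse
    -read pipeline with the AJ axis only, and returns the Mann-Whitney AUC
    of the rescaled AJ score against subpanel membership.
    """
    panel = simulate_reference_panel(m_sites=m_sites, seed=seed)
    truth = simulate_admixed_cohort(panel, n_ind,
                                    dirichlet_alpha=(1e-3, 1e-3, 1.0),
                                    subpop_fraction=aj_fraction, seed=seed + 1)
    reads = simulate_reads(truth, mean_depth=depth, error_rate=0.01,
                           seed=seed + 2)
    model = AncestryModel(reads, panel, axes_spec={"aj": ("AJ", "EUR")},
                          hmm=HMMParams(n_hap_used=max(100, panel.n_hap)))
    res = model.fit(anchors_from_truth(truth, axes=("aj",)), seed=seed + 3)
    return {"n": n_ind, "n_aj": int(truth.subpop_flag.sum()),
            "auc": binary_auc(res.scores["aj_score"], truth.subpop_flag)}
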