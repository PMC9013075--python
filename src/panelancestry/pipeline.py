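"""End-to-end pipeline: simulate -> impute -> project -> associate -> summarize."""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .impute import HMMParams
from .io import write_scores_tsv, write_tsv
from .model import AlterationAssociationModel, AncestryModel, anchors_from_truth
from .projection import binary_auc, score_concordance
from .simulate import (EffectModel, simulate_admixed_cohort,
                       simulate_clinical_and_somatic, simulate_reads,
                       simulate_reference_panel)
from .association import summarize_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                out = fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, out_dir, effect_model: EffectModel | None = None) -> dict:
    """Run all stages and write the report bundle.

    Writes scores.tsv, association.tsv, summary.tsv, validation.json and
    run_log.txt under ``out_dir``.  Identical configs produce byte-identical
    outputs.  Returns the validation report as a dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    meta = {"seed": cfg.seed, "config_hash": cfg.hash}
    sim = cfg.simulator
    log_lines = [f"panelancestry pipeline, seed={cfg.seed}, config_hash={cfg.hash}"]

    panel = _stage("simulate_panel")(simulate_reference_panel)(
        n_pops=sim.n_pops, fst=sim.fst, n_hap_per_pop=sim.n_hap_per_pop,
        m_sites=sim.m_sites, seed=cfg.seed,
        subpop_fst=sim.subpop_fst, n_hap_subpop=sim.n_hap_subpop)
    log_lines.append(f"simulate_panel: {panel.n_hap} haplotypes x {panel.n_sites} sites")

    truth = _stage("simulate_cohort")(simulate_admixed_cohort)(
        panel, sim.n_ind, dirichlet_alpha=sim.alpha,
        subpop_fraction=sim.subpop_fraction, seed=cfg.seed + 1)
    pileup = _stage("simulate_reads")(simulate_reads)(
        truth, mean_depth=sim.depth, error_rate=sim.error_rate, seed=cfg.seed + 2)
    log_lines.append(
        f"simulate_reads: mean depth {pileup.depth.mean():.3f} across "
        f"{pileup.n_ind} individuals")

    try:
        model = AncestryModel(
            pileup, panel, error_rate=sim.error_rate,
            hmm=HMMParams(rho=cfg.hmm.rho, theta=cfg.hmm.theta,
                          n_hap_used=cfg.hmm.n_hap_used),
            info_min=cfg.filters.info_min, af_min=cfg.filters.af_min)
        res = model.fit(anchors_from_truth(truth), seed=cfg.seed + 3,
                        thresholds=vars(cfg.thresholds))
    except ValueError as exc:
        if "no sites survive" in str(exc) or "thresholds" in str(exc):
            raise PipelineError("filter_sites", str(exc)) from exc
        raise PipelineError("ancestry", str(exc)) from exc
    log_lines.append(
        f"filter_sites: kept {int(res.site_mask.sum())}/{panel.n_sites} sites "
        f"(INFO > {cfg.filters.info_min}, minor AF > {cfg.filters.af_min})")

    cohort = _stage("clinical")(simulate_clinical_and_somatic)(
        truth, effect_model or EffectModel.nsclc_default(), seed=cfg.seed + 4)
    cohort = pd.concat([cohort, res.scores.reset_index(drop=True)], axis=1)

    assoc = _stage("associate")(
        lambda: AlterationAssociationModel(
            cohort, n_tests=cfg.testing.n_tests, q_cut=cfg.testing.q_cut).fit())()
    summary = _stage("summarize")(summarize_cohort)(cohort, strata=["histology"])

    # validation report: score-truth concordance and AJ classification
    report = {"seed": cfg.seed, "config_hash": cfg.hash,
              "n_individuals": int(sim.n_ind),
              "n_sites_kept": int(res.site_mask.sum()),
              "mean_info": round(res.mean_info, 6)}
    dense = res.project_genotypes(truth.genotypes[:, res.weights.site_index])
    for axis, pop in (("african_pct", "AFR"), ("asian_pct", "EAS")):
        if axis in res.scores:
            report[f"r_truth_{axis}"] = round(
                score_concordance(res.scores[axis], 100 * truth.fraction(pop)), 6)
            report[f"r_sparse_dense_{axis}"] = round(
                score_concordance(res.scores[axis], dense[axis]), 6)
    if "aj_score" in res.scores and 0 < truth.subpop_flag.sum() < len(truth.subpop_flag):
        report["auc_aj"] = round(
            binary_auc(res.scores["aj_score"], truth.subpop_flag), 6)

    write_scores_tsv(res.scores, pileup.samples, out / "scores.tsv", meta)
    write_tsv(assoc.table, out / "association.tsv", meta)
    write_tsv(summary, out / "summary.tsv", meta)
    with open(out / "validation.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return report
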