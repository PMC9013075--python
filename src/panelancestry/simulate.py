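"""Synthetic data generation.

The generator produces the statistical structure the downstream analysis
assumes: diverged populations under the Balding–Nichols model (plus a
weakly drifted Ashkenazi-Jewish-like subpanel inside the European panel),
admixed individuals with Dirichlet ancestry fractions, ultra-low-coverage
error-prone reads at panel sites, and clinical tables whose somatic
alteration flags follow a logistic generative model in ancestry, smoking,
histology, and sex.  It also builds deterministic fixture cohorts that
replay printed contingency tables exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ReferencePanel
from .impute import PileupCounts

__all__ = [
    "ALTERATIONS",
    "HISTOLOGIES",
    "SMOKING_BINS",
    "SimTruth",
    "EffectModel",
    "simulate_reference_panel",
    "simulate_admixed_cohort",
    "simulate_reads",
    "simulate_clinical_and_somatic",
    "build_fixture_cohort",
]

#: The eight targetable-alteration flags carried by every cohort table.
ALTERATIONS = (
    "EGFR_sens", "KRAS_G12C", "MET_alt", "BRAF_V600E",
    "ALK_fus", "ROS1_fus", "RET_fus", "NTRK_fus",
)

HISTOLOGIES = ("LUAD", "LUSC", "carcinoid", "LCLC", "LUASC", "other")

#: Pack-year bin labels (never smokers are pack_years == 0).
SMOKING_BINS = ("never", "1-15", "16-30", "31-45", "46-59", "60+")

# Representative pack-year value per bin, used by fixture cohorts.
_BIN_REPRESENTATIVE = {
    "never": 0.0, "1-15": 8.0, "16-30": 22.0,
    "31-45": 38.0, "46-59": 50.0, "60+": 70.0,
}

_DEFAULT_POPS3 = ("AFR", "EAS", "EUR")
# Per-population Balding-Nichols divergence from the shared ancestral pool.
# Pairwise Hudson FST between pops i, j is approximately (F_i + F_j) / 2,
# giving ~0.15 AFR-EUR and ~0.11 EAS-EUR, typical continental values.
_DEFAULT_FST3 = {"AFR": 0.20, "EAS": 0.12, "EUR": 0.10}

_RACE_MAP = {"AFR": "Black", "EAS": "Asian", "EUR": "White"}


# ======================================================================
# containers
# ======================================================================

@dataclass
class SimTruth:
    """Ground truth for a simulated cohort.

    admixture : (n_ind, n_pops) rows sum to 1 over ``pops``
    genotypes : (n_ind, n_sites) values in {0, 1, 2}
    subpop_flag : per-individual membership in the drifted subpanel
    self_report : emulated self-reported population label (None if admixed
        beyond the reporting threshold); the analog of self-reported race.
    """

    admixture: np.ndarray
    pops: tuple
    genotypes: np.ndarray
    subpop_flag: np.ndarray
    self_report: np.ndarray = field(default=None)

    def __post_init__(self):
        self.admixture = np.asarray(self.admixture, dtype=float)
        self.genotypes = np.asarray(self.genotypes)
        if not np.allclose(self.admixture.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("admixture rows must sum to 1")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotypes must be in {0,1,2}")

    @property
    def n_ind(self) -> int:
        return self.genotypes.shape[0]

    def fraction(self, pop: str) -> np.ndarray:
        return self.admixture[:, list(self.pops).index(pop)]


@dataclass
class EffectModel:
    """Generative logistic model for the eight alteration flags.

    ``intercept[alt]`` is the log-odds for the reference stratum
    (European-ancestry, never-smoker, LUAD, female); ``coef[alt]`` maps
    predictor names to log-odds-ratio coefficients.  Recognised predictors:
    ``african``, ``asian`` (ancestry fractions in [0, 1]), ``aj`` (0/1),
    ``pack_years`` (per pack-year), ``sex_male`` (0/1), and ``hist_<H>``
    indicator columns for non-LUAD histologies.
    """

    intercept: dict
    coef: dict

    def __post_init__(self):
        for alt in ALTERATIONS:
            if alt not in self.intercept:
                raise ValueError(f"missing intercept for {alt}")
            if not math.isfinite(self.intercept[alt]):
                raise ValueError(f"non-finite intercept for {alt}")
            for k, v in self.coef.get(alt, {}).items():
                if not math.isfinite(v):
                    raise ValueError(f"non-finite coefficient {k} for {alt}")

    @classmethod
    def null(cls, prevalence: float = 0.1) -> "EffectModel":
        """All effects zero; every alteration at the given prevalence."""
        b0 = math.log(prevalence / (1 - prevalence))
        return cls(intercept={a: b0 for a in ALTERATIONS},
                   coef={a: {} for a in ALTERATIONS})

    @classmethod
    def nsclc_default(cls) -> "EffectModel":
        """Default effect structure emulating an NSCLC panel cohort.

        Prevalences anchor near the observed cohort frequencies; the Asian
        axis drives sensitizing-EGFR up (OR ~ 4.9 over the full ancestry
        range) and KRAS G12C down; the AJ flag enriches MET alterations
        (~2.7-fold); smoking raises KRAS G12C and depletes EGFR/ROS1/ALK.
        """
        logit = lambda p: math.log(p / (1 - p))
        intercept = {
            "EGFR_sens": logit(0.25), "KRAS_G12C": logit(0.02),
            "MET_alt": logit(0.04), "BRAF_V600E": logit(0.02),
            "ALK_fus": logit(0.05), "ROS1_fus": logit(0.03),
            "RET_fus": logit(0.02), "NTRK_fus": logit(0.002),
        }
        coef = {
            "EGFR_sens": {"asian": math.log(4.9), "pack_years": -0.04,
                          "hist_LUSC": -2.5, "hist_carcinoid": -6.0},
            "KRAS_G12C": {"asian": -1.5, "pack_years": 0.06,
                          "hist_carcinoid": -6.0},
            "MET_alt": {"aj": math.log(2.7), "hist_carcinoid": -6.0},
            "BRAF_V600E": {"hist_carcinoid": -6.0},
            "ALK_fus": {"pack_years": -0.05, "hist_LUSC": -1.5,
                        "hist_carcinoid": -6.0},
            "ROS1_fus": {"pack_years": -0.08, "hist_LUSC": -2.0,
                         "hist_carcinoid": -6.0},
            "RET_fus": {"hist_carcinoid": -6.0},
            "NTRK_fus": {"hist_carcinoid": -6.0},
        }
        return cls(intercept=intercept, coef=coef)


# ======================================================================
# reference panel
# ======================================================================

def simulate_reference_panel(
    n_pops: int = 3,
    fst=None,
    n_hap_per_pop: int = 60,
    m_sites: int = 2000,
    seed: int = 0,
    *,
    pop_names=None,
    ancestral_range=(0.05, 0.95),
    subpop: str | None = "AJ",
    subpop_parent: str | None = None,
    subpop_fst: float = 0.004,
    n_hap_subpop: int = 40,
) -> ReferencePanel:
    """Simulate a Balding–Nichols reference panel.

    Ancestral allele frequencies are Uniform(*ancestral_range*); each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around the
    ancestral p, and haplotypes are Bernoulli draws from the population
    frequency.  Optionally a weakly drifted subpanel (default ``AJ`` inside
    ``EUR``, F = 0.004) is appended, drifting from the *parent's* latent
    frequency.  Deterministic under ``seed``.
    """
    if n_pops < 1 or m_sites < 1 or n_hap_per_pop < 2:
        raise ValueError("n_pops, m_sites and n_hap_per_pop must be positive (n_hap >= 2)")
    if pop_names is None:
        pop_names = list(_DEFAULT_POPS3) if n_pops == 3 else [f"POP{i+1}" for i in range(n_pops)]
    pop_names = list(pop_names)
    if len(pop_names) != n_pops:
        raise ValueError("pop_names length must equal n_pops")

    if fst is None:
        fst = [_DEFAULT_FST3.get(p, 0.1) for p in pop_names]
    elif np.isscalar(fst):
        fst = [float(fst)] * n_pops
    elif isinstance(fst, dict):
        fst = [float(fst[p]) for p in pop_names]
    else:
        fst = [float(f) for f in fst]
    if len(fst) != n_pops:
        raise ValueError("fst must be scalar or one value per population")
    for f in fst + ([subpop_fst] if subpop else []):
        if not (0.0 < f < 1.0):
            raise ValueError("fst values must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(ancestral_range[0], ancestral_range[1], m_sites)

    latent = {}
    hap_blocks, labels = [], []
    for name, f in zip(pop_names, fst):
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        pk = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        latent[name] = pk
        hap_blocks.append((rng.random((n_hap_per_pop, m_sites)) < pk).astype(np.uint8))
        labels += [name] * n_hap_per_pop

    if subpop is not None and n_hap_subpop > 0:
        if subpop_parent is None:
            # default: drift out of the European panel when present,
            # otherwise out of the last population
            subpop_parent = "EUR" if "EUR" in pop_names else pop_names[-1]
        if subpop_parent not in pop_names:
            raise ValueError(f"subpop parent {subpop_parent!r} not in panel populations")
        pp = latent[subpop_parent]
        a = pp * (1 - subpop_fst) / subpop_fst
        b = (1 - pp) * (1 - subpop_fst) / subpop_fst
        pk = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        latent[subpop] = pk
        hap_blocks.append((rng.random((n_hap_subpop, m_sites)) < pk).astype(np.uint8))
        labels += [subpop] * n_hap_subpop
    else:
        subpop = None

    bases = np.array(["A", "C", "G", "T"])
    ref_idx = rng.integers(0, 4, m_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, m_sites)) % 4
    sites = pd.DataFrame({
        "chrom": "1",
        "pos": np.arange(m_sites, dtype=np.int64) * 100 + 1,
        "ref": bases[ref_idx],
        "alt": bases[alt_idx],
    })
    return ReferencePanel(
        sites=sites,
        haplotypes=np.vstack(hap_blocks),
        pop_label=np.array(labels),
        latent_freq=pd.DataFrame.from_dict(latent, orient="index"),
        ancestral_freq=p_anc,
        subpop=subpop,
        subpop_parent=subpop_parent if subpop else None,
    )


# ======================================================================
# admixed cohort
# ======================================================================

def simulate_admixed_cohort(
    panel: ReferencePanel,
    n_ind: int,
    dirichlet_alpha=0.1,
    subpop_fraction: float = 0.0,
    seed: int = 0,
    *,
    report_threshold: float = 0.8,
) -> SimTruth:
    """Simulate admixed diploid individuals from a reference panel.

    Per-individual ancestry fractions are Dirichlet(*dirichlet_alpha*) over
    the panel's main populations; each allele copy picks a source population
    from those fractions, then draws Bernoulli from that population's
    empirical allele frequency.  A fraction ``subpop_fraction`` of
    individuals is instead drawn from the drifted subpanel (AJ-like); their
    continental admixture is recorded as 100 % of the parent population.
    """
    if panel.n_sites < 1 or panel.n_hap < 2:
        raise ValueError("empty reference panel")
    if not (0.0 <= subpop_fraction <= 1.0):
        raise ValueError("subpop_fraction must lie in [0, 1]")
    if subpop_fraction > 0 and panel.subpop is None:
        raise ValueError("panel has no drifted subpanel to draw from")
    pops = panel.main_pops
    K = len(pops)
    alpha = np.full(K, float(dirichlet_alpha)) if np.isscalar(dirichlet_alpha) \
        else np.asarray(dirichlet_alpha, dtype=float)
    if alpha.shape != (K,) or np.any(alpha <= 0):
        raise ValueError("dirichlet_alpha must be positive, one per main population")

    rng = np.random.default_rng(seed)
    m = panel.n_sites
    admix = rng.dirichlet(alpha, size=n_ind)

    n_sub = int(round(subpop_fraction * n_ind))
    flags = np.zeros(n_ind, dtype=bool)
    if n_sub:
        flags[rng.choice(n_ind, n_sub, replace=False)] = True
        parent_idx = pops.index(panel.subpop_parent)
        admix[flags] = np.eye(K)[parent_idx]

    # Frequency matrix: main populations, plus the subpanel as row K.
    freq = np.vstack([panel.pop_af.loc[p].to_numpy() for p in pops])
    eff = np.hstack([admix, np.zeros((n_ind, 1))])
    if panel.subpop is not None:
        freq = np.vstack([freq, panel.pop_af.loc[panel.subpop].to_numpy()])
        eff = eff.copy()
        eff[flags, :] = 0.0
        eff[flags, K] = 1.0
    cum = np.cumsum(eff, axis=1)

    G = np.zeros((n_ind, m), dtype=np.int8)
    cols = np.arange(m)
    for _ in range(2):
        u = rng.random((n_ind, m))
        src = (u[:, :, None] >= cum[:, None, :]).sum(axis=2)
        src = np.minimum(src, freq.shape[0] - 1)
        G += (rng.random((n_ind, m)) < freq[src, cols[None, :]]).astype(np.int8)

    top = admix.argmax(axis=1)
    report = np.array([
        pops[t] if admix[i, t] >= report_threshold else None
        for i, t in enumerate(top)
    ], dtype=object)
    return SimTruth(admixture=admix, pops=tuple(pops), genotypes=G,
                    subpop_flag=flags, self_report=report)


# ======================================================================
# reads
# ======================================================================

def simulate_reads(
    truth: SimTruth,
    mean_depth: float = 1.0,
    error_rate: float = 0.01,
    seed: int = 0,
) -> PileupCounts:
    """Simulate ultra-low-coverage panel reads at every site.

    Per-site depth is Poisson(*mean_depth*); alt reads are Binomial with
    success probability {e, 1/2, 1-e} for genotype {0, 1, 2}.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    g = truth.genotypes
    depth = rng.poisson(mean_depth, size=g.shape)
    q = np.array([error_rate, 0.5, 1.0 - error_rate])[g]
    alt = rng.binomial(depth, q)
    return PileupCounts(ref_reads=depth - alt, alt_reads=alt)


# ======================================================================
# clinical + somatic tables
# ======================================================================

_DEFAULT_HIST_PROBS = {
    "LUAD": 0.769, "LUSC": 0.108, "carcinoid": 0.024,
    "LCLC": 0.008, "LUASC": 0.005, "other": 0.086,
}


def simulate_clinical_and_somatic(
    truth: SimTruth,
    model: EffectModel,
    seed: int = 0,
    *,
    never_smoker_fraction: float = 0.23,
    missing_packyears: float = 0.05,
    female_fraction: float = 0.6,
    hist_probs: dict | None = None,
    tmb_median: float = 9.6,
    tmb_median_aj: float = 6.1,
    tmb_sigma: float = 0.8,
) -> pd.DataFrame:
    """Draw clinical covariates and somatic alteration flags for a cohort.

    Covariate marginals emulate a tertiary-center NSCLC panel cohort (age
    ~ N(66, 10) clipped to [30, 92], 60 % female, histology mix dominated
    by LUAD, 23 % never smokers with Gamma-distributed pack-years among
    smokers, log-normal TMB with a lower median in the AJ-like group).
    Each alteration flag is Bernoulli(logistic(linear predictor)) under
    ``model``; ancestry predictors come from the simulation truth, so the
    generating coefficients are recoverable by refitting.
    """
    rng = np.random.default_rng(seed)
    n = truth.n_ind
    hist_probs = dict(_DEFAULT_HIST_PROBS if hist_probs is None else hist_probs)
    hists = list(hist_probs)
    pvec = np.array([hist_probs[h] for h in hists], dtype=float)
    pvec /= pvec.sum()

    age = np.clip(rng.normal(66, 10, n), 30, 92).round(1)
    sex = np.where(rng.random(n) < female_fraction, "female", "male")
    histology = rng.choice(hists, size=n, p=pvec)
    smoker = rng.random(n) >= never_smoker_fraction
    pack_years = np.where(smoker, rng.gamma(2.0, 16.0, n).round(1), 0.0)
    pack_years = pack_years.astype(float)
    miss = rng.random(n) < missing_packyears
    pack_years[miss] = np.nan

    aj = truth.subpop_flag.astype(float)
    med = np.where(truth.subpop_flag, tmb_median_aj, tmb_median)
    tmb = np.exp(rng.normal(np.log(med), tmb_sigma)).round(2)

    pred = {
        "pack_years": np.nan_to_num(pack_years, nan=0.0),
        "sex_male": (sex == "male").astype(float),
        "aj": aj,
    }
    for p in truth.pops:
        pred[p.lower()] = truth.fraction(p)
    # conventional axis names when the panel uses the default populations
    if "afr" in pred:
        pred["african"] = pred["afr"]
    if "eas" in pred:
        pred["asian"] = pred["eas"]
    for h in hists:
        pred[f"hist_{h}"] = (histology == h).astype(float)

    cohort = pd.DataFrame({
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "sample_age": age,
        "sex": sex,
        "histology": histology,
        "pack_years": pack_years,
        "self_reported_race": [
            None if r is None else _RACE_MAP.get(r, r) for r in truth.self_report
        ],
        "tmb": tmb,
    })
    for alt in ALTERATIONS:
        lp = np.full(n, model.intercept[alt], dtype=float)
        for name, beta in model.coef.get(alt, {}).items():
            if name not in pred:
                raise ValueError(f"unknown predictor {name!r} in effect model")
            lp += beta * pred[name]
        cohort[alt] = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))
    return cohort


# ======================================================================
# fixture cohorts
# ======================================================================

def build_fixture_cohort(count_spec) -> pd.DataFrame:
    """Build a deterministic cohort replaying per-stratum counts.

    ``count_spec`` is a sequence of stratum dicts with keys:

    - ``n`` (required): stratum size;
    - ``histology``, ``smoking_bin``, ``ancestry_group``: optional labels
      (defaults ``LUAD`` / ``never`` / ``European``);
    - ``alterations``: mapping of alteration flag to count within the
      stratum; flags are assigned to disjoint patients unless
      ``allow_overlap`` is true;
    - ``allow_overlap``: optional bool.

    Emits exactly one row per counted patient; column sums of the flags
    equal the per-flag counts exactly.
    """
    rows = []
    pid = 0
    for stratum in count_spec:
        n = stratum.get("n")
        if n is None or int(n) != n or n < 0:
            raise ValueError("each stratum needs a non-negative integer 'n'")
        n = int(n)
        alts = dict(stratum.get("alterations", {}))
        for k, v in alts.items():
            if k not in ALTERATIONS:
                raise ValueError(f"unknown alteration flag {k!r}")
            if int(v) != v or v < 0:
                raise ValueError("alteration counts must be non-negative integers")
        overlap = bool(stratum.get("allow_overlap", False))
        if not overlap and sum(alts.values()) > n:
            raise ValueError(
                f"alteration counts exceed stratum size ({sum(alts.values())} > {n})")
        if overlap and any(v > n for v in alts.values()):
            raise ValueError("an alteration count exceeds the stratum size")

        hist = stratum.get("histology", "LUAD")
        sbin = stratum.get("smoking_bin", "never")
        if sbin not in _BIN_REPRESENTATIVE:
            raise ValueError(f"unknown smoking bin {sbin!r}")
        group = stratum.get("ancestry_group", "European")

        flags = {a: np.zeros(n, dtype=bool) for a in ALTERATIONS}
        cursor = 0
        for a, c in alts.items():
            c = int(c)
            if overlap:
                flags[a][:c] = True
            else:
                flags[a][cursor:cursor + c] = True
                cursor += c
        for i in range(n):
            row = {
                "patient_id": f"F{pid:06d}",
                "sample_age": 66.0,
                "sex": "female",
                "histology": hist,
                "smoking_bin": sbin,
                "pack_years": _BIN_REPRESENTATIVE[sbin],
                "ancestry_group": group,
                "self_reported_race": None,
                "tmb": np.nan,
            }
            for a in ALTERATIONS:
                row[a] = bool(flags[a][i])
            rows.append(row)
            pid += 1
    cols = ["patient_id", "sample_age", "sex", "histology", "smoking_bin",
            "pack_years", "ancestry_group", "self_reported_race", "tmb",
            *ALTERATIONS]
    return pd.DataFrame(rows, columns=cols)
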