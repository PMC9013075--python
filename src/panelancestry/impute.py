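"""Low-coverage genotype imputation with a reference-panel haplotype-copying HMM.

Sparse per-site read counts are first converted to three-state genotype
likelihoods under a symmetric sequencing-error model, then combined with a
phased reference panel by a diploid Li–Stephens hidden Markov model: the
two chromosomes of a target individual are modelled as imperfect mosaics of
panel haplotypes, with a per-interval switch probability (the recombination
analog) and a per-site copying-error probability.  Forward–backward over
ordered haplotype pairs yields per-site posterior genotype probabilities,
from which alt-allele dosages and an IMPUTE-style per-site INFO score are
derived.  Sites are filtered on INFO and minor-allele frequency with the
strict thresholds INFO > 0.4 and MAF > 0.01.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .panel import ReferencePanel

__all__ = [
    "PileupCounts",
    "GenotypeLikelihoods",
    "HMMParams",
    "ImputedDosages",
    "genotype_likelihoods",
    "li_stephens_posterior",
    "dosage_and_info",
    "filter_sites",
]


# ======================================================================
# containers
# ======================================================================

@dataclass
class PileupCounts:
    """Per-individual per-site read evidence (ref/alt counts)."""

    ref_reads: np.ndarray
    alt_reads: np.ndarray
    samples: list | None = None

    def __post_init__(self):
        self.ref_reads = np.asarray(self.ref_reads)
        self.alt_reads = np.asarray(self.alt_reads)
        if self.ref_reads.shape != self.alt_reads.shape:
            raise ValueError("ref and alt count matrices must share a shape")
        if (self.ref_reads < 0).any() or (self.alt_reads < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.samples is None:
            self.samples = [f"S{i:05d}" for i in range(self.ref_reads.shape[0])]

    @property
    def n_ind(self) -> int:
        return self.ref_reads.shape[0]

    @property
    def n_sites(self) -> int:
        return self.ref_reads.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.ref_reads + self.alt_reads


@dataclass
class GenotypeLikelihoods:
    """P(reads | g) for g in {0, 1, 2}; shape (n_ind, n_sites, 3).

    Zero-depth sites carry flat likelihoods (1, 1, 1).
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("likelihoods must have shape (n_ind, n_sites, 3)")
        if (self.values < 0).any():
            raise ValueError("likelihoods must be non-negative")
        if not (self.values.max(axis=2) > 0).all():
            raise ValueError("every site needs at least one positive likelihood")

    @property
    def n_ind(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class HMMParams:
    """Li–Stephens parameters.

    rho : switch-rate scale; the per-interval switch probability is
        ``1 - exp(-rho / H)`` with H haplotypes in use.  The default gives
        an expected ~1 switch per 100 sites at H = 100.
    theta : per-site copying-error probability.
    n_hap_used : cap on panel haplotypes (seeded subsampling above the cap)
        keeping the O(H^2 m) diploid cost desk-scale.
    """

    rho: float = 1.0
    theta: float = 0.01
    n_hap_used: int = 100

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if not (0.0 <= self.theta < 0.5):
            raise ValueError("theta must lie in [0, 0.5)")
        if self.n_hap_used < 2:
            raise ValueError("n_hap_used must be >= 2")

    def switch_prob(self, n_hap: int) -> float:
        return 1.0 - math.exp(-self.rho / n_hap)


@dataclass
class ImputedDosages:
    """Posterior alt-allele dosages with per-site INFO.

    dosage : (n_ind, n_sites) in [0, 2]
    info : (n_sites,) in [0, 1]; NaN where the panel frequency is 0 or 1
        (flagged for removal by :func:`filter_sites`).
    panel_af : (n_sites,) panel alt-allele frequency.
    """

    dosage: np.ndarray
    info: np.ndarray
    panel_af: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dosage, dtype=float)
        if (d < -1e-9).any() or (d > 2 + 1e-9).any():
            raise ValueError("dosages must lie in [0, 2]")
        self.dosage = np.clip(d, 0.0, 2.0)


# ======================================================================
# genotype likelihoods
# ======================================================================

def genotype_likelihoods(pileup: PileupCounts, error_rate: float = 0.01) -> GenotypeLikelihoods:
    """Binomial read-count likelihoods for the three diploid genotypes.

    L(g) = C(n, k) q_g^k (1-q_g)^(n-k) with alt-read probability
    q_g in {e, 1/2, 1-e}.  Zero-depth sites return flat (1, 1, 1).
    """
    if not (0.0 < error_rate < 0.5):
        raise ValueError("error_rate must lie in (0, 0.5)")
    n = pileup.depth
    k = pileup.alt_reads
    q = np.array([error_rate, 0.5, 1.0 - error_rate])
    L = binom.pmf(k[..., None], n[..., None], q[None, None, :])
    return GenotypeLikelihoods(values=L)


# ======================================================================
# diploid Li-Stephens forward-backward
# ======================================================================

def _pair_emission(L_t: np.ndarray, x_t: np.ndarray, mu_t: np.ndarray):
    """Emission over ordered haplotype pairs at one site.

    With per-haplotype alt probability mu (copying error folded in) and
    x = 1 - mu, the emission e[c, j, k] = sum_g L[c, g] P(g | j, k) is
    rank-2 in (j, k):  e = a_j x_k + b_j mu_k  with  a = L0 x + L1 mu,
    b = L1 x + L2 mu.
    """
    a = L_t[:, 0, None] * x_t[None, :] + L_t[:, 1, None] * mu_t[None, :]
    b = L_t[:, 1, None] * x_t[None, :] + L_t[:, 2, None] * mu_t[None, :]
    e = a[:, :, None] * x_t[None, None, :] + b[:, :, None] * mu_t[None, None, :]
    return e


def _transition_apply(f: np.ndarray, s: float, H: int) -> np.ndarray:
    """One diploid transition step, factorised per chromosome.

    Each chromosome independently stays with probability 1 - s or jumps to
    a uniformly chosen haplotype with probability s.
    """
    q = s / H
    rs = f.sum(axis=1)          # sum over j, indexed by k
    cs = f.sum(axis=2)          # sum over k, indexed by j
    tot = rs.sum(axis=1)
    out = ((1.0 - s) ** 2) * f
    out += (1.0 - s) * q * (rs[:, None, :] + cs[:, :, None])
    out += q * q * tot[:, None, None]
    return out


def _fb_genotype_posterior(L: np.ndarray, mu: np.ndarray, s: float,
                           dtype=np.float64) -> np.ndarray:
    """Forward–backward genotype posteriors for a chunk of individuals.

    L : (C, m, 3) genotype likelihoods; mu : (H, m) per-haplotype alt
    probability.  Returns (C, m, 3) normalised posteriors.  Messages are
    renormalised at every site; a zero normaliser raises rather than
    propagating NaN.  ``dtype`` selects the compute precision of the
    message recursions (float32 is adequate for pipeline-scale runs since
    messages are renormalised per site; float64 is the default and is used
    wherever exact oracle agreement matters).
    """
    C, m, _ = L.shape
    H = mu.shape[0]
    x = (1.0 - mu).astype(dtype)
    muc = mu.astype(dtype)
    Lc = np.ascontiguousarray(L, dtype=dtype)
    one_s = dtype(1.0 - s)
    q = dtype(s / H)
    c_ss = one_s * one_s
    c_sq = one_s * q
    c_qq = q * q

    F = np.empty((m, C, H, H), dtype=np.float32)
    e = np.empty((C, H, H), dtype=dtype)
    work = np.empty_like(e)

    def emission(t, out):
        # rank-2 emission: out[c, j, k] = a[c, j] x[k] + b[c, j] mu[k]
        xt, mt = x[:, t], muc[:, t]
        a = Lc[:, t, 0, None] * xt[None, :]
        a += Lc[:, t, 1, None] * mt[None, :]
        b = Lc[:, t, 1, None] * xt[None, :]
        b += Lc[:, t, 2, None] * mt[None, :]
        np.multiply(a[:, :, None], xt[None, None, :], out=out)
        out += b[:, :, None] * mt[None, None, :]
        return out

    def transition(f, out):
        rs = f.sum(axis=1)              # sum over j, indexed by k
        cs = f.sum(axis=2)              # sum over k, indexed by j
        tot = rs.sum(axis=1)
        np.multiply(f, c_ss, out=out)
        out += (c_sq * rs)[:, None, :]
        out += (c_sq * cs)[:, :, None]
        out += (c_qq * tot)[:, None, None]
        return out

    f = emission(0, e).copy()
    for t in range(m):
        if t:
            transition(f, work)
            emission(t, e)
            np.multiply(e, work, out=f)
        norm = f.sum(axis=(1, 2))
        if not (norm > 0).all():
            raise FloatingPointError("forward message underflow: zero normaliser")
        f /= norm[:, None, None]
        F[t] = f

    post = np.empty((C, m, 3))
    bw = np.ones((C, H, H), dtype=dtype)
    V = np.empty_like(bw)
    for t in range(m - 1, -1, -1):
        emission(t, e)
        np.multiply(F[t], bw, out=V)    # state posterior (unnormalised) x e_t
        V /= e                          # divide back out this site's emission
        xt, mt = x[:, t], muc[:, t]
        Vx = V @ xt
        Vm = V @ mt
        P0 = Lc[:, t, 0] * (Vx @ xt)
        P1 = Lc[:, t, 1] * (Vx @ mt + Vm @ xt)
        P2 = Lc[:, t, 2] * (Vm @ mt)
        tot = P0 + P1 + P2
        if not (tot > 0).all():
            raise FloatingPointError("posterior underflow: zero normaliser")
        post[:, t, 0] = P0 / tot
        post[:, t, 1] = P1 / tot
        post[:, t, 2] = P2 / tot
        if t:
            bw *= e
            transition(bw, work)
            bw, work = work, bw
            bnorm = bw.sum(axis=(1, 2))
            if not (bnorm > 0).all():
                raise FloatingPointError("backward message underflow: zero normaliser")
            bw /= bnorm[:, None, None]
    if np.isnan(post).any():
        raise FloatingPointError("NaN in HMM posteriors")
    return post


def li_stephens_posterior(
    gl: GenotypeLikelihoods,
    panel: ReferencePanel,
    params: HMMParams | None = None,
    seed: int = 0,
    *,
    chunk_bytes: float = 6e8,
    dtype=np.float64,
) -> np.ndarray:
    """Per-site diploid genotype posteriors under the Li–Stephens model.

    The hidden state is an ordered pair of panel haplotypes; per interval
    each chromosome switches to a uniformly drawn haplotype with
    probability ``1 - exp(-rho/H)``; emissions integrate the genotype
    likelihood over the copied pair with copying error ``theta``.  When the
    panel exceeds ``params.n_hap_used`` haplotypes a seeded subsample is
    used.  Individuals with no read evidence at any site are short-circuited
    to the Hardy–Weinberg prior at the panel allele frequency, so their
    expected dosage is exactly ``2 * panel_af``.

    Returns an (n_ind, n_sites, 3) array of normalised posterior triples.
    """
    params = params or HMMParams()
    L = gl.values
    if L.shape[1] != panel.n_sites:
        raise ValueError(
            f"site misalignment: likelihoods cover {L.shape[1]} sites, "
            f"panel has {panel.n_sites}")
    H_full = panel.n_hap
    if params.n_hap_used > H_full:
        A = panel.haplotypes
    else:
        idx = np.random.default_rng(seed).choice(H_full, params.n_hap_used, replace=False)
        A = panel.haplotypes[np.sort(idx)]
    H = A.shape[0]
    if H < 2:
        raise ValueError("need at least 2 panel haplotypes")
    s = params.switch_prob(H)
    mu = params.theta + A.astype(np.float64) * (1.0 - 2.0 * params.theta)

    n, m = L.shape[0], L.shape[1]
    post = np.empty((n, m, 3))

    # individuals with flat likelihoods everywhere: HWE prior at panel AF
    flat = np.isclose(L, L[..., :1]).all(axis=(1, 2))
    if flat.any():
        p = panel.af
        hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1)
        post[flat] = hwe[None, :, :]

    todo = np.flatnonzero(~flat)
    if todo.size:
        chunk = max(1, int(chunk_bytes / (m * H * H * 4)))
        for start in range(0, todo.size, chunk):
            sel = todo[start:start + chunk]
            post[sel] = _fb_genotype_posterior(L[sel], mu, s, dtype=dtype)
    return post


# ======================================================================
# dosage, INFO, filters
# ======================================================================

def dosage_and_info(posteriors: np.ndarray, panel_af: np.ndarray) -> ImputedDosages:
    """Expected dosages and IMPUTE-style INFO from posterior triples.

    dosage = P(1) + 2 P(2).  INFO = 1 - mean_i Var_i(g) / (2 p (1-p)) with
    p the panel allele frequency, clamped to [0, 1]; sites with p in
    {0, 1} get INFO = NaN and are dropped by the filter.
    """
    post = np.asarray(posteriors, dtype=float)
    sums = post.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("posterior triples must be normalised")
    p = np.asarray(panel_af, dtype=float)
    dosage = post[..., 1] + 2.0 * post[..., 2]
    eg2 = post[..., 1] + 4.0 * post[..., 2]
    var = np.clip(eg2 - dosage ** 2, 0.0, None)
    denom = 2.0 * p * (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        info = 1.0 - var.mean(axis=0) / denom
    info = np.where(denom > 0, np.clip(info, 0.0, 1.0), np.nan)
    return ImputedDosages(dosage=dosage, info=info, panel_af=p)


def filter_sites(
    dosages: ImputedDosages,
    info_min: float = 0.4,
    af_min: float = 0.01,
) -> np.ndarray:
    """Boolean keep-mask: INFO > info_min AND minor AF > af_min (strict).

    The frequency filter is applied to the panel minor-allele frequency;
    sites with undefined INFO (monomorphic panel frequency) are dropped.
    """
    if not (0.0 <= info_min <= 1.0 and 0.0 <= af_min <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    minor = np.minimum(dosages.panel_af, 1.0 - dosages.panel_af)
    with np.errstate(invalid="ignore"):
        keep = (dosages.info > info_min) & (minor > af_min)
    return np.where(np.isnan(dosages.info), False, keep)
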