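"""Reference haplotype panels.

A :class:`ReferencePanel` holds phased binary haplotypes at biallelic SNV
sites together with a per-haplotype population label.  It is the substrate
for both genotype imputation (the haplotype-copying HMM copies from it) and
ancestry-weight training (PCA on its diploid genotypes).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

__all__ = ["ReferencePanel"]


@dataclass
class ReferencePanel:
    """Phased reference haplotypes with population labels.

    Parameters
    ----------
    sites : pandas.DataFrame
        One row per site with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``.  Positions must be strictly increasing within a
        chromosome.
    haplotypes : ndarray of shape (n_hap, n_sites)
        Binary alt-allele indicators, entries in {0, 1}.
    pop_label : ndarray of shape (n_hap,)
        Population identifier per haplotype.
    latent_freq : pandas.DataFrame, optional
        Model (latent) per-population alt-allele frequencies used by the
        simulator; index = population, columns = site index.  Informational.
    ancestral_freq : ndarray, optional
        Ancestral allele frequency per site used by the simulator.
    subpop : str, optional
        Name of a drifted subpopulation embedded in the panel (e.g. an
        Ashkenazi-Jewish-like subpanel inside the European panel).
    subpop_parent : str, optional
        The population the drifted subpanel diverged from.
    """

    sites: pd.DataFrame
    haplotypes: np.ndarray
    pop_label: np.ndarray
    latent_freq: pd.DataFrame | None = None
    ancestral_freq: np.ndarray | None = None
    subpop: str | None = None
    subpop_parent: str | None = None
    _pop_af: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes)
        self.pop_label = np.asarray(self.pop_label)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D (n_hap, n_sites) matrix")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if len(self.pop_label) != self.haplotypes.shape[0]:
            raise ValueError("pop_label length must equal the number of haplotypes")
        if len(self.sites) != self.haplotypes.shape[1]:
            raise ValueError("sites table and haplotype matrix disagree on site count")
        for _, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")

    # ------------------------------------------------------------------
    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        """All population labels, in order of first appearance."""
        return list(pd.unique(self.pop_label))

    @property
    def main_pops(self) -> list[str]:
        """Populations excluding the drifted subpanel."""
        return [p for p in self.populations if p != self.subpop]

    @cached_property
    def pop_af(self) -> pd.DataFrame:
        """Empirical per-population alt-allele frequency (haplotype means)."""
        rows = {p: self.haplotypes[self.pop_label == p].mean(axis=0)
                for p in self.populations}
        return pd.DataFrame.from_dict(rows, orient="index")

    @cached_property
    def af(self) -> np.ndarray:
        """Panel-wide alt-allele frequency per site."""
        return self.haplotypes.mean(axis=0)

    # ------------------------------------------------------------------
    def diploid_genotypes(self) -> tuple[np.ndarray, np.ndarray]:
        """Pair consecutive haplotypes into diploid reference individuals.

        Returns
        -------
        G : ndarray (n_hap // 2, n_sites)
            Genotypes in {0, 1, 2}.
        pops : ndarray (n_hap // 2,)
            Population label per individual.

        Raises
        ------
        ValueError
            If the panel has an odd haplotype count or a pair straddles
            two populations.
        """
        if self.n_hap % 2:
            raise ValueError("odd haplotype count; cannot pair into individuals")
        a = self.haplotypes[0::2]
        b = self.haplotypes[1::2]
        pa = self.pop_label[0::2]
        pb = self.pop_label[1::2]
        if not (pa == pb).all():
            raise ValueError("haplotype pair straddles two populations")
        return (a + b).astype(np.int64), pa

    def subset_sites(self, mask: np.ndarray) -> "ReferencePanel":
        """Return a panel restricted to ``mask`` (boolean or index array)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ReferencePanel(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            haplotypes=self.haplotypes[:, idx],
            pop_label=self.pop_label,
            latent_freq=None if self.latent_freq is None else self.latent_freq.iloc[:, idx],
            ancestral_freq=None if self.ancestral_freq is None else self.ancestral_freq[idx],
            subpop=self.subpop,
            subpop_parent=self.subpop_parent,
        )
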