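"""Readers and writers for the pipeline's tabular and VCF artifacts.

All tabular artifacts are tab-separated with ``#key=value`` comment
headers (tool version, seed, config hash); the reference panel is written
as a phased VCF plus a sample->population sidecar TSV.  Coordinates are
1-based as in VCF.  Every writer/reader pair is a lossless round trip on
valid inputs.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import __version__
from .panel import ReferencePanel
from .impute import ImputedDosages, PileupCounts

__all__ = [
    "write_tsv", "read_tsv",
    "write_panel_vcf", "read_panel_vcf",
    "write_pileup_tsv", "read_pileup_tsv",
    "write_dosages_tsv", "write_scores_tsv", "read_scores_tsv",
]


def _meta_lines(meta: dict | None) -> str:
    meta = {"tool": f"panelancestry {__version__}", **(meta or {})}
    return "".join(f"#{k}={v}\n" for k, v in meta.items())


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None,
              float_format: str = "%.6g") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return pd.read_csv(_io.StringIO("".join(lines)), sep="\t")


# ----------------------------------------------------------------------
# reference panel VCF
# ----------------------------------------------------------------------

def write_panel_vcf(panel: ReferencePanel, vcf_path, popmap_path) -> None:
    """Write the panel as a phased VCF plus a sample->population TSV."""
    if panel.n_hap % 2:
        raise ValueError("panel must have an even haplotype count")
    G, pops = panel.diploid_genotypes()  # validates pairing
    n_ind = panel.n_hap // 2
    samples = [f"REF{i:04d}" for i in range(n_ind)]
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=panelancestry {__version__}\n")
        for chrom in pd.unique(panel.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        H = panel.haplotypes
        for j, site in enumerate(panel.sites.itertuples(index=False)):
            gts = "\t".join(f"{H[2*i, j]}|{H[2*i+1, j]}" for i in range(n_ind))
            fh.write(f"{site.chrom}\t{site.pos}\tsnp{j}\t{site.ref}\t{site.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")
    pd.DataFrame({"sample": samples, "population": pops}).to_csv(
        popmap_path, sep="\t", index=False)


def read_panel_vcf(vcf_path, popmap_path) -> ReferencePanel:
    """Read a phased biallelic-SNV VCF and population sidecar into a panel.

    Unphased genotypes, multi-allelic records, and samples without a
    population label are errors naming the offending record/sample.
    """
    popmap = pd.read_csv(popmap_path, sep="\t").set_index("sample")["population"]
    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    missing = [s for s in samples if s not in popmap.index]
    if missing:
        raise ValueError(f"samples without population label: {missing}")
    chroms, poss, refs, alts, cols = [], [], [], [], []
    for v in vcf:
        where = f"{v.CHROM}:{v.POS}"
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic record at {where}: ALT={','.join(v.ALT)}")
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            raise ValueError(f"non-SNV record at {where}")
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], g[-1]
            if not phased or a < 0 or b < 0:
                raise ValueError(f"unphased or missing genotype at {where}, "
                                 f"sample {samples[i]}")
            col[2 * i], col[2 * i + 1] = a, b
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        cols.append(col)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    hap = np.column_stack(cols) if cols else np.zeros((2 * len(samples), 0), np.uint8)
    labels = np.repeat(popmap.loc[samples].to_numpy(), 2)
    return ReferencePanel(sites=sites, haplotypes=hap, pop_label=labels)


# ----------------------------------------------------------------------
# pileups, dosages, scores
# ----------------------------------------------------------------------

def write_pileup_tsv(pileup: PileupCounts, sites: pd.DataFrame, path,
                     meta: dict | None = None) -> None:
    """Long-format pileup TSV: sample, chrom, pos, ref_reads, alt_reads.

    Zero-depth cells are omitted (the reader restores them)."""
    n, m = pileup.ref_reads.shape
    samp = np.repeat(pileup.samples, m)
    chrom = np.tile(sites["chrom"].to_numpy(), n)
    pos = np.tile(sites["pos"].to_numpy(), n)
    ref = pileup.ref_reads.ravel()
    alt = pileup.alt_reads.ravel()
    nz = (ref + alt) > 0
    df = pd.DataFrame({"sample": samp[nz], "chrom": chrom[nz], "pos": pos[nz],
                       "ref_reads": ref[nz], "alt_reads": alt[nz]})
    write_tsv(df, path, meta)


def read_pileup_tsv(path, sites: pd.DataFrame) -> PileupCounts:
    df = read_tsv(path)
    key = {(c, p): j for j, (c, p) in enumerate(
        zip(sites["chrom"].astype(str), sites["pos"]))}
    samples = list(pd.unique(df["sample"]))
    sidx = {s: i for i, s in enumerate(samples)}
    ref = np.zeros((len(samples), len(sites)), dtype=np.int64)
    alt = np.zeros_like(ref)
    for row in df.itertuples(index=False):
        j = key.get((str(row.chrom), row.pos))
        if j is None:
            raise ValueError(f"pileup site {row.chrom}:{row.pos} not in the panel")
        i = sidx[row.sample]
        ref[i, j] = row.ref_reads
        alt[i, j] = row.alt_reads
    return PileupCounts(ref_reads=ref, alt_reads=alt, samples=samples)


def write_dosages_tsv(dosages: ImputedDosages, sites: pd.DataFrame, samples,
                      dosage_path, info_path, meta: dict | None = None) -> None:
    d = pd.DataFrame(dosages.dosage.T, columns=list(samples))
    d.insert(0, "chrom", sites["chrom"].to_numpy())
    d.insert(1, "pos", sites["pos"].to_numpy())
    write_tsv(d, dosage_path, meta)
    info = pd.DataFrame({"chrom": sites["chrom"], "pos": sites["pos"],
                         "info": dosages.info, "panel_af": dosages.panel_af})
    write_tsv(info, info_path, meta)


def write_scores_tsv(scores: pd.DataFrame, samples, path,
                     meta: dict | None = None) -> None:
    out = scores.copy()
    out.insert(0, "sample", list(samples))
    write_tsv(out, path, meta)


def read_scores_tsv(path) -> pd.DataFrame:
    return read_tsv(path).set_index("sample")
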