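"""Allele-specific expression from DNA-called SNPs and RNA nucleotide profiles.

For each DNA-called SNP inside an exon of an expressed gene, the RNA
major-allele frequency is computed over the two DNA alleles only (reads for
any third base are treated as sequencing error), requiring >= 10 RNA reads on
the two alleles.  A gene's ASE is the median of its per-SNP frequencies;
genes observed monoallelically (ASE exactly 1.0 in count space) are flagged
removed, since they typically reflect collapsed paralogs rather than true
allele silencing.  The SD-region-vs-autosome comparison is a two-sided
Mann-Whitney U test per individual and tissue with Bonferroni adjustment over
the tests performed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .formats import BASE_INDEX

logger = logging.getLogger(__name__)


def snp_rna_frequency(allele_a: str, allele_b: str, rna_counts,
                      min_rna_cov: int = 10) -> float | None:
    """RNA major-allele frequency over the two DNA alleles, or None.

    ``rna_counts`` is a mapping base -> count or a length-4 A/C/G/T array.
    Ineligible (None) when the two-allele RNA total is below ``min_rna_cov``.
    """
    if rna_counts is None:
        return None
    if isinstance(rna_counts, dict):
        ca = rna_counts.get(allele_a, 0)
        cb = rna_counts.get(allele_b, 0)
    else:
        ca = int(rna_counts[BASE_INDEX[allele_a]])
        cb = int(rna_counts[BASE_INDEX[allele_b]])
    total = ca + cb
    if total < min_rna_cov:
        return None
    return max(ca, cb) / total


def gene_ase(frequencies) -> tuple[float, bool]:
    """(median major-allele frequency, removed flag).

    The removed flag marks exact monoallelic observation (ASE == 1.0).
    """
    freqs = [f for f in frequencies if f is not None]
    if not freqs:
        raise ValueError("gene has no eligible SNPs")
    med = float(np.median(freqs))
    return med, med == 1.0


def build_ase_table(snps_by_individual: dict, rna: pd.DataFrame,
                    genes: pd.DataFrame, min_rna_cov: int = 10) -> pd.DataFrame:
    """Per (gene, individual, tissue) ASE records.

    ``rna`` is a long profile table (individual, tissue, scaffold, pos,
    A, C, G, T); ``genes`` has gene, scaffold, cds_start, cds_end (the exon
    interval used for SNP-to-gene matching).  Genes without eligible SNPs are
    absent from the output.
    """
    if not len(rna):
        return pd.DataFrame(columns=["gene", "individual", "tissue", "n_snps",
                                     "ase", "removed"])
    rna_idx = rna.set_index(["individual", "tissue", "scaffold", "pos"])
    rows = []
    for ind, snps in snps_by_individual.items():
        if not len(snps):
            continue
        by_scaf = dict(tuple(snps.groupby("scaffold")))
        for g in genes.itertuples(index=False):
            sub = by_scaf.get(g.scaffold)
            if sub is None:
                continue
            inside = sub[(sub["position"] >= g.cds_start + 1)
                         & (sub["position"] <= g.cds_end)]
            if not len(inside):
                continue
            for tissue in rna["tissue"].unique():
                freqs = []
                for snp in inside.itertuples(index=False):
                    key = (ind, tissue, g.scaffold, snp.position)
                    try:
                        counts = rna_idx.loc[key, ["A", "C", "G", "T"]].to_numpy()
                    except KeyError:
                        continue
                    f = snp_rna_frequency(snp.major, snp.minor, counts,
                                          min_rna_cov)
                    if f is not None:
                        freqs.append(f)
                if freqs:
                    med, removed = gene_ase(freqs)
                    rows.append((g.gene, ind, tissue, len(freqs), med, removed))
    return pd.DataFrame(rows, columns=["gene", "individual", "tissue",
                                       "n_snps", "ase", "removed"])


def ase_region_test(records: pd.DataFrame, region_of_gene: dict) -> pd.DataFrame:
    """Mann-Whitney U of SD vs autosomal gene ASE, per individual and tissue.

    Exact p for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's automatic policy).  Genes flagged removed
    (100% ASE) are excluded.  The Bonferroni multiplier is the number of
    tests actually performed.
    """
    df = records[~records["removed"]].copy()
    df["region"] = df["gene"].map(lambda g: region_of_gene.get(g, "autosome"))
    rows = []
    for (ind, tissue), grp in df.groupby(["individual", "tissue"], sort=True):
        sd = grp.loc[grp["region"] == "SD", "ase"].to_numpy()
        auto = grp.loc[grp["region"] == "autosome", "ase"].to_numpy()
        if len(sd) == 0 or len(auto) == 0:
            logger.info("ase_region_test: skipped %s/%s (empty group)",
                        ind, tissue)
            continue
        u, p = sps.mannwhitneyu(sd, auto, alternative="two-sided",
                                method="auto")
        rows.append({"individual": ind, "tissue": tissue, "U": float(u),
                     "p": float(p), "n_sd": len(sd), "n_autosome": len(auto)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
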