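"""SNP calling from nucleotide profiles and per-scaffold coverage/density stats.

A site is called a SNP for one individual when its total read depth is at
least ``min_coverage`` (default 10x) and the second most frequent base makes
up at least ``min_maf`` (default 30%) of the depth.  Exactly the top two
bases are recorded; a third allele is handled downstream (triallelic filter
in the divergence module).  Per-scaffold SNP density is the SNP count divided
by the number of eligible (>= min_coverage) sites, which corrects for
scaffold length; scaffolds without eligible sites carry no density.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .formats import BASES, ProfileMatrix

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["scaffold", "position", "major", "minor",
               "major_count", "minor_count", "coverage", "maf", "individual"]


class ConsistencyError(ValueError):
    pass


def call_snps(profiles: ProfileMatrix, min_coverage: int = 10,
              min_maf: float = 0.30) -> pd.DataFrame:
    """Call biallelic SNPs for one individual.

    Ties for the major allele (50/50) resolve to the alphabetically first
    base; the frequency is unaffected.  Returns a DataFrame with 1-based
    positions, one row per called site.
    """
    frames = []
    base_arr = np.array(list(BASES))
    for scaffold in profiles.scaffolds():
        mat = profiles.counts[scaffold]
        cov = mat.sum(axis=1)
        # stable sort on descending counts keeps alphabetical order for ties
        order = np.argsort(-mat, axis=1, kind="stable")
        top = np.take_along_axis(mat, order, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            maf = np.where(cov > 0, top[:, 1] / np.maximum(cov, 1), 0.0)
        mask = (cov >= min_coverage) & (maf >= min_maf)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        frames.append(pd.DataFrame({
            "scaffold": scaffold,
            "position": idx + 1,
            "major": base_arr[order[idx, 0]],
            "minor": base_arr[order[idx, 1]],
            "major_count": top[idx, 0],
            "minor_count": top[idx, 1],
            "coverage": cov[idx],
            "maf": maf[idx],
            "individual": profiles.individual,
        }))
    if not frames:
        return pd.DataFrame(columns=SNP_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def scaffold_stats(snps: pd.DataFrame, profiles: ProfileMatrix,
                   min_coverage: int = 10) -> pd.DataFrame:
    """Per-scaffold statistics for one individual.

    ``mean_cov`` averages over covered sites only (sites with >= 1 read);
    ``snp_density`` = SNPs / eligible sites, NaN where no site reaches
    ``min_coverage`` (such scaffolds are excluded from density analyses).
    """
    known = set(profiles.scaffolds())
    if len(snps):
        missing = set(snps["scaffold"]) - known
        if missing:
            raise ConsistencyError(
                f"SNPs reference scaffolds absent from profiles: {sorted(missing)}")
    snp_counts = snps.groupby("scaffold").size() if len(snps) else pd.Series(dtype=int)
    rows = []
    for scaffold in profiles.scaffolds():
        cov = profiles.coverage(scaffold)
        covered = cov[cov > 0]
        eligible = int((cov >= min_coverage).sum())
        n_snps = int(snp_counts.get(scaffold, 0))
        rows.append({
            "scaffold": scaffold,
            "individual": profiles.individual,
            "n_covered": covered.size,
            "mean_cov": covered.mean() if covered.size else 0.0,
            "n_eligible": eligible,
            "n_snps": n_snps,
            "snp_density": n_snps / eligible if eligible else np.nan,
        })
    return pd.DataFrame(rows)


def normalize_coverage(stats: pd.DataFrame) -> pd.DataFrame:
    """Divide each scaffold's mean coverage by the individual's median.

    The median of the normalized values is 1 by construction.  Raises on a
    zero median (degenerate dataset).
    """
    out = stats.copy()
    med = out["mean_cov"].median()
    if not med > 0:
        raise ValueError("median scaffold coverage is 0; cannot normalize")
    out["norm_cov"] = out["mean_cov"] / med
    return out


def exclude_full_ase_scaffolds(stats: pd.DataFrame,
                               ase: pd.DataFrame | None,
                               gene_scaffolds: pd.DataFrame | None = None
                               ) -> pd.DataFrame:
    """Drop scaffolds whose genes all show 100% allele-specific expression.

    Such scaffolds are expected to represent misassemblies of merged
    paralogs, inflating apparent SNP density.  ``ase`` needs columns ``gene``
    and ``ase`` (plus ``scaffold``, or supply a ``gene_scaffolds`` map with
    columns ``gene`` and ``scaffold``).  With no ASE data this is a no-op
    with a warning.
    """
    if ase is None or not len(ase):
        logger.warning("exclude_full_ase_scaffolds: no ASE data supplied; "
                       "keeping all scaffolds")
        return stats
    df = ase
    if "scaffold" not in df.columns:
        if gene_scaffolds is None:
            raise ValueError("need scaffold column in ase or a gene_scaffolds map")
        df = df.merge(gene_scaffolds[["gene", "scaffold"]], on="gene")
    full = df.groupby("scaffold")["ase"].agg(lambda v: bool((v == 1.0).all()))
    removed = set(full.index[full])
    if removed:
        logger.info("exclude_full_ase_scaffolds: removed %d scaffolds: %s",
                    len(removed), sorted(removed))
    return stats[~stats["scaffold"].isin(removed)].reset_index(drop=True)
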