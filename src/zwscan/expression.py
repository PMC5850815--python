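"""Sex-biased expression: filtering, per-gene tests, windowed tracks, clustering.

A gene passes the expression filter when its FPKM exceeds 1 in at least half
of the individuals of a tissue (filtering per tissue).  Sex bias is a Welch
t-test on log2(FPKM + 1) with Benjamini-Hochberg correction within tissue;
a gene is sex-biased when q < 0.05 and |log2 fold change| > 1, with the fold
change computed on sex-mean FPKM with a pseudocount of 1.  The windowed
female:male track and its bootstrap band reuse the genome-scan machinery
with the candidate sex chromosome excluded from the background.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from . import genomescan


def filter_expressed(matrix: pd.DataFrame, min_fpkm: float = 1.0,
                     min_fraction: float = 0.5) -> pd.Index:
    """Genes expressed above ``min_fpkm`` in >= ``min_fraction`` of samples."""
    n = matrix.shape[1]
    need = math.ceil(min_fraction * n)
    keep = (matrix > min_fpkm).sum(axis=1) >= need
    return matrix.index[keep]


def sex_bias(matrix: pd.DataFrame, sexes: dict, pseudocount: float = 1.0,
             alpha: float = 0.05, min_abs_log2fc: float = 1.0) -> pd.DataFrame:
    """Per-gene sex-bias statistics for one tissue.

    ``matrix`` is genes x samples (already expression-filtered); ``sexes``
    maps sample name to 'F'/'M', each sex needing >= 2 replicates.
    """
    f_cols = [c for c in matrix.columns if sexes[c] == "F"]
    m_cols = [c for c in matrix.columns if sexes[c] == "M"]
    if len(f_cols) < 2 or len(m_cols) < 2:
        raise ValueError("need >= 2 replicates per sex")
    mean_f = matrix[f_cols].mean(axis=1)
    mean_m = matrix[m_cols].mean(axis=1)
    log2fc = np.log2((mean_f + pseudocount) / (mean_m + pseudocount))
    logged = np.log2(matrix + 1.0)
    t, p = sps.ttest_ind(logged[f_cols], logged[m_cols], axis=1,
                         equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame({
        "gene": matrix.index,
        "mean_f": mean_f.to_numpy(),
        "mean_m": mean_m.to_numpy(),
        "log2fc": log2fc.to_numpy(),
        "t": t,
        "p": p,
        "q": q,
    })
    out["biased"] = (out["q"] < alpha) & (out["log2fc"].abs() > min_abs_log2fc)
    return out


def expression_track(records: pd.DataFrame, anchors: pd.DataFrame,
                     window: int = 25, set_size: int = 25, n_boot: int = 1000,
                     exclude_chromosome: str = "chr15", rng=None
                     ) -> tuple[pd.DataFrame, genomescan.BootstrapBand]:
    """Moving-average log2 F:M expression track with its bootstrap band.

    ``records`` needs columns gene and log2fc; ``anchors`` maps gene to
    chromosome and position.  The band background is restricted to genes not
    on ``exclude_chromosome``.
    """
    df = records.merge(anchors[["gene", "chromosome", "position"]], on="gene")
    df = df.rename(columns={"gene": "unit", "log2fc": "value"})
    track = genomescan.moving_average(df, window=window)
    background = track.loc[track["chromosome"] != exclude_chromosome,
                           "value"].to_numpy()
    band = genomescan.bootstrap_band(background,
                                     set_size=min(set_size, background.size),
                                     n_boot=n_boot, rng=rng)
    return track, band


def heatmap_order(matrix: pd.DataFrame) -> dict:
    """Deterministic hierarchical-clustering orders for a heatmap.

    Agglomerative clustering with Euclidean distance and average (UPGMA)
    linkage, on samples (columns) and genes (rows).  Columns are pre-sorted
    by label so distance ties resolve deterministically.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    mat = matrix[sorted(matrix.columns)]
    sample_link = linkage(pdist(mat.T.to_numpy(), metric="euclidean"),
                          method="average")
    sample_order = [mat.columns[i] for i in leaves_list(sample_link)]
    if matrix.shape[0] >= 2:
        gene_link = linkage(pdist(mat.to_numpy(), metric="euclidean"),
                            method="average")
        gene_order = [mat.index[i] for i in leaves_list(gene_link)]
    else:
        gene_link = None
        gene_order = list(mat.index)
    return {"sample_order": sample_order, "gene_order": gene_order,
            "sample_linkage": sample_link, "gene_linkage": gene_link}
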