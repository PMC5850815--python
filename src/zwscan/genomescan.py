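"""Chromosome anchoring and sliding-window scan machinery.

Implements the genome-scan layer: assignment of scaffolds to chromosomes from
transcript hit tables (>= 70% agreement rule), female:male log2 ratio tracks,
centered moving averages that never span chromosome ends, bootstrap 95%
confidence bands from autosomal background units, one-sided permutation tests
for region means, and detection of contiguous runs exceeding the band (the
candidate sex-determination region).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class BootstrapBand:
    lo: float
    median: float
    hi: float


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def assign_scaffolds(hits: pd.DataFrame,
                     min_agreement: float = 0.70) -> pd.DataFrame:
    """Assign scaffolds to chromosomes by transcript-hit agreement.

    Per transcript only the best hit (lowest e-value, then highest bitscore)
    is used; a transcript with two equally best hits poisons its scaffold,
    which is discarded outright.  A scaffold is assigned to a chromosome when
    at least ``min_agreement`` of its transcripts' best hits agree; its
    position is the median chromosome position of the agreeing transcripts.

    Returns a DataFrame with columns scaffold, chromosome, position; only
    assigned scaffolds appear.
    """
    if not len(hits):
        return pd.DataFrame(columns=["scaffold", "chromosome", "position"])
    discarded: set[str] = set()
    best_rows = []
    for transcript, grp in hits.groupby("transcript", sort=True):
        ranked = grp.sort_values(["evalue", "bitscore"],
                                 ascending=[True, False], kind="stable")
        top = ranked.iloc[0]
        if len(ranked) > 1:
            second = ranked.iloc[1]
            if (second["evalue"] == top["evalue"]
                    and second["bitscore"] == top["bitscore"]):
                discarded.update(grp["scaffold"].unique())
                continue
        best_rows.append(top)
    if not best_rows:
        return pd.DataFrame(columns=["scaffold", "chromosome", "position"])
    best = pd.DataFrame(best_rows)
    best = best[~best["scaffold"].isin(discarded)]
    if discarded:
        logger.info("assign_scaffolds: discarded %d scaffolds with tied best "
                    "hits", len(discarded))

    rows = []
    for scaffold, grp in best.groupby("scaffold", sort=True):
        counts = grp["chromosome"].value_counts()
        chrom = counts.idxmax()
        if counts.max() / len(grp) >= min_agreement:
            pos = grp.loc[grp["chromosome"] == chrom, "position"].median()
            rows.append((scaffold, chrom, float(pos)))
    return pd.DataFrame(rows, columns=["scaffold", "chromosome", "position"])


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def log2_ratio(values_f: pd.Series, values_m: pd.Series,
               pseudocount: float = 0.0) -> pd.Series:
    """Per-unit log2((F + c) / (M + c)) over the shared index.

    Units missing in one sex, or with a non-positive numerator or denominator
    after the pseudocount, are dropped with a log message.
    """
    common = values_f.index.intersection(values_m.index)
    n_lost = len(values_f.index.union(values_m.index)) - len(common)
    f = values_f.loc[common].astype(float) + pseudocount
    m = values_m.loc[common].astype(float) + pseudocount
    ok = (f > 0) & (m > 0)
    n_lost += int((~ok).sum())
    if n_lost:
        logger.warning("log2_ratio: dropped %d units (missing or zero after "
                       "pseudocount %g)", n_lost, pseudocount)
    return np.log2(f[ok] / m[ok])


def moving_average(track: pd.DataFrame, window: int = 25,
                   value_col: str = "value") -> pd.DataFrame:
    """Centered moving average ordered by (chromosome, position).

    Windows are truncated at chromosome ends (flanks average over the units
    available); they never span a chromosome boundary.
    """
    out = (track.sort_values(["chromosome", "position"], kind="stable")
                .reset_index(drop=True))
    out["smoothed"] = (
        out.groupby("chromosome", sort=False)[value_col]
           .transform(lambda s: s.rolling(window, center=True, min_periods=1)
                                 .mean()))
    return out


def bootstrap_band(background: np.ndarray, set_size: int = 25,
                   n_boot: int = 1000,
                   rng: np.random.Generator | int | None = None
                   ) -> BootstrapBand:
    """95% band of means of random ``set_size``-unit subsets of the background.

    Sets are drawn without replacement within a set and independently across
    sets; the background must exclude the candidate sex chromosome.
    """
    rng = np.random.default_rng(rng)
    background = np.asarray(background, dtype=float)
    if background.size < set_size:
        raise ValueError(f"background ({background.size}) smaller than "
                         f"set_size ({set_size})")
    means = np.empty(n_boot)
    for i in range(n_boot):
        means[i] = rng.choice(background, size=set_size, replace=False).mean()
    lo, med, hi = np.percentile(means, [2.5, 50.0, 97.5])
    return BootstrapBand(lo, med, hi)


def permutation_test(region: np.ndarray, background: np.ndarray,
                     n_perm: int = 1000,
                     rng: np.random.Generator | int | None = None) -> float:
    """One-sided permutation p for the region mean exceeding background means.

    Null statistics are means of ``n_perm`` random background subsets of the
    region's size; p = (1 + #{null >= observed}) / (1 + n_perm), which never
    returns 0.
    """
    rng = np.random.default_rng(rng)
    region = np.asarray(region, dtype=float)
    background = np.asarray(background, dtype=float)
    if region.size == 0:
        raise ValueError("empty region")
    if background.size < region.size:
        raise ValueError("background smaller than region")
    observed = region.mean()
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = rng.choice(background, size=region.size, replace=False).mean()
    return (1 + int((null >= observed).sum())) / (1 + n_perm)


# ---------------------------------------------------------------------------
# region detection
# ---------------------------------------------------------------------------


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) half-open index pairs."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def detect_sd_region(track: pd.DataFrame, band: BootstrapBand,
                     chromosome: str | None = None,
                     smoothed_col: str = "smoothed") -> pd.DataFrame:
    """Maximal runs of consecutive units whose moving average exceeds the band.

    Returns one row per run: chromosome, unit index range, position range,
    run length, and the member unit ids.  Empty result if nothing exceeds.
    """
    df = (track.sort_values(["chromosome", "position"], kind="stable")
               .reset_index(drop=True))
    if chromosome is not None:
        df = df[df["chromosome"] == chromosome].reset_index(drop=True)
    rows = []
    for chrom, grp in df.groupby("chromosome", sort=False):
        grp = grp.reset_index(drop=True)
        mask = grp[smoothed_col].to_numpy() > band.hi
        for start, end in _runs(mask):
            rows.append({
                "chromosome": chrom,
                "start_index": start,
                "end_index": end,
                "start_pos": float(grp["position"].iloc[start]),
                "end_pos": float(grp["position"].iloc[end - 1]),
                "n_units": end - start,
                "units": list(grp["unit"].iloc[start:end])
                         if "unit" in grp.columns else None,
            })
    return pd.DataFrame(rows, columns=["chromosome", "start_index", "end_index",
                                       "start_pos", "end_pos", "n_units",
                                       "units"])


def max_run_length(values: np.ndarray, threshold: float) -> int:
    runs = _runs(np.asarray(values) > threshold)
    return max((e - s for s, e in runs), default=0)


def null_max_run_lengths(background: np.ndarray, threshold: float,
                         n_units: int, window: int = 25, n_sim: int = 1000,
                         rng: np.random.Generator | int | None = None
                         ) -> np.ndarray:
    """Null distribution of the longest above-threshold run on one chromosome.

    Each replicate lays out ``n_units`` values drawn without replacement from
    the background as a pseudo-chromosome, applies the centered moving
    average, and records the longest run exceeding ``threshold``.
    """
    rng = np.random.default_rng(rng)
    bg = np.asarray(background, dtype=float)
    if bg.size < n_units:
        raise ValueError("background smaller than n_units")
    out = np.empty(n_sim, dtype=int)
    for i in range(n_sim):
        draw = rng.choice(bg, size=n_units, replace=False)
        sm = (pd.Series(draw).rolling(window, center=True, min_periods=1)
                             .mean().to_numpy())
        out[i] = max_run_length(sm, threshold)
    return out


def write_bed(regions: pd.DataFrame, path) -> None:
    """Detected intervals as BED (0-based half-open chromosome coordinates)."""
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{int(row.start_pos)}\t"
                     f"{int(row.end_pos) + 1}\tsd_candidate\t{row.n_units}\n")
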