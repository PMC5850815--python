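"""Female-specific (candidate W) scaffold detection and k-mer histograms.

Candidate W scaffolds are scaffolds of a female-derived assembly with
essentially no male read coverage.  A candidate is *supported* when every
male's mean coverage is at or below ``male_max_cov`` (default 0, strictly
female-limited) and every female reaches ``female_min_cov``; scaffolds with
male-free coverage in only some females, or below the female threshold, are
reported in a *weak* tier.

The k-mer histogram counts canonical k-mers (lexicographic minimum of a
k-mer and its reverse complement) and tabulates how many distinct k-mers
occur at each multiplicity.  In a diploid sample the histogram shows a
low-multiplicity peak (k-mers private to one allele) and a high-multiplicity
peak (k-mers shared by both); the relative weight of the low peak tracks
heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint64)
_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class KmerHistogram:
    k: int
    counts: dict          # multiplicity -> number of distinct canonical k-mers
    total_occurrences: int

    @property
    def total_distinct(self) -> int:
        return sum(self.counts.values())


def find_female_specific(coverage: pd.DataFrame, sexes: dict,
                         female_min_cov: float = 1.0,
                         male_max_cov: float = 0.0) -> pd.DataFrame:
    """Classify female-assembly scaffolds by sexed coverage support.

    ``coverage`` is scaffold x individual mean coverage; ``sexes`` maps
    individual to 'F'/'M'.  Returns supported and weak candidates with
    per-sex coverage summaries; scaffolds with any male coverage above
    ``male_max_cov`` are not candidates and are omitted.
    """
    f_cols = [c for c in coverage.columns if sexes[c] == "F"]
    m_cols = [c for c in coverage.columns if sexes[c] == "M"]
    if not f_cols:
        raise ValueError("no female individuals supplied")
    male_ok = (coverage[m_cols] <= male_max_cov).all(axis=1) if m_cols \
        else pd.Series(True, index=coverage.index)
    female_all = (coverage[f_cols] >= female_min_cov).all(axis=1)
    female_any = (coverage[f_cols] > 0).any(axis=1)
    rows = []
    for scaf in coverage.index:
        if not male_ok[scaf] or not female_any[scaf]:
            continue
        tier = "supported" if female_all[scaf] else "weak"
        row = {"scaffold": scaf, "tier": tier,
               "male_max": float(coverage.loc[scaf, m_cols].max()) if m_cols
               else 0.0}
        for c in f_cols:
            row[f"cov_{c}"] = float(coverage.loc[scaf, c])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# k-mers
# ---------------------------------------------------------------------------


def _clean_chunks(seq: str) -> list[str]:
    """Split a sequence into maximal A/C/G/T runs (other characters break windows)."""
    chunks, cur = [], []
    for ch in seq.upper():
        if ch in _CODE:
            cur.append(ch)
        elif cur:
            chunks.append("".join(cur))
            cur = []
    if cur:
        chunks.append("".join(cur))
    return chunks


def _kmer_codes(chunk: str, k: int) -> np.ndarray:
    """Canonical 2-bit-packed codes of all k-mers of one clean chunk (k <= 31)."""
    codes = np.array([_CODE[b] for b in chunk], dtype=np.uint64)
    n = codes.size - k + 1
    weights = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    fwd = windows @ weights
    rc_codes = _COMP_CODE[codes[::-1].astype(np.intp)]
    rc_windows = np.lib.stride_tricks.sliding_window_view(rc_codes, k)
    rev = (rc_windows @ weights)[::-1]
    assert fwd.size == n
    return np.minimum(fwd, rev)


def kmer_histogram(sequences, k: int) -> KmerHistogram:
    """Multiplicity histogram of canonical k-mers over a set of sequences.

    Strand-collapsed counting: a k-mer and its reverse complement are the
    same key.  Non-ACGT characters break k-mer windows.  Uses 2-bit packing
    for k <= 31 and plain string counting beyond.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(sequences, (str, np.ndarray)):
        sequences = [sequences]
    total = 0
    if k <= 31:
        parts = []
        for seq in sequences:
            if isinstance(seq, np.ndarray):
                seq = "".join("ACGT"[c] for c in seq)
            for chunk in _clean_chunks(seq):
                if len(chunk) >= k:
                    parts.append(_kmer_codes(chunk, k))
        if not parts:
            return KmerHistogram(k, {}, 0)
        allcodes = np.concatenate(parts)
        total = allcodes.size
        _, mults = np.unique(allcodes, return_counts=True)
    else:
        table: dict[str, int] = {}
        for seq in sequences:
            if isinstance(seq, np.ndarray):
                seq = "".join("ACGT"[c] for c in seq)
            for chunk in _clean_chunks(seq):
                for i in range(len(chunk) - k + 1):
                    kmer = chunk[i:i + k]
                    rc = "".join(_RC[b] for b in reversed(kmer))
                    key = min(kmer, rc)
                    table[key] = table.get(key, 0) + 1
                    total += 1
        if not table:
            return KmerHistogram(k, {}, 0)
        mults = np.array(list(table.values()))
    vals, cnts = np.unique(mults, return_counts=True)
    return KmerHistogram(k, {int(v): int(c) for v, c in zip(vals, cnts)}, total)


def compare_histograms(hist_a: KmerHistogram, hist_b: KmerHistogram,
                       valley: int, noise_floor: int = 1) -> dict:
    """Low/high-peak fractions of two histograms and their difference.

    The low peak collects distinct k-mers with multiplicity in
    (noise_floor, valley]; the high peak those above the valley; fractions
    are relative to all distinct k-mers above the noise floor (multiplicity-1
    k-mers are dominated by sequencing error and excluded by default).
    """
    out = {}
    for name, h in (("a", hist_a), ("b", hist_b)):
        if not h.counts:
            raise ValueError(f"histogram {name} is empty")
        low = sum(c for m, c in h.counts.items() if noise_floor < m <= valley)
        high = sum(c for m, c in h.counts.items() if m > valley)
        denom = low + high
        out[f"low_fraction_{name}"] = low / denom if denom else np.nan
        out[f"high_fraction_{name}"] = high / denom if denom else np.nan
    out["low_fraction_difference"] = (out["low_fraction_a"]
                                      - out["low_fraction_b"])
    return out


def mean_scaffold_coverage(matrices: dict, scaffolds=None) -> pd.DataFrame:
    """Scaffold x individual mean-coverage table from profile matrices.

    The mean here is over all scaffold positions (so absent scaffolds score
    0), which is the quantity the female-limited classification thresholds.
    """
    rows = {}
    for ind, matrix in matrices.items():
        col = {}
        for scaf in (scaffolds if scaffolds is not None else matrix.scaffolds()):
            cov = matrix.coverage(scaf)
            col[scaf] = float(cov.mean())
        rows[ind] = col
    return pd.DataFrame(rows)
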