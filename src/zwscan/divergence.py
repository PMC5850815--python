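"""Synonymous divergence between alleles (pi_s) and NG86 Ka/Ks.

Site and difference counting follows Nei & Gojobori (1986): each codon
position contributes a fractional synonymous-site count of 1/3 per
single-base change that preserves the amino acid, changes to stop codons
count as nonsynonymous (so S_c + N_c = 3 for every sense codon), and codons
differing at several positions average the synonymous/nonsynonymous split
over all mutational pathways that avoid stop codons.  Proportions are
corrected for multiple hits with the Jukes-Cantor formula
K = -(3/4) ln(1 - (4/3) p).

pi_s between the two alleles of each gene is the summed count of synonymous
allelic differences divided by the summed synonymous sites, per sex and
region.  Sites qualify at >= 10x coverage in the individual; triallelic SNPs
(third allele > 10%) are excluded; codons holding two or more qualifying
heterozygous sites are skipped entirely (the data are unphased, so the
mutational pathway is undefined) and their sites removed from the
denominator.  The two individuals of a sex are pooled by averaging their
Sd/S ratios; 95% CIs come from bootstrapping genes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# standard nuclear genetic code; stops mapped to '*'
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS = set(standard_dna_table.stop_codons)


@dataclass
class CodonSiteCounts:
    codon: str
    synonymous: float
    nonsynonymous: float


@dataclass
class OrthologKaKs:
    pair: tuple
    length: int          # gap-free alignment length (bp)
    S: float
    N: float
    Sd: float
    Nd: float
    Ka: float | None
    Ks: float | None
    ka_ks: float | None
    saturated: bool = False  # p >= 3/4 somewhere; correction undefined


# ---------------------------------------------------------------------------
# codon-level counting
# ---------------------------------------------------------------------------


def syn_site_fractions(codon: str) -> np.ndarray:
    """Per-position synonymous-site fraction of a sense codon.

    Position i contributes 1/3 for each of its three single-base changes
    that preserves the amino acid; a change into a stop codon is
    nonsynonymous.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}: caller must exclude")
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = CODON_TABLE[codon]
    out = np.zeros(3)
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1:]
            if CODON_TABLE[mutant] == aa:  # stops translate to '*', never equal
                out[i] += 1.0 / 3.0
    return out


def ng86_site_counts(codon: str) -> CodonSiteCounts:
    """Synonymous/nonsynonymous site counts of one sense codon (S_c + N_c = 3)."""
    s = float(syn_site_fractions(codon).sum())
    return CodonSiteCounts(codon.upper(), s, 3.0 - s)


def classify_codon_change(codon: str, pos: int, base_a: str,
                          base_b: str) -> str:
    """'synonymous' or 'nonsynonymous' for a single-base allelic difference.

    The two alleles are substituted into the codon at ``pos`` (0-based) and
    the encoded amino acids compared; a stop translates as '*', so a change
    into a stop is nonsynonymous.
    """
    ca = codon[:pos] + base_a + codon[pos + 1:]
    cb = codon[:pos] + base_b + codon[pos + 1:]
    return ("synonymous" if CODON_TABLE[ca.upper()] == CODON_TABLE[cb.upper()]
            else "nonsynonymous")


def classify_allelic_difference(gene, cds_seq: str, snp) -> str:
    """Classify one SNP inside a gene's CDS; 'skipped' when outside.

    ``gene`` needs attributes/keys scaffold, strand, cds_start, cds_end
    (0-based half-open, single interval); ``cds_seq`` is the genomic forward
    strand sequence of that interval; ``snp`` needs position (1-based),
    major, minor.
    """
    get = (lambda o, k: o[k]) if isinstance(gene, (dict, pd.Series)) \
        else (lambda o, k: getattr(o, k))
    start, end = get(gene, "cds_start"), get(gene, "cds_end")
    strand = get(gene, "strand")
    p = int(snp["position"] if isinstance(snp, (dict, pd.Series))
            else snp.position) - 1
    if not start <= p < end:
        return "skipped"
    major = snp["major"] if isinstance(snp, (dict, pd.Series)) else snp.major
    minor = snp["minor"] if isinstance(snp, (dict, pd.Series)) else snp.minor
    if strand == "+":
        off = p - start
        codon_i, pos = divmod(off, 3)
        codon = cds_seq[3 * codon_i:3 * codon_i + 3]
        return classify_codon_change(codon, pos, major, minor)
    # minus strand: read CDS as reverse complement, complement the alleles
    rc = "".join(_COMPLEMENT[b] for b in reversed(cds_seq.upper()))
    off = (end - 1) - p
    codon_i, pos = divmod(off, 3)
    codon = rc[3 * codon_i:3 * codon_i + 3]
    return classify_codon_change(codon, pos, _COMPLEMENT[major.upper()],
                                 _COMPLEMENT[minor.upper()])


# ---------------------------------------------------------------------------
# pi_s
# ---------------------------------------------------------------------------


def _gene_codon_info(cds_seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(per-site synonymous fraction, per-site codon index) over a CDS.

    Sites of internal stop codons get NaN fractions and are excluded.
    """
    n = len(cds_seq) // 3
    fracs = np.empty(3 * n)
    codon_idx = np.repeat(np.arange(n), 3)
    for i in range(n):
        codon = cds_seq[3 * i:3 * i + 3].upper()
        if codon in STOP_CODONS:
            fracs[3 * i:3 * i + 3] = np.nan
        else:
            fracs[3 * i:3 * i + 3] = syn_site_fractions(codon)
    return fracs, codon_idx


def _prepare_gene(gene_row, ref_seq: str) -> dict:
    """Precompute strand-aware codon layout of one single-interval CDS gene."""
    start, end = int(gene_row.cds_start), int(gene_row.cds_end)
    strand = gene_row.strand
    segment = ref_seq[start:end].upper()
    if strand == "-":
        cds = "".join(_COMPLEMENT[b] for b in reversed(segment))
    else:
        cds = segment
    fracs_cds, codon_idx_cds = _gene_codon_info(cds)
    # map genomic offsets within [start, end) to CDS offsets
    L = end - start
    if strand == "+":
        cds_off = np.arange(L)
    else:
        cds_off = (L - 1) - np.arange(L)
    return {
        "gene": gene_row.gene,
        "scaffold": gene_row.scaffold,
        "strand": strand,
        "start": start,
        "end": end,
        "cds": cds,
        "site_syn_frac": fracs_cds[cds_off],     # indexed by genomic offset
        "site_codon": codon_idx_cds[cds_off],    # codon index per genomic offset
    }


def pi_s(genes: pd.DataFrame, reference: dict, snps_by_individual: dict,
         coverage_by_individual: dict, region_of_scaffold: dict,
         sex_of_individual: dict, min_coverage: int = 10,
         max_third_fraction: float = 0.10, n_boot: int = 1000,
         rng=None) -> pd.DataFrame:
    """pi_s per (region, sex) with bootstrap 95% CIs over genes.

    Parameters mirror the pipeline's in-memory objects: ``genes`` has columns
    gene, scaffold, strand, cds_start, cds_end; ``reference`` maps scaffold to
    sequence (str or uint8 codes); ``snps_by_individual`` maps individual to
    a SNP call table; ``coverage_by_individual`` maps individual to
    {scaffold: per-site depth array}; ``region_of_scaffold`` maps scaffold to
    a region label ('SD', 'autosome', ...).
    """
    rng = np.random.default_rng(rng)
    individuals = list(snps_by_individual)
    prep = {}
    for row in genes.itertuples(index=False):
        seq = reference[row.scaffold]
        if not isinstance(seq, str):
            seq = "".join(BASES[c] for c in seq)
        prep[row.gene] = _prepare_gene(row, seq)

    # per-gene, per-individual synonymous sites (S) and differences (Sd)
    S = np.zeros((len(prep), len(individuals)))
    Sd = np.zeros_like(S)
    gene_list = list(prep)
    gene_pos = {g: i for i, g in enumerate(gene_list)}
    n_skipped_codons = 0

    snp_index = {}
    for ind in individuals:
        df = snps_by_individual[ind]
        snp_index[ind] = (df.groupby("scaffold")
                          if len(df) else None)

    for g in gene_list:
        info = prep[g]
        gi = gene_pos[g]
        start, end = info["start"], info["end"]
        for j, ind in enumerate(individuals):
            cov = coverage_by_individual[ind].get(info["scaffold"])
            if cov is None:
                continue
            site_cov = cov[start:end]
            eligible = site_cov >= min_coverage
            # SNPs of this individual inside the CDS, after the triallelic filter
            skipped_codons: set[int] = set()
            snp_sites: list[tuple[int, str, str]] = []  # (offset, major, minor)
            grp = snp_index[ind]
            if grp is not None and info["scaffold"] in grp.groups:
                sub = grp.get_group(info["scaffold"])
                inside = sub[(sub["position"] >= start + 1)
                             & (sub["position"] <= end)]
                third = (inside["coverage"] - inside["major_count"]
                         - inside["minor_count"])
                ok = (third / inside["coverage"]) <= max_third_fraction
                inside = inside[ok]
                offs = inside["position"].to_numpy() - 1 - start
                codons = info["site_codon"][offs]
                uniq, counts = np.unique(codons, return_counts=True)
                skipped_codons = set(uniq[counts >= 2].tolist())
                n_skipped_codons += len(skipped_codons)
                for off, major, minor, codon in zip(
                        offs, inside["major"], inside["minor"], codons):
                    if codon in skipped_codons:
                        continue
                    snp_sites.append((int(off), major, minor))
            # synonymous sites: eligible, not in a skipped codon, not stop/NaN
            frac = info["site_syn_frac"].copy()
            use = eligible & ~np.isnan(frac)
            if skipped_codons:
                use &= ~np.isin(info["site_codon"], list(skipped_codons))
            S[gi, j] = frac[use].sum()
            # synonymous differences
            for off, major, minor in snp_sites:
                if not use[off]:
                    continue
                if info["strand"] == "+":
                    cds_off = off
                    a, b = major, minor
                else:
                    cds_off = (end - start - 1) - off
                    a, b = _COMPLEMENT[major], _COMPLEMENT[minor]
                codon_i, pos = divmod(cds_off, 3)
                codon = info["cds"][3 * codon_i:3 * codon_i + 3]
                if classify_codon_change(codon, pos, a, b) == "synonymous":
                    Sd[gi, j] += 1.0

    if n_skipped_codons:
        logger.info("pi_s: skipped %d codons with >= 2 heterozygous sites",
                    n_skipped_codons)

    region = np.array([region_of_scaffold.get(prep[g]["scaffold"], "autosome")
                       for g in gene_list])
    sexes = np.array([sex_of_individual[i] for i in individuals])

    def _estimate(mask_genes: np.ndarray, mask_inds: np.ndarray,
                  S_=S, Sd_=Sd) -> float:
        s = S_[np.ix_(mask_genes, mask_inds)].sum(axis=0)
        sd = Sd_[np.ix_(mask_genes, mask_inds)].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(s > 0, sd / np.maximum(s, 1e-300), np.nan)
        return float(np.nanmean(ratios)) if np.isfinite(ratios).any() else np.nan

    rows = []
    for reg in sorted(set(region)):
        gmask = region == reg
        for sex in sorted(set(sexes)):
            imask = sexes == sex
            point = _estimate(gmask, imask)
            gidx = np.flatnonzero(gmask)
            boots = np.empty(n_boot)
            Sg, Sdg = S[gidx][:, imask], Sd[gidx][:, imask]
            for b in range(n_boot):
                take = rng.integers(0, len(gidx), size=len(gidx))
                s = Sg[take].sum(axis=0)
                sd = Sdg[take].sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.where(s > 0, sd / np.maximum(s, 1e-300), np.nan)
                boots[b] = np.nanmean(r) if np.isfinite(r).any() else np.nan
            lo, hi = np.nanpercentile(boots, [2.5, 97.5])
            rows.append({
                "region": reg, "sex": sex, "n_genes": int(gmask.sum()),
                "S": float(S[np.ix_(gmask, imask)].sum()),
                "Sd": float(Sd[np.ix_(gmask, imask)].sum()),
                "pi_s": point, "ci_lo": float(lo), "ci_hi": float(hi),
            })
    result = pd.DataFrame(rows)
    result.attrs["per_gene_S"] = pd.DataFrame(S, index=gene_list,
                                              columns=individuals)
    result.attrs["per_gene_Sd"] = pd.DataFrame(Sd, index=gene_list,
                                               columns=individuals)
    return result


# ---------------------------------------------------------------------------
# NG86 Ka/Ks between aligned orthologs
# ---------------------------------------------------------------------------


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (Sd, Nd) over mutational pathways between two codons.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all pathways are used with the stop steps counted as
    nonsynonymous.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff):
        current = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if CODON_TABLE[current] == CODON_TABLE[nxt] \
                    and CODON_TABLE[nxt] != "*":
                sd += 1
            else:
                nd += 1
            if nxt in STOP_CODONS:
                through_stop = True
            current = nxt
        (blocked if through_stop else valid).append((sd, nd))
    use = valid if valid else blocked
    sd = sum(x for x, _ in use) / len(use)
    nd = sum(x for _, x in use) / len(use)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites; undefined at p >= 3/4."""
    if p >= 0.75:
        raise ValueError(f"proportion {p} >= 3/4: correction undefined")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ng86_kaks(cds_a: str, cds_b: str, pair=("a", "b")) -> OrthologKaKs:
    """NG86 Ka/Ks between two equal-length gap-free aligned CDSs.

    Sites are averaged over both sequences; codons containing a stop in
    either sequence are skipped.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDSs must have equal length")
    if len(cds_a) % 3:
        raise ValueError("alignment length must be divisible by 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa = syn_site_fractions(ca).sum()
        sb = syn_site_fractions(cb).sum()
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    ks = ka = ka_ks = None
    saturated = False
    if S > 0 and N > 0:
        ps, pn = Sd / S, Nd / N
        try:
            ks = jukes_cantor(ps)
            ka = jukes_cantor(pn)
            ka_ks = (ka / ks) if ks > 0 else None
        except ValueError:
            saturated = True
            ka = ks = ka_ks = None
    return OrthologKaKs(tuple(pair), len(cds_a), S, N, Sd, Nd, ka, ks, ka_ks,
                        saturated)


def kaks_table(records: list[OrthologKaKs]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_a": r.pair[0], "gene_b": r.pair[1], "length": r.length,
        "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
        "Ka": r.Ka, "Ks": r.Ks, "ka_ks": r.ka_ks, "saturated": r.saturated,
    } for r in records])


def filter_orthologs(records: pd.DataFrame, min_length: int = 100,
                     min_s_ks: float = 1.0, max_ks: float = 2.0) -> pd.DataFrame:
    """Drop pairs with alignment <= min_length bp, S*Ks < 1, or Ks > 2.

    Saturated or undefined-Ks records are also dropped (their Ks cannot pass
    the filters).
    """
    df = records.copy()
    ok = (~df["saturated"]) & df["Ks"].notna()
    df = df[ok]
    keep = ((df["length"] > min_length)
            & (df["S"] * df["Ks"] >= min_s_ks)
            & (df["Ks"] <= max_ks))
    return df[keep].reset_index(drop=True)


def fast_z_test(records: pd.DataFrame, region_of_gene: dict,
                gene_col: str = "gene_a") -> dict:
    """Welch t-test of Ka/Ks between SD-region and autosomal orthologs."""
    df = records[records["ka_ks"].notna()].copy()
    df["region"] = df[gene_col].map(lambda g: region_of_gene.get(g, "autosome"))
    sd = df.loc[df["region"] == "SD", "ka_ks"].to_numpy()
    auto = df.loc[df["region"] == "autosome", "ka_ks"].to_numpy()
    if len(sd) < 2 or len(auto) < 2:
        raise ValueError("need >= 2 Ka/Ks records per group")
    t, p = sps.ttest_ind(sd, auto, equal_var=False)
    return {"t": float(t), "p": float(p),
            "mean_sd": float(sd.mean()), "mean_autosome": float(auto.mean()),
            "n_sd": len(sd), "n_autosome": len(auto)}
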