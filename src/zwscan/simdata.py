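"""Synthetic ZW dataset generator with recorded ground truth.

The generator emulates the data shapes a young-homomorphic-ZW study works
from: a genome of short scaffolds tiled over 19 chromosomes, a sex
determination (SD) region with suppressed recombination on one chromosome,
per-site Z-W divergence layered on top of autosomal heterozygosity, reduced
male Z diversity inside the SD region, a handful of W-limited scaffolds seen
only in females, Poisson read depth with uniform base-miscall error, lognormal
FPKM with planted male-biased genes in the SD region (catkin tissue), and
binomial RNA allele counts with a tunable W:Z expression ratio.

Haplotype model is infinite-sites: each heterozygous site carries exactly two
alleles; additional alleles arise only through sequencing error.  Every
individual draws an independent pair of haplotypes against the same reference,
so site-frequency structure across individuals is not modeled.

Randomness is organised as one stream per (purpose, individual) derived
deterministically from the seed, so adding individuals or downstream stages
never perturbs earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .formats import (BASES, GeneModel, ProfileMatrix, decode_sequence,
                      write_fasta, write_gene_models, write_hits,
                      write_profiles)

# RNG stream domains (second word of the seed sequence)
_STREAM_REFERENCE = 0
_STREAM_HAPLOTYPES = 1
_STREAM_DNA = 2
_STREAM_EXPRESSION = 3
_STREAM_RNA = 4

SENSE_CODONS = None  # filled lazily by _sense_codons()

STOP_CODONS = {"TAA", "TAG", "TGA"}


def _sense_codons() -> list[str]:
    global SENSE_CODONS
    if SENSE_CODONS is None:
        SENSE_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                        if a + b + c not in STOP_CODONS]
    return SENSE_CODONS


class SimConfigError(ValueError):
    """Impossible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Generative parameters; defaults are the scaled study conditions.

    Probabilities are per site.  ``fpkm_log_mean``/``fpkm_log_sd`` are the
    mean and standard deviation of log2(FPKM) (gene-level baseline and
    sample-level replicate noise share the same sd).  ``w_expression_ratio``
    is the expected fraction of female RNA reads drawn from the W allele at
    Z/W divergent sites (0.5 = balanced expression of both alleles).
    """

    n_chromosomes: int = 19
    scaffolds_per_chromosome: int = 40
    scaffold_length: int = 5000
    sd_chromosome: str = "chr15"
    sd_interval: tuple = (50_000, 150_000)  # 0-based half-open, on sd_chromosome
    theta_auto: float = 0.01
    d_zw: float = 0.01
    z_diversity_factor: float = 0.75
    depth_mean: float = 30.0
    error_rate: float = 0.002
    n_w_scaffolds: int = 2
    n_females: int = 2
    n_males: int = 2
    genes_per_scaffold: int = 2
    gene_length: int = 300  # CDS length in bp, multiple of 3
    fpkm_log_mean: float = 4.3
    fpkm_log_sd: float = 0.25
    frac_masculinized: float = 0.5
    bias_fold: float = 4.0
    w_expression_ratio: float = 0.5
    rna_depth_scale: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        chrom_len = self.scaffolds_per_chromosome * self.scaffold_length
        for name in ("theta_auto", "d_zw", "error_rate", "frac_masculinized",
                     "w_expression_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        if self.depth_mean <= 0:
            raise SimConfigError("depth_mean must be > 0")
        if self.n_females < 1 or self.n_males < 1:
            raise SimConfigError("need at least one individual of each sex")
        lo, hi = self.sd_interval
        if not (0 <= lo < hi <= chrom_len):
            raise SimConfigError(
                f"sd_interval {self.sd_interval} outside chromosome extent "
                f"[0, {chrom_len})")
        sd_idx = int(self.sd_chromosome.removeprefix("chr"))
        if not 1 <= sd_idx <= self.n_chromosomes:
            raise SimConfigError(f"{self.sd_chromosome} not among "
                                 f"{self.n_chromosomes} chromosomes")
        if self.gene_length % 3:
            raise SimConfigError("gene_length must be a multiple of 3")
        if self.genes_per_scaffold * (self.gene_length + 2) > self.scaffold_length:
            raise SimConfigError("genes do not fit in scaffold_length")

    # --- serialization (field names are the file schema) ---

    def to_file(self, path) -> None:
        d = asdict(self)
        d["sd_interval"] = list(self.sd_interval)
        text = yaml.safe_dump(d, sort_keys=True)
        Path(path).write_text(text)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        text = Path(path).read_text()
        d = (json.loads(text) if str(path).endswith(".json")
             else yaml.safe_load(text))
        d["sd_interval"] = tuple(d["sd_interval"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    config: SimConfig
    scaffold_table: pd.DataFrame      # scaffold, chromosome, start, end, is_sd
    sd_scaffolds: set
    w_scaffolds: list
    genes: pd.DataFrame               # gene, scaffold, strand, cds_start, cds_end
    individuals: pd.DataFrame         # individual, sex
    reference: dict                   # scaffold -> uint8 codes (incl. W scaffolds)
    haplotypes: dict                  # individual -> scaffold -> (n_hap, L) uint8
    div_sites: dict                   # (individual, scaffold) -> positions of Z/W diffs
    hits: pd.DataFrame                # BLAST-like transcript hit table
    biased_genes: pd.DataFrame        # gene, tissue, direction, fold
    w_expression_ratio: dict = field(default_factory=dict)  # gene -> ratio

    def sex_of(self, individual: str) -> str:
        return self.individuals.set_index("individual")["sex"][individual]


def _rng(config: SimConfig, domain: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, domain, index])


def _individuals(config: SimConfig) -> pd.DataFrame:
    rows = ([(f"F{i + 1}", "F") for i in range(config.n_females)] +
            [(f"M{i + 1}", "M") for i in range(config.n_males)])
    return pd.DataFrame(rows, columns=["individual", "sex"])


def _mutate(ref: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Return a copy of ref with masked sites changed to a different base."""
    out = ref.copy()
    idx = np.flatnonzero(mask)
    out[idx] = (ref[idx] + rng.integers(1, 4, size=idx.size)) % 4
    return out


def simulate_genome(config: SimConfig) -> SimTruth:
    """Draw the genome, per-individual haplotypes, gene models and hit table."""
    config.validate()
    rng_ref = _rng(config, _STREAM_REFERENCE)

    # --- scaffold tiling ---
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        for s in range(config.scaffolds_per_chromosome):
            start = s * config.scaffold_length
            end = start + config.scaffold_length
            mid = (start + end) // 2
            is_sd = (chrom == config.sd_chromosome
                     and config.sd_interval[0] <= mid < config.sd_interval[1])
            rows.append((f"{chrom}_s{s + 1}", chrom, start, end, is_sd))
    scaffold_table = pd.DataFrame(
        rows, columns=["scaffold", "chromosome", "start", "end", "is_sd"])
    sd_scaffolds = set(scaffold_table.loc[scaffold_table["is_sd"], "scaffold"])
    w_scaffolds = [f"W_s{i + 1}" for i in range(config.n_w_scaffolds)]

    # --- reference sequences ---
    reference: dict[str, np.ndarray] = {}
    for scaf in list(scaffold_table["scaffold"]) + w_scaffolds:
        reference[scaf] = rng_ref.integers(0, 4, size=config.scaffold_length,
                                           dtype=np.uint8).astype(np.uint8)

    # --- gene models: evenly spaced single-CDS genes built from sense codons ---
    sense = _sense_codons()
    gene_rows = []
    pitch = config.scaffold_length // config.genes_per_scaffold
    for scaf in scaffold_table["scaffold"]:
        for g in range(config.genes_per_scaffold):
            start = g * pitch + (pitch - config.gene_length) // 2
            end = start + config.gene_length
            strand = "+" if g % 2 == 0 else "-"
            gene_rows.append((f"{scaf}_g{g + 1}", scaf, strand, start, end))
            codons = rng_ref.choice(len(sense), size=config.gene_length // 3)
            cds = "".join(sense[i] for i in codons)
            if strand == "-":
                # genomic forward strand holds the reverse complement
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                cds = "".join(comp[b] for b in reversed(cds))
            reference[scaf][start:end] = [
                "ACGT".index(b) for b in cds]
    genes = pd.DataFrame(
        gene_rows, columns=["gene", "scaffold", "strand", "cds_start", "cds_end"])

    # --- haplotypes ---
    individuals = _individuals(config)
    scaf_info = scaffold_table.set_index("scaffold")
    haplotypes: dict[str, dict[str, np.ndarray]] = {}
    div_sites: dict[tuple, np.ndarray] = {}
    for i, (ind, sex) in enumerate(individuals.itertuples(index=False)):
        rng_i = _rng(config, _STREAM_HAPLOTYPES, i)
        haps: dict[str, np.ndarray] = {}
        for scaf in scaffold_table["scaffold"]:
            ref = reference[scaf]
            L = ref.size
            if scaf in sd_scaffolds:
                if sex == "F":
                    div = rng_i.random(L) < config.d_zw
                    poly = rng_i.random(L) < config.theta_auto
                    het = div | poly
                    div_sites[(ind, scaf)] = np.flatnonzero(div)
                else:
                    het = rng_i.random(L) < (config.theta_auto
                                             * config.z_diversity_factor)
            else:
                het = rng_i.random(L) < config.theta_auto
            hap2 = _mutate(ref, het, rng_i)
            haps[scaf] = np.stack([ref, hap2])
        if sex == "F":
            for scaf in w_scaffolds:
                haps[scaf] = reference[scaf][None, :]  # hemizygous
        haplotypes[ind] = haps

    # --- hit table: one perfect hit per gene/transcript ---
    hit_rows = []
    for gene, scaf, _, cds_start, cds_end in genes.itertuples(index=False):
        chrom = scaf_info.at[scaf, "chromosome"]
        pos = int(scaf_info.at[scaf, "start"]) + (cds_start + cds_end) // 2 + 1
        hit_rows.append((gene, scaf, chrom, pos, 1e-50, 500.0))
    hits = pd.DataFrame(hit_rows, columns=[
        "transcript", "scaffold", "chromosome", "position", "evalue", "bitscore"])

    # --- planted sex-biased genes (catkins, male-biased) ---
    sd_genes = genes.loc[genes["scaffold"].isin(sd_scaffolds), "gene"].tolist()
    n_biased = int(round(config.frac_masculinized * len(sd_genes)))
    chosen = sorted(rng_ref.choice(sd_genes, size=n_biased, replace=False)) \
        if n_biased else []
    biased = pd.DataFrame(
        [(g, "catkin", "male", config.bias_fold) for g in chosen],
        columns=["gene", "tissue", "direction", "fold"])
    w_ratio = {g: (config.w_expression_ratio if s else 0.5)
               for g, s in zip(genes["gene"], genes["scaffold"].isin(sd_scaffolds))}

    return SimTruth(config=config, scaffold_table=scaffold_table,
                    sd_scaffolds=sd_scaffolds, w_scaffolds=w_scaffolds,
                    genes=genes, individuals=individuals, reference=reference,
                    haplotypes=haplotypes, div_sites=div_sites, hits=hits,
                    biased_genes=biased, w_expression_ratio=w_ratio)


# ---------------------------------------------------------------------------
# DNA profiles
# ---------------------------------------------------------------------------

_OTHER_BASES = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


def _profile_counts(haps: np.ndarray, depth_mean: float, error_rate: float,
                    rng: np.random.Generator) -> np.ndarray:
    """(n_hap, L) haplotype codes -> (L, 4) read counts.

    Depth per haplotype is Poisson(depth_mean / 2) (Poisson thinning of a
    Poisson(depth_mean) total split evenly between alleles); each read is
    miscalled uniformly to one of the three other bases with ``error_rate``.
    """
    n_hap, L = haps.shape
    counts = np.zeros((L, 4), dtype=np.int32)
    for h in range(n_hap):
        depth = rng.poisson(depth_mean / 2.0, size=L)
        errors = rng.binomial(depth, error_rate)
        correct = depth - errors
        alleles = haps[h]
        np.add.at(counts, (np.arange(L), alleles), correct)
        if errors.any():
            split = rng.multinomial(errors, [1 / 3] * 3)  # (L, 3)
            others = _OTHER_BASES[alleles]                # (L, 3)
            np.add.at(counts, (np.repeat(np.arange(L), 3), others.ravel()),
                      split.ravel())
    return counts


def simulate_dna_profiles(truth: SimTruth,
                          config: SimConfig | None = None) -> dict[str, ProfileMatrix]:
    """Per-individual nucleotide profiles over all scaffolds.

    W-limited scaffolds are included with zero depth for males, mirroring a
    mapping of male reads against a female-derived assembly.
    """
    config = config or truth.config
    matrices: dict[str, ProfileMatrix] = {}
    all_scaffolds = list(truth.scaffold_table["scaffold"]) + truth.w_scaffolds
    for i, (ind, sex) in enumerate(truth.individuals.itertuples(index=False)):
        rng = _rng(config, _STREAM_DNA, i)
        counts: dict[str, np.ndarray] = {}
        for scaf in all_scaffolds:
            if scaf in truth.haplotypes[ind]:
                counts[scaf] = _profile_counts(
                    truth.haplotypes[ind][scaf], config.depth_mean,
                    config.error_rate, rng)
            else:  # W scaffold in a male: no reads
                counts[scaf] = np.zeros((config.scaffold_length, 4), np.int32)
        matrices[ind] = ProfileMatrix(counts, source="DNA", individual=ind)
    return matrices


# ---------------------------------------------------------------------------
# expression and RNA profiles
# ---------------------------------------------------------------------------

TISSUES = ("catkin", "leaf")


def simulate_expression(truth: SimTruth, config: SimConfig | None = None
                        ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """FPKM matrices per tissue and RNA profiles at heterozygous CDS sites.

    Returns ``(fpkm, rna)`` where ``fpkm[tissue]`` is a gene x individual
    DataFrame and ``rna`` is a long table with columns individual, tissue,
    scaffold, pos (1-based), A, C, G, T.  RNA depth at a site is
    ``round(FPKM * rna_depth_scale)``; allele counts are binomial with the
    W:Z ratio at Z/W divergent sites in females and 0.5 elsewhere.
    """
    config = config or truth.config
    genes = truth.genes
    inds = truth.individuals
    G = len(genes)
    rng_e = _rng(config, _STREAM_EXPRESSION)

    # baseline: gene-level mean and per-sample replicate noise, both on log2
    mu = rng_e.normal(config.fpkm_log_mean, config.fpkm_log_sd, size=G)
    fpkm: dict[str, pd.DataFrame] = {}
    biased = truth.biased_genes.set_index("gene") if len(truth.biased_genes) \
        else pd.DataFrame(columns=["tissue", "direction", "fold"])
    for tissue in TISSUES:
        eps = rng_e.normal(0.0, config.fpkm_log_sd, size=(G, len(inds)))
        mat = 2.0 ** (mu[:, None] + eps)
        df = pd.DataFrame(mat, index=genes["gene"].values,
                          columns=inds["individual"].values)
        for gene, row in biased.iterrows():
            if row["tissue"] != tissue:
                continue
            sex = "M" if row["direction"] == "male" else "F"
            cols = inds.loc[inds["sex"] == sex, "individual"]
            df.loc[gene, cols] *= row["fold"]
        fpkm[tissue] = df

    # RNA allele counts at heterozygous CDS sites
    gene_cols = list(zip(genes["gene"], genes["scaffold"],
                         genes["cds_start"], genes["cds_end"]))
    records = []
    for i, (ind, sex) in enumerate(inds.itertuples(index=False)):
        rng = _rng(config, _STREAM_RNA, i)
        for gene, scaf, cds_start, cds_end in gene_cols:
            haps = truth.haplotypes[ind][scaf]
            if haps.shape[0] < 2:
                continue
            h1, h2 = haps[0], haps[1]
            het = np.flatnonzero(h1[cds_start:cds_end] != h2[cds_start:cds_end])
            if het.size == 0:
                continue
            pos = het + cds_start
            div = truth.div_sites.get((ind, scaf))
            is_div = (np.isin(pos, div) if div is not None
                      else np.zeros(pos.size, bool))
            ratio = np.where(is_div, truth.w_expression_ratio.get(gene, 0.5), 0.5)
            for tissue in TISSUES:
                depth = int(round(fpkm[tissue].at[gene, ind]
                                  * config.rna_depth_scale))
                if depth <= 0:
                    continue
                c2 = rng.binomial(depth, ratio)
                c1 = depth - c2
                for p, b1, b2, n1, n2 in zip(pos, h1[pos], h2[pos], c1, c2):
                    row = [0, 0, 0, 0]
                    row[b1] += int(n1)
                    row[b2] += int(n2)
                    records.append((ind, tissue, scaf, int(p) + 1, *row))
    rna = pd.DataFrame(records, columns=[
        "individual", "tissue", "scaffold", "pos", "A", "C", "G", "T"])
    return fpkm, rna


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------


def write_simulation(truth: SimTruth, outdir, profiles=None, fpkm=None,
                     rna=None) -> None:
    """Write the simulated dataset as plain-text files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config = truth.config
    config.to_file(out / "config.yaml")

    anchored = {s: truth.reference[s] for s in truth.scaffold_table["scaffold"]}
    write_fasta(anchored, out / "reference.fasta")
    if truth.w_scaffolds:
        write_fasta({s: truth.reference[s] for s in truth.w_scaffolds},
                    out / "female_assembly.fasta")

    truth.scaffold_table.to_csv(out / "scaffold_truth.tsv", sep="\t", index=False)
    truth.individuals.to_csv(out / "individuals.tsv", sep="\t", index=False)
    truth.biased_genes.to_csv(out / "biased_genes.tsv", sep="\t", index=False)
    write_hits(truth.hits, out / "hits.tsv")

    models = [GeneModel(g, scaf, strand, exons=[(s, e)], cds=[(s, e, 0)])
              for g, scaf, strand, s, e in truth.genes.itertuples(index=False)]
    write_gene_models(models, out / "genes.gff3")

    if profiles is not None:
        for ind, matrix in profiles.items():
            write_profiles(matrix, out / f"profiles_{ind}.tsv")
    if fpkm is not None:
        for tissue, df in fpkm.items():
            df.to_csv(out / f"fpkm_{tissue}.tsv", sep="\t", index_label="gene")
    if rna is not None:
        rna.to_csv(out / "rna_profiles.tsv", sep="\t", index=False)
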