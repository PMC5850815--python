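"""Readers and writers for the tabular and sequence formats the pipeline touches.

Conventions
-----------
* On disk, coordinates are 1-based inclusive (profile ``pos``, GFF3 intervals,
  hit-table positions).  In memory, intervals are 0-based half-open and single
  positions are 0-based unless a field is explicitly named ``position_1based``.
* Nucleotide profiles are per-site A/C/G/T read counts for one individual, as
  produced by pileup summarizers (Sam2Pro-style): columns
  ``scaffold  pos  A  C  G  T``.
* Expression matrices are dense gene x sample FPKM tables; missing cells are a
  hard error because every downstream filter is defined on all individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

PROFILE_COLUMNS = ["scaffold", "pos", "A", "C", "G", "T"]
HIT_COLUMNS = ["transcript", "scaffold", "chromosome", "position", "evalue", "bitscore"]


class FormatError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class NucleotideProfile:
    """Per-site base counts for one individual at one position (1-based)."""

    scaffold: str
    position: int  # 1-based
    counts: dict
    source: str = "DNA"
    individual: str | None = None

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())


@dataclass
class GeneModel:
    """A gene with exon and CDS intervals (0-based half-open, sorted)."""

    gene_id: str
    scaffold: str
    strand: str
    exons: list = field(default_factory=list)
    cds: list = field(default_factory=list)  # list of (start, end, frame)
    region: str | None = None  # SD | autosome | PAR, assigned downstream

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)

    @property
    def cds_valid(self) -> bool:
        """CDS length divisible by 3 after frame adjustment of the first piece."""
        if not self.cds:
            return False
        frame = self.cds[0][2] if self.strand == "+" else self.cds[-1][2]
        return (self.cds_length - frame) % 3 == 0


@dataclass
class HitTableRow:
    """One BLAST-like hit of a transcript against a reference chromosome."""

    transcript: str
    scaffold: str
    chromosome: str
    position: int
    evalue: float
    bitscore: float


class ProfileMatrix:
    """Dense per-scaffold count matrices for one individual.

    ``counts[scaffold]`` is an ``(L, 4)`` integer array in A, C, G, T order;
    row ``i`` is scaffold position ``i`` (0-based).
    """

    def __init__(self, counts: Mapping[str, np.ndarray] | None = None,
                 source: str = "DNA", individual: str | None = None):
        self.counts: dict[str, np.ndarray] = dict(counts or {})
        self.source = source
        self.individual = individual

    def scaffolds(self) -> list[str]:
        return list(self.counts)

    def coverage(self, scaffold: str) -> np.ndarray:
        return self.counts[scaffold].sum(axis=1)

    def iter_profiles(self) -> Iterator[NucleotideProfile]:
        for scaffold, mat in self.counts.items():
            cov = mat.sum(axis=1)
            for i in np.flatnonzero(cov):
                yield NucleotideProfile(
                    scaffold, int(i) + 1,
                    {b: int(mat[i, j]) for j, b in enumerate(BASES)},
                    self.source, self.individual)

    @classmethod
    def from_profiles(cls, profiles: Iterable[NucleotideProfile],
                      lengths: Mapping[str, int] | None = None,
                      source: str = "DNA",
                      individual: str | None = None) -> "ProfileMatrix":
        records = list(profiles)
        counts: dict[str, np.ndarray] = {}
        if lengths:
            for scaf, L in lengths.items():
                counts[scaf] = np.zeros((L, 4), dtype=np.int32)
        else:
            maxpos: dict[str, int] = {}
            for p in records:
                maxpos[p.scaffold] = max(maxpos.get(p.scaffold, 0), p.position)
            for scaf, L in maxpos.items():
                counts[scaf] = np.zeros((L, 4), dtype=np.int32)
        for p in records:
            row = counts[p.scaffold][p.position - 1]
            for b, c in p.counts.items():
                row[BASE_INDEX[b]] = c
        return cls(counts, source=source, individual=individual)


# ---------------------------------------------------------------------------
# nucleotide profiles (TSV)
# ---------------------------------------------------------------------------


def read_profiles(path, source: str = "DNA",
                  individual: str | None = None) -> Iterator[NucleotideProfile]:
    """Stream validated profiles from a ``scaffold pos A C G T`` TSV."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PROFILE_COLUMNS:
            raise FormatError(f"{path}: line 1: expected header "
                              f"{PROFILE_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 columns")
            scaffold = parts[0]
            try:
                pos = int(parts[1])
                counts = [int(x) for x in parts[2:6]]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if pos < 1:
                raise FormatError(
                    f"{path}: line {lineno}: position {pos} is not 1-based")
            if any(c < 0 for c in counts):
                raise FormatError(f"{path}: line {lineno}: negative count")
            yield NucleotideProfile(scaffold, pos, dict(zip(BASES, counts)),
                                    source, individual)


def write_profiles(profiles: Iterable[NucleotideProfile] | ProfileMatrix, path) -> None:
    if isinstance(profiles, ProfileMatrix):
        profiles = profiles.iter_profiles()
    with open(path, "w") as fh:
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for p in profiles:
            fh.write(f"{p.scaffold}\t{p.position}\t" +
                     "\t".join(str(p.counts.get(b, 0)) for b in BASES) + "\n")


# ---------------------------------------------------------------------------
# coverage tables
# ---------------------------------------------------------------------------


def write_coverage(matrix: ProfileMatrix, path) -> None:
    """Per-site depth TSV (``scaffold pos depth``), covered sites only."""
    with open(path, "w") as fh:
        fh.write("scaffold\tpos\tdepth\n")
        for scaffold in matrix.scaffolds():
            cov = matrix.coverage(scaffold)
            for i in np.flatnonzero(cov):
                fh.write(f"{scaffold}\t{i + 1}\t{cov[i]}\n")


def read_coverage(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["scaffold", "pos", "depth"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}")
    if (df["depth"] < 0).any() or (df["pos"] < 1).any():
        raise FormatError(f"{path}: negative depth or non-1-based position")
    return df


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------


def _parse_attributes(text: str) -> dict:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(path) -> list[GeneModel]:
    """Parse a GFF3 file into gene models.

    Exon and CDS features are attached to the gene named by their ``Parent``
    (or ``ID``) attribute; unknown feature types are skipped with a logged
    count.  Genes whose CDS length is not divisible by 3 are kept but flagged
    via :attr:`GeneModel.cds_valid` so divergence analyses can exclude them.
    """
    genes: dict[str, GeneModel] = {}
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns")
            seqid, _, ftype, start, end, _, strand, frame, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: bad coordinates") from None
            a = _parse_attributes(attrs)
            name = a.get("Parent") or a.get("ID")
            if name is None:
                raise FormatError(f"{path}: line {lineno}: no ID/Parent attribute")
            # mRNA features point at the gene; collapse the two levels
            name = name.split(",")[0]
            if ftype == "gene":
                genes.setdefault(name, GeneModel(name, seqid, strand))
                continue
            if ftype == "mRNA":
                genes.setdefault(name, GeneModel(name, seqid, strand))
                continue
            if ftype not in ("exon", "CDS"):
                skipped += 1
                continue
            gene = genes.setdefault(name, GeneModel(name, seqid, strand))
            iv = (start_i - 1, end_i)  # to 0-based half-open
            if ftype == "exon":
                gene.exons.append(iv)
            else:
                fr = int(frame) if frame in ("0", "1", "2") else 0
                gene.cds.append((iv[0], iv[1], fr))
    if skipped:
        logger.info("read_gene_models: ignored %d records of unknown type", skipped)
    for gene in genes.values():
        gene.exons.sort()
        gene.cds.sort()
        if not gene.exons and gene.cds:
            gene.exons = [(s, e) for s, e, _ in gene.cds]
        if gene.cds and not gene.cds_valid:
            logger.warning("gene %s: CDS length %d not divisible by 3; "
                           "flagged for exclusion", gene.gene_id, gene.cds_length)
    return sorted(genes.values(), key=lambda g: g.gene_id)


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            if g.exons:
                gstart = min(s for s, _ in g.exons) + 1
                gend = max(e for _, e in g.exons)
            else:
                gstart = min(s for s, _, _ in g.cds) + 1
                gend = max(e for _, e, _ in g.cds)
            fh.write(f"{g.scaffold}\tzwscan\tgene\t{gstart}\t{gend}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{g.scaffold}\tzwscan\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tParent={g.gene_id}\n")
            for s, e, fr in g.cds:
                fh.write(f"{g.scaffold}\tzwscan\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t{fr}\tParent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# expression matrices and hit tables
# ---------------------------------------------------------------------------


def read_expression(path) -> pd.DataFrame:
    """Dense gene x sample FPKM matrix; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing cell (gene {bad}); "
                          "a dense matrix is required")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != HIT_COLUMNS:
        raise FormatError(f"{path}: expected columns {HIT_COLUMNS}")
    if (df["evalue"] < 0).any():
        raise FormatError(f"{path}: negative e-value")
    return df


def write_hits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3 (other characters -> 255)."""
    table = np.full(256, 255, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str | np.ndarray], path) -> None:
    records = []
    for name, seq in seqs.items():
        if isinstance(seq, np.ndarray):
            seq = decode_sequence(seq)
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SNP calls (TSV / VCF-style)
# ---------------------------------------------------------------------------


def write_snps(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False)


def read_snps(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_snps_vcf(snps: pd.DataFrame, path, sample: str = "sample") -> None:
    """Minimal VCF: CHROM=scaffold, 1-based POS, REF=major DNA allele, ALT=minor."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=zwscan\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in snps.itertuples(index=False):
            info = f"MAF={row.maf:.4f};DP={row.coverage}"
            fh.write(f"{row.scaffold}\t{row.position}\t.\t{row.major}\t"
                     f"{row.minor}\t.\tPASS\t{info}\n")
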