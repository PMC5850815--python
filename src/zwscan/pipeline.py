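"""End-to-end pipeline over a synthetic dataset.

Runs every stage in order on one simulated dataset: genome + haplotypes, DNA
profiles, SNP calling, per-scaffold statistics, chromosome anchoring, the
female:male SNP-density and coverage scan with bootstrap band / permutation
test / region detection, pi_s per region and sex, sex-biased expression with
windowed tracks, allele-specific expression with the SD-vs-autosome test
(feeding the 100%-ASE scaffold exclusion back into the density scan), and
female-specific scaffold detection.

Region labels for pi_s and the expression/ASE comparisons come from the
simulation's scaffold truth table (standing in for the linkage-map knowledge
of the real study); the scan itself never sees them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import divergence, expression, genomescan, simdata, variants, wfinder
from .formats import write_fasta, write_hits
from .simdata import SimConfig, SimTruth, TISSUES


@dataclass
class PipelineResult:
    truth: SimTruth
    snps: dict                      # individual -> SNP table
    stats: pd.DataFrame             # per scaffold x individual (normalized)
    anchors: pd.DataFrame           # scaffold -> chromosome, position
    density_track: pd.DataFrame
    density_band: genomescan.BootstrapBand
    coverage_track: pd.DataFrame
    coverage_band: genomescan.BootstrapBand
    permutation_p: float
    detected: pd.DataFrame
    pis: pd.DataFrame
    bias: dict                      # tissue -> sex-bias table
    tracks: dict                    # tissue -> (track, band)
    ase_records: pd.DataFrame
    ase_tests: pd.DataFrame
    w_candidates: pd.DataFrame
    extras: dict = field(default_factory=dict)


def _sex_track(stats: pd.DataFrame, truth: SimTruth, value_col: str,
               anchors: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    sexes = truth.individuals.set_index("individual")["sex"]
    wide = stats.pivot(index="scaffold", columns="individual", values=value_col)
    mean_f = wide[[c for c in wide.columns if sexes[c] == "F"]].mean(axis=1)
    mean_m = wide[[c for c in wide.columns if sexes[c] == "M"]].mean(axis=1)
    return genomescan.log2_ratio(mean_f.dropna(), mean_m.dropna(),
                                 pseudocount=pseudocount)


def _make_track(values: pd.Series, anchors: pd.DataFrame,
                window: int) -> pd.DataFrame:
    df = (anchors.merge(values.rename("value"), left_on="scaffold",
                        right_index=True)
                 .rename(columns={"scaffold": "unit"}))
    return genomescan.moving_average(df, window=window)


def run_pipeline(config: SimConfig, window: int = 25, set_size: int = 25,
                 n_boot: int = 1000, n_perm: int = 1000,
                 run_expression: bool = True,
                 run_pis: bool = True) -> PipelineResult:
    truth = simdata.simulate_genome(config)
    profiles = simdata.simulate_dna_profiles(truth, config)
    sd_chrom = config.sd_chromosome
    rng = np.random.default_rng([config.seed, 99])

    # SNP calls and per-scaffold statistics
    snps = {ind: variants.call_snps(mat) for ind, mat in profiles.items()}
    stats = pd.concat(
        [variants.normalize_coverage(
            variants.scaffold_stats(snps[ind], profiles[ind]))
         for ind in profiles], ignore_index=True)

    # anchoring from the transcript hit table (W scaffolds stay unanchored)
    anchors = genomescan.assign_scaffolds(truth.hits)

    # expression, ASE (needed for the 100%-ASE scaffold exclusion)
    region_of_gene = {}
    gene_scaf = truth.genes.set_index("gene")["scaffold"]
    scaf_info = truth.scaffold_table.set_index("scaffold")
    for g, scaf in gene_scaf.items():
        if scaf in truth.sd_scaffolds:
            region_of_gene[g] = "SD"
        elif scaf_info.at[scaf, "chromosome"] == sd_chrom:
            region_of_gene[g] = "PAR"
        else:
            region_of_gene[g] = "autosome"

    bias: dict[str, pd.DataFrame] = {}
    tracks: dict[str, tuple] = {}
    ase_records = pd.DataFrame(columns=["gene", "individual", "tissue",
                                        "n_snps", "ase", "removed"])
    ase_tests = pd.DataFrame()
    fpkm = rna = None
    if run_expression:
        fpkm, rna = simdata.simulate_expression(truth, config)
        gene_anchor = truth.genes.merge(
            truth.scaffold_table[["scaffold", "chromosome", "start"]],
            on="scaffold")
        gene_anchor["position"] = (gene_anchor["start"]
                                   + (gene_anchor["cds_start"]
                                      + gene_anchor["cds_end"]) / 2)
        gene_anchor = gene_anchor[["gene", "chromosome", "position"]]
        sexes = dict(zip(truth.individuals["individual"],
                         truth.individuals["sex"]))
        for tissue in TISSUES:
            expressed = expression.filter_expressed(fpkm[tissue])
            tab = expression.sex_bias(fpkm[tissue].loc[expressed], sexes)
            bias[tissue] = tab
            tracks[tissue] = expression.expression_track(
                tab, gene_anchor, window=window, set_size=set_size,
                n_boot=n_boot, exclude_chromosome=sd_chrom,
                rng=np.random.default_rng([config.seed, 98,
                                           TISSUES.index(tissue)]))
        ase_records = ase_mod.build_ase_table(snps, rna, truth.genes)
        if len(ase_records):
            ase_tests = ase_mod.ase_region_test(ase_records, region_of_gene)

    # 100%-ASE scaffold exclusion feeds back into the SNP-density scan
    gene_map = truth.genes[["gene", "scaffold"]]
    stats_f = variants.exclude_full_ase_scaffolds(
        stats, ase_records if len(ase_records) else None, gene_map)

    # SNP-density and coverage scans
    density = _sex_track(stats_f, truth, "snp_density", anchors)
    coverage = _sex_track(stats_f, truth, "norm_cov", anchors)
    density_track = _make_track(density, anchors, window)
    coverage_track = _make_track(coverage, anchors, window)
    bg_density = density_track.loc[density_track["chromosome"] != sd_chrom,
                                   "value"].to_numpy()
    bg_cov = coverage_track.loc[coverage_track["chromosome"] != sd_chrom,
                                "value"].to_numpy()
    # toy genomes can have fewer background units than the nominal set size
    eff_set = min(set_size, bg_density.size)
    density_band = genomescan.bootstrap_band(bg_density, eff_set, n_boot,
                                             rng=rng)
    coverage_band = genomescan.bootstrap_band(bg_cov, min(set_size,
                                                          bg_cov.size),
                                              n_boot, rng=rng)
    detected = genomescan.detect_sd_region(density_track, density_band,
                                           chromosome=sd_chrom)
    sd_vals = density_track.loc[density_track["unit"]
                                .isin(truth.sd_scaffolds), "value"].to_numpy()
    permutation_p = genomescan.permutation_test(sd_vals, bg_density,
                                                n_perm=n_perm, rng=rng)

    # pi_s per region and sex
    region_of_scaffold = {}
    for row in truth.scaffold_table.itertuples(index=False):
        if row.scaffold in truth.sd_scaffolds:
            region_of_scaffold[row.scaffold] = "SD"
        elif row.chromosome == sd_chrom:
            region_of_scaffold[row.scaffold] = "PAR"
        else:
            region_of_scaffold[row.scaffold] = "autosome"
    coverage_by_ind = {ind: {s: profiles[ind].coverage(s)
                             for s in profiles[ind].scaffolds()}
                       for ind in profiles}
    sex_of = dict(zip(truth.individuals["individual"],
                      truth.individuals["sex"]))
    if run_pis:
        pis = divergence.pi_s(truth.genes, truth.reference, snps,
                              coverage_by_ind, region_of_scaffold, sex_of,
                              n_boot=n_boot, rng=rng)
    else:
        pis = pd.DataFrame(columns=["region", "sex", "n_genes", "S", "Sd",
                                    "pi_s", "ci_lo", "ci_hi"])

    # female-specific scaffolds over the female assembly + anchored scaffolds
    cov_table = wfinder.mean_scaffold_coverage(profiles)
    w_candidates = wfinder.find_female_specific(cov_table, sex_of)

    return PipelineResult(
        truth=truth, snps=snps, stats=stats_f, anchors=anchors,
        density_track=density_track, density_band=density_band,
        coverage_track=coverage_track, coverage_band=coverage_band,
        permutation_p=permutation_p, detected=detected, pis=pis,
        bias=bias, tracks=tracks, ase_records=ase_records,
        ase_tests=ase_tests, w_candidates=w_candidates,
        extras={"fpkm": fpkm, "rna": rna, "profiles": profiles,
                "coverage_table": cov_table})


# ---------------------------------------------------------------------------
# deterministic on-disk output
# ---------------------------------------------------------------------------

_FLOAT = "%.10g"


def _band_df(band: genomescan.BootstrapBand) -> pd.DataFrame:
    return pd.DataFrame([{"lo": band.lo, "median": band.median,
                          "hi": band.hi}])


def write_pipeline_outputs(result: PipelineResult, outdir,
                           write_profiles_tsv: bool = False) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = result.truth
    simdata.write_simulation(
        truth, out / "sim",
        profiles=result.extras["profiles"] if write_profiles_tsv else None,
        fpkm=result.extras["fpkm"], rna=result.extras["rna"])
    for ind, snps in result.snps.items():
        snps.to_csv(out / f"snps_{ind}.tsv", sep="\t", index=False,
                    float_format=_FLOAT)
    result.stats.to_csv(out / "scaffold_stats.tsv", sep="\t", index=False,
                        float_format=_FLOAT)
    result.anchors.to_csv(out / "anchors.tsv", sep="\t", index=False,
                          float_format=_FLOAT)
    for name in ("density", "coverage"):
        track = getattr(result, f"{name}_track").drop(columns=["units"],
                                                      errors="ignore")
        track.to_csv(out / f"{name}_track.tsv", sep="\t", index=False,
                     float_format=_FLOAT)
        _band_df(getattr(result, f"{name}_band")).to_csv(
            out / f"{name}_band.tsv", sep="\t", index=False,
            float_format=_FLOAT)
    detected = result.detected.copy()
    if "units" in detected.columns:
        detected["units"] = detected["units"].map(
            lambda u: ",".join(u) if isinstance(u, list) else "")
    detected.to_csv(out / "detected_regions.tsv", sep="\t", index=False,
                    float_format=_FLOAT)
    if len(result.detected):
        genomescan.write_bed(result.detected, out / "detected_regions.bed")
    result.pis.to_csv(out / "pi_s.tsv", sep="\t", index=False,
                      float_format=_FLOAT)
    with open(out / "permutation.txt", "w") as fh:
        fh.write(f"permutation_p\t{result.permutation_p:.10g}\n")
    for tissue, tab in result.bias.items():
        tab.to_csv(out / f"sex_bias_{tissue}.tsv", sep="\t", index=False,
                   float_format=_FLOAT)
    for tissue, (track, band) in result.tracks.items():
        track.to_csv(out / f"expression_track_{tissue}.tsv", sep="\t",
                     index=False, float_format=_FLOAT)
        _band_df(band).to_csv(out / f"expression_band_{tissue}.tsv", sep="\t",
                              index=False, float_format=_FLOAT)
    result.ase_records.to_csv(out / "ase_records.tsv", sep="\t", index=False,
                              float_format=_FLOAT)
    if len(result.ase_tests):
        result.ase_tests.to_csv(out / "ase_tests.tsv", sep="\t", index=False,
                                float_format=_FLOAT)
    result.w_candidates.to_csv(out / "w_candidates.tsv", sep="\t", index=False,
                               float_format=_FLOAT)
    result.extras["coverage_table"].to_csv(out / "mean_coverage.tsv", sep="\t",
                                           index_label="scaffold",
                                           float_format=_FLOAT)


def tree_digest(root) -> str:
    """SHA256 digest over relative paths and file contents of a directory tree."""
    h = hashlib.sha256()
    root = Path(root)
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        h.update(str(path.relative_to(root)).encode())
        h.update(path.read_bytes())
    return h.hexdigest()
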