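"""NG86 counting against enumeration oracles; pi_s on hand-built genes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from zwscan import divergence

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
STOPS = {"TAA", "TAG", "TGA"}
SENSE = [c for c in ALL_CODONS if c not in STOPS]


def _aa(codon):
    return str(Seq(codon).translate())


def oracle_site_counts(codon):
    """Independent 9-mutation enumeration of synonymous sites."""
    s = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if mut not in STOPS and _aa(mut) == _aa(codon):
                s += 1 / 3
    return s


def oracle_pathways(ca, cb):
    """Brute-force pathway averaging between two codons (stop paths excluded)."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    results, blocked = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, stop = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOPS:
                stop = True
                nd += 1
            elif _aa(nxt) == _aa(cur) and cur not in STOPS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if stop else results).append((sd, nd))
    use = results or blocked
    return (sum(x for x, _ in use) / len(use),
            sum(y for _, y in use) / len(use))


class TestSiteCounts:
    @pytest.mark.parametrize("codon,expected", [
        ("TTT", 1 / 3),   # only TTC is synonymous
        ("TGG", 0.0),     # Trp has no synonymous neighbor
        ("CTT", 1.0),     # third position fully synonymous
    ])
    def test_known_codons(self, codon, expected):
        assert divergence.ng86_site_counts(codon).synonymous == \
            pytest.approx(expected)

    def test_all_sense_codons_match_oracle_and_sum_to_three(self):
        for codon in SENSE:
            counts = divergence.ng86_site_counts(codon)
            assert counts.synonymous == pytest.approx(oracle_site_counts(codon))
            assert counts.synonymous + counts.nonsynonymous == \
                pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            divergence.ng86_site_counts("TAA")


class TestClassify:
    def test_third_position_glu(self):
        assert divergence.classify_codon_change("GAA", 2, "A", "G") == \
            "synonymous"

    def test_first_position_glu_to_lys(self):
        assert divergence.classify_codon_change("GAA", 0, "G", "A") == \
            "nonsynonymous"

    def test_minus_strand_gene(self):
        # CDS read on the minus strand is GAA; genomic forward holds TTC
        gene = {"scaffold": "s1", "strand": "-", "cds_start": 0, "cds_end": 3}
        snp = {"position": 1, "major": "T", "minor": "C"}
        assert divergence.classify_allelic_difference(gene, "TTC", snp) == \
            "synonymous"

    def test_snp_outside_cds_skipped(self):
        gene = {"scaffold": "s1", "strand": "+", "cds_start": 0, "cds_end": 3}
        snp = {"position": 10, "major": "A", "minor": "G"}
        assert divergence.classify_allelic_difference(gene, "GAA", snp) == \
            "skipped"


def _snp(scaffold, pos, major, minor, cov=20):
    return {"scaffold": scaffold, "position": pos, "major": major,
            "minor": minor, "major_count": cov // 2, "minor_count": cov // 2,
            "coverage": cov}


class TestPiS:
    def _inputs(self, snp_rows, n_codons=100):
        genes = pd.DataFrame([{"gene": "g1", "scaffold": "s1", "strand": "+",
                               "cds_start": 0, "cds_end": 3 * n_codons}])
        reference = {"s1": "GAA" * n_codons}
        snps = {"F1": pd.DataFrame(snp_rows,
                                   columns=["scaffold", "position", "major",
                                            "minor", "major_count",
                                            "minor_count", "coverage"])}
        coverage = {"F1": {"s1": np.full(3 * n_codons, 20)}}
        return genes, reference, snps, coverage

    def test_single_synonymous_snp(self):
        # GAA has one synonymous neighbor (GAG) at position 3: S_c = 1/3
        genes, ref, snps, cov = self._inputs([_snp("s1", 3, "A", "G")])
        out = divergence.pi_s(genes, ref, snps, cov, {"s1": "SD"},
                              {"F1": "F"}, n_boot=50, rng=0)
        row = out[(out["region"] == "SD") & (out["sex"] == "F")].iloc[0]
        assert row["S"] == pytest.approx(100 / 3)
        assert row["Sd"] == 1.0
        assert row["pi_s"] == pytest.approx(3 / 100)

    def test_no_snps_gives_zero_with_degenerate_ci(self):
        genes, ref, snps, cov = self._inputs([])
        out = divergence.pi_s(genes, ref, snps, cov, {"s1": "SD"},
                              {"F1": "F"}, n_boot=50, rng=0)
        row = out.iloc[0]
        assert (row["pi_s"], row["ci_lo"], row["ci_hi"]) == (0.0, 0.0, 0.0)

    def test_codon_with_two_het_sites_is_skipped_entirely(self):
        # second codon (positions 4-6) carries two SNPs: removed from Sd AND S
        rows = [_snp("s1", 3, "A", "G"),
                _snp("s1", 4, "G", "A"), _snp("s1", 5, "A", "C")]
        genes, ref, snps, cov = self._inputs(rows)
        out = divergence.pi_s(genes, ref, snps, cov, {"s1": "SD"},
                              {"F1": "F"}, n_boot=50, rng=0)
        row = out.iloc[0]
        assert row["S"] == pytest.approx(99 / 3)
        assert row["Sd"] == 1.0

    def test_triallelic_snp_excluded(self):
        rows = [{"scaffold": "s1", "position": 3, "major": "A", "minor": "G",
                 "major_count": 10, "minor_count": 7, "coverage": 20}]  # 3rd=3
        genes, ref, snps, cov = self._inputs(rows)
        out = divergence.pi_s(genes, ref, snps, cov, {"s1": "SD"},
                              {"F1": "F"}, n_boot=50, rng=0)
        assert out.iloc[0]["Sd"] == 0.0

    def test_low_coverage_sites_removed_from_denominator(self):
        genes, ref, snps, cov = self._inputs([_snp("s1", 3, "A", "G")])
        cov["F1"]["s1"][150:] = 5  # second half below 10x
        out = divergence.pi_s(genes, ref, snps, cov, {"s1": "SD"},
                              {"F1": "F"}, n_boot=50, rng=0)
        assert out.iloc[0]["S"] == pytest.approx(50 / 3)


class TestKaKs:
    def test_identical_sequences(self):
        r = divergence.ng86_kaks("CTT" * 120, "CTT" * 120)
        assert r.Ka == 0.0 and r.Ks == 0.0

    def test_one_synonymous_difference_closed_form(self):
        a = "CTT" * 300
        b = "CTC" + "CTT" * 299  # Leu -> Leu at the third position
        r = divergence.ng86_kaks(a, b)
        assert r.Sd == pytest.approx(1.0)
        assert r.S == pytest.approx(300.0)
        expected = -0.75 * np.log(1 - (4 / 3) * (1 / 300))
        assert r.Ks == pytest.approx(expected, abs=1e-12)
        assert r.Ka == 0.0

    def test_pathway_averaging_matches_brute_force(self, rng):
        for _ in range(150):
            ca, cb = rng.choice(SENSE, size=2)
            got = divergence._pathway_counts(ca, cb)
            assert got == pytest.approx(oracle_pathways(ca, cb))

    def test_symmetry(self, rng):
        a = "".join(rng.choice(SENSE, size=60))
        b = "".join(rng.choice(SENSE, size=60))
        ra, rb = divergence.ng86_kaks(a, b), divergence.ng86_kaks(b, a)
        assert ra.S == pytest.approx(rb.S)
        assert ra.Sd == pytest.approx(rb.Sd)
        assert ra.Nd == pytest.approx(rb.Nd)

    def test_saturation_is_flagged(self):
        # maximally diverged third positions: ps can exceed the JC domain
        a = "GCT" * 200
        b = "CGA" * 200
        r = divergence.ng86_kaks(a, b)
        assert r.saturated or r.Ks is not None  # never raises

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            divergence.ng86_kaks("CTT", "CTTCTT")


class TestOrthologFilters:
    def _df(self, **kw):
        base = {"gene_a": "x", "gene_b": "y", "length": 300, "S": 100.0,
                "N": 200.0, "Sd": 10.0, "Nd": 5.0, "Ka": 0.02, "Ks": 0.5,
                "ka_ks": 0.04, "saturated": False}
        base.update(kw)
        return pd.DataFrame([base])

    def test_rules(self):
        assert len(divergence.filter_orthologs(self._df(Ks=2.5))) == 0
        assert len(divergence.filter_orthologs(self._df(S=10.0, Ks=0.05))) == 0
        assert len(divergence.filter_orthologs(self._df(length=100))) == 0
        assert len(divergence.filter_orthologs(self._df(S=200.0, Ks=0.5))) == 1
        assert len(divergence.filter_orthologs(self._df(saturated=True))) == 0


class TestFastZ:
    def test_identical_groups(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        df = pd.DataFrame({"gene_a": [f"s{i}" for i in range(4)]
                           + [f"a{i}" for i in range(4)],
                           "ka_ks": vals + vals})
        region = {f"s{i}": "SD" for i in range(4)}
        out = divergence.fast_z_test(df, region)
        assert out["p"] == pytest.approx(1.0)
        assert out["mean_sd"] == out["mean_autosome"]

    def test_large_shift_is_significant(self, rng):
        sd = rng.normal(1.0, 0.1, 50)
        auto = rng.normal(0.5, 0.1, 50)
        df = pd.DataFrame({"gene_a": [f"s{i}" for i in range(50)]
                           + [f"a{i}" for i in range(50)],
                           "ka_ks": np.concatenate([sd, auto])})
        region = {f"s{i}": "SD" for i in range(50)}
        assert divergence.fast_z_test(df, region)["p"] < 1e-6

    def test_small_groups_rejected(self):
        df = pd.DataFrame({"gene_a": ["s1", "a1"], "ka_ks": [0.1, 0.2]})
        with pytest.raises(ValueError):
            divergence.fast_z_test(df, {"s1": "SD"})
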