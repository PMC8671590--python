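"""Seed-match strings, sequence scanning, and targetome assembly."""

import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from agoclip.targetome import (
    MiRNA,
    build_targetome,
    cluster_sequence,
    compare_target_sets,
    scan_sequence,
    seed_coverage_fraction,
    seed_match_strings,
    target_genes,
)

RNA_COMP = {"A": "U", "C": "G", "G": "C", "T": "A"}


def brute_force_sites(seq, mirna):
    """Independent oracle: direct substring comparison at every offset, then
    per-core-locus dominance by explicit rank comparison."""
    strings = seed_match_strings(mirna)
    rank = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3}
    raw = []
    for site_type, match in strings.items():
        for off in range(len(seq) - len(match) + 1):
            if all(seq[off + i] == match[i] for i in range(len(match))):
                core = off + (1 if site_type in ("8mer", "7mer-m8") else 0)
                raw.append((core, rank[site_type], off, site_type))
    best = {}
    for core, r, off, site_type in raw:
        if core not in best or r < best[core][0]:
            best[core] = (r, off, site_type)
    return sorted((off, site_type) for r, off, site_type in best.values())


def random_mirna(rng, name="mir"):
    return MiRNA(name, "".join("ACGU"[i] for i in rng.integers(0, 4, 22)))


class TestSeedMatchStrings:
    def test_reference_mirna(self):
        mir = MiRNA("mir-x", "UGGACCCUAGGACCCUAGGACC")
        strings = seed_match_strings(mir)
        assert strings["6mer"] == "GGGTCC"
        assert strings["7mer-m8"] == "AGGGTCC"
        assert strings["7mer-A1"] == "GGGTCCA"
        assert strings["8mer"] == "AGGGTCCA"

    def test_minimum_length_mirna(self):
        strings = seed_match_strings(MiRNA("m", "UGGACCCU"))
        assert set(strings) == {"6mer", "7mer-m8", "7mer-A1", "8mer"}
        assert all(strings.values())

    def test_non_acgu_rejected(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            MiRNA("bad", "UGGACCXUAGG")

    def test_round_trip_over_random_catalogs(self):
        # revcomp of the match core read back in RNA equals the seed
        rng = np.random.default_rng(11)
        for i in range(100):
            mir = random_mirna(rng, f"m{i}")
            strings = seed_match_strings(mir)
            for core, seed in ((strings["6mer"], mir.seed6), (strings["7mer-m8"], mir.seed7)):
                back = "".join(RNA_COMP[b] for b in reversed(core))
                assert back == seed
            assert strings["7mer-A1"] == strings["6mer"] + "A"
            assert strings["8mer"] == strings["7mer-m8"] + "A"


class TestScanSequence:
    MIR = MiRNA("mir-x", "UGGACCCUAGGACCCUAGGACC")

    def test_no_seed_content(self):
        assert scan_sequence("TTTTTTTTTTTT", [self.MIR]) == {}
        assert scan_sequence("", [self.MIR]) == {}

    def test_8mer_dominates_locus(self):
        sites = scan_sequence("TTAGGGTCCATT", [self.MIR])[self.MIR.name]
        assert [(s.offset, s.site_type) for s in sites] == [(2, "8mer")]

    def test_two_6mers(self):
        sites = scan_sequence("GGGTCCGGGTCC", [self.MIR])[self.MIR.name]
        assert [(s.offset, s.site_type) for s in sites] == [(0, "6mer"), (6, "6mer")]

    def test_brute_force_oracle_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            catalog = [random_mirna(rng, f"m{j}") for j in range(3)]
            # random DNA with planted match strings so hits actually occur
            parts = []
            for _ in range(4):
                parts.append("".join("ACGT"[i] for i in rng.integers(0, 4, 15)))
                mir = catalog[rng.integers(3)]
                site_type = ["8mer", "7mer-m8", "7mer-A1", "6mer"][rng.integers(4)]
                parts.append(seed_match_strings(mir)[site_type])
            seq = "".join(parts)
            got = scan_sequence(seq, catalog)
            for mir in catalog:
                expected = brute_force_sites(seq, mir)
                found = [(s.offset, s.site_type) for s in got.get(mir.name, [])]
                assert found == expected

    def test_dominance_no_locus_reports_two_types(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            mir = random_mirna(rng)
            seq = "TT" + seed_match_strings(mir)["8mer"] + "TT"
            sites = scan_sequence(seq, [mir]).get(mir.name, [])
            cores = [s.offset + (1 if s.site_type in ("8mer", "7mer-m8") else 0) for s in sites]
            assert len(cores) == len(set(cores))

    def test_removing_8mer_rule_preserves_or_grows_7mer_count(self):
        mir = self.MIR
        seq = "TTAGGGTCCATTAGGGTCCTT"  # one 8mer locus + one 7mer-m8 locus
        sites = scan_sequence(seq, [mir])[mir.name]
        n_7mer_reported = sum(s.site_type.startswith("7mer") for s in sites)
        strings = seed_match_strings(mir)
        n_7mer_raw = sum(
            seq[i:].startswith(strings[t])
            for t in ("7mer-m8", "7mer-A1")
            for i in range(len(seq))
        )
        assert n_7mer_raw >= n_7mer_reported


def _write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class TestBuildTargetome:
    def test_minus_strand_site_found_after_revcomp(self, tmp_path):
        mir = MiRNA("mir-x", "UGGACCCUAGGACCCUAGGACC")
        match = seed_match_strings(mir)["8mer"]  # AGGGTCCA, transcript sense
        # on the genome's plus strand, a minus-strand gene carries revcomp
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        genome_plus = "T" * 20 + "".join(comp[b] for b in reversed(match)) + "T" * 20
        fa = tmp_path / "g.fa"
        _write_fasta(fa, [("chr1", genome_plus)])
        labeled = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 10, "end": 38, "strand": "-",
                 "stage": "adult", "name": "c0", "feature": "3UTR", "gene_id": "g1"},
                {"chrom": "chr1", "start": 10, "end": 38, "strand": "+",
                 "stage": "adult", "name": "c1", "feature": "3UTR", "gene_id": "g2"},
            ]
        )
        inter = build_targetome(labeled, Fasta(str(fa)), [mir], {"adult": {"mir-x"}})
        assert set(inter["cluster_id"]) == {"c0"}  # plus-strand read misses it
        assert list(inter["site_type"]) == ["8mer"]

    def test_out_of_bounds_cluster_raises(self, tmp_path):
        fa = tmp_path / "g.fa"
        _write_fasta(fa, [("chr1", "ACGT" * 10)])
        labeled = pd.DataFrame(
            [{"chrom": "chr1", "start": 30, "end": 100, "strand": "+",
              "stage": "adult", "name": "c0", "feature": "3UTR", "gene_id": "g"}]
        )
        with pytest.raises(ValueError, match="outside chromosome bounds"):
            build_targetome(labeled, Fasta(str(fa)), [MiRNA("m", "UGGACCCU")], {"adult": {"m"}})

    def test_stage_gating_of_expressed_set(self, tmp_path):
        mir = MiRNA("mir-x", "UGGACCCUAGGACCCUAGGACC")
        fa = tmp_path / "g.fa"
        _write_fasta(fa, [("chr1", "TT" + seed_match_strings(mir)["8mer"] + "TT")])
        mk = lambda stage, name: {
            "chrom": "chr1", "start": 0, "end": 12, "strand": "+", "stage": stage,
            "name": name, "feature": "3UTR", "gene_id": "g1",
        }
        labeled = pd.DataFrame([mk("adult", "c0"), mk("e12.5", "c1")])
        inter = build_targetome(
            labeled, Fasta(str(fa)), [mir], {"adult": {"mir-x"}, "e12.5": set()}
        )
        assert set(inter["stage"]) == {"adult"}


class TestSeedCoverage:
    def test_empty_catalog_gives_zero(self):
        assert seed_coverage_fraction(["ACGTACGTACGT"], []) == 0.0

    def test_direct_count(self):
        mir = MiRNA("mir-x", "UGGACCCUAGGACCCUAGGACC")
        with_site = "TT" + seed_match_strings(mir)["6mer"] + "TT"
        without = "TTTTTTTTTT"
        seqs = [with_site] * 6 + [without] * 4
        assert seed_coverage_fraction(seqs, [mir]) == pytest.approx(0.6)

    def test_monotone_in_catalog(self):
        rng = np.random.default_rng(14)
        mirs = [random_mirna(rng, f"m{i}") for i in range(6)]
        seqs = ["TT" + seed_match_strings(m)["6mer"] + "TT" for m in mirs[:4]]
        fractions = [
            seed_coverage_fraction(seqs, mirs[:k]) for k in range(1, len(mirs) + 1)
        ]
        assert fractions == sorted(fractions)

    def test_empty_cluster_set_raises(self):
        with pytest.raises(ValueError, match="at least one cluster"):
            seed_coverage_fraction([], [MiRNA("m", "UGGACCCU")])


class TestCompareTargetSets:
    def test_identical_sets(self):
        out = compare_target_sets({"a", "b"}, {"a", "b"})
        assert (out["intersection"], out["a_only"], out["b_only"]) == (2, 0, 0)
        assert out["fraction_of_a"] == 1.0

    def test_partial_overlap(self):
        out = compare_target_sets({"a", "b", "c"}, {"b", "c", "d", "e"})
        assert (out["intersection"], out["a_only"], out["b_only"]) == (2, 1, 2)
        assert out["fraction_of_a"] == pytest.approx(2 / 3)
        assert out["fraction_of_b"] == pytest.approx(0.5)

    def test_validated_target_style_fixture(self):
        # synthetic stand-in shaped like a validated-target comparison:
        # 42 curated genes of which 21 are CLIP-detected
        validated = {f"gene{i:03d}" for i in range(42)}
        clip = {f"gene{i:03d}" for i in range(21)} | {f"other{i}" for i in range(100)}
        out = compare_target_sets(clip, validated)
        assert out["intersection"] == 21
        assert out["fraction_of_b"] == pytest.approx(0.5)


def test_cluster_sequence_strand_aware(tmp_path):
    fa = tmp_path / "g.fa"
    _write_fasta(fa, [("chr1", "AACCGGTT")])
    genome = Fasta(str(fa))
    assert cluster_sequence(genome, "chr1", 0, 4, "+") == "AACC"
    assert cluster_sequence(genome, "chr1", 0, 4, "-") == "GGTT"
    with pytest.raises(ValueError, match="absent"):
        cluster_sequence(genome, "chrX", 0, 4, "+")


def test_target_genes_region_and_stage_filters():
    inter = pd.DataFrame(
        [
            {"mirna": "m1", "gene_id": "g1", "cluster_id": "c1", "region": "3UTR",
             "site_type": "8mer", "stage": "adult", "offset": 0},
            {"mirna": "m1", "gene_id": "g2", "cluster_id": "c2", "region": "CDS",
             "site_type": "6mer", "stage": "adult", "offset": 0},
            {"mirna": "m2", "gene_id": "g3", "cluster_id": "c3", "region": "3UTR",
             "site_type": "6mer", "stage": "e12.5", "offset": 0},
        ]
    )
    assert target_genes(inter, "m1") == {"g1", "g2"}
    assert target_genes(inter, "m1", regions=["3UTR"]) == {"g1"}
    assert target_genes(inter, "m2", stages=["adult"]) == set()
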