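"""Generator contracts: determinism, planted-truth completeness, rate models."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from agoclip.synthetic import (
    SynthConfig,
    generate_reference,
    simulate_clip_tags,
    simulate_h3k27ac,
    simulate_ko_expression,
)
from agoclip.targetome import read_mirna_fasta, seed_match_strings
from tests.conftest import SMALL_CONFIG

TINY = SynthConfig(
    rng_seed=0, n_chroms=1, chrom_length=30_000, n_genes=2, n_mirnas=1,
    targets_per_mirna=1, ko_targets=1, background_rate=0.0,
)


def overlaps(site, start, end):
    return site.start < end and start < site.end


class TestGenerateReference:
    def test_zero_genes_gives_gtf_without_coding_records(self, tmp_path):
        config = dataclasses.replace(TINY, n_genes=0)
        ref = generate_reference(config, tmp_path)
        text = ref.gtf.read_text()
        assert "\tCDS\t" not in text
        assert ref.genes == []
        assert ref.planted_sites == []

    def test_determinism_byte_identical(self, tmp_path):
        a = generate_reference(SMALL_CONFIG, tmp_path / "a")
        b = generate_reference(SMALL_CONFIG, tmp_path / "b")
        assert a.genome_fasta.read_bytes() == b.genome_fasta.read_bytes()
        assert a.gtf.read_bytes() == b.gtf.read_bytes()
        assert a.mirna_fasta.read_bytes() == b.mirna_fasta.read_bytes()
        assert a.tss_tsv.read_bytes() == b.tss_tsv.read_bytes()

    def test_catalog_counts_and_lengths(self, tmp_path):
        config = dataclasses.replace(TINY, n_mirnas=10, chrom_length=60_000)
        ref = generate_reference(config, tmp_path)
        catalog = read_mirna_fasta(ref.mirna_fasta)
        assert len(catalog) == 10
        assert all(20 <= len(m.sequence) <= 24 for m in catalog)
        assert all(set(m.sequence) <= set("ACGU") for m in catalog)

    def test_sizing_error_names_constraint(self, tmp_path):
        config = dataclasses.replace(TINY, chrom_length=5_000)
        with pytest.raises(ValueError, match="too small"):
            generate_reference(config, tmp_path)

    def test_gene_blocks_disjoint_and_ordered(self, small_reference):
        for g in small_reference.genes:
            blocks = sorted([g.utr5, g.cds1, g.cds2, g.utr3, g.intron])
            for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
                assert e1 <= s2  # pairwise disjoint
            if g.strand == "+":
                assert g.utr5[0] < g.cds1[0] < g.cds2[0] < g.utr3[0]
            else:
                assert g.utr3[0] < g.cds2[0] < g.cds1[0] < g.utr5[0]

    def test_planted_site_sequence_matches_site_type(self, small_reference):
        genome = Fasta(str(small_reference.genome_fasta))
        strings = {
            m.name: seed_match_strings(m) for m in small_reference.catalog
        }
        comp = str.maketrans("ACGT", "TGCA")
        for site in small_reference.planted_sites:
            raw = str(genome[site.chrom][site.start:site.end]).upper()
            sense = raw.translate(comp)[::-1] if site.strand == "-" else raw
            assert sense == strings[site.mirna][site.site_type]


class TestSimulateClipTags:
    def test_no_background_all_tags_overlap_planted_sites(self, tmp_path):
        config = dataclasses.replace(SMALL_CONFIG, background_rate=0.0)
        ref = generate_reference(config, tmp_path / "ref")
        paths, _ = simulate_clip_tags(ref, tmp_path / "tags")
        for (stage, _), path in paths.items():
            for line in path.read_text().splitlines():
                chrom, start, end, *_ = line.split("\t")
                hit = [
                    s for s in ref.planted_sites
                    if s.chrom == chrom and overlaps(s, int(start), int(end))
                ]
                assert hit, f"background-free tag {line} overlaps no planted site"
                assert any(stage in s.active_stages for s in hit)

    def test_stage_gating(self, tmp_path):
        # with zero background, stages where a site is inactive get no tags
        config = dataclasses.replace(TINY, site_rate=50.0)
        ref = generate_reference(config, tmp_path / "ref")
        paths, _ = simulate_clip_tags(ref, tmp_path / "tags")
        (site,) = ref.planted_sites
        active = site.active_stages[0]
        for (stage, rep), path in paths.items():
            n = len(path.read_text().splitlines())
            if stage == active:
                assert n > 0
            else:
                assert n == 0

    def test_truth_table_complete_and_consistent(self, small_reference, small_tags):
        _, truth_path = small_tags
        truth = pd.read_csv(truth_path, sep="\t")
        assert len(truth) == len(small_reference.planted_sites)
        assert not truth.duplicated(["chrom", "start", "end", "mirna"]).any()
        gene_ids = {g.gene_id for g in small_reference.genes}
        mirnas = {m.name for m in small_reference.catalog}
        assert set(truth["gene_id"]) <= gene_ids
        assert set(truth["mirna"]) <= mirnas
        stages = set(small_reference.stage_labels)
        assert set(truth["active_stages"]) <= stages

    def test_site_tag_count_matches_poisson_mean(self, tmp_path):
        """Monte-Carlo: pooled per-stage tag count at one planted site has
        mean site_rate (within 3 standard errors over 1000 simulations)."""
        counts = []
        for seed in range(1000):
            config = dataclasses.replace(TINY, rng_seed=seed)
            ref = generate_reference(config, tmp_path / "r")
            paths, _ = simulate_clip_tags(ref, tmp_path / "t")
            (site,) = ref.planted_sites
            stage = site.active_stages[0]
            n = 0
            for rep in range(1, config.n_replicates + 1):
                for line in paths[(stage, rep)].read_text().splitlines():
                    _, start, end, *_ = line.split("\t")
                    if overlaps(site, int(start), int(end)):
                        n += 1
            counts.append(n)
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - TINY.site_rate) <= 3 * se

    def test_determinism(self, tmp_path):
        ref = generate_reference(SMALL_CONFIG, tmp_path / "ref")
        p1, _ = simulate_clip_tags(ref, tmp_path / "a")
        p2, _ = simulate_clip_tags(ref, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()


class TestSimulateKoExpression:
    def test_noise_free_limit(self, tmp_path):
        config = dataclasses.replace(SMALL_CONFIG, ko_sigma=1e-9, ko_shift=1.0)
        ref = generate_reference(config, tmp_path / "ref")
        path, ko = simulate_ko_expression(ref, tmp_path / "ko", regions=("3UTR", "CDS", "5UTR"))
        expr = pd.read_csv(path, sep="\t")
        targets = {s.gene_id for s in ref.planted_sites if s.mirna == ko}
        for rec in expr.itertuples(index=False):
            expected = 1.0 if rec.gene_id in targets else 0.0
            assert rec.log2fc == pytest.approx(expected, abs=1e-6)

    def test_null_shift_indistinguishable(self, tmp_path):
        """With ko_shift=0 targets and non-targets come from one distribution:
        the two-sided KS test rejects at its nominal rate, not more."""
        from scipy import stats

        rejections = 0
        for seed in range(20):
            config = dataclasses.replace(
                SMALL_CONFIG, ko_shift=0.0, n_genes=150, n_chroms=2,
                chrom_length=300_000, ko_targets=50, rng_seed=seed,
            )
            ref = generate_reference(config, tmp_path / "ref")
            path, ko = simulate_ko_expression(
                ref, tmp_path / "ko", regions=("3UTR", "CDS", "5UTR")
            )
            expr = pd.read_csv(path, sep="\t")
            targets = {s.gene_id for s in ref.planted_sites if s.mirna == ko}
            t = expr[expr["gene_id"].isin(targets)]["log2fc"]
            b = expr[~expr["gene_id"].isin(targets)]["log2fc"]
            if stats.ks_2samp(t, b).pvalue < 0.05:
                rejections += 1
        assert rejections <= 4  # 20 trials at alpha=0.05: P(>4) ~ 0.3%

    def test_target_mean_matches_planted_shift(self, tmp_path):
        config = dataclasses.replace(
            SMALL_CONFIG, ko_shift=0.5, ko_sigma=0.5, n_genes=150, n_chroms=2,
            chrom_length=300_000, ko_targets=150, rng_seed=3,
        )
        ref = generate_reference(config, tmp_path / "ref")
        values = []
        for seed in range(4):  # 4 x ~150 targets > 500 draws
            ref2 = generate_reference(
                dataclasses.replace(config, rng_seed=seed), tmp_path / "r2"
            )
            path, ko = simulate_ko_expression(
                ref2, tmp_path / "ko", regions=("3UTR", "CDS", "5UTR")
            )
            expr = pd.read_csv(path, sep="\t")
            targets = {s.gene_id for s in ref2.planted_sites if s.mirna == ko}
            values.extend(expr[expr["gene_id"].isin(targets)]["log2fc"])
        mean = np.mean(values)
        se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(mean - 0.5) <= 3 * se

    def test_unknown_mirna_rejected(self, small_reference, tmp_path):
        with pytest.raises(ValueError, match="unknown miRNA"):
            simulate_ko_expression(small_reference, tmp_path, ko_mirna="mir-ghost")

    def test_every_gene_appears_exactly_once(self, small_reference, tmp_path):
        path, _ = simulate_ko_expression(small_reference, tmp_path)
        expr = pd.read_csv(path, sep="\t")
        assert sorted(expr["gene_id"]) == sorted(g.gene_id for g in small_reference.genes)
        assert not expr["gene_id"].duplicated().any()


class TestSimulateH3k27ac:
    def test_single_planted_se_truth(self, tmp_path):
        # one 200 kb chromosome holds 8 region anchors; 8 * 0.13 rounds to 1
        config = dataclasses.replace(SMALL_CONFIG, se_fraction=0.13)
        ref = generate_reference(config, tmp_path / "ref")
        _, truth_path = simulate_h3k27ac(ref, tmp_path / "h3k")
        truth = pd.read_csv(truth_path, sep="\t")
        assert int(truth["is_se"].sum()) == 1

    def test_zero_se_fraction_plants_none(self, tmp_path):
        config = dataclasses.replace(SMALL_CONFIG, se_fraction=0.0)
        ref = generate_reference(config, tmp_path / "ref")
        _, truth_path = simulate_h3k27ac(ref, tmp_path / "h3k")
        truth = pd.read_csv(truth_path, sep="\t")
        assert int(truth["is_se"].sum()) == 0

    def test_invalid_se_fraction_rejected(self):
        with pytest.raises(ValueError, match="se_fraction"):
            dataclasses.replace(SMALL_CONFIG, se_fraction=1.0)
        with pytest.raises(ValueError, match="se_fraction"):
            dataclasses.replace(SMALL_CONFIG, se_fraction=-0.1)

    def test_planted_se_within_window_of_named_mirna_tss(self, tmp_path):
        ref = generate_reference(SMALL_CONFIG, tmp_path / "ref")
        _, truth_path = simulate_h3k27ac(ref, tmp_path / "h3k")
        truth = pd.read_csv(truth_path, sep="\t")
        ses = truth[truth["is_se"]]
        assert len(ses) > 0
        for rec in ses.itertuples(index=False):
            chrom, tss, _ = ref.mirna_tss[rec.mirna]
            assert chrom == rec.chrom
            assert min(abs(rec.start - tss), abs(rec.end - tss)) <= 100_000

    def test_high_component_separated_from_low(self, tmp_path):
        ref = generate_reference(SMALL_CONFIG, tmp_path / "ref")
        paths, truth_path = simulate_h3k27ac(ref, tmp_path / "h3k")
        truth = pd.read_csv(truth_path, sep="\t")
        ses = truth[truth["is_se"]]
        for rec in ses.itertuples(index=False):
            peaks = pd.read_csv(
                paths[rec.active_stage], sep="\t", header=None,
                names=["chrom", "start", "end", "name", "score", "strand"],
            )
            inside = peaks[
                (peaks["chrom"] == rec.chrom)
                & (peaks["start"] >= rec.start)
                & (peaks["end"] <= rec.end)
            ]
            outside = peaks.drop(inside.index)
            assert inside["score"].mean() > 5 * outside["score"].mean()


def test_planted_signal_separation_over_seeds(tmp_path):
    """Site tag coverage exceeds the 99th percentile of background coverage at
    >=95% of planted sites, across 20 seeds."""
    total, clear = 0, 0
    for seed in range(20):
        config = dataclasses.replace(SMALL_CONFIG, rng_seed=seed)
        ref = generate_reference(config, tmp_path / "ref")
        paths, _ = simulate_clip_tags(ref, tmp_path / "tags")
        site_intervals = [(s.chrom, s.start, s.end) for s in ref.planted_sites]
        for stage in config.stages:
            tags = []
            for rep in range(1, config.n_replicates + 1):
                for line in paths[(stage, rep)].read_text().splitlines():
                    chrom, start, end, *_ = line.split("\t")
                    tags.append((chrom, int(start), int(end)))
            depth = {
                c: np.zeros(config.chrom_length, dtype=np.int32)
                for c in ref.genome
            }
            for chrom, start, end in tags:
                depth[chrom][start:end] += 1
            site_mask = {c: np.zeros(config.chrom_length, dtype=bool) for c in ref.genome}
            for chrom, start, end in site_intervals:
                site_mask[chrom][max(0, start - 50) : end + 50] = True
            background = np.concatenate(
                [depth[c][~site_mask[c]] for c in ref.genome]
            )
            bg99 = np.quantile(background, 0.99)
            for s in ref.planted_sites:
                if stage not in s.active_stages:
                    continue
                total += 1
                mid = (s.start + s.end) // 2
                if depth[s.chrom][mid] > bg99:
                    clear += 1
    assert total > 0
    assert clear / total >= 0.95
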