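"""Synthetic-study generators: determinism, planted truth, distributional sanity."""

import numpy as np
import pytest
from scipy import stats

from _oracles import brute_force_overlaps
from tpsmap import (
    SimDesign,
    SiteTruth,
    generate_annotation,
    normalized_position,
    plant_truth,
    simulate_library,
    simulate_ortholog_study,
    simulate_riboseq,
)
from tpsmap.simulate import write_gff3


class TestGenerateAnnotation:
    def test_empty_design(self, tmp_path):
        design = SimDesign(n_genes=0, seed=1)
        genes = generate_annotation(design)
        assert genes == []
        write_gff3(genes, tmp_path / "empty.gff3", {"chr": design.replicon_length})
        from tpsmap import load_annotation

        assert load_annotation(tmp_path / "empty.gff3") == []

    def test_byte_identical_given_seed(self, tmp_path):
        design = SimDesign(n_genes=50, replicon_length=100_000, seed=7)
        for name in ("a.gff3", "b.gff3"):
            write_gff3(generate_annotation(design), tmp_path / name, {"chr": 100_000})
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_no_overlaps_brute_force(self):
        genes = generate_annotation(SimDesign(n_genes=50, replicon_length=100_000, seed=7))
        assert len(genes) == 50
        for strand in "+-":
            intervals = [(g.start, g.end) for g in genes if g.strand == strand]
            assert brute_force_overlaps(intervals) == []

    def test_within_replicon_bounds(self):
        design = SimDesign(n_genes=50, replicon_length=100_000, seed=7)
        for g in generate_annotation(design):
            assert 1 <= g.start <= g.end <= design.replicon_length

    def test_too_short_replicon_raises(self):
        with pytest.raises(ValueError, match="too short"):
            generate_annotation(SimDesign(n_genes=100, replicon_length=5_000, seed=1))

    def test_gff3_roundtrip(self, tmp_path):
        from tpsmap import load_annotation

        design = SimDesign(n_genes=20, seed=3)
        genes = generate_annotation(design)
        write_gff3(genes, tmp_path / "x.gff3", {"chr": design.replicon_length})
        back = load_annotation(tmp_path / "x.gff3")
        assert [(g.locus_tag, g.start, g.end, g.strand) for g in back] == [
            (g.locus_tag, g.start, g.end, g.strand) for g in genes
        ]


class TestPlantTruth:
    GENES = generate_annotation(SimDesign(n_genes=50, replicon_length=100_000, seed=7))

    def test_tss_only(self):
        truth = plant_truth(self.GENES, tps_per_gene=0, tss_per_gene=1, seed=1)
        assert truth.of_kind("TPS") == []
        assert len(truth.of_kind("TSS")) == 50

    def test_exact_tps_count(self):
        truth = plant_truth(self.GENES, tps_per_gene=1, tss_per_gene=0, seed=1)
        assert len(truth.of_kind("TPS")) == 50

    def test_spacing_invariant_pairwise(self):
        truth = plant_truth(self.GENES, tps_per_gene=3, tss_per_gene=1, seed=2)
        by_key: dict[tuple, list[int]] = {}
        for s in truth.sites:
            by_key.setdefault((s.replicon, s.strand, s.kind), []).append(s.position)
        for positions in by_key.values():
            for i in range(len(positions)):
                for j in range(i + 1, len(positions)):
                    assert abs(positions[i] - positions[j]) >= 6

    def test_tps_inside_gene(self):
        truth = plant_truth(self.GENES, tps_per_gene=1, tss_per_gene=0, seed=3)
        gene_by_tag = {g.locus_tag: g for g in self.GENES}
        for s in truth.of_kind("TPS"):
            g = gene_by_tag[s.locus_tag]
            assert g.start <= s.position <= g.end
            assert s.strand == g.strand

    def test_multiplicity_distribution(self):
        truth = plant_truth(
            self.GENES, tps_per_gene={1: 0.59, 2: 0.32, 3: 0.09}, tss_per_gene=0, seed=4
        )
        per_gene: dict[str, int] = {}
        for s in truth.of_kind("TPS"):
            per_gene[s.locus_tag] = per_gene.get(s.locus_tag, 0) + 1
        assert set(per_gene.values()) <= {1, 2, 3}
        assert len(per_gene) == 50

    def test_deterministic(self):
        a = plant_truth(self.GENES, seed=5)
        b = plant_truth(self.GENES, seed=5)
        assert a.to_frame().equals(b.to_frame())


class TestSimulateLibrary:
    def test_all_zero_without_background_or_sites(self):
        design = SimDesign(n_genes=0, replicon_length=1000, lambda_bg=0.0, seed=1)
        track = simulate_library(SiteTruth([], 1), design, "TEX_MINUS")
        assert track.total() == 0

    def test_background_mean_in_band(self):
        design = SimDesign(n_genes=0, replicon_length=100_000, lambda_bg=2.0, seed=8)
        track = simulate_library(SiteTruth([], 8), design, "TEX_MINUS", seed=8)
        mean_plus_strand = track.total() / 2 / design.replicon_length
        # 3-sigma band around lambda = 2 for n = 1e5 positions per strand
        assert 1.95 <= mean_plus_strand <= 2.05

    def test_site_means_match_expectation_over_replicates(self):
        from tpsmap.simulate import SiteRecord

        design = SimDesign(n_genes=0, replicon_length=2000, lambda_bg=2.0,
                           tex_plus_leak=0.02, seed=13)
        truth = SiteTruth([SiteRecord("chr", 1000, "+", "TPS", 50.0)], 13)
        minus_counts, plus_counts = [], []
        for rep in range(1, 201):
            minus = simulate_library(truth, design, "TEX_MINUS", replicate=rep, seed=13)
            plus = simulate_library(truth, design, "TEX_PLUS", replicate=rep, seed=13)
            minus_counts.append(minus.get("chr", "+", 1000))
            plus_counts.append(plus.get("chr", "+", 1000))
        # Monte-Carlo means vs analytic expectations, 3-sigma bands (n = 200)
        m, p = np.mean(minus_counts), np.mean(plus_counts)
        assert abs(m - 52.0) <= 3 * np.sqrt(52.0 / 200)
        assert abs(p - 3.0) <= 3 * np.sqrt(3.0 / 200)

    def test_deterministic_per_treatment_and_replicate(self):
        design = SimDesign(n_genes=0, replicon_length=5000, lambda_bg=1.0, seed=2)
        t1 = simulate_library(SiteTruth([], 2), design, "TEX_MINUS", replicate=1)
        t2 = simulate_library(SiteTruth([], 2), design, "TEX_MINUS", replicate=1)
        t3 = simulate_library(SiteTruth([], 2), design, "TEX_MINUS", replicate=2)
        assert t1.counts == t2.counts
        assert t1.counts != t3.counts

    def test_unknown_treatment_rejected(self):
        design = SimDesign(n_genes=0, replicon_length=100, seed=1)
        with pytest.raises(ValueError, match="treatment"):
            simulate_library(SiteTruth([], 1), design, "TEX")

    def test_null_counts_fit_poisson(self):
        """With no sites, per-position counts pass a chi-square GOF vs Poisson."""
        design = SimDesign(n_genes=0, replicon_length=100_000, lambda_bg=2.0, seed=42)
        track = simulate_library(SiteTruth([], 42), design, "TEX_MINUS", seed=42)
        dense = np.zeros(design.replicon_length)
        sparse = track.counts["chr"]["+"]
        dense[np.array(list(sparse)) - 1] = list(sparse.values())
        kmax = 10
        observed = np.bincount(dense.astype(int), minlength=kmax + 2)
        obs = np.append(observed[:kmax], observed[kmax:].sum())
        expected = stats.poisson.pmf(np.arange(kmax), 2.0) * design.replicon_length
        expected = np.append(expected, design.replicon_length - expected.sum())
        chi2, p = stats.chisquare(obs, expected)
        assert p > 0.01


class TestOrthologStudy:
    DESIGN_A = SimDesign(n_genes=60, replicon_length=120_000, replicon_id="chrA",
                         locus_prefix="HSA", seed=31)
    DESIGN_B = SimDesign(n_genes=60, replicon_length=120_000, replicon_id="chrB",
                         locus_prefix="HVO", seed=32)

    def test_fully_conserved_zero_jitter_equal_lengths(self):
        # with a constant gene length the integer rounding is identical in
        # both species, so zero jitter gives exactly equal D
        da = SimDesign(n_genes=20, replicon_length=30_000, replicon_id="chrA",
                       gene_length_range=(600, 600), locus_prefix="A", seed=1)
        db = SimDesign(n_genes=20, replicon_length=30_000, replicon_id="chrB",
                       gene_length_range=(600, 600), locus_prefix="B", seed=2)
        study = simulate_ortholog_study(da, db, n_pairs=20, conserved_fraction=1.0,
                                        jitter=0.0, seed=3)
        assert len(study.conserved) == 20
        for c in study.conserved:
            assert c.d_a == c.d_b

    def test_exact_conserved_count(self):
        study = simulate_ortholog_study(self.DESIGN_A, self.DESIGN_B, n_pairs=60,
                                        conserved_fraction=0.5, jitter=1.0, seed=3)
        assert len(study.conserved) == 30

    def test_conserved_truth_satisfies_criterion_rederived(self):
        study = simulate_ortholog_study(self.DESIGN_A, self.DESIGN_B, n_pairs=60,
                                        conserved_fraction=0.5, jitter=1.0, seed=3)
        genes_a = {g.locus_tag: g for g in study.genes_a}
        genes_b = {g.locus_tag: g for g in study.genes_b}
        for c in study.conserved:
            d_a = normalized_position(genes_a[c.pair.locus_a], c.position_a)
            d_b = normalized_position(genes_b[c.pair.locus_b], c.position_b)
            assert abs(d_a - d_b) < 3

    def test_non_conserved_pairs_separated(self):
        study = simulate_ortholog_study(self.DESIGN_A, self.DESIGN_B, n_pairs=60,
                                        conserved_fraction=0.5, jitter=1.0, seed=3)
        conserved_keys = {(c.pair.locus_a, c.pair.locus_b) for c in study.conserved}
        sites_a = {s.locus_tag: s for s in study.truth_a.sites if s.strand}
        sites_b = {s.locus_tag: s for s in study.truth_b.sites}
        genes_a = {g.locus_tag: g for g in study.genes_a}
        genes_b = {g.locus_tag: g for g in study.genes_b}
        for pair in study.pairs:
            if (pair.locus_a, pair.locus_b) in conserved_keys:
                continue
            d_a = normalized_position(genes_a[pair.locus_a], sites_a[pair.locus_a].position)
            d_b = normalized_position(genes_b[pair.locus_b], sites_b[pair.locus_b].position)
            assert abs(d_a - d_b) >= 3

    def test_jitter_at_threshold_refused(self):
        with pytest.raises(ValueError, match="jitter"):
            simulate_ortholog_study(self.DESIGN_A, self.DESIGN_B, n_pairs=10,
                                    conserved_fraction=0.5, jitter=3.0, seed=1)


class TestSimulateRiboseq:
    DESIGN = SimDesign(n_genes=10, replicon_length=20_000, seed=17)

    def _fixture(self, peak_fraction):
        genes = generate_annotation(self.DESIGN)
        truth = plant_truth(genes, tps_per_gene=1, tss_per_gene=0, seed=17)
        cov, peaked = simulate_riboseq(genes, truth, peak_fraction,
                                       peak_height=50.0, base=10.0, seed=17)
        return genes, truth, cov, peaked

    def test_zero_fraction_flat_in_cds(self):
        genes, _, cov, peaked = self._fixture(0.0)
        assert peaked == []
        for g in genes:
            values = {cov.get(g.replicon, ".", p) for p in range(g.start, g.end + 1)}
            assert values == {10.0}

    def test_summit_exact_and_everywhere(self):
        _, truth, cov, peaked = self._fixture(1.0)
        positions = sorted(s.position for s in truth.of_kind("TPS"))
        assert peaked == positions
        for pos in positions:
            assert cov.get("chr", ".", pos) == 60.0  # base + peak_height, exact
            assert cov.get("chr", ".", pos) > cov.get("chr", ".", pos - 1)
            assert cov.get("chr", ".", pos) > cov.get("chr", ".", pos + 1)

    def test_invalid_fraction(self):
        genes = generate_annotation(self.DESIGN)
        truth = plant_truth(genes, seed=17)
        with pytest.raises(ValueError):
            simulate_riboseq(genes, truth, 1.5)
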