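import numpy as np
import pandas as pd
import pytest

from trapscan import (
    SyntheticConfig,
    VectorSpec,
    annotate_frame,
    decile_counts,
    decile_pmf,
    filter_tags,
    g_test_uniform,
    generate_annotation,
    generate_library,
    generate_tags,
    is_spliced,
    read_gtf,
)
from trapscan.simulate import ConfigError, NoiseSpec


class TestDecilePmf:
    def test_uniform_mass(self):
        assert decile_pmf("uniform").tolist() == pytest.approx([0.1] * 10)

    def test_five_prime_monotone_decreasing(self):
        pmf = decile_pmf("five_prime_geometric", rho=0.5)
        assert pmf.sum() == pytest.approx(1.0)
        assert (np.diff(pmf) < 0).all()
        # truncated geometric: mass halves per decile at rho = 0.5
        assert pmf[1] / pmf[0] == pytest.approx(0.5)

    def test_three_prime_is_mirror(self):
        five = decile_pmf("five_prime_geometric", rho=0.3)
        three = decile_pmf("three_prime_geometric", rho=0.3)
        assert three.tolist() == pytest.approx(five[::-1].tolist())


class TestGenerateAnnotation:
    def test_requested_counts_and_round_trip(self, tmp_path):
        cfg = SyntheticConfig(
            seed=1,
            genes_per_biotype={"protein_coding": 5, "lincRNA": 3},
            n_integrations_per_vector=0,
        )
        ann = generate_annotation(cfg)
        assert len(ann) == 8
        from trapscan import write_gtf

        write_gtf(ann, tmp_path / "a.gtf")
        assert len(read_gtf(tmp_path / "a.gtf")) == 8

    def test_single_exon_probability_one_forces_unspliced(self):
        cfg = SyntheticConfig(
            seed=2,
            genes_per_biotype={"lincRNA": 20},
            single_exon_probability={"lincRNA": 1.0},
            n_integrations_per_vector=0,
        )
        ann = generate_annotation(cfg)
        assert all(not is_spliced(g) for g in ann)

    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=9, n_integrations_per_vector=50)
        p1 = generate_library(cfg, tmp_path / "r1")
        p2 = generate_library(cfg, tmp_path / "r2")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_differs(self, tmp_path):
        a = generate_library(SyntheticConfig(seed=1, n_integrations_per_vector=50), tmp_path / "a")
        b = generate_library(SyntheticConfig(seed=2, n_integrations_per_vector=50), tmp_path / "b")
        assert a["tags"].read_bytes() != b["tags"].read_bytes()

    def test_capacity_error(self):
        cfg = SyntheticConfig(
            seed=0,
            genes_per_biotype={"protein_coding": 2000},
            chromosome_length=100_000,
            max_chromosomes=2,
            n_integrations_per_vector=0,
        )
        with pytest.raises(ConfigError, match="capacity"):
            generate_annotation(cfg)

    def test_planted_overlap_cases_present(self):
        ann = generate_annotation(SyntheticConfig(seed=4))
        by_biotype: dict[str, list] = {}
        for g in ann:
            by_biotype.setdefault(g.raw_biotype, []).append(g)
        # at least one antisense gene overlaps a PCG on the opposite strand
        def overlaps_pcg(g, same_strand):
            for h in by_biotype["protein_coding"]:
                if h.chrom == g.chrom and g.start < h.end and h.start < g.end:
                    if (h.strand == g.strand) == same_strand:
                        return True
            return False

        assert any(overlaps_pcg(g, False) for g in by_biotype["antisense"])
        assert any(overlaps_pcg(g, True) for g in by_biotype["sense_intronic"])
        assert any(overlaps_pcg(g, True) for g in by_biotype["sense_overlapping"])


class TestGenerateTags:
    def test_no_noise_no_intergenic_all_retained(self):
        cfg = SyntheticConfig(
            seed=3,
            n_integrations_per_vector=200,
            noise=NoiseSpec(0.0, 0.0, 0.0, 0.0),
            intergenic_fraction=0.0,
        )
        ann = generate_annotation(cfg)
        tags, truth = generate_tags(ann, cfg)
        integrations, report = filter_tags(tags)
        assert report.n_retained == 200 * len(cfg.vectors)
        assert report.n_input == report.n_retained  # no discards possible
        assert len(truth.events) == report.n_retained

    def test_intergenic_fraction_recovered(self):
        cfg = SyntheticConfig(seed=6, n_integrations_per_vector=4000)
        ann = generate_annotation(cfg)
        tags, truth = generate_tags(ann, cfg)
        frac = (truth.events["gene_id"] == "").mean()
        n = len(truth.events)
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(frac - 0.40) < 4 * se

    def test_five_prime_decile_mass_matches_analytic(self):
        cfg = SyntheticConfig(
            seed=8,
            vectors=[
                VectorSpec("V", "promoter_trap_SA",
                           positional_model="five_prime_geometric", rho=0.5)
            ],
            n_integrations_per_vector=10_000,
            intergenic_fraction=0.0,
            noise=NoiseSpec(0.0, 0.0, 0.0, 0.0),
        )
        ann = generate_annotation(cfg)
        tags, truth = generate_tags(ann, cfg)
        integrations, _ = filter_tags(tags)
        hits = annotate_frame(integrations, ann)
        counts = sum(
            decile_counts(hits, "promoter_trap_SA", cls)
            for cls in ("protein_coding", "lncRNA", "sncRNA", "pseudogene")
        )
        n = counts.sum()
        pmf = decile_pmf("five_prime_geometric", rho=0.5)
        # per-decile binomial error bound and monotone 5' concentration
        for k in range(10):
            se = np.sqrt(n * pmf[k] * (1 - pmf[k]))
            assert abs(counts[k] - n * pmf[k]) < 5 * se
        assert counts[0] > counts[9]

    def test_uniform_model_type_one_calibration(self):
        """Uniform positional model: decile counts pass the G-test at
        alpha = 0.01 in at least 98 of 100 seeded generator runs."""
        base = dict(
            vectors=[VectorSpec("V", "promoter_trap_SA", positional_model="uniform")],
            n_integrations_per_vector=10_000,
            intergenic_fraction=0.0,
            noise=NoiseSpec(0.0, 0.0, 0.0, 0.0),
        )
        ann = generate_annotation(SyntheticConfig(seed=0, **base))
        arrays_sorted = sorted(ann, key=lambda g: g.gene_id)
        passes = 0
        for seed in range(100):
            cfg = SyntheticConfig(seed=seed, **base)
            tags, truth = generate_tags(ann, cfg)
            deciles = truth.events["decile"].to_numpy()
            counts = np.bincount(deciles, minlength=11)[1:11]
            _, p = g_test_uniform(counts)
            passes += p >= 0.01
        assert passes >= 98

    def test_expression_dependent_vector_needs_expressed_targets(self):
        cfg = SyntheticConfig(
            seed=5,
            expression_fraction={"default": 0.0, "protein_coding": 0.0},
            vectors=[
                VectorSpec("V1", "promoter_trap_SA", expression_dependent=True),
                VectorSpec("V2", "polyA_trap"),
            ],
            n_integrations_per_vector=100,
        )
        ann = generate_annotation(cfg)
        with pytest.raises(ConfigError, match="eligible"):
            generate_tags(ann, cfg)

    def test_expression_dependence_restricts_target_pool(self):
        cfg = SyntheticConfig(
            seed=13,
            expression_fraction={"default": 0.3, "protein_coding": 0.3},
            vectors=[
                VectorSpec("Vdep", "promoter_trap_SA", expression_dependent=True),
                VectorSpec("Vind", "polyA_trap", expression_dependent=False),
            ],
            n_integrations_per_vector=3000,
            intergenic_fraction=0.0,
        )
        ann = generate_annotation(cfg)
        _, truth = generate_tags(ann, cfg)
        ev = truth.events
        dep = set(ev.loc[ev["vector_id"] == "Vdep", "gene_id"])
        ind = set(ev.loc[ev["vector_id"] == "Vind", "gene_id"])
        # the expression-dependent vector reaches only ~30% of genes
        assert len(dep) < 0.6 * len(ind)
        # and the independent vector also covers genes outside that pool
        assert len(ind - dep) > 0

    def test_unknown_multiplier_label_rejected(self):
        cfg = SyntheticConfig(
            seed=1,
            vectors=[
                VectorSpec("V1", "promoter_trap_SA",
                           biotype_multipliers={"no_such_biotype": 2.0}),
                VectorSpec("V2", "polyA_trap"),
            ],
            n_integrations_per_vector=10,
        )
        ann = generate_annotation(cfg)
        with pytest.raises(ConfigError, match="no_such_biotype"):
            generate_tags(ann, cfg)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SyntheticConfig(seed=99, n_integrations_per_vector=25)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SyntheticConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    def test_invalid_config_values_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(intergenic_fraction=1.5)
        with pytest.raises(ConfigError):
            NoiseSpec(p_unmapped=0.7, p_low_quality=0.4)
        with pytest.raises(ConfigError):
            VectorSpec("V", "polyA_trap", positional_model="banana")
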