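import numpy as np
import pandas as pd
import pytest

from trapscan import (
    AnnotationSet,
    GeneHit,
    SyntheticConfig,
    annotate_frame,
    annotate_integration,
    classify_mechanism,
    decile_of,
    filter_tags,
    generate_annotation,
    generate_tags,
    relative_position,
)

from conftest import integration_frame, make_gene


class TestRelativePosition:
    @pytest.mark.parametrize(
        "strand, position, expected_rel, expected_decile",
        [
            ("+", 0, 0.0, 1),      # TSS of plus-strand gene
            ("-", 999, 0.0, 1),    # TSS of minus-strand gene
            ("+", 950, 0.95, 10),
            ("+", 999, 0.999, 10),
            ("-", 0, 0.999, 10),
            ("+", 100, 0.1, 2),
        ],
    )
    def test_examples(self, strand, position, expected_rel, expected_decile):
        gene = make_gene("G", "chr1", 0, 1000, strand, "protein_coding")
        rel = relative_position(gene, position)
        assert rel == pytest.approx(expected_rel)
        assert decile_of(rel) == expected_decile

    def test_position_outside_span_rejected(self):
        gene = make_gene("G", "chr1", 100, 200, "+", "protein_coding")
        for pos in (99, 200):
            with pytest.raises(ValueError):
                relative_position(gene, pos)

    def test_result_always_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            start = int(rng.integers(0, 1000))
            length = int(rng.integers(2, 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = make_gene("G", "chr1", start, start + length, strand, "lincRNA",
                             exons=[(start, start + length)])
            pos = int(rng.integers(start, start + length))
            rel = relative_position(gene, pos)
            assert 0.0 <= rel < 1.0
            assert decile_of(rel) == int(rel * 10) + 1

    def test_mirror_symmetry(self):
        """Reflecting the genome (coordinates and strands) preserves all
        relative positions."""
        L = 100_000
        rng = np.random.default_rng(8)
        for _ in range(100):
            start = int(rng.integers(0, 50_000))
            end = start + int(rng.integers(10, 40_000))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = make_gene("G", "chr1", start, end, strand, "lincRNA",
                             exons=[(start, end)])
            mirrored = make_gene(
                "G", "chr1", L - end, L - start,
                "-" if strand == "+" else "+", "lincRNA",
                exons=[(L - end, L - start)],
            )
            pos = int(rng.integers(start, end))
            assert relative_position(gene, pos) == pytest.approx(
                relative_position(mirrored, L - 1 - pos)
            )


class TestAnnotateIntegration:
    def _one(self, tiny_annotation, chrom, pos, strand="+", vclass="promoter_trap_SA"):
        return annotate_integration(
            {
                "cell_line_id": "CL1",
                "vector_id": "V1",
                "vector_class": vclass,
                "chrom": chrom,
                "position": pos,
                "tag_strand": strand,
            },
            tiny_annotation,
        )

    def test_intergenic_position(self, tiny_annotation):
        res = self._one(tiny_annotation, "chr1", 15000)
        assert res.intergenic and res.hits == []
        assert res.mechanism == "intergenic_activation"

    def test_intron_sense_hit(self, tiny_annotation):
        res = self._one(tiny_annotation, "chr1", 3000, "+")
        assert not res.intergenic
        (hit,) = res.hits
        assert hit.gene_id == "PC1"
        assert hit.region == "intron"
        assert hit.strand_relation == "sense"
        assert res.mechanism == "sense_splice_fusion"

    def test_exon_union_membership(self, tiny_annotation):
        res = self._one(tiny_annotation, "chr1", 5500, "+")
        assert res.hits[0].region == "exon"

    def test_single_exon_lncrna_hit(self, tiny_annotation):
        res = self._one(tiny_annotation, "chr1", 41000, "-")
        (hit,) = res.hits
        assert hit.gene_id == "LN2"
        assert hit.region == "exon"
        assert not hit.host_spliced

    def test_unknown_chromosome_is_intergenic_with_warning(self, tiny_annotation, caplog):
        with caplog.at_level("WARNING"):
            res = self._one(tiny_annotation, "chrUn", 500)
        assert res.intergenic
        assert any("chrUn" in r.message for r in caplog.records)

    def test_overlap_primary_prefers_sense_then_smaller_gene(self, tiny_annotation):
        # position inside both AS1 (-) and PC2 (+); tag on + is sense to PC2
        res = self._one(tiny_annotation, "chr2", 1500, "+")
        assert {h.gene_id for h in res.hits} == {"AS1", "PC2"}
        assert res.primary_hit.gene_id == "PC2"
        # the same position with a - tag is sense to AS1
        res = self._one(tiny_annotation, "chr2", 1500, "-")
        assert res.primary_hit.gene_id == "AS1"

    def test_strandless_tag_defaults_to_sense(self, tiny_annotation):
        res = self._one(tiny_annotation, "chr1", 3000, strand="")
        assert res.hits[0].strand_relation == "sense"

    def test_decile_recomputable_from_relative_position(self, tiny_annotation):
        for pos in (1000, 3500, 6000, 10999):
            res = self._one(tiny_annotation, "chr1", pos)
            h = res.primary_hit
            assert h.decile == int(h.relative_position * 10) + 1


def _hit(**kw):
    base = dict(
        gene_id="G", major_class="lncRNA", lnc_subclass="lincRNA",
        relative_position=0.5, decile=6, region="intron",
        strand_relation="sense", host_spliced=True,
    )
    base.update(kw)
    return GeneHit(**base)


class TestMechanism:
    @pytest.mark.parametrize(
        "hit, vclass, intergenic, expected",
        [
            # spliced lincRNA, sense, SA promoter trap -> splice fusion
            (_hit(), "promoter_trap_SA", False, "sense_splice_fusion"),
            # antisense orientation wins regardless of anything else
            (_hit(lnc_subclass="antisense", strand_relation="antisense"),
             "promoter_trap_SA", False, "antisense_insertion"),
            (_hit(lnc_subclass="bidirectional_promoter", strand_relation="antisense"),
             "polyA_trap", False, "antisense_insertion"),
            # processed transcript, sense, polyA trap -> exon capture
            (_hit(lnc_subclass="processed_transcript"), "polyA_trap", False,
             "polyA_exon_capture"),
            # subclass-specific structural rules beat vector rules
            (_hit(lnc_subclass="bidirectional_promoter"), "promoter_trap_SA", False,
             "bidirectional_promoter_capture"),
            (_hit(lnc_subclass="sense_overlapping"), "polyA_trap", False,
             "host_readthrough_truncation"),
            # unspliced host with an SA vector cannot splice-fuse
            (_hit(host_spliced=False), "promoter_trap_SA", False,
             "unspliced_insertion"),
            (_hit(host_spliced=False), "exon_trap", False, "unspliced_insertion"),
            # every SA-bearing class fuses on spliced hosts
            (_hit(), "exon_trap", False, "sense_splice_fusion"),
            (_hit(), "combined", False, "sense_splice_fusion"),
            (_hit(), "secretory_trap", False, "sense_splice_fusion"),
            (None, None, True, "intergenic_activation"),
        ],
    )
    def test_rule_table(self, hit, vclass, intergenic, expected):
        assert classify_mechanism(hit, vclass, intergenic) == expected

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_mechanism(_hit(), "polyA_trap", True)
        with pytest.raises(ValueError):
            classify_mechanism(None, "polyA_trap", False)


class TestAnnotateFrame:
    def test_counts_sum_and_decile_consistency(self, small_config):
        ann = generate_annotation(small_config)
        tags, truth = generate_tags(ann, small_config)
        integrations, _ = filter_tags(tags)
        hits = annotate_frame(integrations, ann)
        n_genic = int(hits["is_primary"].sum())
        n_inter = int(hits["intergenic"].sum())
        assert n_genic + n_inter == len(integrations)
        genic = hits[hits["is_primary"]]
        assert (
            genic["decile"]
            == (genic["relative_position"] * 10).astype(int) + 1
        ).all()

    def test_ground_truth_decile_matches_pipeline(self, small_config):
        ann = generate_annotation(small_config)
        tags, truth = generate_tags(ann, small_config)
        integrations, _ = filter_tags(tags)
        hits = annotate_frame(integrations, ann)
        prim = hits[hits["is_primary"]].set_index("cell_line_id")
        genic_truth = truth.events[truth.events["gene_id"] != ""].set_index("cell_line_id")
        joined = genic_truth.join(prim[["gene_id", "decile"]], rsuffix="_pipe", how="inner")
        same_gene = joined["gene_id"] == joined["gene_id_pipe"]
        # overlap-planted cases may resolve to the overlapping partner
        assert same_gene.mean() > 0.99
        assert (joined.loc[same_gene, "decile"] == joined.loc[same_gene, "decile_pipe"]).all()

    def test_index_hits_equal_all_pairs_scan(self):
        cfg = SyntheticConfig(seed=17, n_integrations_per_vector=1000)
        ann = generate_annotation(cfg)
        tags, _ = generate_tags(ann, cfg)
        integrations, _ = filter_tags(tags)
        hits = annotate_frame(integrations, ann)
        genes = list(ann)
        starts = np.array([g.start for g in genes])
        ends = np.array([g.end for g in genes])
        chroms = np.array([g.chrom for g in genes])
        ids = np.array([g.gene_id for g in genes])
        by_cell = hits[~hits["intergenic"]].groupby("cell_line_id")["gene_id"].apply(set)
        for rec in integrations.itertuples(index=False):
            mask = (chroms == rec.chrom) & (starts <= rec.position) & (rec.position < ends)
            expected = set(ids[mask])
            got = by_cell.get(rec.cell_line_id, set())
            assert got == expected
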