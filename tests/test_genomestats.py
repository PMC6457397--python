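import numpy as np
import pytest

from caenophylo.genomestats import (
    AnnotationSet,
    Exon,
    Gene,
    Transcript,
    assembly_metrics,
    gene_structure_stats,
    intergenic_distances,
    longest_isoform,
    ortholog_log2_ratios,
    read_gff3,
    write_gff3,
)
from caenophylo.synth import SimulationConfig, sim_annotation_and_assembly


def gene(gene_id, scaffold, *exon_coords, n_transcripts=1):
    exons = tuple(Exon(a, b) for a, b in exon_coords)
    ts = [Transcript(f"{gene_id}.t{i+1}", exons) for i in range(n_transcripts)]
    return Gene(gene_id, scaffold, tuple(ts))


class TestLongestIsoform:
    def test_picks_larger_exon_sum(self):
        g = Gene(
            "g1",
            "s1",
            (
                Transcript("g1.t1", (Exon(1, 900),)),
                Transcript("g1.t2", (Exon(1, 600), Exon(701, 1300))),
            ),
        )
        ann = AnnotationSet(genes=(g,))
        assert longest_isoform(ann) == {"g1": "g1.t2"}  # 900 vs 1200

    def test_single_isoform(self):
        ann = AnnotationSet(genes=(gene("g1", "s1", (1, 100)),))
        assert longest_isoform(ann) == {"g1": "g1.t1"}

    def test_tie_broken_by_id(self):
        g = Gene(
            "g1",
            "s1",
            (
                Transcript("g1.t2", (Exon(1, 900),)),
                Transcript("g1.t1", (Exon(101, 1000),)),
            ),
        )
        ann = AnnotationSet(genes=(g,))
        assert longest_isoform(ann) == {"g1": "g1.t1"}


class TestGeneStructure:
    def test_two_exon_gene(self):
        ann = AnnotationSet(genes=(gene("g1", "s1", (1, 100), (201, 300)),))
        stats = gene_structure_stats(ann)
        row = stats.per_gene.iloc[0]
        assert row.intron_count == 1
        assert row.intron_span == 100  # 201 - 100 - 1
        assert row.exon_span == 200

    def test_single_exon_gene(self):
        ann = AnnotationSet(genes=(gene("g1", "s1", (1, 500)),))
        row = gene_structure_stats(ann).per_gene.iloc[0]
        assert row.intron_count == 0 and row.intron_span == 0

    def test_span_conservation(self):
        # intron_span + exon_span = genomic extent, for every gene
        sim = sim_annotation_and_assembly(
            SimulationConfig(n_scaffolds=2, genes_per_scaffold=20), seed=4
        )
        stats = gene_structure_stats(sim.annotation)
        sel = longest_isoform(sim.annotation)
        for g in sim.annotation.genes:
            t = next(x for x in g.transcripts if x.transcript_id == sel[g.gene_id])
            row = stats.per_gene.set_index("gene_id").loc[g.gene_id]
            assert row.intron_span + row.exon_span == t.end - t.start + 1

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            Transcript("t", (Exon(1, 100), Exon(50, 150)))


class TestIntergenic:
    def test_adjacent_pair_distance(self):
        ann = AnnotationSet(
            genes=(gene("g1", "s1", (1, 100)), gene("g2", "s1", (201, 300)))
        )
        df, mean = intergenic_distances(ann)
        assert df["distance"].tolist() == [100]
        assert mean == 100

    def test_overlap_floored_to_zero(self):
        ann = AnnotationSet(
            genes=(gene("g1", "s1", (1, 100)), gene("g2", "s1", (50, 150)))
        )
        df, _ = intergenic_distances(ann)
        assert df["distance"].tolist() == [0]

    def test_one_gene_per_scaffold_gives_nan_mean(self):
        ann = AnnotationSet(
            genes=(gene("g1", "s1", (1, 100)), gene("g2", "s2", (1, 100)))
        )
        df, mean = intergenic_distances(ann)
        assert df.empty and np.isnan(mean)


class TestAssemblyMetrics:
    def test_n50_hand_count(self):
        m = assembly_metrics({f"s{i}": "A" * L for i, L in enumerate([8, 5, 4, 3])})
        assert m.span == 20 and m.n50 == 5 and m.scaffold_count == 4

    def test_single_scaffold_with_ns(self):
        m = assembly_metrics({"s1": "A" * 96 + "N" * 4})
        assert m.n50 == 100 and m.n_fraction == pytest.approx(4.0)

    def test_equal_lengths(self):
        m = assembly_metrics({f"s{i}": "C" * 50 for i in range(4)})
        assert m.n50 == 50

    def test_invariant_to_order(self):
        seqs = {"a": "A" * 8, "b": "A" * 5, "c": "A" * 4, "d": "A" * 3}
        rev = dict(reversed(list(seqs.items())))
        assert assembly_metrics(seqs) == assembly_metrics(rev)

    def test_empty_assembly_rejected(self):
        with pytest.raises(ValueError):
            assembly_metrics({})

    def test_fasta_file_input(self, tmp_path):
        p = tmp_path / "asm.fasta"
        p.write_text(">s1\nACGT\n>s2\nACGTNN\n")
        m = assembly_metrics(p)
        assert m.span == 10 and m.scaffold_count == 2
        assert m.n_fraction == pytest.approx(20.0)


class TestLog2Ratios:
    def make_stats(self, spans, counts):
        genes = []
        for i, (span, cnt) in enumerate(zip(spans, counts)):
            # cnt introns of ~equal size totalling span, cnt+1 exons of 100
            exons, pos = [], 1
            intron = span // cnt if cnt else 0
            rem = span - intron * cnt if cnt else 0
            for j in range(cnt + 1):
                exons.append((pos, pos + 99))
                pos += 100 + intron + (rem if j == 0 else 0)
            genes.append(gene(f"g{i}", "s1", *exons))
        return gene_structure_stats(AnnotationSet(genes=tuple(genes)))

    def test_identical_structures_give_zero(self):
        a = self.make_stats([200, 300], [2, 3])
        df, dropped = ortholog_log2_ratios(a, a, [("g0", "g0"), ("g1", "g1")])
        assert np.allclose(df["log2_intron_span_ratio"], 0.0)
        assert np.allclose(df["log2_intron_count_ratio"], 0.0)
        assert dropped == 0

    def test_doubled_span_gives_one(self):
        a = self.make_stats([200], [2])
        b = self.make_stats([100], [2])
        df, _ = ortholog_log2_ratios(a, b, [("g0", "g0")])
        assert df["log2_intron_span_ratio"].iloc[0] == pytest.approx(1.0)

    def test_zero_denominator_dropped_and_tallied(self):
        a = self.make_stats([200], [2])
        b = self.make_stats([0], [0])
        df, dropped = ortholog_log2_ratios(a, b, [("g0", "g0")])
        assert df.empty and dropped == 1

    def test_antisymmetry(self):
        a = self.make_stats([200, 500, 120], [2, 5, 1])
        b = self.make_stats([150, 400, 240], [3, 4, 2])
        pairs = [("g0", "g0"), ("g1", "g1"), ("g2", "g2")]
        fwd, _ = ortholog_log2_ratios(a, b, pairs)
        rev, _ = ortholog_log2_ratios(b, a, pairs)
        assert np.allclose(
            fwd["log2_intron_span_ratio"], -rev["log2_intron_span_ratio"]
        )
        assert np.allclose(
            fwd["log2_intron_count_ratio"], -rev["log2_intron_count_ratio"]
        )

    def test_unknown_gene_rejected(self):
        a = self.make_stats([200], [2])
        with pytest.raises(ValueError):
            ortholog_log2_ratios(a, a, [("nope", "g0")])

    def test_planted_contraction_recovered(self):
        rng = np.random.default_rng(0)
        spans_a = rng.integers(500, 2000, size=2000)
        spans_b = (spans_a * 0.8).astype(int)
        a = self.make_stats(spans_a.tolist(), [1] * 2000)
        b = self.make_stats(spans_b.tolist(), [1] * 2000)
        pairs = [(f"g{i}", f"g{i}") for i in range(2000)]
        df, _ = ortholog_log2_ratios(a, b, pairs)
        med = float(df["log2_intron_span_ratio"].median())
        assert med == pytest.approx(np.log2(1 / 0.8), abs=0.05)


class TestGFF3Roundtrip:
    def test_write_then_read_preserves_structure(self, tmp_path):
        sim = sim_annotation_and_assembly(
            SimulationConfig(n_scaffolds=2, genes_per_scaffold=8,
                             multi_isoform_fraction=0.4),
            seed=5,
        )
        path = tmp_path / "ann.gff3"
        write_gff3(sim.annotation, path)
        again = read_gff3(path)
        s1 = gene_structure_stats(sim.annotation).per_gene.sort_values("gene_id")
        s2 = gene_structure_stats(again).per_gene.sort_values("gene_id")
        assert s1["intron_span"].tolist() == s2["intron_span"].tolist()
        assert s1["exon_span"].tolist() == s2["exon_span"].tolist()
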