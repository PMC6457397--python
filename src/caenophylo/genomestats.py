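"""Assembly and annotation structure metrics.

Covers the standard assembly summary (span, scaffold count, N50, N%), gene
structure statistics computed on the longest isoform of each protein-coding
gene (intron count, intron span, exon span, intergenic distances), and the
orthologue-pair log2-ratio comparison of gene structure between two species.
All genomic coordinates are 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Exon",
    "Transcript",
    "Gene",
    "AnnotationSet",
    "GeneStructureStats",
    "AssemblyMetrics",
    "read_gff3",
    "write_gff3",
    "longest_isoform",
    "gene_structure_stats",
    "intergenic_distances",
    "assembly_metrics",
    "ortholog_log2_ratios",
]


@dataclass(frozen=True)
class Exon:
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad exon coordinates [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[Exon, ...]
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = 0
        for e in self.exons:
            if e.start <= prev_end:
                raise ValueError(
                    f"exons of {self.transcript_id} overlap or are unsorted"
                )
            prev_end = e.end

    @property
    def exon_span(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end


@dataclass(frozen=True)
class Gene:
    gene_id: str
    scaffold: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


@dataclass
class AnnotationSet:
    """Genes grouped on scaffolds; IDs unique across the set."""

    genes: tuple[Gene, ...]
    scaffold_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        seen_g, seen_t = set(), set()
        for g in self.genes:
            if g.gene_id in seen_g:
                raise ValueError(f"duplicate gene ID {g.gene_id!r}")
            seen_g.add(g.gene_id)
            for t in g.transcripts:
                if t.transcript_id in seen_t:
                    raise ValueError(f"duplicate transcript ID {t.transcript_id!r}")
                seen_t.add(t.transcript_id)
            L = self.scaffold_lengths.get(g.scaffold)
            if L is not None and g.end > L:
                raise ValueError(
                    f"gene {g.gene_id} extends past scaffold {g.scaffold} ({L} bp)"
                )

    def by_scaffold(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.scaffold, []).append(g)
        return out

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------


def read_gff3(path) -> AnnotationSet:
    """Read gene/mRNA/exon features (ID/Parent attributes) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            exons = tuple(
                Exon(e.start, e.end)
                for e in db.children(t, featuretype="exon", order_by="start")
            )
            if exons:
                transcripts.append(Transcript(t.id, exons, t.strand or "+"))
        if transcripts:
            genes.append(Gene(g.id, g.seqid, tuple(transcripts)))
    return AnnotationSet(genes=tuple(genes))


def write_gff3(annotation: AnnotationSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes, key=lambda g: (g.scaffold, g.start)):
            strand = g.transcripts[0].strand
            fh.write(
                f"{g.scaffold}\tcaenophylo\tgene\t{g.start}\t{g.end}\t.\t{strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.scaffold}\tcaenophylo\tmRNA\t{t.start}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for i, e in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.scaffold}\tcaenophylo\texon\t{e.start}\t{e.end}\t.\t"
                        f"{t.strand}\t.\tID={t.transcript_id}.exon{i};"
                        f"Parent={t.transcript_id}\n"
                    )


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene structure statistics
# ---------------------------------------------------------------------------


def longest_isoform(annotation: AnnotationSet) -> dict[str, str]:
    """Per gene, the transcript with maximal summed exon length (ties broken
    by lexicographically smallest transcript ID)."""
    out = {}
    for g in annotation.genes:
        best = min(g.transcripts, key=lambda t: (-t.exon_span, t.transcript_id))
        out[g.gene_id] = best.transcript_id
    return out


@dataclass
class GeneStructureStats:
    per_gene: pd.DataFrame  # gene_id, scaffold, intron_count, intron_span, exon_span
    mean_intron_count: float
    mean_intron_span: float
    mean_exon_span: float
    gene_count: int


def gene_structure_stats(
    annotation: AnnotationSet, selection: Optional[Mapping[str, str]] = None
) -> GeneStructureStats:
    """Intron/exon statistics on the selected (default: longest) isoform.

    intron_count = exons - 1; intron_span = sum of inter-exon gaps
    (next.start - prev.end - 1); intron_span + exon_span equals the
    transcript's genomic extent.
    """
    if selection is None:
        selection = longest_isoform(annotation)
    rows = []
    for g in annotation.genes:
        tid = selection[g.gene_id]
        t = next(x for x in g.transcripts if x.transcript_id == tid)
        gaps = [
            b.start - a.end - 1 for a, b in zip(t.exons[:-1], t.exons[1:])
        ]
        rows.append(
            {
                "gene_id": g.gene_id,
                "scaffold": g.scaffold,
                "transcript_id": tid,
                "intron_count": len(t.exons) - 1,
                "intron_span": sum(gaps),
                "exon_span": t.exon_span,
            }
        )
    df = pd.DataFrame(rows)
    return GeneStructureStats(
        per_gene=df,
        mean_intron_count=float(df["intron_count"].mean()) if len(df) else float("nan"),
        mean_intron_span=float(df["intron_span"].mean()) if len(df) else float("nan"),
        mean_exon_span=float(df["exon_span"].mean()) if len(df) else float("nan"),
        gene_count=len(df),
    )


def intergenic_distances(
    annotation: AnnotationSet, selection: Optional[Mapping[str, str]] = None
) -> tuple[pd.DataFrame, float]:
    """Distances between adjacent genes on each scaffold (strand ignored,
    scaffold-terminal flanks excluded, overlaps floored at 0).

    Gene spans come from the selected isoform.  Returns (per-pair table,
    mean distance; NaN when no scaffold holds two genes).
    """
    if selection is None:
        selection = longest_isoform(annotation)

    def span(g: Gene) -> tuple[int, int]:
        t = next(x for x in g.transcripts if x.transcript_id == selection[g.gene_id])
        return t.start, t.end

    rows = []
    for scaffold, genes in sorted(annotation.by_scaffold().items()):
        ordered = sorted(genes, key=lambda g: span(g)[0])
        for a, b in zip(ordered[:-1], ordered[1:]):
            dist = max(span(b)[0] - span(a)[1] - 1, 0)
            rows.append(
                {
                    "scaffold": scaffold,
                    "left_gene": a.gene_id,
                    "right_gene": b.gene_id,
                    "distance": dist,
                }
            )
    df = pd.DataFrame(rows, columns=["scaffold", "left_gene", "right_gene", "distance"])
    mean = float(df["distance"].mean()) if len(df) else float("nan")
    return df, mean


# ---------------------------------------------------------------------------
# Assembly metrics
# ---------------------------------------------------------------------------


@dataclass
class AssemblyMetrics:
    span: int
    scaffold_count: int
    n50: int
    n_fraction: float  # percent of bases that are N/n

    def as_row(self) -> dict:
        return {
            "span_bp": self.span,
            "scaffold_count": self.scaffold_count,
            "n50_bp": self.n50,
            "n_percent": self.n_fraction,
        }


def assembly_metrics(source) -> AssemblyMetrics:
    """Span, scaffold count, N50 and N% of an assembly.

    ``source`` is a FASTA path or a mapping scaffold -> sequence.  N50 is the
    largest L such that scaffolds of length >= L jointly cover at least half
    the span.
    """
    if isinstance(source, Mapping):
        seqs = [str(s) for s in source.values()]
    else:
        seqs = [str(rec.seq) for rec in SeqIO.parse(str(source), "fasta")]
    if not seqs:
        raise ValueError("assembly contains no sequences")
    lengths = sorted((len(s) for s in seqs), reverse=True)
    span = sum(lengths)
    acc, n50 = 0, 0
    for L in lengths:
        acc += L
        if acc * 2 >= span:
            n50 = L
            break
    n_count = sum(s.count("N") + s.count("n") for s in seqs)
    return AssemblyMetrics(
        span=span,
        scaffold_count=len(lengths),
        n50=n50,
        n_fraction=100.0 * n_count / span,
    )


# ---------------------------------------------------------------------------
# Orthologue-pair log2 ratios
# ---------------------------------------------------------------------------


def ortholog_log2_ratios(
    stats_a: GeneStructureStats,
    stats_b: GeneStructureStats,
    pairs: Iterable[tuple[str, str]],
) -> tuple[pd.DataFrame, int]:
    """Per orthologue pair, log2(intron_span_A / intron_span_B) and
    log2(intron_count_A / intron_count_B).

    Pairs where either denominator quantity is zero are excluded; the second
    return value is that drop tally.
    """
    a = stats_a.per_gene.set_index("gene_id")
    b = stats_b.per_gene.set_index("gene_id")
    rows, dropped = [], 0
    for ga, gb in pairs:
        if ga not in a.index:
            raise ValueError(f"unknown gene {ga!r} in species A")
        if gb not in b.index:
            raise ValueError(f"unknown gene {gb!r} in species B")
        sa, sb = a.loc[ga], b.loc[gb]
        if min(sa.intron_span, sb.intron_span, sa.intron_count, sb.intron_count) == 0:
            dropped += 1
            continue
        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                # difference of logs keeps A/B vs B/A exactly antisymmetric
                "log2_intron_span_ratio": math.log2(sa.intron_span)
                - math.log2(sb.intron_span),
                "log2_intron_count_ratio": math.log2(sa.intron_count)
                - math.log2(sb.intron_count),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "log2_intron_span_ratio", "log2_intron_count_ratio"],
    )
    return df, dropped
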