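"""Shared construction helpers for the test suite."""

from genarch.annotation_io import (
    CdsSegment,
    GeneModel,
    GenomeAnnotation,
    Scaffold,
    TranscriptModel,
)


def make_transcript(gene_id, segments, strand="+", scaffold="s1", tid=None):
    segs = tuple(CdsSegment(scaffold, a, b, strand) for a, b in segments)
    return TranscriptModel(tid or f"{gene_id}.t1", gene_id, segs, strand)


def make_gene(gene_id, segments, strand="+", scaffold="s1"):
    return GeneModel(gene_id, make_transcript(gene_id, segments, strand, scaffold))


def make_annotation(genes, scaffold_lengths=None):
    scaffolds = (
        [Scaffold(sid, n) for sid, n in scaffold_lengths.items()]
        if scaffold_lengths
        else None
    )
    return GenomeAnnotation(list(genes), scaffolds)


def per_base_partition(annotation, scaffold_lengths):
    """Brute-force per-base labeler: the partition oracle.

    Labels every base coding > intronic > intergenic by literal iteration,
    entirely independent of the interval arithmetic under test.
    """
    counts = {"coding": 0, "intronic": 0, "intergenic": 0}
    for sid, length in scaffold_lengths.items():
        labels = ["intergenic"] * length
        for gene in annotation.genes:
            if gene.scaffold_id != sid:
                continue
            start, end = gene.span
            for pos in range(start, end + 1):
                if labels[pos - 1] == "intergenic":
                    labels[pos - 1] = "intronic"
        for gene in annotation.genes:
            if gene.scaffold_id != sid:
                continue
            for seg in gene.representative.segments:
                for pos in range(seg.start, seg.end + 1):
                    labels[pos - 1] = "coding"
        for label in labels:
            counts[label] += 1
    return counts
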