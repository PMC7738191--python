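# genarch

Tools for quantifying genome streamlining from standard annotation
formats: exact coding/intronic/intergenic partitioning, intron statistics,
cross-species intron gain/loss analysis under Dollo parsimony, orthogroup
count-matrix filters, an h-index horizontal-gene-transfer screen, and
transposable-element coverage from RepeatMasker output. A seeded
synthetic-data module generates every input format together with a truth
ledger, so the whole pipeline is oracle-testable without downloads.

## Modules

| module | purpose |
| --- | --- |
| `genarch.annotation_io` | GFF3/FASTA reading; one representative (longest-CDS) transcript per gene |
| `genarch.genome_metrics` | genome partition, intronless %, CDS introns, medians, 5'-bias profile |
| `genarch.intron_evolution` | intron-site projection onto protein alignments, site tables, Dollo gain/loss tallies, loss-precision calls |
| `genarch.family_dynamics` | orthogroup filters: presence/small-large split, mini-expansions, conserved absences, single-copy sets, essential-gene overlap |
| `genarch.hgt_screen` | per-query best-hit bitscores, h-index, candidate flagging |
| `genarch.repeat_summary` | RepeatMasker `.out` parsing, score-resolved TE coverage, windowed gene/TE densities |
| `genarch.synthetic_data` | seeded generators for all of the above, each with an exact truth ledger |

Conventions: all genomic coordinates are GFF3-style 1-based inclusive;
intron phase is recomputed from CDS segment lengths (the GFF3 phase column
is ignored); a gene's span is its representative's CDS extent; partition
priority is coding > intronic > intergenic with scaffold-terminal
stretches counted as intergenic.

Cluster alignments carry intron annotations in FASTA headers as
`>species|sequence_id|i:c,p;c,p;...` where `c` is the number of coding
nucleotides 5' of the splice junction and `p = c mod 3` its phase.

BLAST tabular subject ids carry their source database as a prefix
(`dbname|accession`); a two-column file maps each database to `metazoan`
or `nonmetazoan`.

## CLI

```sh
genarch metrics  --gff annotation.gff3 --fasta assembly.fasta --out-prefix out
genarch introns  --clusters-dir clusters/ --tree species.nwk --focal SPECIES \
                 --min-flank 5 --min-other-species 11 --out-prefix dollo
genarch families --matrix Orthogroups.GeneCount.tsv --focal SPECIES \
                 --relatives REL1,REL2 --required-class arthropod \
                 --classes species_classes.tsv --out families.json
genarch hgt      --hits blast.outfmt6 --db-classes db_classes.tsv --out calls.tsv
genarch repeats  --rm-out genome.fa.out --fasta assembly.fasta --gff annotation.gff3 \
                 --window 10000 --out-prefix repeats
genarch simulate --config sim.yaml --out-dir synthetic/
```

`simulate` reads a YAML config with any of the sections `genome`,
`intron_history`, `hgt`, `repeats` (see `tests/test_cli.py` for a complete
example) and writes the generated files plus `ledger.json`.

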