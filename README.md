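# homeosort

Subgenome read categorization for allopolyploids. Given sequencing reads from
an organism carrying two ancestral genomes (A and B), `homeosort` assigns each
read pair (fragment) to its genome of origin by one of three methods:

- **dual-reference** (`homeosort dual`) — the same read set is mapped
  independently to both genome references; each fragment's two mappings are
  compared through four serial criteria: unique mapping, mapping quality,
  alignment length, and exact matches (insertions/deletions penalized like
  mismatches). Ties on all four give the unknown label N.
- **SNP vote** (`homeosort vote`) — reads mapped to a single reference vote at
  homoeo-SNP positions (reference positions carrying one diagnostic allele per
  genome); a fragment is categorized when at least 75% (inclusive, per-fragment,
  configurable) of informative votes agree.
- **combined reference** (`homeosort fullref-cat`) — reads mapped to a
  concatenation of both references (genome-tagged sequence names) are
  categorized by the chromosome tag they landed on; cross-genome mate pairs
  become N.

Supporting machinery:

- `homeosort build-index` / `iterate-index` — build a homoeo-SNP index by
  consensus-pileup comparison of two categorized read sets, optionally
  iterating categorize → rebuild to adapt an initial index to the polyploid
  itself;
- `homeosort stats` — error-rate estimation from reads of known origin
  (wrong-genome fraction of mapped fragments, with either a global or a
  per-reference denominator) and method-comparison tables;
- `homeosort simulate` / `map` — a fully deterministic synthetic data
  generator (ancestor → two diverged genomes with substitutions, small indels
  and genome-unique segments; paired-end reads with truth labels) and a naive
  exhaustive unique-best mapper (gapless, toy-scale), so the entire pipeline
  runs and is testable with no external data or aligners.

## Quick start (synthetic end-to-end run)

```sh
homeosort simulate --out sim --seed 1 --ancestor-length 50000 --fragments 2000
homeosort map --r1 sim/reads_R1.fastq --r2 sim/reads_R2.fastq \
    --reference sim/genomeA.fasta --out onA.sam
homeosort map --r1 sim/reads_R1.fastq --r2 sim/reads_R2.fastq \
    --reference sim/genomeB.fasta --out onB.sam
homeosort dual --sam-a onA.sam --sam-b onB.sam --out cat \
    --report report.json --decisions decisions.tsv
homeosort stats --decisions decisions.tsv --truth sim/truth.tsv
```

`dual` writes the four-way output contract — A-fragments on reference A,
A-fragments on reference B, B-fragments on each reference — plus N and
unmapped sinks (`cat.A.onA.sam`, `cat.A.onB.sam`, `cat.B.onA.sam`,
`cat.B.onB.sam`, `cat.N.on{A,B}.sam`, `cat.unmapped.sam`), and a step
attribution report (how many fragments each serial criterion decided).

SNP-vote categorization against the simulator's true-difference index:

```sh
homeosort vote --sam onA.sam --index sim/true_snps.onA.tsv --decisions v.tsv
```

The SNP index format is TSV: `chrom  pos(1-based)  alleleA  alleleB`
(`#` comments allowed); a bi-allelic SNV VCF is also accepted.

## Library layout

| module | contents |
| --- | --- |
| `homeosort.model` | `AlignmentRecord`, `FragmentView`, `CategoryDecision`, genome/criterion enums |
| `homeosort.io_alignments` | SAM/BAM I/O (pysam), match statistics from CIGAR + NM/MD, fragment collation, categorized output |
| `homeosort.dualref` | serial-criteria categorization + step attribution |
| `homeosort.snpcat` | SNP index I/O, per-position base extraction, vote tally and threshold decision |
| `homeosort.indexbuild` | consensus pileups, homoeo-SNP calling, iterative index refinement |
| `homeosort.fullref` | reference concatenation, name maps, chromosome-tag categorization |
| `homeosort.simgen` | genome evolution, read simulation, truth tables, naive mapper |
| `homeosort.stats` | error rates, method comparison, decision TSV I/O |

Coordinates are 1-based (SAM convention) throughout. Secondary and
supplementary alignments are ignored everywhere; inputs are expected to carry
unique best mappings only.
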