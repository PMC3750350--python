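# aflpsim

In-silico AFLP analysis: simulate complete double digestion of annotated
genomes with a rare-cutter / frequent-cutter enzyme pair, derive AFLP
fragments and electrophoretic bands, and quantify how the markers are
distributed across the genome relative to gene locations.

## What it does

- **`aflpsim.genome_io`** — FASTA genomes and GFF3/BED gene annotations in a
  single 0-based half-open coordinate model, with N-run (un-sequenced)
  tracking, candidate-ID selection and per-chromosome gene counts.
- **`aflpsim.digest`** — cut-site scanning (both strands for non-palindromic
  enzymes), double digestion, inclusive size selection (default 40–440 nt,
  PCR lengths 72–472), selective-nucleotide subsampling, and band collapse
  by identical sequence (optionally by length). Built-in catalogue:
  EcoRI/MseI, BsmI/TaqI, SacI/HpaII; extra enzymes via a plain-text config.
- **`aflpsim.annotate`** — marker-to-gene gap distances, cumulative
  percentage-within-threshold statistics for markers and for genes, the
  random-placement expectation (gene union coverage of the sequenced
  genome), the Poisson expectation `100·(1−e^(−λ))` with λ the mean
  overlapping fragments per gene, per-gene fragment-count histograms, and
  candidate-gene subset summaries (0/1/10/100 kb).
- **`aflpsim.landscape`** — non-overlapping window tracks (default 200 kb)
  of fragments, bands, genes, cut sites and GC; genic vs intergenic GC;
  gene-length and inter-marker-distance summaries.
- **`aflpsim.synthetic_genome`** — seeded synthetic genomes with
  GC-contrasted genes, optional pericentromeric tandem-repeat arrays whose
  unit yields exactly one AFLP fragment per copy, N runs and planted sites;
  every planted quantity is recorded in a truth record.
- **`aflpsim.report`** — species-level and candidate-gene reports,
  marker-density regression on genome size, markers-per-centimorgan
  conversion.

## CLI

```sh
aflpsim simulate  --config sim.cfg --out simdir
aflpsim digest    --genome simdir/genome.fa --pair EcoRI,MseI --min 40 --max 440 --bands --out dig
aflpsim annotate  --genome simdir/genome.fa --genes simdir/genes.gff3 --out ann
aflpsim landscape --genome simdir/genome.fa --genes simdir/genes.gff3 --window 200000 --bands --out land
aflpsim table1    --genome simdir/genome.fa --genes simdir/genes.gff3 --pairs "EcoRI,MseI;BsmI,TaqI;SacI,HpaII" --out table1.tsv
aflpsim table2    --genome simdir/genome.fa --genes simdir/genes.gff3 --candidates ids.txt --out table2.tsv
aflpsim regress   --points panel.tsv --exclude outlier_label
```

Exit codes: 0 success, 2 input error, 3 infeasible synthetic-genome config.

A simulate config is plain `key=value` text, e.g.

```
seed=4
chromosome_lengths=3000000
genes=300
genic_gc=0.45
intergenic_gc=0.35
# chrom:position:unit_length:copies:fragment_length:Rare,Frequent
centromere=chr1:1400000:147:63:117:EcoRI,MseI
```

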