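# spliceinfo

Information-theory analysis of allele-specific alternative mRNA splicing,
with the downstream validation stages, end to end on synthetic data:

- **`spliceinfo.infomodel`** — individual-information weight matrices built
  from splice-site training alignments (weights `Riw(b,l) = 2 + log2 f(b,l)
  − e_n(l)` in bits), window scoring (`R_i`), sequence scanning, variant
  `ΔR_i`, and fold-change reporting (`2**|ΔR_i|`; 1 bit ≈ twofold affinity).
- **`spliceinfo.variant_effects`** — evaluation of single-nucleotide variants
  against gene models: natural-site `ΔR_i`, cryptic-site enumeration around
  the affected junction under both alleles, effect classification
  (inactivating / leaky-weakened / strengthened / cryptic-activated /
  pseudoexon candidate), candidate screens (`ΔR_i < −1` bit with
  heterozygosity > 10%), and exon-definition totals.
- **`spliceinfo.exonarray`** — splicing index (probeset intensity over gene
  intensity), SNP-to-probeset linking (nearest like-stranded within 500 nt,
  SNP-overlapping probes removed), and the stepwise genotype filter (het and
  rare-homozygote mean SI < 90% of common, het strictly in between).
- **`spliceinfo.qpcr`** — efficiency-corrected relative expression from
  replicate Ct tables (REST-style, external-reference normalized), a seeded
  fixed-reallocation randomization test, and isoform abundance relative to
  an internal gene reference.
- **`spliceinfo.rnaseq`** — classification of simplified spliced-alignment
  records into junction-evidence categories (wildtype / exon skipping /
  cryptic use / intron retention), a ≥5-read expression gate, per-allele
  splits, and one-sided empirical significance against a control cohort.
- **`spliceinfo.synthetic`** — generators for every input: training sites
  from a ground-truth frequency model, loci with planted natural/cryptic
  sites, variants with a chosen `ΔR_i`, HWE genotype cohorts with
  multiplicative allele-dose intensity effects, genotype-dependent Ct
  tables, and multinomial junction reads; all seeded via one master seed.

## CLI

```sh
spliceinfo build-matrix sites.txt -o donor.tsv --site-kind donor --window-start -3 --pseudocount 0.25
spliceinfo score donor.tsv CAGGTAAGT
spliceinfo scan donor.tsv genome.fa --strand both --min-ri 1.6
spliceinfo evaluate --vcf v.vcf --gff genes.gff3 --fasta genome.fa \
    --donor-matrix donor.tsv --acceptor-matrix acceptor.tsv -o effects.tsv
spliceinfo si-screen --intensities i.tsv --genotypes g.tsv --probesets p.tsv --max-dist 500 --ratio 0.90
spliceinfo qpcr --ct ct.tsv --target iso1 --ref external_ref --groups AA,GG --iters 2000 --seed 7
spliceinfo rnaseq-classify --reads reads.tsv --gff genes.gff3 --variant chrS:512:G:A
spliceinfo simulate --out-dir fixtures/ --seed 1
```

`spliceinfo simulate` emits a complete synthetic fixture set (FASTA, GFF3,
VCF, matrix/intensity/genotype/Ct/read TSVs) plus a JSON truth manifest.

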