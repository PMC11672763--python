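# snpanel

Design and validation of low-density SNP panels ("liquid chips") for
population identification, from multi-population genotypes in VCF.

The pipeline selects a small set of maximally population-differentiating,
probe-feasible SNPs and then validates the panel's ability to identify
populations:

1. **genotypes** — VCF input (biallelic SNVs, ALT-dosage calls, per-genotype
   depth), site-level QC (mean depth ≥ 5X, missing rate < 10%, het rate
   < 30%), sample exclusion.
2. **scoring** — per-population ALT-allele frequencies and pairwise
   allele-frequency differentials (ΔMAF); per-population selection score is
   the max differential involving that population. Includes a Hudson FST
   estimator used as a simulation oracle.
3. **probedesign** — 110 bp flanking-context extraction, GC bounds
   [30%, 70%] (inclusive), and a both-strand central-31-mer genome
   occurrence count capped at 5 as a reproducible homology screen.
4. **panel** — per-population top-K (default 1500) union with provenance,
   capacity allocation (default 6000: all autosomal sites, residual slots to
   sex-chromosome sites by mean differential, Y blacklisted), and
   detection-rate pruning (default ≥ 0.95). Deterministic tie-breaks, BED /
   TSV / VCF exports.
5. **annotate** — gene-structure categories (exonic > UTR5/UTR3 > intronic >
   upstream/downstream > intergenic, 1 kb flanks, combined labels), 1 Mb
   tiled chromosome density, folded-MAF histogram.
6. **validate** — per-sample missing/het/hom-alt/hom-ref counts and rates
   (het/hom/consistency rates over called sites), per-population summary
   table with an unweighted grand-mean row, failed-sample flagging
   (missing rate > 90%).
7. **popstruct** — frequency-standardized GRM with per-pair missing
   handling, PCA of the centered GRM, allele-sharing (1 − IBS) distances,
   Saitou–Nei neighbor joining to Newick, and k-means/ARI cluster-vs-label
   concordance.
8. **synth** — seeded hierarchical Balding–Nichols simulator (three weakly
   diverged types nested in one breed plus two distinct breeds), with
   reference FASTA/GFF3 emission and plantable repeats for homology tests.

## CLI

Subcommands compose over flat files; every run writes a JSON manifest and
outputs are byte-identical for a fixed seed/config.

```sh
snpanel simulate --seed 1 --out-dir sim --with-reference
snpanel qc       --vcf sim/cohort.vcf --popmap sim/popmap.tsv --out-dir qc
snpanel score    --vcf qc/filtered.vcf --popmap qc/popmap.tsv --out-dir scores
snpanel probes   --vcf qc/filtered.vcf --popmap qc/popmap.tsv --fasta sim/reference.fa --out-dir probes
snpanel select   --vcf qc/filtered.vcf --popmap qc/popmap.tsv --probes probes/probes.tsv --out-dir panel
snpanel annotate --panel panel/panel.tsv --gff3 sim/genes.gff3 --vcf qc/filtered.vcf --popmap qc/popmap.tsv --out-dir annot
snpanel validate --vcf qc/filtered.vcf --popmap qc/popmap.tsv --panel panel/panel.tsv --out-dir val
snpanel pca      --vcf qc/filtered.vcf --popmap qc/popmap.tsv --out-dir pca
snpanel tree     --vcf qc/filtered.vcf --popmap qc/popmap.tsv --out-dir tree
snpanel report   --out-dir .
```

`simulate` also accepts a YAML config (`--config`) mirroring every
`SimConfig` field; flags override the file.

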