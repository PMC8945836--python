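# bulkmap

Bulked-segregant QTL scanning and map-based cloning toolkit, driven by a
synthetic F2 population generator so every stage is testable offline.

The pipeline chains:

1. **simpop** — simulate an F2 cross segregating at one causal locus with
   incomplete dominance (SPAD phenotype: mutant < 10, heterozygote 10–20,
   wild type > 20), build phenotype-extreme bulks of 25, and emulate pooled
   sequencing (Poisson depth, binomial allele sampling). Also builds
   deterministic worked-example fixtures (fine-mapping genotype matrix with
   exact per-marker recombinant counts; gene/variant/expression table for
   the candidate-filter cascade).
2. **readqc** — read filters (≥10% N; >50% of bases below phred 5; >10 nt
   adapter overlap at ≤10% mismatch) and exact-duplicate pair removal.
3. **bsaseq** — per-site SNP-index and Δ(SNP-index), 1 Mb / 10 kb sliding
   windows, a depth-conditional Monte-Carlo null band at α, and candidate
   region calling.
4. **finemap** — SPAD classification, recombinant screening among
   mutant-class individuals, marker-by-marker interval narrowing.
5. **genecand** — CDS variant-effect annotation (codon/residue, standard
   genetic code) and the four-step EMS candidate-gene triage cascade.
6. **expr** — median-of-ratios normalization, Welch-on-log differential
   expression with BH FDR < 0.05 and |log2FC| ≥ 1 (a transparent stand-in
   for a negative-binomial DE model), and 2^−ΔΔCt quantification.
7. **markerval** — FAM/HEX fluorescence genotype gating, cosegregation
   checking, and 1:2:1 segregation chi-square.

## CLI

`bulkmap` exposes one subcommand per stage plus an end-to-end runner:

```sh
bulkmap simulate --n 400 --causal-bp 15000000 --seed 1 --out-prefix sim
bulkmap qc --adapter AGATCGGAAGAGC --in1 r1.fq --in2 r2.fq --out1 c1.fq --out2 c2.fq
bulkmap scan sim.vcf --chrom-len 30000000 --alpha 0.05 --seed 1 --out-prefix scan
bulkmap finemap --genotypes geno.tsv --phenotypes phen.tsv --markers panel.tsv
bulkmap triage --seed 1
bulkmap deg counts.tsv
bulkmap ddct ct.tsv --test-condition leaf_mut --calibrator-condition leaf_wt
bulkmap validate signals.tsv --phenotypes phen.tsv --fam-thresh 2 --hex-thresh 2
bulkmap run --seed 1 --outdir out       # full pipeline, deterministic report
```

`bulkmap run` simulates, scans, calls the candidate region, fine-maps it in
iterative marker rounds, tiles the narrowed interval with gene models,
triages them, and validates a marker at the causal SNP; the JSON report
records every stage seed and is byte-identical across reruns of the same
configuration.

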