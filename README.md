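# circlecap

Design and evaluation toolkit for targeted sequencing libraries prepared by
genomic DNA circularization. A restriction digest fragments the genome; a
capture oligonucleotide splints the two ends of a target fragment into a
circle whose middle common region carries the sequencing-adapter components,
so a single amplification (or none at all) yields a ready-to-sequence
library. `circlecap` implements the computational side of that assay:

- **`genome_model`** — sequence/interval/variant types; FASTA, BED, minimal
  VCF and TSV-manifest I/O. All internal coordinates are 0-based half-open.
- **`digest`** — in-silico restriction digestion (MseI `T^TAA` built in;
  any palindromic enzyme configurable) into boundary-annotated fragments.
- **`design`** — capture-oligo enumeration and QC: 20-nt arms with the
  3'-side arm anchored exactly at a cut boundary (the 5' side may be
  flap-displaced into the fragment), SNP avoidance, k-mer uniqueness /
  softmask / homopolymer repeat proxies, circle-size window 200–600 bases
  (hard cap 800) and arm G+C window 30–60%, redundancy-capped deterministic
  selection, region tiling, ROI base-coverage accounting.
- **`assemble`** — full oligo sequence construction
  (`arm + 58-nt + 61-nt adapter components + arm` = 159 nt with defaults),
  the 119-nt universal vector (reverse complement of the common region),
  and deterministic 10× T→U substitution in the common region.
- **`simulate`** — synthetic references with controllable site spacing,
  planted SNPs and repeats; a capture-yield model (logistic size decay ×
  temperature-dependent G+C plateau window); 42-base fragment-end reads
  (single or paired) with off-target and adapter contaminants, with or
  without log-normal PCR skew; FASTQ + truth table + truth SAM output.
- **`evaluate`** — fragment-end tag counting against read-length-wide
  target regions, on/off-target accounting, 1×/30× coverage, median-
  normalized uniformity curves, failed/moderate/high performance
  classification and yield-vs-size/G+C correlates.
- **`cli`** — `circlecap` command wiring all stages plus an `end-to-end`
  synthetic demo driven by a single seed.

## CLI

```sh
circlecap digest   --reference ref.fasta --out-prefix out/dig
circlecap design   --reference ref.fasta --roi rois.bed --snps snps.bed \
                   --config cfg.yaml --out-prefix out/des
circlecap assemble --manifest out/des.manifest.tsv --out-prefix out/asm
circlecap simulate --manifest out/des.manifest.tsv --reference ref.fasta \
                   --seed 1 --out-prefix out/sim
circlecap evaluate --alignments out/sim.truth.sam \
                   --manifest out/des.manifest.tsv --out-prefix out/ev
circlecap end-to-end --out out/demo --seed 1
```

The YAML config may contain `enzymes`, `design`, `adapters`, `simulate`
and `evaluate` sections; CLI flags override the config, which overrides
built-in defaults. Every tabular output records a hash of the effective
configuration in a header comment, and one seed governs all randomness,
so reruns are byte-identical.

Note on sizes: with the default 58/61-nt adapter components and 20-nt
arms the assembled oligo is 20+58+61+20 = 159 nt, consistent with the
119-nt vector; the shipped adapter components are placeholders of the
correct lengths — supply real vendor sequences via the `adapters`
config section.

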