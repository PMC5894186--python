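# strscape

Short tandem repeat (STR) landscapes, GO-level STR enrichment, and
multi-copy immune-gene censuses for genome assemblies.

Codfish genomes (Atlantic cod, haddock) carry unusually dense
microsatellite landscapes — on the order of 10⁵ bp of STRs per Mbp, inside
coding sequence as well as outside — together with strongly expanded
innate-immune gene families (NOD-like receptors, MHC class I) whose
near-identical copies defeat genome assemblers and end up collapsed or
unplaced. `strscape` packages the analyses needed to characterize such
genomes as a tested, reusable library and CLI:

* **STR detection** — maximal perfect tandem arrays of unit size *u* =
  1–10 bp (minimal-period rule, partial trailing units, arrays split at
  N), with density (bp/Mbp) and frequency (loci/Mbp) tables per unit size,
  genome-wide and clipped to CDS.
* **Gene overlap statistics** — genes carrying ≥1 STR, the triple overlap
  of trinucleotide STR × size-3 indel × gene (heterozygous in-frame coding
  STR length variants), and per-bp variant rates by class (SNP / MNP /
  indel / complex) from quality- and depth-filtered VCFs.
* **Enrichment** — per GO term, Fisher's exact test on
  [[with-STR, without-STR]] gene counts, pairwise between species or
  against the within-species background, corrected with the
  Benjamini–Yekutieli FDR (c(m) = Σ 1/i), with enrichment/purification
  read from the odds ratio.
* **Domain census** — six-frame conceptual translation scanned with
  ungapped log-odds profiles (20 amino acids + stop); hits binned by
  fractional domain coverage (all / >50% / >75%), flagged for internal
  stop codons (putative pseudogenes), deduplicated across frames, and
  split by placed/unplaced status. Includes ≥60% partial-copy
  classification and ±10 kb window combination labels for multi-exon
  (MHCI-alpha-style) families.
* **Collapse diagnostics** — per-sequence read depth normalized by the
  assembly mean; domain-bearing sequences with elevated normalized depth
  are flagged as collapsed repeats, with copy number estimated as
  hits × round(normalized depth).
* **Synthetic data** — a generator that plants all of the above (STR
  spectra, GO effects, pseudogenized domain copies, collapsed contigs,
  QUAL/DP-mixed variants) with exact recorded truth, so the whole pipeline
  is testable without external data.

## Worked example

```python
from strscape import (SimulationConfig, simulate, find_strs_assembly,
                      str_statistics, genes_with_strs, read_fasta)

truth = simulate(SimulationConfig(seed=1, n_contigs=4,
                                  contig_length_bp=100_000, n_genes=120),
                 "sim/")
records = read_fasta("sim/assembly.fasta")
loci = find_strs_assembly(records)
table = str_statistics(loci, truth.assembly_bp).table
print(table.loc[[2, 3, "total"], ["density_bp_per_mbp", "frequency_loci_per_mbp"]])
```

prints (seed 1):

```
           density_bp_per_mbp  frequency_loci_per_mbp
unit_size
2                55364.897834             2850.094928
3                20000.270579             1034.963269
total            96364.325109             4872.670205
```

i.e. the recovered spectrum matches the planted codfish-like target
(dinucleotide-dominated, 96,364 bp/Mbp in total) to well within 1%. The
same objects feed the downstream stages: `genes_with_strs(...)` returns
per-gene STR summaries whose `has_str` set equals the planted gene set
exactly, and `census(...)` over the simulated domain contigs recovers
every planted family copy with its pseudogene flag.

The same stages are available from the shell:

```bash
strscape simulate --seed 1 --out sim/
strscape str-scan --fasta sim/assembly.fasta --out strs.gff3
strscape str-stats --strs strs.gff3 --fasta sim/assembly.fasta --gff sim/genes.gff3 --out stats
strscape overlap --genes sim/genes.gff3 --strs strs.gff3 --vcf sim/variants.vcf --out ov
strscape domain-census --fasta sim/assembly.fasta --profiles sim/profiles.txt \
         --placed-map sim/placed.tsv --out census
strscape coverage --depth sim/depth.tsv --hits census.hits.tsv --out cov.tsv
```

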