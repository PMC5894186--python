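# Methods

This note documents the models, defaults and numerical choices behind
`strscape`, and what the synthetic benchmark does and does not establish
about real data.

## Coordinates and file handling

All in-memory coordinates are 0-based half-open; conversion to and from
the 1-based closed conventions of GFF3 and VCF happens only at the file
boundary (`io_formats`). FASTA is read through Biopython, GFF3 through an
in-memory gffutils database (CDS features are attached to their gene
ancestor through `Parent` links, directly or via an mRNA, then sorted and
overlap-merged), and VCF through pysam. Placed/unplaced status (member of
a linkage group or chromosome vs not) is carried as an explicit sidecar
TSV rather than inferred from sequence naming, which differs between
assemblies.

Variant filtering keeps records with quality strictly above 20 and depth
strictly above 5 by default — "more than" read literally — and
multi-allelic records are split into one record per alt allele.
Classification is a declared contract, not a re-derivation of any one
caller's decomposition: equal length 1 → SNP, equal length >1 → MNP, one
allele a strict prefix of the other → indel with signed size
len(alt) − len(ref), anything else → complex.

## STR detection

An STR locus is a **maximal perfect tandem array**: a tract whose minimal
period is u (1–10 bp), that cannot be extended by one base on either side,
with partial trailing units counting toward its length (ACACA is 2.5
copies of AC). Arrays never span N. Detection scans, per unit size, the
match mask s[i] == s[i+u] for runs; a run of r matches is a perfectly
u-periodic tract of r + u bases. Tracts whose minimal period is below u
are reported only at that minimal period, so an AC×n array never
reappears at u = 4.

Mismatch-tolerant (imperfect) repeats are deliberately out of scope:
published tools score imperfect arrays under tunable alignment models
whose settings are rarely recoverable, whereas perfect-only detection has
an exact, oracle-checkable definition. The cost is that long interrupted
arrays are reported as several shorter perfect arrays, so absolute
densities are not comparable with imperfect-mode annotations.

Thresholds default to min_len[u] = max(12, 3u) bp and min_copies[u] =
min_len[u]/u: the 12 bp floor keeps trivially short tracts (which occur
constantly by chance) out of every unit size, and three full copies is
the conventional minimum for calling a tandem array. Both maps are
configurable per unit size.

Motifs are aggregated by canonical class: the lexicographically smallest
string over all rotations of the unit and of its reverse complement, so
GA/AG/TC/CT all count as AG and a sequence and its reverse complement
have identical motif spectra.

Statistics report density (10⁶ × array bp / region bp) and frequency
(10⁶ × loci / region bp) per unit size. Where arrays of different unit
sizes overlap, the smaller unit claims the shared bases, so the totals
row never double counts; per-unit locus counts use the raw maximal
arrays. CDS statistics clip loci at CDS boundaries (array bp recomputed
from the clipped interval) against the total merged CDS length; whether
published coding-region densities clipped or attributed whole loci is
generally unstated, so clipping is this package's declared contract.

## Gene overlaps and variant rates

A gene "has an STR" if any locus overlaps its span (default) or its
merged CDS (option) by ≥1 bp. The triple-overlap statistic counts genes
where a filtered indel of |size| = 3 has its anchor — the first affected
base after the shared ref/alt prefix, assuming left-aligned VCF — inside
a trinucleotide array that overlaps the gene. Such genes carry in-frame
coding STR length variants, i.e. are heterozygous for the repeat in the
sequenced individual. Insertions and deletions count alike. Variant rates
are plain count / assembly bp per class, a single-individual proxy for
nucleotide diversity.

## Enrichment

Per GO term the 2×2 table is genes-with vs genes-without STRs; between
species the two rows are two species' counts for the term, within species
the in-term counts against the rest of the genome. Tests are two-sided
Fisher exact tests (scipy); direction (enrichment vs purification) is
read from the sample odds ratio, not from one-sided tests. Multiple
testing uses Benjamini–Yekutieli (statsmodels), valid under arbitrary
dependence between the strongly overlapping GO terms; for the
between-species design the FDR family pools all term × species-pair
tests, the conservative reading when one corrected family is reported
over all terms. Terms absent in one species are skipped with a warning.
GO-hierarchy propagation is not performed: counts use direct annotations
only, matching how gene→GO TSVs are usually produced, and keeping the
2×2 margins interpretable.

## Domain census

Sequences are conceptually translated in all six frames (stops rendered
`*` and translated through; codons containing N → X; trailing partial
codons dropped). Each frame is scanned with an **ungapped position-specific
scoring matrix** over 21 symbols (20 amino acids + stop): for each
alignment diagonal the best-scoring contiguous run of profile columns is
taken (a local ungapped segment), its column count over the profile
length is the hit's coverage, and candidates above the profile's bit
threshold are kept greedily, best score first, without overlap. This is a
deliberate simplification of profile-HMM search: the quantities of
interest are hit counts above fractional-coverage thresholds, for which
an ungapped local segment is sufficient and exactly analyzable; insert
and delete states, and E-values, are not modeled. The local-segment
formulation is what makes coverage meaningful — a copy truncated to 60%
of the domain embedded in other sequence yields a 0.60-coverage hit, not
a full-coverage hit with a bad score.

Stops score −8 bits per column by default, so a strong hit spans an
internal stop and is flagged (`has_internal_stop`) rather than split:
this is the "with stop codons" pseudogene bin. Residues outside the
alphabet score −1.

Hits are back-projected to genomic coordinates (interval length = 3 ×
aligned columns) and deduplicated: hits of one profile overlapping ≥50%
reciprocally keep only the best score, since near-identical copies are
otherwise recounted across frames. Raw per-frame counts are retained
alongside for comparability with pipelines that count frame hits
directly. The census reports, per profile: all hits, coverage >50%,
coverage >75%, >75% with internal stops, and the placed/unplaced split.

Copy completeness elsewhere (TLR-style BLAST censuses) is classified by
fractional coverage of the reference coding sequence: ≥1.0 full-length,
≥0.60 partial (inclusive), else below. Multi-domain (MHCI-alpha-style)
regions are labeled by the set of distinct alpha domains found within
±10,000 bp windows anchored greedily left to right on the leftmost
unassigned hit.

## Collapse diagnostics

Per-sequence mean depth (from samtools-depth-style per-base TSVs, all
positions including zeros and Ns, or pre-averaged summaries) is divided
by the length-weighted assembly mean, so normalized depth averages to 1
by construction. A sequence is flagged as a collapsed repeat iff its
normalized depth exceeds the threshold **and** it carries a domain hit;
the naive copy estimate is hits × max(1, round(normalized depth)), with
the fractional estimate kept alongside. The default threshold is 2.0,
aimed at ≥2-fold collapse. Note that the assembly mean includes the
collapsed sequences themselves, so a genuine ×2 collapse normalizes
slightly below 2 when collapsed sequence is a non-negligible length
fraction; analyses that must catch ×2 collapses should flag at ~1.5.
Five-fold-and-above outliers are unambiguous at any reasonable setting.

## Synthetic data

The generator emits an assembly (FASTA + placed map), gene models (GFF3),
gene→GO TSV, variants (VCF), per-sequence depth (TSV) and domain profiles,
with all planted features recorded as truth. Defaults emulate a
codfish-like genome at desk scale:

* **STR spectrum**: per-unit-size densities totalling 96,364 bp/Mbp,
  dinucleotide-dominated (55,364 at u=2, 20,000 at u=3). Arrays are
  planted as maximal perfect tracts (geometric length above min_len,
  motifs uniform over canonical classes of exact minimal period, guard
  bases breaking extension) into a background that is scrubbed STR-free
  by rejection, then verified: detection over the final assembly must
  return exactly the planted locus set, or generation fails. Per-unit
  planted bp hit the target exactly (the last array absorbs the
  remainder), so recovered density equals the target up to rounding.
* **Genes and GO**: non-overlapping genes (1–3 CDS exons, ~1.2 kb CDS)
  on the background contigs; GO terms sample genes; a gene carries a CDS
  STR with probability base_p (0.3, codfish-like ~30% of genes) times
  the product of its terms' effect multipliers. Intergenic fill avoids
  gene spans entirely, so the genes-with-STR truth is exact.
* **Heterozygous coding STRs**: a configurable fraction of genes (2.1%
  by default) receives a size-3 indel anchored inside its trinucleotide
  array, always passing the quality/depth filter. Background indel sizes
  exclude |3| so this truth set is exact.
* **Variants**: per-class per-bp rates (defaults at the haddock-like
  5.4/0.2/1.6/0.5 ×10⁻³ for SNP/MNP/indel/complex), with a QUAL/DP
  mixture straddling the filtering thresholds (20% low quality, 10% low
  depth) to exercise the strict inequalities.
* **Domain families**: FISNA-like (72 aa) and NACHT-like (166 aa)
  consensus profiles; copies at 95% identity on dedicated unplaced
  contigs; a configurable fraction pseudogenized by one internal stop;
  collapse simulated mechanistically by emitting one contig for k copies
  and scaling its depth by k. Domain DNA is synonymous-codon resampled
  until STR-free so it never perturbs the STR truth.
* **Depth**: per-contig Poisson at 30× times the collapse multiplier
  (summary TSV by default; per-base available).

One integer seed determines every byte of output. The count-level
generator (`simulate_go_counts`) drives the enrichment power and null
harnesses directly at the per-term binomial level — the exact quantity
the Fisher test sees.

**What passing tests do not show**: the background is uniform-composition
and repeat-free apart from what is planted, so detector exactness here
does not bound false positives in real genomes with transposable
elements, low-complexity DNA and imperfect arrays; domain copies diverge
by point substitution only (no indels, which the ungapped scan would
fragment); depth has no GC or mapping bias; variants are independent of
each other. Recovery rates on this benchmark are therefore upper bounds
on real-data performance; the arithmetic, threshold semantics and
statistical calibration (type-I control under BY) transfer directly.

## Problem sizes and tolerances

The default simulated assembly is ~0.44 Mbp (4 × 100 kb background plus
domain contigs, 120 genes), enough that every per-unit density target is
feasible and all planted sets are recovered exactly; the dinucleotide
density example runs at 10 Mbp. Density recovery is asserted to 1%
relative; Fisher p-values agree with support enumeration to 10⁻⁷
relative (the tie tolerance); collapse multiplicity recovery is asserted
at ≥95% of collapsed contigs under ≥20× Poisson depth. Enrichment power
is measured over 20 replicates of 510 terms (10 carrying a 3× effect,
200 genes per term per species) with detection defined as surviving BY
at α = 0.05.
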