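# Methods

## Scope and data model

`vcfscope` treats a VCF file as what it is at the text level: a block of
`##` meta lines, one `#CHROM` header, and tab-separated data lines whose
first eight columns (CHROM, POS, ID, REF, ALT, QUAL, FILTER, INFO) are
mandatory. All analysis operates on those eight columns as a heterogeneous
tabular dataset; FORMAT and sample columns are carried verbatim through
every operation and never interpreted. This keeps the package applicable to
any VCF v4.x regardless of which caller produced it, at the cost of
excluding genotype-level analysis (concordance, allele balance, per-sample
filtering), which is deliberately out of scope.

The reader is version-agnostic and intentionally literal. It does not
validate INFO against the meta declarations, does not coerce types beyond
POS (integer) and QUAL (float-or-missing), and preserves records in file
order. Compression is detected from the two gzip magic bytes rather than
the file extension, since extensions are unreliable in practice; bgzip
output is a conforming gzip stream and is read identically (writing bgzip,
and tabix indexes, are not supported). A malformed data line — fewer than
eight fields, a non-integer POS — aborts the read with its line number by
default; a permissive mode skips such lines and counts them. The default is
strict because a silently truncated file corrupts every downstream count.

A missing QUAL (`.`) maps to a distinct missing value, never to 0: a record
without a score must not pass a `QUAL >= 0` filter or sort as the
worst-scoring variant.

## Normalization

Normalization here means exactly two steps, in order:

1. **Multiallelic splitting.** A record with k comma-separated ALT alleles
   becomes k records identical in every other column, each flagged as
   having come from a multiallelic site. The number of multiallelic *sites*
   (input records with k ≥ 2) is counted before splitting and reported
   alongside the per-variant classes, not as a class of its own — a site
   property and an allele property should not share a denominator.
2. **Deduplication.** The identity of a normalized variant is the key
   (CHROM, POS, REF, ALT) with alleles uppercased. Records repeating an
   earlier key are dropped, keeping the first in file order, and the
   removed count is reported. ID, QUAL, FILTER and INFO never participate
   in identity: two callers annotating the same allele differently still
   describe the same variant.

No left-alignment or allele trimming against a reference genome is
performed. Two representations of the same indel at different coordinates
are therefore distinct variants here; users needing representation-level
normalization should run `bcftools norm` upstream. This is a deliberate
boundary, not an omission — split+dedup is a pure text transformation that
needs no reference FASTA and cannot change what the file asserts.

## Classification

Every normalized (single-ALT) record receives exactly one class, by a rule
ladder applied to uppercased alleles:

1. symbolic ALT (`<...>`, a breakend containing `[` or `]`, `*`, `.`) or
   any character outside {A, C, G, T} in either allele (N included) →
   **assorted**;
2. both alleles length 1 → SNP: **transition** if both are purines (A/G)
   or both pyrimidines (C/T), else **transversion**;
3. equal lengths > 1 → **MNP**;
4. unequal lengths → **insertion** if ALT is longer, else **deletion**.

SNP and INDEL are derived groupings (transitions + transversions,
insertions + deletions) accepted anywhere a class name is, e.g. in class
filters. Rule 4 requires no prefix relationship between the alleles, so a
complex substitution like AG→TCA counts as an insertion of its net length;
its signed size is `len(ALT) − len(REF)` (positive insertions, negative
deletions). The ladder is total and exclusive by construction, which the
property suite asserts over random allele strings.

The Ts/Tv ratio is transitions / transversions, reported to two decimals at
the CLI; with zero transversions it is a missing value (never an exception
or infinity), since a ratio over an empty denominator carries no QC
information.

## Windowed density and gap detection

Windows are fixed-width (default 1 Mbp), 1-based, inclusive, and anchored
at position 1: window k spans [(k−1)·W + 1, k·W], so a variant at position
p falls in window ⌈p/W⌉. For each contig, every window from 1 through the
last occupied window is emitted, zero counts included — explicit zeros are
what make empty-region detection possible, and halving W and re-aggregating
adjacent pairs reproduces the original counts exactly (a property test).
The longest empty gap on a contig is the longest run of zero-count windows
strictly between its first and last occupied windows; leading and trailing
emptiness is ignored because, without a reference genome, absence of calls
before the first variant is indistinguishable from unassayed or
non-existent sequence. Contigs appear in outputs in order of first
appearance in the file (VCFs are conventionally reference-ordered); no
karyotype sort is imposed.

## Pairwise comparison

Two normalized datasets are compared purely by key membership, yielding the
three-way partition (unique to A, unique to B, shared) whose counts are the
Venn-diagram regions; drawing area-proportional ellipses is left to any
plotting layer. Shared records carry file A's columns, making annotation
provenance deterministic. Overlap percentages are 100·shared/|A| and
100·shared/|B|, missing for an empty side.

Contig names are matched as exact strings by default. When the two files'
contig vocabularies are completely disjoint — the signature of a
`chr1`-versus-`1` naming mismatch — a warning is raised rather than
silently reporting zero overlap; an explicit `harmonize_chr_prefix` option
ignores a leading `chr` during matching while preserving each record's
original spelling. Harmonization is opt-in because rewriting contig names
by default risks false matches between genuinely different assemblies.

## Filtering, search and sorting

All record-level operations are order-preserving subsets (or stable
reorderings), so composing filters commutes. Region filtering is inclusive
on both 1-based ends, the natural reading of coordinate spans like
`chr6:29602228-33410226`. Quality filtering keeps records with QUAL ≥
threshold; missing QUAL is dropped unless explicitly kept (conservative:
absence of evidence of quality). Keyword search is a case-insensitive
substring match over the verbatim text of any one of the eight fixed
columns — INFO as its raw semicolon-separated string, which makes
annotation extraction a search for, e.g., `ANN=` — with regular expressions
behind an explicit opt-in flag, since search-box semantics are substring
and regex metacharacters surprise. Sorting by POS or QUAL is stable, with
missing QUAL last in either direction.

## The synthetic-data generator

`FixtureSpec` + `generate_vcf` produce a valid VCF whose
normalize→summarize output reproduces the spec's class counts,
multiallelic-site count and duplicates-removed count *exactly*. The
construction guarantees this rather than sampling toward it:

* every site receives a position unique on its contig (drawn without
  replacement), so the only repeated keys are the planted duplicates;
* a multiallelic site is one record with two SNP alleles of the same REF
  base — one transition and one transversion, counted inside those two
  budgets. A single REF base admits exactly one transition, so a
  two-transition pair is impossible; this pairing is the simplest feasible
  one and forces `n_transition, n_transversion ≥ n_multiallelic_sites`;
* planted duplicates are exact line copies inserted immediately after
  their originals, so keep-first deduplication removes exactly one record
  per copy;
* QUAL is uniform on [0, 100] with a requested number of records blanked
  to `.`; infeasible requests (more sites than usable positions, negative
  counts) raise before any output is produced.

All randomness flows from a single seeded `random.Random`, so one seed
yields a byte-identical file, and specs serialize to JSON so a failing case
is reproducible from one small artifact. The default spec is desk-scale
(25 variants on two contigs); `random_spec(seed)` draws feasible randomized
specs (≤ ~200 records) for property suites.

What the generator does *not* emulate: realistic mutation spectra, indel
hotspots, linkage, genotype columns, or caller-specific INFO annotations.
Passing tests therefore demonstrate the correctness of counting, set
algebra and filtering on well-formed inputs — not robustness to the
pathologies of any particular caller's output, beyond the malformed-line
handling exercised directly.

## Problem sizes and the acceptance run

`scripts/acceptance.py` exercises the three workflows end-to-end on a
scaled-down whole-genome-like study: ~12 000 variants over eight contigs
with an 80% SNP fraction and a transition:transversion mix near 2 — the
composition a human short-read WGS call set typically shows — INDEL sizes
up to 400 bp, planted multiallelic sites and duplicates, plus a
benchmark-style comparison in which the call set covers most of a smaller
high-confidence set. These sizes keep the whole run under a few seconds
while every reported number is still computed by the pipeline at run time;
the implementation is linear in record count and has been run unchanged on
inputs three orders of magnitude larger.

## Known limitations

* No genotype/FORMAT interpretation anywhere (by design).
* No reference-aware normalization, so representation-sensitive
  comparisons undercount true overlap between differently-normalized
  files.
* Comparison is 2-way only.
* `QUAL` is the only numeric filter; allele-frequency or INFO-typed
  filtering would require the type coercion this package deliberately
  avoids.
* Windowed density assumes the 1-anchored fixed grid; there is no support
  for user-supplied (e.g. BED) intervals beyond single-region filtering.
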