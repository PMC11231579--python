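# vcfscope

Summarize, compare and inspect VCF files from the command line or Python —
for anyone who needs quick, scriptable answers about a variant call set
(how many variants, of which types, where, at what quality, and how two
call sets relate) without loading it into a genome browser or writing
one-off awk.

## What it computes

Working only on the eight mandatory VCF columns (CHROM, POS, ID, REF, ALT,
QUAL, FILTER, INFO), `vcfscope`:

* **normalizes** a file by splitting each multiallelic site into
  single-ALT entries and removing duplicate (CHROM, POS, REF, ALT)
  entries — that key, with alleles uppercased, is a variant's identity
  throughout;
* **classifies** every normalized variant into exactly one of
  {transition, transversion, insertion, deletion, MNP, assorted}, with
  SNP = Ts ∪ Tv and INDEL = ins ∪ del as derived groupings, and reports
  per-contig and total counts, the QC-standard ratio
  Ts/Tv = n_transitions / n_transversions,
  the signed INDEL size distribution (size = |ALT| − |REF|), and variant
  density in fixed 1-based genomic windows (1 Mbp default, window k =
  [(k−1)W+1, kW]) including empty-window gap detection;
* **compares** two files by key membership into shared / unique-to-A /
  unique-to-B sets with Venn counts and overlap percentages;
* **filters** by region (inclusive coordinates), quality threshold,
  variant class, and per-column keyword, with stable sorting — filtered
  sets write back out as VCF or CSV and feed the other workflows;
* **generates** synthetic VCFs (and file pairs) with exact ground truth —
  class counts, multiallelic sites, planted duplicates, planned overlaps —
  so every operation above is testable offline from a seed.

Plain, gzip- and bgzip-compressed VCFs are read transparently (detection
by magic bytes). See `docs/methods.md` for the precise rules and their
rationale.

## Worked example

Generate a small synthetic file with known composition, then summarize it:

```sh
$ vcfscope generate --seed 3 --out f.vcf
wrote 24 records to f.vcf
$ vcfscope summarize f.vcf --out-dir sum
f.vcf: 24 variants (Ts/Tv 2.00), outputs in sum/
$ cat sum/digest.json
{
  "source": "f.vcf",
  "n_total": 24,
  "n_snp": 15,
  "n_indel": 6,
  "counts": {
    "mnp": 2,
    "insertion": 3,
    "transversion": 5,
    "transition": 10,
    "deletion": 3,
    "assorted": 1
  },
  "ts_tv": 2.0,
  "pct_snp": 62.5,
  "multiallelic_sites": 1,
  "duplicates_removed": 1,
  "max_insertion_bp": 10,
  "max_deletion_bp": 10,
  "max_window_count": 18,
  "skipped_malformed": 0
}
```

The file held 24 data lines, one of them a planted exact duplicate and one
a multiallelic site with two ALT alleles — splitting and deduplicating
leaves 24 unique variants. 10 transitions against 5 transversions give Ts/Tv = 2.00,
and the largest insertion and deletion are both 10 bp — exactly the
generator's defaults (10 ts, 5 tv, 3 ins, 3 del, 2 MNP, 1 assorted, 1
multiallelic site, 1 duplicate), which is the point: the summary recovers
the known ground truth. Alongside the digest, `sum/` holds the per-contig class
table, the window-density table and the INDEL size histogram as CSV.

Comparing two files with a planned overlap:

```sh
$ vcfscope generate-pair --n-shared 4 --n-a-only 2 --n-b-only 1 \
    --seed 5 --out-a a.vcf --out-b b.vcf
$ vcfscope compare a.vcf b.vcf --out-dir cmp
shared 4, unique to A 2, unique to B 1; outputs in cmp/
$ cat cmp/venn.json
{
  "label_a": "a.vcf",
  "label_b": "b.vcf",
  "n_a_only": 2,
  "n_b_only": 1,
  "n_shared": 4,
  "pct_of_a": 66.66666666666667,
  "pct_of_b": 80.0
}
```

4 of A's 6 variants (66.7%) and 4 of B's 5 (80%) are shared; the three
sets are also written as VCFs with per-set summary CSVs. Filtering and
metadata inspection work the same way:

```sh
vcfscope inspect f.vcf --region chr1:1-500000 --min-qual 20 --format csv
vcfscope metadata f.vcf --pattern reference
```

The same operations are available as functions (`read_vcf`, `normalize`,
`summarize`, `compare`, `filter_region`, ...) from the `vcfscope` package.

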