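"""Synthetic VCF generation with exact, machine-readable ground truth.

A :class:`FixtureSpec` states how many variants of each class a file should
contain, how many multiallelic sites, planted duplicate lines and missing
QUAL values, over which contigs — and :func:`generate_vcf` emits a valid
VCF whose normalize→summarize output reproduces those counts *exactly*.
That closure property is what makes every other module testable without
real data.

Construction rules that guarantee exactness:

* every site gets a position unique on its contig, so the only duplicate
  keys are the planted ones;
* a multiallelic site is one record with two SNP ALT alleles — one
  transition and one transversion of the same REF base (a single REF base
  admits exactly one transition, so a two-transition pair cannot exist) —
  and its two alleles are counted inside the transition/transversion
  budgets;
* planted duplicates are exact line copies of single-ALT records placed
  immediately after their originals, so each contributes exactly one
  removed record under keep-first deduplication.

The generator makes no attempt at biological realism: no mutation spectrum,
no linkage, no genotype columns.
"""

from __future__ import annotations

import dataclasses
import json
import random
from collections import Counter
from dataclasses import dataclass

from .io import FIXED_COLUMNS, MetaLine, VcfDataset, VcfRecord
from .model import VariantClass, classify
from .summarize import SummaryTable

__all__ = ["FixtureSpec", "InfeasibleSpec", "generate_vcf", "generate_pair", "random_spec"]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_BASES = "ACGT"
_SYMBOLIC_ALTS = ("<DEL>", "<INS>", "*", "N")


class InfeasibleSpec(ValueError):
    """The requested counts cannot be realised on the given contigs."""


@dataclass(frozen=True)
class FixtureSpec:
    """Exact recipe for one synthetic VCF.

    Counts are post-normalization class counts; the two alleles of each
    multiallelic site are drawn from the transition and transversion
    budgets, so ``n_transition >= n_multiallelic_sites`` and
    ``n_transversion >= n_multiallelic_sites`` are required.
    """

    contigs: tuple[tuple[str, int], ...] = (("chr1", 1_000_000), ("chr2", 800_000))
    n_transition: int = 10
    n_transversion: int = 5
    n_insertion: int = 3
    n_deletion: int = 3
    n_mnp: int = 2
    n_assorted: int = 1
    n_multiallelic_sites: int = 1
    n_duplicate_records: int = 1
    n_missing_qual: int = 1
    indel_size_range: tuple[int, int] = (1, 10)
    seed: int = 0

    def class_counts(self) -> dict[VariantClass, int]:
        return {
            VariantClass.TRANSITION: self.n_transition,
            VariantClass.TRANSVERSION: self.n_transversion,
            VariantClass.INSERTION: self.n_insertion,
            VariantClass.DELETION: self.n_deletion,
            VariantClass.MNP: self.n_mnp,
            VariantClass.ASSORTED: self.n_assorted,
        }

    @property
    def n_variants(self) -> int:
        """Normalized record count the generated file must produce."""
        return sum(self.class_counts().values())

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["contigs"] = [list(c) for c in self.contigs]
        d["indel_size_range"] = list(self.indel_size_range)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        d = json.loads(text)
        d["contigs"] = tuple((str(n), int(l)) for n, l in d["contigs"])
        d["indel_size_range"] = tuple(d["indel_size_range"])
        return cls(**d)

    def validate(self) -> None:
        counts = list(self.class_counts().values()) + [
            self.n_multiallelic_sites,
            self.n_duplicate_records,
            self.n_missing_qual,
        ]
        if any(c < 0 for c in counts):
            raise InfeasibleSpec("all counts must be >= 0")
        if not self.contigs:
            raise InfeasibleSpec("at least one contig is required")
        if self.n_multiallelic_sites > min(self.n_transition, self.n_transversion):
            raise InfeasibleSpec(
                "each multiallelic site consumes one transition and one "
                "transversion; increase those counts or reduce "
                "n_multiallelic_sites"
            )
        lo, hi = self.indel_size_range
        if not (1 <= lo <= hi):
            raise InfeasibleSpec("indel_size_range must satisfy 1 <= lo <= hi")


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _plan_sites(spec: FixtureSpec, rng: random.Random):
    """Yield (ref, alts) tuples for every site, classes in shuffled order."""
    sites: list[tuple[str, tuple[str, ...]]] = []
    lo, hi = spec.indel_size_range
    for _ in range(spec.n_multiallelic_sites):
        ref = rng.choice(_BASES)
        sites.append((ref, (_TRANSITION[ref], rng.choice(_TRANSVERSIONS[ref]))))
    for _ in range(spec.n_transition - spec.n_multiallelic_sites):
        ref = rng.choice(_BASES)
        sites.append((ref, (_TRANSITION[ref],)))
    for _ in range(spec.n_transversion - spec.n_multiallelic_sites):
        ref = rng.choice(_BASES)
        sites.append((ref, (rng.choice(_TRANSVERSIONS[ref]),)))
    for _ in range(spec.n_insertion):
        ref = rng.choice(_BASES)
        sites.append((ref, (ref + _random_seq(rng, rng.randint(lo, hi)),)))
    for _ in range(spec.n_deletion):
        alt = rng.choice(_BASES)
        sites.append((alt + _random_seq(rng, rng.randint(lo, hi)), (alt,)))
    for _ in range(spec.n_mnp):
        n = rng.randint(2, 4)
        ref = _random_seq(rng, n)
        alt = "".join(rng.choice([b for b in _BASES if b != r]) for r in ref)
        sites.append((ref, (alt,)))
    for _ in range(spec.n_assorted):
        sites.append((rng.choice(_BASES), (rng.choice(_SYMBOLIC_ALTS),)))
    rng.shuffle(sites)
    return sites


def generate_vcf(spec: FixtureSpec) -> tuple[VcfDataset, SummaryTable]:
    """Emit a synthetic VCF dataset and the summary it must normalize to.

    Deterministic: the same spec (seed included) produces a byte-identical
    file when written.  Raises :class:`InfeasibleSpec` when the requested
    site count does not fit on the contigs.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    sites = _plan_sites(spec, rng)

    # positions must leave room for the longest REF allele
    margin = max(spec.indel_size_range[1] + 1, 4)
    placements: dict[str, list[int]] = {name: [] for name, _ in spec.contigs}
    contig_names = [name for name, _ in spec.contigs]
    assignment = [rng.choice(contig_names) for _ in sites]
    per_contig_n = {name: assignment.count(name) for name in contig_names}
    for name, length in spec.contigs:
        avail = length - margin
        if per_contig_n[name] > max(avail, 0):
            raise InfeasibleSpec(
                f"{per_contig_n[name]} sites assigned to {name} but only "
                f"{max(avail, 0)} usable positions"
            )
        placements[name] = sorted(rng.sample(range(1, avail + 1), per_contig_n[name]))

    # reference-ordered records: contigs in spec order, positions ascending
    by_contig: dict[str, list[tuple[str, tuple[str, ...]]]] = {
        name: [] for name in contig_names
    }
    for contig, site in zip(assignment, sites):
        by_contig[contig].append(site)

    records: list[VcfRecord] = []
    truth_per_contig: dict[str, Counter] = {}
    for name, _ in spec.contigs:
        counter: Counter = Counter()
        for pos, (ref, alts) in zip(placements[name], by_contig[name]):
            qual = round(rng.uniform(0.0, 100.0), 1)
            records.append(
                VcfRecord(
                    chrom=name,
                    pos=pos,
                    id=".",
                    ref=ref,
                    alt=alts,
                    qual=qual,
                    filter="PASS",
                    info=".",
                )
            )
            for alt in alts:
                counter[classify(ref, alt)] += 1
        if counter:
            truth_per_contig[name] = counter

    # blank out QUAL on a deterministic subset
    if spec.n_missing_qual > len(records):
        raise InfeasibleSpec("n_missing_qual exceeds the number of records")
    for idx in rng.sample(range(len(records)), spec.n_missing_qual):
        records[idx] = dataclasses.replace(records[idx], qual=None)

    # plant duplicates: exact copies of single-ALT records, right after the
    # originals, so keep-first dedup removes exactly one per copy
    if spec.n_duplicate_records:
        single_alt_idx = [i for i, r in enumerate(records) if len(r.alt) == 1]
        if not single_alt_idx:
            raise InfeasibleSpec(
                "duplicates require at least one single-ALT record"
            )
        chosen = [rng.choice(single_alt_idx) for _ in range(spec.n_duplicate_records)]
        for i in sorted(chosen, reverse=True):
            records.insert(i + 1, records[i])

    meta = [
        MetaLine.parse("##fileformat=VCFv4.2"),
        MetaLine.parse("##source=vcfscope-fixtures"),
        MetaLine.parse("##reference=synthetic-genome"),
        MetaLine.parse(f"##vcfscope_fixture_seed={spec.seed}"),
    ] + [
        MetaLine.parse(f"##contig=<ID={name},length={length}>")
        for name, length in spec.contigs
    ]
    dataset = VcfDataset(
        meta=meta,
        header_cols=list(FIXED_COLUMNS),
        records=records,
        source_name=f"fixture-seed{spec.seed}",
    )
    truth = SummaryTable(
        per_contig={k: Counter(v) for k, v in truth_per_contig.items()},
        totals=sum((Counter(v) for v in truth_per_contig.values()), Counter()),
        n_multiallelic_sites=spec.n_multiallelic_sites,
        n_duplicates_removed=spec.n_duplicate_records,
        source_name=dataset.source_name,
    )
    return dataset, truth


def generate_pair(
    n_shared: int,
    n_a_only: int,
    n_b_only: int,
    seed: int = 0,
    contig: str = "chr1",
    contig_length: int = 1_000_000,
) -> tuple[VcfDataset, VcfDataset, tuple[int, int, int]]:
    """Two SNP-only datasets with an exact planned overlap.

    Comparison of the two (after normalization) yields precisely
    ``(n_a_only, n_b_only, n_shared)``.
    """
    if min(n_shared, n_a_only, n_b_only) < 0:
        raise InfeasibleSpec("pair counts must be >= 0")
    total = n_shared + n_a_only + n_b_only
    if total > contig_length - 1:
        raise InfeasibleSpec(f"{total} distinct sites do not fit on {contig}")
    rng = random.Random(seed)
    positions = rng.sample(range(1, contig_length), total)

    def snp_at(pos: int) -> VcfRecord:
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        return VcfRecord(
            chrom=contig,
            pos=pos,
            id=".",
            ref=ref,
            alt=(alt,),
            qual=round(rng.uniform(0.0, 100.0), 1),
            filter="PASS",
            info=".",
        )

    all_records = [snp_at(p) for p in positions]
    shared = all_records[:n_shared]
    a_only = all_records[n_shared : n_shared + n_a_only]
    b_only = all_records[n_shared + n_a_only :]

    meta = [
        MetaLine.parse("##fileformat=VCFv4.2"),
        MetaLine.parse("##source=vcfscope-fixtures"),
        MetaLine.parse(f"##contig=<ID={contig},length={contig_length}>"),
    ]

    def build(records: list[VcfRecord], name: str) -> VcfDataset:
        return VcfDataset(
            meta=list(meta),
            header_cols=list(FIXED_COLUMNS),
            records=sorted(records, key=lambda r: r.pos),
            source_name=name,
        )

    return (
        build(shared + a_only, f"pair-A-seed{seed}"),
        build(shared + b_only, f"pair-B-seed{seed}"),
        (n_a_only, n_b_only, n_shared),
    )


def random_spec(seed: int, max_records: int = 200) -> FixtureSpec:
    """A randomized feasible spec, for property suites.

    ``seed`` fully determines the spec; generated counts stay small enough
    that a brute-force oracle over the emitted file is instant.
    """
    rng = random.Random(seed)
    n_multi = rng.randint(0, 5)
    n_ts = rng.randint(n_multi, max_records // 4)
    n_tv = rng.randint(n_multi, max_records // 4)
    n_ins = rng.randint(0, max_records // 8)
    n_del = rng.randint(0, max_records // 8)
    n_mnp = rng.randint(0, max_records // 10)
    n_assorted = rng.randint(0, max_records // 10)
    n_sites = n_ts + n_tv + n_ins + n_del + n_mnp + n_assorted
    n_records = n_sites - n_multi  # one record per multiallelic pair
    n_single_alt = n_sites - 2 * n_multi
    lo = rng.randint(1, 3)
    return FixtureSpec(
        contigs=(
            ("chr1", rng.randint(50_000, 2_000_000)),
            ("chr2", rng.randint(50_000, 1_000_000)),
            ("chrX", rng.randint(50_000, 500_000)),
        ),
        n_transition=n_ts,
        n_transversion=n_tv,
        n_insertion=n_ins,
        n_deletion=n_del,
        n_mnp=n_mnp,
        n_assorted=n_assorted,
        n_multiallelic_sites=n_multi,
        n_duplicate_records=rng.randint(0, 5) if n_single_alt > 0 else 0,
        n_missing_qual=rng.randint(0, min(3, n_records)),
        indel_size_range=(lo, rng.randint(lo, 25)),
        seed=rng.randrange(2**31),
    )
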