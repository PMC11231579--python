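"""Normalization and variant-type classification.

Normalization here means two things only: splitting comma-separated
multiallelic sites into single-ALT entries, and removing duplicate
(CHROM, POS, REF, ALT) entries.  No left-alignment or allele trimming
against a reference is attempted — representation-level normalization in
the ``bcftools norm`` sense is explicitly out of scope.

Each normalized record is assigned exactly one class from the taxonomy
{transition, transversion, insertion, deletion, MNP, assorted}; SNP and
INDEL are derived groupings (SNP = transitions + transversions, INDEL =
insertions + deletions).  Multiallelic is a site-level property counted
before splitting, not a per-variant class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

from .io import MetaLine, VcfDataset, VcfRecord

__all__ = [
    "VariantClass",
    "VariantKey",
    "NormalizedRecord",
    "NormalizedDataset",
    "MalformedAllele",
    "ContractViolation",
    "classify",
    "indel_size",
    "split_multiallelic",
    "deduplicate",
    "normalize",
]


class MalformedAllele(ValueError):
    """REF or ALT allele is empty where a base string is required."""


class ContractViolation(ValueError):
    """An operation was called outside its stated precondition."""


class VariantClass(str, Enum):
    """Exclusive per-variant classes.

    The two SNP subclasses follow the standard definitions: a transition
    swaps within the purines (A<->G) or within the pyrimidines (C<->T); a
    transversion swaps between the two groups.
    """

    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    INSERTION = "insertion"
    DELETION = "deletion"
    MNP = "mnp"
    ASSORTED = "assorted"

    @classmethod
    def expand(cls, names: Iterable[str]) -> "set[VariantClass]":
        """Resolve class names, accepting the groupings SNP and INDEL.

        Raises ``ValueError`` listing valid names on an unknown name.
        """
        out: set[VariantClass] = set()
        for name in names:
            low = str(name).lower()
            if low == "snp":
                out |= {cls.TRANSITION, cls.TRANSVERSION}
            elif low == "indel":
                out |= {cls.INSERTION, cls.DELETION}
            else:
                try:
                    out.add(cls(low))
                except ValueError:
                    valid = [c.value for c in cls] + ["snp", "indel"]
                    raise ValueError(
                        f"unknown variant class {name!r}; valid names: {valid}"
                    ) from None
        return out


SNP_CLASSES = frozenset({VariantClass.TRANSITION, VariantClass.TRANSVERSION})
INDEL_CLASSES = frozenset({VariantClass.INSERTION, VariantClass.DELETION})

_BASES = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a normalized variant: (contig, position, REF, one ALT).

    Alleles are uppercased so identity is case-insensitive.  This key —
    and nothing else (not ID, QUAL, FILTER or INFO) — drives both
    deduplication and pairwise comparison.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if "," in self.alt:
            raise ValueError("VariantKey.alt must be a single allele")

    @classmethod
    def of(cls, record: VcfRecord) -> "VariantKey":
        if len(record.alt) != 1:
            raise ContractViolation(
                "VariantKey requires a single-ALT record; split multiallelics first"
            )
        return cls(record.chrom, record.pos, record.ref.upper(), record.alt[0].upper())


def _is_symbolic(alt: str) -> bool:
    return (
        alt.startswith("<")
        or "[" in alt
        or "]" in alt
        or alt in ("*", ".")
    )


def classify(ref: str, alt: str) -> VariantClass:
    """Classify a single REF/ALT allele pair.

    Rule ladder, applied to uppercased alleles:

    1. symbolic ALT (``<...>``, breakend, ``*``, ``.``) or any non-ACGT
       character (including N) in either allele -> ASSORTED;
    2. both length 1 -> transition or transversion;
    3. equal lengths (> 1) -> MNP;
    4. unequal lengths -> insertion if ALT is longer, else deletion.

    No prefix relationship between the alleles is required for INDELs.
    """
    if not ref or not alt:
        raise MalformedAllele("REF and ALT must be non-empty")
    ref = ref.upper()
    alt = alt.upper()
    if _is_symbolic(alt) or not (_BASES.issuperset(ref) and _BASES.issuperset(alt)):
        return VariantClass.ASSORTED
    if len(ref) == 1 and len(alt) == 1:
        pair = {ref, alt}
        if pair <= _PURINES or pair <= _PYRIMIDINES:
            return VariantClass.TRANSITION
        return VariantClass.TRANSVERSION
    if len(ref) == len(alt):
        return VariantClass.MNP
    return VariantClass.INSERTION if len(alt) > len(ref) else VariantClass.DELETION


def indel_size(ref: str, alt: str) -> int:
    """Signed INDEL length in bp: ``len(alt) - len(ref)``.

    Positive for insertions, negative for deletions.  Calling this on a
    pair that does not classify as an INDEL raises
    :class:`ContractViolation`.
    """
    if classify(ref, alt) not in INDEL_CLASSES:
        raise ContractViolation(
            f"indel_size is defined only for insertions/deletions, "
            f"got {classify(ref, alt).value} for ({ref!r}, {alt!r})"
        )
    return len(alt) - len(ref)


@dataclass(frozen=True)
class NormalizedRecord:
    """A single-ALT record with its identity key and class."""

    record: VcfRecord
    key: VariantKey
    variant_class: VariantClass
    from_multiallelic: bool = False


@dataclass
class NormalizedDataset:
    """Result of normalization: unique single-ALT records, classified.

    ``n_multiallelic_sites`` counts input records that carried >= 2 ALT
    alleles (before splitting); ``n_duplicates_removed`` counts records
    dropped because an earlier record shared their key.
    """

    meta: list[MetaLine] = field(default_factory=list)
    header_cols: list[str] = field(default_factory=list)
    records: list[NormalizedRecord] = field(default_factory=list)
    source_name: str = ""
    n_multiallelic_sites: int = 0
    n_duplicates_removed: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[NormalizedRecord]:
        return iter(self.records)

    def keys(self) -> list[VariantKey]:
        return [r.key for r in self.records]

    def key_set(self) -> set[VariantKey]:
        return {r.key for r in self.records}

    def to_vcf_dataset(self) -> VcfDataset:
        """View as a plain dataset of split records, writable via write_vcf."""
        return VcfDataset(
            meta=list(self.meta),
            header_cols=list(self.header_cols),
            records=[r.record for r in self.records],
            source_name=self.source_name,
        )

    def replace_records(
        self, records: Iterable[NormalizedRecord]
    ) -> "NormalizedDataset":
        return NormalizedDataset(
            meta=list(self.meta),
            header_cols=list(self.header_cols),
            records=list(records),
            source_name=self.source_name,
            n_multiallelic_sites=self.n_multiallelic_sites,
            n_duplicates_removed=self.n_duplicates_removed,
        )


def split_multiallelic(
    dataset: VcfDataset,
) -> tuple[list[tuple[VcfRecord, bool]], int]:
    """Break multiallelic sites into one record per ALT allele.

    Returns the split records (paired with a came-from-multiallelic flag) in
    input order, allele order preserved within a site, plus the number of
    multiallelic input sites.  All columns other than ALT are copied
    verbatim onto each split record.
    """
    out: list[tuple[VcfRecord, bool]] = []
    n_multi = 0
    for rec in dataset.records:
        multi = len(rec.alt) > 1
        if multi:
            n_multi += 1
        for allele in rec.alt:
            out.append((rec.with_alt(allele), multi))
    return out, n_multi


def deduplicate(
    split_records: Sequence[tuple[VcfRecord, bool]],
) -> tuple[list[tuple[VcfRecord, bool]], int]:
    """Drop records whose key repeats an earlier one (keep first occurrence).

    The key is (CHROM, POS, REF, ALT) only; records agreeing on the key but
    differing in ID/QUAL/FILTER/INFO are still duplicates.
    """
    seen: set[VariantKey] = set()
    kept: list[tuple[VcfRecord, bool]] = []
    removed = 0
    for rec, flag in split_records:
        key = VariantKey.of(rec)
        if key in seen:
            removed += 1
            continue
        seen.add(key)
        kept.append((rec, flag))
    return kept, removed


def normalize(dataset: VcfDataset) -> NormalizedDataset:
    """Split multiallelic sites, deduplicate, and classify every survivor."""
    split, n_multi = split_multiallelic(dataset)
    kept, n_removed = deduplicate(split)
    records = [
        NormalizedRecord(
            record=rec,
            key=VariantKey.of(rec),
            variant_class=classify(rec.ref, rec.alt[0]),
            from_multiallelic=flag,
        )
        for rec, flag in kept
    ]
    return NormalizedDataset(
        meta=list(dataset.meta),
        header_cols=list(dataset.header_cols),
        records=records,
        source_name=dataset.source_name,
        n_multiallelic_sites=n_multi,
        n_duplicates_removed=n_removed,
    )
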