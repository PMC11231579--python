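"""Record-level filtering, keyword search and sorting.

Every operation is an order-preserving subset (or stable reordering) and
works on either a raw :class:`~vcfscope.io.VcfDataset` or a
:class:`~vcfscope.model.NormalizedDataset`; only class filtering requires
the normalized form, since it needs each record classified.
"""

from __future__ import annotations

import re
from typing import Iterable, Union

from .io import FIXED_COLUMNS, VcfDataset, VcfRecord
from .model import NormalizedDataset, NormalizedRecord, VariantClass

__all__ = [
    "InvalidInterval",
    "filter_region",
    "filter_qual",
    "filter_class",
    "search_keyword",
    "sort_records",
]

Dataset = Union[VcfDataset, NormalizedDataset]


class InvalidInterval(ValueError):
    """Region start exceeds region end."""


def _vcf_record(item) -> VcfRecord:
    return item.record if isinstance(item, NormalizedRecord) else item


def _filtered(dataset: Dataset, predicate) -> Dataset:
    return dataset.replace_records(
        item for item in dataset.records if predicate(_vcf_record(item))
    )


def filter_region(dataset: Dataset, contig: str, start: int, end: int) -> Dataset:
    """Records on ``contig`` with ``start <= POS <= end`` (1-based, both ends
    inclusive), order preserved."""
    if start > end:
        raise InvalidInterval(f"region start {start} exceeds end {end}")
    return _filtered(
        dataset, lambda r: r.chrom == contig and start <= r.pos <= end
    )


def filter_qual(
    dataset: Dataset, min_qual: float, keep_missing: bool = False
) -> Dataset:
    """Records with ``QUAL >= min_qual``.

    Records with the missing value ``.`` are dropped unless
    ``keep_missing`` — a missing score is not evidence of quality.
    """

    def pred(r: VcfRecord) -> bool:
        if r.qual is None:
            return keep_missing
        return r.qual >= min_qual

    return _filtered(dataset, pred)


def filter_class(
    normalized: NormalizedDataset, classes: Iterable[Union[VariantClass, str]]
) -> NormalizedDataset:
    """Records whose class is in ``classes``.

    Accepts class names or enum members; the grouping names ``snp`` and
    ``indel`` expand to their member classes.  Unknown names raise with the
    list of valid ones.
    """
    wanted = VariantClass.expand(
        c.value if isinstance(c, VariantClass) else c for c in classes
    )
    return normalized.replace_records(
        nr for nr in normalized.records if nr.variant_class in wanted
    )


def _column_text(record: VcfRecord, column: str) -> str:
    if column == "CHROM":
        return record.chrom
    if column == "POS":
        return str(record.pos)
    if column == "ID":
        return record.id
    if column == "REF":
        return record.ref
    if column == "ALT":
        return record.alt_string
    if column == "QUAL":
        return record.qual_string
    if column == "FILTER":
        return record.filter
    if column == "INFO":
        return record.info
    raise AssertionError(column)


def search_keyword(
    dataset: Dataset,
    column: str,
    pattern: str,
    case_insensitive: bool = True,
    regex: bool = False,
) -> Dataset:
    """Substring (or, opted in, regex) match on one of the eight fixed columns.

    The match runs over the column's verbatim text — INFO as its raw
    semicolon-separated string — so annotation-based extraction is a plain
    search for e.g. ``ANN=``.  An empty pattern matches everything.
    """
    col = column.upper().lstrip("#")
    if col not in FIXED_COLUMNS:
        raise ValueError(
            f"unknown column {column!r}; valid columns: {list(FIXED_COLUMNS)}"
        )
    if regex:
        flags = re.IGNORECASE if case_insensitive else 0
        compiled = re.compile(pattern, flags)
        return _filtered(
            dataset, lambda r: compiled.search(_column_text(r, col)) is not None
        )
    needle = pattern.lower() if case_insensitive else pattern

    def pred(r: VcfRecord) -> bool:
        text = _column_text(r, col)
        if case_insensitive:
            text = text.lower()
        return needle in text

    return _filtered(dataset, pred)


def sort_records(dataset: Dataset, by: str = "POS", descending: bool = False) -> Dataset:
    """Stable sort by POS or QUAL; ties keep input order.

    A missing QUAL sorts after every real score regardless of direction, so
    it can never masquerade as the best or the worst variant.
    """
    key_col = by.upper()
    if key_col not in ("POS", "QUAL"):
        raise ValueError(f"sort key must be POS or QUAL, got {by!r}")
    items = list(dataset.records)
    if key_col == "POS":
        items.sort(key=lambda it: _vcf_record(it).pos, reverse=descending)
    else:
        present = [it for it in items if _vcf_record(it).qual is not None]
        missing = [it for it in items if _vcf_record(it).qual is None]
        present.sort(key=lambda it: _vcf_record(it).qual, reverse=descending)
        items = present + missing
    return dataset.replace_records(items)
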