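"""Read and write VCF (plain, gzip or bgzip) and CSV at the 8-column level.

The reader is deliberately literal: the eight fixed columns are parsed,
everything after them (FORMAT and sample columns) is carried verbatim, and
INFO is kept as its raw string so that a read→write→read round trip is
field-identical.  Compression is detected from the gzip magic bytes, never
from the file extension; bgzip output is a valid gzip stream and is read the
same way.  No index files are required or produced.
"""

from __future__ import annotations

import gzip
import io as _stdio
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "MetaLine",
    "VcfRecord",
    "VcfDataset",
    "VcfError",
    "MissingHeader",
    "MalformedRecord",
    "FIXED_COLUMNS",
    "read_vcf",
    "write_vcf",
    "write_csv",
    "extract_metadata",
]

#: The eight mandatory VCF columns, in file order.
FIXED_COLUMNS = ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO")

_GZIP_MAGIC = b"\x1f\x8b"


class VcfError(ValueError):
    """Base class for VCF parsing failures."""


class MissingHeader(VcfError):
    """The file contains no ``#CHROM`` header line."""


class MalformedRecord(VcfError):
    """A data line that cannot be interpreted as a VCF record.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


_STRUCTURED_META = re.compile(r"^##(?P<key>[^=]+)=<(?P<body>.*)>\s*$")
_PLAIN_META = re.compile(r"^##(?P<key>[^=]+)=(?P<value>.*)$")
_META_ID = re.compile(r"(?:^|,)ID=([^,>]+)")
_META_DESC = re.compile(r'Description="((?:[^"\\]|\\.)*)"')


@dataclass(frozen=True)
class MetaLine:
    """One ``##`` meta-information line.

    ``key`` is the part between ``##`` and the first ``=``; structured lines
    (INFO, FORMAT, FILTER, ALT, contig, ...) additionally expose their
    ``ID=`` and ``Description=`` fields.  ``raw_text`` is the verbatim line.
    """

    raw_text: str
    key: str
    entry_id: str | None = None
    description: str | None = None

    @classmethod
    def parse(cls, line: str) -> "MetaLine":
        line = line.rstrip("\r\n")
        m = _STRUCTURED_META.match(line)
        if m:
            body = m.group("body")
            mid = _META_ID.search(body)
            mdesc = _META_DESC.search(body)
            return cls(
                raw_text=line,
                key=m.group("key"),
                entry_id=mid.group(1) if mid else None,
                description=mdesc.group(1) if mdesc else None,
            )
        m = _PLAIN_META.match(line)
        if m:
            return cls(raw_text=line, key=m.group("key"))
        # "##something" with no "=" — keep it, keyed by its own text
        return cls(raw_text=line, key=line[2:])


@dataclass(frozen=True)
class VcfRecord:
    """One data line: the eight fixed columns plus verbatim trailing columns.

    ``alt`` holds the comma-separated ALT alleles already split; ``qual`` is
    ``None`` for the missing value ``"."`` (never coerced to 0); ``info`` is
    the raw INFO string.  ``trailing_cols`` are the FORMAT and sample columns,
    untouched.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: tuple[str, ...]
    qual: float | None
    filter: str
    info: str
    trailing_cols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"POS must be >= 1, got {self.pos}")
        if not self.alt:
            raise ValueError("ALT must hold at least one allele")
        if self.qual is not None and self.qual < 0:
            raise ValueError(f"QUAL must be missing or >= 0, got {self.qual}")

    @property
    def alt_string(self) -> str:
        return ",".join(self.alt)

    @property
    def qual_string(self) -> str:
        if self.qual is None:
            return "."
        return f"{self.qual:g}"

    def info_pairs(self) -> list[tuple[str, str | None]]:
        """Split INFO on ``;`` / ``=`` into ordered (key, value) pairs.

        Flag keys map to ``None``.  Purely lexical — no type coercion against
        the meta declarations.
        """
        pairs: list[tuple[str, str | None]] = []
        if self.info in (".", ""):
            return pairs
        for item in self.info.split(";"):
            if "=" in item:
                k, _, v = item.partition("=")
                pairs.append((k, v))
            else:
                pairs.append((item, None))
        return pairs

    def to_line(self) -> str:
        fields = [
            self.chrom,
            str(self.pos),
            self.id,
            self.ref,
            self.alt_string,
            self.qual_string,
            self.filter,
            self.info,
            *self.trailing_cols,
        ]
        return "\t".join(fields)

    def with_alt(self, alt: str) -> "VcfRecord":
        """Copy of this record with a single ALT allele."""
        return replace(self, alt=(alt,))


@dataclass
class VcfDataset:
    """A parsed VCF: meta lines, header columns and ordered records."""

    meta: list[MetaLine] = field(default_factory=list)
    header_cols: list[str] = field(default_factory=lambda: list(FIXED_COLUMNS))
    records: list[VcfRecord] = field(default_factory=list)
    source_name: str = ""
    n_skipped: int = 0  # malformed lines dropped in permissive mode

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VcfRecord]:
        return iter(self.records)

    def replace_records(self, records: Iterable[VcfRecord]) -> "VcfDataset":
        """Same metadata and header, different record list."""
        return VcfDataset(
            meta=list(self.meta),
            header_cols=list(self.header_cols),
            records=list(records),
            source_name=self.source_name,
            n_skipped=self.n_skipped,
        )


def _open_text(path_or_stream) -> IO[str]:
    """Open a path or binary/text stream as text, decompressing gzip/bgzip.

    Compression is recognised by the two gzip magic bytes, so plain files
    with a ``.gz`` name and compressed files without one both work.
    """
    if hasattr(path_or_stream, "read"):
        stream = path_or_stream
        sample = stream.read(2)
        if isinstance(sample, str):  # already a text stream
            buf = _stdio.StringIO(sample + stream.read())
            return buf
        data = sample + stream.read()
        if data[:2] == _GZIP_MAGIC:
            data = gzip.decompress(data)
        return _stdio.StringIO(data.decode("utf-8"))
    path = Path(path_or_stream)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def parse_record(line: str, line_number: int = 0) -> VcfRecord:
    """Parse a single data line into a :class:`VcfRecord`.

    Raises :class:`MalformedRecord` when fewer than eight tab-separated
    fields are present or POS is not a positive integer.
    """
    fields_ = line.rstrip("\r\n").split("\t")
    if len(fields_) < 8:
        raise MalformedRecord(
            f"expected >= 8 tab-separated fields, found {len(fields_)}",
            line_number,
        )
    chrom, pos_s, rid, ref, alt_s, qual_s, filt, info = fields_[:8]
    try:
        pos = int(pos_s)
    except ValueError:
        raise MalformedRecord(f"POS {pos_s!r} is not an integer", line_number) from None
    if pos < 1:
        raise MalformedRecord(f"POS must be positive, got {pos}", line_number)
    if qual_s == ".":
        qual: float | None = None
    else:
        try:
            qual = float(qual_s)
        except ValueError:
            raise MalformedRecord(
                f"QUAL {qual_s!r} is neither '.' nor a number", line_number
            ) from None
        if qual < 0:
            raise MalformedRecord(f"QUAL must be >= 0, got {qual}", line_number)
    if not ref or not alt_s:
        raise MalformedRecord("REF and ALT must be non-empty", line_number)
    return VcfRecord(
        chrom=chrom,
        pos=pos,
        id=rid,
        ref=ref,
        alt=tuple(alt_s.split(",")),
        qual=qual,
        filter=filt,
        info=info,
        trailing_cols=tuple(fields_[8:]),
    )


def read_vcf(path_or_stream, *, skip_malformed: bool = False) -> VcfDataset:
    """Read a VCF from a path or stream into a :class:`VcfDataset`.

    Plain, gzip- and bgzip-compressed inputs are accepted; compression is
    auto-detected from magic bytes.  Record order is preserved and trailing
    columns are kept verbatim.

    Parameters
    ----------
    path_or_stream
        Filesystem path, or an open binary/text stream.
    skip_malformed
        When false (default) a malformed data line aborts the read with
        :class:`MalformedRecord` naming its line number.  When true such
        lines are skipped and counted in ``dataset.n_skipped``.
    """
    name = ""
    if not hasattr(path_or_stream, "read"):
        name = Path(path_or_stream).name
    meta: list[MetaLine] = []
    header_cols: list[str] | None = None
    records: list[VcfRecord] = []
    n_skipped = 0
    with _open_text(path_or_stream) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                meta.append(MetaLine.parse(line))
                continue
            if line.startswith("#"):
                header_cols = line.rstrip("\r\n").lstrip("#").split("\t")
                continue
            if not line.strip():
                continue
            if header_cols is None:
                raise MissingHeader(
                    f"data line {lineno} appears before any #CHROM header"
                )
            try:
                records.append(parse_record(line, lineno))
            except MalformedRecord:
                if not skip_malformed:
                    raise
                n_skipped += 1
    if header_cols is None:
        raise MissingHeader("no #CHROM header line found")
    return VcfDataset(
        meta=meta,
        header_cols=header_cols,
        records=records,
        source_name=name,
        n_skipped=n_skipped,
    )


def write_vcf(dataset: VcfDataset, path) -> None:
    """Write ``dataset`` as a plain-text VCF.

    ``read_vcf(write_vcf(d))`` is field-identical to ``d`` on the eight fixed
    columns and the trailing columns.
    """
    path = Path(path)
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        for m in dataset.meta:
            fh.write(m.raw_text + "\n")
        fh.write("#" + "\t".join(dataset.header_cols) + "\n")
        for rec in dataset.records:
            fh.write(rec.to_line() + "\n")


def write_csv(table: pd.DataFrame, path) -> None:
    """Write a tabular result as RFC-4180-style CSV with a header row."""
    table.to_csv(path, index=False)


def extract_metadata(dataset: VcfDataset) -> pd.DataFrame:
    """Tabulate the ``##`` meta lines, one row per line in file order.

    Columns: ``key``, ``entry_id``, ``description``, ``raw_text``.  The
    table is plain strings (missing entries are NA) so any substring search
    can run over any column.
    """
    rows = [
        {
            "key": m.key,
            "entry_id": m.entry_id,
            "description": m.description,
            "raw_text": m.raw_text,
        }
        for m in dataset.meta
    ]
    return pd.DataFrame(rows, columns=["key", "entry_id", "description", "raw_text"])


def search_metadata(dataset: VcfDataset, pattern: str) -> pd.DataFrame:
    """Rows of :func:`extract_metadata` where any column contains ``pattern``.

    Case-insensitive substring match; an empty pattern returns everything.
    """
    table = extract_metadata(dataset)
    if not pattern or table.empty:
        return table
    low = pattern.lower()
    mask = table.apply(
        lambda row: any(low in str(v).lower() for v in row if v is not None),
        axis=1,
    )
    return table[mask].reset_index(drop=True)
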