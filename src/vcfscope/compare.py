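"""Pairwise comparison of two normalized variant sets.

Membership is decided purely by the variant key (contig, position, REF,
single ALT): ID, QUAL, FILTER and INFO never affect it.  The result
partitions each input into a shared set and a unique set, with the three
Venn counts and the percentage of each file that is shared.  Shared records
carry file A's columns, so provenance of annotations is deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import pandas as pd

from .model import NormalizedDataset, NormalizedRecord, VariantKey
from .summarize import SummaryTable, summarize

__all__ = ["ComparisonResult", "compare", "venn_counts"]


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def _match_key(key: VariantKey, harmonize: bool) -> VariantKey:
    if not harmonize:
        return key
    return VariantKey(_strip_chr(key.chrom), key.pos, key.ref, key.alt)


@dataclass
class ComparisonResult:
    """Shared / unique-to-A / unique-to-B sets with Venn counts.

    Invariants: ``n_a_only + n_shared == |A|``, ``n_b_only + n_shared ==
    |B|``, and the three key sets are pairwise disjoint.  ``pct_of_a`` /
    ``pct_of_b`` are the shared count as a percentage of each input
    (``None`` for an empty input).
    """

    shared: NormalizedDataset
    unique_a: NormalizedDataset
    unique_b: NormalizedDataset
    n_a_only: int
    n_b_only: int
    n_shared: int
    label_a: str
    label_b: str

    @property
    def venn(self) -> tuple[int, int, int]:
        return (self.n_a_only, self.n_b_only, self.n_shared)

    @property
    def pct_of_a(self) -> float | None:
        n_a = self.n_a_only + self.n_shared
        return 100.0 * self.n_shared / n_a if n_a else None

    @property
    def pct_of_b(self) -> float | None:
        n_b = self.n_b_only + self.n_shared
        return 100.0 * self.n_shared / n_b if n_b else None

    def summaries(self) -> dict[str, SummaryTable]:
        return {
            "shared": summarize(self.shared),
            "unique_a": summarize(self.unique_a),
            "unique_b": summarize(self.unique_b),
        }


def compare(
    a: NormalizedDataset,
    b: NormalizedDataset,
    harmonize_chr_prefix: bool = False,
) -> ComparisonResult:
    """Intersect two normalized datasets by variant key.

    With ``harmonize_chr_prefix`` a leading ``chr`` is ignored when matching
    contig names (records keep their original spelling).  The default is an
    exact string match; when the two contig vocabularies are disjoint a
    ``UserWarning`` flags the likely prefix mismatch instead of silently
    returning an empty intersection.
    """
    contigs_a = {nr.key.chrom for nr in a.records}
    contigs_b = {nr.key.chrom for nr in b.records}
    if contigs_a and contigs_b and not (contigs_a & contigs_b):
        warnings.warn(
            "the contig name vocabularies of the two files are disjoint "
            f"({sorted(contigs_a)[:3]}... vs {sorted(contigs_b)[:3]}...); "
            "a 'chr' prefix mismatch is likely — consider harmonize_chr_prefix",
            UserWarning,
            stacklevel=2,
        )
    keys_a = {_match_key(nr.key, harmonize_chr_prefix) for nr in a.records}
    keys_b = {_match_key(nr.key, harmonize_chr_prefix) for nr in b.records}

    shared_recs: list[NormalizedRecord] = []
    unique_a_recs: list[NormalizedRecord] = []
    for nr in a.records:
        if _match_key(nr.key, harmonize_chr_prefix) in keys_b:
            shared_recs.append(nr)
        else:
            unique_a_recs.append(nr)
    unique_b_recs = [
        nr
        for nr in b.records
        if _match_key(nr.key, harmonize_chr_prefix) not in keys_a
    ]

    def _subset(src: NormalizedDataset, recs, name: str) -> NormalizedDataset:
        out = src.replace_records(recs)
        out.source_name = name
        out.n_multiallelic_sites = 0
        out.n_duplicates_removed = 0
        return out

    label_a = a.source_name or "A"
    label_b = b.source_name or "B"
    return ComparisonResult(
        shared=_subset(a, shared_recs, f"shared({label_a},{label_b})"),
        unique_a=_subset(a, unique_a_recs, f"unique({label_a})"),
        unique_b=_subset(b, unique_b_recs, f"unique({label_b})"),
        n_a_only=len(unique_a_recs),
        n_b_only=len(unique_b_recs),
        n_shared=len(shared_recs),
        label_a=label_a,
        label_b=label_b,
    )


def venn_counts(result: ComparisonResult) -> pd.DataFrame:
    """The three Venn region counts with their labels, as a table.

    Counts only — laying the regions out as area-proportional ellipses is a
    presentation concern left to any plotting layer.
    """
    rows = [
        {"region": f"unique_to_{result.label_a}", "count": result.n_a_only},
        {"region": f"unique_to_{result.label_b}", "count": result.n_b_only},
        {"region": "shared", "count": result.n_shared},
    ]
    return pd.DataFrame(rows, columns=["region", "count"])


def venn_json(result: ComparisonResult) -> str:
    """Venn counts and overlap percentages as a JSON string."""
    return json.dumps(
        {
            "label_a": result.label_a,
            "label_b": result.label_b,
            "n_a_only": result.n_a_only,
            "n_b_only": result.n_b_only,
            "n_shared": result.n_shared,
            "pct_of_a": result.pct_of_a,
            "pct_of_b": result.pct_of_b,
        },
        indent=2,
    )
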