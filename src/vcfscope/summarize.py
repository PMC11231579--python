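"""Summary statistics for a normalized variant set.

Covers the per-contig / per-class count table with the Ts/Tv ratio, the
signed INDEL size histogram, and variant density in fixed genomic windows
(1 Mbp by default).  All outputs export to plot-ready long-format tables.

Windows are 1-based, inclusive, and anchored at position 1: window k of
width W spans [(k-1)W + 1, kW], so a variant at position p falls in window
ceil(p / W).  Zero-count windows up to the last occupied window of a contig
are emitted explicitly, which is what makes empty-region (gap) detection
possible.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .model import (
    INDEL_CLASSES,
    SNP_CLASSES,
    NormalizedDataset,
    VariantClass,
    indel_size,
)

__all__ = [
    "SummaryTable",
    "IndelSizeDistribution",
    "summarize",
    "ts_tv_ratio",
    "window_density",
    "indel_size_distribution",
    "longest_empty_gap",
    "DEFAULT_WINDOW_BP",
]

DEFAULT_WINDOW_BP = 1_000_000

_CLASS_ORDER = [
    VariantClass.TRANSITION,
    VariantClass.TRANSVERSION,
    VariantClass.INSERTION,
    VariantClass.DELETION,
    VariantClass.MNP,
    VariantClass.ASSORTED,
]


@dataclass
class SummaryTable:
    """Per-contig and total variant-class counts with derived statistics.

    ``per_contig`` maps contig -> class -> count, contigs in order of first
    appearance.  Derived quantities: ``n_snp`` (transitions +
    transversions), ``n_indel`` (insertions + deletions), ``ts_tv``
    (``None`` when there are no transversions), ``n_total``, and the
    normalization bookkeeping carried over from the input.
    """

    per_contig: dict[str, Counter] = field(default_factory=dict)
    totals: Counter = field(default_factory=Counter)
    n_multiallelic_sites: int = 0
    n_duplicates_removed: int = 0
    source_name: str = ""

    @property
    def n_total(self) -> int:
        return sum(self.totals.values())

    @property
    def n_snp(self) -> int:
        return sum(self.totals[c] for c in SNP_CLASSES)

    @property
    def n_indel(self) -> int:
        return sum(self.totals[c] for c in INDEL_CLASSES)

    @property
    def ts_tv(self) -> float | None:
        tv = self.totals[VariantClass.TRANSVERSION]
        if tv == 0:
            return None
        return self.totals[VariantClass.TRANSITION] / tv

    def percentages(self) -> dict[VariantClass, float]:
        """Each class as a percentage of ``n_total`` (empty table -> zeros)."""
        n = self.n_total
        if n == 0:
            return {c: 0.0 for c in _CLASS_ORDER}
        return {c: 100.0 * self.totals[c] / n for c in _CLASS_ORDER}

    def count(self, cls: VariantClass) -> int:
        return self.totals[cls]

    def to_frame(self) -> pd.DataFrame:
        """Wide one-row overview table (counts, groupings, Ts/Tv)."""
        row: dict[str, object] = {"source": self.source_name}
        for c in _CLASS_ORDER:
            row[c.value] = self.totals[c]
        row["snp"] = self.n_snp
        row["indel"] = self.n_indel
        row["total"] = self.n_total
        row["ts_tv"] = self.ts_tv
        row["multiallelic_sites"] = self.n_multiallelic_sites
        row["duplicates_removed"] = self.n_duplicates_removed
        return pd.DataFrame([row])

    def per_contig_frame(self) -> pd.DataFrame:
        """Long-format (contig, class, count) table, plot-ready."""
        rows = [
            {"contig": contig, "variant_class": c.value, "count": counts[c]}
            for contig, counts in self.per_contig.items()
            for c in _CLASS_ORDER
        ]
        return pd.DataFrame(rows, columns=["contig", "variant_class", "count"])


def summarize(normalized: NormalizedDataset) -> SummaryTable:
    """Tally unique entries in each class, per contig and in total."""
    per_contig: dict[str, Counter] = {}
    totals: Counter = Counter()
    for nr in normalized.records:
        per_contig.setdefault(nr.key.chrom, Counter())[nr.variant_class] += 1
        totals[nr.variant_class] += 1
    return SummaryTable(
        per_contig=per_contig,
        totals=totals,
        n_multiallelic_sites=normalized.n_multiallelic_sites,
        n_duplicates_removed=normalized.n_duplicates_removed,
        source_name=normalized.source_name,
    )


def ts_tv_ratio(summary: SummaryTable) -> float | None:
    """Transition/transversion ratio; ``None`` when transversions are absent.

    Never raises and never returns infinity — a missing value propagates as
    an empty cell in exported tables.
    """
    return summary.ts_tv


def window_density(
    normalized: NormalizedDataset,
    window_bp: int = DEFAULT_WINDOW_BP,
    class_filter: Iterable[VariantClass] | None = None,
) -> pd.DataFrame:
    """Variant counts in consecutive fixed-width windows per contig.

    Returns a long-format table with columns ``contig``, ``window_index``
    (1-based), ``start``, ``end`` (1-based inclusive bp) and ``count``.
    For every contig, all windows from 1 through the last occupied window
    are present, including zero-count ones.
    """
    if window_bp < 1:
        raise ValueError(f"window_bp must be >= 1, got {window_bp}")
    wanted = set(class_filter) if class_filter is not None else None
    counts: dict[str, Counter] = {}
    for nr in normalized.records:
        if wanted is not None and nr.variant_class not in wanted:
            continue
        win = math.ceil(nr.key.pos / window_bp)
        counts.setdefault(nr.key.chrom, Counter())[win] += 1
    rows = []
    for contig, wins in counts.items():
        last = max(wins)
        for k in range(1, last + 1):
            rows.append(
                {
                    "contig": contig,
                    "window_index": k,
                    "start": (k - 1) * window_bp + 1,
                    "end": k * window_bp,
                    "count": wins.get(k, 0),
                }
            )
    return pd.DataFrame(
        rows, columns=["contig", "window_index", "start", "end", "count"]
    )


@dataclass
class IndelSizeDistribution:
    """Histogram of signed INDEL sizes.

    ``max_insertion`` is the largest positive size, ``max_deletion`` the
    absolute value of the most negative size; both ``None`` when the input
    holds no INDELs of that sign.
    """

    size_counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_indel(self) -> int:
        return sum(self.size_counts.values())

    @property
    def max_insertion(self) -> int | None:
        pos = [s for s in self.size_counts if s > 0]
        return max(pos) if pos else None

    @property
    def max_deletion(self) -> int | None:
        neg = [s for s in self.size_counts if s < 0]
        return -min(neg) if neg else None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"size_bp": s, "count": c} for s, c in sorted(self.size_counts.items())
        ]
        return pd.DataFrame(rows, columns=["size_bp", "count"])


def indel_size_distribution(normalized: NormalizedDataset) -> IndelSizeDistribution:
    """Signed size histogram over all insertion/deletion records."""
    counts: Counter = Counter()
    for nr in normalized.records:
        if nr.variant_class in INDEL_CLASSES:
            counts[indel_size(nr.record.ref, nr.record.alt[0])] += 1
    return IndelSizeDistribution(size_counts=dict(counts))


@dataclass(frozen=True)
class EmptyGap:
    """Longest run of zero-count windows inside a contig's occupied span."""

    n_windows: int
    start_bp: int | None  # 1-based inclusive; None when no gap exists
    end_bp: int | None


def longest_empty_gap(density: pd.DataFrame, contig: str) -> EmptyGap:
    """Longest run of consecutive empty windows on ``contig``.

    Only windows strictly between the first and last occupied windows are
    considered — leading and trailing absence is indistinguishable from
    unassayed sequence without a reference.  Requires a density table that
    includes explicit zero windows (as :func:`window_density` emits).
    """
    sub = density[density["contig"] == contig].sort_values("window_index")
    if sub.empty:
        available = sorted(density["contig"].unique())
        raise KeyError(
            f"contig {contig!r} not present in density table; "
            f"available contigs: {available}"
        )
    occupied = sub[sub["count"] > 0]
    if occupied.empty:
        return EmptyGap(0, None, None)
    first_idx = occupied["window_index"].iloc[0]
    last_idx = occupied["window_index"].iloc[-1]
    span = sub[(sub["window_index"] >= first_idx) & (sub["window_index"] <= last_idx)]
    best_len = 0
    best_start = None
    run_len = 0
    run_start = None
    for _, row in span.iterrows():
        if row["count"] == 0:
            if run_len == 0:
                run_start = int(row["window_index"])
            run_len += 1
            if run_len > best_len:
                best_len = run_len
                best_start = run_start
        else:
            run_len = 0
    if best_len == 0:
        return EmptyGap(0, None, None)
    window_bp = int(span["end"].iloc[0] - span["start"].iloc[0] + 1)
    start_bp = (best_start - 1) * window_bp + 1
    end_bp = (best_start + best_len - 1) * window_bp
    return EmptyGap(best_len, start_bp, end_bp)
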