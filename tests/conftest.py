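"""Shared fixtures and independent brute-force oracles.

The oracles deliberately work on raw VCF text with naive loops and never
call into vcfscope's normalization/summary/comparison code, so agreement
between the two routes is meaningful.
"""

from __future__ import annotations

import math
from collections import Counter

import pytest

from vcfscope import FixtureSpec, generate_vcf, write_vcf

TINY_VCF = """\
##fileformat=VCFv4.2
##reference=GRCh38
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr1\t100\trs1\tA\tG\t50\tPASS\tDP=10
chr1\t200\t.\tC\tT,CT\t.\tq10\tDP=3;ANN=missense
"""


@pytest.fixture
def tiny_vcf_text() -> str:
    return TINY_VCF


@pytest.fixture
def tiny_vcf_path(tmp_path):
    p = tmp_path / "tiny.vcf"
    p.write_text(TINY_VCF)
    return p


@pytest.fixture
def fixture_vcf_path(tmp_path):
    """A generated VCF on disk together with its spec and ground truth."""
    spec = FixtureSpec(seed=42)
    dataset, truth = generate_vcf(spec)
    p = tmp_path / "fixture.vcf"
    write_vcf(dataset, p)
    return p, spec, truth


# ---------------------------------------------------------------- oracles


def data_lines(vcf_text: str) -> list[str]:
    return [
        ln for ln in vcf_text.splitlines() if ln.strip() and not ln.startswith("#")
    ]


def brute_normalized_keys(vcf_text: str) -> list[tuple[str, int, str, str]]:
    """Split on comma, uppercase, unique by (CHROM, POS, REF, ALT), keep first."""
    seen = set()
    keys = []
    for line in data_lines(vcf_text):
        f = line.split("\t")
        for alt in f[4].split(","):
            key = (f[0], int(f[1]), f[3].upper(), alt.upper())
            if key not in seen:
                seen.add(key)
                keys.append(key)
    return keys


def brute_classify(ref: str, alt: str) -> str:
    ref, alt = ref.upper(), alt.upper()
    acgt = set("ACGT")
    if (
        alt.startswith("<")
        or "[" in alt
        or "]" in alt
        or alt in ("*", ".")
        or set(ref) - acgt
        or set(alt) - acgt
    ):
        return "assorted"
    if len(ref) == 1 == len(alt):
        if {ref, alt} in ({"A", "G"}, {"C", "T"}):
            return "transition"
        return "transversion"
    if len(ref) == len(alt):
        return "mnp"
    return "insertion" if len(alt) > len(ref) else "deletion"


def brute_class_counts(vcf_text: str) -> Counter:
    counts: Counter = Counter()
    for chrom, pos, ref, alt in brute_normalized_keys(vcf_text):
        counts[brute_classify(ref, alt)] += 1
    return counts


def brute_window_counts(vcf_text: str, window_bp: int) -> dict[str, Counter]:
    out: dict[str, Counter] = {}
    for chrom, pos, ref, alt in brute_normalized_keys(vcf_text):
        out.setdefault(chrom, Counter())[math.ceil(pos / window_bp)] += 1
    return out


def brute_indel_hist(vcf_text: str) -> Counter:
    hist: Counter = Counter()
    for chrom, pos, ref, alt in brute_normalized_keys(vcf_text):
        if brute_classify(ref, alt) in ("insertion", "deletion"):
            hist[len(alt) - len(ref)] += 1
    return hist


def brute_venn(text_a: str, text_b: str) -> tuple[int, int, int]:
    """Double loop over all key pairs; quadratic on purpose."""
    ka = brute_normalized_keys(text_a)
    kb = brute_normalized_keys(text_b)
    shared_a = sum(1 for x in ka if any(x == y for y in kb))
    a_only = len(ka) - shared_a
    b_only = sum(1 for y in kb if not any(x == y for x in ka))
    return (a_only, b_only, shared_a)
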