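"""Summary statistics: class tallies, Ts/Tv, windows, INDEL sizes, gaps."""

import io
from collections import Counter

import pytest

from vcfscope import (
    NormalizedDataset,
    VariantClass,
    generate_vcf,
    indel_size_distribution,
    longest_empty_gap,
    normalize,
    read_vcf,
    summarize,
    ts_tv_ratio,
    window_density,
    write_vcf,
)
from vcfscope.fixtures import FixtureSpec, random_spec

from conftest import brute_class_counts, brute_indel_hist, brute_window_counts


def _norm(text: str):
    return normalize(read_vcf(io.BytesIO(text.encode())))


def _snp_dataset(positions, contig="chr1"):
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    body = "".join(f"{contig}\t{p}\t.\tA\tG\t10\tPASS\t.\n" for p in positions)
    return _norm(header + body)


class TestSummarize:
    def test_recovers_generator_ground_truth(self):
        spec = FixtureSpec(
            seed=7, n_transition=3, n_transversion=1, n_insertion=2,
            n_deletion=1, n_mnp=1, n_assorted=0, n_multiallelic_sites=1,
            n_duplicate_records=1,
        )
        ds, truth = generate_vcf(spec)
        summ = summarize(normalize(ds))
        assert summ.totals == truth.totals
        assert summ.n_total == 8
        assert summ.n_snp == 4 and summ.n_indel == 3
        assert summ.n_multiallelic_sites == 1
        assert summ.n_duplicates_removed == 1
        assert summ.per_contig == truth.per_contig

    def test_empty_dataset_is_all_zero(self):
        summ = summarize(NormalizedDataset())
        assert summ.n_total == 0 and summ.ts_tv is None
        assert summ.percentages()[VariantClass.TRANSITION] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_totals_match_brute_force(self, seed, tmp_path):
        ds, _ = generate_vcf(random_spec(seed))
        p = tmp_path / "r.vcf"
        write_vcf(ds, p)
        summ = summarize(normalize(ds))
        got = Counter({c.value: n for c, n in summ.totals.items() if n})
        assert got == brute_class_counts(p.read_text())

    def test_percentages_sum_to_100(self):
        ds, _ = generate_vcf(FixtureSpec(seed=3))
        summ = summarize(normalize(ds))
        assert sum(summ.percentages().values()) == pytest.approx(100.0)


class TestTsTv:
    @pytest.mark.parametrize(
        "ts, tv, expected", [(3, 1, 3.0), (0, 5, 0.0), (101, 50, 2.02)]
    )
    def test_ratio(self, ts, tv, expected):
        summ = summarize(NormalizedDataset())
        summ.totals = Counter(
            {VariantClass.TRANSITION: ts, VariantClass.TRANSVERSION: tv}
        )
        assert ts_tv_ratio(summ) == pytest.approx(expected)

    def test_zero_transversions_is_missing_not_infinite(self):
        summ = summarize(NormalizedDataset())
        summ.totals = Counter({VariantClass.TRANSITION: 4})
        assert ts_tv_ratio(summ) is None


class TestWindowDensity:
    def test_boundary_positions(self):
        norm = _snp_dataset([1, 999_999, 1_000_000, 1_000_001])
        dens = window_density(norm, window_bp=1_000_000)
        counts = dict(zip(dens["window_index"], dens["count"]))
        assert counts == {1: 3, 2: 1}
        w1 = dens[dens["window_index"] == 1].iloc[0]
        assert (w1["start"], w1["end"]) == (1, 1_000_000)

    def test_zero_windows_emitted_explicitly(self):
        norm = _snp_dataset([50, 3_500_000])
        dens = window_density(norm, window_bp=1_000_000)
        assert list(dens["window_index"]) == [1, 2, 3, 4]
        assert list(dens["count"]) == [1, 0, 0, 1]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_binning(self, seed, tmp_path):
        ds, _ = generate_vcf(random_spec(seed))
        p = tmp_path / "r.vcf"
        write_vcf(ds, p)
        window = 250_000
        dens = window_density(normalize(ds), window_bp=window)
        expected = brute_window_counts(p.read_text(), window)
        for contig, wins in expected.items():
            sub = dens[dens["contig"] == contig]
            got = {
                int(r["window_index"]): int(r["count"])
                for _, r in sub.iterrows()
                if r["count"] > 0
            }
            assert got == dict(wins)

    def test_per_contig_conservation(self):
        ds, _ = generate_vcf(random_spec(99))
        norm = normalize(ds)
        dens = window_density(norm, window_bp=100_000)
        per_contig = Counter(nr.key.chrom for nr in norm)
        for contig, n in per_contig.items():
            assert dens[dens["contig"] == contig]["count"].sum() == n

    def test_halving_window_reaggregates(self):
        ds, _ = generate_vcf(random_spec(17))
        norm = normalize(ds)
        big = window_density(norm, window_bp=200_000)
        small = window_density(norm, window_bp=100_000)
        for _, row in big.iterrows():
            halves = small[
                (small["contig"] == row["contig"])
                & (small["window_index"].isin([2 * row["window_index"] - 1,
                                               2 * row["window_index"]]))
            ]["count"].sum()
            assert halves == row["count"]

    def test_class_filter_restricts_counts(self):
        norm = _norm(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t10\t.\tA\tG\t1\tPASS\t.\n"
            "chr1\t20\t.\tA\tAC\t1\tPASS\t.\n"
        )
        dens = window_density(norm, class_filter={VariantClass.INSERTION})
        assert dens["count"].sum() == 1


class TestIndelSizes:
    def test_histogram_and_maxima(self):
        norm = _norm(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t10\t.\tA\tACG\t1\tPASS\t.\n"
            "chr1\t20\t.\tT\tTAG\t1\tPASS\t.\n"
            "chr1\t30\t.\tGA\tG\t1\tPASS\t.\n"
        )
        dist = indel_size_distribution(norm)
        assert dist.size_counts == {2: 2, -1: 1}
        assert dist.max_insertion == 2 and dist.max_deletion == 1
        assert dist.n_indel == 3

    def test_no_indels_gives_missing_maxima(self):
        dist = indel_size_distribution(_snp_dataset([10]))
        assert dist.size_counts == {}
        assert dist.max_insertion is None and dist.max_deletion is None

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_tally(self, seed, tmp_path):
        ds, _ = generate_vcf(random_spec(seed))
        p = tmp_path / "r.vcf"
        write_vcf(ds, p)
        dist = indel_size_distribution(normalize(ds))
        assert Counter(dist.size_counts) == brute_indel_hist(p.read_text())


class TestEmptyGap:
    def _density(self, counts, window_bp=1_000_000, contig="chr1"):
        import pandas as pd

        return pd.DataFrame(
            {
                "contig": contig,
                "window_index": range(1, len(counts) + 1),
                "start": [(k - 1) * window_bp + 1 for k in range(1, len(counts) + 1)],
                "end": [k * window_bp for k in range(1, len(counts) + 1)],
                "count": counts,
            }
        )

    def test_longest_zero_run(self):
        gap = longest_empty_gap(self._density([3, 0, 0, 0, 2]), "chr1")
        assert gap.n_windows == 3
        assert gap.start_bp == 1_000_001 and gap.end_bp == 4_000_000

    def test_no_gap(self):
        assert longest_empty_gap(self._density([1, 2, 3]), "chr1").n_windows == 0

    def test_leading_and_trailing_zeros_ignored(self):
        gap = longest_empty_gap(self._density([0, 0, 1, 0, 2, 0]), "chr1")
        assert gap.n_windows == 1

    def test_unknown_contig_lists_available(self):
        with pytest.raises(KeyError, match="chr1"):
            longest_empty_gap(self._density([1]), "chrZ")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        import random

        rng = random.Random(seed)
        counts = [rng.choice([0, 0, 1, 3]) for _ in range(30)]
        dens = self._density(counts)
        occupied = [i for i, c in enumerate(counts) if c > 0]
        if not occupied:
            assert longest_empty_gap(dens, "chr1").n_windows == 0
            return
        inner = counts[occupied[0] : occupied[-1] + 1]
        best = run = 0
        for c in inner:
            run = run + 1 if c == 0 else 0
            best = max(best, run)
        assert longest_empty_gap(dens, "chr1").n_windows == best
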