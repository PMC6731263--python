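"""Variant-caller filters, frequency arithmetic and VCF round-tripping."""
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyoscan import (
    CallerConfig,
    ParameterError,
    PileupParseError,
    UnsortedInputError,
    VariantSite,
    allele_frequency,
    call_variants,
    read_vcf,
    write_vcf,
)
from karyoscan.variants import parse_counts, sites_to_frame


def _row(chrom, pos, ref, depth, counts):
    return (chrom, pos, ref, depth, counts)


def _frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "depth", "counts"])


def brute_force_filter(pileup, config):
    """Independent application of the three retention predicates to every row."""
    kept = []
    for r in pileup.itertuples(index=False):
        counts = parse_counts(r.counts)
        alts = {a: n for a, n in counts.items() if a != r.ref and n > 0}
        if not alts:
            continue
        best = sorted(alts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        ref_n = counts.get(r.ref, 0)
        if best[1] + ref_n == 0:
            continue
        f = best[1] / (best[1] + ref_n)
        masked = any(
            s <= r.pos - 1 < e for s, e in config.mask.get(r.chrom, ())
        )
        if f >= config.min_var_freq and best[1] >= config.min_reads2 and not masked:
            kept.append((r.chrom, r.pos, best[0], best[1]))
    return kept


class TestRetentionFilters:
    def test_balanced_site_at_default_thresholds_is_retained(self):
        pileup = _frame([_row("c1", 100, "A", 370, "A:185,G:185")])
        sites = call_variants(pileup, CallerConfig())
        assert len(sites) == 1 and sites[0].frequency == 0.5

    def test_frequency_below_threshold_is_rejected(self):
        pileup = _frame([_row("c1", 100, "A", 370, "A:300,G:70")])
        assert call_variants(pileup, CallerConfig()) == []

    def test_masked_position_is_excluded(self):
        pileup = _frame([_row("c1", 100, "A", 200, "A:100,G:100")])
        cfg = CallerConfig(mask={"c1": [(90, 105)]})
        assert call_variants(pileup, cfg) == []
        cfg2 = CallerConfig(mask={"c1": [(100, 105)]})  # half-open: pos 100 is index 99
        assert len(call_variants(pileup, cfg2)) == 1

    def test_top_alternate_allele_ties_break_lexicographically(self):
        pileup = _frame([_row("c1", 5, "A", 300, "A:100,T:100,C:100")])
        sites = call_variants(pileup, CallerConfig(min_reads2=10))
        assert sites[0].alt == "C"

    def test_random_pileup_matches_brute_force_oracle(self, rng):
        rows = []
        pos = 0
        for _ in range(2000):
            pos += int(rng.integers(1, 10))
            ref = "ACGT"[rng.integers(4)]
            depth = int(rng.poisson(120))
            alt = [b for b in "ACGT" if b != ref][rng.integers(3)]
            alt_n = int(rng.binomial(depth, rng.choice([0.0, 0.1, 0.33, 0.5])))
            counts = f"{ref}:{depth - alt_n},{alt}:{alt_n}"
            rows.append(_row("c1", pos, ref, depth, counts))
        pileup = _frame(rows)
        cfg = CallerConfig(mask={"c1": [(2000, 4000)]})
        called = [(s.chrom, s.pos, s.alt_count) for s in call_variants(pileup, cfg)]
        oracle = [(c, p, n) for c, p, _a, n in brute_force_filter(pileup, cfg)]
        assert called == oracle

    def test_filter_is_idempotent(self, rng):
        rows = []
        for i in range(500):
            depth = int(rng.poisson(150))
            alt_n = int(rng.binomial(depth, 0.5))
            rows.append(_row("c1", 10 * i + 1, "A", depth, f"A:{depth - alt_n},G:{alt_n}"))
        first = call_variants(_frame(rows), CallerConfig())
        refiltered_rows = [
            _row(s.chrom, s.pos, s.ref[0], s.depth, f"{s.ref[0]}:{s.ref_count},{s.alt[-1]}:{s.alt_count}")
            for s in first
        ]
        second = call_variants(_frame(refiltered_rows), CallerConfig())
        assert [(s.pos, s.alt_count) for s in second] == [(s.pos, s.alt_count) for s in first]

    @given(
        freq=st.floats(0.05, 0.45),
        reads=st.integers(10, 120),
        data=st.data(),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_thresholds_are_monotone(self, freq, reads, data):
        """Raising min frequency or min supporting reads never adds sites."""
        seed = data.draw(st.integers(0, 2**20))
        rr = np.random.default_rng(seed)
        rows = []
        for i in range(200):
            depth = int(rr.poisson(100))
            alt_n = int(rr.binomial(depth, rr.uniform(0, 0.6)))
            rows.append(_row("c1", i + 1, "A", depth, f"A:{depth - alt_n},C:{alt_n}"))
        pileup = _frame(rows)
        base = len(call_variants(pileup, CallerConfig(min_var_freq=freq, min_reads2=reads)))
        tighter_f = len(call_variants(pileup, CallerConfig(min_var_freq=min(freq + 0.1, 0.99), min_reads2=reads)))
        tighter_r = len(call_variants(pileup, CallerConfig(min_var_freq=freq, min_reads2=reads + 20)))
        assert tighter_f <= base and tighter_r <= base


class TestInputValidation:
    def test_unsorted_positions_raise(self):
        pileup = _frame([_row("c1", 10, "A", 5, "A:5"), _row("c1", 9, "C", 5, "C:5")])
        with pytest.raises(UnsortedInputError):
            call_variants(pileup)

    def test_interleaved_chromosomes_raise(self):
        pileup = _frame([
            _row("c1", 1, "A", 5, "A:5"), _row("c2", 1, "A", 5, "A:5"),
            _row("c1", 2, "A", 5, "A:5"),
        ])
        with pytest.raises(UnsortedInputError):
            call_variants(pileup)

    def test_malformed_counts_carry_line_number(self):
        pileup = _frame([
            _row("c1", 1, "A", 5, "A:5"),
            _row("c1", 2, "A", 5, "A;5"),
        ])
        with pytest.raises(PileupParseError, match="line 2"):
            call_variants(pileup)


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "ref_n,alt_n,expected",
        [(37, 74, Fraction(2, 3)), (100, 100, Fraction(1, 2)), (0, 50, Fraction(1, 1))],
    )
    def test_known_ratios(self, ref_n, alt_n, expected):
        assert allele_frequency(ref_n, alt_n) == pytest.approx(float(expected))

    def test_zero_informative_reads_is_an_error(self):
        with pytest.raises(ParameterError, match="zero informative"):
            allele_frequency(0, 0)


class TestVcfRoundTrip:
    def _sites(self, rng, n=1000):
        out = []
        for i in range(n):
            depth = int(rng.poisson(100)) + 10
            alt_n = int(rng.binomial(depth, 0.5))
            if i % 5 == 0:
                ref, alt, vt = "AT", "A", "indel"
            elif i % 5 == 1:
                ref, alt, vt = "A", "ATG", "indel"
            else:
                ref, alt, vt = "A", "G", "SNP"
            out.append(VariantSite("c1", i + 1, ref, alt, vt, depth - alt_n, alt_n, depth))
        return out

    def test_thousand_sites_round_trip_identically(self, rng, tmp_path):
        sites = self._sites(rng)
        path = tmp_path / "sites.vcf"
        write_vcf(sites, path, {"c1": 10_000})
        assert read_vcf(path) == sites

    def test_empty_site_list_yields_header_only_vcf(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf([], path, {"c1": 1000})
        text = path.read_text()
        assert all(line.startswith("#") for line in text.strip().splitlines())
        assert read_vcf(path) == []

    def test_ad_counts_recompute_to_count_ratio(self, tmp_path):
        """Frequencies from an external AD-style VCF equal the counts ratio."""
        records = [(50, 100), (200, 100), (10, 90), (75, 25), (33, 66)]
        sites = [
            VariantSite("c1", i + 1, "A", "G", "SNP", r, a, r + a)
            for i, (r, a) in enumerate(records)
        ]
        path = tmp_path / "ad.vcf"
        write_vcf(sites, path, {"c1": 1000})
        for site, (r, a) in zip(read_vcf(path), records):
            assert site.frequency == pytest.approx(a / (r + a))

    def test_non_acgt_alleles_rejected(self, tmp_path):
        site = VariantSite("c1", 1, "A", "N", "SNP", 10, 10, 20)
        with pytest.raises(ParameterError, match="non-ACGT"):
            write_vcf([site], tmp_path / "bad.vcf", {"c1": 100})


def test_sites_frame_reports_counts_and_frequency(small_pileup):
    sites = call_variants(small_pileup.pileup, CallerConfig(min_reads2=5))
    frame = sites_to_frame(sites)
    assert (frame["f"] == frame["alt_count"] / (frame["alt_count"] + frame["ref_count"])).all()
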