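import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastmark import snpscan
from plastmark.errors import CoordinateError, InsufficientDataError

from conftest import make_alignment, random_alignment


def brute_force_snp_columns(aln):
    """Independent per-column scan: >=2 distinct unambiguous bases."""
    positions = []
    for col in range(aln.length):
        states = {s[col] for s in aln.sequences} & set("ACGT")
        if len(states) >= 2:
            positions.append(col + 1)
    return positions


class TestExtractSnps:
    def test_single_differing_column(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGA", "c": "ACGT"})
        assert snpscan.extract_snps(aln).positions == (4,)

    def test_gap_is_not_a_state(self):
        aln = make_alignment({"a": "A-", "b": "AA"})
        assert snpscan.extract_snps(aln).positions == ()

    def test_ambiguity_codes_ignored(self):
        # R/N/- never create a SNP; a real second base does
        aln = make_alignment({"a": "ARN-", "b": "AANC", "c": "AGN-"})
        assert snpscan.extract_snps(aln).positions == (2,)

    def test_matches_brute_force_scan(self, rng):
        for _ in range(20):
            aln = random_alignment(rng, 20, 100)
            got = list(snpscan.extract_snps(aln).positions)
            assert got == brute_force_snp_columns(aln)

    def test_invariant_to_row_order_and_renaming(self, rng):
        aln = random_alignment(rng, 8, 60)
        shuffled = make_alignment(
            {f"new{i}": s for i, s in enumerate(reversed(aln.sequences))}
        )
        assert (
            snpscan.extract_snps(aln).positions
            == snpscan.extract_snps(shuffled).positions
        )

    def test_states_are_observed_base_multisets(self):
        aln = make_alignment({"a": "AT", "b": "AG", "c": "AG"})
        tbl = snpscan.extract_snps(aln)
        assert tbl.positions == (2,)
        assert tbl.states[0] == {"T": 1, "G": 2}


@st.composite
def alignments(draw):
    n = draw(st.integers(2, 6))
    L = draw(st.integers(1, 40))
    rows = draw(
        st.lists(
            st.text(alphabet="ACGT-NRacg", min_size=L, max_size=L),
            min_size=n,
            max_size=n,
        )
    )
    return make_alignment({f"t{i}": s.upper() for i, s in enumerate(rows)})


@settings(max_examples=60, derandomize=True, deadline=None)
@given(alignments())
def test_snp_extraction_matches_brute_force_property(aln):
    """Any alignment over the full alphabet: SNP calls equal the per-column
    scan and are conserved by the windowed binning."""
    tbl = snpscan.extract_snps(aln)
    assert list(tbl.positions) == brute_force_snp_columns(aln)
    wd = snpscan.bin_density(tbl, aln.length, window_size=7)
    assert sum(w.snp_count for w in wd.windows) == len(tbl)
    assert wd.windows[-1].end == aln.length


class TestBinDensity:
    def test_direct_binning(self):
        tbl = snpscan.SnpTable((10, 900, 1500), ({},) * 3)
        wd = snpscan.bin_density(tbl, length=1600, window_size=800)
        assert [w.snp_count for w in wd.windows] == [1, 2]
        assert [(w.start, w.end) for w in wd.windows] == [(1, 800), (801, 1600)]

    def test_partial_tail_window(self):
        wd = snpscan.bin_density(snpscan.SnpTable((), ()), length=1000, window_size=800)
        assert [(w.start, w.end) for w in wd.windows] == [(1, 800), (801, 1000)]

    def test_counts_match_brute_force_histogram(self, rng):
        for _ in range(10):
            L = int(rng.integers(100, 3000))
            w = int(rng.integers(10, 500))
            pos = tuple(sorted(rng.choice(L, size=min(L, 60), replace=False) + 1))
            wd = snpscan.bin_density(snpscan.SnpTable(pos, ({},) * len(pos)), L, w)
            for win in wd.windows:
                expect = sum(win.start <= p <= win.end for p in pos)
                assert win.snp_count == expect
            assert sum(win.snp_count for win in wd.windows) == len(pos)

    def test_position_beyond_length_rejected(self):
        with pytest.raises(CoordinateError):
            snpscan.bin_density(snpscan.SnpTable((1001,), ({},)), length=1000)


class TestClassifyWindows:
    @staticmethod
    def _wd(counts, size=10):
        windows = tuple(
            snpscan.Window(i * size + 1, (i + 1) * size, c)
            for i, c in enumerate(counts)
        )
        return snpscan.WindowDensity(size, size * len(counts), windows)

    def test_zero_variance_all_low(self):
        wd = snpscan.classify_windows(self._wd([1, 1, 1]))
        assert [w.cls for w in wd.windows] == ["low", "low", "low"]

    def test_z_score_arithmetic(self):
        # counts [0,0,12]: mean 4, sample sd sqrt(48); z(12) = 8/sqrt(48)
        wd = snpscan.classify_windows(self._wd([0, 0, 12]))
        z = [w.z_score for w in wd.windows]
        assert z[2] == pytest.approx(8 / math.sqrt(48), abs=1e-12)
        assert [w.cls for w in wd.windows] == ["low", "low", "moderate"]

    def test_classes_partition_windows(self, rng):
        counts = list(rng.integers(0, 50, size=12))
        wd = snpscan.classify_windows(self._wd(counts))
        assert sum(w.cls in ("low", "moderate", "high") for w in wd.windows) == 12

    def test_shift_invariance_of_classes(self, rng):
        counts = list(rng.integers(0, 30, size=10))
        base = snpscan.classify_windows(self._wd(counts))
        shifted = snpscan.classify_windows(self._wd([c + 7 for c in counts]))
        assert [w.cls for w in base.windows] == [w.cls for w in shifted.windows]

    def test_needs_two_windows(self):
        with pytest.raises(InsufficientDataError):
            snpscan.classify_windows(self._wd([3]))


class TestPercentVariableSites:
    def test_quarter_variable(self):
        assert snpscan.percent_variable_sites(
            make_alignment({"a": "AAAA", "b": "AAAT"})
        ) == pytest.approx(25.0)

    def test_identical_rows_zero(self):
        assert snpscan.percent_variable_sites(
            make_alignment({"a": "ACGT", "b": "ACGT"})
        ) == 0.0

    def test_matches_brute_force(self, rng):
        aln = random_alignment(rng, 10, 200)
        expect = 100.0 * len(brute_force_snp_columns(aln)) / aln.length
        assert snpscan.percent_variable_sites(aln) == pytest.approx(expect)
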