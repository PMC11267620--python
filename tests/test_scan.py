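"""Binding-site scanner: planted-site recovery, oracle equivalence,
region localization and pairing-scheme rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import naive_scan, random_rna
from mirhd.energy import EnergyModel, revcomp
from mirhd.errors import ContractError, InputError
from mirhd.targets import (
    MiRNA,
    Transcript,
    localize_region,
    render_scheme,
    scan,
    scan_many,
    site_count_table,
)


def make_transcript(seq, tid="tx"):
    L = len(seq)
    u5 = max(1, L // 10)
    cds = max(1, (6 * L) // 10)
    return Transcript(
        tid, seq, {"5'UTR": (1, u5), "CDS": (u5 + 1, u5 + cds), "3'UTR": (u5 + cds + 1, L)}
    )


@pytest.fixture
def mirna():
    return MiRNA("mir-x", "ACGGAUCCGUAAGGCUAGGC")


class TestScan:
    def test_planted_perfect_complement_found_at_exact_start(self, mirna, model):
        rng = np.random.default_rng(0)
        bg = random_rna(rng, 300)
        p = 101  # 1-based
        seq = bg[: p - 1] + revcomp(mirna.seq) + bg[p - 1 + len(mirna) :]
        sites = scan(mirna, make_transcript(seq), model)
        assert any(s.start == p and s.ratio == pytest.approx(100.0) for s in sites)

    def test_min_ratio_above_100_retains_nothing(self, mirna, model):
        seq = revcomp(mirna.seq) + "ACGU" * 30
        assert scan(mirna, make_transcript(seq), model, min_ratio=101.0) == []

    def test_short_transcript_warns_and_returns_empty(self, mirna, model):
        tiny = Transcript("t", "ACGUACGUACGUACGUACG")  # 19 nt < 20 nt miRNA
        with pytest.warns(UserWarning):
            assert scan(mirna, tiny, model) == []

    def test_retained_ratios_lie_in_band(self, mirna, model):
        """Every retained site satisfies min_ratio ≤ ΔG/ΔGm ≤ 100."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = random_rna(rng, 400)
            for s in scan(mirna, make_transcript(seq), model, min_ratio=40.0):
                assert 40.0 - 1e-9 <= s.ratio <= 100.0 + 1e-9
                assert s.dG >= s.dGm  # both negative, dGm most favourable
                assert s.ratio == pytest.approx(100.0 * s.dG / s.dGm)

    def test_extra_mismatch_never_raises_ratio(self, model):
        """Monotone degradation: breaking one more pair cannot improve a site."""
        from mirhd.energy import duplex_energy, max_duplex_energy

        mir = "ACGGAUCCGUAAGGCUAGGC"
        window = list(revcomp(mir))
        dgm = max_duplex_energy(mir, model)
        prev = 100.0
        rng = np.random.default_rng(3)
        for j in rng.permutation(len(window)):
            window[j] = mir[len(mir) - 1 - j]  # zero-bond substitution
            ratio = 100.0 * duplex_energy(mir, "".join(window), model) / dgm
            assert ratio <= prev + 1e-9
            prev = ratio

    def test_ratio_100_iff_revcomp_under_strict_model(self, strict_model):
        """With every substitution strictly losing bonds, ratio 100 happens
        only for the exact reverse complement."""
        mir = "ACGGAUCCGUAAGGCUAGGC"
        rc = revcomp(mir)
        from mirhd.energy import duplex_energy, max_duplex_energy

        dgm = max_duplex_energy(mir, strict_model)
        assert duplex_energy(mir, rc, strict_model) == pytest.approx(dgm)
        for j in range(len(rc)):
            for b in "ACGU":
                if b == rc[j]:
                    continue
                window = rc[:j] + b + rc[j + 1 :]
                assert duplex_energy(mir, window, strict_model) > dgm + 1e-12

    def test_wobble_substitution_can_reach_100_under_defaults(self, model):
        """The default bond table scores G–U like A–U, so a non-revcomp
        window can also reach ratio 100 (why the strict model exists)."""
        from mirhd.energy import duplex_energy, max_duplex_energy

        mir = "UACGGAUCCGUAAGGCUAGG"  # starts with U
        rc = revcomp(mir)  # ends with A, pairing the leading U
        window = rc[:-1] + "G"  # U·G wobble instead of U·A
        assert duplex_energy(mir, window, model) == pytest.approx(
            max_duplex_energy(mir, model)
        )


class TestOracleEquivalence:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.text(alphabet="ACGU", min_size=16, max_size=25),
        st.integers(0, 2**31 - 1),
        st.integers(60, 500),
    )
    def test_scan_matches_naive_enumeration(self, mir_seq, seed, tlen):
        """The vectorized scanner equals per-window brute force, retained set
        and ratios alike, at a permissive threshold to exercise the overlap
        filter."""
        rng = np.random.default_rng(seed)
        seq = random_rna(rng, tlen)
        # plant one degraded complement so retained sets are non-trivial
        p = int(rng.integers(0, tlen - len(mir_seq) + 1))
        seq = seq[:p] + revcomp(mir_seq) + seq[p + len(mir_seq) :]
        got = scan(MiRNA("m", mir_seq), make_transcript(seq), EnergyModel(), 50.0)
        expected = naive_scan(mir_seq, seq, 50.0)
        assert [(s.start, pytest.approx(s.ratio)) for s in got] == [
            (st_, pytest.approx(r)) for st_, r in expected
        ]


class TestLocalize:
    def test_start_region_convention(self):
        t = Transcript(
            "g", "A" * 400, {"5'UTR": (1, 120), "CDS": (121, 300), "3'UTR": (301, 400)}
        )
        assert localize_region(77, 24, t) == "5'UTR"  # inside the leader
        assert localize_region(1, 20, t) == "5'UTR"
        assert localize_region(121, 20, t) == "CDS"  # first CDS base
        assert localize_region(110, 24, t) == "5'UTR"  # spans boundary → start's region

    def test_out_of_bounds_site_is_contract_error(self):
        t = Transcript("g", "A" * 50)
        with pytest.raises(ContractError):
            localize_region(40, 20, t)

    def test_regions_must_cover_and_be_contiguous(self):
        with pytest.raises(ContractError):
            Transcript("g", "A" * 50, {"5'UTR": (1, 10), "CDS": (12, 50)})
        with pytest.raises(ContractError):
            Transcript("g", "A" * 50, {"5'UTR": (1, 10), "CDS": (11, 40)})


class TestScheme:
    def test_perfect_duplex_all_pipes(self, mirna, model):
        seq = revcomp(mirna.seq) + "A" * 50
        scheme = render_scheme(mirna, make_transcript(seq), 1, model)
        mid = scheme.splitlines()[2].strip()
        assert mid == "|" * len(mirna)

    def test_single_wobble_single_colon(self, model):
        mir = MiRNA("m", "ACGGAUCCGUAAGGCUAGGC")
        rc = revcomp(mir.seq)
        # replace the base pairing miRNA G (window position L-1-j for j=2)
        j = 2  # miRNA position with G
        assert mir.seq[j] == "G"
        wpos = len(mir.seq) - 1 - j
        window = rc[:wpos] + "U" + rc[wpos + 1 :]  # G·U wobble
        seq = window + "A" * 40
        scheme = render_scheme(mir, make_transcript(seq), 1, model)
        mid = scheme.splitlines()[2][3:]
        assert mid.count(":") == 1
        assert len(mid) == len(mir)

    def test_glyph_count_equals_mirna_length(self, mirna, model):
        rng = np.random.default_rng(11)
        seq = random_rna(rng, 120)
        scheme = render_scheme(mirna, make_transcript(seq), 30, model)
        assert len(scheme.splitlines()[2][3:]) == len(mirna)


class TestScanMany:
    def test_two_planted_sites_counted_with_both_starts(self, model):
        mir = MiRNA("m1", "ACGGAUCCGUAAGGCUAGGC")
        rng = np.random.default_rng(5)
        bg = random_rna(rng, 400)
        rc = revcomp(mir.seq)
        seq = bg[:50] + rc + bg[70:200] + rc + bg[220:]
        sites = scan_many([mir], [make_transcript(seq, "g1")], model)
        assert len(sites) == 2
        table = site_count_table(sites)
        assert table.loc[0, "n_sites"] == 2
        s1, s2 = sorted(sites["start"])
        assert table.loc[0, "start"] == f"{s1}÷{s2} (2)"

    def test_duplicate_ids_rejected(self, model):
        mir = MiRNA("m1", "ACGGAUCCGUAAGGCUAGGC")
        with pytest.raises(InputError):
            scan_many([mir, mir], [make_transcript("ACGU" * 30)], model)

    def test_transcript_order_invariance(self, model):
        mir = MiRNA("m1", "ACGGAUCCGUAAGGCUAGGC")
        rng = np.random.default_rng(9)
        txs = []
        for i in range(4):
            bg = random_rna(rng, 300)
            seq = bg[:100] + revcomp(mir.seq) + bg[120:]
            txs.append(make_transcript(seq, f"g{i}"))
        a = scan_many([mir], txs, model)
        b = scan_many([mir], txs[::-1], model)
        assert a.equals(b)

    def test_empty_inputs_rejected(self, model):
        with pytest.raises(InputError):
            scan_many([], [], model)
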