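"""Period detection and unanimity consensus, checked against independent
brute-force oracles and the exhaustive two-copy base-combination table."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dropcirc as dc
from dropcirc._seq import rotate
from dropcirc.consensus import PeriodRejection

dna = st.text(alphabet="ACGTN", min_size=6, max_size=60)


def brute_period(seq, rate, min_period):
    """Independent lag-scan oracle (pure python, char by char)."""
    n = len(seq)
    if n < 2 * min_period:
        return None
    for p in range(min_period, n // 2 + 1):
        comps = [(seq[i], seq[i + p]) for i in range(n - p)
                 if seq[i] != "N" and seq[i + p] != "N"]
        if not comps:
            continue
        mism = sum(a != b for a, b in comps)
        if mism / len(comps) <= rate:
            return p
    return None


class TestFindPeriod:
    def test_exact_three_copy_repeat(self):
        assert dc.find_period("ACGTACGTACGT", 0.0, 2) == 4

    def test_partial_final_copy(self):
        assert dc.find_period("ACGTACGTAC", 0.0, 2) == 4

    def test_single_mismatch_tolerance(self):
        # "ACGAACGTACGT": lag-4 scan gives 1 mismatch / 8 comparisons = 0.125
        seq = "ACGAACGTACGT"
        assert brute_period(seq, 0.15, 2) == 4
        assert dc.find_period(seq, 0.15, 2) == 4
        assert dc.find_period(seq, 0.25, 2) == 4
        assert isinstance(dc.find_period(seq, 0.10, 2), PeriodRejection)

    def test_too_short_is_rejected(self):
        out = dc.find_period("ACGTACG", 0.0, 4)
        assert isinstance(out, PeriodRejection) and out.reason == "too short"

    @settings(max_examples=200, derandomize=True)
    @given(seq=dna, rate=st.sampled_from([0.0, 0.1, 0.3]))
    def test_matches_brute_force_oracle(self, seq, rate):
        expected = brute_period(seq, rate, 3)
        got = dc.find_period(seq, rate, 3)
        got = None if isinstance(got, PeriodRejection) else got
        assert got == expected

    def test_matches_brute_force_on_random_strings(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            n = int(rng.integers(8, 60))
            seq = "".join("ACGTN"[i] for i in rng.integers(0, 5, n))
            for rate in (0.0, 0.1, 0.3):
                expected = brute_period(seq, rate, 3)
                got = dc.find_period(seq, rate, 3)
                got = None if isinstance(got, PeriodRejection) else got
                assert got == expected, (seq, rate)


def brute_consensus(seq, quals, period):
    """Independent per-offset oracle."""
    unit, counts = [], []
    for o in range(period):
        obs = [(seq[i], quals[i]) for i in range(o, len(seq), period) if seq[i] != "N"]
        counts.append(len(obs))
        bases = {b for b, _ in obs}
        if len(obs) < 2 or len(bases) != 1:
            unit.append("N")
        else:
            unit.append(obs[0][0])
    return "".join(unit), counts


class TestCallConsensus:
    def test_two_exact_copies(self):
        cs = dc.call_consensus("ACGTACGT", 4)
        assert cs.unit == "ACGT"
        assert list(cs.copy_count) == [2, 2, 2, 2]
        assert cs.agreement.all()

    def test_discordant_offset_is_masked(self):
        # copies ACGA / ACGT / ACGT -> offset 3 sees {A,T,T}: masked
        cs = dc.call_consensus("ACGAACGTACGT", 4)
        assert cs.unit == "ACGN"

    def test_single_coverage_is_masked(self):
        # offset 3 observed once -> severe penalty -> masked
        cs = dc.call_consensus("ACGTACG", 4)
        assert cs.unit == "ACGN"
        assert list(cs.copy_count) == [2, 2, 2, 1]

    def test_invalid_period(self):
        with pytest.raises(ValueError):
            dc.call_consensus("ACGT", 0)

    def test_quality_is_summed_and_capped(self):
        quals = np.full(12, 25, dtype=np.int16)
        cs = dc.call_consensus(("ACGTACGTACGT", quals), 4)
        assert (cs.consensus_quality == 60).all()  # 3 x 25 capped at 60
        cs = dc.call_consensus(("ACGTACGT", np.full(8, 25, dtype=np.int16)), 4)
        assert (cs.consensus_quality == 50).all()

    def test_all_two_copy_base_combinations(self):
        # unanimous pairs survive, every discordant pair is masked
        for a, b in itertools.product("ACGT", repeat=2):
            merged = "AAA" + a + "AAA" + b
            cs = dc.call_consensus(merged, 4)
            expected = a if a == b else "N"
            assert cs.unit[3] == expected

    @settings(max_examples=150, derandomize=True)
    @given(seq=st.text(alphabet="ACGTN", min_size=2, max_size=50),
           period=st.integers(min_value=1, max_value=12))
    def test_matches_brute_force_oracle(self, seq, period):
        quals = np.full(len(seq), 30, dtype=np.int16)
        cs = dc.call_consensus((seq, quals), period)
        unit, counts = brute_consensus(seq, quals, period)
        assert cs.unit == unit
        assert list(cs.copy_count) == counts

    def test_matches_brute_force_on_random_strings(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            p = int(rng.integers(2, 12))
            n = int(rng.integers(p, 5 * p))
            seq = "".join("ACGTN"[i] for i in rng.integers(0, 5, n))
            quals = rng.integers(2, 41, n).astype(np.int16)
            cs = dc.call_consensus((seq, quals), p)
            unit, counts = brute_consensus(seq, quals, p)
            assert cs.unit == unit
            assert list(cs.copy_count) == counts

    def test_error_free_reads_recover_fragment_rotation(self, nonoise_run):
        from dropcirc._seq import revcomp

        truth, ref = nonoise_run["truth"], nonoise_run["ref"]
        minor = nonoise_run["minor"]
        mol = truth.molecules.set_index("molecule_id")
        pair_mol = truth.pairs.set_index("pair_id")["molecule_id"]
        assert len(nonoise_run["intermediates"]["cs"]) > 100
        for cs in nonoise_run["intermediates"]["cs"]:
            row = mol.loc[pair_mol[cs.source_read_id]]
            src = minor if row.strain == "minor" else ref
            frag = src[row.origin_start:row.origin_end]
            if row.strand == "-":
                frag = revcomp(frag)
            assert len(cs.unit) == len(frag)
            ok = any(
                all(u in ("N", f) for u, f in zip(cs.unit, rotate(frag, r)))
                for r in range(len(frag))
            )
            assert ok, cs.source_read_id
            # masked exactly where coverage < 2 (no-noise: never by discordance)
            for u, cc in zip(cs.unit, cs.copy_count):
                assert (u == "N") == (cc < 2)
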