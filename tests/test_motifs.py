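"""TRANSFAC parsing, MATCH scoring, scanning, and gene scan statuses."""

import io
import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from promotif.motifs import (
    PWM,
    GeneScanStatus,
    PromoterRecord,
    classify_gene_status,
    define_core,
    information_vector,
    match_score,
    parse_transfac,
    reverse_complement,
    scan_promoter,
    write_transfac,
)

FIXTURE = """\
ID M_A
P0      A      C      G      T
01      4      0      0      0      A
02      0      4      0      0      C
//
"""


def brute_force_match(pwm: PWM, seq: str) -> tuple[float, float]:
    """Independent MATCH implementation: plain loops over the formula."""

    def score(positions):
        cur = mx = mn = 0.0
        for i in positions:
            f = pwm.frequencies[i]
            inf = sum(
                f[b] * math.log(4 * f[b]) if f[b] > 0 else 0.0 for b in range(4)
            )
            cur += inf * f["ACGT".index(seq[i])]
            mx += inf * max(f)
            mn += inf * min(f)
        return (cur - mn) / (mx - mn) if mx > mn else 0.0

    return score(range(len(pwm))), score(list(pwm.core_positions))


class TestParsing:
    def test_fixture_frequencies(self):
        pwms = parse_transfac(FIXTURE)
        assert len(pwms) == 1
        assert np.allclose(
            pwms[0].frequencies, [[1, 0, 0, 0], [0, 1, 0, 0]]
        )

    def test_round_trip_preserves_counts(self, pwms):
        buf = io.StringIO()
        write_transfac(pwms, buf)
        reparsed = parse_transfac(buf.getvalue())
        assert [p.id for p in reparsed] == [p.id for p in pwms]
        for a, b in zip(pwms, reparsed):
            assert np.array_equal(a.counts, b.counts)

    def test_missing_terminator_is_error(self):
        with pytest.raises(ValueError, match="terminator"):
            parse_transfac("ID X\n01 1 2 3 4\n")

    def test_bad_count_row_is_error_naming_line(self):
        with pytest.raises(ValueError, match="line 2"):
            parse_transfac("ID X\n01 1 2 3\n//\n")

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError):
            parse_transfac("ID X\n//\n")


class TestInformationAndCore:
    def test_degenerate_column_attains_ln4(self):
        info = information_vector(np.array([[1.0, 0, 0, 0]]))
        assert info[0] == pytest.approx(math.log(4))

    def test_uniform_column_is_zero(self):
        info = information_vector(np.array([[0.25] * 4]))
        assert info[0] == pytest.approx(0, abs=1e-12)

    @given(
        st.lists(st.floats(0.01, 10.0), min_size=4, max_size=4)
    )
    def test_bounds(self, counts):
        f = np.array(counts) / sum(counts)
        info = information_vector(f[None, :])
        assert -1e-12 <= info[0] <= math.log(4) + 1e-12

    def test_core_is_whole_matrix_when_short(self):
        pwm = PWM(id="x", counts=np.eye(4, 4) * 5 + 1)
        assert list(pwm.core_positions) == [0, 1, 2, 3]

    def test_core_finds_high_information_block(self):
        uniform = np.ones((3, 4))
        block = np.tile([[20.0, 1, 1, 1]], (5, 1))
        counts = np.vstack([uniform, block, uniform])
        assert define_core(information_vector(counts / counts.sum(1, keepdims=True))) == 3

    def test_core_tie_prefers_leftmost(self):
        counts = np.tile([[10.0, 1, 1, 1]], (7, 1))  # every window ties
        assert define_core(information_vector(counts / 13.0)) == 0


class TestMatchScore:
    def test_consensus_scores_one(self, toy_pwm):
        assert match_score(toy_pwm, toy_pwm.consensus) == (1.0, 1.0)

    def test_anti_consensus_scores_zero(self, toy_pwm):
        anti = "".join(
            "ACGT"[i] for i in toy_pwm.frequencies.argmin(axis=1)
        )
        mss, _ = match_score(toy_pwm, anti)
        assert mss == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_4mer_agreement_with_brute_force(self, toy_pwm):
        for kmer in itertools.product("ACGT", repeat=4):
            seq = "".join(kmer)
            got = match_score(toy_pwm, seq)
            expected = brute_force_match(toy_pwm, seq)
            assert got[0] == pytest.approx(expected[0], abs=1e-12)
            assert got[1] == pytest.approx(expected[1], abs=1e-12)

    def test_ranking_invariant_under_base_relabeling(self, toy_pwm):
        """Permuting the base alphabet consistently in matrix and sequence
        leaves every score unchanged."""
        perm = [2, 0, 3, 1]  # A->G, C->A, G->T, T->C
        relabeled = PWM(id="perm", counts=toy_pwm.counts[:, np.argsort(perm)])
        for kmer in itertools.product("ACGT", repeat=4):
            seq = "".join(kmer)
            mapped = "".join("ACGT"[perm["ACGT".index(c)]] for c in seq)
            assert match_score(toy_pwm, seq) == pytest.approx(
                match_score(relabeled, mapped)
            )

    def test_length_mismatch_rejected(self, toy_pwm):
        with pytest.raises(ValueError):
            match_score(toy_pwm, "ACG")


def brute_force_scan(pwms, record, regions, mss_min, css_min):
    """Window-by-window reference scan using match_score directly."""
    allowed = set()
    if regions is None:
        allowed = set(range(len(record.sequence)))
    else:
        for s, e in regions:
            allowed.update(range(s, e))
    hits = []
    for pwm in pwms:
        L = len(pwm)
        for start in range(len(record.sequence) - L + 1):
            if not all(p in allowed for p in range(start, start + L)):
                continue
            window = record.sequence[start : start + L]
            if "N" in window:
                continue
            for strand, oriented in (("+", window), ("-", reverse_complement(window))):
                mss, css = match_score(pwm, oriented)
                if mss >= mss_min and css >= css_min:
                    hits.append((pwm.id, start, strand, mss, css))
    return sorted(hits)


class TestScanPromoter:
    def _random_record(self, seed, length=200):
        rng = np.random.default_rng(seed)
        return PromoterRecord(
            "g", "rat", "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        )

    def test_strict_cutoffs_on_random_sequence_empty(self, toy_pwm):
        rec = self._random_record(0, 300)
        # exclude chance consensus occurrences
        if toy_pwm.consensus in rec.sequence or reverse_complement(
            toy_pwm.consensus
        ) in rec.sequence:
            pytest.skip("chance consensus in random sequence")
        assert scan_promoter([toy_pwm], rec, None, 1.0, 1.0) == []

    def test_planted_consensus_found_at_position(self, pwms):
        pwm = pwms[0]
        seq = "T" * 100 + pwm.consensus + "T" * (200 - len(pwm))
        rec = PromoterRecord("g", "rat", seq)
        hits = [
            h
            for h in scan_promoter([pwm], rec, [(0, len(seq))], 1.0, 0.95)
            if h.mss == 1.0
        ]
        assert [(h.start, h.strand) for h in hits] == [(100, "+")]

    def test_reverse_complement_planted_on_minus_strand(self, pwms):
        pwm = pwms[0]
        rc = reverse_complement(pwm.consensus)
        seq = "T" * 50 + rc + "T" * 100
        rec = PromoterRecord("g", "rat", seq)
        hits = [
            h for h in scan_promoter([pwm], rec, None, 1.0, 0.95) if h.mss == 1.0
        ]
        assert [(h.start, h.strand) for h in hits] == [(50, "-")]

    def test_agrees_with_brute_force_on_random_sequence(self, pwms):
        rec = self._random_record(1, 200)
        regions = [(10, 90), (120, 180)]
        got = scan_promoter(pwms[:2], rec, regions, 0.7, 0.8)
        expected = brute_force_scan(pwms[:2], rec, regions, 0.7, 0.8)
        got_tuples = sorted(
            (h.matrix_id, h.start, h.strand, h.mss, h.css) for h in got
        )
        assert len(got_tuples) == len(expected)
        for g, e in zip(got_tuples, expected):
            assert g[:3] == e[:3]
            assert g[3] == pytest.approx(e[3], abs=1e-9)
            assert g[4] == pytest.approx(e[4], abs=1e-9)

    def test_reverse_complement_mirror_symmetry(self, pwms):
        rec = self._random_record(2, 150)
        mirrored = PromoterRecord("g", "rat", reverse_complement(rec.sequence))
        fwd = scan_promoter(pwms[:2], rec, None, 0.75, 0.8)
        rev = scan_promoter(pwms[:2], mirrored, None, 0.75, 0.8)
        lengths = {p.id: len(p) for p in pwms[:2]}
        mapped = sorted(
            (
                h.matrix_id,
                len(rec.sequence) - h.start - lengths[h.matrix_id],
                "+" if h.strand == "-" else "-",
                round(h.mss, 9),
            )
            for h in rev
        )
        assert mapped == sorted(
            (h.matrix_id, h.start, h.strand, round(h.mss, 9)) for h in fwd
        )

    def test_restricting_regions_never_grows_hits(self, pwms):
        rec = self._random_record(3, 300)
        full = scan_promoter(pwms, rec, None, 0.7, 0.8)
        sub = scan_promoter(pwms, rec, [(50, 200)], 0.7, 0.8)
        full_set = {(h.matrix_id, h.start, h.strand) for h in full}
        sub_set = {(h.matrix_id, h.start, h.strand) for h in sub}
        assert sub_set <= full_set

    def test_windows_with_n_skipped(self, pwms):
        pwm = pwms[0]
        seq = "N" * 40 + pwm.consensus + "N" * 40
        rec = PromoterRecord("g", "rat", seq)
        hits = scan_promoter([pwm], rec, None, 0.9, 0.9)
        assert [(h.start, h.strand, h.mss) for h in hits if h.strand == "+"] == [
            (40, "+", 1.0)
        ]


class TestGeneScanStatus:
    def test_attrition_arithmetic(self):
        """30 cluster genes: 17 without ortholog, 2 with ortholog but no
        sites, leaving 11 analysis-ready."""
        genes = [f"g{i}" for i in range(30)]
        table = {g: (None if i < 17 else f"m_{g}") for i, g in enumerate(genes)}
        hits = {g: ([] if i < 19 else ["hit"]) for i, g in enumerate(genes)}
        statuses = classify_gene_status(genes, table, hits)
        counts = {s: 0 for s in ("no_ortholog", "no_tfbs", "analysis_ready")}
        for s in statuses:
            counts[s.status] += 1
        assert counts == {"no_ortholog": 17, "no_tfbs": 2, "analysis_ready": 11}

    def test_all_ready_when_orthologs_and_hits_present(self):
        statuses = classify_gene_status(
            ["a", "b"], {"a": "ma", "b": "mb"}, {"a": ["h"], "b": ["h"]}
        )
        assert all(s.status == "analysis_ready" for s in statuses)

    def test_empty_cluster_empty_statuses(self):
        assert classify_gene_status([], {}, {}) == []

    def test_missing_gene_in_table_is_error(self):
        with pytest.raises(KeyError):
            classify_gene_status(["a"], {}, {})

    def test_na_string_counts_as_missing_ortholog(self):
        statuses = classify_gene_status(["a"], {"a": "NA"}, {})
        assert statuses[0].status == "no_ortholog"
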