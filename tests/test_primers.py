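"""In-silico PCR: degenerate matching, site finding, amplicon prediction,
screening, typing, contig merging, percent identity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from btchar import primers
from btchar.primers import (
    AmbiguousTypingError,
    NoOverlapError,
    PrimerError,
    PrimerPair,
    VIP3_SCREENING_PAIR,
    VIP3_TYPING_FORWARD,
    VIP3_TYPING_REVERSE,
    find_primer_sites,
    iupac_match,
    merge_contigs,
    percent_identity,
    predict_amplicons,
    reverse_complement,
    round_half_away,
    screen_collection,
    type_vip3,
)

# Expansion sets written out independently of the implementation table.
EXPANSIONS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "S": "GC", "W": "AT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def naive_find_sites(template, primer, max_mismatch=0):
    """Position-by-position scanner used as the independent oracle."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
            "K": "M", "M": "K", "S": "S", "W": "W", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N"}
    rc = "".join(comp[c] for c in reversed(primer))
    hits = []
    for pattern, strand in ((primer, "+"), (rc, "-")):
        for i in range(len(template) - len(pattern) + 1):
            mm = sum(
                1 for t, p in zip(template[i:i + len(pattern)], pattern)
                if t not in EXPANSIONS[p]
            )
            if mm <= max_mismatch:
                hits.append((i + 1, strand))
    return sorted(hits)


def expand_concrete(primer, choice=0):
    """A concrete A/C/G/T realization of a degenerate primer."""
    return "".join(sorted(EXPANSIONS[c])[choice % len(EXPANSIONS[c])] for c in primer)


def random_template(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestIupacMatch:
    def test_full_enumeration(self):
        """All 15x4 code/base combinations agree with the expansion table."""
        for code, allowed in EXPANSIONS.items():
            for base in "ACGT":
                assert iupac_match(code, base) == (base in allowed)

    def test_table_footnote_codes(self):
        assert iupac_match("R", "A") and iupac_match("R", "G")
        assert not iupac_match("R", "C")
        assert iupac_match("N", "T")

    @pytest.mark.parametrize("pattern,base", [("X", "A"), ("R", "U"), ("R", "N")])
    def test_invalid_symbols_raise_naming_offender(self, pattern, base):
        with pytest.raises(PrimerError):
            iupac_match(pattern, base)


class TestFindPrimerSites:
    def test_planted_forward_site(self, rng):
        t = random_template(rng, 200)
        site = expand_concrete(VIP3_SCREENING_PAIR.forward)
        t = t[:9] + site + t[9 + len(site):]
        assert (10, "+") in find_primer_sites(t, VIP3_SCREENING_PAIR.forward)

    def test_planted_reverse_complement_site(self, rng):
        primer = VIP3_TYPING_REVERSE["vip3Aa"].reverse
        t = random_template(rng, 200)
        rc = reverse_complement(expand_concrete(primer))
        t = t[:50] + rc + t[50 + len(rc):]
        hits = [h for h in find_primer_sites(t, primer) if h[1] == "-"]
        assert (51, "-") in hits

    def test_matches_naive_scanner(self, rng):
        """Brute-force oracle equivalence on random templates and primers."""
        codes = list(EXPANSIONS)
        for trial in range(300):
            t = random_template(rng, 120)
            m = int(rng.integers(4, 9))
            primer = "".join(rng.choice(codes, size=m))
            mm = int(rng.integers(0, 3))
            assert find_primer_sites(t, primer, mm) == naive_find_sites(t, primer, mm)

    def test_mismatch_monotonicity(self, rng):
        t = random_template(rng, 500)
        primer = "ACGTRY"
        prev = set()
        for mm in range(4):
            hits = set(find_primer_sites(t, primer, mm))
            assert prev <= hits
            prev = hits

    def test_empty_primer_rejected(self):
        with pytest.raises(PrimerError):
            find_primer_sites("ACGT", "")

    def test_template_must_be_concrete(self):
        with pytest.raises(PrimerError):
            find_primer_sites("ACGN", "AC")


def _template_with_pair(rng, pair, length=2600):
    """Random template with one concrete site pair at the expected span."""
    start, end = pair.expected_span
    t = list(random_template(rng, length))
    fwd = expand_concrete(pair.forward)
    rev = reverse_complement(expand_concrete(pair.reverse))
    t[start - 1:start - 1 + len(fwd)] = list(fwd)
    t[end - len(rev):end] = list(rev)
    return "".join(t)


class TestPredictAmplicons:
    @pytest.mark.parametrize(
        "pair", [VIP3_SCREENING_PAIR] + list(VIP3_TYPING_REVERSE.values()),
        ids=lambda p: p.name,
    )
    def test_expected_spans_give_printed_sizes(self, rng, pair):
        t = _template_with_pair(rng, pair)
        amps = predict_amplicons(t, pair)
        planted = [a for a in amps if a.start == pair.expected_span[0]]
        assert planted and planted[0].end == pair.expected_span[1]
        assert planted[0].length == pair.expected_size

    def test_no_reverse_site_means_no_product(self, rng):
        t = random_template(rng, 500)
        fwd = expand_concrete(VIP3_SCREENING_PAIR.forward)
        t = fwd + t[len(fwd):]
        assert predict_amplicons(t, VIP3_SCREENING_PAIR) == []

    def test_size_limits_suppress_spurious_pairings(self, rng):
        pair = PrimerPair("p", "ACGTAC", "TTTGGG")
        t = random_template(rng, 100)
        t = "ACGTAC" + t[6:50] + reverse_complement("TTTGGG") + t[56:]
        assert predict_amplicons(t, pair, size_limits=(50, 5000)) != []
        assert predict_amplicons(t, pair, size_limits=(100, 5000)) == []

    def test_strand_symmetry(self, rng):
        """Swapping primer roles on the reverse complement mirrors coordinates."""
        pair = VIP3_SCREENING_PAIR
        t = _template_with_pair(rng, pair)
        rc_t = reverse_complement(t)
        swapped = PrimerPair("sw", pair.reverse, pair.forward)
        amps = predict_amplicons(t, pair)
        mirrored = predict_amplicons(rc_t, swapped)
        assert {(a.start, a.end) for a in amps} == {
            (len(t) - a.end + 1, len(t) - a.start + 1) for a in mirrored
        }


class TestScreenCollection:
    def test_counts_and_rounding(self, rng):
        pair = VIP3_SCREENING_PAIR
        genomes = {}
        for i in range(8):
            if i < 3:
                genomes[f"g{i}"] = _template_with_pair(rng, pair)
            else:
                genomes[f"g{i}"] = random_template(rng, 2600)
        res = screen_collection(genomes)
        assert (res.n_positive, res.percent_positive) == (3, 38)  # 37.5 rounds up
        assert res.table.set_index("isolate_id")["positive"].sum() == 3

    def test_zero_carriers(self, rng):
        genomes = {f"g{i}": random_template(rng, 300) for i in range(4)}
        res = screen_collection(genomes)
        assert (res.n_positive, res.percent_positive) == (0, 0)

    def test_duplicate_ids_rejected(self, rng):
        recs = [("a", "ACGT" * 50), ("a", "ACGT" * 50)]
        with pytest.raises(ValueError, match="duplicate"):
            screen_collection(recs)

    def test_percent_rounding_half_away(self):
        assert round_half_away(22.5) == 23
        assert round_half_away(-22.5) == -23
        assert round_half_away(22.4) == 22


class TestTypeVip3:
    @pytest.mark.parametrize("label,size", [("vip3Aa", 1060), ("vip3Af", 1052), ("vip3Ag", 1027)])
    def test_planted_type_assigned_with_printed_size(self, rng, label, size):
        t = _template_with_pair(rng, VIP3_TYPING_REVERSE[label])
        res = type_vip3(t, isolate_id="x")
        assert res.assigned_type == label
        assert res.amplicon.length == size

    def test_no_site_is_none(self, rng):
        res = type_vip3(random_template(rng, 2600))
        assert res.assigned_type == "none" and res.amplicon is None

    def test_two_productive_primers_is_ambiguous(self, rng):
        t = _template_with_pair(rng, VIP3_TYPING_REVERSE["vip3Aa"])
        other = VIP3_TYPING_REVERSE["vip3Ag"]
        rev = reverse_complement(expand_concrete(other.reverse))
        end = other.expected_span[1]
        t = t[:end - len(rev)] + rev + t[end:]
        with pytest.raises(AmbiguousTypingError):
            type_vip3(t, isolate_id="x")


class TestMergeContigs:
    def test_three_base_overlap(self):
        assert merge_contigs("ACGTAC", "TACGG", 3) == "ACGTACGG"

    def test_identity_merge(self):
        x = "ACGTACGTAA"
        assert merge_contigs(x, x, len(x)) == x

    def test_no_overlap_raises(self):
        with pytest.raises(NoOverlapError):
            merge_contigs("AAAA", "CCCC", 2)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(150, 400), st.integers(100, 120))
    def test_split_and_merge_round_trip(self, seed, n, overlap):
        rng = np.random.default_rng(seed)
        original = random_template(rng, n)
        cut = n // 2
        left, right = original[:cut + overlap // 2], original[cut - overlap // 2:]
        assert merge_contigs(left, right, min_overlap=overlap // 2) == original


def naive_endgap_free_identity(query, ref, match=1, mismatch=-1, gap=-2):
    """Exhaustive DP for end-gap-free global alignment; returns best score."""
    n, m = len(ref), len(query)
    NEG = float("-inf")
    score = [[0.0] * (m + 1) for _ in range(n + 1)]  # free leading gaps
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == query[j - 1] else mismatch
            score[i][j] = max(score[i - 1][j - 1] + s,
                              score[i - 1][j] + gap,
                              score[i][j - 1] + gap)
    # free trailing gaps: best over last row/column
    best = max(max(score[n][j] for j in range(m + 1)),
               max(score[i][m] for i in range(n + 1)))
    return best


class TestPercentIdentity:
    def test_identical_sequences(self):
        rep = percent_identity("ACGTACGT", "ACGTACGT")
        assert (rep.identity_pct, rep.query_cover_pct) == (100, 100)

    def test_six_substitutions_in_hundred(self, rng):
        ref = random_template(rng, 100)
        q = list(ref)
        for pos in [3, 17, 40, 55, 71, 90]:
            q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
        rep = percent_identity("".join(q), ref)
        assert rep.identity_pct == 94
        assert rep.query_cover_pct == 100

    def test_alignment_score_matches_dp_oracle(self, rng):
        """The aligner's optimum equals an exhaustive DP on small pairs."""
        from btchar.primers import _make_aligner

        aligner = _make_aligner(1, -1, -2)
        for _ in range(50):
            a = random_template(rng, int(rng.integers(5, 20)))
            b = random_template(rng, int(rng.integers(5, 20)))
            assert aligner.score(a, b) == naive_endgap_free_identity(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("", "ACGT")
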