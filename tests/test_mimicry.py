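import math

import numpy as np
import pytest

from autoab.core_io import ProteinRecord
from autoab.mimicry import (
    MaskedProtein,
    MatchFrequency,
    PeptideSet,
    dedup_exact,
    filter_repeats,
    find_matches,
    has_repeat_run,
    make_peptides,
    match_frequency_test,
    matched_residue_count,
    mimicry_screen,
    seg_mask,
    window_entropy,
)


def unmasked(rec: ProteinRecord) -> MaskedProtein:
    return MaskedProtein(rec.id, rec.sequence, np.zeros(len(rec.sequence), bool))


def brute_force_matches(hosts, peptides, threshold):
    """Independent oracle: all maximal identical runs by direct substring
    comparison over every (host, peptide, host offset, peptide offset) pair,
    with the same containment collapse applied."""
    raw = set()
    for h in hosts:
        ok = ~h.mask
        for pep in peptides.peptides:
            for i in range(len(h.sequence)):
                for j in range(len(pep.sequence)):
                    # run starting exactly at (i, j): must not be extendable left
                    if i > 0 and j > 0 and ok[i - 1] and h.sequence[i - 1] == pep.sequence[j - 1]:
                        continue
                    length = 0
                    while (
                        i + length < len(h.sequence)
                        and j + length < len(pep.sequence)
                        and ok[i + length]
                        and h.sequence[i + length] == pep.sequence[j + length]
                    ):
                        length += 1
                    if length >= threshold:
                        raw.add((h.id, pep.source_id, i, pep.offset + j, length))
    by_pair = {}
    for item in raw:
        by_pair.setdefault((item[0], item[1]), []).append(item)
    final = set()
    for items in by_pair.values():
        for it in items:
            contained = any(
                k[2] <= it[2] and it[2] + it[4] <= k[2] + k[4] and k[4] > it[4] for k in items
            )
            if not contained:
                final.add(it)
    # collapse identical host intervals from overlapping peptide windows
    return {
        (host, src, hstart, length)
        for host, src, hstart, vstart, length in final
    }


class TestPreprocessing:
    def test_dedup_keeps_first(self):
        recs = [ProteinRecord("a", "MKV"), ProteinRecord("b", "MKV")]
        assert dedup_exact(recs) == [recs[0]]

    def test_dedup_distinct_unchanged(self):
        recs = [ProteinRecord("a", "MKV"), ProteinRecord("b", "MKW")]
        assert dedup_exact(recs) == recs

    def test_dedup_matches_set_oracle(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACDE"), 5)) for _ in range(10)]
        recs = [ProteinRecord(f"p{i}", s) for i, s in enumerate(seqs)]
        assert len(dedup_exact(recs)) == len(set(seqs))

    @pytest.mark.parametrize("length,k,expected", [(14, 14, 1), (20, 14, 7), (10, 14, 0)])
    def test_peptide_counts(self, length, k, expected):
        rec = ProteinRecord("p", "ACDEFGHIKLMNPQRSTVWY"[:length] if length <= 20 else "A" * length)
        ps = make_peptides(rec, k=k)
        assert len(ps.peptides) == expected
        if expected:
            assert [p.offset for p in ps.peptides] == list(range(expected))
            assert all(len(p.sequence) == k for p in ps.peptides)

    def test_repeat_filter_rules(self):
        triple = PeptideSet(k=14, peptides=make_peptides(ProteinRecord("p", "AAACDEFGHIKLMN"), 14).peptides)
        assert filter_repeats(triple).peptides == []
        double = make_peptides(ProteinRecord("p", "AACDAEFGHIKLMN"), 14)
        assert len(filter_repeats(double).peptides) == 1

    def test_repeat_filter_matches_scan_oracle(self):
        rng = np.random.default_rng(1)
        peps = ["".join(rng.choice(list("AC"), 14)) for _ in range(100)]
        ps = PeptideSet(k=14, peptides=make_peptides(ProteinRecord("p", "X" * 14), 14).peptides)
        from autoab.mimicry import Peptide

        ps = PeptideSet(k=14, peptides=[Peptide("p", i, s) for i, s in enumerate(peps)])
        survivors = {p.sequence for p in filter_repeats(ps).peptides}
        oracle = {
            s for s in peps
            if not any(s[i] == s[i + 1] == s[i + 2] for i in range(len(s) - 2))
        }
        assert survivors == oracle


class TestSegMask:
    def test_homopolymer_fully_masked(self):
        m = seg_mask(ProteinRecord("p", "K" * 16))
        assert m.mask.all()

    def test_maximal_entropy_unmasked(self):
        m = seg_mask(ProteinRecord("p", "ACDEFGHIKLMNPQRSTVWY"))
        assert not m.mask.any()

    def test_short_sequence_unmasked(self):
        m = seg_mask(ProteinRecord("p", "MKVLA"))
        assert not m.mask.any()

    def test_crafted_mask_agrees_with_entropy_oracle(self):
        seq = "Q" * 20 + "ACDEFGHIKLMNPQRSTVWY"
        m = seg_mask(ProteinRecord("p", seq))
        # independent windowed-entropy computation
        window, locut, hicut = 12, 2.2, 2.5
        ents = []
        for i in range(len(seq) - window + 1):
            win = seq[i : i + window]
            freq = {c: win.count(c) for c in set(win)}
            ents.append(-sum(v / window * math.log2(v / window) for v in freq.values()))
        trigger = [e < locut for e in ents]
        assert any(trigger) and not all(trigger)
        # every residue of a trigger window must be masked
        for i, t in enumerate(trigger):
            if t:
                assert m.mask[i : i + window].all()
        # the diverse tail is unmasked
        assert not m.mask[-6:].any()

    def test_entropy_values(self):
        assert window_entropy("AAAA") == 0.0
        assert window_entropy("ACDE") == pytest.approx(2.0)


class TestFindMatches:
    def host(self, seq, pid="h"):
        return unmasked(ProteinRecord(pid, seq))

    def peptides(self, *seqs, source="v"):
        from autoab.mimicry import Peptide

        return PeptideSet(k=14, peptides=[Peptide(f"{source}{i}", 0, s) for i, s in enumerate(seqs)])

    def test_shared_eightmer_single_match(self):
        # shared "SPRKQEAE" with mismatching flanks: one maximal length-8 match
        host = self.host("MKWDASPRKQEAEGHTV")
        peps = self.peptides("ACSPRKQEAEIKLM")
        matches = find_matches([host], peps, threshold=7)
        assert len(matches) == 1
        assert matches[0].sequence == "SPRKQEAE"
        assert matches[0].length == 8
        assert matches[0].host_start == 5

    def test_shared_sevenmer(self):
        host = self.host("GGWSYFGLRTKDEH")
        peps = self.peptides("ACSYFGLRTYIKLM")
        matches = find_matches([host], peps, threshold=7)
        assert [m.sequence for m in matches] == ["SYFGLRT"]

    def test_below_threshold_empty(self):
        host = self.host("MKWDCSPRKQGHTV")  # shares only a 6-mer SPRKQ+?
        peps = self.peptides("ACSPRKQMWYIKLM")
        assert find_matches([host], peps, threshold=7) == []

    def test_masked_host_residue_breaks_match(self):
        rec = ProteinRecord("h", "MKWDCSPRKQEAEGHTV")
        mask = np.zeros(len(rec.sequence), bool)
        mask[8] = True  # inside the shared peptide
        host = MaskedProtein(rec.id, rec.sequence, mask)
        peps = self.peptides("ACSPRKQEAEIKLM")
        assert find_matches([host], peps, threshold=7) == []

    def test_overlapping_peptides_collapsed(self):
        # the same shared 8-mer seen through several sliding 14-mer windows
        viral = ProteinRecord("v", "ACDFGHSPRKQEAEWYMKCDHF")
        peps = make_peptides(viral, k=14)
        host = self.host("MKWDCSPRKQEAEGHTV")
        matches = find_matches([host], peps, threshold=7)
        assert len(matches) == 1
        assert matches[0].length == 8

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(42)
        alphabet = list("ACDEFG")  # small alphabet forces frequent matches
        hosts = [
            unmasked(ProteinRecord(f"h{i}", "".join(rng.choice(alphabet, 60))))
            for i in range(20)
        ]
        from autoab.mimicry import Peptide

        peps = PeptideSet(
            k=14,
            peptides=[
                Peptide(f"v{i}", int(rng.integers(0, 50)), "".join(rng.choice(alphabet, 14)))
                for i in range(150)
            ],
        )
        got = {
            (m.host_id, m.viral_source_id, m.host_start, m.length)
            for m in find_matches(hosts, peps, threshold=4)
        }
        assert got == brute_force_matches(hosts, peps, threshold=4)

    def test_masking_monotonicity(self):
        rng = np.random.default_rng(3)
        alphabet = list("ACDE")
        seqs = ["".join(rng.choice(alphabet, 40)) for _ in range(5)]
        from autoab.mimicry import Peptide

        peps = PeptideSet(
            k=14, peptides=[Peptide(f"v{i}", 0, "".join(rng.choice(alphabet, 14))) for i in range(40)]
        )
        plain = [unmasked(ProteinRecord(f"h{i}", s)) for i, s in enumerate(seqs)]
        masked = []
        for i, s in enumerate(seqs):
            mask = rng.random(len(s)) < 0.2
            masked.append(MaskedProtein(f"h{i}", s, mask))
        n_plain = len(find_matches(plain, peps, threshold=3))
        n_masked = len(find_matches(masked, peps, threshold=3))
        assert n_masked <= n_plain

    def test_role_swap_symmetry(self):
        # with masking disabled, segmenting either side yields the same shared
        # maximal runs (up to coordinate bookkeeping)
        a = ProteinRecord("a", "MKWDCSPRKQEAEGHTVYLNW")
        b = ProteinRecord("b", "ACSPRKQEAEIKLMWGHTVYL")
        peps_b = make_peptides(b, k=14)
        peps_a = make_peptides(a, k=14)
        m_ab = find_matches([unmasked(a)], peps_b, threshold=7)
        m_ba = find_matches([unmasked(b)], peps_a, threshold=7)
        assert sorted(m.sequence for m in m_ab) == sorted(m.sequence for m in m_ba)


class TestMatchFrequency:
    def test_printed_contingency_significant(self):
        stat, p = match_frequency_test(
            MatchFrequency(201, 34_070), MatchFrequency(5_801, 2_026_890)
        )
        assert p < 0.00001

    def test_identical_frequencies_p_one(self):
        stat, p = match_frequency_test(MatchFrequency(10, 1000), MatchFrequency(100, 10_000))
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_hand_expected_counts_oracle(self):
        # table [[5,95],[5,995]]: chi2 = sum (O-E)^2/E with margins
        # (100, 1000) x (10, 1090), N = 1100
        stat, p = match_frequency_test(MatchFrequency(5, 100), MatchFrequency(5, 1000))
        E = [100 * 10 / 1100, 100 * 1090 / 1100, 1000 * 10 / 1100, 1000 * 1090 / 1100]
        O = [5, 95, 5, 995]
        chi2_hand = sum((o - e) ** 2 / e for o, e in zip(O, E))
        assert stat == pytest.approx(chi2_hand, rel=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            match_frequency_test(MatchFrequency(0, 0), MatchFrequency(1, 10))

    def test_matched_residue_count(self):
        host = unmasked(ProteinRecord("h", "MKWDCSPRKQEAEGHTV"))
        from autoab.mimicry import PeptideMatch

        matches = [
            PeptideMatch("h", "v", 5, 2, 8, "SPRKQEAE"),
            PeptideMatch("h", "w", 7, 0, 7, "RKQEAEG"),  # overlaps the first
        ]
        mf = matched_residue_count([host], matches)
        assert mf.total_residues == 17
        assert mf.matched_residues == 9  # union of [5,13) and [7,14)
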