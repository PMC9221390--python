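"""Molecular-mimicry pipeline: shared ungapped peptides between host and viral proteins.

The pipeline mirrors the standard mimicry screen: viral proteomes are
deduplicated exactly, chopped into overlapping 14-mer peptides (sliding window
1), and peptides containing a run of 3 or more identical residues are
discarded; host (human) proteins are masked for low-complexity regions by a
SEG-style windowed-entropy filter; then every maximal ungapped run of
identical residues of length >= 7 shared between a host protein and a viral
peptide is reported.  Match frequencies at the residue level are compared
between protein groups (e.g. autoantigens vs unreactive proteins) with a
Pearson chi-square test, which replaces alignment-score statistics as the
database-size correction.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from autoab.core_io import ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_KMER = 14
DEFAULT_THRESHOLD = 7
DEFAULT_RUN = 3


@dataclass(frozen=True)
class Peptide:
    """One k-mer cut from a source protein (0-based offset)."""

    source_id: str
    offset: int
    sequence: str


@dataclass
class PeptideSet:
    """Sliding-window peptides, optionally repeat-filtered."""

    k: int
    peptides: list[Peptide] = field(default_factory=list)


@dataclass
class MaskedProtein:
    """A protein with a per-residue low-complexity mask (True = excluded)."""

    id: str
    sequence: str
    mask: np.ndarray  # bool, same length as sequence

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.sequence),):
            raise ValueError(f"{self.id}: mask length != sequence length")


@dataclass(frozen=True)
class PeptideMatch:
    """A maximal ungapped identical-residue run shared by host and viral peptide."""

    host_id: str
    viral_source_id: str
    host_start: int  # 0-based
    viral_start: int  # 0-based within the viral source protein
    length: int
    sequence: str


@dataclass(frozen=True)
class MatchFrequency:
    """Residue-level match burden of a protein database."""

    matched_residues: int
    total_residues: int

    def __post_init__(self) -> None:
        if not 0 <= self.matched_residues <= self.total_residues:
            raise ValueError("need 0 <= matched <= total residues")


# ---------------------------------------------------------------------------
# Preprocessing


def dedup_exact(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep the first occurrence of each exact sequence, order-preserving.

    Identity cut-off 1 semantics: only byte-identical sequences collapse.
    """
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(rec)
    return out


def make_peptides(record: ProteinRecord, k: int = DEFAULT_KMER, step: int = 1) -> PeptideSet:
    """All k-mers of the sequence at the given stride (pre-filter).

    A sequence shorter than k yields an empty set with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    L = len(record.sequence)
    if L < k:
        logger.warning("%s: length %d < k=%d, no peptides generated", record.id, L, k)
        return PeptideSet(k=k)
    peptides = [Peptide(record.id, i, record.sequence[i : i + k]) for i in range(0, L - k + 1, step)]
    return PeptideSet(k=k, peptides=peptides)


def has_repeat_run(sequence: str, run: int = DEFAULT_RUN) -> bool:
    """True if the sequence contains >= run consecutive identical residues."""
    count = 1
    for prev, cur in zip(sequence, sequence[1:]):
        count = count + 1 if cur == prev else 1
        if count >= run:
            return True
    return run <= 1


def filter_repeats(peptides: PeptideSet, run: int = DEFAULT_RUN) -> PeptideSet:
    """Discard whole peptides containing a run of >= ``run`` identical residues.

    Whole-peptide removal (rather than excising the run) avoids creating
    chimeric peptides that never occur in the source proteome.
    """
    if run < 2:
        raise ValueError("run must be >= 2")
    kept = [p for p in peptides.peptides if not has_repeat_run(p.sequence, run)]
    return PeptideSet(k=peptides.k, peptides=kept)


# ---------------------------------------------------------------------------
# SEG-style low-complexity masking


def window_entropy(window: str) -> float:
    """Shannon compositional entropy of a residue window, in bits."""
    freq: dict[str, int] = {}
    for ch in window:
        freq[ch] = freq.get(ch, 0) + 1
    n = len(window)
    return -sum((c / n) * math.log2(c / n) for c in freq.values())


def seg_mask(
    record: ProteinRecord, window: int = 12, locut: float = 2.2, hicut: float = 2.5
) -> MaskedProtein:
    """SEG-style low-complexity masking by windowed Shannon entropy.

    Windows whose compositional entropy (bits) falls below ``locut`` trigger
    candidate regions, which are extended over every overlapping window whose
    entropy stays below ``hicut``.  All residues covered by the extended
    windows are masked.  Sequences shorter than the window are left unmasked.
    X residues (unknown/pre-masked) are always masked.
    """
    if window <= 0 or locut <= 0:
        raise ValueError("window and locut must be positive")
    if locut > hicut:
        raise ValueError("locut must be <= hicut")
    seq = record.sequence
    L = len(seq)
    mask = np.zeros(L, dtype=bool)
    if L >= window:
        n_win = L - window + 1
        ent = np.array([window_entropy(seq[i : i + window]) for i in range(n_win)])
        trigger = ent < locut
        extendable = ent < hicut
        covered = np.zeros(n_win, dtype=bool)
        i = 0
        while i < n_win:
            if trigger[i] and not covered[i]:
                lo = i
                while lo > 0 and extendable[lo - 1]:
                    lo -= 1
                hi = i
                while hi + 1 < n_win and extendable[hi + 1]:
                    hi += 1
                covered[lo : hi + 1] = True
                mask[lo : hi + window] = True
                i = hi + 1
            else:
                i += 1
    for i, ch in enumerate(seq):
        if ch == "X":
            mask[i] = True
    return MaskedProtein(record.id, seq, mask)


# ---------------------------------------------------------------------------
# Ungapped matching


def _maximal_runs_in_peptide(
    host_seq: str,
    host_ok: np.ndarray,
    peptide: str,
    threshold: int,
) -> list[tuple[int, int, int]]:
    """Maximal identical runs (host_start, pep_start, length) >= threshold.

    Host positions where ``host_ok`` is False (masked) break a run; runs are
    maximal within the peptide's extent.  Brute-force over diagonals of the
    host x peptide identity grid.
    """
    out = []
    Lh, Lp = len(host_seq), len(peptide)
    # diagonal d: host index = pep index + d
    for d in range(-(Lp - 1), Lh):
        run = 0
        for j in range(Lp):
            i = j + d
            if 0 <= i < Lh and host_ok[i] and host_seq[i] == peptide[j]:
                run += 1
            else:
                if run >= threshold:
                    out.append((j - run + d, j - run, run))
                run = 0
        if run >= threshold:
            out.append((Lp - run + d, Lp - run, run))
    return out


def find_matches(
    hosts: Sequence[MaskedProtein],
    peptides: PeptideSet,
    threshold: int = DEFAULT_THRESHOLD,
) -> list[PeptideMatch]:
    """All maximal ungapped identical runs of length >= threshold between any
    host protein and any viral peptide.

    Host-side masked residues break matches.  A seed index of host
    ``threshold``-mers keeps the search near-linear in database size.  Reports
    are collapsed twice: (1) identical host intervals reached from different
    overlapping 14-mers count once; (2) a match whose host interval is
    contained in a longer match against the same viral source protein is
    dropped, so a shared 8-mer is reported as one length-8 match, not also as
    its two internal 7-mers.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    # seed index: threshold-mer -> [(host_idx, pos)]
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    oks = []
    for hi, host in enumerate(hosts):
        ok = ~host.mask
        oks.append(ok)
        seq = host.sequence
        for pos in range(len(seq) - threshold + 1):
            if ok[pos : pos + threshold].all():
                index[seq[pos : pos + threshold]].append((hi, pos))

    raw: set[tuple[str, str, int, int, int, str]] = set()
    for pep in peptides.peptides:
        pseq = pep.sequence
        # (host_idx, diagonal) -> peptide-coordinate intervals already extended
        seen_runs: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
        for j in range(len(pseq) - threshold + 1):
            seed = pseq[j : j + threshold]
            for hi, pos in index.get(seed, ()):
                d = pos - j
                if any(lo <= j and j + threshold - 1 <= up for lo, up in seen_runs[(hi, d)]):
                    continue
                host = hosts[hi]
                ok = oks[hi]
                # extend maximally along the diagonal within the peptide
                lo_j, hi_j = j, j + threshold - 1
                while lo_j > 0 and 0 <= lo_j - 1 + d < len(host.sequence) and ok[lo_j - 1 + d] and host.sequence[lo_j - 1 + d] == pseq[lo_j - 1]:
                    lo_j -= 1
                while (
                    hi_j + 1 < len(pseq)
                    and hi_j + 1 + d < len(host.sequence)
                    and ok[hi_j + 1 + d]
                    and host.sequence[hi_j + 1 + d] == pseq[hi_j + 1]
                ):
                    hi_j += 1
                seen_runs[(hi, d)].append((lo_j, hi_j))
                length = hi_j - lo_j + 1
                host_start = lo_j + d
                # verify full identity (seed guaranteed, extension constructed)
                raw.add(
                    (
                        host.id,
                        pep.source_id,
                        host_start,
                        pep.offset + lo_j,
                        length,
                        host.sequence[host_start : host_start + length],
                    )
                )

    # containment collapse per (host, viral source)
    by_pair: dict[tuple[str, str], list[tuple]] = defaultdict(list)
    for item in raw:
        by_pair[(item[0], item[1])].append(item)
    matches: list[PeptideMatch] = []
    for items in by_pair.values():
        items.sort(key=lambda t: (-t[4], t[2], t[3]))
        kept: list[tuple] = []
        for it in items:
            contained = any(
                k[2] <= it[2] and it[2] + it[4] <= k[2] + k[4] and k[4] > it[4] for k in kept
            )
            if not contained:
                kept.append(it)
        # identical host intervals from different viral offsets count once
        seen_iv: set[tuple[int, int, str]] = set()
        for it in sorted(kept, key=lambda t: (t[2], t[3])):
            key = (it[2], it[4], it[5])
            if key in seen_iv:
                continue
            seen_iv.add(key)
            matches.append(PeptideMatch(*it[:2], host_start=it[2], viral_start=it[3], length=it[4], sequence=it[5]))
    matches.sort(key=lambda m: (m.host_id, m.host_start, m.viral_source_id, m.viral_start))
    return matches


def matched_residue_count(hosts: Sequence[MaskedProtein], matches: Sequence[PeptideMatch]) -> MatchFrequency:
    """Residue-level match burden: host residues covered by any reported match."""
    covered: dict[str, set[int]] = defaultdict(set)
    for m in matches:
        covered[m.host_id].update(range(m.host_start, m.host_start + m.length))
    total = sum(len(h.sequence) for h in hosts)
    matched = sum(len(v) for v in covered.values())
    return MatchFrequency(matched, total)


def match_frequency_test(group_a: MatchFrequency, group_b: MatchFrequency) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) comparing residue-level
    match frequencies of two protein databases.

    The 2x2 table is (matched, unmatched) x (group_a, group_b).  Returns
    (statistic, two-sided p).
    """
    if group_a.total_residues == 0 or group_b.total_residues == 0:
        raise ValueError("both databases must contain residues")
    table = np.array(
        [
            [group_a.matched_residues, group_a.total_residues - group_a.matched_residues],
            [group_b.matched_residues, group_b.total_residues - group_b.matched_residues],
        ]
    )
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Convenience: the full screen


def mimicry_screen(
    hosts: Sequence[ProteinRecord],
    viral: Sequence[ProteinRecord],
    threshold: int = DEFAULT_THRESHOLD,
    k: int = DEFAULT_KMER,
    mask_hosts: bool = True,
) -> list[PeptideMatch]:
    """Run the full pipeline: dedup viral, 14-mers, repeat filter, host masking,
    ungapped matching at the threshold."""
    viral_unique = dedup_exact(viral)
    pepset = PeptideSet(k=k)
    for rec in viral_unique:
        pepset.peptides.extend(filter_repeats(make_peptides(rec, k=k)).peptides)
    if mask_hosts:
        masked = [seg_mask(h) for h in hosts]
    else:
        masked = [MaskedProtein(h.id, h.sequence, np.zeros(len(h.sequence), bool)) for h in hosts]
    return find_matches(masked, pepset, threshold=threshold)
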