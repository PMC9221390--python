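"""Synthetic-data generators emulating every input the pipeline consumes.

The generators stand in for the raw study sera and the external sequence /
annotation / expression downloads, reproducing the statistical structure each
analysis stage assumes:

- binary antibody x subject response matrices with logit-normal between-study
  heterogeneity and optionally planted concordant antibody pairs;
- host and viral protein sets with planted shared peptides on clean random
  backgrounds (screened so no accidental >= 7-mer is shared and flanks are
  forced to mismatch, making planted matches maximal at exactly their length);
- organ x gene TPM tables with planted organ-specific genes;
- subcellular-localization annotation tables with exact group frequencies.

Every generator is a pure function of its SimulationConfig: identical seeds
give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from autoab.core_io import AnnotationTable, ProteinRecord, StudyResponseSet, Subject
from autoab.mimicry import has_repeat_run

logger = logging.getLogger(__name__)

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Shared autoantigen-viral peptides reported for common human viruses
#: (respiratory and childhood viruses), as (autoantigen, viral protein
#: accession, peptide).  28 seven-residue peptides and one eight-residue
#: peptide across 21 autoantigens; the default plant set for gen_proteomes.
REFERENCE_MIMICRY_PEPTIDES: list[tuple[str, str, str]] = [
    ("ADNP2", "P16812", "LPVPPGG"),
    ("ADNP2", "H9C1C1", "SYFGLRT"),
    ("AHCY", "F8WQQ3", "GKLNVKL"),
    ("AMY2A", "P16766", "SAGTSST"),
    ("APEX2", "M1JRT8", "NRSGYSG"),
    ("APEX2", "P09289", "ALLAAGS"),
    ("C9orf78", "P16764", "EDCLYEL"),
    ("CTTNBP2NL", "P52529", "EQLRAKL"),
    ("CTTNBP2NL", "C4AL53", "AKLNREE"),
    ("CTTNBP2NL", "Q6SW92", "SSNTVVA"),
    ("FLJ36888", "P52355", "TIKRTLV"),
    ("KAZ", "O09800", "ARCETQN"),
    ("MAK", "P16793", "GTSEVDE"),
    ("MAK", "Q01350", "WPEGYQL"),
    ("MAK", "Q69513", "KSDSELS"),
    ("MAPK13", "Q8QT31", "VIGLLDV"),
    ("MTUS2", "P09284", "IDQNTVV"),
    ("MTUS2", "A0A0D5Z8N5", "SPIKLSP"),
    ("MYLK2", "Q6SWD0", "AEEGKNI"),
    ("PAK1", "P24433", "SVIEPLP"),
    ("PAK7", "P16739", "ATAQELL"),
    ("PELI1", "Q9QJ30", "LRQEINA"),
    ("PML", "A0MK42", "TLGAVVP"),
    ("RABGEF1", "I1V183", "SPRKQEAE"),
    ("SECISBP2", "D3JIS2", "ELTVAAR"),
    ("TAF1D", "P09252", "DATHLED"),
    ("TRAP1", "P0C723", "ALIRKLR"),
    ("TRAP1", "P10200", "AQLGPRR"),
    ("ZNF688", "Q1HVD1", "GAQPPAP"),
]


@dataclass
class SimulationConfig:
    """Parameters for all generators.  ``seed`` is mandatory."""

    seed: int
    # response matrices
    n_studies: int = 5
    subjects_per_study: int = 50
    n_antibodies: int = 50
    true_prevalences: float | Sequence[float] = 0.2
    between_study_sd: float = 0.3  # logit scale
    probed_fraction: float = 1.0
    planted_pairs: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    # proteomes
    planted_peptides: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(REFERENCE_MIMICRY_PEPTIDES)
    )
    n_background_proteins: int = 10
    background_length: int = 200
    viral_background_length: int = 60
    # TPM tables
    tpm_organs: list[str] = field(
        default_factory=lambda: [
            "brain", "testis", "liver", "lung", "heart",
            "kidney", "muscle", "pancreas", "skin", "spleen",
        ]
    )
    tpm_n_genes: int = 100
    tpm_planted: dict[str, str] = field(default_factory=dict)  # gene -> organ
    tpm_fold_change: float = 16.0
    # annotations
    ann_group_fractions: dict[str, float] = field(default_factory=dict)
    ann_n_proteins: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_studies", "subjects_per_study", "n_antibodies", "background_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for (_, _), target in self.planted_pairs:
            if not -1 < target < 1:
                raise ValueError(f"planted phi target must be in (-1, 1), got {target}")


# ---------------------------------------------------------------------------
# Response matrices


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _expit(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x)))


def joint_bernoulli_probs(p1: float, p2: float, phi_target: float) -> tuple[float, float, float, float]:
    """Cell probabilities (p11, p10, p01, p00) of a 2x2 joint Bernoulli with
    the given marginals and phi.  Raises if the target is infeasible."""
    q1, q2 = 1 - p1, 1 - p2
    p11 = p1 * p2 + phi_target * np.sqrt(p1 * q1 * p2 * q2)
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if not lo - 1e-12 <= p11 <= hi + 1e-12:
        phi_lo = (lo - p1 * p2) / np.sqrt(p1 * q1 * p2 * q2)
        phi_hi = (hi - p1 * p2) / np.sqrt(p1 * q1 * p2 * q2)
        raise ValueError(
            f"phi={phi_target} infeasible for marginals ({p1}, {p2}); "
            f"feasible range is [{phi_lo:.3f}, {phi_hi:.3f}]"
        )
    p11 = min(max(p11, lo), hi)
    return p11, p1 - p11, p2 - p11, 1 - p1 - p2 + p11


def gen_response_matrices(config: SimulationConfig) -> list[StudyResponseSet]:
    """Bernoulli response matrices with logit-normal between-study heterogeneity.

    For each antibody, each study's prevalence is drawn logit-normal around
    the antibody's true prevalence with sd ``between_study_sd``; responses are
    Bernoulli per subject.  Planted pairs share a joint Bernoulli with the
    requested phi (built from the study-level marginals).  When
    ``probed_fraction < 1`` each study probes a random antibody subset and the
    rest are missing for all of its subjects.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_antibodies
    truths = np.broadcast_to(np.asarray(config.true_prevalences, dtype=float), (m,)).copy()
    if ((truths <= 0) | (truths >= 1)).any():
        raise ValueError("true prevalences must be in (0, 1)")
    antibodies = [f"AB{i:04d}" for i in range(m)]
    planted_members = {i for (pair, _) in config.planted_pairs for i in pair}
    studies = []
    for s in range(config.n_studies):
        n = config.subjects_per_study
        p_study = _expit(
            np.array([_logit(t) for t in truths]) + rng.normal(0.0, config.between_study_sd, m)
        )
        responses = (rng.random((m, n)) < p_study[:, None]).astype(float)
        for (i, j), target in config.planted_pairs:
            # pair members share one study-level marginal (mean of their true
            # logits plus a common random effect) so the target phi stays
            # feasible; unequal drifted marginals would cap attainable phi
            shared = float(
                _expit(
                    (_logit(truths[i]) + _logit(truths[j])) / 2.0
                    + rng.normal(0.0, config.between_study_sd)
                )
            )
            p_study[i] = p_study[j] = shared
            p11, p10, p01, p00 = joint_bernoulli_probs(p_study[i], p_study[j], target)
            draw = rng.choice(4, size=n, p=[p11, p10, p01, p00])
            responses[i] = np.isin(draw, (0, 1)).astype(float)
            responses[j] = np.isin(draw, (0, 2)).astype(float)
        if config.probed_fraction < 1.0:
            n_probe = max(1, int(round(config.probed_fraction * m)))
            keep = set(rng.choice(m, size=n_probe, replace=False))
            keep |= planted_members
            for i in range(m):
                if i not in keep:
                    responses[i] = np.nan
        subjects = [
            Subject(
                subject_id=f"S{s}_{k:03d}",
                age=float(rng.uniform(0.0, 84.0)),
                sex="female" if k % 2 == 0 else "male",
                group="control",
            )
            for k in range(n)
        ]
        studies.append(StudyResponseSet(f"study_{s + 1}", list(antibodies), subjects, responses))
    return studies


# ---------------------------------------------------------------------------
# Proteomes with planted peptides


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    """Uniform random residues with no run of 3 identical residues."""
    out: list[str] = []
    while len(out) < length:
        ch = _ALPHABET[rng.integers(20)]
        if len(out) >= 2 and out[-1] == out[-2] == ch:
            continue
        out.append(ch)
    return out


def _embed(background: list[str], peptide: str, start: int) -> None:
    background[start : start + len(peptide)] = list(peptide)


def _fix_flanks(seq: list[str], start: int, length: int, forbidden: dict[int, set[str]], rng) -> None:
    """Resample flanking residues so they avoid forbidden characters and runs."""
    for pos in (start - 1, start + length):
        if not 0 <= pos < len(seq):
            continue
        bad = set(forbidden.get(pos, set()))
        for _ in range(100):
            ch = _ALPHABET[rng.integers(20)]
            if ch in bad:
                continue
            seq[pos] = ch
            lo = max(0, pos - 2)
            window = "".join(seq[lo : min(len(seq), pos + 3)])
            if not has_repeat_run(window, 3):
                break
        else:  # pragma: no cover - 100 draws over 20 letters cannot all fail
            raise RuntimeError("could not sample a valid flank residue")


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def gen_proteomes(
    config: SimulationConfig, match_threshold: int = 7, max_retries: int = 50
) -> tuple[list[ProteinRecord], list[ProteinRecord], pd.DataFrame]:
    """Host and viral protein sets with each configured peptide planted once
    in its host and once in a viral protein.

    Backgrounds are uniform random with no 3-runs; host flanks of each plant
    are forced to differ from the corresponding viral flanks so every planted
    match is maximal at exactly the peptide's length.  The whole instance is
    rejected and regenerated if host and viral sets share any
    ``match_threshold``-mer that is not part of a planted peptide, or if a
    planted k-mer occurs outside a plant.  Returns (hosts, viral proteins,
    truth table with exact coordinates).
    """
    for plant in config.planted_peptides:
        host_id, viral_id, pep = plant
        if len(pep) > config.background_length - 2:
            raise ValueError(f"peptide {pep!r} longer than background allows")
        if has_repeat_run(pep, 3):
            raise ValueError(f"peptide {pep!r} contains a 3-run and would be repeat-filtered")

    rng = np.random.default_rng(config.seed)
    by_host: dict[str, list[tuple[str, str]]] = {}
    for host_id, viral_id, pep in config.planted_peptides:
        by_host.setdefault(host_id, []).append((viral_id, pep))

    for attempt in range(max_retries):
        truth_rows = []
        hosts: list[ProteinRecord] = []
        virals: list[ProteinRecord] = []
        host_flanks: dict[tuple[str, str], tuple[str, str]] = {}

        for host_id, plants in by_host.items():
            L = max(config.background_length, sum(len(p) + 6 for _, p in plants) + 10)
            seq = _random_seq(rng, L)
            slot = L // (len(plants) + 1)
            for idx, (viral_id, pep) in enumerate(plants):
                start = slot * (idx + 1) - len(pep) // 2
                _embed(seq, pep, start)
                _fix_flanks(seq, start, len(pep), {}, rng)
                host_flanks[(host_id, pep)] = (
                    seq[start - 1] if start > 0 else "",
                    seq[start + len(pep)] if start + len(pep) < L else "",
                )
                truth_rows.append(
                    {
                        "host_id": host_id,
                        "viral_id": viral_id,
                        "peptide": pep,
                        "host_start": start,
                        "length": len(pep),
                    }
                )
            hosts.append(ProteinRecord(host_id, "".join(seq)))

        for i in range(config.n_background_proteins):
            hosts.append(ProteinRecord(f"BG{i:03d}", "".join(_random_seq(rng, config.background_length))))

        viral_starts = {}
        for host_id, viral_id, pep in config.planted_peptides:
            Lv = max(config.viral_background_length, len(pep) + 10)
            vseq = _random_seq(rng, Lv)
            vstart = int(rng.integers(3, Lv - len(pep) - 3))
            _embed(vseq, pep, vstart)
            left, right = host_flanks[(host_id, pep)]
            forbidden = {}
            if left:
                forbidden[vstart - 1] = {left}
            if right:
                forbidden[vstart + len(pep)] = {right}
            _fix_flanks(vseq, vstart, len(pep), forbidden, rng)
            virals.append(ProteinRecord(viral_id, "".join(vseq)))
            viral_starts[(viral_id, pep)] = vstart

        # screening: no accidental shared k-mers outside the plants
        k = match_threshold
        planted_kmers = {km for _, _, pep in config.planted_peptides for km in _kmers(pep, k)}
        host_all = set().union(*(_kmers(h.sequence, k) for h in hosts))
        viral_all = set().union(*(_kmers(v.sequence, k) for v in virals))
        shared = host_all & viral_all
        if shared - planted_kmers:
            continue
        # planted k-mers must occur only inside planted intervals
        intervals_h: dict[str, list[tuple[int, int]]] = {}
        for row in truth_rows:
            intervals_h.setdefault(row["host_id"], []).append(
                (row["host_start"], row["host_start"] + row["length"])
            )
        clean = True
        for km in planted_kmers:
            for h in hosts:
                pos = h.sequence.find(km)
                while pos != -1:
                    if not any(a <= pos and pos + k <= b for a, b in intervals_h.get(h.id, ())):
                        clean = False
                    pos = h.sequence.find(km, pos + 1)
            for v in virals:
                pos = v.sequence.find(km)
                while pos != -1:
                    ok = False
                    for (vid, pep), s in viral_starts.items():
                        if vid == v.id and s <= pos and pos + k <= s + len(pep):
                            ok = True
                    if not ok:
                        clean = False
                    pos = v.sequence.find(km, pos + 1)
        if not clean:
            continue

        truth = pd.DataFrame(truth_rows)
        if not truth.empty:
            truth["viral_start"] = [
                viral_starts[(r.viral_id, r.peptide)] for r in truth.itertuples()
            ]
        return hosts, virals, truth
    raise RuntimeError(
        f"could not generate a clean proteome instance in {max_retries} attempts; "
        "try longer or more background proteins"
    )


# ---------------------------------------------------------------------------
# TPM tables


def gen_tpm_table(config: SimulationConfig) -> pd.DataFrame:
    """Organ x gene TPM table: log-normal background around a common mean,
    planted genes elevated in one organ by the configured fold change."""
    if len(config.tpm_organs) < 2:
        raise ValueError("need at least 2 organs")
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.tpm_n_genes)]
    for g in config.tpm_planted:
        if g not in genes:
            genes.append(g)
    n_org = len(config.tpm_organs)
    values = rng.lognormal(mean=np.log(5.0), sigma=0.25, size=(n_org, len(genes)))
    df = pd.DataFrame(values, index=config.tpm_organs, columns=genes)
    for gene, organ in config.tpm_planted.items():
        if organ not in config.tpm_organs:
            raise ValueError(f"planted organ {organ!r} not in organ list")
        base = df.loc[:, gene].drop(organ).mean()
        df.loc[organ, gene] = base * config.tpm_fold_change
    return df


# ---------------------------------------------------------------------------
# Localization annotations


_GROUP_TERMS = {
    "intracellular only": ["Cytoplasm"],
    "cell membrane only": ["Cell membrane"],
    "secreted only": ["Secreted"],
    "intracellular & cell membrane": ["Cytoplasm", "Cell membrane"],
    "cell membrane & secreted": ["Cell membrane", "Secreted"],
    "secreted & intracellular": ["Secreted", "Cytoplasm"],
    "intracellular, cell membrane and secreted": ["Cytoplasm", "Cell membrane", "Secreted"],
    "unannotated": [],
}


def gen_annotations(config: SimulationConfig) -> tuple[AnnotationTable, dict[str, str]]:
    """Localization annotations with exact (largest-remainder) group frequencies.

    Returns the annotation table and a truth mapping protein id -> group.
    Allocation is deterministic: frequencies are realized exactly, not
    sampled.
    """
    n = config.ann_n_proteins
    fractions = config.ann_group_fractions
    table = AnnotationTable()
    truth: dict[str, str] = {}
    if n == 0 or not fractions:
        return table, truth
    unknown = set(fractions) - set(_GROUP_TERMS)
    if unknown:
        raise ValueError(f"unknown localization groups: {sorted(unknown)}")
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("group fractions must sum to 1")
    groups = sorted(fractions)
    quotas = {g: fractions[g] * n for g in groups}
    counts = {g: int(np.floor(quotas[g])) for g in groups}
    remainder = n - sum(counts.values())
    for g in sorted(groups, key=lambda g: quotas[g] - counts[g], reverse=True)[:remainder]:
        counts[g] += 1
    i = 0
    for g in groups:
        for _ in range(counts[g]):
            pid = f"P{i:04d}"
            table.localization[pid] = list(_GROUP_TERMS[g])
            truth[pid] = g
            i += 1
    return table, truth
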