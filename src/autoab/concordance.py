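"""Pairwise phi association between autoantibodies and its cross-study combination.

For each antibody pair within a study, the 2x2 co-occurrence table (n11, n10,
n01, n00) yields the phi coefficient

    phi = (n11 n00 - n10 n01) / sqrt(r1 r0 c1 c0)

with r/c the row and column margins.  Phi is *undefined* (not zero) when any
margin is zero — e.g. when one antibody shows no responses at all in a study.
Defined per-study coefficients are combined by Fisher z-transforming each,
inverse-variance weighting with variance 1/(n - 3), averaging, and
back-transforming (fixed-effect combination, the standard default for
correlation meta-analysis).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from autoab.core_io import StudyResponseSet

# |phi| = 1 has infinite Fisher z; clip just inside the open interval.
_PHI_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class PairTable:
    """Joint reactivity counts for one antibody pair within one study."""

    n11: int
    n10: int
    n01: int
    n00: int
    study_id: str = ""

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("pair-table counts must be non-negative")
        if self.total < 1:
            raise ValueError("pair table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass
class CombinedPhi:
    """Cross-study combined phi for one antibody pair."""

    pair: tuple[str, str]
    phi: float | None
    n_studies_defined: int
    per_study: list[tuple[str, float | None]] = field(default_factory=list)


def phi(table: PairTable) -> float | None:
    """Phi coefficient of a 2x2 table; None when any margin is zero."""
    r1 = table.n11 + table.n10
    r0 = table.n01 + table.n00
    c1 = table.n11 + table.n01
    c0 = table.n10 + table.n00
    denom = r1 * r0 * c1 * c0
    if denom == 0:
        return None
    return (table.n11 * table.n00 - table.n10 * table.n01) / math.sqrt(denom)


def combine_phi(per_study: Sequence[tuple[float | None, int]]) -> float | None:
    """Fixed-effect Fisher-z combination of per-study phi coefficients.

    Each entry is (phi or None, study sample size n).  Undefined entries are
    excluded; weights are n - 3 (the inverse of the Fisher-z variance
    1/(n - 3)).  Returns None if every study is undefined.
    """
    zs, ws = [], []
    for value, n in per_study:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        if n < 4:
            raise ValueError(f"Fisher-z combination needs n >= 4 per study, got n={n}")
        if not -1.0 <= value <= 1.0:
            raise ValueError(f"phi out of range: {value}")
        clipped = max(-_PHI_CLIP, min(_PHI_CLIP, value))
        zs.append(math.atanh(clipped))
        ws.append(n - 3)
    if not zs:
        return None
    z_bar = float(np.average(zs, weights=ws))
    return math.tanh(z_bar)


def pair_table_from_responses(
    row_a: np.ndarray, row_b: np.ndarray, study_id: str = ""
) -> PairTable | None:
    """Build the 2x2 table from two response rows, pairwise-excluding missings."""
    ok = ~(np.isnan(row_a) | np.isnan(row_b))
    a, b = row_a[ok].astype(int), row_b[ok].astype(int)
    if a.size == 0:
        return None
    return PairTable(
        n11=int(((a == 1) & (b == 1)).sum()),
        n10=int(((a == 1) & (b == 0)).sum()),
        n01=int(((a == 0) & (b == 1)).sum()),
        n00=int(((a == 0) & (b == 0)).sum()),
        study_id=study_id,
    )


def concordance_screen(
    studies: Sequence[StudyResponseSet],
    antibodies: Sequence[str],
    floor: float = 0.6,
    min_studies: int = 2,
) -> tuple[list[CombinedPhi], "np.ndarray"]:
    """Evaluate all unordered antibody pairs; report concordant ones.

    Returns (all combined-phi records, square combined-phi matrix with NaN for
    undefined cells).  A pair is flagged ``reported`` when its combined phi
    exceeds ``floor`` AND it has a defined per-study phi in at least
    ``min_studies`` studies.
    """
    if not 0 <= floor <= 1:
        raise ValueError("floor must be in [0, 1]")
    if len(antibodies) < 2:
        raise ValueError("concordance screen needs at least 2 antibodies")
    results: list[CombinedPhi] = []
    m = len(antibodies)
    matrix = np.full((m, m), np.nan)
    np.fill_diagonal(matrix, 1.0)
    for ia, ib in itertools.combinations(range(m), 2):
        a, b = antibodies[ia], antibodies[ib]
        per_study: list[tuple[str, float | None]] = []
        contributions: list[tuple[float | None, int]] = []
        for s in studies:
            try:
                ra = s.responses[s.antibodies.index(a)]
                rb = s.responses[s.antibodies.index(b)]
            except ValueError:
                continue
            table = pair_table_from_responses(ra, rb, s.study_id)
            if table is None:
                continue
            value = phi(table)
            per_study.append((s.study_id, value))
            if value is not None and table.total >= 4:
                contributions.append((value, table.total))
        combined = combine_phi(contributions) if contributions else None
        rec = CombinedPhi(
            pair=(a, b),
            phi=combined,
            n_studies_defined=len(contributions),
            per_study=per_study,
        )
        results.append(rec)
        if combined is not None:
            matrix[ia, ib] = matrix[ib, ia] = combined
    return results, matrix


def reported_pairs(
    screen: Sequence[CombinedPhi], floor: float = 0.6, min_studies: int = 2
) -> list[CombinedPhi]:
    """Pairs passing the concordance rule: combined phi > floor and defined in
    at least ``min_studies`` studies."""
    return [
        r
        for r in screen
        if r.phi is not None and r.phi > floor and r.n_studies_defined >= min_studies
    ]
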