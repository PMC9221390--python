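"""Per-protein biochemical and antigenicity calculators feeding the enrichment ranks.

Global properties (length, aromaticity, GRAVY hydrophobicity, isoelectric
point, secondary-structure fractions) are computed from residue composition;
antigenicity-related scores (Chou-Fasman beta turn, Emini surface
accessibility, Karplus-Schulz flexibility, Parker hydrophilicity) are
sliding-window profiles averaged over all windows of a protein.  ``X``
residues (masked/unknown) are dropped from composition metrics and break
windows for profile metrics.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from autoab import scales
from autoab.core_io import ProteinRecord

logger = logging.getLogger(__name__)

#: profile scales: name -> (residue table, default window, aggregation)
PROFILE_SCALES: dict[str, tuple[dict[str, float], int, str]] = {
    "chou_fasman_turn": (scales.CHOU_FASMAN_TURN, 4, "mean"),
    "emini": (scales.EMINI, 6, "product"),
    "karplus_schulz": (scales.KARPLUS_SCHULZ, 7, "mean"),
    "parker": (scales.PARKER, 7, "mean"),
}

GLOBAL_PROPERTIES = [
    "length",
    "aromaticity",
    "gravy",
    "isoelectric_point",
    "helix_fraction",
    "sheet_fraction",
    "turn_fraction",
]


def charge_at_pH(sequence: str, pH: float) -> float:
    """Net charge of the sequence at a given pH (Henderson-Hasselbalch).

    Uses the pinned Bjellqvist pKa set in :mod:`autoab.scales`, including the
    residue-specific adjustments for the terminal groups; each terminus
    counts once.
    """
    pos = scales.POSITIVE_PKS
    neg = scales.NEGATIVE_PKS
    nterm_pk = scales.PK_NTERMINAL.get(sequence[0], pos["Nterm"])
    cterm_pk = scales.PK_CTERMINAL.get(sequence[-1], neg["Cterm"])
    charge = 1.0 / (1.0 + 10 ** (pH - nterm_pk))
    charge -= 1.0 / (1.0 + 10 ** (cterm_pk - pH))
    for res, pk in pos.items():
        if res == "Nterm":
            continue
        charge += sequence.count(res) / (1.0 + 10 ** (pH - pk))
    for res, pk in neg.items():
        if res == "Cterm":
            continue
        charge -= sequence.count(res) / (1.0 + 10 ** (pk - pH))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-6) -> float:
    """pH at which the net charge vanishes, solved by bisection on (0, 14).

    The net-charge function is strictly decreasing in pH, so the root is
    unique; the returned pI satisfies |charge(pI)| well below 1e-4.
    """
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if charge_at_pH(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return (lo + hi) / 2.0


def global_properties(record: ProteinRecord) -> dict[str, float]:
    """Composition-level properties of one protein.

    X residues are excluded and the composition renormalized over the
    remaining canonical residues.
    """
    seq = record.sequence.replace("X", "")
    if not seq:
        raise ValueError(f"{record.id}: no canonical residues after removing X")
    n = len(seq)
    aromatic = sum(seq.count(r) for r in scales.AROMATIC_RESIDUES) / n
    gravy = sum(scales.KYTE_DOOLITTLE[r] for r in seq) / n
    helix = sum(seq.count(r) for r in scales.HELIX_RESIDUES) / n
    turn = sum(seq.count(r) for r in scales.TURN_RESIDUES) / n
    sheet = sum(seq.count(r) for r in scales.SHEET_RESIDUES) / n
    return {
        "length": float(len(record.sequence)),
        "aromaticity": aromatic,
        "gravy": gravy,
        "isoelectric_point": isoelectric_point(seq),
        "helix_fraction": helix,
        "sheet_fraction": sheet,
        "turn_fraction": turn,
    }


def residue_profile(
    record: ProteinRecord, scale_name: str, window: int | None = None
) -> np.ndarray:
    """Sliding-window profile of one antigenicity scale over the sequence.

    Mean aggregation for Chou-Fasman / Karplus-Schulz / Parker; product-based
    (normalized by the 0.37^window random expectation) for Emini.  Windows
    containing an X residue yield NaN.  The profile has length
    ``L - window + 1``.
    """
    if scale_name not in PROFILE_SCALES:
        raise ValueError(f"unknown scale {scale_name!r}; choose from {sorted(PROFILE_SCALES)}")
    table, default_window, agg = PROFILE_SCALES[scale_name]
    w = default_window if window is None else window
    seq = record.sequence
    if len(seq) < w:
        raise ValueError(f"{record.id}: length {len(seq)} < minimum window {w} for {scale_name}")
    values = np.array([table.get(r, np.nan) for r in seq])
    out = np.empty(len(seq) - w + 1)
    for i in range(len(out)):
        win = values[i : i + w]
        if np.isnan(win).any():
            out[i] = np.nan
        elif agg == "mean":
            out[i] = win.mean()
        else:  # product (Emini surface probability)
            out[i] = float(np.prod(win) / (0.37**w))
    return out


def property_table(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """One row per protein: global properties plus windowed-score means.

    Proteins too short for a profile window (or with every window broken by
    X) get NaN for that score, with a warning.
    """
    if not records:
        raise ValueError("property_table requires at least one record")
    rows = []
    for rec in records:
        row: dict[str, float] = {"protein_id": rec.id}
        row.update(global_properties(rec))
        for name in PROFILE_SCALES:
            try:
                profile = residue_profile(rec, name)
            except ValueError:
                logger.warning("%s: too short for %s window, score missing", rec.id, name)
                row[name] = math.nan
                continue
            finite = profile[~np.isnan(profile)]
            if finite.size == 0:
                logger.warning("%s: every %s window broken by X, score missing", rec.id, name)
                row[name] = math.nan
            else:
                row[name] = float(finite.mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein_id")
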