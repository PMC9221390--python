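"""Subcellular-localization classification and organ-specificity scoring.

Free-text localization terms map to three base flags — intracellular, cell
membrane, secreted — via a configurable keyword vocabulary; the seven possible
flag combinations partition annotated proteins.  Antibody accessibility is
summarized by the fraction of "intracellular only" proteins, compared between
a protein subset (e.g. common autoantigens) and the probed universe with a
two-proportion z test.

Organ specificity from an organ x gene TPM table: per-gene log2 fold change
of each organ's TPM against the mean TPM of all other organs (with a small
pseudocount so zero backgrounds stay finite); organs clearing the log2
fold-change cutoff (default 3) are called specific; the per-gene log2-FC row
is standardized to z scores for visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger(__name__)

#: keyword -> base flag; matching is case-insensitive substring-free exact-term
DEFAULT_VOCABULARY: dict[str, str] = {
    "cytoplasm": "intracellular",
    "cytosol": "intracellular",
    "nucleus": "intracellular",
    "nucleolus": "intracellular",
    "mitochondrion": "intracellular",
    "endoplasmic reticulum": "intracellular",
    "golgi": "intracellular",
    "lysosome": "intracellular",
    "peroxisome": "intracellular",
    "endosome": "intracellular",
    "cytoskeleton": "intracellular",
    "chromosome": "intracellular",
    "cell membrane": "cell_membrane",
    "plasma membrane": "cell_membrane",
    "secreted": "secreted",
    "extracellular": "secreted",
}

GROUP_NAMES = {
    ("intracellular",): "intracellular only",
    ("cell_membrane",): "cell membrane only",
    ("secreted",): "secreted only",
    ("cell_membrane", "intracellular"): "intracellular & cell membrane",
    ("cell_membrane", "secreted"): "cell membrane & secreted",
    ("intracellular", "secreted"): "secreted & intracellular",
    ("cell_membrane", "intracellular", "secreted"): "intracellular, cell membrane and secreted",
}


@dataclass
class LocalizationCall:
    """Base accessibility flags and the 7-group label for one protein."""

    protein_id: str
    intracellular: bool = False
    cell_membrane: bool = False
    secreted: bool = False

    @property
    def annotated(self) -> bool:
        return self.intracellular or self.cell_membrane or self.secreted

    @property
    def group(self) -> str | None:
        flags = tuple(
            sorted(
                name
                for name, on in [
                    ("intracellular", self.intracellular),
                    ("cell_membrane", self.cell_membrane),
                    ("secreted", self.secreted),
                ]
                if on
            )
        )
        return GROUP_NAMES.get(flags)


@dataclass
class OrganSpecificity:
    """Per-gene organ profile: log2 fold changes, z scores, specific organs."""

    gene_id: str
    organs: list[str]
    tpm: np.ndarray
    log2_fc: np.ndarray
    z: np.ndarray
    specific_organs: list[str] = field(default_factory=list)


def classify_localization(
    protein_id: str,
    terms: Iterable[str],
    vocabulary: Mapping[str, str] | None = None,
) -> LocalizationCall:
    """Map free-text localization terms to the three base flags.

    Unrecognized terms are logged and ignored; with no mapped term the
    protein stays unannotated (no group).
    """
    vocab = DEFAULT_VOCABULARY if vocabulary is None else dict(vocabulary)
    call = LocalizationCall(protein_id)
    for term in terms:
        key = term.strip().lower()
        flag = vocab.get(key)
        if flag is None:
            # allow keyword containment, e.g. "Golgi apparatus"
            flag = next((f for k, f in vocab.items() if k in key), None)
        if flag is None:
            logger.debug("%s: unrecognized localization term %r", protein_id, term)
            continue
        setattr(call, flag, True)
    return call


def localization_proportion_test(
    subset_calls: Sequence[LocalizationCall],
    universe_calls: Sequence[LocalizationCall],
    group: str = "intracellular only",
) -> dict:
    """Fraction of a localization group in subset vs universe, with a
    two-proportion z test (two-sided).

    Fractions are reported over *annotated* proteins; the count over all
    supplied proteins is included as an alternative denominator.
    """
    sub_ann = [c for c in subset_calls if c.annotated]
    uni_ann = [c for c in universe_calls if c.annotated]
    if not sub_ann or not uni_ann:
        raise ValueError("both groups need at least one annotated protein")
    sub_hit = sum(1 for c in sub_ann if c.group == group)
    uni_hit = sum(1 for c in uni_ann if c.group == group)
    z, p = proportions_ztest(
        count=np.array([sub_hit, uni_hit]),
        nobs=np.array([len(sub_ann), len(uni_ann)]),
        alternative="two-sided",
    )
    return {
        "group": group,
        "subset_fraction": sub_hit / len(sub_ann),
        "universe_fraction": uni_hit / len(uni_ann),
        "subset_fraction_all": sub_hit / len(subset_calls),
        "universe_fraction_all": uni_hit / len(universe_calls),
        "subset_n_annotated": len(sub_ann),
        "universe_n_annotated": len(uni_ann),
        "z": float(z),
        "p": float(p),
    }


def average_tissues_to_organs(
    tpm: pd.DataFrame, organ_map: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Arithmetic mean of member-tissue TPM rows per organ.

    ``tpm`` has tissues as rows and genes as columns; the organ map lists the
    member tissues of each organ.
    """
    rows = {}
    for organ, tissues in organ_map.items():
        missing = [t for t in tissues if t not in tpm.index]
        if missing:
            raise ValueError(f"organ {organ!r}: tissues not in table: {missing}")
        rows[organ] = tpm.loc[list(tissues)].mean(axis=0)
    return pd.DataFrame(rows).T


def organ_specificity(
    tpm: pd.DataFrame, cutoff: float = 3.0, pseudocount: float = 0.01
) -> list[OrganSpecificity]:
    """Organ-specificity calls for every gene of an organ x gene TPM table.

    For gene g and organ o, fold change = (TPM[o, g] + pseudocount) /
    (mean TPM of other organs + pseudocount); organs with log2 FC > cutoff are
    specific.  The log2-FC row is z-standardized (mean 0, sd 1) when its sd is
    positive.  Results are invariant under organ-column reordering and under
    rescaling the whole table by a positive constant up to the pseudocount.
    """
    if tpm.shape[0] < 2:
        raise ValueError("organ specificity needs at least 2 organs")
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    organs = [str(o) for o in tpm.index]
    n_org = len(organs)
    values = tpm.to_numpy(dtype=float)
    out = []
    for j, gene in enumerate(tpm.columns):
        col = values[:, j]
        total = col.sum()
        others_mean = (total - col) / (n_org - 1)
        fc = (col + pseudocount) / (others_mean + pseudocount)
        log2_fc = np.log2(fc)
        sd = log2_fc.std(ddof=0)
        z = (log2_fc - log2_fc.mean()) / sd if sd > 0 else np.zeros_like(log2_fc)
        specific = [organs[i] for i in range(n_org) if log2_fc[i] > cutoff]
        out.append(
            OrganSpecificity(
                gene_id=str(gene),
                organs=organs,
                tpm=col.copy(),
                log2_fc=log2_fc,
                z=z,
                specific_organs=specific,
            )
        )
    return out
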