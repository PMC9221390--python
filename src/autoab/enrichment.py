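"""From-scratch preranked gene-set enrichment (ES / NES / permutation p / BH FDR).

Proteins are ranked by a property in descending order; the classic weighted
Kolmogorov-Smirnov running sum walks the list, incrementing by
``|metric|^weight / N_R`` at set members (N_R the sum of those weights over
the set) and decrementing by ``1/(N - N_H)`` at non-members.  The enrichment
score is the maximum-magnitude deviation (signed); a set concentrated at the
bottom of the descending list yields a negative ES.  Significance uses a
gene-set permutation null (random same-size sets), with a +1 Laplace
correction so the permutation p is never exactly zero; NES divides the ES by
the mean magnitude of same-sign null scores.  FDR across multiple properties
is Benjamini-Hochberg on the nominal p values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class RankedList:
    """(protein_id, metric) pairs sorted descending by metric, ties by id."""

    ids: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.ids) != self.metric.size:
            raise ValueError("ids and metric must align")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in ranked list")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class EnrichmentResult:
    """One gene set against one ranked property list."""

    set_name: str
    es: float
    nes: float
    p: float
    fdr: float | None
    set_size: int
    curve: np.ndarray = field(repr=False, default=None)
    hit_positions: np.ndarray = field(repr=False, default=None)
    unstable: bool = False


def rank_by_property(table: pd.DataFrame, property_name: str) -> RankedList:
    """Rank proteins by one property column, descending, ties broken by id.

    Missing values are excluded with a warning; an all-missing column raises.
    """
    if property_name not in table.columns:
        raise ValueError(f"property {property_name!r} not in table")
    col = table[property_name]
    valid = col.dropna()
    if valid.empty:
        raise ValueError(f"property {property_name!r} has no finite values")
    order = sorted(valid.index, key=lambda pid: (-valid[pid], str(pid)))
    return RankedList([str(i) for i in order], valid.loc[order].to_numpy())


def _running_sum(metric: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    """Running enrichment curve for one hit indicator vector."""
    n = metric.size
    nh = int(hits.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must be a non-empty proper subset of the ranked list")
    w = np.abs(metric) ** weight
    nr = float(w[hits].sum())
    if nr == 0:
        # all hit metrics are exactly zero: fall back to unweighted steps
        steps = np.where(hits, 1.0 / nh, -1.0 / (n - nh))
    else:
        steps = np.where(hits, w / nr, -1.0 / (n - nh))
    return np.cumsum(steps)


def _es_from_curve(curve: np.ndarray) -> float:
    i = int(np.argmax(np.abs(curve)))
    return float(curve[i])


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and its running curve.

    Returns (ES, curve); the curve has one point per ranked protein and
    returns to 0 at the end of the list (conservation).
    """
    members = set(gene_set)
    if not members:
        raise ValueError("gene set is empty")
    hits = np.array([pid in members for pid in ranked.ids])
    if not hits.any():
        raise ValueError("gene set is disjoint from the ranked list")
    curve = _running_sum(ranked.metric, hits, weight)
    return _es_from_curve(curve), curve


def _null_es(
    metric: np.ndarray, nh: int, n_perm: int, weight: float, rng: np.random.Generator
) -> np.ndarray:
    """ES values for random same-size gene sets (drawn without replacement)."""
    n = metric.size
    w = np.abs(metric) ** weight
    # random nh-subsets: smallest nh entries of random keys per row
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, nh - 1, axis=1)[:, :nh]
    hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hits, idx, True, axis=1)
    nr = (w[None, :] * hits).sum(axis=1)
    nr = np.where(nr == 0, 1.0, nr)
    steps = np.where(hits, w[None, :] / nr[:, None], -1.0 / (n - nh))
    running = np.cumsum(steps, axis=1)
    pos = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), pos]


def nes_and_significance(
    ranked: RankedList,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    set_name: str = "",
) -> EnrichmentResult:
    """ES, NES and nominal permutation p for one gene set.

    NES = ES / mean(|null ES| of matching sign); nominal
    p = (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign null}).
    Results with fewer than 10 same-sign null samples are flagged unstable.
    Deterministic under (inputs, seed).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    members = [pid for pid in ranked.ids if pid in set(gene_set)]
    es, curve = enrichment_score(ranked, members, weight)
    rng = np.random.default_rng(seed)
    null = _null_es(ranked.metric, len(members), n_perm, weight, rng)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size == 0:
        nes = np.inf * np.sign(es)
        p = 1.0 / (1.0 + 0)
        unstable = True
    else:
        nes = es / float(np.mean(np.abs(same_sign)))
        extreme = int((np.abs(same_sign) >= abs(es)).sum())
        p = (1.0 + extreme) / (1.0 + same_sign.size)
        unstable = same_sign.size < 10
    hits = np.array([i for i, pid in enumerate(ranked.ids) if pid in set(members)])
    return EnrichmentResult(
        set_name=set_name,
        es=es,
        nes=float(nes),
        p=float(p),
        fdr=None,
        set_size=len(members),
        curve=curve,
        hit_positions=hits,
        unstable=unstable,
    )


def adjust_fdr(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """Benjamini-Hochberg adjustment across a family of enrichment results."""
    if not results:
        return []
    ps = [r.p for r in results]
    _, fdr, _, _ = multipletests(ps, method="fdr_bh")
    for r, q in zip(results, fdr):
        r.fdr = float(q)
    return list(results)


def enrich_properties(
    table: pd.DataFrame,
    gene_set: Iterable[str],
    properties: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> list[EnrichmentResult]:
    """Run the preranked enrichment of one gene set against every property
    column, with BH FDR across properties."""
    props = list(properties) if properties is not None else list(table.columns)
    results = []
    for i, prop in enumerate(props):
        ranked = rank_by_property(table, prop)
        results.append(
            nes_and_significance(
                ranked, gene_set, n_perm=n_perm, seed=seed + i, weight=weight, set_name=prop
            )
        )
    return adjust_fdr(results)
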