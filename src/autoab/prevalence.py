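"""Cross-study weighted prevalence of autoantibodies with moment-based heterogeneity.

Each study i contributes a prevalence ``p_i = x_i / n_i`` for an antibody, with
inverse sampling variance ``v_i = n_i / (p_i (1 - p_i))``.  Between-study
variance tau^2 is estimated by the DerSimonian-Laird-style moment formula from
Cochran's Q:

    Q    = sum v_i (p_i - pbar)^2,   pbar = sum v_i p_i / sum v_i
    U    = (k - 1) (vbar - s^2 / (k vbar))
    tau2 = (Q - (k - 1)) / U  if Q > k - 1, else 0

with ``vbar = mean(v_i)`` and ``s^2`` the sample variance of the v_i.  The
pooled ("weighted") prevalence is the weight-weighted mean of the per-study
prevalences.  Two weighting modes are provided:

``standard``
    w_i = 1 / (1/v_i + tau2) — classical random-effects weights, where the
    per-study *sampling variance* 1/v_i is inflated by tau2.  The default.
``paper_literal``
    w_i = 1 / (v_i + tau2) — adds tau2 to the inverse variance itself.  This
    mixes scales (an inverse variance plus a variance) but is provided so that
    results can be matched against analyses that used this exact expression.

Boundary prevalences p in {0, 1} make v_i undefined; for the variance
computation only they are stabilized by x' = x + 0.5, n' = n + 1 (the point
estimate p_i stays x/n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from autoab.core_io import StudyResponseSet

Mode = Literal["standard", "paper_literal"]

#: Human development stages used for the age comparison, as (label, lo, hi].
AGE_GROUPS: list[tuple[str, float, float]] = [
    ("0-6", 0.0, 6.0),
    ("6-12", 6.0, 12.0),
    ("12-18", 12.0, 18.0),
    ("18-51", 18.0, 51.0),
    ("51-84", 51.0, 84.0),
]


@dataclass(frozen=True)
class StudyCount:
    """Reactive count x out of n probed subjects in one study."""

    x: int
    n: int
    study_id: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"study {self.study_id!r}: n must be >= 1, got {self.n}")
        if not 0 <= self.x <= self.n:
            raise ValueError(f"study {self.study_id!r}: need 0 <= x <= n, got x={self.x}, n={self.n}")


@dataclass
class MetaPrevalence:
    """Weighted prevalence of one antibody with its heterogeneity components."""

    antibody_id: str
    k: int
    p_hat: float
    tau2: float
    Q: float
    U: float
    p_bar: float
    p_study: list[float]
    v_study: list[float]
    weights: list[float]
    study_ids: list[str] = field(default_factory=list)


def study_prevalence(count: StudyCount) -> float:
    """Per-study prevalence x/n."""
    return count.x / count.n


def _stabilized_variance_terms(counts: Sequence[StudyCount]) -> np.ndarray:
    """Inverse sampling variances v_i = n/(p(1-p)), with boundary stabilization.

    For p in {0, 1} the variance is computed from x' = x + 0.5, n' = n + 1;
    the point estimate is untouched.
    """
    v = np.empty(len(counts))
    for i, c in enumerate(counts):
        p = c.x / c.n
        if p in (0.0, 1.0):
            ps = (c.x + 0.5) / (c.n + 1)
            v[i] = (c.n + 1) / (ps * (1 - ps))
        else:
            v[i] = c.n / (p * (1 - p))
    return v


def heterogeneity(
    counts: Sequence[StudyCount], mode: Mode = "standard"
) -> tuple[np.ndarray, float, float, float, float]:
    """Moment-based heterogeneity for one antibody across studies.

    Returns ``(v, Q, U, tau2, p_bar)`` where v are the per-study inverse
    sampling variances (boundary-stabilized), Q is Cochran's heterogeneity
    statistic around the fixed-effect mean p_bar, and tau2 is the truncated
    moment estimate of between-study variance.  For a single study Q = 0 and
    tau2 = 0.  ``mode`` is accepted for interface symmetry with
    :func:`weighted_prevalence`; the moment equations themselves are shared.
    """
    if mode not in ("standard", "paper_literal"):
        raise ValueError(f"unknown mode {mode!r}")
    k = len(counts)
    if k == 0:
        raise ValueError("heterogeneity requires at least one study")
    p = np.array([c.x / c.n for c in counts])
    v = _stabilized_variance_terms(counts)
    p_bar = float(np.sum(v * p) / np.sum(v))
    if k == 1:
        return v, 0.0, float("nan"), 0.0, p_bar
    Q = float(np.sum(v * (p - p_bar) ** 2))
    v_bar = float(np.mean(v))
    s2 = float((np.sum(v**2) - k * v_bar**2) / (k - 1))
    U = float((k - 1) * (v_bar - s2 / (k * v_bar)))
    tau2 = (Q - (k - 1)) / U if Q > k - 1 else 0.0
    return v, Q, U, max(0.0, tau2), p_bar


def weighted_prevalence(
    counts: Sequence[StudyCount], mode: Mode = "standard", antibody_id: str = ""
) -> MetaPrevalence:
    """Pooled prevalence across studies under the chosen weighting mode.

    The estimate is the weight-weighted mean of the per-study prevalences and
    always lies within [min p_i, max p_i]; for a single study it equals that
    study's prevalence.
    """
    if not counts:
        raise ValueError("weighted_prevalence requires at least one study")
    p = np.array([c.x / c.n for c in counts])
    v, Q, U, tau2, p_bar = heterogeneity(counts, mode)
    if mode == "standard":
        w = 1.0 / (1.0 / v + tau2)
    else:
        w = 1.0 / (v + tau2)
    p_hat = float(np.sum(w * p) / np.sum(w))
    return MetaPrevalence(
        antibody_id=antibody_id,
        k=len(counts),
        p_hat=p_hat,
        tau2=tau2,
        Q=Q,
        U=U,
        p_bar=p_bar,
        p_study=[float(x) for x in p],
        v_study=[float(x) for x in v],
        weights=[float(x) for x in w],
        study_ids=[c.study_id for c in counts],
    )


def prevalence_table(
    studies: Sequence[StudyResponseSet],
    mode: Mode = "standard",
    group: str | None = "control",
    sex: str | None = None,
) -> list[MetaPrevalence]:
    """Weighted prevalence for every antibody probed in at least one study.

    ``group``/``sex`` restrict subjects (None = no restriction).  Antibodies
    unprobed in a study simply do not contribute a StudyCount from it.
    """
    if not studies:
        raise ValueError("no studies supplied")
    antibodies = studies[0].antibodies
    results = []
    for ab in antibodies:
        counts: list[StudyCount] = []
        for s in studies:
            keep = [
                j
                for j, subj in enumerate(s.subjects)
                if (group is None or subj.group == group) and (sex is None or subj.sex == sex)
            ]
            if not keep:
                continue
            i = s.antibodies.index(ab)
            row = s.responses[i, keep]
            ok = ~np.isnan(row)
            if not ok.any():
                continue
            counts.append(StudyCount(int(row[ok].sum()), int(ok.sum()), s.study_id))
        if counts:
            results.append(weighted_prevalence(counts, mode, antibody_id=ab))
    return results


def call_common(meta: Iterable[MetaPrevalence], threshold: float = 0.10) -> list[str]:
    """Antibody ids with weighted prevalence >= threshold, sorted by descending
    prevalence then id."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    hits = [m for m in meta if m.p_hat >= threshold]
    hits.sort(key=lambda m: (-m.p_hat, m.antibody_id))
    return [m.antibody_id for m in hits]


def subject_autoantibody_counts(studies: Sequence[StudyResponseSet]) -> list[dict]:
    """Per-subject totals of reactive antibodies, with age/sex/group labels."""
    rows = []
    for s in studies:
        for j, subj in enumerate(s.subjects):
            col = s.responses[:, j]
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "study_id": s.study_id,
                    "age": subj.age,
                    "sex": subj.sex,
                    "group": subj.group,
                    "count": int(np.nansum(col)),
                }
            )
    return rows


def _age_group(age: float) -> str | None:
    for label, lo, hi in AGE_GROUPS:
        if (age > lo or (lo == 0.0 and age >= 0.0)) and age <= hi:
            return label
    return None


def group_compare(
    a: Sequence[float],
    b: Sequence[float],
    design: Literal["welch_age_groups", "unpaired_gender", "paired_prevalence"],
) -> tuple[float, float]:
    """Two-sided t test between two groups of per-subject totals or prevalences.

    welch_age_groups -> Welch's t (unequal variances), for adjacent
    development-stage age groups; unpaired_gender -> pooled-variance two-sample
    t; paired_prevalence -> paired t on matched prevalence vectors.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if design == "welch_age_groups":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif design == "unpaired_gender":
        res = stats.ttest_ind(a, b, equal_var=True)
    elif design == "paired_prevalence":
        if len(a) != len(b):
            raise ValueError("paired design requires equal-length vectors")
        res = stats.ttest_rel(a, b)
    else:
        raise ValueError(f"unknown design {design!r}")
    return float(res.statistic), float(res.pvalue)


def age_group_compare(subject_rows: Sequence[dict]) -> list[dict]:
    """Welch t tests between adjacent development-stage groups of subject counts."""
    by_group: dict[str, list[float]] = {label: [] for label, _, _ in AGE_GROUPS}
    for row in subject_rows:
        if row["age"] is None:
            continue
        g = _age_group(float(row["age"]))
        if g is not None:
            by_group[g].append(row["count"])
    out = []
    labels = [label for label, _, _ in AGE_GROUPS]
    for g1, g2 in zip(labels, labels[1:]):
        if len(by_group[g1]) >= 2 and len(by_group[g2]) >= 2:
            t, p = group_compare(by_group[g1], by_group[g2], "welch_age_groups")
            out.append({"group_a": g1, "group_b": g2, "t": t, "p": p})
    return out
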