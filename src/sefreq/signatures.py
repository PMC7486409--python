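"""Latent-signature similarity and pharmacological enrichment statistics.

A drug's signature is its row of W; a side effect's signature is its column
of H.  Cosine similarity between signatures is used as a score in binary
classification experiments (do two drugs share an ATC class? a protein
target? do two side effects share a MedDRA organ class?), benchmarked by
AUROC against baselines such as Jaccard side-effect-profile similarity.
Individual signature components are linked to drug/side-effect categories
by one-tailed Wilcoxon rank-sum tests with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .datamodel import CategoryMap, ValidationError
from .evaluation import auroc

__all__ = [
    "cosine_similarity",
    "pairwise_cosine",
    "jaccard_profile_similarity",
    "shared_category_auroc",
    "wilcoxon_one_tailed",
    "benjamini_hochberg",
    "ComponentAssociation",
    "component_associations",
    "compare_score_groups",
]

log = logging.getLogger(__name__)

#: exact rank-sum enumeration is used up to this pooled sample size
EXACT_LIMIT = 12


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two signatures; in [0, 1] for non-negative input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def pairwise_cosine(X: np.ndarray) -> np.ndarray:
    """Cosine similarity matrix between the rows of X."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValidationError("zero signature vector")
    Xn = X / norms[:, None]
    return Xn @ Xn.T


def jaccard_profile_similarity(set_a, set_b) -> float:
    """|A∩B| / |A∪B| for two side-effect sets."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValidationError("Jaccard similarity undefined for two empty sets")
    return len(a & b) / len(union)


def shared_category_auroc(
    signatures: np.ndarray,
    entity_ids: list[str],
    category_map: CategoryMap,
    level: str,
) -> tuple[float, int, int]:
    """Can signature similarity tell whether two entities share a category?

    Over all pairs of annotated entities, the label is 1 iff the code sets
    at ``level`` intersect and the score is the cosine similarity of the two
    signatures (rows of ``signatures``).  Returns (AUROC, n_share, n_not).
    """
    annotated = [e for e in entity_ids if category_map.codes_of(e, level)]
    if len(annotated) < 2:
        raise ValidationError("need at least 2 annotated entities")
    idx = {e: i for i, e in enumerate(entity_ids)}
    rows = np.array([idx[e] for e in annotated])
    S = pairwise_cosine(np.asarray(signatures, dtype=float)[rows])
    codes = [category_map.codes_of(e, level) for e in annotated]
    scores, labels = [], []
    for a, b in combinations(range(len(annotated)), 2):
        scores.append(S[a, b])
        labels.append(1.0 if codes[a] & codes[b] else 0.0)
    labels = np.asarray(labels)
    if labels.all() or not labels.any():
        raise ValidationError("degenerate labels: every pair has the same label")
    return auroc(np.asarray(scores), labels), int(labels.sum()), int(labels.size - labels.sum())


# ---------------------------------------------------------------------------
# Rank-sum test and multiple-testing adjustment
# ---------------------------------------------------------------------------

def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """P(rank sum of x >= observed) by enumeration of all group assignments.

    Midranks handle ties; the null permutes group membership over the pooled
    sample, so tied pools are enumerated correctly.
    """
    nx = x.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    observed = ranks[:nx].sum()
    total = comb(pooled.size, nx)
    hits = sum(1 for c in combinations(range(pooled.size), nx)
               if ranks[list(c)].sum() >= observed - 1e-12)
    return hits / total


def _normal_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """One-tailed normal approximation with midranks, tie-corrected variance
    and a 0.5 continuity correction."""
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    U = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    if var <= 0:  # all values identical
        return 1.0
    z = (U - mu - 0.5) / sqrt(var)
    return 0.5 * (1.0 - erf(z / sqrt(2.0)))


def wilcoxon_one_tailed(x, y) -> float:
    """One-tailed Wilcoxon rank-sum p-value for "x stochastically greater than y".

    Exact enumeration of the permutation null when the pooled size is at
    most ``EXACT_LIMIT``; otherwise the tie- and continuity-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if x.size + y.size <= EXACT_LIMIT:
        return _exact_rank_sum_p(x, y)
    return _normal_rank_sum_p(x, y)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Component-category associations
# ---------------------------------------------------------------------------

@dataclass
class ComponentAssociation:
    """One (signature component, category group) enrichment test."""

    component: int  # 1-based, matching how components are usually reported
    group: str
    n_group: int
    raw_p: float
    adjusted_p: float
    effect_size: float  # median within group − median over all entities
    significant: bool


def component_associations(
    signatures: np.ndarray,
    entity_ids: list[str],
    category_map: CategoryMap,
    level: str,
    significance: float = 0.01,
) -> list[ComponentAssociation]:
    """Which components are activated for which category of drugs/side effects?

    For every component p and every group g at the hierarchy level, the
    component-p values of group members are compared to those of all other
    entities with a one-tailed rank-sum test (members greater).  All
    (p, g) tests at the level form one Benjamini–Hochberg family.
    """
    X = np.asarray(signatures, dtype=float)
    if X.shape[0] != len(entity_ids):
        raise ValidationError("signatures rows must match entity_ids")
    idx = {e: i for i, e in enumerate(entity_ids)}
    tests = []
    for group, members in sorted(category_map.groups(level).items()):
        members = [m for m in members if m in idx]
        if len(members) < 2:
            log.info("group %r skipped: fewer than 2 members", group)
            continue
        member_rows = np.array([idx[m] for m in members])
        in_group = np.zeros(X.shape[0], dtype=bool)
        in_group[member_rows] = True
        for p_comp in range(X.shape[1]):
            col = X[:, p_comp]
            raw = wilcoxon_one_tailed(col[in_group], col[~in_group])
            effect = float(np.median(col[in_group]) - np.median(col))
            tests.append((p_comp + 1, group, int(in_group.sum()), raw, effect))
    if not tests:
        return []
    adjusted = benjamini_hochberg([t[3] for t in tests])
    return [
        ComponentAssociation(
            component=c,
            group=g,
            n_group=n,
            raw_p=raw,
            adjusted_p=float(adj),
            effect_size=eff,
            significant=bool(adj < significance),
        )
        for (c, g, n, raw, eff), adj in zip(tests, adjusted)
    ]


def compare_score_groups(score_groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise one-tailed rank-sum p-values between named score groups.

    Entry (a, b) is the p-value for "scores of group a are stochastically
    greater than scores of group b"; the diagonal is NaN.
    """
    names = list(score_groups)
    if len(names) < 2:
        raise ValidationError("need at least 2 groups")
    for n, v in score_groups.items():
        if np.asarray(v).size == 0:
            raise ValidationError(f"group {n!r} is empty")
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        for b in names:
            if a != b:
                out.loc[a, b] = wilcoxon_one_tailed(score_groups[a], score_groups[b])
    return out
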