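"""Metrics and evaluation protocols for frequency-class prediction.

Implements the experimental designs used to validate the decomposition:
random held-out split, tenfold cross-validation with (k, alpha) grid
search, single-drug removal, class-accumulation test sets (very rare /
+rare / +infrequent), cold-start evaluation of a newly added drug row, and
leave-one-out; plus the metrics they report (RMSE against integer classes,
AUROC for association detection, AUPRC at controlled class-imbalance
ratios, Pearson correlation, and confusion/accuracy tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import average_precision_score, roc_auc_score

from .datamodel import FrequencyMatrix, ValidationError
from .decomposition import DecompositionConfig, FactorModel, fit, predict_scores

__all__ = [
    "rmse",
    "auroc",
    "auprc",
    "auprc_at_ratio",
    "pearson_score_class",
    "SplitPlan",
    "make_holdout",
    "holdout_report",
    "CVPointResult",
    "CVResult",
    "cross_validate",
    "single_drug_protocol",
    "class_accumulation_sets",
    "cold_start_evaluation",
    "leave_one_out",
    "accuracy_report",
    "EvaluationReport",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rmse(predicted, true_classes) -> float:
    """Root mean squared error of predicted scores against integer classes."""
    predicted = np.asarray(predicted, dtype=float)
    true_classes = np.asarray(true_classes, dtype=float)
    if predicted.size == 0:
        raise ValidationError("empty input")
    if predicted.shape != true_classes.shape:
        raise ValidationError("length mismatch")
    return float(np.sqrt(np.mean((predicted - true_classes) ** 2)))


def auroc(scores, labels) -> float:
    """Rank-based AUROC with midrank tie handling (Mann–Whitney statistic)."""
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValidationError("labels must contain exactly two classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Area under the precision–recall curve, step-wise estimator."""
    return float(average_precision_score(np.asarray(labels), np.asarray(scores, dtype=float)))


def auprc_at_ratio(pos_scores, neg_pool, ratio: int, seed: int = 0) -> float:
    """AUPRC with negatives subsampled to ``ratio`` times the positives.

    Controls the class imbalance of the test set: ``ratio``·n_pos negatives
    are drawn without replacement from the candidate pool.
    """
    pos = np.asarray(pos_scores, dtype=float)
    pool = np.asarray(neg_pool, dtype=float)
    n_neg = ratio * pos.size
    if pool.size < n_neg:
        raise ValidationError(
            f"negative pool ({pool.size}) smaller than ratio×positives ({n_neg})"
        )
    rng = np.random.default_rng(seed)
    neg = rng.choice(pool, size=n_neg, replace=False)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(n_neg)])
    return auprc(scores, labels)


def pearson_score_class(predicted, true_classes) -> tuple[float, float]:
    """Pearson r (and p-value) between predicted scores and integer classes."""
    r, p = pearsonr(np.asarray(predicted, dtype=float), np.asarray(true_classes, dtype=float))
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """A set of observed cells hidden for testing, plus the training matrix."""

    test_rows: np.ndarray
    test_cols: np.ndarray
    test_classes: np.ndarray
    training: FrequencyMatrix
    seed: int | None = None

    def __post_init__(self):
        if np.any(self.training.values[self.test_rows, self.test_cols] != 0):
            raise ValidationError("test cells leak into the training matrix")
        if np.any(self.test_classes < 1) or np.any(self.test_classes > 5):
            raise ValidationError("test classes must be in 1..5")

    @property
    def n_test(self) -> int:
        return int(self.test_rows.size)


def make_holdout(matrix: FrequencyMatrix, fraction: float, seed: int = 0) -> SplitPlan:
    """Hide a uniform random fraction of the observed cells for testing."""
    if not (0.0 < fraction < 1.0):
        raise ValidationError("fraction must lie strictly between 0 and 1")
    ii, jj = matrix.observed_indices()
    n_test = int(np.floor(fraction * ii.size))
    if n_test == 0 or n_test == ii.size:
        raise ValidationError("fraction leaves no test or no training cells")
    rng = np.random.default_rng(seed)
    pick = rng.choice(ii.size, size=n_test, replace=False)
    training = matrix.copy()
    training.values[ii[pick], jj[pick]] = 0
    return SplitPlan(
        test_rows=ii[pick],
        test_cols=jj[pick],
        test_classes=matrix.values[ii[pick], jj[pick]],
        training=training,
        seed=seed,
    )


def _zero_cell_scores(source: FrequencyMatrix, scores: np.ndarray) -> np.ndarray:
    """Scores at the zero cells of the source matrix (the AUROC negatives)."""
    return scores[source.values == 0]


def holdout_report(
    matrix: FrequencyMatrix,
    plan: SplitPlan,
    model: FactorModel,
    ratios: tuple[int, ...] = (1, 10),
    seed: int = 0,
) -> "EvaluationReport":
    """Held-out metrics: RMSE, AUROC (vs all source zeros), AUPRC, Pearson."""
    scores = predict_scores(model)
    test_scores = scores[plan.test_rows, plan.test_cols]
    neg = _zero_cell_scores(matrix, scores)
    all_scores = np.concatenate([test_scores, neg])
    all_labels = np.concatenate([np.ones(test_scores.size), np.zeros(neg.size)])
    r, _ = pearson_score_class(test_scores, plan.test_classes)
    report = EvaluationReport(
        rmse=rmse(test_scores, plan.test_classes),
        auroc=auroc(all_scores, all_labels),
        auprc_by_ratio={
            ratio: auprc_at_ratio(test_scores, neg, ratio, seed=seed + ratio)
            for ratio in ratios
        },
        pearson_r=r,
    )
    return report


# ---------------------------------------------------------------------------
# Cross-validation with grid model selection
# ---------------------------------------------------------------------------

@dataclass
class CVPointResult:
    k: int
    alpha: float
    fold_rmse: np.ndarray
    fold_auroc: np.ndarray
    pooled_scores: np.ndarray
    pooled_classes: np.ndarray

    @property
    def mean_rmse(self) -> float:
        return float(self.fold_rmse.mean())

    @property
    def sd_rmse(self) -> float:
        return float(self.fold_rmse.std(ddof=1))

    @property
    def mean_auroc(self) -> float:
        return float(self.fold_auroc.mean())

    @property
    def sd_auroc(self) -> float:
        return float(self.fold_auroc.std(ddof=1))


@dataclass
class CVResult:
    points: list[CVPointResult]
    n_folds: int
    seed: int

    def best(self, metric: str = "rmse") -> CVPointResult:
        """Grid point minimising mean RMSE (or maximising mean AUROC)."""
        if metric == "rmse":
            return min(self.points, key=lambda p: p.mean_rmse)
        if metric == "auroc":
            return max(self.points, key=lambda p: p.mean_auroc)
        raise ValidationError(f"unknown selection metric {metric!r}")


def cross_validate(
    matrix: FrequencyMatrix,
    ks=(10,),
    alphas=(0.05,),
    n_folds: int = 10,
    seed: int = 0,
    config: DecompositionConfig | None = None,
    **fit_overrides,
) -> CVResult:
    """K-fold CV over observed cells, for every (k, alpha) grid point.

    The fold partition of Ω is drawn once per seed and reused across the
    whole grid.  Per fold, validation cells are zeroed in the training copy;
    fold AUROC uses the validation cells as positives and all zero cells of
    the source matrix as negatives.  Pooled validation (score, class) pairs
    are kept per grid point — they feed the class calibration.
    """
    base = config or DecompositionConfig()
    ii, jj = matrix.observed_indices()
    if ii.size < n_folds:
        raise ValidationError("fewer observed cells than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(ii.size)
    folds = np.array_split(order, n_folds)
    neg_mask = matrix.values == 0
    points = []
    for k in ks:
        for alpha in alphas:
            fold_rmse, fold_auroc = [], []
            pooled_s, pooled_c = [], []
            for f, val_idx in enumerate(folds):
                if val_idx.size == 0:
                    raise ValidationError(f"fold {f} has no validation cells")
                training = matrix.copy()
                training.values[ii[val_idx], jj[val_idx]] = 0
                cfg_kwargs = dict(k=k, alpha=alpha, seed=seed * 1009 + f, **fit_overrides)
                model = fit(training, config=_with(base, **cfg_kwargs))
                scores = predict_scores(model)
                vs = scores[ii[val_idx], jj[val_idx]]
                vc = matrix.values[ii[val_idx], jj[val_idx]]
                fold_rmse.append(rmse(vs, vc))
                neg = scores[neg_mask]
                fold_auroc.append(
                    auroc(
                        np.concatenate([vs, neg]),
                        np.concatenate([np.ones(vs.size), np.zeros(neg.size)]),
                    )
                )
                pooled_s.append(vs)
                pooled_c.append(vc)
            points.append(
                CVPointResult(
                    k=k,
                    alpha=alpha,
                    fold_rmse=np.asarray(fold_rmse),
                    fold_auroc=np.asarray(fold_auroc),
                    pooled_scores=np.concatenate(pooled_s),
                    pooled_classes=np.concatenate(pooled_c),
                )
            )
    return CVResult(points=points, n_folds=n_folds, seed=seed)


def _with(config: DecompositionConfig, **kw) -> DecompositionConfig:
    from dataclasses import replace

    return replace(config, **kw)


# ---------------------------------------------------------------------------
# Single-drug and class-accumulation protocols
# ---------------------------------------------------------------------------

def single_drug_protocol(
    matrix: FrequencyMatrix,
    drug_id: str,
    removal_fraction: float | None = None,
    removal_classes: set[int] | None = None,
    config: DecompositionConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove associations of one drug, refit, and return scores for them.

    Either a random ``removal_fraction`` of the drug's associations or all
    associations in ``removal_classes`` is hidden.  Returns the true classes
    and the predicted scores for the removed cells (empty if nothing was
    removable).
    """
    i = matrix.drug_index(drug_id)
    row = matrix.values[i]
    cand = np.nonzero(row > 0)[0]
    if removal_classes is not None:
        cand = cand[np.isin(row[cand], list(removal_classes))]
    elif removal_fraction is not None:
        rng = np.random.default_rng(seed)
        n_rm = int(np.floor(removal_fraction * cand.size))
        cand = rng.choice(cand, size=n_rm, replace=False) if n_rm else cand[:0]
    if cand.size == 0:
        log.info("drug %s: no removable associations, skipped", drug_id)
        return np.empty(0, dtype=np.int64), np.empty(0)
    training = matrix.copy()
    training.values[i, cand] = 0
    model = fit(training, config=config or DecompositionConfig())
    scores = predict_scores(model)
    return matrix.values[i, cand].copy(), scores[i, cand]


def class_accumulation_sets(matrix: FrequencyMatrix) -> dict[str, SplitPlan]:
    """Chronology-mimicking test sets A/B/C: per drug, remove the rarest classes.

    A hides each drug's very rare associations, B adds rare, C adds
    infrequent — emulating the order in which trials discover side effects
    (frequent first).  A drug contributes only if it retains at least one
    training association after removal.
    """
    plans = {}
    for name, classes in (("A", {1}), ("B", {1, 2}), ("C", {1, 2, 3})):
        rows, cols = [], []
        for i in range(matrix.n_drugs):
            row = matrix.values[i]
            rm = np.nonzero(np.isin(row, list(classes)) & (row > 0))[0]
            if rm.size == 0:
                continue
            if np.count_nonzero(row) - rm.size < 1:
                log.info("drug %s dropped from set %s: no training association left",
                         matrix.drug_ids[i], name)
                continue
            rows.append(np.full(rm.size, i))
            cols.append(rm)
        if rows:
            rr = np.concatenate(rows)
            cc = np.concatenate(cols)
        else:
            rr = np.empty(0, dtype=np.int64)
            cc = np.empty(0, dtype=np.int64)
        training = matrix.copy()
        training.values[rr, cc] = 0
        plans[name] = SplitPlan(
            test_rows=rr,
            test_cols=cc,
            test_classes=matrix.values[rr, cc],
            training=training,
        )
    return plans


def cold_start_evaluation(
    matrix: FrequencyMatrix,
    drug_id: str,
    seeded: dict[str, int],
    test_sets: dict[str, list[str]],
    config: DecompositionConfig | None = None,
) -> dict[str, dict[str, float]]:
    """Append a new drug row with few seeded associations, fit, rank the rest.

    ``seeded`` maps side-effect id -> class for the few associations known
    (e.g. from phase I of a trial); each entry of ``test_sets`` names a set
    of side-effect ids discovered later.  For each test set, all side
    effects unobserved at training are ranked by predicted score and
    AUROC/AUPRC are computed with that set as positives.
    """
    if drug_id in matrix.drug_ids:
        raise ValidationError(f"drug {drug_id!r} already present in the matrix")
    if not seeded:
        raise ValidationError("at least one seeded association is required")
    new_row = np.zeros((1, matrix.n_side_effects), dtype=matrix.values.dtype)
    for se, cls in seeded.items():
        new_row[0, matrix.side_effect_index(se)] = cls
    extended = FrequencyMatrix(
        np.vstack([matrix.values, new_row]),
        matrix.drug_ids + [drug_id],
        list(matrix.side_effect_ids),
    )
    model = fit(extended, config=config or DecompositionConfig())
    scores = predict_scores(model)[-1]
    unobserved = np.nonzero(new_row[0] == 0)[0]
    results = {}
    for name, ses in test_sets.items():
        pos_idx = {matrix.side_effect_index(se) for se in ses}
        labels = np.array([j in pos_idx for j in unobserved], dtype=float)
        if labels.sum() == 0:
            raise ValidationError(f"test set {name!r} has no unobserved positives")
        s = scores[unobserved]
        results[name] = {
            "auroc": auroc(s, labels),
            "auprc": auprc(s, labels),
            "n_pos": int(labels.sum()),
            "n_neg": int(labels.size - labels.sum()),
        }
    return results


def leave_one_out(
    matrix: FrequencyMatrix,
    config: DecompositionConfig | None = None,
    enable_full: bool = False,
    max_cells: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """One fit per observed cell; returns (true classes, predicted scores).

    Costs |Ω| fits, so matrices with more than ``max_cells`` observed cells
    require ``enable_full=True``.
    """
    ii, jj = matrix.observed_indices()
    if ii.size > max_cells and not enable_full:
        raise ValidationError(
            f"leave-one-out over {ii.size} cells requires enable_full=True"
        )
    true, pred = [], []
    for i, j in zip(ii, jj):
        training = matrix.copy()
        training.values[i, j] = 0
        model = fit(training, config=config or DecompositionConfig())
        pred.append(predict_scores(model)[i, j])
        true.append(matrix.values[i, j])
    return np.asarray(true), np.asarray(pred)


# ---------------------------------------------------------------------------
# Confusion / accuracy report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Container for the evaluation metrics; unused fields stay None."""

    rmse: float | None = None
    auroc: float | None = None
    auprc_by_ratio: dict[int, float] = field(default_factory=dict)
    pearson_r: float | None = None
    confusion: np.ndarray | None = None  # 6 predicted (0-5) × 5 true (1-5), column %
    accuracy_exact: dict | None = None
    accuracy_with_neighbors: dict | None = None


def accuracy_report(true_classes, predicted_classes) -> EvaluationReport:
    """Column-normalised confusion table and exact / neighbour accuracies.

    Columns are the true classes 1–5, rows the predicted classes 0–5; each
    column sums to 100%.  Neighbour accuracy counts a prediction within one
    class of the truth (clipped to 1..5) as correct.
    """
    t = np.asarray(true_classes, dtype=np.int64)
    p = np.asarray(predicted_classes, dtype=np.int64)
    if t.size == 0:
        raise ValidationError("empty input")
    if np.any(t < 1) or np.any(t > 5) or np.any(p < 0) or np.any(p > 5):
        raise ValidationError("class codes outside the valid range")
    confusion = np.zeros((6, 5))
    for c in range(1, 6):
        col = p[t == c]
        if col.size:
            confusion[:, c - 1] = 100.0 * np.bincount(col, minlength=6) / col.size
    exact = {c: float(np.mean(p[t == c] == c)) for c in range(1, 6) if np.any(t == c)}
    neigh = {
        c: float(np.mean((np.abs(p[t == c] - c) <= 1) & (p[t == c] >= 1)))
        for c in range(1, 6)
        if np.any(t == c)
    }
    return EvaluationReport(
        confusion=confusion,
        accuracy_exact={"per_class": exact, "mean": float(np.mean(p == t))},
        accuracy_with_neighbors={
            "per_class": neigh,
            "mean": float(np.mean((np.abs(p - t) <= 1) & (p >= 1))),
        },
    )
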