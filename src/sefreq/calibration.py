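"""Maximum-likelihood calibration of predicted scores into frequency classes.

Predicted scores are real numbers; to report a frequency class we need five
cut-points.  For each class c in 1..5 a normal-kernel density of the scores
that cross-validation assigned to that class is estimated; the boundary
between adjacent classes is the score at which the two densities are equal
(the maximum-likelihood decision switches class there).  The zero threshold
— below which a score is called "no association" — is chosen on the
empirical ROC of observed-vs-zero discrimination at a target specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .datamodel import CLASS_NAMES, ValidationError

__all__ = [
    "ClassDensities",
    "ThresholdSet",
    "silverman_bandwidth",
    "fit_class_densities",
    "ml_thresholds",
    "zero_threshold",
    "classify_score",
    "classify_scores",
    "calibrate",
]

_GRID_SIZE = 1024


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 · min(sd, IQR/1.34) · n^(−1/5)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        spread = max(abs(x.mean()), 1.0) * 1e-3  # degenerate sample guard
    return 0.9 * spread * n ** (-0.2)


@dataclass
class ClassDensities:
    """Per-class smoothed score densities on a shared evaluation grid."""

    grid: np.ndarray
    densities: dict[int, np.ndarray]
    bandwidths: dict[int, float]
    counts: dict[int, int]
    medians: dict[int, float]

    def integral(self, c: int) -> float:
        return float(np.trapezoid(self.densities[c], self.grid))


def fit_class_densities(
    scores: np.ndarray,
    labels: np.ndarray,
    bandwidth: float | None = None,
    grid_size: int = _GRID_SIZE,
) -> ClassDensities:
    """Fit one normal-kernel density per frequency class.

    ``bandwidth`` overrides the per-class Silverman default.  The grid has
    ``grid_size`` points spanning [min score − 3·bw, max score + 3·bw].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(int(c) for c in np.unique(labels))
    for c in classes:
        if c not in CLASS_NAMES:
            raise ValidationError(f"label {c} is not a frequency class 1..5")
        if np.count_nonzero(labels == c) < 2:
            raise ValidationError(
                f"class {c} ({CLASS_NAMES[c]}) has fewer than 2 samples"
            )
    bws = {
        c: float(bandwidth) if bandwidth is not None else silverman_bandwidth(scores[labels == c])
        for c in classes
    }
    bw_max = max(bws.values())
    grid = np.linspace(scores.min() - 3 * bw_max, scores.max() + 3 * bw_max, grid_size)
    densities, counts, medians = {}, {}, {}
    for c in classes:
        x = scores[labels == c]
        sd = x.std(ddof=1)
        if sd == 0:  # gaussian_kde needs nonzero variance; jitter-free fallback
            densities[c] = np.exp(-0.5 * ((grid - x.mean()) / bws[c]) ** 2) / (
                bws[c] * np.sqrt(2 * np.pi)
            )
        else:
            kde = gaussian_kde(x, bw_method=bws[c] / sd)
            densities[c] = kde(grid)
        counts[c] = int(x.size)
        medians[c] = float(np.median(x))
    return ClassDensities(grid=grid, densities=densities, bandwidths=bws, counts=counts, medians=medians)


def ml_thresholds(densities: ClassDensities) -> np.ndarray:
    """Boundaries t1..t4 between adjacent classes, at density crossings.

    For each adjacent pair (c, c+1) the crossing of the two class densities
    is searched on the grid around the class medians (the inter-median
    interval extended by half its width on each side, which tolerates
    strongly overlapping neighbouring classes); with multiple crossings,
    the one closest to the midpoint of the medians is taken.
    """
    for c in range(1, 6):
        if c not in densities.densities:
            raise ValidationError(f"missing density for class {c}")
    grid = densities.grid
    bounds = []
    for c in range(1, 5):
        lo, hi = densities.medians[c], densities.medians[c + 1]
        if hi <= lo:
            raise ValidationError(f"class medians not ordered between {c} and {c + 1}")
        pad = 0.5 * (hi - lo)
        sel = (grid >= lo - pad) & (grid <= hi + pad)
        g = grid[sel]
        diff = densities.densities[c][sel] - densities.densities[c + 1][sel]
        sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
        if sign_change.size == 0:
            raise ValidationError(
                f"densities of classes {c} and {c + 1} do not cross between their medians"
            )
        # linear interpolation of each crossing, then pick closest to median midpoint
        crossings = []
        for i in sign_change:
            x0, x1 = g[i], g[i + 1]
            d0, d1 = diff[i], diff[i + 1]
            crossings.append(x0 if d0 == d1 else x0 - d0 * (x1 - x0) / (d1 - d0))
        mid = 0.5 * (lo + hi)
        bounds.append(min(crossings, key=lambda t: abs(t - mid)))
    bounds = np.asarray(bounds)
    if not np.all(np.diff(bounds) > 0):
        raise ValidationError(f"class boundaries are not ascending: {bounds}")
    return bounds


def zero_threshold(
    scores: np.ndarray, labels: np.ndarray, target_specificity: float = 0.57
) -> tuple[float, float]:
    """Score cut separating predicted zeros from predicted associations.

    Candidate thresholds are the sorted unique scores (a score counts as an
    association when >= threshold).  Among thresholds whose specificity over
    the negative labels is >= target, the one closest to the target is
    returned, together with the sensitivity achieved there.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValidationError("both positive and negative labels are required")
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    candidates = np.unique(scores)
    # specificity(t) = P(neg < t); sensitivity(t) = P(pos >= t)
    spec = np.searchsorted(neg, candidates, side="left") / neg.size
    sens = 1.0 - np.searchsorted(pos, candidates, side="left") / pos.size
    ok = spec >= target_specificity
    if not ok.any():  # highest cut: everything predicted zero for negatives
        t = float(candidates[-1] + 1.0)
        return t, 0.0
    idx = np.nonzero(ok)[0]
    best = idx[np.argmin(spec[idx] - target_specificity)]
    return float(candidates[best]), float(sens[best])


@dataclass(frozen=True)
class ThresholdSet:
    """Five cut-points mapping a real score to a class in {0, 1, ..., 5}."""

    t_zero: float
    class_bounds: tuple[float, float, float, float]

    def __post_init__(self):
        cuts = (self.t_zero, *self.class_bounds)
        if not all(a < b for a, b in zip(cuts, cuts[1:])):
            raise ValidationError(f"thresholds must be strictly ascending: {cuts}")

    def as_dict(self) -> dict:
        return {"t_zero": self.t_zero, "class_bounds": list(self.class_bounds)}


def classify_scores(x, thresholds: ThresholdSet) -> np.ndarray:
    """Vectorised :func:`classify_score`."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("scores must be finite")
    cuts = np.asarray((thresholds.t_zero, *thresholds.class_bounds))
    # class = number of cuts <= x; upper bins are left-closed (x == cut goes up)
    return np.searchsorted(cuts, x, side="right").astype(np.int64)


def classify_score(x: float, thresholds: ThresholdSet) -> int:
    """Map a score to {0 (zero), 1 (very rare), ..., 5 (very frequent)}.

    zero if x < t_zero; class c if t_{c-1} <= x < t_c; very frequent if
    x >= t4 — boundaries belong to the upper class.
    """
    return int(classify_scores(np.asarray([x]), thresholds)[0])


def map_classify(x, densities: ClassDensities, priors=None) -> np.ndarray:
    """Maximum-a-posteriori class for each score.

    With ``priors=None`` this is plain maximum likelihood over the five
    class-conditional densities; with class priors (e.g. the training-set
    class marginals) it is the Bayes classifier.  Used by the synthetic
    recovery experiments, where — unlike for real reporting data — the
    training marginals are a meaningful prior.
    """
    x = np.asarray(x, dtype=float)
    classes = sorted(densities.densities)
    if priors is None:
        priors = np.ones(len(classes))
    priors = np.asarray(priors, dtype=float)
    like = np.stack(
        [np.interp(x, densities.grid, densities.densities[c]) for c in classes]
    )
    return np.asarray(classes)[np.argmax(like * priors[:, None], axis=0)]


def calibrate(
    cv_scores: np.ndarray,
    cv_classes: np.ndarray,
    roc_scores: np.ndarray,
    roc_labels: np.ndarray,
    target_specificity: float = 0.57,
    bandwidth: float | None = None,
) -> tuple[ThresholdSet, float]:
    """Full calibration: ML class boundaries + ROC zero threshold.

    ``cv_scores``/``cv_classes`` are pooled validation-fold predictions with
    their true classes; ``roc_scores``/``roc_labels`` are held-out scores
    with binary observed-vs-zero labels.  Returns the threshold set and the
    sensitivity at the chosen zero threshold.
    """
    dens = fit_class_densities(cv_scores, cv_classes, bandwidth=bandwidth)
    bounds = ml_thresholds(dens)
    t0, sens = zero_threshold(roc_scores, roc_labels, target_specificity)
    if t0 >= bounds[0]:  # zero cut must sit below the very-rare/rare boundary
        t0 = bounds[0] - 1e-9
    return ThresholdSet(t_zero=float(t0), class_bounds=tuple(bounds)), sens
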