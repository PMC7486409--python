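"""Core data types and I/O for drug × side-effect frequency-class matrices.

The central object is :class:`FrequencyMatrix`: an integer matrix ``R`` with
entries in {0, 1, ..., 5}, where 1–5 code the five frequency classes used in
randomised controlled trials (very rare, rare, infrequent, frequent, very
frequent) and 0 marks an unobserved drug–side-effect pair.  The observed
index set is written Ω and the zero set O; every cell belongs to exactly one
of the two.

On-disk formats are plain text: a long-format TSV (``drug_id``,
``side_effect_id``, ``class``) is the canonical form, a dense CSV/TSV with
header row and index column is supported for small fixtures, and fitted
models round-trip through ``W.tsv`` / ``H.tsv`` / ``model.json`` bundles.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_NAMES",
    "CLASS_CODES",
    "FrequencyMatrix",
    "MaskPair",
    "FrequencySpec",
    "CategoryMap",
    "standardize_frequency",
    "masks_of",
    "load_frequency_matrix",
    "save_frequency_matrix",
    "load_annotations",
    "save_model",
    "load_model",
]

#: class code -> canonical name
CLASS_NAMES = {1: "very rare", 2: "rare", 3: "infrequent", 4: "frequent", 5: "very frequent"}
#: canonical name -> class code (also accepts underscored variants)
CLASS_CODES = {name: code for code, name in CLASS_NAMES.items()}

# Proportion bins for the five classes.  Left-closed, with "frequent"
# covering [1/100, 1/10] and "very frequent" strictly >1/10.
_BIN_EDGES = (1e-4, 1e-3, 1e-2, 1e-1)


class ValidationError(ValueError):
    """Raised when an input table or object violates a structural invariant."""


@dataclass(frozen=True)
class MaskPair:
    """Complementary binary masks M^Ω (observed) and M^O (zeros)."""

    observed: np.ndarray
    zero: np.ndarray

    def __post_init__(self):
        if self.observed.shape != self.zero.shape:
            raise ValidationError("mask shapes differ")
        if not np.array_equal(self.observed + self.zero, np.ones_like(self.observed)):
            raise ValidationError("masks are not complementary")


@dataclass
class FrequencyMatrix:
    """Integer-coded drug × side-effect frequency-class matrix.

    Parameters
    ----------
    values : ndarray of int, shape (n_drugs, n_side_effects)
        Entries in {0, ..., 5}; 0 = unobserved.
    drug_ids, side_effect_ids : sequence of str
        Unique axis labels, in matrix order.
    """

    values: np.ndarray
    drug_ids: list[str]
    side_effect_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.round(self.values)):
                raise ValidationError("matrix entries must be integers")
            self.values = self.values.astype(np.int64)
        if self.values.min(initial=0) < 0 or self.values.max(initial=0) > 5:
            raise ValidationError("matrix entries must lie in 0..5")
        self.drug_ids = list(self.drug_ids)
        self.side_effect_ids = list(self.side_effect_ids)
        if len(self.drug_ids) != self.values.shape[0]:
            raise ValidationError("drug_ids length does not match matrix rows")
        if len(self.side_effect_ids) != self.values.shape[1]:
            raise ValidationError("side_effect_ids length does not match matrix columns")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValidationError("duplicate drug ids")
        if len(set(self.side_effect_ids)) != len(self.side_effect_ids):
            raise ValidationError("duplicate side effect ids")

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_side_effects(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        """|Ω| — number of cells carrying a frequency class 1–5."""
        return int(np.count_nonzero(self.values))

    @property
    def density(self) -> float:
        return self.n_observed / self.values.size

    def observed_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of Ω, in C order."""
        return np.nonzero(self.values)

    def copy(self) -> "FrequencyMatrix":
        return FrequencyMatrix(self.values.copy(), list(self.drug_ids), list(self.side_effect_ids))

    def drug_index(self, drug_id: str) -> int:
        return self.drug_ids.index(drug_id)

    def side_effect_index(self, side_effect_id: str) -> int:
        return self.side_effect_ids.index(side_effect_id)


def masks_of(matrix: FrequencyMatrix) -> MaskPair:
    """Build the projection masks M^Ω (observed entries) and M^O (zeros)."""
    observed = (matrix.values > 0).astype(np.float64)
    return MaskPair(observed=observed, zero=1.0 - observed)


@dataclass(frozen=True)
class FrequencySpec:
    """One reported side-effect frequency, in any of the three source formats.

    ``kind`` is ``exact_proportion`` (value: proportion of treated patients),
    ``proportion_range`` (value: (low, high) proportions) or ``class_label``
    (value: one of the five class names).
    """

    kind: str
    value: object

    def __post_init__(self):
        if self.kind not in ("exact_proportion", "proportion_range", "class_label"):
            raise ValidationError(f"unknown frequency spec kind: {self.kind!r}")


def _class_of_proportion(p: float) -> int:
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"proportion {p} outside [0, 1]")
    if p > _BIN_EDGES[3]:
        return 5  # very frequent: > 1 in 10
    if p >= _BIN_EDGES[2]:
        return 4  # frequent: [1/100, 1/10]
    if p >= _BIN_EDGES[1]:
        return 3  # infrequent: [1/1000, 1/100)
    if p >= _BIN_EDGES[0]:
        return 2  # rare: [1/10000, 1/1000)
    return 1  # very rare: < 1 in 10,000


def standardize_frequency(spec: FrequencySpec, range_rule: str = "midpoint") -> int:
    """Map a reported frequency to its integer class code in {1..5}.

    Classes follow the clinical-trial convention: very rare (<1/10,000),
    rare ([1/10,000, 1/1,000)), infrequent ([1/1,000, 1/100)), frequent
    ([1/100, 1/10]) and very frequent (>1/10).  Ranges map through their
    midpoint by default; ``range_rule="upper"`` maps through the upper bound.
    """
    if spec.kind == "class_label":
        label = str(spec.value).strip().lower().replace("_", " ")
        if label not in CLASS_CODES:
            raise ValidationError(f"unknown frequency class label: {spec.value!r}")
        return CLASS_CODES[label]
    if spec.kind == "exact_proportion":
        return _class_of_proportion(float(spec.value))
    low, high = (float(v) for v in spec.value)
    if not (0.0 <= low <= high <= 1.0):
        raise ValidationError(f"invalid proportion range ({low}, {high})")
    if range_rule == "midpoint":
        return _class_of_proportion((low + high) / 2.0)
    if range_rule == "upper":
        return _class_of_proportion(high)
    raise ValidationError(f"unknown range rule: {range_rule!r}")


# ---------------------------------------------------------------------------
# Matrix I/O
# ---------------------------------------------------------------------------

def _parse_class_cell(x) -> int:
    """Accept an integer code 0..5 or a class name."""
    if isinstance(x, str) and not x.strip().lstrip("-").isdigit():
        label = x.strip().lower().replace("_", " ")
        if label not in CLASS_CODES:
            raise ValidationError(f"unknown class label {x!r}")
        return CLASS_CODES[label]
    v = float(x)
    if v != round(v) or not (0 <= v <= 5):
        raise ValidationError(f"class code {x!r} outside 0..5")
    return int(v)


def load_frequency_matrix(path: str | os.PathLike, format: str = "auto") -> FrequencyMatrix:
    """Read a frequency matrix from a long-format or dense table.

    Long format (canonical): columns ``drug_id``, ``side_effect_id``,
    ``class`` — one row per observed association; unlisted cells are 0.
    Dense format: header row of side-effect ids, first column of drug ids.
    """
    path = os.fspath(path)
    sep = "," if path.endswith(".csv") else "\t"
    if format == "auto":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        format = "long" if header[:2] == ["drug_id", "side_effect_id"] else "dense"
    if format == "long":
        df = pd.read_csv(path, sep=sep, dtype={"drug_id": str, "side_effect_id": str})
        required = {"drug_id", "side_effect_id", "class"}
        if not required.issubset(df.columns):
            raise ValidationError(f"long table must have columns {sorted(required)}")
        if df.duplicated(subset=["drug_id", "side_effect_id"]).any():
            dup = df[df.duplicated(subset=["drug_id", "side_effect_id"])].iloc[0]
            raise ValidationError(
                f"duplicate pair ({dup['drug_id']}, {dup['side_effect_id']})"
            )
        drugs = list(dict.fromkeys(df["drug_id"]))
        effects = list(dict.fromkeys(df["side_effect_id"]))
        values = np.zeros((len(drugs), len(effects)), dtype=np.int64)
        di = {d: i for i, d in enumerate(drugs)}
        sj = {s: j for j, s in enumerate(effects)}
        for d, s, c in zip(df["drug_id"], df["side_effect_id"], df["class"]):
            values[di[d], sj[s]] = _parse_class_cell(c)
        return FrequencyMatrix(values, drugs, effects)
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy()
    if not np.all(np.isfinite(values.astype(float))):
        raise ValidationError("dense matrix contains non-finite or ragged cells")
    return FrequencyMatrix(
        values.astype(np.int64) if np.all(values == np.round(values.astype(float))) else values,
        [str(d) for d in df.index],
        [str(s) for s in df.columns],
    )


def save_frequency_matrix(matrix: FrequencyMatrix, path: str | os.PathLike, format: str = "long") -> None:
    """Write a frequency matrix as long-format TSV (default) or dense table."""
    path = os.fspath(path)
    sep = "," if path.endswith(".csv") else "\t"
    if format == "long":
        ii, jj = matrix.observed_indices()
        pd.DataFrame(
            {
                "drug_id": [matrix.drug_ids[i] for i in ii],
                "side_effect_id": [matrix.side_effect_ids[j] for j in jj],
                "class": matrix.values[ii, jj],
            }
        ).to_csv(path, sep=sep, index=False)
    else:
        pd.DataFrame(matrix.values, index=matrix.drug_ids, columns=matrix.side_effect_ids).to_csv(
            path, sep=sep
        )


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class CategoryMap:
    """Hierarchical multi-label annotations (ATC levels, MedDRA levels, routes).

    ``assignments[level][entity_id]`` is a non-empty set of category codes.
    """

    levels: list[str]
    assignments: dict[str, dict[str, set]] = field(default_factory=dict)

    def __post_init__(self):
        for level in self.levels:
            self.assignments.setdefault(level, {})
        for level, ents in self.assignments.items():
            if level not in self.levels:
                raise ValidationError(f"assignment level {level!r} not declared")
            for e, codes in ents.items():
                if not codes:
                    raise ValidationError(f"empty category set for {e!r} at level {level!r}")
                ents[e] = set(codes)

    def entities(self, level: str) -> list[str]:
        """Annotated entity ids at a level, insertion order."""
        return list(self.assignments[level])

    def codes_of(self, entity_id: str, level: str) -> set:
        return self.assignments[level].get(entity_id, set())

    def groups(self, level: str) -> dict[str, list[str]]:
        """category code -> list of member entity ids at the level."""
        out: dict[str, list[str]] = {}
        for e, codes in self.assignments[level].items():
            for c in sorted(codes):
                out.setdefault(c, []).append(e)
        return out

    def validate_against(self, entity_ids: Iterable[str]) -> None:
        """Check every annotated entity appears on the given matrix axis."""
        known = set(entity_ids)
        for level, ents in self.assignments.items():
            missing = set(ents) - known
            if missing:
                raise ValidationError(
                    f"annotated entities absent from matrix axis at level {level!r}: "
                    f"{sorted(missing)[:5]}"
                )


def load_annotations(path: str | os.PathLike) -> CategoryMap:
    """Read an annotation TSV with columns entity_id, level, category_code."""
    df = pd.read_csv(os.fspath(path), sep="\t", dtype=str)
    required = {"entity_id", "level", "category_code"}
    if not required.issubset(df.columns):
        raise ValidationError(f"annotation table must have columns {sorted(required)}")
    levels = list(dict.fromkeys(df["level"]))
    cm = CategoryMap(levels=levels)
    for e, lvl, c in zip(df["entity_id"], df["level"], df["category_code"]):
        cm.assignments[lvl].setdefault(e, set()).add(c)
    return cm


# ---------------------------------------------------------------------------
# Model bundle I/O (W.tsv / H.tsv / model.json)
# ---------------------------------------------------------------------------

def save_model(model, directory: str | os.PathLike) -> None:
    """Write a fitted factor model to ``W.tsv``, ``H.tsv`` and ``model.json``."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    np.savetxt(os.path.join(directory, "W.tsv"), model.W, delimiter="\t", fmt="%.17g")
    np.savetxt(os.path.join(directory, "H.tsv"), model.H, delimiter="\t", fmt="%.17g")
    cfg = model.config
    header = {
        "n": int(model.W.shape[0]),
        "m": int(model.H.shape[1]),
        "k": int(cfg.k),
        "alpha": cfg.alpha,
        "epsilon": cfg.epsilon,
        "tol_x": cfg.tol_x,
        "max_iter": cfg.max_iter,
        "init_low": cfg.init_low,
        "init_high": cfg.init_high,
        "seed": cfg.seed,
        "normalization": cfg.normalization,
        "n_iter": int(model.n_iter),
        "final_loss": float(model.loss_trace[-1]) if len(model.loss_trace) else None,
        "stop_reason": model.stop_reason,
        "loss_trace": [float(v) for v in model.loss_trace],
    }
    with open(os.path.join(directory, "model.json"), "w") as fh:
        json.dump(header, fh, indent=1)


def load_model(directory: str | os.PathLike):
    """Read a model bundle written by :func:`save_model`."""
    from .decomposition import DecompositionConfig, FactorModel

    directory = os.fspath(directory)
    with open(os.path.join(directory, "model.json")) as fh:
        header = json.load(fh)
    W = np.loadtxt(os.path.join(directory, "W.tsv"), delimiter="\t", ndmin=2)
    H = np.loadtxt(os.path.join(directory, "H.tsv"), delimiter="\t", ndmin=2)
    if W.shape != (header["n"], header["k"]) or H.shape != (header["k"], header["m"]):
        raise ValidationError(
            f"model bundle shape mismatch: header says W {header['n']}×{header['k']}, "
            f"H {header['k']}×{header['m']}; files are {W.shape} and {H.shape}"
        )
    cfg = DecompositionConfig(
        k=header["k"],
        alpha=header["alpha"],
        epsilon=header["epsilon"],
        tol_x=header["tol_x"],
        max_iter=header["max_iter"],
        init_low=header["init_low"],
        init_high=header["init_high"],
        seed=header["seed"],
        normalization=header["normalization"],
    )
    return FactorModel(
        W=W,
        H=H,
        loss_trace=np.asarray(header["loss_trace"], dtype=float),
        n_iter=header["n_iter"],
        config=cfg,
        stop_reason=header["stop_reason"],
    )
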