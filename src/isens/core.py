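"""Surrogate insulin-sensitivity indices and their rank-based equivalence.

Fasting surrogate indices such as HOMA-IR, QUICKI and FIRI are algebraic
functions of the same two measurements — fasting plasma glucose and fasting
plasma insulin — and are strictly monotone transformations of one another.
Consequently every statistic that depends on the data only through ranks
(Spearman correlation, Mann-Whitney tests, ROC curves and their AUCs) gives
identical results for all three, while moment-based statistics (Pearson
correlation, t-tests) generally differ.  This module provides:

* calculators for the common surrogate measures (fasting and OGTT-based)
  and the exact closed-form transformations between HOMA-IR, QUICKI and
  FIRI;
* a rank-statistics toolkit written directly from the defining formulas:
  Pearson and mid-rank Spearman correlation, the bivariate-normal
  Spearman-to-Pearson conversion r = 2 sin(rho*pi/6), threshold-sweep ROC
  curves with trapezoidal AUC and a brute-force pairwise-probability AUC
  oracle, and Mann-Whitney (normal approximation, tie + continuity
  corrected) next to Welch t-tests;
* a seeded synthetic-cohort generator with independent lognormal fasting
  glucose and insulin and a lognormal clamp measure M_LBM (glucose infusion
  rate per kg lean body mass) whose latent Gaussian coupling is calibrated
  by bisection so that Pearson(QUICKI, M_LBM) hits a configured target;
* a study pipeline that assembles correlation matrices, per-index ROC/AUC
  against the clamp-defined insulin-resistance label (M_LBM < cutoff), a
  rank-test identity table, and machine-checkable equivalence verdicts.

The file is organised in the order the method runs: index calculators,
evaluation toolkit, cohort simulation and I/O, then the study pipeline.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import stdtr

logger = logging.getLogger("isens")

# --------------------------------------------------------------------------
# Configuration constants
# --------------------------------------------------------------------------

LN10 = math.log(10.0)
HOMA_DENOMINATOR = 22.5  # (mmol/L)·(µU/mL): normal G0·I0 product
FIRI_DENOMINATOR = 25.0
DEFAULT_RESISTANCE_CUTOFF = 4.7  # mg/(kg·min), M_LBM below => resistant

# Fixed stream for the calibration Monte Carlo, independent of cohort seeds
# so that calibration is a deterministic function of the marginal parameters
# and target alone.
_CALIBRATION_SEED = 180626

#: Canonical cohort CSV schema (comma separator, decimal point, UTF-8).
COHORT_COLUMNS = (
    "subject_id",
    "glucose_mmol_l",
    "insulin_uU_ml",
    "homa_ir",
    "quicki",
    "firi",
    "m_lbm_mg_kg_min",
    "resistant",
)


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class IsensError(Exception):
    """Base class for all handled errors raised by this package."""


class InvalidInputError(IsensError, ValueError):
    """A physiological quantity is non-positive, non-finite or malformed."""


class MissingFieldError(InvalidInputError):
    """An index was requested whose required field is absent (never imputed)."""


class DegenerateInputError(IsensError, ValueError):
    """Mathematically degenerate input (e.g. QUICKI denominator zero)."""


class UnsupportedTransformError(IsensError, ValueError):
    """transform_index called outside the HOMA-IR/QUICKI/FIRI trio."""


class ConfigurationError(IsensError, ValueError):
    """Invalid simulation or study configuration."""


class CalibrationError(IsensError, RuntimeError):
    """The target correlation is unattainable within the latent range."""

    def __init__(self, message: str, closest_achieved: float):
        super().__init__(message)
        self.closest_achieved = closest_achieved


class SchemaError(IsensError, ValueError):
    """A delimited-text table does not match the expected column schema."""


class UndefinedStatisticError(IsensError, ValueError):
    """A correlation is undefined (constant series / too few observations)."""


class DegenerateLabelsError(IsensError, ValueError):
    """ROC analysis needs both a positive and a negative class."""


class DegenerateDataError(IsensError, ValueError):
    """Group comparison is undefined (e.g. zero variance in both groups)."""


# ==========================================================================
# Section 1 — surrogate index calculators
# ==========================================================================


def _require_positive_finite(name: str, value: float) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError) as exc:
        raise InvalidInputError(f"{name} must be a number, got {value!r}") from exc
    if not math.isfinite(v):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")
    if v <= 0.0:
        raise InvalidInputError(f"{name} must be strictly positive, got {value!r}")
    return v


class Orientation(enum.Enum):
    """Direction in which an index reads: does a larger value mean more
    insulin *resistance* or more insulin *sensitivity*?  Needed to orient
    ROC analysis and rank tests consistently across indices."""

    RESISTANCE_UP = "resistance_up"
    SENSITIVITY_UP = "sensitivity_up"


class IndexKind(enum.Enum):
    """The surrogate measures supported by this package.

    Declaration order is the stable reporting order used by
    :func:`compute_all`.
    """

    HOMA_IR = "homa_ir"
    QUICKI = "quicki"
    FIRI = "firi"
    MATSUDA = "matsuda"
    STUMVOLL = "stumvoll"
    REVISED_QUICKI = "revised_quicki"
    INSULIN_GLUCOSE_RATIO = "insulin_glucose_ratio"
    GLUCOSE_INSULIN_RATIO = "glucose_insulin_ratio"

    @property
    def orientation(self) -> Orientation:
        if self in _RESISTANCE_UP_KINDS:
            return Orientation.RESISTANCE_UP
        return Orientation.SENSITIVITY_UP


_RESISTANCE_UP_KINDS = frozenset(
    {IndexKind.HOMA_IR, IndexKind.FIRI, IndexKind.INSULIN_GLUCOSE_RATIO}
)

#: Human-readable labels used in reports and tables.
INDEX_LABELS: dict[IndexKind, str] = {
    IndexKind.HOMA_IR: "HOMA-IR",
    IndexKind.QUICKI: "QUICKI",
    IndexKind.FIRI: "FIRI",
    IndexKind.MATSUDA: "Matsuda",
    IndexKind.STUMVOLL: "Stumvoll",
    IndexKind.REVISED_QUICKI: "Revised QUICKI",
    IndexKind.INSULIN_GLUCOSE_RATIO: "I0/G0",
    IndexKind.GLUCOSE_INSULIN_RATIO: "G0/I0",
}

#: The mutually transformable fasting trio.
FASTING_TRIO = (IndexKind.HOMA_IR, IndexKind.QUICKI, IndexKind.FIRI)


@dataclass(frozen=True)
class FastingSample:
    """One subject's fasting measurements.

    Units: glucose in mmol/L, insulin in µU/mL — the convention under which
    the HOMA-IR denominator 22.5 (and FIRI's 25) is defined.  No unit
    conversion is ever performed silently.
    """

    glucose_fasting: float  # G0, mmol/L
    insulin_fasting: float  # I0, µU/mL

    def __post_init__(self) -> None:
        _require_positive_finite("glucose_fasting", self.glucose_fasting)
        _require_positive_finite("insulin_fasting", self.insulin_fasting)


@dataclass(frozen=True)
class OGTTRecord:
    """Extended per-subject record for OGTT-based indices.

    Non-fasting fields are individually optional; an index whose required
    field is absent fails with :class:`MissingFieldError` rather than
    imputing.  Documented units: Matsuda expects glucose in mg/dL and
    insulin in µU/mL; Stumvoll expects I120 in pmol/L and G90 in mmol/L.
    """

    fasting: FastingSample
    glucose_mean_ogtt: float | None = None  # G_mean
    insulin_mean_ogtt: float | None = None  # I_mean
    glucose_90min: float | None = None      # G_90
    insulin_120min: float | None = None     # I_120
    bmi: float | None = None                # kg/m²
    nefa: float | None = None               # non-esterified fatty acids

    def __post_init__(self) -> None:
        for name in (
            "glucose_mean_ogtt",
            "insulin_mean_ogtt",
            "glucose_90min",
            "insulin_120min",
            "bmi",
            "nefa",
        ):
            value = getattr(self, name)
            if value is not None:
                _require_positive_finite(name, value)

    def _require(self, *names: str) -> list[float]:
        values = []
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise MissingFieldError(
                    f"field {name!r} is required for this index and is absent"
                )
            values.append(float(value))
        return values


@dataclass(frozen=True)
class IndexValue:
    """A computed surrogate-index value (dimensionless)."""

    kind: IndexKind
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise InvalidInputError(
                f"{self.kind.name} value must be finite, got {self.value!r}"
            )


def homa_ir(s: FastingSample) -> IndexValue:
    """Homeostasis model of insulin resistance: (G0·I0)/22.5.

    Larger values indicate more insulin resistance.
    """
    return IndexValue(
        IndexKind.HOMA_IR, s.glucose_fasting * s.insulin_fasting / HOMA_DENOMINATOR
    )


def quicki(s: FastingSample) -> IndexValue:
    """Quantitative insulin sensitivity check index: 1/(log10 G0 + log10 I0).

    Base-10 logarithms (the convention of the index's originating
    literature).  Larger values indicate more insulin sensitivity.  The
    value is undefined when G0·I0 = 1 (zero denominator).
    """
    denom = math.log10(s.glucose_fasting) + math.log10(s.insulin_fasting)
    if denom == 0.0:
        raise DegenerateInputError(
            "QUICKI undefined: log10(G0) + log10(I0) = 0 (G0*I0 = 1)"
        )
    return IndexValue(IndexKind.QUICKI, 1.0 / denom)


def firi(s: FastingSample) -> IndexValue:
    """Fasting insulin resistance index: (G0·I0)/25 — a rescaled HOMA-IR."""
    return IndexValue(
        IndexKind.FIRI, s.glucose_fasting * s.insulin_fasting / FIRI_DENOMINATOR
    )


def matsuda(r: OGTTRecord) -> IndexValue:
    """Matsuda whole-body insulin sensitivity index.

    10000 / sqrt(G0·I0·G_mean·I_mean), with fasting and OGTT-mean glucose
    in mg/dL and insulin in µU/mL.  Larger values = more sensitive.
    """
    g_mean, i_mean = r._require("glucose_mean_ogtt", "insulin_mean_ogtt")
    product = (
        r.fasting.glucose_fasting * r.fasting.insulin_fasting * g_mean * i_mean
    )
    return IndexValue(IndexKind.MATSUDA, 10000.0 / math.sqrt(product))


def stumvoll(r: OGTTRecord) -> IndexValue:
    """Stumvoll metabolic clearance rate index.

    18.3 − 0.271·BMI − 0.0052·I120 − 0.27·G90 with I120 in pmol/L and G90
    in mmol/L; may be negative.  Larger values = more sensitive.
    """
    bmi, i120, g90 = r._require("bmi", "insulin_120min", "glucose_90min")
    return IndexValue(
        IndexKind.STUMVOLL, 18.3 - 0.271 * bmi - 0.0052 * i120 - 0.27 * g90
    )


def revised_quicki(r: OGTTRecord) -> IndexValue:
    """Revised QUICKI: 1/(log10 G0 + log10 I0 + log10 NEFA)."""
    (nefa,) = r._require("nefa")
    denom = (
        math.log10(r.fasting.glucose_fasting)
        + math.log10(r.fasting.insulin_fasting)
        + math.log10(nefa)
    )
    if denom == 0.0:
        raise DegenerateInputError(
            "revised QUICKI undefined: log10(G0)+log10(I0)+log10(NEFA) = 0"
        )
    return IndexValue(IndexKind.REVISED_QUICKI, 1.0 / denom)


def fasting_ratio(s: FastingSample, direction: str) -> IndexValue:
    """Fasting insulin/glucose ratio (or its reciprocal).

    ``direction`` is ``"insulin_over_glucose"`` (I0/G0, resistance-up) or
    ``"glucose_over_insulin"`` (G0/I0, sensitivity-up).
    """
    if direction == "insulin_over_glucose":
        return IndexValue(
            IndexKind.INSULIN_GLUCOSE_RATIO,
            s.insulin_fasting / s.glucose_fasting,
        )
    if direction == "glucose_over_insulin":
        return IndexValue(
            IndexKind.GLUCOSE_INSULIN_RATIO,
            s.glucose_fasting / s.insulin_fasting,
        )
    raise InvalidInputError(
        "direction must be 'insulin_over_glucose' or 'glucose_over_insulin', "
        f"got {direction!r}"
    )


def transform_index(v: IndexValue, target: IndexKind) -> IndexValue:
    """Exact transformation within the HOMA-IR / QUICKI / FIRI trio.

    All three are bijections of the product P = G0·I0:
    HOMA-IR = P/22.5, FIRI = P/25, QUICKI = 1/log10(P); so the transform
    recovers P and re-expresses it.  Matches the base-10 convention of
    :func:`quicki` (HOMA-IR = 10^(1/QUICKI)/22.5).  Transform to the own
    kind is the identity; round trips are exact to floating precision.
    """
    trio = set(FASTING_TRIO)
    if v.kind not in trio or target not in trio:
        raise UnsupportedTransformError(
            f"transform {v.kind.name} -> {target.name} is not supported; "
            "only HOMA_IR, QUICKI and FIRI are mutually transformable"
        )
    if v.kind is target:
        return IndexValue(target, v.value)
    if v.kind is IndexKind.QUICKI:
        if v.value == 0.0:
            raise DegenerateInputError("QUICKI value 0 has no finite preimage")
        product = 10.0 ** (1.0 / v.value)
    elif v.kind is IndexKind.HOMA_IR:
        product = v.value * HOMA_DENOMINATOR
    else:  # FIRI
        product = v.value * FIRI_DENOMINATOR
    if target is IndexKind.QUICKI:
        denom = math.log10(product)
        if denom == 0.0:
            raise DegenerateInputError("QUICKI undefined for G0*I0 = 1")
        return IndexValue(IndexKind.QUICKI, 1.0 / denom)
    if target is IndexKind.HOMA_IR:
        return IndexValue(IndexKind.HOMA_IR, product / HOMA_DENOMINATOR)
    return IndexValue(IndexKind.FIRI, product / FIRI_DENOMINATOR)


@dataclass(frozen=True)
class IndexResult:
    """Outcome of one requested index in :func:`compute_all`: either a
    value or an explicit per-kind failure message (never silently dropped)."""

    kind: IndexKind
    value: IndexValue | None
    error: str | None

    @property
    def ok(self) -> bool:
        return self.error is None


_INDEX_DISPATCH: dict[IndexKind, Callable[[OGTTRecord], IndexValue]] = {
    IndexKind.HOMA_IR: lambda r: homa_ir(r.fasting),
    IndexKind.QUICKI: lambda r: quicki(r.fasting),
    IndexKind.FIRI: lambda r: firi(r.fasting),
    IndexKind.MATSUDA: matsuda,
    IndexKind.STUMVOLL: stumvoll,
    IndexKind.REVISED_QUICKI: revised_quicki,
    IndexKind.INSULIN_GLUCOSE_RATIO: lambda r: fasting_ratio(
        r.fasting, "insulin_over_glucose"
    ),
    IndexKind.GLUCOSE_INSULIN_RATIO: lambda r: fasting_ratio(
        r.fasting, "glucose_over_insulin"
    ),
}


def compute_all(
    record: OGTTRecord, requested: Sequence[IndexKind] | set[IndexKind]
) -> list[IndexResult]:
    """Compute every requested index for one record.

    Results come back in the declaration order of :class:`IndexKind`.
    Kinds whose required fields are absent (or otherwise fail) are reported
    as explicit per-kind failures.
    """
    requested = set(requested)
    if not requested:
        raise InvalidInputError("requested index set must be non-empty")
    results: list[IndexResult] = []
    for kind in IndexKind:
        if kind not in requested:
            continue
        try:
            results.append(IndexResult(kind, _INDEX_DISPATCH[kind](record), None))
        except (MissingFieldError, DegenerateInputError, InvalidInputError) as exc:
            results.append(IndexResult(kind, None, str(exc)))
    return results


# ==========================================================================
# Section 2 — evaluation toolkit (correlation, ROC/AUC, group tests)
# ==========================================================================


def _as_1d_float(name: str, values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite or missing values")
    return arr


@dataclass(frozen=True)
class PairedSamples:
    """Two equal-length series of paired observations (x_i, y_i)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", _as_1d_float("x", self.x))
        object.__setattr__(self, "y", _as_1d_float("y", self.y))
        if self.x.shape[0] != self.y.shape[0]:
            raise InvalidInputError(
                f"paired series lengths differ: {self.x.shape[0]} vs {self.y.shape[0]}"
            )

    @property
    def n(self) -> int:
        return int(self.x.shape[0])


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    method: str  # "pearson" | "spearman"
    n: int


def midranks(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks (1-based; ties receive the average of their rank block)."""
    a = _as_1d_float("values", values)
    n = a.shape[0]
    order = np.argsort(a, kind="mergesort")
    sorted_a = a[order]
    # tie-group ids along the sorted array
    new_group = np.r_[True, sorted_a[1:] != sorted_a[:-1]]
    group_ids = np.cumsum(new_group) - 1
    counts = np.bincount(group_ids)
    ends = np.cumsum(counts)          # 1-based end rank of each group
    starts = ends - counts + 1
    group_rank = (starts + ends) / 2.0
    ranks = np.empty(n, dtype=float)
    ranks[order] = group_rank[group_ids]
    return ranks


def _pearson_xy(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson coefficient sum((x-x̄)(y-ȳ)) / sqrt(sum(x-x̄)² · sum(y-ȳ)²).

    The denominator is a single square root of the product so that exactly
    anti-monotone rank vectors yield exactly −1.0 (sqrt(s·s) == s in IEEE
    round-to-nearest), which the rank-equivalence checks rely on.
    """
    n = x.shape[0]
    if n < 3:
        raise UndefinedStatisticError(f"correlation requires n >= 3, got n={n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sx2 = float(np.dot(dx, dx))
    sy2 = float(np.dot(dy, dy))
    if sx2 == 0.0 or sy2 == 0.0:
        raise UndefinedStatisticError(
            "correlation undefined for a constant series (zero denominator)"
        )
    r = float(np.dot(dx, dy)) / math.sqrt(sx2 * sy2)
    return min(1.0, max(-1.0, r))


def pearson(p: PairedSamples) -> CorrelationResult:
    """Pearson's linear correlation coefficient of paired observations."""
    return CorrelationResult(_pearson_xy(p.x, p.y), "pearson", p.n)


def spearman(p: PairedSamples) -> CorrelationResult:
    """Spearman's rank correlation: Pearson applied to mid-ranks.

    Invariant under any strictly increasing transform of either series,
    which is the root of the HOMA-IR/QUICKI/FIRI equivalence.
    """
    return CorrelationResult(
        _pearson_xy(midranks(p.x), midranks(p.y)), "spearman", p.n
    )


def spearman_to_pearson(rho: float) -> float:
    """Convert a Spearman rho to the Pearson r implied under bivariate
    normality: r = 2·sin(rho·pi/6).

    The conversion is unreliable for skewed data (most insulin-sensitivity
    measures are skewed) and is provided for meta-analytic comparability
    only.  Endpoints ±1 are returned exactly (2·sin(±pi/6) = ±1).
    """
    if not (math.isfinite(rho) and -1.0 <= rho <= 1.0):
        raise InvalidInputError(f"rho must lie in [-1, 1], got {rho!r}")
    if abs(rho) == 1.0:
        return math.copysign(1.0, rho)
    return 2.0 * math.sin(rho * math.pi / 6.0)


@dataclass(frozen=True)
class ROCCurve:
    """An ROC curve as an ordered staircase of (FPR, TPR) points.

    Points start at (0, 0), end at (1, 1) and are non-decreasing in both
    coordinates; tied scores move as a block (one vertex per distinct
    oriented score).  ``auc`` is the trapezoidal area, which equals the
    tie-corrected pairwise win probability.
    """

    points: np.ndarray        # shape (k+1, 2): columns (fpr, tpr)
    thresholds: np.ndarray    # distinct oriented scores, descending (k,)
    orientation: str
    auc: float

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[bool],
    orientation: str = "higher_is_positive",
) -> ROCCurve:
    """ROC curve of a continuous score against a binary condition.

    ``orientation="lower_is_positive"`` negates the scores first (used for
    sensitivity-up indices like QUICKI, where *low* values flag insulin
    resistance).  At each distinct oriented score t, subjects with score
    >= t are called positive; TPR is the fraction of true positives so
    called, FPR the fraction of true negatives so called.
    """
    if orientation not in ("higher_is_positive", "lower_is_positive"):
        raise InvalidInputError(f"unknown orientation {orientation!r}")
    s = _as_1d_float("scores", scores)
    lab = np.asarray(labels, dtype=bool)
    if lab.shape != s.shape:
        raise InvalidInputError("scores and labels must have equal length")
    n_pos = int(lab.sum())
    n_neg = int(lab.shape[0] - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            f"ROC needs both classes; got {n_pos} positives, {n_neg} negatives"
        )
    oriented = -s if orientation == "lower_is_positive" else s
    order = np.argsort(-oriented, kind="mergesort")
    ss = oriented[order]
    ll = lab[order]
    block_end = np.r_[ss[1:] != ss[:-1], True]  # last element of each tie block
    tp = np.cumsum(ll)[block_end]
    fp = np.cumsum(~ll)[block_end]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        points=np.column_stack([fpr, tpr]),
        thresholds=ss[block_end],
        orientation=orientation,
        auc=auc,
    )


def auc_probability_oracle(
    scores_pos: Sequence[float], scores_neg: Sequence[float]
) -> float:
    """Brute-force AUC: (wins + 0.5·ties) / (n_pos·n_neg) over all
    positive-negative pairs — the probability a random positive outranks a
    random negative.  Independent check for :class:`ROCCurve` ``auc``."""
    pos = _as_1d_float("scores_pos", scores_pos)
    neg = _as_1d_float("scores_neg", scores_neg)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateLabelsError("both classes must be non-empty")
    wins = float((pos[:, None] > neg[None, :]).sum())
    ties = float((pos[:, None] == neg[None, :]).sum())
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def classify_resistant(m_lbm: float, cutoff: float = DEFAULT_RESISTANCE_CUTOFF) -> bool:
    """Insulin-resistance label from the clamp: True iff M_LBM < cutoff
    (strict; a subject exactly at the cutoff is not resistant)."""
    _require_positive_finite("m_lbm", m_lbm)
    _require_positive_finite("cutoff", cutoff)
    return m_lbm < cutoff


@dataclass(frozen=True)
class GroupTestResult:
    method: str  # "mann_whitney" | "t_test"
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> GroupTestResult:
    """Mann-Whitney rank-sum test, two-sided, normal approximation with
    mid-ranks, tie correction and continuity correction.

    The statistic is U for the first group (number of (a, b) pairs with
    a > b, counting ties as 1/2).  Because the test depends on the data
    only through the combined ranks, it returns identical results for any
    strictly increasing re-expression of the measurements.
    """
    xa = _as_1d_float("a", a)
    xb = _as_1d_float("b", b)
    n_a, n_b = xa.size, xb.size
    if n_a < 2 or n_b < 2:
        raise DegenerateDataError("each group needs at least two observations")
    combined = np.concatenate([xa, xb])
    ranks = midranks(combined)
    n = n_a + n_b
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    # tie correction on the combined sample
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0.0:
        # all observations identical: no evidence against the null
        return GroupTestResult("mann_whitney", u_a, 1.0, n_a, n_b)
    diff = u_a - mu
    cc = 0.5 * math.copysign(1.0, diff) if diff != 0.0 else 0.0
    z = (diff - cc) / math.sqrt(var)
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return GroupTestResult("mann_whitney", u_a, min(1.0, p), n_a, n_b)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> GroupTestResult:
    """Welch two-sample t-test (unequal variances), two-sided."""
    xa = _as_1d_float("a", a)
    xb = _as_1d_float("b", b)
    n_a, n_b = xa.size, xb.size
    if n_a < 2 or n_b < 2:
        raise DegenerateDataError("each group needs at least two observations")
    va = float(xa.var(ddof=1))
    vb = float(xb.var(ddof=1))
    se2 = va / n_a + vb / n_b
    if se2 == 0.0:
        raise DegenerateDataError("zero variance in both groups: t undefined")
    t = float(xa.mean() - xb.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
    )
    p = 2.0 * float(stdtr(df, -abs(t)))
    return GroupTestResult("t_test", t, min(1.0, p), n_a, n_b)


def group_tests(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[GroupTestResult, GroupTestResult]:
    """Run the rank-based and the parametric two-group test on the same data.

    Returns (Mann-Whitney, Welch t).  Across rank-equivalent indices the
    Mann-Whitney results are identical; the t-test results generally are
    not.
    """
    return mann_whitney(values_a, values_b), welch_t_test(values_a, values_b)


# ==========================================================================
# Section 3 — synthetic cohort generation and I/O
# ==========================================================================


@dataclass(frozen=True)
class LognormalParams:
    """Parameters of a lognormal marginal on the natural-log scale."""

    mu_log: float
    sigma_log: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu_log) and math.isfinite(self.sigma_log)):
            raise ConfigurationError("lognormal parameters must be finite")
        if self.sigma_log <= 0.0:
            raise ConfigurationError(
                f"sigma_log must be > 0, got {self.sigma_log!r}"
            )


# Physiologically plausible defaults: median fasting glucose 5.4 mmol/L with
# mild spread, median fasting insulin 8 µU/mL with the wide spread typical of
# insulin, and median M_LBM 6.5 mg/(kg·min) giving a realistic resistant
# fraction (~24%) under the 4.7 cutoff.  All are configuration values.
DEFAULT_GLUCOSE_PARAMS = LognormalParams(math.log(5.4), 0.11)
DEFAULT_INSULIN_PARAMS = LognormalParams(math.log(8.0), 0.5)
DEFAULT_MLBM_PARAMS = LognormalParams(math.log(6.5), 0.45)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic cohort reproducibly."""

    n_subjects: int = 1000
    glucose_params: LognormalParams = DEFAULT_GLUCOSE_PARAMS
    insulin_params: LognormalParams = DEFAULT_INSULIN_PARAMS
    mlbm_params: LognormalParams = DEFAULT_MLBM_PARAMS
    target_pearson_quicki_mlbm: float = 0.75
    resistance_cutoff: float = DEFAULT_RESISTANCE_CUTOFF
    seed: int = 0
    calibration_tolerance: float = 0.01
    calibration_mc_size: int = 100_000

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if not abs(self.target_pearson_quicki_mlbm) < 1.0:
            raise ConfigurationError("|target correlation| must be < 1")
        if self.resistance_cutoff <= 0.0:
            raise ConfigurationError("resistance_cutoff must be > 0")
        if self.calibration_tolerance <= 0.0:
            raise ConfigurationError("calibration_tolerance must be > 0")
        if self.calibration_mc_size < 100:
            raise ConfigurationError("calibration_mc_size must be >= 100")


def _draw_fasting_arrays(
    rng: np.random.Generator, n: int, gp: LognormalParams, ip: LognormalParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    zg = rng.standard_normal(n)
    zi = rng.standard_normal(n)
    g = np.exp(gp.mu_log + gp.sigma_log * zg)
    i = np.exp(ip.mu_log + ip.sigma_log * zi)
    return g, i, zg, zi


def simulate_fasting(
    n: int, gp: LognormalParams, ip: LognormalParams, seed: int
) -> list[FastingSample]:
    """Draw n independent fasting samples: glucose ~ lognormal(gp),
    insulin ~ lognormal(ip), mutually independent.  Identical seeds yield
    bit-identical output."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    g, i, _, _ = _draw_fasting_arrays(np.random.default_rng(seed), n, gp, ip)
    return [FastingSample(float(gv), float(iv)) for gv, iv in zip(g, i)]


def _sensitivity_score(
    zg: np.ndarray, zi: np.ndarray, gp: LognormalParams, ip: LognormalParams
) -> np.ndarray:
    """Standardized latent sensitivity direction: the negated, standardized
    log-score −(ln G0 + ln I0 − E)/SD.  QUICKI is strictly increasing in
    this score, so a positive latent correlation with ln(M_LBM) induces a
    positive raw-scale Pearson(QUICKI, M_LBM)."""
    scale = math.hypot(gp.sigma_log, ip.sigma_log)
    return -(gp.sigma_log * zg + ip.sigma_log * zi) / scale


def calibrate_latent_correlation(cfg: SimulationConfig) -> float:
    """Find the latent Gaussian correlation r* between ln(M_LBM) and the
    standardized sensitivity score such that the raw-scale
    Pearson(QUICKI, M_LBM) achieves the configured target.

    Bisection over r* in (−1, 1) with a common-random-numbers Monte Carlo
    of size ``calibration_mc_size`` at a fixed internal seed; the achieved
    correlation is strictly increasing in r*.  A target of exactly 0 is
    returned as r* = 0 (independence).  Raises :class:`CalibrationError`
    (reporting the closest achieved value) if the target is unattainable.
    """
    target = cfg.target_pearson_quicki_mlbm
    if target == 0.0:
        return 0.0
    gp, ip, mp = cfg.glucose_params, cfg.insulin_params, cfg.mlbm_params
    rng = np.random.default_rng(_CALIBRATION_SEED)
    mc = cfg.calibration_mc_size
    zg = rng.standard_normal(mc)
    zi = rng.standard_normal(mc)
    ze = rng.standard_normal(mc)
    log_sum = (gp.mu_log + ip.mu_log) + gp.sigma_log * zg + ip.sigma_log * zi
    q = LN10 / log_sum  # QUICKI = 1/log10(G0·I0)
    x = _sensitivity_score(zg, zi, gp, ip)

    def achieved(r: float) -> float:
        z = r * x + math.sqrt(1.0 - r * r) * ze
        m = np.exp(mp.mu_log + mp.sigma_log * z)
        return _pearson_xy(q, m)

    lo, hi = -1.0 + 1e-9, 1.0 - 1e-9
    f_lo, f_hi = achieved(lo), achieved(hi)
    tol = cfg.calibration_tolerance
    if target > f_hi + tol:
        raise CalibrationError(
            f"target {target} unattainable: closest achieved {f_hi:.6f}", f_hi
        )
    if target < f_lo - tol:
        raise CalibrationError(
            f"target {target} unattainable: closest achieved {f_lo:.6f}", f_lo
        )
    mid = 0.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        fm = achieved(mid)
        if abs(fm - target) <= 0.5 * tol:
            return mid
        if fm < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13:
            break
    fm = achieved(mid)
    if abs(fm - target) <= tol:
        return mid
    raise CalibrationError(
        f"calibration did not converge: closest achieved {fm:.6f}", fm
    )


@dataclass
class SimulatedCohort:
    """A cohort table (canonical :data:`COHORT_COLUMNS` schema) plus
    provenance.  ``glucose_mmol_l``/``insulin_uU_ml`` may be NaN for
    cohorts loaded from index-only files."""

    table: pd.DataFrame
    config: SimulationConfig | None = None
    latent_correlation: float | None = None
    achieved_pearson_quicki_mlbm: float | None = None

    @property
    def n(self) -> int:
        return int(len(self.table))

    @property
    def homa_ir(self) -> np.ndarray:
        return self.table["homa_ir"].to_numpy(dtype=float)

    @property
    def quicki(self) -> np.ndarray:
        return self.table["quicki"].to_numpy(dtype=float)

    @property
    def firi(self) -> np.ndarray:
        return self.table["firi"].to_numpy(dtype=float)

    @property
    def m_lbm(self) -> np.ndarray:
        return self.table["m_lbm_mg_kg_min"].to_numpy(dtype=float)

    @property
    def resistant(self) -> np.ndarray:
        return self.table["resistant"].to_numpy(dtype=bool)

    def fasting_samples(self) -> list[FastingSample]:
        g = self.table["glucose_mmol_l"].to_numpy(dtype=float)
        i = self.table["insulin_uU_ml"].to_numpy(dtype=float)
        if np.isnan(g).any() or np.isnan(i).any():
            raise MissingFieldError(
                "this cohort carries index values only (no fasting samples)"
            )
        return [FastingSample(float(a), float(b)) for a, b in zip(g, i)]


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort.

    Fasting glucose and insulin are independent lognormals; the three
    fasting indices are computed per subject through the index calculators;
    ln(M_LBM) is a normal with the configured marginal whose correlation
    with the standardized sensitivity score is the calibrated r*; the
    resistance label is the strict cutoff comparison M_LBM < cutoff.
    Bit-reproducible for a fixed config.
    """
    r_star = calibrate_latent_correlation(cfg)
    gp, ip, mp = cfg.glucose_params, cfg.insulin_params, cfg.mlbm_params
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    g, i, zg, zi = _draw_fasting_arrays(rng, n, gp, ip)
    ze = rng.standard_normal(n)
    x = _sensitivity_score(zg, zi, gp, ip)
    z = r_star * x + math.sqrt(1.0 - r_star * r_star) * ze
    m = np.exp(mp.mu_log + mp.sigma_log * z)

    samples = [FastingSample(float(a), float(b)) for a, b in zip(g, i)]
    homa = np.array([homa_ir(s).value for s in samples])
    qui = np.array([quicki(s).value for s in samples])
    fir = np.array([firi(s).value for s in samples])
    resistant = m < cfg.resistance_cutoff

    table = pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1),
            "glucose_mmol_l": g,
            "insulin_uU_ml": i,
            "homa_ir": homa,
            "quicki": qui,
            "firi": fir,
            "m_lbm_mg_kg_min": m,
            "resistant": resistant,
        }
    )
    try:
        achieved = _pearson_xy(qui, m)
    except UndefinedStatisticError:
        achieved = float("nan")
    logger.info(
        "stage=simulate n=%d seed=%d latent_r=%.6f achieved_pearson=%.6f "
        "resistant=%d",
        n, cfg.seed, r_star, achieved, int(resistant.sum()),
    )
    return SimulatedCohort(table, cfg, r_star, achieved)


def save_cohort(cohort: SimulatedCohort, path: str | Path) -> None:
    """Write the cohort table as CSV in the canonical schema (UTF-8, comma
    separator, decimal point).  Floats round-trip exactly."""
    cohort.table.to_csv(path, index=False, float_format="%.17g")


_REQUIRED_LOAD_COLUMNS = {
    "homa_ir": ("homair",),
    "quicki": ("quicki",),
    "firi": ("firi",),
    "m_lbm_mg_kg_min": ("mlbm",),
}
_OPTIONAL_LOAD_COLUMNS = {
    "glucose_mmol_l": ("gluc",),
    "insulin_uU_ml": ("insulin",),
    "subject_id": ("subjectid", "subject", "id"),
}


def _normalise_header(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


def load_cohort(
    path: str | Path,
    fmt: str | None = None,
    cutoff: float = DEFAULT_RESISTANCE_CUTOFF,
) -> SimulatedCohort:
    """Load a cohort from a delimited-text (CSV) or spreadsheet (XLSX)
    table.

    Headers are matched case- and punctuation-insensitively; columns for
    the three fasting indices and M_LBM are required (e.g. ``HOMA-IR``,
    ``QUICKI``, ``FIRI``, ``M_LBM``), fasting glucose/insulin are optional.
    Resistance labels are recomputed from ``cutoff``; index values are
    taken as given.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "csv":
        raw = pd.read_csv(path, float_precision="round_trip")
    elif fmt == "xlsx":
        raw = pd.read_excel(path)
    else:
        raise ConfigurationError(f"unknown format {fmt!r}; use 'csv' or 'xlsx'")

    normalised = {_normalise_header(c): c for c in raw.columns}

    def find(prefixes: tuple[str, ...]) -> str | None:
        for norm, original in normalised.items():
            if any(norm.startswith(p) for p in prefixes):
                return original
        return None

    data: dict[str, np.ndarray] = {}
    missing = []
    for canonical, prefixes in _REQUIRED_LOAD_COLUMNS.items():
        col = find(prefixes)
        if col is None:
            missing.append(canonical)
        else:
            data[canonical] = raw[col].to_numpy(dtype=float)
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing}; expected headers matching "
            f"{sorted(p for v in _REQUIRED_LOAD_COLUMNS.values() for p in v)}, "
            f"found {list(raw.columns)}"
        )
    n = len(raw)
    for canonical, prefixes in _OPTIONAL_LOAD_COLUMNS.items():
        col = find(prefixes)
        if col is not None:
            data[canonical] = raw[col].to_numpy()
    if "subject_id" not in data:
        data["subject_id"] = np.arange(1, n + 1)
    for optional in ("glucose_mmol_l", "insulin_uU_ml"):
        if optional not in data:
            data[optional] = np.full(n, np.nan)
    m = data["m_lbm_mg_kg_min"]
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise InvalidInputError("M_LBM values must be positive and finite")
    data["resistant"] = m < cutoff
    table = pd.DataFrame({c: data[c] for c in COHORT_COLUMNS})
    logger.info("stage=load path=%s n=%d cutoff=%s", path, n, cutoff)
    return SimulatedCohort(table, config=None)


# ==========================================================================
# Section 4 — study pipeline
# ==========================================================================

_COHORT_COLUMN_FOR: dict[IndexKind, str] = {
    IndexKind.HOMA_IR: "homa_ir",
    IndexKind.QUICKI: "quicki",
    IndexKind.FIRI: "firi",
}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the end-to-end demonstration study."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    use_log_mlbm_panels: bool = True
    indices_to_report: tuple[IndexKind, ...] = FASTING_TRIO
    report_path: str | None = None

    def __post_init__(self) -> None:
        if not self.indices_to_report:
            raise ConfigurationError("indices_to_report must be non-empty")
        for kind in self.indices_to_report:
            if kind not in _COHORT_COLUMN_FOR:
                raise ConfigurationError(
                    f"the equivalence study evaluates the fasting trio only; "
                    f"got {kind!r}"
                )


@dataclass(frozen=True)
class Verdict:
    """A boolean equivalence verdict with its numeric evidence: the largest
    observed discrepancy from the claimed identity."""

    passed: bool
    discrepancy: float


@dataclass
class EvaluationReport:
    """All numeric outputs of one study run."""

    pearson_indices: pd.DataFrame
    spearman_indices: pd.DataFrame
    mlbm_correlations: pd.DataFrame
    roc_curves: dict[str, ROCCurve]
    auc_table: pd.DataFrame
    group_tests: pd.DataFrame
    verdicts: dict[str, Verdict]
    provenance: dict


def _safe_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    """Correlation or NaN where it is undefined (flagged, never fabricated)."""
    try:
        if method == "pearson":
            return _pearson_xy(x, y)
        return _pearson_xy(midranks(x), midranks(y))
    except UndefinedStatisticError:
        return float("nan")


def run_study(
    cfg: StudyConfig, cohort: SimulatedCohort | None = None
) -> EvaluationReport:
    """Run the full demonstration on a simulated (or supplied) cohort.

    Produces both correlation coefficients between the reported indices and
    against M_LBM (and log M_LBM), per-index ROC curves and AUCs against
    the clamp-defined resistance label, Mann-Whitney and Welch tests for a
    median split of M_LBM, and the three equivalence verdicts with their
    observed discrepancies.  Deterministic given the seed.
    """
    if cohort is None:
        cohort = simulate_cohort(cfg.simulation)
    kinds = list(cfg.indices_to_report)
    labels = [INDEX_LABELS[k] for k in kinds]
    values = {
        INDEX_LABELS[k]: cohort.table[_COHORT_COLUMN_FOR[k]].to_numpy(dtype=float)
        for k in kinds
    }
    m = cohort.m_lbm
    resistant = cohort.resistant

    # -- correlation matrices between the indices (Fig. 2 analogue) --------
    pearson_m = pd.DataFrame(index=labels, columns=labels, dtype=float)
    spearman_m = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for la in labels:
        for lb in labels:
            pearson_m.loc[la, lb] = _safe_corr(values[la], values[lb], "pearson")
            spearman_m.loc[la, lb] = _safe_corr(values[la], values[lb], "spearman")

    # -- per-index correlations with M_LBM and log M_LBM (Fig. 3 analogue) -
    cols = ["pearson_mlbm", "spearman_mlbm"]
    if cfg.use_log_mlbm_panels:
        cols += ["pearson_log_mlbm", "spearman_log_mlbm"]
    mlbm_corr = pd.DataFrame(index=labels, columns=cols, dtype=float)
    log_m = np.log(m) if cfg.use_log_mlbm_panels else None
    for la in labels:
        mlbm_corr.loc[la, "pearson_mlbm"] = _safe_corr(values[la], m, "pearson")
        mlbm_corr.loc[la, "spearman_mlbm"] = _safe_corr(values[la], m, "spearman")
        if cfg.use_log_mlbm_panels:
            mlbm_corr.loc[la, "pearson_log_mlbm"] = _safe_corr(
                values[la], log_m, "pearson"
            )
            mlbm_corr.loc[la, "spearman_log_mlbm"] = _safe_corr(
                values[la], log_m, "spearman"
            )

    # -- ROC / AUC against the resistance label (Fig. 4 analogue) ----------
    roc_curves: dict[str, ROCCurve] = {}
    auc_rows = []
    for kind, la in zip(kinds, labels):
        orientation = (
            "higher_is_positive"
            if kind.orientation is Orientation.RESISTANCE_UP
            else "lower_is_positive"
        )
        curve = roc_curve(values[la], resistant, orientation)
        roc_curves[la] = curve
        auc_rows.append({"index": la, "orientation": orientation, "auc": curve.auc})
    auc_table = pd.DataFrame(auc_rows).set_index("index")

    # -- rank-based vs parametric group tests on a median split of M_LBM ---
    median = float(np.median(m))
    mask_low = m < median
    if not mask_low.any() or mask_low.all():
        raise DegenerateDataError("median split produced an empty group")
    test_rows = []
    for kind, la in zip(kinds, labels):
        v = values[la]
        # orientation-reverse sensitivity-up indices so the Mann-Whitney
        # statistic (not just the two-sided p) is identical across the trio
        oriented = v if kind.orientation is Orientation.RESISTANCE_UP else -v
        row = {"index": la}
        try:
            mw = mann_whitney(oriented[mask_low], oriented[~mask_low])
            row["mann_whitney_U"], row["mann_whitney_p"] = mw.statistic, mw.p_value
        except DegenerateDataError:
            row["mann_whitney_U"] = row["mann_whitney_p"] = float("nan")
        try:
            tt = welch_t_test(v[mask_low], v[~mask_low])
            row["welch_t"], row["welch_p"] = tt.statistic, tt.p_value
        except DegenerateDataError:
            row["welch_t"] = row["welch_p"] = float("nan")
        test_rows.append(row)
    tests = pd.DataFrame(test_rows).set_index("index")

    # -- equivalence verdicts with numeric evidence -------------------------
    verdicts: dict[str, Verdict] = {}

    discs = [0.0]
    for i, (ka, la) in enumerate(zip(kinds, labels)):
        for kb, lb in zip(kinds[i + 1:], labels[i + 1:]):
            expected = 1.0 if ka.orientation is kb.orientation else -1.0
            discs.append(abs(float(spearman_m.loc[la, lb]) - expected))
    abs_s = np.abs(mlbm_corr["spearman_mlbm"].to_numpy(dtype=float))
    if abs_s.size > 1:
        discs.append(float(abs_s.max() - abs_s.min()))
    disc = float(np.max(discs))  # NaN (undefined correlation) propagates
    verdicts["spearman_rank_equivalence"] = Verdict(bool(disc == 0.0), disc)

    ref = roc_curves[labels[0]]
    points_identical = all(
        roc_curves[la].points.shape == ref.points.shape
        and np.array_equal(roc_curves[la].points, ref.points)
        for la in labels[1:]
    )
    aucs = auc_table["auc"].to_numpy(dtype=float)
    auc_disc = float(aucs.max() - aucs.min()) if aucs.size else 0.0
    verdicts["roc_identity"] = Verdict(
        bool(points_identical and auc_disc <= 1e-12), auc_disc
    )

    u = tests["mann_whitney_U"].to_numpy(dtype=float)
    p = tests["mann_whitney_p"].to_numpy(dtype=float)
    rank_disc = float(max(u.max() - u.min(), p.max() - p.min()))
    verdicts["rank_test_identity"] = Verdict(bool(rank_disc == 0.0), rank_disc)

    tp = tests["welch_p"].to_numpy(dtype=float)
    t_disc = float(tp.max() - tp.min())
    verdicts["welch_results_differ"] = Verdict(bool(t_disc > 0.0), t_disc)

    provenance = {
        "n_subjects": cohort.n,
        "seed": cohort.config.seed if cohort.config is not None else None,
        "config": asdict(cohort.config) if cohort.config is not None else None,
        "latent_correlation": cohort.latent_correlation,
        "achieved_pearson_quicki_mlbm": cohort.achieved_pearson_quicki_mlbm,
        "resistance_cutoff": (
            cohort.config.resistance_cutoff
            if cohort.config is not None
            else DEFAULT_RESISTANCE_CUTOFF
        ),
        "n_resistant": int(resistant.sum()),
        "median_split_at": median,
    }
    logger.info(
        "stage=evaluate n=%d verdicts=%s",
        cohort.n,
        {k: v.passed for k, v in verdicts.items()},
    )
    return EvaluationReport(
        pearson_indices=pearson_m,
        spearman_indices=spearman_m,
        mlbm_correlations=mlbm_corr,
        roc_curves=roc_curves,
        auc_table=auc_table,
        group_tests=tests,
        verdicts=verdicts,
        provenance=provenance,
    )


def _fmt(v: float) -> str:
    if isinstance(v, float) and math.isnan(v):
        return "undefined"
    return f"{v:.6f}"


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Write the report to a directory: a human-readable ``report.txt`` plus
    machine-readable CSV tables (correlation matrices, per-index ROC
    points, AUC table, group tests).  Re-running on the same report is
    byte-identical."""
    directory = Path(path)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        report.pearson_indices.to_csv(directory / "pearson_indices.csv")
        report.spearman_indices.to_csv(directory / "spearman_indices.csv")
        report.mlbm_correlations.to_csv(directory / "mlbm_correlations.csv")
        report.auc_table.to_csv(directory / "auc.csv")
        report.group_tests.to_csv(directory / "group_tests.csv")

        rows = []
        for la, curve in report.roc_curves.items():
            thresholds = np.r_[np.nan, curve.thresholds]
            for j, ((fpr, tpr), thr) in enumerate(
                zip(curve.points, thresholds)
            ):
                rows.append(
                    {
                        "index": la,
                        "point": j,
                        "threshold": thr,
                        "fpr": fpr,
                        "tpr": tpr,
                    }
                )
        pd.DataFrame(rows).to_csv(
            directory / "roc_points.csv", index=False, float_format="%.17g"
        )

        lines = ["Insulin-sensitivity surrogate equivalence report", ""]
        lines.append("Provenance")
        for key, value in report.provenance.items():
            if key == "config":
                continue
            lines.append(f"  {key}: {value}")
        for title, frame in (
            ("Pearson correlations between indices", report.pearson_indices),
            ("Spearman correlations between indices", report.spearman_indices),
            ("Correlations with M_LBM", report.mlbm_correlations),
        ):
            lines += ["", title]
            lines.append(frame.to_string(float_format=_fmt))
        lines += ["", "AUC against the M_LBM resistance label"]
        lines.append(report.auc_table.to_string(float_format=_fmt))
        lines += ["", "Group tests (median split of M_LBM)"]
        lines.append(report.group_tests.to_string(float_format=_fmt))
        lines += ["", "Equivalence verdicts"]
        for name, verdict in report.verdicts.items():
            lines.append(
                f"  {name}: {'PASS' if verdict.passed else 'FAIL'} "
                f"(discrepancy={_fmt(verdict.discrepancy)})"
            )
        lines.append("")
        (directory / "report.txt").write_text("\n".join(lines), encoding="utf-8")
    except OSError as exc:
        raise IsensError(f"failed to write report under {directory}: {exc}") from exc
    logger.info("stage=report path=%s", directory)


def plot_report(report: EvaluationReport, path: str | Path) -> None:
    """Optional: overlay the per-index ROC curves in a PNG (requires
    matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 5))
    for la, curve in report.roc_curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{la} (AUC={curve.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(directory / "roc_curves.png", dpi=150)
    plt.close(fig)


# --------------------------------------------------------------------------
# Flat key=value configuration files (CLI support)
# --------------------------------------------------------------------------

#: Recognised configuration keys for the flat key=value config format.
CONFIG_KEYS = (
    "n_subjects",
    "glucose_mu_log",
    "glucose_sigma_log",
    "insulin_mu_log",
    "insulin_sigma_log",
    "mlbm_mu_log",
    "mlbm_sigma_log",
    "target_pearson_quicki_mlbm",
    "resistance_cutoff",
    "seed",
    "calibration_tolerance",
    "calibration_mc_size",
    "use_log_mlbm_panels",
)


def parse_config_file(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 'key = value', got {line!r}"
            )
        key, _, value = stripped.partition("=")
        key = key.strip()
        if key not in CONFIG_KEYS:
            raise ConfigurationError(
                f"{path}:{lineno}: unknown key {key!r}; known keys: {CONFIG_KEYS}"
            )
        mapping[key] = value.strip()
    return mapping


def simulation_config_from_mapping(
    mapping: Mapping[str, str],
    seed: int | None = None,
    cutoff: float | None = None,
    n_subjects: int | None = None,
) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a flat string mapping, with
    optional overrides (CLI flags) taking precedence."""

    def get(key: str, cast, default):
        return cast(mapping[key]) if key in mapping else default

    base = SimulationConfig()
    return SimulationConfig(
        n_subjects=(
            n_subjects
            if n_subjects is not None
            else get("n_subjects", int, base.n_subjects)
        ),
        glucose_params=LognormalParams(
            get("glucose_mu_log", float, base.glucose_params.mu_log),
            get("glucose_sigma_log", float, base.glucose_params.sigma_log),
        ),
        insulin_params=LognormalParams(
            get("insulin_mu_log", float, base.insulin_params.mu_log),
            get("insulin_sigma_log", float, base.insulin_params.sigma_log),
        ),
        mlbm_params=LognormalParams(
            get("mlbm_mu_log", float, base.mlbm_params.mu_log),
            get("mlbm_sigma_log", float, base.mlbm_params.sigma_log),
        ),
        target_pearson_quicki_mlbm=get(
            "target_pearson_quicki_mlbm", float, base.target_pearson_quicki_mlbm
        ),
        resistance_cutoff=(
            cutoff
            if cutoff is not None
            else get("resistance_cutoff", float, base.resistance_cutoff)
        ),
        seed=seed if seed is not None else get("seed", int, base.seed),
        calibration_tolerance=get(
            "calibration_tolerance", float, base.calibration_tolerance
        ),
        calibration_mc_size=get(
            "calibration_mc_size", int, base.calibration_mc_size
        ),
    )


def study_config_from_mapping(
    mapping: Mapping[str, str],
    seed: int | None = None,
    cutoff: float | None = None,
    n_subjects: int | None = None,
) -> StudyConfig:
    sim = simulation_config_from_mapping(
        mapping, seed=seed, cutoff=cutoff, n_subjects=n_subjects
    )
    use_log = mapping.get("use_log_mlbm_panels", "true").strip().lower() in (
        "1",
        "true",
        "yes",
    )
    return StudyConfig(simulation=sim, use_log_mlbm_panels=use_log)
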