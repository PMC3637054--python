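"""Decision statistics for recognizing higher-activity mutants.

Each screen compares two clone panels: the *starting material* (lower
catalytic capacity) and the *positive candidate* (higher).  Either the
activity concentration (AC, U/mL) or the specific activity (SA, U/mg)
serves as the decision index.  Separability is measured by the empirical
ROC AUC (Mann-Whitney form: the fraction of positive/negative pairs where
the positive's index is higher, ties counted half), and the practical
decision rule is a threshold at

    mean(starting material) + k * SD(starting material),   k = 1.4

whose normalized cutoff k targets ~92% specificity under a normal index
distribution (Phi(1.4) ~ 0.919).  A clone calls positive only when its
index strictly exceeds the threshold, so ties stay with the starting
material and specificity is conservative.

Supporting kernels (CV summary, Shapiro-Wilk normality, two-sided F test
for homoscedasticity, equal-variance Student t, Pearson r) wrap scipy's
implementations behind the small validation contracts a screening report
needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DomainError,
    InsufficientDataError,
    NormalizationError,
    UndefinedStatisticError,
)
from .panels import ClonePanel, load_table1

__all__ = [
    "Summary",
    "PairDesign",
    "RocReport",
    "ThresholdRule",
    "summarize",
    "empirical_auc",
    "roc_curve",
    "apply_threshold_rule",
    "binormal_auc",
    "replicate_pair_auc",
    "replicate_threshold_rule",
    "screen_report",
    "normality_test",
    "variance_homogeneity_test",
    "mean_difference_test",
    "pearson_r",
    "DEFAULT_PAIRS",
]

INDEXES = ("activity_concentration", "specific_activity")

#: Screen pairs as (positive candidate, starting material), capacity descending A>B>C>D.
DEFAULT_PAIRS = (("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"), ("B", "D"), ("A", "D"))


class Summary(NamedTuple):
    mean: float
    sd: float
    cv: float


def summarize(values) -> Summary:
    """Sample mean, SD (n-1 denominator), and CV = SD/mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 values to summarize")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return Summary(mean, sd, sd / mean)


def empirical_auc(positives, negatives) -> float:
    """Mann-Whitney AUC: P(positive > negative) with ties counted 0.5."""
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("both groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = float(ranks[: pos.size].sum()) - pos.size * (pos.size + 1) / 2.0
    return u / (pos.size * neg.size)


def _index_values(panel: ClonePanel, index: str) -> np.ndarray:
    if index == "activity_concentration":
        return np.asarray(panel.ac_U_per_mL, dtype=float)
    if index == "specific_activity":
        return np.asarray(panel.sa_U_per_mg, dtype=float)
    raise DomainError(f"index must be one of {INDEXES}, got {index!r}")


@dataclass(frozen=True)
class PairDesign:
    """A screen pair: lower-capacity starting material vs positive candidate."""

    starting_material: ClonePanel
    positive_candidate: ClonePanel
    index: str = "specific_activity"

    def __post_init__(self):
        if self.index not in INDEXES:
            raise DomainError(f"index must be one of {INDEXES}")
        if self.starting_material.n == 0 or self.positive_candidate.n == 0:
            raise DomainError("panels must be nonempty")
        if self.starting_material.candidate == self.positive_candidate.candidate:
            raise DomainError("starting material and positive candidate must differ")

    @property
    def negatives(self) -> np.ndarray:
        return _index_values(self.starting_material, self.index)

    @property
    def positives(self) -> np.ndarray:
        return _index_values(self.positive_candidate, self.index)


@dataclass(frozen=True)
class RocReport:
    """Empirical ROC over all observed cutoffs, plus normalized cutoffs
    ((cutoff - mean_SM) / SD_SM) for threshold-rule reading."""

    auc: float
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    normalized_cutoffs: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "normalized_cutoff": self.normalized_cutoffs,
                "sensitivity": self.sensitivity,
                "one_minus_specificity": 1.0 - self.specificity,
            }
        )


@dataclass(frozen=True)
class ThresholdRule:
    """The mean + k*SD decision rule evaluated on a pair."""

    k: float
    threshold: float
    sensitivity: float
    specificity: float


def roc_curve(design: PairDesign) -> RocReport:
    """Empirical ROC with cutoffs at every distinct observed value.

    A clone calls positive when its index strictly exceeds the cutoff.
    The trapezoidal area of (1-specificity, sensitivity) equals the
    Mann-Whitney AUC identically (ties contribute half).
    """
    pos, neg = design.positives, design.negatives
    sm = summarize(neg)
    if sm.sd == 0:
        raise NormalizationError("starting material has zero SD; cannot normalize cutoffs")
    finite = np.unique(np.concatenate([pos, neg]))
    cutoffs = np.concatenate([[-np.inf], finite, [np.inf]])
    sens = np.array([(pos > c).mean() for c in cutoffs])
    spec = np.array([(neg <= c).mean() for c in cutoffs])
    x = 1.0 - spec  # descending in cutoff
    auc = float(-np.trapezoid(sens, x))
    normalized = (cutoffs - sm.mean) / sm.sd
    return RocReport(auc=auc, cutoffs=cutoffs, sensitivity=sens,
                     specificity=spec, normalized_cutoffs=normalized)


def apply_threshold_rule(design: PairDesign, k: float = 1.4) -> ThresholdRule:
    """Threshold = SM mean + k*SM SD; sensitivity/specificity at it."""
    pos, neg = design.positives, design.negatives
    sm = summarize(neg)
    threshold = sm.mean + k * sm.sd
    return ThresholdRule(
        k=k,
        threshold=threshold,
        sensitivity=float((pos > threshold).mean()),
        specificity=float((neg <= threshold).mean()),
    )


def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Closed-form AUC for two normal index distributions:
    Phi((mu_pos - mu_neg) / sqrt(sd_pos^2 + sd_neg^2))."""
    return float(stats.norm.cdf((mu_pos - mu_neg) / math.hypot(sd_pos, sd_neg)))


def _auc_batch(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC for (reps, n) sample matrices."""
    reps, n_pos = pos.shape
    n_neg = neg.shape[1]
    both = np.concatenate([pos, neg], axis=1)
    ranks = stats.rankdata(both, axis=1)
    u = ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def replicate_pair_auc(
    mu_pos: float,
    sd_pos: float,
    mu_neg: float,
    sd_neg: float,
    n: int = 30,
    reps: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Replicate-averaged empirical AUC for gaussian index panels.

    Each replicate draws n clones per group from N(mu, sd) and scores the
    Mann-Whitney AUC; the average over replicates converges to the
    binormal value for large ``reps``.
    """
    if reps < 1:
        raise DomainError("reps must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pos = rng.normal(mu_pos, sd_pos, size=(reps, n))
    neg = rng.normal(mu_neg, sd_neg, size=(reps, n))
    return float(_auc_batch(pos, neg).mean())


def replicate_threshold_rule(
    mu_sm: float,
    sd_sm: float,
    mu_pos: float,
    sd_pos: float,
    k: float = 1.4,
    n: int = 30,
    reps: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Replicate-averaged (sensitivity, specificity) of the mean + k*SD rule.

    Per replicate the threshold is computed from that replicate's starting
    material sample (mean + k * sample SD) and evaluated on both panels,
    mirroring how a screen would set its cutoff from the data at hand.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sm = rng.normal(mu_sm, sd_sm, size=(reps, n))
    pos = rng.normal(mu_pos, sd_pos, size=(reps, n))
    thr = sm.mean(axis=1) + k * sm.std(axis=1, ddof=1)
    sens = (pos > thr[:, None]).mean(axis=1)
    spec = (sm <= thr[:, None]).mean(axis=1)
    return float(sens.mean()), float(spec.mean())


def screen_report(
    summary: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    n: int = 30,
    reps: int = 2000,
    seed: int | None = None,
    ratios_purified: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulated screen report over candidate pairs by both indexes.

    ``summary`` maps candidate -> {"activity_concentration": [mean, sd],
    "specific_activity": [mean, sd]}; defaults to the built-in fixture.
    Mean-index ratios come directly from the summary means; AUCs are
    replicate-averaged empirical AUCs on gaussian panels of ``n`` clones.
    Returns (aggregate, per-replicate) frames; each pair draws from its own
    child stream of ``seed`` so adding pairs never perturbs earlier ones.
    """
    fixture = load_table1()
    if summary is None:
        summary = fixture["candidates"]
    if ratios_purified is None:
        ratios_purified = {name: meta["ratio_purified"]
                           for name, meta in fixture.get("pairs", {}).items()}
    if pairs is None:
        pairs = DEFAULT_PAIRS
    for hi, lo in pairs:
        for name in (hi, lo):
            if name not in summary:
                raise DomainError(f"unknown candidate label {name!r}")

    streams = np.random.SeedSequence(seed).spawn(len(pairs))
    agg_rows, rep_rows = [], []
    for (hi, lo), ss in zip(pairs, streams):
        rng = np.random.default_rng(ss)
        label = f"{hi}-{lo}"
        row = {"pair": label, "ratio_purified": ratios_purified.get(label, float("nan"))}
        for index, tag in (("activity_concentration", "ac"), ("specific_activity", "sa")):
            mu_hi, sd_hi = (float(x) for x in summary[hi][index])
            mu_lo, sd_lo = (float(x) for x in summary[lo][index])
            pos = rng.normal(mu_hi, sd_hi, size=(reps, n))
            neg = rng.normal(mu_lo, sd_lo, size=(reps, n))
            aucs = _auc_batch(pos, neg)
            row[f"ratio_{tag}"] = mu_hi / mu_lo
            row[f"auc_{tag}"] = float(aucs.mean())
            for i, a in enumerate(aucs):
                rep_rows.append({"pair": label, "replicate": i + 1,
                                 "index": index, "auc": float(a)})
        agg_rows.append(row)
    aggregate = pd.DataFrame(
        agg_rows, columns=["pair", "ratio_purified", "ratio_ac", "auc_ac", "ratio_sa", "auc_sa"]
    )
    per_replicate = pd.DataFrame(rep_rows)
    return aggregate, per_replicate


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston algorithm via scipy)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise InsufficientDataError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("Shapiro-Wilk undefined for constant input")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def variance_homogeneity_test(a, b) -> tuple[float, float]:
    """Classical two-sided F ratio test on sample variances."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise UndefinedStatisticError("both groups have zero variance")
    if vy == 0:
        return float("inf"), 0.0
    f = float(vx / vy)
    dist = stats.f(x.size - 1, y.size - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return f, float(min(p, 1.0))


def mean_difference_test(a, b) -> tuple[float, float]:
    """Two-sample Student t-test (equal-variance form)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise UndefinedStatisticError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise InsufficientDataError("need paired samples with n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("Pearson r undefined for constant input")
    return float(stats.pearsonr(xa, ya).statistic)
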