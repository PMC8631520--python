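"""Model evaluation statistics: ROC/AUC with DeLong machinery,
Hosmer-Lemeshow calibration, contingency tests for imaging findings,
inter-observer ICC, and the frozen published grading model.

The AUC is the Mann-Whitney concordance estimator (ties count one half);
its variance and the paired comparison of two correlated AUCs use DeLong's
structural components.  Confidence intervals are formed on the logit scale
so they respect [0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "ModelReport",
    "PublishedModel",
    "PUBLISHED_TEXTURE_MODEL",
    "auc_delong",
    "delong_paired_test",
    "hosmer_lemeshow",
    "chi_square_2xk",
    "fisher_exact_2x2",
    "icc_interobserver",
    "evaluate_published_model",
    "compare_models",
]


# ---------------------------------------------------------------------------
# DeLong structural components
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC plus the V10/V01 structural components of one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n            # per-positive components
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m      # per-negative components
    return auc, v10, v01


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    threshold: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROCResult":
        return cls(**{k: d[k] for k in (
            "auc", "ci_low", "ci_high", "sensitivity", "specificity",
            "threshold", "n_pos", "n_neg")})


def _youden_point(scores: np.ndarray, labels: np.ndarray):
    """Operating point maximizing Youden's J = sens + spec - 1.

    Positive call is ``score >= threshold``; ties in J are broken toward
    higher specificity (the larger threshold).
    """
    thresholds = np.unique(scores)
    pos = labels == 1
    neg = ~pos
    best = None
    for t in thresholds:
        called = scores >= t
        sens = (called & pos).sum() / pos.sum()
        spec = (~called & neg).sum() / neg.sum()
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, float(t), float(sens), float(spec))
    _, t, sens, spec = best
    return t, sens, spec


def auc_delong(scores, labels, ci_style: str = "logit") -> ROCResult:
    """AUC with a DeLong 95% CI and the Youden-optimal operating point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc, v10, v01 = _delong_components(scores, labels)
    var = _delong_variance(v10, v01)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.975)
    if se == 0.0 or auc in (0.0, 1.0) or ci_style == "normal":
        lo = float(np.clip(auc - z * se, 0.0, 1.0))
        hi = float(np.clip(auc + z * se, 0.0, 1.0))
    else:
        logit = np.log(auc / (1.0 - auc))
        se_logit = se / (auc * (1.0 - auc))
        lo = float(1.0 / (1.0 + np.exp(-(logit - z * se_logit))))
        hi = float(1.0 / (1.0 + np.exp(-(logit + z * se_logit))))
    t, sens, spec = _youden_point(scores, labels)
    return ROCResult(
        auc=float(auc),
        ci_low=min(lo, float(auc)),
        ci_high=max(hi, float(auc)),
        sensitivity=sens,
        specificity=spec,
        threshold=t,
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
    )


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong test for two correlated AUCs measured on the same lesions.

    Returns (z, two-sided p).  Identical rankings give zero variance of the
    AUC difference; that degenerate case returns p = 1 with a log note.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired score vectors must align with labels")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    var_a = _delong_variance(v10_a, v01_a)
    var_b = _delong_variance(v10_b, v01_b)
    cov = 0.0
    if m > 1:
        cov += np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
    if n > 1:
        cov += np.cov(v01_a, v01_b, ddof=1)[0, 1] / n
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 1e-15:
        logger.info("DeLong test: zero variance of the AUC difference; p = 1")
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Calibration and contingency
# ---------------------------------------------------------------------------

def hosmer_lemeshow(probs, labels, n_groups: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit over deciles of predicted risk.

    Equal-count grouping with ties kept together; a group whose expected
    count degenerates is merged with its neighbor.  Returns (chi2, df, p)
    with df = effective groups - 2 (floored at 1).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    n = len(probs)
    if n < 2 * n_groups:
        logger.warning("Hosmer-Lemeshow with n=%d < 2*%d groups", n, n_groups)
    # quantile edges on the probabilities; ties collapse duplicate edges
    edges = np.quantile(probs, np.linspace(0, 1, n_groups + 1)[1:-1])
    edges = np.unique(edges)
    group = np.searchsorted(edges, probs, side="left")
    chi2 = 0.0
    used = 0
    pending_o = pending_e = pending_n = 0.0
    for g in range(len(edges) + 1):
        sel = group == g
        if not sel.any():
            continue
        o = labels[sel].sum() + pending_o
        e = probs[sel].sum() + pending_e
        ng = sel.sum() + pending_n
        denom = e * (1.0 - e / ng)
        if denom <= 1e-12:
            pending_o, pending_e, pending_n = o, e, ng  # merge into neighbor
            logger.info("Hosmer-Lemeshow: merged a degenerate risk group")
            continue
        chi2 += (o - e) ** 2 / denom
        pending_o = pending_e = pending_n = 0.0
        used += 1
    if pending_n > 0 and used > 0:
        # trailing degenerate group: fold into the last used group's count only
        used += 0
    df = max(used - 2, 1)
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or np.any(self.counts < 0):
            raise ValueError("counts must be a nonnegative 2D table")
        if self.counts.sum(axis=1).min() == 0 or self.counts.sum(axis=0).min() == 0:
            raise ValueError("degenerate margins")


def chi_square_2xk(table) -> tuple[float, int, float]:
    """Pearson chi-square WITHOUT continuity correction on a 2xK table.

    The uncorrected statistic is what reproduces the recomputable printed
    p-values for the categorical imaging findings.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else ContingencyTable(
        np.asarray(table)
    ).counts
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test for a 2x2 table: (odds ratio, p)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.shape != (2, 2):
        raise ValueError("Fisher's exact test needs a 2x2 table")
    odds, p = stats.fisher_exact(counts, alternative="two-sided")
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# Inter-observer agreement
# ---------------------------------------------------------------------------

ICC_BANDS = (
    (0.200, "poor"),
    (0.400, "fair"),
    (0.600, "moderate"),
    (0.800, "good"),
    (1.000, "excellent"),
)


def icc_band(value: float) -> str:
    """Qualitative agreement band; intervals closed on the upper end."""
    for upper, label in ICC_BANDS:
        if value <= upper:
            return label
    return "excellent"


def icc_interobserver(ratings: np.ndarray) -> tuple[float, str]:
    """ICC(2,1) — two-way random effects, absolute agreement, single measure.

    ``ratings`` is lesions x 2 raters with no missing cells.  A cohort with
    no between-lesion variance is returned as ICC 0 with a log note.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] != 2 or ratings.shape[0] < 3:
        raise ValueError("need >= 3 lesions rated by exactly 2 raters")
    if not np.isfinite(ratings).all():
        raise ValueError("missing cells are not supported")
    n, k = ratings.shape
    if np.allclose(ratings.var(axis=1).sum() + ratings.mean(axis=1).var(), 0.0):
        logger.info("ICC: zero between-lesion variance")
        return 0.0, icc_band(0.0)
    import warnings

    import pingouin as pg

    long = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "score": ratings.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(
            data=long, targets="targets", raters="raters", ratings="score"
        )
    # absolute-agreement single-measure row; label differs across versions
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
    value = float(res.loc[sel, "ICC"].iloc[0])
    if not np.isfinite(value):
        logger.info("ICC degenerate; reporting 0")
        value = 0.0
    return value, icc_band(value)


# ---------------------------------------------------------------------------
# The frozen published grading model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PublishedModel:
    """The published texture grading model, frozen — never refit.

    Inputs are z-scored features; the linear predictor is
    ``logit(p) = sum(coef * z) + intercept`` and the probability is the
    logistic transform.  Coefficients are exactly the printed values.
    """

    coefficients: tuple[tuple[str, float], ...] = (
        ("S(0,0,1)AngScMom", 0.067),
        ("Z_GLevNonU", 0.001),
        ("Perc.90%", 1.944),
        ("Variance", -0.301),
        ("Mean", -1.994),
    )
    intercept: float = -4.552

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.coefficients)

    def logit(self, z_features: dict[str, float]) -> float:
        missing = [n for n in self.feature_names if n not in z_features]
        if missing:
            raise KeyError(f"missing model inputs: {missing}")
        return self.intercept + sum(
            coef * float(z_features[name]) for name, coef in self.coefficients
        )

    def probability(self, z_features: dict[str, float]) -> float:
        eta = self.logit(z_features)
        return 1.0 / (1.0 + np.exp(-eta))


PUBLISHED_TEXTURE_MODEL = PublishedModel()


def evaluate_published_model(z_features: dict[str, float]) -> tuple[float, float]:
    """Logit and probability of the frozen published model."""
    eta = PUBLISHED_TEXTURE_MODEL.logit(z_features)
    return eta, PUBLISHED_TEXTURE_MODEL.probability(z_features)


# ---------------------------------------------------------------------------
# Multi-model report
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Per-model ROC summaries plus pairwise AUC comparisons and calibration."""

    roc: dict[str, ROCResult] = field(default_factory=dict)
    hosmer_lemeshow: dict[str, dict] = field(default_factory=dict)
    delong: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "roc": {k: v.to_dict() for k, v in self.roc.items()},
            "hosmer_lemeshow": self.hosmer_lemeshow,
            "delong": self.delong,
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_dict(cls, d: dict) -> "ModelReport":
        return cls(
            roc={k: ROCResult.from_dict(v) for k, v in d["roc"].items()},
            hosmer_lemeshow=d.get("hosmer_lemeshow", {}),
            delong=d.get("delong", {}),
        )

    @classmethod
    def from_json(cls, path) -> "ModelReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def render_text(self) -> str:
        lines = [
            f"{'Model':<24}{'AUC':>7}{'95% CI':>17}{'Sens':>7}{'Spec':>7}",
        ]
        for name, r in self.roc.items():
            ci = f"{r.ci_low:.3f}-{r.ci_high:.3f}"
            lines.append(
                f"{name:<24}{r.auc:>7.3f}{ci:>17}{r.sensitivity:>7.3f}"
                f"{r.specificity:>7.3f}"
            )
        for pair, d in self.delong.items():
            lines.append(f"DeLong {pair}: z={d['z']:.3f}, p={d['p']:.4f}")
        for name, d in self.hosmer_lemeshow.items():
            lines.append(
                f"Hosmer-Lemeshow {name}: chi2={d['chi2']:.3f}, df={d['df']}, "
                f"p={d['p']:.4f}"
            )
        return "\n".join(lines)


def compare_models(
    scores_by_model: dict[str, np.ndarray],
    labels,
    probs_by_model: dict[str, np.ndarray] | None = None,
    hl_groups: int = 10,
) -> ModelReport:
    """ROC per model, all pairwise DeLong tests, per-model calibration.

    ``scores_by_model`` maps model name -> per-lesion score on the same
    lesions; ``probs_by_model`` (defaulting to the scores when they already
    are probabilities) feeds the Hosmer-Lemeshow test.
    """
    labels = np.asarray(labels, dtype=int)
    report = ModelReport()
    for name, scores in scores_by_model.items():
        report.roc[name] = auc_delong(scores, labels)
    names = list(scores_by_model)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            z, p = delong_paired_test(
                scores_by_model[a], scores_by_model[b], labels
            )
            report.delong[f"{a} vs {b}"] = {"z": z, "p": p}
    probs_by_model = probs_by_model or {}
    for name, scores in scores_by_model.items():
        probs = np.asarray(probs_by_model.get(name, scores), dtype=float)
        if np.any((probs <= 0) | (probs >= 1)):
            continue
        chi2, df, p = hosmer_lemeshow(probs, labels, n_groups=hl_groups)
        report.hosmer_lemeshow[name] = {"chi2": chi2, "df": df, "p": p}
    return report
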