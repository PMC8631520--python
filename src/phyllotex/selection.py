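"""Four-stage feature-reduction cascade and multivariate model building.

Stages, in order:

1. variance threshold on the raw (unstandardized) features — columns with
   sample variance strictly below the threshold (default 0.8) are removed;
2. column standardization (z-scoring) of the survivors;
3. univariate screen: per feature, Kolmogorov-Smirnov normality (per group,
   against a normal with estimated parameters) and Levene homogeneity gate
   the choice between a pooled-variance t-test and a Mann-Whitney U test;
   keep p < 0.05;
4. univariate logistic screen (Wald p < 0.05), then multivariate logistic
   regression with backward stepwise elimination by likelihood-ratio
   removal p (default retention at p <= 0.10).

The variance threshold deliberately runs BEFORE standardization: z-scored
columns all have variance ~1, which would make a 0.8 threshold vacuous.

Every removal is recorded in a SelectionTrace with its reason, and the kept
sets are nested across stages.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CascadeConfig",
    "SelectionTrace",
    "StageRecord",
    "LogisticModel",
    "standardize",
    "variance_filter",
    "univariate_screen",
    "univariate_logistic_screen",
    "multivariate_backward",
    "run_cascade",
]


@dataclass
class CascadeConfig:
    variance_threshold: float = 0.8
    alpha_univariate: float = 0.05
    alpha_logistic: float = 0.05
    p_remove: float = 0.10
    normality_alpha: float = 0.05
    #: cap on candidates entering backward elimination in small cohorts
    max_multivariate_candidates: int = 10
    variance_on_raw: bool = True


@dataclass
class StageRecord:
    stage: str
    kept: list[str]
    details: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"stage": self.stage, "kept": self.kept, "details": self.details}


@dataclass
class SelectionTrace:
    stages: list[StageRecord] = field(default_factory=list)

    def add(self, record: StageRecord) -> None:
        if self.stages and not set(record.kept) <= set(self.stages[-1].kept):
            raise ValueError("kept sets must be nested across stages")
        self.stages.append(record)

    def kept_at(self, stage: str) -> list[str]:
        for rec in self.stages:
            if rec.stage == stage:
                return rec.kept
        raise KeyError(stage)

    def to_json(self, path=None) -> str:
        payload = json.dumps([r.to_dict() for r in self.stages], indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass
class LogisticModel:
    """A fitted (or frozen) logistic model on optionally standardized inputs."""

    intercept: float
    coefficients: dict[str, float]
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    n: int = 0
    converged: bool = True

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.coefficients if f not in table.columns]
        if missing:
            raise KeyError(f"missing model inputs: {missing}")
        eta = np.full(len(table), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            x = table[name].to_numpy(dtype=float)
            if name in self.standardization:
                mean, sd = self.standardization[name]
                if sd > 0:
                    x = (x - mean) / sd
            eta += coef * x
        return eta

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(table))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "n": self.n,
            "converged": self.converged,
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            standardization={
                k: (float(v[0]), float(v[1]))
                for k, v in d.get("standardization", {}).items()
            },
            n=int(d.get("n", 0)),
            converged=bool(d.get("converged", True)),
        )

    @classmethod
    def from_json(cls, path) -> "LogisticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def standardize(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score each column with sample sd; constant columns left unscaled.

    Returns the standardized table and the per-column (mean, sd) record, with
    sd = 0 marking a column that was flagged and left unchanged.
    """
    if len(table) < 2:
        raise ValueError("standardization needs >= 2 rows")
    out = table.copy()
    params: dict[str, tuple[float, float]] = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        mean = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            logger.warning("zero-variance column %r left unstandardized", col)
            params[col] = (mean, 0.0)
        else:
            out[col] = (x - mean) / sd
            params[col] = (mean, sd)
    return out, params


def variance_filter(
    table: pd.DataFrame, threshold: float = 0.8
) -> tuple[pd.DataFrame, StageRecord]:
    """Drop columns with sample variance strictly below ``threshold``."""
    variances = table.var(ddof=1)
    kept = [c for c in table.columns if variances[c] >= threshold]
    details = {
        c: {
            "variance": float(variances[c]),
            "kept": c in kept,
            "reason": None if c in kept else f"variance {variances[c]:.4g} < {threshold}",
        }
        for c in table.columns
    }
    record = StageRecord(stage="variance", kept=kept, details=details)
    if not kept:
        logger.warning("variance filter removed every feature")
    return table[kept], record


def _route_and_test(
    g0: np.ndarray, g1: np.ndarray, normality_alpha: float
) -> tuple[str, float, float]:
    """Choose t-test vs Mann-Whitney per the normality/homogeneity gate."""

    def group_normal(g: np.ndarray) -> bool:
        sd = g.std(ddof=1)
        if sd == 0 or len(g) < 3:
            return False
        p = stats.kstest(g, "norm", args=(g.mean(), sd)).pvalue
        return p > normality_alpha

    normal = group_normal(g0) and group_normal(g1)
    homogeneous = False
    if normal:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lev_p = stats.levene(g0, g1).pvalue
        homogeneous = lev_p > normality_alpha
    if normal and homogeneous:
        res = stats.ttest_ind(g0, g1, equal_var=True)
        return "t-test", float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(g0, g1, alternative="two-sided")
    return "mann-whitney", float(res.statistic), float(res.pvalue)


def univariate_screen(
    table: pd.DataFrame,
    labels: Sequence[int],
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> tuple[list[str], StageRecord]:
    """Per-feature two-group comparison; keep features with p < alpha.

    Features whose values are all tied (no between- or within-group spread)
    cannot be tested and are dropped with a recorded reason.
    """
    y = np.asarray(labels, dtype=int)
    if (y == 0).sum() < 3 or (y == 1).sum() < 3:
        raise ValueError("both classes need >= 3 lesions")
    kept: list[str] = []
    details: dict[str, dict] = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        g0 = x[ok & (y == 0)]
        g1 = x[ok & (y == 1)]
        if len(g0) < 3 or len(g1) < 3:
            details[col] = {"kept": False, "reason": "too many missing values"}
            continue
        if np.all(x[ok] == x[ok][0]):
            details[col] = {
                "kept": False,
                "test": "none",
                "statistic": 0.0,
                "p": 1.0,
                "reason": "all values tied",
            }
            continue
        test, stat, p = _route_and_test(g0, g1, normality_alpha)
        keep = p < alpha
        details[col] = {
            "kept": keep,
            "test": test,
            "statistic": stat,
            "p": p,
            "reason": None if keep else f"p={p:.4g} >= {alpha}",
        }
        if keep:
            kept.append(col)
    return kept, StageRecord(stage="univariate", kept=kept, details=details)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Logit fit with a quiet Newton/BFGS fallback; None on failure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.Logit(y, X)
            res = model.fit(disp=0, maxiter=100)
            if not res.mle_retvals.get("converged", False):
                res = model.fit(disp=0, method="bfgs", maxiter=500)
            return res
        except Exception:
            try:
                return sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500)
            except Exception:
                return None


def _is_separated(res, y: np.ndarray) -> bool:
    fitted = np.asarray(res.predict())
    return bool(np.all(np.abs(fitted - y) < 1e-6)) or bool(
        np.any(np.abs(np.asarray(res.params)) > 50)
    )


def univariate_logistic_screen(
    table: pd.DataFrame, labels: Sequence[int], alpha: float = 0.05
) -> tuple[list[str], StageRecord]:
    """One-predictor logistic fit per feature; keep Wald p < alpha.

    Perfectly separating features are flagged and retained (separation is
    informative in tiny cohorts); non-convergent fits are excluded.
    """
    y = np.asarray(labels, dtype=float)
    kept: list[str] = []
    details: dict[str, dict] = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < len(x):
            details[col] = {"kept": False, "reason": "missing values"}
            continue
        if max(x[y == 0].min(), x[y == 1].min()) > min(x[y == 0].max(), x[y == 1].max()):
            # the classes do not overlap on this feature: perfect separation
            sign = 1.0 if x[y == 1].min() > x[y == 0].max() else -1.0
            details[col] = {
                "kept": True, "separated": True, "coef": None,
                "coef_sign": sign, "p": None, "reason": None,
            }
            kept.append(col)
            continue
        X = sm.add_constant(x, has_constant="add")
        res = _fit_logit(y, X)
        if res is None:
            details[col] = {"kept": False, "reason": "fit failed"}
            logger.warning("univariate logistic fit failed for %r", col)
            continue
        if _is_separated(res, y):
            details[col] = {
                "kept": True,
                "separated": True,
                "coef": float(res.params[1]),
                "p": None,
                "reason": None,
            }
            kept.append(col)
            continue
        p = float(res.pvalues[1])
        keep = p < alpha
        details[col] = {
            "kept": keep,
            "separated": False,
            "coef": float(res.params[1]),
            "p": p,
            "reason": None if keep else f"Wald p={p:.4g} >= {alpha}",
        }
        if keep:
            kept.append(col)
    return kept, StageRecord(stage="univariate_logistic", kept=kept, details=details)


def multivariate_backward(
    table: pd.DataFrame,
    labels: Sequence[int],
    p_remove: float = 0.10,
    max_candidates: int | None = None,
    rank_by: dict[str, float] | None = None,
) -> tuple[LogisticModel, StageRecord]:
    """Backward stepwise logistic regression by likelihood-ratio removal p.

    Starts from the full model and repeatedly removes the feature with the
    largest likelihood-ratio p above ``p_remove`` until every survivor meets
    the retention criterion.  When ``max_candidates`` is given and exceeded,
    candidates are pre-ranked (by ``rank_by`` p-values when supplied,
    otherwise univariate-logistic p) and only the best enter — small cohorts
    cannot support a saturated full model.
    """
    y = np.asarray(labels, dtype=float)
    candidates = list(table.columns)
    steps: list[dict] = []
    if max_candidates is not None and len(candidates) > max_candidates:
        if rank_by is None:
            rank_by = {}
            for col in candidates:
                X = sm.add_constant(table[col].to_numpy(dtype=float), has_constant="add")
                res = _fit_logit(y, X)
                rank_by[col] = float(res.pvalues[1]) if res is not None else 1.0
        ranked = sorted(candidates, key=lambda c: (rank_by.get(c, 1.0), c))
        dropped = ranked[max_candidates:]
        candidates = [c for c in table.columns if c in set(ranked[:max_candidates])]
        steps.append(
            {
                "action": "cap",
                "dropped": dropped,
                "reason": f"candidate cap {max_candidates} for n={len(y)}",
            }
        )
    if len(y) <= len(candidates) + 1:
        logger.warning(
            "backward selection with n=%d and %d candidates: unstable fits likely",
            len(y),
            len(candidates),
        )

    def fit_set(cols: list[str]):
        if not cols:
            X = np.ones((len(y), 1))
        else:
            X = sm.add_constant(table[cols].to_numpy(dtype=float), has_constant="add")
        return _fit_logit(y, X)

    current = list(candidates)
    while current:
        full = fit_set(current)
        if full is None:
            # drop the candidate whose removal is least harmful by refit
            removed = current[-1]
            current.remove(removed)
            steps.append({"action": "remove", "feature": removed, "reason": "fit failed"})
            continue
        removal_p: dict[str, float] = {}
        for col in current:
            reduced = fit_set([c for c in current if c != col])
            if reduced is None:
                removal_p[col] = 0.0  # cannot assess: keep
                continue
            lr = 2.0 * (full.llf - reduced.llf)
            removal_p[col] = float(stats.chi2.sf(max(lr, 0.0), df=1))
        worst = max(removal_p, key=lambda c: (removal_p[c], c))
        if removal_p[worst] > p_remove:
            current.remove(worst)
            steps.append(
                {
                    "action": "remove",
                    "feature": worst,
                    "removal_p": removal_p[worst],
                    "reason": f"LR p={removal_p[worst]:.4g} > {p_remove}",
                }
            )
        else:
            break

    if not current:
        logger.warning("backward selection removed every feature; intercept-only model")
        p1 = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        model = LogisticModel(
            intercept=float(np.log(p1 / (1 - p1))),
            coefficients={},
            n=len(y),
            converged=True,
        )
        record = StageRecord(
            stage="multivariate",
            kept=[],
            details={"steps": {"list": steps}, "final": {"features": []}},
        )
        return model, record

    final = fit_set(current)
    converged = final is not None and final.mle_retvals.get("converged", True)
    if final is None:
        raise RuntimeError("final multivariate fit failed")
    params = np.asarray(final.params)
    model = LogisticModel(
        intercept=float(params[0]),
        coefficients={c: float(params[i + 1]) for i, c in enumerate(current)},
        n=len(y),
        converged=bool(converged),
    )
    record = StageRecord(
        stage="multivariate",
        kept=current,
        details={
            "steps": {"list": steps},
            "final": {
                "features": current,
                "coefficients": model.coefficients,
                "intercept": model.intercept,
            },
        },
    )
    return model, record


def run_cascade(
    table: pd.DataFrame,
    labels: Sequence[int],
    config: CascadeConfig | None = None,
) -> tuple[LogisticModel, SelectionTrace]:
    """Full cascade: variance -> standardize -> univariate -> univariate
    logistic -> backward stepwise multivariate.

    The returned model's coefficients are on the standardized feature scale;
    the standardization record is stored on the model so predictions can be
    made from raw feature tables.
    """
    config = config or CascadeConfig()
    trace = SelectionTrace()
    y = np.asarray(labels, dtype=int)

    # columns with undefined values disqualify themselves from the
    # multivariate stage; keep them for univariate stages (listwise drop)
    if config.variance_on_raw:
        filtered, record = variance_filter(table, config.variance_threshold)
        trace.add(record)
        std_table, std_params = standardize(filtered) if len(filtered.columns) else (
            filtered,
            {},
        )
    else:
        std_table, std_params = standardize(table)
        filtered, record = variance_filter(std_table, config.variance_threshold)
        trace.add(record)
        std_table = filtered

    if not len(std_table.columns):
        model = LogisticModel(intercept=0.0, coefficients={}, n=len(y))
        return model, trace

    kept_uni, rec_uni = univariate_screen(
        std_table, y, alpha=config.alpha_univariate,
        normality_alpha=config.normality_alpha,
    )
    trace.add(rec_uni)
    if not kept_uni:
        model = LogisticModel(intercept=0.0, coefficients={}, n=len(y),
                              standardization=std_params)
        return model, trace

    kept_log, rec_log = univariate_logistic_screen(
        std_table[kept_uni], y, alpha=config.alpha_logistic
    )
    trace.add(rec_log)
    if not kept_log:
        model = LogisticModel(intercept=0.0, coefficients={}, n=len(y),
                              standardization=std_params)
        return model, trace

    complete = [c for c in kept_log if np.isfinite(std_table[c]).all()]
    rank_by = {
        c: (rec_log.details[c].get("p") if rec_log.details[c].get("p") is not None else 0.0)
        for c in complete
    }
    model, rec_multi = multivariate_backward(
        std_table[complete],
        y,
        p_remove=config.p_remove,
        max_candidates=config.max_multivariate_candidates,
        rank_by=rank_by,
    )
    trace.add(rec_multi)
    model.standardization = {c: std_params[c] for c in model.coefficients}
    return model, trace
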