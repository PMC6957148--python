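"""Cohort-level statistics: group comparison, model selection, ROC analysis.

This is the inferential stage of the pipeline.  Given a per-subject feature
table with a binary group label (case vs control), it reproduces the classic
radiomics-epidemiology workflow:

1. per-feature two-group comparison (pooled-variance Student t test by
   default; Welch and Mann-Whitney U available);
2. univariate screen at α (default 0.05);
3. multivariable logistic regression on the screened candidates, reduced by
   backward elimination (likelihood-ratio criterion, removal threshold
   0.10 by default, Wald selectable), reporting per-unit odds ratios with
   95% Wald confidence intervals plus per-SD odds ratios;
4. ROC analysis of each retained feature: empirical curve, trapezoidal AUC,
   and the optimal cutoff by the Youden index J = sensitivity +
   specificity − 1 (ties broken toward the cutoff nearest the case-group
   median).

The public surface follows the statsmodels idiom: build a
:class:`TextureCohortModel` from a DataFrame (or CSV), call ``fit()``, and
read estimates, diagnostics and a ``summary()`` off the returned
:class:`TextureCohortResults`.  The module-level functions
(:func:`two_group_test`, :func:`univariate_screen`,
:func:`backward_elimination_logistic`, :func:`roc_analysis`,
:func:`cohort_report`) expose each stage individually.

Undefined quantities (e.g. a t statistic when both groups are constant, an
AUC for a constant feature) are returned as NaN with an explanatory message
rather than raised.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .config import DEFAULT_CONFIG, RunConfig
from .features import FEATURE_NAMES

__all__ = [
    "GroupComparison",
    "LogisticModel",
    "ROCAnalysis",
    "TextureCohortModel",
    "TextureCohortResults",
    "two_group_test",
    "univariate_screen",
    "backward_elimination_logistic",
    "roc_analysis",
    "cohort_report",
]

logger = logging.getLogger("pantex.cohort")

CASE = "case"
CONTROL = "control"


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    statistic: float
    p_value: float
    test_used: str        # "t" or "mann_whitney"
    message: str = ""

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "mean_case": self.mean_case,
            "sd_case": self.sd_case,
            "mean_control": self.mean_control,
            "sd_control": self.sd_control,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "test_used": self.test_used,
        }


@dataclass(frozen=True)
class LogisticTerm:
    feature: str
    coefficient: float          # per-unit log-odds slope
    odds_ratio: float           # exp(coefficient * scale)
    ci_low: float
    ci_high: float
    p_value: float              # Wald p
    scale: float = 1.0          # reporting multiplier (e.g. 1e3 for mm² features)
    odds_ratio_per_sd: float = float("nan")
    separation_flag: bool = False

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "coefficient": self.coefficient,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "scale": self.scale,
            "odds_ratio_per_sd": self.odds_ratio_per_sd,
            "separation_flag": self.separation_flag,
        }


@dataclass(frozen=True)
class LogisticModel:
    terms: tuple[LogisticTerm, ...]
    eliminated: tuple[tuple[str, float], ...]  # (feature, LR/Wald p at removal)
    converged: bool
    separation_flag: bool
    n_obs: int
    log_likelihood: float

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(t.feature for t in self.terms)

    def as_dict(self) -> dict:
        return {
            "terms": [t.as_dict() for t in self.terms],
            "eliminated": [list(e) for e in self.eliminated],
            "converged": self.converged,
            "separation_flag": self.separation_flag,
            "n_obs": self.n_obs,
            "log_likelihood": self.log_likelihood,
        }


@dataclass(frozen=True)
class ROCAnalysis:
    feature: str
    auc: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    direction: str              # "higher" if cases tend to larger values
    message: str = ""
    curve: pd.DataFrame = field(default=None, repr=False, compare=False)

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "auc": self.auc,
            "optimal_cutoff": self.optimal_cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "direction": self.direction,
        }


# ---------------------------------------------------------------------------
# validation helpers


def _split_groups(table: pd.DataFrame, feature: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Case and control values for one feature, complete cases only."""
    if "group" not in table.columns:
        raise ValueError("table is missing the 'group' column")
    if feature not in table.columns:
        raise ValueError(f"table is missing feature column {feature!r}")
    groups = set(table["group"].unique())
    if not groups <= {CASE, CONTROL}:
        raise ValueError(
            f"group labels must be {{'{CASE}', '{CONTROL}'}}, got {sorted(groups)}"
        )
    col = pd.to_numeric(table[feature], errors="coerce")
    keep = col.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with missing values", feature, n_dropped)
    x = col[keep & (table["group"] == CASE)].to_numpy(dtype=float)
    y = col[keep & (table["group"] == CONTROL)].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(
            f"need >= 2 subjects per group for {feature!r}; got {len(x)} case, {len(y)} control"
        )
    return x, y, n_dropped


# ---------------------------------------------------------------------------
# two-group tests


def two_group_test(
    table: pd.DataFrame,
    feature: str,
    method: str = "t",
    variant: str = "student",
) -> GroupComparison:
    """Two-sided two-group comparison of one feature.

    ``method="t"`` runs the independent-sample t test (pooled-variance
    Student by default, Welch with ``variant="welch"``); ``"mann_whitney"``
    runs the Mann-Whitney U test, with exact enumeration of the null when
    n1 + n2 ≤ 12 and there are no ties, else the normal approximation with
    tie correction.
    """
    x, y, _ = _split_groups(table, feature)
    msg = ""
    if method == "t":
        if np.var(x) == 0 and np.var(y) == 0:
            stat, p = float("nan"), float("nan")
            msg = "t test undefined: zero variance in both groups"
        else:
            res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
            stat, p = float(res.statistic), float(res.pvalue)
        used = "t"
    elif method == "mann_whitney":
        n_total = len(x) + len(y)
        has_ties = len(np.unique(np.concatenate([x, y]))) < n_total
        how = "exact" if (n_total <= 12 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=how)
        stat, p = float(res.statistic), float(res.pvalue)
        used = "mann_whitney"
    else:
        raise ValueError(f"unknown method {method!r}; expected 't' or 'mann_whitney'")
    return GroupComparison(
        feature=feature,
        mean_case=float(x.mean()),
        sd_case=float(x.std(ddof=1)),
        mean_control=float(y.mean()),
        sd_control=float(y.std(ddof=1)),
        statistic=stat,
        p_value=p,
        test_used=used,
        message=msg,
    )


def univariate_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    features: tuple[str, ...] = FEATURE_NAMES,
    method: str = "t",
    variant: str = "student",
) -> list[str]:
    """Features whose two-group p is below ``alpha``, in column order."""
    selected = []
    for feat in features:
        cmp_ = two_group_test(table, feat, method=method, variant=variant)
        if np.isfinite(cmp_.p_value) and cmp_.p_value < alpha:
            selected.append(feat)
    return selected


# ---------------------------------------------------------------------------
# logistic regression with backward elimination


_SEPARATION_COEF = 15.0  # |per-SD log-odds| beyond this flags near-separation


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Newton/IRLS fit with a BFGS fallback; returns (results, converged)."""
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-8)
            return res, bool(res.mle_retvals.get("converged", False))
        except Exception:
            pass
        try:
            res = model.fit(disp=0, method="bfgs", maxiter=200)
            return res, bool(res.mle_retvals.get("converged", False))
        except Exception:
            return None, False


def backward_elimination_logistic(
    table: pd.DataFrame,
    candidates: list[str],
    p_remove: float = 0.10,
    criterion: str = "lr",
    reporting_multipliers: dict[str, float] | None = None,
) -> LogisticModel:
    """Backward-elimination multivariable logistic regression.

    Fits case-vs-control on all candidate features by maximum likelihood,
    then iteratively removes the feature with the largest removal p ≥
    ``p_remove`` (likelihood-ratio test by default; ``criterion="wald"``
    uses Wald p) until every remaining feature is below the threshold.

    Predictors are standardized internally for numerical stability; reported
    coefficients, odds ratios and confidence intervals are translated back
    to the per-unit scale.  Near-separation (a per-SD |log-odds| above 15 or
    a failed fit) is flagged, and flagged features are retained rather than
    silently dropped — infinite odds ratios are informative, not noise.

    Raises
    ------
    ValueError
        If no candidate is given or group labels are invalid.
    """
    if not candidates:
        raise ValueError("need at least one candidate feature")
    reporting_multipliers = reporting_multipliers or {}

    cols = ["group", *candidates]
    data = table[cols].copy()
    for c in candidates:
        data[c] = pd.to_numeric(data[c], errors="coerce")
    n_before = len(data)
    data = data.dropna()
    if (dropped := n_before - len(data)):
        logger.warning("logistic model: dropped %d incomplete rows", dropped)
    y = (data["group"] == CASE).to_numpy(dtype=float)
    n_obs = len(data)
    if n_obs <= 10 * len(candidates):
        logger.warning(
            "only %d observations for %d candidates; estimates may be unstable",
            n_obs, len(candidates),
        )

    mu = {c: float(data[c].mean()) for c in candidates}
    sigma = {c: float(data[c].std(ddof=1)) for c in candidates}
    for c in candidates:
        if not np.isfinite(sigma[c]) or sigma[c] == 0:
            raise ValueError(f"candidate feature {c!r} is constant; cannot enter the model")
    Z = {c: (data[c].to_numpy(dtype=float) - mu[c]) / sigma[c] for c in candidates}

    def design(feats: list[str]) -> np.ndarray:
        X = np.column_stack([Z[c] for c in feats]) if feats else np.empty((n_obs, 0))
        return np.column_stack([np.ones(n_obs), X])

    current = list(candidates)
    eliminated: list[tuple[str, float]] = []
    separation = False
    res, converged = None, False

    while current:
        res, converged = _fit_logit(y, design(current))
        if res is None:
            separation = True
            break
        if np.any(np.abs(res.params[1:]) > _SEPARATION_COEF):
            separation = True
        # removal p for each feature in the current model
        removal_p = {}
        for k, feat in enumerate(current):
            if criterion == "lr":
                reduced = [f for f in current if f != feat]
                res_red, _ = _fit_logit(y, design(reduced))
                if res_red is None:
                    removal_p[feat] = 0.0
                else:
                    lr = 2.0 * (res.llf - res_red.llf)
                    removal_p[feat] = float(sps.chi2.sf(max(lr, 0.0), df=1))
            elif criterion == "wald":
                removal_p[feat] = float(res.pvalues[k + 1])
            else:
                raise ValueError(f"unknown criterion {criterion!r}; expected 'lr' or 'wald'")
        worst = max(current, key=lambda f: removal_p[f])
        if removal_p[worst] >= p_remove:
            logger.info("eliminating %s (removal p = %.4g)", worst, removal_p[worst])
            eliminated.append((worst, removal_p[worst]))
            current.remove(worst)
        else:
            break

    terms: list[LogisticTerm] = []
    llf = float("nan")
    if current and res is not None:
        llf = float(res.llf)
        ci = res.conf_int(alpha=0.05)
        for k, feat in enumerate(current):
            beta_sd = float(res.params[k + 1])
            lo_sd, hi_sd = float(ci[k + 1, 0]), float(ci[k + 1, 1])
            beta = beta_sd / sigma[feat]          # back to per-unit scale
            lo, hi = lo_sd / sigma[feat], hi_sd / sigma[feat]
            scale = float(reporting_multipliers.get(feat, 1.0))
            flagged = abs(beta_sd) > _SEPARATION_COEF
            with np.errstate(over="ignore"):
                terms.append(
                    LogisticTerm(
                        feature=feat,
                        coefficient=beta,
                        odds_ratio=float(np.exp(beta * scale)),
                        ci_low=float(np.exp(lo * scale)),
                        ci_high=float(np.exp(hi * scale)),
                        p_value=float(res.pvalues[k + 1]),
                        scale=scale,
                        odds_ratio_per_sd=float(np.exp(beta_sd)),
                        separation_flag=flagged,
                    )
                )
    return LogisticModel(
        terms=tuple(terms),
        eliminated=tuple(eliminated),
        converged=converged,
        separation_flag=separation,
        n_obs=n_obs,
        log_likelihood=llf,
    )


# ---------------------------------------------------------------------------
# ROC analysis


def roc_analysis(table: pd.DataFrame, feature: str) -> ROCAnalysis:
    """Empirical ROC curve, trapezoidal AUC and Youden-optimal cutoff.

    The direction is auto-detected so the reported AUC is ≥ 0.5: if cases
    tend to lower values, the curve is built on the negated feature and
    ``direction`` is ``"lower"``.  The AUC equals the Mann-Whitney estimate
    U/(n1·n2) (midranks under ties).  Among cutoffs with maximal Youden J,
    the one closest to the case-group median is reported.
    """
    x, y, _ = _split_groups(table, feature)  # x = cases, y = controls
    if np.ptp(np.concatenate([x, y])) == 0:
        return ROCAnalysis(
            feature=feature, auc=float("nan"), optimal_cutoff=float("nan"),
            sensitivity=float("nan"), specificity=float("nan"),
            direction="higher", message="constant feature: ROC undefined",
        )
    def _empirical_curve(xs: np.ndarray, ys: np.ndarray):
        """Sens/spec over all observed thresholds (rule: case iff value >= t)."""
        thresholds = np.unique(np.concatenate([xs, ys]))
        sens = np.array([(xs >= t).mean() for t in thresholds])
        spec = np.array([(ys < t).mean() for t in thresholds])
        return thresholds, sens, spec

    def _trapezoid_auc(sens: np.ndarray, spec: np.ndarray) -> float:
        # close the curve at (0,0) and (1,1) in (FPR, TPR) space
        fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
        tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
        return float(np.trapezoid(tpr, fpr))

    thresholds, sens, spec = _empirical_curve(x, y)
    auc_higher = _trapezoid_auc(sens, spec)
    if auc_higher >= 0.5:
        direction, xs, ys = "higher", x, y
        auc = auc_higher
    else:
        direction, xs, ys = "lower", -x, -y
        thresholds, sens, spec = _empirical_curve(xs, ys)
        auc = _trapezoid_auc(sens, spec)
    j = sens + spec - 1.0
    best = np.flatnonzero(np.isclose(j, j.max(), rtol=0, atol=1e-12))
    case_median = float(np.median(xs))
    pick = best[np.argmin(np.abs(thresholds[best] - case_median))]
    cutoff = float(thresholds[pick])
    curve = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )
    if direction == "lower":
        curve = curve.assign(threshold=-curve["threshold"]).iloc[::-1].reset_index(drop=True)
    return ROCAnalysis(
        feature=feature,
        auc=auc,
        optimal_cutoff=cutoff if direction == "higher" else -cutoff,
        sensitivity=float(sens[pick]),
        specificity=float(spec[pick]),
        direction=direction,
        curve=curve,
    )


# ---------------------------------------------------------------------------
# statsmodels-style model / results objects


class TextureCohortModel:
    """Case-control analysis of a texture-feature cohort.

    Parameters
    ----------
    table : DataFrame
        One row per subject with columns ``subject_id``, ``group`` (values
        ``"case"`` / ``"control"``) and the feature columns; optional
        covariates (``age``, ``bmi``) are carried through but not modelled
        by default (the study design matches on them instead).
    features : sequence of str, optional
        Feature columns to analyse; defaults to the canonical 17.
    config : RunConfig
        Statistical knobs (α, p_remove, test variant, cutoff criterion).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        features: tuple[str, ...] | None = None,
        config: RunConfig = DEFAULT_CONFIG,
    ) -> None:
        if "group" not in table.columns:
            raise ValueError("table is missing the 'group' column")
        self.table = table.reset_index(drop=True)
        self.features = tuple(features) if features is not None else tuple(
            f for f in FEATURE_NAMES if f in table.columns
        )
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise ValueError(f"table is missing feature columns: {missing}")
        if not self.features:
            raise ValueError("no feature columns found in table")
        self.config = config
        counts = table["group"].value_counts()
        for label in (CASE, CONTROL):
            if counts.get(label, 0) < 2:
                raise ValueError(f"need >= 2 subjects in group {label!r}")

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "TextureCohortModel":
        return cls(table, **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "TextureCohortModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> "TextureCohortResults":
        """Run the full comparison → screen → elimination → ROC pipeline."""
        cfg = self.config
        comparisons = [
            two_group_test(self.table, f, method="t", variant=cfg.t_test_variant)
            for f in self.features
        ]
        screened = univariate_screen(
            self.table, alpha=cfg.alpha, features=self.features,
            variant=cfg.t_test_variant,
        )
        if screened:
            logistic = backward_elimination_logistic(
                self.table, screened, p_remove=cfg.p_remove,
                criterion=cfg.elimination_criterion,
            )
        else:
            logistic = LogisticModel(
                terms=(), eliminated=(), converged=True, separation_flag=False,
                n_obs=len(self.table), log_likelihood=float("nan"),
            )
        roc = [roc_analysis(self.table, t.feature) for t in logistic.terms]
        return TextureCohortResults(
            model=self,
            comparisons=tuple(comparisons),
            screened=tuple(screened),
            logistic=logistic,
            roc=tuple(roc),
        )


class TextureCohortResults:
    """Fit results: comparison table, selected logistic model, ROC block."""

    def __init__(self, model, comparisons, screened, logistic, roc) -> None:
        self.model = model
        self.comparisons = comparisons
        self.screened = screened
        self.logistic = logistic
        self.roc = roc

    # --- tabular views -----------------------------------------------------

    @property
    def comparison_table(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_dict() for c in self.comparisons])

    @property
    def logistic_table(self) -> pd.DataFrame:
        cols = ["feature", "coefficient", "odds_ratio", "ci_low", "ci_high",
                "p_value", "scale", "odds_ratio_per_sd", "separation_flag"]
        return pd.DataFrame([t.as_dict() for t in self.logistic.terms], columns=cols)

    @property
    def roc_table(self) -> pd.DataFrame:
        cols = ["feature", "auc", "optimal_cutoff", "sensitivity",
                "specificity", "direction"]
        return pd.DataFrame([r.as_dict() for r in self.roc], columns=cols)

    # --- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable three-block report."""
        lines = ["Texture cohort analysis", "=" * 60]
        n_case = int((self.model.table["group"] == CASE).sum())
        n_ctrl = int((self.model.table["group"] == CONTROL).sum())
        lines.append(f"subjects: {n_case} case / {n_ctrl} control")
        lines.append("")
        lines.append("Per-feature comparison (mean ± SD, two-sided p):")
        for c in self.comparisons:
            star = " *" if np.isfinite(c.p_value) and c.p_value < self.model.config.alpha else ""
            lines.append(
                f"  {c.feature:<22s} {c.mean_case:>10.4g} ± {c.sd_case:<9.4g}"
                f" vs {c.mean_control:>10.4g} ± {c.sd_control:<9.4g}"
                f"  p={c.p_value:.4g}{star}"
            )
        lines.append("")
        lines.append(f"Univariate screen (alpha={self.model.config.alpha}): "
                     f"{', '.join(self.screened) if self.screened else '(none)'}")
        lines.append("")
        lines.append("Multivariable logistic model (backward elimination):")
        if self.logistic.terms:
            for t in self.logistic.terms:
                flag = "  [near-separation]" if t.separation_flag else ""
                lines.append(
                    f"  {t.feature:<22s} OR={t.odds_ratio:.4g} "
                    f"(95% CI {t.ci_low:.4g}–{t.ci_high:.4g}) p={t.p_value:.4g}{flag}"
                )
        else:
            lines.append("  (no feature retained)")
        for feat, p in self.logistic.eliminated:
            lines.append(f"  eliminated: {feat} (removal p = {p:.4g})")
        lines.append("")
        lines.append("ROC analysis of retained features:")
        if self.roc:
            for r in self.roc:
                lines.append(
                    f"  {r.feature:<22s} AUC={r.auc:.3f} cutoff={r.optimal_cutoff:.4g}"
                    f" sens={r.sensitivity:.1%} spec={r.specificity:.1%}"
                    f" (cases {r.direction})"
                )
        else:
            lines.append("  (none)")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "config": self.model.config.to_dict(),
            "n_case": int((self.model.table["group"] == CASE).sum()),
            "n_control": int((self.model.table["group"] == CONTROL).sum()),
            "comparisons": [c.as_dict() for c in self.comparisons],
            "univariate_significant": list(self.screened),
            "logistic": self.logistic.as_dict(),
            "roc": [r.as_dict() for r in self.roc],
        }

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write report.csv, roc.csv and report.json into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "report_csv": out / "report.csv",
            "roc_csv": out / "roc.csv",
            "report_json": out / "report.json",
        }
        self.comparison_table.to_csv(paths["report_csv"], index=False, float_format="%.10g")
        self.roc_table.to_csv(paths["roc_csv"], index=False, float_format="%.10g")
        paths["report_json"].write_text(json.dumps(self.as_dict(), indent=2, allow_nan=True) + "\n")
        return paths

    def plot_roc(self, ax=None):
        """Plot the ROC curves of retained features (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for r in self.roc:
            if r.curve is None:
                continue
            fpr = 1.0 - r.curve["specificity"].to_numpy()
            tpr = r.curve["sensitivity"].to_numpy()
            order = np.argsort(fpr, kind="stable")
            ax.plot(fpr[order], tpr[order], label=f"{r.feature} (AUC={r.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right", fontsize=8)
        return ax


def cohort_report(
    table: pd.DataFrame,
    config: RunConfig = DEFAULT_CONFIG,
    out_dir: str | Path | None = None,
) -> TextureCohortResults:
    """One-call cohort analysis; writes report files when ``out_dir`` given."""
    results = TextureCohortModel(table, config=config).fit()
    if out_dir is not None:
        results.save(out_dir)
    return results
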