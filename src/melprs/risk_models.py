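"""Decile stratification and logistic-regression odds ratios.

Case-control risk is expressed as odds ratios against a reference stratum
of the score distribution: deciles of the control series for the melanoma
(case vs. control) outcome and deciles of the case series for the multiple-
vs.-single-primary outcome. ORs come from two interchangeable routes — the
closed-form 2x2 cross-product and a logistic fit with stratum indicators —
which agree exactly for saturated layouts. Confidence intervals are Wald
intervals on the log-odds scale throughout.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecileScheme",
    "ContingencyTable2x2",
    "LogisticFit",
    "ORRecord",
    "SeparationError",
    "decile_cutpoints",
    "assign_deciles",
    "or_2x2",
    "wald_ci",
    "fit_logistic",
    "decile_or_table",
    "decile_report",
    "per_sd_or",
    "expand_counts",
]

Z_95 = float(stats.norm.ppf(0.975))  # 1.959964...


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


@dataclass
class DecileScheme:
    """Reference-distribution decile cutpoints plus optional label merging.

    ``merged_groups`` maps decile numbers (1..10) to group labels, e.g.
    {5: "5-6", 6: "5-6"}; unmapped deciles keep their number as label.
    """

    cutpoints: np.ndarray
    merged_groups: dict[int, str] = field(default_factory=dict)
    reference_group: str = "5-6"

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if self.cutpoints.shape != (9,):
            raise ValueError("a decile scheme needs exactly 9 cutpoints")
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError("cutpoints must be strictly ascending")
        labels = {self.merged_groups.get(d, str(d)) for d in range(1, 11)}
        if self.reference_group not in labels:
            raise ValueError(
                f"reference group {self.reference_group!r} not among decile labels"
            )

    def label_of(self, decile: int) -> str:
        return self.merged_groups.get(decile, str(decile))

    @property
    def group_labels(self) -> list[str]:
        """Group labels in decile order, merged labels deduplicated."""
        out: list[str] = []
        for d in range(1, 11):
            lab = self.label_of(d)
            if lab not in out:
                out.append(lab)
        return out


MERGE_5_6 = {5: "5-6", 6: "5-6"}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (exposed-case a, exposed-noncase b, reference-case c, reference-noncase d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit."""

    coefficients: np.ndarray
    covariance: np.ndarray
    converged: bool
    n_iter: int
    names: list[str]
    log_likelihood: float
    fitted_probabilities: np.ndarray

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def wald(self, name: str, level: float = 0.95) -> "ORRecord":
        """Odds ratio, Wald CI and two-sided p for one coefficient."""
        k = self.names.index(name)
        beta = self.coefficients[k]
        se = self.se[k]
        z = stats.norm.ppf(0.5 + level / 2)
        p = 2 * stats.norm.sf(abs(beta / se))
        return ORRecord(
            label=name,
            or_value=float(np.exp(beta)),
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            p_value=float(p),
        )


@dataclass(frozen=True)
class ORRecord:
    """Per-stratum odds ratio with 95% CI and Wald p-value."""

    label: str
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError("CI must bracket the OR")


def decile_cutpoints(reference_scores: np.ndarray) -> np.ndarray:
    """10%..90% empirical quantiles of the reference distribution.

    Linear interpolation between order statistics (the type-7 convention).
    """
    ref = np.asarray(reference_scores, dtype=float)
    if ref.size < 10:
        raise ValueError("need at least 10 reference scores for deciles")
    cuts = np.quantile(ref, np.arange(1, 10) / 10)
    if np.any(np.diff(cuts) <= 0):
        warnings.warn("degenerate reference distribution: tied decile cutpoints")
    return cuts


def assign_deciles(scores: np.ndarray, scheme: DecileScheme) -> np.ndarray:
    """Group label per individual under left-open/right-closed decile bins.

    Decile d covers (cutpoint_{d-1}, cutpoint_d]; a score exactly at a
    cutpoint falls in the lower decile. Merged-group labels are applied
    after decile assignment.
    """
    scores = np.asarray(scores, dtype=float)
    deciles = np.searchsorted(scheme.cutpoints, scores, side="left") + 1
    return np.array([scheme.label_of(int(d)) for d in deciles], dtype=object)


def or_2x2(table: ContingencyTable2x2, haldane: bool = False) -> float:
    """Cross-product odds ratio (a*d)/(b*c).

    Zero ``b`` or ``c`` is an error unless ``haldane=True``, which applies
    the 0.5 continuity correction to all four cells (exploratory use only).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        raise ValueError("OR undefined: zero cell in denominator (b*c = 0)")
    return (a * d) / (b * c)


def wald_ci(
    table: ContingencyTable2x2, level: float = 0.95, haldane: bool = False
) -> tuple[float, float]:
    """Wald confidence interval for the 2x2 odds ratio on the log scale."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        raise ValueError("Wald CI undefined with a zero cell")
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def fit_logistic(design: np.ndarray | pd.DataFrame, outcome: np.ndarray) -> LogisticFit:
    """ML logistic regression (Newton/IRLS) of a binary outcome on ``design``.

    ``design`` must already contain the intercept column. Raises
    :class:`SeparationError` on (quasi-)complete separation and ValueError
    on a singular design or a constant non-intercept column.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if isinstance(design, pd.DataFrame):
        names = [str(c) for c in design.columns]
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes, coded 0/1")

    n_const = 0
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            n_const += 1
    if n_const > 1:
        raise ValueError("more than one constant column in the design")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", maxiter=50, tol=1e-8, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        if isinstance(exc, np.linalg.LinAlgError):
            raise ValueError("singular design matrix") from exc
        raise SeparationError(str(exc)) from exc

    coefs = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(coefs)) or np.max(np.abs(coefs)) > 30:
        raise SeparationError("diverging coefficients suggest separation")
    cov = np.asarray(res.cov_params(), dtype=float)
    if not np.all(np.isfinite(cov)):
        raise SeparationError("non-finite coefficient covariance")

    return LogisticFit(
        coefficients=coefs,
        covariance=cov,
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iter=int(res.mle_retvals.get("iterations", 0)),
        names=names,
        log_likelihood=float(res.llf),
        fitted_probabilities=np.asarray(res.predict(X), dtype=float),
    )


def _group_sort_key(label: str) -> tuple[float, str]:
    m = re.match(r"(\d+)", str(label))
    return (float(m.group(1)) if m else np.inf, str(label))


def indicator_design(
    labels: np.ndarray,
    reference: str,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Intercept + one indicator per non-reference group (+ covariates)."""
    labels = np.asarray(labels, dtype=object)
    groups = sorted(set(labels) - {reference}, key=_group_sort_key)
    cols = {"intercept": np.ones(labels.size)}
    for g in groups:
        cols[str(g)] = (labels == g).astype(float)
    X = pd.DataFrame(cols)
    if covariates is not None:
        for c in covariates.columns:
            X[str(c)] = np.asarray(covariates[c], dtype=float)
    return X


def decile_or_table(
    labels: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    reference: str = "5-6",
) -> list[ORRecord]:
    """Per-stratum ORs vs. a reference group from one logistic fit.

    One model with indicator columns for every non-reference group (plus
    any adjustment covariates, e.g. age as continuous and sex as binary);
    each record is exp(coefficient) with its Wald CI and p. Groups that are
    empty after filtering are omitted with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    outcome = np.asarray(outcome, dtype=float)
    if not (labels == reference).any():
        raise ValueError(f"reference group {reference!r} is empty")
    present = set(labels)
    X = indicator_design(labels, reference, covariates)
    fit = fit_logistic(X, outcome)
    records = []
    for g in sorted(present - {reference}, key=_group_sort_key):
        if str(g) not in fit.names:
            warnings.warn(f"group {g!r} empty; omitted from OR table")
            continue
        rec = fit.wald(str(g))
        records.append(rec)
    return records


def per_sd_or(
    std_scores: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> ORRecord:
    """OR per one SD of the standardized score from a logistic fit.

    Crude by default; pass ``covariates`` for an adjusted model.
    """
    std_scores = np.asarray(std_scores, dtype=float)
    cols = {"intercept": np.ones(std_scores.size), "score": std_scores}
    X = pd.DataFrame(cols)
    if covariates is not None:
        for c in covariates.columns:
            X[str(c)] = np.asarray(covariates[c], dtype=float)
    fit = fit_logistic(X, np.asarray(outcome, dtype=float))
    rec = fit.wald("score")
    return ORRecord("per_sd", rec.or_value, rec.ci_low, rec.ci_high, rec.p_value)


def decile_report(
    labels: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    reference: str = "5-6",
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """Stratified OR report table: group, n (%) per class, OR (CI), p.

    One row per group in decile order; crude ORs always, adjusted ORs when
    ``covariates`` is supplied. ORs and CI bounds are rounded to 2 d.p. at
    report time only.
    """
    labels = np.asarray(labels, dtype=object)
    outcome = np.asarray(outcome, dtype=float)
    crude = {r.label: r for r in decile_or_table(labels, outcome, None, reference)}
    adjusted = (
        {r.label: r for r in decile_or_table(labels, outcome, covariates, reference)}
        if covariates is not None
        else None
    )
    if group_order is None:
        group_order = sorted(set(labels), key=_group_sort_key)
    n1_tot = int(outcome.sum())
    n0_tot = int((1 - outcome).sum())

    def fmt(rec: ORRecord | None) -> str:
        if rec is None:
            return "ref."
        return f"{rec.or_value:.2f} ({rec.ci_low:.2f}, {rec.ci_high:.2f})"

    rows = []
    for g in group_order:
        mask = labels == g
        n1 = int(outcome[mask].sum())
        n0 = int((1 - outcome)[mask].sum())
        rec = crude.get(str(g))
        row = {
            "group": str(g),
            "n_outcome": f"{n1} ({100 * n1 / n1_tot:.1f}%)",
            "n_reference": f"{n0} ({100 * n0 / n0_tot:.1f}%)",
            "or_ci": fmt(rec if g != reference else None),
        }
        if adjusted is not None:
            arec = adjusted.get(str(g))
            row["adj_or_ci"] = fmt(arec if g != reference else None)
            row["p_value"] = f"{arec.p_value:.3f}" if g != reference and arec else ""
        else:
            row["p_value"] = f"{rec.p_value:.3f}" if g != reference and rec else ""
        rows.append(row)
    return pd.DataFrame(rows)


def expand_counts(counts: dict[str, tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild individual-level (labels, outcome) from per-group counts.

    ``counts`` maps each group label to (n_outcome_1, n_outcome_0) — e.g.
    (cases, controls) — as printed in a stratified report table.
    """
    labels: list[str] = []
    outcome: list[int] = []
    for g, (n1, n0) in counts.items():
        labels.extend([g] * (n1 + n0))
        outcome.extend([1] * n1 + [0] * n0)
    return np.array(labels, dtype=object), np.array(outcome, dtype=float)
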