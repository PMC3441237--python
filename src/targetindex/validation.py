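"""Statistical validation of index scores against pathological response.

The battery mirrors standard practice for evaluating a continuous
predictor of a binary clinical endpoint: ROC/AUC with a rank-based
significance test, t-test comparison of group means (Welch's correction
when group variances differ), univariate and multivariate logistic
regression with Wald odds-ratio intervals, and one-way ANOVA with Tukey
HSD for comparing several predictors. All tests are two-sided at
alpha = 0.05.

AUC is the Mann-Whitney statistic U/(n1*n0) with ties counted 1/2 — the
probability that a randomly chosen responder (pCR) scores above a randomly
chosen non-responder (RD). Its p-value is the tie-corrected
normal-approximation Mann-Whitney test of AUC = 0.5.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .io import ClinicalTable, RESPONSE_PCR, RESPONSE_RD
from .scoring import IndexScores

logger = logging.getLogger(__name__)

ALPHA = 0.05


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge."""


@dataclass
class OddsRatioRow:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError(f"CI does not bracket OR for term {self.term!r}")


@dataclass
class ValidationReport:
    """Joint result of the ROC, t-test and (optional) logistic analyses."""

    index_name: str
    n_pcr: int
    n_rd: int
    auc: float
    auc_p: float
    mean_rd: float
    mean_pcr: float
    t_stat: float
    t_p: float
    welch_used: bool
    or_table: list[OddsRatioRow] = field(default_factory=list)
    model_auc: float | None = None
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _aligned_groups(scores: IndexScores, labels: ClinicalTable) -> tuple[np.ndarray, np.ndarray]:
    """Split scores into (pCR, RD) arrays over samples with known response."""
    resp = labels.response.reindex(scores.scores.index)
    known = resp.notna()
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("dropping %d samples without response", n_dropped)
    s = scores.scores[known]
    resp = resp[known]
    return s[resp == RESPONSE_PCR].to_numpy(), s[resp == RESPONSE_RD].to_numpy()


def roc_auc(scores: IndexScores, labels: ClinicalTable) -> tuple[float, float]:
    """AUC (higher score -> pCR) and its two-sided Mann-Whitney p-value."""
    pcr, rd = _aligned_groups(scores, labels)
    if len(pcr) == 0 or len(rd) == 0:
        raise ValueError("need at least one sample in each response class")
    res = stats.mannwhitneyu(pcr, rd, alternative="two-sided", method="asymptotic")
    auc = float(res.statistic) / (len(pcr) * len(rd))
    return auc, float(res.pvalue)


def compare_groups(
    scores: IndexScores, labels: ClinicalTable, variance_rule: str = "auto"
) -> tuple[float, float, float, float, bool]:
    """Two-sided t-test of index scores between pCR and RD.

    Returns (mean_RD, mean_pCR, t, p, welch_used). Under ``auto``, Welch's
    correction is applied when a two-sided F-test rejects variance equality
    at 0.05; ``student`` / ``welch`` force the choice.
    """
    if variance_rule not in {"auto", "student", "welch"}:
        raise ValueError(f"unknown variance rule {variance_rule!r}")
    pcr, rd = _aligned_groups(scores, labels)
    if len(pcr) < 2 or len(rd) < 2:
        raise ValueError("need at least two samples per response class")
    if variance_rule == "auto":
        v1, v0 = pcr.var(ddof=1), rd.var(ddof=1)
        if v1 == 0.0 and v0 == 0.0:
            welch = False
        else:
            f = v1 / v0 if v0 > 0 else np.inf
            p_f = 2.0 * min(
                stats.f.cdf(f, len(pcr) - 1, len(rd) - 1),
                stats.f.sf(f, len(pcr) - 1, len(rd) - 1),
            )
            welch = bool(p_f < ALPHA)
        logger.info("variance rule auto -> %s", "welch" if welch else "student")
    else:
        welch = variance_rule == "welch"
    t, p = stats.ttest_ind(pcr, rd, equal_var=not welch)
    return float(rd.mean()), float(pcr.mean()), float(t), float(p), welch


def _encode_covariate(name: str, col: pd.Series) -> pd.Series:
    """Clinical covariate encodings used throughout: age in decades, grade
    ordinal numeric, ER/node as 1 = positive indicators."""
    if name == "age":
        return pd.to_numeric(col, errors="coerce") / 10.0
    if name in {"er_status", "node"}:
        return col.map({"positive": 1.0, "negative": 0.0})
    if name == "grade":
        return pd.to_numeric(col, errors="coerce")
    return pd.to_numeric(col, errors="coerce")


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> sm.Logit:
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except PerfectSeparationError as e:
            raise SeparationError(f"perfect separation in {list(X.columns)}: {e}") from e
        except PerfectSeparationWarning as e:
            raise SeparationError(f"perfect separation in {list(X.columns)}: {e}") from e
    if not fit.mle_retvals.get("converged", True):
        raise ConvergenceError(f"logistic fit did not converge: {fit.mle_retvals}")
    coefs = fit.params.drop("const")
    if np.abs(coefs.to_numpy()).max(initial=0.0) > 30:
        worst = coefs.abs().idxmax()
        raise SeparationError(f"coefficient for {worst!r} diverged; data likely separated")
    return fit


def logistic_fit(
    labels: ClinicalTable,
    predictors: pd.DataFrame,
    multivariate: bool = False,
) -> tuple[list[OddsRatioRow], float | None]:
    """Logistic regression of pCR (=1) on score/covariate columns.

    Clinical covariates are encoded by convention: ``age`` is rescaled to
    decades before fitting, ``grade`` enters as ordinal numeric, ``er_status``
    and ``node`` as 1 = positive indicators; any other column is used as a
    numeric score. Rows with a missing outcome or missing used covariates
    are dropped and logged. Univariate mode fits one single-predictor model
    per column; multivariate mode fits the joint model and also reports the
    AUC of its fitted probabilities.
    """
    resp = labels.response
    X_all = pd.DataFrame(
        {name: _encode_covariate(name, predictors[name].reindex(resp.index))
         for name in predictors.columns},
        index=resp.index,
    )

    def prepare(cols: list[str]) -> tuple[np.ndarray, pd.DataFrame]:
        keep = resp.notna() & X_all[cols].notna().all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("logistic fit (%s): dropping %d incomplete rows", cols, dropped)
        y = (resp[keep] == RESPONSE_PCR).to_numpy(dtype=float)
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("outcome has a single class after dropping incomplete rows")
        return y, X_all.loc[keep, cols]

    rows: list[OddsRatioRow] = []
    model_auc: float | None = None
    if multivariate:
        y, X = prepare(list(X_all.columns))
        fit = _fit_logit(y, X)
        ci = fit.conf_int(alpha=ALPHA)
        for term in X.columns:
            rows.append(OddsRatioRow(
                term=term,
                odds_ratio=float(np.exp(fit.params[term])),
                ci_low=float(np.exp(ci.loc[term, 0])),
                ci_high=float(np.exp(ci.loc[term, 1])),
                p=float(fit.pvalues[term]),
            ))
        fitted = np.asarray(fit.predict())
        res = stats.mannwhitneyu(fitted[y == 1], fitted[y == 0],
                                 alternative="two-sided", method="asymptotic")
        model_auc = float(res.statistic) / int((y == 1).sum() * (y == 0).sum())
    else:
        for term in X_all.columns:
            y, X = prepare([term])
            fit = _fit_logit(y, X)
            ci = fit.conf_int(alpha=ALPHA)
            rows.append(OddsRatioRow(
                term=term,
                odds_ratio=float(np.exp(fit.params[term])),
                ci_low=float(np.exp(ci.loc[term, 0])),
                ci_high=float(np.exp(ci.loc[term, 1])),
                p=float(fit.pvalues[term]),
            ))
    return rows, model_auc


def compare_predictors(
    performances: dict[str, list[float]],
) -> tuple[float, float, list[tuple[str, str, float, float, bool]]]:
    """One-way ANOVA plus Tukey HSD across predictors' performance values.

    ``performances`` maps each predictor to its replicate performance
    values (e.g. per-dataset AUCs); the replicate unit is the caller's
    choice. Returns (F, p, [(group1, group2, mean_diff, p_adj, reject)]).
    """
    if len(performances) < 2:
        raise ValueError("need at least two predictors to compare")
    for name, vals in performances.items():
        if len(vals) < 2:
            raise ValueError(f"predictor {name!r} needs at least two performance values")
    groups = [np.asarray(v, dtype=float) for v in performances.values()]
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0.0:
        # all values identical: no variance anywhere, F is 0 by convention
        names = list(performances)
        pairs = [
            (names[i], names[j], 0.0, 1.0, False)
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        return 0.0, 1.0, pairs
    f_stat, p = stats.f_oneway(*groups)
    values = flat
    labels = np.concatenate([[name] * len(v) for name, v in performances.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
    group_pairs = [
        (i, j)
        for i in range(len(tukey.groupsunique))
        for j in range(i + 1, len(tukey.groupsunique))
    ]
    pairs = [
        (str(tukey.groupsunique[i]), str(tukey.groupsunique[j]), float(d), float(pa), bool(r))
        for (i, j), d, pa, r in zip(group_pairs, tukey.meandiffs, tukey.pvalues, tukey.reject)
    ]
    return float(f_stat), float(p), pairs


def validate_index(
    scores: IndexScores,
    labels: ClinicalTable,
    variance_rule: str = "auto",
    covariates: list[str] | None = None,
    multivariate: bool = False,
) -> ValidationReport:
    """Run the full battery on one index and assemble a report.

    If ``covariates`` is given, those clinical columns are added to the
    logistic model next to the score; otherwise the logistic fit is
    univariate on the score alone.
    """
    pcr, rd = _aligned_groups(scores, labels)
    auc, auc_p = roc_auc(scores, labels)
    mean_rd, mean_pcr, t, t_p, welch = compare_groups(scores, labels, variance_rule)
    predictors = pd.DataFrame({scores.index_name: scores.scores})
    for cov in covariates or []:
        predictors[cov] = labels.data[cov].reindex(scores.scores.index)
    or_table, model_auc = logistic_fit(labels, predictors, multivariate=multivariate)
    return ValidationReport(
        index_name=scores.index_name,
        n_pcr=len(pcr),
        n_rd=len(rd),
        auc=auc,
        auc_p=auc_p,
        mean_rd=mean_rd,
        mean_pcr=mean_pcr,
        t_stat=t,
        t_p=t_p,
        welch_used=welch,
        or_table=or_table,
        model_auc=model_auc,
        provenance={
            "variance_rule": variance_rule,
            "covariates": covariates or [],
            "multivariate": multivariate,
            "n_scored": len(scores.scores),
        },
    )
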