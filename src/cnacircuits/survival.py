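"""Risk-score survival modeling.

Training/testing split balanced on gender and age, univariate Cox screen of
module genes, linear risk score r_i = sum_k beta_k * e_ki on log2(x+1)
expression, dichotomization at the training median (threshold frozen for
test and external cohorts), log-rank comparison, and a covariate-adjusted
multivariate Cox fit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

logger = logging.getLogger("cnacircuits")

__all__ = [
    "split_cohort",
    "cox_screen",
    "risk_scores",
    "dichotomize",
    "logrank",
    "adjusted_cox",
    "RiskModel",
]


class RiskModel:
    """A frozen risk-score model: gene coefficients, the expression
    transform, and the training-median threshold."""

    transform = "log2(x+1)"

    def __init__(self, betas: pd.Series, threshold: float):
        if not len(betas):
            raise ValueError("risk model needs at least one gene")
        self.betas = betas.astype(float)
        self.threshold = float(threshold)

    def to_dict(self) -> dict:
        return {
            "genes": list(self.betas.index),
            "beta": [float(b) for b in self.betas],
            "threshold": self.threshold,
            "transform": self.transform,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(pd.Series(d["beta"], index=d["genes"]), d["threshold"])


def split_cohort(clinical: pd.DataFrame, seed: int = 0, frac: float = 0.5) -> tuple:
    """50/50 training/testing split balanced on gender and age.

    Within each gender stratum, age-sorted adjacent pairs are split one to
    each half (random orientation), keeping group age means within a couple
    of years. Deterministic given the seed; singleton strata go to training
    (logged).
    """
    if not {"age", "gender"} <= set(clinical.columns):
        raise ValueError("clinical table needs age and gender columns")
    rng = np.random.default_rng(seed)
    strata = pd.Series(list(clinical["gender"]), index=clinical.index)
    train, test = [], []
    n_singleton = 0
    for _, members in sorted(strata.groupby(strata).groups.items()):
        ids = list(members)
        if len(ids) == 1:
            train.extend(ids)
            n_singleton += 1
            continue
        # age-sorted adjacent pairs split across the two halves, so group
        # age means agree to within a within-pair difference
        ids.sort(key=lambda s: (float(clinical.loc[s, "age"]), s))
        for i in range(0, len(ids) - 1, 2):
            a, b = ids[i], ids[i + 1]
            if rng.random() < 0.5:
                a, b = b, a
            train.append(a)
            test.append(b)
        if len(ids) % 2:
            (train if rng.random() < 0.5 else test).append(ids[-1])
    if n_singleton:
        logger.info("split_cohort: %d singleton strata assigned to training", n_singleton)
    return sorted(train), sorted(test)


def _surv_frame(survival: pd.DataFrame, ids) -> pd.DataFrame:
    sub = survival.loc[list(ids), ["time", "event"]].astype(float)
    if (sub["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return sub


def cox_screen(
    gene_expr: pd.DataFrame,
    survival: pd.DataFrame,
    genes,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate Cox per gene on log2(x+1) expression over the given
    samples (training set); keep Wald p < alpha.

    Returns gene, beta, p and a protective/risk tag (beta < 0 protective).
    Constant or non-convergent genes are dropped with a log line.
    """
    ids = [s for s in survival.index if s in gene_expr.columns]
    surv = _surv_frame(survival, ids)
    rows = []
    for g in genes:
        if g not in gene_expr.index:
            raise KeyError(f"gene {g} missing from expression matrix")
        x = np.log2(gene_expr.loc[g, ids].to_numpy(dtype=float) + 1.0)
        if np.ptp(x) == 0:
            logger.info("cox_screen: %s constant, dropped", g)
            continue
        df = surv.copy()
        df["x"] = x
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, Exception) as exc:  # lifelines raises broadly
            logger.info("cox_screen: %s fit failed (%s), dropped", g, exc)
            continue
        beta = float(cph.params_["x"])
        p = float(cph.summary.loc["x", "p"])
        rows.append(
            {
                "gene": g,
                "beta": beta,
                "p": p,
                "kind": "protective" if beta < 0 else "risk",
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "beta", "p", "kind"])
    kept = df[df["p"] < alpha].reset_index(drop=True)
    logger.info("cox_screen: %d of %d genes pass p < %s", len(kept), len(df), alpha)
    return kept


def risk_scores(betas: pd.Series, gene_expr: pd.DataFrame, sample_ids) -> pd.Series:
    """r_i = sum_k beta_k * log2(e_ki + 1); missing genes are a hard error."""
    missing = [g for g in betas.index if g not in gene_expr.index]
    if missing:
        raise KeyError(f"model genes missing from expression matrix: {missing}")
    sub = np.log2(gene_expr.loc[list(betas.index), list(sample_ids)].to_numpy(dtype=float) + 1.0)
    return pd.Series(betas.to_numpy() @ sub, index=list(sample_ids), name="risk")


def dichotomize(train_scores: pd.Series, test_scores: pd.Series = None) -> tuple:
    """Label samples low/high at the training median; scores strictly above
    the threshold are high, at or below are low. The threshold is frozen for
    test or external cohorts."""
    if not len(train_scores):
        raise ValueError("empty training scores")
    if np.ptp(train_scores.to_numpy(dtype=float)) == 0:
        raise ValueError("degenerate risk model: all training scores identical")
    threshold = float(np.median(train_scores))

    def lab(s):
        return pd.Series(
            np.where(s.to_numpy(dtype=float) > threshold, "high", "low"), index=s.index
        )

    labels = lab(train_scores)
    if test_scores is not None:
        labels = pd.concat([labels, lab(test_scores)])
    return labels, threshold


def logrank(groups: pd.Series, survival: pd.DataFrame) -> tuple:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {levels}")
    ids = list(groups.index)
    surv = _surv_frame(survival, ids)
    if surv["event"].sum() < 1:
        raise ValueError("log-rank needs at least one event")
    mask = groups == levels[0]
    res = logrank_test(
        surv.loc[mask.values, "time"],
        surv.loc[~mask.values, "time"],
        event_observed_A=surv.loc[mask.values, "event"],
        event_observed_B=surv.loc[~mask.values, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def adjusted_cox(
    groups: pd.Series,
    survival: pd.DataFrame,
    covariates: pd.DataFrame = None,
) -> dict:
    """Multivariate Cox of the high-risk indicator adjusted for covariates
    (age, grade, gender, IDH when present).

    Incomplete records are dropped listwise (counted in the result). Returns
    the high-vs-low HR with CI and p, plus per-covariate HRs. Separation or
    rank deficiency surfaces as a ValueError with the lifelines diagnostic.
    """
    df = pd.DataFrame({"risk_high": (groups == "high").astype(float)})
    if covariates is not None:
        cov = covariates.loc[groups.index].copy()
        if "grade" in cov:
            cov["grade"] = cov["grade"].map({"II": 2, "III": 3, "IV": 4}).astype(float)
        if "gender" in cov:
            cov["gender"] = (cov["gender"] == "male").astype(float)
        if "idh" in cov:
            cov["idh"] = (cov["idh"] == "mutant").astype(float)
        df = pd.concat([df, cov], axis=1)
    df = pd.concat([df, _surv_frame(survival, groups.index)], axis=1)
    n0 = len(df)
    df = df.dropna()
    dropped = n0 - len(df)
    if dropped:
        logger.info("adjusted_cox: %d incomplete records dropped", dropped)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise ValueError(f"adjusted Cox failed to converge: {exc}") from exc
    summary = cph.summary
    out = {
        "hr": float(np.exp(cph.params_["risk_high"])),
        "ci_low": float(np.exp(summary.loc["risk_high", "coef lower 95%"])),
        "ci_high": float(np.exp(summary.loc["risk_high", "coef upper 95%"])),
        "p": float(summary.loc["risk_high", "p"]),
        "n": int(len(df)),
        "n_dropped": int(dropped),
        "covariates": {
            c: {
                "hr": float(np.exp(cph.params_[c])),
                "p": float(summary.loc[c, "p"]),
            }
            for c in df.columns
            if c not in ("time", "event", "risk_high")
        },
    }
    return out
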