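"""Gene-level weighted burden association.

Per-subject burden scores (sum of dosage x overall weight over qualifying
variants) are tested against case status by maximum-likelihood logistic
regression with sex and 20 principal components as covariates. The p-value
comes from a likelihood-ratio test of the score term; the result is reported
as a signed log10 p-value (SLP), positive when the score is higher in cases
(operationalised as the sign of the fitted score coefficient). A Wald p-value
is carried along for diagnostics.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from burdenscan.model import CohortTable, GeneResult, MISSING, WeightedVariant

logger = logging.getLogger(__name__)

MAX_ITER = 100


def burden_scores(
    weighted_variants: Iterable[WeightedVariant], cohort: CohortTable
) -> np.ndarray:
    """Per-subject weighted burden score.

    score_s = sum_v dosage(s, v) x overall_weight(v); a missing genotype
    contributes 0 and the subject is retained.
    """
    scores = np.zeros(cohort.n, dtype=float)
    for wv in weighted_variants:
        dosage = wv.variant.genotypes.astype(float)
        dosage[wv.variant.genotypes == MISSING] = 0.0
        scores += dosage * wv.overall_weight
    return scores


def slp_from_p(p: float, higher_in_cases: bool) -> float:
    """Signed log10 p-value: -log10(p), positive when higher in cases."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    magnitude = -math.log10(p)
    return magnitude if higher_in_cases else -magnitude


def _drop_degenerate_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove constant columns (keeping the first as intercept) and, iteratively,
    columns that make the design rank deficient. Returns (X_kept, kept_mask)."""
    n, k = X.shape
    keep = np.ones(k, dtype=bool)
    ptp = X.max(axis=0) - X.min(axis=0)
    keep[1:] &= ptp[1:] > 0
    while True:
        idx = np.flatnonzero(keep)
        if np.linalg.matrix_rank(X[:, idx]) == len(idx):
            break
        # drop the last collinear column
        for j in idx[::-1]:
            trial = keep.copy()
            trial[j] = False
            tidx = np.flatnonzero(trial)
            if np.linalg.matrix_rank(X[:, tidx]) == len(tidx):
                keep = trial
                logger.warning("dropped collinear design column %d", j)
                break
    return X[:, keep], keep


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Newton/IRLS logistic fit. Returns (params, loglik, converged)."""
    model = sm.Logit(y, X)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            res = model.fit(disp=0, maxiter=MAX_ITER, method="newton")
        except Exception:  # singular Hessian under separation: fall back to BFGS
            res = model.fit(disp=0, maxiter=500, method="bfgs")
        converged = bool(res.mle_retvals.get("converged", True))
    return np.asarray(res.params), float(res.llf), converged


def covariate_matrix(cohort: CohortTable, n_pcs: Optional[int] = None) -> np.ndarray:
    """[sex, PC1..PCk] design block (no intercept column)."""
    k = cohort.pcs.shape[1] if n_pcs is None else n_pcs
    return np.column_stack([cohort.sex.astype(float), cohort.pcs[:, :k]])


def lrt_score_term(
    scores: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[float, float, float, Optional[float], bool]:
    """Likelihood-ratio test of the score term in a covariate-adjusted logistic fit.

    Returns (beta_score, lrt_p, lrt_stat, wald_p, converged).
    """
    n = len(y)
    X_full = np.column_stack([np.ones(n), scores, covariates])
    X_full, keep = _drop_degenerate_columns(X_full)
    if not keep[1]:  # score column was constant
        raise ValueError("degenerate score vector")

    X_red = np.delete(X_full, 1, axis=1)
    params_full, llf_full, conv_full = _fit_logit(y, X_full)
    _, llf_red, conv_red = _fit_logit(y, X_red)
    lrt = max(0.0, 2.0 * (llf_full - llf_red))
    p = float(stats.chi2.sf(lrt, df=1))
    p = min(max(p, np.finfo(float).tiny), 1.0)

    # Wald diagnostic from the observed information of the full fit
    wald_p: Optional[float] = None
    try:
        eta = X_full @ params_full
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        info = X_full.T @ (X_full * W[:, None])
        se = math.sqrt(np.linalg.inv(info)[1, 1])
        wald_p = float(2.0 * stats.norm.sf(abs(params_full[1]) / se))
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
        pass
    return float(params_full[1]), p, lrt, wald_p, conv_full and conv_red


def fit_burden_model(
    scores: np.ndarray,
    cohort: CohortTable,
    gene: str = "",
    n_qualifying_variants: int = 0,
    n_pcs: Optional[int] = None,
) -> GeneResult:
    """Fit the burden logistic model for one gene and summarise as a GeneResult.

    A constant score vector yields SLP 0 with the ``degenerate`` flag set.
    ``n_pcs`` limits the number of principal components used (all by default);
    small fixtures need fewer columns than subjects.
    """
    cohort._require_status()
    y = cohort.is_case.astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")

    mean_cases = float(scores[cohort.is_case].mean())
    mean_controls = float(scores[~cohort.is_case].mean())

    if np.ptp(scores) == 0:
        return GeneResult(
            gene=gene, slp=0.0, beta=0.0, p_value=1.0,
            n_qualifying_variants=n_qualifying_variants,
            score_mean_cases=mean_cases, score_mean_controls=mean_controls,
            degenerate=True,
        )

    beta, p, _, wald_p, converged = lrt_score_term(
        scores, y, covariate_matrix(cohort, n_pcs)
    )
    higher_in_cases = beta > 0 or (beta == 0 and mean_cases >= mean_controls)
    return GeneResult(
        gene=gene,
        slp=slp_from_p(p, higher_in_cases),
        beta=beta,
        p_value=p,
        n_qualifying_variants=n_qualifying_variants,
        score_mean_cases=mean_cases,
        score_mean_controls=mean_controls,
        wald_p=wald_p,
        converged=converged,
    )


def gene_burden_test(
    weighted_variants: Sequence[WeightedVariant],
    cohort: CohortTable,
    gene: str,
    n_pcs: Optional[int] = None,
) -> GeneResult:
    """Convenience wrapper: scores + model fit for one gene's qualifying variants."""
    scores = burden_scores(weighted_variants, cohort)
    return fit_burden_model(
        scores, cohort, gene=gene,
        n_qualifying_variants=len(weighted_variants), n_pcs=n_pcs,
    )
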