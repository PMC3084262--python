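"""Multi-recruiter linear model of co-repressor occupancy.

The model predicts co-repressor occupancy per region as an intercept plus a
weighted sum of recruiter occupancies.  Missing recruiter entries are filled
by Gaussian imputation from the observed column moments (several independent
draws, averaged at the estimate level).  Candidate recruiters are screened
univariately (positive slope, significant at alpha); the multivariate model
is fitted on random half-genome splits with repeated random-subsampling
cross-validation — coefficients averaged over imputation draws within each
split, then over splits — and evaluated on the held-out halves.
Non-significant recruiters are dropped and nested models are compared with
a partial F-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearityError,
    DegenerateRegressorError,
    EmptyModelError,
    MissingRecruiterError,
    NonNestedError,
    UnimputableColumnError,
)


@dataclass
class ImputedMatrix:
    """A matrix with missing entries filled by Gaussian draws.

    ``draws`` holds ``n_draws`` independently filled copies; non-missing
    entries are identical across draws.
    """

    base: pd.DataFrame
    draws: list[pd.DataFrame]
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.draws)


@dataclass
class RegressionModel:
    """Fitted multi-recruiter model.

    Weights, intercept and p-values are means over the split x imputation
    fits; ``r2_heldout`` is the mean held-out R^2 across splits.
    """

    intercept: float
    weights: dict[str, float]
    param_p: dict[str, float]
    r2_train: float
    r2_heldout: float
    included: list[str]
    n_splits: int
    n_imputations: int
    seed: int = 0
    nonsignificant: list[str] = field(default_factory=list)


def impute_missing(matrix: pd.DataFrame, n_draws: int = 10,
                   seed: int = 0) -> ImputedMatrix:
    """Fill each missing entry with a draw from Normal(col mean, col sd).

    Moments are computed on the observed entries of each column; observed
    entries are never modified.  Each of the ``n_draws`` filled matrices
    uses independent draws.
    """
    rng = np.random.default_rng(seed)
    for col in matrix.columns:
        if matrix[col].notna().sum() < 2:
            raise UnimputableColumnError(
                f"column {col} has fewer than 2 observed values")
    draws = []
    miss = matrix.isna()
    means = matrix.mean()
    sds = matrix.std(ddof=1).fillna(0.0)
    for _ in range(n_draws):
        filled = matrix.copy()
        for col in matrix.columns:
            m = miss[col].to_numpy()
            if m.any():
                filled.loc[m, col] = rng.normal(
                    means[col], sds[col], int(m.sum()))
        draws.append(filled)
    return ImputedMatrix(base=matrix, draws=draws, seed=seed)


def univariate_screen(y: pd.Series, recruiters: pd.DataFrame,
                      alpha: float = 0.01, min_pairs: int = 10
                      ) -> list[str]:
    """Retain recruiters whose simple OLS slope on the co-repressor is
    positive and significant at ``alpha`` (complete pairs only)."""
    kept = []
    for col in recruiters.columns:
        x = recruiters[col]
        ok = x.notna() & y.notna()
        if ok.sum() < min_pairs:
            warnings.warn(f"{col}: only {int(ok.sum())} complete pairs; "
                          "skipped", stacklevel=2)
            continue
        res = stats.linregress(x[ok], y[ok])
        if res.slope > 0 and res.pvalue < alpha:
            kept.append(col)
    return kept


def _check_collinearity(X: pd.DataFrame) -> None:
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(Xv)), Xv]))
    if rank < Xv.shape[1] + 1:
        corr = np.corrcoef(Xv, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise CollinearityError(
            f"singular design: columns {X.columns[i]!r} and "
            f"{X.columns[j]!r} are collinear")


def fit_with_cv(y: pd.Series, recruiters: pd.DataFrame,
                n_splits: int = 5, n_imputations: int = 10,
                seed: int = 0, alpha: float = 0.01) -> RegressionModel:
    """Half-genome OLS with repeated random-subsampling cross-validation.

    For each of ``n_splits`` random half/half partitions of the regions the
    model is fitted on one half — once per imputation draw, coefficients
    averaged over draws — and its R^2 evaluated on the held-out half.
    Final parameters are means over splits; per-parameter p-values combine
    the averaged coefficient with the mean per-fit standard error.
    Recruiters with pooled p > ``alpha`` are flagged non-significant.
    """
    if recruiters.shape[1] < 1:
        raise EmptyModelError("no recruiters to fit")
    if len(y) < 50:
        raise DegenerateRegressorError("need >= 50 regions")
    imputed = impute_missing(recruiters, n_draws=n_imputations, seed=seed)
    _check_collinearity(imputed.draws[0])

    rng = np.random.default_rng(seed)
    cols = list(recruiters.columns)
    n = len(y)
    yv = y.to_numpy(dtype=float)
    coefs, ses, r2_tr, r2_ho = [], [], [], []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        train, test = perm[: n // 2], perm[n // 2:]
        split_coefs, split_ses = [], []
        for filled in imputed.draws:
            Xd = sm.add_constant(filled.to_numpy(dtype=float)[train])
            fit = sm.OLS(yv[train], Xd).fit()
            split_coefs.append(fit.params)
            split_ses.append(fit.bse)
        beta = np.mean(split_coefs, axis=0)
        coefs.append(beta)
        ses.append(np.mean(split_ses, axis=0))
        # evaluate the split-average model on both halves, per draw
        tr_scores, ho_scores = [], []
        for filled in imputed.draws:
            Xv = filled.to_numpy(dtype=float)
            pred = beta[0] + Xv @ beta[1:]
            for idx, sink in ((train, tr_scores), (test, ho_scores)):
                ss_res = float(((yv[idx] - pred[idx]) ** 2).sum())
                ss_tot = float(((yv[idx] - yv[idx].mean()) ** 2).sum())
                sink.append(1.0 - ss_res / ss_tot)
        r2_tr.append(np.mean(tr_scores))
        r2_ho.append(np.mean(ho_scores))

    beta = np.mean(coefs, axis=0)
    se = np.mean(ses, axis=0)
    df_resid = n // 2 - len(cols) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)

    weights = {c: float(beta[i + 1]) for i, c in enumerate(cols)}
    param_p = {c: float(pvals[i + 1]) for i, c in enumerate(cols)}
    return RegressionModel(
        intercept=float(beta[0]),
        weights=weights,
        param_p=param_p,
        r2_train=float(np.clip(np.mean(r2_tr), 0.0, 1.0)),
        r2_heldout=float(np.clip(np.mean(r2_ho), 0.0, 1.0)),
        included=cols,
        n_splits=n_splits,
        n_imputations=n_imputations,
        seed=seed,
        nonsignificant=[c for c in cols if param_p[c] > alpha],
    )


def drop_nonsignificant(model: RegressionModel, y: pd.Series,
                        recruiters: pd.DataFrame, alpha: float = 0.01
                        ) -> RegressionModel:
    """Remove recruiters with pooled p > alpha and refit on the rest."""
    keep = [c for c in model.included if model.param_p[c] <= alpha]
    if not keep:
        raise EmptyModelError("all recruiters are non-significant")
    if keep == model.included:
        return model
    return fit_with_cv(y, recruiters[keep], n_splits=model.n_splits,
                       n_imputations=model.n_imputations, seed=model.seed,
                       alpha=alpha)


def compare_models(base: RegressionModel, extended: RegressionModel,
                   y: pd.Series, recruiters: pd.DataFrame
                   ) -> tuple[float, float]:
    """Nested-model partial F-test on a full-data fit.

    ``recruiters`` must be complete (impute first).  Returns
    (delta_r2, p_value); identical recruiter sets give (0, 1).
    """
    b, e = set(base.included), set(extended.included)
    if not b <= e:
        raise NonNestedError("base recruiters must be a subset of extended")
    if b == e:
        return 0.0, 1.0
    yv = y.to_numpy(dtype=float)
    fits = {}
    for name, cols in (("base", base.included), ("ext", extended.included)):
        X = sm.add_constant(recruiters[cols].to_numpy(dtype=float))
        fits[name] = sm.OLS(yv, X).fit()
    q = len(e) - len(b)
    df2 = len(yv) - len(e) - 1
    ssr_b, ssr_e = fits["base"].ssr, fits["ext"].ssr
    f = ((ssr_b - ssr_e) / q) / (ssr_e / df2)
    p = float(stats.f.sf(f, q, df2))
    return float(fits["ext"].rsquared - fits["base"].rsquared), p


def predict(model: RegressionModel, recruiters: pd.DataFrame) -> pd.Series:
    """Predicted co-repressor occupancy: intercept + sum(beta_r * x_r)."""
    missing = [c for c in model.included if c not in recruiters.columns]
    if missing:
        raise MissingRecruiterError(f"missing recruiter columns: {missing}")
    X = recruiters[model.included].to_numpy(dtype=float)
    beta = np.array([model.weights[c] for c in model.included])
    return pd.Series(model.intercept + X @ beta, index=recruiters.index,
                     name="predicted")


def full_pipeline(y: pd.Series, recruiters: pd.DataFrame,
                  n_splits: int = 5, n_imputations: int = 10,
                  seed: int = 0, alpha: float = 0.01) -> RegressionModel:
    """Impute, screen univariately, fit with cross-validation, and drop
    non-significant recruiters."""
    kept = univariate_screen(y, recruiters, alpha=alpha)
    if not kept:
        raise EmptyModelError("no recruiter passed the univariate screen")
    model = fit_with_cv(y, recruiters[kept], n_splits=n_splits,
                        n_imputations=n_imputations, seed=seed, alpha=alpha)
    return drop_nonsignificant(model, y, recruiters, alpha=alpha)
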