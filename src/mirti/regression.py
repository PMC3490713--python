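"""Elastic-net regression of expression / activity profiles on miRTI columns.

Each patient's gene-expression profile (and, in the second application,
the per-gene ActivityScore profile) is modeled as a linear combination
of the miRTI columns: the design matrix has one row per gene and one
column per miRNA, holding ``miRTI(miR_j, gene)``.  Fitting uses the
elastic-net penalty

    P_alpha(beta) = sum_j [ (1 - alpha)/2 * beta_j^2 + alpha * |beta_j| ]

with mixing ``alpha = 0.5`` by default (a middle ground between ridge
and lasso that keeps correlated miRNA predictors together), a 100-value
log-spaced lambda path from lambda_max down to ``lambda_max * 1e-3``,
and the lambda minimizing the 10-fold cross-validated mean squared
error.  Observations are genes, so CV folds are seeded shuffles of the
gene set.  An intercept is included.  Per-patient fits are independent,
so results do not depend on execution order.

Predictors enter on their miRTI scale by default
(``standardize=False``): the influence weights are themselves evidence,
and column-wise unit-variance scaling would let near-zero influence
columns compete on equal footing with strong ones — erasing exactly the
information that distinguishes the weighted design from a binary
target-relation design.  ``standardize=True`` restores the glmnet-style
convention (coefficients are then mapped back to the original scale).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

__all__ = [
    "ElasticNetConfig",
    "InfluenceMatrix",
    "build_design",
    "lambda_path",
    "fit_fixed_lambda",
    "fit_patient_influence",
    "fit_activity_influence",
    "write_influence_matrix",
]

# ridge (alpha=0) has no finite lambda that zeroes all coefficients; the
# path top is computed with the mixing floored here, as glmnet does
_MIXING_FLOOR = 1e-3


@dataclass(frozen=True)
class ElasticNetConfig:
    """Elastic-net fitting policy.

    alpha is the ridge/lasso mixing (0 = ridge, 1 = lasso); n_lambda the
    length of the log-spaced penalty path; n_folds the CV fold count.
    """

    alpha: float = 0.5
    n_lambda: int = 100
    n_folds: int = 10
    standardize: bool = False
    seed: int = 0
    lambda_min_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_lambda < 1 or self.n_folds < 2:
            raise ValueError("n_lambda must be >= 1 and n_folds >= 2")


@dataclass
class InfluenceMatrix:
    """Fitted miRNA influence coefficients.

    ``coefficients`` is miRNAs x columns (patients, or the single
    pseudo-column ``"activity"``); ``chosen_lambda`` / ``cv_mse`` /
    ``intercept`` are per-column sidecar series.
    """

    coefficients: pd.DataFrame
    chosen_lambda: pd.Series
    cv_mse: pd.Series
    intercept: pd.Series


def build_design(net: pd.DataFrame, gene_universe: Sequence[str]) -> pd.DataFrame:
    """Genes x miRNAs design matrix of miRTI scores.

    Cell (gene, miR) holds ``miRTI(miR, gene)``, 0 where the influence
    network has no entry.  miRNAs whose column is entirely zero on the
    universe are dropped with their names logged.
    """
    gene_universe = list(gene_universe)
    if not gene_universe:
        raise ValueError("empty gene universe")
    if net.empty:
        raise ValueError("empty influence network")
    design = (
        net.pivot_table(index="target", columns="miRNA", values="mirti", aggfunc="sum")
        .reindex(index=gene_universe)
        .fillna(0.0)
    )
    design = design.loc[:, sorted(design.columns)]
    zero_cols = design.columns[(design == 0).all(axis=0)]
    if len(zero_cols):
        log.info(
            "dropping %d all-zero miRNA column(s): %s",
            len(zero_cols),
            ", ".join(map(str, zero_cols[:10])),
        )
        design = design.drop(columns=zero_cols)
    design.index.name = "gene"
    return design


def _standardize(X: np.ndarray, cfg: ElasticNetConfig) -> tuple[np.ndarray, np.ndarray]:
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    if not cfg.standardize:
        sd = np.ones_like(sd)
    return X / sd, sd


def lambda_path(X: np.ndarray, y: np.ndarray, cfg: ElasticNetConfig) -> np.ndarray:
    """Log-spaced penalty path from lambda_max down to its min ratio.

    lambda_max is the smallest penalty zeroing every coefficient,
    ``max_j |x_j . (y - ybar)| / (n * alpha)`` on standardized
    predictors, with the mixing floored for the ridge end.
    """
    Xs, _ = _standardize(X, cfg)
    Xc = Xs - Xs.mean(axis=0)
    yc = y - y.mean()
    lam_max = np.abs(Xc.T @ yc).max() / (len(y) * max(cfg.alpha, _MIXING_FLOOR))
    if lam_max <= 0:
        lam_max = 1e-4  # constant response: any penalty zeroes the fit
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * cfg.lambda_min_ratio), cfg.n_lambda
    )


def _path_coefs(
    Xc: np.ndarray, yc: np.ndarray, lambdas: np.ndarray, cfg: ElasticNetConfig
) -> np.ndarray:
    """Coefficients along a decreasing lambda path (features x lambdas)."""
    _, coefs, _ = enet_path(Xc, yc, l1_ratio=cfg.alpha, alphas=lambdas)
    return coefs


def fit_fixed_lambda(
    X: np.ndarray, y: np.ndarray, lam: float, cfg: ElasticNetConfig
) -> tuple[np.ndarray, float]:
    """Single elastic-net fit at a fixed penalty.

    Returns coefficients on the original predictor scale and the
    intercept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs, sd = _standardize(X, cfg)
    mu = Xs.mean(axis=0)
    ybar = y.mean()
    # warm-started descent down the path to lam stabilizes the solution
    lams = lambda_path(X, y, cfg)
    lams = np.append(lams[lams > lam], lam)
    coefs = _path_coefs(Xs - mu, y - ybar, lams, cfg)
    beta_s = coefs[:, -1]
    beta = beta_s / sd
    intercept = float(ybar - mu @ beta_s)
    return beta, intercept


def _fit_column(
    X: np.ndarray, y: np.ndarray, cfg: ElasticNetConfig
) -> tuple[np.ndarray, float, float, float]:
    """CV over the lambda path, then a full-data fit at the chosen lambda.

    Returns (coefficients on the original scale, intercept,
    chosen lambda, CV MSE at the chosen lambda).
    """
    n = len(y)
    if np.ptp(y) == 0:
        return np.zeros(X.shape[1]), float(y.mean()), 0.0, 0.0
    Xs, sd = _standardize(X, cfg)
    lambdas = lambda_path(X, y, cfg)
    folds = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    sq_err = np.zeros(len(lambdas))
    for train, test in folds.split(Xs):
        mu = Xs[train].mean(axis=0)
        ybar = y[train].mean()
        coefs = _path_coefs(Xs[train] - mu, y[train] - ybar, lambdas, cfg)
        preds = (Xs[test] - mu) @ coefs + ybar
        sq_err += ((preds - y[test, None]) ** 2).sum(axis=0)
    cv_mse = sq_err / n
    best = int(np.argmin(cv_mse))  # ties resolve to the larger (sparser) lambda
    mu = Xs.mean(axis=0)
    ybar = y.mean()
    coefs = _path_coefs(Xs - mu, y - ybar, lambdas[: best + 1], cfg)
    beta_s = coefs[:, -1]
    return beta_s / sd, float(ybar - mu @ beta_s), float(lambdas[best]), float(cv_mse[best])


def fit_patient_influence(
    design: pd.DataFrame, expr: pd.DataFrame, cfg: ElasticNetConfig = ElasticNetConfig()
) -> InfluenceMatrix:
    """Per-patient elastic net of gene expression on miRTI columns.

    Each patient (column of ``expr``) is fit independently over the
    shared gene universe; the result is the miRNA x patient influence
    matrix of coefficients at the per-patient CV-optimal lambda.
    """
    if list(design.index) != list(expr.index):
        raise ValueError("design rows must match the expression gene universe")
    if len(design) < 2 * cfg.n_folds:
        raise ValueError(
            f"need at least {2 * cfg.n_folds} genes for {cfg.n_folds}-fold CV"
        )
    X = design.to_numpy(dtype=float)
    coef_cols, lams, mses, intercepts = {}, {}, {}, {}
    for patient in expr.columns:
        beta, intercept, lam, mse = _fit_column(
            X, expr[patient].to_numpy(dtype=float), cfg
        )
        coef_cols[patient] = beta
        lams[patient] = lam
        mses[patient] = mse
        intercepts[patient] = intercept
    coefficients = pd.DataFrame(coef_cols, index=design.columns)
    coefficients.index.name = "miRNA"
    return InfluenceMatrix(
        coefficients=coefficients,
        chosen_lambda=pd.Series(lams, name="lambda"),
        cv_mse=pd.Series(mses, name="cv_mse"),
        intercept=pd.Series(intercepts, name="intercept"),
    )


def fit_activity_influence(
    design: pd.DataFrame,
    scores: pd.Series,
    cfg: ElasticNetConfig = ElasticNetConfig(),
) -> InfluenceMatrix:
    """Elastic net of the ActivityScore profile on miRTI columns.

    Single-response variant of :func:`fit_patient_influence`; positive
    coefficients mark miRNAs whose influence pattern positively explains
    the gene activity profile.
    """
    frame = scores.to_frame(name="activity")
    return fit_patient_influence(design, frame.reindex(design.index), cfg)


def write_influence_matrix(
    im: InfluenceMatrix, path, sidecar_path=None, comments: Iterable[str] = ()
) -> None:
    """Write the coefficient matrix (and optionally the lambda/MSE sidecar)."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        im.coefficients.to_csv(fh, sep="\t", index_label="miRNA", lineterminator="\n")
    if sidecar_path is not None:
        side = pd.DataFrame(
            {
                "lambda": im.chosen_lambda,
                "cv_mse": im.cv_mse,
                "intercept": im.intercept,
            }
        )
        with open(sidecar_path, "w") as fh:
            for line in comments:
                fh.write(f"# {line}\n")
            side.to_csv(fh, sep="\t", index_label="column", lineterminator="\n")
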