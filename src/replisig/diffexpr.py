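"""Per-gene linear models with empirical-Bayes variance moderation.

For each gene i the model is

    y_ij = b_i0 + b_i^Gr x_j^Gr + b_i^B x_j^B + b_i^Ge x_j^Ge
           + b_i^Ag x_j^Ag + b_i^An x_j^An + e_ij,   e_ij ~ N(0, sigma_i^2),

with treatment coding (reference levels: control, first batch, male,
anxiety 0). The case/control contrast b_i^Gr is tested with a moderated
t-statistic: residual variances s_i^2 are shrunk towards a prior value s0^2
estimated across genes, gaining d0 prior degrees of freedom,

    s~_i^2 = (d0 s0^2 + d s_i^2) / (d0 + d),
    t~_i  = b_i^Gr / sqrt(c_g s~_i^2),   t~_i ~ t(d0 + d) under H0,

where d = n - rank(X) and c_g is the group-column diagonal of (X'X)^-1.
The prior (d0, s0^2) is estimated by method of moments on log s_i^2 using
the digamma/trigamma relations of the scaled-F sampling distribution.
Permutation p-values (labels shuffled within batch strata) and a module
eigengene summary are also provided.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .exceptions import ConfigError, DesignError, EstimationError, ParameterError, ValidationError
from .study import CASE, CONTROL, ExpressionStudy

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES: tuple[str, ...] = ("group", "batch", "sex", "age", "anxiety")

#: reference level per factor covariate (treatment coding)
FACTOR_REFERENCES = {"group": CONTROL, "sex": "male", "anxiety": 0}
CONTINUOUS_COVARIATES = {"age", "bmi"}

_P_FLOOR = np.finfo(float).tiny  # p-values are never reported as exactly 0


@dataclass
class DesignMatrix:
    """Numeric design matrix with named columns and a fixed group contrast."""

    frame: pd.DataFrame      # samples x p, first column the intercept
    group_col: str           # column holding the case indicator

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> pd.Index:
        return self.frame.columns


@dataclass
class GeneModelFits:
    """Per-gene OLS results shared across the study."""

    coef: pd.DataFrame       # genes x design columns
    sigma2: np.ndarray       # residual variances s_i^2 (log2^2)
    df_residual: int         # d = n - rank(X), common to all genes
    c_group: float           # group-column diagonal of (X'X)^-1
    group_col: str

    @property
    def gene_ids(self) -> pd.Index:
        return self.coef.index

    @property
    def group_coef(self) -> np.ndarray:
        return self.coef[self.group_col].to_numpy()


@dataclass
class VariancePrior:
    """Empirical-Bayes hyperparameters of the gene-variance distribution."""

    d0: float        # prior degrees of freedom; math.inf when no excess spread
    s0_sq: float     # prior variance, log2^2

    def __post_init__(self) -> None:
        if not (self.d0 >= 0 or math.isinf(self.d0)):
            raise ParameterError("d0 must be nonnegative or infinite")
        if self.s0_sq <= 0:
            raise ParameterError("s0_sq must be positive")

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.d0)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    sample_table: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> DesignMatrix:
    """Treatment-coded design matrix with fixed reference levels.

    Reference levels: control, lowest batch, male, anxiety 0; continuous
    covariates (age, bmi) enter as-is. Factors with a single observed level
    are dropped with a logged warning; the group factor must have both
    levels.
    """
    if "group" not in covariates:
        raise DesignError("model must include the group factor")
    n = len(sample_table)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    group_col = None
    for cov in covariates:
        if cov not in sample_table.columns:
            raise DesignError(f"covariate '{cov}' missing from sample table")
        x = sample_table[cov]
        if x.isna().any():
            bad = sample_table.index[x.isna()].tolist()
            raise DesignError(f"covariate '{cov}' has missing values for {bad[:5]}")
        if cov in CONTINUOUS_COVARIATES:
            cols[cov] = x.to_numpy(dtype=float)
            continue
        levels = sorted(pd.unique(x), key=str)
        if cov == "group":
            if set(levels) != {CASE, CONTROL}:
                raise DesignError(
                    f"group must contain both 'case' and 'control', found {levels}"
                )
            group_col = f"group[{CASE}]"
            cols[group_col] = (x == CASE).to_numpy(dtype=float)
            continue
        if len(levels) < 2:
            logger.warning(
                "factor '%s' has a single level (%r); column dropped", cov, levels[0]
            )
            continue
        ref = FACTOR_REFERENCES.get(cov, levels[0])
        if ref not in levels:
            ref = levels[0]
        for lev in levels:
            if lev == ref:
                continue
            cols[f"{cov}[{lev}]"] = (x == lev).to_numpy(dtype=float)
    frame = pd.DataFrame(cols, index=sample_table.index)
    X = frame.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(
            f"design matrix is rank deficient (columns: {list(frame.columns)})"
        )
    return DesignMatrix(frame=frame, group_col=group_col)


# ---------------------------------------------------------------------------
# per-gene OLS
# ---------------------------------------------------------------------------

def fit_gene_models(study: ExpressionStudy, design: DesignMatrix) -> GeneModelFits:
    """Vectorised per-gene ordinary least squares against a shared design."""
    if not design.frame.index.equals(study.sample_ids):
        try:
            design = DesignMatrix(
                design.frame.loc[study.sample_ids], design.group_col
            )
        except KeyError as err:
            raise DesignError(f"design rows do not match study samples: {err}")
    X = design.values
    n, p = X.shape
    if n <= p:
        raise DesignError(f"need more samples ({n}) than design columns ({p})")
    Y = study.expression.to_numpy(dtype=float)  # genes x n
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise DesignError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv            # genes x p
    resid = Y - beta @ X.T
    d = n - rank
    sigma2 = np.einsum("ij,ij->i", resid, resid) / d
    g = design.frame.columns.get_loc(design.group_col)
    return GeneModelFits(
        coef=pd.DataFrame(beta, index=study.gene_ids, columns=design.columns),
        sigma2=sigma2,
        df_residual=d,
        c_group=float(xtx_inv[g, g]),
        group_col=design.group_col,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes prior
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = x for y > 0 by bisection (trigamma is decreasing)."""
    if x <= 0:
        raise EstimationError("trigamma inverse requires a positive argument")
    lo, hi = 1e-9, 1e9
    while special.polygamma(1, lo) < x:
        lo /= 10.0
    while special.polygamma(1, hi) > x:
        hi *= 10.0
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > x:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_variance_prior(fits: GeneModelFits) -> VariancePrior:
    """Method-of-moments fit of the scaled-F model for the sample variances.

    Given s_i^2 ~ s0^2 F(d, d0), log s_i^2 has mean and excess variance
    expressible through digamma/trigamma at d/2 and d0/2; matching the first
    two moments of log s^2 yields (d0, s0^2). Zero or non-finite variances
    are excluded from estimation (but are still shrunk downstream). When the
    observed spread of log s^2 does not exceed the sampling spread, d0 is
    flagged infinite and s0^2 set so that the prior mean matches.
    """
    d = fits.df_residual
    s2 = np.asarray(fits.sigma2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise EstimationError("all residual variances are zero; cannot estimate prior")
    s2 = s2[ok]
    if n_ok == 1 or np.allclose(s2, s2[0]):
        logger.warning("no spread in residual variances; prior df flagged infinite")
        return VariancePrior(d0=math.inf, s0_sq=float(s2.mean()))
    if n_ok < 30:
        logger.warning("variance prior estimated from only %d genes", n_ok)
    e = np.log(s2) - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if e_var <= 0:
        return VariancePrior(d0=math.inf, s0_sq=float(math.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(e_var)
    if d0 >= 1e6:
        return VariancePrior(d0=math.inf, s0_sq=float(math.exp(e_mean)))
    s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return VariancePrior(d0=float(d0), s0_sq=float(s0_sq))


# ---------------------------------------------------------------------------
# moderated statistics
# ---------------------------------------------------------------------------

def _moderated_t(
    beta: np.ndarray, sigma2: np.ndarray, d: int, c_g: float, prior: VariancePrior
) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (t, s2_post, df_total)."""
    if c_g <= 0:
        raise EstimationError("nonpositive unscaled variance of the group coefficient")
    if prior.is_infinite:
        s2_post = np.full_like(sigma2, prior.s0_sq)
        df_total = math.inf
    elif prior.d0 == 0:
        s2_post = sigma2.copy()  # no-shrinkage limit: ordinary t exactly
        df_total = float(d)
    else:
        s2_post = (prior.d0 * prior.s0_sq + d * sigma2) / (prior.d0 + d)
        df_total = prior.d0 + d
    with np.errstate(divide="ignore"):
        t = beta / np.sqrt(c_g * s2_post)
    return t, s2_post, df_total


def moderated_statistics(fits: GeneModelFits, prior: VariancePrior) -> pd.DataFrame:
    """Per-gene moderated t-statistics and two-sided p-values.

    Returns a frame indexed by gene id with columns ``log2fc``, ``s2_post``,
    ``t``, ``df`` and ``pvalue``. With ``d0 = 0`` the statistic reduces to
    the ordinary t; with infinite ``d0`` the reference distribution is
    normal.
    """
    beta = fits.group_coef
    t, s2_post, df_total = _moderated_t(
        beta, fits.sigma2, fits.df_residual, fits.c_group, prior
    )
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, _P_FLOOR, 1.0)
    return pd.DataFrame(
        {
            "log2fc": beta,
            "s2_post": s2_post,
            "t": t,
            "df": df_total,
            "pvalue": p,
        },
        index=fits.gene_ids,
    )


# ---------------------------------------------------------------------------
# permutation p-values
# ---------------------------------------------------------------------------

def _strata_indices(sample_table: pd.DataFrame, strata: str | None) -> list[np.ndarray]:
    if strata is None or strata not in sample_table.columns:
        return [np.arange(len(sample_table))]
    return [
        np.flatnonzero((sample_table[strata] == lev).to_numpy())
        for lev in pd.unique(sample_table[strata])
    ]


def permutation_pvalues(
    study: ExpressionStudy,
    design: DesignMatrix,
    prior: VariancePrior | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    strata: str | None = "batch",
    exact: bool = False,
) -> pd.Series:
    """Permutation p-values for the moderated t, labels shuffled within strata.

    Case/control labels are permuted within batch strata (the largest nuisance
    factor); the moderated t is recomputed for every permutation with the
    *same* prior as the observed analysis. Monte-Carlo p-values use the
    add-one estimator p = (1 + #{|t*| >= |t_obs|}) / (1 + n_perm), so the
    smallest attainable p is 1/(n_perm + 1). With ``exact=True`` all distinct
    stratified label assignments are enumerated instead (the observed
    assignment included) and p is the exact tail proportion.
    """
    if n_perm < 1 and not exact:
        raise ConfigError("n_perm must be at least 1")
    fits = fit_gene_models(study, design)
    if prior is None:
        prior = estimate_variance_prior(fits)
    t_obs, _, _ = _moderated_t(
        fits.group_coef, fits.sigma2, fits.df_residual, fits.c_group, prior
    )
    abs_obs = np.abs(t_obs)

    X = design.values.copy()
    gcol = design.frame.columns.get_loc(design.group_col)
    is_case = X[:, gcol].copy()
    Y = study.expression.to_numpy(dtype=float)
    n, p = X.shape
    d = n - p
    idx_strata = _strata_indices(study.samples, strata)
    for idx in idx_strata:
        labs = set(is_case[idx])
        if len(idx) < 2 or labs != {0.0, 1.0}:
            raise ConfigError(
                "each permutation stratum must contain both group labels"
            )

    def t_for(labels: np.ndarray) -> np.ndarray:
        Xp = X.copy()
        Xp[:, gcol] = labels
        xtx = Xp.T @ Xp
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            raise ConfigError("permuted design became singular")
        beta = Y @ Xp @ xtx_inv
        resid = Y - beta @ Xp.T
        s2 = np.einsum("ij,ij->i", resid, resid) / d
        t, _, _ = _moderated_t(
            beta[:, gcol], s2, d, float(xtx_inv[gcol, gcol]), prior
        )
        return t

    if exact:
        per_stratum = []
        total = 1
        for idx in idx_strata:
            k = int(is_case[idx].sum())
            combos = list(itertools.combinations(range(len(idx)), k))
            total *= len(combos)
            if total > 100_000:
                raise ConfigError("too many label assignments for exact enumeration")
            per_stratum.append((idx, combos))
        count = np.zeros(Y.shape[0])
        n_assign = 0
        for assignment in itertools.product(*(c for _, c in per_stratum)):
            labels = np.zeros(n)
            for (idx, _), pick in zip(per_stratum, assignment):
                labels[idx[list(pick)]] = 1.0
            count += np.abs(t_for(labels)) >= abs_obs
            n_assign += 1
        pvals = count / n_assign
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(Y.shape[0])
        for _ in range(n_perm):
            labels = is_case.copy()
            for idx in idx_strata:
                labels[idx] = rng.permutation(labels[idx])
            count += np.abs(t_for(labels)) >= abs_obs
        pvals = (1.0 + count) / (1.0 + n_perm)
    return pd.Series(pvals, index=study.gene_ids, name="p_perm")


# ---------------------------------------------------------------------------
# module eigengene
# ---------------------------------------------------------------------------

def module_eigengene(
    study: ExpressionStudy, gene_ids: list[str] | pd.Index
) -> tuple[pd.Series, float]:
    """First-principal-component summary of a gene module, with a group test.

    Genes are standardised across samples (sample sd, ddof=1); the eigengene
    is the first right singular vector of the standardised matrix, scaled to
    unit variance and sign-oriented to correlate positively with the module's
    mean standardised profile. Returns (eigengene, two-sided Welch p for the
    case-control difference).
    """
    present = study.gene_ids.intersection(pd.Index(gene_ids))
    if len(present) == 0:
        raise ValidationError("no module genes present in the study")
    Z = study.expression.loc[present].to_numpy(dtype=float)
    sd = Z.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValidationError("all module genes are constant across samples")
    if (~keep).any():
        logger.warning("dropping %d constant genes from module", int((~keep).sum()))
    Z = (Z[keep] - Z[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    scores = vt[0]
    scores = scores / scores.std(ddof=1)
    mean_profile = Z.mean(axis=0)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    eigengene = pd.Series(scores, index=study.sample_ids, name="eigengene")
    case = eigengene[study.is_case.to_numpy()]
    ctrl = eigengene[~study.is_case.to_numpy()]
    _, pvalue = stats.ttest_ind(case, ctrl, equal_var=False)
    return eigengene, float(pvalue)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class ModeratedTTest(BaseEstimator):
    """Per-gene case-control differential expression with variance moderation.

    Parameters
    ----------
    covariates
        Model terms; must include ``group``. Sensitivity variants (e.g. a
        model without anxiety, or with BMI) are expressed by changing this
        tuple.
    n_perm
        Number of label permutations for nonparametric p-values; 0 disables
        them.
    permute_within
        Stratification column for the permutation scheme.
    seed
        Seed for the permutation stream.

    Attributes (after ``fit``)
    --------------------------
    design_ : DesignMatrix
    fits_ : GeneModelFits
    prior_ : VariancePrior
    results_ : DataFrame with log2fc, t, df, pvalue (and p_perm if requested)
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        n_perm: int = 0,
        permute_within: str | None = "batch",
        seed: int = 0,
    ):
        self.covariates = covariates
        self.n_perm = n_perm
        self.permute_within = permute_within
        self.seed = seed

    def fit(self, study: ExpressionStudy, y=None) -> "ModeratedTTest":
        self.design_ = build_design(study.samples, tuple(self.covariates))
        self.fits_ = fit_gene_models(study, self.design_)
        self.prior_ = estimate_variance_prior(self.fits_)
        self.results_ = moderated_statistics(self.fits_, self.prior_)
        if self.n_perm > 0:
            self.results_["p_perm"] = permutation_pvalues(
                study,
                self.design_,
                self.prior_,
                n_perm=self.n_perm,
                seed=self.seed,
                strata=self.permute_within,
            )
        logger.info(
            "%s: fitted %d genes, d=%d, prior d0=%.3g s0^2=%.4g",
            study.name,
            len(self.results_),
            self.fits_.df_residual,
            self.prior_.d0,
            self.prior_.s0_sq,
        )
        return self


def differential_expression(
    study: ExpressionStudy,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Convenience wrapper: fit :class:`ModeratedTTest` and return its table."""
    return ModeratedTTest(
        covariates=covariates, n_perm=n_perm, seed=seed
    ).fit(study).results_
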