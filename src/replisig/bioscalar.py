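"""Coupled UP/DOWN signature scoring and subject stratification.

Each subject is summarised by two signature means: the average (z-scored)
expression over the UP consensus genes and over the DOWN consensus genes.
Among cases these two means are strongly negatively correlated — the
coupling. Regressing meanDOWN on meanUP over cases gives a coupling line;
every subject's point is orthogonally projected onto that line and described
by a single signed coordinate (the *bioscalar*), measured from the line
point nearest the origin, increasing with meanUP. Downstream summaries:
Cohen's d between groups, ROC AUC, and a top-tertile cutoff classifier with
its specificity in controls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from .exceptions import EstimationError, ValidationError
from .study import CASE, ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingLine",
    "TertileClassification",
    "signature_scores",
    "fit_coupling_line",
    "project_bioscalar",
    "cohens_d",
    "roc_auc",
    "tertile_classify",
    "CoupledSignatureScorer",
]


@dataclass
class CouplingLine:
    """Least-squares line meanDOWN ~ meanUP fitted on cases."""

    slope: float
    intercept: float
    r: float          # Pearson correlation among cases
    pvalue: float     # two-sided p for the correlation
    n_cases: int


@dataclass
class TertileClassification:
    """Top-tertile cutoff classifier for the most-affected case subgroup."""

    cutoff: float
    inflamed: pd.Series        # boolean per case: bioscalar > cutoff
    sensitivity: float         # over the defining subgroup; 1.0 by construction
    specificity: float | None  # fraction of controls at or below the cutoff


def _zscore_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores (sample sd); returns (z, keep-mask of non-constant rows)."""
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    z = np.empty_like(values)
    z[keep] = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return z, keep


def signature_scores(
    study: ExpressionStudy,
    up_ids,
    down_ids,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-subject mean expression over the UP and DOWN gene lists.

    Genes are z-scored across all samples of the study before averaging
    (``standardize=False`` averages raw log2 values instead). Constant genes
    are dropped with a warning. Returns a frame indexed by sample id with
    columns ``mean_up``, ``mean_down`` and ``group``.
    """
    up = pd.Index(up_ids)
    down = pd.Index(down_ids)
    if len(up.intersection(down)):
        raise ValidationError("UP and DOWN lists must be disjoint")
    means = {}
    for label, ids in (("mean_up", up), ("mean_down", down)):
        present = study.gene_ids.intersection(ids)
        if len(present) == 0:
            raise ValidationError(f"no {label} genes present in the study")
        vals = study.expression.loc[present].to_numpy(dtype=float)
        if standardize:
            z, keep = _zscore_rows(vals)
            if not keep.any():
                raise ValidationError(f"all {label} genes are constant")
            if (~keep).any():
                logger.warning(
                    "%s: dropped %d constant genes from %s",
                    study.name, int((~keep).sum()), label,
                )
            means[label] = z[keep].mean(axis=0)
        else:
            means[label] = vals.mean(axis=0)
    out = pd.DataFrame(means, index=study.sample_ids)
    out["group"] = study.samples["group"]
    return out


def fit_coupling_line(scores: pd.DataFrame) -> CouplingLine:
    """Regress meanDOWN on meanUP over cases; report the Pearson correlation."""
    cases = scores[scores["group"] == CASE]
    if len(cases) < 3:
        raise ValidationError("need at least 3 cases to fit the coupling line")
    x = cases["mean_up"].to_numpy(float)
    y = cases["mean_down"].to_numpy(float)
    if np.isclose(x.var(ddof=1), 0.0):
        raise EstimationError("meanUP has no variance among cases; cannot fit line")
    fit = stats.linregress(x, y)
    return CouplingLine(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        pvalue=float(fit.pvalue),
        n_cases=len(cases),
    )


def project_bioscalar(scores: pd.DataFrame, line: CouplingLine) -> pd.Series:
    """Signed arc-length coordinate of each subject's projection onto the line.

    Each (meanUP, meanDOWN) point is orthogonally projected onto the coupling
    line; the bioscalar is the signed distance along the line measured from
    the line point closest to the origin, positive in the direction of
    increasing meanUP. For a line through the origin this is exactly the
    signed distance of the projected point from the origin.
    """
    m, b = line.slope, line.intercept
    norm = math.sqrt(1.0 + m * m)
    ux, uy = 1.0 / norm, m / norm              # unit direction, increasing meanUP
    x0, y0 = -m * b / (1.0 + m * m), b / (1.0 + m * m)  # foot of perpendicular from origin
    x = scores["mean_up"].to_numpy(float)
    y = scores["mean_down"].to_numpy(float)
    t = (x - x0) * ux + (y - y0) * uy
    return pd.Series(t, index=scores.index, name="bioscalar")


def cohens_d(case_values, control_values) -> float:
    """Standardised mean difference with the (n-1)-weighted pooled SD."""
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 values per group")
    pooled = math.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if pooled == 0:
        raise EstimationError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def roc_auc(scores, labels) -> float:
    """AUC as the rank statistic P(case score > control score), ties counted 1/2."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def tertile_classify(
    case_scores, control_scores=None
) -> TertileClassification:
    """Top-tertile cutoff classifier for the most-affected cases.

    The cutoff is the ceil(2n/3)-th order statistic of the case scores
    (nearest-rank convention); a case is flagged when its score is strictly
    above the cutoff, so the flagged subgroup *is* the top tertile and
    sensitivity on that subgroup is 1 by construction (computed, not
    asserted). Specificity is the fraction of controls at or below the
    cutoff.
    """
    cases = pd.Series(case_scores, dtype=float)
    if len(cases) < 3:
        raise ValidationError("need at least 3 case scores")
    n = len(cases)
    k = math.ceil(2 * n / 3)
    cutoff = float(np.sort(cases.to_numpy())[k - 1])
    inflamed = cases > cutoff
    subgroup = cases > cutoff
    sensitivity = (
        float((inflamed & subgroup).sum() / subgroup.sum()) if subgroup.any() else 1.0
    )
    specificity = None
    if control_scores is not None:
        ctrl = np.asarray(control_scores, dtype=float)
        if ctrl.size:
            specificity = float((ctrl <= cutoff).mean())
    return TertileClassification(
        cutoff=cutoff,
        inflamed=inflamed,
        sensitivity=sensitivity,
        specificity=specificity,
    )


class CoupledSignatureScorer(BaseEstimator):
    """Per-subject coupled UP/DOWN scoring with ROC and tertile summaries.

    Parameters
    ----------
    up_ids, down_ids
        Disjoint consensus gene lists (overexpressed / underexpressed in
        cases).
    standardize
        Z-score genes within the study before averaging (default); raw-scale
        averaging behind the flag.

    Attributes (after ``fit``)
    --------------------------
    scores_ : DataFrame with mean_up, mean_down, group, bioscalar per subject
    line_ : CouplingLine fitted on cases
    tertile_ : TertileClassification
    summary_ : dict with r, r_pvalue, cohens_d, auc, cutoff, sensitivity,
               specificity
    """

    def __init__(self, up_ids=(), down_ids=(), standardize: bool = True):
        self.up_ids = up_ids
        self.down_ids = down_ids
        self.standardize = standardize

    def fit(self, study: ExpressionStudy, y=None) -> "CoupledSignatureScorer":
        scores = signature_scores(
            study, self.up_ids, self.down_ids, standardize=self.standardize
        )
        self.line_ = fit_coupling_line(scores)
        scores = scores.assign(bioscalar=project_bioscalar(scores, self.line_))
        self.scores_ = scores
        case = scores.loc[scores["group"] == CASE, "bioscalar"]
        ctrl = scores.loc[scores["group"] != CASE, "bioscalar"]
        self.tertile_ = tertile_classify(case, ctrl)
        self.summary_ = {
            "r": self.line_.r,
            "r_pvalue": self.line_.pvalue,
            "cohens_d": cohens_d(case, ctrl),
            "auc": roc_auc(
                scores["bioscalar"], (scores["group"] == CASE).astype(int)
            ),
            "cutoff": self.tertile_.cutoff,
            "sensitivity": self.tertile_.sensitivity,
            "specificity": self.tertile_.specificity,
        }
        return self

    def transform(self, study: ExpressionStudy) -> pd.Series:
        """Project a (possibly different) study onto the fitted coupling line."""
        scores = signature_scores(
            study, self.up_ids, self.down_ids, standardize=self.standardize
        )
        return project_bioscalar(scores, self.line_)
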