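"""Container for one case-control expression study.

An :class:`ExpressionStudy` couples a log2 expression matrix (genes x samples)
with a per-sample covariate table (group, batch, sex, age, anxiety, optionally
BMI). All downstream stages (differential expression, signature scoring)
consume this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ValidationError

#: canonical group labels
CASE, CONTROL = "case", "control"


@dataclass
class ExpressionStudy:
    """One study's log2 expression matrix plus sample covariates.

    Parameters
    ----------
    expression
        Genes x samples data frame of log2 expression; index = gene ids,
        columns = sample ids.
    samples
        Sample table indexed by sample id with at least a ``group`` column
        taking values ``"case"``/``"control"``. Typical additional columns:
        ``batch``, ``sex``, ``age``, ``anxiety``, ``bmi``.
    name
        Short label used in logs and output file names.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    name: str = "study"

    def __post_init__(self) -> None:
        self.validate()

    # -- properties ------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def is_case(self) -> pd.Series:
        return self.samples["group"].eq(CASE)

    def case_ids(self) -> pd.Index:
        return self.samples.index[self.samples["group"] == CASE]

    def control_ids(self) -> pd.Index:
        return self.samples.index[self.samples["group"] == CONTROL]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        expr, meta = self.expression, self.samples
        if expr.index.has_duplicates:
            dup = expr.index[expr.index.duplicated()].unique().tolist()
            raise ValidationError(f"{self.name}: duplicated gene ids {dup[:5]}")
        if expr.columns.has_duplicates:
            dup = expr.columns[expr.columns.duplicated()].unique().tolist()
            raise ValidationError(f"{self.name}: duplicated sample ids {dup[:5]}")
        if meta.index.has_duplicates:
            dup = meta.index[meta.index.duplicated()].unique().tolist()
            raise ValidationError(f"{self.name}: duplicated metadata rows {dup[:5]}")
        missing = expr.columns.difference(meta.index)
        if len(missing):
            raise ValidationError(
                f"{self.name}: samples missing from metadata: {missing.tolist()[:5]}"
            )
        extra = meta.index.difference(expr.columns)
        if len(extra):
            raise ValidationError(
                f"{self.name}: metadata rows without expression: {extra.tolist()[:5]}"
            )
        if expr.isna().any().any():
            bad = expr.index[expr.isna().any(axis=1)].tolist()
            raise ValidationError(
                f"{self.name}: missing expression values in genes {bad[:5]}"
            )
        if "group" not in meta.columns:
            raise ValidationError(f"{self.name}: metadata lacks a 'group' column")
        levels = set(meta["group"].unique())
        if not levels <= {CASE, CONTROL}:
            raise ValidationError(
                f"{self.name}: unknown group labels {sorted(levels - {CASE, CONTROL})}"
            )
        if levels != {CASE, CONTROL}:
            raise ValidationError(
                f"{self.name}: both group levels required, found only {sorted(levels)}"
            )
        # canonical order: metadata rows follow the expression columns
        if not meta.index.equals(expr.columns):
            object.__setattr__(self, "samples", meta.loc[expr.columns])

    def sorted_by_gene(self) -> "ExpressionStudy":
        """Return a copy with genes sorted lexicographically by id."""
        return ExpressionStudy(
            self.expression.sort_index(), self.samples.copy(), self.name
        )
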