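"""Study tables: the rectangular unit of analysis.

A :class:`StudyTable` holds one continuous outcome (logarithmic visual
acuity on the decimal 5-point scale, roughly 4.0-5.3) and an n x s matrix
of candidate covariates (weekly exercise days, questionnaire scores).
Construction enforces the structural invariants every downstream step
assumes: complete cases only, residual degrees of freedom for the full
model, and non-degenerate covariate columns.

The intercept of the linear model is never a column here; it is handled
by mean-centering (:func:`validate_and_center`), which makes the
intercept orthogonal to every regressor so each candidate model needs
only its own covariate block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataValidationError

__all__ = ["StudyTable", "CenteringReport", "validate_and_center", "read_study_csv"]


@dataclass(frozen=True)
class CenteringReport:
    """Raw-scale means removed by centering, plus row bookkeeping.

    Keeping the original means lets reports be expressed on the raw
    questionnaire scales even though all model fitting happens on
    centered data.
    """

    outcome_mean: float
    covariate_means: dict[str, float]
    n_dropped: int = 0


@dataclass(frozen=True)
class StudyTable:
    """Outcome vector plus covariate matrix for one school stage.

    Parameters
    ----------
    outcome
        Length-n vector of right-eye logarithmic visual acuity.
    covariates
        n x s matrix of numeric risk-factor scores.
    names
        The s covariate column labels.
    stage_label
        Free-text label (e.g. ``"junior"``); carried through reports.
    n_dropped
        Rows removed by complete-case filtering before construction.
    """

    outcome: np.ndarray
    covariates: np.ndarray
    names: tuple[str, ...]
    stage_label: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        y = np.asarray(self.outcome, dtype=float)
        x = np.asarray(self.covariates, dtype=float)
        if x.ndim != 2:
            raise DataValidationError("covariates must be a 2-D matrix")
        if y.ndim != 1 or y.shape[0] != x.shape[0]:
            raise DataValidationError(
                f"outcome length {y.shape} does not match covariate rows {x.shape}"
            )
        names = tuple(str(c) for c in self.names)
        if len(names) != x.shape[1]:
            raise DataValidationError(
                f"{len(names)} names for {x.shape[1]} covariate columns"
            )
        if len(set(names)) != len(names):
            raise DataValidationError("covariate names must be unique")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(x)):
            raise DataValidationError(
                "missing or non-finite values present; drop incomplete rows "
                "before constructing a StudyTable"
            )
        n, s = x.shape
        if n <= s + 2:
            raise DataValidationError(
                f"n={n} rows is too few for s={s} covariates; need n > s + 2 "
                "so the full model keeps residual degrees of freedom"
            )
        sds = x.std(axis=0)
        for j, sd in enumerate(sds):
            if sd == 0.0:
                raise DataValidationError(
                    f"covariate column '{names[j]}' is constant (zero variance)"
                )
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "covariates", x)
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return self.outcome.shape[0]

    @property
    def s(self) -> int:
        return self.covariates.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome_column: str,
        covariate_columns: list[str] | tuple[str, ...] | None = None,
        stage_label: str = "",
    ) -> "StudyTable":
        """Build a table from a DataFrame, dropping incomplete rows.

        ``covariate_columns=None`` takes every non-outcome column. The
        number of dropped rows is recorded on the returned table.
        """
        if outcome_column not in df.columns:
            raise DataValidationError(f"outcome column '{outcome_column}' not found")
        if covariate_columns is None:
            covariate_columns = [c for c in df.columns if c != outcome_column]
        missing = [c for c in covariate_columns if c not in df.columns]
        if missing:
            raise DataValidationError(f"covariate columns not found: {missing}")
        if outcome_column in covariate_columns:
            raise DataValidationError(
                f"outcome column '{outcome_column}' cannot also be a covariate"
            )
        sub = df[[outcome_column, *covariate_columns]].apply(
            pd.to_numeric, errors="coerce"
        )
        complete = sub.dropna()
        n_dropped = len(sub) - len(complete)
        return cls(
            outcome=complete[outcome_column].to_numpy(dtype=float),
            covariates=complete[list(covariate_columns)].to_numpy(dtype=float),
            names=tuple(covariate_columns),
            stage_label=stage_label,
            n_dropped=n_dropped,
        )

    def to_dataframe(self, outcome_column: str = "acuity") -> pd.DataFrame:
        data = {outcome_column: self.outcome}
        for j, name in enumerate(self.names):
            data[name] = self.covariates[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path, outcome_column: str = "acuity") -> None:
        self.to_dataframe(outcome_column).to_csv(path, index=False)


def read_study_csv(
    path,
    outcome_column: str,
    covariate_columns: list[str] | None = None,
    stage_label: str = "",
) -> StudyTable:
    """Read a UTF-8, '.'-decimal CSV with a header row into a StudyTable."""
    df = pd.read_csv(path)
    return StudyTable.from_dataframe(
        df, outcome_column, covariate_columns, stage_label=stage_label
    )


def validate_and_center(table: StudyTable) -> tuple[StudyTable, CenteringReport]:
    """Subtract the sample mean from the outcome and every covariate.

    Centering absorbs the always-included intercept: on centered data the
    intercept's least-squares estimate is exactly zero in every candidate
    model, so model fitting can work with the covariate block alone. The
    report retains the removed means so results can be mapped back to the
    raw questionnaire scales.
    """
    y_mean = float(table.outcome.mean())
    x_means = table.covariates.mean(axis=0)
    centered = StudyTable(
        outcome=table.outcome - y_mean,
        covariates=table.covariates - x_means,
        names=table.names,
        stage_label=table.stage_label,
        n_dropped=table.n_dropped,
    )
    report = CenteringReport(
        outcome_mean=y_mean,
        covariate_means={name: float(m) for name, m in zip(table.names, x_means)},
        n_dropped=table.n_dropped,
    )
    return centered, report
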