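"""Demographic inequality modelling of chronic-pain register membership.

Fits the multivariable binary logistic regression of register membership on
categorical demographic factors — 10-year age bands, sex, within-sample
deprivation quintiles, grouped ethnicity, language preference and country of
birth — and reports adjusted odds ratios (aOR) with Wald 95% confidence
intervals from observed-information standard errors.

Missing-data handling follows the reporting conventions of register studies:
ethnicity recorded as unknown is an analysis level in its own right
(``unknown_as_level``), while covariates whose missingness has no reported
level (language, country of birth, deprivation) default to complete-case
dropping, with the drops counted in a missingness report.

The model-fitting surface is statsmodels-flavoured: build an
:class:`InequalityModel` from a cohort and a register, call ``fit()``, and
read estimates off the returned :class:`OddsRatioTable`. The maximum
likelihood fit itself is delegated to :class:`statsmodels.api.Logit`
(Newton-Raphson); this module owns the design construction, the reference
coding, the missingness policy and the reporting shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import AGE_BANDS, ETHNICITY_LEVELS

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateSpec",
    "RegressionSpec",
    "OddsRatioTable",
    "InequalityModel",
    "default_spec",
    "prepare_design",
    "fit_logistic",
    "odds_ratio_report",
]

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class CovariateSpec:
    """One categorical factor: its column, ordered levels and reference."""

    name: str
    column: str
    levels: tuple[str, ...]  # declared order, reference included
    reference: str
    missing_policy: str = "complete_case"  # or "unknown_as_level"
    unknown_level: str = "unknown"

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise ValueError(
                f"reference {self.reference!r} not among levels of {self.name!r}"
            )
        if self.missing_policy not in ("complete_case", "unknown_as_level"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass(frozen=True)
class RegressionSpec:
    """Ordered covariates plus the outcome register name."""

    outcome: str = "chronic_pain"
    covariates: tuple[CovariateSpec, ...] = ()


def default_spec() -> RegressionSpec:
    """The reported model: age, sex, deprivation, ethnicity, language, country."""
    return RegressionSpec(
        outcome="chronic_pain",
        covariates=(
            CovariateSpec("age_band", "age_band", tuple(AGE_BANDS), "18-29"),
            CovariateSpec("sex", "sex", ("male", "female"), "male"),
            CovariateSpec(
                "imd_quintile", "imd_quintile", ("1", "2", "3", "4", "5"), "1"
            ),
            CovariateSpec(
                "ethnicity",
                "ethnicity_grouped",
                tuple(ETHNICITY_LEVELS),
                "White",
                missing_policy="unknown_as_level",
            ),
            CovariateSpec(
                "language", "language_preference", ("English", "non-English"), "English"
            ),
            CovariateSpec("country", "country_of_birth", ("UK", "non-UK"), "UK"),
        ),
    )


@dataclass
class OddsRatioTable:
    """Fitted adjusted odds ratios with 95% CIs and fit diagnostics.

    ``frame`` has one row per non-reference level: columns ``covariate``,
    ``level``, ``coef``, ``se``, ``aor``, ``ci_low``, ``ci_high``. Reference
    levels carry aOR 1 implicitly and appear only in the formatted report.
    """

    frame: pd.DataFrame
    n_used: int
    n_dropped_missing: int
    missingness: dict[str, int] = field(default_factory=dict)
    converged: bool = True
    llf: float = float("nan")

    def aor(self, covariate: str, level: str) -> float:
        rows = self.frame[
            (self.frame["covariate"] == covariate) & (self.frame["level"] == level)
        ]
        if rows.empty:
            raise KeyError(f"no fitted level {covariate!r}={level!r}")
        return float(rows["aor"].iloc[0])

    def ci(self, covariate: str, level: str) -> tuple[float, float]:
        rows = self.frame[
            (self.frame["covariate"] == covariate) & (self.frame["level"] == level)
        ]
        if rows.empty:
            raise KeyError(f"no fitted level {covariate!r}={level!r}")
        return float(rows["ci_low"].iloc[0]), float(rows["ci_high"].iloc[0])

    def summary(self) -> pd.DataFrame:
        return odds_ratio_report(self)


def prepare_design(
    cohort: pd.DataFrame,
    register: pd.DataFrame,
    spec: RegressionSpec | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Design matrix, outcome vector and missingness report.

    One indicator column per declared non-reference level that is observed;
    rows missing a complete-case covariate are dropped and counted. The
    outcome is the register's ``on_register`` flag aligned on ``patient_id``.
    """
    spec = spec or default_spec()
    df = cohort.merge(
        register[["patient_id", "on_register"]], on="patient_id", how="inner"
    )

    missingness: dict[str, int] = {}
    keep = pd.Series(True, index=df.index)
    prepared: dict[str, pd.Series] = {}
    for cov in spec.covariates:
        series = df[cov.column]
        if isinstance(series.dtype, pd.CategoricalDtype):
            series = series.astype(object)
        series = series.map(lambda v: str(v) if pd.notna(v) else np.nan)
        missing = series.isna()
        missingness[cov.name] = int(missing.sum())
        if cov.missing_policy == "unknown_as_level":
            series = series.where(~missing, cov.unknown_level)
        else:
            keep &= ~missing
        prepared[cov.name] = series

    n_dropped = int((~keep).sum())
    df = df[keep]
    prepared = {name: s[keep] for name, s in prepared.items()}

    y = df["on_register"].astype(int)
    y.index = df.index
    if y.nunique() < 2:
        raise ValueError("outcome is constant after missing-data handling; cannot fit")

    columns: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    meta: list[tuple[str, str]] = []
    for cov in spec.covariates:
        series = prepared[cov.name]
        observed = set(series.unique())
        for level in cov.levels:
            if level == cov.reference:
                continue
            if level not in observed:
                logger.warning(
                    "level %r of %s unobserved; column omitted", level, cov.name
                )
                continue
            columns[f"{cov.name}[{level}]"] = (series == level).to_numpy(float)
            meta.append((cov.name, level))

    X = pd.DataFrame(columns, index=df.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient ({rank} < {X.shape[1]}); "
            "perfectly collinear covariate levels"
        )
    report = {
        "n_used": int(len(df)),
        "n_dropped_missing": n_dropped,
        "missing_by_covariate": missingness,
        "terms": meta,
    }
    return X, y, report


def fit_logistic(
    X: pd.DataFrame, y: pd.Series, report: dict | None = None
) -> OddsRatioTable:
    """Maximum-likelihood logistic fit with Wald 95% CIs.

    Newton-Raphson via statsmodels ``Logit``; convergence requires a score
    norm below 1e-8 within 100 iterations, otherwise an error is raised with
    diagnostics. Standard errors come from the observed information matrix;
    CIs are exp(coef +/- 1.959964 * SE).
    """
    report = report or {"n_used": int(len(y)), "n_dropped_missing": 0,
                        "missing_by_covariate": {}, "terms": None}
    model = sm.Logit(np.asarray(y), X)
    try:
        res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-12)
    except np.linalg.LinAlgError as exc:  # singular information matrix
        raise ValueError(
            "logistic fit failed (singular information matrix); check for "
            "separation or collinearity — penalised fitting is out of scope"
        ) from exc
    score_norm = float(np.linalg.norm(model.score(res.params)))
    if not res.mle_retvals.get("converged", False) or score_norm > 1e-8:
        raise ValueError(
            f"logistic fit did not converge (score norm {score_norm:.3e} after "
            f"{res.mle_retvals.get('iterations', '?')} iterations)"
        )
    if np.any(np.abs(res.params) > 15):
        raise ValueError(
            "implausibly large coefficient suggests separation; penalised "
            "fitting is out of scope"
        )

    terms = report.get("terms")
    if terms is None:
        terms = [_parse_term(c) for c in X.columns if c != "const"]
    rows = []
    for (cov, level), name in zip(terms, [c for c in X.columns if c != "const"]):
        coef = float(res.params[name])
        se = float(res.bse[name])
        rows.append(
            {
                "covariate": cov,
                "level": level,
                "coef": coef,
                "se": se,
                "aor": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - Z_95 * se)),
                "ci_high": float(np.exp(coef + Z_95 * se)),
            }
        )
    return OddsRatioTable(
        frame=pd.DataFrame(rows),
        n_used=report["n_used"],
        n_dropped_missing=report["n_dropped_missing"],
        missingness=report.get("missing_by_covariate", {}),
        converged=True,
        llf=float(res.llf),
    )


def _parse_term(column: str) -> tuple[str, str]:
    cov, _, rest = column.partition("[")
    return cov, rest.rstrip("]")


def odds_ratio_report(
    table: OddsRatioTable, spec: RegressionSpec | None = None
) -> pd.DataFrame:
    """Reporting-shaped table: one row per level, references labelled.

    aORs and CI bounds are formatted to two decimal places, rows ordered as
    the covariates were declared, each reference level printed as
    ``REFERENCE GROUP``.
    """
    spec = spec or default_spec()
    rows = []
    fitted = {(r["covariate"], r["level"]): r for _, r in table.frame.iterrows()}
    for cov in spec.covariates:
        for level in cov.levels:
            if level == cov.reference:
                rows.append(
                    {
                        "covariate": cov.name,
                        "level": level,
                        "adjusted_odds_ratio": "REFERENCE GROUP",
                        "ci_95": "",
                    }
                )
            elif (cov.name, level) in fitted:
                r = fitted[(cov.name, level)]
                rows.append(
                    {
                        "covariate": cov.name,
                        "level": level,
                        "adjusted_odds_ratio": f"{r['aor']:.2f}",
                        "ci_95": f"{r['ci_low']:.2f} to {r['ci_high']:.2f}",
                    }
                )
        # unknown-as-level rows not in the declared levels (e.g. ethnicity
        # handled explicitly via its own level list) are already covered
    return pd.DataFrame(rows)


class InequalityModel:
    """statsmodels-style front door: construct from data, ``fit()`` for results."""

    def __init__(
        self,
        cohort: pd.DataFrame,
        register: pd.DataFrame,
        spec: RegressionSpec | None = None,
    ) -> None:
        self.spec = spec or default_spec()
        self.X, self.y, self.report = prepare_design(cohort, register, self.spec)

    @classmethod
    def from_dataframes(
        cls, cohort: pd.DataFrame, register: pd.DataFrame, **kwargs
    ) -> "InequalityModel":
        return cls(cohort, register, **kwargs)

    def fit(self) -> OddsRatioTable:
        return fit_logistic(self.X, self.y, self.report)
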