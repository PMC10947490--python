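"""Sex-stratified regression of body composition on activity metrics.

The analysis asks whether activity volume (average-acceleration) and the
intensity distribution (intensity-gradient) are independently associated
with bone mineral content, lean mass and fat mass in children, via an
incremental sequence of ordinary-least-squares models fit separately in
females and males:

* Model 1 — one activity metric at a time, adjusted for age, stature,
  pubertal status and accelerometer wear time;
* Model 2 — both activity metrics together;
* Model 3 — plus their interaction (computed from mean-centred scores);
* Models 4/5/6 — Model 3 plus lean mass, fat mass, or both (for bone
  outcomes).  For lean mass as outcome the final model adjusts for fat
  mass (Model 5); for fat mass, for lean mass (Model 4).

With MVPA as the exposure the same sequence applies with a single
activity term and no alternate-metric or interaction steps.
Unstandardised coefficients, t-based 95% CIs and two-sided p-values are
reported; activity variables are mean-centred within sex before entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_COVARIATES = ("age", "stature", "pubertal", "wear_time_h")

GROUP_LABELS = (
    "low-vol/low-int",
    "low-vol/high-int",
    "high-vol/low-int",
    "high-vol/high-int",
)


def mean_centre(values, return_mean=True):
    """Centre a vector on its mean; the mean is returned for reporting."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("cannot centre an empty vector")
    m = values.mean()
    return (values - m, float(m)) if return_mean else values - m


def _outcome_kind(outcome: str) -> str:
    name = outcome.lower()
    if "lean" in name:
        return "lean"
    if "fat" in name:
        return "fat"
    return "bmc"


def _check_rank(X: pd.DataFrame):
    """Raise naming the collinear columns if the design is rank-deficient."""
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    culprits, cols = [], []
    for j, name in enumerate(X.columns):
        cols.append(j)
        if np.linalg.matrix_rank(arr[:, cols]) < len(cols):
            culprits.append(name)
            cols.pop()
    raise ValueError(f"rank-deficient design: collinear terms {culprits}")


@dataclass
class ModelResult:
    """One fitted model of the sequence."""

    model_index: int
    outcome: str
    sex: str
    exposure_set: str
    terms: pd.DataFrame  # term, beta, ci_lo, ci_hi, p
    n: int
    activity_variable: str | None = None  # set for the Model-1 single fits

    def coef(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "beta"])

    def ci(self, term: str):
        row = self.terms.set_index("term").loc[term]
        return float(row["ci_lo"]), float(row["ci_hi"])

    def pvalue(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "p"])

    @property
    def term_names(self):
        return [t for t in self.terms["term"] if t != "intercept"]


@dataclass
class ModelSequenceResults:
    """Results of the full model sequence for one outcome and stratum."""

    outcome: str
    sex: str
    exposure_set: str
    results: list = field(default_factory=list)
    exposure_means: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.results)

    def model(self, index: int, activity_variable: str | None = None) -> ModelResult:
        for r in self.results:
            if r.model_index == index and (
                activity_variable is None or r.activity_variable == activity_variable
            ):
                return r
        raise KeyError(f"no model {index} ({activity_variable}) in sequence")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            for _, t in r.terms.iterrows():
                rows.append(
                    {
                        "stratum": r.sex,
                        "outcome": r.outcome,
                        "exposure_set": r.exposure_set,
                        "model": r.model_index,
                        "activity_variable": r.activity_variable,
                        "term": t["term"],
                        "beta": t["beta"],
                        "ci_lo": t["ci_lo"],
                        "ci_hi": t["ci_hi"],
                        "p": t["p"],
                        "n": r.n,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Outcome: {self.outcome}   stratum: {self.sex}   "
            f"exposures: {self.exposure_set}",
            "=" * 78,
        ]
        for r in self.results:
            tag = f" [{r.activity_variable}]" if r.activity_variable else ""
            lines.append(f"Model {r.model_index}{tag}  (n = {r.n})")
            lines.append(
                f"  {'term':<22}{'beta':>12}{'95% CI':>26}{'p':>10}"
            )
            for _, t in r.terms.iterrows():
                ci = f"({t['ci_lo']:.3f} to {t['ci_hi']:.3f})"
                lines.append(
                    f"  {t['term']:<22}{t['beta']:>12.4f}{ci:>26}{t['p']:>10.4f}"
                )
            lines.append("-" * 78)
        return "\n".join(lines)


class BodyCompositionModel:
    """Incremental OLS sequence linking activity metrics to one outcome.

    Parameters
    ----------
    data : pandas.DataFrame
        Cohort table with covariates, exposures and outcomes.
    outcome : str
        Outcome column (kg).  Names containing ``lean``/``fat`` select
        the shortened sequences; anything else is treated as a bone
        outcome getting the full Models 1-6.
    sex : str
        Stratum to fit (value of the sex column).
    exposure_set : {"volume_intensity", "mvpa"}
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        sex: str,
        exposure_set: str = "volume_intensity",
        volume_col: str = "average_acceleration",
        intensity_col: str = "intensity_gradient",
        mvpa_col: str = "mvpa_min_day",
        covariates=DEFAULT_COVARIATES,
        lean_col: str = "lean_kg",
        fat_col: str = "fat_kg",
        sex_col: str = "sex",
    ):
        if exposure_set not in ("volume_intensity", "mvpa"):
            raise ValueError("exposure_set must be 'volume_intensity' or 'mvpa'")
        stratum = data[data[sex_col] == sex]
        if len(stratum) == 0:
            raise ValueError(f"empty stratum: no subjects with {sex_col} == {sex!r}")

        exposures = (
            [volume_col, intensity_col] if exposure_set == "volume_intensity" else [mvpa_col]
        )
        kind = _outcome_kind(outcome)
        body_cols = {"lean": lean_col, "fat": fat_col}
        needed = set(exposures) | set(covariates) | {outcome}
        if kind == "bmc":
            needed |= {lean_col, fat_col}
        elif kind == "lean":
            needed |= {fat_col}
        else:
            needed |= {lean_col}
        stratum = stratum.dropna(subset=sorted(needed))  # complete-case
        if len(stratum) == 0:
            raise ValueError("empty stratum after complete-case filtering")

        self.data = stratum.reset_index(drop=True)
        self.outcome = outcome
        self.sex = sex
        self.exposure_set = exposure_set
        self.exposures = exposures
        self.covariates = list(covariates)
        self.kind = kind
        self.body_cols = body_cols

    @classmethod
    def from_dataframe(cls, data, outcome, sex, **kwargs):
        return cls(data, outcome, sex, **kwargs)

    # -- design construction -------------------------------------------------

    def _design_base(self):
        """Centred exposures plus covariates; returns (frame, means)."""
        X = pd.DataFrame(index=self.data.index)
        means = {}
        for col in self.exposures:
            centred, m = mean_centre(self.data[col])
            X[col] = centred
            means[col] = m
        if len(self.exposures) == 2:
            X["x".join(self.exposures)] = X[self.exposures[0]] * X[self.exposures[1]]
        for cov in self.covariates:
            X[cov] = self.data[cov].to_numpy(dtype=float)
        for col in set(self.body_cols.values()):
            if col in self.data.columns and col != self.outcome and col not in X:
                X[col] = self.data[col].to_numpy(dtype=float)
        return X, means

    def _fit_one(self, model_index, columns, X_full, activity_variable=None) -> ModelResult:
        X = X_full[columns].copy()
        y = self.data[self.outcome].to_numpy(dtype=float)
        if len(y) <= len(columns) + 1:
            raise ValueError(
                f"stratum too small (n={len(y)}) for {len(columns) + 1} terms"
            )
        _check_rank(sm.add_constant(X))
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        ci = fit.conf_int(alpha=0.05)
        terms = pd.DataFrame(
            {
                "term": ["intercept"] + list(columns),
                "beta": fit.params.to_numpy(),
                "ci_lo": ci[0].to_numpy(),
                "ci_hi": ci[1].to_numpy(),
                "p": fit.pvalues.to_numpy(),
            }
        )
        return ModelResult(
            model_index=model_index,
            outcome=self.outcome,
            sex=self.sex,
            exposure_set=self.exposure_set,
            terms=terms,
            n=int(len(y)),
            activity_variable=activity_variable,
        )

    def _sequence_columns(self):
        """Yield (model_index, columns, activity_variable) per fit."""
        lean, fat = self.body_cols["lean"], self.body_cols["fat"]
        covs = self.covariates
        if self.exposure_set == "volume_intensity":
            vol, inten = self.exposures
            inter = f"{vol}x{inten}"
            m3 = [vol, inten, inter] + covs
            yield 1, [vol] + covs, vol
            yield 1, [inten] + covs, inten
            yield 2, [vol, inten] + covs, None
            yield 3, m3, None
            if self.kind == "bmc":
                yield 4, m3 + [lean], None
                yield 5, m3 + [fat], None
                yield 6, m3 + [lean, fat], None
            elif self.kind == "lean":
                yield 5, m3 + [fat], None
            else:  # fat outcome
                yield 4, m3 + [lean], None
        else:
            (mvpa,) = self.exposures
            m1 = [mvpa] + covs
            yield 1, m1, mvpa
            if self.kind == "bmc":
                yield 4, m1 + [lean], None
                yield 5, m1 + [fat], None
                yield 6, m1 + [lean, fat], None
            elif self.kind == "lean":
                yield 5, m1 + [fat], None
            else:
                yield 4, m1 + [lean], None

    def fit(self) -> ModelSequenceResults:
        X, means = self._design_base()
        out = ModelSequenceResults(
            outcome=self.outcome,
            sex=self.sex,
            exposure_set=self.exposure_set,
            exposure_means=means,
        )
        for idx, cols, act in self._sequence_columns():
            out.results.append(self._fit_one(idx, cols, X, act))
        return out


def fit_model_sequence(
    table: pd.DataFrame, outcome: str, exposure_set: str, sex: str, **kwargs
) -> ModelSequenceResults:
    """Functional entry point over :class:`BodyCompositionModel`."""
    return BodyCompositionModel(
        table, outcome, sex, exposure_set=exposure_set, **kwargs
    ).fit()


# -- descriptive stratification and group summaries --------------------------


def stratify_groups(
    table: pd.DataFrame,
    sex: str,
    volume_col: str = "average_acceleration",
    intensity_col: str = "intensity_gradient",
    sex_col: str = "sex",
) -> pd.Series:
    """Assign each subject of a sex stratum to one of four volume x
    intensity groups split at the sex-specific means (>= mean is high)."""
    stratum = table[table[sex_col] == sex]
    if len(stratum) == 0:
        raise ValueError(f"empty stratum: {sex}")
    vol_mean = stratum[volume_col].mean()
    int_mean = stratum[intensity_col].mean()
    hi_vol = stratum[volume_col] >= vol_mean
    hi_int = stratum[intensity_col] >= int_mean
    labels = np.select(
        [~hi_vol & ~hi_int, ~hi_vol & hi_int, hi_vol & ~hi_int],
        GROUP_LABELS[:3],
        default=GROUP_LABELS[3],
    )
    return pd.Series(labels, index=stratum.index, name="group")


def group_mx_summary(
    table: pd.DataFrame, assignment: pd.Series, mx_columns=None
) -> pd.DataFrame:
    """Per-group mean and SEM of each M_X, raw and sex-standardized.

    Standardized values divide by the sex-specific overall mean of each
    M_X.  Groups with a single subject get an undefined (NaN) SEM; empty
    groups are simply absent from the output.
    """
    sub = table.loc[assignment.index]
    if mx_columns is None:
        mx_columns = [c for c in sub.columns if c.startswith("m") and c[1:].isdigit()]
    overall = sub[mx_columns].mean()
    rows = []
    for group, chunk in sub.groupby(assignment):
        n = len(chunk)
        for col in mx_columns:
            vals = chunk[col].to_numpy(dtype=float)
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append(
                {
                    "group": group,
                    "x": int(col[1:]),
                    "n": n,
                    "raw_mean": float(vals.mean()),
                    "raw_sem": sem,
                    "std_mean": float(vals.mean() / overall[col]),
                    "std_sem": sem / float(overall[col]) if n > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows).sort_values(["group", "x"]).reset_index(drop=True)
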