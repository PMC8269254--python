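"""Composite metabolic disease score.

Seven fasting blood markers (triglycerides, glucose, insulin, LDL, HDL,
leptin, adiponectin) are z-scored and their first principal component,
oriented so that triglycerides load positively, is shifted to a minimum of 1
on the fitting panel and natural-log transformed:

    score_i = ln( s_i - min_j s_j + 1 ),   s = oriented PC1 coordinates.

High scores indicate dyslipidemia (high triglycerides, low HDL) and insulin
resistance (high fasting glucose and insulin); the minimum subject of the
fitting panel scores exactly 0. An impairment cutoff is derived by
regressing the score on each of the four markers with well-defined clinical
thresholds (triglycerides, glucose, HDL, LDL), evaluating each regression at
its threshold, and averaging the four intersections; the study-scale value
of that average is 1.4. Subjects strictly above the cutoff are classified
metabolically impaired.

The model may be fitted on a reference panel larger than the analysis
cohort; new subjects below the fitting panel's minimum legitimately score
below 0 and are not clamped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from metsynth.exceptions import DegenerateDataError, SchemaError
from metsynth.synthetic import MARKERS

#: clinical thresholds used to anchor the impairment cutoff. Triglycerides
#: >200 mg/dl is the printed unhealthy bound; glucose >100 mg/dl (impaired
#: fasting glucose), HDL <40 mg/dl and LDL >160 mg/dl are the conventional
#: values. ``direction`` is the unhealthy side of the threshold.
DEFAULT_CLINICAL_THRESHOLDS: Mapping[str, tuple[float, str]] = {
    "triglycerides": (200.0, "high"),
    "glucose": (100.0, "high"),
    "hdl": (40.0, "low"),
    "ldl": (160.0, "high"),
}

DEFAULT_CUTOFF = 1.4


class MetabolicScoreModel:
    """PCA-based composite score model over a subject x marker panel.

    Parameters
    ----------
    markers : DataFrame
        Subject x marker panel containing the seven marker columns; extra
        columns are ignored. At least 3 subjects, no missing values.
    """

    def __init__(self, markers: pd.DataFrame):
        missing = [m for m in MARKERS if m not in markers.columns]
        if missing:
            raise SchemaError(f"marker panel missing columns: {missing}")
        panel = markers.loc[:, list(MARKERS)].astype(float)
        if panel.isna().any().any():
            raise SchemaError("marker panel contains missing values")
        if (panel.to_numpy() < 0).any() or not np.isfinite(panel.to_numpy()).all():
            raise SchemaError("marker values must be finite and >= 0")
        if len(panel) < 3:
            raise DegenerateDataError("need >= 3 subjects to fit the score model")
        self.markers = panel

    def fit(self) -> "MetabolicScoreResults":
        X = self.markers.to_numpy()
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        if np.any(scale <= 0):
            bad = [m for m, s in zip(MARKERS, scale) if s <= 0]
            raise DegenerateDataError(f"constant marker column(s): {bad}")
        Z = (X - center) / scale
        # PC1 of the covariance of the scaled matrix
        cov = np.cov(Z, rowvar=False, ddof=1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        loadings = eigvecs[:, -1]
        orientation = 1.0 if loadings[MARKERS.index("triglycerides")] >= 0 else -1.0
        pc1 = orientation * (Z @ loadings)
        min_pc1 = float(pc1.min())
        return MetabolicScoreResults(
            model=self,
            center=pd.Series(center, index=MARKERS),
            scale=pd.Series(scale, index=MARKERS),
            loadings=pd.Series(loadings, index=MARKERS),
            orientation=orientation,
            min_pc1=min_pc1,
            explained_fraction=float(eigvals[-1] / eigvals.sum()),
        )


@dataclass
class MetabolicScoreResults:
    """Fitted score transform: center/scale vectors, oriented PC1 loadings,
    shift constant and the impairment cutoff (default-populated with 1.4,
    replaceable by :meth:`derive_cutoff`)."""

    model: MetabolicScoreModel | None
    center: pd.Series
    scale: pd.Series
    loadings: pd.Series
    orientation: float
    min_pc1: float
    explained_fraction: float = float("nan")
    log_base: str = "e"
    cutoff: float = DEFAULT_CUTOFF
    clinical_thresholds: Mapping[str, tuple[float, str]] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_THRESHOLDS))

    @property
    def shift(self) -> float:
        """Additive shift so the fitting panel's minimal PC1 maps to 1."""
        return 1.0 - self.min_pc1

    def pc1(self, markers: pd.DataFrame | None = None) -> pd.Series:
        if markers is None:
            markers = self.model.markers
        missing = [m for m in MARKERS if m not in markers.columns]
        if missing:
            raise SchemaError(f"marker panel missing columns: {missing}")
        Z = (markers.loc[:, list(MARKERS)].astype(float) - self.center) / self.scale
        return self.orientation * (Z @ self.loadings)

    def score(self, markers: pd.DataFrame | None = None) -> pd.Series:
        """ln(PC1 - min_fit + 1); exact 0 at the fitting panel's minimum."""
        pc1 = self.pc1(markers)
        shifted = pc1 - self.min_pc1 + 1.0
        if (shifted <= 0).any():
            n_bad = int((shifted <= 0).sum())
            raise DegenerateDataError(
                f"{n_bad} subject(s) fall so far below the fitting panel that "
                "the shifted PC1 is non-positive")
        out = np.log(shifted)
        if (out < 0).any():
            warnings.warn(f"{int((out < 0).sum())} subject(s) score below 0 "
                          "(below the fitting panel's minimum); not clamped")
        return pd.Series(out, index=pc1.index, name="score")

    def classify(self, markers: pd.DataFrame | None = None,
                 cutoff: float | None = None) -> pd.DataFrame:
        """Subject table with score and class in {normal, impaired}."""
        cutoff = self.cutoff if cutoff is None else cutoff
        s = self.score(markers)
        return pd.DataFrame({
            "score": s,
            "class": np.where(s > cutoff, "impaired", "normal"),
        }, index=s.index)

    def derive_cutoff(self, markers: pd.DataFrame | None = None,
                      clinical_thresholds: Mapping[str, tuple[float, str]] | None = None,
                      update: bool = True) -> float:
        """Impairment cutoff from the four clinically anchored regressions.

        For each marker with a clinical threshold, fit OLS score ~ marker and
        evaluate the fitted score at the threshold; the cutoff is the mean of
        the four evaluated scores.
        """
        thresholds = dict(clinical_thresholds or self.clinical_thresholds)
        markers_df = self.model.markers if markers is None else markers
        for name in thresholds:
            if name not in markers_df.columns:
                raise SchemaError(f"threshold marker {name} missing from panel")
        s = self.score(markers_df).to_numpy()
        intersections = []
        for name, (threshold, _direction) in thresholds.items():
            x = markers_df[name].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise DegenerateDataError(f"zero-variance marker {name}")
            res = sm.OLS(s, sm.add_constant(x)).fit()
            intersections.append(float(res.params[0] + res.params[1] * threshold))
        cutoff = float(np.mean(intersections))
        if update:
            self.cutoff = cutoff
        return cutoff

    def summary(self) -> str:
        lines = ["Metabolic disease score model",
                 "=" * 34,
                 f"fitting panel n: {len(self.model.markers) if self.model else 'n/a'}",
                 f"PC1 variance fraction: {self.explained_fraction:.3f}",
                 f"shift: {self.shift:.4f}  log base: {self.log_base}",
                 f"impairment cutoff: {self.cutoff:.3f}",
                 "", "oriented loadings (triglycerides positive):"]
        for m in MARKERS:
            lines.append(f"  {m:<14} {self.orientation * self.loadings[m]:+.4f}")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "center": self.center.tolist(), "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(), "orientation": self.orientation,
            "min_pc1": self.min_pc1, "shift": self.shift, "log_base": self.log_base,
            "cutoff": self.cutoff,
            "clinical_thresholds": {k: list(v) for k, v in self.clinical_thresholds.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MetabolicScoreResults":
        d = json.loads(Path(path).read_text())
        return cls(model=None,
                   center=pd.Series(d["center"], index=MARKERS),
                   scale=pd.Series(d["scale"], index=MARKERS),
                   loadings=pd.Series(d["loadings"], index=MARKERS),
                   orientation=d["orientation"], min_pc1=d["min_pc1"],
                   log_base=d["log_base"], cutoff=d["cutoff"],
                   clinical_thresholds={k: tuple(v) for k, v
                                        in d["clinical_thresholds"].items()})


def age_cohort_model(scores: pd.Series, age: pd.Series, cohort: pd.Series,
                     reference: str | None = None) -> pd.DataFrame:
    """OLS fit of score ~ age + cohort + age x cohort with treatment coding.

    Returns a table with one row per cohort carrying that cohort's age slope
    (reference slope plus interaction), its standard error and two-sided
    p-value, so per-cohort claims about the age association are expressible.
    """
    df = pd.DataFrame({"score": scores, "age": age, "cohort": cohort}).dropna()
    levels = list(pd.unique(df["cohort"]))
    if len(levels) < 2:
        raise DegenerateDataError("need >= 2 cohorts")
    if (df.groupby("cohort").size() < 3).any():
        raise DegenerateDataError("need >= 3 subjects per cohort")
    reference = reference or levels[0]
    res = smf.ols(
        f"score ~ age * C(cohort, Treatment(reference={reference!r}))", data=df).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise DegenerateDataError("rank-deficient design")

    rows = []
    names = list(res.params.index)
    for level in levels:
        contrast = np.zeros(len(names))
        contrast[names.index("age")] = 1.0
        if level != reference:
            inter = (f"age:C(cohort, Treatment(reference={reference!r}))"
                     f"[T.{level}]")
            contrast[names.index(inter)] = 1.0
        tt = res.t_test(contrast)
        rows.append({"cohort": level,
                     "age_slope": float(np.ravel(tt.effect)[0]),
                     "se": float(np.ravel(tt.sd)[0]),
                     "p": float(np.ravel(tt.pvalue)[0])})
    table = pd.DataFrame(rows).set_index("cohort")
    table.attrs["ols_results"] = res
    return table
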