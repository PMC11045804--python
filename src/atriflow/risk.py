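"""Merge hemodynamic medians with functional metrics and fit per-pair
logistic separations.

"Separation" of a (functional metric, hemodynamic median) pair means the
probability-1/2 line of a lightly L2-penalized two-covariate logistic fit
classifies every case correctly.  The small ridge penalty keeps the
maximum-likelihood problem finite under complete separation (n is small)
without moving the boundary in the separable limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError

__all__ = [
    "SeparationResult", "assemble_cohort_table", "fit_separation",
    "correlation_matrix", "normalize_features",
    "DEFAULT_FEATURES", "DEFAULT_METRICS",
]

DEFAULT_FEATURES = {
    "LA": ["la_fs", "la_tawss", "la_osi", "la_rrt", "la_ecap",
           "la_vort_e", "la_vort_a", "la_vort_sys"],
    "LAA": ["laa_fs", "laa_tawss", "laa_osi", "laa_rrt", "laa_ecap",
            "laa_vort_e", "laa_vort_a", "laa_vort_sys"],
}
DEFAULT_METRICS = {
    "LA": ["v_max", "v_min", "sv", "ef", "bpm"],
    "LAA": ["v_max", "v_min", "sv", "ef", "bpm", "tortuosity", "ostium_area"],
}


@dataclass
class SeparationResult:
    x_name: str
    y_name: str
    intercept: float
    slope_x: float         # on standardized x
    slope_y: float         # on standardized y
    x_center: float
    x_scale: float
    y_center: float
    y_scale: float
    penalty_weight: float
    separated: bool
    misclassified_ids: list = field(default_factory=list)

    def boundary_xy(self, x_values):
        """y of the probability-1/2 line at given raw x (needs slope_y != 0)."""
        if self.slope_y == 0:
            raise ZeroDivisionError("boundary is vertical (slope_y = 0)")
        xs = (np.asarray(x_values) - self.x_center) / self.x_scale
        ys = -(self.intercept + self.slope_x * xs) / self.slope_y
        return ys * self.y_scale + self.y_center

    def decision_values(self, x, y):
        xs = (np.asarray(x) - self.x_center) / self.x_scale
        ys = (np.asarray(y) - self.y_center) / self.y_scale
        return self.intercept + self.slope_x * xs + self.slope_y * ys


def assemble_cohort_table(cases: list[dict]) -> pd.DataFrame:
    """Rectangular cohort table, one row per case.

    Each case is a flat dict that must contain ``case_id`` and ``group``;
    all other keys become columns.  Duplicate ids are rejected.
    """
    base_cols = ["case_id", "group"]
    if not cases:
        return pd.DataFrame(columns=base_cols)
    df = pd.DataFrame(cases)
    for col in base_cols:
        if col not in df.columns:
            raise ValueError(f"case records must carry a '{col}' field")
    if df["case_id"].duplicated().any():
        dups = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case ids: {dups}")
    if df["group"].isna().any():
        raise ValueError("missing group labels")
    ordered = base_cols + [c for c in df.columns if c not in base_cols]
    return df[ordered].reset_index(drop=True)


def _standardize(v: np.ndarray):
    c = float(v.mean())
    s = float(v.std())
    if s == 0.0:
        s = 1.0
    return (v - c) / s, c, s


def fit_separation(
    table: pd.DataFrame, x_name: str, y_name: str, penalty_weight: float = 1e-4,
    max_iter: int = 200, grad_tol: float = 1e-8,
) -> SeparationResult:
    """Two-covariate penalized logistic fit of group against (x, y).

    Covariates are standardized; slopes carry an L2 penalty of weight
    ``penalty_weight``; Newton/IRLS iterates until the penalized gradient
    norm drops below ``grad_tol``.
    """
    y_lab = np.asarray(table["group"])
    groups = set(y_lab.tolist())
    if len(groups) < 2:
        raise DegenerateDataError("both groups must be present to fit a separation")
    t = (y_lab == "stroke").astype(float)
    xv = np.asarray(table[x_name], dtype=float)
    yv = np.asarray(table[y_name], dtype=float)
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError(f"non-finite covariates in ({x_name}, {y_name})")

    xs, xc, xsc = _standardize(xv)
    ys, yc, ysc = _standardize(yv)
    X = np.column_stack([np.ones_like(xs), xs, ys])
    lam = np.diag([0.0, penalty_weight, penalty_weight])

    beta = np.zeros(3)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        g = X.T @ (p - t) + lam @ beta
        if np.linalg.norm(g) < grad_tol:
            break
        w = np.maximum(p * (1 - p), 1e-12)
        H = (X * w[:, None]).T @ X + lam
        beta -= np.linalg.solve(H, g)
    else:
        eta = X @ beta
        g = X.T @ (1.0 / (1.0 + np.exp(-eta)) - t) + lam @ beta
        if np.linalg.norm(g) > 1e-4:
            raise DegenerateDataError("logistic fit did not converge")

    decision = X @ beta
    pred = decision > 0
    mis = np.nonzero(pred != (t > 0.5))[0]
    ids = (
        table["case_id"].iloc[mis].tolist()
        if "case_id" in table.columns else mis.tolist()
    )
    return SeparationResult(
        x_name=x_name, y_name=y_name,
        intercept=float(beta[0]), slope_x=float(beta[1]), slope_y=float(beta[2]),
        x_center=xc, x_scale=xsc, y_center=yc, y_scale=ysc,
        penalty_weight=penalty_weight, separated=len(mis) == 0,
        misclassified_ids=ids,
    )


def correlation_matrix(
    table: pd.DataFrame, feature_cols=None, metric_cols=None, region: str = "LA",
    penalty_weight: float = 1e-4,
) -> pd.DataFrame:
    """Separated/not-separated flags for every (feature, metric) pair.

    Rows are hemodynamic medians, columns functional metrics; a cell is
    True when the fitted probability-1/2 line classifies all cases
    correctly (the analog of a green cell in a correlation table).
    """
    if feature_cols is None:
        feature_cols = [c for c in DEFAULT_FEATURES[region] if c in table.columns]
    if metric_cols is None:
        metric_cols = [c for c in DEFAULT_METRICS[region] if c in table.columns]
    # drop pairs with missing data (e.g. undetectable E/A waves leave the
    # phase-gated vorticity medians unset for some cases)
    feature_cols = [c for c in feature_cols
                    if np.isfinite(np.asarray(table[c], dtype=float)).all()]
    metric_cols = [c for c in metric_cols
                   if np.isfinite(np.asarray(table[c], dtype=float)).all()]
    out = pd.DataFrame(index=feature_cols, columns=metric_cols, dtype=bool)
    for f in feature_cols:
        for m in metric_cols:
            out.loc[f, m] = fit_separation(table, m, f, penalty_weight).separated
    return out


def normalize_features(table: pd.DataFrame, denominator_name: str,
                       feature_cols=None) -> pd.DataFrame:
    """Append ratio columns feature / functional-denominator.

    Rows with a zero denominator get NaN in the ratio columns; original
    columns are untouched.
    """
    if feature_cols is None:
        feature_cols = [
            c for cols in DEFAULT_FEATURES.values() for c in cols if c in table.columns
        ]
    den = np.asarray(table[denominator_name], dtype=float)
    out = table.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for c in feature_cols:
            ratio = np.asarray(table[c], dtype=float) / den
            ratio[den == 0] = np.nan
            out[f"{c}_per_{denominator_name}"] = ratio
    return out
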