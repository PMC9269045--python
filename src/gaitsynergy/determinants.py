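"""Kinematic determinants of gait synergy: collinearity screen + stepwise OLS.

A CRP deviation summary (degrees) is regressed on candidate gait
kinematics — stance/swing decomposition indices, hip and knee ranges
of motion, swing percentage and walking speed.  Predictors are first
screened for collinearity (variance inflation factors and condition
indices), then selected by classical bidirectional stepwise ordinary
least squares on partial-F p-values with entry and removal thresholds
both at the 0.1 significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_PREDICTORS = (
    "di_stance",
    "di_swing",
    "rom_hip",
    "rom_knee",
    "swing_percentage",
    "speed",
)


@dataclass
class CollinearityReport:
    vif: pd.Series  # per predictor; inf flags perfect collinearity
    condition_indices: np.ndarray
    flagged: list[str] = field(default_factory=list)  # VIF > threshold


def collinearity_diagnostics(
    table: pd.DataFrame,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    vif_threshold: float = 10.0,
) -> CollinearityReport:
    """Variance inflation factors and condition indices of a predictor set."""
    X = table.loc[:, list(predictors)].astype(float)
    if X.isna().any().any():
        raise ValueError("predictor columns contain missing values")
    vifs = {}
    for col in predictors:
        others = [c for c in predictors if c != col]
        y = X[col].to_numpy()
        if np.std(y) < 1e-12:
            vifs[col] = float("inf")
            continue
        design = sm.add_constant(X[others].to_numpy())
        r2 = sm.OLS(y, design).fit().rsquared
        vifs[col] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    vif = pd.Series(vifs)
    # condition indices of the unit-length-scaled design (with intercept)
    design = sm.add_constant(X.to_numpy())
    norms = np.linalg.norm(design, axis=0)
    norms[norms == 0] = 1.0
    sv = np.linalg.svd(design / norms, compute_uv=False)
    cond = sv.max() / np.where(sv > 1e-15, sv, 1e-15)
    flagged = [c for c in predictors if not np.isfinite(vif[c]) or vif[c] > vif_threshold]
    return CollinearityReport(vif=vif, condition_indices=cond, flagged=flagged)


@dataclass
class StepwiseResults:
    """Outcome of one bidirectional stepwise selection."""

    selected: list[str]
    params: pd.Series
    pvalues: pd.Series
    rsquared: float
    steps: list[tuple[str, str, float]]  # (action, predictor, p-value)
    collinearity: CollinearityReport | None = None

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"coef": self.params, "p": self.pvalues})
        out.attrs["rsquared"] = self.rsquared
        out.attrs["selected"] = list(self.selected)
        return out


class StepwiseOLS:
    """Bidirectional stepwise ordinary least squares (statsmodels-backed).

    At each iteration the candidate with the smallest partial-F
    p-value enters if it is at or below ``alpha_enter``; any retained
    predictor whose p-value exceeds ``alpha_remove`` is then removed
    (largest first).  Ties break on column order.  Predictors flagged
    as perfectly collinear are excluded up front.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        response: str,
        predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
        alpha_enter: float = 0.1,
        alpha_remove: float = 0.1,
        screen_collinearity: bool = True,
        drop_flagged: bool = False,
    ):
        missing = [c for c in (response, *predictors) if c not in table.columns]
        if missing:
            raise ValueError(f"columns missing from table: {missing}")
        if len(table) < len(predictors) + 2:
            raise ValueError("need at least predictors + 2 rows")
        self.table = table.reset_index(drop=True)
        self.response = response
        self.predictors = list(predictors)
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove
        self.collinearity = (
            collinearity_diagnostics(table, predictors) if screen_collinearity else None
        )
        if self.collinearity is not None:
            infinite = [p for p in self.predictors if not np.isfinite(self.collinearity.vif[p])]
            drop = infinite + (self.collinearity.flagged if drop_flagged else [])
            self.predictors = [p for p in self.predictors if p not in drop]

    def _fit(self, cols: list[str]):
        y = self.table[self.response].to_numpy(dtype=float)
        X = sm.add_constant(self.table[cols].to_numpy(dtype=float)) if cols else np.ones(
            (len(y), 1)
        )
        return sm.OLS(y, X).fit()

    def fit(self, max_iter: int = 100) -> StepwiseResults:
        current: list[str] = []
        steps: list[tuple[str, str, float]] = []
        for _ in range(max_iter):
            changed = False
            # entry: smallest partial-F p-value at or below alpha_enter
            best_p, best_var = None, None
            for cand in self.predictors:
                if cand in current:
                    continue
                res = self._fit(current + [cand])
                p = float(res.pvalues[-1])
                if p <= self.alpha_enter and (best_p is None or p < best_p):
                    best_p, best_var = p, cand
            if best_var is not None:
                current.append(best_var)
                steps.append(("add", best_var, best_p))
                changed = True
            # removal: any retained predictor above alpha_remove
            while current:
                res = self._fit(current)
                pvals = pd.Series(res.pvalues[1:], index=current)
                worst = pvals.idxmax()
                if pvals[worst] > self.alpha_remove:
                    current.remove(worst)
                    steps.append(("remove", worst, float(pvals[worst])))
                    changed = True
                else:
                    break
            if not changed:
                break
        final = self._fit(current)
        names = ["const"] + current
        return StepwiseResults(
            selected=list(current),
            params=pd.Series(final.params, index=names),
            pvalues=pd.Series(final.pvalues, index=names),
            rsquared=float(final.rsquared) if current else 0.0,
            steps=steps,
            collinearity=self.collinearity,
        )
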