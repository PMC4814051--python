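"""Variance decomposition of same-drug pair concordance.

Forward-stepwise ordinary least squares quantifies how much of the variation
in pairwise concordance is explained by dose difference, time difference,
dosing-schedule difference, and the transcriptional activity of the least /
most perturbing treatment. Covariates enter as named groups (the 3-level
schedule factor contributes two indicator contrasts that enter together); at
each step the group with the largest R-squared increase enters, and the
increase is recorded in percent. All groups eventually enter, so the final
model equals the ordinary full fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: covariate group -> design columns
COVARIATE_GROUPS = {
    "log10_dose_ratio": ["log10_dose_ratio"],
    "log10_time_ratio": ["log10_time_ratio"],
    "schedule_diff": ["schedule_both_repeat", "schedule_mixed"],
    "min_activity": ["min_activity"],
    "max_activity": ["max_activity"],
}


@dataclass
class DecompositionResult:
    steps: list          # ordered (covariate group, added R^2 in percent)
    total_r2: float      # fraction, = full-model R^2
    coefficients: pd.Series

    def added_r2(self, covariate: str) -> float:
        return dict(self.steps)[covariate]

    def entry_order(self) -> list:
        return [name for name, _ in self.steps]

    def as_frame(self, order: str = "fixed") -> pd.DataFrame:
        """Table-shaped summary; ``order`` is 'entry' (stepwise order) or
        'fixed' (the canonical covariate listing)."""
        d = dict(self.steps)
        names = self.entry_order() if order == "entry" else [
            k for k in COVARIATE_GROUPS if k in d
        ]
        return pd.DataFrame({"covariate": names,
                             "added_r2_percent": [d[n] for n in names]})


def pair_covariates(pairs: pd.DataFrame) -> pd.DataFrame:
    """Design matrix columns for a pair table.

    Expects log10_dose_ratio, log10_time_ratio, schedule_diff and the two
    activity columns (min_activity, max_activity: avg. abs. EG of the least /
    most perturbing experiment). Schedule is coded as two indicators against
    the both-single baseline.
    """
    out = pd.DataFrame(index=pairs.index)
    out["log10_dose_ratio"] = pairs["log10_dose_ratio"].astype(float)
    out["log10_time_ratio"] = pairs["log10_time_ratio"].astype(float)
    out["schedule_both_repeat"] = (pairs["schedule_diff"] == "both_repeat").astype(float)
    out["schedule_mixed"] = (pairs["schedule_diff"] == "mixed").astype(float)
    out["min_activity"] = pairs["min_activity"].astype(float)
    out["max_activity"] = pairs["max_activity"].astype(float)
    return out


def _r2(X: np.ndarray, y: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (resid**2).sum() / tss)


def stepwise_fit(
    pairs: pd.DataFrame,
    response: str,
    groups: dict | None = None,
    condition_limit: float = 1e8,
) -> DecompositionResult:
    """Forward-selection decomposition of concordance variance.

    ``pairs`` carries the response column and the design columns from
    :func:`pair_covariates`. Covariate groups whose columns are constant or
    that make the design ill-conditioned are dropped with a warning.
    """
    groups = dict(groups or COVARIATE_GROUPS)
    design = pair_covariates(pairs)
    y = pairs[response].to_numpy(dtype=float)
    ok = np.isfinite(y)
    if (~ok).any():
        logger.warning("dropping %d pairs with missing response", int((~ok).sum()))
    y = y[ok]
    design = design.reset_index(drop=True)[ok]
    n = len(y)
    n_cols = sum(len(c) for c in groups.values())
    if n < 10 * n_cols:
        raise ValueError(f"need >= {10 * n_cols} pairs for {n_cols} design columns, got {n}")

    # drop constant / collinear groups up front
    usable = {}
    cols_so_far: list = []
    for name, cols in groups.items():
        Xg = design[cols].to_numpy()
        if np.all(Xg.std(axis=0) == 0):
            logger.warning("covariate %s is constant; dropped", name)
            continue
        trial = np.column_stack([np.ones(n)] + cols_so_far + [Xg])
        if np.linalg.cond(trial) > condition_limit:
            logger.warning("covariate %s is collinear with earlier covariates; dropped", name)
            continue
        usable[name] = Xg
        cols_so_far.append(Xg)

    steps = []
    selected: list = []
    remaining = dict(usable)
    current_r2 = 0.0
    while remaining:
        best_name, best_gain, best_r2 = None, -np.inf, 0.0
        for name, Xg in remaining.items():
            X = np.column_stack(selected + [Xg]) if selected else Xg
            r2 = _r2(X, y)
            if r2 - current_r2 > best_gain:
                best_name, best_gain, best_r2 = name, r2 - current_r2, r2
        selected.append(remaining.pop(best_name))
        steps.append((best_name, 100.0 * best_gain))
        current_r2 = best_r2

    X_full = np.column_stack(selected)
    design_full = np.column_stack([np.ones(n), X_full])
    beta, *_ = np.linalg.lstsq(design_full, y, rcond=None)
    col_names = ["intercept"] + [c for name, _ in steps for c in groups[name]]
    coefficients = pd.Series(beta, index=col_names)
    return DecompositionResult(steps=steps, total_r2=current_r2, coefficients=coefficients)
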