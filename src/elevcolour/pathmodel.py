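"""Path analysis of temperature -> relative brightness -> trait variation.

A recursive two-edge path model fitted as sequential standardized OLS
regressions on the assemblage table: assemblage mean temperature predicts
the mean brightness index B, which predicts log T_IC/IR.  For
single-predictor edges the standardized coefficient equals the Pearson
correlation, and sequential OLS coincides with structural-equation
estimation of a recursive chain; no global fit statistic is produced.  The
indirect (mediated) effect is the product of the two edge coefficients.

A side check regresses log T_IC/IR on the mean saturation index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["PathEdge", "PathFit", "fit_path", "fit_saturation_check"]


@dataclass(frozen=True)
class PathEdge:
    source: str
    target: str
    coefficient: float  # standardized
    r2: float
    f_stat: float
    p_value: float
    ci: tuple[float, float]


@dataclass(frozen=True)
class PathFit:
    temp_to_brightness: PathEdge
    brightness_to_variation: PathEdge
    indirect_effect: float
    n: int
    extra_edges: tuple[PathEdge, ...] = ()


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    # relative threshold: a constant column can have sd ~ 1e-16 from rounding
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise ValueError("constant variable cannot be standardized")
    return (x - x.mean()) / sd


def _edge(x: np.ndarray, y: np.ndarray, source: str, target: str) -> PathEdge:
    res = sm.OLS(_zscore(y), sm.add_constant(_zscore(x))).fit()
    ci = res.conf_int(alpha=0.05)
    return PathEdge(
        source=source,
        target=target,
        coefficient=float(res.params[1]),
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        ci=(float(ci[1, 0]), float(ci[1, 1])),
    )


def fit_path(
    table: pd.DataFrame,
    temperature_col: str = "temperature",
    brightness_col: str = "b_index",
    variation_col: str = "t_ic_ir",
    include_saturation_edge: bool = False,
    saturation_col: str = "s_index",
) -> PathFit:
    """Fit the standardized path chain on the assemblage table.

    Log transformation is applied to T_IC/IR before z-scoring.  Requires at
    least 4 assemblages and strictly positive T_IC/IR.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 assemblages")
    t = table[temperature_col].to_numpy(dtype=float)
    b = table[brightness_col].to_numpy(dtype=float)
    v = table[variation_col].to_numpy(dtype=float)
    if np.any(v <= 0):
        raise ValueError("T_IC/IR must be positive for the log transform")
    logv = np.log(v)
    e1 = _edge(t, b, temperature_col, brightness_col)
    e2 = _edge(b, logv, brightness_col, f"log_{variation_col}")
    extras: tuple[PathEdge, ...] = ()
    if include_saturation_edge:
        s = table[saturation_col].to_numpy(dtype=float)
        extras = (
            _edge(t, s, temperature_col, saturation_col),
            _edge(s, logv, saturation_col, f"log_{variation_col}"),
        )
    return PathFit(
        temp_to_brightness=e1,
        brightness_to_variation=e2,
        indirect_effect=e1.coefficient * e2.coefficient,
        n=len(table),
        extra_edges=extras,
    )


def fit_saturation_check(
    table: pd.DataFrame,
    saturation_col: str = "s_index",
    variation_col: str = "t_ic_ir",
):
    """OLS of log T_IC/IR on the assemblage mean saturation index."""
    from .assemblage import fit_trend

    v = table[variation_col].to_numpy(dtype=float)
    if np.any(v <= 0):
        raise ValueError("T_IC/IR must be positive for the log transform")
    return fit_trend(table[saturation_col].to_numpy(dtype=float), np.log(v))
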