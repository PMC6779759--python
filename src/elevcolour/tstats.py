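"""Variance partitioning of a one-dimensional trait across nested levels.

Following trait-based community assembly T-statistics, individuals (specimen
images) nest in populations (a species within one assemblage), populations
in communities (the 100-m elevational assemblage), and communities in the
regional pool (all individuals).  Two ratios are computed per assemblage:

* T_IC/IR — variance of individuals within the community divided by the
  variance of all individuals in the region; low values indicate external
  (environmental) filtering of the trait;
* T_IP/IC — pooled within-population variance divided by the
  within-community variance; low values indicate internal filtering
  (interspecific divergence / competition).

The trait is the 1-D classical-MDS coordinate of the image feature vectors
computed once over the whole regional pool, so every assemblage shares a
common axis.  Variances use denominator n by default (the population
variance convention of the trait literature); both ratios are invariant to
affine rescaling of the trait axis, so the sign/scale indeterminacy of MDS
cannot affect them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assemblage import TrendFit, fit_trend

__all__ = ["TStatRecord", "t_ic_ir", "t_ip_ic", "compute_tstats", "tstat_trend"]


@dataclass(frozen=True)
class TStatRecord:
    label: str
    midpoint: float
    n_individuals: int
    t_ip_ic: float
    t_ic_ir: float
    var_within_population: float
    var_within_community: float
    var_within_region: float


def _var(x: np.ndarray, ddof: int) -> float:
    return float(np.var(np.asarray(x, dtype=float), ddof=ddof))


def t_ic_ir(region: np.ndarray, community: np.ndarray, ddof: int = 0) -> float:
    """Within-community variance over within-region variance."""
    region = np.asarray(region, dtype=float)
    community = np.asarray(community, dtype=float)
    if community.size < 2 or region.size < 2:
        raise ValueError("need at least 2 individuals at each level")
    v_r = _var(region, ddof)
    if v_r == 0:
        raise ValueError("zero regional variance")
    return _var(community, ddof) / v_r


def t_ip_ic(
    community: np.ndarray, species: Sequence, ddof: int = 0
) -> float:
    """Pooled within-population variance over within-community variance.

    ``species`` labels each individual in ``community``.  The pooled
    within-population variance is the mean squared deviation of individuals
    from their own species mean (singleton species contribute zero).
    """
    x = np.asarray(community, dtype=float)
    sp = np.asarray(species)
    if x.size < 2:
        raise ValueError("need at least 2 individuals in the community")
    v_c = _var(x, ddof)
    if v_c == 0:
        raise ValueError("zero community variance")
    dev2 = np.empty_like(x)
    for s in np.unique(sp):
        sel = sp == s
        dev2[sel] = (x[sel] - x[sel].mean()) ** 2
    if ddof == 0:
        v_p = float(dev2.mean())
    else:
        k = len(np.unique(sp))
        denom = x.size - k
        v_p = float(dev2.sum() / denom) if denom > 0 else 0.0
    return v_p / v_c


def compute_tstats(
    obs: pd.DataFrame, trait_col: str = "trait", ddof: int = 0
) -> list[TStatRecord]:
    """Per-assemblage T-statistics from an individual-level table.

    ``obs`` needs columns ``trait`` (1-D trait value), ``species_id``,
    ``assemblage`` (label), ``midpoint`` (assemblage elevation, m).  The law
    of total variance (within-community = pooled within-population +
    variance of population means) is asserted on every assemblage.
    """
    region = obs[trait_col].to_numpy(dtype=float)
    records = []
    for label, grp in obs.groupby("assemblage", sort=True):
        x = grp[trait_col].to_numpy(dtype=float)
        sp = grp["species_id"].to_numpy()
        v_c = _var(x, 0)
        ratio_ir = t_ic_ir(region, x, ddof=ddof)
        ratio_pc = t_ip_ic(x, sp, ddof=ddof) if v_c > 0 else float("nan")

        # law of total variance (denominator-n components)
        means = np.array([x[sp == s].mean() for s in sp])
        v_p = float(((x - means) ** 2).mean())
        v_between = float(((means - x.mean()) ** 2).mean())
        if not np.isclose(v_c, v_p + v_between, atol=1e-10, rtol=1e-8):
            raise AssertionError("law of total variance violated")

        records.append(
            TStatRecord(
                label=str(label),
                midpoint=float(grp["midpoint"].iloc[0]),
                n_individuals=int(len(grp)),
                t_ip_ic=ratio_pc,
                t_ic_ir=ratio_ir,
                var_within_population=v_p,
                var_within_community=v_c,
                var_within_region=_var(region, 0),
            )
        )
    return sorted(records, key=lambda r: r.midpoint)


def tstat_trend(
    records: Sequence[TStatRecord], predictor: Sequence[float], which: str = "t_ic_ir"
) -> TrendFit:
    """OLS trend of a T-ratio against a gradient predictor."""
    y = np.array([getattr(r, which) for r in records], dtype=float)
    keep = np.isfinite(y)
    return fit_trend(np.asarray(predictor, dtype=float)[keep], y[keep])
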