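"""Elevational assemblages, feature diversity, trend fits and bootstraps.

Species are binned into half-open 100-m elevation intervals by their mean
elevation; within-assemblage image feature diversity is the mean pairwise
cosine distance among member species' representative feature vectors.  The
diversity-elevation trend is an ordinary least-squares regression (a
Gaussian GLM), with 95% confidence intervals for its coefficients from two
resampling schemes:

* pairwise bootstrap — in each repeat every assemblage's diversity is the
  mean of m pairwise distances drawn with replacement from that assemblage
  (m defaulting to the pair count of the smallest assemblage), correcting
  for unequal assemblage sizes;
* family bootstrap — in each repeat four families are drawn with replacement
  from those present in the assemblage and the diversity is recomputed on
  the pooled species of the distinct sampled families, a grouped resampling
  that stands in for phylogenetic random effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import pairwise_cosine

__all__ = [
    "Assemblage",
    "DiversityRecord",
    "TrendFit",
    "BootstrapCI",
    "bin_species",
    "within_diversity",
    "fit_trend",
    "bootstrap_pairwise",
    "bootstrap_family",
    "beta_diversity_profile",
]


@dataclass(frozen=True)
class Assemblage:
    """One 100-m elevational species assemblage."""

    lo: float
    hi: float
    species: tuple[str, ...]

    @property
    def label(self) -> str:
        return f"{self.lo:g}–{self.hi:g} m"

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class DiversityRecord:
    label: str
    midpoint: float
    n_species: int
    diversity: float


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of an assemblage statistic on a gradient predictor."""

    intercept: float
    slope: float
    r2: float
    f_stat: float
    p_value: float
    df: tuple[int, int]
    slope_ci: tuple[float, float]
    n: int


@dataclass(frozen=True)
class BootstrapCI:
    parameter: str
    lower: float
    upper: float
    reps: int
    seed: int

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def bin_species(
    mean_elevations: Mapping[str, float] | pd.Series, width: float = 100.0
) -> list[Assemblage]:
    """Group species into half-open [k*w, (k+1)*w) bins by mean elevation.

    Empty bins are omitted.  Assemblages with fewer than two species are
    returned (they exist as assemblages) but cannot contribute a diversity
    value; callers exclude them from trend fitting.
    """
    elev = pd.Series(dict(mean_elevations)) if not isinstance(mean_elevations, pd.Series) else mean_elevations
    if (elev < 0).any():
        raise ValueError("negative species mean elevation")
    idx = np.floor(elev.values / width).astype(int)
    out = []
    for k in sorted(set(idx)):
        members = tuple(sorted(elev.index[idx == k]))
        out.append(Assemblage(lo=k * width, hi=(k + 1) * width, species=members))
    return out


def _pair_distances(assemblage: Assemblage, vectors: Mapping[str, np.ndarray]) -> np.ndarray:
    mat = pairwise_cosine(np.stack([vectors[s] for s in assemblage.species]))
    iu = np.triu_indices(len(assemblage.species), k=1)
    return mat[iu]


def within_diversity(
    assemblage: Assemblage, vectors: Mapping[str, np.ndarray]
) -> DiversityRecord:
    """Mean cosine distance over all unordered member pairs."""
    if assemblage.n_species < 2:
        raise ValueError(f"assemblage {assemblage.label} has < 2 species")
    pairs = _pair_distances(assemblage, vectors)
    return DiversityRecord(
        label=assemblage.label,
        midpoint=assemblage.midpoint,
        n_species=assemblage.n_species,
        diversity=float(pairs.mean()),
    )


def fit_trend(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """Gaussian-GLM (OLS) fit of y on a single gradient predictor x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 records to fit a trend")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return TrendFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        df=(1, int(res.df_resid)),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        n=int(x.size),
    )


def _vectorised_trends(x: np.ndarray, ys: np.ndarray) -> dict[str, np.ndarray]:
    """OLS of each row of ys on x; returns intercept, slope, r2, F arrays."""
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = (ys - ys.mean(axis=1, keepdims=True)) @ xc / sxx
    intercept = ys.mean(axis=1) - slope * x.mean()
    fitted = intercept[:, None] + slope[:, None] * x
    ss_res = ((ys - fitted) ** 2).sum(axis=1)
    ss_tot = ((ys - ys.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        dof = x.size - 2
        f = np.where(ss_res > 0, (ss_tot - ss_res) / (ss_res / dof), np.inf)
        f = np.where(ss_tot > 0, f, 0.0)
    return {"intercept": intercept, "slope": slope, "r2": r2, "f_stat": f}


def _percentile_cis(
    stats: dict[str, np.ndarray], reps: int, seed: int
) -> dict[str, BootstrapCI]:
    out = {}
    for name, vals in stats.items():
        vals = vals[np.isfinite(vals)]
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[name] = BootstrapCI(parameter=name, lower=float(lo), upper=float(hi),
                                reps=reps, seed=seed)
    return out


def _check_reps(reps: int) -> None:
    if reps < 100:
        warnings.warn(f"only {reps} bootstrap repeats; intervals will be noisy",
                      stacklevel=3)


def bootstrap_pairwise(
    assemblages: Sequence[Assemblage],
    vectors: Mapping[str, np.ndarray],
    m: int | None = None,
    reps: int = 5000,
    seed: int = 0,
) -> dict[str, BootstrapCI]:
    """Pairwise-distance bootstrap of the diversity-elevation trend.

    Each repeat resamples m pairwise distances with replacement from every
    assemblage (default m = pair count of the smallest assemblage), takes
    their mean as that assemblage's diversity, and refits the trend;
    percentile 95% CIs are reported for intercept, slope, R^2 and F.
    """
    usable = [a for a in assemblages if a.n_species >= 2]
    if not usable:
        raise ValueError("no assemblage with at least one pair")
    if m is None:
        nmin = min(a.n_species for a in usable)
        m = nmin * (nmin - 1) // 2
    if m <= 0:
        raise ValueError("bootstrap draw size m must be positive")
    _check_reps(reps)
    rng = np.random.default_rng(seed)
    x = np.array([a.midpoint for a in usable])
    boot = np.empty((reps, len(usable)))
    for j, a in enumerate(usable):
        pairs = _pair_distances(a, vectors)
        draws = rng.integers(0, pairs.size, size=(reps, m))
        boot[:, j] = pairs[draws].mean(axis=1)
    return _percentile_cis(_vectorised_trends(x, boot), reps, seed)


def bootstrap_family(
    assemblages: Sequence[Assemblage],
    vectors: Mapping[str, np.ndarray],
    families: Mapping[str, str],
    n_families: int = 4,
    reps: int = 1000,
    seed: int = 0,
) -> dict[str, BootstrapCI]:
    """Family-grouped bootstrap of the diversity-elevation trend.

    Each repeat draws ``n_families`` families with replacement per
    assemblage from those present and recomputes diversity on the pooled
    species of the distinct families drawn (an assemblage is skipped in a
    repeat if fewer than two species are pooled; a repeat is skipped if
    fewer than three assemblages remain).
    """
    usable = [a for a in assemblages if a.n_species >= 2]
    if not usable:
        raise ValueError("no assemblage with at least one pair")
    _check_reps(reps)
    rng = np.random.default_rng(seed)
    x_all = np.array([a.midpoint for a in usable])

    by_family: list[dict[str, list[int]]] = []
    mats = []
    for a in usable:
        mats.append(pairwise_cosine(np.stack([vectors[s] for s in a.species])))
        fam: dict[str, list[int]] = {}
        for i, s in enumerate(a.species):
            fam.setdefault(families[s], []).append(i)
        by_family.append(fam)

    cache: list[dict[frozenset, float | None]] = [dict() for _ in usable]
    stats = {k: [] for k in ("intercept", "slope", "r2", "f_stat")}
    for _ in range(reps):
        xs, ys = [], []
        for j, a in enumerate(usable):
            fams = sorted(by_family[j])
            chosen = frozenset(rng.choice(len(fams), size=n_families, replace=True))
            key = chosen
            if key not in cache[j]:
                idx = sorted(
                    i for c in chosen for i in by_family[j][fams[c]]
                )
                if len(idx) < 2:
                    cache[j][key] = None
                else:
                    sub = mats[j][np.ix_(idx, idx)]
                    n = len(idx)
                    cache[j][key] = float(sub.sum() / (n * (n - 1)))
            div = cache[j][key]
            if div is not None:
                xs.append(x_all[j])
                ys.append(div)
        if len(xs) < 3 or np.ptp(xs) == 0:
            continue
        t = _vectorised_trends(np.array(xs), np.array(ys)[None, :])
        for k in stats:
            stats[k].append(t[k][0])
    return _percentile_cis({k: np.array(v) for k, v in stats.items()}, reps, seed)


def beta_diversity_profile(
    assemblages: Sequence[Assemblage],
    species_ranges: pd.DataFrame | None = None,
    width: float = 100.0,
) -> pd.DataFrame:
    """Sorensen turnover between adjacent assemblages.

    When ``species_ranges`` (columns lo, hi per species) is given, a species
    occupies every bin its full elevational range crosses; otherwise
    occupancy is assemblage membership alone.
    """
    if len(assemblages) < 2:
        raise ValueError("need at least 2 assemblages")
    occ: dict[float, set[str]] = {a.lo: set(a.species) for a in assemblages}
    if species_ranges is not None:
        for a in assemblages:
            for sp, row in species_ranges.iterrows():
                if row["lo"] < a.hi and row["hi"] >= a.lo:
                    occ[a.lo].add(str(sp))
    rows = []
    ordered = sorted(occ)
    for lo1, lo2 in zip(ordered, ordered[1:]):
        s1, s2 = occ[lo1], occ[lo2]
        shared = len(s1 & s2)
        denom = len(s1) + len(s2)
        rows.append(
            {
                "lower_bin": lo1,
                "upper_bin": lo2,
                "turnover": 1.0 - (2 * shared / denom if denom else 0.0),
            }
        )
    return pd.DataFrame(rows)
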