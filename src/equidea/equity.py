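"""Equity measurement: Lorenz curves, Gini coefficients and the Theil index.

Two Gini variants are exposed because both circulate in the health-equity
literature under the same name:

* ``gini_hoover`` — half the sum of absolute share differences,
  ``G = ½ Σ|X_i − Y_i|``.  This is the Hoover (Robin Hood) index and equals
  the maximum vertical gap between the Lorenz curve and the diagonal.
* ``gini_lorenz`` — the classical Lorenz-area Gini computed by the
  trapezoid rule after sorting units by resource-per-base ratio.  This is
  the default headline measure.

The Theil index used here is the population-weighted mean log deviation
``T = Σ P_i ln(P_i / Y_i)`` (P_i: base share, Y_i: resource share), which
decomposes additively into a within-group and a between-group component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .panel import ResourcePanel

__all__ = [
    "ShareVector",
    "LorenzCurve",
    "GiniResult",
    "GroupTerm",
    "TheilDecomposition",
    "make_shares",
    "gini_hoover",
    "gini_paper",
    "gini_lorenz",
    "lorenz_points",
    "theil",
    "theil_decompose",
    "contribution_rates",
    "equality_band",
]

log = logging.getLogger(__name__)

_SHARE_TOL = 1e-12

Base = Literal["population", "area"]


@dataclass(frozen=True)
class ShareVector:
    """Paired relative shares over k units.

    ``X`` holds resource shares and ``Y`` the base (population or area)
    shares; both are nonnegative and sum to one.  The ratio X_i/Y_i is the
    unit's resource endowment per unit of base.
    """

    units: tuple[str, ...]
    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if not (len(self.units) == X.size == Y.size):
            raise ValueError("units, X and Y must have equal length")
        if np.any(X < 0):
            raise ValueError("resource shares must be >= 0")
        if np.any(Y <= 0):
            raise ValueError("base shares must be > 0")
        if abs(X.sum() - 1.0) > 1e-9 or abs(Y.sum() - 1.0) > 1e-9:
            raise ValueError("shares must each sum to 1")

    @property
    def k(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class LorenzCurve:
    """Ordered cumulative (base, resource) points from (0,0) to (1,1)."""

    points: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class GiniResult:
    value: float
    method: str  # "paper_eq1" (Hoover) | "lorenz_trapezoid"
    band: str


@dataclass(frozen=True)
class GroupTerm:
    group: str
    p_g: float  # group base share
    y_g: float  # group resource share
    t_g: float  # within-group Theil


@dataclass(frozen=True)
class TheilDecomposition:
    T: float
    T_intra: float
    T_inter: float
    group_terms: tuple[GroupTerm, ...]

    @property
    def contribution_intra(self) -> float:
        return self.T_intra / self.T

    @property
    def contribution_inter(self) -> float:
        return self.T_inter / self.T


def equality_band(value: float) -> str:
    """Map a Gini value to the conventional equality label.

    Bands are half-open: exactly 0.2 is 'relative equality', exactly 0.5
    'serious inequality'.
    """
    if value < 0.2:
        return "absolute equality"
    if value < 0.3:
        return "relative equality"
    if value < 0.4:
        return "proper equality"
    if value < 0.5:
        return "relative inequality"
    return "serious inequality"


def make_shares(
    panel: ResourcePanel,
    year: int,
    resource: str,
    base: Base = "population",
) -> ShareVector:
    """Resource and base shares across the DMUs present in ``year``."""
    recs = panel.year_records(year)
    units = tuple(r.dmu for r in recs)
    res = np.array([r.quantity(resource) for r in recs], dtype=float)
    base_field = "population" if base == "population" else "area_km2"
    b = np.array([r.quantity(base_field) for r in recs], dtype=float)
    if res.sum() <= 0:
        raise ValueError(f"resource {resource!r} has zero total in {year}")
    if np.any(b <= 0):
        bad = [u for u, v in zip(units, b) if v <= 0]
        raise ValueError(f"nonpositive {base} for units: {bad}")
    return ShareVector(units, res / res.sum(), b / b.sum())


def gini_hoover(shares: ShareVector) -> GiniResult:
    """Hoover index ``½ Σ|X_i − Y_i|`` over paired shares."""
    value = 0.5 * float(np.abs(shares.X - shares.Y).sum())
    return GiniResult(value=value, method="paper_eq1", band=equality_band(value))


# alias: the literal printed formula of the source equation
gini_paper = gini_hoover


def _lorenz_order(shares: ShareVector) -> np.ndarray:
    ratio = shares.X / shares.Y
    # ties broken by unit identifier for determinism
    return np.lexsort((np.asarray(shares.units), ratio))


def gini_lorenz(shares: ShareVector) -> GiniResult:
    """Lorenz-area Gini by the trapezoid rule.

    Units are sorted ascending by X_i/Y_i, then
    ``G = 1 − Σ Y_i (cumX_{i−1} + cumX_i)``.
    """
    order = _lorenz_order(shares)
    X = shares.X[order]
    Y = shares.Y[order]
    cumX = np.cumsum(X)
    prev = np.concatenate(([0.0], cumX[:-1]))
    value = 1.0 - float(np.sum(Y * (prev + cumX)))
    value = max(value, 0.0)  # clip −0.0 fuzz on perfect equality
    return GiniResult(value=value, method="lorenz_trapezoid", band=equality_band(value))


def lorenz_points(shares: ShareVector) -> LorenzCurve:
    """Cumulative-share curve after the ascending X/Y sort."""
    order = _lorenz_order(shares)
    cumY = np.concatenate(([0.0], np.cumsum(shares.Y[order])))
    cumX = np.concatenate(([0.0], np.cumsum(shares.X[order])))
    cumY[-1] = cumX[-1] = 1.0  # exact endpoints
    return LorenzCurve(tuple(zip(cumY.tolist(), cumX.tolist())))


def theil(shares: ShareVector) -> float:
    """Theil index ``T = Σ P_i ln(P_i / Y_i)`` with natural log.

    P_i is the base (population/area) share and Y_i the resource share; a
    unit with zero resource share makes the index undefined and raises.
    """
    P = shares.Y  # base shares
    Yres = shares.X  # resource shares
    if np.any(Yres <= 0):
        bad = [u for u, v in zip(shares.units, Yres) if v <= 0]
        raise ValueError(f"Theil undefined: zero resource share for {bad}")
    return float(np.sum(P * np.log(P / Yres)))


def theil_decompose(
    panel: ResourcePanel,
    year: int,
    resource: str,
    base: Base = "population",
    grouping: Mapping[str, str] | None = None,
) -> TheilDecomposition:
    """Within/between-group decomposition of the Theil index.

    For group g with base share p_g and resource share y_g:
    ``T_intra = Σ p_g t_g`` where t_g is the Theil index of the shares
    renormalized inside g, and ``T_inter = Σ p_g ln(p_g / y_g)``.
    The two components add up exactly to the pooled index.
    """
    shares = make_shares(panel, year, resource, base)
    grouping = dict(grouping) if grouping is not None else dict(panel.groups)
    ungrouped = [u for u in shares.units if u not in grouping]
    if ungrouped:
        raise ValueError(f"no group label for units: {ungrouped}")
    if np.any(shares.X <= 0):
        bad = [u for u, v in zip(shares.units, shares.X) if v <= 0]
        raise ValueError(f"Theil undefined: zero resource share for {bad}")

    labels = sorted({grouping[u] for u in shares.units})
    terms = []
    T_intra = 0.0
    T_inter = 0.0
    for g in labels:
        idx = np.array([grouping[u] == g for u in shares.units])
        if not idx.any():
            raise ValueError(f"empty group {g!r}")
        p_g = float(shares.Y[idx].sum())
        y_g = float(shares.X[idx].sum())
        sub = ShareVector(
            tuple(u for u, m in zip(shares.units, idx) if m),
            shares.X[idx] / y_g,
            shares.Y[idx] / p_g,
        )
        t_g = theil(sub)
        terms.append(GroupTerm(group=g, p_g=p_g, y_g=y_g, t_g=t_g))
        T_intra += p_g * t_g
        T_inter += p_g * np.log(p_g / y_g)
    return TheilDecomposition(
        T=T_intra + T_inter,
        T_intra=T_intra,
        T_inter=float(T_inter),
        group_terms=tuple(terms),
    )


def contribution_rates(
    series: Sequence[TheilDecomposition],
    mode: Literal["mean_of_ratios", "pooled"] = "mean_of_ratios",
) -> float:
    """Multi-year intra-group contribution rate, as a fraction of total T.

    ``mean_of_ratios`` (default) averages the yearly T_intra/T ratios;
    ``pooled`` divides summed T_intra by summed T.  Years with T == 0 are
    excluded with a warning (the ratio is undefined there).
    """
    usable = [d for d in series if d.T > 0]
    skipped = len(series) - len(usable)
    if skipped:
        log.warning("contribution_rates: excluded %d year(s) with T == 0", skipped)
    if not usable:
        raise ValueError("no decomposition with T > 0")
    if mode == "pooled":
        return sum(d.T_intra for d in usable) / sum(d.T for d in usable)
    return float(np.mean([d.T_intra / d.T for d in usable]))
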