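"""Output-oriented radial DEA with two-stage slacks and RTS classification.

The envelopment problem for DMU o against technology {(x_j, y_j)} is

    max φ   s.t.  Σ_j λ_j x_j ≤ x_o   (each input)
                  Σ_j λ_j y_j ≥ φ y_o (each output)
                  λ ≥ 0,  and Σ λ_j = 1 under VRS (BCC model).

φ ≥ 1 is the maximal equiproportional output expansion; technical
efficiency is te = 1/φ ≤ 1 (DEAP-style score).  A second LP at fixed φ
maximizes total input excess + output shortfall (two-stage slacks, free of
non-Archimedean ε).  Returns to scale are classified from the CRS
reference weights via the Banker Σλ criterion, with an alternate-optima
interval check (min/max Σλ at the optimal φ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import INPUT_QUANTITIES, OUTPUT_QUANTITIES, ResourcePanel

__all__ = [
    "Technology",
    "DEAResult",
    "DEAError",
    "solve_radial",
    "solve_slacks",
    "classify_rts",
    "efficiency_table",
    "slack_table",
]

_TOL = 1e-7  # LP feasibility/optimality target
_RTS_TOL = 1e-6  # Σλ interval tolerance for the Banker criterion


class DEAError(RuntimeError):
    """LP failure with diagnostics (should not occur for valid own-period data)."""


@dataclass(frozen=True)
class Technology:
    """Input/output matrices of n DMUs: X is m×n, Y is s×n, all entries > 0."""

    dmus: tuple[str, ...]
    X: np.ndarray
    Y: np.ndarray
    rts: str = "CRS"  # "CRS" | "VRS"
    input_names: tuple[str, ...] = INPUT_QUANTITIES
    output_names: tuple[str, ...] = OUTPUT_QUANTITIES

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if self.rts not in ("CRS", "VRS"):
            raise ValueError(f"rts must be CRS or VRS, got {self.rts!r}")
        n = len(self.dmus)
        if X.shape[1] != n or Y.shape[1] != n:
            raise ValueError("X and Y must have one column per DMU")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("technology matrices must be finite")
        if np.any(X <= 0) or np.any(Y <= 0):
            raise ValueError("all inputs and outputs must be strictly positive")
        if len(self.input_names) != X.shape[0]:
            object.__setattr__(self, "input_names", tuple(f"in{i + 1}" for i in range(X.shape[0])))
        if len(self.output_names) != Y.shape[0]:
            object.__setattr__(self, "output_names", tuple(f"out{r + 1}" for r in range(Y.shape[0])))

    @classmethod
    def from_panel(cls, panel: ResourcePanel, year: int, rts: str = "CRS") -> "Technology":
        recs = panel.year_records(year)
        dmus = tuple(r.dmu for r in recs)
        X = np.array([[r.inputs[q] for r in recs] for q in INPUT_QUANTITIES])
        Y = np.array([[r.outputs[q] for r in recs] for q in OUTPUT_QUANTITIES])
        return cls(dmus=dmus, X=X, Y=Y, rts=rts)

    def column(self, dmu: str) -> tuple[np.ndarray, np.ndarray]:
        j = self.dmus.index(dmu)
        return self.X[:, j].copy(), self.Y[:, j].copy()


@dataclass
class DEAResult:
    """Radial score, peers, slacks (internal nonnegative) and RTS class."""

    dmu: str
    phi: float
    lambdas: dict[str, float]
    input_slacks: dict[str, float] = field(default_factory=dict)
    output_slacks: dict[str, float] = field(default_factory=dict)
    rts_class: str | None = None

    @property
    def te(self) -> float:
        return 1.0 / self.phi

    @property
    def strongly_efficient(self) -> bool:
        slacks = list(self.input_slacks.values()) + list(self.output_slacks.values())
        return abs(self.phi - 1.0) < 1e-6 and all(abs(s) < 1e-6 for s in slacks)


def _lp(c, A_ub, b_ub, A_eq, b_eq, bounds, what: str):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": _TOL, "dual_feasibility_tolerance": _TOL},
    )
    if not res.success:
        raise DEAError(f"{what}: LP failed with status {res.status} ({res.message})")
    return res


def _radial_phi(tech: Technology, x0: np.ndarray, y0: np.ndarray) -> tuple[float, np.ndarray]:
    """max φ for observation (x0, y0) against ``tech``; returns (φ, λ)."""
    m, n = tech.X.shape
    s = tech.Y.shape[0]
    # variables: [phi, lambda_1..lambda_n]
    c = np.zeros(n + 1)
    c[0] = -1.0
    A_ub = np.zeros((m + s, n + 1))
    b_ub = np.zeros(m + s)
    A_ub[:m, 1:] = tech.X
    b_ub[:m] = x0
    A_ub[m:, 0] = y0
    A_ub[m:, 1:] = -tech.Y
    A_eq = b_eq = None
    if tech.rts == "VRS":
        A_eq = np.zeros((1, n + 1))
        A_eq[0, 1:] = 1.0
        b_eq = [1.0]
    res = _lp(c, A_ub, b_ub, A_eq, b_eq, [(0, None)] * (n + 1), "radial")
    return float(res.x[0]), res.x[1:].copy()


def solve_radial(tech: Technology, dmu: str) -> DEAResult:
    """Radial output-expansion score of ``dmu`` against its own technology."""
    x0, y0 = tech.column(dmu)
    phi, lam = _radial_phi(tech, x0, y0)
    lambdas = {d: float(v) for d, v in zip(tech.dmus, lam) if v > 1e-9}
    return DEAResult(dmu=dmu, phi=phi, lambdas=lambdas)


def cross_distance(tech: Technology, x_obs: np.ndarray, y_obs: np.ndarray) -> float:
    """Radial φ of an arbitrary observation against ``tech``'s frontier.

    Used for cross-period Malmquist distances; φ < 1 means the observation
    lies beyond the frontier of the reference period.
    """
    phi, _ = _radial_phi(tech, np.asarray(x_obs, float), np.asarray(y_obs, float))
    return phi


def solve_slacks(tech: Technology, dmu: str, phi: float) -> DEAResult:
    """Second stage: maximize total slack at the fixed radial score φ.

    Constraints: Σλ x_j + s⁻ = x_o and Σλ y_j − s⁺ = φ y_o with all
    variables nonnegative.  Slacks are stored nonnegative; the report layer
    serializes input slacks with a negative sign.
    """
    x0, y0 = tech.column(dmu)
    m, n = tech.X.shape
    s = tech.Y.shape[0]
    nv = n + m + s  # lambda, s-, s+
    c = np.zeros(nv)
    c[n:] = -1.0
    rows = m + s + (1 if tech.rts == "VRS" else 0)
    A_eq = np.zeros((rows, nv))
    b_eq = np.zeros(rows)
    A_eq[:m, :n] = tech.X
    A_eq[:m, n : n + m] = np.eye(m)
    b_eq[:m] = x0
    A_eq[m : m + s, :n] = tech.Y
    A_eq[m : m + s, n + m :] = -np.eye(s)
    b_eq[m : m + s] = phi * y0
    if tech.rts == "VRS":
        A_eq[-1, :n] = 1.0
        b_eq[-1] = 1.0
    try:
        res = _lp(c, None, None, A_eq, b_eq, [(0, None)] * nv, f"slacks({dmu})")
    except DEAError:
        # φ at the numerical boundary: back off infinitesimally
        b_eq2 = b_eq.copy()
        b_eq2[m : m + s] = phi * (1 - 1e-9) * y0
        res = _lp(c, None, None, A_eq, b_eq2, [(0, None)] * nv, f"slacks({dmu})")
    lam = res.x[:n]
    s_in = res.x[n : n + m]
    s_out = res.x[n + m :]
    clip = lambda v: 0.0 if abs(v) < 1e-7 else float(v)
    return DEAResult(
        dmu=dmu,
        phi=phi,
        lambdas={d: float(v) for d, v in zip(tech.dmus, lam) if v > 1e-9},
        input_slacks={q: clip(v) for q, v in zip(tech.input_names, s_in)},
        output_slacks={q: clip(v) for q, v in zip(tech.output_names, s_out)},
    )


def classify_rts(tech: Technology, dmu: str) -> str:
    """Returns-to-scale class via the Σλ interval of the CRS solution.

    With the CRS radial score fixed, Σλ is minimized and maximized over the
    alternate optima; 'CRS' if 1 lies in [min, max] (±1e-6), 'IRS' if the
    whole interval is below 1, 'DRS' if above.
    """
    crs = Technology(tech.dmus, tech.X, tech.Y, rts="CRS",
                     input_names=tech.input_names, output_names=tech.output_names)
    x0, y0 = crs.column(dmu)
    phi, _ = _radial_phi(crs, x0, y0)
    m, n = crs.X.shape
    s = crs.Y.shape[0]
    A_ub = np.vstack([crs.X, -crs.Y])
    b_ub = np.concatenate([x0, -phi * (1 - 1e-9) * y0])
    ones = np.ones(n)
    bounds = [(0, None)] * n
    lo = _lp(ones, A_ub, b_ub, None, None, bounds, f"rts-min({dmu})").fun
    hi = -_lp(-ones, A_ub, b_ub, None, None, bounds, f"rts-max({dmu})").fun
    if lo - _RTS_TOL <= 1.0 <= hi + _RTS_TOL:
        return "CRS"
    return "IRS" if hi < 1.0 else "DRS"


def efficiency_table(panel: ResourcePanel, year: int, rts: str = "VRS") -> list[DEAResult]:
    """Full DEA run for one year: radial score, slacks and RTS class per DMU."""
    tech = Technology.from_panel(panel, year, rts=rts)
    results = []
    for dmu in tech.dmus:
        try:
            r = solve_radial(tech, dmu)
            r = solve_slacks(tech, dmu, r.phi)
            r.rts_class = classify_rts(tech, dmu)
        except DEAError as exc:
            raise DEAError(f"DMU {dmu!r}, year {year}: {exc}") from exc
        results.append(r)
    return results


def slack_table(results: Sequence[DEAResult], ndigits: int = 3) -> pd.DataFrame:
    """Report table: input slacks negated (reduction needed), outputs positive."""
    rows = []
    for r in results:
        row: dict[str, object] = {"dmu": r.dmu}
        for q, v in r.input_slacks.items():
            row[q] = round(-v, ndigits)
        for q, v in r.output_slacks.items():
            row[q] = round(v, ndigits)
        row["phi"] = round(r.phi, ndigits)
        row["te"] = round(r.te, ndigits)
        row["rts_class"] = r.rts_class
        rows.append(row)
    return pd.DataFrame(rows)
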