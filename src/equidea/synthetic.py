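"""Synthetic panels with known ground truth for every analysis stage.

Two generators are provided:

* :func:`gen_panel` draws a province-like panel from grouped log-normal
  laws — positive, right-skewed quantities with between-group level
  differences, within-group dispersion and deterministic secular growth —
  the statistical structure the equity measures assume.
* :func:`gen_frontier_panel` places DMUs on a constructed constant-returns
  production ray and radially contracts the outputs of non-frontier DMUs
  by known factors c_j, so DEA must recover φ = 1/c_j exactly; a
  Hicks-neutral shift g per year makes the true technical change g.

Randomness contract: a single integer seed drives one named stream per
quantity (fixed stream ids), so adding a quantity never perturbs the
draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .equity import ShareVector
from .panel import INPUT_QUANTITIES, OUTPUT_QUANTITIES, PanelRecord, ResourcePanel

__all__ = [
    "PanelSpec",
    "FrontierSpec",
    "gen_panel",
    "gen_frontier_panel",
    "gen_share_vector",
    "DEFAULT_GROUP_SIZES",
]

#: east/middle/west province counts of the mainland-China 31-DMU split
DEFAULT_GROUP_SIZES: dict[str, int] = {"eastern": 11, "middle": 8, "western": 12}

_QUANTITIES = INPUT_QUANTITIES + OUTPUT_QUANTITIES + ("population", "area_km2")

# fixed per-quantity stream ids — append-only registry
_STREAM_IDS: dict[str, int] = {
    "institutions": 0,
    "beds": 1,
    "staff": 2,
    "outpatient_visits": 3,
    "discharged_patients": 4,
    "population": 5,
    "area_km2": 6,
    "scale": 7,
    "inefficiency": 8,
    "shares_x": 9,
    "shares_y": 10,
    "noise": 11,
}

# typical province-level magnitudes (log means) and annualized growth of the
# national 2013-2017 health-resource totals
_DEFAULT_LOG_MEANS: dict[str, float] = {
    "institutions": np.log(1200.0),
    "beds": np.log(24000.0),
    "staff": np.log(18000.0),
    "outpatient_visits": np.log(2500.0),
    "discharged_patients": np.log(700000.0),
    "population": np.log(4.4e7),
    "area_km2": np.log(2.5e5),
}

_DEFAULT_GROWTH: dict[str, float] = {
    "institutions": 1.066,
    "beds": 1.094,
    "staff": 1.074,
    "outpatient_visits": 1.059,
    "discharged_patients": 1.097,
    "population": 1.005,
    "area_km2": 1.0,
}

_DEFAULT_SIGMAS: dict[str, float] = {
    "institutions": 0.55,
    "beds": 0.50,
    "staff": 0.50,
    "outpatient_visits": 0.55,
    "discharged_patients": 0.55,
    "population": 0.60,
    "area_km2": 0.85,
}

# additive log offsets per group: eastern provinces are resource-rich and
# dense, western ones sparse with large land area
_DEFAULT_GROUP_OFFSETS: dict[str, dict[str, float]] = {
    "eastern": {
        **{q: 0.6 for q in INPUT_QUANTITIES + OUTPUT_QUANTITIES},
        "population": 0.35,
        "area_km2": -0.6,
    },
    "middle": {
        **{q: 0.0 for q in INPUT_QUANTITIES + OUTPUT_QUANTITIES},
        "population": 0.1,
        "area_km2": -0.3,
    },
    "western": {
        **{q: -1.0 for q in INPUT_QUANTITIES + OUTPUT_QUANTITIES},
        "population": -0.5,
        "area_km2": 0.7,
    },
}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM_IDS[name],)))


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of the grouped log-normal panel generator."""

    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    years: tuple[int, ...] = (2013, 2014, 2015, 2016, 2017)
    log_means: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_LOG_MEANS))
    sigmas: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SIGMAS))
    group_offsets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in _DEFAULT_GROUP_OFFSETS.items()}
    )
    growth: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_GROWTH))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes or any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if len(self.years) < 1:
            raise ValueError("at least one year required")
        for q in _QUANTITIES:
            if self.sigmas.get(q, 0.0) < 0:
                raise ValueError(f"negative dispersion for {q}")
            if self.growth.get(q, 1.0) <= 0:
                raise ValueError(f"nonpositive growth for {q}")
        for g in self.group_sizes:
            if g not in self.group_offsets:
                raise ValueError(f"no level offsets for group {g!r}")


def _dmu_names(group_sizes: Mapping[str, int]) -> list[tuple[str, str]]:
    out = []
    for g in group_sizes:
        for i in range(group_sizes[g]):
            out.append((f"{g}_{i + 1:02d}", g))
    return out


def gen_panel(spec: PanelSpec) -> ResourcePanel:
    """Draw a reproducible grouped log-normal panel.

    Per quantity q and DMU j in group g, the base-year level is
    ``exp(mu_q + offset_{g,q} + sigma_q * z)`` with z standard normal from
    q's own stream; later years multiply by the deterministic growth
    factor of q.
    """
    names = _dmu_names(spec.group_sizes)
    n = len(names)
    base: dict[str, np.ndarray] = {}
    for q in _QUANTITIES:
        z = _stream(spec.seed, q).standard_normal(n)
        mu = np.array(
            [spec.log_means[q] + spec.group_offsets[g][q] for _, g in names]
        )
        base[q] = np.exp(mu + spec.sigmas[q] * z)
    records = []
    for yi, year in enumerate(spec.years):
        for j, (dmu, g) in enumerate(names):
            level = {q: base[q][j] * spec.growth[q] ** yi for q in _QUANTITIES}
            records.append(
                PanelRecord(
                    dmu=dmu,
                    year=year,
                    group=g,
                    inputs={q: level[q] for q in INPUT_QUANTITIES},
                    outputs={q: level[q] for q in OUTPUT_QUANTITIES},
                    population=level["population"],
                    area_km2=level["area_km2"],
                )
            )
    return ResourcePanel(tuple(records))


@dataclass(frozen=True)
class FrontierSpec:
    """Constructed constant-returns frontier with known inefficiencies.

    All DMUs share the input/output mix of a reference ray
    (``base_inputs``, ``base_outputs``) at random scales; a DMU with
    inefficiency factor c_j < 1 has its outputs multiplied by c_j, so its
    true radial expansion factor is 1/c_j.  Outputs additionally grow by
    the Hicks-neutral factor g each year (true techch = g under CRS).
    """

    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    years: tuple[int, ...] = (2013, 2014, 2015, 2016, 2017)
    base_inputs: tuple[float, ...] = (1200.0, 24000.0, 18000.0)
    base_outputs: tuple[float, ...] = (2500.0, 700000.0)
    scale_sigma: float = 0.6
    n_efficient: int = 8
    c_range: tuple[float, float] = (0.60, 0.95)
    c: Sequence[float] | None = None  # explicit per-DMU factors, overrides n_efficient
    g: float = 1.05
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("technology shift g must be > 0")
        if self.scale_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("dispersions must be >= 0")
        if any(v <= 0 for v in self.base_inputs + self.base_outputs):
            raise ValueError("base ray coordinates must be > 0")
        n = sum(self.group_sizes.values())
        if self.c is not None:
            if len(self.c) != n:
                raise ValueError(f"c must have one factor per DMU ({n})")
            if any(not 0 < cj <= 1 for cj in self.c):
                raise ValueError("inefficiency factors must lie in (0, 1]")
        elif not 0 <= self.n_efficient <= n:
            raise ValueError("n_efficient out of range")


def gen_frontier_panel(spec: FrontierSpec) -> tuple[ResourcePanel, pd.DataFrame]:
    """Panel plus a truth table of (dmu, year, true_phi, c, g)."""
    names = _dmu_names(spec.group_sizes)
    n = len(names)
    scales = np.exp(spec.scale_sigma * _stream(spec.seed, "scale").standard_normal(n))
    if spec.c is not None:
        c = np.asarray(spec.c, dtype=float)
    else:
        rng = _stream(spec.seed, "inefficiency")
        c = rng.uniform(*spec.c_range, size=n)
        # spread the efficient DMUs evenly over the roster
        eff_idx = np.linspace(0, n - 1, spec.n_efficient).round().astype(int) if spec.n_efficient else []
        c[eff_idx] = 1.0
    pop = np.exp(
        _DEFAULT_LOG_MEANS["population"]
        + 0.5 * _stream(spec.seed, "population").standard_normal(n)
    )
    area = np.exp(
        _DEFAULT_LOG_MEANS["area_km2"]
        + 0.5 * _stream(spec.seed, "area_km2").standard_normal(n)
    )
    noise = (
        np.exp(spec.noise_sigma * _stream(spec.seed, "noise").standard_normal((len(spec.years), n)))
        if spec.noise_sigma > 0
        else np.ones((len(spec.years), n))
    )
    x0 = np.asarray(spec.base_inputs)
    y0 = np.asarray(spec.base_outputs)
    records, truth = [], []
    for yi, year in enumerate(spec.years):
        shift = spec.g**yi
        for j, (dmu, grp) in enumerate(names):
            xs = scales[j] * x0
            ys = scales[j] * c[j] * shift * noise[yi, j] * y0
            records.append(
                PanelRecord(
                    dmu=dmu,
                    year=year,
                    group=grp,
                    inputs=dict(zip(INPUT_QUANTITIES, xs.tolist())),
                    outputs=dict(zip(OUTPUT_QUANTITIES, ys.tolist())),
                    population=float(pop[j]),
                    area_km2=float(area[j]),
                )
            )
            truth.append(
                {"dmu": dmu, "year": year, "true_phi": 1.0 / c[j], "c": c[j], "g": spec.g}
            )
    return ResourcePanel(tuple(records)), pd.DataFrame(truth)


def gen_share_vector(
    n: int,
    concentration: float = 1.0,
    seed: int = 0,
    base_concentration: float | None = None,
) -> ShareVector:
    """Random paired shares for property tests.

    Resource shares X are symmetric-Dirichlet(concentration): large values
    approach equal shares (Gini → 0), small values concentrate mass in few
    units (Lorenz Gini → 1 − 1/n against an equal base).  Base shares Y
    are equal unless ``base_concentration`` requests a Dirichlet draw.
    """
    if n < 2:
        raise ValueError("need at least 2 units")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    X = _stream(seed, "shares_x").dirichlet(np.full(n, concentration))
    if base_concentration is None:
        Y = np.full(n, 1.0 / n)
    else:
        Y = _stream(seed, "shares_y").dirichlet(np.full(n, base_concentration))
        Y = np.maximum(Y, 1e-12)
        Y = Y / Y.sum()
    units = tuple(f"u{i + 1:03d}" for i in range(n))
    return ShareVector(units, X, Y)
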