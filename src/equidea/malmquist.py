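"""Adjacent-period Malmquist productivity index and its four-way decomposition.

For each DMU, with output distance functions D^a(b) = 1/φ measured against
the period-a frontier at the period-b observation (CRS unless noted):

    effch  = D^{t+1}(t+1) / D^t(t)
    techch = [ (D^t(t+1)/D^{t+1}(t+1)) · (D^t(t)/D^{t+1}(t)) ]^{1/2}
    pech   = D_VRS^{t+1}(t+1) / D_VRS^t(t)
    sech   = effch / pech
    tfpch  = effch · techch

This is the Färe–Grosskopf–Norris–Zhang construction (the DEAP default):
the CRS technology carries effch/techch/tfpch while the pure-efficiency
term is measured against the VRS frontier, so the decomposition identities
hold exactly and cross-period problems stay feasible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dea import Technology, cross_distance
from .panel import ResourcePanel

__all__ = [
    "MalmquistComponents",
    "MalmquistSummary",
    "malmquist_pair",
    "malmquist_panel",
    "summarize",
]

log = logging.getLogger(__name__)

COMPONENTS = ("effch", "techch", "pech", "sech", "tfpch")

#: width of the "=1" class after 3-dp rounding in frequency tables
_UNITY_BAND = 5e-4


@dataclass(frozen=True)
class MalmquistComponents:
    dmu: str
    period_pair: tuple[int, int]
    effch: float
    techch: float
    pech: float
    sech: float
    tfpch: float

    def __post_init__(self) -> None:
        if abs(self.tfpch - self.effch * self.techch) > 1e-9:
            raise ValueError("tfpch must equal effch * techch")
        if abs(self.effch - self.pech * self.sech) > 1e-9:
            raise ValueError("effch must equal pech * sech")

    def component(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class MalmquistSummary:
    """Geometric-mean and frequency-distribution views of all period pairs."""

    by_dmu: pd.DataFrame      # index dmu, columns COMPONENTS (geomean over pairs)
    by_pair: pd.DataFrame     # index "t-t1", columns COMPONENTS (geomean over DMUs)
    frequency: pd.DataFrame   # index (pair, class in {">1","=1","<1"}), columns COMPONENTS
    overall: dict[str, float]  # geomean over all pairs of the per-pair means


def malmquist_pair(panel: ResourcePanel, t: int, t1: int) -> list[MalmquistComponents]:
    """Components for every DMU between adjacent periods ``t`` and ``t1``."""
    recs_t = {r.dmu: r for r in panel.year_records(t)}
    recs_t1 = {r.dmu: r for r in panel.year_records(t1)}
    asym = set(recs_t) ^ set(recs_t1)
    if asym:
        raise ValueError(
            f"periods {t} and {t1} are unbalanced; asymmetric DMUs: {sorted(asym)}"
        )
    crs_t = Technology.from_panel(panel, t, rts="CRS")
    crs_t1 = Technology.from_panel(panel, t1, rts="CRS")
    vrs_t = Technology.from_panel(panel, t, rts="VRS")
    vrs_t1 = Technology.from_panel(panel, t1, rts="VRS")

    out = []
    for dmu in crs_t.dmus:
        x_t, y_t = crs_t.column(dmu)
        x_t1, y_t1 = crs_t1.column(dmu)
        try:
            # D^a(b) = 1/phi^a(b)
            phi_t_t = cross_distance(crs_t, x_t, y_t)
            phi_t1_t1 = cross_distance(crs_t1, x_t1, y_t1)
            phi_t_t1 = cross_distance(crs_t, x_t1, y_t1)
            phi_t1_t = cross_distance(crs_t1, x_t, y_t)
            phi_v_t = cross_distance(vrs_t, x_t, y_t)
            phi_v_t1 = cross_distance(vrs_t1, x_t1, y_t1)
        except Exception as exc:  # pragma: no cover - guarded, CRS is feasible
            log.warning("Malmquist %s (%s,%s): %s — excluded", dmu, t, t1, exc)
            continue
        effch = phi_t_t / phi_t1_t1
        techch = math.sqrt((phi_t1_t1 / phi_t_t1) * (phi_t1_t / phi_t_t))
        pech = phi_v_t / phi_v_t1
        sech = effch / pech
        out.append(
            MalmquistComponents(
                dmu=dmu,
                period_pair=(t, t1),
                effch=effch,
                techch=techch,
                pech=pech,
                sech=sech,
                tfpch=effch * techch,
            )
        )
    return out


def malmquist_panel(panel: ResourcePanel) -> list[MalmquistComponents]:
    """Components for every adjacent year pair of the panel."""
    out: list[MalmquistComponents] = []
    for t, t1 in zip(panel.years[:-1], panel.years[1:]):
        out.extend(malmquist_pair(panel, t, t1))
    return out


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def _classify(value: float) -> str:
    r = round(value, 3)
    if abs(r - 1.0) <= _UNITY_BAND:
        return "=1"
    return ">1" if r > 1.0 else "<1"


def summarize(components: Sequence[MalmquistComponents]) -> MalmquistSummary:
    """Geometric means per DMU and per pair, plus >1/=1/<1 frequency tables.

    Frequency class membership is decided after rounding to 3 decimals,
    mirroring how DEAP-style tables are read.
    """
    if not components:
        raise ValueError("no Malmquist components to summarize")
    df = pd.DataFrame(
        [
            {
                "dmu": c.dmu,
                "pair": f"{c.period_pair[0]}-{c.period_pair[1]}",
                **{k: c.component(k) for k in COMPONENTS},
            }
            for c in components
        ]
    )
    by_dmu = df.groupby("dmu")[list(COMPONENTS)].agg(_geomean)
    by_pair = df.groupby("pair")[list(COMPONENTS)].agg(_geomean)
    freq_rows = []
    for pair, sub in df.groupby("pair"):
        for klass in (">1", "=1", "<1"):
            row = {"pair": pair, "class": klass}
            for comp in COMPONENTS:
                row[comp] = int(sum(_classify(v) == klass for v in sub[comp]))
            freq_rows.append(row)
    frequency = pd.DataFrame(freq_rows).set_index(["pair", "class"])
    overall = {k: _geomean(by_pair[k].to_numpy()) for k in COMPONENTS}
    return MalmquistSummary(by_dmu=by_dmu, by_pair=by_pair, frequency=frequency, overall=overall)
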