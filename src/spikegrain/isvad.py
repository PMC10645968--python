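"""Intra-spike variation as standard deviation (ISVAD) and derived indices.

ISVAD of a grain-size parameter is the *population* standard deviation of
that parameter across all N grains of one spike (divisor N, not N-1):

    sigma = sqrt( sum_i (x_i - mu)^2 ) / sqrt(N)

computed per whole spike and per spike region (bottom / middle / top) for
grain width (MinFeret), length (Feret), projected area and perimeter.  A
low ISVAD means the spike filled its grains uniformly.

Also provided: percent decrease of a trait mean under stress relative to
control, and the heat susceptibility index (HSI) in the Fischer-Maurer
formulation, HSI = (1 - Y_stress / Y_control) / D with D the trial-wide
mean relative depression under stress.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .morphometry import GrainMorphometrics
from .segment import SpikeLayout

__all__ = [
    "TRAITS",
    "REGIONS",
    "ISVADSummary",
    "isvad",
    "summarize_spike",
    "summaries_to_frame",
    "percent_change",
    "round_half_up",
    "heat_susceptibility_index",
    "mean_depression",
]

#: trait name -> GrainMorphometrics attribute
TRAITS: dict[str, str] = {
    "width": "minferet_mm",
    "length": "feret_mm",
    "area": "area_mm2",
    "perimeter": "perimeter_mm",
}

REGIONS = ("bottom", "middle", "top")


def isvad(values: Sequence[float]) -> float:
    """Population standard deviation of the values (divisor N).

    Zero for a single value; raises on an empty input.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("ISVAD of an empty set is undefined")
    mu = x.mean()
    return float(np.sqrt(np.sum((x - mu) ** 2) / x.size))


@dataclass
class ISVADSummary:
    """Per-spike and per-region ISVAD of the four grain-size traits."""

    spike_id: str
    n_grains: int
    mean: dict[str, float]               # trait -> mean across the spike
    isvad: dict[str, float]              # trait -> ISVAD across the spike
    mean_length_width_ratio: float
    region_n: dict[str, int] | None      # None when rows < 3
    region_mean: dict[str, dict[str, float]] | None   # region -> trait -> mean
    region_isvad: dict[str, dict[str, float]] | None  # region -> trait -> ISVAD
    n_rows: int = 0

    @property
    def regions_defined(self) -> bool:
        return self.region_n is not None


def summarize_spike(
    morphometrics: Sequence[GrainMorphometrics],
    layout: SpikeLayout,
    spike_id: str = "spike",
) -> ISVADSummary:
    """ISVAD summary of one measured spike.

    Region-level statistics need at least three spikelet rows to define the
    bottom/middle/top thirds; shorter spikes report them as missing.
    """
    if len(morphometrics) == 0:
        raise ValueError("no grains to summarize")
    if len(morphometrics) != layout.n_grains:
        raise ValueError("morphometrics and layout disagree on grain count")

    values = {t: np.array([getattr(m, attr) for m in morphometrics])
              for t, attr in TRAITS.items()}
    mean = {t: float(v.mean()) for t, v in values.items()}
    sigma = {t: isvad(v) for t, v in values.items()}
    lw = float(np.mean([m.feret_mm / m.minferet_mm for m in morphometrics]))

    region_n = region_mean = region_isvad = None
    if layout.regions_defined:
        region_n = {}
        region_mean = {}
        region_isvad = {}
        reg = np.array(layout.region)
        for r in REGIONS:
            sel = reg == r
            region_n[r] = int(sel.sum())
            region_mean[r] = {t: float(v[sel].mean()) for t, v in values.items()}
            region_isvad[r] = {t: isvad(v[sel]) for t, v in values.items()}

    return ISVADSummary(
        spike_id=spike_id,
        n_grains=len(morphometrics),
        mean=mean,
        isvad=sigma,
        mean_length_width_ratio=lw,
        region_n=region_n,
        region_mean=region_mean,
        region_isvad=region_isvad,
        n_rows=layout.n_rows,
    )


def summaries_to_frame(summaries: Sequence[ISVADSummary]) -> pd.DataFrame:
    """Flatten summaries into one row per spike (region columns included)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"spike_id": s.spike_id,
                                  "n_grains": s.n_grains,
                                  "n_rows": s.n_rows}
        for t in TRAITS:
            row[f"mean_{t}"] = s.mean[t]
            row[f"isvad_{t}"] = s.isvad[t]
        row["lw_ratio"] = s.mean_length_width_ratio
        for r in REGIONS:
            row[f"n_{r}"] = s.region_n[r] if s.region_n else np.nan
            for t in TRAITS:
                row[f"isvad_{t}_{r}"] = (
                    s.region_isvad[r][t] if s.region_isvad else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def percent_change(control_mean: float, treatment_mean: float) -> float:
    """Percent decrease of a trait mean from control to treatment.

    Positive when the trait decreased under treatment.  Use
    :func:`round_half_up` for display at one decimal.
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be > 0")
    return 100.0 * (control_mean - treatment_mean) / control_mean


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero (so 6.25 -> 6.3 at one decimal).

    Binary floats sit a hair off the decimal tie (0.03/0.48 stores as
    6.249999...); eight guard digits are rounded off first so that exact
    decimal ties are treated as ties.
    """
    d = Decimal(repr(value))
    d = d.quantize(Decimal(1).scaleb(-(decimals + 8)))
    return float(d.quantize(Decimal(1).scaleb(-decimals),
                            rounding=ROUND_HALF_UP))


def heat_susceptibility_index(
    y_stress: float, y_control: float, depression: float
) -> float:
    """Fischer-Maurer heat susceptibility index.

    HSI = (1 - y_stress / y_control) / D, where D is the trial-wide mean
    relative depression under stress (see :func:`mean_depression`).
    HSI < 1 marks a genotype more stable than the trial average.
    """
    if y_control <= 0:
        raise ValueError("y_control must be > 0")
    if not 0 < depression <= 1:
        raise ValueError("depression must be in (0, 1]")
    return (1.0 - y_stress / y_control) / depression


def mean_depression(stress_means: Sequence[float] | Mapping[str, float],
                    control_means: Sequence[float] | Mapping[str, float]) -> float:
    """Trial-wide depression D = 1 - mean(stress) / mean(control)."""
    if isinstance(stress_means, Mapping):
        stress_means = list(stress_means.values())
    if isinstance(control_means, Mapping):
        control_means = list(control_means.values())
    c = float(np.mean(control_means))
    if c <= 0:
        raise ValueError("control grand mean must be > 0")
    return 1.0 - float(np.mean(stress_means)) / c
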