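"""Deterministic calculators for the in vitro cholesterol and qPCR readouts.

* Cholesterol efflux: the fraction of fluorescent (NBD) cholesterol
  exported to the medium, 100 * FI_medium / (FI_medium + FI_lysate).
* Relative gene expression: the 2^-ddCt method against a GAPDH reference.
* Percent change: reduction of a treated mean relative to control, with
  increases reported as negative reductions.

Replicates are aggregated as the mean of per-replicate efflux percentages,
not the efflux of summed fluorescence.  An optional blank reading may be
subtracted before computation; background subtraction is otherwise not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class FluorescenceReading:
    """Medium / lysate fluorescence (arbitrary units, ex 469 nm / em 537 nm)."""

    fi_medium: float
    fi_lysate: float
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.fi_medium < 0 or self.fi_lysate < 0:
            raise ValueError("fluorescence intensities must be non-negative")


@dataclass(frozen=True)
class ExpressionMeasurement:
    """qPCR cycle thresholds for target and reference (GAPDH) in one well."""

    ct_target: float
    ct_reference: float
    sample_group: str = ""

    def __post_init__(self) -> None:
        for ct in (self.ct_target, self.ct_reference):
            if not 0.0 < ct < 45.0:
                raise ValueError("Ct values must lie in (0, 45) cycles")


def efflux_percent(r: FluorescenceReading, blank: float = 0.0) -> float:
    """Cholesterol efflux percentage, 100 * medium / (medium + lysate)."""
    med = max(r.fi_medium - blank, 0.0)
    lys = max(r.fi_lysate - blank, 0.0)
    total = med + lys
    if total <= 0:
        raise ValueError("medium + lysate fluorescence must be positive")
    return 100.0 * med / total


def mean_efflux_percent(readings: Sequence[FluorescenceReading], blank: float = 0.0) -> float:
    """Mean of per-replicate efflux percentages."""
    if not readings:
        raise ValueError("no readings")
    return mean(efflux_percent(r, blank) for r in readings)


def relative_expression(
    kd: Sequence[ExpressionMeasurement], ctrl: Sequence[ExpressionMeasurement]
) -> float:
    """Fold expression of the knockdown group by 2^-ddCt.

    dCt = Ct_target - Ct_reference per well; ddCt = mean dCt(kd) - mean
    dCt(ctrl); returned fold = 2^-ddCt (1.0 means no change, 0.5 means
    halved expression).
    """
    if not kd or not ctrl:
        raise ValueError("both groups must be non-empty")
    d_kd = mean(m.ct_target - m.ct_reference for m in kd)
    d_ctrl = mean(m.ct_target - m.ct_reference for m in ctrl)
    return 2.0 ** (-(d_kd - d_ctrl))


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Percent reduction of treated vs control; an increase comes out negative."""
    if control_mean == 0:
        raise ValueError("control mean must be non-zero")
    return 100.0 * (control_mean - treated_mean) / control_mean


def efflux_summary(readings: pd.DataFrame, blank: float = 0.0) -> pd.DataFrame:
    """Per-condition efflux summary from a TSV-style frame.

    Expects columns condition, replicate, fi_medium, fi_lysate.
    """
    rows = []
    for cond, grp in readings.groupby("condition", sort=True):
        rs = [
            FluorescenceReading(r.fi_medium, r.fi_lysate, cond, int(r.replicate))
            for r in grp.itertuples()
        ]
        rows.append(
            {
                "condition": cond,
                "n_replicates": len(rs),
                "mean_efflux_percent": mean_efflux_percent(rs, blank),
            }
        )
    return pd.DataFrame(rows)
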