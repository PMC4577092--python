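"""Control-based assay-quality statistics: Z′ factor and percent inhibition.

The Z′ factor summarizes the separation between the screen's two control
states,

    Z′ = 1 − 3·(σ_p + σ_n) / |μ_p − μ_n|,

where (μ_n, σ_n) describe the negative controls (DMSO vehicle; probe bound,
high FP) and (μ_p, σ_p) the positive controls (excess unlabeled RNA; probe
displaced, low FP).  Z′ ≤ 1 always; Z′ ≥ 0.5 is the conventional bar for an
HTS-ready assay.  Percent inhibition rescales a well so negative controls
read 0 and positive controls 100; artifact wells may legitimately fall
outside [0, 100] and are not clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_io import ScreenTable

__all__ = [
    "ControlStats",
    "control_stats",
    "per_plate_control_stats",
    "zprime",
    "per_plate_zprime",
    "percent_inhibition",
]


@dataclass(frozen=True)
class ControlStats:
    """Per-plate (or assay-global) control summary.

    ``p`` = positive (displaced, low-FP) controls; ``n`` = negative (DMSO,
    high-FP) controls.  σ uses the sample (n−1) denominator.
    """

    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float
    n_p: int
    n_n: int

    def __post_init__(self) -> None:
        if self.n_p < 2 or self.n_n < 2:
            raise ValueError("need >= 2 controls of each class")
        if self.sigma_p < 0 or self.sigma_n < 0:
            raise ValueError("control σ must be >= 0")


def _stats(values: np.ndarray) -> tuple[float, float, int]:
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1)), int(v.size)


def control_stats(table: ScreenTable, plate_id: str | None = None) -> ControlStats:
    """Control means/σ from a screen table, optionally restricted to one plate."""
    df = table.df if plate_id is None else table.df[table.df["plate_id"] == plate_id]
    pos = df.loc[df["role"] == "pos_control", "fp_mP"].to_numpy()
    neg = df.loc[df["role"] == "neg_control", "fp_mP"].to_numpy()
    if pos.size < 2 or neg.size < 2:
        raise ValueError(
            f"plate {plate_id or '<all>'}: needs >= 2 controls of each class "
            f"(found {pos.size} pos, {neg.size} neg)"
        )
    mu_p, sd_p, n_p = _stats(pos)
    mu_n, sd_n, n_n = _stats(neg)
    return ControlStats(mu_p, sd_p, mu_n, sd_n, n_p, n_n)


def per_plate_control_stats(table: ScreenTable) -> dict[str, ControlStats]:
    out: dict[str, ControlStats] = {}
    for plate in table.plates():
        try:
            out[plate] = control_stats(table, plate)
        except ValueError as e:
            warnings.warn(f"plate {plate} excluded from control stats: {e}")
    return out


def zprime(stats: ControlStats) -> float:
    """Z′ = 1 − 3(σp+σn)/|μp−μn|; raises when the control means coincide."""
    window = abs(stats.mu_p - stats.mu_n)
    if window == 0:
        raise ZeroDivisionError("Z' undefined: positive and negative control means coincide")
    return 1.0 - 3.0 * (stats.sigma_p + stats.sigma_n) / window


def per_plate_zprime(table: ScreenTable) -> dict[str, float]:
    """One Z′ per plate from that plate's own controls.

    Plates lacking a control class (or with coincident control means) are
    excluded with a warning rather than failing the whole screen.
    """
    out: dict[str, float] = {}
    for plate, stats in per_plate_control_stats(table).items():
        try:
            out[plate] = zprime(stats)
        except ZeroDivisionError as e:
            warnings.warn(f"plate {plate} excluded from Z': {e}")
    return out


def percent_inhibition(fp_well, stats: ControlStats):
    """%inhibition = 100·(μn − FP)/(μn − μp): 0 at the negative-control mean,
    100 at the positive-control mean, linear in FP and not clipped."""
    window = stats.mu_n - stats.mu_p
    if window == 0:
        raise ZeroDivisionError("percent inhibition undefined: zero assay window")
    fp = np.asarray(fp_well, dtype=float)
    out = 100.0 * (stats.mu_n - fp) / window
    return float(out) if out.ndim == 0 else out


def qc_report(table: ScreenTable) -> pd.DataFrame:
    """Per-plate QC table: control counts, means, σ and Z′."""
    rows = []
    for plate, s in per_plate_control_stats(table).items():
        try:
            z = zprime(s)
        except ZeroDivisionError:
            z = np.nan
        rows.append(
            {
                "plate_id": plate,
                "n_n": s.n_n,
                "n_p": s.n_p,
                "mu_n": s.mu_n,
                "mu_p": s.mu_p,
                "sigma_n": s.sigma_n,
                "sigma_p": s.sigma_p,
                "zprime": z,
            }
        )
    return pd.DataFrame(rows)
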