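"""Binding equilibria behind the fluorescence-polarization readout.

A fluorescently labeled RNA probe (L) binds a protein (P) with dissociation
constant ``kd``; an unlabeled competitor (I) — unlabeled RNA or a screening
compound — may compete for the same site with constant ``ki``.  The free probe
tumbles fast and reads low polarization; the protein-bound probe reads high.
These solvers give the exact equilibrium speciation under total-concentration
mass balance (no "free ≈ total" approximation), so they serve both as the
physics of the screen simulator and as the oracle against which the simplified
fit equations are compared.

All concentrations are nM internally; callers working in µM convert at the
boundary (1 µM = 1000 nM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "BindingSystem",
    "EquilibriumState",
    "FPSignalModel",
    "solve_single",
    "solve_competitive",
    "fp_signal",
]

#: relative tolerance to which mass balances must close
MASS_BALANCE_RTOL = 1e-9


@dataclass(frozen=True)
class BindingSystem:
    """Total concentrations and dissociation constants of a P + L (+ I) mixture.

    Parameters
    ----------
    p_tot, l_tot : float
        Total protein and labeled-probe concentrations, nM.
    kd : float
        Probe dissociation constant, nM (> 0).
    i_tot : float
        Total competitor concentration, nM (0 when absent).
    ki : float
        Competitor dissociation constant, nM; ignored when ``i_tot == 0``.
    """

    p_tot: float
    l_tot: float
    kd: float
    i_tot: float = 0.0
    ki: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("p_tot", "l_tot", "i_tot"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (math.isfinite(self.kd) and self.kd > 0):
            raise ValueError(f"kd must be finite and > 0, got {self.kd}")
        if self.i_tot > 0 and not (math.isfinite(self.ki) and self.ki > 0):
            raise ValueError(f"ki must be finite and > 0 when i_tot > 0, got {self.ki}")


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium speciation, nM: complexes (pl, pi) and free species."""

    pl: float
    pi: float
    p_free: float
    l_free: float
    i_free: float
    frac_bound: float

    def check_mass_balance(self, sys: BindingSystem) -> None:
        """Raise if any of the three mass balances is violated."""
        for got, tot, name in (
            (self.p_free + self.pl + self.pi, sys.p_tot, "protein"),
            (self.l_free + self.pl, sys.l_tot, "probe"),
            (self.i_free + self.pi, sys.i_tot, "competitor"),
        ):
            if abs(got - tot) > MASS_BALANCE_RTOL * max(tot, 1.0):
                raise ArithmeticError(
                    f"{name} mass balance violated: {got} vs total {tot}"
                )


@dataclass(frozen=True)
class FPSignalModel:
    """Maps equilibrium speciation to the observed (FP, total intensity) pair.

    ``fp_free``/``fp_bound`` are the polarizations (mP) of fully free and fully
    bound probe; ``q_ratio`` is the bound/free quantum-yield ratio (1 = no
    fluorescence change on binding); ``intensity_free`` is the total-intensity
    reading of the fully free probe at the assay probe concentration.
    """

    fp_free: float = 60.0
    fp_bound: float = 235.0
    q_ratio: float = 1.0
    intensity_free: float = 10000.0

    def __post_init__(self) -> None:
        if not self.fp_bound > self.fp_free:
            raise ValueError("fp_bound must exceed fp_free")
        if not self.q_ratio > 0:
            raise ValueError("q_ratio must be > 0")


def solve_single(sys: BindingSystem) -> EquilibriumState:
    """Exact single-site equilibrium P + L <-> PL (no competitor).

    Uses the physical root of the binding quadratic,

        pl = ((p + l + kd) - sqrt((p + l + kd)^2 - 4 p l)) / 2,

    evaluated in the numerically stable form 2pl / (b + sqrt(b^2 - 4pl)).
    """
    if sys.i_tot != 0:
        raise ValueError("solve_single requires i_tot == 0; use solve_competitive")
    p, l, kd = sys.p_tot, sys.l_tot, sys.kd
    if p == 0 or l == 0:
        pl = 0.0
    else:
        b = p + l + kd
        disc = math.sqrt(b * b - 4.0 * p * l)
        pl = 2.0 * p * l / (b + disc)
    state = EquilibriumState(
        pl=pl,
        pi=0.0,
        p_free=p - pl,
        l_free=l - pl,
        i_free=0.0,
        frac_bound=pl / l if l > 0 else 0.0,
    )
    state.check_mass_balance(sys)
    return state


def _protein_balance_residual(p_free: float, sys: BindingSystem) -> float:
    # Given free protein, both complexes follow in closed form; the residual is
    # the protein mass balance.  Monotone increasing in p_free.
    pl = p_free * sys.l_tot / (sys.kd + p_free)
    pi = p_free * sys.i_tot / (sys.ki + p_free) if sys.i_tot > 0 else 0.0
    return p_free + pl + pi - sys.p_tot


def solve_competitive(sys: BindingSystem) -> EquilibriumState:
    """Exact two-ligand competitive equilibrium P + L <-> PL, P + I <-> PI.

    Solved as a bracketed 1-D root find on the free-protein concentration over
    [0, p_tot] (the residual is monotone, so the root is unique), with the two
    complexes recovered by analytic back-substitution.  Reduces exactly to
    :func:`solve_single` when ``i_tot == 0``.
    """
    if sys.i_tot == 0:
        return solve_single(sys)
    p = sys.p_tot
    if p == 0:
        state = EquilibriumState(0.0, 0.0, 0.0, sys.l_tot, sys.i_tot, 0.0)
        state.check_mass_balance(sys)
        return state
    lo, hi = 0.0, p
    try:
        p_free = brentq(
            _protein_balance_residual, lo, hi, args=(sys,), xtol=1e-14, rtol=1e-15,
            maxiter=200,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - bracketed
        raise ArithmeticError(
            f"competitive solver failed: residual at bracket ends "
            f"{_protein_balance_residual(lo, sys)}, "
            f"{_protein_balance_residual(hi, sys)}"
        ) from exc
    pl = p_free * sys.l_tot / (sys.kd + p_free)
    pi = p_free * sys.i_tot / (sys.ki + p_free)
    state = EquilibriumState(
        pl=pl,
        pi=pi,
        p_free=p_free,
        l_free=sys.l_tot - pl,
        i_free=sys.i_tot - pi,
        frac_bound=pl / sys.l_tot if sys.l_tot > 0 else 0.0,
    )
    state.check_mass_balance(sys)
    return state


def fp_signal(state: EquilibriumState, model: FPSignalModel) -> tuple[float, float]:
    """Observed (fp_mP, total_intensity) of a mixed free/bound probe population.

    FP is the intensity-weighted average of the free and bound limiting
    polarizations, with weights ``q_ratio * [PL]`` and ``[L]free``; total
    intensity is proportional to the summed weight, normalized so that fully
    free probe reads ``intensity_free``.
    """
    l_tot = state.l_free + state.pl
    if l_tot <= 0:
        raise ValueError("undefined FP signal: no labeled probe present")
    w_b = model.q_ratio * state.pl
    w_f = state.l_free
    fp = (w_b * model.fp_bound + w_f * model.fp_free) / (w_b + w_f)
    intensity = model.intensity_free * (w_b + w_f) / l_tot
    return fp, intensity
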