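import numpy as np
import pytest

from fpscreen.screen_sim import SimConfig, simulate_screen


@pytest.fixture(scope="session")
def small_sim():
    """A one-plate screen (300 compounds) shared by fast tests."""
    cfg = SimConfig(n_compounds=300, seed=7)
    screen, truths = simulate_screen(cfg)
    return cfg, screen, truths


@pytest.fixture(scope="session")
def competitive_oracle():
    """Brute-force competitive-equilibrium solver, independent of the package.

    Nested bisection: the outer loop bisects free protein on [0, p_tot]; for
    each candidate, the two complex concentrations are themselves obtained by
    bisection on their dissociation equations (never by the package's
    closed-form back-substitution).  Vectorized over systems.
    """

    def solve(p, l, kd, i, ki, iters=100):
        p, l, kd, i, ki = (np.atleast_1d(np.asarray(a, float)) for a in (p, l, kd, i, ki))

        def complex_given(pf, tot, k):
            lo = np.zeros_like(tot)
            hi = tot.copy()
            for _ in range(iters):
                mid = 0.5 * (lo + hi)
                high = k * mid - pf * (tot - mid) > 0
                hi = np.where(high, mid, hi)
                lo = np.where(high, lo, mid)
            return 0.5 * (lo + hi)

        lo = np.zeros_like(p)
        hi = p.copy()
        for _ in range(iters):
            pf = 0.5 * (lo + hi)
            pl = complex_given(pf, l, kd)
            pi = complex_given(pf, i, ki)
            over = pf + pl + pi - p > 0
            hi = np.where(over, pf, hi)
            lo = np.where(over, lo, pf)
        pf = 0.5 * (lo + hi)
        return complex_given(pf, l, kd), complex_given(pf, i, ki), pf

    return solve
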