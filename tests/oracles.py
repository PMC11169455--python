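"""Independent oracles used by the test suite.

Deliberately naive re-implementations that share no code with the package:
rate laws are written out formula-by-formula, the ODE integrator is a
fixed-step classical RK4 loop, the LP oracle enumerates polytope vertices,
and group comparison is checked against a permutation test.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


# ---------------------------------------------------------------------------
# naive rate evaluation + fixed-step RK4

def naive_rates(model, conc: dict[str, float]) -> list[float]:
    """Evaluate every reaction rate directly from its law formula."""
    out = []
    for rxn in model.reactions:
        law = rxn.law
        s = [max(conc[m], 0.0) for m in law.substrate_ids]
        if law.law_type == "MM1":
            v = law.vmax * s[0] / (law.km + s[0])
        elif law.law_type == "MM2":
            v = law.vmax * s[0] * s[1] / ((law.km_a + s[0]) * (law.km_b + s[1]))
        elif law.law_type == "MM2_ping_pong":
            d = law.km_b * s[0] + law.km_a * s[1] + s[0] * s[1]
            v = law.vmax * s[0] * s[1] / d if d else 0.0
        elif law.law_type == "mass_action":
            v = law.k
            for x in s:
                v *= x
        elif law.law_type == "constant_flux":
            v = law.k
        else:
            raise AssertionError(law.law_type)
        out.append(v)
    return out


def rk4_trajectory(model, t_grid: np.ndarray, dt: float = 1e-3) -> np.ndarray:
    """Classical fixed-step RK4 solution sampled on t_grid (shape: met x time)."""
    ids = model.metabolite_ids
    clamped = {m.id for m in model.metabolites if m.boundary}

    def deriv(y: np.ndarray) -> np.ndarray:
        conc = dict(zip(ids, y))
        v = naive_rates(model, conc)
        dy = np.zeros_like(y)
        for j, rxn in enumerate(model.reactions):
            for met, coeff in rxn.stoichiometry.items():
                if met not in clamped:
                    dy[ids.index(met)] += coeff * v[j]
        return dy

    y = np.array(model.initial_state(), dtype=float)
    out = np.empty((len(ids), len(t_grid)))
    t = 0.0
    gi = 0
    if t_grid[0] == 0.0:
        out[:, 0] = y
        gi = 1
    t_end = float(t_grid[-1])
    n_steps = int(round(t_end / dt))
    for step in range(n_steps):
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = (step + 1) * dt
        while gi < len(t_grid) and t_grid[gi] <= t + 1e-12:
            out[:, gi] = y  # grid must align with step multiples
            gi += 1
    assert gi == len(t_grid), "t_grid points must be multiples of dt"
    return out


# ---------------------------------------------------------------------------
# LP oracle: brute-force vertex enumeration

def lp_vertex_max(A_eq: np.ndarray, lower, upper, c) -> tuple[float, np.ndarray]:
    """Maximize c·v over {A_eq v = 0, l <= v <= u} by enumerating vertices.

    Works for small problems only (n choose n-rank subsets times sign
    patterns).  Returns (best objective, argmax vertex).
    """
    A = np.atleast_2d(np.asarray(A_eq, dtype=float))
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    c = np.asarray(c, dtype=float)
    n = len(lower)
    rank = np.linalg.matrix_rank(A) if A.size else 0
    n_fix = n - rank
    best_val, best_v = -np.inf, None
    for fixed in combinations(range(n), n_fix):
        free = [i for i in range(n) if i not in fixed]
        for signs in product((0, 1), repeat=n_fix):
            v = np.empty(n)
            for i, s in zip(fixed, signs):
                v[i] = lower[i] if s == 0 else upper[i]
            if free:
                A_free = A[:, free]
                rhs = -A[:, fixed] @ v[list(fixed)] if n_fix else np.zeros(A.shape[0])
                sol, res, rk, _ = np.linalg.lstsq(A_free, rhs, rcond=None)
                if rk < len(free):
                    continue  # not a unique vertex
                v[free] = sol
            if np.any(np.abs(A @ v) > 1e-9):
                continue
            if np.any(v < lower - 1e-9) or np.any(v > upper + 1e-9):
                continue
            val = float(c @ v)
            if val > best_val:
                best_val, best_v = val, v.copy()
    return best_val, best_v


# ---------------------------------------------------------------------------
# permutation oracle for two-group comparison

def permutation_p_two_groups(a, b, exact_limit: int = 200_000) -> float:
    """Exact permutation p-value for |mean(a) - mean(b)| under relabelling."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = abs(a.mean() - b.mean())
    idx = range(len(pooled))
    count = 0
    total = 0
    for pick in combinations(idx, n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(pick)] = True
        diff = abs(pooled[mask].mean() - pooled[~mask].mean())
        if diff >= observed - 1e-12:
            count += 1
        total += 1
        if total > exact_limit:
            raise AssertionError("group too large for the exact oracle")
    return count / total
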