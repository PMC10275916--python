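"""Independent brute-force oracles built on scipy.optimize.linprog (HiGHS).

These re-solve the fixture problems from the raw stoichiometric arrays,
sharing no LP machinery with the package's GLPK/optlang path, so they can
serve as ground truth for gap-fill optimality, pFBA parsimony and flux
feasibility.
"""

from itertools import combinations

import numpy as np
from cobra.util.array import create_stoichiometric_matrix
from scipy.optimize import linprog

TOL = 1e-6


def model_arrays(model):
    """(S, lb, ub, reaction ids) pulled straight from the model structure."""
    S = create_stoichiometric_matrix(model)
    rxn_ids = [r.id for r in model.reactions]
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return S, lb, ub, rxn_ids


def max_objective(S, lb, ub, obj_idx):
    """LP: maximize v[obj_idx] s.t. S·v = 0, bounds. Returns optimum or None."""
    n = S.shape[1]
    c = np.zeros(n)
    c[obj_idx] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    return -res.fun if res.status == 0 else None


def min_subset_flux(S, lb, ub, obj_idx, subset_idx, min_growth):
    """Minimal Σ|v_i| over ``subset_idx`` with growth ≥ min_growth.

    Absolute values are linearized with one auxiliary t_i ≥ ±v_i per
    subset member.  Returns the optimum, or None when infeasible.
    """
    n = S.shape[1]
    k = len(subset_idx)
    c = np.concatenate([np.zeros(n), np.ones(k)])
    A_eq = np.hstack([S, np.zeros((S.shape[0], k))])
    rows = []
    for j, i in enumerate(subset_idx):
        row = np.zeros(n + k)
        row[i], row[n + j] = 1.0, -1.0
        rows.append(row)
        row = np.zeros(n + k)
        row[i], row[n + j] = -1.0, -1.0
        rows.append(row)
    growth_row = np.zeros(n + k)
    growth_row[obj_idx] = -1.0
    rows.append(growth_row)
    A_ub = np.vstack(rows)
    b_ub = np.concatenate([np.zeros(2 * k), [-min_growth]])
    bounds = list(zip(lb, ub)) + [(0.0, None)] * k
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(S.shape[0]), A_ub=A_ub,
                  b_ub=b_ub, bounds=bounds, method="highs")
    return res.fun if res.status == 0 else None


def bruteforce_min_candidate_flux(model, candidate_ids, objective_id, min_growth):
    """Enumerate every candidate subset; return the global minimal flux.

    For each subset the non-members are clamped to zero flux, a
    feasibility LP checks growth ≥ min_growth, and a second LP minimizes
    the summed absolute candidate flux.  Returns (best objective,
    best subset, number of feasible subsets); best objective is None when
    no subset sustains growth.
    """
    S, lb, ub, rxn_ids = model_arrays(model)
    idx = {r: i for i, r in enumerate(rxn_ids)}
    obj_idx = idx[objective_id]
    cand_idx = [idx[r] for r in candidate_ids]
    best, best_subset, feasible = None, None, 0
    for k in range(len(cand_idx) + 1):
        for subset in combinations(range(len(cand_idx)), k):
            lb_s, ub_s = lb.copy(), ub.copy()
            off = [cand_idx[j] for j in range(len(cand_idx)) if j not in subset]
            lb_s[off] = 0.0
            ub_s[off] = 0.0
            growth = max_objective(S, lb_s, ub_s, obj_idx)
            if growth is None or growth < min_growth - TOL:
                continue
            feasible += 1
            on = [cand_idx[j] for j in subset]
            value = (
                0.0 if not on
                else min_subset_flux(S, lb_s, ub_s, obj_idx, on, min_growth)
            )
            if value is not None and (best is None or value < best - 1e-12):
                best = value
                best_subset = {candidate_ids[j] for j in subset}
    return best, best_subset, feasible


def total_flux_alternatives(model, objective_id, fraction, n_directions, seed):
    """Σ|v| of random feasible vertices achieving fraction·z*.

    Optimizing random linear objectives over the growth-constrained
    polytope enumerates alternative flux distributions a pFBA solution
    must not exceed in total flux.
    """
    S, lb, ub, rxn_ids = model_arrays(model)
    obj_idx = rxn_ids.index(objective_id)
    z_star = max_objective(S, lb, ub, obj_idx)
    assert z_star is not None
    growth_row = np.zeros(S.shape[1])
    growth_row[obj_idx] = -1.0
    rng = np.random.default_rng(seed)
    totals = []
    for _ in range(n_directions):
        c = rng.standard_normal(S.shape[1])
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      A_ub=growth_row[None, :], b_ub=[-fraction * z_star],
                      bounds=list(zip(lb, ub)), method="highs")
        if res.status == 0:
            totals.append(float(np.abs(res.x).sum()))
    return z_star, totals
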