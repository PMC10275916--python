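"""Solver-facing analyses on constraint-based models.

FBA, parsimonious FBA, GPR evaluation, single-gene essentiality and
seeded hit-and-run flux sampling.  Models are plain :class:`cobra.Model`
objects, so everything here composes with the wider COBRApy toolbox.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import cobra
import numpy as np
import pandas as pd
from cobra.core.gene import GPR
from cobra.flux_analysis import pfba as _cobra_pfba
from cobra.util.array import create_stoichiometric_matrix
from scipy.linalg import null_space

from .constants import FLUX_TOLERANCE

logger = logging.getLogger(__name__)


class InfeasibleModelError(RuntimeError):
    """Raised when an LP required by an analysis has no feasible solution."""


@dataclass
class FluxDistribution:
    """One steady-state flux vector.

    ``fluxes`` indexes net flux by reaction id; ``objective_value`` is the
    flux through the model objective (``None`` when the LP was not solved
    to optimality — the ``status`` flag says why); ``total_flux`` is
    Σ|v| where the producing analysis minimizes it.
    """

    fluxes: pd.Series
    objective_value: float | None
    status: str
    total_flux: float | None = None


def fba(model: cobra.Model) -> FluxDistribution:
    """Flux balance analysis: maximize the objective subject to S·v = 0."""
    sol = model.optimize()
    if sol.status != "optimal":
        return FluxDistribution(pd.Series(dtype=float), None, sol.status)
    return FluxDistribution(sol.fluxes, float(sol.objective_value), "optimal")


def pfba(model: cobra.Model, fraction: float = 1.0) -> FluxDistribution:
    """Parsimonious FBA: minimize Σ|v| holding the objective at fraction·z*.

    Models minimal total enzyme usage at (near-)maximal growth.  The
    absolute-value objective is linearized by the forward/reverse variable
    split already present in the solver interface.
    """
    obj_ids = [r.id for r in model.reactions if r.objective_coefficient != 0]
    with model:
        sol = _cobra_pfba(model, fraction_of_optimum=fraction)
    if sol.status != "optimal":
        raise InfeasibleModelError(f"pFBA did not solve: status {sol.status}")
    obj_flux = float(sum(sol.fluxes[rid] for rid in obj_ids))
    return FluxDistribution(
        sol.fluxes, obj_flux, "optimal", total_flux=float(sol.objective_value)
    )


def evaluate_gpr(gpr: str, knocked: set[str] | frozenset[str] = frozenset()) -> bool:
    """Evaluate a boolean gene–protein–reaction rule under knockouts.

    Knocked genes are False, all others True; the empty rule is always
    active (spontaneous / orphan reactions survive any knockout).
    """
    if not gpr or not gpr.strip():
        return True
    return GPR.from_string(gpr).eval(knockouts=knocked)


def single_gene_deletion(
    model: cobra.Model, threshold_fraction: float = 0.01
) -> dict[str, str]:
    """Classify every gene as essential or nonessential by single knockout.

    A gene is essential when zeroing the reactions its loss inactivates
    (per GPR logic) drops the FBA optimum below ``threshold_fraction`` of
    the wild-type optimum (default 1%).
    """
    wild_type = model.slim_optimize()
    if not np.isfinite(wild_type) or wild_type <= 0:
        raise InfeasibleModelError(
            "wild-type model does not grow; essentiality is undefined"
        )
    calls: dict[str, str] = {}
    for gene in sorted(model.genes, key=lambda g: g.id):
        with model:
            model.genes.get_by_id(gene.id).knock_out()
            ko = model.slim_optimize()
        ko = 0.0 if not np.isfinite(ko) else max(ko, 0.0)
        calls[gene.id] = (
            "essential" if ko < threshold_fraction * wild_type else "nonessential"
        )
    return calls


def sample_fluxes(
    model: cobra.Model,
    n: int,
    seed: int,
    warmup: int = 100,
    thinning: int = 10,
) -> list[FluxDistribution]:
    """Seeded hit-and-run sampling of the steady-state flux polytope.

    Walks inside {v : S·v = 0, lb ≤ v ≤ ub} along random directions drawn
    from the null space of S, taking a uniform point on each feasible
    chord; after ``warmup`` burn-in steps, every ``thinning``-th point is
    recorded until ``n`` samples are collected.  Identical seeds give
    bitwise-identical output.  The contract is feasibility and determinism;
    no statistical-uniformity guarantee is asserted.
    """
    sol = model.optimize()
    if sol.status != "optimal":
        raise InfeasibleModelError(f"cannot sample an infeasible model: {sol.status}")
    rxn_ids = [r.id for r in model.reactions]
    obj_ids = {r.id for r in model.reactions if r.objective_coefficient != 0}
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    S = create_stoichiometric_matrix(model)
    basis = null_space(S)
    v = sol.fluxes.loc[rxn_ids].to_numpy(dtype=float)
    v = np.clip(v, lb, ub)

    rng = np.random.default_rng(seed)
    samples: list[FluxDistribution] = []
    if basis.shape[1] == 0:
        # Fully determined flux space: the solution point is the polytope.
        point = pd.Series(v, index=rxn_ids)
        obj = float(sum(point[r] for r in obj_ids))
        return [FluxDistribution(point.copy(), obj, "optimal") for _ in range(n)]

    step = 0
    needed = warmup + n * thinning
    while step < needed:
        step += 1
        direction = basis @ rng.standard_normal(basis.shape[1])
        norm = np.linalg.norm(direction)
        if norm < 1e-12:
            continue
        direction /= norm
        # Feasible chord [t_lo, t_hi] along the direction within the bounds.
        t_lo, t_hi = -np.inf, np.inf
        for i, d in enumerate(direction):
            if d > 1e-10:
                t_hi = min(t_hi, (ub[i] - v[i]) / d)
                t_lo = max(t_lo, (lb[i] - v[i]) / d)
            elif d < -1e-10:
                t_hi = min(t_hi, (lb[i] - v[i]) / d)
                t_lo = max(t_lo, (ub[i] - v[i]) / d)
        if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi <= t_lo:
            t = 0.0
        else:
            t = rng.uniform(t_lo, t_hi)
        v = np.clip(v + t * direction, lb, ub)
        if step > warmup and (step - warmup) % thinning == 0:
            point = pd.Series(v.copy(), index=rxn_ids)
            obj = float(sum(point[r] for r in obj_ids))
            samples.append(FluxDistribution(point, obj, "optimal"))
    return samples


def stoichiometric_residual(model: cobra.Model, fluxes: pd.Series) -> float:
    """Max |S·v| over metabolites — the steady-state feasibility residual."""
    S = create_stoichiometric_matrix(model)
    v = fluxes.loc[[r.id for r in model.reactions]].to_numpy(dtype=float)
    return float(np.max(np.abs(S @ v))) if S.size else 0.0
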