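"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they verify: the LP oracle enumerates
polytope vertices instead of calling a solver; the rule oracle evaluates the
original boolean string with Python's own evaluator; the gap-fill oracle
searches candidate subsets exhaustively.
"""

from __future__ import annotations

import itertools
import re

import numpy as np

from gemforge.model_core import MetabolicModel


def vertex_enumeration_optimum(model: MetabolicModel,
                               objective: str | None = None) -> float | None:
    """Maximum of the objective flux over {Sv=0, lb<=v<=ub} by enumerating
    basic solutions.  All bounds must be finite.  Returns None if no feasible
    vertex exists (the region, containing 0 for our generators, is then
    degenerate and the caller should skip)."""
    rxn_ids = list(model.reactions)
    met_ids = list(model.metabolites)
    n = len(rxn_ids)
    S = np.zeros((len(met_ids), n))
    for j, rid in enumerate(rxn_ids):
        for mid, coef in model.reactions[rid].stoichiometry.items():
            S[met_ids.index(mid), j] = float(coef)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    assert np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))
    obj = objective or model.objective[0]
    c = np.zeros(n)
    c[rxn_ids.index(obj)] = 1.0

    r = np.linalg.matrix_rank(S) if S.size else 0
    k = n - r  # number of bounds active at a vertex
    best = None
    for free in itertools.combinations(range(n), k):
        for pick in itertools.product([0, 1], repeat=k):
            rows = [S]
            rhs = [np.zeros(S.shape[0])]
            fixed = np.zeros(n)
            for idx, j in enumerate(free):
                e = np.zeros(n)
                e[j] = 1.0
                rows.append(e[None, :])
                rhs.append(np.array([lb[j] if pick[idx] == 0 else ub[j]]))
            A = np.vstack(rows)
            b = np.concatenate(rhs)
            if np.linalg.matrix_rank(A) < n:
                continue
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ v - b)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    return best


def eval_rule_string(rule: str, active: set[str]) -> bool:
    """Evaluate a gene-rule string under a knockout assignment, independently
    of the package's DNF machinery."""
    def repl(match: re.Match) -> str:
        tok = match.group(0)
        if tok.lower() in ("and", "or"):
            return tok.lower()
        return str(tok in active)

    expr = re.sub(r"[^\s()]+", repl, rule)
    return bool(eval(expr))  # noqa: S307 - controlled test input


def exhaustive_gap_fill_size(model: MetabolicModel, pool: MetabolicModel,
                             min_objective: float) -> int | None:
    """Minimum number of pool reactions whose addition restores growth,
    by exhaustive subset search (pool must be small)."""
    from gemforge.model_core import add_reactions
    from gemforge.simulate import fba

    candidates = [rid for rid in pool.reactions if rid not in model.reactions]
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            trial = add_reactions(model, pool, list(subset))
            sol = fba(trial)
            if sol.status == "optimal" and sol.objective_value >= min_objective - 1e-6:
                return size
    return None
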