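"""Constraint-based analysis: FBA, gap analysis, MILP gap filling, gene
essentiality, growth-media screening and FSEOF target scanning.

All linear programs share one formulation — maximize/minimize c·v subject to
steady state S·v = 0 and flux bounds lb ≤ v ≤ ub — solved with the HiGHS
solvers behind :func:`scipy.optimize.linprog` / :func:`scipy.optimize.milp`.
Fluxes are in mmol·gDW⁻¹·h⁻¹; the numerical tolerance is 1e-6 throughout and
is reported in result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .db_recon import UniversalModel
from .model_core import MetabolicModel, ModelError, Reaction

__all__ = [
    "EssentialityResult",
    "FluxDistribution",
    "FseofResult",
    "GapReport",
    "GrowthScreenResult",
    "TOL",
    "fba",
    "fseof",
    "gap_fill",
    "gap_report",
    "growth_screen",
    "single_gene_deletion",
]

TOL = 1e-6
BIG_M = 1000.0
ESSENTIALITY_CUTOFF = 0.25  # strict: "more than 75% reduction" in growth


# ---------------------------------------------------------------------------
# Shared LP scaffolding
# ---------------------------------------------------------------------------


class _Network:
    """Stoichiometric matrix plus index maps for one model."""

    def __init__(self, model: MetabolicModel):
        self.rxn_ids = list(model.reactions)
        self.met_ids = list(model.metabolites)
        met_pos = {m: i for i, m in enumerate(self.met_ids)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(self.rxn_ids):
            for mid, coef in model.reactions[rid].stoichiometry.items():
                rows.append(met_pos[mid])
                cols.append(j)
                vals.append(float(coef))
        self.S = sp.csr_matrix((vals, (rows, cols)),
                               shape=(len(self.met_ids), len(self.rxn_ids)))
        self.lb = np.array([model.reactions[r].lower_bound for r in self.rxn_ids])
        self.ub = np.array([model.reactions[r].upper_bound for r in self.rxn_ids])
        self.pos = {r: j for j, r in enumerate(self.rxn_ids)}

    def solve(self, c: np.ndarray, sense: str,
              lb: Optional[np.ndarray] = None, ub: Optional[np.ndarray] = None):
        lb = self.lb if lb is None else lb
        ub = self.ub if ub is None else ub
        obj = -c if sense == "maximize" else c
        res = linprog(obj, A_eq=self.S, b_eq=np.zeros(self.S.shape[0]),
                      bounds=np.column_stack([lb, ub]), method="highs")
        return res

    def min_total_flux(self, lb: np.ndarray, ub: np.ndarray) -> Optional[np.ndarray]:
        """Minimize Σ|v| over the feasible region (split-variable LP).

        Used to pick a solver-stable representative among degenerate optima.
        """
        n = len(self.rxn_ids)
        # variables: v (n), t (n) with t >= v, t >= -v
        c = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq = sp.hstack([self.S, sp.csr_matrix(self.S.shape)])
        eye = sp.identity(n, format="csr")
        A_ub = sp.vstack([sp.hstack([eye, -eye]), sp.hstack([-eye, -eye])])
        bounds = np.column_stack([
            np.concatenate([lb, np.zeros(n)]),
            np.concatenate([ub, np.full(n, np.inf)]),
        ])
        res = linprog(c, A_eq=A_eq, b_eq=np.zeros(self.S.shape[0]),
                      A_ub=A_ub, b_ub=np.zeros(2 * n), bounds=bounds, method="highs")
        if res.status != 0:
            return None
        return res.x[:n]


@dataclass
class FluxDistribution:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float
    fluxes: dict[str, float]
    tolerance: float = TOL

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


_STATUS = {0: "optimal", 1: "infeasible", 2: "infeasible", 3: "unbounded", 4: "infeasible"}


def fba(model: MetabolicModel, objective_override: Optional[tuple[str, str]] = None,
        bound_overrides: Optional[dict[str, tuple[float, float]]] = None,
        _net: Optional[_Network] = None) -> FluxDistribution:
    """Flux balance analysis: optimize the objective flux at steady state."""
    objective = objective_override or model.objective
    if objective is None:
        raise ModelError("model has no objective reaction")
    obj_rxn, sense = objective
    net = _net or _Network(model)
    if obj_rxn not in net.pos:
        raise ModelError(f"objective reaction {obj_rxn!r} not in model")
    lb, ub = net.lb.copy(), net.ub.copy()
    for rid, (lo, hi) in (bound_overrides or {}).items():
        j = net.pos[rid]
        lb[j], ub[j] = lo, hi
    c = np.zeros(len(net.rxn_ids))
    c[net.pos[obj_rxn]] = 1.0
    res = net.solve(c, sense, lb, ub)
    if res.status != 0:
        return FluxDistribution(status=_STATUS.get(res.status, "infeasible"),
                                objective_value=float("nan"), fluxes={})
    fluxes = {rid: float(res.x[j]) for rid, j in net.pos.items()}
    return FluxDistribution(status="optimal", objective_value=float(res.x[net.pos[obj_rxn]]),
                            fluxes=fluxes)


# ---------------------------------------------------------------------------
# Gap analysis
# ---------------------------------------------------------------------------


@dataclass
class GapReport:
    dead_end_metabolites: list[str]
    blocked_reactions: list[str]
    leaky_metabolites: list[str]
    consumable_from_nothing: list[str]
    components: list[set[str]]  # mixed metabolite/reaction ids per component
    tolerance: float = TOL


def _is_exchange(rxn: Reaction) -> bool:
    return rxn.exchange or len(rxn.stoichiometry) == 1


def gap_report(model: MetabolicModel) -> GapReport:
    """Dead ends, blocked reactions, leak/consumption tests and connectivity.

    Dead ends come from a reversibility-aware stoichiometric scan; blocked
    reactions from flux variability; the leak test closes exchange imports
    (lower bounds to 0), gives each metabolite a temporary sink and maximizes
    it — a positive optimum flags the metabolite as producible from nothing,
    indicating an unbalanced reaction.  The consumption test mirrors this with
    a temporary source and exchange upper bounds at 0.
    """
    net = _Network(model)
    produced: set[str] = set()
    consumed: set[str] = set()
    for rxn in model.reactions.values():
        for mid, coef in rxn.stoichiometry.items():
            if (coef > 0 and rxn.upper_bound > 0) or (coef < 0 and rxn.lower_bound < 0):
                produced.add(mid)
            if (coef < 0 and rxn.upper_bound > 0) or (coef > 0 and rxn.lower_bound < 0):
                consumed.add(mid)
    dead_ends = sorted(set(model.metabolites) - (produced & consumed))

    blocked: list[str] = []
    zero = np.zeros(len(net.rxn_ids))
    for rid, j in net.pos.items():
        c = zero.copy()
        c[j] = 1.0
        hi = net.solve(c, "maximize")
        if hi.status == 3:
            continue  # unbounded in this sense: certainly not blocked
        if hi.status == 0 and abs(hi.x[j]) > TOL:
            continue
        lo = net.solve(c, "minimize")
        if lo.status == 3:
            continue
        if lo.status == 0 and abs(lo.x[j]) > TOL:
            continue
        blocked.append(rid)

    met_pos = {m: i for i, m in enumerate(net.met_ids)}
    n = len(net.rxn_ids)

    def probe(close: str, direction: float) -> list[str]:
        lb, ub = net.lb.copy(), net.ub.copy()
        for rid, j in net.pos.items():
            if _is_exchange(model.reactions[rid]):
                if close == "lower":
                    lb[j] = max(lb[j], 0.0)
                else:
                    ub[j] = min(ub[j], 0.0)
        flagged = []
        for mid, i in met_pos.items():
            col = sp.csr_matrix(([direction], ([i], [0])), shape=(len(net.met_ids), 1))
            S_ext = sp.hstack([net.S, col])
            c = np.zeros(n + 1)
            c[n] = -1.0  # maximize the probe flux
            res = linprog(c, A_eq=S_ext, b_eq=np.zeros(len(net.met_ids)),
                          bounds=np.column_stack([np.append(lb, 0.0), np.append(ub, BIG_M)]),
                          method="highs")
            if res.status == 3 or (res.status == 0 and res.x[n] > TOL):
                flagged.append(mid)
        return sorted(flagged)

    leaky = probe("lower", -1.0)       # sink consumes the metabolite
    consumable = probe("upper", +1.0)  # source produces it; network must absorb

    graph = nx.Graph()
    graph.add_nodes_from(model.metabolites)
    graph.add_nodes_from(model.reactions)
    for rid, rxn in model.reactions.items():
        for mid in rxn.stoichiometry:
            graph.add_edge(rid, mid)
    components = [set(comp) for comp in nx.connected_components(graph)]
    components.sort(key=lambda s: (-len(s), min(s)))

    return GapReport(dead_end_metabolites=dead_ends, blocked_reactions=sorted(blocked),
                     leaky_metabolites=leaky, consumable_from_nothing=consumable,
                     components=components)


# ---------------------------------------------------------------------------
# Gap filling (minimal-cardinality MILP)
# ---------------------------------------------------------------------------


def gap_fill(model: MetabolicModel, universal: Union[UniversalModel, MetabolicModel],
             min_objective: float) -> list[str]:
    """Smallest set of database reactions restoring objective flux ≥ ``min_objective``.

    Binary indicator y_j per candidate with −M·y_j ≤ v_j ≤ M·y_j (M = 1000);
    minimize Σ y_j subject to steady state over the joint network and the
    objective floor.  Raises "unfillable" when even the full pool cannot reach
    the floor.
    """
    if model.objective is None:
        raise ModelError("model has no objective reaction")
    pool = universal.as_candidate_model() if isinstance(universal, UniversalModel) else universal
    candidates = [rid for rid in pool.reactions if rid not in model.reactions]

    wt = fba(model)
    if wt.status == "optimal" and wt.objective_value >= min_objective - TOL:
        return []

    rxns: list[tuple[str, Reaction]] = [(rid, model.reactions[rid]) for rid in model.reactions]
    rxns += [(rid, pool.reactions[rid]) for rid in candidates]
    met_ids: list[str] = sorted({m for _, rxn in rxns for m in rxn.stoichiometry})
    met_pos = {m: i for i, m in enumerate(met_ids)}
    n_v = len(rxns)
    n_y = len(candidates)

    rows, cols, vals = [], [], []
    for j, (_, rxn) in enumerate(rxns):
        for mid, coef in rxn.stoichiometry.items():
            rows.append(met_pos[mid])
            cols.append(j)
            vals.append(float(coef))
    S = sp.csr_matrix((vals, (rows, cols)), shape=(len(met_ids), n_v + n_y))

    lb = np.array([max(r.lower_bound, -BIG_M) for _, r in rxns] + [0.0] * n_y)
    ub = np.array([min(r.upper_bound, BIG_M) for _, r in rxns] + [1.0] * n_y)

    obj_rxn, sense = model.objective
    obj_j = next(j for j, (rid, _) in enumerate(rxns) if rid == obj_rxn)

    constraints = [LinearConstraint(S, 0.0, 0.0)]
    floor = np.zeros(n_v + n_y)
    floor[obj_j] = 1.0 if sense == "maximize" else -1.0
    constraints.append(LinearConstraint(floor, min_objective if sense == "maximize" else -np.inf,
                                        np.inf if sense == "maximize" else -min_objective))
    ind_rows, ind_cols, ind_vals = [], [], []
    for k, _ in enumerate(candidates):
        j = len(model.reactions) + k
        # v_j - M*y_k <= 0  and  -v_j - M*y_k <= 0
        ind_rows += [2 * k, 2 * k, 2 * k + 1, 2 * k + 1]
        ind_cols += [j, n_v + k, j, n_v + k]
        ind_vals += [1.0, -BIG_M, -1.0, -BIG_M]
    if n_y:
        A_ind = sp.csr_matrix((ind_vals, (ind_rows, ind_cols)), shape=(2 * n_y, n_v + n_y))
        constraints.append(LinearConstraint(A_ind, -np.inf, 0.0))

    c = np.concatenate([np.zeros(n_v), np.ones(n_y)])
    integrality = np.concatenate([np.zeros(n_v), np.ones(n_y)])
    res = milp(c=c, constraints=constraints, integrality=integrality,
               bounds=Bounds(lb, ub))
    if res.status != 0 or res.x is None:
        raise ModelError("unfillable: no candidate subset reaches the objective floor")
    chosen = [candidates[k] for k in range(n_y) if res.x[n_v + k] > 0.5]
    return sorted(chosen)


# ---------------------------------------------------------------------------
# Single-gene essentiality
# ---------------------------------------------------------------------------


@dataclass
class EssentialityResult:
    wild_type_growth: float
    per_gene: dict[str, dict]  # gene -> {growth, ratio, essential}
    cutoff: float = ESSENTIALITY_CUTOFF

    @property
    def essential_genes(self) -> set[str]:
        return {g for g, d in self.per_gene.items() if d["essential"]}


def single_gene_deletion(model: MetabolicModel,
                         cutoff: float = ESSENTIALITY_CUTOFF) -> EssentialityResult:
    """Knock out each gene in turn and re-run FBA.

    A reaction is disabled (bounds [0, 0]) when its gene rule evaluates false
    without the knocked-out gene; reactions without rules are untouched.  A
    gene is essential iff knockout/wild-type growth ratio < ``cutoff``
    (default 0.25, i.e. strictly more than 75 % growth-rate reduction).
    """
    net = _Network(model)
    wt = fba(model, _net=net)
    if wt.status != "optimal" or wt.objective_value <= TOL:
        raise ModelError("wild type does not grow; essentiality is undefined")
    all_genes = set(model.genes)
    per_gene: dict[str, dict] = {}
    for gene in model.genes:
        active = all_genes - {gene}
        overrides: dict[str, tuple[float, float]] = {}
        for rid, rxn in model.reactions.items():
            if rxn.gene_rule is not None and not rxn.gene_rule.evaluate(active):
                overrides[rid] = (0.0, 0.0)
        if overrides:
            ko = fba(model, bound_overrides=overrides, _net=net)
            growth = ko.objective_value if ko.status == "optimal" else 0.0
        else:
            growth = wt.objective_value
        ratio = max(growth, 0.0) / wt.objective_value
        per_gene[gene] = {"growth": growth, "ratio": ratio, "essential": ratio < cutoff}
    return EssentialityResult(wild_type_growth=wt.objective_value, per_gene=per_gene,
                              cutoff=cutoff)


# ---------------------------------------------------------------------------
# Growth-media screening
# ---------------------------------------------------------------------------


@dataclass
class GrowthScreenResult:
    per_condition: list[dict]  # {exchange, observed, predicted, objective}
    sensitivity: Optional[float]
    specificity: Optional[float]


def growth_screen(model: MetabolicModel, conditions: Sequence[dict],
                  minimal_media: Optional[dict[str, float]] = None,
                  default_bound: float = 10.0) -> GrowthScreenResult:
    """Predict growth per nutrient condition and score against observations.

    Each condition dict has ``exchange`` (exchange reaction id), optional
    ``uptake_bound`` (default 10) and optional boolean ``observed``.  For each
    condition all exchange imports are closed except the fixed minimal-media
    set and the condition's own exchange; growth means objective > 1e-6.
    """
    if not conditions:
        raise ModelError("empty condition list")
    minimal_media = minimal_media or {}
    net = _Network(model)
    for ex in minimal_media:
        if ex not in model.reactions:
            raise ModelError(f"minimal-media exchange {ex!r} not in model")
    base: dict[str, tuple[float, float]] = {}
    for rid, rxn in model.reactions.items():
        if _is_exchange(rxn):
            base[rid] = (0.0, rxn.upper_bound)
    for ex, bound in minimal_media.items():
        base[ex] = (-abs(bound), model.reactions[ex].upper_bound)

    rows: list[dict] = []
    tp = tn = fp = fn = 0
    for cond in conditions:
        ex = cond["exchange"]
        if ex not in model.reactions:
            raise ModelError(f"condition {cond!r}: unknown exchange reaction {ex!r}")
        overrides = dict(base)
        overrides[ex] = (-abs(cond.get("uptake_bound", default_bound)),
                         model.reactions[ex].upper_bound)
        sol = fba(model, bound_overrides=overrides, _net=net)
        grows = sol.status == "optimal" and sol.objective_value > TOL
        row = {"exchange": ex, "predicted": grows,
               "objective": sol.objective_value if sol.status == "optimal" else 0.0}
        if "observed" in cond:
            row["observed"] = bool(cond["observed"])
            if row["observed"] and grows:
                tp += 1
            elif row["observed"] and not grows:
                fn += 1
            elif not row["observed"] and grows:
                fp += 1
            else:
                tn += 1
        rows.append(row)
    sensitivity = tp / (tp + fn) if (tp + fn) else None
    specificity = tn / (tn + fp) if (tn + fp) else None
    return GrowthScreenResult(per_condition=rows, sensitivity=sensitivity,
                              specificity=specificity)


# ---------------------------------------------------------------------------
# FSEOF
# ---------------------------------------------------------------------------


@dataclass
class FseofResult:
    levels: list[float]                  # enforced product-flux lower bounds
    fluxes: dict[str, list[float]]       # reaction -> flux trajectory
    targets: set[str]
    direction: dict[str, int]            # 1 forward, -1 reverse, 0 irreversible
    slope: dict[str, float]              # final |flux| - initial |flux|
    v_product_max: float = 0.0
    tolerance: float = TOL


def fseof(model: MetabolicModel, biomass_rxn: str, product_rxn: str,
          n_levels: int = 10, max_fraction: float = 0.9,
          tol: float = TOL) -> FseofResult:
    """Flux scanning with enforced objective function.

    The product flux is stepped from its value at maximal growth up to
    ``max_fraction`` of its theoretical maximum in ``n_levels`` increments;
    at each level growth is maximized (with a secondary Σ|v| minimization for
    solver-stable trajectories).  Amplification targets are reactions whose
    absolute flux increases monotonically with constant sign.  Direction codes:
    0 for irreversible reactions, otherwise the sign of the carried flux.
    """
    for rid in (biomass_rxn, product_rxn):
        if rid not in model.reactions:
            raise ModelError(f"reaction {rid!r} not in model")
    net = _Network(model)
    c_prod = np.zeros(len(net.rxn_ids))
    c_prod[net.pos[product_rxn]] = 1.0
    res_max = net.solve(c_prod, "maximize")
    if res_max.status != 0 or res_max.x[net.pos[product_rxn]] <= tol:
        raise ModelError("product unreachable: maximum product flux is not positive")
    v_max = float(res_max.x[net.pos[product_rxn]])

    c_bio = np.zeros(len(net.rxn_ids))
    c_bio[net.pos[biomass_rxn]] = 1.0

    def biomass_step(product_floor: Optional[float]) -> np.ndarray:
        lb, ub = net.lb.copy(), net.ub.copy()
        if product_floor is not None:
            lb[net.pos[product_rxn]] = max(lb[net.pos[product_rxn]], product_floor)
        res = net.solve(c_bio, "maximize", lb, ub)
        if res.status != 0:
            raise ModelError(f"biomass LP infeasible at enforced product flux {product_floor}")
        growth = float(res.x[net.pos[biomass_rxn]])
        lb2, ub2 = lb.copy(), ub.copy()
        lb2[net.pos[biomass_rxn]] = growth - 1e-9
        v = net.min_total_flux(lb2, ub2)
        return v if v is not None else res.x

    v_base = biomass_step(None)
    v0 = float(v_base[net.pos[product_rxn]])

    levels: list[float] = []
    traj = [v_base]
    for k in range(1, n_levels + 1):
        floor = v0 + (k / n_levels) * (max_fraction * v_max - v0)
        levels.append(floor)
        traj.append(biomass_step(floor))

    fluxes = {rid: [float(v[j]) for v in traj] for rid, j in net.pos.items()}
    targets: set[str] = set()
    direction: dict[str, int] = {}
    slope: dict[str, float] = {}
    for rid, series in fluxes.items():
        absser = [abs(v) for v in series]
        monotone = all(absser[i + 1] >= absser[i] - tol for i in range(len(absser) - 1))
        increasing = absser[-1] > absser[0] + tol
        signs = {1 if v > tol else -1 for v in series if abs(v) > tol}
        sign_const = len(signs) <= 1
        slope[rid] = absser[-1] - absser[0]
        targets_it = monotone and increasing and sign_const
        if targets_it:
            targets.add(rid)
        if not model.reactions[rid].reversible:
            direction[rid] = 0
        elif signs:
            direction[rid] = signs.pop() if len(signs) == 1 else (
                1 if max(series, key=abs) > 0 else -1)
        else:
            direction[rid] = 1  # reversible, never carries flux: report forward
    return FseofResult(levels=levels, fluxes=fluxes, targets=targets,
                       direction=direction, slope=slope, v_product_max=v_max)
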