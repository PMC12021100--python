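"""Context-constrained flux balance analysis on packaged toy models.

The models are deliberately small stoichiometric networks (a glycolysis-like
core with oxidative phosphorylation, a lactate overflow branch, a tryptophan
-> kynurenine transport block and a biomass sink) standing in for a
genome-scale reconstruction.  Context integration is threshold gating of
gene-associated reactions (AND = min, OR = max over expression) plus scaling
of exchange bounds by relative metabolite levels, with a short task list the
contextualized model must still pass.

FBA maximizes the biomass objective subject to S v = 0 and bounds; fluxes
below 1e-7 mmol/gDCW/h are treated as inactive and a 250-unit display cut
flags figure-level fluxes, with log2 values attached to transport reactions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

INF = float("inf")


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]          # metabolite -> coefficient
    lb: float = 0.0
    ub: float = INF
    subsystem: str = ""
    gene_rule: str = ""
    objective: float = 0.0

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lb > ub")

    @property
    def is_exchange(self) -> bool:
        return self.subsystem == "exchange"

    @property
    def is_transport(self) -> bool:
        return self.subsystem == "transport"


@dataclass
class Task:
    name: str
    objective_reaction: str
    media: dict[str, float] = field(default_factory=dict)  # exchange rxn -> ub


@dataclass
class MetabolicModel:
    id: str
    reactions: list[Reaction]
    tasks: list[Task] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")
        objs = [r for r in self.reactions if r.objective != 0]
        if not objs:
            raise ValueError("model has no objective reaction")

    @property
    def metabolites(self) -> list[str]:
        mets: list[str] = []
        seen = set()
        for r in self.reactions:
            for m in r.stoich:
                if m not in seen:
                    seen.add(m)
                    mets.append(m)
        return mets

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        mets = self.metabolites
        mi = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoich.items():
                S[mi[m], j] = c
        return S, mets, [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(self.id, [replace(r, stoich=dict(r.stoich))
                                        for r in self.reactions],
                              [Task(t.name, t.objective_reaction, dict(t.media))
                               for t in self.tasks])


@dataclass
class FBAResult:
    status: str
    objective: float
    fluxes: pd.Series


def fba(model: MetabolicModel, objective_reaction: str | None = None) -> FBAResult:
    """Maximize the objective subject to S v = 0 and the bounds.

    Returns one optimal vertex; an unbounded problem raises an error naming
    the unbounded-capable reaction set (infinite-bound reactions).
    """
    S, _mets, rids = model.stoichiometric_matrix()
    c = np.zeros(len(rids))
    if objective_reaction is not None:
        c[rids.index(objective_reaction)] = 1.0
    else:
        for j, r in enumerate(model.reactions):
            c[j] = r.objective
    bounds = [(r.lb if np.isfinite(r.lb) else None,
               r.ub if np.isfinite(r.ub) else None) for r in model.reactions]
    res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    if res.status == 3:
        unbounded = [r.id for r in model.reactions
                     if not np.isfinite(r.ub) or not np.isfinite(r.lb)]
        raise ValueError(f"unbounded objective; infinite-bound reactions: {unbounded}")
    if res.status != 0:
        return FBAResult("infeasible", float("nan"),
                         pd.Series(np.nan, index=rids))
    return FBAResult("optimal", float(-res.fun), pd.Series(res.x, index=rids))


_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+")


def eval_gene_rule(rule: str, expression: dict[str, float],
                   default: float = 0.0) -> float:
    """Evaluate a simple AND/OR gene-reaction rule (AND = min, OR = max)."""
    tokens = _TOKEN.findall(rule)
    pos = 0

    def parse_or() -> float:
        nonlocal pos
        val = parse_and()
        while pos < len(tokens) and tokens[pos] == "or":
            pos += 1
            val = max(val, parse_and())
        return val

    def parse_and() -> float:
        nonlocal pos
        val = parse_atom()
        while pos < len(tokens) and tokens[pos] == "and":
            pos += 1
            val = min(val, parse_atom())
        return val

    def parse_atom() -> float:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            val = parse_or()
            if pos < len(tokens) and tokens[pos] == ")":
                pos += 1
            return val
        return float(expression.get(tok, default))

    if not tokens:
        raise ValueError("empty gene rule")
    return parse_or()


class TaskFailure(ValueError):
    def __init__(self, failed: list[str]):
        self.failed = failed
        super().__init__(f"context model fails tasks: {failed}")


def check_tasks(model: MetabolicModel, eps: float = 1e-9) -> list[str]:
    """Names of tasks whose objective cannot be made positive under the
    task's media overrides."""
    failed = []
    for t in model.tasks:
        m = model.copy()
        for rid, ub in t.media.items():
            r = m.reaction(rid)
            r.ub = ub
        res = fba(m, objective_reaction=t.objective_reaction)
        if res.status != "optimal" or res.objective <= eps:
            failed.append(t.name)
    return failed


def contextualize(model: MetabolicModel, expression: dict[str, float],
                  metabolite_levels: dict[str, float] | None = None,
                  expr_threshold: float = 0.5, bound_scale: float = 1.0,
                  reference: dict[str, float] | None = None) -> MetabolicModel:
    """Threshold-gate gene-associated reactions and scale exchange bounds.

    A reaction closes (bounds 0) when its gene rule evaluates below
    ``expr_threshold``; the exchange upper bound of each measured metabolite
    scales as ``bound_scale * level / reference``.  The contextualized model
    must still pass every task or it is rejected.
    """
    ctx = model.copy()
    ctx.id = model.id + "_ctx"
    for r in ctx.reactions:
        if r.gene_rule and eval_gene_rule(r.gene_rule, expression) < expr_threshold:
            r.lb, r.ub = 0.0, 0.0
    if metabolite_levels:
        reference = reference or {}
        for r in ctx.reactions:
            if not r.is_exchange:
                continue
            # exchange reactions touch exactly one metabolite
            met = next(iter(r.stoich))
            base = met.rsplit("_", 1)[0]
            if base in metabolite_levels and np.isfinite(r.ub) and r.ub > 0:
                ref = reference.get(base, 1.0)
                r.ub = r.ub * bound_scale * metabolite_levels[base] / ref
    failed = check_tasks(ctx)
    if failed:
        raise TaskFailure(failed)
    return ctx


def filter_fluxes(fluxes: pd.Series, model: MetabolicModel | None = None,
                  flux_eps: float = 1e-7, display_cut: float = 250.0) -> pd.DataFrame:
    """Drop fluxes with |v| < flux_eps; flag the display set |v| >= cut and
    attach log2(|v|) for transport reactions."""
    sub = {}
    transport = set()
    if model is not None:
        for r in model.reactions:
            sub[r.id] = r.subsystem
            if r.is_transport:
                transport.add(r.id)
    keep = fluxes[np.abs(fluxes) >= flux_eps]
    df = pd.DataFrame({
        "flux": keep,
        "direction": np.sign(keep).astype(int),
        "display": np.abs(keep) >= display_cut,
        "subsystem": [sub.get(r, "") for r in keep.index],
    })
    df["log2_abs"] = np.where(df.index.isin(list(transport)),
                              np.log2(np.abs(df["flux"])), np.nan)
    return df


def group_specific_fluxes(flux_tables: dict[str, pd.Series], target: str = "at-risk",
                          flux_eps: float = 1e-7) -> pd.DataFrame:
    """Classify each reaction as target-only, direction-flipped or shared.

    target-only: active in the target context, inactive in every other;
    direction-flipped: active in all contexts with the target's sign opposite
    to every other; shared: any other activity pattern; absent: inactive
    everywhere.
    """
    if target not in flux_tables:
        raise ValueError(f"missing group {target!r}")
    others = [g for g in flux_tables if g != target]
    if not others:
        raise ValueError("need at least two groups")
    all_rxns = sorted(set().union(*[set(t.index) for t in flux_tables.values()]))
    rows = []
    for rid in all_rxns:
        v = {g: float(flux_tables[g].get(rid, 0.0)) for g in flux_tables}
        active = {g: abs(v[g]) >= flux_eps for g in flux_tables}
        if active[target] and not any(active[o] for o in others):
            cls = "target-only"
        elif active[target] and all(active[o] for o in others) and \
                all(np.sign(v[o]) == -np.sign(v[target]) for o in others):
            cls = "direction-flipped"
        elif any(active.values()):
            cls = "shared"
        else:
            cls = "absent"
        rows.append({"reaction": rid, "class": cls, **{f"flux_{g}": v[g] for g in flux_tables}})
    return pd.DataFrame(rows).set_index("reaction")


def individual_flux_test(activity: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-reaction Fisher exact test of activity x group at the individual
    level (BH across reactions)."""
    from scipy.stats import fisher_exact as _fisher
    from .dpa import bh_adjust

    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) != 2:
        raise ValueError("individual flux test requires two groups")
    if min((labels == g).sum() for g in groups) < 2:
        raise ValueError("need at least 2 individuals per group")
    rows = []
    for rid in activity.columns:
        act = activity[rid].astype(bool).to_numpy()
        if not act.any():
            continue
        table = np.array([[np.sum(act & (labels == g)), np.sum(~act & (labels == g))]
                          for g in groups]).T
        _, p = _fisher(table, alternative="two-sided")
        rows.append({"reaction": rid, "p": float(p),
                     "active_" + str(groups[0]): int(table[0, 0]),
                     "active_" + str(groups[1]): int(table[0, 1])})
    df = pd.DataFrame(rows).set_index("reaction")
    if len(df):
        df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# packaged toy models
# ---------------------------------------------------------------------------

def toy_chain_model(uptake_ub: float = 5.0) -> MetabolicModel:
    """Minimal linear chain: uptake -> A -> biomass; objective = uptake bound."""
    rxns = [
        Reaction("EX_a_in", {"a_e": 1.0}, 0, uptake_ub, "exchange"),
        Reaction("At", {"a_e": -1.0, "a_c": 1.0}, 0, INF, "transport", "gAT"),
        Reaction("BIOMASS", {"a_c": -1.0, "bio": 1.0}, 0, INF, "biomass", objective=1.0),
        Reaction("EX_bio", {"bio": -1.0}, 0, INF, "exchange"),
    ]
    tasks = [Task("biomass_on_a", "BIOMASS", {})]
    return MetabolicModel("toy_chain", rxns, tasks)


def toy_cell_model() -> MetabolicModel:
    """Glycolysis-like toy cell with oxphos, lactate overflow, a tryptophan
    -> kynurenine transport block and a biomass objective (~25 reactions)."""
    rxns = [
        Reaction("EX_glc", {"glc_e": 1.0}, 0, 5.0, "exchange"),
        Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, 0, INF, "transport", "gGLUT1"),
        Reaction("HEX1", {"glc_c": -1, "atp": -1, "g6p": 1, "adp": 1}, 0, INF,
                 "glycolysis", "gHK1 or gHK2"),
        Reaction("PGI", {"g6p": -1, "f6p": 1}, -INF, INF, "glycolysis", "gPGI"),
        Reaction("PFK", {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1}, 0, INF,
                 "glycolysis", "gPFK"),
        Reaction("FBA", {"fdp": -1, "g3p": 2}, 0, INF, "glycolysis", "gALDOA"),
        Reaction("GAPD", {"g3p": -1, "nad": -1, "adp": -1, "pg3": 1, "nadh": 1,
                          "atp": 1}, 0, INF, "glycolysis", "gGAPDH and gPGK1"),
        Reaction("PYK", {"pg3": -1, "adp": -1, "pyr": 1, "atp": 1}, 0, INF,
                 "glycolysis", "gPKM"),
        Reaction("LDH", {"pyr": -1, "nadh": -1, "lac_c": 1, "nad": 1}, -INF, INF,
                 "fermentation", "gLDHA"),
        Reaction("LACt", {"lac_c": -1, "lac_e": 1}, 0, INF, "transport", "gMCT1"),
        Reaction("EX_lac", {"lac_e": -1}, 0, INF, "exchange"),
        Reaction("PDH", {"pyr": -1, "nad": -1, "accoa": 1, "nadh": 1, "co2": 1},
                 0, INF, "tca", "gPDHA1"),
        Reaction("TCA", {"accoa": -1, "nad": -3, "adp": -1, "nadh": 3, "atp": 1,
                         "co2": 2}, 0, INF, "tca", "gCS and gIDH3A"),
        Reaction("OXPHOS", {"nadh": -1, "o2": -0.5, "adp": -2, "nad": 1, "atp": 2},
                 0, INF, "oxphos", "gNDUFA1 and gATP5F1"),
        Reaction("EX_o2", {"o2": 1.0}, 0, 1000.0, "exchange"),
        Reaction("EX_co2", {"co2": -1.0}, 0, INF, "exchange"),
        Reaction("ATPM", {"atp": -1, "adp": 1}, 0, INF, "maintenance"),
        Reaction("EX_trp", {"trp_e": 1.0}, 0, 1.0, "exchange"),
        Reaction("TRPt", {"trp_e": -1, "trp_c": 1}, 0, INF, "transport", "gSLC7A5"),
        Reaction("IDO", {"trp_c": -1, "kyn_c": 1}, 0, INF, "tryptophan", "gIDO1"),
        Reaction("KYNt", {"kyn_c": -1, "kyn_e": 1}, 0, INF, "transport", "gSLC7A11"),
        Reaction("EX_kyn", {"kyn_e": -1}, 0, INF, "exchange"),
        Reaction("BIOMASS", {"g6p": -1, "pyr": -1, "atp": -2, "trp_c": -0.1,
                             "adp": 2, "bio": 1}, 0, INF, "biomass", objective=1.0),
        Reaction("EX_bio", {"bio": -1}, 0, INF, "exchange"),
    ]
    tasks = [
        Task("biomass_on_glucose", "BIOMASS", {}),
        Task("atp_from_glucose", "ATPM", {}),
        Task("kynurenine_secretion", "EX_kyn", {}),
    ]
    return MetabolicModel("toy_cell", rxns, tasks)


# ---------------------------------------------------------------------------
# tabular model I/O
# ---------------------------------------------------------------------------

def write_model(model: MetabolicModel, stoich_path: str | Path,
                reactions_path: str | Path) -> None:
    srows = [{"reaction": r.id, "metabolite": m, "coefficient": c}
             for r in model.reactions for m, c in r.stoich.items()]
    pd.DataFrame(srows).to_csv(stoich_path, sep="\t", index=False)
    rrows = [{"reaction": r.id, "lb": r.lb, "ub": r.ub, "subsystem": r.subsystem,
              "gene_rule": r.gene_rule, "objective": r.objective}
             for r in model.reactions]
    pd.DataFrame(rrows).to_csv(reactions_path, sep="\t", index=False)


def read_model(stoich_path: str | Path, reactions_path: str | Path,
               model_id: str = "model") -> MetabolicModel:
    stoich = pd.read_csv(stoich_path, sep="\t")
    rtab = pd.read_csv(reactions_path, sep="\t", keep_default_na=False,
                       na_values=[], dtype={"gene_rule": str, "subsystem": str})
    by_rxn: dict[str, dict[str, float]] = {}
    for _, row in stoich.iterrows():
        by_rxn.setdefault(row["reaction"], {})[row["metabolite"]] = float(row["coefficient"])
    rxns = []
    for _, row in rtab.iterrows():
        rxns.append(Reaction(row["reaction"], by_rxn.get(row["reaction"], {}),
                             float(row["lb"]), float(row["ub"]),
                             str(row["subsystem"]), str(row["gene_rule"]),
                             float(row["objective"])))
    return MetabolicModel(model_id, rxns)
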