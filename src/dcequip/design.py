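"""Experimental design for paired discrete choice experiments.

Builds the scenario catalogue (full factorial or a level-balanced,
near-orthogonal fraction found by seeded search), pairs every scenario
against one fixed comparator, and partitions the resulting choice sets
into respondent blocks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AttributeSpec",
    "Scenario",
    "ChoiceSet",
    "DesignDiagnostics",
    "DesignPlan",
    "enumerate_full_factorial",
    "generate_fractional_design",
    "design_diagnostics",
    "build_choice_sets",
    "block_design",
    "check_dominance",
    "choose_comparator",
    "read_attributes",
    "write_attributes",
    "read_design",
    "write_design",
    "read_choice_sets",
    "write_choice_sets",
]


@dataclass(frozen=True)
class AttributeSpec:
    """One experimental attribute and its levels.

    ``numeric_values`` carries the per-level value for continuous
    attributes (e.g. annual remuneration in euros); categorical
    attributes leave it ``None``.
    """

    name: str
    levels: tuple[str, ...]
    kind: str = "categorical"  # "categorical" | "continuous"
    numeric_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError(f"attribute {self.name!r} has no levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"attribute {self.name!r} has duplicate levels")
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.kind == "continuous":
            if self.numeric_values is None or len(self.numeric_values) != len(self.levels):
                raise ValueError(
                    f"continuous attribute {self.name!r} needs one numeric value per level"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def numeric(self, level: str) -> float:
        """Numeric value of a level (index order for categoricals)."""
        idx = self.levels.index(level)
        if self.numeric_values is not None:
            return float(self.numeric_values[idx])
        return float(idx)


@dataclass(frozen=True)
class Scenario:
    """A complete attribute profile (one hypothetical program)."""

    scenario_id: int
    assignment: tuple[tuple[str, str], ...]  # (attribute, level) pairs

    def level(self, attribute: str) -> str:
        for a, lvl in self.assignment:
            if a == attribute:
                return lvl
        raise KeyError(attribute)

    def as_dict(self) -> dict[str, str]:
        return dict(self.assignment)


@dataclass(frozen=True)
class ChoiceSet:
    """A forced pair: candidate scenario versus the fixed comparator."""

    set_id: int
    alternatives: tuple[Scenario, Scenario]  # (candidate, comparator)
    block_id: int | None = None

    def __post_init__(self) -> None:
        if len(self.alternatives) != 2:
            raise ValueError("a choice set holds exactly two alternatives")


@dataclass(frozen=True)
class DesignDiagnostics:
    level_counts: dict[str, dict[str, int]]
    max_abs_column_correlation: float
    d_efficiency: float
    undefined_correlations: tuple[tuple[str, str], ...] = ()
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class DesignPlan:
    attributes: tuple[AttributeSpec, ...]
    scenarios: tuple[Scenario, ...]
    choice_sets: tuple[ChoiceSet, ...] = ()
    n_blocks: int = 0
    diagnostics: DesignDiagnostics | None = None
    seed: int | None = None

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def scenario(self, scenario_id: int) -> Scenario:
        for s in self.scenarios:
            if s.scenario_id == scenario_id:
                return s
        raise KeyError(scenario_id)


def enumerate_full_factorial(attributes: list[AttributeSpec]) -> list[Scenario]:
    """Cartesian product of all attribute levels.

    The count equals the product of per-attribute level counts (864 for
    the bundled eight-attribute table with levels 3,3,2,3,2,2,2,2).
    """
    if not attributes:
        raise ValueError("no attributes")
    names = [a.name for a in attributes]
    out = []
    for i, combo in enumerate(itertools.product(*(a.levels for a in attributes)), start=1):
        out.append(Scenario(scenario_id=i, assignment=tuple(zip(names, combo))))
    return out


def _effects_columns(attributes: tuple[AttributeSpec, ...] | list[AttributeSpec]):
    """Internal effects coding used for design diagnostics only.

    Categorical attributes: last declared level is the reference (-1 on
    every column); continuous attributes contribute their numeric value
    as a single column. Coding choice only matters for correlations
    between columns of multi-level categoricals; any full-rank effects
    coding gives the same balance behaviour.
    """
    cols: list[tuple[str, str]] = []  # (attribute, column label)
    coders: list[tuple[str, callable]] = []
    for a in attributes:
        if a.kind == "continuous":
            cols.append((a.name, a.name))

            def make_cont(a=a):
                return lambda lvl: np.array([a.numeric(lvl)])

            coders.append((a.name, make_cont()))
        else:
            non_ref = a.levels[:-1]
            for lvl in non_ref:
                cols.append((a.name, f"{a.name}:{lvl}"))

            def make_cat(a=a, non_ref=non_ref):
                def f(lvl):
                    v = np.zeros(len(non_ref))
                    if lvl == a.levels[-1]:
                        v[:] = -1.0
                    else:
                        v[non_ref.index(lvl)] = 1.0
                    return v

                return f

            coders.append((a.name, make_cat()))
    return cols, coders


def _coded_matrix(scenarios, attributes):
    cols, coders = _effects_columns(attributes)
    rows = []
    for s in scenarios:
        parts = [f(s.level(name)) for name, f in coders]
        rows.append(np.concatenate(parts))
    return np.asarray(rows), cols


def design_diagnostics(
    scenarios: list[Scenario], attributes: list[AttributeSpec]
) -> DesignDiagnostics:
    """Level balance, cross-attribute correlation and D-efficiency.

    Correlations are computed between effects-coded columns belonging to
    different attributes; a constant column's correlations are reported
    as undefined rather than raising. D-efficiency is
    ``det(X'X / n) ** (1/p)`` on the column-normalised coded matrix with
    ``p`` coded columns.
    """
    if len(scenarios) < 2:
        raise ValueError("need at least two scenarios for diagnostics")
    level_counts = {
        a.name: {lvl: sum(1 for s in scenarios if s.level(a.name) == lvl) for lvl in a.levels}
        for a in attributes
    }
    X, cols = _coded_matrix(scenarios, attributes)
    n, p = X.shape
    sd = X.std(axis=0)
    undefined = []
    max_corr = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            if cols[i][0] == cols[j][0]:
                continue  # same attribute: within-attribute coding correlation is structural
            if sd[i] == 0 or sd[j] == 0:
                undefined.append((cols[i][1], cols[j][1]))
                continue
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            max_corr = max(max_corr, abs(float(r)))
    # D-efficiency on max-abs-normalised columns so euro-scale continuous
    # attributes do not dominate the determinant.
    scale = np.abs(X).max(axis=0)
    scale[scale == 0] = 1.0
    Xn = X / scale
    M = Xn.T @ Xn / n
    det = float(np.linalg.det(M))
    d_eff = det ** (1.0 / p) if det > 0 else 0.0
    return DesignDiagnostics(
        level_counts=level_counts,
        max_abs_column_correlation=float(max_corr),
        d_efficiency=float(d_eff),
        undefined_correlations=tuple(undefined),
    )


def _balanced_column(levels: tuple[str, ...], n_runs: int, rng: np.random.Generator):
    """Column with each level repeated as equally as possible."""
    L = len(levels)
    base, extra = divmod(n_runs, L)
    counts = [base + (1 if i < extra else 0) for i in range(L)]
    col = [lvl for lvl, c in zip(levels, counts) for _ in range(c)]
    rng.shuffle(col)
    return col, extra == 0


def _corr_objective(X: np.ndarray, attr_of_col: np.ndarray) -> tuple[float, float]:
    """(max |corr|, sum corr^2) over cross-attribute column pairs.

    The second component breaks ties between designs with the same worst
    pair, which keeps the swap search from stalling on the flat max
    objective.
    """
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xc = (X - X.mean(axis=0))
        denom = np.where(sd > 0, sd, 1.0)
        Z = Xc / denom
        C = Z.T @ Z / X.shape[0]
    p = X.shape[1]
    mask = (attr_of_col[:, None] != attr_of_col[None, :]) & (sd[:, None] > 0) & (sd[None, :] > 0)
    mask &= ~np.eye(p, dtype=bool)
    if not mask.any():
        return 0.0, 0.0
    vals = C[mask]
    return float(np.abs(vals).max()), float((vals**2).sum())


def _max_abs_corr(X: np.ndarray, attr_of_col: np.ndarray) -> float:
    return _corr_objective(X, attr_of_col)[0]


def generate_fractional_design(
    attributes: list[AttributeSpec],
    n_runs: int,
    seed: int = 0,
    n_iter: int = 10_000,
) -> DesignPlan:
    """Level-balanced, near-orthogonal fractional design by seeded search.

    Starts from independently shuffled exactly-balanced columns and
    performs pairwise swaps within one attribute's column at a time,
    keeping the best design seen (objective: maximum absolute pairwise
    correlation between effects-coded columns of different attributes).
    Deterministic given ``seed``. Exact balance requires ``n_runs``
    divisible by every attribute's level count; otherwise a best-effort
    balance is used and a warning is recorded in the diagnostics.
    """
    if not attributes:
        raise ValueError("no attributes")
    full = 1
    for a in attributes:
        full *= a.n_levels
    if n_runs > full:
        raise ValueError(f"n_runs={n_runs} exceeds the full factorial size {full}")
    rng = np.random.default_rng(seed)
    warnings = []
    columns: dict[str, list[str]] = {}
    for a in attributes:
        col, exact = _balanced_column(a.levels, n_runs, rng)
        columns[a.name] = col
        if not exact:
            warnings.append(
                f"attribute {a.name!r}: {n_runs} runs not divisible by {a.n_levels} levels; "
                "best-effort balance"
            )

    names = [a.name for a in attributes]

    def scenarios_from(cols):
        return [
            Scenario(scenario_id=i + 1, assignment=tuple((nm, cols[nm][i]) for nm in names))
            for i in range(n_runs)
        ]

    # Precompute coded representation per attribute level for fast objective.
    _, coders = _effects_columns(attributes)
    coder = dict(coders)
    widths = {a.name: len(coder[a.name](a.levels[0])) for a in attributes}
    attr_of_col = np.concatenate(
        [np.full(widths[nm], k) for k, nm in enumerate(names)]
    )

    def coded(cols):
        parts = []
        for nm in names:
            parts.append(np.asarray([coder[nm](lvl) for lvl in cols[nm]]))
        return np.concatenate(parts, axis=1)

    current = {nm: list(columns[nm]) for nm in names}
    cur_obj = _corr_objective(coded(current), attr_of_col)
    best = {nm: list(current[nm]) for nm in names}
    best_obj = cur_obj
    swappable = [nm for nm in names if len(set(current[nm])) > 1]
    for _ in range(n_iter):
        if best_obj[0] == 0.0 or not swappable:
            break
        nm = swappable[rng.integers(len(swappable))]
        i, j = rng.integers(n_runs), rng.integers(n_runs)
        if current[nm][i] == current[nm][j]:
            continue
        current[nm][i], current[nm][j] = current[nm][j], current[nm][i]
        obj = _corr_objective(coded(current), attr_of_col)
        if obj <= cur_obj:  # accept sideways moves, keep best separately
            cur_obj = obj
            if obj < best_obj:
                best_obj = obj
                best = {nm2: list(current[nm2]) for nm2 in names}
        else:
            current[nm][i], current[nm][j] = current[nm][j], current[nm][i]

    scen = scenarios_from(best)
    diag = design_diagnostics(scen, attributes)
    if diag.max_abs_column_correlation > 0.05:
        warnings.append(
            "max absolute column correlation "
            f"{diag.max_abs_column_correlation:.4f} exceeds 0.05"
        )
    diag = replace(diag, warnings=tuple(warnings))
    return DesignPlan(
        attributes=tuple(attributes),
        scenarios=tuple(scen),
        diagnostics=diag,
        seed=seed,
    )


def build_choice_sets(plan: DesignPlan, comparator_id: int) -> DesignPlan:
    """Pair every non-comparator scenario against the fixed comparator.

    Yields ``len(scenarios) - 1`` choice sets (23 for a 24-run design).
    """
    try:
        comparator = plan.scenario(comparator_id)
    except KeyError:
        raise ValueError(f"unknown comparator scenario id {comparator_id}") from None
    sets = []
    sid = 1
    for s in plan.scenarios:
        if s.scenario_id == comparator_id:
            continue
        sets.append(ChoiceSet(set_id=sid, alternatives=(s, comparator)))
        sid += 1
    return replace(plan, choice_sets=tuple(sets))


def block_design(plan: DesignPlan, n_blocks: int, seed: int = 0) -> DesignPlan:
    """Randomly partition the choice sets into blocks of near-equal size.

    Block sizes differ by at most one (23 sets in 4 blocks gives sizes
    6,6,6,5); the assignment is reproducible from ``seed``.
    """
    n_sets = len(plan.choice_sets)
    if n_blocks < 1 or n_blocks > n_sets:
        raise ValueError(f"n_blocks must be in [1, {n_sets}], got {n_blocks}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_sets)
    base, extra = divmod(n_sets, n_blocks)
    sizes = [base + (1 if b < extra else 0) for b in range(n_blocks)]
    block_of = np.empty(n_sets, dtype=int)
    pos = 0
    for b, size in enumerate(sizes):
        block_of[order[pos : pos + size]] = b + 1
        pos += size
    sets = tuple(
        replace(cs, block_id=int(block_of[i])) for i, cs in enumerate(plan.choice_sets)
    )
    return replace(plan, choice_sets=sets, n_blocks=n_blocks, seed=plan.seed)


def _prefers(direction: str, cand_val: float, comp_val: float) -> int:
    """-1/0/+1: comparator worse / equal / better on this attribute."""
    if direction == "higher":
        diff = comp_val - cand_val
    elif direction == "lower":
        diff = cand_val - comp_val
    else:
        raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")
    return int(np.sign(diff))


def check_dominance(
    choice_set: ChoiceSet,
    sign_assumptions: dict[str, str],
    attributes: list[AttributeSpec] | tuple[AttributeSpec, ...],
) -> str:
    """A priori dominance verdict for the comparator of a pair.

    ``sign_assumptions`` maps attribute names to a preferred direction
    ('higher'/'lower') over the attribute's numeric values (level order
    for categoricals). The comparator is 'dominant' iff it is weakly
    preferred on every signed attribute and strictly on at least one;
    'dominated' is the mirror case; anything else (including no signed
    attributes at all) is 'neither'.
    """
    cand, comp = choice_set.alternatives
    attr_by_name = {a.name: a for a in attributes}
    signs = []
    for name, direction in sign_assumptions.items():
        a = attr_by_name[name]
        signs.append(_prefers(direction, a.numeric(cand.level(name)), a.numeric(comp.level(name))))
    if not signs:
        return "neither"
    if all(s >= 0 for s in signs) and any(s > 0 for s in signs):
        return "dominant"
    if all(s <= 0 for s in signs) and any(s < 0 for s in signs):
        return "dominated"
    return "neither"


def choose_comparator(plan: DesignPlan, sign_assumptions: dict[str, str]) -> int:
    """Default comparator rule: the scenario that a-priori dominates the
    fewest of the other scenarios, ties broken by lowest scenario id."""
    best_id, best_count = None, None
    for cand_comp in plan.scenarios:
        count = 0
        for other in plan.scenarios:
            if other.scenario_id == cand_comp.scenario_id:
                continue
            cs = ChoiceSet(set_id=0, alternatives=(other, cand_comp))
            if check_dominance(cs, sign_assumptions, plan.attributes) == "dominant":
                count += 1
        if best_count is None or count < best_count:
            best_id, best_count = cand_comp.scenario_id, count
    return int(best_id)


# ---------------------------------------------------------------------------
# delimited-text I/O

def write_attributes(attributes, path) -> None:
    rows = []
    for a in attributes:
        for i, lvl in enumerate(a.levels):
            rows.append(
                {
                    "attribute": a.name,
                    "level": lvl,
                    "ordinal": i,
                    "numeric_value": (
                        a.numeric_values[i] if a.numeric_values is not None else ""
                    ),
                    "kind": a.kind,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_attributes(path) -> list[AttributeSpec]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for name, g in df.groupby("attribute", sort=False):
        g = g.sort_values("ordinal")
        kind = str(g["kind"].iloc[0])
        numeric = None
        if kind == "continuous":
            numeric = tuple(float(v) for v in g["numeric_value"])
        out.append(
            AttributeSpec(
                name=str(name), levels=tuple(g["level"].astype(str)), kind=kind,
                numeric_values=numeric,
            )
        )
    return out


def write_design(plan: DesignPlan, path) -> None:
    rows = [
        {"scenario_id": s.scenario_id, "attribute": a, "level": lvl}
        for s in plan.scenarios
        for a, lvl in s.assignment
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_design(path, attributes) -> DesignPlan:
    df = pd.read_csv(path, keep_default_na=False)
    scen = []
    for sid, g in df.groupby("scenario_id", sort=True):
        scen.append(
            Scenario(
                scenario_id=int(sid),
                assignment=tuple(zip(g["attribute"].astype(str), g["level"].astype(str))),
            )
        )
    return DesignPlan(attributes=tuple(attributes), scenarios=tuple(scen))


def write_choice_sets(plan: DesignPlan, path) -> None:
    rows = []
    for cs in plan.choice_sets:
        for idx, s in enumerate(cs.alternatives):
            rows.append(
                {
                    "set_id": cs.set_id,
                    "alternative_index": idx,
                    "scenario_id": s.scenario_id,
                    "block_id": cs.block_id if cs.block_id is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_choice_sets(path, plan: DesignPlan) -> DesignPlan:
    df = pd.read_csv(path)
    sets = []
    for sid, g in df.groupby("set_id", sort=True):
        g = g.sort_values("alternative_index")
        alts = tuple(plan.scenario(int(s)) for s in g["scenario_id"])
        block = g["block_id"].iloc[0]
        block_id = int(block) if pd.notna(block) and block != "" else None
        sets.append(ChoiceSet(set_id=int(sid), alternatives=alts, block_id=block_id))
    n_blocks = len({cs.block_id for cs in sets if cs.block_id is not None})
    return replace(plan, choice_sets=tuple(sets), n_blocks=n_blocks)
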