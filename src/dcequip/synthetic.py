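"""Synthetic respondent populations and choice simulation.

Generates preference vectors from either a continuous multivariate-
normal (independent components) or a discrete finite-mixture
population, assigns respondents to design blocks, and simulates
forced choices under the random-utility model (deterministic utility
plus i.i.d. type-I extreme-value noise, so choice probabilities are
exactly the logit probabilities the estimators assume). Separate RNG
streams are used for preference draws and for choice noise so the two
can be varied independently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import ASC_COLUMN, CodingSpec, ResponseDataset, assemble_long_format, effects_code
from .design import DesignPlan

__all__ = [
    "PopulationSpec",
    "SimulationTruth",
    "draw_population",
    "simulate_choices",
    "recovery_report",
    "match_class_labels",
    "write_truth",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Ground-truth preference distribution.

    ``kind='normal'``: independent normal coefficients with the given
    means and SDs (an SD of zero makes that coefficient homogeneous).
    ``kind='classes'``: a discrete mixture with per-class coefficient
    vectors and population shares. Column order must match the coded
    covariates of the data the estimators will see (including the
    alternative-specific constant last, if used).
    """

    kind: str
    columns: tuple[str, ...]
    n_respondents: int
    seed: int = 0
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    class_coefs: np.ndarray | None = None
    shares: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "normal":
            if self.means is None or self.sds is None:
                raise ValueError("normal population needs means and sds")
            if len(self.means) != len(self.columns) or len(self.sds) != len(self.columns):
                raise ValueError("means/sds dimension mismatch with columns")
            if np.any(np.asarray(self.sds) < 0):
                raise ValueError("sds must be non-negative")
        elif self.kind == "classes":
            if self.class_coefs is None or self.shares is None:
                raise ValueError("class population needs class_coefs and shares")
            if np.asarray(self.class_coefs).shape[1] != len(self.columns):
                raise ValueError("class_coefs dimension mismatch with columns")
            sh = np.asarray(self.shares, dtype=float)
            if np.any(sh <= 0) or abs(sh.sum() - 1.0) > 1e-8:
                raise ValueError("shares must be positive and sum to 1")
        else:
            raise ValueError(f"unknown population kind {self.kind!r}")


@dataclass
class SimulationTruth:
    """Per-respondent ground truth, joinable to the generated responses
    by respondent id."""

    betas: pd.DataFrame                  # respondents x columns
    class_labels: pd.Series | None       # 1-based class label (discrete case)
    blocks: pd.Series | None = None      # block assignment, filled at simulation
    spec: PopulationSpec | None = None


def draw_population(spec: PopulationSpec) -> SimulationTruth:
    """Draw each respondent's true coefficient vector (seeded)."""
    rng = np.random.default_rng(spec.seed)
    idx = pd.RangeIndex(1, spec.n_respondents + 1, name="respondent_id")
    if spec.kind == "normal":
        z = rng.standard_normal((spec.n_respondents, len(spec.columns)))
        betas = np.asarray(spec.means)[None, :] + z * np.asarray(spec.sds)[None, :]
        labels = None
    else:
        labels_arr = rng.choice(len(spec.shares), size=spec.n_respondents, p=spec.shares)
        betas = np.asarray(spec.class_coefs)[labels_arr]
        labels = pd.Series(labels_arr + 1, index=idx, name="class_label")
    return SimulationTruth(
        betas=pd.DataFrame(betas, index=idx, columns=list(spec.columns)),
        class_labels=labels,
        spec=spec,
    )


def simulate_choices(
    truth: SimulationTruth,
    plan: DesignPlan,
    coding: CodingSpec,
    seed: int = 0,
    include_asc: bool = True,
    block_assignment: dict[int, int] | None = None,
) -> ResponseDataset:
    """Simulate forced two-alternative choices on a blocked plan.

    Respondents are assigned to blocks round-robin unless an explicit
    assignment is given. For each choice set the chosen alternative is
    the arg-max of beta'x (+ ASC for the candidate) plus Gumbel noise
    drawn by inverse CDF from a dedicated stream, which makes empirical
    choice frequencies converge to the closed-form logit probabilities.
    """
    if not plan.choice_sets:
        raise ValueError("plan has no choice sets; build and block them first")
    blocks = sorted({cs.block_id for cs in plan.choice_sets})
    if blocks == [None]:
        raise ValueError("plan is not blocked")
    resp_ids = list(truth.betas.index)
    if block_assignment is None:
        block_assignment = {r: blocks[i % len(blocks)] for i, r in enumerate(resp_ids)}
    cols = list(truth.betas.columns)
    use_asc = include_asc and ASC_COLUMN in cols
    code_cols = [c for c in cols if c != ASC_COLUMN]
    if code_cols != coding.columns:
        raise ValueError("truth columns do not match the coding spec")
    coded = {s.scenario_id: effects_code(s, coding) for s in plan.scenarios}
    sets_by_block: dict[int, list] = {}
    for cs in plan.choice_sets:
        sets_by_block.setdefault(cs.block_id, []).append(cs)
    noise_rng = np.random.default_rng(seed)
    choices: dict[tuple[int, int], int] = {}
    for r in resp_ids:
        beta = truth.betas.loc[r, code_cols].to_numpy(dtype=float)
        asc = float(truth.betas.loc[r, ASC_COLUMN]) if use_asc else 0.0
        for cs in sets_by_block[block_assignment[r]]:
            u = np.array([
                beta @ coded[cs.alternatives[0].scenario_id] + asc,
                beta @ coded[cs.alternatives[1].scenario_id],
            ])
            unif = noise_rng.random(2)
            gumbel = -np.log(-np.log(unif))
            choices[(r, cs.set_id)] = int(np.argmax(u + gumbel))
    truth.blocks = pd.Series(block_assignment, name="block_id").reindex(resp_ids)
    truth.blocks.index.name = "respondent_id"
    return assemble_long_format(plan, block_assignment, choices, coding, include_asc=use_asc)


def match_class_labels(true_coefs: np.ndarray, est_coefs: np.ndarray) -> tuple[int, ...]:
    """Best permutation mapping estimated classes onto true classes by
    minimising the total squared coefficient distance (columns are
    standardised first so euro-scale money coefficients do not vanish
    from the criterion)."""
    true_coefs = np.asarray(true_coefs, dtype=float)
    est_coefs = np.asarray(est_coefs, dtype=float)
    scale = np.abs(true_coefs).max(axis=0)
    scale[scale == 0] = 1.0
    t, e = true_coefs / scale, est_coefs / scale
    C = t.shape[0]
    best_perm, best_cost = None, None
    for perm in itertools.permutations(range(C)):
        cost = float(((t - e[list(perm)]) ** 2).sum())
        if best_cost is None or cost < best_cost:
            best_perm, best_cost = perm, cost
    return best_perm


def recovery_report(truth_spec: PopulationSpec, estimate, posterior=None,
                    true_labels=None) -> dict:
    """Bias, RMSE and nominal-95% CI coverage per parameter.

    For a normal population ``estimate`` is a MixedLogitEstimate (or a
    ClogitEstimate, checked against the means only); for a discrete
    population it is a LatentClassEstimate, whose classes are first
    matched to the true ones by :func:`match_class_labels`, adding share
    errors and (given posteriors and true labels) a class-confusion
    matrix.
    """
    rows = []
    extras: dict = {}
    if truth_spec.kind == "normal":
        true_means = pd.Series(np.asarray(truth_spec.means), index=list(truth_spec.columns))
        if hasattr(estimate, "means"):
            est_means, se_means = estimate.means, estimate.se_means
        else:  # conditional logit
            est_means, se_means = estimate.params, estimate.se
        for c in est_means.index:
            err = float(est_means[c] - true_means[c])
            se = float(se_means[c])
            rows.append({"parameter": f"mean:{c}", "true": float(true_means[c]),
                         "estimate": float(est_means[c]), "bias": err,
                         "rmse": abs(err), "se": se,
                         "z": err / se if se > 0 else np.nan,
                         "covered95": bool(abs(err) <= 1.96 * se) if se > 0 else False})
        if hasattr(estimate, "sds"):
            true_sds = pd.Series(np.asarray(truth_spec.sds), index=list(truth_spec.columns))
            for c in estimate.sds.index:
                err = float(estimate.sds[c] - true_sds[c])
                se = float(estimate.se_sds[c])
                rows.append({"parameter": f"sd:{c}", "true": float(true_sds[c]),
                             "estimate": float(estimate.sds[c]), "bias": err,
                             "rmse": abs(err), "se": se,
                             "z": err / se if se > 0 else np.nan,
                             "covered95": bool(abs(err) <= 1.96 * se) if se > 0 else False})
    else:
        true_coefs = np.asarray(truth_spec.class_coefs)
        est_coefs = estimate.class_coefs.to_numpy()
        perm = match_class_labels(true_coefs, est_coefs)
        extras["permutation"] = perm
        shares_est = estimate.shares[list(perm)]
        extras["share_errors"] = shares_est - np.asarray(truth_spec.shares)
        for c_true, c_est in enumerate(perm):
            for j, col in enumerate(truth_spec.columns):
                err = float(est_coefs[c_est, j] - true_coefs[c_true, j])
                se = float(estimate.se.to_numpy()[c_est, j])
                rows.append({"parameter": f"class{c_true + 1}:{col}",
                             "true": float(true_coefs[c_true, j]),
                             "estimate": float(est_coefs[c_est, j]),
                             "bias": err, "rmse": abs(err), "se": se,
                             "z": err / se if se > 0 else np.nan,
                             "covered95": bool(abs(err) <= 1.96 * se) if se > 0 else False})
        if posterior is not None and true_labels is not None:
            assigned = np.asarray(posterior).argmax(axis=1)
            C = true_coefs.shape[0]
            conf = np.zeros((C, C), dtype=int)
            inv = {c_est: c_true for c_true, c_est in enumerate(perm)}
            for lbl, a in zip(np.asarray(true_labels) - 1, assigned):
                conf[lbl, inv[a]] += 1
            extras["confusion"] = conf
    report = pd.DataFrame(rows)
    return {"parameters": report, **extras}


def write_truth(truth: SimulationTruth, path) -> None:
    df = truth.betas.copy()
    if truth.class_labels is not None:
        df.insert(0, "class_label", truth.class_labels)
    if truth.blocks is not None:
        df.insert(0, "block_id", truth.blocks)
    df.to_csv(path)
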