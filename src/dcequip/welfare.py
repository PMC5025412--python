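"""Compensating-variation policy simulation.

A policy is an attribute profile; its indirect utility for a subgroup is
the significance-filtered dot product of the subgroup's coefficients
with the policy's coded vector (attributes a policy leaves out
contribute nothing, and coefficients that are statistically
indistinguishable from zero are set to zero before the product — a
respondent indifferent to an attribute gains no welfare from changing
it). The money-metric welfare change of replacing a baseline program by
an alternative is the compensating variation

    CV = -(1/beta_w) [ln sum_j exp(V_j^0) - ln sum_j exp(V_j^1)]

which for one option per state collapses to
CV = -(V^0 - V^1)/beta_w, with beta_w the marginal utility of income.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .coding import CodingSpec
from .estimation import (
    IndividualCoefficients,
    LatentClassEstimate,
    MixedLogitEstimate,
)

__all__ = [
    "PolicyProfile",
    "SubgroupSpec",
    "WelfareTable",
    "code_policy",
    "significance_filter",
    "indirect_utility",
    "cv_two_option",
    "cv_logsum",
    "welfare_table",
    "max_satisfaction_policy",
    "implied_beta_w",
    "read_policies",
    "write_policies",
    "write_welfare_table",
]

ABSENT = (None, "", "NA", "n/a", "na")


@dataclass(frozen=True)
class PolicyProfile:
    """Attribute-level profile of one program.

    ``levels`` maps attribute names to a declared level label (or a raw
    numeric value for continuous attributes); an attribute mapped to
    ``None`` (or omitted) is not part of the program and contributes
    zero utility.
    """

    name: str
    levels: dict[str, object] = field(default_factory=dict)

    def declared(self) -> dict[str, object]:
        return {a: v for a, v in self.levels.items() if not _is_absent(v)}


def _is_absent(v) -> bool:
    return v is None or (isinstance(v, str) and v.strip() in ABSENT)


def code_policy(policy: PolicyProfile, coding: CodingSpec) -> tuple[np.ndarray, np.ndarray]:
    """Coded vector and activity mask of a policy over ``coding.columns``.

    Mask entries are False for columns of attributes the policy leaves
    out. The alternative-specific constant is not part of policy coding.
    """
    K = len(coding.columns)
    x = np.zeros(K)
    active = np.zeros(K, dtype=bool)
    declared = policy.declared()
    for ac in coding.codings:
        name = ac.attribute.name
        if name not in declared:
            continue
        sl = coding.column_slice(name)
        value = declared[name]
        if ac.kind == "continuous" and isinstance(value, (int, float)) and not isinstance(value, bool):
            x[sl] = float(value)
        elif ac.kind == "continuous" and isinstance(value, str):
            try:
                x[sl] = float(value.replace(",", ""))
            except ValueError:
                x[sl] = ac.code(value)
        else:
            x[sl] = ac.code(str(value))
        active[sl] = True
    unknown = set(declared) - {ac.attribute.name for ac in coding.codings}
    if unknown:
        raise ValueError(f"policy {policy.name!r}: unknown attributes {sorted(unknown)}")
    return x, active


def significance_filter(
    coefs: pd.Series, tstats: pd.Series, alpha: float = 0.05
) -> pd.Series:
    """Zero out coefficients with |t| below the two-sided normal critical
    value at ``alpha``. ``alpha=1`` keeps everything; the filter is
    idempotent."""
    crit = norm.ppf(1.0 - alpha / 2.0)
    t = tstats.reindex(coefs.index)
    keep = t.abs().to_numpy() >= crit
    keep &= np.isfinite(t.to_numpy())
    return coefs.where(pd.Series(keep, index=coefs.index), 0.0)


def indirect_utility(
    coefs: pd.Series,
    tstats: pd.Series,
    x: np.ndarray,
    active: np.ndarray,
    alpha: float = 0.05,
) -> float:
    """Significance-filtered indirect utility of a coded policy."""
    if len(coefs) != len(x) or len(x) != len(active):
        raise ValueError("coefficient vector not aligned with policy coding")
    filtered = significance_filter(coefs, tstats, alpha).to_numpy()
    return float((filtered * x * active).sum())


def cv_two_option(v0: float, v1: float, beta_w: float) -> float:
    """CV = -(1/beta_w)(V^0 - V^1): euros per year that make a respondent
    indifferent between keeping the baseline and adopting the
    alternative. Positive when the alternative is preferred (beta_w>0)."""
    if beta_w == 0:
        raise ValueError("beta_w must be nonzero: CV is undefined without a money coefficient")
    return -(v0 - v1) / beta_w


def cv_logsum(v0, v1, beta_w: float) -> float:
    """Logsum compensating variation over option sets; reduces exactly to
    :func:`cv_two_option` when each state offers a single option."""
    v0 = np.atleast_1d(np.asarray(v0, dtype=float))
    v1 = np.atleast_1d(np.asarray(v1, dtype=float))
    if v0.size == 0 or v1.size == 0:
        raise ValueError("option sets must be non-empty")
    if beta_w == 0:
        raise ValueError("beta_w must be nonzero: CV is undefined without a money coefficient")
    return float(-(logsumexp(v0) - logsumexp(v1)) / beta_w)


def implied_beta_w(v0: float, v1s, cvs) -> np.ndarray:
    """Back out the money coefficient from utilities and CVs: a published
    welfare table is internally consistent when (V1-V0)/CV is constant
    across the alternatives of a row."""
    v1s = np.asarray(v1s, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    return (v1s - v0) / cvs


@dataclass(frozen=True)
class SubgroupSpec:
    """Which respondents and which coefficient source a welfare row uses.

    kind 'all' uses the mixed-logit population means; 'sign' restricts
    to respondents whose conditional coefficient on ``coefficient`` has
    the given direction and averages their conditional vectors; 'class'
    uses one latent class's coefficient vector.
    """

    kind: str  # "all" | "sign" | "class"
    name: str
    coefficient: str | None = None
    direction: str | None = None  # "positive" | "negative"
    class_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("all", "sign", "class"):
            raise ValueError(f"unknown subgroup kind {self.kind!r}")
        if self.kind == "sign" and (self.coefficient is None or self.direction not in ("positive", "negative")):
            raise ValueError("sign subgroup needs a coefficient and a direction")
        if self.kind == "class" and self.class_index is None:
            raise ValueError("class subgroup needs a class index")


@dataclass
class WelfareTable:
    table: pd.DataFrame  # subgroup, policy, V, CV, is_baseline, note
    manifest: dict

    def pivot(self, value: str = "CV") -> pd.DataFrame:
        return self.table.pivot(index="subgroup", columns="policy", values=value)


def _subgroup_source(
    sub: SubgroupSpec,
    coding: CodingSpec,
    mxl: MixedLogitEstimate | None,
    individuals: IndividualCoefficients | None,
    lcm: LatentClassEstimate | None,
    money: str,
):
    cols = coding.columns
    if sub.kind in ("all", "sign"):
        if mxl is None:
            raise ValueError(f"subgroup {sub.name!r} needs a mixed-logit estimate")
        tstats = mxl.tstat_means.reindex(cols)
        if sub.kind == "all":
            coefs = mxl.means.reindex(cols)
            n_members = mxl.n_respondents
        else:
            if individuals is None:
                raise ValueError(f"subgroup {sub.name!r} needs conditional coefficients")
            vals = individuals.means[sub.coefficient]
            members = vals > 0 if sub.direction == "positive" else vals < 0
            n_members = int(members.sum())
            if n_members == 0:
                return None, tstats, np.nan, 0
            coefs = individuals.means.loc[members, cols].mean()
        beta_w = abs(float(coefs[money]))
        return coefs, tstats, beta_w, n_members
    # latent class
    if lcm is None:
        raise ValueError(f"subgroup {sub.name!r} needs a latent-class estimate")
    coefs = lcm.class_coefs.loc[sub.class_index].reindex(cols)
    tstats = lcm.tstat.loc[sub.class_index].reindex(cols)
    beta_w = abs(float(coefs[money]))
    n_members = int(round(lcm.shares[sub.class_index - 1] * lcm.n_respondents))
    return coefs, tstats, beta_w, n_members


def welfare_table(
    policies,
    baseline: str,
    coding: CodingSpec,
    subgroups,
    mxl: MixedLogitEstimate | None = None,
    individuals: IndividualCoefficients | None = None,
    lcm: LatentClassEstimate | None = None,
    alpha: float = 0.05,
    money: str = "remuneration",
    sign_normalize_beta_w: bool = True,
) -> WelfareTable:
    """Subgroup-by-policy indirect utilities and CVs against a baseline.

    Each subgroup's marginal utility of income is the magnitude of its
    own money coefficient (``sign_normalize_beta_w=False`` keeps the raw
    sign instead; a negative denominator flips every CV in the row, so
    the default normalisation is what makes rows comparable). The
    baseline policy's CV cell is marked rather than computed.
    """
    policies = list(policies)
    names = [p.name for p in policies]
    if baseline not in names:
        raise ValueError(f"baseline {baseline!r} not among policies {names}")
    coded = {p.name: code_policy(p, coding) for p in policies}
    rows = []
    beta_ws = {}
    for sub in subgroups:
        coefs, tstats, beta_w, n_members = _subgroup_source(
            sub, coding, mxl, individuals, lcm, money
        )
        if coefs is None:
            for p in policies:
                rows.append({"subgroup": sub.name, "policy": p.name, "V": np.nan,
                             "CV": np.nan, "is_baseline": p.name == baseline,
                             "note": "empty subgroup"})
            beta_ws[sub.name] = np.nan
            continue
        if not sign_normalize_beta_w:
            beta_w = float(coefs[money])
        beta_ws[sub.name] = beta_w
        v = {p.name: indirect_utility(coefs, tstats, *coded[p.name], alpha=alpha)
             for p in policies}
        v0 = v[baseline]
        for p in policies:
            is_base = p.name == baseline
            cv = np.nan if is_base else cv_two_option(v0, v[p.name], beta_w)
            rows.append({"subgroup": sub.name, "policy": p.name, "V": v[p.name],
                         "CV": cv, "is_baseline": is_base,
                         "note": f"n={n_members}"})
    manifest = {
        "alpha": alpha,
        "baseline": baseline,
        "money_coefficient": money,
        "sign_normalize_beta_w": sign_normalize_beta_w,
        "beta_w": beta_ws,
    }
    return WelfareTable(table=pd.DataFrame(rows), manifest=manifest)


def max_satisfaction_policy(
    coefs: pd.Series,
    tstats: pd.Series,
    coding: CodingSpec,
    alpha: float = 0.05,
    name: str = "Maximum satisfaction",
    overrides: dict | None = None,
) -> PolicyProfile:
    """Benchmark program: each attribute set to the level maximising the
    significance-filtered utility; attributes whose every level
    contributes zero (all their coefficients filtered out) are left out
    of the program. ``overrides`` pins chosen attributes (e.g. a fixed
    budget for the money attribute) instead of optimising them."""
    filtered = significance_filter(coefs.reindex(coding.columns), tstats, alpha)
    levels: dict[str, object] = {}
    for ac in coding.codings:
        attr = ac.attribute.name
        if overrides and attr in overrides:
            levels[attr] = overrides[attr]
            continue
        sl = coding.column_slice(attr)
        w = filtered.to_numpy()[sl]
        contribs = {lvl: float(w @ ac.code(lvl)) for lvl in ac.attribute.levels}
        if all(abs(v) < 1e-12 for v in contribs.values()):
            levels[attr] = None
        else:
            levels[attr] = max(contribs, key=contribs.get)
    return PolicyProfile(name=name, levels=levels)


# ---------------------------------------------------------------------------
# I/O

def write_policies(policies, path) -> None:
    rows = []
    for p in policies:
        for attr, lvl in p.levels.items():
            rows.append({"policy": p.name, "attribute": attr,
                         "level": "NA" if _is_absent(lvl) else lvl})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_policies(path) -> list[PolicyProfile]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for name, g in df.groupby("policy", sort=False):
        levels = {}
        for _, r in g.iterrows():
            lvl = r["level"]
            levels[str(r["attribute"])] = None if (pd.isna(lvl) or _is_absent(lvl)) else lvl
        out.append(PolicyProfile(name=str(name), levels=levels))
    return out


def write_welfare_table(wt: WelfareTable, path) -> None:
    wt.table.to_csv(path, index=False)
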