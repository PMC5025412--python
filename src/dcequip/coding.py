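"""Effects coding and long-format choice-data assembly.

Categorical attributes are effects coded: an L-level attribute yields
L-1 columns, the j-th non-reference level codes +1 on its own column and
0 elsewhere, and the reference level codes -1 on every column, so the
level effects sum to zero. Continuous attributes (remuneration) enter as
a single column carrying the level's numeric value in euros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import AttributeSpec, DesignPlan, Scenario

__all__ = [
    "AttributeCoding",
    "CodingSpec",
    "ResponseDataset",
    "effects_code",
    "assemble_long_format",
    "validate_dataset",
    "read_responses",
    "write_responses",
]

ASC_COLUMN = "asc"
ID_COLUMNS = ("respondent_id", "set_id", "alternative_index", "chosen")


@dataclass(frozen=True)
class AttributeCoding:
    attribute: AttributeSpec
    kind: str  # "effects" | "continuous"
    reference: str | None
    columns: tuple[str, ...]

    def code(self, level: str) -> np.ndarray:
        if level not in self.attribute.levels:
            raise ValueError(
                f"unknown level {level!r} for attribute {self.attribute.name!r}"
            )
        if self.kind == "continuous":
            return np.array([self.attribute.numeric(level)])
        v = np.zeros(len(self.columns))
        if level == self.reference:
            v[:] = -1.0
        else:
            non_ref = [l for l in self.attribute.levels if l != self.reference]
            v[non_ref.index(level)] = 1.0
        return v

    def decode(self, vector: np.ndarray) -> str:
        """Inverse of :meth:`code` (exact match required)."""
        for lvl in self.attribute.levels:
            if np.allclose(self.code(lvl), vector):
                return lvl
        raise ValueError(
            f"vector {vector} does not code any level of {self.attribute.name!r}"
        )


@dataclass(frozen=True)
class CodingSpec:
    """Per-attribute coding rules and the resulting column layout."""

    codings: tuple[AttributeCoding, ...]

    @classmethod
    def build(
        cls,
        attributes,
        references: dict[str, str] | None = None,
        column_labels: dict[str, tuple[str, ...]] | None = None,
    ) -> "CodingSpec":
        """Effects-code every categorical attribute (continuous ones pass
        their numeric value through). ``references`` picks the -1 level;
        default is the last declared level. ``column_labels`` overrides
        the generated ``attribute:level`` labels."""
        references = references or {}
        column_labels = column_labels or {}
        codings = []
        for a in attributes:
            if a.kind == "continuous":
                cols = column_labels.get(a.name, (a.name,))
                codings.append(
                    AttributeCoding(attribute=a, kind="continuous", reference=None, columns=tuple(cols))
                )
            else:
                if a.n_levels < 2:
                    raise ValueError(f"attribute {a.name!r} needs >=2 levels to effects-code")
                ref = references.get(a.name, a.levels[-1])
                if ref not in a.levels:
                    raise ValueError(f"reference {ref!r} is not a level of {a.name!r}")
                non_ref = [l for l in a.levels if l != ref]
                cols = column_labels.get(
                    a.name, tuple(f"{a.name}:{l}" for l in non_ref)
                )
                if len(cols) != len(non_ref):
                    raise ValueError(f"attribute {a.name!r}: wrong number of column labels")
                codings.append(
                    AttributeCoding(attribute=a, kind="effects", reference=ref, columns=tuple(cols))
                )
        return cls(codings=tuple(codings))

    @property
    def columns(self) -> list[str]:
        return [c for coding in self.codings for c in coding.columns]

    def coding_for(self, attribute: str) -> AttributeCoding:
        for c in self.codings:
            if c.attribute.name == attribute:
                return c
        raise KeyError(attribute)

    def column_slice(self, attribute: str) -> slice:
        start = 0
        for c in self.codings:
            if c.attribute.name == attribute:
                return slice(start, start + len(c.columns))
            start += len(c.columns)
        raise KeyError(attribute)


def effects_code(scenario: Scenario, coding: CodingSpec) -> np.ndarray:
    """Coded covariate vector of a scenario, ordered as ``coding.columns``."""
    return np.concatenate([c.code(scenario.level(c.attribute.name)) for c in coding.codings])


@dataclass
class ResponseDataset:
    """Long-format panel of coded choice observations.

    One row per (respondent, choice set, alternative); exactly two
    alternatives per set and exactly one with ``chosen == 1``.
    """

    df: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"response data missing columns: {missing}")
        if not self.covariates:
            self.covariates = [c for c in self.df.columns if c not in ID_COLUMNS]

    @property
    def respondents(self) -> np.ndarray:
        return self.df["respondent_id"].unique()

    @property
    def n_respondents(self) -> int:
        return int(self.df["respondent_id"].nunique())

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def n_choice_observations(self) -> int:
        return int(len(self.df.groupby(["respondent_id", "set_id"])))


def assemble_long_format(
    plan: DesignPlan,
    assignments: dict[int, int],
    choices: dict[tuple[int, int], int],
    coding: CodingSpec,
    include_asc: bool = True,
) -> ResponseDataset:
    """Build the estimation panel from a blocked plan and observed choices.

    ``assignments`` maps respondent id to block id, ``choices`` maps
    (respondent, set) to the chosen alternative index (0 = candidate,
    1 = comparator). The alternative-specific constant is 1 for the
    candidate and 0 for the fixed comparator.
    """
    sets_by_block: dict[int, list] = {}
    for cs in plan.choice_sets:
        sets_by_block.setdefault(cs.block_id, []).append(cs)
    columns = coding.columns
    coded_cache = {s.scenario_id: effects_code(s, coding) for s in plan.scenarios}
    rows = []
    for resp, block in assignments.items():
        if block not in sets_by_block:
            raise ValueError(f"respondent {resp}: unknown block {block}")
        block_sets = {cs.set_id for cs in sets_by_block[block]}
        answered = {s for (r, s) in choices if r == resp}
        if answered != block_sets:
            missing = sorted(block_sets - answered)
            extra = sorted(answered - block_sets)
            raise ValueError(
                f"respondent {resp}: choices do not cover block {block} exactly "
                f"(missing sets {missing}, extraneous sets {extra})"
            )
        for cs in sets_by_block[block]:
            chosen_idx = choices[(resp, cs.set_id)]
            if chosen_idx not in (0, 1):
                raise ValueError(
                    f"respondent {resp}, set {cs.set_id}: chosen index must be 0 or 1"
                )
            for alt_idx, scen in enumerate(cs.alternatives):
                row = {
                    "respondent_id": resp,
                    "set_id": cs.set_id,
                    "alternative_index": alt_idx,
                    "chosen": int(alt_idx == chosen_idx),
                }
                row.update(dict(zip(columns, coded_cache[scen.scenario_id])))
                if include_asc:
                    row[ASC_COLUMN] = float(alt_idx == 0)
                rows.append(row)
    covs = columns + ([ASC_COLUMN] if include_asc else [])
    df = pd.DataFrame(rows, columns=list(ID_COLUMNS) + covs)
    return ResponseDataset(df=df, covariates=covs)


def validate_dataset(data: ResponseDataset) -> list[str]:
    """Report invariant violations; an empty list means a clean panel."""
    issues: list[str] = []
    df = data.df
    for cov in data.covariates:
        if not np.isfinite(df[cov].to_numpy(dtype=float)).all():
            issues.append(f"non-finite values in covariate {cov!r}")
    for (resp, sid), g in df.groupby(["respondent_id", "set_id"]):
        if len(g) != 2:
            issues.append(
                f"respondent {resp}, set {sid}: expected 2 alternatives, found {len(g)}"
            )
        n_chosen = int(g["chosen"].sum())
        if n_chosen != 1:
            kind = "no chosen alternative" if n_chosen == 0 else f"{n_chosen} chosen rows"
            issues.append(f"respondent {resp}, set {sid}: {kind}")
    return issues


def write_responses(data: ResponseDataset, path) -> None:
    data.df.to_csv(path, index=False)


def read_responses(path) -> ResponseDataset:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty response file") from None
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: schema mismatch, missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no response rows")
    return ResponseDataset(df=df)
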