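"""Bundled study fixtures: the eight-attribute QIP experiment, its
coding conventions, the policy catalogue, and synthetic populations.

The attribute table describes quality-improvement programs for French
general practitioners: an annual remuneration increase (euros), the
payment method (partial-capitation *forfait*, possibly combined with
fee-for-service or pay-for-performance), payment frequency, prevention
clinical guidelines, performance feedback, continuing education, type of
practice, and assistance by non-physician providers (NPP).
"""

from __future__ import annotations

import numpy as np

from .coding import CodingSpec
from .design import AttributeSpec
from .synthetic import PopulationSpec
from .welfare import PolicyProfile

__all__ = [
    "ATTRIBUTES",
    "REFERENCE_LEVELS",
    "COLUMN_LABELS",
    "SIGN_ASSUMPTIONS",
    "default_coding",
    "POLICIES",
    "BASELINE_POLICY",
    "mn1_like_population",
    "four_class_population",
    "two_class_population",
]

ATTRIBUTES: tuple[AttributeSpec, ...] = (
    AttributeSpec(
        name="remuneration",
        levels=("100 Euros", "6100 Euros", "12100 Euros"),
        kind="continuous",
        numeric_values=(100.0, 6100.0, 12100.0),
    ),
    AttributeSpec(
        name="method",
        levels=(
            "Lump sum (forfait)",
            "Lump sum and fee-for-service",
            "Lump sum and pay-for-performance",
        ),
    ),
    AttributeSpec(name="frequency", levels=("Monthly", "Annually")),
    AttributeSpec(
        name="guidelines",
        levels=("None", "Participatory guidelines", "Pre-established guidelines"),
    ),
    AttributeSpec(name="feedback", levels=("Yes", "No")),
    AttributeSpec(name="education", levels=("Yes", "No")),
    AttributeSpec(name="practice", levels=("Group of GPs", "Solo practice")),
    AttributeSpec(name="npp", levels=("Yes", "No")),
)

# Reference (-1) levels: payment method relative to forfait+FFS, guidelines
# relative to none; two-level attributes code +1 = {monthly, yes, solo}.
REFERENCE_LEVELS: dict[str, str] = {
    "method": "Lump sum and fee-for-service",
    "frequency": "Annually",
    "guidelines": "None",
    "feedback": "No",
    "education": "No",
    "practice": "Group of GPs",
    "npp": "No",
}

COLUMN_LABELS: dict[str, tuple[str, ...]] = {
    "method": ("forfait", "p4p"),
    "frequency": ("frequency_monthly",),
    "guidelines": ("guidelines_participatory", "guidelines_preestablished"),
    "feedback": ("feedback",),
    "education": ("education",),
    "practice": ("solo_practice",),
    "npp": ("npp_assistance",),
}

# A-priori preference directions used by the dominance screen when picking
# the fixed comparator. Only the money attribute has an uncontroversial
# direction a priori; every other attribute is left unsigned (preferences
# over them are exactly what the experiment measures).
SIGN_ASSUMPTIONS: dict[str, str] = {"remuneration": "higher"}


def default_coding() -> CodingSpec:
    return CodingSpec.build(ATTRIBUTES, references=REFERENCE_LEVELS, column_labels=COLUMN_LABELS)


# ---------------------------------------------------------------------------
# Policy catalogue: the CAPI contract and four alternative programs.
# ``None`` marks an attribute the policy leaves out entirely (zero utility
# contribution); the literal "No" level of the yes/no attributes is a real
# level, not an absence.

POLICIES: tuple[PolicyProfile, ...] = (
    PolicyProfile(
        name="CAPI",
        levels={
            "remuneration": 4200.0,
            "method": "Lump sum and pay-for-performance",
            "frequency": "Annually",
            "guidelines": "None",
            "education": "No",
            "feedback": "Yes",
            "practice": "Solo practice",
            "npp": "No",
        },
    ),
    PolicyProfile(
        name="Integrated primary care model (P1)",
        levels={
            "remuneration": 4200.0,
            "method": "Lump sum (forfait)",
            "frequency": "Annually",
            "guidelines": "Pre-established guidelines",
            "education": "Yes",
            "feedback": "Yes",
            "practice": "Group of GPs",
            "npp": "Yes",
        },
    ),
    PolicyProfile(
        name="Mixed remuneration (P2)",
        levels={
            "remuneration": 4200.0,
            "method": "Lump sum and fee-for-service",
            "frequency": "Annually",
            "guidelines": "None",
            "education": "No",
            "feedback": "No",
            "practice": "Solo practice",
            "npp": "No",
        },
    ),
    PolicyProfile(
        name="Non-financial interventions (P3)",
        levels={
            "remuneration": 0.0,
            "method": None,
            "frequency": None,
            "guidelines": "Participatory guidelines",
            "education": "Yes",
            "feedback": "Yes",
            "practice": "Solo practice",
            "npp": "No",
        },
    ),
    PolicyProfile(
        name="Maximum satisfaction (P4)",
        levels={
            "remuneration": 4200.0,
            "method": "Lump sum and fee-for-service",
            "frequency": None,
            "guidelines": "Participatory guidelines",
            "education": "Yes",
            "feedback": "Yes",
            "practice": "Solo practice",
            "npp": None,
        },
    ),
)

BASELINE_POLICY = "CAPI"


# ---------------------------------------------------------------------------
# Synthetic populations. Column order must match default_coding().columns
# plus the trailing alternative-specific constant.

def _columns() -> list[str]:
    return default_coding().columns + ["asc"]


def mn1_like_population(n_respondents: int = 500, seed: int = 0) -> PopulationSpec:
    """Continuous-normal population with magnitudes typical of a GP
    quality-program experiment: a small positive money coefficient on the
    euro scale, mild dislike of forfait/P4P at the mean with strong
    heterogeneity on P4P and NPP assistance, positive education/feedback
    effects. Money coefficient and the constant are homogeneous."""
    means = {
        "remuneration": 0.000155,
        "forfait": -0.4706,
        "p4p": -0.5085,
        "frequency_monthly": 0.2652,
        "guidelines_participatory": 0.4966,
        "guidelines_preestablished": 0.2563,
        "education": 0.6580,
        "feedback": 0.4070,
        "solo_practice": 0.3476,
        "npp_assistance": 0.1057,
        "asc": 1.3462,
    }
    sds = {
        "remuneration": 0.0,
        "forfait": 0.1203,
        "p4p": 0.9771,
        "frequency_monthly": 0.0782,
        "guidelines_participatory": 0.2992,
        "guidelines_preestablished": 0.1060,
        "education": 0.3710,
        "feedback": 0.4751,
        "solo_practice": 0.2119,
        "npp_assistance": 0.9063,
        "asc": 0.0,
    }
    cols = _columns()
    return PopulationSpec(
        kind="normal",
        columns=tuple(cols),
        means=np.array([means[c] for c in cols]),
        sds=np.array([sds[c] for c in cols]),
        n_respondents=n_respondents,
        seed=seed,
    )


_FOUR_CLASS_RAW = {
    #                       class 1   class 2   class 3    class 4
    "remuneration":        (-0.0001,  0.0002,   0.0023,   -0.0030),
    "forfait":             (-0.2202, -0.8085,  -9.6873,  -26.8455),
    "p4p":                 (-1.5179,  0.6209, -24.0380,  -20.2301),
    "frequency_monthly":   (-0.5197,  0.9612,   1.2295,   34.5608),
    "guidelines_participatory": (1.8732, -0.1382, -3.8807, 46.0073),
    "guidelines_preestablished": (2.0941, 0.5921, -14.4822, 17.9852),
    "education":           (3.6665,  -1.0573,  11.0212,   -6.5797),
    "feedback":            (-0.6791,  0.1495,   7.4359,   -4.5607),
    "solo_practice":       (-1.2745,  1.0318,  -3.9727,   -8.1784),
    "npp_assistance":      (-1.3672,  0.4714, -11.7878,   40.3411),
    "asc":                 (2.8629,   2.7353, -67.6568,   72.4956),
}
_FOUR_CLASS_SHARES = (0.136, 0.317, 0.231, 0.316)


def four_class_population(n_respondents: int = 600, seed: int = 0) -> PopulationSpec:
    """Discrete four-class population preserving the sign pattern of four
    physician archetypes but rescaled to moderate magnitudes: classes 3
    and 4 are divided by 10 and all non-money coefficients clipped at
    |2.5| (the raw archetype magnitudes would make choices effectively
    deterministic and useless for testing estimators)."""
    cols = _columns()
    C = 4
    coefs = np.zeros((C, len(cols)))
    for j, col in enumerate(cols):
        vals = np.array(_FOUR_CLASS_RAW[col], dtype=float)
        vals[2:] = vals[2:] / 10.0
        if col != "remuneration":
            vals = np.clip(vals, -2.5, 2.5)
        coefs[:, j] = vals
    return PopulationSpec(
        kind="classes",
        columns=tuple(cols),
        class_coefs=coefs,
        shares=np.array(_FOUR_CLASS_SHARES),
        n_respondents=n_respondents,
        seed=seed,
    )


def two_class_population(
    n_respondents: int = 600, seed: int = 0, shares: tuple[float, float] = (0.6, 0.4)
) -> PopulationSpec:
    """Two well-separated classes for mixture-recovery exercises."""
    cols = _columns()
    a = {
        "remuneration": 0.0002, "forfait": -0.8, "p4p": 1.0,
        "frequency_monthly": 0.5, "guidelines_participatory": 0.8,
        "guidelines_preestablished": 0.3, "education": 1.0, "feedback": 0.5,
        "solo_practice": -0.8, "npp_assistance": 1.2, "asc": 0.3,
    }
    b = {
        "remuneration": -0.0001, "forfait": 0.9, "p4p": -1.2,
        "frequency_monthly": -0.6, "guidelines_participatory": -0.7,
        "guidelines_preestablished": 0.5, "education": -1.0, "feedback": -0.4,
        "solo_practice": 0.9, "npp_assistance": -1.3, "asc": -0.3,
    }
    coefs = np.array([[a[c] for c in cols], [b[c] for c in cols]])
    return PopulationSpec(
        kind="classes",
        columns=tuple(cols),
        class_coefs=coefs,
        shares=np.array(shares, dtype=float),
        n_respondents=n_respondents,
        seed=seed,
    )
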