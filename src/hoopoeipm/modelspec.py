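"""Model-variant specifications.

Three model variants drive the three analysis steps:

* variant I  — annual variation of every vital rate as independent year
  random effects with habitat-specific standard deviations (used for the
  retrospective LTRE decomposition),
* variant II — year as a continuous linear trend, habitat-specific or shared
  (used to test for habitat-heterogeneous trends),
* variant III — explanatory covariates (spring weather, research activity,
  clutch size, hatching date) replacing the year structure on fledglings and
  survival; reproductive success keeps its year random effects and
  immigration reduces to habitat intercepts.

Movement probabilities are time-constant in every variant.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

RATES = ("succ", "fled", "s1", "s2", "omega")

#: covariates measured per brood record (enter the fledgling model directly,
#: and the survival models through annual habitat-level means)
RECORD_TERMS = ("hat", "cs", "del", "meth", "partag", "tag")
#: covariates measured per year
YEAR_TERMS = ("temp", "prec")
#: research-activity terms — removable entirely by backward simplification
RESEARCH_TERMS = ("del", "meth", "partag", "tag")


@dataclass
class Term:
    """One covariate term of a rate's linear predictor.

    ``quadratic`` adds an x^2 coefficient next to the linear one;
    ``by_habitat`` makes the coefficients habitat-specific (an interaction
    with habitat quality); ``threshold`` applies the capture-delay rule
    (slope fixed to zero for non-negative delays, linear below zero).
    """

    name: str
    quadratic: bool = False
    by_habitat: bool = False
    threshold: bool = False

    def coef_names(self) -> list[str]:
        out = [self.name]
        if self.quadratic:
            out.append(self.name + "2")
        return out


@dataclass
class RateFormula:
    """Structure of one vital rate's linear predictor (habitat intercepts
    always included)."""

    year_re: bool = False  # annual random deviations, sd per habitat
    year_trend: str = "none"  # "none" | "shared" | "by_habitat"
    terms: list[Term] = field(default_factory=list)

    def term(self, name: str) -> Term | None:
        for t in self.terms:
            if t.name == name:
                return t
        return None


@dataclass
class ModelSpec:
    variant: str
    formulas: dict = field(default_factory=dict)  # rate -> RateFormula
    movement_constant: bool = True

    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)

    def formula(self, rate: str) -> RateFormula:
        return self.formulas[rate]


def model_I() -> ModelSpec:
    return ModelSpec(
        variant="I",
        formulas={r: RateFormula(year_re=True) for r in RATES},
    )


def model_II(final: bool = False) -> ModelSpec:
    """Year as a continuous variable; the starting form interacts the trend
    with habitat quality, the reduced form uses a shared trend (immigration:
    intercept only, adult survival: intercept only in the reduced form)."""
    if not final:
        f = {r: RateFormula(year_trend="by_habitat") for r in RATES}
    else:
        f = {
            "succ": RateFormula(year_trend="shared"),
            "fled": RateFormula(year_trend="shared"),
            "s1": RateFormula(year_trend="shared"),
            "s2": RateFormula(year_trend="none"),
            "omega": RateFormula(year_trend="none"),
        }
    return ModelSpec(variant="II", formulas=f)


def model_III(final: bool = False) -> ModelSpec:
    """Covariate models.  The starting form carries habitat interactions on
    the quadratic environmental terms plus the research-activity terms; the
    final form is the reduced structure retained after backward
    simplification (habitat-specific quadratic temperature on fledglings,
    shared quadratic precipitation, quadratic hatching date, clutch size and
    the threshold capture delay)."""
    if not final:
        fled = [
            Term("temp", quadratic=True, by_habitat=True),
            Term("prec", quadratic=True, by_habitat=True),
            Term("hat", quadratic=True, by_habitat=True),
            Term("cs"),
            Term("del", threshold=True),
            Term("meth"),
            Term("partag"),
        ]
        s1 = [
            Term("temp", quadratic=True),
            Term("prec", quadratic=True),
            Term("del", threshold=True),
            Term("meth"),
            Term("partag"),
        ]
        s2 = [Term("temp", quadratic=True), Term("prec", quadratic=True), Term("tag")]
    else:
        fled = [
            Term("temp", quadratic=True, by_habitat=True),
            Term("prec", quadratic=True),
            Term("hat", quadratic=True),
            Term("cs"),
            Term("del", threshold=True),
        ]
        s1 = [Term("temp"), Term("prec", quadratic=True), Term("del", threshold=True)]
        s2 = [Term("temp")]
    return ModelSpec(
        variant="III",
        formulas={
            "succ": RateFormula(year_re=True),
            "fled": RateFormula(terms=fled),
            "s1": RateFormula(terms=s1),
            "s2": RateFormula(terms=s2),
            "omega": RateFormula(),
        },
    )
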