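"""Worked design case studies: published cohort analyses re-examined.

Two birth-cohort analyses serve as end-to-end examples: a pregnancy cohort
relating urinary bisphenols to fetal growth (1,379 pregnancies, two urine
samples averaged per woman) and a mother-child cohort relating urinary
triclosan to neurodevelopment at age 3 (377 pairs / 184 boys, single spot
urines).  Each fixture records the variance components, actual sample sizes
and design effect sizes, and :func:`run_case_report` recomputes the design
quantities a planner would want: repeats needed for validity 0.7/0.9,
expected slope bias at the actual number of repeats, required subjects at
confirmatory power, and the minimum detectable effect at the actual size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from . import error_model, linear_design
from .error_model import ReliabilityQuery, VarianceComponents
from .linear_design import CONFIRMATORY, LinearDesign, TestSpec

__all__ = ["CaseStudyFixture", "load_case_studies", "run_case_report"]


@dataclass(frozen=True)
class CaseStudyFixture:
    """Parameters of one published case study, traceable to its source.

    ``vc`` holds the exposure variance components (derived from an ICC and a
    best-case between-person variance when the source reports only a total);
    ``icc_design`` is the rounded reliability used as input to the repeats
    calculator; ``citation`` records where each number comes from.
    """

    key: str
    label: str
    vc: VarianceComponents
    n_actual: int
    m_actual: int
    sigma2_outcome: float
    beta_design: float
    icc_design: float
    citation: str
    effects_reported: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_actual < 1 or self.m_actual < 1:
            raise ValueError("n_actual and m_actual must be >= 1")
        if self.sigma2_outcome <= 0:
            raise ValueError("sigma2_outcome must be positive")
        if not 0 < self.icc_design < 1:
            raise ValueError("icc_design must be in (0, 1)")


def _fixture_from_mapping(key: str, raw: dict) -> CaseStudyFixture:
    if "sigma2_within" in raw:
        vc = VarianceComponents(raw["sigma2_between"], raw["sigma2_within"])
    else:
        # Only an ICC and a (best-case between-person) variance are reported.
        vc = VarianceComponents.from_icc(raw["icc"], raw["sigma2_between"])
    return CaseStudyFixture(
        key=key,
        label=raw["label"],
        vc=vc,
        n_actual=int(raw["n_actual"]),
        m_actual=int(raw["m_actual"]),
        sigma2_outcome=float(raw["sigma2_outcome"]),
        beta_design=float(raw["beta_design"]),
        icc_design=float(raw["icc_design"]),
        citation=raw["citation"].strip(),
        effects_reported=tuple(
            (e["effect"], e["note"]) for e in raw.get("effects_reported", ())
        ),
    )


def load_case_studies() -> dict[str, CaseStudyFixture]:
    """Load the shipped case-study fixtures, keyed by short name."""
    text = (
        resources.files("expower").joinpath("data/case_studies.yaml").read_text()
    )
    raw = yaml.safe_load(text)
    return {key: _fixture_from_mapping(key, val) for key, val in raw.items()}


def run_case_report(
    fixture: CaseStudyFixture,
    test: TestSpec = CONFIRMATORY,
    m_grid: tuple[int, ...] = (1, 2, 10),
    rho_targets: tuple[float, ...] = (0.7, 0.9),
) -> dict:
    """Recompute the design quantities for one case study.

    Returns a nested dict with: required repeats for each target validity
    coefficient (from the design ICC), expected percent slope bias at the
    actual number of repeats, required subjects over ``m_grid`` at the given
    test spec, and the minimum detectable slope at the actual study size
    over the same grid.
    """
    repeats = {}
    for rho in rho_targets:
        _, m_int = error_model.repeats_for_validity(
            ReliabilityQuery(icc=fixture.icc_design, rho=rho)
        )
        repeats[rho] = m_int

    bias_at_actual = error_model.percent_bias(fixture.vc, fixture.m_actual)

    n_required = {}
    mde = {}
    for m in m_grid:
        design = LinearDesign(
            sigma2_outcome=fixture.sigma2_outcome,
            beta=fixture.beta_design,
            vc=fixture.vc,
            m=m,
            n=fixture.n_actual,
        )
        n_required[m] = linear_design.n_with_error(design, test)
        mde[m] = linear_design.mde_for_n(design, test)

    return {
        "key": fixture.key,
        "label": fixture.label,
        "inputs": {
            "sigma2_between": fixture.vc.sigma2_between,
            "sigma2_within": fixture.vc.sigma2_within,
            "icc": fixture.vc.icc,
            "icc_design": fixture.icc_design,
            "n_actual": fixture.n_actual,
            "m_actual": fixture.m_actual,
            "sigma2_outcome": fixture.sigma2_outcome,
            "beta_design": fixture.beta_design,
            "alpha": test.alpha,
            "power": test.power,
        },
        "repeats_for_validity": repeats,
        "percent_bias_at_actual_m": bias_at_actual,
        "n_required": n_required,
        "mde_at_actual_n": mde,
        "citation": fixture.citation,
    }
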