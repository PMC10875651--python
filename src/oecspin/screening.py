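"""Multi-criteria screening of candidate cluster models against experiment.

Ammonia-bound S2-state models of the oxygen-evolving complex are screened
against magnetic-resonance observables:

* hard criterion — the ground spin state must be a doublet (S_GS = 1/2),
  as required by the g ~ 2 multiline EPR signal of ammonia-treated samples;
* the gap to the first excited spin multiplet, expected near 30 cm^-1
  (acceptance window 16-46 cm^-1);
* the three successive ratios of the descending-sorted 55Mn hyperfine
  couplings, compared (root-mean-square) with ENDOR-derived references;
* the nuclear quadrupole asymmetry eta of the bound ammonia-derived 14N,
  expected in a window around the experimental 0.4-0.6 spread;
* range checks on 17O hyperfine couplings of exchangeable/terminal oxygen
  ligands (flagging any value above 16 MHz, or the absence of any
  coupling above 4 MHz);
* optionally, the electron-affinity difference EA(S2) - EA(S2-NH3), whose
  experimental estimate is 2.70 kcal/mol (the EAs themselves are inputs).

Models passing the hard criterion are ranked by a weighted sum of soft
deviations.  The composite score is a package convention — the underlying
experiments define no numeric aggregate — and the weights are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .heisenberg import GroundStateAnalysis
from .spin_system import ExperimentalReference, ValidationError

__all__ = [
    "ScreeningConfig",
    "CriterionOutcome",
    "ModelReport",
    "ScreeningReport",
    "check_ground_spin",
    "check_excited_gap",
    "compare_hfc_ratios",
    "compare_nqi",
    "check_o17",
    "ea_difference",
    "screen_models",
]

PASS = "pass"
FAIL = "fail"
NOT_EVALUATED = "not_evaluated"


@dataclass(frozen=True)
class ScreeningConfig:
    """Windows, references and weights for the screening criteria."""

    gap_reference_cm1: float = 30.0
    gap_window_cm1: tuple[float, float] = (16.0, 46.0)
    eta_window: tuple[float, float] = (0.4, 0.6)
    o17_large_mhz: float = 16.0
    o17_small_mhz: float = 4.0
    ea_reference_kcal: float = 2.70
    weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "excited_gap": 1.0,
            "hfc_ratios": 1.0,
            "nqi_eta": 1.0,
            "o17": 1.0,
            "ea_difference": 1.0,
        }
    )

    def __post_init__(self):
        if self.gap_window_cm1[0] > self.gap_window_cm1[1]:
            raise ValidationError("gap window bounds out of order")
        if not (0 <= self.eta_window[0] <= self.eta_window[1] <= 1):
            raise ValidationError("eta window must be ordered within [0, 1]")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("criterion weights must be non-negative")


@dataclass(frozen=True)
class CriterionOutcome:
    """Outcome of one criterion for one model."""

    criterion: str
    status: str  # pass / fail / not_evaluated
    value: object = None
    reference: object = None
    deviation: float | None = None  # soft score, >= 0, 0 is perfect
    units: str = ""
    note: str = ""


@dataclass(frozen=True)
class ModelReport:
    """All criterion outcomes plus the composite verdict for one model."""

    model: str
    outcomes: tuple[CriterionOutcome, ...]
    verdict: str  # consistent / excluded / ambiguous
    score: float | None  # weighted soft score; None when excluded

    def outcome(self, criterion: str) -> CriterionOutcome | None:
        for o in self.outcomes:
            if o.criterion == criterion:
                return o
        return None


@dataclass(frozen=True)
class ScreeningReport:
    """Ranked screening results over a collection of models."""

    reports: tuple[ModelReport, ...]
    config: ScreeningConfig
    provenance: Mapping[str, str] = field(default_factory=dict)

    def ranking(self) -> list[str]:
        """Model names, best first; excluded models trail in name order."""
        ranked = sorted(
            (r for r in self.reports if r.verdict != "excluded"),
            key=lambda r: (r.score, r.model),
        )
        excluded = sorted(
            (r for r in self.reports if r.verdict == "excluded"),
            key=lambda r: r.model,
        )
        return [r.model for r in ranked] + [r.model for r in excluded]

    def rank_of(self, model: str) -> int:
        return self.ranking().index(model)


def check_ground_spin(analysis: GroundStateAnalysis) -> CriterionOutcome:
    """Hard criterion: the ground multiplet must be a spin doublet."""
    ok = analysis.S_GS == Fraction(1, 2)
    return CriterionOutcome(
        criterion="ground_spin",
        status=PASS if ok else FAIL,
        value=str(analysis.S_GS),
        reference="1/2",
        deviation=0.0 if ok else None,
    )


def check_excited_gap(
    analysis: GroundStateAnalysis, config: ScreeningConfig = ScreeningConfig()
) -> CriterionOutcome:
    """Gap to the first excited multiplet vs the ~30 cm^-1 expectation."""
    if analysis.dE_ES is None:
        return CriterionOutcome(
            criterion="excited_gap",
            status=NOT_EVALUATED,
            note="single-multiplet ladder",
        )
    gap = analysis.dE_ES
    lo, hi = config.gap_window_cm1
    deviation = abs(gap - config.gap_reference_cm1)
    return CriterionOutcome(
        criterion="excited_gap",
        status=PASS if lo <= gap <= hi else FAIL,
        value=gap,
        reference=(lo, hi),
        deviation=deviation,
        units="cm-1",
    )


def compare_hfc_ratios(
    model_ratios: Sequence[float],
    references: Sequence[ExperimentalReference],
) -> CriterionOutcome:
    """RMS difference of the three 55Mn HFC ratios vs each reference.

    The minimum RMS over the supplied reference organisms is reported, so a
    model consistent with any organism's ENDOR data scores well.
    """
    if len(model_ratios) != 3:
        raise ValidationError("expected 3 hyperfine ratios")
    refs = [r for r in references if r.hfc_ratios is not None]
    if not refs:
        return CriterionOutcome(
            criterion="hfc_ratios", status=NOT_EVALUATED, note="no references"
        )
    devs = {
        r.organism: float(
            np.sqrt(
                np.mean(
                    (np.asarray(model_ratios) - np.asarray(r.hfc_ratios)) ** 2
                )
            )
        )
        for r in refs
    }
    best = min(devs, key=lambda k: (devs[k], k))
    return CriterionOutcome(
        criterion="hfc_ratios",
        status=PASS,
        value=tuple(round(r, 2) for r in model_ratios),
        reference=best,
        deviation=devs[best],
    )


def compare_nqi(
    eta_model: float, config: ScreeningConfig = ScreeningConfig()
) -> CriterionOutcome:
    """14N quadrupole asymmetry vs the experimental window."""
    if not (0.0 <= eta_model <= 1.0):
        raise ValidationError(f"eta={eta_model} outside [0, 1]")
    lo, hi = config.eta_window
    inside = lo <= eta_model <= hi
    deviation = 0.0 if inside else min(abs(eta_model - lo), abs(eta_model - hi))
    return CriterionOutcome(
        criterion="nqi_eta",
        status=PASS if inside else FAIL,
        value=eta_model,
        reference=(lo, hi),
        deviation=deviation,
    )


def check_o17(
    o17_values: Mapping[str, float],
    config: ScreeningConfig = ScreeningConfig(),
) -> CriterionOutcome:
    """Range checks on 17O hyperfine couplings.

    Fails when any |A_iso| exceeds the large-coupling flag (default 16 MHz,
    far above the ~7 MHz exchangeable-oxygen signal) or when every value
    falls below the small-coupling floor (default 4 MHz, indicating loss of
    the exchangeable bridging oxygen).  The soft deviation is 1 for a
    flagged model, 0 otherwise.
    """
    values = [abs(v) for v in o17_values.values()]
    if not values:
        return CriterionOutcome(
            criterion="o17", status=NOT_EVALUATED, note="no 17O data"
        )
    if max(values) > config.o17_large_mhz:
        note = f"|A| > {config.o17_large_mhz} MHz"
        status, dev = FAIL, 1.0
    elif max(values) < config.o17_small_mhz:
        note = f"all |A| < {config.o17_small_mhz} MHz (no exchangeable O)"
        status, dev = FAIL, 1.0
    else:
        note = ""
        status, dev = PASS, 0.0
    return CriterionOutcome(
        criterion="o17",
        status=status,
        value=dict(o17_values),
        deviation=dev,
        units="MHz",
        note=note,
    )


def ea_difference(
    ea_s2: float,
    ea_nh3: float,
    reference: float = 2.70,
) -> CriterionOutcome:
    """Electron-affinity difference EA(S2) - EA(S2-NH3).

    The ammonia-bound state must be harder to reduce (positive difference);
    the soft score is the distance from the experimental estimate.
    """
    delta = ea_s2 - ea_nh3
    return CriterionOutcome(
        criterion="ea_difference",
        status=PASS if delta > 0 else FAIL,
        value=delta,
        reference=reference,
        deviation=abs(delta - reference),
        units="kcal/mol",
    )


@dataclass(frozen=True)
class ModelInputs:
    """Everything known about one candidate model entering the screen."""

    analysis: GroundStateAnalysis
    mn_ratios: Sequence[float] | None = None
    n14_eta: float | None = None
    o17_aiso: Mapping[str, float] | None = None
    ea_model: float | None = None
    ea_parent: float | None = None


def _soft_score(
    outcomes: Sequence[CriterionOutcome], config: ScreeningConfig
) -> float:
    """Weighted sum of normalized soft deviations (lower is better)."""
    total = 0.0
    for o in outcomes:
        if o.status == NOT_EVALUATED or o.deviation is None:
            continue
        w = config.weights.get(o.criterion, 0.0)
        dev = o.deviation
        if o.criterion == "excited_gap":
            dev = dev / config.gap_reference_cm1
        elif o.criterion == "ea_difference":
            dev = dev / config.ea_reference_kcal
        total += w * dev
    return total


def screen_models(
    models: Mapping[str, ModelInputs],
    references: Sequence[ExperimentalReference],
    config: ScreeningConfig = ScreeningConfig(),
    provenance: Mapping[str, str] | None = None,
) -> ScreeningReport:
    """Run every applicable criterion on every model and rank the field.

    A model failing the hard ground-spin criterion is excluded outright and
    carries no composite score.  Criteria lacking inputs are reported as
    not evaluated, never silently passed.  Output order (and hence report
    bytes) is deterministic: scores ties break on the model name.
    """
    if not models:
        raise ValidationError("no models to screen")
    reports = []
    for name in sorted(models):
        inputs = models[name]
        outcomes = [check_ground_spin(inputs.analysis)]
        excluded = outcomes[0].status == FAIL
        if not excluded:
            outcomes.append(check_excited_gap(inputs.analysis, config))
        if inputs.mn_ratios is not None:
            outcomes.append(compare_hfc_ratios(inputs.mn_ratios, references))
        else:
            outcomes.append(
                CriterionOutcome("hfc_ratios", NOT_EVALUATED, note="no 55Mn data")
            )
        if inputs.n14_eta is not None:
            outcomes.append(compare_nqi(inputs.n14_eta, config))
        else:
            outcomes.append(
                CriterionOutcome("nqi_eta", NOT_EVALUATED, note="no 14N data")
            )
        if inputs.o17_aiso is not None:
            outcomes.append(check_o17(inputs.o17_aiso, config))
        else:
            outcomes.append(
                CriterionOutcome("o17", NOT_EVALUATED, note="no 17O data")
            )
        if inputs.ea_model is not None and inputs.ea_parent is not None:
            outcomes.append(
                ea_difference(
                    inputs.ea_parent, inputs.ea_model, config.ea_reference_kcal
                )
            )
        else:
            outcomes.append(
                CriterionOutcome(
                    "ea_difference", NOT_EVALUATED, note="no EA inputs"
                )
            )
        if excluded:
            verdict, score = "excluded", None
        else:
            evaluated = [o for o in outcomes if o.status != NOT_EVALUATED]
            verdict = (
                "consistent"
                if all(o.status == PASS for o in evaluated)
                else "ambiguous"
            )
            score = _soft_score(outcomes, config)
        reports.append(
            ModelReport(
                model=name,
                outcomes=tuple(outcomes),
                verdict=verdict,
                score=score,
            )
        )
    return ScreeningReport(
        reports=tuple(reports),
        config=config,
        provenance=dict(provenance or {}),
    )
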