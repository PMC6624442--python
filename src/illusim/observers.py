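"""Simulated 2AFC observers for eye-size comparison judgments.

A simulated participant judges, on every trial, whether the comparison
face's eyes look larger than the standard face's eyes.  The probability of
answering "comparison larger" follows a lapse-mixed cumulative-Gaussian
psychometric function of the comparison eye size (in percent of the
original eye size).  Each observer carries condition-wise true points of
subjective equality (PSEs): a baseline near 100%, an eyeshadow shift (the
true illusion magnitude for that observer), optional per-orientation
shifts, and optional eyeshadow x orientation interaction shifts.

Observer populations are drawn with independent normal random effects on
each of these parameters, which is the between-subject structure a
repeated-measures analysis of the resulting PSE table assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "COMPARATIVE_LARGER",
    "STANDARD_LARGER",
    "PsychometricObserver",
    "ThresholdObserver",
    "PopulationSpec",
    "sample_population",
    "respond",
]

#: Response label: the comparison stimulus was judged to have larger eyes.
COMPARATIVE_LARGER = "comparative_larger"
#: Response label: the standard stimulus was judged to have larger eyes.
STANDARD_LARGER = "standard_larger"

_SQRT2 = math.sqrt(2.0)


class ConfigurationError(ValueError):
    """Raised for invalid observer or population specifications."""


@dataclass(frozen=True)
class PsychometricObserver:
    """One simulated participant of the eye-size comparison task.

    Parameters
    ----------
    subject_id
        Identifier carried through trial logs and PSE tables.
    baseline_pse
        True PSE (percent of original eye size) for a no-eyeshadow
        standard at an orientation with zero orientation shift.
    shadow_shift
        True eyeshadow illusion magnitude for this observer, in percent:
        how much eyeshadow inflates the perceived eye size of the standard.
    orientation_shifts
        Map orientation angle (degrees) -> additive PSE shift in percent.
        Angles missing from the map contribute zero.
    interaction_shifts
        Map ``(shadow, angle)`` -> additive shift.  All zero (the default)
        encodes a viewpoint-invariant illusion.
    slope
        Spread (standard deviation, percent) of the cumulative-Gaussian
        psychometric function; must be positive.
    lapse_rate
        Probability of a stimulus-independent guess, mixed symmetrically
        into both tails; must lie in [0, 0.5).
    """

    subject_id: str
    baseline_pse: float = 100.0
    shadow_shift: float = 0.0
    orientation_shifts: Mapping[float, float] = field(default_factory=dict)
    interaction_shifts: Mapping[tuple[int, float], float] = field(default_factory=dict)
    slope: float = 2.0
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ConfigurationError(f"slope must be > 0, got {self.slope}")
        if not (0.0 <= self.lapse_rate < 0.5):
            raise ConfigurationError(
                f"lapse_rate must be in [0, 0.5), got {self.lapse_rate}"
            )

    def true_pse(self, shadow: int, angle: float) -> float:
        """Latent PSE (percent) for one standard stimulus condition."""
        pse = self.baseline_pse + float(self.orientation_shifts.get(angle, 0.0))
        if shadow:
            pse += self.shadow_shift
        pse += float(self.interaction_shifts.get((int(bool(shadow)), angle), 0.0))
        if not math.isfinite(pse):
            raise ConfigurationError(
                f"non-finite true PSE for subject {self.subject_id}, "
                f"shadow={shadow}, angle={angle}"
            )
        return pse

    def p_comparative_larger(
        self, shadow: int, angle: float, comparative_size: float
    ) -> float:
        """P(judge the comparison's eyes larger) at ``comparative_size``.

        Lapse-mixed cumulative Gaussian:
        ``lapse + (1 - 2*lapse) * Phi((x - pse) / slope)``.
        """
        if not math.isfinite(comparative_size):
            raise ValueError("comparative_size must be finite")
        z = (comparative_size - self.true_pse(shadow, angle)) / self.slope
        phi = 0.5 * (1.0 + math.erf(z / _SQRT2))
        return self.lapse_rate + (1.0 - 2.0 * self.lapse_rate) * phi

    def respond(self, shadow: int, angle: float, comparative_size: float, rng) -> str:
        p = self.p_comparative_larger(shadow, angle, comparative_size)
        return COMPARATIVE_LARGER if rng.random() < p else STANDARD_LARGER


@dataclass(frozen=True)
class ThresholdObserver:
    """Deterministic test observer: comparison larger iff level > threshold.

    The strict inequality makes the 1-up/1-down staircase oscillate on the
    two grid levels that bracket the threshold, which gives exact hand-
    checkable trial sequences.  Used by the toy preset and the test suite.
    """

    subject_id: str
    threshold: float = 100.0

    def true_pse(self, shadow: int, angle: float) -> float:
        return self.threshold

    def p_comparative_larger(
        self, shadow: int, angle: float, comparative_size: float
    ) -> float:
        return 1.0 if comparative_size > self.threshold else 0.0

    def respond(self, shadow: int, angle: float, comparative_size: float, rng) -> str:
        return (
            COMPARATIVE_LARGER
            if comparative_size > self.threshold
            else STANDARD_LARGER
        )


def respond(
    observer, shadow: int, angle: float, comparative_size: float, rng
) -> str:
    """Draw one binary judgment from an observer's psychometric function."""
    return observer.respond(shadow, angle, comparative_size, rng)


@dataclass(frozen=True)
class PopulationSpec:
    """Between-subject distribution of observer parameters.

    Each observer's baseline PSE, eyeshadow shift, per-orientation shifts
    and interaction shifts are drawn independently from normal
    distributions with the means and SDs given here; slope and lapse rate
    are shared constants.  Defaults follow the study design this package
    simulates: 20 subjects, a +2.42% mean eyeshadow shift, no orientation
    or interaction effects (a viewpoint-invariant illusion).
    """

    n_subjects: int = 20
    baseline_pse_mean: float = 100.0
    baseline_pse_sd: float = 1.0
    shadow_shift_mean: float = 2.42
    shadow_shift_sd: float = 1.0
    orientation_shift_means: Mapping[float, float] = field(default_factory=dict)
    orientation_shift_sd: float = 0.0
    interaction_shift_means: Mapping[tuple[int, float], float] = field(
        default_factory=dict
    )
    interaction_shift_sd: float = 0.0
    slope: float = 2.0
    lapse_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError(
                f"n_subjects must be >= 2, got {self.n_subjects}"
            )
        for name in (
            "baseline_pse_sd",
            "shadow_shift_sd",
            "orientation_shift_sd",
            "interaction_shift_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not self.slope > 0:
            raise ConfigurationError("slope must be > 0")
        if not (0.0 <= self.lapse_rate < 0.5):
            raise ConfigurationError("lapse_rate must be in [0, 0.5)")


def sample_population(
    spec: PopulationSpec,
    angles: Sequence[float] = (),
    rng: np.random.Generator | None = None,
) -> list[PsychometricObserver]:
    """Draw a reproducible observer population from ``spec``.

    ``angles`` lists the orientations for which per-subject orientation and
    interaction random effects are drawn (angles absent from
    ``orientation_shift_means`` get mean 0).  If ``rng`` is omitted, a
    generator is seeded from ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    observers = []
    for i in range(spec.n_subjects):
        orient = {
            float(a): float(
                rng.normal(
                    spec.orientation_shift_means.get(float(a), 0.0),
                    spec.orientation_shift_sd,
                )
            )
            for a in angles
        }
        inter = {
            (s, float(a)): float(
                rng.normal(
                    spec.interaction_shift_means.get((s, float(a)), 0.0),
                    spec.interaction_shift_sd,
                )
            )
            for s in (0, 1)
            for a in angles
        }
        observers.append(
            PsychometricObserver(
                subject_id=f"s{i + 1:02d}",
                baseline_pse=float(
                    rng.normal(spec.baseline_pse_mean, spec.baseline_pse_sd)
                ),
                shadow_shift=float(
                    rng.normal(spec.shadow_shift_mean, spec.shadow_shift_sd)
                ),
                orientation_shifts=orient,
                interaction_shifts=inter,
                slope=spec.slope,
                lapse_rate=spec.lapse_rate,
            )
        )
    return observers
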