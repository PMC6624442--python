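"""Point-of-subjective-equality estimation from staircase reversals.

The PSE of one design cell (subject x eyeshadow x orientation) is the mean
of the comparison levels at which that cell's two staircases (ascending
and descending) reversed direction.  Reversal levels are recomputed by
replaying the logged responses through the staircase state machine in
trial order, so the estimate depends only on the ordered response
sequence, never on row order or side metadata in the log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .staircase import (
    StaircaseConfig,
    StaircaseState,
    TrialRecord,
    TrialTable,
    run_block,
    update_staircase,
)

__all__ = [
    "PSETable",
    "PSEEstimationError",
    "estimate_pse",
    "pse_table",
    "simulate_pse_table",
    "illusion_magnitude",
    "IllusionSummary",
]


class PSEEstimationError(ValueError):
    """Raised when a design cell yields no usable reversals."""


class IncompleteDesignError(ValueError):
    """Raised when the trial log or PSE table misses design cells."""


def _replay_reversals(
    records: Sequence[TrialRecord], config: StaircaseConfig
) -> list[float]:
    """Reversal levels of one staircase, recomputed from its ordered log."""
    ordered = sorted(records, key=lambda r: r.trial_index)
    first = ordered[0]
    state = StaircaseState.start(first.shadow, first.direction, config)
    levels: list[float] = []
    for rec in ordered:
        if state.terminated:
            break
        presented = state.current_level
        if abs(presented - rec.comparative_level) > 1e-9:
            raise ValueError(
                f"trial log inconsistent with staircase state machine: "
                f"staircase {first.staircase_id} trial {rec.trial_index} "
                f"logged level {rec.comparative_level}, replay expected "
                f"{presented}"
            )
        if update_staircase(state, rec.response, config):
            levels.append(presented)
    return levels


def estimate_pse(
    cell_records: Iterable[TrialRecord],
    config: StaircaseConfig,
    pooling: str = "pooled",
) -> float:
    """PSE of one subject x eyeshadow x orientation cell.

    ``pooling="pooled"`` (default) averages all reversal levels of the
    cell's staircases together; ``pooling="per_staircase"`` first averages
    within each staircase, then across staircases.  The two agree whenever
    every staircase contributes the same number of reversals, which is the
    normal case (termination at a fixed reversal count).
    """
    by_staircase: dict[str, list[TrialRecord]] = {}
    for rec in cell_records:
        by_staircase.setdefault(rec.staircase_id, []).append(rec)
    if not by_staircase:
        raise PSEEstimationError("cell contains no trials")
    reversal_sets = {
        sid: _replay_reversals(recs, config)
        for sid, recs in by_staircase.items()
    }
    if all(len(v) == 0 for v in reversal_sets.values()):
        raise PSEEstimationError("cell contains no reversals")
    if pooling == "pooled":
        pooled = [lv for v in reversal_sets.values() for lv in v]
        return float(np.mean(pooled))
    if pooling == "per_staircase":
        means = [float(np.mean(v)) for v in reversal_sets.values() if v]
        return float(np.mean(means))
    raise ValueError(f"unknown pooling {pooling!r}")


@dataclass(frozen=True)
class PSETable:
    """Balanced subject x eyeshadow x orientation table of estimated PSEs.

    ``frame`` is tidy with columns ``subject``, ``shadow`` (0/1), ``angle``
    (degrees) and ``pse`` (percent of original eye size), exactly one row
    per design cell.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "shadow", "angle", "pse"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"PSE table missing columns: {sorted(missing)}")
        counts = self.frame.groupby(
            ["subject", "shadow", "angle"], sort=True
        ).size()
        if (counts != 1).any():
            raise IncompleteDesignError("duplicate subject/shadow/angle cells")
        expected = (
            len(self.subjects) * len(self.shadow_levels) * len(self.angles)
        )
        if len(self.frame) != expected:
            missing_cells = [
                cell
                for cell in (
                    (s, sh, a)
                    for s in self.subjects
                    for sh in self.shadow_levels
                    for a in self.angles
                )
                if cell not in set(counts.index)
            ]
            raise IncompleteDesignError(
                f"incomplete design, missing cells: {missing_cells[:10]}"
            )
        if not np.isfinite(self.frame["pse"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite PSE values")

    @property
    def subjects(self) -> list:
        return sorted(self.frame["subject"].unique())

    @property
    def shadow_levels(self) -> list[int]:
        return sorted(int(s) for s in self.frame["shadow"].unique())

    @property
    def angles(self) -> list[float]:
        return sorted(float(a) for a in self.frame["angle"].unique())

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    def to_wide(self) -> np.ndarray:
        """Array of shape (n_subjects, n_shadow, n_angles), sorted keys."""
        pivot = self.frame.pivot_table(
            index="subject", columns=["shadow", "angle"], values="pse",
            sort=True,
        )
        n_sh, n_an = len(self.shadow_levels), len(self.angles)
        return pivot.to_numpy(dtype=float).reshape(self.n_subjects, n_sh, n_an)

    @classmethod
    def from_wide(
        cls,
        data: np.ndarray,
        subjects: Sequence | None = None,
        angles: Sequence[float] | None = None,
    ) -> "PSETable":
        data = np.asarray(data, dtype=float)
        n_sub, n_sh, n_an = data.shape
        subjects = (
            [f"s{i + 1:02d}" for i in range(n_sub)]
            if subjects is None else list(subjects)
        )
        angles = list(range(n_an)) if angles is None else list(angles)
        rows = [
            (subjects[i], sh, float(angles[a]), data[i, sh, a])
            for i in range(n_sub)
            for sh in range(n_sh)
            for a in range(n_an)
        ]
        return cls(pd.DataFrame(rows, columns=["subject", "shadow", "angle", "pse"]))

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PSETable":
        return cls(pd.read_csv(path))


def pse_table(
    trials: TrialTable | pd.DataFrame,
    config: StaircaseConfig | None = None,
    pooling: str = "pooled",
) -> PSETable:
    """Estimate every design cell's PSE from a trial log.

    Cells with no reversals raise: the downstream repeated-measures
    analysis requires a complete balanced table, so silently dropping
    cells is never correct here.
    """
    if config is None:
        config = StaircaseConfig()
    if isinstance(trials, pd.DataFrame):
        trials = TrialTable.from_frame(trials)
    cells: dict[tuple, list[TrialRecord]] = {}
    for rec in trials.records:
        cells.setdefault((rec.subject_id, rec.shadow, rec.block), []).append(rec)
    subjects = sorted({k[0] for k in cells})
    angles = sorted({k[2] for k in cells})
    rows = []
    missing = []
    for s in subjects:
        for sh in (0, 1):
            for a in angles:
                recs = cells.get((s, sh, a))
                if not recs:
                    missing.append((s, sh, a))
                    continue
                rows.append((s, sh, a, estimate_pse(recs, config, pooling)))
    if missing:
        raise IncompleteDesignError(f"missing design cells: {missing[:10]}")
    return PSETable(pd.DataFrame(rows, columns=["subject", "shadow", "angle", "pse"]))


def simulate_pse_table(
    population: Sequence,
    angles: Sequence[float],
    config: StaircaseConfig,
    seed,
    pooling: str = "pooled",
) -> PSETable:
    """Run the staircase protocol and estimate PSEs without keeping logs.

    Equivalent to ``pse_table(run_experiment(...))`` — reversal levels are
    read off the final staircase states instead of replayed from the trial
    log — but allocates no per-trial records, which matters for replicate
    studies (type-I calibration, parameter recovery) that run the full
    protocol hundreds of times.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for child, observer in zip(ss.spawn(len(population)), population):
        rng = np.random.default_rng(child)
        order = rng.permutation(len(angles))
        for idx in order:
            angle = float(angles[idx])
            _, states = run_block(observer, angle, config, rng, return_states=True)
            for sh in (0, 1):
                sets = [st.reversal_levels for st in states if st.shadow == sh]
                if all(len(v) == 0 for v in sets):
                    raise PSEEstimationError(
                        f"no reversals for subject {observer.subject_id}, "
                        f"shadow={sh}, angle={angle}"
                    )
                if pooling == "pooled":
                    pooled = [lv for v in sets for lv in v]
                    pse = float(np.mean(pooled))
                else:
                    pse = float(np.mean([np.mean(v) for v in sets if v]))
                rows.append((observer.subject_id, sh, angle, pse))
    frame = (
        pd.DataFrame(rows, columns=["subject", "shadow", "angle", "pse"])
        .sort_values(["subject", "shadow", "angle"], kind="mergesort")
        .reset_index(drop=True)
    )
    return PSETable(frame)


@dataclass(frozen=True)
class IllusionSummary:
    """Eyeshadow illusion magnitudes: PSE(shadow) - PSE(no shadow).

    ``per_angle`` has one row per orientation with the across-subject mean,
    SD and standard error of the subject-wise difference; the grand values
    summarise each subject's difference averaged over orientations.
    """

    per_angle: pd.DataFrame
    grand_mean: float
    grand_sd: float
    grand_se: float
    n_subjects: int

    def to_dict(self) -> dict:
        return {
            "grand_mean": self.grand_mean,
            "grand_sd": self.grand_sd,
            "grand_se": self.grand_se,
            "n_subjects": self.n_subjects,
            "per_angle": self.per_angle.to_dict(orient="records"),
        }


def illusion_magnitude(table: PSETable) -> IllusionSummary:
    """Per-orientation and grand eyeshadow effects from a PSE table.

    Positive values mean eyeshadow enlarged the perceived eye size (the
    standard with eyeshadow required a larger comparison to match).
    """
    wide = table.to_wide()  # (subjects, shadow, angles)
    if wide.shape[1] != 2:
        raise ValueError("illusion magnitude requires exactly 2 shadow levels")
    diff = wide[:, 1, :] - wide[:, 0, :]  # (subjects, angles)
    n = diff.shape[0]
    per_angle = pd.DataFrame(
        {
            "angle": table.angles,
            "mean": diff.mean(axis=0),
            "sd": diff.std(axis=0, ddof=1),
            "se": diff.std(axis=0, ddof=1) / np.sqrt(n),
        }
    )
    subj_means = diff.mean(axis=1)
    return IllusionSummary(
        per_angle=per_angle,
        grand_mean=float(subj_means.mean()),
        grand_sd=float(subj_means.std(ddof=1)),
        grand_se=float(subj_means.std(ddof=1) / np.sqrt(n)),
        n_subjects=n,
    )
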