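"""End-to-end experiment runners: cohorts in, significance grid out.

Experiment 1 manipulates the splay *rate* during flight (dynamic rod
modes plus the parallel/narrow controls) and asks, per condition cell,
whether altitude differs across time bins around the motion onset
(Friedman omnibus + exact all-pairs post hoc).  Experiment 2 sets the
splay *angle* between flights (static modes) and compares whole-flight
median altitudes against the matching parallel control (Mann–Whitney).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .controller import ControllerParams, Trajectory
from .pipeline import bin_median, epoch_split, ground_following_filter
from .stats import (
    FriedmanResult,
    PairwiseTestResult,
    friedman_allpairs_exact,
    friedman_test,
    mann_whitney,
)
from .synthio import CohortSpec, generate_cohort

__all__ = [
    "EXP1_MODES",
    "EXP2_MODES",
    "TEXTURES",
    "CellOutcome",
    "analyze_experiment1",
    "analyze_experiment2",
    "run_full_study",
    "pattern_grid",
]

EXP1_MODES = ("parallel", "narrow", "dynamic_converging", "dynamic_diverging")
EXP2_MODES = ("parallel", "narrow", "static_converging", "static_diverging")
TEXTURES = ("white", "striped")

ALPHA = 0.01


@dataclass(frozen=True)
class CellOutcome:
    """Analysis verdict for one (rod mode, texture) condition cell."""

    experiment: int
    rod_mode: str
    texture: str
    test: str  # "friedman" or "mann-whitney"
    statistic: float
    pvalue: float
    significant: bool
    direction: str  # "increase", "decrease" or "none"
    n_flights: int
    posthoc: tuple = field(default=())


def _cell_flights(flights: list[Trajectory], mode: str, texture: str) -> list[Trajectory]:
    out = [
        f
        for f in flights
        if f.condition.get("rod_mode") == mode and f.condition.get("texture") == texture
    ]
    return [f for f in out if ground_following_filter(f)]


def _median_altitudes(flights: list[Trajectory]) -> np.ndarray:
    return np.array([float(np.median(f.z)) for f in flights])


def analyze_experiment1(
    flights: list[Trajectory],
    onset: float = 2.0,
    n_before: int = 3,
    n_after: int = 3,
    alpha: float = ALPHA,
    seed: int = 0,
) -> list[CellOutcome]:
    """Friedman omnibus (+ post hoc when significant) per dynamic cell."""
    outcomes = []
    for texture in TEXTURES:
        for mode in EXP1_MODES:
            cell = _cell_flights(flights, mode, texture)
            if len(cell) < 2:
                continue
            binned = [bin_median(f) for f in cell]
            matrix = epoch_split(binned, onset=onset, n_before=n_before, n_after=n_after)
            res: FriedmanResult = friedman_test(matrix)
            posthoc: tuple = ()
            if res.pvalue < alpha:
                posthoc = tuple(friedman_allpairs_exact(matrix, seed=seed))
            pre = matrix.values[:, :n_before].mean()
            post = matrix.values[:, n_before:].mean()
            significant = res.pvalue < alpha
            direction = "none"
            if significant:
                direction = "increase" if post > pre else "decrease"
            outcomes.append(
                CellOutcome(
                    experiment=1,
                    rod_mode=mode,
                    texture=texture,
                    test="friedman",
                    statistic=res.statistic,
                    pvalue=res.pvalue,
                    significant=significant,
                    direction=direction,
                    n_flights=len(cell),
                    posthoc=posthoc,
                )
            )
    return outcomes


def analyze_experiment2(
    flights: list[Trajectory],
    alpha: float = ALPHA,
) -> list[CellOutcome]:
    """Mann–Whitney of each cell's median altitudes vs the parallel control.

    The parallel cells themselves are reported against the narrow
    control so every cell carries a verdict.
    """
    outcomes = []
    for texture in TEXTURES:
        reference = _median_altitudes(_cell_flights(flights, "parallel", texture))
        for mode in EXP2_MODES:
            cell = _cell_flights(flights, mode, texture)
            if len(cell) < 2 or reference.size < 2:
                continue
            values = _median_altitudes(cell)
            if mode == "parallel":
                other = _median_altitudes(_cell_flights(flights, "narrow", texture))
                if other.size < 2:
                    continue
                u, p = mann_whitney(values, other)
            else:
                u, p = mann_whitney(values, reference)
            significant = p < alpha
            direction = "none"
            if significant:
                direction = "increase" if np.median(values) > np.median(reference) else "decrease"
            outcomes.append(
                CellOutcome(
                    experiment=2,
                    rod_mode=mode,
                    texture=texture,
                    test="mann-whitney",
                    statistic=u,
                    pvalue=p,
                    significant=significant,
                    direction=direction,
                    n_flights=len(cell),
                )
            )
    return outcomes


def run_full_study(
    n_flights: int = 10,
    seed: int = 0,
    params: ControllerParams | None = None,
    n_before: int = 3,
    n_after: int = 3,
    alpha: float = ALPHA,
) -> list[CellOutcome]:
    """Simulate both experiments' cohorts and analyze all 16 cells."""
    params = params or ControllerParams()
    exp1_spec = CohortSpec(
        n_flights=n_flights,
        conditions=tuple((m, t) for t in TEXTURES for m in EXP1_MODES),
        seed=seed,
    )
    exp2_spec = CohortSpec(
        n_flights=n_flights,
        conditions=tuple((m, t) for t in TEXTURES for m in EXP2_MODES),
        seed=seed + 1,
    )
    exp1 = generate_cohort(exp1_spec, params)
    exp2 = generate_cohort(exp2_spec, params)
    out = analyze_experiment1(exp1, onset=exp1_spec.onset, n_before=n_before, n_after=n_after, alpha=alpha, seed=seed)
    out += analyze_experiment2(exp2, alpha=alpha)
    return out


def null_cohort_epochs(
    rng: np.random.Generator,
    n_flights: int = 10,
    duration: float = 1.05,
    onset: float = 0.5,
):
    """One epoch matrix from a no-manipulation cohort (type-I harness).

    Parallel rods over white ground, so the controller receives no rod
    stimulation and the bins differ only by noise.  Short flights keep
    repeated calls cheap; the onset is placed mid-flight so the default
    3+3 bin window fits.
    """
    spec = CohortSpec(
        n_flights=n_flights,
        conditions=(("parallel", "white"),),
        duration=duration,
        onset=onset,
        seed=int(rng.integers(2**31)),
    )
    flights = generate_cohort(spec)
    binned = [bin_median(f) for f in flights]
    return epoch_split(binned, onset=onset)


def pattern_grid(outcomes: list[CellOutcome]) -> pd.DataFrame:
    """Condition-by-outcome summary table of the qualitative pattern."""
    rows = []
    for o in outcomes:
        rows.append(
            {
                "experiment": o.experiment,
                "rod_mode": o.rod_mode,
                "texture": o.texture,
                "test": o.test,
                "statistic": round(o.statistic, 4),
                "pvalue": round(o.pvalue, 6),
                "significant": o.significant,
                "direction": o.direction,
                "n_flights": o.n_flights,
            }
        )
    return pd.DataFrame(rows).sort_values(["experiment", "texture", "rod_mode"]).reset_index(drop=True)
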