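"""Clonal fitness estimation and trajectory/architecture classification.

A clone's VAF is modelled as deterministic exponential growth between
two draws:

    VAF2 = VAF1 * (1 + CF)^T

so the annual proportional growth rate (clonal fitness) is

    CF = (VAF2 / VAF1)^(1/T) - 1

with T the elapsed time in years.  CF = 0.08 means the clone's VAF
grows 8% per year; CF is bounded below by -1 (complete loss).

Cohort-level classification: the 10% of clones with the smallest |CF|
are labelled stagnant; the rest are expansion (CF > 0) or reduction
(CF < 0).  Two-mutation individuals are called sub-clonal when both
clones sit in the same trajectory class and their within-class
standard scores differ by less than 0.6; otherwise the clones are
called distinct.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .panel_and_variants import ClonePair

logger = logging.getLogger("chipdyn")

STAGNANT = "stagnant"
EXPANSION = "expansion"
REDUCTION = "reduction"

SUB_CLONE = "sub-clone"
DISTINCT = "distinct"


@dataclass(frozen=True)
class DynamicsConfig:
    """Knobs of the trajectory/architecture classifier.

    stagnant_fraction: cohort quantile of |CF| labelled stagnant (0.10).
    z_gap_threshold: within-class z-score gap at or above which two
        same-direction clones are called distinct (0.6).
    floor_vaf: detection-limit imputation value, echoed for provenance.
    """

    stagnant_fraction: float = 0.10
    z_gap_threshold: float = 0.6
    floor_vaf: float = 0.001

    def __post_init__(self) -> None:
        if not 0 < self.stagnant_fraction < 1:
            raise ValueError("stagnant_fraction must be in (0, 1)")
        if self.z_gap_threshold <= 0:
            raise ValueError("z_gap_threshold must be > 0")


def compute_growth_rate(vaf1: float, vaf2: float, dt_years: float) -> float:
    """Annual proportional growth rate: (vaf2/vaf1)^(1/dt) - 1.

    Evaluated in log space, exp(log(vaf2/vaf1)/dt) - 1, which is exact
    for the ratio-of-powers form and stable at extreme ratios (e.g. a
    detection-limit 0.001 growing to 0.5 within a year).
    """
    if vaf1 <= 0:
        raise ValueError("vaf1 must be > 0 (impute the detection floor first)")
    if vaf2 <= 0:
        raise ValueError("vaf2 must be > 0")
    if dt_years <= 0:
        raise ValueError("dt_years must be > 0")
    return math.expm1(math.log(vaf2 / vaf1) / dt_years)


def project_vaf(vaf1: float, cf: float, dt_years: float) -> float:
    """Forward model: VAF after dt_years of growth at rate cf.

    The inverse of :func:`compute_growth_rate`.  A projection above 1
    is clamped (a clone cannot exceed the full cell fraction).
    """
    if vaf1 <= 0:
        raise ValueError("vaf1 must be > 0")
    if cf <= -1:
        raise ValueError("cf must be > -1")
    vaf2 = math.exp(math.log(vaf1) + dt_years * math.log1p(cf))
    if vaf2 > 1:
        logger.warning("projected VAF %.3f > 1 clamped to 1", vaf2)
        return 1.0
    return vaf2


@dataclass
class TrajectoryAssignment:
    """A clone's growth rate, trajectory class, and within-class z-score."""

    clone: ClonePair
    cf: float
    trajectory: str | None = None
    zscore: float | None = None

    @property
    def sort_key(self) -> tuple:
        return (self.clone.individual_id, self.clone.mutation_key)


def stagnant_count(n: int, stagnant_fraction: float) -> int:
    """Nearest-rank ceiling: number of clones labelled stagnant."""
    return math.ceil(stagnant_fraction * n) if n else 0


def classify_trajectories(
    pairs: Sequence[ClonePair],
    config: DynamicsConfig | None = None,
) -> list[TrajectoryAssignment]:
    """Assign stagnant/expansion/reduction labels across the whole cohort.

    The ceil(stagnant_fraction * n) clones with the smallest |CF| are
    stagnant (ties broken by individual id then mutation key, so input
    order never matters); remaining clones are labelled by the sign of
    CF.  Output preserves input order.
    """
    config = config or DynamicsConfig()
    assignments = [
        TrajectoryAssignment(clone=p, cf=compute_growth_rate(p.vaf1, p.vaf2, p.dt_years))
        for p in pairs
    ]
    n = len(assignments)
    if n == 0:
        return []
    k = stagnant_count(n, config.stagnant_fraction)
    ranked = sorted(assignments, key=lambda a: (abs(a.cf), a.sort_key))
    stagnant_ids = {id(a) for a in ranked[:k]}
    for a in assignments:
        if id(a) in stagnant_ids:
            a.trajectory = STAGNANT
        elif a.cf > 0:
            a.trajectory = EXPANSION
        else:
            a.trajectory = REDUCTION
    cutoff = stagnant_cutoff(assignments)
    logger.info(
        "classify_trajectories: n=%d, stagnant=%d (|cf| cutoff %.4g), "
        "expansion=%d, reduction=%d",
        n, k, cutoff if cutoff is not None else float("nan"),
        sum(a.trajectory == EXPANSION for a in assignments),
        sum(a.trajectory == REDUCTION for a in assignments),
    )
    return assignments


def stagnant_cutoff(assignments: Sequence[TrajectoryAssignment]) -> float | None:
    """Largest |CF| among stagnant clones — the implied stagnancy cutoff."""
    values = [abs(a.cf) for a in assignments if a.trajectory == STAGNANT]
    return max(values) if values else None


def zscore_within_class(
    assignments: Sequence[TrajectoryAssignment],
) -> list[TrajectoryAssignment]:
    """Standard-score each clone's CF within its trajectory class.

    Sample SD (n-1 denominator).  A class of size 1, or with zero
    spread, gets z = 0 for all members so that z-gap comparisons stay
    defined.  Mutates and returns the assignments.
    """
    by_class: dict[str, list[TrajectoryAssignment]] = {}
    for a in assignments:
        if a.trajectory is None:
            raise ValueError("trajectories must be assigned before z-scoring")
        by_class.setdefault(a.trajectory, []).append(a)
    for members in by_class.values():
        cfs = np.array([m.cf for m in members], dtype=float)
        if len(members) < 2 or np.std(cfs, ddof=1) == 0:
            for m in members:
                m.zscore = 0.0
            continue
        mean, sd = cfs.mean(), np.std(cfs, ddof=1)
        for m in members:
            m.zscore = (m.cf - mean) / sd
    return list(assignments)


@dataclass(frozen=True)
class ArchitectureCall:
    """Sub-clone vs distinct-clone call for a two-mutation individual."""

    individual_id: str
    clones: tuple[TrajectoryAssignment, TrajectoryAssignment]
    architecture: str
    z_gap: float | None


def classify_architecture(
    clones: Sequence[TrajectoryAssignment],
    config: DynamicsConfig | None = None,
) -> ArchitectureCall:
    """Call one two-mutation individual as sub-clone or distinct.

    Clones in different trajectory classes grow in different directions
    and are distinct.  Same-class clones are sub-clonal when their
    within-class z-scores differ by less than the threshold (0.6), and
    distinct at or above it.  z_gap is reported only for same-class
    pairs, where the scores are comparable.
    """
    config = config or DynamicsConfig()
    if len(clones) != 2:
        raise ValueError(
            f"architecture is called for exactly two clones, got {len(clones)}"
        )
    a, b = clones
    if a.trajectory is None or b.trajectory is None or a.zscore is None or b.zscore is None:
        raise ValueError("clones need trajectory and z-score before architecture call")
    if a.clone.individual_id != b.clone.individual_id:
        raise ValueError("clones belong to different individuals")
    if a.trajectory != b.trajectory:
        return ArchitectureCall(
            individual_id=a.clone.individual_id,
            clones=(a, b),
            architecture=DISTINCT,
            z_gap=None,
        )
    z_gap = abs(a.zscore - b.zscore)
    architecture = SUB_CLONE if z_gap < config.z_gap_threshold else DISTINCT
    return ArchitectureCall(
        individual_id=a.clone.individual_id,
        clones=(a, b),
        architecture=architecture,
        z_gap=z_gap,
    )


def call_architectures(
    assignments: Sequence[TrajectoryAssignment],
    config: DynamicsConfig | None = None,
) -> list[ArchitectureCall]:
    """Architecture calls for every two-mutation individual in a cohort.

    Individuals with one mutation, or three or more, get no call (the
    heuristic is defined only for pairs).
    """
    config = config or DynamicsConfig()
    by_individual: dict[str, list[TrajectoryAssignment]] = {}
    for a in assignments:
        by_individual.setdefault(a.clone.individual_id, []).append(a)
    calls = []
    for individual in sorted(by_individual):
        members = by_individual[individual]
        if len(members) == 2:
            calls.append(classify_architecture(members, config))
    return calls


def assign_dynamics(
    pairs: Sequence[ClonePair],
    config: DynamicsConfig | None = None,
) -> tuple[list[TrajectoryAssignment], list[ArchitectureCall], dict]:
    """Full dynamics stage: rates, trajectories, z-scores, architectures.

    Returns the assignments, the architecture calls, and a summary dict
    (class counts, implied stagnant cutoff, config echo).
    """
    config = config or DynamicsConfig()
    assignments = classify_trajectories(pairs, config)
    zscore_within_class(assignments)
    arch_calls = call_architectures(assignments, config)
    summary = {
        "n_clones": len(assignments),
        "n_stagnant": sum(a.trajectory == STAGNANT for a in assignments),
        "n_expansion": sum(a.trajectory == EXPANSION for a in assignments),
        "n_reduction": sum(a.trajectory == REDUCTION for a in assignments),
        "stagnant_cutoff_abs_cf": stagnant_cutoff(assignments),
        "n_architecture_calls": len(arch_calls),
        "n_sub_clone": sum(c.architecture == SUB_CLONE for c in arch_calls),
        "n_distinct": sum(c.architecture == DISTINCT for c in arch_calls),
        "config": {
            "stagnant_fraction": config.stagnant_fraction,
            "z_gap_threshold": config.z_gap_threshold,
            "floor_vaf": config.floor_vaf,
        },
    }
    return assignments, arch_calls, summary


def assignments_to_frame(assignments: Sequence[TrajectoryAssignment]):
    """Per-clone table: identity, VAFs, growth rate, class, z-score."""
    import pandas as pd

    rows = []
    for a in assignments:
        p = a.clone
        contig, pos, ref, alt = p.mutation_key
        rows.append({
            "individual_id": p.individual_id, "gene": p.gene,
            "contig": contig, "pos": pos, "ref": ref, "alt": alt,
            "vaf1": p.vaf1, "vaf2": p.vaf2, "dt_years": p.dt_years,
            "cf": a.cf, "trajectory": a.trajectory, "zscore": a.zscore,
        })
    return pd.DataFrame(rows, columns=[
        "individual_id", "gene", "contig", "pos", "ref", "alt",
        "vaf1", "vaf2", "dt_years", "cf", "trajectory", "zscore",
    ])


def architectures_to_frame(calls: Sequence[ArchitectureCall]):
    import pandas as pd

    rows = []
    for c in calls:
        g1, g2 = (a.clone.gene for a in c.clones)
        rows.append({
            "individual_id": c.individual_id,
            "gene1": g1, "gene2": g2,
            "trajectory1": c.clones[0].trajectory,
            "trajectory2": c.clones[1].trajectory,
            "architecture": c.architecture,
            "z_gap": c.z_gap,
        })
    return pd.DataFrame(rows, columns=[
        "individual_id", "gene1", "gene2", "trajectory1", "trajectory2",
        "architecture", "z_gap",
    ])
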