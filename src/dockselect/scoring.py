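"""Gated composite pose scoring.

A docked pose is judged on two axes: geometric accuracy (heavy-atom RMSD to
the crystal reference, in Å) and physicochemical plausibility (a binary
PoseBusters-validity flag covering the 18 standard checks, consumed here as a
precomputed boolean).  The composite score multiplies a smooth sigmoid RMSD
score by the validity gate, so a geometrically perfect but chemically
impossible pose scores exactly zero.

The RMSD score is

    s_RMSD(x; lam) = (1 + exp(-2*lam)) / (1 + exp(lam * (x - 2)))

which equals 1 at x = 0, is strictly decreasing, and has its steepest descent
at the conventional 2 Å success threshold, so borderline improvements are
rewarded most strongly.  Unlike hard-threshold scores it never becomes exactly
zero, preserving information about moderately poor poses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "PostProcess",
    "ScoringConfig",
    "PoseEvaluation",
    "MissingFlagError",
    "rmsd_score",
    "pb_gate",
    "composite_score",
    "success_label",
]


class PostProcess(str, enum.Enum):
    """Post-processing regime applied to a solver's output pose."""

    NONE = "none"
    RELAXATION = "relaxation"
    MM_MIN = "mm_min"


class MissingFlagError(ValueError):
    """A required validity flag was absent (never coerced to pass or fail)."""


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the composite score and the success criteria.

    Parameters
    ----------
    lambda_:
        Steepness of the RMSD sigmoid (unitless, > 0).  Default 3; 1 and 5
        are the standard sensitivity-ablation settings.
    center:
        Å position of the sigmoid inflection; fixed at the 2 Å convention.
    strict_threshold, relaxed_threshold:
        Å thresholds of the strict / relaxed success criteria (1 Å / 2 Å),
        both additionally requiring PB-validity.  Thresholds are inclusive.
    """

    lambda_: float = 3.0
    center: float = 2.0
    strict_threshold: float = 1.0
    relaxed_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not self.lambda_ > 0:
            raise ValueError(f"lambda_ must be > 0, got {self.lambda_}")
        if not self.center > 0:
            raise ValueError(f"center must be > 0, got {self.center}")
        if not self.strict_threshold < self.relaxed_threshold:
            raise ValueError("strict_threshold must be < relaxed_threshold")


@dataclass(frozen=True)
class PoseEvaluation:
    """One (instance, solver) docking outcome."""

    instance_id: str
    solver_id: str
    rmsd: float
    pb_valid: bool | None
    postprocess: PostProcess = PostProcess.NONE

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError(f"rmsd must be >= 0, got {self.rmsd}")


def rmsd_score(rmsd, config: ScoringConfig = ScoringConfig()):
    """Sigmoid RMSD score in (0, 1]; 1 at rmsd = 0, inflection at 2 Å.

    Accepts a scalar or array of non-negative RMSD values (Å).
    """
    lam = config.lambda_
    x = np.asarray(rmsd, dtype=float)
    if np.any(x < 0):
        raise ValueError("rmsd must be non-negative")
    # 1/(1+e^z) = expit(-z) keeps the denominator overflow-free for large rmsd
    num = 1.0 + np.exp(-config.center * lam)
    out = num * expit(-lam * (x - config.center))
    if np.isscalar(rmsd) or np.ndim(rmsd) == 0:
        return float(out)
    return out


def pb_gate(pb_valid) -> int:
    """Binary PoseBusters-validity gate: 1 iff the pose passed all checks.

    A missing flag raises :class:`MissingFlagError`; it is never silently
    treated as a pass (or a fail).
    """
    if pb_valid is None or (isinstance(pb_valid, float) and np.isnan(pb_valid)):
        raise MissingFlagError("PB-validity flag is missing")
    return 1 if bool(pb_valid) else 0


def composite_score(evaluation: PoseEvaluation, config: ScoringConfig = ScoringConfig()) -> float:
    """RMSD score gated by PB-validity: ``s = s_RMSD * s_PB`` in [0, 1]."""
    return rmsd_score(evaluation.rmsd, config) * pb_gate(evaluation.pb_valid)


def success_label(
    evaluation: PoseEvaluation,
    criterion: str,
    config: ScoringConfig = ScoringConfig(),
) -> int:
    """Binary success under the strict (1 Å) or relaxed (2 Å) criterion.

    Success requires RMSD <= threshold (inclusive) AND PB-validity.
    """
    if criterion == "strict":
        threshold = config.strict_threshold
    elif criterion == "relaxed":
        threshold = config.relaxed_threshold
    else:
        raise ValueError(f"unknown criterion {criterion!r}; use 'strict' or 'relaxed'")
    return 1 if (evaluation.rmsd <= threshold and pb_gate(evaluation.pb_valid) == 1) else 0
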