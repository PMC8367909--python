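"""Deterministic seed derivation for grid experiments.

Child seeds are derived from the master seed through
``numpy.random.SeedSequence`` spawn keys rather than sequential draws, so
every (cell, replication, stage) gets its own independent stream and
replications can run in any order — or in parallel — with identical
results.  The derivation rule is part of the package contract: a grid
report is reproducible from its master seed alone.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = ["Stage", "SeedPlan"]


class Stage(IntEnum):
    """What a derived stream is used for."""

    EVALUATION = 0  # replications under the configured new-test distributions
    THRESHOLD = 1  # replications with new-test distributions equal to the base
    RETRY = 2  # one fresh stream for a failed replication


@dataclass(frozen=True)
class SeedPlan:
    """Maps (C_R, C_I, replication, stage) to a child seed stream.

    The mapping is injective because distinct spawn keys yield distinct
    ``SeedSequence`` states, and stable across runs and process
    boundaries.
    """

    master: int

    def sequence(self, C_R: int, C_I: int, rep: int, stage: Stage | int) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.master, spawn_key=(C_R, C_I, rep, int(stage)))

    def integer(self, C_R: int, C_I: int, rep: int, stage: Stage | int) -> int:
        """A plain int seed (< 2**31) for interfaces that want one."""
        return int(self.sequence(C_R, C_I, rep, stage).generate_state(1)[0] % (2**31))
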