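"""Rater-set assignment designs (missing-by-design rating data).

In operational performance tests only a few raters grade each
(examinee, task) evaluation target, so most of the J x I x R rating array
is missing by design.  The generalized rater-set design enumerates all
C(R, N_R) subsets of size N_R and deals them out to evaluation targets in
a fixed cycle, which balances rater load and, as soon as every subset is
used at least once, connects all raters through shared targets — the
condition under which linking/joint calibration is possible at all.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .errors import DesignError

__all__ = [
    "AssignmentDesign",
    "enumerate_rater_sets",
    "build_design",
    "missing_rate",
    "connectivity_check",
    "full_cycle_load",
]


@dataclass(frozen=True)
class AssignmentDesign:
    """Which raters grade which (examinee, task) target.

    ``assignment`` has shape (J, I, N_R) and holds 0-based rater indices,
    each row sorted ascending and free of duplicates.
    """

    J: int
    I: int  # noqa: E741
    R: int
    N_R: int
    assignment: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.assignment, dtype=np.int64)
        if arr.shape != (self.J, self.I, self.N_R):
            raise DesignError(
                f"assignment shape {arr.shape} != {(self.J, self.I, self.N_R)}"
            )
        if not (2 <= self.N_R <= self.R):
            raise DesignError(f"N_R must satisfy 2 <= N_R <= R, got N_R={self.N_R}, R={self.R}")
        if arr.size and (arr.min() < 0 or arr.max() >= self.R):
            raise DesignError("rater index outside [0, R)")
        flat = arr.reshape(-1, self.N_R)
        if np.any(np.diff(np.sort(flat, axis=1), axis=1) == 0):
            raise DesignError("a target has duplicate raters")
        object.__setattr__(self, "assignment", arr)

    @property
    def n_targets(self) -> int:
        return self.J * self.I

    def rater_loads(self) -> np.ndarray:
        """Number of targets assigned to each rater, shape (R,)."""
        return np.bincount(self.assignment.ravel(), minlength=self.R)

    def to_dataframe(self):
        """Assigned (examinee, task, rater) triples, 1-based, long format."""
        import pandas as pd

        jj, ii, _ = np.meshgrid(
            np.arange(self.J), np.arange(self.I), np.arange(self.N_R), indexing="ij"
        )
        return pd.DataFrame(
            {
                "examinee": jj.ravel() + 1,
                "task": ii.ravel() + 1,
                "rater": self.assignment.ravel() + 1,
            }
        )


def enumerate_rater_sets(R: int, N_R: int) -> list[tuple[int, ...]]:
    """All size-N_R rater subsets, lexicographic in sorted member indices."""
    if not (2 <= N_R <= R):
        raise DesignError(f"N_R must satisfy 2 <= N_R <= R, got N_R={N_R}, R={R}")
    return list(combinations(range(R), N_R))


def build_design(J: int, I: int, R: int, N_R: int) -> AssignmentDesign:  # noqa: E741
    """Deal rater subsets to evaluation targets cyclically.

    Targets are enumerated examinee-major (examinee outer, task inner);
    target t receives subset t mod C(R, N_R) of the lexicographic
    enumeration.  Pure function of its arguments.

    When J*I < C(R, N_R) not every subset is used and the design may leave
    raters disconnected; a warning is emitted and callers should consult
    :func:`connectivity_check`.
    """
    subsets = np.array(enumerate_rater_sets(R, N_R), dtype=np.int64)
    n_subsets = len(subsets)
    if J * I < n_subsets:
        warnings.warn(
            f"J*I = {J * I} targets < C({R},{N_R}) = {n_subsets} rater sets: "
            "design may be disconnected; check connectivity_check()",
            stacklevel=2,
        )
    t = np.arange(J * I)
    assignment = subsets[t % n_subsets].reshape(J, I, N_R)
    return AssignmentDesign(J=J, I=I, R=R, N_R=N_R, assignment=assignment)


def missing_rate(R: int, N_R: int) -> float:
    """Percentage of the complete J x I x R array left unobserved: [1 - N_R/R] * 100."""
    if not (2 <= N_R <= R):
        raise DesignError(f"N_R must satisfy 2 <= N_R <= R, got N_R={N_R}, R={R}")
    return (1.0 - N_R / R) * 100.0


def connectivity_check(design: AssignmentDesign) -> tuple[bool, str]:
    """Whether all R raters form one component through shared targets.

    Raters are linked when they co-grade a target; linking (and joint
    estimation generally) requires a single component covering every
    rater.  Returns (connected, diagnostic message).
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(design.R))
    for row in design.assignment.reshape(-1, design.N_R):
        for a, b in zip(row[:-1], row[1:]):
            g.add_edge(int(a), int(b))
    unused = [r for r in range(design.R) if design.rater_loads()[r] == 0]
    components = list(nx.connected_components(g))
    if unused:
        return False, f"raters with no assigned targets: {sorted(unused)}"
    if len(components) > 1:
        return False, f"{len(components)} disconnected rater groups: {sorted(map(sorted, components))}"
    return True, f"all {design.R} raters connected through shared targets"


def full_cycle_load(R: int, N_R: int) -> int:
    """Targets per rater in one full cycle through all subsets: C(R-1, N_R-1).

    Per-rater loads of :func:`build_design` differ by at most this amount
    (the imbalance of one partial cycle).
    """
    return comb(R - 1, N_R - 1)
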