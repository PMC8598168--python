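"""Combinatorial stimulus space: conditions, canonical ordering, design matrix.

A *condition* is a subset of the stimulus elements presented simultaneously
(for the five-whisker experiment: pistons targeting C2, C1, B1, D1 and the
gamma whisker).  With ``n`` elements there are ``2**n - 1`` non-empty subsets;
an optional *catch* condition (empty subset, no stimulus) is appended last and
serves as the null distribution for baselines and significance tests.

The canonical ordering — subset size ascending, then lexicographic on sorted
element indices — is fixed so that design matrices, tuning vectors and
population matrices are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

DEFAULT_ELEMENT_LABELS = ("C2", "C1", "B1", "D1", "gamma")


@dataclass(frozen=True)
class Condition:
    """One stimulus: a frozenset of 0-based element indices, or catch if empty."""

    mask: frozenset
    is_catch: bool = False

    def __post_init__(self):
        object.__setattr__(self, "mask", frozenset(self.mask))
        if self.is_catch != (len(self.mask) == 0):
            raise ValueError("catch flag must be set exactly when the mask is empty")

    @property
    def size(self) -> int:
        return len(self.mask)

    @property
    def is_singleton(self) -> bool:
        return len(self.mask) == 1

    @property
    def is_multi(self) -> bool:
        return len(self.mask) >= 2

    def bitstring(self, n_elements: int) -> str:
        """Serialize as e.g. ``"01011"``; character j is 1 iff element j present."""
        return "".join("1" if j in self.mask else "0" for j in range(n_elements))

    @classmethod
    def from_bitstring(cls, bits: str) -> "Condition":
        mask = frozenset(j for j, b in enumerate(bits) if b == "1")
        return cls(mask=mask, is_catch=len(mask) == 0)

    def __repr__(self):
        if self.is_catch:
            return "Condition(catch)"
        return f"Condition({{{','.join(map(str, sorted(self.mask)))}}})"


def _canonical_key(c: Condition):
    return (len(c.mask), tuple(sorted(c.mask)))


@dataclass(frozen=True)
class StimulusSpace:
    """All conditions of an n-element combinatorial experiment, canonically ordered."""

    n_elements: int
    conditions: tuple
    element_labels: tuple = ()

    def __post_init__(self):
        if not self.element_labels:
            if self.n_elements == 5:
                labels = DEFAULT_ELEMENT_LABELS
            else:
                labels = tuple(f"e{j}" for j in range(self.n_elements))
            object.__setattr__(self, "element_labels", labels)

    @property
    def has_catch(self) -> bool:
        return any(c.is_catch for c in self.conditions)

    @property
    def non_catch(self) -> tuple:
        return tuple(c for c in self.conditions if not c.is_catch)

    @property
    def singletons(self) -> tuple:
        return tuple(c for c in self.conditions if c.is_singleton)

    @property
    def multis(self) -> tuple:
        return tuple(c for c in self.conditions if c.is_multi)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def index(self, c: Condition) -> int:
        return self.conditions.index(c)

    @property
    def multi_indices(self) -> np.ndarray:
        """Indices (into the non-catch ordering) of multi-element conditions."""
        return np.array([i for i, c in enumerate(self.non_catch) if c.is_multi])

    @property
    def singleton_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.non_catch) if c.is_singleton])

    def labels(self) -> list:
        """Human-readable condition labels, e.g. ``C2+B1``."""
        out = []
        for c in self.conditions:
            if c.is_catch:
                out.append("catch")
            else:
                out.append("+".join(self.element_labels[j] for j in sorted(c.mask)))
        return out


def enumerate_conditions(n_elements: int = 5, include_catch: bool = True) -> StimulusSpace:
    """Enumerate all non-empty element subsets in canonical order.

    Parameters
    ----------
    n_elements:
        Number of stimulus elements (1..16); the five-whisker experiment uses 5,
        giving 31 combinations.
    include_catch:
        Append the empty (no-stimulus) catch condition at the end.
    """
    if not (1 <= int(n_elements) <= 16):
        raise ValueError(f"n_elements must be in [1, 16], got {n_elements}")
    n_elements = int(n_elements)
    conds = []
    for k in range(1, n_elements + 1):
        for combo in combinations(range(n_elements), k):
            conds.append(Condition(mask=frozenset(combo)))
    conds.sort(key=_canonical_key)
    if include_catch:
        conds.append(Condition(mask=frozenset(), is_catch=True))
    return StimulusSpace(n_elements=n_elements, conditions=tuple(conds))


def design_matrix(space: StimulusSpace) -> np.ndarray:
    """Binary design matrix: one row per non-catch condition, one column per element.

    Entry (i, j) is 1 iff element j is presented in condition i; this is the
    x_ij regressor matrix of the linear-nonlinear model.
    """
    non_catch = space.non_catch
    if len(non_catch) == 0:
        raise ValueError("stimulus space has no non-catch conditions")
    x = np.zeros((len(non_catch), space.n_elements), dtype=int)
    for i, c in enumerate(non_catch):
        for j in c.mask:
            x[i, j] = 1
    return x


def singleton_components(c: Condition) -> list:
    """The single-element conditions composing ``c``, in canonical order."""
    if c.is_catch:
        raise ValueError("catch condition has no singleton components")
    return [Condition(mask=frozenset({j})) for j in sorted(c.mask)]
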