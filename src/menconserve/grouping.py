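"""Assigning samples to gradient groups, or to random control groups."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._seeds import rng_for
from .synth import SampleMetadata

__all__ = ["Grouping", "assign_ph_groups", "random_grouping"]


@dataclasses.dataclass(frozen=True)
class Grouping:
    """Ordered assignment of samples to groups G1..Gk."""

    group_labels: tuple[str, ...]
    assignment: dict[str, str]  # sample id -> group label

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    @property
    def sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in self.group_labels}

    def group_index(self, group: str) -> int:
        return self.group_labels.index(group)


def _cut_sizes(n_samples: int, n_groups: int, target_sizes: Sequence[int] | None) -> list[int]:
    if target_sizes is not None:
        sizes = list(target_sizes)
        if sum(sizes) != n_samples:
            raise ValueError("target_sizes must sum to the number of samples")
        if len(sizes) != n_groups:
            raise ValueError("target_sizes length must equal n_groups")
        return sizes
    base, extra = divmod(n_samples, n_groups)
    # distribute the remainder over the first `extra` groups
    return [base + (1 if i < extra else 0) for i in range(n_groups)]


def assign_ph_groups(
    metadata: SampleMetadata,
    n_groups: int = 6,
    target_sizes: Sequence[int] | None = None,
) -> Grouping:
    """Cut the pH-sorted samples into contiguous, near-equal groups.

    Groups are ordered by increasing pH: every sample in G(i) has pH less
    than or equal to every sample in G(i+1).
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if metadata.n_samples < n_groups:
        raise ValueError("need at least one sample per group")
    sizes = _cut_sizes(metadata.n_samples, n_groups, target_sizes)
    order = metadata.ph.sort_values(kind="stable").index.tolist()
    labels = tuple(f"G{i + 1}" for i in range(n_groups))
    assignment: dict[str, str] = {}
    pos = 0
    for label, size in zip(labels, sizes):
        for s in order[pos : pos + size]:
            assignment[s] = label
        pos += size
    return Grouping(group_labels=labels, assignment=assignment)


def random_grouping(
    metadata: SampleMetadata, group_sizes: Sequence[int], seed: int = 0
) -> Grouping:
    """Randomly permute samples and cut into the given group sizes."""
    sizes = list(group_sizes)
    if sum(sizes) != metadata.n_samples:
        raise ValueError("group_sizes must sum to the number of samples")
    rng = rng_for(seed, "random-grouping")
    order = list(metadata.sample_ids)
    rng.shuffle(order)
    labels = tuple(f"G{i + 1}" for i in range(len(sizes)))
    assignment: dict[str, str] = {}
    pos = 0
    for label, size in zip(labels, sizes):
        for s in order[pos : pos + size]:
            assignment[s] = label
        pos += size
    return Grouping(group_labels=labels, assignment=assignment)
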