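"""Active/silent phenotype classification from duplicate cytokine measurements.

Each strain is assayed for induced cytokine production (pg/mL, measured in
duplicate); the per-strain level is the mean of the two replicates. Within a
(species, cytokine) comparison, strains at or above the median level are
"active" and the rest are "silent". Two cytokines (IL-10, IL-12) over one
species therefore yield two independent bipartitions of the same strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np

CYTOKINES = ("IL10", "IL12")


class CytokineReading(NamedTuple):
    """One strain's duplicate measurements for one cytokine (pg/mL)."""

    rep1: float
    rep2: float
    mean: float


@dataclass(frozen=True)
class StrainPhenotype:
    """A strain's species label and per-cytokine duplicate measurements."""

    strain_id: str
    species: str
    values: Mapping[str, CytokineReading]

    def mean(self, cytokine: str) -> float:
        return self.values[cytokine].mean


@dataclass(frozen=True)
class PhenotypeGroups:
    """The active/silent bipartition for one (species, cytokine) comparison.

    ``degenerate`` is set when one side is empty (all strains tied at the
    median); downstream screening refuses degenerate groups.
    """

    species: str
    cytokine: str
    median: float
    active: frozenset[str]
    silent: frozenset[str]
    degenerate: bool = False

    @property
    def strains(self) -> frozenset[str]:
        return self.active | self.silent

    def label_of(self, strain_id: str) -> str:
        if strain_id in self.active:
            return "active"
        if strain_id in self.silent:
            return "silent"
        raise KeyError(strain_id)


def summarize_duplicates(rep1: float, rep2: float) -> float:
    """Mean of duplicate ELISA readings; both must be non-negative pg/mL."""
    if rep1 < 0 or rep2 < 0:
        raise ValueError(
            f"cytokine measurements must be non-negative, got ({rep1}, {rep2})"
        )
    return (rep1 + rep2) / 2.0


def classify_active_silent(
    strains: Iterable[StrainPhenotype],
    species: str,
    cytokine: str,
    *,
    strict_gt: bool = False,
    pooled_median: bool = False,
) -> PhenotypeGroups:
    """Split one species' strains into active/silent at the median level.

    Parameters
    ----------
    strains
        Phenotype records; only those matching ``species`` are used.
    cytokine
        Which cytokine's means define the split.
    strict_gt
        If True, "active" requires strictly exceeding the median instead of
        the default at-or-above rule.
    pooled_median
        If True, the threshold is the median of the pooled per-strain means
        over *all* cytokines of the species (a single per-species median)
        rather than the per-cytokine median.
    """
    pool = sorted(
        (s for s in strains if s.species == species), key=lambda s: s.strain_id
    )
    if len(pool) < 2:
        raise ValueError(
            f"need at least 2 strains of species {species!r}, got {len(pool)}"
        )
    if pooled_median:
        threshold = float(
            np.median([s.mean(c) for s in pool for c in s.values])
        )
    else:
        threshold = float(np.median([s.mean(cytokine) for s in pool]))

    if strict_gt:
        active = frozenset(s.strain_id for s in pool if s.mean(cytokine) > threshold)
    else:
        active = frozenset(s.strain_id for s in pool if s.mean(cytokine) >= threshold)
    silent = frozenset(s.strain_id for s in pool) - active
    return PhenotypeGroups(
        species=species,
        cytokine=cytokine,
        median=threshold,
        active=active,
        silent=silent,
        degenerate=not active or not silent,
    )


def classify_all(
    strains: Iterable[StrainPhenotype],
    *,
    strict_gt: bool = False,
    pooled_median: bool = False,
) -> list[PhenotypeGroups]:
    """One PhenotypeGroups per (species, cytokine) present in the input."""
    strains = list(strains)
    species_seen = sorted({s.species for s in strains})
    cytokines = sorted({c for s in strains for c in s.values})
    return [
        classify_active_silent(
            strains, sp, cy, strict_gt=strict_gt, pooled_median=pooled_median
        )
        for sp in species_seen
        for cy in cytokines
    ]
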