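"""Grouping structures for the hierarchical model and thermal allocation.

Five alternative ways of pooling strains are supported:

* ``I``   — all strains in a single group;
* ``II``  — by taxonomic domain (Bacteria / Archaea / Eukarya);
* ``III`` — as II, with Eukarya split into unicellular and multicellular;
* ``IV``  — by thermal group (psychrophile / mesophile / thermophile /
  hyperthermophile), allocated from each strain's stability temperature;
* ``V``   — as IV, except Ascomycota strains form their own group.

Thermal allocation uses thresholds on ``T_star`` (the temperature of
minimal denaturation, obtained from an initial model fit); a strain whose
``T_star`` falls exactly on a boundary goes to the colder group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .constants import THERMAL_THRESHOLDS

__all__ = ["ThermalThresholds", "ModelStructure", "allocate_thermal_groups"]

STRUCTURE_NAMES = ("I", "II", "III", "IV", "V")
THERMAL_GROUPS = ("psychrophile", "mesophile", "thermophile", "hyperthermophile")


@dataclass(frozen=True)
class ThermalThresholds:
    """Boundaries on T_star (K) separating the four thermal groups."""

    psychro_meso: float = THERMAL_THRESHOLDS[0]
    meso_thermo: float = THERMAL_THRESHOLDS[1]
    thermo_hyper: float = THERMAL_THRESHOLDS[2]

    def __post_init__(self) -> None:
        if not self.psychro_meso < self.meso_thermo < self.thermo_hyper:
            raise ValueError("thermal thresholds must be strictly increasing")

    def classify(self, t_star: float) -> str:
        # ties go to the colder group
        if t_star <= self.psychro_meso:
            return "psychrophile"
        if t_star <= self.meso_thermo:
            return "mesophile"
        if t_star <= self.thermo_hyper:
            return "thermophile"
        return "hyperthermophile"


def allocate_thermal_groups(t_star: Mapping[str, float],
                            thresholds: ThermalThresholds | None = None,
                            taxonomy: pd.DataFrame | None = None,
                            separate_ascomycota: bool = False) -> dict[str, str]:
    """Allocate strains to thermal groups from their stability temperatures.

    ``taxonomy`` (columns ``strain_id`` and ``ascomycota``) is only needed
    when ``separate_ascomycota`` is set, in which case flagged strains are
    routed to an ``"ascomycota"`` group regardless of ``T_star``.
    """
    thresholds = thresholds or ThermalThresholds()
    asco: set = set()
    if separate_ascomycota:
        if taxonomy is None or "ascomycota" not in taxonomy.columns:
            raise ValueError("separate_ascomycota requires taxonomy with an "
                             "'ascomycota' column")
        asco = set(taxonomy.loc[taxonomy["ascomycota"].astype(bool), "strain_id"])
    return {sid: ("ascomycota" if sid in asco else thresholds.classify(ts))
            for sid, ts in t_star.items()}


@dataclass(frozen=True)
class ModelStructure:
    """A named partition of strains into parameter-sharing groups."""

    name: str
    groups: tuple[str, ...]
    assignment: dict = field(default_factory=dict)  # strain_id -> group name

    def __post_init__(self) -> None:
        missing = {g for g in self.assignment.values()} - set(self.groups)
        if missing:
            raise ValueError(f"assignment refers to unknown groups: {missing}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_index(self, strain_id: str) -> int:
        return self.groups.index(self.assignment[strain_id])

    # -- constructors -------------------------------------------------------

    @classmethod
    def single_group(cls, strain_ids: Sequence[str]) -> "ModelStructure":
        """Structure I: one group for all strains."""
        return cls("I", ("all",), {s: "all" for s in strain_ids})

    @classmethod
    def from_labels(cls, labels: Mapping[str, str], name: str = "labels"
                    ) -> "ModelStructure":
        """Structure from an explicit strain -> group-label mapping."""
        groups = tuple(sorted(set(labels.values())))
        return cls(name, groups, dict(labels))

    @classmethod
    def from_taxonomy(cls, taxonomy: pd.DataFrame, split_cellularity: bool = False
                      ) -> "ModelStructure":
        """Structures II/III from a taxonomy table.

        ``taxonomy`` needs columns ``strain_id`` and ``domain`` (Bacteria /
        Archaea / Eukarya); structure III additionally needs
        ``cellularity`` (unicellular / multicellular) to split Eukarya.
        """
        labels = {}
        for _, row in taxonomy.iterrows():
            dom = str(row["domain"])
            if split_cellularity and dom == "Eukarya":
                dom = f"Eukarya_{row['cellularity']}"
            labels[row["strain_id"]] = dom
        return cls("III" if split_cellularity else "II",
                   tuple(sorted(set(labels.values()))), labels)

    @classmethod
    def from_thermal(cls, t_star: Mapping[str, float],
                     thresholds: ThermalThresholds | None = None,
                     taxonomy: pd.DataFrame | None = None,
                     separate_ascomycota: bool = False) -> "ModelStructure":
        """Structures IV/V by thermal allocation on T_star."""
        labels = allocate_thermal_groups(t_star, thresholds, taxonomy,
                                         separate_ascomycota)
        return cls("V" if separate_ascomycota else "IV",
                   tuple(sorted(set(labels.values()))), labels)
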