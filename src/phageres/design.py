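"""Experimental design: phages, selection regimes, lineage enumeration.

The study design this package emulates selects spontaneous phage-resistant
mutants of *Pseudomonas aeruginosa* PAO1 from three independent ancestral
clones (fluctuation-test replicates), against four phages that adsorb to one
of two cell-surface receptors (LPS or the type IV pilus).  Resistance is
selected in three regimes: against a single phage (the first step of
sequential selection), against a second phage applied to a first-step mutant
(second step; order matters), or against a pair of phages applied together
(simultaneous; order does not matter).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field


class Receptor(str, enum.Enum):
    """Cell-surface adsorption target of a phage."""

    LPS = "LPS"
    TYPE_IV_PILUS = "TYPE_IV_PILUS"


class RegimeKind(str, enum.Enum):
    FIRST_STEP = "first_step"
    SECOND_STEP = "second_step"
    SIMULTANEOUS = "simultaneous"


@dataclass(frozen=True)
class Phage:
    name: str
    receptor: Receptor

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("phage name must be non-empty")
        object.__setattr__(self, "receptor", Receptor(self.receptor))


@dataclass(frozen=True)
class SelectionRegime:
    """A selection treatment: which phage(s), applied in which pattern.

    ``phages`` holds phage *names*.  For SECOND_STEP the order is
    (first-step phage, second-step phage) and is meaningful; SIMULTANEOUS
    pairs are stored sorted by name so (A, B) and (B, A) compare equal.
    """

    kind: RegimeKind
    phages: tuple[str, ...]

    def __post_init__(self) -> None:
        kind = RegimeKind(self.kind)
        object.__setattr__(self, "kind", kind)
        phages = tuple(self.phages)
        if kind is RegimeKind.FIRST_STEP:
            if len(phages) != 1:
                raise ValueError("FIRST_STEP regime takes exactly one phage")
        else:
            if len(phages) != 2:
                raise ValueError(f"{kind.value} regime takes exactly two phages")
            if phages[0] == phages[1]:
                raise ValueError("the two phages of a pair must be distinct")
            if kind is RegimeKind.SIMULTANEOUS:
                phages = tuple(sorted(phages))
        object.__setattr__(self, "phages", phages)

    @property
    def label(self) -> str:
        joiner = "+" if self.kind is RegimeKind.SIMULTANEOUS else ">"
        return f"{self.kind.value}:{joiner.join(self.phages)}"


@dataclass(frozen=True)
class Lineage:
    """One independently selected resistant mutant.

    ``regime`` may be None for an unselected ancestral control clone.
    """

    ancestor_id: str
    regime: SelectionRegime | None
    replicate_label: str = "r1"

    @property
    def label(self) -> str:
        if self.regime is None:
            return f"{self.ancestor_id}|ancestor|{self.replicate_label}"
        return f"{self.ancestor_id}|{self.regime.label}|{self.replicate_label}"


@dataclass
class ExperimentDesign:
    """Ancestors × phages and which phage treatments were discarded."""

    ancestors: list[str]
    phages: list[Phage]
    excluded_phages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.phages]
        if len(set(names)) != len(names):
            raise ValueError("phage names must be unique within a design")
        unknown = set(self.excluded_phages) - set(names)
        if unknown:
            raise ValueError(f"excluded phages not in design: {sorted(unknown)}")

    @property
    def phage_names(self) -> list[str]:
        return [p.name for p in self.phages]

    def receptor_of(self, phage_name: str) -> Receptor:
        for p in self.phages:
            if p.name == phage_name:
                return p.receptor
        raise KeyError(f"unknown phage: {phage_name}")

    def included_phages(self, exclude: bool = True) -> list[str]:
        if not exclude:
            return self.phage_names
        return [n for n in self.phage_names if n not in self.excluded_phages]


def default_design() -> ExperimentDesign:
    """The 3-ancestor × 4-phage PAO1 design (PT7 treatments discarded)."""
    return ExperimentDesign(
        ancestors=["PAO1_FT1", "PAO1_FT2", "PAO1_FT3"],
        phages=[
            Phage("PA5P2", Receptor.TYPE_IV_PILUS),
            Phage("PT7", Receptor.TYPE_IV_PILUS),
            Phage("PA10P2", Receptor.LPS),
            Phage("14/1", Receptor.LPS),
        ],
        excluded_phages=["PT7"],
    )


def enumerate_lineages(
    design: ExperimentDesign,
    kind: RegimeKind | str,
    exclude: bool = False,
    replicate_label: str = "r1",
) -> list[Lineage]:
    """Enumerate every lineage of one selection regime in the design.

    FIRST_STEP yields ancestors × phages; SIMULTANEOUS yields ancestors ×
    unordered pairs; SECOND_STEP yields ancestors × ordered pairs of
    distinct phages.  With ``exclude=True``, treatments containing an
    excluded phage are dropped.
    """
    try:
        kind = RegimeKind(kind)
    except ValueError as exc:
        raise ValueError(f"unknown regime kind: {kind!r}") from exc
    if len(design.ancestors) < 1 or len(design.phages) < 2:
        raise ValueError("design needs at least 1 ancestor and 2 phages")
    phages = design.included_phages(exclude=exclude)
    if kind is RegimeKind.FIRST_STEP:
        combos: list[tuple[str, ...]] = [(p,) for p in phages]
    elif kind is RegimeKind.SIMULTANEOUS:
        combos = list(itertools.combinations(sorted(phages), 2))
    elif kind is RegimeKind.SECOND_STEP:
        combos = list(itertools.permutations(phages, 2))
    else:  # pragma: no cover - RegimeKind is exhaustive
        raise ValueError(f"unknown regime kind: {kind!r}")
    return [
        Lineage(anc, SelectionRegime(kind, combo), replicate_label)
        for anc in design.ancestors
        for combo in combos
    ]


def multiplicity_of_infection(phage_density: float, cell_density: float) -> float:
    """MOI = phage particles per bacterial cell at inoculation.

    Both densities are per-ml counts and must be positive.
    """
    if phage_density <= 0 or cell_density <= 0:
        raise ValueError("densities must be positive")
    return phage_density / cell_density
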