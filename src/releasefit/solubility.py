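"""Hoftyzer–Van Krevelen group-contribution solubility parameters.

A molecule is described as a multiset of group fragments; each fragment
contributes a dispersion molar attraction Fd, a polar molar attraction Fp, a
hydrogen-bond cohesion energy Eh, and a Fedors molar-volume increment Vg.
With V = Σ count·Vg the three components are

    δd = Σ Fd / V
    δp = √(Σ Fp²) / V
    δh = √(Σ Eh / V)

and the total parameter is the Euclidean norm δt = √(δd² + δp² + δh²), all
in (MJ/m³)^½ (numerically equal to MPa^½).  Similar δt between a drug and a
polymer implies a favourable interaction — here, swelling of the cellulose
matrix and slower release.

The shipped group table and drug multisets are human-editable YAML data
(``releasefit/data``); both can be overridden per call.  Note that different
editions of the reference tables differ at the few-percent level, so computed
δt values carry that uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import DomainError, UnknownGroupError, ValidationError

__all__ = [
    "GroupContributionEntry",
    "MoleculeGroups",
    "SolubilityParameters",
    "load_group_table",
    "load_molecules",
    "molecule_groups",
    "molar_volume",
    "delta_components",
    "total_delta",
    "solubility_parameters",
    "DRUG_IDS",
]


@dataclass(frozen=True)
class GroupContributionEntry:
    """One fragment's contributions: Fd, Fp ((MJ/m³)^½·cm³·mol⁻¹), Eh (J·mol⁻¹), Vg (cm³·mol⁻¹)."""

    group_label: str
    fd: float
    fp: float
    eh: float
    vg: float


@dataclass(frozen=True)
class MoleculeGroups:
    """A drug as a multiset of (group label, count) with positive counts."""

    drug_id: str
    group_counts: Mapping[str, int]

    def __post_init__(self):
        for label, count in self.group_counts.items():
            if not (isinstance(count, int) and count > 0):
                raise ValidationError(
                    f"{self.drug_id}: count for {label!r} must be a positive "
                    f"integer, got {count!r}"
                )


@dataclass(frozen=True)
class SolubilityParameters:
    """Dispersion, polar, hydrogen-bond and total parameters, (MJ/m³)^½."""

    delta_d: float
    delta_p: float
    delta_h: float
    delta_t: float
    molar_volume: float


def _data_path(name: str) -> Path:
    return Path(str(resources.files("releasefit") / "data" / name))


def load_group_table(path=None) -> dict[str, GroupContributionEntry]:
    """Load a group table (the embedded one by default)."""
    raw = yaml.safe_load(Path(path or _data_path("hvk_groups.yaml")).read_text())
    table = {}
    for label, row in raw["groups"].items():
        table[label] = GroupContributionEntry(
            label, float(row["fd"]), float(row["fp"]), float(row["eh"]), float(row["vg"])
        )
    return table


def load_molecules(path=None) -> dict[str, MoleculeGroups]:
    """Load molecule multisets (the embedded nine drugs by default)."""
    raw = yaml.safe_load(Path(path or _data_path("drug_fragments.yaml")).read_text())
    return {
        drug: MoleculeGroups(drug, {g: int(c) for g, c in counts.items()})
        for drug, counts in raw["molecules"].items()
    }


_DEFAULT_TABLE: dict[str, GroupContributionEntry] | None = None
_DEFAULT_MOLECULES: dict[str, MoleculeGroups] | None = None


def _default_table() -> dict[str, GroupContributionEntry]:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_group_table()
    return _DEFAULT_TABLE


def _default_molecules() -> dict[str, MoleculeGroups]:
    global _DEFAULT_MOLECULES
    if _DEFAULT_MOLECULES is None:
        _DEFAULT_MOLECULES = load_molecules()
    return _DEFAULT_MOLECULES


DRUG_IDS = (
    "PHBA", "MPDB", "PABA", "MPAB", "EPAB", "BPAB", "2-MBA", "3-MBA", "4-MBA",
)


def molecule_groups(drug_id: str) -> MoleculeGroups:
    """Registry lookup for one of the nine shipped drugs."""
    mols = _default_molecules()
    if drug_id not in mols:
        raise UnknownGroupError(
            f"no multiset for {drug_id!r}; known drugs: {', '.join(mols)}"
        )
    return mols[drug_id]


def _resolve(groups, table):
    if isinstance(groups, str):
        groups = molecule_groups(groups)
    table = table or _default_table()
    for label in groups.group_counts:
        if label not in table:
            raise UnknownGroupError(
                f"group {label!r} is not in the active contribution table"
            )
    return groups, table


def molar_volume(groups, table=None) -> float:
    """Σ count·Vg over the multiset (cm³·mol⁻¹)."""
    groups, table = _resolve(groups, table)
    total = 0.0
    for label, count in groups.group_counts.items():
        entry = table[label]
        if entry.vg <= 0:
            raise ValidationError(
                f"group {label!r} has non-positive volume increment"
            )
        total += count * entry.vg
    return total


def delta_components(groups, table=None, correction=(0.0, 0.0, 0.0)) -> tuple[float, float, float]:
    """(δd, δp, δh) from the three Hoftyzer–Van Krevelen formulas.

    ``correction`` is an optional per-molecule additive adjustment
    (ΔΣFd, ΔΣFp², ΔΣEh) applied before division by the molar volume, e.g. for
    ring-conjugation corrections present in some table editions (default: none).
    """
    groups, table = _resolve(groups, table)
    v = molar_volume(groups, table)
    if v <= 0:
        raise DomainError("molar volume must be positive")
    sum_fd, sum_fp2, sum_eh = correction
    for label, count in groups.group_counts.items():
        entry = table[label]
        sum_fd += count * entry.fd
        sum_fp2 += count * entry.fp**2
        sum_eh += count * entry.eh
    if sum_eh < 0 or sum_fp2 < 0:
        raise DomainError("corrected sums must remain non-negative")
    return (sum_fd / v, math.sqrt(sum_fp2) / v, math.sqrt(sum_eh / v))


def total_delta(components) -> float:
    """δt = √(δd² + δp² + δh²)."""
    dd, dp, dh = components
    if dd < 0 or dp < 0 or dh < 0:
        raise DomainError("solubility-parameter components must be non-negative")
    return math.sqrt(dd * dd + dp * dp + dh * dh)


def solubility_parameters(groups, table=None, correction=(0.0, 0.0, 0.0)) -> SolubilityParameters:
    """Full (δd, δp, δh, δt, V) for a drug label or an explicit multiset."""
    groups, table = _resolve(groups, table)
    comps = delta_components(groups, table, correction)
    return SolubilityParameters(
        delta_d=comps[0],
        delta_p=comps[1],
        delta_h=comps[2],
        delta_t=total_delta(comps),
        molar_volume=molar_volume(groups, table),
    )
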