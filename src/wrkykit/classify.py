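"""Group assignment for WRKY proteins: structural rules plus nearest-reference.

Rules: two assembled domains mean group I; a single domain whose finger is
CCHC means group III.  A single CCHH/CCHY domain cannot be placed among the
group II subgroups (or the non-group) on structure alone, so its domain
region is aligned against a subgroup-labelled reference panel and the best
identity at or above the floor decides; below the floor the protein falls
into the non-group (NG).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from . import align
from .domains import ProteinRecord

VALID_PANEL_LABELS = frozenset({"I", "IIa", "IIb", "IIc", "IId", "IIe", "III"})
GROUPS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III", "NG", "unclassified")

DEFAULT_IDENTITY_FLOOR = 0.35


class PanelError(ValueError):
    """Raised for an invalid or missing reference panel."""


@dataclass(frozen=True)
class PanelEntry:
    reference_id: str
    subgroup: str
    sequence: str


@dataclass
class ReferencePanel:
    """Subgroup-labelled WRKY domain sequences used for nearest-reference calls."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.subgroup not in VALID_PANEL_LABELS:
                raise PanelError(f"invalid panel label {e.subgroup!r} for {e.reference_id}")
            if not e.sequence:
                raise PanelError(f"empty panel sequence for {e.reference_id}")

    def sorted_entries(self) -> list[PanelEntry]:
        return sorted(self.entries, key=lambda e: e.reference_id)


@dataclass(frozen=True)
class GroupAssignment:
    protein_id: str
    group: str
    basis: str  # rule | reference | rule+reference
    best_reference: Optional[str] = None
    reference_identity: Optional[float] = None


def domain_region(protein: ProteinRecord, index: int = 0) -> str:
    """Sequence from the heptapeptide start through the finger end."""
    d = protein.domains[index]
    return protein.sequence[d.heptapeptide.start : d.finger.end]


def _best_panel_match(
    region: str, panel: ReferencePanel, matrix=None
) -> tuple[PanelEntry, float]:
    best: Optional[tuple[PanelEntry, float]] = None
    for entry in panel.sorted_entries():
        ident = align.align_pair(region, entry.sequence, matrix).identity
        if best is None or ident > best[1]:
            best = (entry, ident)
    assert best is not None
    return best


def classify(
    protein: ProteinRecord,
    panel: Optional[ReferencePanel] = None,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    matrix=None,
) -> GroupAssignment:
    """Assign a protein to I / IIa–e / III / NG / unclassified.

    Invariant to panel entry order (ties broken by reference id).
    """
    pid = protein.protein_id
    if protein.n_domains == 0:
        return GroupAssignment(pid, "unclassified", "rule")
    if protein.n_domains >= 2:
        return GroupAssignment(pid, "I", "rule")
    finger_type = protein.domains[0].finger.finger_type
    if finger_type == "CCHC":
        return GroupAssignment(pid, "III", "rule")
    # single CCHH/CCHY domain: delegate to the reference panel
    if panel is None or not panel.entries:
        raise PanelError(
            f"protein {pid} needs a reference panel for subgroup assignment"
        )
    entry, ident = _best_panel_match(domain_region(protein), panel, matrix)
    if ident >= identity_floor:
        return GroupAssignment(pid, entry.subgroup, "rule+reference", entry.reference_id, ident)
    return GroupAssignment(pid, "NG", "rule+reference", entry.reference_id, ident)


def classify_all(
    proteins: Sequence[ProteinRecord],
    panel: Optional[ReferencePanel] = None,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    matrix=None,
) -> list[GroupAssignment]:
    return [classify(p, panel, identity_floor, matrix) for p in proteins]
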