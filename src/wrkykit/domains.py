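"""Detection of WRKY heptapeptide motifs and zinc-finger spacing signatures.

A WRKY domain is modelled as a heptapeptide anchor (canonical ``WRKYGQK`` or
a variant with mismatches at non-anchor positions) followed, within a bounded
linker, by a zinc-finger block ``C-X{a}-C-X{b}-HX{T}`` where the terminal
coordinating residue ``T`` is one of H, C or Y.  The finger type (CCHH, CCHC,
CCHY) is determined by that terminal residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

CANONICAL_HEPTAPEPTIDE = "WRKYGQK"
#: 0-based anchor positions within the heptapeptide that must match exactly.
ANCHOR_POSITIONS = (0, 2, 3)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET_X = AA_ALPHABET | {"X"}

DEFAULT_SPACER1_RANGE = (3, 7)
DEFAULT_SPACER2_RANGE = (5, 27)
DEFAULT_LINKER_MAX = 120
DEFAULT_MAX_MISMATCHES = 3

_SIGNATURE_RE = re.compile(r"^C-X(\d+)-C-X(\d+)-HX([HCY])$")


class SequenceAlphabetError(ValueError):
    """Raised when a protein sequence contains a non-amino-acid character."""


@dataclass(frozen=True)
class HeptapeptideHit:
    """One heptapeptide window matching the WRKY anchor pattern."""

    protein_id: str
    start: int
    motif: str
    mismatches: int

    @property
    def canonical(self) -> bool:
        return self.mismatches == 0

    @property
    def end(self) -> int:
        """Index one past the last residue of the motif."""
        return self.start + 7


@dataclass(frozen=True)
class ZincFingerSignature:
    """Spacing signature of a zinc finger: C-X{a}-C-X{b}-HX{T}."""

    protein_id: str
    start: int
    spacer1: int
    spacer2: int
    terminal: str

    @property
    def signature(self) -> str:
        return render_signature(self.spacer1, self.spacer2, self.terminal)

    @property
    def finger_type(self) -> str:
        return {"H": "CCHH", "C": "CCHC", "Y": "CCHY"}[self.terminal]

    @property
    def end(self) -> int:
        """Index one past the terminal coordinating residue."""
        return self.start + self.spacer1 + self.spacer2 + 5


@dataclass(frozen=True)
class WRKYDomain:
    """A validated WRKY domain: heptapeptide plus downstream zinc finger."""

    heptapeptide: HeptapeptideHit
    finger: ZincFingerSignature
    terminal_position: str = "only"  # one of N, C, only


@dataclass
class ProteinRecord:
    """A protein with its assembled WRKY domains (one row of the survey report)."""

    protein_id: str
    sequence: str
    domains: list[WRKYDomain]

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def motifs(self) -> list[str]:
        return [d.heptapeptide.motif for d in self.domains]

    @property
    def signatures(self) -> list[str]:
        return [d.finger.signature for d in self.domains]


def render_signature(spacer1: int, spacer2: int, terminal: str) -> str:
    """Render a (spacer1, spacer2, terminal) triple as ``C-X{a}-C-X{b}-HX{T}``."""
    if terminal not in "HCY":
        raise ValueError(f"terminal residue must be H, C or Y, got {terminal!r}")
    return f"C-X{spacer1}-C-X{spacer2}-HX{terminal}"


def parse_signature(text: str) -> tuple[int, int, str]:
    """Parse a rendered signature string back into (spacer1, spacer2, terminal)."""
    m = _SIGNATURE_RE.match(text.strip())
    if m is None:
        raise ValueError(f"not a zinc-finger signature: {text!r}")
    return int(m.group(1)), int(m.group(2)), m.group(3)


def validate_protein(sequence: str) -> None:
    """Check the 20-letter alphabet (X tolerated); report the first bad position."""
    for i, ch in enumerate(sequence):
        if ch not in AA_ALPHABET_X:
            raise SequenceAlphabetError(
                f"invalid amino-acid character {ch!r} at position {i}"
            )


def find_heptapeptides(
    sequence: str,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    protein_id: str = "",
) -> list[HeptapeptideHit]:
    """Find every 7-residue window with W/K/Y anchors within the mismatch budget.

    Anchors (W at position 1, K at 3, Y at 4, 1-based) must match exactly;
    the remaining four positions may diverge from ``WRKYGQK`` up to
    ``max_mismatches`` Hamming mismatches.  ``X`` never matches any literal.
    Overlapping windows are all reported, ordered by start.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    validate_protein(sequence)
    hits: list[HeptapeptideHit] = []
    for start in range(len(sequence) - 6):
        window = sequence[start : start + 7]
        if any(window[p] != CANONICAL_HEPTAPEPTIDE[p] for p in ANCHOR_POSITIONS):
            continue
        mism = sum(
            1
            for a, b in zip(window, CANONICAL_HEPTAPEPTIDE)
            if a != b or a == "X"
        )
        if mism <= max_mismatches:
            hits.append(HeptapeptideHit(protein_id, start, window, mism))
    return hits


def _finger_candidates(
    sequence: str,
    from_index: int,
    spacer1_range: tuple[int, int],
    spacer2_range: tuple[int, int],
) -> Iterator[tuple[int, int, int, str]]:
    n = len(sequence)
    lo1, hi1 = spacer1_range
    lo2, hi2 = spacer2_range
    for s in range(from_index, n):
        if sequence[s] != "C":
            continue
        for a in range(lo1, hi1 + 1):
            c2 = s + 1 + a
            if c2 >= n or sequence[c2] != "C":
                continue
            for b in range(lo2, hi2 + 1):
                h = c2 + 1 + b
                t = h + 2
                if t >= n:
                    break
                if sequence[h] == "H" and sequence[t] in "HCY":
                    yield s, a, b, sequence[t]


def find_zinc_finger(
    sequence: str,
    from_index: int = 0,
    spacer1_range: tuple[int, int] = DEFAULT_SPACER1_RANGE,
    spacer2_range: tuple[int, int] = DEFAULT_SPACER2_RANGE,
    protein_id: str = "",
) -> Optional[ZincFingerSignature]:
    """First zinc-finger match at or after ``from_index``, or None.

    Matches ``C X{a} C X{b} H X [HCY]`` with a, b inside the configured
    ranges.  Ties are broken by smallest start, then smallest spacer1, then
    smallest spacer2.
    """
    if from_index < 0 or from_index > len(sequence):
        raise ValueError(f"from_index {from_index} outside sequence")
    validate_protein(sequence)
    for s, a, b, terminal in _finger_candidates(
        sequence, from_index, spacer1_range, spacer2_range
    ):
        return ZincFingerSignature(protein_id, s, a, b, terminal)
    return None


def assemble_domains(
    sequence: str,
    protein_id: str = "",
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    spacer1_range: tuple[int, int] = DEFAULT_SPACER1_RANGE,
    spacer2_range: tuple[int, int] = DEFAULT_SPACER2_RANGE,
    linker_max: int = DEFAULT_LINKER_MAX,
) -> list[WRKYDomain]:
    """Pair heptapeptide hits with validating zinc fingers.

    Each heptapeptide hit is paired with the first finger starting within
    ``linker_max`` residues after its end; hits without such a finger are
    dropped (this is also the filter that validates variant heptapeptides).
    When exactly two domains assemble, they are labelled N and C by order;
    otherwise every domain is labelled "only".
    """
    hits = find_heptapeptides(sequence, max_mismatches, protein_id)
    domains: list[WRKYDomain] = []
    for hit in hits:
        finger = find_zinc_finger(
            sequence, hit.end, spacer1_range, spacer2_range, protein_id
        )
        if finger is None or finger.start - hit.end > linker_max:
            continue
        domains.append(WRKYDomain(hit, finger))
    if len(domains) == 2:
        domains = [
            WRKYDomain(domains[0].heptapeptide, domains[0].finger, "N"),
            WRKYDomain(domains[1].heptapeptide, domains[1].finger, "C"),
        ]
    return domains


def survey_proteins(
    records: Sequence[tuple[str, str]],
    **kwargs,
) -> list[ProteinRecord]:
    """Assemble domains for (id, sequence) pairs into ProteinRecords."""
    return [
        ProteinRecord(pid, seq, assemble_domains(seq, protein_id=pid, **kwargs))
        for pid, seq in records
    ]
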