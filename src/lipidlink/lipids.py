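"""Lipid species nomenclature.

Shotgun-lipidomics identifiers follow a ``CLASS(c1:d1/c2:d2[/c3:d3])`` grammar:
a class abbreviation (TG, PC, SM, ...) followed by one or more acyl chains given
as ``carbons:double_bonds``.  A species may instead carry only a *total*
composition (e.g. ``TG(52:2)``) when the individual chains were not resolved.
An optional trailing ``[+]`` / ``[-]`` marks the ion mode the species was
measured in; species seen in both modes appear twice before merging.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: Lipid class abbreviations recognised by the parser.
LIPID_CLASSES = (
    "CE", "CL", "DG", "FFA", "ME", "PA", "PC", "PE", "PG", "PI", "PS",
    "SM", "TG", "LPC", "LPE", "pPC", "pPE",
)

_ID_RE = re.compile(
    r"^(?P<cls>[A-Za-z]+)\((?P<chains>[0-9]+:[0-9]+(?:/[0-9]+:[0-9]+)*)\)"
    r"(?P<mode>\[[+-]\])?$"
)

#: Number of acyl chains carried by each class when fully resolved.
CHAINS_PER_CLASS = {
    "TG": 3, "DG": 2, "CE": 1, "FFA": 1, "ME": 1, "LPC": 1, "LPE": 1,
    "PA": 2, "PC": 2, "PE": 2, "PG": 2, "PI": 2, "PS": 2, "SM": 2,
    "pPC": 2, "pPE": 2, "CL": 4,
}


class LipidParseError(ValueError):
    """Raised for identifiers that do not follow the class(chains) grammar."""


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid identifier.

    ``acyl_chains`` is empty when the identifier carries only a total
    composition for a multi-chain class (e.g. ``TG(52:2)``).
    """

    raw_id: str
    lipid_class: str
    acyl_chains: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    ion_mode: str = "merged"  # {"positive", "negative", "merged"}

    @property
    def species_key(self) -> str:
        """Identifier with the ion-mode suffix stripped; equal across modes."""
        return self.raw_id.removesuffix("[+]").removesuffix("[-]")

    @property
    def total_composition(self) -> tuple[int, int]:
        """(total carbons, total double bonds) summed over chains."""
        return (
            sum(c for c, _ in self.acyl_chains),
            sum(d for _, d in self.acyl_chains),
        )

    @property
    def has_resolved_chains(self) -> bool:
        return len(self.acyl_chains) > 0


def parse_lipid_id(raw_id: str) -> LipidSpecies:
    """Parse ``CLASS(c1:d1/c2:d2[/...])[ion mode]`` into a :class:`LipidSpecies`.

    A single ``c:d`` token inside the parentheses of a multi-chain class is
    read as a total composition (unresolved chains), mirroring identifiers
    like ``TG(52:2)``.

    Raises
    ------
    LipidParseError
        For malformed identifiers or unknown class abbreviations.
    """
    m = _ID_RE.match(raw_id.strip())
    if m is None:
        raise LipidParseError(f"malformed lipid identifier: {raw_id!r}")
    cls = m.group("cls")
    if cls not in LIPID_CLASSES:
        raise LipidParseError(f"unknown lipid class {cls!r} in {raw_id!r}")
    chains = tuple(
        (int(c), int(d))
        for c, d in (tok.split(":") for tok in m.group("chains").split("/"))
    )
    expected = CHAINS_PER_CLASS[cls]
    if len(chains) == 1 and expected > 1:
        chains = ()  # total composition only, chains unresolved
    elif len(chains) != expected:
        raise LipidParseError(
            f"{raw_id!r}: {cls} species carry {expected} chains, got {len(chains)}"
        )
    mode = {"[+]": "positive", "[-]": "negative", None: "merged"}[m.group("mode")]
    return LipidSpecies(
        raw_id=raw_id.strip(), lipid_class=cls, acyl_chains=chains, ion_mode=mode
    )


def format_chain(chain: tuple[int, int]) -> str:
    """``(16, 0) -> 'C16:0'`` — the fatty-acid naming used in composition sums."""
    return f"C{chain[0]}:{chain[1]}"
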