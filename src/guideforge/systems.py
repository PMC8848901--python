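"""Registry of CRISPR nuclease systems and IUPAC PAM pattern compilation.

A system is pure data: PAM motif, which side of the protospacer the PAM
sits on, guide length, scoring-context flank, and the signed cut offset
from the PAM-proximal end of the protospacer.  New Cas systems are added
as entries (or via a key=value config file), not as code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SystemConfigError(ValueError):
    pass


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CrisprSystem:
    """Geometry of one Cas nuclease.

    cut_offset is the signed distance (in bases) from the PAM-proximal end
    of the protospacer to the blunt cut; SpCas9 cuts 3 bp inside the
    protospacer from the PAM, hence -3.
    """

    name: str = "cas9"
    pam_pattern: str = "NGG"
    pam_side: str = "3prime"
    guide_length: int = 20
    context_flank: int = 5
    cut_offset: int = -3

    def __post_init__(self):
        if self.guide_length <= 0:
            raise SystemConfigError("guide_length must be positive")
        if self.context_flank < 0:
            raise SystemConfigError("context_flank must be non-negative")
        if self.pam_side not in ("3prime", "5prime"):
            raise SystemConfigError(f"pam_side must be 3prime or 5prime, got {self.pam_side!r}")
        bad = set(self.pam_pattern.upper()) - set(IUPAC)
        if bad:
            raise SystemConfigError(f"illegal IUPAC code(s) in PAM pattern: {sorted(bad)}")

    @property
    def pam_length(self) -> int:
        return len(self.pam_pattern)

    @property
    def context_length(self) -> int:
        return self.guide_length + 2 * self.context_flank


REGISTRY: dict[str, CrisprSystem] = {"cas9": CrisprSystem()}


def get_system(name: str) -> CrisprSystem:
    try:
        return REGISTRY[name.lower()]
    except KeyError:
        raise SystemConfigError(f"unknown CRISPR system {name!r}; known: {sorted(REGISTRY)}") from None


def register_system(system: CrisprSystem) -> None:
    REGISTRY[system.name.lower()] = system


def load_system_config(path: str) -> CrisprSystem:
    """Read a key=value config file defining a CRISPR system and register it.

    Recognized keys: name, pam, side, guide_length, flank, cut_offset.
    """
    values: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            values[key.strip().lower()] = val.strip()
    try:
        system = CrisprSystem(
            name=values.get("name", "custom"),
            pam_pattern=values.get("pam", "NGG").upper(),
            pam_side=values.get("side", "3prime"),
            guide_length=int(values.get("guide_length", 20)),
            context_flank=int(values.get("flank", 5)),
            cut_offset=int(values.get("cut_offset", -3)),
        )
    except ValueError as exc:
        raise SystemConfigError(f"{path}: {exc}") from exc
    register_system(system)
    return system


def iupac_regex(motif: str) -> str:
    """Expand an IUPAC motif into a concrete regex over {A,C,G,T}."""
    parts = []
    for code in motif.upper():
        if code not in IUPAC:
            raise SystemConfigError(f"illegal IUPAC code {code!r} in motif {motif!r}")
        bases = IUPAC[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def compile_pam(system: CrisprSystem) -> re.Pattern:
    """Compile the system's PAM motif into a regex that finds *overlapping*
    occurrences (zero-width lookahead wrapping the concrete pattern)."""
    return re.compile(f"(?=({iupac_regex(system.pam_pattern)}))")


def iupac_matches(motif: str, word: str) -> bool:
    """Membership test: does `word` belong to the set the motif denotes?"""
    if len(word) != len(motif):
        return False
    return all(b in IUPAC[c] for c, b in zip(motif.upper(), word))
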