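"""Peptide chemistry for LC-MS quality-control panels.

Monoisotopic masses and m/z for the monitored QC peptides, tryptic
missed-cleavage counting, and the two bundled panels: QC1 (tryptic BSA,
low complexity, run several times a day) and QC2 (tryptic HeLa digest,
high complexity, run weekly as a system-suitability sample).

Sequences use the 20 canonical residues; cysteines carrying a fixed
carbamidomethyl group are written with an inline ``(CAM)`` tag, e.g.
``EAC(CAM)FAVEGPK``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Optional

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "CAM_DELTA",
    "Modification",
    "PeptideTarget",
    "parse_peptide",
    "monoisotopic_mass",
    "mz",
    "count_missed_cleavages",
    "qc_panel",
    "load_panel_table",
    "PANELS",
]

# Community constants (monoisotopic, Da).
PROTON_MASS = 1.007276466
WATER_MASS = 18.0105646863
CAM_DELTA = 57.02146  # carbamidomethyl on Cys
CAM_NAME = "CAM"

#: IUPAC monoisotopic residue masses (Da), internal residues (no termini).
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711379,
    "S": 87.03202840,
    "P": 97.05276385,
    "V": 99.06841391,
    "T": 101.04767847,
    "C": 103.00918496,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857751,
    "K": 128.09496301,
    "E": 129.04259309,
    "M": 131.04048491,
    "H": 137.05891186,
    "F": 147.06841391,
    "R": 156.10111102,
    "Y": 163.06332853,
    "W": 186.07931295,
}

PANELS = ("QC1", "QC2")


class PeptideParseError(ValueError):
    """Raised for malformed peptide strings (bad residue or tag)."""


@dataclass(frozen=True)
class Modification:
    """A fixed modification at a 1-based residue position."""

    position: int
    name: str
    mass_delta: float


@dataclass(frozen=True)
class PeptideTarget:
    """A monitored QC peptide.

    ``charge`` and ``theoretical_mz`` may be unset on a freshly parsed
    peptide; :func:`qc_panel` returns fully populated targets.
    ``expected_rt`` (seconds) is chromatographic-method dependent and is
    configuration, not a constant of the peptide.
    """

    sequence: str
    modifications: tuple[Modification, ...] = ()
    charge: Optional[int] = None
    theoretical_mz: Optional[float] = None
    expected_rt: Optional[float] = None
    panel: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in RESIDUE_MASS:
                raise PeptideParseError(
                    f"non-canonical residue {aa!r} at position {i}"
                )
        n = len(self.sequence)
        for m in self.modifications:
            if not 1 <= m.position <= n:
                raise ValueError(
                    f"modification position {m.position} outside sequence of length {n}"
                )
            if m.name == CAM_NAME and self.sequence[m.position - 1] != "C":
                raise ValueError(
                    f"CAM modification at position {m.position} is not on a Cys"
                )
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be a positive integer")
        if self.theoretical_mz is not None:
            if self.charge is None:
                raise ValueError("theoretical_mz set without a charge")
            expect = mz(self, self.charge)
            if abs(self.theoretical_mz - expect) > 1e-6:
                raise ValueError(
                    f"theoretical_mz {self.theoretical_mz} inconsistent with "
                    f"recomputed {expect}"
                )
        if self.panel is not None and self.panel not in PANELS:
            raise ValueError(f"unknown panel {self.panel!r}")

    def with_charge(self, charge: int) -> "PeptideTarget":
        """Return a copy with ``charge`` set and ``theoretical_mz`` computed."""
        if charge < 1:
            raise ValueError("charge must be a positive integer")
        target = replace(self, charge=charge, theoretical_mz=None)
        return replace(target, theoretical_mz=mz(target, charge))

    def display(self) -> str:
        """Sequence with inline ``(CAM)`` tags restored."""
        tagged = {m.position for m in self.modifications}
        return "".join(
            aa + "(CAM)" if i in tagged else aa
            for i, aa in enumerate(self.sequence, start=1)
        )


_TOKEN = re.compile(r"([A-Z])(\((\w+)\))?")


def parse_peptide(text: str) -> PeptideTarget:
    """Parse a peptide string with inline ``(CAM)`` tags.

    Returns an uncharged :class:`PeptideTarget` (no m/z yet) whose sequence
    has the tags stripped and one carbamidomethyl modification recorded at
    each tagged position.
    """
    sequence: list[str] = []
    mods: list[Modification] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise PeptideParseError(
                f"malformed peptide {text!r} at character {pos + 1}"
            )
        aa, tag = m.group(1), m.group(3)
        if aa not in RESIDUE_MASS:
            raise PeptideParseError(
                f"non-canonical residue {aa!r} at position {len(sequence) + 1}"
            )
        sequence.append(aa)
        if tag is not None:
            if tag != CAM_NAME:
                raise PeptideParseError(
                    f"unsupported modification tag {tag!r} at position {len(sequence)}"
                )
            mods.append(Modification(len(sequence), CAM_NAME, CAM_DELTA))
        pos = m.end()
    return PeptideTarget(sequence="".join(sequence), modifications=tuple(mods))


def monoisotopic_mass(p: PeptideTarget | str) -> float:
    """Monoisotopic neutral mass (Da): residues + water + modification deltas."""
    if isinstance(p, str):
        p = parse_peptide(p)
    return (
        sum(RESIDUE_MASS[aa] for aa in p.sequence)
        + WATER_MASS
        + sum(m.mass_delta for m in p.modifications)
    )


def mz(p: PeptideTarget | str, charge: int) -> float:
    """Theoretical m/z (Th) at ``charge``: (M + z·m_proton) / z."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (monoisotopic_mass(p) + charge * PROTON_MASS) / charge


def count_missed_cleavages(p: PeptideTarget | str) -> int:
    """Number of uncut internal tryptic sites.

    Counts K/R at internal positions (all but the last residue) that are
    not immediately followed by P.
    """
    seq = p if isinstance(p, str) else p.sequence
    return sum(
        1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    )


def load_panel_table(lines: Iterable[str]) -> list[PeptideTarget]:
    """Load peptide targets from a tab-separated panel table.

    Columns: ``peptide`` (with inline CAM tags), ``panel``, ``charge``,
    optional ``expected_rt`` (seconds; blank for method-dependent).
    """
    targets: list[PeptideTarget] = []
    reader = csv.DictReader(lines, delimiter="\t")
    for row in reader:
        t = parse_peptide(row["peptide"].strip())
        panel = row["panel"].strip().upper()
        if panel not in PANELS:
            raise ValueError(f"unknown panel {row['panel']!r}")
        t = replace(t, panel=panel)
        t = t.with_charge(int(row.get("charge") or 2))
        rt = (row.get("expected_rt") or "").strip()
        if rt:
            t = replace(t, expected_rt=float(rt))
        targets.append(t)
    return targets


def _bundled_targets() -> list[PeptideTarget]:
    text = (
        resources.files("lcmsqc.data").joinpath("panels.tsv").read_text()
    )
    return load_panel_table(text.splitlines())


def qc_panel(panel: str) -> list[PeptideTarget]:
    """Return the bundled peptide panel, in table order.

    QC1 is the 10-peptide tryptic-BSA panel; QC2 the 15-peptide HeLa panel.
    """
    panel = panel.upper()
    if panel not in PANELS:
        raise ValueError(f"unknown panel {panel!r}; expected one of {PANELS}")
    return [t for t in _bundled_targets() if t.panel == panel]
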