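"""Elemental-formula arithmetic, monoisotopic masses and the neutral-loss catalog.

Everything downstream of this module reasons about positive-mode (``[M+H]+``)
electrospray spectra of flavonoid glycosides, where structure assignment rests
on mass differences: whole glycosyl residues detach from O-glycosides
(hexose 162 Da, pentose 132 Da, deoxyhexose 146 Da), C-glycosides shed only
cross-ring fragments of the sugar (90/96/120/150 Da for hexoses, 60/90/120 Da
for pentoses), and acyl decorations contribute either a neutral loss
(malonyl 86 Da) or a diagnostic marker ion (feruloyl m/z 177, coumaroyl m/z 147).
This module provides the arithmetic; :mod:`glycoflav.annotate` provides the rules.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Formula",
    "LossCatalogEntry",
    "MassMatch",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "match_mz",
    "default_loss_catalog",
    "load_loss_catalog",
    "write_loss_catalog",
    "PROTON_MASS",
    "MONOISOTOPIC",
]

#: Monoisotopic atomic masses (Da) of the elements that occur in flavonoid
#: glycosides and proteinogenic amino acids.
MONOISOTOPIC: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Proton mass used for [M+H]+ adduct arithmetic; the electron mass is
#: neglected (three orders of magnitude below the fragment tolerance).
PROTON_MASS = 1.00728

_HILL_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or illegal formula arithmetic."""


@dataclass(frozen=True)
class Formula:
    """An elemental composition, e.g. ``Formula({"C": 6, "H": 10, "O": 5})``.

    Counts are non-negative integers; the empty formula has mass zero.
    Addition and subtraction are element-wise; subtraction that would drive
    a count negative raises :class:`FormulaError`.
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.element_counts.items():
            if el not in MONOISOTOPIC:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n:
                clean[el] = n
        object.__setattr__(self, "element_counts", dict(clean))

    def __hash__(self) -> int:  # dict field defeats the generated hash
        return hash(tuple(sorted(self.element_counts.items())))

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            remaining = counts.get(el, 0) - n
            if remaining < 0:
                raise FormulaError(
                    f"subtraction yields negative count for {el}: {counts.get(el, 0)} - {n}"
                )
            counts[el] = remaining
        return Formula(counts)

    def __bool__(self) -> bool:
        return bool(self.element_counts)

    def hill(self) -> str:
        """Canonical Hill-order string: C first, then H, then other elements
        alphabetically (plain alphabetical when no carbon is present)."""
        counts = self.element_counts
        if not counts:
            return ""

        def fmt(el: str) -> str:
            n = counts[el]
            return el if n == 1 else f"{el}{n}"

        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else [])
            order += sorted(el for el in counts if el not in ("C", "H"))
        else:
            order = sorted(counts)
        return "".join(fmt(el) for el in order)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string such as ``"C15H10O6"``."""
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _HILL_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Formula(counts)


def monoisotopic_mass(f: Formula) -> float:
    """Monoisotopic mass in Da (sum of count x lightest-isotope mass)."""
    return sum(n * MONOISOTOPIC[el] for el, n in f.element_counts.items())


def protonated_mz(f: Formula) -> float:
    """m/z of the [M+H]+ ion of a neutral molecule with composition *f*."""
    if not f:
        raise FormulaError("cannot protonate the empty formula")
    return monoisotopic_mass(f) + PROTON_MASS


@dataclass(frozen=True)
class MassMatch:
    """Outcome of comparing an observed against a theoretical m/z."""

    observed: float
    theoretical: float
    delta_da: float
    delta_ppm: float
    within: bool


def match_mz(observed: float, theoretical: float, tol_mode: str = "da", tol: float = 0.5) -> MassMatch:
    """Compare two m/z values under a Da or ppm tolerance.

    ``within`` is true iff ``|observed - theoretical|`` <= *tol* (Da mode) or
    ``|delta| / theoretical * 1e6`` <= *tol* (ppm mode).
    """
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    if tol_mode not in ("da", "ppm"):
        raise ValueError(f"tol_mode must be 'da' or 'ppm', got {tol_mode!r}")
    delta = observed - theoretical
    ppm = delta / theoretical * 1e6 if theoretical else math.inf
    within = abs(delta) <= tol if tol_mode == "da" else abs(ppm) <= tol
    return MassMatch(observed, theoretical, delta, ppm, within)


# -- neutral-loss catalog ----------------------------------------------------

CATEGORIES = (
    "O-glycosyl-whole",
    "C-glycosyl-partial-hexose",
    "C-glycosyl-partial-pentose",
    "acyl",
    "small-neutral",
)


@dataclass(frozen=True)
class LossCatalogEntry:
    """A named neutral loss.

    Cross-ring (partial) sugar losses at 96 and 150 Da are carried as
    nominal-only entries without a committed elemental composition, because
    the literature is inconsistent about it; they must always be matched with
    a Da tolerance.
    """

    name: str
    formula: Formula | None
    nominal_da: int
    exact_da: float | None
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown loss category {self.category!r}")
        if self.formula is not None:
            mono = monoisotopic_mass(self.formula)
            if self.exact_da is None or abs(self.exact_da - mono) > 1e-6:
                raise ValueError(
                    f"{self.name}: exact_da {self.exact_da} inconsistent with formula mass {mono:.6f}"
                )
            if self.nominal_da != round(self.exact_da):
                raise ValueError(
                    f"{self.name}: nominal_da {self.nominal_da} != round(exact) {round(self.exact_da)}"
                )

    @property
    def best_da(self) -> float:
        """Exact mass when a composition is committed, else the nominal mass."""
        return self.exact_da if self.exact_da is not None else float(self.nominal_da)


def _entry(name: str, formula_text: str | None, nominal: int, category: str) -> LossCatalogEntry:
    if formula_text is None:
        return LossCatalogEntry(name, None, nominal, None, category)
    f = parse_formula(formula_text)
    return LossCatalogEntry(name, f, nominal, monoisotopic_mass(f), category)


def default_loss_catalog() -> list[LossCatalogEntry]:
    """The neutral losses diagnostic for glycosylated/acylated flavonoids.

    Whole-residue losses mark O-glycosides; cross-ring partial losses mark
    C-glycosides (the 90 and 120 Da entries are shared between the hexose and
    pentose series and are therefore ambiguous on their own); acyl losses and
    water complete the set.
    """
    return [
        _entry("hexose-residue", "C6H10O5", 162, "O-glycosyl-whole"),
        _entry("pentose-residue", "C5H8O4", 132, "O-glycosyl-whole"),
        _entry("deoxyhexose-residue", "C6H10O4", 146, "O-glycosyl-whole"),
        _entry("malonyl", "C3H2O3", 86, "acyl"),
        _entry("feruloyl", "C10H8O3", 176, "acyl"),
        _entry("coumaroyl", "C9H6O2", 146, "acyl"),
        _entry("water", "H2O", 18, "small-neutral"),
        _entry("hexose-cross-ring-90", "C3H6O3", 90, "C-glycosyl-partial-hexose"),
        _entry("hexose-cross-ring-96", None, 96, "C-glycosyl-partial-hexose"),
        _entry("hexose-cross-ring-120", "C4H8O4", 120, "C-glycosyl-partial-hexose"),
        _entry("hexose-cross-ring-150", None, 150, "C-glycosyl-partial-hexose"),
        _entry("pentose-cross-ring-60", "C2H4O2", 60, "C-glycosyl-partial-pentose"),
        _entry("pentose-cross-ring-90", "C3H6O3", 90, "C-glycosyl-partial-pentose"),
        _entry("pentose-cross-ring-120", "C4H8O4", 120, "C-glycosyl-partial-pentose"),
    ]


def write_loss_catalog(entries: Iterable[LossCatalogEntry], path: str | Path) -> None:
    """Serialize a catalog to TSV (name, formula, nominal_da, exact_da, category)."""
    lines = ["name\tformula\tnominal_da\texact_da\tcategory"]
    for e in entries:
        formula = e.formula.hill() if e.formula is not None else ""
        exact = f"{e.exact_da:.6f}" if e.exact_da is not None else ""
        lines.append(f"{e.name}\t{formula}\t{e.nominal_da}\t{exact}\t{e.category}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_loss_catalog(path: str | Path) -> list[LossCatalogEntry]:
    """Read a catalog TSV written by :func:`write_loss_catalog`."""
    entries = []
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[0] != "name":
        raise ValueError(f"{path}: not a loss-catalog TSV")
    for ln in lines[1:]:
        if not ln.strip():
            continue
        name, formula, nominal, exact, category = ln.split("\t")
        entries.append(
            LossCatalogEntry(
                name=name,
                formula=parse_formula(formula) if formula else None,
                nominal_da=int(nominal),
                exact_da=float(exact) if exact else None,
                category=category,
            )
        )
    return entries
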