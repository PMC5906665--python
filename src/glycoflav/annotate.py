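"""Rule-based structure annotation of glycosylated flavonoids from MS/MS.

The annotator turns the field's manual elucidation logic into an algorithm.
For a positive-mode [M+H]+ precursor it asks, for every aglycone in the
dictionary: can the mass budget ``precursor - aglycone`` be explained by at
most two glycosyl residues and one acyl group?  Each arithmetically valid
candidate structure (a C/O linkage template drawn from the observed chemical
classes: bare aglycone, O-mono, C-mono, di-C,C, C,O-di, and their acylated
variants) predicts a fragment pattern:

* O-linked units detach whole (hexose 162, pentose 132, deoxyhexose 146 Da),
  exposing the protonated aglycone ion;
* C-linked units shed only cross-ring fragments (hexose 90/96/120/150 Da,
  pentose 60/90/120 Da) from the precursor or from the C-core ion that
  remains after the O-side is lost, plus a water loss;
* acyl groups leave with their sugar (malonyl 86 Da) or additionally give a
  marker ion (feruloyl m/z 177, coumaroyl m/z 147).

Observed fragments are scored against each prediction; unexplained losses
are penalized; the best-scoring structure wins with deterministic
tie-breaking.  Aglycones of identical elemental composition (isobars) cannot
be told apart by mass alone and are kept together as a ranked candidate set.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .masscalc import (
    Formula,
    LossCatalogEntry,
    MassMatch,
    default_loss_catalog,
    match_mz,
    parse_formula,
    protonated_mz,
)
from .spectra import Spectrum

__all__ = [
    "Aglycone",
    "ModificationEvent",
    "Evidence",
    "Annotation",
    "AnnotatorConfig",
    "default_aglycone_dict",
    "default_aglycone_names",
    "load_aglycones",
    "find_aglycone_ions",
    "enumerate_losses",
    "decompose_loss",
    "detect_c_signature",
    "detect_acyl_markers",
    "score_candidates",
    "annotate",
    "canonical_name",
    "names_equivalent",
    "parse_printed_name",
    "printed_structure_mz",
    "fixture_mass_screen",
    "is_mass_consistent",
]

# Residue masses of the glycosyl units (loss of the unit == loss of the
# residue, i.e. sugar minus water).
SUGAR_MASS = {
    "hexose": 162.052823,
    "pentose": 132.042259,
    "deoxyhexose": 146.057909,
}
ACYL_MASS = {
    "malonyl": 86.000394,
    "feruloyl": 176.047344,
    "coumaroyl": 146.036779,
}
#: Diagnostic acylium/acyl marker ions in positive mode.
ACYL_MARKER_MZ = {"feruloyl": 177.0546, "coumaroyl": 147.0441}
WATER = 18.010565

#: Cross-ring (partial) losses of C-linked sugars.  96 and 150 Da are
#: nominal-only (no committed composition) and matched in Da mode.
C_PARTIAL = {
    "hexose": {90: 90.031694, 96: 96.0, 120: 120.042259, 150: 150.0},
    "pentose": {60: 60.021129, 90: 90.031694, 120: 120.042259},
}
#: Nominal partial losses shared by the hexose and pentose series.
AMBIGUOUS_PARTIALS = frozenset({90, 120})

DEFAULT_WEIGHTS = {
    "aglycone-ion": 3.0,
    "whole-sugar-loss": 2.0,
    "acyl-marker-ion": 2.0,
    "partial-sugar-loss": 1.0,
    "water-loss": 0.5,
}
UNEXPLAINED_PENALTY = 1.0
#: Losses smaller than this (Da) are common small neutrals / in-ring
#: fragmentation and are never penalized when unexplained.
PENALTY_FLOOR_DA = 40.0


@dataclass(frozen=True)
class Aglycone:
    """A flavonoid core with its composition and [M+H]+ m/z."""

    name: str
    formula: Formula
    protonated_mz: float
    synonyms: tuple[str, ...] = ()

    @classmethod
    def from_formula(cls, name: str, formula_text: str, synonyms: Sequence[str] = ()) -> "Aglycone":
        f = parse_formula(formula_text)
        return cls(name=name, formula=f, protonated_mz=protonated_mz(f), synonyms=tuple(synonyms))


@dataclass(frozen=True)
class ModificationEvent:
    """One glycosylation event: linkage (O or C), sugar unit, optional acyl
    decoration of that sugar."""

    linkage: str  # "O" | "C"
    unit: str  # "hexose" | "pentose" | "deoxyhexose"
    acyl: str = "none"  # "none" | "malonyl" | "feruloyl" | "coumaroyl"

    def __post_init__(self) -> None:
        if self.linkage not in ("O", "C"):
            raise ValueError(f"linkage must be O or C, got {self.linkage!r}")
        if self.unit not in SUGAR_MASS:
            raise ValueError(f"unknown sugar unit {self.unit!r}")
        if self.acyl != "none" and self.acyl not in ACYL_MASS:
            raise ValueError(f"unknown acyl group {self.acyl!r}")

    @property
    def exact_mass(self) -> float:
        m = SUGAR_MASS[self.unit]
        if self.acyl != "none":
            m += ACYL_MASS[self.acyl]
        return m


@dataclass(frozen=True)
class Evidence:
    """A single matched diagnostic observation supporting an annotation."""

    kind: str
    observed_mz: float
    expected: float
    delta: float
    ambiguous_sugar: bool = False

    @property
    def weight(self) -> float:
        w = DEFAULT_WEIGHTS[self.kind]
        if self.ambiguous_sugar and self.kind == "partial-sugar-loss":
            return w / 2.0
        return w


@dataclass(frozen=True)
class Annotation:
    """A ranked structure hypothesis for one spectrum."""

    aglycone_candidates: tuple[Aglycone, ...]
    events: tuple[ModificationEvent, ...]
    glyco_class: str
    score: float
    evidence: tuple[Evidence, ...]
    spectrum_id: str = ""
    precursor_mz: float = 0.0
    mass_inconsistent: bool = False

    @property
    def aglycone(self) -> Aglycone | None:
        return self.aglycone_candidates[0] if self.aglycone_candidates else None


GLYCO_CLASSES = (
    "aglycone-only",
    "O-mono",
    "C-mono",
    "di-C-C",
    "C-O-di",
    "acylated-O",
    "acylated-C-O",
    "unknown",
)


def _classify_events(events: Sequence[ModificationEvent]) -> str:
    """Map an event multiset onto the glycosylation-class vocabulary."""
    n_c = sum(1 for e in events if e.linkage == "C")
    n_o = sum(1 for e in events if e.linkage == "O")
    acylated = any(e.acyl != "none" for e in events)
    key = (n_c, n_o, acylated)
    table = {
        (0, 0, False): "aglycone-only",
        (0, 1, False): "O-mono",
        (1, 0, False): "C-mono",
        (2, 0, False): "di-C-C",
        (1, 1, False): "C-O-di",
        (0, 1, True): "acylated-O",
        (1, 1, True): "acylated-C-O",
    }
    return table.get(key, "unknown")


# -- dictionary --------------------------------------------------------------


def load_aglycones(path: str | Path) -> list[Aglycone]:
    """Read an aglycone dictionary TSV (name, Hill formula, synonyms)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("name\t"):
        raise ValueError(f"{path}: not an aglycone TSV")
    out = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        name, formula = parts[0], parts[1]
        synonyms = tuple(s for s in parts[2].split(",") if s) if len(parts) > 2 and parts[2] else ()
        out.append(Aglycone.from_formula(name, formula, synonyms))
    if not out:
        raise ValueError(f"{path}: empty aglycone dictionary")
    return out


def default_aglycone_dict() -> list[Aglycone]:
    """The packaged dictionary of flavonoid cores observed in liquorice leaves."""
    p = resources.files("glycoflav").joinpath("data/aglycones.tsv")
    return load_aglycones(str(p))


def default_aglycone_names() -> set[str]:
    return {a.name for a in default_aglycone_dict()}


def isobar_group(aglycone: Aglycone, dictionary: Sequence[Aglycone], tol_da: float = 0.01) -> frozenset[str]:
    """Names of dictionary aglycones indistinguishable from *aglycone* by mass."""
    return frozenset(
        a.name for a in dictionary if abs(a.protonated_mz - aglycone.protonated_mz) <= tol_da
    )


# -- evidence primitives -----------------------------------------------------


def find_aglycone_ions(
    s: Spectrum, dictionary: Sequence[Aglycone], tol_da: float = 0.5
) -> list[tuple[Aglycone, MassMatch]]:
    """All (aglycone, match) pairs among the fragments, plus the precursor
    itself (bare-aglycone case).  Isobaric aglycones are all returned."""
    hits = []
    candidates = list(s.fragment_mzs) + [s.precursor_mz]
    for agl in dictionary:
        for mz in candidates:
            m = match_mz(mz, agl.protonated_mz, "da", tol_da)
            if m.within:
                hits.append((agl, m))
                break
    return hits


def enumerate_losses(s: Spectrum) -> list[tuple[float, float, float]]:
    """(from_mz, to_mz, loss) for precursor-to-fragment and
    fragment-to-fragment pairs, at full precision."""
    out = []
    for f in s.fragment_mzs:
        if f < s.precursor_mz:
            out.append((s.precursor_mz, f, s.precursor_mz - f))
    frags = s.fragment_mzs
    for hi, lo in itertools.combinations(sorted(frags, reverse=True), 2):
        if hi > lo:
            out.append((hi, lo, hi - lo))
    return out


def decompose_loss(
    delta: float,
    catalog: Sequence[LossCatalogEntry] | None = None,
    max_units: int = 3,
    tol_da: float = 0.5,
) -> list[tuple[tuple[str, ...], float]]:
    """All multisets of <= *max_units* whole-unit losses explaining *delta*.

    Only whole-residue, acyl and small-neutral catalog entries participate
    (cross-ring partials are not whole units).  Returns (names, residual)
    sorted by |residual|, then fewer units, then names.
    """
    if max_units < 1:
        raise ValueError("max_units must be >= 1")
    catalog = default_loss_catalog() if catalog is None else list(catalog)
    units = [
        e for e in catalog if e.category in ("O-glycosyl-whole", "acyl", "small-neutral")
    ]
    results = []
    for n in range(1, max_units + 1):
        for combo in itertools.combinations_with_replacement(units, n):
            total = sum(e.best_da for e in combo)
            residual = delta - total
            if abs(residual) <= tol_da:
                names = tuple(sorted(e.name for e in combo))
                results.append((names, residual))
    seen: set[tuple[str, ...]] = set()
    unique = []
    for names, residual in sorted(results, key=lambda r: (abs(r[1]), len(r[0]), r[0])):
        if names not in seen:
            seen.add(names)
            unique.append((names, residual))
    return unique


def detect_c_signature(
    s: Spectrum, tol_da: float = 0.5, base_mz: float | None = None
) -> list[Evidence]:
    """Cross-ring partial-loss evidence relative to *base_mz* (default: the
    precursor), plus the water loss.  Losses of 90 and 120 Da fit both the
    hexose and pentose series and are flagged ambiguous."""
    base = s.precursor_mz if base_mz is None else base_mz
    partials: dict[int, float] = {}
    for series in C_PARTIAL.values():
        partials.update(series)
    evidence = []
    for f in s.fragment_mzs:
        loss = base - f
        if loss <= 0:
            continue
        for nominal, exact in sorted(partials.items()):
            if abs(loss - exact) <= tol_da:
                evidence.append(
                    Evidence(
                        kind="partial-sugar-loss",
                        observed_mz=f,
                        expected=base - exact,
                        delta=loss - exact,
                        ambiguous_sugar=nominal in AMBIGUOUS_PARTIALS,
                    )
                )
                break
        if abs(loss - WATER) <= tol_da:
            evidence.append(
                Evidence(kind="water-loss", observed_mz=f, expected=base - WATER, delta=loss - WATER)
            )
    return evidence


def detect_acyl_markers(s: Spectrum, tol_da: float = 0.5) -> list[Evidence]:
    """Diagnostic acyl marker ions among the fragments (feruloyl m/z 177,
    coumaroyl m/z 147).  Malonyl has no marker; it is evidenced through loss
    arithmetic (86 Da alone or 248 Da with its hexose)."""
    evidence = []
    for name, marker in ACYL_MARKER_MZ.items():
        for f in s.fragment_mzs:
            if abs(f - marker) <= tol_da:
                evidence.append(
                    Evidence(kind="acyl-marker-ion", observed_mz=f, expected=marker, delta=f - marker)
                )
                break
    return evidence


# -- mass-consistency screen -------------------------------------------------


def is_mass_consistent(
    precursor_mz: float,
    dictionary: Sequence[Aglycone] | None = None,
    tol_da: float = 0.1,
) -> bool:
    """Whether the precursor is within *tol_da* of some reconstructable
    [M+H]+ composition: aglycone + <=2 sugars + <=1 acyl (acyl requires a
    sugar).  Printed masses that fail this screen cannot be [M+H]+ values of
    any structure in the chemical space and are annotated in nominal-Da mode
    only."""
    dictionary = default_aglycone_dict() if dictionary is None else list(dictionary)
    for agl in dictionary:
        for sugars, acyls in _unit_multisets():
            theo = agl.protonated_mz + sum(SUGAR_MASS[u] for u in sugars) + sum(
                ACYL_MASS[a] for a in acyls
            )
            if abs(precursor_mz - theo) <= tol_da:
                return True
    return False


def _unit_multisets() -> Iterable[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All (sugar multiset, acyl multiset) combinations with <= 2 sugars and
    <= 1 acyl, acyl only in the presence of a sugar."""
    sugar_opts: list[tuple[str, ...]] = [()]
    sugar_opts += [(u,) for u in SUGAR_MASS]
    sugar_opts += [
        tuple(sorted(c)) for c in itertools.combinations_with_replacement(SUGAR_MASS, 2)
    ]
    for sugars in sugar_opts:
        yield sugars, ()
        if sugars:
            for a in ACYL_MASS:
                yield sugars, (a,)


# -- candidate structures and scoring ----------------------------------------


@dataclass(frozen=True)
class AnnotatorConfig:
    """Tolerances, dictionary, allowed glycosylation space and weights.

    The default O-sugar space excludes pentose: in the flavonoid chemical
    space this package targets, pentoses occur C-linked while O-glycosides
    are hexosides (possibly acylated).  Both spaces are configurable.
    """

    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.5
    budget_tol_da: float = 0.5
    max_units: int = 3
    o_sugars: tuple[str, ...] = ("hexose", "deoxyhexose")
    c_sugars: tuple[str, ...] = ("hexose", "pentose")
    dictionary: tuple[Aglycone, ...] = field(default_factory=lambda: tuple(default_aglycone_dict()))
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))


def _candidate_templates(
    sugars: tuple[str, ...],
    acyls: tuple[str, ...],
    o_sugars: tuple[str, ...] = ("hexose", "deoxyhexose"),
    c_sugars: tuple[str, ...] = ("hexose", "pentose"),
) -> list[tuple[ModificationEvent, ...]]:
    """Linkage templates for a unit multiset, restricted to the observed
    chemical classes; acyls always decorate an O-linked sugar."""
    templates: list[tuple[ModificationEvent, ...]] = []
    n_acyl = len(acyls)
    if n_acyl > len(sugars) or n_acyl > 1:
        return []
    acyl = acyls[0] if acyls else "none"
    if len(sugars) == 0:
        return [()] if not acyls else []
    if len(sugars) == 1:
        u = sugars[0]
        if u in o_sugars:
            templates.append((ModificationEvent("O", u, acyl),))
        if acyl == "none" and u in c_sugars:
            templates.append((ModificationEvent("C", u),))
        return templates
    # two sugars: C+O (acyl on the O sugar) or C+C (no acyl)
    u1, u2 = sugars
    assignments = [(u1, u2)] if u1 == u2 else [(u1, u2), (u2, u1)]
    for c_sugar, o_sugar in assignments:
        if c_sugar in c_sugars and o_sugar in o_sugars:
            templates.append(
                (ModificationEvent("C", c_sugar), ModificationEvent("O", o_sugar, acyl))
            )
    if acyl == "none" and u1 in c_sugars and u2 in c_sugars:
        templates.append((ModificationEvent("C", u1), ModificationEvent("C", u2)))
    return templates


#: Penalty for an expected primary diagnostic ion that is absent.
MISSING_EXPECTED_PENALTY = 0.5
#: Score lost per Da of disagreement between the precursor and the candidate
#: composition; separates near-isobaric candidates (e.g. aglycones 0.036 Da
#: apart) that a 0.5-Da fragment tolerance alone cannot.
ACCURACY_PENALTY_PER_DA = 2.0


def _score_structure(
    s: Spectrum,
    aglycone: Aglycone,
    events: tuple[ModificationEvent, ...],
    tol_da: float,
    weights: dict[str, float],
) -> tuple[float, tuple[Evidence, ...]]:
    """Score one candidate structure against the observed fragments.

    Positive evidence: the free aglycone ion (expected only for the bare
    aglycone and pure O-glycosides, since a C-linked sugar never detaches
    completely), whole-unit loss ions for every sub-multiset of O-linked
    units, cross-ring partials of C-linked sugars measured from the
    precursor and from the C-core (the ion left after the O-side departs),
    successive water losses (up to 3 x 18 Da) from precursor and core for
    C-glycosides, and acyl marker ions.  Negative evidence: one point per
    unexplained precursor-to-fragment loss above 40 Da, and half a point for
    each missing primary expectation (absent aglycone ion for an O-only
    template, absent core ion for a C,O-template, no partial losses at all
    for a C-template).
    """
    evidence: list[Evidence] = []
    explained: set[float] = set()
    frags = s.fragment_mzs

    def observe(kind: str, theo: float, ambiguous: bool = False) -> bool:
        for f in frags:
            if abs(f - theo) <= tol_da:
                evidence.append(
                    Evidence(kind=kind, observed_mz=f, expected=theo, delta=f - theo,
                             ambiguous_sugar=ambiguous)
                )
                explained.add(f)
                return True
        return False

    o_units = [e for e in events if e.linkage == "O"]
    c_units = [e for e in events if e.linkage == "C"]
    penalties = 0.0

    # free aglycone ion: expected only when no sugar is C-linked
    if not c_units:
        agl_seen = observe("aglycone-ion", aglycone.protonated_mz)
        if not events and abs(s.precursor_mz - aglycone.protonated_mz) <= tol_da and not agl_seen:
            evidence.append(
                Evidence(kind="aglycone-ion", observed_mz=s.precursor_mz,
                         expected=aglycone.protonated_mz,
                         delta=s.precursor_mz - aglycone.protonated_mz)
            )
            agl_seen = True
        if o_units and not agl_seen:
            penalties += MISSING_EXPECTED_PENALTY

    # whole losses of every non-empty sub-multiset of O-linked units
    core_mzs = [s.precursor_mz]
    full_o_loss_seen = not o_units
    full_o_mass = sum(e.exact_mass for e in o_units)
    for r in range(1, len(o_units) + 1):
        for combo in sorted(set(itertools.combinations(range(len(o_units)), r))):
            lost = sum(o_units[i].exact_mass for i in combo)
            ion = s.precursor_mz - lost
            if observe("whole-sugar-loss", ion):
                core_mzs.append(ion)
                if abs(lost - full_o_mass) <= 1e-9:
                    full_o_loss_seen = True
    if c_units and o_units and not full_o_loss_seen:
        penalties += MISSING_EXPECTED_PENALTY
    # the theoretical C-core (aglycone + C sugars) even when the O-loss ion
    # itself was not recorded: partial and water losses are counted from it
    if c_units:
        theo_core = aglycone.protonated_mz + sum(e.exact_mass for e in c_units)
        if all(abs(theo_core - m) > tol_da for m in core_mzs):
            core_mzs.append(theo_core)

    # cross-ring partials of C sugars, from precursor and core ions; each
    # C unit should leave some cross-ring trace, ideally one specific to its
    # sugar series (hexose 96/150, pentose 60) rather than the shared 90/120
    partial_defs: dict[int, float] = {}
    for e in c_units:
        partial_defs.update(C_PARTIAL.get(e.unit, {}))
    matched_nominals: set[int] = set()
    seen_partial: set[tuple[float, int]] = set()
    for base in core_mzs:
        for nominal, exact in sorted(partial_defs.items()):
            for f in frags:
                if abs((base - f) - exact) <= tol_da and (f, nominal) not in seen_partial:
                    seen_partial.add((f, nominal))
                    matched_nominals.add(nominal)
                    evidence.append(
                        Evidence(
                            kind="partial-sugar-loss", observed_mz=f,
                            expected=base - exact, delta=(base - f) - exact,
                            ambiguous_sugar=nominal in AMBIGUOUS_PARTIALS,
                        )
                    )
                    explained.add(f)
                    break
    # simultaneous fragmentation of two C sugars: combined pairwise losses
    if len(c_units) == 2:
        s1 = C_PARTIAL.get(c_units[0].unit, {})
        s2 = C_PARTIAL.get(c_units[1].unit, {})
        for (n1, x1) in sorted(s1.items()):
            for (n2, x2) in sorted(s2.items()):
                theo = s.precursor_mz - (x1 + x2)
                for f in frags:
                    if abs(f - theo) <= tol_da and f not in explained:
                        evidence.append(
                            Evidence(
                                kind="partial-sugar-loss", observed_mz=f,
                                expected=theo, delta=f - theo,
                                ambiguous_sugar=(
                                    n1 in AMBIGUOUS_PARTIALS and n2 in AMBIGUOUS_PARTIALS
                                ),
                            )
                        )
                        explained.add(f)
                        break
    for e in c_units:
        unit_matched = set(C_PARTIAL.get(e.unit, {})) & matched_nominals
        if not unit_matched:
            penalties += MISSING_EXPECTED_PENALTY
        elif unit_matched <= AMBIGUOUS_PARTIALS:
            penalties += MISSING_EXPECTED_PENALTY / 2.0

    # acyl markers
    for e in events:
        if e.acyl in ACYL_MARKER_MZ:
            observe("acyl-marker-ion", ACYL_MARKER_MZ[e.acyl])

    # water losses: single from the precursor always; successive (2-3 x 18)
    # from precursor and C-core for hydroxyl-rich C-glycosyl structures
    water_bases = {round(s.precursor_mz, 6)}
    if c_units:
        water_bases.update(round(m, 6) for m in core_mzs)
    seen_water: set[float] = set()
    max_k = 3 if c_units else 1
    for base in sorted(water_bases):
        for k in range(1, max_k + 1):
            theo = base - k * WATER
            for f in frags:
                if abs(f - theo) <= tol_da and f not in seen_water:
                    seen_water.add(f)
                    evidence.append(
                        Evidence(kind="water-loss", observed_mz=f, expected=theo,
                                 delta=f - theo)
                    )
                    explained.add(f)
                    break

    score = sum(
        (weights.get(ev.kind, 0.0) / 2.0)
        if (ev.ambiguous_sugar and ev.kind == "partial-sugar-loss")
        else weights.get(ev.kind, 0.0)
        for ev in evidence
    )
    score -= penalties
    for f in frags:
        loss = s.precursor_mz - f
        if loss > PENALTY_FLOOR_DA and f not in explained:
            score -= UNEXPLAINED_PENALTY
    residual = s.precursor_mz - (aglycone.protonated_mz + sum(e.exact_mass for e in events))
    score -= ACCURACY_PENALTY_PER_DA * abs(residual)
    # quantize so that sub-millipoint accuracy differences between truly
    # isobaric candidates do not defeat the deterministic tie-break
    return round(score, 3), tuple(evidence)


def score_candidates(
    s: Spectrum, config: AnnotatorConfig | None = None
) -> list[Annotation]:
    """Rank all candidate structures for a spectrum.

    Candidates whose aglycone compositions are isobaric and whose events,
    class and score coincide are merged into a single annotation carrying the
    full aglycone candidate set.  Ordering: score desc, fewer events,
    alphabetical aglycone name.
    """
    cfg = config or AnnotatorConfig()
    dictionary = list(cfg.dictionary)
    if not dictionary:
        raise ValueError("empty aglycone dictionary")
    exact = is_mass_consistent(s.precursor_mz, dictionary)
    budget_tol = cfg.budget_tol_da if exact else 0.5
    scored: list[Annotation] = []
    for agl in dictionary:
        budget = s.precursor_mz - agl.protonated_mz
        if abs(budget) <= budget_tol:
            templates: list[tuple[ModificationEvent, ...]] = [()]
        elif budget < 0:
            continue
        else:
            templates = []
            for sugars, acyls in _unit_multisets():
                if not sugars:
                    continue
                if len(sugars) + len(acyls) > cfg.max_units:
                    continue
                theo = sum(SUGAR_MASS[u] for u in sugars) + sum(ACYL_MASS[a] for a in acyls)
                if abs(budget - theo) <= budget_tol:
                    templates.extend(
                        _candidate_templates(sugars, acyls, cfg.o_sugars, cfg.c_sugars)
                    )
        for events in templates:
            glyco_class = _classify_events(events)
            if glyco_class == "unknown":
                continue
            score, evidence = _score_structure(s, agl, events, cfg.fragment_tol_da, cfg.weights)
            scored.append(
                Annotation(
                    aglycone_candidates=(agl,),
                    events=tuple(sorted(events, key=lambda e: (e.linkage, e.unit, e.acyl))),
                    glyco_class=glyco_class,
                    score=score,
                    evidence=evidence,
                    spectrum_id=s.id,
                    precursor_mz=s.precursor_mz,
                    mass_inconsistent=not exact,
                )
            )
    scored.sort(key=lambda a: (-a.score, len(a.events), a.aglycone.name))
    return _merge_isobars(scored)


def _merge_isobars(ranked: list[Annotation]) -> list[Annotation]:
    merged: list[Annotation] = []
    for ann in ranked:
        for i, prev in enumerate(merged):
            same_structure = (
                prev.events == ann.events
                and prev.glyco_class == ann.glyco_class
                and abs(prev.score - ann.score) < 1e-9
                and abs(prev.aglycone.protonated_mz - ann.aglycone.protonated_mz) <= 0.01
            )
            if same_structure:
                cands = tuple(
                    sorted(
                        set(prev.aglycone_candidates) | set(ann.aglycone_candidates),
                        key=lambda a: a.name,
                    )
                )
                merged[i] = Annotation(
                    aglycone_candidates=cands,
                    events=prev.events,
                    glyco_class=prev.glyco_class,
                    score=prev.score,
                    evidence=prev.evidence,
                    spectrum_id=prev.spectrum_id,
                    precursor_mz=prev.precursor_mz,
                    mass_inconsistent=prev.mass_inconsistent,
                )
                break
        else:
            merged.append(ann)
    return merged


def annotate(s: Spectrum, config: AnnotatorConfig | None = None) -> Annotation:
    """Top-ranked annotation, or an 'unknown' annotation when no aglycone
    budget decomposes."""
    ranked = score_candidates(s, config)
    if not ranked:
        return Annotation(
            aglycone_candidates=(),
            events=(),
            glyco_class="unknown",
            score=0.0,
            evidence=(),
            spectrum_id=s.id,
            precursor_mz=s.precursor_mz,
        )
    top = ranked[0]
    if top.score < 0:
        top = Annotation(
            aglycone_candidates=top.aglycone_candidates, events=top.events,
            glyco_class=top.glyco_class, score=0.0, evidence=top.evidence,
            spectrum_id=top.spectrum_id, precursor_mz=top.precursor_mz,
            mass_inconsistent=top.mass_inconsistent,
        )
    return top


# -- naming grammar ----------------------------------------------------------

_UNIT_SIDE = {"hexose": "hexoside", "pentose": "pentoside", "deoxyhexose": "deoxyhexoside"}
_UNIT_SYL = {"hexose": "hexosyl", "pentose": "pentosyl", "deoxyhexose": "deoxyhexosyl"}

#: Aglycone pairs with identical elemental composition; indistinguishable
#: from mass-only evidence.
ISOBAR_PAIRS = (
    frozenset({"quercetin", "tricetin"}),
    frozenset({"chrysoeriol", "methylluteolin"}),
    frozenset({"apigenin", "resokaempferol"}),
)


def canonical_name(a: Annotation) -> str:
    """Emit the compound name in the field's naming grammar.

    Bare aglycone -> "Aglycone"; O-mono -> "Aglycone O-hexoside" (acyl
    prefixed, e.g. "O-malonylhexoside"); C-mono -> "C-hexosyl-aglycone";
    di-C,C same sugar -> "di-C,C-hexosyl-aglycone"; mixed ->
    "C-pentosyl-C-hexosyl-aglycone" (pentosyl first); C,O-di ->
    "C-hexosyl-aglycone O-[acyl]hexoside".  Positional locants are never
    emitted (they are not inferable from mass).
    """
    if a.glyco_class == "unknown":
        raise ValueError("cannot name an unknown-class annotation")
    agl = a.aglycone.name
    events = a.events
    if a.glyco_class == "aglycone-only":
        return agl.capitalize()
    if a.glyco_class in ("O-mono", "acylated-O"):
        e = events[0]
        side = _UNIT_SIDE[e.unit]
        if e.acyl != "none":
            side = f"{e.acyl}{side}"
        return f"{agl.capitalize()} O-{side}"
    if a.glyco_class == "C-mono":
        return f"C-{_UNIT_SYL[events[0].unit]}-{agl}"
    if a.glyco_class == "di-C-C":
        units = sorted((e.unit for e in events), key=lambda u: (u != "pentose", u))
        if units[0] == units[1]:
            return f"di-C,C-{_UNIT_SYL[units[0]]}-{agl}"
        return f"C-{_UNIT_SYL[units[0]]}-C-{_UNIT_SYL[units[1]]}-{agl}"
    # C-O-di / acylated-C-O
    c_ev = next(e for e in events if e.linkage == "C")
    o_ev = next(e for e in events if e.linkage == "O")
    side = _UNIT_SIDE[o_ev.unit]
    if o_ev.acyl != "none":
        side = f"{o_ev.acyl}{side}"
    return f"C-{_UNIT_SYL[c_ev.unit]}-{agl} O-{side}"


_SUGAR_TOKENS = {
    "hexoside": "hexose", "hexosyl": "hexose", "glucoside": "hexose",
    "glucosyl": "hexose", "galactoside": "hexose",
    "pentoside": "pentose", "pentosyl": "pentose", "xyloside": "pentose",
    "arabinoside": "pentose",
    "deoxyhexoside": "deoxyhexose", "deoxyhexosyl": "deoxyhexose",
    "rhamnoside": "deoxyhexose", "rhamnosyl": "deoxyhexose",
}
_ACYL_TOKENS = ("malonyl", "feruloyl", "coumaroyl")


def _normalize_printed(name: str) -> str:
    n = name.lower().strip()
    n = n.replace("apeignin", "apigenin")  # printed typo in the source table
    n = re.sub(r"\(.*?\)", " ", n)
    n = re.sub(r"\bderivative\b|\bisomer\b", " ", n)
    n = re.sub(r"\b\d+[′']*[-,]?", "", n)  # strip positional locants: 6-C, 7-O, 5-O
    n = n.replace("*", "").replace("p-", "")
    n = re.sub(r"\s+", " ", n).strip(" -")
    return n


def parse_printed_name(name: str) -> tuple[str | None, tuple[ModificationEvent, ...]]:
    """Parse a printed compound name into (aglycone, event multiset).

    Understands the grammar used in the source table: "di-C,C-<sugar>syl-agl",
    "C-<sugar>syl-agl O-<acyl><sugar>side", "Agl <n>-O-<sugar>side",
    "Agl <sugar>side", locant "6-C-glucoside" synonyms, etc.  Returns
    ``(None, ())`` when no known aglycone token is present.
    """
    n = _normalize_printed(name)
    aglycone = None
    for agl in sorted(default_aglycone_names(), key=len, reverse=True):
        if agl in n:
            aglycone = agl
            break
    if aglycone is None:
        return None, ()
    events: list[ModificationEvent] = []
    # di-C,C pattern: one sugar token doubled
    di = re.search(r"di-?c,?c-([a-z]+)", n)
    if di:
        unit = _SUGAR_TOKENS.get(di.group(1))
        if unit:
            return aglycone, (ModificationEvent("C", unit), ModificationEvent("C", unit))
    # explicit C-sugaryl prefixes
    for m in re.finditer(r"c-([a-z]+?(?:syl|side))", n):
        unit = _SUGAR_TOKENS.get(m.group(1))
        if unit:
            events.append(ModificationEvent("C", unit))
    # O-side groups, optionally acylated
    for m in re.finditer(r"o-([a-z]+)", n):
        token = m.group(1)
        acyl = "none"
        for a in _ACYL_TOKENS:
            if token.startswith(a):
                acyl = a
                token = token[len(a):]
                break
        unit = _SUGAR_TOKENS.get(token)
        if unit:
            events.append(ModificationEvent("O", unit, acyl))
    if not events:
        # bare-sugar suffix without linkage marker, e.g. "luteolin glucoside"
        for tok, unit in _SUGAR_TOKENS.items():
            if re.search(rf"(?<![a-z]){tok}\b", n):
                linkage = "C" if " c " in f" {n} " or "c-" in name.lower() else "O"
                events.append(ModificationEvent(linkage, unit))
                break
    return aglycone, tuple(sorted(events, key=lambda e: (e.linkage, e.unit, e.acyl)))


def _isobar_equivalent(a: str, b: str) -> bool:
    if a == b:
        return True
    return any(a in pair and b in pair for pair in ISOBAR_PAIRS)


def _aglycone_by_name(name: str) -> Aglycone | None:
    for a in default_aglycone_dict():
        if a.name == name:
            return a
    return None


def _c_core_mass(aglycone_name: str, events: Sequence[ModificationEvent]) -> float | None:
    """Monoisotopic [M+H]+ mass of the C-glycosyl core (aglycone plus all
    C-linked residues); the part of a structure that mass evidence cannot
    decompose further."""
    agl = _aglycone_by_name(aglycone_name)
    if agl is None:
        return None
    return agl.protonated_mz + sum(e.exact_mass for e in events if e.linkage == "C")


def names_equivalent(predicted: str, printed: str) -> bool:
    """Structure-level name comparison at mass-only evidence.

    Both names are parsed to (aglycone, events) after stripping locants,
    treating glucoside as hexoside, and ignoring "derivative"/"isomer"
    suffixes.  Two structures are equivalent when their glycosylation classes
    and O-side events (unit + acyl) match and their C-core compositions
    (aglycone + C-linked residues) have the same mass: fragmentation cannot
    cleave a C-glycosidic bond completely, so e.g. a C-hexosyl core on one
    aglycone is indistinguishable from a C-pentosyl core on its +CH2O
    homolog, exactly as isobaric bare aglycones are indistinguishable.
    """
    agl_p, ev_p = parse_printed_name(predicted)
    agl_q, ev_q = parse_printed_name(printed)
    if agl_p is None or agl_q is None:
        return False
    if _classify_events(ev_p) != _classify_events(ev_q):
        return False
    o_p = sorted((e.unit, e.acyl) for e in ev_p if e.linkage == "O")
    o_q = sorted((e.unit, e.acyl) for e in ev_q if e.linkage == "O")
    if o_p != o_q:
        return False
    # same number of C attachments, same total core composition
    n_c_p = sum(1 for e in ev_p if e.linkage == "C")
    n_c_q = sum(1 for e in ev_q if e.linkage == "C")
    if n_c_p != n_c_q:
        return False
    m_p = _c_core_mass(agl_p, ev_p)
    m_q = _c_core_mass(agl_q, ev_q)
    if m_p is None or m_q is None:
        return _isobar_equivalent(agl_p, agl_q) and ev_p == ev_q
    return abs(m_p - m_q) <= 0.01


# -- fixture audit -----------------------------------------------------------


def printed_structure_mz(name: str) -> float | None:
    """[M+H]+ m/z implied by a printed compound name, or None when the name
    does not describe a complete structure."""
    agl_name, events = parse_printed_name(name)
    if agl_name is None:
        return None
    n = _normalize_printed(name)
    tokens_present = any(
        tok in n for tok in ("hexos", "glucos", "pentos", "malonyl", "feruloyl", "coumaroyl")
    )
    if tokens_present and not events:
        return None  # name mentions modifications the grammar could not place
    agl = _aglycone_by_name(agl_name)
    if agl is None:
        return None
    return agl.protonated_mz + sum(e.exact_mass for e in events)


def fixture_mass_screen(name: str, precursor_mz: float, tol_da: float = 0.1) -> bool | None:
    """Audit screen for packaged-table records: is the printed precursor
    within *tol_da* of the [M+H]+ mass its own printed name implies?

    Returns None when the printed name is not a complete structure
    ("derivative" rows) and therefore outside the audit denominator.
    """
    raw = name.lower()
    if "derivative" in raw:
        return None
    theo = printed_structure_mz(name)
    if theo is None:
        return None
    return abs(precursor_mz - theo) <= tol_da

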