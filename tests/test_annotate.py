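"""Structure annotation: evidence primitives, scoring, naming grammar."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycoflav.annotate import (
    AnnotatorConfig,
    ModificationEvent,
    annotate,
    canonical_name,
    decompose_loss,
    detect_acyl_markers,
    detect_c_signature,
    enumerate_losses,
    find_aglycone_ions,
    fixture_mass_screen,
    is_mass_consistent,
    names_equivalent,
    parse_printed_name,
    score_candidates,
)
from glycoflav.masscalc import default_loss_catalog
from glycoflav.spectra import Peak, Spectrum


def _spec(mz, frags, sid="s"):
    return Spectrum(id=sid, precursor_mz=mz, peaks=tuple(Peak(f) for f in frags))


class TestFindAglyconeIons:
    def test_fragment_hit_returns_isobars(self, record_by_name, aglycone_dict):
        rec = record_by_name("Chrysoeriol 7-O-hexoside")
        hits = {a.name for a, _ in find_aglycone_ions(rec.to_spectrum(), aglycone_dict)}
        assert {"chrysoeriol", "methylluteolin"} <= hits

    def test_precursor_tested_for_bare_aglycone(self, record_by_name, aglycone_dict):
        rec = record_by_name("Luteolin")
        hits = {a.name for a, _ in find_aglycone_ions(rec.to_spectrum(), aglycone_dict)}
        assert "luteolin" in hits

    def test_empty_spectrum(self, aglycone_dict):
        assert find_aglycone_ions(_spec(999.9, []), aglycone_dict) == []


class TestEnumerateLosses:
    def test_hexose_loss_from_precursor(self):
        losses = enumerate_losses(_spec(463.1234, [301.1]))
        assert any(abs(l - 162.02) < 0.01 for _, _, l in losses)

    def test_fragment_pair_loss(self):
        losses = {(round(a, 1), round(b, 1)): round(l, 1)
                  for a, b, l in enumerate_losses(_spec(500.0, [359.1, 329.1]))}
        assert losses[(359.1, 329.1)] == 30.0


def _brute_decompositions(delta, entries, max_units, tol):
    """Independent exhaustive enumeration over whole-unit combinations."""
    found = set()
    for n in range(1, max_units + 1):
        for combo in itertools.combinations_with_replacement(entries, n):
            if abs(delta - sum(e.best_da for e in combo)) <= tol:
                found.add(tuple(sorted(e.name for e in combo)))
    return found


class TestDecomposeLoss:
    def test_hexose_plus_malonyl(self):
        names = [n for n, _ in decompose_loss(248.05, max_units=2, tol_da=0.01)]
        assert ("hexose-residue", "malonyl") in names

    def test_single_hexose(self):
        names = [n for n, _ in decompose_loss(162.05, max_units=1, tol_da=0.1)]
        assert names == [("hexose-residue",)]

    def test_unexplainable(self):
        assert decompose_loss(7.77, max_units=3, tol_da=0.1) == []

    @given(st.floats(min_value=10, max_value=600).map(lambda x: round(x, 2)))
    def test_agrees_with_exhaustive_oracle(self, delta):
        catalog = default_loss_catalog()
        whole = [e for e in catalog
                 if e.category in ("O-glycosyl-whole", "acyl", "small-neutral")]
        got = {names for names, _ in decompose_loss(delta, catalog, max_units=3, tol_da=0.3)}
        assert got == _brute_decompositions(delta, whole, 3, 0.3)


class TestCSignature:
    def test_c_hexoside_partial_losses(self, record_by_name):
        rec = record_by_name("Luteolin 6-C-glucoside")
        ev = detect_c_signature(rec.to_spectrum())
        nominals = {round(rec.precursor_mz - e.observed_mz) for e in ev
                    if e.kind == "partial-sugar-loss"}
        assert nominals == {90, 120, 150}

    def test_di_c_combined_row(self, record_by_name):
        rec = record_by_name("C-pentosyl-C-hexosyl-apigenin")
        ev = detect_c_signature(rec.to_spectrum())
        nominals = {round(rec.precursor_mz - e.observed_mz) for e in ev
                    if e.kind == "partial-sugar-loss"}
        assert {60, 90, 120, 150} <= nominals

    def test_whole_o_loss_is_not_a_c_signature(self):
        ev = detect_c_signature(_spec(463.1234, [463.1234 - 162.0528]))
        assert [e for e in ev if e.kind == "partial-sugar-loss"] == []

    def test_ambiguity_flags(self):
        ev = detect_c_signature(_spec(500.0, [500.0 - 90.03, 500.0 - 96.0]))
        flags = {round(500.0 - e.observed_mz): e.ambiguous_sugar for e in ev
                 if e.kind == "partial-sugar-loss"}
        assert flags[90] is True and flags[96] is False


class TestAcylMarkers:
    def test_feruloyl_marker(self, record_by_name):
        rec = record_by_name("C-hexosyl-chrysoeriol O-feruloylhexoside")
        ev = detect_acyl_markers(rec.to_spectrum())
        assert any(round(e.observed_mz) == 177 for e in ev)

    def test_coumaroyl_marker(self, record_by_name):
        rec = record_by_name("C-hexosyl-apigenin O-p-coumaroylhexoside")
        ev = detect_acyl_markers(rec.to_spectrum())
        assert any(round(e.observed_mz) == 147 for e in ev)

    def test_no_markers(self):
        assert detect_acyl_markers(_spec(463.12, [301.1])) == []


class TestWorkedElucidations:
    """The four structure types elucidated step by step in the study."""

    @pytest.mark.parametrize(
        "name, want_class, want_aglycone",
        [
            ("Chrysoeriol 7-O-hexoside", "O-mono", "chrysoeriol"),
            ("Luteolin 6-C-glucoside", "C-mono", "luteolin"),
            ("C-pentosyl-C-hexosyl-apigenin", "di-C-C", "apigenin"),
            ("C-hexosyl-chrysoeriol O-feruloylhexoside", "acylated-C-O", "chrysoeriol"),
        ],
    )
    def test_top_annotation(self, record_by_name, name, want_class, want_aglycone):
        ann = annotate(record_by_name(name).to_spectrum())
        assert ann.glyco_class == want_class
        assert want_aglycone in {a.name for a in ann.aglycone_candidates}

    def test_di_c_c_units(self, record_by_name):
        ann = annotate(record_by_name("C-pentosyl-C-hexosyl-apigenin").to_spectrum())
        assert sorted(e.unit for e in ann.events) == ["hexose", "pentose"]
        assert all(e.linkage == "C" for e in ann.events)

    def test_acylated_c_o_events(self, record_by_name):
        ann = annotate(record_by_name("C-hexosyl-chrysoeriol O-feruloylhexoside").to_spectrum())
        by_linkage = {e.linkage: e for e in ann.events}
        assert by_linkage["C"].unit == "hexose" and by_linkage["C"].acyl == "none"
        assert by_linkage["O"].unit == "hexose" and by_linkage["O"].acyl == "feruloyl"


class TestAnnotateContracts:
    def test_unknown_when_nothing_fits(self):
        ann = annotate(_spec(100.0, []))
        assert ann.glyco_class == "unknown" and ann.events == ()

    def test_empty_dictionary_is_error(self):
        with pytest.raises(ValueError):
            score_candidates(_spec(463.12, [301.1]), AnnotatorConfig(dictionary=()))

    def test_mass_conservation(self, flavonoid_records):
        """Precursor equals aglycone + event masses within tolerance for
        every exact-mode annotation."""
        for rec in flavonoid_records:
            if not is_mass_consistent(rec.precursor_mz):
                continue
            ann = annotate(rec.to_spectrum())
            if ann.glyco_class == "unknown":
                continue
            theo = ann.aglycone.protonated_mz + sum(e.exact_mass for e in ann.events)
            assert abs(rec.precursor_mz - theo) <= 0.5, rec.name

    def test_scores_non_negative_and_ranked(self, flavonoid_records):
        for rec in flavonoid_records[:10]:
            ranked = score_candidates(rec.to_spectrum())
            scores = [a.score for a in ranked]
            assert scores == sorted(scores, reverse=True)
            assert annotate(rec.to_spectrum()).score >= 0


class TestNaming:
    @pytest.mark.parametrize(
        "aglycone, events, expected",
        [
            ("luteolin", (), "Luteolin"),
            ("naringenin", (ModificationEvent("O", "hexose", "malonyl"),),
             "Naringenin O-malonylhexoside"),
            ("apigenin", (ModificationEvent("C", "pentose"), ModificationEvent("C", "hexose")),
             "C-pentosyl-C-hexosyl-apigenin"),
            ("luteolin", (ModificationEvent("C", "hexose"),), "C-hexosyl-luteolin"),
            ("chrysoeriol", (ModificationEvent("C", "hexose"),
                             ModificationEvent("O", "hexose", "feruloyl")),
             "C-hexosyl-chrysoeriol O-feruloylhexoside"),
            ("apigenin", (ModificationEvent("C", "pentose"), ModificationEvent("C", "pentose")),
             "di-C,C-pentosyl-apigenin"),
        ],
    )
    def test_canonical_name_grammar(self, aglycone, events, expected):
        from glycoflav.annotate import Annotation, _aglycone_by_name, _classify_events

        ann = Annotation(
            aglycone_candidates=(_aglycone_by_name(aglycone),),
            events=events,
            glyco_class=_classify_events(events),
            score=1.0,
            evidence=(),
        )
        assert canonical_name(ann) == expected

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("C-hexosyl-luteolin", "Luteolin 6-C-glucoside", True),
            ("Quercetin O-malonylhexoside", "Tricetin O-malonylhexoside", True),
            ("Apigenin", "Luteolin", False),
            ("Apigenin", "Resokaempferol", True),
            ("Chrysoeriol O-hexoside", "Chrysoeriol 7-O-hexoside", True),
            # same-class, same-O-side structures with identical C-core formula
            ("C-hexosyl-apigenin O-feruloylhexoside",
             "C-pentosyl-chrysoeriol O-feruloylhexoside", True),
            # different O side: not equivalent
            ("C-pentosyl-apigenin O-feruloylhexoside",
             "C-hexosyl-apigenin O-feruloylhexoside", False),
        ],
    )
    def test_names_equivalent(self, a, b, expected):
        assert names_equivalent(a, b) is expected

    def test_parse_printed_name_grammar(self):
        agl, events = parse_printed_name("Luteolin 6-C-glucoside")
        assert agl == "luteolin"
        assert events == (ModificationEvent("C", "hexose"),)
        agl, events = parse_printed_name("di-C,C-pentosyl-apigenin")
        assert events == (ModificationEvent("C", "pentose"), ModificationEvent("C", "pentose"))
        agl, events = parse_printed_name("C-pentosyl-apeignin O-feruloylhexoside")
        assert agl == "apigenin"  # printed typo normalized


class TestMassScreen:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("Sakuranetin", False),
            ("Eriodictyol C-hexoside", False),
            ("Luteolin O-malonylhexoside", False),
            ("Naringenin O-malonylhexoside", False),
            ("Tricin O-malonylhexoside", True),
            ("Quercetin O-malonylhexoside", True),
            ("Luteolin 6-C-glucoside", True),
            ("Tricin derivative", None),
        ],
    )
    def test_fixture_screen(self, record_by_name, name, expected):
        rec = record_by_name(name)
        assert fixture_mass_screen(rec.name, rec.precursor_mz) is expected
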