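"""Core UPO/CPO grammar verdicts, pair spacing, and aromatic context."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tests.conftest import make_record, random_protein
from upomine.grammar import aromatic_context, find_core_grammar, pair_spacing
from upomine.motifs import scan_motif
from upomine.synthetic import _build_upo_template


def planted_record(seed=1, subfamily=None, distal="EGD", spacing=6, registry=None):
    from upomine.motifs import default_registry

    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    seq, planted, coords = _build_upo_template(
        rng, registry, subfamily, distal=distal, spacing=spacing
    )
    return make_record("".join(seq)), coords


class TestPairSpacing:
    def test_printed_exemplar_positions(self):
        assert pair_spacing(189, 196) == 6

    def test_adjacency(self):
        assert pair_spacing(1, 2) == 0

    def test_seven_residue_variant(self):
        assert pair_spacing(10, 18) == 7

    def test_order_violation_raises(self):
        with pytest.raises(ValueError):
            pair_spacing(196, 189)

    @given(st.integers(1, 10**6), st.integers(1, 10**6), st.integers(0, 10**6))
    @settings(max_examples=100, deadline=None)
    def test_translation_invariance(self, a, gap, k):
        b = a + gap
        assert pair_spacing(a + k, b + k) == pair_spacing(a, b)


class TestCoreGrammar:
    def test_planted_aaeupo_anatomy_is_upo_core_with_spacing_six(self, registry):
        rec, coords = planted_record(seed=3)
        g = find_core_grammar(rec, registry)
        assert g.grammar_class == "UPO_core"
        assert g.spacing == 6
        assert g.distal_variant == "EGD"
        assert g.proximal_cys == coords["PCP"][0] + 1
        assert g.distal_pos == coords["distal"][0]
        assert g.stabilizer_pos == coords["R"][0]
        assert g.catalytic_glu_pos == coords["E"][0]

    def test_ehd_without_stabilizer_is_cpo_core(self, registry):
        rec, coords = planted_record(seed=4)
        # swap EGD -> EHD and break S[IL]G so the UPO chain cannot complete
        chars = list(rec.residues)
        ds = coords["distal"][0]
        chars[ds - 1 : ds + 2] = "EHD"
        ss = coords["S[IL]G"][0]
        chars[ss - 1] = "A"
        rec2 = make_record("".join(chars))
        g = find_core_grammar(rec2, registry)
        assert g.grammar_class == "CPO_core"
        assert g.stabilizer_pos is None and g.spacing is None
        assert g.distal_variant == "EHD"

    def test_all_alanine_sequence_is_none(self, registry):
        g = find_core_grammar(make_record("A" * 250), registry)
        assert g.grammar_class == "none"

    def test_short_sequence_is_none(self, registry):
        g = find_core_grammar(make_record("PCP" + "A" * 30), registry)
        assert g.grammar_class == "none"

    @pytest.mark.parametrize("distal", ["EAD", "ETD"])
    def test_distal_variants_yield_upo_like_cpo(self, registry, distal):
        rec, _ = planted_record(seed=5, distal=distal)
        g = find_core_grammar(rec, registry)
        assert g.grammar_class == "UPO_like_CPO"
        assert g.distal_variant == distal
        assert g.spacing == 6

    def test_spacing_seven_with_egd_yields_upo_like_cpo(self, registry):
        rec, _ = planted_record(seed=6, spacing=7)
        g = find_core_grammar(rec, registry)
        assert g.grammar_class == "UPO_like_CPO"
        assert g.spacing == 7

    @pytest.mark.parametrize("spacing", [0, 1, 2, 3, 4, 5, 8, 9, 10])
    def test_other_spacings_complete_no_upo_grammar(self, registry, spacing):
        """Both UPO grammars reject every spacing in 0-10 except 6 and 7."""
        rec, _ = planted_record(seed=7, spacing=spacing)
        g = find_core_grammar(rec, registry)
        assert g.grammar_class == "none"

    def test_missing_sxxrxd_fails_unless_relaxed(self, registry):
        rec, coords = planted_record(seed=8)
        chars = list(rec.residues)
        ss = coords["SXXRXD"][0]
        chars[ss - 1] = "A"  # break the Ser
        rec2 = make_record("".join(chars))
        assert find_core_grammar(rec2, registry).grammar_class == "none"
        relaxed = find_core_grammar(rec2, registry, require_sxxrxd=False)
        assert relaxed.grammar_class == "UPO_core"

    def test_upo_core_hits_replay_through_the_scanner(self, registry, rng):
        """Grammar soundness: every claimed position is a real motif hit."""
        for seed in range(12):
            rec, _ = planted_record(seed=100 + seed)
            g = find_core_grammar(rec, registry)
            assert g.grammar_class == "UPO_core"
            pcp = {h.start for h in scan_motif(registry["PCP"], rec.residues)}
            assert g.proximal_cys - 1 in pcp
            distal = {h.start for h in scan_motif(registry[g.distal_variant],
                                                  rec.residues)}
            assert g.distal_pos in distal
            assert rec.residues[g.stabilizer_pos - 1] == "R"
            assert rec.residues[g.catalytic_glu_pos - 1] == "E"
            for name, hits in g.supporting.items():
                scanned = {(h.start, h.end) for h in
                           scan_motif(registry[name], rec.residues)}
                assert {(h.start, h.end) for h in hits} <= scanned


class TestAromaticContext:
    def test_counts_aromatics_in_window(self, registry):
        rec, coords = planted_record(seed=9)
        g = find_core_grammar(rec, registry)
        mid = g.distal_pos + 1
        window = rec.residues[max(0, mid - 16) : mid + 15]
        expected = sum(1 for c in window if c in "FYW")
        assert aromatic_context(rec, g, window=15) == expected

    def test_requires_grammar(self, registry):
        from upomine.grammar import GrammarResult

        with pytest.raises(ValueError):
            aromatic_context(make_record("A" * 100), GrammarResult("none"))

    def test_all_alanine_context_counts_zero(self, registry):
        rec, coords = planted_record(seed=10)
        g = find_core_grammar(rec, registry)
        chars = list(rec.residues)
        mid = g.distal_pos + 1
        for p in range(max(1, mid - 15), min(len(chars), mid + 15) + 1):
            if chars[p - 1] in "FYW":
                chars[p - 1] = "A"
        rec2 = make_record("".join(chars))
        assert aromatic_context(rec2, g, window=15) == 0
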