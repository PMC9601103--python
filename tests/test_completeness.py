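"""Completeness engine: step counting, best-path maximisation, thresholding."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from named.accessions import Accession
from named.annotations import GeneAnnotation, MagAnnotationSet
from named.completeness import (
    detect_metabolism,
    module_completeness,
    path_completeness,
    score_all,
)
from named.grammar import GAP_STEP, ModuleDefinition, parse_definition

from conftest import oracle_completeness, tree_strategy

K = lambda n: Accession("KO", f"K{n:05d}")
S = lambda *ns: frozenset(K(n) for n in ns)


def make_mag(mag_id, accessions, e_value=1e-50):
    anns = [
        GeneAnnotation(
            gene_id=f"g{i}",
            contig_id="c0",
            gene_order_on_contig=i,
            source={"KO": "KOfam", "COG": "COG", "EC": "EC"}[a.source],
            accession=a,
            function_text="",
            e_value=e_value,
        )
        for i, a in enumerate(accessions)
    ]
    return MagAnnotationSet(mag_id=mag_id, annotations=anns, contig_ids={"c0"})


def make_module(module_id, raw):
    return ModuleDefinition(module_id, f"module {module_id}", raw, parse_definition(raw))


class TestPathCompleteness:
    @pytest.mark.parametrize(
        "path, present, expected",
        [
            ((S(1), S(2)), S(1, 2), (2, 2)),
            ((S(1), S(2), S(3)), S(1, 2), (2, 3)),
            # a complex step stays unsatisfied until every subunit is present
            ((S(1, 2), S(3)), S(1, 3), (1, 2)),
            ((S(1, 2), S(3)), S(1, 2, 3), (2, 2)),
            ((S(1), GAP_STEP), S(1), (1, 2)),
        ],
    )
    def test_counts(self, path, present, expected):
        assert path_completeness(path, present) == expected

    def test_complex_matches_brute_force_subset_check(self):
        path = (S(1, 2), S(3))
        for present in [S(), S(1), S(1, 2), S(1, 3), S(1, 2, 3)]:
            sat, tot = path_completeness(path, present)
            assert tot == 2
            assert sat == sum(1 for step in path if step <= present)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            path_completeness((), S(1))


class TestModuleCompleteness:
    def test_alternative_branch_fully_present(self):
        c, *_ = module_completeness(parse_definition("K00001,K00002"), S(1))
        assert c == 1

    def test_partial_path(self):
        c, *_ = module_completeness(parse_definition("(K00001,K00002) K00003"), S(2))
        assert c == Fraction(1, 2)

    def test_empty_presence_scores_zero(self):
        c, *_ = module_completeness(parse_definition("K00001 K00002+K00003"), S())
        assert c == 0

    def test_greedy_branch_choice_would_be_wrong(self):
        # OR branch ratios invert after summation with the sibling steps:
        # branch K00001 scores 0/1 locally but yields 3/4 overall, while
        # branch (K00005..K00008, one present) scores 1/4 locally but only
        # 4/7 overall.  The evaluator must still find 3/4.
        raw = "(K00001,K00005 K00006 K00007 K00008) K00002 K00003 K00004"
        present = S(2, 3, 4, 5)
        c, path, sat, tot = module_completeness(parse_definition(raw), present)
        assert (sat, tot) == (3, 4)
        assert c == oracle_completeness(parse_definition(raw), present)

    def test_best_path_is_a_witness(self):
        tree = parse_definition("(K00001,K00002 K00003) K00004")
        present = S(1, 4)
        c, path, sat, tot = module_completeness(tree, present)
        assert path_completeness(path, present) == (sat, tot)
        assert Fraction(sat, tot) == c == 1

    def test_tie_breaks_prefer_fewer_steps_then_lexicographic(self):
        tree = parse_definition("K00002 K00003,K00001")
        c, path, sat, tot = module_completeness(tree, S())
        assert c == 0 and tot == 1
        assert path == (S(1),)
        tree = parse_definition("K00002,K00001")
        _, path, _, _ = module_completeness(tree, S())
        assert path == (S(1),)

    def test_all_optional_path_is_degenerate_zero(self):
        c, path, sat, tot = module_completeness(parse_definition("-K00001"), S())
        assert (c, sat, tot) == (0, 0, 0) and path == ()

    def test_invalid_count_mode(self):
        with pytest.raises(ValueError):
            module_completeness(parse_definition("K00001"), S(), count_mode="units")

    def test_genes_mode_counts_subunits_individually(self):
        tree = parse_definition("K00001+K00002 K00003")
        c_steps, *_ = module_completeness(tree, S(1, 3), count_mode="steps")
        c_genes, *_ = module_completeness(tree, S(1, 3), count_mode="genes")
        assert c_steps == Fraction(1, 2)
        assert c_genes == Fraction(2, 3)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(tree=tree_strategy(max_leaves=12), data=st.data())
    def test_oracle_equivalence_on_random_trees(self, tree, data):
        """Frontier evaluation equals exhaustive path enumeration exactly."""
        leaves = sorted(set(tree.leaves()))
        present = frozenset(
            data.draw(st.sets(st.sampled_from(leaves), max_size=len(leaves)))
            if leaves
            else set()
        )
        c, path, sat, tot = module_completeness(tree, present)
        assert c == oracle_completeness(tree, present)
        if path:
            assert path_completeness(path, present) == (sat, tot)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(tree=tree_strategy(max_leaves=10), data=st.data())
    def test_monotone_in_presence(self, tree, data):
        leaves = sorted(set(tree.leaves()))
        if not leaves:
            return
        present = frozenset(data.draw(st.sets(st.sampled_from(leaves))))
        extra = data.draw(st.sampled_from(leaves))
        c_before, *_ = module_completeness(tree, present)
        c_after, *_ = module_completeness(tree, present | {extra})
        assert c_after >= c_before


class TestDetect:
    def test_two_of_three_steps_is_present_at_default_threshold(self):
        module = make_module("M1", "K00001 K00002 K00003")
        result = detect_metabolism(module, make_mag("A", [K(1), K(2)]))
        assert result.completeness == Fraction(2, 3)
        assert result.present

    def test_one_of_three_steps_is_absent(self):
        module = make_module("M1", "K00001 K00002 K00003")
        result = detect_metabolism(module, make_mag("A", [K(1)]))
        assert result.completeness == Fraction(1, 3)
        assert not result.present

    def test_single_step_module_present_at_any_threshold(self):
        module = make_module("M1", "K00001")
        result = detect_metabolism(module, make_mag("A", [K(1)]), threshold=1)
        assert result.present

    def test_threshold_validation(self):
        module = make_module("M1", "K00001")
        with pytest.raises(ValueError):
            detect_metabolism(module, make_mag("A", [K(1)]), threshold=1.5)

    def test_evalue_filter_applies_before_scoring(self):
        module = make_module("M1", "K00001")
        mag = make_mag("A", [K(1)], e_value=1e-50)
        r = detect_metabolism(module, mag, evalue_thresholds={"KOfam": 1e-80})
        assert r.completeness == 0


class TestScoreAll:
    def test_cartesian_cardinality_and_ordering(self):
        mods = [make_module("M2", "K00001"), make_module("M1", "K00002")]
        mags = [make_mag("B", [K(1)]), make_mag("A", [K(2)])]
        df = score_all(mags, mods)
        assert len(df) == 4
        assert list(df["mag_id"]) == ["A", "A", "B", "B"]
        assert list(df["module_id"]) == ["M1", "M2", "M1", "M2"]

    def test_empty_mag_scores_zero_everywhere(self):
        mods = [make_module("M1", "K00001 K00002")]
        df = score_all([make_mag("A", [])], mods)
        assert (df["completeness"] == 0).all()

    def test_deterministic_output(self):
        mods = [make_module("M1", "(K00001,K00002) K00003")]
        mags = [make_mag("A", [K(1), K(3)]), make_mag("B", [K(2)])]
        a = score_all(mags, mods).to_csv(sep="\t", index=False)
        b = score_all(list(reversed(mags)), mods).to_csv(sep="\t", index=False)
        assert a == b

    def test_duplicate_mag_id_rejected(self):
        mods = [make_module("M1", "K00001")]
        with pytest.raises(ValueError, match="duplicate"):
            score_all([make_mag("A", []), make_mag("A", [])], mods)
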