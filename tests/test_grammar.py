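"""Definition grammar: parsing, serialisation, path enumeration."""

import pytest
from hypothesis import given, settings

from named.accessions import Accession
from named.grammar import (
    GAP_STEP,
    DefinitionNode,
    DefinitionParseError,
    count_paths,
    enumerate_paths,
    normalize,
    parse_definition,
    read_kegg_module_file,
    read_kegg_module_text,
    serialize_definition,
)

from conftest import tree_strategy

K = lambda n: Accession("KO", f"K{n:05d}")
LEAF = lambda n: DefinitionNode("LEAF", accession=K(n))


class TestParse:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("K00001 K00002", DefinitionNode("AND", (LEAF(1), LEAF(2)))),
            ("K02588", DefinitionNode("LEAF", accession=Accession("KO", "K02588"))),
            (
                "(K00001,K00002) K00003+K00004",
                DefinitionNode(
                    "AND",
                    (
                        DefinitionNode("OR", (LEAF(1), LEAF(2))),
                        DefinitionNode("COMPLEX", (LEAF(3), LEAF(4))),
                    ),
                ),
            ),
            # minus prefix marks a non-essential component
            ("-K00001", DefinitionNode("OPTIONAL", (LEAF(1),))),
            # minus inside a complex marks a non-essential subunit
            (
                "K00001-K00002",
                DefinitionNode(
                    "COMPLEX", (LEAF(1), DefinitionNode("OPTIONAL", (LEAF(2),)))
                ),
            ),
            ("--", DefinitionNode("GAP")),
        ],
    )
    def test_structures(self, raw, expected):
        assert parse_definition(raw) == expected

    def test_whitespace_insensitive(self):
        a = parse_definition("K00001 K00002   (K00003 , K00004)")
        b = parse_definition("K00001  K00002 (K00003,K00004)")
        assert a == b

    def test_comma_binds_looser_than_space(self):
        # "a b,c" reads as OR(AND(a, b), c), not AND(a, OR(b, c))
        tree = parse_definition("K00001 K00002,K00003")
        assert tree.kind == "OR"
        assert tree.children[0].kind == "AND"

    def test_unbalanced_parens_reports_offset(self):
        with pytest.raises(DefinitionParseError, match="offset"):
            parse_definition("(K00001 K00002")
        with pytest.raises(DefinitionParseError, match="offset 8"):
            parse_definition("K00001 K)")

    def test_malformed_token_is_named(self):
        with pytest.raises(DefinitionParseError, match="K123"):
            parse_definition("K00001 K123")

    @pytest.mark.parametrize("raw", ["K00001,,K00002", "K00001,", "(K00001,)"])
    def test_empty_or_branch(self, raw):
        with pytest.raises(DefinitionParseError):
            parse_definition(raw)

    @pytest.mark.parametrize("raw", ["", "   "])
    def test_empty_definition(self, raw):
        with pytest.raises(DefinitionParseError):
            parse_definition(raw)

    def test_nested_same_kind_nodes_are_flattened(self):
        tree = parse_definition("(K00001 K00002) K00003")
        assert tree.kind == "AND" and len(tree.children) == 3
        tree = parse_definition("(K00001,K00002),K00003")
        assert tree.kind == "OR" and len(tree.children) == 3


class TestSerialize:
    @pytest.mark.parametrize(
        "tree, expected",
        [
            (DefinitionNode("AND", (LEAF(1), LEAF(2))), "K00001 K00002"),
            (DefinitionNode("LEAF", accession=Accession("KO", "K02588")), "K02588"),
            (
                DefinitionNode(
                    "OR", (LEAF(1), DefinitionNode("AND", (LEAF(2), LEAF(3))))
                ),
                "K00001,K00002 K00003",
            ),
        ],
    )
    def test_canonical_forms(self, tree, expected):
        assert serialize_definition(tree) == expected
        assert parse_definition(serialize_definition(tree)) == tree

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(tree=tree_strategy())
    def test_round_trip_random_trees(self, tree):
        assert parse_definition(serialize_definition(tree)) == tree

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(tree=tree_strategy())
    def test_normalization_idempotent(self, tree):
        assert normalize(tree) == tree
        assert normalize(normalize(tree)) == normalize(tree)


class TestEnumeratePaths:
    def test_single_leaf(self):
        paths, truncated = enumerate_paths(LEAF(1))
        assert paths == [(frozenset({K(1)}),)] and not truncated

    def test_or_under_and_expands_to_two_paths(self):
        tree = parse_definition("(K00001,K00002) K00003")
        paths, _ = enumerate_paths(tree)
        assert paths == [
            (frozenset({K(1)}), frozenset({K(3)})),
            (frozenset({K(2)}), frozenset({K(3)})),
        ]

    def test_complex_is_one_multi_member_step(self):
        paths, _ = enumerate_paths(parse_definition("K00001+K00002"))
        assert paths == [(frozenset({K(1), K(2)}),)]

    def test_optional_omitted_from_steps(self):
        paths, _ = enumerate_paths(parse_definition("K00001 -K00002"))
        assert paths == [(frozenset({K(1)}),)]

    def test_gap_contributes_unsatisfiable_step(self):
        paths, _ = enumerate_paths(parse_definition("K00001 --"))
        assert paths == [(frozenset({K(1)}), GAP_STEP)]

    def test_truncation_flag(self):
        tree = parse_definition("(K00001,K00002) (K00003,K00004) (K00005,K00006)")
        paths, truncated = enumerate_paths(tree, max_paths=3)
        assert len(paths) == 3 and truncated

    def test_max_paths_validation(self):
        with pytest.raises(ValueError):
            enumerate_paths(LEAF(1), max_paths=0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(tree=tree_strategy(allow_gap=False, allow_optional=False))
    def test_path_count_law(self, tree):
        """Without gaps/optionals, path count = product of OR branch counts
        whenever no OR sits beneath another OR's branch."""
        paths, truncated = enumerate_paths(tree, max_paths=100_000)
        assert not truncated
        assert len(paths) == count_paths(tree)

        def or_free(node):
            return node.kind != "OR" and all(or_free(c) for c in node.children)

        def parallel_ors(node):
            if node.kind == "OR":
                return all(or_free(c) for c in node.children)
            return all(parallel_ors(c) for c in node.children)

        def or_branch_product(node):
            prod = 1
            if node.kind == "OR":
                prod *= len(node.children)
            for c in node.children:
                prod *= or_branch_product(c)
            return prod

        if parallel_ors(tree):
            assert len(paths) == or_branch_product(tree)


class TestModuleFile:
    GOOD = (
        "ENTRY       M00001\n"
        "NAME        Test module\n"
        "DEFINITION  K00001 (K00002,K00003)\n"
        "///\n"
    )
    NO_DEF = "ENTRY       M00002\nNAME        Broken record\n///\n"

    def test_single_record(self, tmp_path):
        p = tmp_path / "mods.txt"
        p.write_text(self.GOOD)
        mods = read_kegg_module_file(p)
        assert len(mods) == 1
        assert mods[0].module_id == "M00001"
        assert mods[0].name == "Test module"
        assert parse_definition(mods[0].raw_definition) == mods[0].root

    def test_record_missing_definition_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "mods.txt"
        p.write_text(self.GOOD + self.NO_DEF)
        with caplog.at_level("WARNING"):
            mods = read_kegg_module_file(p)
        assert len(mods) == 1
        assert any("M00002" in r.message for r in caplog.records)

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        with pytest.raises(ValueError):
            read_kegg_module_file(p)

    def test_continuation_lines_join(self):
        text = (
            "ENTRY       M00003\n"
            "NAME        Long\n"
            "DEFINITION  K00001\n"
            "            K00002\n"
            "///\n"
        )
        mods = read_kegg_module_text(text)
        assert mods[0].root == parse_definition("K00001 K00002")

    def test_real_definition_lines_round_trip(self, example_modules_path):
        mods = read_kegg_module_file(example_modules_path)
        assert len(mods) == 5
        for m in mods:
            again = parse_definition(serialize_definition(m.root))
            assert again == m.root
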