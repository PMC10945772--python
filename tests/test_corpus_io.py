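import numpy as np
import pytest

from synbold import corpus_io as cio


# -- bracketed trees --------------------------------------------------------

class TestBracketedTrees:
    def test_simple_tree_structure_and_spans(self):
        tree = cio.parse_bracketed("(S (NP Mary) (VP eats))")
        assert tree.label == "S"
        assert tree.terminals() == ["Mary", "eats"]
        assert tree.span == (0, 2)
        np_node, vp_node = tree.children
        assert (np_node.label, np_node.span) == ("NP", (0, 1))
        assert (vp_node.label, vp_node.span) == ("VP", (1, 2))

    def test_single_terminal_tree(self):
        tree = cio.parse_bracketed("(X a)")
        assert tree.terminals() == ["a"]
        assert tree.span == (0, 1)

    @pytest.mark.parametrize("bad", ["((S a)", "(S (NP Mary)", "(S a))"])
    def test_unbalanced_raises_with_record_number(self, bad, tmp_path):
        p = tmp_path / "trees.txt"
        p.write_text(bad + "\n")
        with pytest.raises(cio.ParseError, match="record 1"):
            cio.read_bracketed_trees(p)

    def test_roundtrip_identity(self, tree_suite, tmp_path):
        trees = [t for t, _ in tree_suite[:50]]
        p = tmp_path / "trees.txt"
        cio.write_bracketed_trees(trees, p)
        back = cio.read_bracketed_trees(p)
        assert len(back) == len(trees)
        for a, b in zip(trees, back):
            assert a.to_bracketed() == b.to_bracketed()
            assert [n.span for n in a.nonterminals()] == [
                n.span for n in b.nonterminals()
            ]
            assert [n.is_preterminal for n in a.nonterminals()] == [
                n.is_preterminal for n in b.nonterminals()
            ]

    def test_multiline_block_and_empty_record(self, tmp_path):
        p = tmp_path / "trees.txt"
        p.write_text("(S (NP Mary)\n   (VP eats))\n\n(X a)\n")
        trees = cio.read_bracketed_trees(p)
        assert [t.terminals() for t in trees] == [["Mary", "eats"], ["a"]]

    def test_punctuation_stripping_renumbers_spans(self):
        tree = cio.parse_bracketed("(S (NP Mary) (VP eats) (. .))")
        stripped = cio.strip_punctuation(tree, {"."})
        assert stripped.terminals() == ["Mary", "eats"]
        assert stripped.span == (0, 2)

    def test_pos_wrapped_detection(self):
        wrapped = cio.parse_bracketed("(S (NP (NNP Mary)) (VP (VBZ eats)))")
        flags = {n.label: n.is_preterminal for n in wrapped.nonterminals()}
        assert flags == {"S": False, "NP": False, "NNP": True,
                         "VP": False, "VBZ": True}
        # mixed bracketing: one bare terminal => nothing is a POS wrapper,
        # so single-terminal-child phrases like the NP still count
        mixed = cio.parse_bracketed("(S (NP Mary) (VP eats daily))")
        assert not any(n.is_preterminal for n in mixed.nonterminals())


# -- dependencies -----------------------------------------------------------

class TestDependency:
    def test_read_heads_and_head_set(self, tmp_path):
        p = tmp_path / "d.conllu"
        p.write_text(
            "# sent_id = 1\n"
            "1\tMary\t_\t_\t_\t_\t2\tnsubj\t_\t_\n"
            "2\teats\t_\t_\t_\t_\t0\troot\t_\t_\n"
            "3\tapples\t_\t_\t_\t_\t2\tobj\t_\t_\n"
            "4\tdaily\t_\t_\t_\t_\t2\tadvmod\t_\t_\n\n"
        )
        parses = cio.read_dependency(p)
        assert len(parses) == 1
        assert parses[0].head == [2, 0, 2, 2]
        assert parses[0].head_set() == {1}

    def test_two_roots_rejected(self):
        with pytest.raises(cio.FormatError, match="root"):
            cio.DependencyParse(head=[0, 0])

    def test_self_head_rejected(self):
        with pytest.raises(cio.FormatError, match="own head"):
            cio.DependencyParse(head=[1, 0])

    def test_empty_block_skipped_with_warning(self, tmp_path):
        p = tmp_path / "d.conllu"
        p.write_text("# only a comment\n\n1\ta\t_\t_\t_\t_\t0\troot\t_\t_\n\n")
        with pytest.warns(UserWarning, match="empty"):
            parses = cio.read_dependency(p)
        assert len(parses) == 1

    def test_multiword_token_lines_ignored(self, tmp_path):
        p = tmp_path / "d.conllu"
        p.write_text(
            "1-2\tdel\t_\t_\t_\t_\t_\t_\t_\t_\n"
            "1\tde\t_\t_\t_\t_\t2\tcase\t_\t_\n"
            "2\tel\t_\t_\t_\t_\t0\troot\t_\t_\n\n"
        )
        assert cio.read_dependency(p)[0].head == [2, 0]

    def test_alignment_error_names_counts(self, t1):
        dep = cio.DependencyParse(head=[2, 0, 2])
        with pytest.raises(cio.FormatError, match="3 tokens"):
            cio.align_tree_dependency(t1, dep)


# -- timings ----------------------------------------------------------------

class TestTimings:
    def test_read_basic_row(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("word\tonset\toffset\nso\t12.10\t12.31\n")
        (t,) = cio.read_word_timings(p)
        assert (t.token, t.onset, t.offset) == ("so", 12.10, 12.31)

    def test_unordered_rows_reordered_with_warning(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("word\tonset\toffset\nb\t2.0\t2.2\na\t1.0\t1.2\n")
        with pytest.warns(UserWarning, match="reordered"):
            ts = cio.read_word_timings(p)
        assert [t.token for t in ts] == ["a", "b"]

    def test_offset_before_onset_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("word\tonset\toffset\nx\t12.1\t11.9\n")
        with pytest.raises(cio.FormatError, match="offset"):
            cio.read_word_timings(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("word\tonset\nx\t1.0\n")
        with pytest.raises(cio.FormatError, match="offset"):
            cio.read_word_timings(p)


# -- segmentation -----------------------------------------------------------

def _timing(token, onset, offset, sid=0, rid="r"):
    return cio.TokenTiming(token=token, onset=onset, offset=offset,
                           sentence_id=sid, recall_id=rid)


class TestSegmentation:
    def test_long_pause_inserts_boundary(self):
        # a 2.6 s silence after "because" starts a new sentence
        ts = [
            _timing("suspicious", 0.0, 0.5),
            _timing("because", 0.6, 1.0),
            _timing("they're", 3.6, 3.9),
        ]
        seg = cio.segment_sentences(ts, pause_threshold=1.0)
        assert [t.sentence_id for t in seg] == [0, 0, 1]

    def test_no_boundary_when_gaps_small(self):
        ts = [_timing(c, i * 0.4, i * 0.4 + 0.3) for i, c in enumerate("abcd")]
        seg = cio.segment_sentences(ts, pause_threshold=1.0)
        assert [t.sentence_id for t in seg] == [0, 0, 0, 0]

    def test_idempotent(self):
        ts = [
            _timing("a", 0.0, 0.2),
            _timing("b", 1.5, 1.7),
            _timing("c", 1.8, 2.0),
        ]
        once = cio.segment_sentences(ts, 1.0)
        twice = cio.segment_sentences(once, 1.0)
        assert [t.sentence_id for t in once] == [t.sentence_id for t in twice]

    def test_sentence_count_matches_bruteforce_gap_scan(self, rng):
        # independent oracle: 1 + number of gaps >= threshold
        for trial in range(20):
            r = np.random.default_rng(trial)
            gaps = r.uniform(0, 0.12, size=60)
            onsets = np.cumsum(0.2 + gaps)
            ts = [
                _timing(f"w{i}", float(o), float(o + 0.18))
                for i, o in enumerate(onsets)
            ]
            threshold = 0.05
            seg = cio.segment_sentences(ts, threshold)
            brute = 1 + sum(
                (ts[i].onset - ts[i - 1].offset) >= threshold
                for i in range(1, len(ts))
            )
            assert len({t.sentence_id for t in seg}) == brute

    def test_empty_input(self):
        assert cio.segment_sentences([], 1.0) == []


# -- ROI tables -------------------------------------------------------------

class TestROITables:
    def test_roundtrip_grouping(self, tmp_path, rng):
        series = [
            cio.ROITimeseries(f"p{i}", roi, rng.normal(size=100))
            for i in range(3)
            for roi in ("BA44", "BA45", "LpMTG")
        ]
        p = tmp_path / "bold.tsv"
        cio.write_roi_timeseries(series, p)
        back = cio.read_roi_timeseries(p)
        assert len(back) == 9
        assert all(s.n_scans == 100 for s in back)
        np.testing.assert_allclose(back[0].values, series[0].values)

    def test_duplicate_row_rejected(self, tmp_path):
        p = tmp_path / "bold.tsv"
        p.write_text(
            "participant\troi\ttr_index\tvalue\n"
            "p0\tBA44\t0\t1.0\np0\tBA44\t0\t2.0\n"
        )
        with pytest.raises(cio.IntegrityError, match="duplicate"):
            cio.read_roi_timeseries(p)

    def test_gap_in_tr_index_rejected(self, tmp_path):
        p = tmp_path / "bold.tsv"
        p.write_text(
            "participant\troi\ttr_index\tvalue\n"
            "p0\tBA44\t0\t1.0\np0\tBA44\t2\t2.0\n"
        )
        with pytest.raises(cio.IntegrityError, match="gap"):
            cio.read_roi_timeseries(p)

    def test_non_numeric_value_rejected(self, tmp_path):
        p = tmp_path / "bold.tsv"
        p.write_text(
            "participant\troi\ttr_index\tvalue\np0\tBA44\t0\thigh\n"
        )
        with pytest.raises(cio.FormatError, match="numeric"):
            cio.read_roi_timeseries(p)
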