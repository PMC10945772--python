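"""Readers, writers and segmentation for the pipeline's text formats.

The pipeline consumes four plain-text inputs: Penn-Treebank-style bracketed
constituent parses, CoNLL-U dependency parses, word-timing tables (TSV) and
ROI-averaged BOLD tables (TSV).  This module also performs the
disfluency-informed sentence segmentation used for spontaneous speech, where
a long silent pause starts a new planning unit (and hence a new parse).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised for malformed bracketed parse input."""


class FormatError(ValueError):
    """Raised for structurally invalid dependency / table input."""


class IntegrityError(ValueError):
    """Raised when a table violates a uniqueness or contiguity constraint."""


# ---------------------------------------------------------------------------
# Parse trees
# ---------------------------------------------------------------------------

@dataclass
class ParseTree:
    """Rooted, labeled, ordered constituent tree over a sentence's tokens.

    ``children`` holds ``ParseTree`` nodes and/or terminal tokens (plain
    strings).  ``span`` is the half-open terminal index range ``[i, j)``
    covered by the node; children's spans partition the parent's span in
    order.  ``is_preterminal`` marks part-of-speech-level wrappers in trees
    where every terminal is singly wrapped (see :func:`tag_preterminals`).
    """

    label: str
    children: list[Union["ParseTree", str]] = field(default_factory=list)
    span: tuple[int, int] = (0, 0)
    is_preterminal: bool = False

    # -- structure -----------------------------------------------------

    def terminals(self) -> list[str]:
        out: list[str] = []
        for c in self.children:
            if isinstance(c, ParseTree):
                out.extend(c.terminals())
            else:
                out.append(c)
        return out

    def nonterminals(self) -> Iterator["ParseTree"]:
        """Pre-order iterator over all nonterminal nodes (self included)."""
        yield self
        for c in self.children:
            if isinstance(c, ParseTree):
                yield from c.nonterminals()

    @property
    def n_terminals(self) -> int:
        return self.span[1] - self.span[0]

    def has_single_terminal_child(self) -> bool:
        return len(self.children) == 1 and isinstance(self.children[0], str)

    # -- serialisation -------------------------------------------------

    def to_bracketed(self) -> str:
        parts = [
            c.to_bracketed() if isinstance(c, ParseTree) else c
            for c in self.children
        ]
        return "(" + " ".join([self.label] + parts) + ")"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_bracketed()


def _assign_spans(node: ParseTree, start: int) -> int:
    pos = start
    for c in node.children:
        if isinstance(c, ParseTree):
            pos = _assign_spans(c, pos)
        else:
            pos += 1
    node.span = (start, pos)
    return pos


def tag_preterminals(tree: ParseTree) -> None:
    """Tag POS-level wrapper nodes in a fully POS-wrapped tree.

    A tree counts as POS-wrapped only when *every* terminal's immediate
    parent has exactly one child (the standard shape of constituency-parser
    output).  In such trees the wrappers are POS tags, not phrases, and are
    tagged ``is_preterminal``.  In mixed bracketings such as
    ``(S (NP Mary) (VP eats))`` where some terminal sits directly under a
    phrasal node, single-terminal-child nodes like the NP are genuine
    phrases and nothing is tagged.  The root is never tagged.
    """
    parents: list[ParseTree] = []

    def collect(node: ParseTree) -> bool:
        ok = True
        for c in node.children:
            if isinstance(c, ParseTree):
                ok = ok and collect(c)
            else:
                if node.has_single_terminal_child():
                    parents.append(node)
                else:
                    ok = False
        return ok

    fully_wrapped = collect(tree)
    if fully_wrapped:
        for p in parents:
            if p is not tree:
                p.is_preterminal = True


_PUNCT_DEFAULT: frozenset[str] = frozenset()


def strip_punctuation(tree: ParseTree, punct: Iterable[str]) -> ParseTree:
    """Remove punctuation terminals (and their wrappers), renumbering spans.

    ``punct`` is the set of terminal strings to drop.  A nonterminal left
    childless by the removal is dropped as well.  Default behaviour of the
    readers is to strip nothing: spontaneous-speech transcripts carry no
    punctuation.
    """
    punct = set(punct)

    def rebuild(node: ParseTree) -> ParseTree | None:
        kids: list[ParseTree | str] = []
        for c in node.children:
            if isinstance(c, ParseTree):
                sub = rebuild(c)
                if sub is not None:
                    kids.append(sub)
            elif c not in punct:
                kids.append(c)
        if not kids:
            return None
        return ParseTree(node.label, kids)

    out = rebuild(tree)
    if out is None:
        raise ParseError("stripping punctuation left an empty tree")
    _assign_spans(out, 0)
    tag_preterminals(out)
    return out


def _tokenize_sexpr(text: str) -> list[str]:
    return text.replace("(", " ( ").replace(")", " ) ").split()


def parse_bracketed(text: str, record: int = 1) -> ParseTree:
    """Parse a single balanced bracketing into a :class:`ParseTree`."""
    toks = _tokenize_sexpr(text)
    if not toks:
        raise ParseError(f"empty record {record}")

    pos = 0

    def parse_node() -> ParseTree:
        nonlocal pos
        if toks[pos] != "(":
            raise ParseError(f"expected '(' at record {record}")
        pos += 1
        if pos >= len(toks) or toks[pos] in "()":
            raise ParseError(f"missing node label at record {record}")
        node = ParseTree(toks[pos])
        pos += 1
        while pos < len(toks) and toks[pos] != ")":
            if toks[pos] == "(":
                node.children.append(parse_node())
            else:
                node.children.append(toks[pos])
                pos += 1
        if pos >= len(toks):
            raise ParseError(f"unbalanced brackets at record {record}")
        pos += 1  # consume ')'
        if not node.children:
            raise ParseError(f"childless node '{node.label}' at record {record}")
        return node

    tree = parse_node()
    if pos != len(toks):
        raise ParseError(f"unbalanced brackets at record {record}")
    _assign_spans(tree, 0)
    tag_preterminals(tree)
    return tree


def read_bracketed_trees(
    path: str | Path,
    punctuation: Iterable[str] = _PUNCT_DEFAULT,
) -> list[ParseTree]:
    """Read one bracketed parse per line (or per balanced block).

    Empty records are skipped with a warning; unbalanced records raise
    :class:`ParseError` naming the record number.
    """
    text = Path(path).read_text(encoding="utf-8")
    records: list[tuple[int, str]] = []
    buf: list[str] = []
    depth = 0
    rec = 0
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped and depth == 0:
            if buf:
                rec += 1
                records.append((rec, " ".join(buf)))
                buf = []
            continue
        depth += stripped.count("(") - stripped.count(")")
        buf.append(stripped)
        if depth == 0 and buf:
            rec += 1
            records.append((rec, " ".join(buf)))
            buf = []
        elif depth < 0:
            rec += 1
            raise ParseError(f"unbalanced brackets at record {rec}")
    if buf:
        rec += 1
        raise ParseError(f"unbalanced brackets at record {rec}")

    trees: list[ParseTree] = []
    for recno, chunk in records:
        if not chunk.strip():
            warnings.warn(f"record {recno} is empty; skipped")
            continue
        tree = parse_bracketed(chunk, record=recno)
        if punctuation:
            tree = strip_punctuation(tree, punctuation)
        trees.append(tree)
    return trees


def write_bracketed_trees(trees: Sequence[ParseTree], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(t.to_bracketed() for t in trees) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Dependency parses
# ---------------------------------------------------------------------------

@dataclass
class DependencyParse:
    """Per-token head indices for one sentence.

    ``head[i]`` is the 1-based index of token ``i``'s head, 0 for the root.
    Exactly one root is required and no token may head itself.
    """

    head: list[int]
    relation: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.head)
        if not self.relation:
            self.relation = [""] * n
        if sum(1 for h in self.head if h == 0) != 1:
            raise FormatError(
                f"dependency parse must have exactly one root, got heads {self.head}"
            )
        for i, h in enumerate(self.head):
            if h < 0 or h > n:
                raise FormatError(f"head index {h} out of range for {n} tokens")
            if h == i + 1:
                raise FormatError(f"token {i + 1} is its own head")

    @property
    def n_tokens(self) -> int:
        return len(self.head)

    def head_set(self) -> set[int]:
        """0-based indices of tokens with at least one dependent."""
        return {h - 1 for h in self.head if h > 0}


def read_dependency(path: str | Path) -> list[DependencyParse]:
    """Read CoNLL-U; uses columns 1 (ID), 7 (HEAD), 8 (DEPREL).

    Comment lines and multiword-token / empty-node IDs (``1-2``, ``1.1``)
    are ignored.  Sentence blocks with no token lines are skipped with a
    warning.
    """
    parses: list[DependencyParse] = []
    heads: list[int] = []
    rels: list[str] = []
    blocks = 0

    def flush() -> None:
        nonlocal heads, rels, blocks
        blocks += 1
        if heads:
            parses.append(DependencyParse(head=list(heads), relation=list(rels)))
        else:
            warnings.warn(f"empty sentence block {blocks}; skipped")
        heads, rels = [], []

    saw_any = False
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            if saw_any:
                flush()
                saw_any = False
            continue
        saw_any = True
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise FormatError(f"CoNLL-U line has {len(cols)} columns: {line!r}")
        tok_id = cols[0]
        if "-" in tok_id or "." in tok_id:
            continue
        heads.append(int(cols[6]))
        rels.append(cols[7])
    if saw_any:
        flush()
    return parses


def write_dependency(parses: Sequence[DependencyParse],
                     tokens: Sequence[Sequence[str]],
                     path: str | Path) -> None:
    """Write minimal 10-column CoNLL-U for the given sentences."""
    lines: list[str] = []
    for dep, toks in zip(parses, tokens):
        if dep.n_tokens != len(toks):
            raise FormatError("token count mismatch between parse and tokens")
        for i, (tok, h, rel) in enumerate(zip(toks, dep.head, dep.relation), 1):
            lines.append(
                "\t".join([str(i), tok, "_", "_", "_", "_", str(h), rel or "dep",
                           "_", "_"])
            )
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def align_tree_dependency(tree: ParseTree, dep: DependencyParse) -> None:
    if tree.n_terminals != dep.n_tokens:
        raise FormatError(
            f"alignment error: tree has {tree.n_terminals} terminals but "
            f"dependency parse has {dep.n_tokens} tokens"
        )


# ---------------------------------------------------------------------------
# Word timings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TokenTiming:
    """One spoken word with onset/offset (seconds) inside a recall."""

    token: str
    onset: float
    offset: float
    sentence_id: int = 0
    recall_id: str = ""

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise FormatError(
                f"offset {self.offset} < onset {self.onset} for token "
                f"{self.token!r}"
            )
        if self.onset < 0:
            raise FormatError(f"negative onset for token {self.token!r}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def read_word_timings(path: str | Path) -> list[TokenTiming]:
    """Read a TSV with columns word/onset/offset (+ optional sentence_id,
    recall_id); rows are ordered by onset within each recall."""
    df = pd.read_csv(path, sep="\t")
    required = {"word", "onset", "offset"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"timing table missing columns: {sorted(missing)}")
    for col in ("onset", "offset"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"column {col!r} is not numeric")
    if "recall_id" not in df.columns:
        df["recall_id"] = ""
    if "sentence_id" not in df.columns:
        df["sentence_id"] = 0
    bad = df[df["offset"] < df["onset"]]
    if len(bad):
        raise FormatError(
            f"offset < onset in rows {bad.index.tolist()}"
        )
    out: list[TokenTiming] = []
    for rid, grp in df.groupby("recall_id", sort=False):
        if not grp["onset"].is_monotonic_increasing:
            warnings.warn(f"rows of recall {rid!r} reordered by onset")
            grp = grp.sort_values("onset", kind="stable")
        for row in grp.itertuples(index=False):
            out.append(TokenTiming(token=str(row.word), onset=float(row.onset),
                                   offset=float(row.offset),
                                   sentence_id=int(row.sentence_id),
                                   recall_id=str(rid)))
    return out


def write_word_timings(timings: Sequence[TokenTiming], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "word": [t.token for t in timings],
            "onset": [t.onset for t in timings],
            "offset": [t.offset for t in timings],
            "sentence_id": [t.sentence_id for t in timings],
            "recall_id": [t.recall_id for t in timings],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def segment_sentences(
    timings: Sequence[TokenTiming], pause_threshold: float = 1.0
) -> list[TokenTiming]:
    """Disfluency-informed segmentation: a silent gap of at least
    ``pause_threshold`` seconds before a word starts a new sentence.

    Existing sentence boundaries are preserved; the returned list carries
    consecutive ``sentence_id`` values from 0 (per full input, recalls are
    kept separate).  Idempotent at a fixed threshold.
    """
    if pause_threshold <= 0:
        raise ValueError("pause_threshold must be > 0")
    if not timings:
        return []
    out: list[TokenTiming] = []
    sid = -1
    prev: TokenTiming | None = None
    for t in timings:
        new_sentence = (
            prev is None
            or t.recall_id != prev.recall_id
            or t.sentence_id != prev.sentence_id
            or (t.onset - prev.offset) >= pause_threshold
        )
        if new_sentence:
            sid += 1
        out.append(replace(t, sentence_id=sid))
        prev = t
    return out


# ---------------------------------------------------------------------------
# ROI BOLD tables
# ---------------------------------------------------------------------------

@dataclass
class ROITimeseries:
    """ROI-averaged BOLD series for one participant and ROI."""

    participant: str
    roi: str
    values: np.ndarray
    tr: float = 1.5

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_scans(self) -> int:
        return len(self.values)


def read_roi_timeseries(path: str | Path, tr: float = 1.5) -> list[ROITimeseries]:
    """Read a long TSV (participant, roi, tr_index, value) into per-series
    arrays; requires unique and contiguous tr_index per (participant, roi)."""
    df = pd.read_csv(path, sep="\t")
    required = {"participant", "roi", "tr_index", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"BOLD table missing columns: {sorted(missing)}")
    if not np.issubdtype(df["value"].dtype, np.number):
        raise FormatError("column 'value' is not numeric")
    out: list[ROITimeseries] = []
    for (p, r), grp in df.groupby(["participant", "roi"], sort=False):
        idx = grp["tr_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            dup = int(idx[pd.Series(idx).duplicated()][0])
            raise IntegrityError(
                f"duplicate (participant={p}, roi={r}, tr_index={dup})"
            )
        order = np.argsort(idx)
        idx = idx[order]
        if not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
            raise IntegrityError(
                f"gap in tr_index for (participant={p}, roi={r})"
            )
        vals = grp["value"].to_numpy()[order]
        out.append(ROITimeseries(str(p), str(r), vals, tr=tr))
    return out


def write_roi_timeseries(series: Sequence[ROITimeseries], path: str | Path) -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "participant": s.participant,
                    "roi": s.roi,
                    "tr_index": np.arange(s.n_scans),
                    "value": s.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
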