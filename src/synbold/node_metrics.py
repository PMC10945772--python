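"""Word-by-word incremental syntactic complexity metrics.

Each metric assigns to every word of a sentence the number of phrase-structure
nodes hypothesised to be *built* at that word, under a given parsing strategy:

- ``top_down``      — nodes counted when a phrase is opened (anticipatory);
- ``bottom_up``     — nodes counted when a phrase is closed, i.e. once all of
  its daughters have been met (integratory);
- ``left_corner``   — nodes announced once their leftmost daughter completes;
- ``open_nodes``    — nodes opened but not yet closed at the word: an index of
  working-memory load;
- ``early_top_down``— production-specific: each word's top-down nodes are
  attributed to the previous word (structure built before articulation);
- ``chunked``       — production-specific head-driven counting: all nodes of a
  dependency-head-delimited chunk are assigned to the chunk-initial word;
  non-head, non-initial words carry zero.

All strategies distribute the same total node count across the words of a
sentence; they differ only in the hypothesised *timing* of the operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import DependencyParse, ParseTree, align_tree_dependency

STRATEGIES = (
    "top_down",
    "bottom_up",
    "left_corner",
    "open_nodes",
    "early_top_down",
    "chunked",
)


@dataclass(frozen=True)
class NodeCountVector:
    """Per-word node counts for one sentence under one strategy."""

    values: np.ndarray
    strategy: str
    count_preterminals: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=int)
        )
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if (self.values < 0).any():
            raise ValueError("node counts must be non-negative")

    @property
    def n(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def countable_nodes(
    tree: ParseTree, count_preterminals: bool = False
) -> list[tuple[ParseTree, tuple[int, int]]]:
    """Enumerate the nodes that metrics count, with their terminal spans.

    Every nonterminal is listed once.  POS-level preterminal wrappers (tagged
    at read time in fully POS-wrapped trees) are included only when
    ``count_preterminals`` is set.  The root always counts, including in the
    degenerate single-terminal tree where it is itself preterminal-shaped.
    """
    out = []
    for node in tree.nonterminals():
        if node.is_preterminal and not count_preterminals and node is not tree:
            continue
        out.append((node, node.span))
    return out


def _first_daughter_end(node: ParseTree) -> int:
    """Index of the terminal at which the node's first daughter completes."""
    first = node.children[0]
    if isinstance(first, ParseTree):
        return first.span[1] - 1
    return node.span[0]


def top_down_counts(
    tree: ParseTree, count_preterminals: bool = False
) -> NodeCountVector:
    """Nodes opened at each word: a node is counted at its leftmost terminal.

    Anticipatory: in "Mary eats apples daily", the VP that will dominate
    "daily" is already counted at "eats"."""
    values = np.zeros(tree.n_terminals, dtype=int)

    def walk(node: ParseTree, start: int) -> None:
        if count_preterminals or not node.is_preterminal or node is tree:
            values[start] += 1
        pos = start
        for c in node.children:
            if isinstance(c, ParseTree):
                walk(c, pos)
                pos = c.span[1]
            else:
                pos += 1

    walk(tree, 0)
    return NodeCountVector(values, "top_down", count_preterminals)


def bottom_up_counts(
    tree: ParseTree, count_preterminals: bool = False
) -> NodeCountVector:
    """Nodes closed at each word: a node is counted at its rightmost terminal,
    once all of its daughters have been met."""
    values = np.zeros(tree.n_terminals, dtype=int)

    def walk(node: ParseTree) -> None:
        if count_preterminals or not node.is_preterminal or node is tree:
            values[node.span[1] - 1] += 1
        for c in node.children:
            if isinstance(c, ParseTree):
                walk(c)

    walk(tree)
    return NodeCountVector(values, "bottom_up", count_preterminals)


def left_corner_counts(
    tree: ParseTree, count_preterminals: bool = False
) -> NodeCountVector:
    """Nodes announced when their leftmost daughter is complete.

    A node whose first daughter is a terminal is announced at that terminal.
    Intermediate between top-down (announce at opening) and bottom-up
    (announce at closing)."""
    values = np.zeros(tree.n_terminals, dtype=int)

    def walk(node: ParseTree) -> None:
        if count_preterminals or not node.is_preterminal or node is tree:
            values[_first_daughter_end(node)] += 1
        for c in node.children:
            if isinstance(c, ParseTree):
                walk(c)

    walk(tree)
    return NodeCountVector(values, "left_corner", count_preterminals)


def open_node_counts(
    tree: ParseTree,
    count_preterminals: bool = False,
    open_timing: str = "after",
) -> NodeCountVector:
    """Nodes opened but not yet closed at each word (working-memory load).

    ``open(w) = cumsum(top_down)(w) - cumsum(bottom_up)(w)``, measured after
    the closures at word ``w`` (default), so the final word of a complete
    sentence carries 0.  ``open_timing='before'`` measures the load as the
    word is presented, before its closures."""
    td = top_down_counts(tree, count_preterminals).values
    bu = bottom_up_counts(tree, count_preterminals).values
    if open_timing == "after":
        values = np.cumsum(td) - np.cumsum(bu)
    elif open_timing == "before":
        values = np.cumsum(td) - np.concatenate([[0], np.cumsum(bu)[:-1]])
    else:
        raise ValueError("open_timing must be 'after' or 'before'")
    return NodeCountVector(values, "open_nodes", count_preterminals)


def early_top_down_counts(
    tree: ParseTree, count_preterminals: bool = False
) -> NodeCountVector:
    """Production-specific shift of the top-down counts one word earlier.

    The nodes associated with word ``w+1`` are counted while word ``w`` is
    being articulated; the first word absorbs its own nodes as well as the
    second word's (rather than positing pre-sentence events).  A single-word
    sentence reduces to the plain top-down counts."""
    td = top_down_counts(tree, count_preterminals).values
    n = len(td)
    if n == 1:
        return NodeCountVector(td, "early_top_down", count_preterminals)
    values = np.zeros(n, dtype=int)
    values[0] = td[0] + td[1]
    values[1:-1] = td[2:]
    return NodeCountVector(values, "early_top_down", count_preterminals)


def chunked_counts(
    tree: ParseTree,
    dep: DependencyParse,
    count_preterminals: bool = False,
) -> NodeCountVector:
    """Head-driven chunked counting over dependency-head-delimited spans.

    Heads are the words with at least one dependent.  All top-down nodes from
    the first word up to and including the first head are assigned to the
    first word; nodes from there up to and including the next head are
    assigned to the previous head, and so on.  Nodes after the last head are
    assigned to the last head, preserving the total node count.  Non-head,
    non-initial words (e.g. sentence-final words) carry zero."""
    align_tree_dependency(tree, dep)
    td = top_down_counts(tree, count_preterminals).values
    n = len(td)
    heads = sorted(dep.head_set())
    values = np.zeros(n, dtype=int)
    if not heads:
        values[0] = td.sum()
        return NodeCountVector(values, "chunked", count_preterminals)
    h1 = heads[0]
    values[0] = td[: h1 + 1].sum()
    for k, h in enumerate(heads):
        nxt = heads[k + 1] if k + 1 < len(heads) else None
        if nxt is not None:
            values[h] += td[h + 1: nxt + 1].sum()
        else:
            values[h] += td[h + 1:].sum()
    return NodeCountVector(values, "chunked", count_preterminals)


def span_oracle(
    tree: ParseTree, strategy: str, count_preterminals: bool = False
) -> NodeCountVector:
    """Brute-force span-attribution reference for the three parsing metrics.

    Enumerates every countable node and attributes it by direct span
    inspection — no incremental traversal — so it serves as an independent
    check on the traversal implementations."""
    if strategy not in {"top_down", "bottom_up", "left_corner"}:
        raise ValueError(f"span_oracle does not cover strategy {strategy!r}")
    values = np.zeros(tree.n_terminals, dtype=int)
    for node, (i, j) in countable_nodes(tree, count_preterminals):
        if strategy == "top_down":
            values[i] += 1
        elif strategy == "bottom_up":
            values[j - 1] += 1
        else:
            first = node.children[0]
            w = first.span[1] - 1 if isinstance(first, ParseTree) else i
            values[w] += 1
    return NodeCountVector(values, strategy, count_preterminals)


def all_metrics(
    tree: ParseTree,
    dep: DependencyParse | None = None,
    count_preterminals: bool = False,
) -> dict[str, np.ndarray]:
    """All per-word metrics for one sentence, keyed by strategy name.

    ``chunked`` requires a dependency parse and is omitted when none is
    given."""
    out = {
        "top_down": top_down_counts(tree, count_preterminals).values,
        "bottom_up": bottom_up_counts(tree, count_preterminals).values,
        "left_corner": left_corner_counts(tree, count_preterminals).values,
        "open_nodes": open_node_counts(tree, count_preterminals).values,
        "early_top_down": early_top_down_counts(tree, count_preterminals).values,
    }
    if dep is not None:
        out["chunked"] = chunked_counts(tree, dep, count_preterminals).values
    return out
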