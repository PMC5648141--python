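"""Literature mining: from publication records to the prior-knowledge matrix.

A *functional gene group* (typically one box of a KEGG pathway diagram) is a
named set of gene symbols and aliases treated as a single network node.  A
publication "mentions" a group if any member term occurs in its title or
abstract under strict delimiter rules, and a publication enters the
prior-knowledge matrix only if it mentions at least two distinct groups —
co-occurrence being the evidence of a potential interaction.

Term matching is deliberately rudimentary (no tokenization, no NLP): a member
term matches where it is delimited at its start by text-begin, space,
parenthesis, bracket, or dash, and at its end additionally by period, comma,
colon, or semicolon.  Commas and periods are *not* valid start delimiters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "AbstractRecord",
    "GeneGroup",
    "PriorKnowledgeMatrix",
    "match_term",
    "count_term",
    "rank_members",
    "build_prior_matrix",
]

# Delimiters allowed on both sides of a term; '.' ',' ':' ';' only at the end.
_BOTH = " ()[]-"
_END_ONLY = ".,:;"

_START_CLASS = "[" + re.escape(_BOTH) + "]"
_END_CLASS = "[" + re.escape(_BOTH + _END_ONLY) + "]"


def _term_pattern(term: str, case_insensitive: bool) -> re.Pattern:
    if not term:
        raise ValueError("search term must be non-empty")
    # Lookarounds keep delimiters unconsumed so adjacent occurrences and
    # occurrence counting behave; the term itself is matched literally.
    pat = (
        rf"(?:(?<={_START_CLASS})|^)"
        + re.escape(term)
        + rf"(?={_END_CLASS}|$)"
    )
    return re.compile(pat, re.IGNORECASE if case_insensitive else 0)


def match_term(term: str, text: str, case_insensitive: bool = True) -> bool:
    """True iff ``term`` occurs in ``text`` with valid boundary delimiters.

    Regex metacharacters in ``term`` are treated literally.  Raises
    ``ValueError`` for an empty term; an empty text simply yields False.
    """
    return _term_pattern(term, case_insensitive).search(text) is not None


def count_term(term: str, text: str, case_insensitive: bool = True) -> int:
    """Number of delimiter-valid, non-overlapping occurrences of ``term``."""
    return sum(1 for _ in _term_pattern(term, case_insensitive).finditer(text))


@dataclass(frozen=True)
class AbstractRecord:
    """One publication: identifier plus title/abstract free text."""

    pub_id: str
    title: str
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.pub_id:
            raise ValueError("pub_id must be non-empty")

    @property
    def text(self) -> str:
        """Title and abstract joined by a single space, the search target."""
        return f"{self.title} {self.abstract}"


@dataclass(frozen=True)
class GeneGroup:
    """A named gene group with an ordered member (symbol/alias) list."""

    name: str
    members: tuple[str, ...]
    node_index: int = 0

    def __init__(self, name: str, members: Sequence[str], node_index: int = 0):
        if not members:
            raise ValueError(f"group {name!r} has no members")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", tuple(members))
        object.__setattr__(self, "node_index", node_index)

    def mentioned_in(self, text: str, case_insensitive: bool = True) -> bool:
        return any(match_term(m, text, case_insensitive) for m in self.members)


@dataclass
class PriorKnowledgeMatrix:
    """Binary publications x gene-groups matrix, the evidence for learning.

    Every retained row has at least two ones: a publication must co-mention
    two distinct groups to count as (weak) interaction evidence.
    """

    row_ids: list[str]
    group_names: list[str]
    values: np.ndarray  # shape (n_pubs, n_groups), dtype int8, entries {0,1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.group_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.group_names)} groups"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at row {self.row_ids[r]!r}, "
                f"column {self.group_names[c]!r}"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_groups(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, indices: Sequence[int] | np.ndarray) -> "PriorKnowledgeMatrix":
        idx = np.asarray(indices, dtype=int)
        return PriorKnowledgeMatrix(
            row_ids=[self.row_ids[i] for i in idx],
            group_names=list(self.group_names),
            values=self.values[idx],
        )


def rank_members(
    group: GeneGroup,
    corpus: Sequence[AbstractRecord],
    top_k: int,
    case_insensitive: bool = True,
    by: Literal["documents", "occurrences"] = "documents",
) -> GeneGroup:
    """Restrict ``group`` to its ``top_k`` most commonly observed members.

    Frequency is the number of corpus records whose title or abstract
    contains the member (``by="documents"``, the default) or the total
    occurrence count across the corpus (``by="occurrences"``).  Ties keep
    the original member order, so the result is deterministic.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if by not in ("documents", "occurrences"):
        raise ValueError(f"unknown ranking mode {by!r}")

    def freq(member: str) -> int:
        if by == "documents":
            return sum(
                match_term(member, rec.text, case_insensitive) for rec in corpus
            )
        return sum(count_term(member, rec.text, case_insensitive) for rec in corpus)

    scored = [(member, freq(member)) for member in group.members]
    # stable sort: descending frequency, original order breaks ties
    ranked = sorted(scored, key=lambda mf: -mf[1])
    return replace(group, members=tuple(m for m, _ in ranked[:top_k]))


def build_prior_matrix(
    corpus: Sequence[AbstractRecord],
    groups: Sequence[GeneGroup],
    case_insensitive: bool = True,
) -> PriorKnowledgeMatrix:
    """Build the binary prior-knowledge matrix from a corpus.

    A record is retained iff members of at least two *distinct* groups match
    its title or abstract; cell (record, group) is 1 iff any member of the
    group matches.  Row order follows corpus order; column order follows the
    order of ``groups``.
    """
    if len(groups) < 2:
        raise ValueError("at least two gene groups are required")
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names")
    seen_ids: set[str] = set()
    rows: list[np.ndarray] = []
    row_ids: list[str] = []
    for rec in corpus:
        if rec.pub_id in seen_ids:
            raise ValueError(f"duplicate pub_id {rec.pub_id!r}")
        seen_ids.add(rec.pub_id)
        presence = np.fromiter(
            (g.mentioned_in(rec.text, case_insensitive) for g in groups),
            dtype=np.int8,
            count=len(groups),
        )
        if int(presence.sum()) >= 2:
            rows.append(presence)
            row_ids.append(rec.pub_id)
    values = (
        np.vstack(rows) if rows else np.zeros((0, len(groups)), dtype=np.int8)
    )
    return PriorKnowledgeMatrix(row_ids=row_ids, group_names=names, values=values)
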