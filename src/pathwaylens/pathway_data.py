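"""Core domain types for pathway membership and per-sample expressed ortholog groups.

A pathway is modelled as a set of ortholog groups (KEGG KO identifiers such
as ``K00001`` or Enzyme Commission numbers such as ``1.1.1.1``).  A family of
pathways over a shared ortholog-group universe is a :class:`PathwayCollection`,
which maintains a reverse index from each group to the pathways containing it.
Per-sample expression is binary: an ortholog group either has RNA-Seq evidence
in a sample or it does not (:class:`SampleExpression`).

KO and EC identifiers are accepted side by side but never translated into one
another; translation would require an external database and is out of scope.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "PathwayDefinition",
    "PathwayCollection",
    "SampleExpression",
    "MembershipParseError",
    "normalize_group_id",
    "read_pathway_membership",
    "write_pathway_membership",
    "read_expressed_set",
    "restrict_to_sample",
    "filter_min_mapped",
]

_KO_RE = re.compile(r"^K\d+$", re.IGNORECASE)
_PATHWAY_ID_RE = re.compile(r"^ko\d{5}$")


class MembershipParseError(ValueError):
    """Raised on a malformed membership or expressed-set line."""


def normalize_group_id(raw: str) -> str:
    """Normalize an ortholog-group identifier.

    KO identifiers are upper-cased (``k00001`` -> ``K00001``); dotted EC
    numbers pass through unchanged.  Comparison everywhere downstream is
    exact string equality.
    """
    gid = raw.strip()
    if not gid:
        raise ValueError("empty ortholog group identifier")
    if _KO_RE.match(gid):
        return gid.upper()
    return gid


@dataclass(frozen=True)
class PathwayDefinition:
    """One pathway: an identifier plus its set of member ortholog groups."""

    pathway_id: str
    members: frozenset[str]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")


@dataclass
class PathwayCollection:
    """A family of pathways with a group -> pathways reverse index.

    The reverse index is rebuilt from the membership on construction so the
    inversion invariant (g in members(w) iff w in group_index[g]) holds by
    derivation, never by bookkeeping.
    """

    pathways: dict[str, PathwayDefinition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._group_index: dict[str, frozenset[str]] = {}
        index: dict[str, set[str]] = {}
        for pid, pw in self.pathways.items():
            if pid != pw.pathway_id:
                raise ValueError(f"key {pid!r} != pathway_id {pw.pathway_id!r}")
            for g in pw.members:
                index.setdefault(g, set()).add(pid)
        self._group_index = {g: frozenset(ps) for g, ps in index.items()}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PathwayCollection":
        """Build a collection from (pathway_id, group_id) pairs, collapsing duplicates."""
        members: dict[str, set[str]] = {}
        for pid, gid in pairs:
            members.setdefault(pid, set()).add(normalize_group_id(gid))
        return cls(
            {pid: PathwayDefinition(pid, frozenset(ms)) for pid, ms in members.items()}
        )

    @property
    def group_index(self) -> Mapping[str, frozenset[str]]:
        return self._group_index

    @property
    def all_groups(self) -> frozenset[str]:
        return frozenset(self._group_index)

    def __len__(self) -> int:
        return len(self.pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.pathways

    def __getitem__(self, pathway_id: str) -> PathwayDefinition:
        return self.pathways[pathway_id]

    def __iter__(self):
        return iter(self.pathways.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCollection):
            return NotImplemented
        return self.pathways == other.pathways


@dataclass(frozen=True)
class SampleExpression:
    """The binary expressed ortholog-group set of one sample.

    ``expressed`` may be empty (a degenerate sample with no annotated
    transcripts); membership tests are O(1) set lookups.
    """

    sample_id: str
    expressed: frozenset[str]


def read_pathway_membership(path: str | os.PathLike) -> PathwayCollection:
    """Read a two-column TSV ``pathway_id <TAB> group_id`` into a collection.

    Lines beginning with ``#`` and blank lines are ignored.  Duplicate
    (pathway, group) pairs collapse.  An empty file yields a valid empty
    collection.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise MembershipParseError(
                    f"{path}: line {lineno}: expected 'pathway<TAB>group', got {line!r}"
                )
            pairs.append((parts[0].strip(), parts[1].strip()))
    return PathwayCollection.from_pairs(pairs)


def write_pathway_membership(
    collection: PathwayCollection, path: str | os.PathLike
) -> None:
    """Write a collection back to the two-column TSV dialect (sorted, stable)."""
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(collection.pathways):
            for gid in sorted(collection[pid].members):
                fh.write(f"{pid}\t{gid}\n")


def read_expressed_set(
    path: str | os.PathLike, sample_id: str | None = None
) -> SampleExpression:
    """Read an expressed-set file into a :class:`SampleExpression`.

    Accepts either one group id per line, or a two-column TSV
    ``contig_id <TAB> group_id`` (column 2 is collected).  Duplicates are
    deduplicated; ``sample_id`` defaults to the file basename without
    extension.
    """
    expressed: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            gid = parts[1] if len(parts) >= 2 else parts[0]
            expressed.add(normalize_group_id(gid))
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return SampleExpression(sample_id=sample_id, expressed=frozenset(expressed))


def restrict_to_sample(
    collection: PathwayCollection, sample: SampleExpression
) -> PathwayCollection:
    """Intersect each pathway's members with the sample's expressed set.

    Pathways left with no expressed member are dropped; the reverse index is
    rebuilt.  Idempotent.
    """
    kept: dict[str, PathwayDefinition] = {}
    for pw in collection:
        inter = pw.members & sample.expressed
        if inter:
            kept[pw.pathway_id] = PathwayDefinition(pw.pathway_id, inter, pw.name)
    return PathwayCollection(kept)


def filter_min_mapped(
    collection: PathwayCollection, min_groups: int = 3
) -> PathwayCollection:
    """Keep only pathways with at least ``min_groups`` member groups.

    The default of 3 matches the exclusion rule applied on the graph branch:
    pathways with fewer than 3 mapped ortholog groups carry too little signal
    for the topology tests.
    """
    if min_groups < 0:
        raise ValueError("min_groups must be >= 0")
    kept = {
        pw.pathway_id: pw for pw in collection if len(pw.members) >= min_groups
    }
    return PathwayCollection(kept)
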