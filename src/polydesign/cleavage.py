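"""Proteasomal / immunoproteasomal cleavage-site ranking.

Cleavage efficiency at a scissile bond is expressed on an 11-level rank
scale: 1 = most efficient, 11 = least efficient.  A model is a list of
degenerate sequence patterns over a fixed context window around the bond
(default 4 residues upstream, P4-P1, and 2 downstream, P1'-P2'), each mapped
to a rank, plus a default rank for unmatched contexts.  The proteasome and
the cytokine-inducible immunoproteasome get independent tables since their
cleavage specificities differ.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .core import AMINO_ACIDS, InputError, validate_sequence

RANK_MIN, RANK_MAX = 1, 11

#: Padding character used when the context window extends past a terminus;
#: it matches only unconstrained (wildcard) pattern slots.
_PAD = "-"

_SLOT_TOKEN = re.compile(r"\[([A-Za-z]+)\]|([A-Za-z.])")


@dataclass(frozen=True)
class CleavagePattern:
    """One degenerate context pattern: per-slot residue sets (None = wildcard)."""

    slots: tuple[Optional[frozenset[str]], ...]
    rank: int
    raw: str

    @property
    def specificity(self) -> int:
        return sum(1 for s in self.slots if s is not None)

    def matches(self, context: str) -> bool:
        return all(s is None or ch in s for s, ch in zip(self.slots, context))


def _parse_pattern(raw: str, width: int, rank: int, where: str) -> CleavagePattern:
    slots: list[Optional[frozenset[str]]] = []
    pos = 0
    while pos < len(raw):
        m = _SLOT_TOKEN.match(raw, pos)
        if m is None:
            raise InputError(f"{where}: cannot parse pattern {raw!r} at character {pos + 1}")
        if m.group(1):
            residues = validate_sequence(m.group(1), where=where)
            slots.append(frozenset(residues))
        elif m.group(2) == ".":
            slots.append(None)
        else:
            slots.append(frozenset(validate_sequence(m.group(2), where=where)))
        pos = m.end()
    if len(slots) != width:
        raise InputError(f"{where}: pattern {raw!r} has {len(slots)} slots, window needs {width}")
    return CleavagePattern(slots=tuple(slots), rank=rank, raw=raw)


@dataclass(frozen=True)
class CleavageModel:
    """A ranked cleavage-specificity table for one proteasome form.

    Matching is deterministic: the most specific pattern (most constrained
    slots) wins; ties are broken by file order; an unmatched context gets
    ``default_rank``.
    """

    kind: str  # "proteasome" | "immunoproteasome"
    upstream: int = 4
    downstream: int = 2
    patterns: tuple[CleavagePattern, ...] = ()
    default_rank: int = 6

    def __post_init__(self) -> None:
        if self.kind not in ("proteasome", "immunoproteasome"):
            raise ValueError(f"unknown cleavage model kind {self.kind!r}")
        if self.upstream < 1 or self.downstream < 1:
            raise ValueError("cleavage window needs >= 1 residue on each side of the bond")
        for p in list(self.patterns) + []:
            if not RANK_MIN <= p.rank <= RANK_MAX:
                raise ValueError(f"pattern {p.raw!r}: rank {p.rank} outside {RANK_MIN}..{RANK_MAX}")
        if not RANK_MIN <= self.default_rank <= RANK_MAX:
            raise ValueError(f"default rank {self.default_rank} outside {RANK_MIN}..{RANK_MAX}")

    @property
    def width(self) -> int:
        return self.upstream + self.downstream

    @classmethod
    def from_file(cls, path: str | Path) -> "CleavageModel":
        """Read a cleavage table: headers ``#kind``, ``#window``, ``#default``;
        body lines ``pattern<TAB>rank``."""
        path = Path(path)
        kind = window = default = None
        body: list[tuple[int, str]] = []
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.rstrip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                key, val = key.strip().lower(), val.strip()
                if key == "kind":
                    kind = val
                elif key == "window":
                    window = tuple(int(x) for x in val.replace(",", " ").split())
                elif key == "default":
                    default = int(val)
                continue
            body.append((lineno, line))
        if kind is None or window is None or default is None:
            raise InputError(f"{path}: required headers #kind, #window, #default")
        up, down = window
        patterns = []
        for lineno, line in body:
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 'pattern<TAB>rank'")
            try:
                rank = int(parts[1])
            except ValueError:
                raise InputError(f"{path}:{lineno}: rank {parts[1]!r} is not an integer") from None
            patterns.append(_parse_pattern(parts[0].strip(), up + down, rank, f"{path}:{lineno}"))
        return cls(kind=kind, upstream=up, downstream=down,
                   patterns=tuple(patterns), default_rank=default)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#kind: {self.kind}\n")
            fh.write(f"#window: {self.upstream},{self.downstream}\n")
            fh.write(f"#default: {self.default_rank}\n")
            for p in self.patterns:
                fh.write(f"{p.raw}\t{p.rank}\n")


@dataclass(frozen=True)
class CleavageSiteRank:
    """Cleavage ranks at one scissile bond (after 1-based ``position``)."""

    position: int
    rank_pr: int
    rank_impr: int

    def __post_init__(self) -> None:
        for r in (self.rank_pr, self.rank_impr):
            if not RANK_MIN <= r <= RANK_MAX:
                raise ValueError(f"rank {r} outside {RANK_MIN}..{RANK_MAX}")


def _context(sequence: str, position: int, model: CleavageModel) -> str:
    # Window around the bond after residue `position` (1-based): P_up..P1 | P1'..P_down'.
    chars = []
    for i in range(position - model.upstream + 1, position + model.downstream + 1):
        chars.append(sequence[i - 1] if 1 <= i <= len(sequence) else _PAD)
    return "".join(chars)


def rank_cleavage(sequence: str, position: int, model: CleavageModel) -> int:
    """Rank (1-11) of cleavage after the residue at 1-based ``position``.

    Requires at least one residue on each side of the bond; asking for a
    terminal "cleavage" is an error.
    """
    if not 1 <= position < len(sequence):
        raise ValueError(
            f"position {position} leaves no residue on one side of the bond "
            f"(sequence length {len(sequence)})"
        )
    context = _context(sequence, position, model)
    best: Optional[CleavagePattern] = None
    for p in model.patterns:  # file order; strict > keeps the first of equal specificity
        if p.matches(context):
            if best is None or p.specificity > best.specificity:
                best = p
    return best.rank if best is not None else model.default_rank


def rank_epitope_cterm(
    pep1: str,
    ss: str,
    pep2_context: str,
    model_pr: CleavageModel,
    model_impr: CleavageModel,
) -> CleavageSiteRank:
    """Rank the bond at pep1's C-terminus inside ``pep1 + ss + pep2_context``.

    This is the liberation-relevant site for the first epitope of a pair:
    the spacer (and, for a direct junction, the start of the next flanked
    peptide) supplies the downstream context.
    """
    if not pep1:
        raise ValueError("pep1 must be non-empty")
    full = pep1 + ss + pep2_context
    pos = len(pep1)
    return CleavageSiteRank(
        position=pos,
        rank_pr=rank_cleavage(full, pos, model_pr),
        rank_impr=rank_cleavage(full, pos, model_impr),
    )
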