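"""Minimal epitope subsets covering an HLA repertoire with redundancy.

Choosing which epitopes enter a construct is a set-multicover problem: every
allele of the requested repertoire should be bound ("covered") by at least
``r`` selected epitopes.  The classical greedy heuristic is used — pick the
epitope covering the most still-uncovered demand, ties broken by the summed
genotypic frequency of the alleles whose coverage it advances, then by id —
and small instances can be checked against exhaustive subset search in
tests.  An infeasible repertoire yields a partial solution flagged
``complete=False`` rather than an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .core import AlleleFrequencyTable, InputError
from .mhc import MhcPssm, binding_rank, predict_pic50

logger = logging.getLogger("polydesign")


@dataclass(frozen=True)
class CoverageSolution:
    """Selected epitope ids plus per-allele coverage bookkeeping."""

    selected: tuple[str, ...]
    per_allele_cover: dict[str, int]
    redundancy: int
    complete: bool


def select_minimal_set(
    binding: Mapping[str, set[str]],
    repertoire: Sequence[str],
    r: int = 1,
    freqs: Optional[AlleleFrequencyTable] = None,
) -> CoverageSolution:
    """Greedy set-multicover of ``repertoire`` (each allele covered >= r times).

    ``binding`` maps epitope id -> set of alleles it binds.  Iteration stops
    when every requested allele is covered ``r`` times or no remaining
    epitope adds coverage; ``complete`` records which.
    """
    if r < 1:
        raise ValueError("redundancy r must be >= 1")
    freqs = freqs or AlleleFrequencyTable()
    requested = list(dict.fromkeys(repertoire))
    covered = {a: 0 for a in requested}
    remaining = dict(binding)
    selected: list[str] = []
    while any(c < r for c in covered.values()) and remaining:
        def gain_key(eid: str) -> tuple:
            news = [a for a in remaining[eid] if a in covered and covered[a] < r]
            gain = len(news)
            freq_sum = sum(freqs.get(a) for a in news)
            # max gain, then max freq of newly covered alleles, then smallest id
            return (-gain, -freq_sum, eid)

        best = min(remaining, key=gain_key)
        best_gain = -gain_key(best)[0]
        if best_gain == 0:
            break
        selected.append(best)
        for a in remaining[best]:
            if a in covered:
                covered[a] += 1
        del remaining[best]
    return CoverageSolution(
        selected=tuple(selected),
        per_allele_cover=covered,
        redundancy=r,
        complete=all(c >= r for c in covered.values()),
    )


def read_binding_map(path: str | Path) -> dict[str, set[str]]:
    """Read ``epitope<TAB>allele`` pairs into a binding map (header optional)."""
    path = Path(path)
    binding: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputError(f"{path}:{lineno}: expected 'epitope<TAB>allele'")
        if lineno == 1 and parts[0].lower() in ("epitope", "id"):
            continue
        binding.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    if not binding:
        raise InputError(f"{path}: no binding pairs found")
    return binding


def binding_from_panel(
    epitopes: Mapping[str, str],
    panel: Sequence[MhcPssm],
    min_rank: int = 1,
) -> dict[str, set[str]]:
    """Derive a binding map from PSSM predictions: epitope id -> alleles whose
    matrices (of matching length) predict affinity rank >= ``min_rank``."""
    binding: dict[str, set[str]] = {eid: set() for eid in epitopes}
    for eid, seq in epitopes.items():
        for pssm in panel:
            if pssm.length == len(seq):
                if binding_rank(predict_pic50(seq, pssm)) >= min_rank:
                    binding[eid].add(pssm.allele)
    return binding
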