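"""T-helper fragment selection and joining.

Instead of concatenating individual class-II epitopes, whole antigen windows
of 20-40 residues that are dense in predicted T-helper epitope cores (9-mer
class-II binding cores) across the widest repertoire of HLA class II
allomorphs are selected, then extended by five residues on each side —
flanking residues influence CD4+ T-cell receptor recognition.  Fragments are
joined through a [KR][KR]-motif spacer forming lysosomal cathepsin cleavage
sites, with the junction candidates ranked by the same weighting machinery
used for the CTL module (including the class-I junctional-epitope scan).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .cleavage import CleavageModel
from .core import AlleleFrequencyTable, Epitope, RunConfig, SpacerMotif, parse_motif
from .junctions import JunctionEvaluation, best_junction
from .mhc import MhcPssm, predict_pic50
from .tap import FlankedEpitope

logger = logging.getLogger("polydesign")

CORE_LENGTH = 9
MIN_FRAGMENT, MAX_FRAGMENT = 20, 40
EXTENSION = 5

#: Default join motif: dibasic cathepsin cleavage sites.
KR_MOTIF = "[KR][KR]"


@dataclass(frozen=True)
class ThFragment:
    """A T-helper-rich antigen window (1-based closed intervals).

    The core interval is the selected 20-40 residue window; the extended
    interval adds five residues per side, clamped at the antigen termini.
    ``n_epitopes`` counts distinct predicted 9-mer core positions inside the
    core interval; ``n_alleles`` counts class-II allomorphs with at least one
    such core.
    """

    antigen_id: str
    core_start: int
    core_end: int
    extended_start: int
    extended_end: int
    n_epitopes: int
    n_alleles: int
    sequence: str

    @property
    def core_length(self) -> int:
        return self.core_end - self.core_start + 1


def scan_th_cores(
    antigen: str,
    class2_panel: Sequence[MhcPssm],
    threshold: Union[float, dict[str, float]],
) -> dict[str, list[int]]:
    """Per-allele 1-based start positions of predicted T-helper 9-mer cores.

    Every 9-mer window scoring at or above the allele's threshold is a hit.
    ``threshold`` may be a single value applied to all alleles or a
    per-allele mapping.
    """
    hits: dict[str, list[int]] = {}
    for pssm in class2_panel:
        if pssm.length != CORE_LENGTH:
            raise ValueError(
                f"class-II matrix {pssm.allele} has length {pssm.length}; "
                f"expected {CORE_LENGTH}-mer core matrices"
            )
        cut = threshold[pssm.allele] if isinstance(threshold, dict) else threshold
        starts = [
            i + 1
            for i in range(len(antigen) - CORE_LENGTH + 1)
            if predict_pic50(antigen[i : i + CORE_LENGTH], pssm) >= cut
        ]
        if starts:
            hits[pssm.allele] = starts
    return hits


def _window_stats(hits: dict[str, list[int]], start: int, end: int) -> tuple[int, int]:
    """(n_alleles, n_epitopes) for cores fully inside [start, end] (1-based closed)."""
    cores: set[int] = set()
    alleles = 0
    for allele, starts in hits.items():
        contained = [s for s in starts if s >= start and s + CORE_LENGTH - 1 <= end]
        if contained:
            alleles += 1
            cores.update(contained)
    return alleles, len(cores)


def select_fragments(
    antigen_id: str,
    antigen: str,
    hits: dict[str, list[int]],
    count: Optional[int] = None,
) -> list[ThFragment]:
    """Pick non-overlapping 20-40 residue windows maximizing T-helper content.

    All windows of every length 20-40 are scored; candidates are ranked by
    (allele repertoire desc, distinct cores desc, length asc, start asc) and
    accepted greedily while their cores stay pairwise disjoint, up to
    ``count`` fragments (all acceptable ones when ``count`` is None).  Each
    accepted core is extended by five residues per side, clamped to the
    antigen.
    """
    n = len(antigen)
    if n < MIN_FRAGMENT:
        logger.warning("antigen %s shorter than %d residues; no fragments selectable",
                       antigen_id, MIN_FRAGMENT)
        return []
    if not hits:
        return []
    candidates = []
    for length in range(MIN_FRAGMENT, min(MAX_FRAGMENT, n) + 1):
        for start in range(1, n - length + 2):
            end = start + length - 1
            n_alleles, n_epitopes = _window_stats(hits, start, end)
            if n_epitopes == 0:
                continue
            candidates.append((-n_alleles, -n_epitopes, length, start, end))
    candidates.sort()
    accepted: list[ThFragment] = []
    taken: list[tuple[int, int]] = []
    for neg_a, neg_e, length, start, end in candidates:
        if count is not None and len(accepted) >= count:
            break
        if any(start <= t_end and end >= t_start for t_start, t_end in taken):
            continue
        ext_start = max(1, start - EXTENSION)
        ext_end = min(n, end + EXTENSION)
        accepted.append(ThFragment(
            antigen_id=antigen_id,
            core_start=start,
            core_end=end,
            extended_start=ext_start,
            extended_end=ext_end,
            n_epitopes=-neg_e,
            n_alleles=-neg_a,
            sequence=antigen[ext_start - 1 : ext_end],
        ))
        taken.append((start, end))
    return accepted


@dataclass(frozen=True)
class ThModuleDesign:
    """Assembled T-helper module: fragments in input order plus chosen joins."""

    fragments: tuple[ThFragment, ...]
    junctions: tuple[JunctionEvaluation, ...]
    sequence: str


def join_fragments(
    fragments: Sequence[ThFragment],
    model_pr: CleavageModel,
    model_impr: CleavageModel,
    panel: Sequence[MhcPssm],
    freqs: AlleleFrequencyTable,
    config: RunConfig,
    motif: Optional[SpacerMotif] = None,
) -> ThModuleDesign:
    """Join fragments in input order through the minimal-weight [KR][KR] spacer.

    Each adjacent junction evaluates the direct join plus the motif's prefix
    expansions (K, R, KK, KR, RK, RR by default) with the CTL ranking
    function; no admissibility gate is applied — the least-weight candidate
    always wins.  Fragment order is not optimized here.
    """
    if not fragments:
        raise ValueError("need at least 1 fragment to assemble a T-helper module")
    if motif is None:
        motif = parse_motif(KR_MOTIF)
    wrapped = [
        FlankedEpitope(
            epitope=Epitope(id=f"th{i}", sequence=f.sequence),
            flank="",
            tap_score_before=0.0,
            tap_score_after=0.0,
        )
        for i, f in enumerate(fragments, 1)
    ]
    junctions: list[JunctionEvaluation] = []
    pieces = [wrapped[0].full_sequence]
    for left, right in zip(wrapped, wrapped[1:]):
        ev = best_junction(
            left, right, motif, model_pr, model_impr, panel, freqs, config,
            targets=set(), require_admissible=False,
        )
        junctions.append(ev)
        pieces.append(ev.spacer)
        pieces.append(right.full_sequence)
    return ThModuleDesign(
        fragments=tuple(fragments),
        junctions=tuple(junctions),
        sequence="".join(pieces),
    )
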