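"""Spacer enumeration and per-pair junction optimization.

For an ordered pair of flanked epitopes the designer tries the direct
junction plus every prefix expansion of the spacer motif, and scores each
candidate with the ranking function

    W = sum_HLA(rank_HLA x freq_HLA) + len(ss)
        + 0.5 x min(rank_pr, rank_impr)
        + 0.05 x (4 - mean rank_HLA)
        + 0.05 x N_eps + 0.05 x N_HLA
        + 0.25 x rank_pr + 0.25 x rank_impr

where rank_pr / rank_impr are the proteasomal / immunoproteasomal cleavage
ranks (1-11) at the first epitope's C-terminus, and the HLA terms summarize
predicted junctional (off-target) epitopes.  Smaller W is better: it rewards
efficient liberation of the first epitope, few and weak junctional binders,
and short spacers.  A pair is admissible only if its best candidate creates
a usable cleavage site: min(rank_pr, rank_impr) <= the configured allowance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .cleavage import CleavageModel, rank_epitope_cterm
from .core import AlleleFrequencyTable, RunConfig, SpacerMotif
from .mhc import JunctionSummary, MhcPssm, scan_junction, summarize_junction
from .tap import FlankedEpitope


class Disallowed:
    """Sentinel: no candidate spacer makes this ordered pair admissible."""

    _instance: Optional["Disallowed"] = None

    def __new__(cls) -> "Disallowed":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "DISALLOWED"


DISALLOWED = Disallowed()


@dataclass(frozen=True)
class JunctionEvaluation:
    """Full scoring record for one (pep1, spacer, pep2) candidate."""

    pep1_id: str
    pep2_id: str
    spacer: str
    rank_pr: int
    rank_impr: int
    summary: JunctionSummary
    weight: float


def enumerate_spacers(motif: SpacerMotif) -> list[str]:
    """All candidate spacers: the direct junction plus every prefix expansion.

    For each prefix length k = 1..len(motif) the Cartesian product of the
    first k residue sets is generated.  Order is deterministic: shorter
    candidates first, then lexicographic.

    >>> from .core import parse_motif
    >>> enumerate_spacers(parse_motif("[KR][KR]"))
    ['', 'K', 'R', 'KK', 'KR', 'RK', 'RR']
    """
    candidates = [""]
    seen = {""}
    for k in range(1, len(motif) + 1):
        # Position sets are stored sorted, so the product is lexicographic.
        for combo in itertools.product(*motif.positions[:k]):
            ss = "".join(combo)
            if ss not in seen:
                seen.add(ss)
                candidates.append(ss)
    return candidates


def ranking_weight(
    summary: JunctionSummary,
    ss: str,
    rank_pr: int,
    rank_impr: int,
    *,
    empty_mean_term: bool = False,
) -> float:
    """Evaluate the spacer ranking function W for one candidate.

    The 0.05 x (4 - mean rank_HLA) term is taken as 0 when there are no
    junctional hits (N_eps = 0) so a hit-free junction is never penalized;
    set ``empty_mean_term=True`` to apply it verbatim (contributing 0.2).
    """
    mean_term = 0.05 * (4.0 - summary.mean_rank)
    if summary.n_eps == 0 and not empty_mean_term:
        mean_term = 0.0
    return (
        summary.weighted_sum
        + len(ss)
        + 0.5 * min(rank_pr, rank_impr)
        + mean_term
        + 0.05 * summary.n_eps
        + 0.05 * summary.n_hla
        + 0.25 * rank_pr
        + 0.25 * rank_impr
    )


def evaluate_junction(
    pep1: FlankedEpitope,
    pep2: FlankedEpitope,
    ss: str,
    model_pr: CleavageModel,
    model_impr: CleavageModel,
    panel: Sequence[MhcPssm],
    freqs: AlleleFrequencyTable,
    config: RunConfig,
    targets: Iterable[str],
) -> JunctionEvaluation:
    """Score a single candidate spacer for an ordered pair of flanked epitopes."""
    site = rank_epitope_cterm(
        pep1.full_sequence, ss, pep2.full_sequence, model_pr, model_impr
    )
    hits = scan_junction(pep1.full_sequence, ss, pep2.full_sequence, panel, targets, config)
    summary = summarize_junction(hits, freqs)
    weight = ranking_weight(
        summary, ss, site.rank_pr, site.rank_impr,
        empty_mean_term=config.empty_junction_mean_term,
    )
    return JunctionEvaluation(
        pep1_id=pep1.id,
        pep2_id=pep2.id,
        spacer=ss,
        rank_pr=site.rank_pr,
        rank_impr=site.rank_impr,
        summary=summary,
        weight=weight,
    )


def best_junction(
    pep1: FlankedEpitope,
    pep2: FlankedEpitope,
    motif: SpacerMotif,
    model_pr: CleavageModel,
    model_impr: CleavageModel,
    panel: Sequence[MhcPssm],
    freqs: AlleleFrequencyTable,
    config: RunConfig,
    targets: Optional[Iterable[str]] = None,
    *,
    require_admissible: bool = True,
) -> JunctionEvaluation | Disallowed:
    """Select the minimal-W spacer for the ordered pair (pep1 -> pep2).

    Every candidate from :func:`enumerate_spacers` is evaluated; the one with
    the least weight wins, ties broken by shorter spacer then lexicographic
    order.  When ``require_admissible`` (the default) no candidate with
    min(rank_pr, rank_impr) above ``config.cleavage_allow_threshold`` can be
    chosen, and :data:`DISALLOWED` is returned if none qualifies.
    """
    if targets is None:
        targets = {pep1.epitope.sequence, pep2.epitope.sequence}
    best: Optional[JunctionEvaluation] = None
    # enumerate_spacers yields (shorter, then lexicographic) order, so a
    # strict < comparison implements the tie-break for free.
    for ss in enumerate_spacers(motif):
        ev = evaluate_junction(
            pep1, pep2, ss, model_pr, model_impr, panel, freqs, config, targets
        )
        if require_admissible and min(ev.rank_pr, ev.rank_impr) > config.cleavage_allow_threshold:
            continue
        if best is None or ev.weight < best.weight:
            best = ev
    return best if best is not None else DISALLOWED
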