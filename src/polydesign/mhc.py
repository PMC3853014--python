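"""Peptide-HLA binding prediction and junctional-epitope scanning.

Binding is predicted with per-(allele, length) position-specific scoring
matrices whose output is pIC50 = -log10(IC50 / M); higher = stronger
binding.  Predicted pIC50 maps onto a 3-level affinity rank:

    rank 0   pIC50 < 6.3          non-binder
    rank 1   6.3 <= pIC50 < 7.3   moderate affinity
    rank 2   7.3 <= pIC50 < 8.3   high affinity
    rank 3   pIC50 >= 8.3         highest affinity

Junctional epitopes are peptides created by the artificial juxtaposition of
two target epitopes (plus any spacer): windows of the joined sequence that
are not fully contained in either flanked peptide alone.  They are off-target
immunogenicity risks, so the spacer-ranking function penalizes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .core import AMINO_ACIDS, AlleleFrequencyTable, InputError, RunConfig

logger = logging.getLogger("polydesign")

#: pIC50 thresholds for affinity ranks 1, 2, 3 (closed lower bounds).
RANK_THRESHOLDS = (6.3, 7.3, 8.3)


@dataclass(frozen=True)
class MhcPssm:
    """Position-specific scoring matrix for one (allele, peptide length).

    ``predict(peptide) = intercept + sum_i weights[(i, peptide[i-1])]``
    with positions 1-based.  ``mhc_class`` distinguishes class-I matrices
    (whole-ligand) from class-II 9-mer core matrices.
    """

    allele: str
    length: int
    weights: dict[tuple[int, str], float]
    intercept: float = 0.0
    mhc_class: str = "I"

    def __post_init__(self) -> None:
        missing = [
            (i, aa)
            for i in range(1, self.length + 1)
            for aa in AMINO_ACIDS
            if (i, aa) not in self.weights
        ]
        if missing:
            raise ValueError(
                f"PSSM {self.allele}/{self.length}: {len(missing)} missing cells, e.g. {missing[0]}"
            )

    def predict(self, peptide: str) -> float:
        return predict_pic50(peptide, self)

    @classmethod
    def from_file(cls, path: str | Path) -> "MhcPssm":
        """Read a PSSM TSV: ``#allele``, ``#length``, ``#intercept``, ``#class``
        headers, then rows = residues x columns = positions 1..length."""
        path = Path(path)
        allele = length = intercept = None
        mhc_class = "I"
        body = []
        for line in path.read_text().splitlines():
            line = line.rstrip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                key, val = key.strip().lower(), val.strip()
                if key == "allele":
                    allele = val
                elif key == "length":
                    length = int(val)
                elif key == "intercept":
                    intercept = float(val)
                elif key == "class":
                    mhc_class = val.upper()
                continue
            body.append(line)
        if allele is None or length is None or intercept is None:
            raise InputError(f"{path}: required headers #allele, #length, #intercept")
        weights: dict[tuple[int, str], float] = {}
        for line in body[1:]:  # body[0] is the position-number header row
            parts = line.split("\t")
            aa = parts[0].strip().upper()
            for i, val in enumerate(parts[1 : length + 1], 1):
                weights[(i, aa)] = float(val)
        return cls(allele=allele, length=length, weights=weights,
                   intercept=intercept, mhc_class=mhc_class)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#allele: {self.allele}\n")
            fh.write(f"#length: {self.length}\n")
            fh.write(f"#intercept: {self.intercept:.6f}\n")
            fh.write(f"#class: {self.mhc_class}\n")
            fh.write("residue\t" + "\t".join(str(i) for i in range(1, self.length + 1)) + "\n")
            for aa in AMINO_ACIDS:
                row = "\t".join(f"{self.weights[(i, aa)]:.6f}" for i in range(1, self.length + 1))
                fh.write(f"{aa}\t{row}\n")


def predict_pic50(peptide: str, pssm: MhcPssm) -> float:
    """Predicted pIC50 of ``peptide`` for ``pssm``'s allele (length must match)."""
    if len(peptide) != pssm.length:
        raise ValueError(
            f"peptide length {len(peptide)} does not match PSSM {pssm.allele}/{pssm.length}"
        )
    w = pssm.weights
    return pssm.intercept + sum(w[(i, aa)] for i, aa in enumerate(peptide, 1))


def binding_rank(pic50: float) -> int:
    """Map predicted pIC50 to the 0-3 affinity rank scale (closed lower bounds)."""
    rank = 0
    for threshold in RANK_THRESHOLDS:
        if pic50 >= threshold:
            rank += 1
    return rank


@dataclass(frozen=True)
class JunctionalEpitope:
    """A non-target peptide spanning a junction, with its best predicted binding."""

    peptide: str
    start: int  # 1-based offset within the joined junction context
    allele: str
    pic50: float
    rank: int


@dataclass(frozen=True)
class JunctionSummary:
    """Aggregate junctional burden for one (pep1, spacer, pep2) triple.

    ``n_eps`` counts (peptide, allele) hit pairs; ``n_hla`` counts alleles
    with at least one hit; ``weighted_sum`` is sum over alleles of
    best rank x genotypic frequency; ``mean_rank`` is the mean of per-allele
    best ranks (0 when there are no hits).
    """

    per_allele_best: dict[str, int] = field(default_factory=dict)
    n_eps: int = 0
    n_hla: int = 0
    mean_rank: float = 0.0
    weighted_sum: float = 0.0


def scan_junction(
    pep1_full: str,
    ss: str,
    pep2_full: str,
    panel: Sequence[MhcPssm],
    targets: Iterable[str],
    config: RunConfig,
) -> list[JunctionalEpitope]:
    """Enumerate junction-spanning windows and return those predicted to bind.

    For each scanned length L (``config.junction_lengths``) every L-mer of
    ``pep1_full + ss + pep2_full`` that is *not* fully contained in either
    flanked peptide alone is predicted against every panel matrix of length
    L.  Windows whose sequence equals a target epitope are excluded.  Only
    windows with affinity rank >= 1 are returned.
    """
    if not panel:
        logger.warning("scan_junction: empty MHC panel; no junctional epitopes can be found")
        return []
    joined = pep1_full + ss + pep2_full
    len1 = len(pep1_full)
    pep2_start = len1 + len(ss)  # 0-based start of pep2_full in `joined`
    target_set = set(targets)
    by_length: dict[int, list[MhcPssm]] = {}
    for pssm in panel:
        by_length.setdefault(pssm.length, []).append(pssm)
    hits: list[JunctionalEpitope] = []
    for L in config.junction_lengths:
        matrices = by_length.get(L, [])
        if not matrices:
            continue
        for s in range(len(joined) - L + 1):
            inside_pep1 = s + L <= len1
            inside_pep2 = s >= pep2_start
            if inside_pep1 or inside_pep2:
                continue
            window = joined[s : s + L]
            if window in target_set:
                continue
            for pssm in matrices:
                pic50 = predict_pic50(window, pssm)
                rank = binding_rank(pic50)
                if rank >= 1:
                    hits.append(JunctionalEpitope(window, s + 1, pssm.allele, pic50, rank))
    return hits


def count_junction_windows(len1: int, len_ss: int, len2: int, L: int) -> int:
    """Number of length-L windows straddling the junction (bookkeeping helper)."""
    total = max(0, len1 + len_ss + len2 - L + 1)
    inside1 = max(0, len1 - L + 1)
    inside2 = max(0, len2 - L + 1)
    return total - inside1 - inside2


def summarize_junction(
    hits: Sequence[JunctionalEpitope], freqs: AlleleFrequencyTable
) -> JunctionSummary:
    """Aggregate hit list into the quantities consumed by the ranking function."""
    if not hits:
        return JunctionSummary()
    per_allele: dict[str, int] = {}
    pairs = set()
    for h in hits:
        per_allele[h.allele] = max(per_allele.get(h.allele, 0), h.rank)
        pairs.add((h.peptide, h.allele))
    best = sorted(per_allele.items())
    return JunctionSummary(
        per_allele_best=dict(best),
        n_eps=len(pairs),
        n_hla=len(per_allele),
        mean_rank=sum(r for _, r in best) / len(best),
        weighted_sum=sum(r * freqs.get(a) for a, r in best),
    )


def load_pssm_panel(directory: str | Path, mhc_class: Optional[str] = None) -> list[MhcPssm]:
    """Load every ``*.tsv`` PSSM under ``directory`` (sorted by filename),
    optionally filtered to one MHC class."""
    directory = Path(directory)
    panel = []
    for path in sorted(directory.glob("*.tsv")):
        pssm = MhcPssm.from_file(path)
        if mhc_class is None or pssm.mhc_class == mhc_class.upper():
            panel.append(pssm)
    return panel
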