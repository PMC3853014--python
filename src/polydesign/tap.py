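"""Additive TAP-binding scoring and N-terminal flank selection.

The transporter associated with antigen processing (TAP) pumps cytosolic
peptides into the endoplasmic reticulum, and its sequence preference is
dominated by the first three N-terminal residues and the C-terminal residue
of the peptide.  The score of a peptide is therefore the sum of four table
lookups.  Epitopes that transport poorly are rescued by prepending a short
(up to three residues) N-terminal flank, which ER aminopeptidases later trim
away; the flank is chosen to restore TAP transport with the least sequence
added.
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass
from pathlib import Path

from .core import AMINO_ACIDS, Epitope, InputError, RunConfig

#: The four positions contributing to TAP affinity.
TAP_ROLES = ("N1", "N2", "N3", "C")


@dataclass(frozen=True)
class TapMatrix:
    """Per-(position role, residue) additive score contributions.

    Orientation: higher score = better TAP binding (declared in the
    parameter-file header to avoid sign drift between matrix sources).
    """

    contributions: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        missing = [
            (role, aa)
            for role in TAP_ROLES
            for aa in AMINO_ACIDS
            if (role, aa) not in self.contributions
        ]
        if missing:
            raise ValueError(f"TAP matrix incomplete: missing {missing[:3]}... "
                             f"({len(missing)} of 80 cells)")

    @classmethod
    def from_file(cls, path: str | Path) -> "TapMatrix":
        """Read a TAP matrix TSV: rows = 20 residues, columns = N1 N2 N3 C.

        The header comment ``#orientation: higher=better`` is required.
        """
        path = Path(path)
        lines = path.read_text().splitlines()
        if not any("orientation" in l and "higher=better" in l.replace(" ", "")
                   for l in lines if l.startswith("#")):
            raise InputError(f"{path}: missing '#orientation: higher=better' header")
        body = [l for l in lines if l.strip() and not l.startswith("#")]
        header = body[0].split("\t")
        if [h.strip() for h in header[1:5]] != list(TAP_ROLES):
            raise InputError(f"{path}: expected columns residue, N1, N2, N3, C")
        contributions: dict[tuple[str, str], float] = {}
        for line in body[1:]:
            parts = line.split("\t")
            aa = parts[0].strip().upper()
            if aa not in AMINO_ACIDS:
                raise InputError(f"{path}: unknown residue row {aa!r}")
            for role, val in zip(TAP_ROLES, parts[1:5]):
                contributions[(role, aa)] = float(val)
        return cls(contributions=contributions)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#orientation: higher=better\n")
            fh.write("residue\t" + "\t".join(TAP_ROLES) + "\n")
            for aa in AMINO_ACIDS:
                row = "\t".join(f"{self.contributions[(role, aa)]:.6f}" for role in TAP_ROLES)
                fh.write(f"{aa}\t{row}\n")


@dataclass(frozen=True)
class FlankedEpitope:
    """An epitope plus the chosen N-terminal flank (possibly empty)."""

    epitope: Epitope
    flank: str
    tap_score_before: float
    tap_score_after: float

    @property
    def full_sequence(self) -> str:
        return self.flank + self.epitope.sequence

    @property
    def id(self) -> str:
        return self.epitope.id


def score_tap(peptide: str, matrix: TapMatrix) -> float:
    """TAP affinity score: contributions of residues 1-3 plus the C-terminal residue."""
    if len(peptide) < 4:
        raise ValueError(f"peptide {peptide!r} shorter than 4 residues; TAP score undefined")
    c = matrix.contributions
    try:
        return (
            c[("N1", peptide[0])]
            + c[("N2", peptide[1])]
            + c[("N3", peptide[2])]
            + c[("C", peptide[-1])]
        )
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0][1]!r} absent from TAP matrix") from None


def select_flank(epitope: Epitope, matrix: TapMatrix, config: RunConfig) -> FlankedEpitope:
    """Choose the N-terminal flank (0 to ``config.max_flank`` residues) for one epitope.

    If the bare epitope already reaches ``config.tap_threshold`` no flank is
    added.  Otherwise all flanks of length 1..max_flank are scored
    exhaustively (20 + 400 + 8000 candidates at the default length 3) and the
    *shortest* flank reaching the threshold is chosen (ties: highest score,
    then lexicographic).  If no flank reaches the threshold, the candidate
    (including the empty flank) with maximal score wins, ties broken by
    shorter flank then lexicographic order — so the TAP score never
    decreases.
    """
    if config.tap_threshold is None:
        raise ValueError("config.tap_threshold is unset; calibrate it before flank selection")
    threshold = config.tap_threshold
    base = score_tap(epitope.sequence, matrix)
    if base >= threshold or config.max_flank == 0:
        return FlankedEpitope(epitope, "", base, base)

    # (flank, score) candidates in (length asc, lexicographic) order.
    best_reaching: tuple[float, str] | None = None  # (score, flank), len fixed per tier
    best_overall: tuple[float, int, str] = (base, 0, "")  # (score, len, flank)
    for length in range(1, config.max_flank + 1):
        for combo in itertools.product(AMINO_ACIDS, repeat=length):
            flank = "".join(combo)
            score = score_tap(flank + epitope.sequence, matrix)
            if score >= threshold:
                if best_reaching is None or score > best_reaching[0]:
                    best_reaching = (score, flank)
            if score > best_overall[0]:
                best_overall = (score, length, flank)
        if best_reaching is not None:
            score, flank = best_reaching
            return FlankedEpitope(epitope, flank, base, score)
    score, _, flank = best_overall
    return FlankedEpitope(epitope, flank, base, score)


def median_ninemer_score(antigen: str, matrix: TapMatrix) -> float:
    """Median TAP score over all 9-mer windows of ``antigen``.

    Used to self-calibrate the "inefficient binder" threshold against a
    reference antigen when no explicit cutoff is configured.
    """
    if len(antigen) < 9:
        raise ValueError("reference antigen shorter than 9 residues")
    scores = [score_tap(antigen[i : i + 9], matrix) for i in range(len(antigen) - 8)]
    return statistics.median(scores)
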