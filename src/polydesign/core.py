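"""Domain types, file readers and run configuration.

The design pipeline works on short class-I epitope peptides (8-11 residues by
default), a table of HLA genotypic frequencies for the target population, and
a spacer motif written in bracket notation (``"ADLVKV"``,
``"[ARSP][DLIT][LGA][VKA]"``).  Everything is plain text: epitope lists are
one peptide per line with optional tab-separated restricting alleles,
frequency tables are two-column TSV, antigens are FASTA.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger("polydesign")

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class InputError(ValueError):
    """Malformed user input (always names the offending file/line)."""


def validate_sequence(seq: str, *, where: str = "sequence") -> str:
    """Return ``seq`` uppercased, or raise :class:`InputError` on a non-standard residue."""
    seq = seq.strip().upper()
    bad = set(seq) - _AA_SET
    if bad:
        raise InputError(
            f"{where}: illegal residue(s) {sorted(bad)} (only the 20 standard "
            f"one-letter codes are accepted)"
        )
    return seq


@dataclass(frozen=True)
class Epitope:
    """A CTL epitope peptide with optional restriction/provenance metadata."""

    id: str
    sequence: str
    restricting_alleles: tuple[str, ...] = ()
    source: Optional[tuple[str, int]] = None  # (antigen id, 1-based start)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence, where=f"epitope {self.id}"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlleleFrequencyTable:
    """HLA allele -> genotypic frequency (fraction of individuals carrying the allele)."""

    entries: dict[str, float] = field(default_factory=dict)
    _warned: set = field(default_factory=set, repr=False, compare=False)

    def get(self, allele: str) -> float:
        """Frequency of ``allele``; unknown alleles count as 0 (warned once each)."""
        if allele not in self.entries:
            if allele not in self._warned:
                logger.warning("allele %s absent from frequency table; using frequency 0", allele)
                self._warned.add(allele)
            return 0.0
        return self.entries[allele]

    def __contains__(self, allele: str) -> bool:
        return allele in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SpacerMotif:
    """A spacer motif: an ordered list of residue choice sets, at most six positions.

    ``positions[k]`` is the sorted tuple of residues allowed at spacer position
    k.  A plain string like ``"ADLVKV"`` has singleton sets; bracket groups
    like ``"[KR][KR]"`` are degenerate positions.
    """

    positions: tuple[tuple[str, ...], ...]
    raw: str

    MAX_POSITIONS = 6

    @property
    def degenerate(self) -> bool:
        return any(len(p) > 1 for p in self.positions)

    def __len__(self) -> int:
        return len(self.positions)

    def normalized(self) -> str:
        """Canonical bracket notation (singletons unbracketed, groups sorted)."""
        return "".join(p[0] if len(p) == 1 else "[" + "".join(p) + "]" for p in self.positions)


_MOTIF_TOKEN = re.compile(r"\[([A-Za-z]+)\]|([A-Za-z])")


def parse_motif(raw: str) -> SpacerMotif:
    """Parse bracket-notation motif into a :class:`SpacerMotif`.

    >>> parse_motif("[KR][KR]").positions
    (('K', 'R'), ('K', 'R'))
    """
    s = raw.strip()
    if not s:
        raise InputError("motif: empty motif string")
    positions: list[tuple[str, ...]] = []
    pos = 0
    while pos < len(s):
        m = _MOTIF_TOKEN.match(s, pos)
        if m is None:
            raise InputError(f"motif {raw!r}: cannot parse at character {pos + 1} "
                             "(unbalanced bracket or illegal character?)")
        group = m.group(1) or m.group(2)
        residues = validate_sequence(group, where=f"motif {raw!r} position {len(positions) + 1}")
        if not residues:
            raise InputError(f"motif {raw!r}: empty bracket group at position {len(positions) + 1}")
        positions.append(tuple(sorted(set(residues))))
        pos = m.end()
    if len(positions) > SpacerMotif.MAX_POSITIONS:
        raise InputError(
            f"motif {raw!r}: {len(positions)} positions exceed the maximum of "
            f"{SpacerMotif.MAX_POSITIONS}"
        )
    return SpacerMotif(positions=tuple(positions), raw=s)


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm settings for the epitope-ordering solver."""

    population: int = 80
    generations: int = 500
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    tournament_size: int = 2
    elitism: int = 1

    def validate(self) -> None:
        if self.population < 1:
            raise ValueError("GA population must be >= 1")
        if self.generations < 0:
            raise ValueError("GA generations must be >= 0")
        if not (0.0 <= self.crossover_rate <= 1.0 and 0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("GA rates must lie in [0, 1]")
        if self.tournament_size < 1 or self.elitism < 0:
            raise ValueError("GA tournament_size >= 1 and elitism >= 0 required")


#: Weight assigned to a disallowed epitope matching when completing the digraph.
DISALLOWED_WEIGHT = 5000.0


@dataclass
class RunConfig:
    """Run-wide thresholds and knobs.

    tap_threshold
        TAP score (matrix units, higher = better transport) above which an
        epitope needs no N-terminal flank.  ``None`` means "calibrate at
        startup" (median 9-mer score of a reference antigen).
    max_flank
        Maximal N-terminal flank length searched (default 3).
    junction_lengths
        Peptide lengths scanned for junctional epitopes (default 9 and 10,
        the dominant class-I ligand lengths).
    cleavage_allow_threshold
        A junction is admissible when min(rank_pr, rank_impr) does not exceed
        this rank (scale 1-11, 1 = most efficient cleavage).
    disallowed_weight
        Edge weight for inadmissible pairings; fixed at 5000.
    empty_junction_mean_term
        If True, the 0.05 x (4 - mean rank) term of the ranking function is
        applied even when there are no junctional hits (contributing 0.2);
        default False treats a hit-free junction as the best case.
    """

    tap_threshold: Optional[float] = None
    max_flank: int = 3
    junction_lengths: tuple[int, ...] = (9, 10)
    cleavage_allow_threshold: int = 7
    disallowed_weight: float = DISALLOWED_WEIGHT
    empty_junction_mean_term: bool = False
    redundancy: int = 1
    min_epitope_length: int = 8
    max_epitope_length: int = 11
    ga: GAParams = field(default_factory=GAParams)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_flank < 0:
            raise ValueError("max_flank must be >= 0")
        if not self.junction_lengths:
            raise ValueError("junction_lengths must be non-empty")
        if not 1 <= self.cleavage_allow_threshold <= 11:
            raise ValueError("cleavage_allow_threshold must lie in 1..11")
        if self.redundancy < 1:
            raise ValueError("redundancy must be >= 1")
        self.ga.validate()

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a flat ``key = value`` config file; keyword args override file keys."""
        values: dict[str, object] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InputError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key in ("max_flank", "cleavage_allow_threshold", "redundancy", "seed",
                       "min_epitope_length", "max_epitope_length"):
                values[key] = int(val)
            elif key in ("tap_threshold", "disallowed_weight"):
                values[key] = float(val)
            elif key == "junction_lengths":
                values[key] = tuple(int(x) for x in val.replace(",", " ").split())
            elif key == "empty_junction_mean_term":
                values[key] = val.lower() in ("1", "true", "yes")
            elif key.startswith("ga_"):
                ga = values.setdefault("_ga", {})
                ga[key[3:]] = float(val) if "rate" in key else int(val)
            else:
                raise InputError(f"{path}:{lineno}: unknown config key {key!r}")
        ga_kwargs = values.pop("_ga", {})
        values.update(overrides)
        cfg = cls(**{k: v for k, v in values.items() if k != "_ga"})
        if ga_kwargs:
            cfg.ga = replace(cfg.ga, **ga_kwargs)
        return cfg


def read_epitopes(path: str | Path, *, min_length: int = 8, max_length: int = 11) -> list[Epitope]:
    """Read an epitope list: one peptide per line, optional tab-separated alleles.

    Lines starting with ``#`` are comments.  Duplicate peptide sequences are
    collapsed into one epitope with merged allele annotations (warned).
    Ids are auto-assigned e1..eN in input order.
    """
    path = Path(path)
    by_seq: dict[str, list[str]] = {}
    order: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            seq = validate_sequence(parts[0], where="peptide")
        except InputError as exc:
            raise InputError(f"{path}:{lineno}: {exc}") from None
        if not min_length <= len(seq) <= max_length:
            raise InputError(
                f"{path}:{lineno}: peptide length {len(seq)} outside the allowed "
                f"range {min_length}-{max_length}"
            )
        alleles: list[str] = []
        for extra in parts[1:]:
            alleles.extend(a.strip() for a in extra.split(",") if a.strip())
        if seq in by_seq:
            logger.warning("%s:%d: duplicate epitope %s collapsed (alleles merged)", path, lineno, seq)
            for a in alleles:
                if a not in by_seq[seq]:
                    by_seq[seq].append(a)
        else:
            by_seq[seq] = alleles
            order.append(seq)
    if not order:
        raise InputError(f"{path}: no epitopes found")
    return [
        Epitope(id=f"e{i}", sequence=seq, restricting_alleles=tuple(by_seq[seq]))
        for i, seq in enumerate(order, 1)
    ]


def read_frequency_table(path: str | Path) -> AlleleFrequencyTable:
    """Read a two-column TSV ``allele<TAB>frequency`` (header required)."""
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip() and not l.startswith("#")]
    if not lines:
        logger.warning("%s: empty frequency table; all allele lookups will return 0", path)
        return AlleleFrequencyTable()
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if header[:2] != ["allele", "frequency"]:
        raise InputError(f"{path}: expected header 'allele<TAB>frequency', got {lines[0]!r}")
    entries: dict[str, float] = {}
    for lineno, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputError(f"{path}:{lineno}: expected two tab-separated columns")
        allele = parts[0].strip()
        try:
            freq = float(parts[1])
        except ValueError:
            raise InputError(f"{path}:{lineno}: frequency {parts[1]!r} is not a number") from None
        if not 0.0 <= freq <= 1.0:
            raise InputError(f"{path}:{lineno}: frequency {freq} outside [0, 1]")
        if allele in entries:
            raise InputError(f"{path}:{lineno}: duplicate allele {allele}")
        entries[allele] = freq
    if not entries:
        logger.warning("%s: frequency table has no data rows; lookups default to 0", path)
    return AlleleFrequencyTable(entries=entries)


def read_antigens(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA antigen sequences as (id, validated sequence) pairs."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, validate_sequence(str(rec.seq), where=f"antigen {rec.id}")))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return records
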