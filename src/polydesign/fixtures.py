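"""Synthetic parameter-table generator with planted, recoverable structure.

Real TAP matrices, proteasome cleavage tables and per-allele MHC scoring
matrices are literature-derived and distributed separately; this module
emits syntactically identical synthetic tables whose *optima are known by
construction*, so every pipeline stage can be tested against a manifest of
planted answers:

* cleavage rank is controlled entirely by the residue immediately downstream
  of the scissile bond (P1'): one designated "good" residue gets rank 1
  (proteasome) / 2 (immunoproteasome), all others get inefficient ranks
  above the admissibility threshold;
* epitopes never begin with the good residue, so a direct junction is
  inadmissible and the planted optimal spacer is the single good residue;
* class-I matrices are centred well below the binding threshold, keeping
  junctions free of off-target hits.

Same seed -> byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cleavage import CleavageModel, CleavagePattern
from .core import AMINO_ACIDS
from .mhc import MhcPssm
from .tap import TAP_ROLES, TapMatrix

#: Motif whose first position is the planted good spacer residue.
DEFAULT_MOTIF = "ADLVKV"
GOOD_RESIDUE = "A"


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible recipe for one synthetic parameter set."""

    seed: int
    n_epitopes: int = 6
    n_alleles: int = 3
    epitope_length: int = 9
    antigen_length: int = 120
    motif: str = DEFAULT_MOTIF
    good_residue: str = GOOD_RESIDUE


def _pattern_on_p1prime(residue: str, rank: int, upstream: int = 4, downstream: int = 2) -> CleavagePattern:
    slots = [None] * (upstream + downstream)
    slots[upstream] = frozenset(residue)  # first downstream slot = P1'
    raw = "." * upstream + residue + "." * (downstream - 1)
    return CleavagePattern(slots=tuple(slots), rank=rank, raw=raw)


def make_cleavage_model(kind: str, good_residue: str, good_rank: int,
                        rng: np.random.Generator) -> CleavageModel:
    """Cleavage table keyed on P1': ``good_residue`` -> ``good_rank``, every
    other residue -> an inefficient rank in 8..11."""
    patterns = []
    for aa in AMINO_ACIDS:
        rank = good_rank if aa == good_residue else int(rng.integers(8, 12))
        patterns.append(_pattern_on_p1prime(aa, rank))
    return CleavageModel(kind=kind, upstream=4, downstream=2,
                         patterns=tuple(patterns), default_rank=9)


def make_tap_matrix(rng: np.random.Generator) -> TapMatrix:
    contributions = {
        (role, aa): float(np.round(rng.normal(0.0, 1.0), 6))
        for role in TAP_ROLES
        for aa in AMINO_ACIDS
    }
    return TapMatrix(contributions=contributions)


def make_class1_pssm(allele: str, length: int, rng: np.random.Generator) -> MhcPssm:
    # Centred at pIC50 ~ 4.5 with small weights: junctional hits are rare,
    # matching a regime where most random peptides are non-binders.
    weights = {
        (i, aa): float(np.round(rng.normal(0.0, 0.15), 6))
        for i in range(1, length + 1)
        for aa in AMINO_ACIDS
    }
    return MhcPssm(allele=allele, length=length, weights=weights,
                   intercept=4.5, mhc_class="I")


def make_class2_pssm(allele: str, rng: np.random.Generator) -> MhcPssm:
    weights = {
        (i, aa): float(np.round(rng.normal(0.0, 1.0), 6))
        for i in range(1, 10)
        for aa in AMINO_ACIDS
    }
    return MhcPssm(allele=allele, length=9, weights=weights,
                   intercept=0.0, mhc_class="II")


def _random_peptide(length: int, rng: np.random.Generator, forbidden_first: str) -> str:
    allowed_first = [aa for aa in AMINO_ACIDS if aa not in forbidden_first]
    first = allowed_first[int(rng.integers(0, len(allowed_first)))]
    rest = "".join(AMINO_ACIDS[int(k)] for k in rng.integers(0, 20, size=length - 1))
    return first + rest


def make_fixtures(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic parameter set under ``outdir``.

    Emits TAP matrix, proteasomal and immunoproteasomal cleavage tables,
    class-I PSSMs (lengths 9 and 10 per allele), class-II PSSMs, an allele
    frequency table, an epitope list, a reference antigen FASTA and a
    ``manifest.json`` recording the planted optima.  Returns name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    paths: dict[str, Path] = {}

    tap = make_tap_matrix(rng)
    paths["tap_matrix"] = outdir / "tap_matrix.tsv"
    tap.to_file(paths["tap_matrix"])

    pr = make_cleavage_model("proteasome", spec.good_residue, 1, rng)
    impr = make_cleavage_model("immunoproteasome", spec.good_residue, 2, rng)
    paths["cleavage_pr"] = outdir / "cleavage_proteasome.tsv"
    paths["cleavage_impr"] = outdir / "cleavage_immunoproteasome.tsv"
    pr.to_file(paths["cleavage_pr"])
    impr.to_file(paths["cleavage_impr"])

    alleles = [f"HLA-A*{i:02d}:01" for i in range(1, spec.n_alleles + 1)]
    mhc1_dir = outdir / "mhc_classI"
    mhc1_dir.mkdir(exist_ok=True)
    for allele in alleles:
        for length in (9, 10):
            pssm = make_class1_pssm(allele, length, rng)
            safe = allele.replace("*", "").replace(":", "")
            pssm.to_file(mhc1_dir / f"{safe}_L{length}.tsv")
    paths["mhc_classI"] = mhc1_dir

    class2_alleles = [f"HLA-DRB1*{i:02d}:01" for i in range(1, 3)]
    mhc2_dir = outdir / "mhc_classII"
    mhc2_dir.mkdir(exist_ok=True)
    for allele in class2_alleles:
        pssm = make_class2_pssm(allele, rng)
        safe = allele.replace("*", "").replace(":", "")
        pssm.to_file(mhc2_dir / f"{safe}_L9.tsv")
    paths["mhc_classII"] = mhc2_dir

    freqs = {a: float(np.round(rng.uniform(0.02, 0.35), 4)) for a in alleles + class2_alleles}
    paths["freqs"] = outdir / "freqs.tsv"
    with open(paths["freqs"], "w") as fh:
        fh.write("allele\tfrequency\n")
        for a in alleles + class2_alleles:
            fh.write(f"{a}\t{freqs[a]:.4f}\n")

    # Epitopes never start with the good residue (nor any first-position
    # motif residue), so direct junctions stay inadmissible by construction.
    forbidden = spec.good_residue + spec.motif[0]
    epitopes = []
    while len(epitopes) < spec.n_epitopes:
        pep = _random_peptide(spec.epitope_length, rng, forbidden)
        if pep not in epitopes:
            epitopes.append(pep)
    paths["epitopes"] = outdir / "epitopes.txt"
    with open(paths["epitopes"], "w") as fh:
        fh.write("# synthetic epitope list\n")
        for i, pep in enumerate(epitopes):
            fh.write(f"{pep}\t{alleles[i % len(alleles)]}\n")

    antigen = "".join(AMINO_ACIDS[int(k)] for k in rng.integers(0, 20, size=spec.antigen_length))
    paths["antigen"] = outdir / "antigen.fasta"
    with open(paths["antigen"], "w") as fh:
        fh.write(">synthetic_antigen\n")
        for i in range(0, len(antigen), 60):
            fh.write(antigen[i : i + 60] + "\n")

    manifest = {
        "seed": spec.seed,
        "motif": spec.motif,
        "good_residue": spec.good_residue,
        "planted_best_spacer": spec.good_residue,
        "planted_rank_pr": 1,
        "planted_rank_impr": 2,
        "epitopes": epitopes,
        "class1_alleles": alleles,
        "class2_alleles": class2_alleles,
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return paths


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file (determinism checks)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
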