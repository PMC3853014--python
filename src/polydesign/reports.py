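"""Tabular and FASTA output writers for finished designs."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly import DesignGraph, PolyepitopeDesign
from .core import RunConfig

JUNCTION_COLUMNS = [
    "pep1", "pep2", "spacer", "rank_pr", "rank_impr",
    "N_eps", "N_HLA", "weighted_sum", "W", "status",
]


def junction_report(graph: DesignGraph) -> pd.DataFrame:
    """One row per directed edge of the design graph."""
    rows = []
    for i in graph.node_ids:
        for j in graph.node_ids:
            if i == j:
                continue
            data = graph.edge(i, j)
            ev = data["evaluation"]
            if data["allowed"] and ev is not None:
                rows.append({
                    "pep1": i, "pep2": j, "spacer": ev.spacer or "-",
                    "rank_pr": ev.rank_pr, "rank_impr": ev.rank_impr,
                    "N_eps": ev.summary.n_eps, "N_HLA": ev.summary.n_hla,
                    "weighted_sum": round(ev.summary.weighted_sum, 6),
                    "W": round(ev.weight, 6), "status": "allowed",
                })
            else:
                rows.append({
                    "pep1": i, "pep2": j, "spacer": "-",
                    "rank_pr": "", "rank_impr": "", "N_eps": "", "N_HLA": "",
                    "weighted_sum": "", "W": round(data["weight"], 6),
                    "status": "disallowed",
                })
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS)


def write_design(
    design: PolyepitopeDesign,
    graph: DesignGraph,
    out_prefix: str | Path,
    run_name: str = "polyepitope",
    config: Optional[RunConfig] = None,
) -> dict[str, Path]:
    """Write <prefix>.fasta, <prefix>.junctions.tsv and <prefix>.summary.txt."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_prefix.with_suffix(".fasta"),
        "junctions": Path(str(out_prefix) + ".junctions.tsv"),
        "summary": Path(str(out_prefix) + ".summary.txt"),
    }
    record = SeqRecord(Seq(design.sequence), id=run_name,
                       description=f"length={len(design.sequence)} total_weight={design.total_weight:.6f}")
    with open(paths["fasta"], "w") as fh:
        SeqIO.write([record], fh, "fasta")
    junction_report(graph).to_csv(paths["junctions"], sep="\t", index=False)
    lines = [
        f"order\t{'->'.join(design.order)}",
        f"total_weight\t{design.total_weight:.6f}",
        f"sequence_length\t{len(design.sequence)}",
        f"contains_disallowed\t{str(design.contains_disallowed).lower()}",
        f"sequence\t{design.sequence}",
    ]
    for edge in design.junctions:
        lines.append(
            f"junction\t{edge.src}->{edge.dst}\tspacer={edge.spacer or '-'}"
            f"\tweight={edge.weight:.6f}\tallowed={str(edge.allowed).lower()}"
        )
    if config is not None:
        lines.append(f"config\ttap_threshold={config.tap_threshold}"
                     f"\tmax_flank={config.max_flank}"
                     f"\tjunction_lengths={','.join(map(str, config.junction_lengths))}"
                     f"\tcleavage_allow={config.cleavage_allow_threshold}"
                     f"\tdisallowed_weight={config.disallowed_weight:g}"
                     f"\tseed={config.seed}")
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
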