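"""File-format readers and writers (CSV/TSV, FASTA, Newick, JSON).

All tables are UTF-8 with a header row and "." decimals.  Each written
output is accompanied by a manifest entry (config hash, seed, version) in
the run's ``manifest.json``; see :mod:`microniche.pipeline`.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .ecoplate import PLATE_COLUMNS


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"culture_id": str})
    if "partner_id" not in df.columns:
        df["partner_id"] = ""
    df["partner_id"] = df["partner_id"].fillna("").astype(str)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV {path} lacks columns {sorted(missing)}")
    return df[list(PLATE_COLUMNS)]


def write_plate_csv(plates: pd.DataFrame, path) -> None:
    plates[list(PLATE_COLUMNS)].to_csv(path, index=False)


def read_node_sets_tsv(path) -> dict[str, set[str]]:
    """Per-strain metabolite node sets from a two-column TSV
    (strain_id, node_id; one node per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"strain_id", "node_id"}.issubset(df.columns):
        raise ValueError(f"node-set TSV {path} needs columns strain_id, node_id")
    sets = {s: set(g["node_id"]) for s, g in df.groupby("strain_id")}
    for s, nodes in sets.items():
        if not nodes:
            raise ValueError(f"strain {s} has an empty node set")
    return sets


def write_node_sets_tsv(node_sets: dict[str, set[str]], path) -> None:
    rows = [
        {"strain_id": s, "node_id": n}
        for s in sorted(node_sets) for n in sorted(node_sets[s])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alignment_fasta(path) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if len(seqs) < 2:
        raise ValueError(f"alignment {path} has fewer than two sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"alignment {path} has unequal sequence lengths {lengths}")
    return seqs


def write_alignment_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n{seqs[name]}\n")


def read_inhibition_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"focal": str, "target": str})
    required = {"focal", "target", "resource_level", "halo"}
    if not required.issubset(df.columns):
        raise ValueError(f"inhibition CSV {path} needs columns {sorted(required)}")
    return df


def read_growth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"time_h", "od"}.issubset(df.columns):
        raise ValueError(f"growth CSV {path} needs columns time_h, od")
    return df


def read_supernatant_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"grower": str, "donor": str})
    required = {"grower", "donor", "resource_level", "replicate",
                "od_spent", "od_fresh"}
    if not required.issubset(df.columns):
        raise ValueError(f"supernatant CSV {path} needs columns {sorted(required)}")
    return df


def write_matrix_csv(matrix: pd.DataFrame, path) -> None:
    """Square distance matrix with header row and label column."""
    matrix.to_csv(path, index_label="id")


def read_matrix_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
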