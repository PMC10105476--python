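"""Readers and writers for the package's plain-text exchange formats.

Every tabular artifact is TSV; gene sets are GMT (tab-delimited: name,
description, genes...); reports are JSON.  The universal in-memory
container for omics data is a pandas DataFrame with features in rows and
samples in columns (an "omics matrix").
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "Opensea")
POSITION_CLASSES = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR")


def read_omics_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample numeric matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_omics_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t", index_label="feature")


def read_cpg_annotation(path: str | Path) -> pd.DataFrame:
    """Read a CpG probe annotation table (probe_id, gene, island_relation,
    position_class) and validate its closed vocabularies."""
    annot = pd.read_csv(path, sep="\t", dtype=str)
    validate_cpg_annotation(annot)
    return annot


def validate_cpg_annotation(annot: pd.DataFrame) -> None:
    required = {"probe_id", "gene", "island_relation", "position_class"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"CpG annotation missing columns: {sorted(missing)}")
    bad_rel = set(annot["island_relation"]) - set(ISLAND_RELATIONS)
    if bad_rel:
        raise ValueError(f"unknown island_relation values: {sorted(bad_rel)}")
    bad_pos = set(annot["position_class"]) - set(POSITION_CLASSES)
    if bad_pos:
        raise ValueError(f"unknown position_class values: {sorted(bad_pos)}")
    if annot.duplicated(["probe_id", "gene"]).any():
        raise ValueError("duplicate probe_id-gene rows in CpG annotation")


def write_cpg_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index=False)


def read_target_list(path: str | Path, source_name: str | None = None):
    """Read a 2-column miRNA->gene target list; returns (name, set of pairs)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"target list {path} needs >= 2 columns (mirna, gene)")
    pairs = set(zip(df.iloc[:, 0], df.iloc[:, 1]))
    name = source_name if source_name is not None else Path(path).stem
    return name, pairs


def write_target_list(pairs, path: str | Path) -> None:
    df = pd.DataFrame(sorted(pairs), columns=["mirna", "gene"])
    df.to_csv(path, sep="\t", index=False)


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival table (sample, time, event in {0,1})."""
    surv = pd.read_csv(path, sep="\t", dtype={"sample": str})
    validate_survival_table(surv)
    return surv


def validate_survival_table(surv: pd.DataFrame) -> None:
    required = {"sample", "time", "event"}
    missing = required - set(surv.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if surv["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in survival table")
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not set(surv["event"].unique()) <= {0, 1}:
        raise ValueError("event must be 0 (censored) or 1 (event)")


def write_survival_table(surv: pd.DataFrame, path: str | Path) -> None:
    surv.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered {set name: gene list} mapping."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name in GMT: {name}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"empty gene set in GMT: {name}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
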