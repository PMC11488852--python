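"""Plain-text readers and writers for the pipeline's file contracts.

Counts are TSV with genes in rows and samples in columns; sample metadata
is CSV indexed by sample; allele depths are tidy TSV (scaffold, pos,
allele, group, genotype, depth, library_size); mating trials are CSV;
gene annotation is TSV (gene, chromosome, family); differential
expression results are TSV (id, log2fc, t, p, p_adj); ground truth is
JSON.  These match the deposited-data formats the pipeline accepts, so a
fetched copy of the study deposit can be run through the same entry
points.
"""

from __future__ import annotations

import pandas as pd

from .de import DEResult

__all__ = [
    "write_counts", "read_counts",
    "write_metadata", "read_metadata",
    "write_allele_depths", "read_allele_depths",
    "write_trials", "read_trials",
    "write_de_result", "read_de_result",
    "write_annotation", "read_annotation",
    "write_module_table", "read_module_table",
]


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index_label="sample")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample")


def write_allele_depths(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_allele_depths(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_de_result(result: DEResult, path) -> None:
    table = result.table.copy()
    table.index.name = "id"
    table.to_csv(path, sep="\t")


def read_de_result(path, contrast: str = "IIIM-YM") -> DEResult:
    table = pd.read_csv(path, sep="\t", index_col="id")
    return DEResult(table=table, contrast=contrast)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="gene")


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_module_table(modules: pd.Series, kwithin: pd.Series, path) -> None:
    pd.DataFrame({"module": modules, "kWithin": kwithin}).to_csv(
        path, sep="\t", index_label="gene"
    )


def read_module_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
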