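"""Readers and writers for the pipeline's text dialects.

- pedigree CSV: header ``animal,sire,dam,generation,sex`` (generation/sex
  optional on read); ``0`` = unknown parent.
- phenotype CSV: header with the standard record columns.
- genotype dosage file (PLINK .raw-like, marker-major): header
  ``marker_id,<animal ids...>``; fields 0/1/2 or ``NA`` for missing.
- quality matrix: same shape/dialect, float scores.
- map TSV: ``chrom  marker_id  bp`` (1-based positions, sorted).

All positions are 1-based inclusive. Malformed lines raise errors carrying
file and line context.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import PHENOTYPE_COLUMNS, GenotypePanel, Pedigree, validate_phenotypes


class DialectError(ValueError):
    """A file failed the strict dialect checks."""


def write_pedigree(pedigree: Pedigree, path: str) -> None:
    pedigree.df.to_csv(path, index=False)


def read_pedigree(path: str) -> Pedigree:
    df = pd.read_csv(path, dtype=str)
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise DialectError(f"{path}: missing column {col!r}")
        df[col] = df[col].fillna("0")
    if "generation" not in df.columns:
        df["generation"] = _infer_generations(df)
    df["generation"] = df["generation"].astype(int)
    if "sex" not in df.columns:
        df["sex"] = "F"
    try:
        return Pedigree(df)
    except ValueError as exc:
        raise DialectError(f"{path}: {exc}") from exc


def _infer_generations(df: pd.DataFrame) -> list[int]:
    gen: dict[str, int] = {}
    out = []
    for row in df.itertuples(index=False):
        g = 0
        for parent in (row.sire, row.dam):
            if parent != "0" and parent in gen:
                g = max(g, gen[parent] + 1)
        gen[row.animal] = g
        out.append(g)
    return out


def write_phenotypes(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    try:
        validate_phenotypes(df)
    except ValueError as exc:
        raise DialectError(f"{path}: {exc}") from exc
    return df


def write_genotypes(panel: GenotypePanel, prefix: str) -> dict[str, str]:
    """Write dosages, quality and map next to each other; returns paths."""
    paths = {"dosages": prefix + ".dosages.csv",
             "quality": prefix + ".quality.csv",
             "map": prefix + ".map.tsv"}
    dos = pd.DataFrame(panel.dosages, columns=panel.animal_ids)
    dos.insert(0, "marker_id", panel.marker_ids)
    dos.to_csv(paths["dosages"], index=False, na_rep="NA")
    qual = pd.DataFrame(np.round(panel.quality, 4), columns=panel.animal_ids)
    qual.insert(0, "marker_id", panel.marker_ids)
    qual.to_csv(paths["quality"], index=False)
    panel.marker_map.to_csv(paths["map"], sep="\t", index=False)
    return paths


def read_map(path: str) -> pd.DataFrame:
    mmap = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "marker_id", "bp"):
        if col not in mmap.columns:
            raise DialectError(f"{path}: missing column {col!r}")
    grouped = mmap.groupby("chrom", sort=False)["bp"]
    if not all(g.is_monotonic_increasing for _, g in grouped):
        raise DialectError(
            f"{path}: map not sorted by (chrom, bp); sort it and retry")
    return mmap


def read_genotypes(dosage_path: str, map_path: str,
                   quality_path: str | None = None) -> GenotypePanel:
    mmap = read_map(map_path)
    dos = pd.read_csv(dosage_path, na_values=["NA"])
    if "marker_id" != dos.columns[0]:
        raise DialectError(f"{dosage_path}: first column must be marker_id")
    if list(dos["marker_id"]) != list(mmap["marker_id"]):
        raise DialectError(
            f"{dosage_path}: marker order differs from {map_path}")
    animal_ids = list(dos.columns[1:])
    dosages = dos.iloc[:, 1:].to_numpy(float)
    bad = ~(np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise DialectError(
            f"{dosage_path}: line {r + 2}, column {c + 2}: dosage "
            f"{dosages[r, c]!r} not in {{0,1,2,NA}}")
    if quality_path is not None and os.path.exists(quality_path):
        qual = pd.read_csv(quality_path)
        quality = qual.iloc[:, 1:].to_numpy(float)
        if quality.shape != dosages.shape:
            raise DialectError(f"{quality_path}: shape differs from dosages")
    else:  # absent quality file: every genotype passes the GC rule
        quality = np.ones_like(dosages)
    try:
        return GenotypePanel(dosages, quality, mmap, animal_ids)
    except ValueError as exc:
        raise DialectError(f"{dosage_path}: {exc}") from exc


def write_chain(chain, path: str) -> None:
    chain.to_frame().to_csv(path, index=False)


def read_chain(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sigma_a2" not in df.columns:
        raise DialectError(f"{path}: not a chain file (no sigma_a2 column)")
    return df


def write_sparse_coo(matrix, path: str) -> None:
    """Coordinate-format text (i, j, value), 1-based indices."""
    coo = matrix.tocoo()
    with open(path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1}\t{j + 1}\t{v:.10g}\n")
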