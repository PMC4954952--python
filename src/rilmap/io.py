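"""Readers and writers for the map, genotype and trait tables.

All genomic coordinates are genetic (cM).  The canonical genotype file is
"rotated": markers as rows (marker, chromosome, position_cM, then one
column per line, calls in {A, B, NA}); the transposed orientation (lines as
rows) is accepted via a flag.  Trait data interchange is a long-format CSV
``line,experiment,block,trait,value``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mapping import GeneticMap, GenotypeMatrix

TRAIT_COLUMNS = ["line", "experiment", "block", "trait", "value"]
_GENO_META = ["marker", "chromosome", "position_cM"]


def read_map(path) -> GeneticMap:
    """Map CSV with columns marker, chromosome, position_cM."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for req in ("marker", "chromosome"):
        if req not in cols:
            raise ValueError(f"map file missing column {req!r}")
    pos_col = cols.get("position_cm")
    if pos_col is None:
        raise ValueError("map file missing column 'position_cM'")
    out = df.rename(
        columns={cols["marker"]: "marker", cols["chromosome"]: "chromosome", pos_col: "position_cm"}
    )
    return GeneticMap.from_frame(out)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.rename(columns={"position_cm": "position_cM"}).to_csv(path, index=False)


def read_genotypes(path, orientation: str = "markers_as_rows"):
    """Genotype CSV -> (marker metadata frame, GenotypeMatrix).

    markers_as_rows (default): columns marker, chromosome, position_cM then
    one column per line.  lines_as_rows: first column ``line`` then one
    column per marker (no map metadata; pair with a map file).
    """
    df = pd.read_csv(path, dtype=str)
    if orientation == "markers_as_rows":
        missing = [c for c in _GENO_META if c not in df.columns]
        if missing:
            raise ValueError(f"genotype file missing columns: {missing}")
        line_cols = [c for c in df.columns if c not in _GENO_META]
        if not line_cols:
            raise ValueError("genotype file has no line columns")
        meta = df[_GENO_META].rename(columns={"position_cM": "position_cm"})
        meta["position_cm"] = meta["position_cm"].astype(float)
        calls = df[line_cols].fillna("NA").to_numpy().T  # lines x markers
        geno = GenotypeMatrix.from_strings(line_cols, calls)
        return meta, geno
    if orientation == "lines_as_rows":
        if df.columns[0] != "line":
            raise ValueError("transposed genotype file must start with a 'line' column")
        markers = list(df.columns[1:])
        calls = df[markers].fillna("NA").to_numpy()
        geno = GenotypeMatrix.from_strings(df["line"].tolist(), calls)
        meta = pd.DataFrame({"marker": markers})
        return meta, geno
    raise ValueError(f"unknown orientation: {orientation!r}")


def write_genotypes(gmap: GeneticMap, genotypes: GenotypeMatrix, path) -> None:
    """Write the rotated (markers-as-rows) genotype CSV."""
    body = pd.DataFrame(
        genotypes.to_strings().T, columns=genotypes.line_ids
    )
    meta = gmap.table.rename(columns={"position_cm": "position_cM"}).reset_index(drop=True)
    pd.concat([meta, body], axis=1).to_csv(path, index=False)


def read_genotype_map(map_path, genotype_path, orientation: str = "markers_as_rows"):
    """Read and cross-validate the map and genotype files together."""
    gmap = read_map(map_path)
    meta, geno = read_genotypes(genotype_path, orientation)
    markers = list(meta["marker"])
    map_markers = list(gmap.table["marker"])
    extra = set(markers) - set(map_markers)
    if extra:
        raise ValueError(f"genotype marker(s) absent from map: {sorted(extra)[:5]}")
    missing = set(map_markers) - set(markers)
    if missing:
        raise ValueError(f"map marker(s) absent from genotypes: {sorted(missing)[:5]}")
    if markers != map_markers:  # reorder columns to map order
        order = [markers.index(m) for m in map_markers]
        geno = GenotypeMatrix(geno.line_ids, geno.calls[:, order], geno.parents)
    return gmap, geno


def read_trait_table(path) -> pd.DataFrame:
    """Long-format trait CSV with validated keys and numeric values."""
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait file missing columns: {missing}")
    df = df[TRAIT_COLUMNS].copy()
    df["line"] = df["line"].astype(str)
    df["experiment"] = df["experiment"].astype(int)
    df["block"] = df["block"].astype(int)
    df["trait"] = df["trait"].astype(str)
    try:
        df["value"] = pd.to_numeric(df["value"])
    except (ValueError, TypeError) as err:
        raise ValueError(f"non-numeric trait values: {err}") from err
    dup = df.duplicated(subset=["line", "experiment", "block", "trait"])
    if dup.any():
        key = df.loc[dup, ["line", "experiment", "block", "trait"]].iloc[0].tolist()
        raise ValueError(f"duplicated observation key: {key}")
    return df


def write_trait_table(traits: pd.DataFrame, path) -> None:
    traits[TRAIT_COLUMNS].to_csv(path, index=False)


def require_columns(df: pd.DataFrame, columns, table_name: str) -> None:
    """Schema guard used by every table writer in the pipeline."""
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{table_name} table missing columns: {missing}")


def write_table(df: pd.DataFrame, columns, path, table_name: str) -> None:
    require_columns(df, columns, table_name)
    df[list(columns)].to_csv(path, index=False)
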