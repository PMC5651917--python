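"""Tab-delimited readers and writers for genotypes, phenotypes, kinship
matrices and genetic maps.

All files are plain TSV with a header row; lines starting with ``#`` are
comments (output files begin with a parameter header).  Kinship matrices
round-trip at 17 significant digits, i.e. bit-exactly for doubles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix
from .simulate import GeneticMap, GenotypeMatrix, PhenotypeTable

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_phenotypes", "write_phenotypes",
    "read_kinship", "write_kinship",
    "read_map", "write_map",
    "format_header",
]

_VALID_CODES = (-1, 0, 1)


def format_header(subcommand: str, params: dict) -> str:
    """Comment header recording tool version, subcommand and parameters."""
    from . import __version__
    lines = [f"# gsherit {__version__}", f"# subcommand: {subcommand}"]
    for key, val in params.items():
        lines.append(f"# {key}: {val}")
    return "\n".join(lines) + "\n"


def read_genotypes(path, missing: str = "NA") -> GenotypeMatrix:
    """Genotype TSV: first column individual id, header row of locus ids,
    body codes in {-1, 0, 1} (``missing`` token becomes NaN for later
    imputation)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     na_values=[missing], keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate individual id {dup!r} in {path}")
    values = df.to_numpy()
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric genotype cell in {path}: {exc}") from exc
    bad = ~np.isin(values, _VALID_CODES) & ~np.isnan(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype code {values[i, j]!r} at individual "
            f"{df.index[i]!r}, locus {df.columns[j]!r} in {path}"
        )
    if not np.isnan(values).any():
        values = values.astype(np.int8)
    return GenotypeMatrix(values, tuple(map(str, df.index)),
                          tuple(map(str, df.columns)))


def write_genotypes(geno: GenotypeMatrix, path, header: str = "") -> None:
    df = pd.DataFrame(geno.values, index=list(geno.individual_ids),
                      columns=list(geno.locus_ids))
    df.index.name = "id"
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t")


def read_phenotypes(path) -> PhenotypeTable:
    """Phenotype TSV with columns id, replicate, value."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"id": str})
    missing = {"id", "replicate", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file {path} lacks columns {sorted(missing)}")
    return PhenotypeTable(df[["id", "replicate", "value"]])


def write_phenotypes(pheno: PhenotypeTable, path, header: str = "",
                     genetic_values_path=None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        pheno.data.to_csv(fh, sep="\t", index=False)
    if genetic_values_path is not None and pheno.genetic_values is not None:
        xi = pheno.genetic_values.rename_axis("id").rename("xi")
        with open(genetic_values_path, "w") as fh:
            if header:
                fh.write(header)
            xi.to_csv(fh, sep="\t")


def read_kinship(path) -> KinshipMatrix:
    """Square kinship TSV with id header row and id first column."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     float_precision="round_trip")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"kinship file {path} row/column ids disagree")
    return KinshipMatrix(df.to_numpy(dtype=float),
                         tuple(map(str, df.index)))


def write_kinship(K: KinshipMatrix, path, header: str = "") -> None:
    df = pd.DataFrame(K.values, index=list(K.individual_ids),
                      columns=list(K.individual_ids))
    df.index.name = "id"
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", float_format="%.17g")


def read_map(path) -> GeneticMap:
    """Map TSV with columns chromosome, locus, position_cm."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"chromosome", "locus", "position_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"map file {path} lacks columns {sorted(missing)}")
    return GeneticMap(df["chromosome"].to_numpy(),
                      df["position_cm"].to_numpy(dtype=float),
                      tuple(map(str, df["locus"])))


def write_map(gmap: GeneticMap, path, header: str = "") -> None:
    df = pd.DataFrame({
        "chromosome": gmap.chromosome,
        "locus": list(gmap.locus_ids),
        "position_cm": gmap.position_cm,
    })
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", index=False)
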