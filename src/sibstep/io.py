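"""Readers and writers for the tabular dialects used around BLUP pipelines.

Pedigree and phenotype tables are plain CSV.  Genotypes come in two
dialects: the BLUPF90 convention (animal id followed by a fixed-width
string of 0/1/2 gene contents, 5 = missing) and the PLINK ``.raw``
additive export (header row, NA = missing).  Sparse relationship matrices
are exchanged as 1-based coordinate text (i, j, value).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .genomic import MISSING, GenotypeMatrix
from .pedigree import Pedigree, validate_and_renumber

__all__ = [
    "write_pedigree_csv",
    "read_pedigree_csv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
    "write_genotypes_blupf90",
    "read_genotypes_blupf90",
    "write_genotypes_raw",
    "read_genotypes_raw",
    "write_coordinate_matrix",
    "read_coordinate_matrix",
    "write_truth_csv",
    "FormatError",
]


class FormatError(ValueError):
    """A file violated its declared dialect; message carries the location."""


# -- pedigree / phenotypes -------------------------------------------------


def write_pedigree_csv(ped: Pedigree, path, batches: pd.DataFrame | None = None) -> None:
    df = ped.to_frame()
    if batches is not None and "batch" in batches.columns:
        lut = batches.set_index("family_id")["batch"]
        df["batch"] = lut.reindex(df["family_id"]).fillna("").to_numpy()
    df.to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "animal_id" not in df.columns:
        raise FormatError(f"{path}: pedigree CSV needs a header with animal_id")
    return validate_and_renumber(df)


def write_phenotypes_csv(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str, "generation": str, "batch": str, "family_id": str})
    required = {"animal_id", "tag_weight_g"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: phenotype CSV lacks columns {sorted(missing)}")
    return df


# -- genotypes -------------------------------------------------------------


def write_genotypes_blupf90(gm: GenotypeMatrix, path) -> None:
    """BLUPF90 dialect: id, space, fixed-width gene-content string, 5 = missing.

    Fractional (imputed) gene content cannot be represented; round first or
    use the .raw writer.
    """
    vals = gm.values
    if np.issubdtype(vals.dtype, np.floating):
        if np.any(np.isnan(vals)):
            vals = np.where(np.isnan(vals), MISSING, vals)
        if not np.allclose(vals[vals != MISSING] % 1, 0):
            raise FormatError("BLUPF90 dialect cannot hold fractional gene content")
        vals = vals.astype(np.int64)
    width = max(len(str(s)) for s in gm.sample_ids) + 1
    with open(path, "w") as fh:
        for sid, row in zip(gm.sample_ids, vals):
            s = "".join("5" if g == MISSING else str(int(g)) for g in row)
            fh.write(f"{str(sid):<{width}}{s}\n")


def read_genotypes_blupf90(path, snp_ids=None) -> GenotypeMatrix:
    samples, rows = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 'id genotypes', got {len(parts)} fields")
            sid, s = parts
            row = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
            bad = ~np.isin(row, (0, 1, 2, 5))
            if bad.any():
                col = int(np.flatnonzero(bad)[0]) + 1
                raise FormatError(
                    f"{path}:{ln}: illegal gene-content code {s[col - 1]!r} "
                    f"for animal {sid} at SNP column {col}"
                )
            samples.append(sid)
            rows.append(row.astype(np.int8))
    vals = np.vstack(rows)
    if len({len(r) for r in rows}) != 1:
        raise FormatError(f"{path}: ragged genotype rows")
    vals[vals == 5] = MISSING
    if snp_ids is None:
        snp_ids = [f"SNP{j + 1}" for j in range(vals.shape[1])]
    return GenotypeMatrix(np.asarray(samples, dtype=object), np.asarray(snp_ids, dtype=object), vals)


_RAW_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_genotypes_raw(gm: GenotypeMatrix, path) -> None:
    """PLINK .raw additive dialect (NA = missing)."""
    vals = gm.values
    miss = gm.missing_mask()
    with open(path, "w") as fh:
        fh.write(" ".join(_RAW_LEAD + [f"{s}_A" for s in gm.snp_ids]) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            row = vals[i]
            cells = [
                "NA" if miss[i, j] else (str(int(row[j])) if float(row[j]).is_integer() else f"{row[j]:g}")
                for j in range(gm.n_snps)
            ]
            fh.write(f"{sid} {sid} 0 0 0 -9 " + " ".join(cells) + "\n")


def read_genotypes_raw(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if header[: len(_RAW_LEAD)] != _RAW_LEAD:
            raise FormatError(f"{path}:1: not a PLINK .raw header")
        snp_ids = [c[:-2] if c.endswith("_A") else c for c in header[len(_RAW_LEAD):]]
        samples, rows = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if len(parts) != len(header):
                raise FormatError(f"{path}:{ln}: expected {len(header)} fields, got {len(parts)}")
            samples.append(parts[1])
            row = np.empty(len(snp_ids), dtype=np.float64)
            for j, tok in enumerate(parts[len(_RAW_LEAD):]):
                if tok == "NA":
                    row[j] = np.nan
                else:
                    try:
                        row[j] = float(tok)
                    except ValueError:
                        raise FormatError(
                            f"{path}:{ln}: illegal gene content {tok!r} at SNP {snp_ids[j]}"
                        ) from None
            rows.append(row)
    vals = np.vstack(rows)
    if np.all(np.isnan(vals) | (vals % 1 == 0)):
        ints = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
        bad = ~np.isin(ints, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"{path}: illegal gene content {vals[i, j]} for {samples[i]} at {snp_ids[j]}"
            )
        vals = ints
    return GenotypeMatrix(np.asarray(samples, dtype=object), np.asarray(snp_ids, dtype=object), vals)


# -- matrices / truth ------------------------------------------------------


def write_coordinate_matrix(M: sparse.spmatrix, path) -> None:
    """1-based (i, j, value) text for a sparse symmetric matrix."""
    coo = sparse.coo_matrix(M)
    with open(path, "w") as fh:
        fh.write(f"# {coo.shape[0]} {coo.shape[1]}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1} {j + 1} {v:.12g}\n")


def read_coordinate_matrix(path) -> sparse.csr_matrix:
    with open(path) as fh:
        head = fh.readline().split()
        n, m = int(head[1]), int(head[2])
        rows, cols, vals = [], [], []
        for line in fh:
            i, j, v = line.split()
            rows.append(int(i) - 1)
            cols.append(int(j) - 1)
            vals.append(float(v))
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, m)).tocsr()


def write_truth_csv(truth, path) -> None:
    df = pd.DataFrame({"animal_id": truth.animal_ids, "tbv": truth.tbv})
    if truth.tbv2 is not None:
        df["tbv2"] = truth.tbv2
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_solutions_tsv(solution, path) -> None:
    """Mixed-model solutions as TSV: effect class, level/id, estimate."""
    rows = []
    for name, est in solution.b.items():
        rows.append(("fixed", name, est))
    for aid, est in solution.u.items():
        rows.append(("animal", aid, est))
    if solution.c is not None:
        for fid, est in solution.c.items():
            rows.append(("family", fid, est))
    pd.DataFrame(rows, columns=["effect", "level", "estimate"]).to_csv(
        path, sep="\t", index=False
    )
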