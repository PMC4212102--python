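"""File readers and writers for the pipeline's plain-text formats.

Pedigree and phenotype tables are CSV; genotypes use a PLINK-.raw-like
dialect (header of SNP ids, then one row per animal: id followed by
whitespace-separated 0/1/2/NA dosages); relationship matrices are
exchanged in coordinate (i, j, value) text with an id-map sidecar.
Readers reject malformed input with line-addressed messages rather
than coercing silently.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .genomic import GenotypeMatrix
from .pedigree import PedigreeTable

log = logging.getLogger("ssgblup")

__all__ = [
    "ParseError",
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "write_report",
    "write_matrix_coo",
    "read_matrix_coo",
    "load_config",
    "save_sim_output",
]


class ParseError(ValueError):
    pass


def read_pedigree(path) -> PedigreeTable:
    """CSV with columns animal,sire,dam[,birth_year,breed,sex]; 0/empty = unknown."""
    df = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str})
    try:
        return PedigreeTable.from_frame(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_genotypes(path, ped: PedigreeTable | None = None) -> GenotypeMatrix:
    """PLINK-.raw-like text: header 'animal snp1 snp2 ...', rows of dosages.

    Breed labels are taken from the pedigree when given (empty
    otherwise).  Ragged rows and illegal dosage codes raise
    :class:`ParseError` with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 2:
            raise ParseError(f"{path}:1: expected 'animal' plus SNP ids in the header")
        snp_ids = header[1:]
        ids, rows = [], []
        for ln, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != len(snp_ids) + 1:
                raise ParseError(
                    f"{path}:{ln}: expected {len(snp_ids) + 1} fields, got {len(tok)}"
                )
            ids.append(tok[0])
            row = np.empty(len(snp_ids))
            for j, t in enumerate(tok[1:]):
                if t in ("NA", "na", "nan"):
                    row[j] = np.nan
                elif t in ("0", "1", "2"):
                    row[j] = float(t)
                else:
                    raise ParseError(
                        f"{path}:{ln}: illegal dosage code {t!r} (want 0/1/2/NA)"
                    )
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no genotype rows")
    breed = np.full(len(ids), "", dtype=object)
    if ped is not None:
        idx = ped.indices_of(ids)
        breed = ped.breed[idx]
    return GenotypeMatrix(
        ids=np.array(ids, dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        dosages=np.vstack(rows),
        breed=breed,
    )


def write_genotypes(genos: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal " + " ".join(str(s) for s in genos.snp_ids) + "\n")
        for i, a in enumerate(genos.ids):
            row = [
                "NA" if np.isnan(v) else str(int(v)) for v in genos.dosages[i]
            ]
            fh.write(f"{a} " + " ".join(row) + "\n")


def read_phenotypes(path) -> pd.DataFrame:
    """Long-format CSV: animal,breed,trait,parity,herd,year,weight,value."""
    df = pd.read_csv(path, dtype={"animal": str})
    for col in ("animal", "value"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if "weight" not in df.columns:
        log.warning("%s: no weight column; defaulting all record weights to 1.0", path)
        df["weight"] = 1.0
    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any():
        ln = int(df.index[vals.isna()][0]) + 2
        raise ParseError(f"{path}:{ln}: non-numeric record value")
    df["value"] = vals
    w = pd.to_numeric(df["weight"], errors="coerce")
    if w.isna().any() or (w <= 0).any():
        bad = w.isna() | (w <= 0)
        ln = int(df.index[bad][0]) + 2
        raise ParseError(f"{path}:{ln}: record weight must be a positive number")
    df["weight"] = w
    if not np.all(np.isfinite(df["value"])):
        raise ParseError(f"{path}: non-finite record value")
    return df


def write_phenotypes(phenos: pd.DataFrame, path) -> None:
    phenos.to_csv(path, index=False)


def write_report(report: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write a result table as TSV or JSON (identical numbers either way)."""
    path = Path(path)
    if fmt == "tsv":
        report.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif fmt == "json":
        records = json.loads(report.to_json(orient="records"))
        path.write_text(json.dumps(records, indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def write_matrix_coo(mat, ids, path) -> None:
    """Matrix in coordinate text (i j value, 0-based) + .ids sidecar."""
    path = Path(path)
    if sp.issparse(mat):
        coo = mat.tocoo()
        trip = zip(coo.row, coo.col, coo.data)
    else:
        mat = np.asarray(mat)
        nz = np.nonzero(mat)
        trip = zip(nz[0], nz[1], mat[nz])
    with open(path, "w") as fh:
        for i, j, v in trip:
            fh.write(f"{i} {j} {v:.12g}\n")
    Path(str(path) + ".ids").write_text("\n".join(str(a) for a in ids) + "\n")


def read_matrix_coo(path, dense: bool = True):
    path = Path(path)
    data = np.loadtxt(path, ndmin=2)
    ids = Path(str(path) + ".ids").read_text().split()
    n = len(ids)
    mat = sp.coo_matrix((data[:, 2], (data[:, 0].astype(int), data[:, 1].astype(int))), shape=(n, n))
    return (mat.toarray() if dense else mat.tocsr()), ids


def load_config(path) -> dict:
    """YAML key-value run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: expected a mapping of options")
    for key in ("maf_min", "callrate_min", "tau"):
        if key in cfg and not (0.0 < float(cfg[key]) <= 1.0):
            raise ParseError(f"{path}: {key} must lie in (0, 1]")
    return cfg


def save_sim_output(sim, out_dir) -> dict:
    """Write a simulated dataset (pedigree, genotypes, phenotypes, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.csv",
        "genotypes": out / "genotypes.raw",
        "phenotypes": out / "phenotypes.csv",
        "true_values": out / "true_values.csv",
        "params": out / "true_params.yaml",
    }
    write_pedigree(sim.pedigree, paths["pedigree"])
    write_genotypes(sim.genotypes, paths["genotypes"])
    write_phenotypes(sim.phenotypes, paths["phenotypes"])
    truth = pd.DataFrame(
        {
            "animal": sim.pedigree.ids,
            f"true_bv_{sim.config.breeds[0]}": sim.true_bv[:, 0],
            f"true_bv_{sim.config.breeds[1]}": sim.true_bv[:, 1],
            "true_pe": sim.true_pe,
        }
    )
    truth.to_csv(paths["true_values"], index=False)
    with open(paths["params"], "w") as fh:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in sim.true_params.items()},
            fh,
        )
    return {k: str(v) for k, v in paths.items()}
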