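"""Plain-text I/O: genotype/marker/family tables, phenotypes, allocations.

Schemas
-------
genotypes.tsv   first column ``ril_id``, one column per marker; entries in
                {0, 1, 2} or ``NA`` for missing.
markers.tsv     columns ``marker``, ``chromosome``, ``order``.
families.tsv    columns ``ril_id``, ``family_id``, ``ancestry_group``.
phenotypes.csv  columns ``ril_id,family_id,ancestry_group,env_id,value,observed``.
allocation.json ``{"envs": {env: {"no_rils": [...], "o_rils": [...],
                "prediction": [...]}}, "o_rils": [...], "meta": {...}}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sparse_design import Allocation
from .synthetic_nam import NamPopulation


class IOError_(ValueError):
    """Malformed input file."""


def write_genotypes(pop: NamPopulation, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    markers = pop.marker_map["marker"].tolist()
    geno = pd.DataFrame(pop.genotypes, columns=markers)
    geno.insert(0, "ril_id", pop.ril_ids)
    paths = {
        "genotypes": out_dir / "genotypes.tsv",
        "markers": out_dir / "markers.tsv",
        "families": out_dir / "families.tsv",
    }
    geno.to_csv(paths["genotypes"], sep="\t", index=False)
    pop.marker_map.to_csv(paths["markers"], sep="\t", index=False)
    pop.family_table().to_csv(paths["families"], sep="\t", index=False)
    return paths


def load_genotypes(
    path: str | Path,
    families_path: str | Path | None = None,
    markers_path: str | Path | None = None,
) -> dict:
    """Validated genotype matrix plus companion tables (when present).

    Returns a dict with ``matrix`` (float ndarray, NaN for missing),
    ``ril_ids``, ``markers`` and optional ``families`` / ``marker_map``
    frames. Duplicate RIL ids and dosages outside {0, 1, 2} are errors.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"ril_id": str})
    if "ril_id" not in table.columns:
        raise IOError_(f"{path}: first column must be 'ril_id'")
    ril_ids = table["ril_id"].tolist()
    dup = table["ril_id"].duplicated()
    if dup.any():
        raise IOError_(f"{path}: duplicate ril_id {table['ril_id'][dup].iloc[0]!r}")
    matrix = table.drop(columns="ril_id").to_numpy(dtype=float)
    bad = np.isfinite(matrix) & ~np.isin(matrix, (0.0, 1.0, 2.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise IOError_(
            f"{path}: invalid dosage {matrix[r, c]!r} at row {ril_ids[r]!r}, "
            f"column {table.columns[c + 1]!r}"
        )
    out = {
        "matrix": matrix,
        "ril_ids": ril_ids,
        "markers": list(table.columns[1:]),
    }
    if families_path is not None:
        fam = pd.read_csv(families_path, sep="\t", dtype=str)
        required = {"ril_id", "family_id", "ancestry_group"}
        if not required <= set(fam.columns):
            raise IOError_(f"{families_path}: needs columns {sorted(required)}")
        out["families"] = fam
    if markers_path is not None:
        out["marker_map"] = pd.read_csv(markers_path, sep="\t")
    return out


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pheno.to_csv(path, index=False)
    return path


def load_phenotypes(path: str | Path) -> pd.DataFrame:
    pheno = pd.read_csv(path, dtype={"ril_id": str, "family_id": str, "env_id": str})
    required = {"ril_id", "env_id", "value"}
    if not required <= set(pheno.columns):
        raise IOError_(f"{path}: needs columns {sorted(required)}")
    if "observed" not in pheno.columns:
        pheno["observed"] = True
    return pheno


def write_allocation(alloc: Allocation, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "envs": {
            str(j): {
                "no_rils": list(alloc.no_rils[j]),
                "prediction": list(alloc.prediction[j]),
            }
            for j in alloc.envs
        },
        "o_rils": list(alloc.o_rils),
        "never_observed": list(alloc.never_observed),
        "meta": alloc.meta,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_allocation(path: str | Path) -> Allocation:
    payload = json.loads(Path(path).read_text())
    envs = payload["envs"]
    alloc = Allocation(
        no_rils={int(j): tuple(v["no_rils"]) for j, v in envs.items()},
        o_rils=tuple(payload.get("o_rils", ())),
        prediction={int(j): tuple(v["prediction"]) for j, v in envs.items()},
        never_observed=tuple(payload.get("never_observed", ())),
        meta=payload.get("meta", {}),
    )
    alloc.validate()
    return alloc


def write_provenance(path: str | Path, **fields) -> Path:
    """Provenance JSON sufficient to re-run a stage bit-identically."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"package": "sparsegp", "version": __version__, **fields}
    path.write_text(json.dumps(payload, indent=1, default=str))
    return path
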