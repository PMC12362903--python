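"""File formats: PLINK .raw-style genotypes, locus maps, animal tables, GRMs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grm import GRM
from .popsim import GenomeMap, Population, TraitArchitecture

__all__ = [
    "write_genotypes_raw",
    "read_genotypes_raw",
    "write_locus_map",
    "write_animal_table",
    "write_grm_binary",
    "read_grm_binary",
    "write_grm_text",
]


def write_genotypes_raw(path, ids, dosages, locus_names) -> None:
    """Additive 0/1/2 genotypes in the PLINK ``--recode A`` (.raw) layout."""
    dosages = np.asarray(dosages)
    df = pd.DataFrame(dosages, columns=list(locus_names))
    meta = pd.DataFrame(
        {
            "FID": ids, "IID": ids,
            "PAT": 0, "MAT": 0, "SEX": 0, "PHENOTYPE": -9,
        }
    )
    pd.concat([meta, df], axis=1).to_csv(path, sep=" ", index=False)


def read_genotypes_raw(path):
    df = pd.read_csv(path, sep=r"\s+")
    ids = df["IID"].to_numpy()
    loci = [c for c in df.columns if c not in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
    return ids, df[loci].to_numpy(dtype=np.uint8), np.array(loci)


def write_locus_map(
    path, genome: GenomeMap, p: np.ndarray | None = None,
    arch: TraitArchitecture | None = None,
) -> None:
    """Tab-delimited locus table: chrom, id, cM, class, frequency, effect."""
    df = pd.DataFrame(
        {
            "chrom": genome.chromosome + 1,
            "id": genome.locus_ids,
            "cM": genome.position_cM,
            "class": genome.locus_class,
        }
    )
    if p is not None:
        df["frequency"] = np.asarray(p)
    if arch is not None:
        eff = np.zeros(genome.n_loci)
        eff[arch.qtl_loci] = arch.effects
        df["effect"] = eff
    df.to_csv(path, sep="\t", index=False)


def write_animal_table(path, pop: Population, role: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "id": pop.ids, "sire": pop.sire, "dam": pop.dam,
            "sex": np.where(pop.sex == 0, "M", "F"),
            "generation": pop.generation,
        }
    )
    for col, arr in (("tbv", pop.tbv), ("phenotype", pop.phenotype), ("ebv", pop.ebv)):
        if arr is not None:
            df[col] = arr
    if role is not None:
        df["role"] = role
    df.to_csv(path, index=False)


def write_grm_binary(path, grm: GRM, ids) -> None:
    np.savez_compressed(
        path, matrix=grm.matrix, p=grm.p, scale=grm.scale,
        weights=np.array([]) if grm.weights is None else grm.weights,
        ids=np.asarray(ids),
    )


def read_grm_binary(path):
    d = np.load(path, allow_pickle=False)
    w = d["weights"]
    return GRM(d["matrix"], d["p"], float(d["scale"]), None if w.size == 0 else w), d["ids"]


def write_grm_text(path, grm: GRM, ids) -> None:
    """Lower triangle as (id_i, id_j, value), common REML-tool interchange."""
    ids = np.asarray(ids)
    n = grm.n
    i, j = np.tril_indices(n)
    pd.DataFrame({"id1": ids[i], "id2": ids[j], "value": grm.matrix[i, j]}).to_csv(
        path, sep="\t", index=False, header=False
    )
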