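"""Text-format I/O: PLINK .ped/.map dialect, dosage CSV, pedigree CSV.

The PLINK dialect is the classic 6-column text format (family, animal, sire,
dam, sex, phenotype) followed by two space-separated alleles per SNP, coded
A/B; ``0 0`` marks a missing genotype. The companion .map file carries
chromosome, SNP id, genetic distance (unused, written 0) and base-pair
position; positions are converted to Mb in memory.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinship import Pedigree, RelationshipMatrix
from .qc import GenotypeMatrix

__all__ = [
    "read_plink",
    "write_plink",
    "read_dosage_csv",
    "write_dosage_csv",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_matrix_csv",
    "write_matrix_csv",
    "load_genotypes",
    "write_config",
    "read_config",
]

_ALLELE_TO_COUNT = {"A": 0, "B": 1}


def load_genotypes(path, format: str = "plink_ped_map", **kw) -> GenotypeMatrix:
    """Dispatch loader: ``plink_ped_map`` expects a shared prefix for .ped and
    .map; ``dosage_csv`` expects the dosage CSV path (SNP map in a companion
    ``<stem>.snps.csv`` unless ``map_path`` is given)."""
    if format == "plink_ped_map":
        return read_plink(path)
    if format == "dosage_csv":
        return read_dosage_csv(path, **kw)
    raise ValueError(f"unknown genotype format {format!r}")


def read_plink(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    chroms, snp_ids, pos_mb = [], [], []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ValueError(
                    f"{map_path}: line {ln}: expected 4 fields, got {len(fields)}"
                )
            chroms.append(fields[0])
            snp_ids.append(fields[1])
            try:
                pos_mb.append(float(fields[3]) / 1e6)
            except ValueError:
                raise ValueError(
                    f"{map_path}: line {ln}: bad position field {fields[3]!r}"
                ) from None
    n_snps = len(snp_ids)

    animal_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * n_snps} fields "
                    f"for {n_snps} SNPs, got {len(fields)}"
                )
            animal_ids.append(fields[1])
            dos = np.empty(n_snps)
            alleles = fields[6:]
            for j in range(n_snps):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    dos[j] = np.nan
                else:
                    c1 = _ALLELE_TO_COUNT.get(a1)
                    c2 = _ALLELE_TO_COUNT.get(a2)
                    if c1 is None or c2 is None:
                        dos[j] = np.nan  # unrecognized allele -> missing
                    else:
                        dos[j] = c1 + c2
            rows.append(dos)

    return GenotypeMatrix(
        animal_ids=animal_ids,
        snp_ids=snp_ids,
        chromosome=np.asarray(chroms),
        position_mb=np.asarray(pos_mb),
        dosage=np.vstack(rows) if rows else np.empty((0, n_snps)),
    )


def write_plink(g: GenotypeMatrix, prefix, pedigree: Pedigree | None = None) -> None:
    """Write .ped/.map; dosages must be integral or missing (mean-imputed
    fractional dosages have no biallelic representation)."""
    prefix = Path(prefix)
    obs = g.dosage[~np.isnan(g.dosage)]
    if obs.size and not np.allclose(obs, np.round(obs)):
        raise ValueError("fractional dosages cannot be written as .ped alleles")

    with open(prefix.with_suffix(".map"), "w") as fh:
        for c, s, pos in zip(g.chromosome, g.snp_ids, g.position_mb):
            fh.write(f"{c}\t{s}\t0\t{int(round(pos * 1e6))}\n")

    parents = {}
    if pedigree is not None:
        for i, a in enumerate(pedigree.ids):
            s = pedigree.sire[i]
            d = pedigree.dam[i]
            parents[str(a)] = (
                "0" if s < 0 else str(pedigree.ids[s]),
                "0" if d < 0 else str(pedigree.ids[d]),
            )
    geno_str = {0: "A A", 1: "A B", 2: "B B"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, a in enumerate(g.animal_ids):
            sire, dam = parents.get(str(a), ("0", "0"))
            cells = [
                "0 0" if np.isnan(d) else geno_str[int(round(d))]
                for d in g.dosage[i]
            ]
            fh.write("\t".join(["FAM1", str(a), sire, dam, "0", "-9"] + cells) + "\n")


def write_dosage_csv(g: GenotypeMatrix, path, map_path=None) -> None:
    path = Path(path)
    g.to_frame().to_csv(path, index_label="animal_id")
    map_path = Path(map_path) if map_path else path.with_suffix(".snps.csv")
    pd.DataFrame(
        {
            "snp_id": [str(s) for s in g.snp_ids],
            "chromosome": g.chromosome,
            "position_mb": g.position_mb,
        }
    ).to_csv(map_path, index=False)


def read_dosage_csv(path, map_path=None) -> GenotypeMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col="animal_id")
    map_path = Path(map_path) if map_path else path.with_suffix(".snps.csv")
    snps = pd.read_csv(map_path, dtype={"snp_id": str, "chromosome": str})
    if list(df.columns) != list(snps["snp_id"]):
        raise ValueError(f"{path}: SNP columns do not match map file {map_path}")
    return GenotypeMatrix(
        animal_ids=[str(a) for a in df.index],
        snp_ids=list(snps["snp_id"]),
        chromosome=snps["chromosome"].to_numpy(),
        position_mb=snps["position_mb"].to_numpy(dtype=float),
        dosage=df.to_numpy(dtype=float),
    )


def write_pedigree_csv(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str)
    return Pedigree.from_records(df[["animal", "sire", "dam"]].itertuples(index=False))


def write_matrix_csv(rel: RelationshipMatrix, path) -> None:
    rel.to_frame().to_csv(path, index_label="animal_id")


def read_matrix_csv(path, kind: str) -> RelationshipMatrix:
    df = pd.read_csv(path, index_col="animal_id")
    return RelationshipMatrix(kind=kind, ids=list(df.index), values=df.to_numpy())


def write_config(cfg, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def read_config(path, cls):
    with open(path) as fh:
        return cls(**yaml.safe_load(fh))
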