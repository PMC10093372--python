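"""Genotype container and sequential SNP quality control.

Dosages count copies of the B allele (0/1/2); missing entries are ``NaN``.
The QC pipeline applies three filters strictly in order: (a) animals with
more than 50% missing genotypes, (b) SNPs with more than 5% missing calls
among the surviving animals, (c) SNPs whose minor allele frequency —
computed after the first two removals — is below 10%. Missing entries are
then imputed, by per-SNP mean dosage or by drawing two Bernoulli(p) alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "QcReport", "apply_qc", "impute_missing"]


@dataclass
class GenotypeMatrix:
    """Animals × SNPs dosage matrix with map positions.

    ``dosage`` is float with ``NaN`` for missing calls; observed entries are
    0/1/2 counts of the B (counted) allele, or fractional values after mean
    imputation. ``position_mb`` holds megabase coordinates and must be
    strictly increasing within a chromosome.
    """

    animal_ids: list
    snp_ids: list
    chromosome: np.ndarray
    position_mb: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome)
        self.position_mb = np.asarray(self.position_mb, dtype=float)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, p = len(self.animal_ids), len(self.snp_ids)
        if self.dosage.shape != (n, p):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != ({n} animals, {p} snps)"
            )
        if self.chromosome.shape != (p,) or self.position_mb.shape != (p,):
            raise ValueError("chromosome/position arrays must have one entry per SNP")
        for c in np.unique(self.chromosome):
            pos = self.position_mb[self.chromosome == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    @property
    def allele_freq(self) -> np.ndarray:
        """B-allele frequency per SNP from observed calls (NaN if all missing)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.allele_freq
        return np.minimum(f, 1.0 - f)

    def subset(
        self,
        animals: np.ndarray | None = None,
        snps: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        ai = np.arange(self.n_animals) if animals is None else np.asarray(animals)
        si = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            animal_ids=[self.animal_ids[i] for i in ai],
            snp_ids=[self.snp_ids[j] for j in si],
            chromosome=self.chromosome[si],
            position_mb=self.position_mb[si],
            dosage=self.dosage[np.ix_(ai, si)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage,
            index=[str(a) for a in self.animal_ids],
            columns=[str(s) for s in self.snp_ids],
        )


@dataclass
class QcReport:
    n_animals_in: int
    n_animals_out: int
    n_snps_in: int
    n_snps_out: int
    removed_animals: dict = field(default_factory=dict)  # id -> missing fraction
    removed_snps_callrate: list = field(default_factory=list)
    removed_snps_maf: list = field(default_factory=list)
    n_imputed: int = 0

    def __post_init__(self) -> None:
        assert self.n_animals_in - len(self.removed_animals) == self.n_animals_out
        n_removed = len(self.removed_snps_callrate) + len(self.removed_snps_maf)
        assert self.n_snps_in - n_removed == self.n_snps_out
        assert not set(self.removed_snps_callrate) & set(self.removed_snps_maf)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("animal_missingness", str(a), frac)
            for a, frac in self.removed_animals.items()
        ]
        rows += [("snp_callrate", str(s), np.nan) for s in self.removed_snps_callrate]
        rows += [("snp_maf", str(s), np.nan) for s in self.removed_snps_maf]
        return pd.DataFrame(rows, columns=["filter", "id", "missing_fraction"])

    def summary(self) -> str:
        msg = (
            f"QC: {self.n_animals_in} -> {self.n_animals_out} animals "
            f"({len(self.removed_animals)} removed > missingness), "
            f"{self.n_snps_in} -> {self.n_snps_out} SNPs "
            f"({len(self.removed_snps_callrate)} removed by call rate, "
            f"{len(self.removed_snps_maf)} by MAF)"
        )
        if self.n_imputed:
            msg += f"; {self.n_imputed} genotypes imputed"
        return msg


def apply_qc(
    g: GenotypeMatrix,
    animal_missing_max: float = 0.50,
    snp_missing_max: float = 0.05,
    maf_min: float = 0.10,
) -> tuple[GenotypeMatrix, QcReport]:
    """Sequential three-stage quality control.

    The order matters and is fixed: animal missingness first, then SNP
    missingness among surviving animals, then MAF computed from the
    survivors of both earlier stages. Removal is strict (``>`` missingness,
    ``<`` MAF).
    """
    for t, name in (
        (animal_missing_max, "animal_missing_max"),
        (snp_missing_max, "snp_missing_max"),
        (maf_min, "maf_min"),
    ):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")

    miss = g.missing_mask
    # (a) animals
    an_frac = miss.mean(axis=1)
    keep_an = an_frac <= animal_missing_max
    removed_animals = {
        g.animal_ids[i]: float(an_frac[i]) for i in np.flatnonzero(~keep_an)
    }
    if not keep_an.any():
        raise ValueError("QC removed every animal (animal missingness filter)")
    # (b) SNP call rate among surviving animals
    snp_frac = miss[keep_an].mean(axis=0)
    keep_cr = snp_frac <= snp_missing_max
    removed_callrate = [g.snp_ids[j] for j in np.flatnonzero(~keep_cr)]
    # (c) MAF among survivors of (a) and (b)
    sub = g.dosage[np.ix_(keep_an, keep_cr)]
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(sub, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = maf >= maf_min
    cr_ids = np.flatnonzero(keep_cr)
    removed_maf = [g.snp_ids[cr_ids[j]] for j in np.flatnonzero(~keep_maf)]
    keep_snps = cr_ids[keep_maf]
    if keep_snps.size == 0:
        raise ValueError("QC removed every SNP")

    out = g.subset(np.flatnonzero(keep_an), keep_snps)
    report = QcReport(
        n_animals_in=g.n_animals,
        n_animals_out=out.n_animals,
        n_snps_in=g.n_snps,
        n_snps_out=out.n_snps,
        removed_animals=removed_animals,
        removed_snps_callrate=removed_callrate,
        removed_snps_maf=removed_maf,
    )
    logger.info(report.summary())
    return out, report


def impute_missing(
    g: GenotypeMatrix, mode: str = "mean", seed: int | None = None
) -> GenotypeMatrix:
    """Fill missing dosages; observed entries are never changed.

    ``mean`` fills with the per-SNP mean dosage (continuous values);
    ``bernoulli_2p`` draws two Bernoulli(p) alleles per missing call using the
    per-SNP observed B-allele frequency, so imputed values stay in {0, 1, 2}.
    """
    miss = g.missing_mask
    n_missing = int(miss.sum())
    if n_missing == 0:
        return g.subset()
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = [str(g.snp_ids[j]) for j in np.flatnonzero(all_missing)]
        raise ValueError(
            f"cannot impute SNPs with no observed calls: {bad[:5]}"
            + ("..." if len(bad) > 5 else "")
        )
    dosage = g.dosage.copy()
    freq = g.allele_freq
    if mode == "mean":
        fill = np.broadcast_to(2.0 * freq, dosage.shape)
        dosage[miss] = fill[miss]
    elif mode == "bernoulli_2p":
        rng = np.random.default_rng(seed)
        rows, cols = np.nonzero(miss)
        p = freq[cols]
        dosage[rows, cols] = rng.binomial(2, p).astype(float)
    else:
        raise ValueError(f"unknown imputation mode {mode!r}")
    out = g.subset()
    out.dosage = dosage
    return out
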