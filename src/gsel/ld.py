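"""Linkage disequilibrium: pairwise r², decay summaries, marker density.

r² between two loci is ``(p_AB − p_A p_B)² / (p_A p_a p_B p_b)`` in terms of
haplotype and allele frequencies. With unphased data two estimators are
offered: the squared Pearson correlation of dosage vectors (composite LD,
the default and what genotype-based LD tooling computes) and a two-locus EM
estimate of ``p_AB`` from diplotypes followed by the frequency formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix

__all__ = [
    "r2_from_freqs",
    "r2_phased",
    "em_haplotype_freq",
    "pairwise_r2",
    "ld_decay_profile",
    "LdDecaySummary",
    "snp_density",
]


def r2_from_freqs(p_ab: float, p_a: float, p_b: float) -> float:
    """r² from the AB-haplotype frequency and the two A/B allele
    frequencies (of the counted alleles at each locus)."""
    denom = p_a * (1.0 - p_a) * p_b * (1.0 - p_b)
    if denom <= 0.0:
        raise ValueError("r2 undefined for a monomorphic locus")
    return (p_ab - p_a * p_b) ** 2 / denom


def r2_phased(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Direct haplotype-count r² from phased 0/1 allele vectors (one entry
    per gamete)."""
    hap_a = np.asarray(hap_a, dtype=float).ravel()
    hap_b = np.asarray(hap_b, dtype=float).ravel()
    return r2_from_freqs((hap_a * hap_b).mean(), hap_a.mean(), hap_b.mean())


def em_haplotype_freq(
    dos_a: np.ndarray,
    dos_b: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> float:
    """EM estimate of the B·B haplotype frequency p_AB from unphased
    dosages at two loci.

    Only the double heterozygote is phase-ambiguous; EM splits its
    contribution between the coupling (AB/ab) and repulsion (Ab/aB)
    resolutions according to the current haplotype frequencies.
    """
    dos_a = np.asarray(dos_a)
    dos_b = np.asarray(dos_b)
    n = len(dos_a)
    counts = np.zeros((3, 3))
    for i, j in zip(dos_a.astype(int), dos_b.astype(int)):
        counts[i, j] += 1
    n_hap = 2.0 * n

    # known haplotype counts: every genotype except 1/1 resolves uniquely
    # haplotype classes: AB (1,1), Ab (1,0), aB (0,1), ab (0,0) in counted-allele space
    known = np.zeros(4)  # AB, Ab, aB, ab
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            c = counts[i, j]
            # with at least one homozygous locus the haplotype split is forced
            if i != 1 and j != 1:
                known[_hap_class(i // 2, j // 2)] += 2 * c
            elif i == 1:  # locus A het, locus B hom
                known[_hap_class(1, j // 2)] += c
                known[_hap_class(0, j // 2)] += c
            else:  # locus B het, locus A hom
                known[_hap_class(i // 2, 1)] += c
                known[_hap_class(i // 2, 0)] += c
    n_dh = counts[1, 1]

    p = np.full(4, 0.25)
    for _ in range(max_iter):
        denom = p[0] * p[3] + p[1] * p[2]
        frac = 0.5 if denom == 0 else (p[0] * p[3]) / denom
        new = known.copy()
        new[0] += n_dh * frac
        new[3] += n_dh * frac
        new[1] += n_dh * (1.0 - frac)
        new[2] += n_dh * (1.0 - frac)
        new /= n_hap
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    return float(p[0])


def _hap_class(a: int, b: int) -> int:
    # 0: AB (both counted alleles), 1: Ab, 2: aB, 3: ab
    return {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(a, b)]


def pairwise_r2(
    g: GenotypeMatrix,
    max_distance_mb: float | None = 5.0,
    same_chromosome_only: bool = True,
    method: str = "dosage_corr",
) -> pd.DataFrame:
    """All same-chromosome SNP pairs within ``max_distance_mb``.

    Returns a DataFrame (snp_i, snp_j, chromosome, distance_mb, r2); pairs
    involving a monomorphic SNP are skipped and counted in
    ``df.attrs["n_skipped_monomorphic"]``. Missing dosages must have been
    imputed.
    """
    if not same_chromosome_only:
        raise NotImplementedError("cross-chromosome pairs are not profiled")
    if method not in ("dosage_corr", "haplotype_em"):
        raise ValueError(f"unknown LD method {method!r}")
    if np.isnan(g.dosage).any():
        raise ValueError("missing dosages present; run imputation first")

    records = []
    n_skipped = 0
    X = g.dosage
    sd = X.std(axis=0)
    Xc = X - X.mean(axis=0)
    for chrom in pd.unique(g.chromosome):
        idx = np.flatnonzero(g.chromosome == chrom)
        pos = g.position_mb[idx]
        for a, ja in enumerate(idx):
            if max_distance_mb is None:
                hi = len(idx)
            else:
                hi = np.searchsorted(pos, pos[a] + max_distance_mb, side="right")
            for b in range(a + 1, hi):
                jb = idx[b]
                if sd[ja] == 0.0 or sd[jb] == 0.0:
                    n_skipped += 1
                    continue
                if method == "dosage_corr":
                    r = (Xc[:, ja] @ Xc[:, jb]) / (len(X) * sd[ja] * sd[jb])
                    r2 = r * r
                else:
                    p_ab = em_haplotype_freq(X[:, ja], X[:, jb])
                    r2 = r2_from_freqs(
                        p_ab, X[:, ja].mean() / 2.0, X[:, jb].mean() / 2.0
                    )
                records.append(
                    (g.snp_ids[ja], g.snp_ids[jb], chrom, pos[b] - pos[a], r2)
                )
    df = pd.DataFrame(
        records, columns=["snp_i", "snp_j", "chromosome", "distance_mb", "r2"]
    )
    df.attrs["n_skipped_monomorphic"] = n_skipped
    return df


@dataclass
class LdDecaySummary:
    """Binned decay profile plus cumulative tail fractions.

    ``profile`` has one row per distance bin (left-closed, right-open) with
    mean/sd r² (NaN for an empty bin) and the pair count; ``tail_fractions``
    reports, for each r² threshold and cumulative range [0, d], the fraction
    of pairs exceeding the threshold.
    """

    profile: pd.DataFrame
    tail_fractions: pd.DataFrame


def ld_decay_profile(
    pairs: pd.DataFrame,
    bin_edges_mb: list[float] = (0.0, 0.1, 0.5, 2.0, np.inf),
    thresholds: list[float] = (0.5,),
    cumulative_ranges_mb: list[float] = (0.1, 0.2, 0.5),
) -> LdDecaySummary:
    if len(pairs) == 0:
        raise ValueError("no LD pairs to summarize")
    edges = np.asarray(bin_edges_mb, dtype=float)
    d = pairs["distance_mb"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d >= lo) & (d < hi)
        n = int(sel.sum())
        rows.append(
            {
                "bin_lo_mb": lo,
                "bin_hi_mb": hi,
                "n_pairs": n,
                "mean_r2": float(r2[sel].mean()) if n else np.nan,
                "sd_r2": float(r2[sel].std()) if n else np.nan,
            }
        )
    tail = []
    for thr in thresholds:
        for dmax in cumulative_ranges_mb:
            sel = d <= dmax
            n = int(sel.sum())
            frac = float((r2[sel] > thr).mean()) if n else np.nan
            tail.append(
                {"threshold": thr, "max_distance_mb": dmax, "n_pairs": n,
                 "frac_gt_threshold": frac}
            )
    return LdDecaySummary(
        profile=pd.DataFrame(rows), tail_fractions=pd.DataFrame(tail)
    )


def snp_density(
    g: GenotypeMatrix, window_mb: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome marker summary and per-window counts.

    The summary gives SNP count, chromosome length (max position), SNP/Mb
    density and adjacent-marker spacing statistics (NaN where fewer than two
    SNPs). Windows are [k·w, (k+1)·w) up to the last marker.
    """
    sum_rows, win_rows = [], []
    for chrom in pd.unique(g.chromosome):
        pos = np.sort(g.position_mb[g.chromosome == chrom])
        m = len(pos)
        length = float(pos.max()) if m else np.nan
        spacing = np.diff(pos) if m >= 2 else None
        sum_rows.append(
            {
                "chromosome": chrom,
                "n_snps": m,
                "length_mb": length,
                "density_per_mb": m / length if m and length > 0 else np.nan,
                "spacing_min_mb": float(spacing.min()) if spacing is not None else np.nan,
                "spacing_max_mb": float(spacing.max()) if spacing is not None else np.nan,
                "spacing_mean_mb": float(spacing.mean()) if spacing is not None else np.nan,
            }
        )
        if m:
            n_win = max(int(np.ceil((length + 1e-12) / window_mb)), 1)
            counts, _ = np.histogram(
                pos, bins=np.arange(n_win + 1) * window_mb
            )
            for k, c in enumerate(counts):
                win_rows.append(
                    {
                        "chromosome": chrom,
                        "window_start_mb": k * window_mb,
                        "n_snps": int(c),
                    }
                )
    cols_s = [
        "chromosome", "n_snps", "length_mb", "density_per_mb",
        "spacing_min_mb", "spacing_max_mb", "spacing_mean_mb",
    ]
    cols_w = ["chromosome", "window_start_mb", "n_snps"]
    return (
        pd.DataFrame(sum_rows, columns=cols_s),
        pd.DataFrame(win_rows, columns=cols_w),
    )
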