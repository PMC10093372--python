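"""Cross-validation loop, predictive ability and GEBV accuracy.

For each fold the model is trained on the other k−1 folds and the held-out
animals' phenotypes are predicted. Predictive ability is the Pearson
correlation r(y, ŷ) in the validation set (ŷ includes fixed effects by
default); GEBV accuracy divides the pooled validation correlation by the
square root of the pooled training heritability, ``r / √h²`` — the proxy
for the correlation between true and estimated breeding values when true
breeding values are unobservable. Accuracies above 1 (possible when h² is
small relative to r) are reported as-is with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .folds import FoldAssignment
from .kinship import RelationshipMatrix, build_G
from .models import DesignSpec, ModelFit, ModelSpec, fit_bayes, fit_gblup, predict
from .qc import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["CvResult", "run_cv", "gebv_accuracy", "aggregate_report"]


def gebv_accuracy(r: float, h2: float) -> float:
    """GEBV accuracy ``r / √h²``; errors on nonpositive h²."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"heritability must be in (0, 1], got {h2}")
    acc = r / math.sqrt(h2)
    if abs(acc) > 1.0:
        logger.warning(
            "GEBV accuracy %.3f exceeds 1 (r=%.3f, h2=%.3f); reported as-is",
            acc, r, h2,
        )
    return acc


@dataclass
class CvResult:
    """Per-fold and pooled cross-validation metrics for one model run."""

    trait: str
    method: str
    scheme: str
    replicate: int
    per_fold: pd.DataFrame  # fold, n_train, n_val, h2_train, r_train, r_validation
    n_excluded_folds: int = 0

    @property
    def mean_h2(self) -> float:
        return float(self.per_fold["h2_train"].mean())

    @property
    def mean_r_train(self) -> float:
        return float(self.per_fold["r_train"].mean())

    @property
    def mean_r_validation(self) -> float:
        return float(self.per_fold["r_validation"].mean())

    @property
    def sd_r_validation(self) -> float:
        return float(self.per_fold["r_validation"].std())

    @property
    def accuracy(self) -> float:
        return gebv_accuracy(self.mean_r_validation, self.mean_h2)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def run_cv(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    folds: FoldAssignment,
    spec: ModelSpec,
    factors=("cg", "dam_age"),
    blend_weight: float = 0.01,
    adjusted_phenotype: bool = False,
) -> CvResult:
    """k-fold cross-validation of one method on one trait.

    Trains on k−1 folds, predicts the held-out fold, and records per-fold
    training heritability and training/validation correlations. Folds whose
    validation phenotypes (or predictions) are constant have no defined
    correlation; they are dropped from pooling and counted.

    With ``adjusted_phenotype=True`` the validation correlation is computed
    between ``y − X b̂`` and the GEBV instead of raw y vs full ŷ.
    """
    design = DesignSpec.from_phenotypes(phenotypes, trait, factors=factors)
    id_to_row = {str(a): i for i, a in enumerate(genotypes.animal_ids)}
    try:
        geno_rows = np.asarray([id_to_row[a] for a in design.animal_ids])
    except KeyError as exc:
        raise KeyError(f"phenotyped animal {exc.args[0]!r} has no genotype") from None
    M = genotypes.dosage[geno_rows]
    fold_of = folds.fold_of.reindex(design.animal_ids)
    if fold_of.isna().any():
        missing = list(fold_of.index[fold_of.isna()])[:5]
        raise KeyError(f"animals missing from fold assignment: {missing}")
    fold_vec = fold_of.to_numpy()

    if spec.method == "GBLUP":
        G_all = build_G(M).values

    rows = []
    n_excluded = 0
    for f in range(1, folds.k + 1):
        va = np.flatnonzero(fold_vec == f)
        tr = np.flatnonzero(fold_vec != f)
        if va.size == 0:
            raise ValueError(f"fold {f} is empty")
        d_tr = design.subset(tr)
        fold_spec = replace(spec, seed=_fold_seed(spec.seed, f, folds.replicate))
        if spec.method == "GBLUP":
            fit = fit_gblup(
                d_tr, G_all[np.ix_(tr, tr)], fold_spec, blend_weight=blend_weight
            )
            yhat_va, gebv_va = predict(
                fit, design.X[va], g_cross=G_all[np.ix_(va, tr)]
            )
        else:
            fit = fit_bayes(d_tr, M[tr], fold_spec)
            yhat_va, gebv_va = predict(fit, design.X[va], markers_new=M[va])
        yhat_tr = d_tr.X @ fit.b_mean + fit.gebv
        if adjusted_phenotype:
            r_tr = _pearson(d_tr.y - d_tr.X @ fit.b_mean, fit.gebv)
            r_va = _pearson(design.y[va] - design.X[va] @ fit.b_mean, gebv_va)
        else:
            r_tr = _pearson(d_tr.y, yhat_tr)
            r_va = _pearson(design.y[va], yhat_va)
        if np.isnan(r_va):
            n_excluded += 1
            logger.warning(
                "fold %d: validation correlation undefined (constant values); "
                "excluded from pooling", f,
            )
            continue
        rows.append(
            {
                "fold": f,
                "n_train": len(tr),
                "n_val": len(va),
                "h2_train": fit.h2,
                "r_train": r_tr,
                "r_validation": r_va,
            }
        )
    per_fold = pd.DataFrame(
        rows,
        columns=["fold", "n_train", "n_val", "h2_train", "r_train", "r_validation"],
    )
    return CvResult(
        trait=trait,
        method=spec.method,
        scheme=folds.scheme,
        replicate=folds.replicate,
        per_fold=per_fold,
        n_excluded_folds=n_excluded,
    )


def _fold_seed(seed: int, fold: int, replicate: int) -> int:
    return int(
        np.random.SeedSequence((int(seed), fold, replicate)).generate_state(1)[0]
        % (2**31 - 1)
    )


def aggregate_report(results: list[CvResult]) -> pd.DataFrame:
    """Summary table per trait × method × scheme.

    Replicates of the same scheme are pooled (their folds concatenated).
    Reports mean/min/max training h², mean ± sd training and validation
    correlations, and the GEBV accuracy computed from the pooled means —
    so the table is internally consistent: accuracy always equals
    ``gebv_accuracy(mean r_validation, mean h²)``.
    """
    if not results:
        raise ValueError("no CV results to aggregate")
    rows = []
    keyed: dict[tuple, list[CvResult]] = {}
    for res in results:
        keyed.setdefault((res.trait, res.method, res.scheme), []).append(res)
    for (trait, method, scheme), group in keyed.items():
        folds_all = pd.concat([g.per_fold for g in group], ignore_index=True)
        h2 = folds_all["h2_train"]
        r_tr = folds_all["r_train"]
        r_va = folds_all["r_validation"]
        rows.append(
            {
                "trait": trait,
                "method": method,
                "scheme": scheme,
                "n_folds": len(folds_all),
                "h2_mean": h2.mean(),
                "h2_min": h2.min(),
                "h2_max": h2.max(),
                "r_train_mean": r_tr.mean(),
                "r_train_sd": r_tr.std(),
                "r_validation_mean": r_va.mean(),
                "r_validation_sd": r_va.std(),
                "accuracy": gebv_accuracy(r_va.mean(), h2.mean()),
            }
        )
    report = pd.DataFrame(rows)

    # cross-method and cross-scheme averages of per-cell accuracies
    report.attrs["accuracy_by_trait_scheme"] = (
        report.groupby(["trait", "scheme"])["accuracy"].mean().to_dict()
    )
    report.attrs["accuracy_by_trait_method"] = (
        report.groupby(["trait", "method"])["accuracy"].mean().to_dict()
    )
    return report
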