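"""QTL ranking, inclusion scenarios, and prediction evaluation.

QTL are ranked by the additive variance they explain, 2 p q alpha^2, and a
scenario ``QTLx`` includes the smallest top-ranked prefix whose cumulative
share of that variance reaches x percent (QTL0 includes none; models then
see SNPs only).  QTL whose individual share is negligible (< 0.0005% of the
total) are excluded from the ranking; they still contribute to true breeding
values, only the model features change.

Predictions are scored against true breeding values in the test set:
accuracy is the Pearson correlation and dispersion bias the ordinary
least-squares slope of TBV on prediction (1 = no dispersion bias, > 1 =
underdispersed predictions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grm import qtl_variance
from .popsim import TraitArchitecture

__all__ = [
    "QtlRanking",
    "Scenario",
    "FeatureSet",
    "rank_qtl",
    "build_scenario",
    "assemble_features",
    "accuracy",
    "dispersion_bias",
    "decay_analysis",
    "overfitting_check",
    "importance_compare",
]

NEGLIGIBLE_FRACTION = 5e-6  # individual share below 0.0005% of total variance


@dataclass(frozen=True)
class QtlRanking:
    """Segregating QTL sorted by descending explained variance."""

    qtl_loci: np.ndarray  # genome locus indices, ranking order
    variances: np.ndarray  # 2 p q a^2 per ranked QTL
    cum_proportion: np.ndarray  # cumulative share over included QTL, ends at 1
    excluded_loci: np.ndarray  # negligible tail (and fixed QTL)

    @property
    def n(self) -> int:
        return len(self.qtl_loci)


@dataclass(frozen=True)
class Scenario:
    """A prefix of the QTL ranking to be added to the model features."""

    label: str
    threshold: float
    qtl_loci: np.ndarray
    qtl_variances: np.ndarray
    achieved_proportion: float

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_loci)


def rank_qtl(
    arch: TraitArchitecture,
    p: np.ndarray,
    negligible_fraction: float = NEGLIGIBLE_FRACTION,
) -> QtlRanking:
    """Rank segregating QTL by 2 p q a^2; drop the negligible tail.

    ``p`` holds allele frequencies for every locus in the genome map (or for
    the QTL columns only, aligned to ``arch.qtl_loci``).
    """
    p = np.asarray(p, dtype=np.float64)
    pq = p[arch.qtl_loci] if len(p) > len(arch.qtl_loci) else p
    if len(pq) != len(arch.qtl_loci):
        raise ValueError("frequency vector does not match the QTL set")
    var = qtl_variance(pq, arch.effects)
    seg = (pq > 0) & (pq < 1)
    total = var[seg].sum()
    if total <= 0:
        raise ValueError("no segregating QTL")
    keep = seg & (var / total >= negligible_fraction)
    # descending variance, ties broken by locus index
    order = np.lexsort((arch.qtl_loci[keep], -var[keep]))
    loci = arch.qtl_loci[keep][order]
    v = var[keep][order]
    cum = np.cumsum(v) / v.sum()
    cum[-1] = 1.0
    return QtlRanking(loci, v, cum, arch.qtl_loci[~keep])


def build_scenario(ranking: QtlRanking, threshold: float) -> Scenario:
    """Smallest ranking prefix whose cumulative variance share >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    label = f"QTL{int(round(threshold * 100))}"
    if threshold == 0.0:
        k = 0
    else:
        k = int(np.searchsorted(ranking.cum_proportion, threshold - 1e-12)) + 1
        k = min(k, ranking.n)
    achieved = float(ranking.cum_proportion[k - 1]) if k else 0.0
    return Scenario(label, threshold, ranking.qtl_loci[:k].copy(),
                    ranking.variances[:k].copy(), achieved)


@dataclass
class FeatureSet:
    """Model inputs assembled for one scenario."""

    mode: str
    pooled: np.ndarray | None = None  # SNPs + included QTL (GBLUP/RF/SVR)
    qtl: np.ndarray | None = None  # QTL dosages (2GBLUP component 1)
    snp: np.ndarray | None = None  # SNP dosages (2GBLUP component 2)
    qtl_weights: np.ndarray | None = None  # per-QTL 2 p q a^2 (w2GBLUP)


def assemble_features(
    dosages: np.ndarray,
    snp_loci: np.ndarray,
    scenario: Scenario,
    mode: str,
) -> FeatureSet:
    """Slice the full dosage matrix into model inputs for one scenario.

    mode "pooled": one matrix of SNPs plus included QTL (equal weights);
    mode "split": separate (QTL, SNP) matrices for the two-component model;
    mode "split-weighted": additionally attach per-QTL variance weights.
    """
    dosages = np.asarray(dosages)
    if scenario.n_qtl and scenario.qtl_loci.max() >= dosages.shape[1]:
        raise ValueError("scenario QTL columns outside the genotype matrix")
    if mode == "pooled":
        cols = np.concatenate([snp_loci, scenario.qtl_loci]).astype(np.intp)
        return FeatureSet(mode, pooled=dosages[:, cols])
    if mode in ("split", "split-weighted"):
        fs = FeatureSet(
            mode,
            qtl=dosages[:, scenario.qtl_loci.astype(np.intp)],
            snp=dosages[:, np.asarray(snp_loci, dtype=np.intp)],
        )
        if mode == "split-weighted":
            fs.qtl_weights = scenario.qtl_variances.copy()
        return fs
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def accuracy(pred: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between predictions and true breeding values."""
    pred = np.asarray(pred, dtype=np.float64)
    tbv = np.asarray(tbv, dtype=np.float64)
    if pred.shape != tbv.shape:
        raise ValueError("prediction and TBV vectors must align")
    if pred.std() == 0 or tbv.std() == 0:
        raise ValueError("accuracy undefined for a constant vector")
    return float(np.corrcoef(pred, tbv)[0, 1])


def dispersion_bias(pred: np.ndarray, tbv: np.ndarray) -> float:
    """OLS slope of TBV on prediction: cov(tbv, pred) / var(pred)."""
    pred = np.asarray(pred, dtype=np.float64)
    tbv = np.asarray(tbv, dtype=np.float64)
    if pred.shape != tbv.shape:
        raise ValueError("prediction and TBV vectors must align")
    vp = pred.var()
    if vp == 0:
        raise ValueError("dispersion bias undefined for constant predictions")
    return float(np.cov(tbv, pred, ddof=0)[0, 1] / vp)


def decay_analysis(
    predictions: Mapping[int, np.ndarray], tbvs: Mapping[int, np.ndarray]
) -> pd.DataFrame:
    """Accuracy and bias per test generation with a fixed training set."""
    rows = []
    for g in sorted(predictions):
        rows.append(
            dict(
                generation=g,
                accuracy=accuracy(predictions[g], tbvs[g]),
                dispersion_bias=dispersion_bias(predictions[g], tbvs[g]),
            )
        )
    return pd.DataFrame(rows)


def overfitting_check(
    train_pred: np.ndarray, y_train: np.ndarray, h2: float, margin: float = 0.05
) -> tuple[float, bool]:
    """Training-set correlation and an overfitting flag.

    A prediction that captures only genetic signal cannot correlate with the
    phenotype beyond sqrt(h2) in expectation; exceeding that ceiling by more
    than ``margin`` flags overfitting.
    """
    r = float(np.corrcoef(train_pred, y_train)[0, 1])
    return r, r > np.sqrt(h2) + margin


def importance_compare(
    rf_importances: np.ndarray,
    backsolved_vars: np.ndarray,
    true_vars: np.ndarray,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-locus importance comparison against the true variance shares.

    All three vectors are normalised to sum to one; returns the joint table
    and Spearman rank correlations of each estimate with the truth.
    """
    vecs = [np.asarray(v, dtype=np.float64) for v in
            (rf_importances, backsolved_vars, true_vars)]
    n = len(vecs[0])
    if any(len(v) != n for v in vecs):
        raise ValueError("importance vectors must cover the same loci")
    vecs = [v / v.sum() if v.sum() > 0 else v for v in vecs]
    table = pd.DataFrame(
        {"rf_importance": vecs[0], "gblup_backsolved": vecs[1], "true_variance": vecs[2]}
    )
    corrs = pd.Series(
        {
            "rf_importance": stats.spearmanr(vecs[0], vecs[2]).statistic,
            "gblup_backsolved": stats.spearmanr(vecs[1], vecs[2]).statistic,
        },
        name="spearman_vs_truth",
    )
    return table, corrs
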