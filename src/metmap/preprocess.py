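"""Transformation chain and covariate screening.

The chain is order-fixed: per-(tissue, platform) missingness filter (drop
metabolites missing in more than 25% of samples), constant imputation with
1.00001, elementwise log2, platform merge, and per-metabolite z-scoring
within tissue.  Covariate contribution to the group separation is screened
with an elastic-net logistic model (mixing 0.5, penalty by stratified 10-fold
CV) and with Spearman correlations under Benjamini-Hochberg FDR control;
sample structure is inspected with tissue-specific PCA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .errors import PreprocessError
from .ingest_annotate import IntensityTable, SampleRecord

logger = logging.getLogger(__name__)

DEFAULT_MISSING_THRESHOLD = 0.25
DEFAULT_IMPUTE_CONSTANT = 1.00001


@dataclass
class ScaledTable:
    """Analysis-ready matrix: per-metabolite standardized log2 intensities."""

    tissue: str
    values: pd.DataFrame  # metabolites x samples, mean 0 / sd 1 per row
    provenance: dict = field(default_factory=dict)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CovariateScreenResult:
    elastic_net_coefficients: dict[str, float]
    cv_lambda: float
    spearman: pd.DataFrame | None = None


def filter_missing(table: IntensityTable, threshold: float = DEFAULT_MISSING_THRESHOLD,
                   ) -> tuple[IntensityTable, list[str]]:
    """Drop metabolites missing in strictly more than ``threshold`` of samples.

    The fraction is computed within this (tissue, platform) table.  Returns
    the filtered table and the list of removed metabolite ids.
    """
    if not 0 < threshold < 1:
        raise PreprocessError(f"threshold must be in (0,1), got {threshold}")
    frac = table.values.isna().mean(axis=1)
    keep = frac <= threshold
    removed = list(table.values.index[~keep])
    if not keep.any():
        raise PreprocessError(
            f"{table.tissue}/{table.platform}: all metabolites exceed the "
            f"{threshold:.0%} missingness threshold; review the threshold")
    filtered = IntensityTable(table.tissue, table.platform,
                              table.values.loc[keep].copy())
    return filtered, removed


def impute_and_log2(table: IntensityTable,
                    constant: float = DEFAULT_IMPUTE_CONSTANT,
                    ) -> tuple[pd.DataFrame, int]:
    """Replace missing cells by the imputation constant, then take log2.

    Returns the log2 matrix and the number of imputed cells.  Present values
    must be strictly positive (log2 undefined otherwise).
    """
    vals = table.values
    present = vals.notna()
    if (vals[present] <= 0).any().any():
        bad = vals[(vals <= 0) & present].stack().index[0]
        raise PreprocessError(
            f"{table.tissue}/{table.platform}: non-positive intensity at {bad}")
    n_imputed = int((~present).to_numpy().sum())
    return np.log2(vals.fillna(constant)), n_imputed


def merge_platforms(gc_log2: pd.DataFrame, lc_log2: pd.DataFrame,
                    suffixes: tuple[str, str] = ("GC-MS", "LC-MS")) -> pd.DataFrame:
    """Stack the two platform matrices over the common sample set.

    Platforms are not deduplicated: an id present on both platforms is kept
    twice with platform-suffixed ids.
    """
    if gc_log2.empty:
        return lc_log2.copy()
    if lc_log2.empty:
        return gc_log2.copy()
    gc_samples, lc_samples = set(gc_log2.columns), set(lc_log2.columns)
    if gc_samples != lc_samples:
        only_gc = sorted(gc_samples - lc_samples)
        only_lc = sorted(lc_samples - gc_samples)
        raise PreprocessError(
            f"platform sample sets differ; only in {suffixes[0]}: {only_gc}, "
            f"only in {suffixes[1]}: {only_lc}")
    lc_log2 = lc_log2[gc_log2.columns]
    shared = set(gc_log2.index) & set(lc_log2.index)
    if shared:
        gc_log2 = gc_log2.rename(
            index={i: f"{i}__{suffixes[0]}" for i in shared})
        lc_log2 = lc_log2.rename(
            index={i: f"{i}__{suffixes[1]}" for i in shared})
    return pd.concat([gc_log2, lc_log2], axis=0)


def scale_zscore(merged_log2: pd.DataFrame, tissue: str = "",
                 ddof: int = 1, provenance: dict | None = None) -> ScaledTable:
    """Standardize each metabolite row to mean 0 and sd 1 (sd with ``ddof``).

    Zero-variance rows are dropped and recorded in provenance.
    """
    if merged_log2.shape[1] < 3:
        raise PreprocessError("need at least 3 samples to scale")
    vals = merged_log2.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=ddof)
    keep = sd > 0
    dropped = list(merged_log2.index[~keep])
    if dropped:
        logger.info("%s: dropped %d zero-variance metabolites", tissue, len(dropped))
    vals = vals[keep]
    mean = vals.mean(axis=1, keepdims=True)
    scaled = (vals - mean) / sd[keep, None]
    prov = dict(provenance or {})
    prov["zero_variance_dropped"] = dropped
    prov["scale_ddof"] = ddof
    return ScaledTable(
        tissue=tissue,
        values=pd.DataFrame(scaled, index=merged_log2.index[keep],
                            columns=merged_log2.columns),
        provenance=prov,
    )


def preprocess_tissue(
    gc_table: IntensityTable,
    lc_table: IntensityTable,
    threshold: float = DEFAULT_MISSING_THRESHOLD,
    constant: float = DEFAULT_IMPUTE_CONSTANT,
    ddof: int = 1,
) -> ScaledTable:
    """Run the full chain filter -> impute -> log2 -> merge -> scale for one
    tissue's pair of platform tables."""
    if gc_table.tissue != lc_table.tissue:
        raise PreprocessError("platform tables belong to different tissues")
    prov: dict = {"removed_by_missingness": {}, "imputed_cells": {}}
    logs = []
    for tbl in (gc_table, lc_table):
        filt, removed = filter_missing(tbl, threshold)
        log2, n_imp = impute_and_log2(filt, constant)
        prov["removed_by_missingness"][tbl.platform] = removed
        prov["imputed_cells"][tbl.platform] = n_imp
        logs.append(log2)
    merged = merge_platforms(logs[0], logs[1],
                             suffixes=(gc_table.platform, lc_table.platform))
    return scale_zscore(merged, tissue=gc_table.tissue, ddof=ddof, provenance=prov)


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------

def _covariate_frame(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    """Default covariate matrix: age, BMI, gender (female=1), sample weight.
    HbA1c and GSIS are deliberately excluded (they define / track the
    outcome)."""
    return pd.DataFrame(
        {
            "age_years": [s.age_years for s in samples],
            "bmi": [s.bmi for s in samples],
            "gender_female": [1.0 if s.gender == "F" else 0.0 for s in samples],
            "sample_weight": [s.sample_weight for s in samples],
        },
        index=[s.sample_id for s in samples],
    )


def covariate_elastic_net(
    samples: Sequence[SampleRecord],
    covariates: pd.DataFrame | None = None,
    l1_ratio: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    Cs: int | Sequence[float] = 25,
) -> CovariateScreenResult:
    """Elastic-net logistic screen of covariate contribution to the
    non-diabetes vs T2D separation.

    The penalty strength is chosen by stratified ``n_folds``-fold CV
    (log-loss); per-covariate coefficients at the selected penalty are
    returned together with the selected lambda (= 1/C).
    """
    y = np.array([0 if s.non_diabetes else 1 for s in samples])
    if len(np.unique(y)) < 2:
        raise PreprocessError("degenerate outcome: only one phenotype class present")
    X = covariates if covariates is not None else _covariate_frame(samples)
    Xs = (X - X.mean()) / X.std(ddof=1).replace(0, 1.0)
    if isinstance(Cs, int):
        Cs = np.logspace(-4, 2, Cs)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=Cs, cv=cv, penalty="elasticnet", solver="saga",
        l1_ratios=[l1_ratio], scoring="neg_log_loss", max_iter=20000,
        random_state=seed, tol=1e-8,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs.to_numpy(), y)
    coefs = dict(zip(X.columns, model.coef_.ravel()))
    return CovariateScreenResult(
        elastic_net_coefficients={k: float(v) for k, v in coefs.items()},
        cv_lambda=float(1.0 / model.C_[0]),
    )


def covariate_spearman(
    scaled: ScaledTable,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman correlation of every metabolite with every covariate.

    Mid-rank rho, p from the t approximation, Benjamini-Hochberg adjustment
    across all (metabolite, covariate) pairs of this tissue.  Constant
    covariates are skipped with a warning.
    """
    n = len(scaled.sample_ids)
    if n < 5:
        raise PreprocessError("need at least 5 samples for correlation screening")
    cov = covariates.loc[scaled.sample_ids]
    rows = []
    for cname in cov.columns:
        c = cov[cname].to_numpy(dtype=float)
        if np.nanstd(c) == 0:
            warnings.warn(f"covariate {cname!r} is constant; skipped", stacklevel=2)
            continue
        rc = stats.rankdata(c)
        for mid in scaled.metabolite_ids:
            v = scaled.values.loc[mid].to_numpy(dtype=float)
            rv = stats.rankdata(v)
            rho = np.corrcoef(rc, rv)[0, 1]
            if abs(rho) >= 1.0:
                p = 0.0
            else:
                t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
                p = 2 * stats.t.sf(abs(t), df=n - 2)
            rows.append((mid, cname, rho, p))
    df = pd.DataFrame(rows, columns=["metabolite_id", "covariate", "rho", "p"])
    if len(df):
        df["fdr_p"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["fdr_p"] = []
    df.insert(0, "tissue", scaled.tissue)
    return df


def qc_pca(scaled: ScaledTable, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Tissue-level PCA of the samples.

    Returns per-sample scores on the first k components and the variance
    explained fractions.  Sign convention: for each component the
    largest-magnitude loading is made positive, so scores are deterministic.
    """
    X = scaled.values.to_numpy(dtype=float).T  # samples x metabolites
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncated", stacklevel=2)
        k = rank
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    cols = [f"PC{j + 1}" for j in range(k)]
    return (pd.DataFrame(scores, index=scaled.sample_ids, columns=cols),
            pca.explained_variance_ratio_[:k])
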