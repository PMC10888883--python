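"""Quality assessment and curation of feature tables.

Every operation here is a pure transform: it takes a :class:`FeatureTable`,
leaves it untouched, and returns a new table with an updated provenance tag,
so operations can be chained in any order.  All correlation/PCA computations
work on log10(x + 1); raw intensities are never log-transformed in place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .errors import PipelineError
from .models import FeatureTable


def _log10(matrix):
    return np.log10(matrix.astype(float) + 1.0)


# ---------------------------------------------------------------------------
# Acquisition metrics and failed-injection detection
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionMetrics:
    """Per-acquisition QC metrics with z-scores (population sd, ddof=0)."""

    table: pd.DataFrame  # index: acquisition; columns: metric and z_<metric>

    def z(self, metric, acquisition):
        return float(self.table.at[acquisition, f"z_{metric}"])


def _zscore(series):
    sd = series.std(ddof=0)
    if sd == 0:
        return pd.Series(0.0, index=series.index)
    return (series - series.mean()) / sd


def acquisition_metrics(table: FeatureTable) -> AcquisitionMetrics:
    """Feature count, TIC and median inter-sample correlation per acquisition.

    Counts and TICs use raw intensities; correlations use log10(x + 1).
    """
    if len(table.acquisitions) < 2:
        raise PipelineError("acquisition metrics require >= 2 acquisitions")
    m = table.intensity_matrix()
    counts = (m > 0).sum(axis=0).astype(float)
    tic = m.sum(axis=0)
    corr = _log10(m).corr(method="pearson")  # columns = acquisitions
    med_corr = corr.where(~np.eye(len(corr), dtype=bool)).median(axis=0)
    out = pd.DataFrame(
        {
            "feature_count": counts,
            "tic": tic,
            "median_correlation": med_corr,
        }
    )
    for col in ("feature_count", "tic", "median_correlation"):
        out[f"z_{col}"] = _zscore(out[col].fillna(0.0))
    return AcquisitionMetrics(table=out)


def detect_failed_acquisitions(metrics: AcquisitionMetrics, z_threshold: float = -2.0):
    """Flag acquisitions whose feature-count z-score falls below threshold.

    Returns a list of (acquisition, z) pairs, most extreme first.
    """
    flagged = [
        (acq, float(z))
        for acq, z in metrics.table["z_feature_count"].items()
        if z < z_threshold
    ]
    flagged.sort(key=lambda t: t[1])
    return flagged


# ---------------------------------------------------------------------------
# Normalization / masking / filtering / imputation
# ---------------------------------------------------------------------------

def _median(values):
    # even count: arithmetic mean of the two central values
    return float(np.median(np.asarray(values, dtype=float)))


def tic_normalize(table: FeatureTable, reference: str = "median"):
    """Scale each acquisition so its TIC equals the median TIC.

    Returns ``(table', factors)`` with ``factor_s = median(TICs) / TIC_s``.
    Idempotent: normalizing twice is the identity.
    """
    if reference != "median":
        raise PipelineError(f"unknown reference {reference!r}")
    m = table.intensity_matrix()
    tics = m.sum(axis=0)
    zero = [a for a, t in tics.items() if t <= 0]
    if zero:
        raise PipelineError(
            f"zero-TIC acquisitions {zero}; remove failed injections first"
        )
    target = _median(tics.values)
    factors = {a: target / t for a, t in tics.items()}
    normalized = m * pd.Series(factors)
    return (
        table.with_matrix(normalized, f"{table.provenance_tag}+tic_normalized"),
        factors,
    )


def blank_mask(
    table: FeatureTable,
    blank_ids,
    ratio_k: float = 3.0,
    aggregator: str = "mean",
):
    """Drop features not sufficiently above the process blanks.

    A feature is dropped iff aggregator(study intensities) <
    ratio_k * aggregator(blank intensities).  Blank columns are removed from
    the surviving table.  Returns ``(table', dropped_feature_ids)``.
    """
    blank_ids = list(blank_ids)
    if not blank_ids:
        raise PipelineError("blank_mask requires at least one blank acquisition")
    missing = [b for b in blank_ids if b not in table.acquisitions]
    if missing:
        raise PipelineError(f"blank acquisitions not in table: {missing}")
    if aggregator not in ("mean", "max"):
        raise PipelineError(f"unknown aggregator {aggregator!r}")
    agg = np.mean if aggregator == "mean" else np.max
    m = table.intensity_matrix()
    study_cols = [a for a in table.acquisitions if a not in set(blank_ids)]
    dropped = []
    keep = []
    for fid in m.index:
        study_val = float(agg(m.loc[fid, study_cols].values)) if study_cols else 0.0
        blank_val = float(agg(m.loc[fid, blank_ids].values))
        if study_val < ratio_k * blank_val:
            dropped.append(fid)
        else:
            keep.append(fid)
    sub = m.loc[keep, study_cols]
    return table.with_matrix(sub, f"{table.provenance_tag}+blank_masked"), dropped


def drop_rare_features(table: FeatureTable, min_fraction: float = 0.25):
    """Keep features nonzero in at least ceil(min_fraction * n_samples) samples."""
    if not 0 <= min_fraction <= 1:
        raise PipelineError("min_fraction must be in [0, 1]")
    m = table.intensity_matrix()
    n = len(table.acquisitions)
    threshold = int(np.ceil(min_fraction * n))
    nonzero = (m > 0).sum(axis=1)
    keep = [fid for fid in m.index if nonzero[fid] >= threshold]
    return table.with_matrix(m.loc[keep], f"{table.provenance_tag}+rare_dropped")


def impute_missing(table: FeatureTable, method: str = "half_min_feature"):
    """Replace zeros with half the feature's minimum nonzero intensity."""
    if method != "half_min_feature":
        raise PipelineError(f"unknown imputation method {method!r}")
    m = table.intensity_matrix().copy()
    for fid in m.index:
        row = m.loc[fid]
        nonzero = row[row > 0]
        if nonzero.empty:
            raise PipelineError(
                f"feature {fid!r} is all-zero; run drop_rare_features first"
            )
        m.loc[fid] = row.replace(0.0, float(nonzero.min()) / 2.0)
    return table.with_matrix(m, f"{table.provenance_tag}+imputed")


# ---------------------------------------------------------------------------
# Batch correction (parametric empirical-Bayes location/scale model)
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted per-batch location/scale effects on the log10(x+1) scale."""

    batches: list
    gamma_star: pd.DataFrame  # features x batches, shrunk location (standardized units)
    delta_sq_star: pd.DataFrame  # features x batches, shrunk scale (> 0)
    gamma_hat: pd.DataFrame
    pooled_sd: pd.Series
    grand_mean: pd.Series

    def location_effect(self, batch):
        """De-standardized additive location effect of a batch (log10 scale)."""
        return self.gamma_star[batch] * self.pooled_sd


def _aprior(delta_hat_row):
    m, s2 = delta_hat_row.mean(), delta_hat_row.var(ddof=1)
    return (2 * s2 + m**2) / s2 if s2 > 0 else 2.0


def _bprior(delta_hat_row):
    m, s2 = delta_hat_row.mean(), delta_hat_row.var(ddof=1)
    return (m * s2 + m**3) / s2 if s2 > 0 else m


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative EB solution for one batch's gamma*, delta2* (per feature)."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        resid2 = ((z_batch.T - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * resid2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_correct(
    table: FeatureTable,
    batch_labels: dict,
    parametric: bool = True,
    return_model: bool = False,
):
    """Remove additive/multiplicative batch effects (parametric ComBat-style).

    Intensities are log10(x+1)-transformed internally, standardized per
    feature, per-batch location/scale effects are estimated and shrunk via
    normal / inverse-gamma priors fitted by method of moments, the data are
    adjusted, de-standardized and back-transformed.  Constant features pass
    through unadjusted with a warning.
    """
    if not parametric:
        raise PipelineError("only the parametric variant is implemented")
    m = table.intensity_matrix()
    missing = [a for a in table.acquisitions if a not in batch_labels]
    if missing:
        raise PipelineError(f"no batch label for acquisitions: {missing}")
    batches = sorted({batch_labels[a] for a in table.acquisitions})
    if len(batches) < 2:
        raise PipelineError("batch correction requires >= 2 batches")
    members = {b: [a for a in table.acquisitions if batch_labels[a] == b] for b in batches}
    for b, cols in members.items():
        if len(cols) < 2:
            raise PipelineError(f"batch {b!r} has fewer than 2 samples")

    log = _log10(m)
    n_total = log.shape[1]

    var0 = log.var(axis=1, ddof=0)
    constant = var0[var0 == 0].index
    if len(constant):
        warnings.warn(f"{len(constant)} constant features passed through unadjusted")
    work = log.drop(index=constant)

    # feature-wise grand mean weighted by batch size, and pooled variance
    batch_means = pd.DataFrame({b: work[cols].mean(axis=1) for b, cols in members.items()})
    weights = pd.Series({b: len(cols) / n_total for b, cols in members.items()})
    grand_mean = batch_means.mul(weights, axis=1).sum(axis=1)
    resid = work.sub(
        pd.DataFrame(
            {a: batch_means[batch_labels[a]] for a in work.columns}
        )
    )
    pooled_var = (resid**2).sum(axis=1) / n_total
    pooled_sd = np.sqrt(pooled_var)
    pooled_sd[pooled_sd == 0] = 1.0

    z = work.sub(grand_mean, axis=0).div(pooled_sd, axis=0)

    gamma_hat = pd.DataFrame({b: z[cols].mean(axis=1) for b, cols in members.items()})
    delta_hat = pd.DataFrame({b: z[cols].var(axis=1, ddof=1) for b, cols in members.items()})
    delta_hat = delta_hat.clip(lower=1e-12)

    gamma_star = pd.DataFrame(index=z.index, columns=batches, dtype=float)
    delta_star = pd.DataFrame(index=z.index, columns=batches, dtype=float)
    for b in batches:
        g_bar = gamma_hat[b].mean()
        t2 = gamma_hat[b].var(ddof=1)
        if not np.isfinite(t2) or t2 <= 0:
            t2 = 1e-12
        a = _aprior(delta_hat[b])
        bp = _bprior(delta_hat[b])
        g_star, d_star = _it_sol(
            z[members[b]].values,
            gamma_hat[b].values,
            delta_hat[b].values,
            g_bar,
            t2,
            a,
            bp,
        )
        gamma_star[b] = g_star
        delta_star[b] = np.maximum(d_star, 1e-12)

    adjusted = z.copy()
    for b, cols in members.items():
        adjusted[cols] = (
            z[cols].sub(gamma_star[b], axis=0).div(np.sqrt(delta_star[b]), axis=0)
        )
    corrected_log = adjusted.mul(pooled_sd, axis=0).add(grand_mean, axis=0)
    corrected = (10.0**corrected_log - 1.0).clip(lower=0.0)
    # constant features bypass the transform entirely (raw pass-through)
    corrected = pd.concat([corrected, m.loc[constant]]).loc[m.index]
    out = table.with_matrix(corrected, f"{table.provenance_tag}+batch_corrected")
    if return_model:
        model = BatchModel(
            batches=batches,
            gamma_star=gamma_star,
            delta_sq_star=delta_star,
            gamma_hat=gamma_hat,
            pooled_sd=pooled_sd,
            grand_mean=grand_mean,
        )
        return out, model
    return out


# ---------------------------------------------------------------------------
# Ordination summaries
# ---------------------------------------------------------------------------

def pca_summary(table: FeatureTable, n_components: int = 2):
    """PCA of acquisitions on log10(x+1), feature-centered.

    Returns ``(coordinates, explained_variance_fractions)``; coordinate signs
    are fixed so the largest-magnitude loading of each component is positive.
    """
    from sklearn.decomposition import PCA

    if len(table.acquisitions) < 2:
        raise PipelineError("PCA requires >= 2 acquisitions")
    log = _log10(table.intensity_matrix())
    X = log.T.values  # samples x features
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    coord_df = pd.DataFrame(
        coords,
        index=list(table.acquisitions),
        columns=[f"PC{j + 1}" for j in range(coords.shape[1])],
    )
    return coord_df, pca.explained_variance_ratio_.copy()


def correlation_clustermap_data(table: FeatureTable):
    """Pearson correlation of acquisitions plus a dendrogram leaf order.

    Correlation on log10(x+1); hierarchical clustering with average linkage
    on distance 1 - r.  Returns ``(correlation DataFrame, leaf order list)``.
    """
    if len(table.acquisitions) < 2:
        raise PipelineError("correlation map requires >= 2 acquisitions")
    log = _log10(table.intensity_matrix())
    corr = log.corr(method="pearson").fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    dist = 1.0 - corr.values
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    linkage = average(condensed)
    order = [table.acquisitions[i] for i in leaves_list(linkage)]
    return corr, order
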