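"""Cross-condensate comparison: correlations, profiles, clustering, DE.

Detection-frequency profiles of different condensate types (or replicate
experiments) are compared by Pearson correlation over the shared
transcript set.  Single condensates are embedded by PCA of
input-normalized enriched-transcript profiles (first five components by
default) and clustered with k-means; differential transcripts between two
clusters are found with a two-sided Wilcoxon rank-sum test under a
Bonferroni-adjusted significance threshold (default 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .enrichment import detection_frequency

logger = logging.getLogger(__name__)

__all__ = [
    "type_frequency_matrix",
    "type_correlations",
    "build_profiles",
    "embed_and_cluster",
    "CondensateEmbedding",
    "differential_transcripts",
]


def type_frequency_matrix(adata: ad.AnnData, tpm_min: float = 1.0) -> pd.DataFrame:
    """Detection frequency (percent) per transcript x condensate type."""
    if "condensate_type" not in adata.obs:
        raise ValueError("metadata lacks condensate_type")
    cols = {}
    for ctype in adata.obs["condensate_type"].unique():
        sub = adata[adata.obs["condensate_type"] == ctype]
        cols[ctype] = detection_frequency(sub, tpm_min)["detect_freq"]
    return pd.DataFrame(cols, index=adata.var_names)


def type_correlations(freq: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix between type frequency vectors.

    Types with zero variance yield NaN off-diagonal entries with a
    warning; the diagonal is 1.
    """
    if freq.shape[1] < 2:
        raise ValueError("need at least 2 condensate types")
    types = list(freq.columns)
    out = pd.DataFrame(np.eye(len(types)), index=types, columns=types)
    for i, a in enumerate(types):
        for b in types[i + 1:]:
            x, y = freq[a].to_numpy(), freq[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                logger.warning("zero-variance frequency vector (%s/%s)", a, b)
                r = np.nan
            else:
                r = float(stats.pearsonr(x, y)[0])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def build_profiles(
    adata: ad.AnnData,
    enriched_ids,
    input_tpm: pd.Series | None = None,
) -> pd.DataFrame:
    """Input-normalized, per-experiment scaled enriched-transcript profiles.

    Per condensate and enriched transcript:
    ``log2((condensate TPM + 1) / (input TPM + 1))``, then centered and
    unit-scaled per transcript within each experiment batch.  Transcripts
    absent from the input pool (input TPM 0) are excluded with a log
    message.  Returns a condensates x transcripts DataFrame.
    """
    if "tpm" not in adata.layers:
        raise ValueError("matrix lacks a tpm layer; run QC first")
    enriched_ids = [t for t in enriched_ids if t in adata.var_names]
    if not enriched_ids:
        raise ValueError("no enriched transcripts present in the matrix")
    if input_tpm is None:
        input_tpm = adata.var["input_tpm"]
    itpm = input_tpm.loc[enriched_ids].to_numpy(dtype=float)
    keep = itpm > 0
    if (~keep).any():
        logger.info("excluding %d input-absent transcript(s) from profiles",
                    int((~keep).sum()))
    ids = [t for t, k in zip(enriched_ids, keep) if k]
    itpm = itpm[keep]
    sub = adata[:, ids]
    ratio = np.log2((np.asarray(sub.layers["tpm"]) + 1.0) / (itpm[None, :] + 1.0))
    prof = pd.DataFrame(ratio, index=adata.obs_names, columns=ids)
    batches = adata.obs["experiment"] if "experiment" in adata.obs else \
        pd.Series("all", index=adata.obs_names)
    for batch in batches.unique():
        rows = batches == batch
        block = prof.loc[rows.to_numpy()]
        centered = block - block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        prof.loc[rows.to_numpy()] = centered / sd
    return prof


@dataclass
class CondensateEmbedding:
    """PCA coordinates and cluster labels for single condensates."""

    coords: pd.DataFrame            # condensate x PC1..PCn
    labels: pd.Series | None        # cluster label per condensate, None if degenerate
    k: int | None
    cluster_mean_fsc: pd.Series | None
    degenerate: bool = False


def embed_and_cluster(
    profiles: pd.DataFrame,
    n_components: int = 5,
    k: int | None = None,
    seed: int = 0,
    fsc: pd.Series | None = None,
) -> CondensateEmbedding:
    """PCA to ``n_components`` then seeded k-means.

    When ``k`` is None it is chosen in 2..6 by silhouette score.  When all
    profiles are identical the embedding is flagged degenerate and no
    labels are emitted.  Requires at least ``2*k`` condensates.
    """
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if np.allclose(X, X[0]):
        logger.warning("all condensate profiles identical; clustering degenerate")
        coords = pd.DataFrame(
            np.zeros((n, n_components)), index=profiles.index,
            columns=[f"PC{i+1}" for i in range(n_components)],
        )
        return CondensateEmbedding(coords, None, None, None, degenerate=True)
    n_comp = min(n_components, n - 1, X.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    Z = pca.fit_transform(X)
    coords = pd.DataFrame(Z, index=profiles.index,
                          columns=[f"PC{i+1}" for i in range(n_comp)])
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds {n} condensates")
    if k is None:
        best_k, best_s = None, -np.inf
        for kk in range(2, min(6, n - 1) + 1):
            lab = KMeans(kk, n_init=10, random_state=seed).fit_predict(Z)
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(Z, lab)
            if s > best_s:
                best_k, best_s = kk, s
        k = best_k or 2
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} condensates for k={k}")
    labels = pd.Series(
        KMeans(k, n_init=10, random_state=seed).fit_predict(Z),
        index=profiles.index, name="cluster",
    )
    mean_fsc = None
    if fsc is not None:
        mean_fsc = fsc.groupby(labels).mean()
        mean_fsc.index.name = "cluster"
    return CondensateEmbedding(coords, labels, k, mean_fsc)


def differential_transcripts(
    adata: ad.AnnData,
    labels: pd.Series,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential transcripts between two clusters.

    Tests log2(TPM+1) per transcript between exactly two label groups
    (each with at least 3 condensates); Bonferroni correction over the
    tested transcripts; ``significant`` when adjusted p < ``alpha``.
    Transcripts with all-zero values in both groups are excluded and
    logged.
    """
    if "tpm" not in adata.layers:
        raise ValueError("matrix lacks a tpm layer; run QC first")
    labels = labels.loc[adata.obs_names]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two label groups, got {len(groups)}")
    ga, gb = (labels == groups[0]).to_numpy(), (labels == groups[1]).to_numpy()
    if ga.sum() < 3 or gb.sum() < 3:
        raise ValueError("each group needs at least 3 condensates")
    tpm = np.asarray(adata.layers["tpm"])
    log_tpm = np.log2(tpm + 1.0)
    nonzero = (tpm[ga].sum(axis=0) + tpm[gb].sum(axis=0)) > 0
    n_skip = int((~nonzero).sum())
    if n_skip:
        logger.info("excluding %d all-zero transcript(s) from DE testing", n_skip)
    rows = []
    for j in np.nonzero(nonzero)[0]:
        stat, p = stats.ranksums(log_tpm[ga, j], log_tpm[gb, j])
        rows.append((adata.var_names[j], float(stat), float(p)))
    df = pd.DataFrame(rows, columns=["transcript_id", "statistic", "p"])
    df["p_adj"] = np.minimum(df["p"] * len(df), 1.0)
    df["significant"] = df["p_adj"] < alpha
    return df.set_index("transcript_id")
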