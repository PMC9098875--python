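"""TPM computation, quality-control filters and partition coefficients.

The filters mirror the study's QC cascade for single-condensate
libraries, applied in a fixed order:

1. condensate filter — drop condensates with pseudoalignment fraction
   below 5% *and* FSC above 2e4 (large droplets with poor libraries);
2. transcript coverage filter — when the dataset's mean pseudoalignment
   is below 40% and per-transcript read-coverage fractions are supplied,
   drop transcripts with coverage below 20%;
3. detection threshold — recompute TPM on the survivors and zero out
   entries below 1 TPM ("not detected in that condensate").

Filtering is idempotent, and every removal is recorded in a QC report.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import anndata as ad

from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["compute_tpm", "add_tpm", "filter_matrix", "partition_coefficient",
           "detection_mask"]


def compute_tpm(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Transcripts-per-million from a transcripts x condensates count matrix.

    Per condensate (column): ``rate_t = count_t / length_t`` and
    ``tpm_t = rate_t / sum(rate) * 1e6``.  Columns with no counts stay
    all-zero with a logged warning.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts / lengths[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        logger.warning("%d all-zero condensate column(s) in TPM computation",
                       int(zero.sum()))
    colsum[zero] = 1.0
    return rate / colsum * 1e6


def add_tpm(adata: ad.AnnData) -> ad.AnnData:
    """Attach a ``tpm`` layer computed from counts and var['length']."""
    if "length" not in adata.var:
        raise ValueError("var must carry a 'length' column")
    adata.layers["tpm"] = compute_tpm(
        np.asarray(adata.X).T, adata.var["length"].to_numpy()
    ).T
    return adata


def detection_mask(adata: ad.AnnData, tpm_min: float = 1.0) -> np.ndarray:
    """Boolean condensates x transcripts detection matrix (TPM >= threshold)."""
    if "tpm" not in adata.layers:
        raise ValueError("run add_tpm/filter_matrix first")
    return np.asarray(adata.layers["tpm"]) >= tpm_min


def filter_matrix(
    adata: ad.AnnData, config: PipelineConfig | None = None
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply the QC cascade; returns the filtered matrix and a report.

    The report has one row per removed or zeroed entity with columns
    entity, kind, reason, value, threshold.  The returned AnnData carries
    a recomputed ``tpm`` layer in which sub-threshold entries are zeroed.
    """
    config = config or PipelineConfig()
    report_rows: list[tuple] = []
    out = adata.copy()

    if config.pseudoalign_min > 0:
        if "pseudoalign_frac" not in out.obs:
            raise ValueError(
                "pseudoalign_frac missing from metadata but the condensate "
                "filter is enabled"
            )
        pa = out.obs["pseudoalign_frac"].to_numpy(dtype=float)
        fsc = out.obs["fsc"].to_numpy(dtype=float)
        drop = (pa < config.pseudoalign_min) & (fsc > config.fsc_cut)
        for cid, v in zip(out.obs_names[drop], pa[drop]):
            report_rows.append(
                (cid, "condensate", "low_pseudoalignment_large_fsc",
                 float(v), config.pseudoalign_min)
            )
        out = out[~drop].copy()

    mean_pa = float(out.obs["pseudoalign_frac"].mean()) if "pseudoalign_frac" in out.obs else 1.0
    if mean_pa < config.low_pseudoalign_dataset and "coverage" in out.var:
        cov = out.var["coverage"].to_numpy(dtype=float)
        drop_t = cov < config.coverage_min
        for tid, v in zip(out.var_names[drop_t], cov[drop_t]):
            report_rows.append(
                (tid, "transcript", "low_read_coverage", float(v), config.coverage_min)
            )
        out = out[:, ~drop_t].copy()

    out = add_tpm(out)
    tpm = np.asarray(out.layers["tpm"])
    n_zeroed = int((tpm < config.tpm_min)[tpm > 0].sum())
    tpm[tpm < config.tpm_min] = 0.0
    out.layers["tpm"] = tpm
    if n_zeroed:
        report_rows.append(
            ("(matrix entries)", "entry", "tpm_below_detection",
             float(n_zeroed), config.tpm_min)
        )
    report = pd.DataFrame(
        report_rows, columns=["entity", "kind", "reason", "value", "threshold"]
    )
    logger.info(
        "QC: %d/%d condensates, %d/%d transcripts retained",
        out.n_obs, adata.n_obs, out.n_vars, adata.n_vars,
    )
    return out, report


def partition_coefficient(
    droplet_intensities, supernatant_intensity: float
) -> tuple[float, float]:
    """Partition coefficient K from fluorescence intensities.

    ``K_i = droplet_i / supernatant``; returns the mean and sample
    standard deviation (n-1 denominator; 0 when a single droplet).
    """
    droplets = np.asarray(droplet_intensities, dtype=float)
    if droplets.size < 1:
        raise ValueError("need at least one droplet intensity")
    if supernatant_intensity <= 0:
        raise ValueError("supernatant intensity must be positive")
    k = droplets / supernatant_intensity
    sd = float(np.std(k, ddof=1)) if k.size > 1 else 0.0
    return float(k.mean()), sd
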