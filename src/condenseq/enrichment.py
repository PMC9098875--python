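"""Detection-frequency enrichment: model, results and length correlations.

The central statistical question: which transcripts are found in far more
condensates than their input abundance predicts?  Detection frequency
(percent of passing condensates in which a transcript is detected) is
regressed on log10 input abundance with a penalized cubic smoothing
spline (smoothing parameter by generalized cross-validation); transcripts
whose residual exceeds a threshold (default 30 percentage points) are
called enriched.  A LOESS smoother is available as an alternative and
serves as an independent oracle in tests.

The API follows the model/results convention: build an
:class:`EnrichmentModel` from data (or from a condensate matrix), call
``fit()``, and read estimates and diagnostics off the returned
:class:`EnrichmentResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy.interpolate import make_smoothing_spline
from scipy import stats

from .qc import detection_mask

logger = logging.getLogger(__name__)

__all__ = [
    "detection_frequency",
    "frequency_bin",
    "EnrichmentModel",
    "EnrichmentResults",
    "call_enriched",
    "binned_length_correlation",
]


def detection_frequency(adata: ad.AnnData, tpm_min: float = 1.0) -> pd.DataFrame:
    """Per-transcript detection frequency (percent) across passing condensates.

    Control wells (``is_control``) are excluded.  Returns a DataFrame with
    ``detect_freq`` in [0, 100] and the categorical ``bin``
    {not detected, <10%, 10-90%, >90%}.
    """
    keep = ~adata.obs["is_control"].to_numpy(dtype=bool) if "is_control" in adata.obs \
        else np.ones(adata.n_obs, dtype=bool)
    n_pass = int(keep.sum())
    if n_pass == 0:
        raise ValueError("zero passing condensates")
    det = detection_mask(adata, tpm_min)[keep]
    freq = 100.0 * det.sum(axis=0) / n_pass
    return pd.DataFrame(
        {"detect_freq": freq, "bin": [frequency_bin(f) for f in freq]},
        index=adata.var_names,
    )


def frequency_bin(freq: float) -> str:
    """Categorical detection-frequency bin."""
    if freq == 0.0:
        return "not detected"
    if freq < 10.0:
        return "<10%"
    if freq <= 90.0:
        return "10-90%"
    return ">90%"


def call_enriched(residuals: np.ndarray, threshold: float = 30.0) -> np.ndarray:
    """Enriched flags: residual strictly greater than the threshold."""
    return np.asarray(residuals) > threshold


def _fit_spline(x: np.ndarray, y: np.ndarray, lam: float | None) -> np.ndarray:
    """Penalized cubic smoothing spline, GCV-selected lambda by default.

    Duplicate abscissae are collapsed to their mean with multiplicity
    weights before fitting; the abscissa is rescaled to [0, 1] for
    conditioning.  When scipy's GCV solve is numerically ill-posed the
    smoothing parameter falls back to 5-fold cross-validation on a
    log-spaced grid.
    """
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: all input abundances equal")
    # quantize to a fine grid: collapses near-duplicate abscissae that make
    # the penalized system ill-conditioned, at no cost to the smooth fit
    xq = np.round((x - x.min()) / np.ptp(x) * 2048.0) / 2048.0
    ux, inverse, counts = np.unique(xq, return_inverse=True, return_counts=True)
    if len(ux) < 4:
        raise ValueError("degenerate abscissa: too few distinct input abundances")
    uy = np.bincount(inverse, weights=y) / counts
    w = counts.astype(float)
    if lam is None:
        spl = None
        try:
            spl = make_smoothing_spline(ux, uy, w=w, lam=None)
        except (ValueError, np.linalg.LinAlgError):
            pass
        if spl is not None:
            fitted = np.asarray(spl(ux))
            margin = np.ptp(uy)
            if not (np.all(np.isfinite(fitted))
                    and fitted.min() > uy.min() - margin
                    and fitted.max() < uy.max() + margin):
                spl = None  # GCV lambda produced a divergent fit
        if spl is None:
            lam = _cv_lambda(ux, uy, w)
            logger.info("GCV unstable; cross-validated lambda %.3g", lam)
            spl = make_smoothing_spline(ux, uy, w=w, lam=lam)
    else:
        spl = make_smoothing_spline(ux, uy, w=w, lam=lam)
    return np.asarray(spl(xq))


def _cv_lambda(x: np.ndarray, y: np.ndarray, w: np.ndarray, n_folds: int = 5) -> float:
    """Smoothing parameter by k-fold cross-validation on a log grid."""
    grid = np.logspace(-9, 1, 16)
    folds = np.arange(len(x)) % n_folds
    best_lam, best_err = grid[0], np.inf
    for lam in grid:
        err = 0.0
        for f in range(n_folds):
            tr = folds != f
            if tr.sum() < 4:
                continue
            spl = make_smoothing_spline(x[tr], y[tr], w=w[tr], lam=lam)
            resid = y[~tr] - spl(x[~tr])
            err += float(np.sum(w[~tr] * resid**2))
        if err < best_err:
            best_lam, best_err = lam, err
    return float(best_lam)


def _fit_loess(x: np.ndarray, y: np.ndarray, frac: float) -> np.ndarray:
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: all input abundances equal")
    return lowess(y, x, frac=frac, return_sorted=False)


class EnrichmentModel:
    """Detection frequency as a smooth function of input abundance.

    Parameters
    ----------
    detect_freq : array-like, percent in [0, 100] per transcript.
    input_tpm : array-like, input-pool abundance per transcript.
    lengths : optional transcript lengths (enables length correlations).
    transcript_ids : optional identifiers.
    truth_enriched : optional ground-truth labels (simulated data), used
        only for diagnostics in the results summary.
    """

    def __init__(self, detect_freq, input_tpm, lengths=None,
                 transcript_ids=None, truth_enriched=None):
        self.detect_freq = np.asarray(detect_freq, dtype=float)
        self.input_tpm = np.asarray(input_tpm, dtype=float)
        n = len(self.detect_freq)
        if len(self.input_tpm) != n:
            raise ValueError("detect_freq and input_tpm length mismatch")
        if ((self.detect_freq < 0) | (self.detect_freq > 100)).any():
            raise ValueError("detect_freq must be in [0, 100]")
        self.lengths = None if lengths is None else np.asarray(lengths, dtype=int)
        self.transcript_ids = (
            list(transcript_ids) if transcript_ids is not None
            else [f"T{i:05d}" for i in range(n)]
        )
        self.truth_enriched = (
            None if truth_enriched is None else np.asarray(truth_enriched, dtype=bool)
        )

    @classmethod
    def from_matrix(cls, adata: ad.AnnData, tpm_min: float = 1.0) -> "EnrichmentModel":
        """Build the model from a QC-filtered condensate matrix.

        Requires var columns ``input_tpm`` and ``length`` (and optionally
        ``truth_enriched`` on simulated data).
        """
        freq = detection_frequency(adata, tpm_min)["detect_freq"].to_numpy()
        return cls(
            freq,
            adata.var["input_tpm"].to_numpy(),
            lengths=adata.var["length"].to_numpy(),
            transcript_ids=list(adata.var_names),
            truth_enriched=adata.var["truth_enriched"].to_numpy()
            if "truth_enriched" in adata.var else None,
        )

    def fit(
        self,
        smoother: str = "spline",
        threshold: float = 30.0,
        lam: float | None = None,
        loess_frac: float = 0.3,
    ) -> "EnrichmentResults":
        """Fit the smoother and call enriched transcripts.

        Transcripts absent from the input pool (``input_tpm == 0``) are
        excluded from the fit and reported separately (``in_fit`` False,
        residual NaN).  Requires at least 20 transcripts in the fit.
        """
        in_fit = self.input_tpm > 0
        n_fit = int(in_fit.sum())
        if n_fit < 20:
            raise ValueError(f"need >= 20 transcripts with input_tpm > 0, got {n_fit}")
        x = np.log10(self.input_tpm[in_fit] + 1.0)
        y = self.detect_freq[in_fit]
        if smoother == "spline":
            fitted_sub = _fit_spline(x, y, lam)
        elif smoother == "loess":
            fitted_sub = _fit_loess(x, y, loess_frac)
        else:
            raise ValueError(f"unknown smoother {smoother!r}")
        fitted = np.full(len(self.detect_freq), np.nan)
        fitted[in_fit] = fitted_sub
        residual = self.detect_freq - fitted
        enriched = np.zeros(len(residual), dtype=bool)
        enriched[in_fit] = call_enriched(residual[in_fit], threshold)
        n_excluded = int((~in_fit).sum())
        if n_excluded:
            logger.info("%d transcript(s) absent from the input pool excluded "
                        "from the smoother fit", n_excluded)
        return EnrichmentResults(self, fitted, residual, enriched, in_fit,
                                 smoother, threshold)


@dataclass
class EnrichmentResults:
    """Fitted expectations, residuals and enrichment calls."""

    model: EnrichmentModel
    fitted: np.ndarray
    residual: np.ndarray
    enriched: np.ndarray
    in_fit: np.ndarray
    smoother: str
    threshold: float

    @property
    def table(self) -> pd.DataFrame:
        """The per-transcript enrichment table."""
        m = self.model
        df = pd.DataFrame(
            {
                "transcript_id": m.transcript_ids,
                "input_tpm": m.input_tpm,
                "detect_freq": m.detect_freq,
                "fitted_freq": self.fitted,
                "residual": self.residual,
                "enriched": self.enriched,
                "in_fit": self.in_fit,
                "bin": [frequency_bin(f) for f in m.detect_freq],
            }
        )
        if m.lengths is not None:
            df["length"] = m.lengths
        return df.set_index("transcript_id")

    @property
    def n_enriched(self) -> int:
        return int(self.enriched.sum())

    def recovery(self) -> tuple[float, float]:
        """(sensitivity, precision) of the calls vs planted ground truth."""
        truth = self.model.truth_enriched
        if truth is None:
            raise ValueError("no ground-truth labels available")
        tp = int((self.enriched & truth).sum())
        sens = tp / max(int(truth.sum()), 1)
        prec = tp / max(self.n_enriched, 1)
        return sens, prec

    def binned_length_correlation(self, n_bins: int = 10) -> pd.Series:
        if self.model.lengths is None:
            raise ValueError("model built without transcript lengths")
        return binned_length_correlation(self.table, n_bins)

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.model
        lines = [
            "Detection-frequency enrichment",
            "=" * 46,
            f"{'transcripts':<28}{len(m.detect_freq):>10d}",
            f"{'in smoother fit':<28}{int(self.in_fit.sum()):>10d}",
            f"{'smoother':<28}{self.smoother:>10}",
            f"{'residual threshold':<28}{self.threshold:>10.1f}",
            f"{'enriched called':<28}{self.n_enriched:>10d}",
            f"{'mean residual (fit set)':<28}"
            f"{float(np.nanmean(self.residual[self.in_fit])):>10.3f}",
        ]
        if m.truth_enriched is not None:
            sens, prec = self.recovery()
            lines.append(f"{'sensitivity vs truth':<28}{sens:>10.3f}")
            lines.append(f"{'precision vs truth':<28}{prec:>10.3f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Detection frequency vs input abundance with the fit and calls."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        x = np.log10(m.input_tpm + 1.0)
        ax.scatter(x[~self.enriched], m.detect_freq[~self.enriched],
                   s=6, c="0.6", label="transcripts")
        ax.scatter(x[self.enriched], m.detect_freq[self.enriched],
                   s=10, c="crimson", label="enriched")
        order = np.argsort(x[self.in_fit])
        ax.plot(x[self.in_fit][order], self.fitted[self.in_fit][order],
                c="k", lw=1.5, label=f"{self.smoother} fit")
        ax.set_xlabel("log10(input TPM + 1)")
        ax.set_ylabel("detection frequency (%)")
        ax.legend(frameon=False)
        return ax


def binned_length_correlation(table: pd.DataFrame, n_bins: int = 10) -> pd.Series:
    """Pearson r of transcript length vs residual within input-TPM bins.

    Transcripts are split into ``n_bins`` near-equal-count quantile bins
    of input abundance; bins with fewer than 5 transcripts give NaN.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    tab = table[table["in_fit"]] if "in_fit" in table else table
    if len(tab) < 5 * n_bins:
        raise ValueError(f"need at least {5 * n_bins} transcripts for {n_bins} bins")
    bins = pd.qcut(tab["input_tpm"], n_bins, labels=False, duplicates="drop")
    out = {}
    for b in range(n_bins):
        sel = tab[bins == b]
        if len(sel) < 5 or sel["length"].nunique() < 2 or sel["residual"].nunique() < 2:
            out[b] = np.nan
            continue
        out[b] = float(stats.pearsonr(sel["length"], sel["residual"])[0])
    return pd.Series(out, name="pearson_r")
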