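"""Motif scanning, co-occurrence, spacing statistics and k-mer discovery.

Motifs are 4 x width letter-probability matrices (or consensus strings
promoted to degenerate-free matrices).  Scanning slides the log-odds
matrix over both strands of each transcript and keeps windows scoring at
least a fraction of the motif's maximum attainable score — a deliberate,
documented stand-in for MAST-style E-value significance, whose
composition model is out of scope here.

Spacing statistics follow the nearest-5'-neighbor convention: for every
motif occurrence, the start-to-start distance to the closest occurrence
with a strictly smaller start on the same transcript, grouped by the
(hit motif, neighbor motif) pair.

``discover_kmers`` is a discovery-lite stand-in for de novo motif
discovery: transcript-level k-mer presence counts in an enriched vs a
background pool, one-sided hypergeometric enrichment, Bonferroni over all
4^k tests, and greedy assembly of overlapping significant k-mers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .align import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "Motif",
    "scan",
    "cis_cooccurrence",
    "neighbor_distances",
    "discover_kmers",
    "background_composition",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class Motif:
    """A sequence motif as a 4 x width letter-probability matrix.

    Rows are ordered A, C, G, T; every column sums to 1 (tolerance 1e-6).
    The consensus is the per-column argmax with alphabetical tie-break
    A < C < G < T.
    """

    motif_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"motif {self.motif_id}: matrix must be 4 x width")
        if not 4 <= self.width <= 100:
            raise ValueError(
                f"motif {self.motif_id}: width {self.width} outside [4, 100]"
            )
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"motif {self.motif_id}: columns must sum to 1")

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str) -> "Motif":
        consensus = consensus.upper()
        if set(consensus) - set("ACGT"):
            raise ValueError(f"invalid alphabet in consensus {consensus!r}")
        mat = np.zeros((4, len(consensus)))
        for j, c in enumerate(consensus):
            mat[_BASE_INDEX[c], j] = 1.0
        return cls(motif_id, mat)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.matrix, axis=0))

    def log_odds(self, background: np.ndarray | None = None, alpha: float = 0.01) -> np.ndarray:
        """5 x width log2-odds matrix against a background composition.

        Probabilities are smoothed with a background-proportional
        pseudocount ``alpha``; row 4 (N) is each column's minimum so that
        ambiguous bases can never create a hit.
        """
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6 or (bg <= 0).any():
            raise ValueError("background must be 4 positive frequencies summing to 1")
        p = (self.matrix + alpha * bg[:, None]) / (1.0 + alpha)
        lo = np.log2(p / bg[:, None])
        return np.vstack([lo, lo.min(axis=0)])


def background_composition(sequences: Sequence[str]) -> np.ndarray:
    """Empirical mononucleotide frequencies of a sequence pool (ACGT)."""
    counts = np.zeros(4)
    for s in sequences:
        codes = _encode(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no ACGT bases in background sequences")
    return counts / total


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.upper()
        .translate(str.maketrans("ACGTN", "\x00\x01\x02\x03\x04"))
        .encode("latin1"),
        dtype=np.uint8,
    )


def _scan_one_strand(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    w = lom.shape[1]
    if len(codes) < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return lom[windows, np.arange(w)].sum(axis=1)


def scan(
    transcripts: Mapping[str, str],
    motif_list: Sequence[Motif],
    threshold_frac: float = 0.85,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scan transcripts for motif occurrences on both strands.

    A window is a hit when its log-odds score reaches
    ``threshold_frac * max attainable score`` for that motif.  Overlapping
    hits of the same motif on the same strand keep only the highest score
    (ties: leftmost).  Hits are reported in transcript coordinates,
    0-based half-open.  Transcripts shorter than a motif produce no hits.
    """
    if not 0.0 < threshold_frac <= 1.0:
        raise ValueError("threshold_frac must be in (0, 1]")
    if background is None:
        background = background_composition(list(transcripts.values()))
    rows: list[tuple] = []
    mats = []
    for m in motif_list:
        lom = m.log_odds(background)
        mats.append((m, lom, float(lom[:4].max(axis=0).sum())))
    for tid, seq in transcripts.items():
        fwd = _encode(seq)
        rev = _encode(reverse_complement(seq))
        L = len(seq)
        for m, lom, max_score in mats:
            w = m.width
            cut = threshold_frac * max_score
            for strand, codes in (("+", fwd), ("-", rev)):
                scores = _scan_one_strand(codes, lom)
                for s in np.nonzero(scores >= cut - 1e-9)[0]:
                    start = int(s) if strand == "+" else L - int(s) - w
                    rows.append(
                        (tid, start, start + w, strand, m.motif_id, float(scores[s]))
                    )
    hits = pd.DataFrame(
        rows, columns=["transcript_id", "start", "end", "strand", "motif_id", "score"]
    )
    return _resolve_overlaps(hits)


def _resolve_overlaps(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep the best hit among same-motif same-strand overlaps (ties leftmost)."""
    if hits.empty:
        return hits
    kept = []
    for _, group in hits.groupby(["transcript_id", "motif_id", "strand"], sort=False):
        g = group.sort_values(["score", "start"], ascending=[False, True])
        taken: list[tuple[int, int]] = []
        for row in g.itertuples():
            if all(row.start >= e or row.end <= s for s, e in taken):
                taken.append((row.start, row.end))
                kept.append(row.Index)
    out = hits.loc[sorted(kept)].sort_values(
        ["transcript_id", "start", "motif_id"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def cis_cooccurrence(
    hits: pd.DataFrame,
    motif_a: str,
    motif_b: str,
    transcript_ids: Sequence[str],
    detect_freq: pd.Series | None = None,
) -> pd.DataFrame:
    """Classify transcripts by presence of two motifs (cis complementarity).

    Labels every transcript "both", "a-only", "b-only" or "none".  When a
    detection-frequency series is supplied, the returned frame carries it
    so class means (mean detection frequency conditional on motif content)
    can be compared, mirroring the conditional-uptake analysis.
    """
    known = set(hits["motif_id"].unique())
    for m in (motif_a, motif_b):
        if not hits.empty and m not in known:
            raise KeyError(f"unknown motif id {m!r}")
    has = hits.groupby("transcript_id")["motif_id"].agg(set) if not hits.empty else {}
    labels = []
    for tid in transcript_ids:
        present = has.get(tid, set()) if len(has) else set()
        a, b = motif_a in present, motif_b in present
        labels.append("both" if a and b else "a-only" if a else "b-only" if b else "none")
    out = pd.DataFrame({"transcript_id": list(transcript_ids), "class": labels})
    if detect_freq is not None:
        out["detect_freq"] = out["transcript_id"].map(detect_freq).to_numpy()
    return out


def class_mean_frequency(coocc: pd.DataFrame) -> pd.Series:
    """Mean detection frequency per cis-co-occurrence class."""
    if "detect_freq" not in coocc:
        raise ValueError("co-occurrence table lacks detect_freq")
    return coocc.groupby("class")["detect_freq"].mean()


def neighbor_distances(hits: pd.DataFrame) -> pd.DataFrame:
    """Start-to-start distance from every hit to its nearest 5' neighbor.

    For each hit, the neighbor is the hit with the largest strictly
    smaller start on the same transcript (any motif, either strand).
    Returns one row per hit that has a neighbor, with the (hit motif,
    neighbor motif) pair; transcripts with a single hit contribute
    nothing.  The result is invariant to input row order.
    """
    if hits.empty:
        return pd.DataFrame(
            columns=["transcript_id", "motif_id", "neighbor_motif_id", "distance"]
        )
    rows = []
    for tid, group in hits.groupby("transcript_id"):
        g = group.sort_values(["start", "motif_id"], kind="mergesort")
        starts = g["start"].to_numpy()
        mids = g["motif_id"].to_numpy()
        for i in range(len(g)):
            smaller = np.nonzero(starts < starts[i])[0]
            if len(smaller) == 0:
                continue
            dist = starts[i] - starts[smaller]
            j = smaller[np.argmin(dist)]
            rows.append((tid, mids[i], mids[j], int(starts[i] - starts[j])))
    return pd.DataFrame(
        rows, columns=["transcript_id", "motif_id", "neighbor_motif_id", "distance"]
    )


def distance_medians(distances: pd.DataFrame) -> pd.Series:
    """Median nearest-5'-neighbor distance per (motif, neighbor motif) pair."""
    if distances.empty:
        return pd.Series(dtype=float)
    return distances.groupby(["motif_id", "neighbor_motif_id"])["distance"].median()


# ---------------------------------------------------------------------------
# k-mer discovery-lite

def _kmer_presence(sequences: Sequence[str], k: int) -> np.ndarray:
    """Per-k-mer transcript presence counts, counting both strands."""
    n_kmers = 4**k
    counts = np.zeros(n_kmers, dtype=np.int64)
    mult = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    for seq in sequences:
        present: list[np.ndarray] = []
        for s in (seq, reverse_complement(seq)):
            codes = _encode(s)
            if len(codes) < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, k)
            valid = (win < 4).all(axis=1)
            if valid.any():
                present.append((win[valid].astype(np.int64) * mult).sum(axis=1))
        if present:
            counts[np.unique(np.concatenate(present))] += 1
    return counts


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def discover_kmers(
    enriched: Sequence[str],
    background: Sequence[str],
    k: int = 8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank k-mers over-represented in an enriched vs a background pool.

    Counts, for each of the 4^k k-mers, the number of transcripts
    containing it on either strand; tests enrichment with a one-sided
    hypergeometric test and Bonferroni-corrects over all 4^k k-mers.
    Significant k-mers are greedily merged when they overlap by k-1 with
    consistent offsets, yielding longer consensus strings.  Returns a
    DataFrame of merged k-mers sorted by best adjusted p.
    """
    if not 4 <= k <= 12:
        raise ValueError("k must be in [4, 12]")
    if len(enriched) == 0 or len(background) == 0:
        raise ValueError("both pools must be non-empty")
    ce = _kmer_presence(enriched, k)
    cb = _kmer_presence(background, k)
    n_e, n_b = len(enriched), len(background)
    total = ce + cb
    candidates = np.nonzero(ce > 0)[0]
    # one-sided: P(X >= ce) drawing n_e transcripts from n_e+n_b with `total` carriers
    pvals = hypergeom.sf(ce[candidates] - 1, n_e + n_b, total[candidates], n_e)
    p_adj = np.minimum(pvals * (4.0**k), 1.0)
    sig = candidates[p_adj < alpha]
    if len(sig) == 0:
        return pd.DataFrame(
            columns=["kmer", "width", "count_enriched", "count_background",
                     "p", "p_adj", "members"]
        )
    sig_info = {
        _decode_kmer(int(c), k): (
            float(pvals[np.searchsorted(candidates, c)]),
            float(p_adj[np.searchsorted(candidates, c)]),
            int(ce[c]),
            int(cb[c]),
        )
        for c in sig
    }
    merged = _greedy_merge(sig_info, k)
    df = pd.DataFrame(merged, columns=["kmer", "width", "count_enriched",
                                       "count_background", "p", "p_adj", "members"])
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


def _greedy_merge(sig_info: dict[str, tuple], k: int) -> list[tuple]:
    """Assemble overlapping (by k-1) significant k-mers into longer strings."""
    remaining = dict(sig_info)
    out = []
    while remaining:
        seed = min(remaining, key=lambda s: (remaining[s][0], s))
        members = [seed]
        assembled = seed
        del remaining[seed]
        extended = True
        while extended:
            extended = False
            suffix = assembled[-(k - 1):]
            nexts = [s for s in remaining if s[: k - 1] == suffix]
            if nexts:
                nxt = min(nexts, key=lambda s: (remaining[s][0], s))
                assembled += nxt[-1]
                members.append(nxt)
                del remaining[nxt]
                extended = True
        extended = True
        while extended:
            extended = False
            prefix = assembled[: k - 1]
            prevs = [s for s in remaining if s[-(k - 1):] == prefix]
            if prevs:
                prv = min(prevs, key=lambda s: (remaining[s][0], s))
                assembled = prv[0] + assembled
                members.append(prv)
                del remaining[prv]
                extended = True
        best = min(sig_info[m][0] for m in members)
        best_adj = min(sig_info[m][1] for m in members)
        ce = max(sig_info[m][2] for m in members)
        cb = min(sig_info[m][3] for m in members)
        out.append((assembled, len(assembled), ce, cb, best, best_adj, ",".join(members)))
    return out
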