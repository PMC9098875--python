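"""Smith-Waterman local alignment and sequence-complementarity scoring.

Local alignment underlies two analyses in this package: *trans*
complementarity (does one transcript align well to the reverse complement
of another?) and homology of enriched sequence motifs to SINE
(short interspersed element) references.  Both use nucleotide
match/mismatch scoring with affine gaps, under two named parameter sets:

``trans``
    match 2, mismatch -1, gap open 30, gap extend 0.05.  The near-zero
    extension cost means a gap of any length costs barely more than 30,
    so high scores arise from chains of well-matched blocks.
``sine``
    match 2, mismatch -1, gap open 10, gap extend 0.

The gap convention is the one of the Biostrings/EMBOSS family: a gap of
length L costs ``gap_open + L * gap_extend`` (opening is charged once, and
extension is charged for every gap position including the first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from numba import njit

__all__ = [
    "ScoringScheme",
    "AlignmentScore",
    "TRANS",
    "SINE",
    "reverse_complement",
    "sw_score",
    "complementarity_score",
    "pool_complementarity",
    "PoolComplementarity",
    "sample_length_matched_background",
    "sine_homology",
]

_ALPHABET = "ACGTN"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap nucleotide scoring scheme.

    ``gap_open`` and ``gap_extend`` are *costs* (non-negative); a gap of
    length L is penalized by ``gap_open + L * gap_extend``.
    """

    name: str
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = 30.0
    gap_extend: float = 0.05

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")

    def substitution_matrix(self) -> np.ndarray:
        """5x5 score matrix over ACGTN; N scores as mismatch vs everything."""
        m = np.full((5, 5), self.mismatch, dtype=np.float64)
        for i in range(4):
            m[i, i] = self.match
        m[4, :] = self.mismatch
        m[:, 4] = self.mismatch
        return m


#: Scheme for trans-complementarity between transcripts.
TRANS = ScoringScheme("trans", 2.0, -1.0, 30.0, 0.05)
#: Scheme for motif-vs-SINE homology scoring.
SINE = ScoringScheme("sine", 2.0, -1.0, 10.0, 0.0)

_SCHEMES = {"trans": TRANS, "sine": SINE}


def get_scheme(name: str) -> ScoringScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise KeyError(f"unknown scoring scheme {name!r}; known: {sorted(_SCHEMES)}")


@dataclass
class AlignmentScore:
    """Result of a local alignment; spans are 0-based half-open when present."""

    score: float
    query_id: str = ""
    target_id: str = ""
    scheme: str = ""
    query_span: tuple[int, int] | None = None
    target_span: tuple[int, int] | None = None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes 0..4."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from exc


@njit(cache=True)
def _sw_kernel(a, b, sub, gap_first, gap_ext):  # pragma: no cover - jitted
    n, m = a.shape[0], b.shape[0]
    neg = -1e30
    h_prev = np.zeros(m + 1)
    h_cur = np.zeros(m + 1)
    e_col = np.full(m + 1, neg)  # gap in b (consuming a), per column
    best = 0.0
    for i in range(n):
        h_cur[0] = 0.0
        f = neg  # gap in a (consuming b), within row
        for j in range(1, m + 1):
            e_col[j] = max(h_prev[j] - gap_first, e_col[j] - gap_ext)
            f = max(h_cur[j - 1] - gap_first, f - gap_ext)
            h = h_prev[j - 1] + sub[a[i], b[j - 1]]
            if e_col[j] > h:
                h = e_col[j]
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
    return best


def sw_score(
    a: str,
    b: str,
    scheme: ScoringScheme = TRANS,
    *,
    query_id: str = "",
    target_id: str = "",
    traceback: bool = False,
) -> AlignmentScore:
    """Optimal Smith-Waterman local alignment score of ``a`` vs ``b``.

    Affine gaps: a gap of length L costs ``gap_open + L * gap_extend``.
    The score is 0 when no positive-scoring local alignment exists; empty
    sequences score 0.  With ``traceback=True`` the aligned spans are
    recovered (ties broken diagonal > up > left).
    """
    if len(a) == 0 or len(b) == 0:
        return AlignmentScore(0.0, query_id, target_id, scheme.name)
    ca, cb = encode(a), encode(b)
    sub = scheme.substitution_matrix()
    if traceback:
        score, qs, ts = _sw_traceback(ca, cb, sub, scheme)
        return AlignmentScore(score, query_id, target_id, scheme.name, qs, ts)
    score = float(
        _sw_kernel(ca, cb, sub, scheme.gap_open + scheme.gap_extend, scheme.gap_extend)
    )
    return AlignmentScore(score, query_id, target_id, scheme.name)


def _sw_traceback(ca, cb, sub, scheme):
    """Full-matrix Gotoh with pointer recovery; quadratic memory."""
    n, m = len(ca), len(cb)
    neg = -1e30
    go = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] - go, E[i - 1, j] - ge)
            F[i, j] = max(H[i, j - 1] - go, F[i, j - 1] - ge)
            H[i, j] = max(
                0.0, H[i - 1, j - 1] + sub[ca[i - 1], cb[j - 1]], E[i, j], F[i, j]
            )
    best = float(H.max())
    if best <= 0:
        return 0.0, None, None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    end_i, end_j = i, j
    # ties: diagonal > up (gap consuming a) > left (gap consuming b)
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            diag = H[i - 1, j - 1] + sub[ca[i - 1], cb[j - 1]]
            if H[i, j] == diag:
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if E[i, j] == H[i - 1, j] - go:
                state = "H"
            i -= 1
        else:
            if F[i, j] == H[i, j - 1] - go:
                state = "H"
            j -= 1
    return best, (int(i), int(end_i)), (int(j), int(end_j))


def complementarity_score(
    a: str,
    b: str,
    scheme: ScoringScheme = TRANS,
    *,
    mode: str = "revcomp",
    query_id: str = "",
    target_id: str = "",
) -> AlignmentScore:
    """Trans-complementarity score between two transcripts.

    ``mode="revcomp"`` (default) aligns ``a`` against the reverse
    complement of ``b``, so a high score means the two RNAs can base-pair
    over a long stretch.  The operation is symmetric in its arguments.
    ``mode="direct"`` scores plain similarity instead.
    """
    if mode == "revcomp":
        other = reverse_complement(b)
    elif mode == "direct":
        other = b
    else:
        raise ValueError(f"mode must be 'revcomp' or 'direct', got {mode!r}")
    res = sw_score(a, other, scheme, query_id=query_id, target_id=target_id)
    return res


@dataclass
class PoolComplementarity:
    """All-pairs complementarity scores for three comparison classes."""

    scores: Mapping[str, np.ndarray]
    pairs: Mapping[str, list[tuple[str, str]]]
    maxima: Mapping[str, float] = field(default_factory=dict)
    enriched_exceeds: bool = False

    def __post_init__(self) -> None:
        if not self.maxima:
            self.maxima = {
                k: (float(np.max(v)) if len(v) else float("nan"))
                for k, v in self.scores.items()
            }
        other = max(
            self.maxima["enriched_vs_background"],
            self.maxima["background_vs_background"],
        )
        self.enriched_exceeds = self.maxima["enriched_vs_enriched"] > other

    @property
    def outside_maximum(self) -> float:
        """Maximum score outside enriched-vs-enriched (the dotted-line level)."""
        return max(
            self.maxima["enriched_vs_background"],
            self.maxima["background_vs_background"],
        )


def pool_complementarity(
    enriched: Mapping[str, str],
    background: Mapping[str, str],
    scheme: ScoringScheme = TRANS,
    *,
    mode: str = "revcomp",
) -> PoolComplementarity:
    """Complementarity score distributions within and between transcript pools.

    Computes all unordered pair scores for enriched x enriched,
    enriched x background and background x background (self-pairs
    excluded), and reports whether the enriched x enriched maximum exceeds
    the maximum seen in the other two classes.
    """
    if len(enriched) < 2 or len(background) < 2:
        raise ValueError("each pool needs at least 2 sequences")
    classes = {
        "enriched_vs_enriched": list(combinations(sorted(enriched), 2)),
        "background_vs_background": list(combinations(sorted(background), 2)),
        "enriched_vs_background": [
            (e, b) for e in sorted(enriched) for b in sorted(background) if e != b
        ],
    }
    scores: dict[str, np.ndarray] = {}
    for cls, pairs in classes.items():
        vals = np.empty(len(pairs))
        for idx, (x, y) in enumerate(pairs):
            sx = enriched[x] if x in enriched else background[x]
            sy = enriched.get(y, background.get(y))
            vals[idx] = complementarity_score(sx, sy, scheme, mode=mode).score
        scores[cls] = vals
    return PoolComplementarity(scores=scores, pairs=classes)


def sample_length_matched_background(
    candidates: Mapping[str, str],
    target_lengths: Sequence[int],
    n: int,
    seed: int,
    n_strata: int = 10,
) -> dict[str, str]:
    """Draw ``n`` background sequences length-matched to a target pool.

    Candidates are stratified into ``n_strata`` quantile bins of the target
    length distribution; draws are allocated per stratum in proportion to
    the target pool, falling back to the nearest non-empty stratum.
    """
    if n > len(candidates):
        raise ValueError("not enough background candidates")
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(candidates))
    lens = np.array([len(candidates[i]) for i in ids])
    target = np.asarray(target_lengths, dtype=float)
    edges = np.quantile(target, np.linspace(0, 1, n_strata + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    strata = np.clip(np.searchsorted(edges, lens, side="right") - 1, 0, n_strata - 1)
    t_strata = np.clip(
        np.searchsorted(edges, target, side="right") - 1, 0, n_strata - 1
    )
    want = np.bincount(t_strata, minlength=n_strata).astype(float)
    want = np.round(want / want.sum() * n).astype(int)
    while want.sum() < n:
        want[np.argmax(want)] += 1
    while want.sum() > n:
        want[np.argmax(want)] -= 1
    chosen: list[str] = []
    available = {s: list(ids[strata == s]) for s in range(n_strata)}
    for s in range(n_strata):
        pool = available[s]
        k = min(want[s], len(pool))
        if k:
            picks = rng.choice(len(pool), size=k, replace=False)
            for p in sorted(picks, reverse=True):
                chosen.append(pool.pop(p))
        want[s] -= k
    deficit = int(want.sum())
    if deficit:
        rest = [i for s in available.values() for i in s]
        picks = rng.choice(len(rest), size=deficit, replace=False)
        chosen.extend(rest[p] for p in picks)
    return {i: candidates[i] for i in chosen}


def sine_homology(
    motif_hits: Mapping[str, Sequence[str]],
    sine_refs: Mapping[str, str],
    scheme: ScoringScheme = SINE,
):
    """Mean alignment score of each motif's top hit sequences vs SINE references.

    For every motif, each of its (at most five) highest-scoring hit
    sequences is aligned against every reference; the per-reference scores
    are averaged over the hits.  Motifs with no hits are dropped with a
    warning.  Returns a motifs x references DataFrame.
    """
    import logging

    import pandas as pd

    if not sine_refs:
        raise ValueError("no SINE reference sequences provided")
    rows = {}
    for motif_id, hits in motif_hits.items():
        if len(hits) == 0:
            logging.getLogger(__name__).warning(
                "motif %s has no hits; omitted from SINE scoring", motif_id
            )
            continue
        if len(hits) > 5:
            raise ValueError(f"motif {motif_id}: more than 5 hit sequences supplied")
        if len(hits) < 5:
            logging.getLogger(__name__).info(
                "motif %s: averaging over %d hit(s)", motif_id, len(hits)
            )
        rows[motif_id] = {
            ref_id: float(
                np.mean([sw_score(h, ref_seq, scheme).score for h in hits])
            )
            for ref_id, ref_seq in sine_refs.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")
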