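"""Synthetic transcript pools and condensate populations.

The generator emulates the statistical structure of a single-condensate
RNA-sequencing experiment: a heavy-tailed input RNA pool, a planted pair
of mutually reverse-complementary sequence motifs carried by a fraction of
transcripts, a population of phase-separated droplets with log-normal
sizes, size-dependent RNA capture (molecule depth scaling with a power of
forward scatter), abundance-dominated uptake with a motif-dependent boost,
ambient RNA contamination from the liquid surrounding each sorted droplet,
and multinomial count-level sampling noise.

Every draw is reproducible from an integer seed, and the planted
``truth_enriched`` labels provide ground truth for parameter-recovery
tests of the downstream enrichment caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import anndata as ad

from .align import reverse_complement

__all__ = [
    "TranscriptPool",
    "UptakeModel",
    "DEFAULT_MOTIF",
    "generate_pool",
    "simulate_condensates",
    "write_fixture",
    "simulate_from_manifest",
]

_BASES = np.array(list("ACGT"))
# i.i.d. base frequencies at GC content 0.45
_BASE_P = np.array([0.275, 0.225, 0.225, 0.275])

#: Default planted consensus (25 nt, mid-range of typical enriched motif
#: widths); the planted pair is this motif plus its reverse complement.
DEFAULT_MOTIF = "ACGGTTCACGTAAGCTGATTCCAGT"


@dataclass
class TranscriptPool:
    """A synthetic input RNA pool.

    ``input_tpm`` sums to 1e6; ``planted_motifs`` maps transcript_id to a
    list of ``(motif_id, start, strand)`` occurrences (0-based starts).
    """

    transcript_ids: list[str]
    sequences: list[str]
    input_tpm: np.ndarray
    truth_enriched: np.ndarray
    planted_motifs: dict[str, list[tuple[str, int, str]]]
    motif_pair: tuple[str, str]
    params: dict = field(default_factory=dict)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.sequences], dtype=int)

    def __len__(self) -> int:
        return len(self.transcript_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.transcript_ids,
                "length": self.lengths,
                "input_tpm": self.input_tpm,
                "truth_enriched": self.truth_enriched,
            }
        ).set_index("transcript_id")

    def validate(self) -> None:
        lens = self.lengths
        if lens.min() < 200:
            raise ValueError("transcript lengths must be >= 200 nt")
        if abs(self.input_tpm.sum() - 1e6) > 1e-3:
            raise ValueError("input_tpm must sum to 1e6")
        for tid, occs in self.planted_motifs.items():
            seq = self.sequences[self.transcript_ids.index(tid)]
            for motif_id, start, strand in occs:
                idx = 0 if motif_id.endswith("1") else 1
                motif = self.motif_pair[idx]
                if strand == "-":
                    motif = reverse_complement(motif)
                if seq[start : start + len(motif)] != motif:
                    raise ValueError(
                        f"{tid}: planted motif {motif_id} not found at {start}"
                    )


@dataclass
class UptakeModel:
    """Parameters of droplet RNA uptake.

    Per-transcript uptake weight:
    ``w_t ∝ input_tpm_t^beta_abundance * exp(beta_length*log(length_t)
    + beta_motif*1[truth_enriched] + type_offset_t)``.
    Molecule depth per condensate: ``D ~ Poisson(depth_scale * fsc^capacity_exponent)``,
    with counts multinomial from weights mixed with ambient (input-pool)
    proportions at ``ambient_fraction``.
    """

    beta_abundance: float = 1.0
    beta_length: float = 0.3
    beta_motif: float = 2.0
    type_weights: Mapping[str, np.ndarray | float] = field(default_factory=dict)
    capacity_exponent: float = 3.0
    ambient_fraction: float = 0.05
    depth_scale: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 <= self.ambient_fraction <= 1.0:
            raise ValueError("ambient_fraction must be in [0, 1]")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")

    def weights(self, pool: TranscriptPool, condensate_type: str) -> np.ndarray:
        """Normalized per-transcript uptake probabilities for one type."""
        tpm = pool.input_tpm
        logtpm = np.log(tpm, out=np.zeros_like(tpm), where=tpm > 0)
        logw = np.where(tpm > 0, self.beta_abundance * logtpm, -np.inf)
        logw = logw + self.beta_length * np.log(pool.lengths)
        logw = logw + self.beta_motif * pool.truth_enriched.astype(float)
        offset = self.type_weights.get(condensate_type, 0.0)
        logw = logw + np.asarray(offset, dtype=float)
        finite = np.isfinite(logw)
        if not finite.any():
            raise ValueError("all-zero uptake weight vector")
        w = np.exp(logw - np.max(logw[finite]))
        w[~np.isfinite(w)] = 0.0
        total = w.sum()
        if total <= 0:
            raise ValueError("all-zero uptake weight vector")
        return w / total


def _random_sequences(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    total = int(lengths.sum())
    draws = rng.choice(4, size=total, p=_BASE_P)
    chars = _BASES[draws]
    seqs, pos = [], 0
    for L in lengths:
        seqs.append("".join(chars[pos : pos + L]))
        pos += L
    return seqs


def generate_pool(
    n_transcripts: int = 2000,
    motif_pair: tuple[str, str] | None = None,
    frac_enriched: float = 0.05,
    spacing: int = 70,
    seed: int = 0,
    *,
    length_median: float = 2000.0,
    length_sigma: float = 0.6,
    tpm_sigma: float = 1.0,
) -> TranscriptPool:
    """Generate a synthetic input transcript pool with a planted motif pair.

    Lengths are log-normal (median ``length_median``, floor 200 nt); input
    abundances are log-normal with shape ``tpm_sigma`` and normalized to
    1e6 TPM.  A fraction ``frac_enriched`` of transcripts carries both
    motifs of the pair on the forward strand, ``spacing`` nt apart
    start-to-start, and is labeled ``truth_enriched``.
    """
    if n_transcripts < 10:
        raise ValueError("n_transcripts must be >= 10")
    if not 0.0 <= frac_enriched <= 0.5:
        raise ValueError("frac_enriched must be in [0, 0.5]")
    if motif_pair is None:
        motif_pair = (DEFAULT_MOTIF, reverse_complement(DEFAULT_MOTIF))
    m1, m2 = (m.upper() for m in motif_pair)
    for m in (m1, m2):
        if not 6 <= len(m) <= 50:
            raise ValueError("motif consensus length must be in [6, 50]")
        if set(m) - set("ACGT"):
            raise ValueError(f"invalid alphabet in motif consensus {m!r}")
    min_len = 200
    if spacing + len(m2) > min_len:
        raise ValueError(
            f"spacing {spacing} + motif length {len(m2)} exceeds the minimum "
            f"transcript length {min_len}"
        )
    if spacing < len(m1):
        raise ValueError("spacing smaller than the first motif width: motifs overlap")

    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        min_len,
        np.round(rng.lognormal(np.log(length_median), length_sigma, n_transcripts)),
    ).astype(int)
    raw = rng.lognormal(0.0, tpm_sigma, n_transcripts)
    input_tpm = raw / raw.sum() * 1e6
    seqs = _random_sequences(rng, lengths)
    ids = [f"T{i:05d}" for i in range(n_transcripts)]

    n_enriched = round(frac_enriched * n_transcripts)
    truth = np.zeros(n_transcripts, dtype=bool)
    planted: dict[str, list[tuple[str, int, str]]] = {}
    if n_enriched:
        chosen = rng.choice(n_transcripts, size=n_enriched, replace=False)
        truth[chosen] = True
        span = spacing + len(m2)
        for t in sorted(chosen):
            start = int(rng.integers(0, lengths[t] - span + 1))
            s = seqs[t]
            s = s[:start] + m1 + s[start + len(m1) :]
            s = s[: start + spacing] + m2 + s[start + spacing + len(m2) :]
            seqs[t] = s
            planted[ids[t]] = [
                ("motif_1", start, "+"),
                ("motif_2", start + spacing, "+"),
            ]
    params = {
        "n_transcripts": n_transcripts,
        "motif_pair": [m1, m2],
        "frac_enriched": frac_enriched,
        "spacing": spacing,
        "seed": seed,
        "length_median": length_median,
        "length_sigma": length_sigma,
        "tpm_sigma": tpm_sigma,
    }
    return TranscriptPool(ids, seqs, input_tpm, truth, planted, (m1, m2), params)


def simulate_condensates(
    pool: TranscriptPool,
    model: UptakeModel | None = None,
    n_condensates: int = 192,
    types: Sequence[str] = ("CM-Dex:PDDA",),
    seed: int = 0,
    *,
    fsc_median: float = 1e4,
    fsc_sigma: float = 0.35,
    experiment: str = "sim",
) -> ad.AnnData:
    """Simulate a sequenced condensate population from an input pool.

    Returns an AnnData with obs = condensates (fsc, ssc, condensate_type,
    experiment, well, is_control, pseudoalign_frac), var = transcripts
    (length, input_tpm, truth_enriched) and X = integer counts.  Condensate
    sizes are log-normal; molecule depth is Poisson with rate
    ``depth_scale * fsc^capacity_exponent``; counts are multinomial over
    uptake weights mixed with ambient input-pool proportions.
    """
    if n_condensates < 2:
        raise ValueError("n_condensates must be >= 2")
    model = model or UptakeModel()
    rng = np.random.default_rng(seed)
    n_t = len(pool)
    fsc = rng.lognormal(np.log(fsc_median), fsc_sigma, n_condensates)
    ssc = fsc * rng.lognormal(-0.7, 0.2, n_condensates)
    cond_types = [types[i % len(types)] for i in range(n_condensates)]
    type_probs = {t: model.weights(pool, t) for t in set(cond_types)}
    ambient = pool.input_tpm / pool.input_tpm.sum()
    counts = np.zeros((n_condensates, n_t), dtype=np.int64)
    depth_rate = model.depth_scale * fsc**model.capacity_exponent
    depths = rng.poisson(depth_rate)
    for c in range(n_condensates):
        p = (
            (1.0 - model.ambient_fraction) * type_probs[cond_types[c]]
            + model.ambient_fraction * ambient
        )
        counts[c] = rng.multinomial(depths[c], p)
    pseudoalign = rng.beta(40.0, 2.0, n_condensates)
    obs = pd.DataFrame(
        {
            "fsc": fsc,
            "ssc": ssc,
            "condensate_type": cond_types,
            "experiment": experiment,
            "well": [f"{chr(65 + i % 8)}{i // 8 + 1:02d}" for i in range(n_condensates)],
            "is_control": False,
            "pseudoalign_frac": pseudoalign,
        },
        index=pd.Index([f"C{i:04d}" for i in range(n_condensates)], name="condensate_id"),
    )
    adata = ad.AnnData(X=counts, obs=obs, var=pool.to_dataframe())
    adata.uns["simulation"] = {
        "seed": seed,
        "n_condensates": n_condensates,
        "types": list(types),
        "fsc_median": fsc_median,
        "fsc_sigma": fsc_sigma,
        "experiment": experiment,
        "uptake_model": {
            k: v for k, v in asdict(model).items() if k != "type_weights"
        },
        "type_weights": {
            k: (np.asarray(v).tolist() if np.ndim(v) else float(v))
            for k, v in model.type_weights.items()
        },
    }
    return adata


def write_fixture(
    pool: TranscriptPool, adata: ad.AnnData, out_dir: str | Path
) -> dict:
    """Write a complete on-disk fixture and return its manifest.

    Emits transcripts.fasta, counts.tsv, a MatrixMarket triplet
    (matrix.mtx + features.tsv + barcodes.tsv), metadata.csv, truth.tsv
    and manifest.yaml recording all generator parameters and seeds.
    """
    from . import io as cio

    if len(pool) == 0:
        raise ValueError("empty transcript pool; nothing written")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_fasta(out / "transcripts.fasta", dict(zip(pool.transcript_ids, pool.sequences)))
    cio.write_count_matrix_tsv(out / "counts.tsv", adata)
    cio.write_count_matrix_mtx(out / "mtx", adata)
    cio.write_metadata(out / "metadata.csv", adata)
    truth = pool.to_dataframe()[["truth_enriched"]]
    truth.to_csv(out / "truth.tsv", sep="\t")
    pool.to_dataframe()[["input_tpm"]].to_csv(out / "input_tpm.tsv", sep="\t")
    manifest = {
        "generator": "condenseq.simulate",
        "pool": pool.params,
        "simulation": {
            k: v
            for k, v in adata.uns.get("simulation", {}).items()
            if k != "type_weights" or v
        },
    }
    cio.write_manifest(out / "manifest.yaml", manifest)
    return manifest


def simulate_from_manifest(manifest: Mapping) -> tuple[TranscriptPool, ad.AnnData]:
    """Regenerate a pool and condensate matrix from a fixture manifest."""
    p = dict(manifest["pool"])
    pool = generate_pool(
        n_transcripts=p["n_transcripts"],
        motif_pair=tuple(p["motif_pair"]),
        frac_enriched=p["frac_enriched"],
        spacing=p["spacing"],
        seed=p["seed"],
        length_median=p["length_median"],
        length_sigma=p["length_sigma"],
        tpm_sigma=p["tpm_sigma"],
    )
    s = dict(manifest["simulation"])
    um = dict(s.get("uptake_model", {}))
    tw = {k: np.asarray(v) if np.ndim(v) else v for k, v in s.get("type_weights", {}).items()}
    model = UptakeModel(type_weights=tw, **um)
    adata = simulate_condensates(
        pool,
        model,
        n_condensates=s["n_condensates"],
        types=tuple(s["types"]),
        seed=s["seed"],
        fsc_median=s["fsc_median"],
        fsc_sigma=s["fsc_sigma"],
        experiment=s["experiment"],
    )
    return pool, adata
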