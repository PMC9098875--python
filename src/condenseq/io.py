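"""Readers and writers for the on-disk formats used by the pipeline.

Formats: FASTA (transcript and SINE reference sequences), dense TSV and
MatrixMarket triplet count matrices (with features.tsv / barcodes.tsv id
lists), CSV condensate metadata, a minimal MEME-style motif text format
(plus a one-line ``id<TAB>consensus`` alternative), BED-like motif-hit
TSVs, and YAML manifests/configs.  All coordinates are 0-based,
half-open; strands are "+" or "-".  Every writer round-trips losslessly
through its reader.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import anndata as ad
import scipy.io
import scipy.sparse
import yaml
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import Motif

logger = logging.getLogger(__name__)

METADATA_COLUMNS = [
    "condensate_id",
    "fsc",
    "ssc",
    "condensate_type",
    "experiment",
    "well",
    "is_control",
    "pseudoalign_frac",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Count matrices

def _check_ids(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.duplicated().any():
        dupes = s[s.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")


def read_count_matrix(path: str | Path) -> ad.AnnData:
    """Read a transcript-by-condensate matrix from TSV or MatrixMarket.

    ``path`` is either a TSV file (rows = transcripts, first column
    transcript_id, remaining columns condensates) or a directory holding
    ``matrix.mtx`` (transcripts x condensates triplet), ``features.tsv``
    and ``barcodes.tsv``.  Returns an AnnData with obs = condensates and
    var = transcripts.
    """
    path = Path(path)
    if path.is_dir():
        mtx = scipy.io.mmread(path / "matrix.mtx")
        features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].tolist()
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        mat = np.asarray(mtx.todense() if scipy.sparse.issparse(mtx) else mtx)
        if mat.shape != (len(features), len(barcodes)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match {len(features)} features "
                f"x {len(barcodes)} barcodes"
            )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.isna().any().any():
            raise ValueError(f"missing values in matrix {path}")
        features = df.index.tolist()
        barcodes = df.columns.tolist()
        mat = df.to_numpy()
    _check_ids(features, "transcript")
    _check_ids(barcodes, "condensate")
    if (mat < 0).any():
        raise ValueError("negative values in count matrix")
    return ad.AnnData(
        X=np.ascontiguousarray(mat.T),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="condensate_id")),
        var=pd.DataFrame(index=pd.Index(features, name="transcript_id")),
    )


def write_count_matrix_tsv(path: str | Path, adata: ad.AnnData) -> None:
    """Write counts as a dense TSV (rows transcripts, columns condensates)."""
    df = pd.DataFrame(
        np.asarray(adata.X).T, index=adata.var_names, columns=adata.obs_names
    )
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t")


def write_count_matrix_mtx(out_dir: str | Path, adata: ad.AnnData) -> None:
    """Write counts as MatrixMarket triplet + features.tsv/barcodes.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(np.asarray(adata.X).T)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sparse, field="integer"
                     if np.issubdtype(adata.X.dtype, np.integer) else "real")
    pd.Series(adata.var_names).to_csv(out / "features.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t",
                                      index=False, header=False)


# ---------------------------------------------------------------------------
# Metadata

def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns: {sorted(missing)}")
    _check_ids(df["condensate_id"], "condensate")
    bad = df["pseudoalign_frac"].lt(0) | df["pseudoalign_frac"].gt(1)
    if bad.any():
        raise ValueError("pseudoalign_frac outside [0, 1]")
    return df.set_index("condensate_id")


def write_metadata(path: str | Path, adata: ad.AnnData) -> None:
    cols = [c for c in METADATA_COLUMNS if c != "condensate_id"]
    df = adata.obs[cols].copy()
    df.index.name = "condensate_id"
    df.to_csv(path)


def attach_metadata(adata: ad.AnnData, meta: pd.DataFrame) -> ad.AnnData:
    """Join a metadata table onto the obs axis (ids must cover all condensates)."""
    missing = adata.obs_names.difference(meta.index)
    if len(missing):
        raise ValueError(f"metadata missing condensates: {list(missing[:5])}")
    adata.obs = adata.obs.join(meta.loc[adata.obs_names])
    return adata


# ---------------------------------------------------------------------------
# Motifs

def read_motifs(path: str | Path) -> list[Motif]:
    """Read motifs from minimal MEME-format text or ``id<TAB>consensus`` lines.

    A file whose first non-blank line starts with "MEME version" is parsed
    as MEME minimal format (letter-probability matrices); otherwise each
    non-comment line must be ``motif_id<TAB>consensus``.  An empty file
    yields an empty list with a warning.
    """
    path = Path(path)
    text = path.read_text()
    stripped = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not stripped:
        logger.warning("motif file %s is empty", path)
        return []
    result: list[Motif] = []
    if stripped[0].startswith("MEME version"):
        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "minimal")
        for m in parsed:
            pwm = np.array([m.pwm[b] for b in "ACGT"])
            result.append(Motif(m.name, pwm))
    else:
        for ln in stripped:
            parts = ln.split("\t")
            if len(parts) != 2:
                raise ValueError(f"bad consensus line in {path}: {ln!r}")
            result.append(Motif.from_consensus(parts[0], parts[1]))
    return result


def write_motifs(path: str | Path, motif_list: list[Motif]) -> None:
    """Write motifs in minimal MEME format."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "",
             "strands: + -", "",
             "Background letter frequencies", "A 0.25 C 0.25 G 0.25 T 0.25", ""]
    for m in motif_list:
        lines.append(f"MOTIF {m.motif_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0"
        )
        for col in m.matrix.T:
            lines.append(" ".join(f"{v:.6f}" for v in col))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Hits, tables, manifests

HIT_COLUMNS = ["transcript_id", "start", "end", "strand", "motif_id", "score"]


def write_hits(path: str | Path, hits: pd.DataFrame) -> None:
    """Write motif hits as a BED-like TSV (0-based half-open)."""
    hits[HIT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table {path} missing columns {sorted(missing)}")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    if (df["start"] >= df["end"]).any() or (df["start"] < 0).any():
        raise ValueError("invalid half-open hit coordinates")
    return df


def write_table(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path: str | Path, manifest: Mapping) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(manifest), fh, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
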