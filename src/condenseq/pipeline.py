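"""End-to-end pipeline runner: QC -> enrichment -> motifs -> complementarity.

Each stage logs entity counts in/out, writes its table under the
configured output directory, and contributes to a summary report.  Any
stage failure aborts with the stage name and the underlying cause.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import align, compare, io as cio, motifs as mt, qc
from .config import PipelineConfig
from .enrichment import EnrichmentModel

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis described by ``config``; returns the report.

    Required config paths: counts, fasta, metadata; optional: motifs and
    SINE references (their stages are skipped when absent).  Outputs are
    written under ``config.out_dir``.
    """
    for attr in ("counts_path", "fasta_path", "metadata_path", "out_dir"):
        if getattr(config, attr) is None:
            raise ValueError(f"config.{attr} is required for the full pipeline")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    stage = "load"
    try:
        adata = cio.read_count_matrix(config.counts_path)
        seqs = cio.read_fasta(config.fasta_path)
        meta = cio.read_metadata(config.metadata_path)
        cio.attach_metadata(adata, meta)
        missing = [t for t in adata.var_names if t not in seqs]
        if missing:
            raise ValueError(f"sequences missing for transcripts {missing[:5]}")
        adata.var["length"] = [len(seqs[t]) for t in adata.var_names]
        report["n_condensates_in"] = adata.n_obs
        report["n_transcripts_in"] = adata.n_vars
        logger.info("load: %d condensates x %d transcripts", adata.n_obs, adata.n_vars)

        stage = "qc"
        adata = qc.add_tpm(adata)
        adata, qc_report = qc.filter_matrix(adata, config)
        cio.write_table(out / "qc_report.tsv", qc_report)
        report["n_condensates_pass"] = adata.n_obs
        report["n_transcripts_pass"] = adata.n_vars
        logger.info("qc: %d condensates, %d transcripts pass", adata.n_obs, adata.n_vars)

        stage = "enrichment"
        if config.input_tpm_path:
            itpm = cio.read_table(config.input_tpm_path).set_index("transcript_id")
            adata.var["input_tpm"] = (
                itpm["input_tpm"].reindex(adata.var_names).fillna(0.0).to_numpy()
            )
        if "input_tpm" not in adata.var:
            # input pool abundance approximated by mean TPM across condensates
            adata.var["input_tpm"] = np.asarray(adata.layers["tpm"]).mean(axis=0)
            logger.info("enrichment: input_tpm not provided; using mean condensate TPM")
        model = EnrichmentModel.from_matrix(adata, config.tpm_min)
        results = model.fit(smoother=config.smoother,
                            threshold=config.residual_threshold)
        table = results.table
        cio.write_table(out / "enrichment.tsv", table.reset_index())
        report["n_enriched"] = results.n_enriched
        logger.info("enrichment: %d/%d transcripts enriched",
                    results.n_enriched, len(table))

        enriched_ids = table.index[table["enriched"]].tolist()
        stage = "motif_scan"
        hits = pd.DataFrame(columns=cio.HIT_COLUMNS)
        if config.motifs_path:
            motif_list = cio.read_motifs(config.motifs_path)
            bg = mt.background_composition(list(seqs.values()))
            hits = mt.scan({t: seqs[t] for t in adata.var_names}, motif_list,
                           config.scan_threshold_frac, bg)
            cio.write_hits(out / "motif_hits.tsv", hits)
            dists = mt.neighbor_distances(
                hits[hits["transcript_id"].isin(enriched_ids)]
            )
            cio.write_table(out / "motif_distances.tsv", dists)
            report["n_motif_hits"] = len(hits)
            logger.info("motif_scan: %d hits", len(hits))

        stage = "complementarity"
        if len(enriched_ids) >= 2:
            non_enriched = table.index[~table["enriched"] & table["in_fit"]].tolist()
            background = align.sample_length_matched_background(
                {t: seqs[t] for t in non_enriched},
                [len(seqs[t]) for t in enriched_ids],
                n=min(len(enriched_ids), len(non_enriched)),
                seed=config.seed,
            )
            pc = align.pool_complementarity(
                {t: seqs[t] for t in enriched_ids}, background,
                align.get_scheme(config.trans_scheme),
                mode=config.complementarity_mode,
            )
            rows = [
                {"class": cls, "query_id": a, "target_id": b,
                 "scheme": config.trans_scheme, "score": s}
                for cls, pairs in pc.pairs.items()
                for (a, b), s in zip(pairs, pc.scores[cls])
            ]
            cio.write_table(out / "complementarity.tsv", pd.DataFrame(rows))
            report["complementarity_maxima"] = dict(pc.maxima)
            report["enriched_exceeds_outside"] = bool(pc.enriched_exceeds)
            logger.info("complementarity: enriched max %.1f vs outside max %.1f",
                        pc.maxima["enriched_vs_enriched"], pc.outside_maximum)

        stage = "sine"
        if config.sine_refs_path and config.motifs_path and not hits.empty:
            refs = cio.read_fasta(config.sine_refs_path)
            top_hits: dict[str, list[str]] = {}
            eh = hits[hits["transcript_id"].isin(enriched_ids)]
            for mid, g in eh.groupby("motif_id"):
                best = g.sort_values("score", ascending=False).head(5)
                top_hits[mid] = [
                    seqs[r.transcript_id][r.start:r.end] for r in best.itertuples()
                ]
            if top_hits:
                sine_scores = align.sine_homology(top_hits, refs)
                cio.write_table(out / "sine_scores.tsv",
                                sine_scores.reset_index(names="motif_id"))
                report["n_sine_motifs"] = len(sine_scores)

        stage = "compare"
        if adata.obs["condensate_type"].nunique() >= 2:
            freq = compare.type_frequency_matrix(adata, config.tpm_min)
            corr = compare.type_correlations(freq)
            cio.write_table(out / "type_correlations.tsv",
                            corr.reset_index(names="condensate_type"))
            report["type_correlations"] = {
                f"{a}|{b}": float(corr.loc[a, b])
                for i, a in enumerate(corr.index) for b in corr.index[i + 1:]
            }
        if enriched_ids:
            prof = compare.build_profiles(adata, enriched_ids)
            emb = compare.embed_and_cluster(
                prof, config.n_components, config.cluster_k, config.seed,
                fsc=adata.obs["fsc"] if "fsc" in adata.obs else None,
            )
            if not emb.degenerate:
                emb_df = emb.coords.copy()
                emb_df["cluster"] = emb.labels
                cio.write_table(out / "embedding.tsv",
                                emb_df.reset_index(names="condensate_id"))
                report["n_clusters"] = emb.k
                if emb.k == 2 and emb.labels.value_counts().min() >= 3:
                    de = compare.differential_transcripts(adata, emb.labels,
                                                          config.de_alpha)
                    cio.write_table(out / "differential.tsv", de.reset_index())
                    report["n_significant_de"] = int(de["significant"].sum())
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, exc) from exc

    cio.write_manifest(out / "report.yaml", report)
    return report
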