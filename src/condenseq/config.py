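"""Pipeline configuration with the study's default thresholds."""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable stage parameters, with defaults matching the analysis.

    Thresholds: TPM detection floor 1; read-coverage floor 20% (applied
    when the dataset mean pseudoalignment is below 40%); condensate filter
    at pseudoalignment < 5% for FSC > 2e4; enrichment residual threshold
    30 percentage points; motif-scan score fraction 0.85; 5 principal
    components; Bonferroni alpha 0.01 for differential tests.
    """

    # quantify/QC
    tpm_min: float = 1.0
    coverage_min: float = 0.2
    low_pseudoalign_dataset: float = 0.4
    pseudoalign_min: float = 0.05
    fsc_cut: float = 2e4
    # enrichment
    residual_threshold: float = 30.0
    smoother: str = "spline"
    n_bins: int = 10
    # motif scanning / discovery
    scan_threshold_frac: float = 0.85
    kmer_k: int = 8
    kmer_alpha: float = 0.05
    # complementarity
    trans_scheme: str = "trans"
    sine_scheme: str = "sine"
    complementarity_mode: str = "revcomp"
    # comparison
    n_components: int = 5
    cluster_k: int | None = None
    de_alpha: float = 0.01
    # randomness
    seed: int = 0
    # paths (optional; used by the full-pipeline runner)
    counts_path: str | None = None
    fasta_path: str | None = None
    metadata_path: str | None = None
    input_tpm_path: str | None = None
    motifs_path: str | None = None
    sine_refs_path: str | None = None
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
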