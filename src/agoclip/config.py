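"""Pipeline configuration: one YAML/JSON document with full defaulting."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import SynthConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds.

    In synthetic mode the generator produces every input under
    <outdir>/synthetic; otherwise `inputs` must name existing files:
    tag_manifest (TSV: stage, replicate, path), gtf, genome_fasta,
    mirna_fasta, mirna_counts, ko_log2fc, ko_mirna, h3k27ac_manifest
    (TSV: stage, path), tss.
    """

    synthetic: bool = True
    synth: SynthConfig = field(default_factory=SynthConfig)
    inputs: dict = field(default_factory=dict)
    outdir: str = "agoclip_out"
    rng_seed: int = 0

    # cluster calling
    min_peak_height: int = 5
    min_replicates: int = 2
    # targetome
    expressed_min_share: float = 0.01  # stage RPM share defining "expressed"
    top_n_coverage: int = 100  # catalog size for the seed-coverage readout
    # profiles
    n_profile_clusters: int = 5
    pseudocount: float = 1.0
    # motifs
    kmer_k: int = 7
    n_shuffles: int = 100
    # super-enhancers
    stitch_distance: int = 12_500
    tss_window: int = 100_000

    def __post_init__(self) -> None:
        if self.min_peak_height < 1 or self.min_replicates < 1:
            raise ValueError("min_peak_height and min_replicates must be >= 1")
        if not 5 <= self.kmer_k <= 8:
            raise ValueError("kmer_k must be in [5, 8]")
        if self.stitch_distance < 0 or self.tss_window < 0:
            raise ValueError("distances must be non-negative")
        if not self.synthetic:
            required = {
                "tag_manifest", "gtf", "genome_fasta", "mirna_fasta",
                "mirna_counts", "ko_log2fc", "ko_mirna", "h3k27ac_manifest", "tss",
            }
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"non-synthetic mode lacks inputs: {sorted(missing)}")
            for key in required - {"ko_mirna"}:
                if not Path(self.inputs[key]).exists():
                    raise FileNotFoundError(f"input {key}: {self.inputs[key]} not found")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from YAML or JSON with full defaulting."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return config_from_dict(data or {})


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    synth_data = data.pop("synth", {})
    known = {f.name for f in dataclasses.fields(SynthConfig)}
    bad = set(synth_data) - known
    if bad:
        raise ValueError(f"unknown synth config keys: {sorted(bad)}")
    synth = SynthConfig(**synth_data)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    bad = set(data) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return PipelineConfig(synth=synth, **data)
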