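"""Run configuration: every threshold of the pipeline in one place.

Defaults are the published operating points of the procedure: score bands
60/85% CHI and -8 kcal/mol, position bins at 500/1000 nt, round-1 cut at
final score 4 with a 100-nt 3'-proximity exclusion, round-2 cut at 8 with
85% CHI and 1500-nt exclusions, SSR/SBR thresholds 10/2, CV threshold
0.75, and a 1.5 x 95% CI intensity band.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # inputs
    genome: str | None = None
    annotation: str | None = None
    est: str | None = None
    probes: str | None = None
    hits: str | None = None            # external 12-column alignment hits
    intensities: str | None = None
    rescue_list: str | None = None
    expert_overrides: str | None = None  # TSV: cds_id, probe_id
    new_cds: str | None = None           # updated CDS FASTA for rescoring
    # in silico thresholds
    chi_band_low: float = 60.0
    chi_band_high: float = 85.0
    delta_g_cutoff: float = -8.0
    pos_near: int = 500
    pos_mid: int = 1000
    adjacency_window: int = 10
    round1_score_cutoff: int = 4
    round1_min_distance: int = 100
    round2_score_cutoff: int = 8
    round2_chi_cutoff: float = 85.0
    round2_max_distance: int = 1500
    panel_size: int = 4
    min_panel: int = 2
    # search parameters
    word_size: int = 7
    match_reward: int = 2
    mismatch_penalty: int = 3
    min_window: int = 20
    min_window_identity: float = 70.0
    xdrop: int = 20
    # experimental thresholds
    ssr: float = 10.0
    sbr: float = 2.0
    cv: float = 0.75
    ci_factor: float = 1.5
    ci_level: float = 0.95
    ci_method: str = "normal"
    # misc
    qc_enabled: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def manifest(self) -> dict:
        return {"config": dataclasses.asdict(self)}

    def write_manifest(self, path, extra: dict | None = None) -> None:
        doc = self.manifest()
        if extra:
            doc.update(extra)
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
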