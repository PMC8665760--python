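"""Pipeline configuration: one JSON-serializable object holding every stage
parameter. Defaults are the protocol's published cutoffs: search E-value
cutoff 1; discovery clustering at P 1e-10 with a minimum cluster size of 10;
map clustering at P 1e-3 with connections displayed at 1e-2; redundancy
filtering at 0.9 identity (0.7 for very large families) with coverage 0.7.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields


@dataclass
class PipelineConfig:
    # search stage
    e_cutoff: float = 1.0
    psearch_max_rounds: int = 6
    pseudocount_weight: float = 20.0
    motif_max_mismatches: int = 1
    calib_shuffles: int = 500

    # discovery loop
    discovery_cluster_p: float = 1e-10
    discovery_min_cluster_size: int = 10
    discovery_max_rounds: int = 6
    fragment_identity: float = 0.95
    fragment_coverage: float = 0.95

    # map stage
    map_cluster_p: float = 1e-3
    map_display_p: float = 1e-2
    edge_p_keep: float = 0.1
    outlier_max_link_fraction: float = 0.0

    # redundancy filtering
    filter_max_identity: float = 0.9
    filter_min_coverage: float = 0.7
    large_family_max_identity: float = 0.7

    # alignment scoring
    gap_open: float = 11.0
    gap_extend: float = 1.0

    # force-directed layout
    attract_k: float = 1.0
    repulse_k: float = 0.05
    p_floor: float = 1e-40
    layout_max_iter: int = 300
    layout_cooling: float = 0.97
    layout_tolerance: float = 1e-4

    rng_seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def default_config() -> PipelineConfig:
    return PipelineConfig()
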