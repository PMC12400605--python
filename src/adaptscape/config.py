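"""Pipeline configuration with protocol defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import constants
from .simulate import SimConfig


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    Analysis thresholds default to the published protocol constants (see
    :mod:`adaptscape.constants`); a synthetic dataset is generated when no
    VCF is supplied.
    """

    out_dir: Path = Path("adaptscape_out")
    vcf: Path | None = None
    populations: Path | None = None
    gff: Path | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    maf_scan: float = constants.MAF_SCAN
    maf_ld: float = constants.MAF_LD
    pod_size: int = constants.POD_SIZE
    pod_quantile: float = constants.POD_QUANTILE
    bf_threshold_db: float = constants.BF_STRONG_DB
    merge_dist: int = constants.MERGE_DIST
    pad: int = constants.PAD
    ld_multiple: float = constants.LD_MULTIPLE
    min_cluster_span: int = constants.MIN_CLUSTER_SPAN
    n_perm: int = constants.N_PERM
    fdr: float = constants.FDR
    n_runs: int = constants.N_RUNS
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "maf_scan", "maf_ld", "pod_size", "pod_quantile", "bf_threshold_db",
            "merge_dist", "pad", "ld_multiple", "min_cluster_span", "n_perm",
            "fdr", "n_runs",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Registry of protocol defaults; PipelineConfig must agree with it (tested).
DEFAULTS_REGISTRY = {
    "maf_scan": constants.MAF_SCAN,
    "maf_ld": constants.MAF_LD,
    "pod_size": constants.POD_SIZE,
    "pod_quantile": constants.POD_QUANTILE,
    "bf_threshold_db": constants.BF_STRONG_DB,
    "merge_dist": constants.MERGE_DIST,
    "pad": constants.PAD,
    "ld_multiple": constants.LD_MULTIPLE,
    "min_cluster_span": constants.MIN_CLUSTER_SPAN,
    "n_perm": constants.N_PERM,
    "fdr": constants.FDR,
    "n_runs": constants.N_RUNS,
}


def config_defaults() -> dict:
    cfg = asdict(PipelineConfig())
    return {k: cfg[k] for k in DEFAULTS_REGISTRY}
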