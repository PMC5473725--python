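"""Analysis configuration: thresholds, windows and tolerances."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from . import heidi as _heidi
from .sumstats import DEFAULT_CIS_WINDOW, DEFAULT_FREQ_TOL


@dataclass
class AnalysisConfig:
    """Thresholds and windows governing a discovery run.

    ``qtl_p_threshold`` is the per-dataset instrument threshold (1e-10 for a
    well-powered blood mQTL study; 1e-8 for a smaller fetal-brain study;
    5e-8 for eQTLs). The family-wise SMR threshold itself is derived at run
    time as ``alpha_fw`` divided by the number of probes actually tested.
    """

    alpha_fw: float = 0.05
    qtl_p_threshold: float = 1e-10
    heidi_threshold: float = 0.05
    gwas_sig_threshold: float = 5e-8
    novel_locus_window: int = 500_000
    min_tested_sites: int = 20_000
    cis_window: int = DEFAULT_CIS_WINDOW
    freq_tol: float = DEFAULT_FREQ_TOL
    heidi_r2_min: float = _heidi.R2_MIN
    heidi_r2_max: float = _heidi.R2_MAX
    heidi_max_snps: int = _heidi.MAX_SNPS
    heidi_min_snps: int = _heidi.MIN_SNPS
    heidi_p_include: float = _heidi.P_INCLUDE

    def __post_init__(self) -> None:
        for name in ("alpha_fw", "qtl_p_threshold", "heidi_threshold",
                     "gwas_sig_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name}={v} outside (0,1)")
        if self.novel_locus_window <= 0 or self.cis_window <= 0:
            raise ValueError("windows must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
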