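"""Analysis configuration with YAML round-tripping.

Defaults are the analysis parameters of the fibril-stability protocol this
package implements: 0.35 nm contact cutoff, 0.1 nm cluster cutoff, a 25 ns
analysis window and a 50 ns clustering window.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """All tunable parameters of the analysis pipeline.

    Attributes
    ----------
    contact_cutoff_nm
        Ligand-residue and chain-chain contact distance cutoff.
    cluster_cutoff_nm
        Single-linkage RMSD threshold for frame clustering.
    analysis_window_ns
        Trailing window over which stability metrics are averaged.
    cluster_window_ns
        Trailing window fed to the clustering stage.
    ordp_fit
        Least-squares fit frames onto the reference before the order
        parameter.
    ordp_com_mode
        "chain" (chain centroid to residue CA) or "residue" (residue
        centroid to its CA).
    sasa_probe_nm, sasa_points
        Shrake-Rupley probe radius and quadrature density.
    beta_counting
        "EB" counts extended and isolated-bridge residues as beta;
        "E" counts extended only.
    seed
        Seed recorded in outputs and used by synthetic stages.
    chain_order
        Override of the fibril stacking order (default: file order).
    time_per_frame_ns
        Nanoseconds per trajectory frame for window arithmetic.
    """

    contact_cutoff_nm: float = 0.35
    cluster_cutoff_nm: float = 0.1
    analysis_window_ns: float = 25.0
    cluster_window_ns: float = 50.0
    ordp_fit: bool = True
    ordp_com_mode: str = "chain"
    sasa_probe_nm: float = 0.14
    sasa_points: int = 960
    beta_counting: str = "EB"
    seed: int = 0
    chain_order: list[str] | None = None
    time_per_frame_ns: float = 0.25

    def __post_init__(self) -> None:
        if self.contact_cutoff_nm <= 0 or self.cluster_cutoff_nm <= 0:
            raise ValueError("cutoffs must be > 0")
        if self.analysis_window_ns <= 0 or self.cluster_window_ns <= 0:
            raise ValueError("windows must be > 0")
        if self.beta_counting not in ("EB", "E"):
            raise ValueError("beta_counting must be 'EB' or 'E'")
        if self.ordp_com_mode not in ("chain", "residue"):
            raise ValueError("ordp_com_mode must be 'chain' or 'residue'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def header_lines(self) -> list[str]:
        """Config echo written at the top of every output file."""
        items = ", ".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return [f"# fibrilkit config: {items}"]
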