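"""Stratification of coverage failures by influencer volume change.

The influencers (bladder, rectum) guide the automatic propagation of the
boost target; large differences between their reference-CT volume and their
online volume degrade the proposed delineation.  Sessions are binned by that
volume difference (half-open bins of 50 cm³ for the bladder, 25 cm³ for the
rectum, last bin open-ended) and the fraction of sessions failing the V95
coverage requirement is tabulated per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import StratificationConfig, ValidationError, VolumeGrid, mask_volume

__all__ = ["StratumTable", "volume_difference", "bin_edges", "assign_bin", "failure_table"]


@dataclass
class StratumTable:
    """Per-bin session counts and coverage-failure percentages."""

    influencer: str
    target: str
    edges: list[float]  # left edges; last bin is [edges[-1], inf)
    labels: list[str]
    counts: list[int] = field(default_factory=list)
    percent_failing: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.labels,
                "n_sessions": self.counts,
                "percent_failing": self.percent_failing,
            }
        )


def volume_difference(
    reference_volume: float, online_mask: VolumeGrid, signed: bool = False
) -> float:
    """Difference (cm³) between the reference-CT volume and the online mask
    volume; absolute by default."""
    if reference_volume is None or not reference_volume > 0:
        raise ValidationError("reference volume missing or non-positive")
    diff = mask_volume(online_mask) - reference_volume
    return float(diff if signed else abs(diff))


def bin_edges(influencer_role: str, config: StratificationConfig) -> list[float]:
    """Left edges of the half-open bins [0,w), [w,2w), ..., [(k-1)·w, ∞)."""
    w = config.bin_width(influencer_role)
    return [i * w for i in range(config.max_bins)]


def _label(lo: float, hi: float | None) -> str:
    fmt = lambda x: f"{x:g}"
    return f"[{fmt(lo)},{fmt(hi)})" if hi is not None else f"[{fmt(lo)},inf)"


def assign_bin(diff: float, influencer_role: str, config: StratificationConfig) -> str:
    """Interval label for a volume difference, e.g. ``\"[0,50)\"``."""
    if diff < 0:
        raise ValidationError("binning expects a non-negative volume difference")
    w = config.bin_width(influencer_role)
    i = min(int(diff // w), config.max_bins - 1)
    hi = (i + 1) * w if i < config.max_bins - 1 else None
    return _label(i * w, hi)


def failure_table(
    records: pd.DataFrame,
    target_role: str,
    influencer_role: str,
    config: StratificationConfig | None = None,
) -> StratumTable:
    """Tabulate coverage failures per influencer-volume-difference bin.

    ``records`` must hold one row per session with columns
    ``{influencer_role}_volume_difference`` (cm³, non-negative) and
    ``meets_requirement`` (bool, coverage of ``target_role`` under D_auto).
    """
    config = config or StratificationConfig()
    col = f"{influencer_role}_volume_difference"
    for needed in (col, "meets_requirement"):
        if needed not in records.columns:
            raise ValidationError(f"records missing column {needed!r}")

    edges = bin_edges(influencer_role, config)
    labels = [
        _label(e, edges[i + 1] if i + 1 < len(edges) else None)
        for i, e in enumerate(edges)
    ]
    table = StratumTable(
        influencer=influencer_role, target=target_role, edges=edges, labels=labels
    )
    diffs = records[col].to_numpy(dtype=float)
    fails = ~records["meets_requirement"].to_numpy(dtype=bool)
    w = config.bin_width(influencer_role)
    idx = np.minimum((diffs // w).astype(int), config.max_bins - 1)
    for i in range(config.max_bins):
        sel = idx == i
        n = int(sel.sum())
        table.counts.append(n)
        table.percent_failing.append(100.0 * fails[sel].sum() / n if n else 0.0)
    return table
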