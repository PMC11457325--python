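"""End-to-end two-arm evaluation: per-session records → cohort tables → summary.

For every session the pipeline computes

* geometric agreement records (auto vs clinical contours) for the bladder,
  rectum and CTV_boost;
* dosimetric coverage records on the *clinical* contours under both dose
  arms for GTV, CTV_boost, PTV_boost, CTV_elective and PTV_elective,
  including the dose spill V95_out;

and aggregates them into median [min–max] summaries, paired Wilcoxon
signed-rank tests between the arms (Bonferroni-corrected), manual-correction
frequencies, the percent of sessions meeting the 98% coverage requirement
per arm, and coverage-failure tables stratified by influencer volume change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .core import (
    INFLUENCER_ROLES,
    TARGET_ROLES,
    PrescriptionConfig,
    Session,
    StatsConfig,
    StratificationConfig,
    ValidationError,
)
from .dosimetry import dosimetric_record
from .geometry import geometric_record
from .io import write_report
from .stats import PairedSample, correction_frequencies, summarize, wilcoxon_signed_rank
from .stratify import failure_table, volume_difference

__all__ = [
    "GEOMETRIC_ROLES",
    "STRATIFICATION_TARGETS",
    "CohortResult",
    "evaluate_sessions",
    "run_evaluation",
]

#: Structures entering the geometric contour comparison.
GEOMETRIC_ROLES = ("bladder", "rectum", "CTV_boost")

#: Coverage targets tabulated against influencer volume change.
STRATIFICATION_TARGETS = ("CTV_boost", "CTV_elective")


@dataclass
class CohortResult:
    """Cohort tables plus the aggregated summary."""

    geometric: pd.DataFrame
    dosimetric: pd.DataFrame
    sessions: pd.DataFrame
    summary: dict
    stratification: dict = field(default_factory=dict)

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        tables = {
            "geometric": self.geometric,
            "dosimetric": self.dosimetric,
            "sessions": self.sessions,
        }
        for key, tab in self.stratification.items():
            tables[f"stratification_{key}"] = tab.to_frame()
        return tables

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        return write_report(self.tables, self.summary, out_dir)


def _format_range(median: float, lo: float, hi: float) -> str:
    fmt = lambda v: f"{v:.3g}"
    return f"{fmt(median)} [{fmt(lo)}-{fmt(hi)}]"


def _as_session_iter(
    sessions: Iterable[Session | tuple[Session, dict]],
) -> Iterator[Session]:
    for item in sessions:
        yield item[0] if isinstance(item, tuple) else item


GEOMETRIC_METRICS = ("dsc", "relative_volume", "hd95", "mda")
DOSIMETRIC_METRICS = ("v95_percent", "v95_out_abs")


def evaluate_sessions(
    sessions: Iterable[Session | tuple[Session, dict]],
    prescription: PrescriptionConfig | None = None,
    stats_config: StatsConfig | None = None,
    strat_config: StratificationConfig | None = None,
    geometric_roles: Sequence[str] = GEOMETRIC_ROLES,
    dosimetric_roles: Sequence[str] = TARGET_ROLES,
    dosimetry: bool = True,
    skip_invalid: bool = False,
    validate: bool = False,
) -> CohortResult:
    """Run the full two-arm evaluation over a session stream.

    ``validate=True`` re-checks every session's invariants (synthetic
    sessions are validated at generation time already); with
    ``skip_invalid`` a failing session is dropped and counted instead of
    aborting the run.
    """
    prescription = prescription or PrescriptionConfig()
    stats_config = stats_config or StatsConfig()
    strat_config = strat_config or StratificationConfig()

    geo_rows: list[dict] = []
    dos_rows: list[dict] = []
    ses_rows: list[dict] = []
    n_skipped = 0

    for session in _as_session_iter(sessions):
        if validate:
            try:
                session.validate()
            except ValidationError as exc:
                if skip_invalid:
                    n_skipped += 1
                    continue
                raise ValidationError(
                    f"session {session.patient_id}/fx{session.fraction} failed "
                    f"validation: {exc}"
                ) from exc
        key = {"patient_id": session.patient_id, "fraction": session.fraction}

        for role in geometric_roles:
            rec = geometric_record(session, role)
            geo_rows.append(key | {
                "structure": role,
                "dsc": rec.dsc,
                "relative_volume": rec.relative_volume,
                "hd95": rec.hd95,
                "mda": rec.mda,
                "v_auto": rec.v_auto,
                "v_clin": rec.v_clin,
            })

        if dosimetry:
            for role in dosimetric_roles:
                for arm in ("clin", "auto"):
                    rec = dosimetric_record(session, role, arm, prescription)
                    dos_rows.append(key | {
                        "structure": role,
                        "arm": arm,
                        "v95_percent": rec.v95_percent,
                        "v95_abs": rec.v95_abs,
                        "v95_body_abs": rec.v95_body_abs,
                        "v95_out_abs": rec.v95_out_abs,
                        "meets_requirement": rec.meets_requirement,
                        "threshold_gy": rec.threshold_gy,
                    })

        row = dict(key)
        for role, flag in session.corrections.items():
            row[f"corrected_{role}"] = bool(flag)
        for role in INFLUENCER_ROLES:
            if role in session.reference_volumes and role in session.contours_clin:
                row[f"{role}_reference_volume"] = session.reference_volumes[role]
                row[f"{role}_volume_difference"] = volume_difference(
                    session.reference_volumes[role],
                    session.contours_clin[role],
                    signed=strat_config.signed,
                )
        ses_rows.append(row)

    geometric = pd.DataFrame(geo_rows)
    dosimetric = pd.DataFrame(dos_rows)
    session_tab = pd.DataFrame(ses_rows)
    summary: dict = {"n_sessions": len(ses_rows), "n_skipped": n_skipped}

    summary["geometric"] = _summarize_geometric(geometric, geometric_roles)
    if dosimetry and not dosimetric.empty:
        summary["dosimetric"] = _summarize_dosimetric(dosimetric, dosimetric_roles)
        summary["wilcoxon"] = _wilcoxon_tests(dosimetric, dosimetric_roles, stats_config)
        summary["requirement"] = _requirement_rates(dosimetric, dosimetric_roles)
    summary["corrections"] = _corrections_summary(session_tab)
    summary["stats_config"] = {
        "family_alpha": stats_config.family_alpha,
        "family_size": stats_config.family_size,
        "corrected_alpha": stats_config.corrected_alpha,
    }

    stratification: dict = {}
    if dosimetry and not dosimetric.empty and not session_tab.empty:
        strata_summary: dict = {}
        for target in STRATIFICATION_TARGETS:
            flags = dosimetric[
                (dosimetric["structure"] == target) & (dosimetric["arm"] == "auto")
            ][["patient_id", "fraction", "meets_requirement"]]
            joined = session_tab.merge(flags, on=["patient_id", "fraction"])
            for influencer in INFLUENCER_ROLES:
                col = f"{influencer}_volume_difference"
                if col not in joined.columns:
                    continue
                tab = failure_table(joined, target, influencer, strat_config)
                key = f"{target}_by_{influencer}"
                stratification[key] = tab
                strata_summary[key] = {
                    "bins": tab.labels,
                    "n_sessions": tab.counts,
                    "percent_failing": tab.percent_failing,
                }
        summary["stratification"] = strata_summary

    return CohortResult(
        geometric=geometric,
        dosimetric=dosimetric,
        sessions=session_tab,
        summary=summary,
        stratification=stratification,
    )


def _summarize_geometric(geometric: pd.DataFrame, roles: Sequence[str]) -> dict:
    out: dict = {}
    if geometric.empty:
        return out
    for role in roles:
        sub = geometric[geometric["structure"] == role]
        if sub.empty:
            continue
        entry = {}
        for metric in GEOMETRIC_METRICS:
            med, lo, hi = summarize(sub[metric])
            entry[metric] = {
                "median": med, "min": lo, "max": hi,
                "formatted": _format_range(med, lo, hi),
            }
        out[role] = entry
    return out


def _summarize_dosimetric(dosimetric: pd.DataFrame, roles: Sequence[str]) -> dict:
    out: dict = {}
    for role in roles:
        entry: dict = {}
        for arm in ("clin", "auto"):
            sub = dosimetric[
                (dosimetric["structure"] == role) & (dosimetric["arm"] == arm)
            ]
            if sub.empty:
                continue
            arm_entry = {}
            for metric in DOSIMETRIC_METRICS:
                med, lo, hi = summarize(sub[metric])
                arm_entry[metric] = {
                    "median": med, "min": lo, "max": hi,
                    "formatted": _format_range(med, lo, hi),
                }
            entry[arm] = arm_entry
        paired = _paired_frame(dosimetric, role)
        if not paired.empty:
            diff = paired["v95_percent_clin"] - paired["v95_percent_auto"]
            med, lo, hi = summarize(diff)
            entry["v95_percent_clin_minus_auto"] = {
                "median": med, "min": lo, "max": hi,
                "formatted": _format_range(med, lo, hi),
            }
        out[role] = entry
    return out


def _paired_frame(dosimetric: pd.DataFrame, role: str) -> pd.DataFrame:
    sub = dosimetric[dosimetric["structure"] == role]
    clin = sub[sub["arm"] == "clin"]
    auto = sub[sub["arm"] == "auto"]
    return clin.merge(
        auto, on=["patient_id", "fraction"], suffixes=("_clin", "_auto")
    ).sort_values(["patient_id", "fraction"])


def _wilcoxon_tests(
    dosimetric: pd.DataFrame, roles: Sequence[str], config: StatsConfig
) -> dict:
    out: dict = {}
    for role in roles:
        paired = _paired_frame(dosimetric, role)
        if paired.empty:
            continue
        entry = {}
        for metric in DOSIMETRIC_METRICS:
            sample = PairedSample(
                label=f"{role}/{metric}",
                values_clin=paired[f"{metric}_clin"].to_numpy(),
                values_auto=paired[f"{metric}_auto"].to_numpy(),
            )
            try:
                res = wilcoxon_signed_rank(sample, config)
            except ValidationError:
                entry[metric] = {"p_value": None, "note": "all differences zero"}
                continue
            entry[metric] = {
                "W": res.statistic,
                "p_value": res.p_value,
                "n_effective": res.n_effective,
                "significant": res.significant,
                "method": res.method,
            }
        out[role] = entry
    return out


def _requirement_rates(dosimetric: pd.DataFrame, roles: Sequence[str]) -> dict:
    out: dict = {}
    for role in roles:
        entry = {}
        for arm in ("clin", "auto"):
            sub = dosimetric[
                (dosimetric["structure"] == role) & (dosimetric["arm"] == arm)
            ]
            if sub.empty:
                continue
            entry[arm] = {
                "percent_meeting": 100.0 * float(sub["meets_requirement"].mean()),
                "n": int(len(sub)),
            }
        out[role] = entry
    return out


def _corrections_summary(session_tab: pd.DataFrame) -> dict:
    cols = [c for c in session_tab.columns if c.startswith("corrected_")]
    if not cols:
        return {}
    roles = [c.removeprefix("corrected_") for c in cols]
    flags = [
        {role: bool(row[f"corrected_{role}"]) for role in roles}
        for _, row in session_tab.iterrows()
    ]
    return correction_frequencies(flags, roles)


@dataclass
class RunConfig:
    """Input binding for one evaluation run: manifests XOR synthetic cohort."""

    manifests: list[str] | None = None
    phantom: "object | None" = None  # PhantomConfig
    prescription: PrescriptionConfig = field(default_factory=PrescriptionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    stratification: StratificationConfig = field(default_factory=StratificationConfig)
    out_dir: str | Path = "oarteval_report"
    skip_invalid: bool = False

    def __post_init__(self) -> None:
        if (self.manifests is None) == (self.phantom is None):
            raise ValidationError(
                "exactly one input source required: manifests or a phantom config"
            )


def run_evaluation(config: RunConfig) -> CohortResult:
    """Execute an evaluation run and write the report bundle."""
    if config.manifests is not None:
        from .io import read_session

        def _iter():
            for path in config.manifests:
                yield read_session(path, validate=False)

        sessions: Iterable = _iter()
        validate = True
    else:
        from .phantom import iter_cohort

        sessions = iter_cohort(config.phantom, prescription=config.prescription)
        validate = False

    result = evaluate_sessions(
        sessions,
        prescription=config.prescription,
        stats_config=config.stats,
        strat_config=config.stratification,
        skip_invalid=config.skip_invalid,
        validate=validate,
    )
    result.write(config.out_dir)
    return result
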