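"""Declarative reanalysis pipeline: config in, Bayes-factor table out.

A config (JSON, canonical; or flat CSV) lists two-arm comparisons, one per
trial/outcome/subgroup.  Each comparison carries one of three payload kinds:

``continuous_summary``
    per-arm mean/SD or median/Q1/Q3  -> pooled two-sample t -> JZS BF.
``ratio_ci``
    ratio point estimate with CI     -> log-ratio z treated as t -> JZS BF.
``binary_counts``
    per-arm event counts             -> 2x2 contingency BF.

Every comparison is analyzed separately — no pooling, no cross-record state —
and the emitted table records the test, the prior, BF01/BF10, the evidence
category, an optional prior-sensitivity stability flag, and notes listing
every reconstruction approximation that was applied.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .bf_contingency import (
    CONTINGENCY_VARIANTS,
    ContingencyTable2x2,
    mortality_bf,
)
from .bf_t import BayesFactorResult, PriorSpec, jzs_bf01
from .evidence import categorize
from .sensitivity import (
    DEFAULT_SCALE_GRID,
    contingency_sensitivity_curve,
    robustness_summary,
    sensitivity_curve,
)
from .summary_stats import (
    ArmSummary,
    RatioSummary,
    TwoArmComparison,
    t_from_arm_summaries,
    t_from_ratio_ci,
)

__all__ = [
    "ComparisonRecord",
    "ResultsRow",
    "RunOptions",
    "ConfigError",
    "read_config",
    "write_config",
    "run_reanalysis",
    "write_results",
    "display_round",
    "example_config_path",
]

log = logging.getLogger("trialbf")

OUTCOME_KINDS = ("continuous_summary", "ratio_ci", "binary_counts")
DIRECTIONS = ("greater_is_benefit", "lower_is_benefit")

#: stable results-table column order
RESULT_COLUMNS = [
    "trial_id", "outcome", "subgroup", "test", "prior", "bf01", "bf10",
    "bf01_display", "category", "sensitivity_stable", "notes",
]


class ConfigError(ValueError):
    """Config failed validation; message itemizes every offending record."""


@dataclass(frozen=True)
class ComparisonRecord:
    """One trial/outcome/subgroup comparison with its input payload."""

    trial_id: str
    outcome: str
    outcome_kind: str
    payload: dict
    subgroup: str = ""
    direction: str = "greater_is_benefit"
    notes: str = ""

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.trial_id, self.outcome, self.subgroup)


@dataclass(frozen=True)
class ResultsRow:
    trial_id: str
    outcome: str
    subgroup: str
    test: str
    prior: str
    bf01: float
    bf10: float
    category: str
    sensitivity_stable: Optional[bool]
    notes: str


@dataclass(frozen=True)
class RunOptions:
    prior_scale: float = PriorSpec().scale
    contingency_variant: str = "indep_binomial"
    sensitivity: bool = False
    sensitivity_scales: Sequence[float] = DEFAULT_SCALE_GRID
    quartile_rule: str = "wan"

    def __post_init__(self) -> None:
        if self.contingency_variant not in CONTINGENCY_VARIANTS:
            raise ValueError(
                f"contingency_variant must be one of {CONTINGENCY_VARIANTS}"
            )


# ---------------------------------------------------------------------------
# config reading / writing
# ---------------------------------------------------------------------------

_ARM_FIELDS = ("label", "n", "mean", "sd", "median", "q1", "q3")


def _validate_record(d: dict, locator: str, errors: list[str]) -> Optional[ComparisonRecord]:
    def err(msg: str) -> None:
        errors.append(f"{locator}: {msg}")

    kind = d.get("outcome_kind")
    if kind not in OUTCOME_KINDS:
        err(f"outcome_kind must be one of {OUTCOME_KINDS}, got {kind!r}")
        return None
    direction = d.get("direction", "greater_is_benefit")
    if direction not in DIRECTIONS:
        err(f"direction must be one of {DIRECTIONS}, got {direction!r}")
        return None
    payload = d.get("payload")
    if not isinstance(payload, dict):
        err("payload must be a mapping")
        return None
    try:
        _build_payload(kind, payload)
    except (ValueError, KeyError, TypeError) as exc:
        err(str(exc))
        return None
    for fld in ("trial_id", "outcome"):
        if not d.get(fld):
            err(f"missing required field {fld!r}")
            return None
    return ComparisonRecord(
        trial_id=str(d["trial_id"]),
        outcome=str(d["outcome"]),
        subgroup=str(d.get("subgroup") or ""),
        outcome_kind=kind,
        direction=direction,
        payload=payload,
        notes=str(d.get("notes") or ""),
    )


def _build_payload(kind: str, payload: dict):
    """Instantiate the domain type matching ``kind`` (validates invariants)."""
    if kind == "binary_counts":
        return ContingencyTable2x2(
            n1=payload["n1"], n2=payload["n2"],
            y1=payload["y1"], y2=payload["y2"],
        )
    if kind == "ratio_ci":
        return RatioSummary(
            ratio=payload["ratio"],
            ci_lower=payload["ci_lower"],
            ci_upper=payload["ci_upper"],
            level=payload.get("level", 0.95),
            n1=payload["n1"], n2=payload["n2"],
        )
    if kind == "continuous_summary":
        arms = []
        for arm_key in ("arm1", "arm2"):
            arm = payload[arm_key]
            arms.append(ArmSummary(**{k: arm.get(k) for k in _ARM_FIELDS if arm.get(k) is not None}))
        return tuple(arms)
    raise ValueError(f"unknown outcome_kind {kind!r}")


def read_config(path: str | Path) -> list[ComparisonRecord]:
    """Read and validate a JSON or CSV comparison config.

    Raises :class:`ConfigError` listing every invalid record with a locator.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix.lower() == ".csv":
        raw = _read_csv_config(path)
    else:
        with open(path) as fh:
            doc = json.load(fh)
        raw = doc.get("comparisons")
        if not isinstance(raw, list):
            raise ConfigError(f"{path}: top-level 'comparisons' list missing")
    if not raw:
        raise ConfigError(f"{path}: config contains no comparisons")
    errors: list[str] = []
    records = []
    seen = set()
    for i, d in enumerate(raw):
        locator = f"{path.name}#{i} ({d.get('trial_id', '?')}/{d.get('outcome', '?')})"
        rec = _validate_record(d, locator, errors)
        if rec is None:
            continue
        if rec.key in seen:
            errors.append(f"{locator}: duplicate trial_id/outcome/subgroup")
            continue
        seen.add(rec.key)
        records.append(rec)
    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))
    return records


_CSV_PAYLOAD_COLS = {
    "binary_counts": ("n1", "y1", "n2", "y2"),
    "ratio_ci": ("ratio", "ci_lower", "ci_upper", "level", "n1", "n2"),
    "continuous_summary": (
        "n1", "mean1", "sd1", "median1", "q1_1", "q3_1",
        "n2", "mean2", "sd2", "median2", "q1_2", "q3_2",
    ),
}


def _read_csv_config(path: Path) -> list[dict]:
    df = pd.read_csv(path)
    raw = []
    for _, row in df.iterrows():
        kind = row.get("outcome_kind")
        d = {
            "trial_id": row.get("trial_id"),
            "outcome": row.get("outcome"),
            "subgroup": "" if pd.isna(row.get("subgroup")) else row.get("subgroup"),
            "outcome_kind": kind,
            "direction": row.get("direction", "greater_is_benefit"),
            "notes": "" if pd.isna(row.get("notes")) else row.get("notes"),
        }
        payload: dict = {}
        if kind == "continuous_summary":
            for arm_key, suffix in (("arm1", "1"), ("arm2", "2")):
                arm = {"label": arm_key, "n": row.get(f"n{suffix}")}
                for src, dst in ((f"mean{suffix}", "mean"), (f"sd{suffix}", "sd"),
                                 (f"median{suffix}", "median"),
                                 (f"q1_{suffix}", "q1"), (f"q3_{suffix}", "q3")):
                    v = row.get(src)
                    if v is not None and not pd.isna(v):
                        arm[dst] = float(v)
                if not pd.isna(arm["n"]):
                    arm["n"] = int(arm["n"])
                payload[arm_key] = arm
        elif kind in _CSV_PAYLOAD_COLS:
            for col in _CSV_PAYLOAD_COLS[kind]:
                v = row.get(col)
                if v is not None and not pd.isna(v):
                    payload[col] = int(v) if col in ("n1", "n2", "y1", "y2") else float(v)
        d["payload"] = payload
        raw.append(d)
    return raw


def write_config(records: Sequence[ComparisonRecord], path: str | Path) -> None:
    """Write records as canonical JSON (sorted keys, fixed indentation)."""
    doc = {
        "comparisons": [
            {
                "trial_id": r.trial_id,
                "outcome": r.outcome,
                "subgroup": r.subgroup,
                "outcome_kind": r.outcome_kind,
                "direction": r.direction,
                "payload": r.payload,
                "notes": r.notes,
            }
            for r in records
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# running
# ---------------------------------------------------------------------------


def display_round(x: float) -> str:
    """Paper-style display rounding: 2 significant figures, at least 1 decimal.

    45.37 -> "45.4", 2.826 -> "2.8", 0.1329 -> "0.13".
    """
    if not (math.isfinite(x) and x > 0):
        raise ValueError(f"cannot display-round {x}")
    decimals = max(1, 1 - math.floor(math.log10(x)))
    return f"{round(x, decimals):.{decimals}f}"


def _analyze_record(rec: ComparisonRecord, options: RunOptions) -> ResultsRow:
    notes = [rec.notes] if rec.notes else []
    prior = PriorSpec(scale=options.prior_scale)
    stable: Optional[bool] = None

    if rec.outcome_kind == "binary_counts":
        tab: ContingencyTable2x2 = _build_payload(rec.outcome_kind, rec.payload)
        result = mortality_bf(tab, variant=options.contingency_variant)
        prior_desc = "per-arm rate ~ Beta(1,1)" if tab.prior_a == 1 else (
            f"per-arm rate ~ Beta({tab.prior_a:g},{tab.prior_a:g})"
        )
        if options.sensitivity:
            curve = contingency_sensitivity_curve(
                tab, variant=options.contingency_variant,
                analysis_id="/".join(rec.key),
            )
            stable = robustness_summary(curve).stable
    else:
        cmp = _reconstruct(rec, options, notes)
        result = jzs_bf01(cmp, prior)
        prior_desc = f"delta ~ {prior.describe()}"
        if options.sensitivity:
            curve = sensitivity_curve(
                cmp, options.sensitivity_scales, analysis_id="/".join(rec.key)
            )
            stable = robustness_summary(curve).stable

    # category from the serialized 4-sig-fig value so the stored pair is
    # always self-consistent
    bf01 = float(f"{result.bf01:.4g}")
    return ResultsRow(
        trial_id=rec.trial_id,
        outcome=rec.outcome,
        subgroup=rec.subgroup,
        test=result.test,
        prior=prior_desc,
        bf01=bf01,
        bf10=float(f"{result.bf10:.4g}"),
        category=categorize(bf01).value,
        sensitivity_stable=stable,
        notes="; ".join(notes),
    )


def _reconstruct(rec: ComparisonRecord, options: RunOptions, notes: list[str]) -> TwoArmComparison:
    if rec.outcome_kind == "ratio_ci":
        base = _build_payload(rec.outcome_kind, rec.payload)
        rs = RatioSummary(
            ratio=base.ratio, ci_lower=base.ci_lower, ci_upper=base.ci_upper,
            level=base.level, n1=base.n1, n2=base.n2,
            greater_is_benefit=(rec.direction == "greater_is_benefit"),
        )
        cmp = t_from_ratio_ci(rs)
        msg = (
            f"log-ratio CI converted to t={cmp.t:.4g} (df={cmp.df:g}); "
            "z treated as t"
        )
        notes.append(msg)
        log.info("%s/%s: %s", rec.trial_id, rec.outcome, msg)
        return cmp
    # continuous_summary
    arm1, arm2 = _build_payload(rec.outcome_kind, rec.payload)
    for arm in (arm1, arm2):
        if arm.mean is None:
            msg = f"arm {arm.label!r}: mean/SD estimated from quartiles ({options.quartile_rule} rule)"
            notes.append(msg)
            log.info("%s/%s: %s", rec.trial_id, rec.outcome, msg)
    cmp = t_from_arm_summaries(arm1, arm2, quartile_rule=options.quartile_rule)
    if rec.direction == "lower_is_benefit":
        cmp = TwoArmComparison(t=-cmp.t, df=cmp.df, n1=cmp.n1, n2=cmp.n2,
                               source=cmp.source)
        notes.append("sign flipped: lower outcome is beneficial")
    return cmp


def run_reanalysis(
    records: Sequence[ComparisonRecord],
    options: Optional[RunOptions] = None,
) -> tuple[list[ResultsRow], list[tuple[ComparisonRecord, Exception]]]:
    """Analyze every record independently.

    Returns ``(rows, failures)``; a failing record is collected with its
    exception and the run continues.  Deterministic: identical records and
    options yield identical rows.
    """
    options = options or RunOptions()
    rows: list[ResultsRow] = []
    failures: list[tuple[ComparisonRecord, Exception]] = []
    for rec in records:
        try:
            rows.append(_analyze_record(rec, options))
        except Exception as exc:  # noqa: BLE001 - per-record fault isolation
            log.error("record %s failed: %s", rec.key, exc)
            failures.append((rec, exc))
    return rows, failures


def results_frame(rows: Sequence[ResultsRow]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                **row.__dict__,
                "bf01_display": display_round(row.bf01),
            }
            for row in rows
        ],
        columns=RESULT_COLUMNS,
    )
    return df


def write_results(rows: Sequence[ResultsRow], path: str | Path, format: str = "csv") -> None:
    """Write the results table with stable column order.

    BF columns carry 4 significant figures; ``bf01_display`` mirrors the
    2-significant-figure display rule.
    """
    df = results_frame(rows)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        df.to_json(path, orient="records", indent=2)
    else:
        raise ValueError("format must be 'csv' or 'json'")


def example_config_path() -> Path:
    """Path of the packaged remdesivir-trials config."""
    return Path(__file__).parent / "data" / "remdesivir_trials.json"
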