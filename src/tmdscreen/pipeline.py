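"""End-to-end orchestration: plate-table I/O, config, and the full
fit -> aggregate -> normalize -> classify -> pattern-stats run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from tmdscreen.dose_response import (
    DoseResponseSeries,
    FitConfig,
    LD50Result,
    NoEstimateError,
    aggregate_ld50,
    fit_hill,
    normalize_affinity,
)
from tmdscreen.library_design import TMDPair
from tmdscreen.pattern_stats import (
    PatternPredicate,
    isolates_to_frame,
    load_isolates,
    overrepresentation,
    positional_distribution,
    summarize_by_class,
    within_spacing,
)

__all__ = [
    "RunConfig",
    "PlateTableError",
    "read_plate_table",
    "write_plate_table",
    "run_screen_analysis",
]

REQUIRED_COLUMNS = ("pair_id", "replicate", "ampicillin_ug_ml", "a544")


class PlateTableError(ValueError):
    """Malformed plate table; the message lists the offending rows."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_plate_table(path) -> list[DoseResponseSeries]:
    """Parse a long-format plate table into dose-response series.

    Expected columns: pair_id, replicate, ampicillin_ug_ml, a544, plus an
    optional condition column.  Rows are grouped by (pair_id, replicate);
    errors report offending line numbers (1-based, header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PlateTableError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )

    problems = []
    for col in ("ampicillin_ug_ml", "a544"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[numeric.isna() & df[col].notna()]:
            problems.append(f"line {i + 2}: non-numeric {col} {df.at[i, col]!r}")
        for i in df.index[df[col].isna()]:
            problems.append(f"line {i + 2}: missing {col}")
        df[col] = numeric
    dup = df.duplicated(
        subset=["pair_id", "replicate", "ampicillin_ug_ml"], keep=False
    )
    for i in df.index[dup & ~df.duplicated(
        subset=["pair_id", "replicate", "ampicillin_ug_ml"], keep="first"
    )]:
        problems.append(
            f"line {i + 2}: duplicate dose {df.at[i, 'ampicillin_ug_ml']} "
            f"for ({df.at[i, 'pair_id']}, {df.at[i, 'replicate']})"
        )
    if problems:
        raise PlateTableError(f"{path}: " + "; ".join(problems))

    series = []
    for (pair_id, replicate), group in df.groupby(
        ["pair_id", "replicate"], sort=True
    ):
        condition = ""
        if "condition" in group.columns:
            condition = str(group["condition"].iloc[0])
            if condition == "nan":
                condition = ""
        group = group.sort_values("ampicillin_ug_ml")
        series.append(
            DoseResponseSeries(
                pair_id=str(pair_id),
                replicate_id=str(replicate),
                concentrations=tuple(group["ampicillin_ug_ml"]),
                responses=tuple(group["a544"]),
                condition=condition,
            )
        )
    return series


def write_plate_table(series: Sequence[DoseResponseSeries], path) -> None:
    """Write series to the long-format dialect read_plate_table consumes."""
    path = Path(path)
    rows = []
    for s in series:
        for x, y in zip(s.concentrations, s.responses):
            rows.append(
                {
                    "pair_id": s.pair_id,
                    "replicate": s.replicate_id,
                    "ampicillin_ug_ml": x,
                    "a544": y,
                    "condition": s.condition,
                }
            )
    pd.DataFrame(rows).to_csv(
        path, sep=_sep_for(path), index=False, float_format="%.17g"
    )


@dataclass
class RunConfig:
    """Settings for one end-to-end analysis run."""

    plate_table: Path
    reference_pair_id: str
    out_dir: Path
    isolate_table: Optional[Path] = None
    r_squared_min: float = 0.85
    predicate_positions: tuple[int, ...] = (6, 7)
    predicate_relation: str = "opposite"
    n_isolates: Optional[int] = None
    seed: Optional[int] = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {
            "plate_table", "reference_pair_id", "out_dir", "isolate_table",
            "r_squared_min", "predicate_positions", "predicate_relation",
            "n_isolates", "seed",
        }
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        for key in ("plate_table", "isolate_table", "out_dir"):
            if kwargs.get(key) is not None:
                value = Path(kwargs[key])
                if not value.is_absolute():
                    value = path.parent / value
                kwargs[key] = value
        if "predicate_positions" in kwargs:
            kwargs["predicate_positions"] = tuple(kwargs["predicate_positions"])
        return cls(extra=extra, **kwargs)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "plate_table": str(config.plate_table),
            "isolate_table": str(config.isolate_table),
            "reference_pair_id": config.reference_pair_id,
            "r_squared_min": config.r_squared_min,
            "predicate_positions": list(config.predicate_positions),
            "predicate_relation": config.predicate_relation,
            "n_isolates": config.n_isolates,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_screen_analysis(config: RunConfig) -> dict:
    """Execute the full analysis and write TSV/JSON reports plus a manifest.

    Stages: read plate table -> Hill fits per replicate -> LD50 aggregation
    -> normalization to the reference pair -> affinity classes; then, when
    an isolate table is given, charge-pattern summaries and the
    overrepresentation statistic.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fit_config = FitConfig(r_squared_min=config.r_squared_min)

    try:
        series = read_plate_table(config.plate_table)
    except Exception as exc:
        raise StageError(f"stage read_plate_table failed: {exc}") from exc

    fit_rows = []
    fits_by_pair: dict[str, list] = {}
    try:
        for s in series:
            params, diag = fit_hill(s, fit_config)
            fits_by_pair.setdefault(s.pair_id, []).append((params, diag))
            fit_rows.append(
                {
                    "pair_id": s.pair_id,
                    "replicate": s.replicate_id,
                    "c": params.c if params else None,
                    "k": params.k if params else None,
                    "g": params.g if params else None,
                    "r_squared": diag.r_squared,
                    "rss": diag.rss,
                    "n_points": diag.n_points,
                    "converged": diag.converged,
                    "accepted": diag.accepted,
                    "reason": diag.reason,
                }
            )
    except Exception as exc:
        raise StageError(f"stage fit_hill failed: {exc}") from exc

    try:
        results: dict[str, LD50Result] = {}
        skipped = []
        for pair_id, fits in fits_by_pair.items():
            try:
                results[pair_id] = aggregate_ld50(pair_id, fits)
            except NoEstimateError as exc:
                skipped.append(str(exc))
        if config.reference_pair_id not in results:
            raise ValueError(
                f"reference pair {config.reference_pair_id!r} has no LD50 estimate"
            )
        reference = results[config.reference_pair_id]
    except Exception as exc:
        raise StageError(f"stage aggregate_ld50 failed: {exc}") from exc

    try:
        ld50_rows = []
        for pair_id in sorted(results):
            res = results[pair_id]
            rel = normalize_affinity(res, reference)
            ld50_rows.append(
                {
                    "pair_id": pair_id,
                    "ld50_mean": res.ld50_mean,
                    "ld50_sem": res.ld50_sem,
                    "n": res.n,
                    "n_rejected": res.n_rejected,
                    "percent_of_reference": rel.percent_of_reference,
                    "affinity_class": rel.affinity_class,
                }
            )
    except Exception as exc:
        raise StageError(f"stage normalize_affinity failed: {exc}") from exc

    ld50_path = out_dir / "ld50_results.tsv"
    pd.DataFrame(ld50_rows).to_csv(
        ld50_path, sep="\t", index=False, float_format="%.6g"
    )
    fits_path = out_dir / "fit_report.json"
    with open(fits_path, "w") as fh:
        json.dump(fit_rows, fh, indent=1, default=float)

    report: dict = {
        "n_series": len(series),
        "n_pairs": len(results),
        "skipped": skipped,
        "reference_pair_id": config.reference_pair_id,
        "outputs": [str(ld50_path), str(fits_path)],
    }

    if config.isolate_table is not None:
        try:
            isolates = load_isolates(config.isolate_table)
            summary = summarize_by_class(
                [p for p in isolates if p.affinity_class is not None]
            )
            spacing = within_spacing(
                [p for p in isolates if p.affinity_class is not None]
            )
            positions = positional_distribution(isolates)
            predicate = PatternPredicate(
                position_set=frozenset(config.predicate_positions),
                charge_relation=config.predicate_relation,
            )
            observed = sum(
                p.observed_count if p.observed_count > 0 else 1
                for p in isolates
                if predicate.matches(p)
            )
            n_isolates = config.n_isolates or sum(
                p.observed_count if p.observed_count > 0 else 1
                for p in isolates
            )
            overrep = overrepresentation(predicate, n_isolates, observed)
        except Exception as exc:
            raise StageError(f"stage pattern_stats failed: {exc}") from exc

        summary_path = out_dir / "class_summary.tsv"
        summary.to_csv(summary_path, sep="\t", index=False)
        positions_path = out_dir / "positional_distribution.tsv"
        positions.to_csv(positions_path, sep="\t", index=False)
        overrep_path = out_dir / "overrepresentation.json"
        with open(overrep_path, "w") as fh:
            json.dump(overrep.report(), fh, indent=1)
        report["overrepresentation"] = overrep.report()
        report["within_spacing"] = spacing
        report["outputs"] += [
            str(summary_path), str(positions_path), str(overrep_path)
        ]

    manifest = {
        "config_hash": _config_hash(config),
        "inputs": {
            "plate_table": str(config.plate_table),
            "isolate_table": (
                str(config.isolate_table) if config.isolate_table else None
            ),
        },
        "reference_pair_id": config.reference_pair_id,
        "r_squared_min": config.r_squared_min,
        "predicate": {
            "positions": list(config.predicate_positions),
            "relation": config.predicate_relation,
        },
        "seed": config.seed,
        "outputs": report["outputs"],
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    report["manifest"] = str(manifest_path)
    return report


def write_isolate_table(pairs: Sequence[TMDPair], path) -> None:
    """Write isolates in the TSV dialect load_isolates consumes."""
    isolates_to_frame(pairs).to_csv(path, sep="\t", index=False)
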