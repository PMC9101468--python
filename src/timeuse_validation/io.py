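"""CSV readers/writers, configuration handling, and the analysis pipeline.

The long activity-log format has columns
``participant_id,method,day_type,slot_start,activity_code``: one row per
recorded activity per slot.  Slots with no rows are empty; the reserved code
``__missing__`` marks a slot with no usable data (such records are
incomplete and excluded from analysis).  Synthetic and field data use the
same format, so the pipeline consumes both identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import yaml

from .agreement import (
    bland_altman,
    cronbach_alpha,
    shape_diagnostics,
    threshold_counts,
    weighted_kappa,
)
from .catalog import (
    ActivityCatalog,
    DIVISIONS,
    MethodRecord,
    TimeslotGrid,
    build_default_catalog,
    build_grid,
)
from .crediting import CreditTable, concurrency_profile, credit_records
from .descriptives import summary_table
from .simulate import MethodErrorModel, SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

MISSING_CODE = "__missing__"


# ---------------------------------------------------------------------------
# Activity-log CSV

_LOG_COLUMNS = ["participant_id", "method", "day_type", "slot_start", "activity_code"]


def write_activity_log(records: Iterable[MethodRecord], path: Union[str, Path], grid: TimeslotGrid) -> None:
    """Write records in the long activity-log format.

    Records whose every slot is empty leave no rows and therefore do not
    survive a round trip; field instruments always record something, and the
    generator guarantees a foreground activity per slot.
    """
    labels = grid.slot_start_labels()
    rows = []
    for rec in records:
        if rec.n_slots != grid.n_slots:
            raise ValueError(
                f"record {rec.participant_id}/{rec.method} does not match the grid"
            )
        for i, slot in enumerate(rec.slots):
            codes = [MISSING_CODE] if i in rec.missing_slots else sorted(slot)
            for code in codes:
                rows.append((rec.participant_id, rec.method, rec.day_type, labels[i], code))
    pd.DataFrame(rows, columns=_LOG_COLUMNS).to_csv(path, index=False)


def read_activity_log(
    path: Union[str, Path],
    catalog: ActivityCatalog,
    grid: TimeslotGrid,
) -> list[MethodRecord]:
    """Read a long activity-log CSV into MethodRecords.

    Rows are grouped by participant x method x day_type; every grid slot
    without rows is an empty set.  Unknown activity codes and slot starts
    off the grid are rejected with their CSV row numbers; exact duplicate
    rows are deduplicated with a warning.
    """
    df = pd.read_csv(path, dtype=str)
    missing_cols = set(_LOG_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"activity log missing columns: {sorted(missing_cols)}")
    df = df[_LOG_COLUMNS]
    if df.isna().any().any():
        bad = (df.isna().any(axis=1)).to_numpy().nonzero()[0] + 2  # 1-based + header
        raise ValueError(f"malformed (incomplete) rows at lines: {bad.tolist()}")

    dup_mask = df.duplicated()
    if dup_mask.any():
        logger.warning("deduplicated %d duplicate activity-log rows", int(dup_mask.sum()))
        df = df[~dup_mask]

    bad_lines: list[int] = []
    slot_idx = []
    for pos, slot_start in zip(df.index, df["slot_start"]):
        try:
            slot_idx.append(grid.slot_index(slot_start))
        except ValueError:
            bad_lines.append(pos + 2)
            slot_idx.append(-1)
    if bad_lines:
        raise ValueError(f"slot starts off the grid at lines: {bad_lines}")
    df = df.assign(_slot=slot_idx)

    known = {e.code for e in catalog} | {MISSING_CODE}
    unknown = df[~df["activity_code"].isin(known)]
    if not unknown.empty:
        detail = ", ".join(
            f"{code!r} (line {pos + 2})"
            for pos, code in zip(unknown.index[:10], unknown["activity_code"][:10])
        )
        raise ValueError(f"unknown activity codes: {detail}")

    records = []
    for (pid, method, day_type), grp in df.groupby(
        ["participant_id", "method", "day_type"], sort=True
    ):
        slots: list[set[str]] = [set() for _ in range(grid.n_slots)]
        missing: set[int] = set()
        for i, code in zip(grp["_slot"], grp["activity_code"]):
            if code == MISSING_CODE:
                missing.add(i)
            else:
                slots[i].add(code)
        records.append(
            MethodRecord(
                participant_id=pid,
                method=method,
                day_type=day_type,
                slots=tuple(frozenset(s) for s in slots),
                missing_slots=frozenset(missing),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-level settings wrapped around the simulation conditions."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mode: str = "simultaneous_aware"
    loa_multiplier: float = 2.0
    kappa_scheme: str = "linear"
    thresholds: tuple[float, ...] = (30.0, 120.0)
    methods: tuple[str, ...] = ("R24H", "IAR")
    alpha_level: float = 0.05
    input_log: str | None = None  # analyse a file instead of simulating
    catalog_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = dict(raw.pop("simulation", {}))
        catalog_csv = raw.get("catalog_csv")
        catalog = (
            ActivityCatalog.from_csv(catalog_csv) if catalog_csv else build_default_catalog()
        )
        grid_raw = sim_raw.pop("grid", {})
        grid = build_grid(
            grid_raw.get("window_start", "08:00"),
            grid_raw.get("window_end", "20:00"),
            int(grid_raw.get("slot_minutes", 15)),
        )
        errors_raw = sim_raw.pop("error_models", None)
        sim_kwargs = dict(sim_raw, grid=grid, catalog=catalog)
        if errors_raw is not None:
            sim_kwargs["error_models"] = {
                m: MethodErrorModel(**v) for m, v in errors_raw.items()
            }
        simulation = SimulationConfig(**sim_kwargs)
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in raw:
            raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(simulation=simulation, **raw)

    def to_dict(self) -> dict:
        sim = self.simulation
        return {
            "simulation": {
                "n_participants": sim.n_participants,
                "seed": sim.seed,
                "grid": {
                    "window_start": f"{sim.grid.window_start // 60:02d}:{sim.grid.window_start % 60:02d}",
                    "window_end": f"{sim.grid.window_end // 60:02d}:{sim.grid.window_end % 60:02d}",
                    "slot_minutes": sim.grid.slot_minutes,
                },
                "sim_presence": dict(sim.sim_presence),
                "division_weights": dict(sim.division_weights),
                "persistence": sim.persistence,
                "p_second_foreground": sim.p_second_foreground,
                "error_models": {
                    m: dataclasses.asdict(v) for m, v in sim.error_models.items()
                },
                "omission_unit": sim.omission_unit,
                "reactivity_caregiving": sim.reactivity_caregiving,
                "reactivity_own_production": sim.reactivity_own_production,
                "missing_slot_rate": sim.missing_slot_rate,
            },
            "mode": self.mode,
            "loa_multiplier": self.loa_multiplier,
            "kappa_scheme": self.kappa_scheme,
            "thresholds": list(self.thresholds),
            "methods": list(self.methods),
            "alpha_level": self.alpha_level,
            "input_log": self.input_log,
            "catalog_csv": self.catalog_csv,
        }


# ---------------------------------------------------------------------------
# Pipeline


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, decimals: Mapping[str, int]) -> None:
    out = df.copy()
    for col, nd in decimals.items():
        if col in out.columns:
            out[col] = out[col].astype(float).round(nd)
    out.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig, outdir: Union[str, Path]) -> dict[str, Path]:
    """Simulate (or load), credit, compare, and write the report bundle.

    Emits per-division descriptives (medians/quartiles/non-participation),
    the Bland-Altman agreement report with shape diagnostics and threshold
    counts, the reliability report (alpha per division, kappa for
    concurrency), per-pair plot-data CSVs, and a run manifest.  Minutes are
    written with one decimal, statistics with four, so identical configs and
    inputs yield byte-identical reports.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    grid, catalog = sim.grid, sim.catalog

    input_digests = {}
    if config.input_log:
        stage = "read"
        try:
            records = read_activity_log(config.input_log, catalog, grid)
        except Exception as exc:  # pragma: no cover - message shaping
            raise RuntimeError(f"[{stage}] {exc}") from exc
        input_digests[str(config.input_log)] = _sha256(Path(config.input_log))
    else:
        records = list(simulate_cohort(sim, methods=config.methods).records)
    if config.catalog_csv:
        input_digests[str(config.catalog_csv)] = _sha256(Path(config.catalog_csv))

    by_method = {
        m: [r for r in records if r.method == m and r.day_type == "observation" and r.is_complete]
        for m in ("OBS",) + tuple(config.methods)
    }
    if not by_method["OBS"]:
        raise RuntimeError("[credit] no complete criterion (OBS) records")
    # complete-case rule across methods: keep participants complete everywhere
    complete_ids = set.intersection(
        *(set(r.participant_id for r in recs) for recs in by_method.values())
    )
    tables: dict[str, CreditTable] = {}
    for m, recs in by_method.items():
        recs = [r for r in recs if r.participant_id in complete_ids]
        tables[m] = credit_records(recs, catalog, grid, config.mode)

    # -- descriptives -------------------------------------------------------
    table2 = summary_table(
        {m: tables[m] for m in ("OBS",) + tuple(config.methods)}, tables["OBS"]
    )
    _write_csv(
        table2,
        outdir / "descriptives.csv",
        {"non_participation_pct": 1, "median": 1, "p25": 1, "p75": 1,
         "partaker_median": 1, "wilcoxon_p": 4},
    )

    # -- agreement ----------------------------------------------------------
    plotdir = outdir / "plotdata"
    plotdir.mkdir(exist_ok=True)
    agree_rows, thresh_rows, rel_rows = [], [], []
    order = sorted(complete_ids)
    for m in config.methods:
        for division in DIVISIONS:
            crit = tables["OBS"].minutes.loc[order, division].to_numpy()
            test = tables[m].minutes.loc[order, division].to_numpy()
            if crit.std() == 0 and test.std() == 0:
                continue  # empty division (e.g. MD5/MD6): nothing to compare
            res = bland_altman(
                crit, test, config.loa_multiplier, label=division, method_pair=("OBS", m)
            )
            shape = shape_diagnostics(res, config.alpha_level)
            agree_rows.append(
                {
                    "division": division, "method": m, "n": res.n,
                    "bias": res.bias, "sd_diff": res.sd_diff,
                    "loa_low": res.loa_low, "loa_high": res.loa_high,
                    "n_above_zero": res.counts_above_zero,
                    "n_below_zero": res.counts_below_zero, "n_ties": res.ties,
                    "shape": shape.classification,
                    "slope_p": shape.slope_p, "spread_p": shape.spread_p,
                }
            )
            for row in threshold_counts(res.differences, config.thresholds):
                thresh_rows.append({"division": division, "method": m, **row})
            rel = cronbach_alpha(crit, test)
            rel_rows.append(
                {"division": division, "method": m, "statistic": "alpha",
                 "value": rel.alpha, "label": rel.label}
            )
            pd.DataFrame({"mean": res.means, "difference": res.differences}).round(4).to_csv(
                plotdir / f"{division}_{m}.csv", index=False
            )

    # -- concurrency --------------------------------------------------------
    conc_rows = []
    medians: dict[str, dict[str, float]] = {}
    for m in ("OBS",) + tuple(config.methods):
        medians[m] = {}
        for rec in by_method[m]:
            if rec.participant_id not in complete_ids:
                continue
            _, med, prop = concurrency_profile(rec)
            medians[m][rec.participant_id] = med
            conc_rows.append(
                {"participant_id": rec.participant_id, "method": m,
                 "median_concurrency": med, "prop_multi_activity": prop}
            )
    for m in config.methods:
        crit = [medians["OBS"][p] for p in order]
        test = [medians[m][p] for p in order]
        res = bland_altman(crit, test, config.loa_multiplier,
                           label="concurrency", method_pair=("OBS", m))
        agree_rows.append(
            {"division": "concurrency", "method": m, "n": res.n,
             "bias": res.bias, "sd_diff": res.sd_diff,
             "loa_low": res.loa_low, "loa_high": res.loa_high,
             "n_above_zero": res.counts_above_zero,
             "n_below_zero": res.counts_below_zero, "n_ties": res.ties,
             "shape": shape_diagnostics(res, config.alpha_level).classification,
             "slope_p": float("nan"), "spread_p": float("nan")}
        )
        kap = weighted_kappa(crit, test, config.kappa_scheme)
        rel_rows.append(
            {"division": "concurrency", "method": m,
             "statistic": f"kappa_{kap.scheme}", "value": kap.kappa, "label": kap.label}
        )

    _write_csv(
        pd.DataFrame(agree_rows), outdir / "agreement.csv",
        {"bias": 1, "sd_diff": 1, "loa_low": 1, "loa_high": 1,
         "slope_p": 4, "spread_p": 4},
    )
    _write_csv(
        pd.DataFrame(thresh_rows), outdir / "threshold_counts.csv",
        {"pct_within": 1, "pct_beyond": 1},
    )
    _write_csv(pd.DataFrame(rel_rows), outdir / "reliability.csv", {"value": 4})
    _write_csv(
        pd.DataFrame(conc_rows), outdir / "concurrency.csv",
        {"median_concurrency": 1, "prop_multi_activity": 4},
    )
    for m, table in tables.items():
        _write_csv(table.to_tidy(), outdir / f"credits_{m}.csv", {"minutes": 1})

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "input_digests": input_digests,
        "catalog_entries": len(catalog),
        "software_version": __version__,
        "seed": sim.seed,
        "n_analyzed": len(complete_ids),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*.csv")
        ),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {p.stem: p for p in outdir.glob("*.csv")} | {"manifest": outdir / "manifest.json"}
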