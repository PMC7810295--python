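"""End-to-end orchestration: logs -> landmarks -> indices -> statistics.

A :class:`RunConfig` names exactly one input source — a set of equipment
logs plus a cohort table, a deposited dataset workbook, or a synthetic
cohort preset — together with extraction and statistics settings.
:func:`run_pipeline` writes ``params.csv``, ``indices.csv``, a
``report.json`` with the full statistical battery, and a human-readable
``summary.txt`` comparing per-group index means against the bundled
published reference values.  Outputs are deterministic functions of the
configuration and inputs; the report stamps the package version, a
configuration hash, the roll-off convention and every seed used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, reference
from .errors import DataError, DegenerateInputError, FormatError, NoRolloffError, RfaError
from .indices import compute_indices
from .io import (
    CohortTable,
    ImpedanceCurve,
    read_cohort_table,
    read_rfa_log,
    write_results,
)
from .params import extract_parameters
from .stats import (
    FACTORIAL_GROUPS,
    flag_outliers,
    levene,
    marginal_means,
    one_way_anova,
    shapiro_wilk,
    spearman_correlation,
    tukey_hsd,
    two_way_anova,
)
from .synthetic import generate_cohort, published_cohort_preset

__all__ = ["RunConfig", "run_pipeline", "read_dataset_workbook", "indices_table"]

log = logging.getLogger("rfacurve")

INDEX_COLS = ("delta", "dr", "ar")


@dataclass
class RunConfig:
    """One pipeline run.  Exactly one input source must be set."""

    log_paths: list[str] = field(default_factory=list)
    cohort_path: str | None = None
    dataset_path: str | None = None
    simulate_preset: str | None = None  # currently "published-cohort"

    # extraction settings
    mode: str = "log_end"
    factor: float = 1.5
    init_k: int = 1
    median_window: int = 9

    # statistics settings
    ci_method: str = "parametric"
    bootstrap_B: int = 1000
    alpha: float = 0.05
    seed: int = 0

    out_dir: str = "rfacurve_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        sources = sum(
            [bool(self.log_paths), self.dataset_path is not None,
             self.simulate_preset is not None]
        )
        if sources != 1:
            raise ValueError(
                "exactly one input source required: log files, a dataset "
                "workbook, or a simulation preset"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.simulate_preset is not None and self.simulate_preset != "published-cohort":
            raise ValueError(f"unknown preset {self.simulate_preset!r}")

    def hash(self) -> str:
        """Hash of the scientific configuration (where outputs land and how
        verbosely we log do not change what is computed)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        payload.pop("log_level")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def indices_table(
    curves: list[ImpedanceCurve],
    cohort: CohortTable | None = None,
    *,
    mode: str = "log_end",
    factor: float = 1.5,
    init_k: int = 1,
    median_window: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract landmarks and indices for every curve.

    Returns ``(params_df, indices_df)``; when a cohort table is given the
    indices frame carries group, factor levels and volume columns, ready
    for the statistical battery.

    Curves that never reach the threshold level (possible only in
    threshold mode) are aborted ablations, not pipeline failures: they are
    excluded and listed in the ``no_rolloff`` attribute of the returned
    indices frame.  Any other extraction failure aborts with the stage and
    sample named.
    """
    prows, irows, no_rolloff = [], [], []
    for curve in curves:
        try:
            p = extract_parameters(
                curve, mode=mode, factor=factor, init_k=init_k,
                median_window=median_window,
            )
        except NoRolloffError as exc:
            log.warning("sample %s: %s (excluded)", curve.sample_id, exc)
            no_rolloff.append(curve.sample_id)
            continue
        except RfaError as exc:
            raise DataError(
                f"extraction stage, sample {curve.sample_id!r}: {exc}"
            ) from exc
        prows.append(dataclasses.asdict(p))
        irows.append(dataclasses.asdict(compute_indices(p)))
    if not prows:
        raise DataError("extraction stage: no curve reached roll-off")
    params_df = pd.DataFrame(prows)
    idx_df = pd.DataFrame(irows)
    idx_df.attrs["no_rolloff"] = no_rolloff
    if cohort is not None:
        idx_df = idx_df.merge(cohort.data, on="sample_id", how="left")
        missing = idx_df["group"].isna()
        if missing.any():
            raise DataError(
                f"samples absent from cohort table: "
                f"{idx_df.loc[missing, 'sample_id'].tolist()}"
            )
        idx_df.attrs["no_rolloff"] = no_rolloff
    return params_df, idx_df


def _tukey_records(df: pd.DataFrame) -> list[dict]:
    return df.to_dict(orient="records")


def statistical_report(
    idx_df: pd.DataFrame,
    ci_method: str = "parametric",
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Run the full battery on an indices table with cohort columns."""
    report: dict = {
        "assumptions": {},
        "anova": {},
        "tukey": {},
        "two_way_anova": {},
        "marginal_means": {},
        "correlations": [],
        "outliers": {},
        "alpha": alpha,
    }
    groups = sorted(idx_df["group"].unique())
    for col in INDEX_COLS:
        vals = idx_df[col].to_numpy(float)
        grp = idx_df["group"].to_numpy(str)
        resid = vals - idx_df.groupby("group")[col].transform("mean").to_numpy()
        report["assumptions"][col] = {
            "shapiro_wilk_residuals": dataclasses.asdict(shapiro_wilk(resid)),
            "levene": dataclasses.asdict(
                levene([vals[grp == g] for g in groups])
            ),
        }
        report["anova"][col] = dataclasses.asdict(one_way_anova(vals, grp))
        report["tukey"][col] = _tukey_records(tukey_hsd(vals, grp, alpha=alpha))
        fact = idx_df[idx_df["group"].isin(FACTORIAL_GROUPS)]
        try:
            report["two_way_anova"][col] = {
                k: dataclasses.asdict(v)
                for k, v in two_way_anova(
                    fact[col], fact["solution"], fact["temperature"]
                ).items()
            }
        except DegenerateInputError as exc:
            # partial cohorts cannot support the 2x2 factorial
            report["two_way_anova"][col] = {"error": str(exc)}
        report["marginal_means"][col] = {}
        for i, grouping in enumerate(("group", "solution", "temperature")):
            mm = marginal_means(
                idx_df.rename(columns={col: "value"}),
                grouping=grouping,
                ci_method=ci_method,
                B=B,
                seed=seed + i,
            )
            report["marginal_means"][col][grouping] = mm.to_dict(orient="records")
        report["outliers"][col] = {}
        for g in groups:
            try:
                report["outliers"][col][g] = idx_df.loc[
                    (grp == g) & flag_outliers_by_group(vals, grp, g),
                    "sample_id",
                ].tolist()
            except DegenerateInputError as exc:
                report["outliers"][col][g] = {"error": str(exc)}
        if idx_df["volume"].notna().all():
            for g in groups:
                sub = idx_df[idx_df["group"] == g]
                try:
                    rho, p = spearman_correlation(sub["volume"], sub[col])
                except DegenerateInputError as exc:
                    report["correlations"].append(
                        {"index": col, "group": g, "error": str(exc)}
                    )
                    continue
                report["correlations"].append(
                    {"index": col, "group": g, "rho": rho, "p_value": p,
                     "n": len(sub)}
                )
    return report


def flag_outliers_by_group(values, grp, g) -> np.ndarray:
    """Boolean mask over all samples: Tukey-fence outliers within group g."""
    mask = np.zeros(len(values), dtype=bool)
    sel = grp == g
    mask[sel] = flag_outliers(np.asarray(values)[sel])
    return mask


def read_dataset_workbook(path: str | Path):
    """Ingest a deposited dataset workbook, auto-detecting its layout.

    Two layouts are recognized, sheet by sheet:

    * long curve sheets — columns for time plus impedance (or voltage and
      current), optionally a sample-id column holding several curves;
    * index sheets — a group column plus precomputed delta/dr/ar columns
      (and optionally volume).

    Returns ``(curves, cohort, precomputed_indices, description)`` where
    unused slots are ``None``/empty; ``description`` records what was
    detected for the run report.
    """
    path = Path(path)
    book = pd.read_excel(path, sheet_name=None)
    curves: list[ImpedanceCurve] = []
    idx_frames = []
    cohort_rows = []
    detected = []
    for sheet, df in book.items():
        cols = {str(c).lower().strip(): c for c in df.columns}
        has_t = any(k in cols for k in ("t", "time", "time_s"))
        has_z = any(k in cols for k in ("z", "impedance"))
        has_vi = ("v" in cols or "voltage" in cols) and (
            "i" in cols or "current" in cols
        )
        has_idx = all(k in cols for k in ("delta", "dr", "ar")) and "group" in cols
        if has_idx:
            sub = df.rename(columns={v: k for k, v in cols.items()})
            idx_frames.append(sub)
            detected.append(f"sheet {sheet!r}: precomputed index table")
        elif has_t and (has_z or has_vi):
            sid_col = next(
                (cols[k] for k in ("sample_id", "sample", "id") if k in cols), None
            )
            if sid_col is None:
                tmp = path.parent / f".{path.stem}_{sheet}.csv"
                df.to_csv(tmp, index=False)
                try:
                    curves.append(read_rfa_log(tmp, sample_id=sheet))
                finally:
                    tmp.unlink(missing_ok=True)
                detected.append(f"sheet {sheet!r}: one curve")
            else:
                for sid, sub in df.groupby(sid_col):
                    tmp = path.parent / f".{path.stem}_{sid}.csv"
                    sub.drop(columns=[sid_col]).to_csv(tmp, index=False)
                    try:
                        curves.append(read_rfa_log(tmp, sample_id=str(sid)))
                    finally:
                        tmp.unlink(missing_ok=True)
                detected.append(f"sheet {sheet!r}: long curve table")
        elif "group" in cols and any(
            k in cols for k in ("sample_id", "sample", "id")
        ):
            cohort_rows.append(df)
            detected.append(f"sheet {sheet!r}: cohort table")
        else:
            detected.append(f"sheet {sheet!r}: unrecognized, skipped")
    cohort = None
    if cohort_rows:
        cohort = CohortTable(
            pd.concat(cohort_rows).rename(
                columns=lambda c: str(c).lower().strip()
            )
        )
    pre_idx = pd.concat(idx_frames, ignore_index=True) if idx_frames else None
    if not curves and pre_idx is None:
        raise FormatError(
            f"{path.name}: no curve or index sheets recognized "
            f"({'; '.join(detected)})"
        )
    return curves, cohort, pre_idx, "; ".join(detected)


def run_pipeline(config: RunConfig) -> dict:
    """Execute one configured run and write the report bundle.

    On a stage failure the error message carries the stage and sample; any
    partial outputs already written are moved to a ``quarantine/``
    subdirectory so a rerun never mixes them with complete results.
    """
    config.validate()
    try:
        return _run_pipeline(config)
    except RfaError:
        out = Path(config.out_dir)
        partial = [p for p in out.glob("*") if p.is_file()]
        if partial:
            qdir = out / "quarantine"
            qdir.mkdir(exist_ok=True)
            for p in partial:
                p.rename(qdir / p.name)
        raise


def _run_pipeline(config: RunConfig) -> dict:
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "tool_version": __version__,
        "config_hash": config.hash(),
        "rolloff_mode": config.mode,
        "seed": config.seed,
    }
    log.info("run %s (seed %d, mode %s)", meta["config_hash"], config.seed, config.mode)

    pre_idx = None
    if config.simulate_preset is not None:
        spec = published_cohort_preset(seed=config.seed)
        curves, cohort = generate_cohort(spec)
        meta["input"] = f"simulated preset {config.simulate_preset!r}"
    elif config.dataset_path is not None:
        curves, cohort, pre_idx, detected = read_dataset_workbook(config.dataset_path)
        meta["input"] = f"dataset workbook {config.dataset_path} ({detected})"
    else:
        curves = [read_rfa_log(p) for p in config.log_paths]
        cohort = (
            read_cohort_table(config.cohort_path) if config.cohort_path else None
        )
        meta["input"] = f"{len(curves)} log files"

    if pre_idx is not None and not curves:
        idx_df = pre_idx.copy()
        idx_df["rolloff_mode"] = "precomputed"
        if "volume" not in idx_df:
            idx_df["volume"] = np.nan
        if "sample_id" not in idx_df:
            idx_df["sample_id"] = [f"s{i+1:02d}" for i in range(len(idx_df))]
        idx_df = CohortTable(
            idx_df[["sample_id", "group", "volume"]]
        ).data.merge(idx_df.drop(columns=["volume"]), on=["sample_id", "group"])
        params_df = None
    else:
        params_df, idx_df = indices_table(
            curves, cohort,
            mode=config.mode, factor=config.factor,
            init_k=config.init_k, median_window=config.median_window,
        )
        write_results(params_df, out / "params.csv", "csv")
        meta["no_rolloff_samples"] = idx_df.attrs.get("no_rolloff", [])
    write_results(idx_df, out / "indices.csv", "csv")

    report = {"meta": meta}
    if cohort is not None or "group" in idx_df.columns:
        report.update(
            statistical_report(
                idx_df,
                ci_method=config.ci_method,
                B=config.bootstrap_B,
                alpha=config.alpha,
                seed=config.seed,
            )
        )
    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    (out / "summary.txt").write_text(_summary_text(idx_df, report))
    return report


def group_means(idx_df: pd.DataFrame) -> pd.DataFrame:
    """Observed per-group means of the three indices."""
    return idx_df.groupby("group")[list(INDEX_COLS)].mean()


def _summary_text(idx_df: pd.DataFrame, report: dict) -> str:
    lines = ["rfacurve run summary", "=" * 60]
    meta = report["meta"]
    lines.append(
        f"version {meta['tool_version']}  config {meta['config_hash']}  "
        f"mode {meta['rolloff_mode']}  seed {meta['seed']}"
    )
    lines.append(f"input: {meta['input']}")
    lines.append(f"samples: {len(idx_df)}")
    if "group" in idx_df.columns:
        gm = group_means(idx_df)
        lines.append("")
        lines.append("observed group means vs published reference (delta/dr/ar, %):")
        header = f"{'group':<10}" + "".join(
            f"{c + ' obs':>12}{c + ' ref':>12}" for c in INDEX_COLS
        )
        lines.append(header)
        for g in gm.index:
            row = f"{g:<10}"
            for c in INDEX_COLS:
                ref = reference.GROUP_MEANS[c].get(g, (float("nan"),) * 3)[0]
                row += f"{gm.loc[g, c]:>12.2f}{ref:>12.2f}"
            lines.append(row)
    return "\n".join(lines) + "\n"
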