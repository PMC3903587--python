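"""End-to-end orchestration: preprocess -> PLI -> graph metrics -> statistics.

A run is driven by a YAML config naming a manifest CSV (one row per
recording: file, subject_id, site_id, group, visit, rate, optionally
pp_exclude and memory_z). Stage outputs are plain CSV/JSON in the output
directory, plus a provenance file (config, seeds, library versions,
per-file epoch offsets) sufficient to reproduce the run bit for bit.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import PhaseLagIndex
from .metrics import measures_per_recording
from .preprocessing import (
    AverageReference,
    BandpassFilter,
    EpochSelector,
    detect_artifacts,
    read_eeg_ascii,
)
from .stats import TrajectoryMMRM, descriptive_table
from .types import DEFAULT_BANDS, BandDefinition

_KNOWN_KEYS = {
    "manifest", "output_dir", "labels", "epoch_len", "n_epochs",
    "amp_thresh_uv", "flat_run", "bands", "surrogates", "seed",
    "edge_trim", "filter_order", "average_order", "epoch_before_filter",
    "stats", "pp_column",
}
_KNOWN_STATS_KEYS = {"df_method", "pool_min_n"}


@dataclass
class PipelineConfig:
    manifest: Path
    output_dir: Path
    labels: list[str] | None = None
    epoch_len: int = 4096
    n_epochs: int = 4
    amp_thresh_uv: float = 100.0
    flat_run: int | None = None
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    surrogates: int = 50
    seed: int = 0
    edge_trim: int = 128
    filter_order: int = 4
    average_order: str = "measures"
    epoch_before_filter: bool = False
    df_method: str = "between_within"
    pool_min_n: int = 16
    pp_column: str = "pp_exclude"
    raw: dict = field(default_factory=dict)


class ConfigError(ValueError):
    pass


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default and schema-check a YAML pipeline config.

    Unknown keys are rejected with a closest-match suggestion; bands must
    have low < high; the manifest path must exist.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    for key in raw:
        if key not in _KNOWN_KEYS:
            hint = difflib.get_close_matches(key, _KNOWN_KEYS, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ConfigError(f"unknown config key {key!r}{suffix}")
    if "manifest" not in raw:
        raise ConfigError("config key 'manifest' is required")
    manifest = (path.parent / raw["manifest"]).resolve()
    if not manifest.exists():
        raise ConfigError(f"manifest not found: {manifest}")
    bands = DEFAULT_BANDS
    if "bands" in raw:
        parsed = []
        for b in raw["bands"]:
            try:
                band = BandDefinition(b["name"], float(b["low"]),
                                      float(b["high"]))
            except (KeyError, ValueError) as exc:
                raise ConfigError(
                    f"invalid band {b.get('name', '?')!r}: {exc}") from None
            parsed.append(band)
        bands = tuple(parsed)
    stats_raw = raw.get("stats", {}) or {}
    for key in stats_raw:
        if key not in _KNOWN_STATS_KEYS:
            hint = difflib.get_close_matches(key, _KNOWN_STATS_KEYS, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ConfigError(f"unknown stats config key {key!r}{suffix}")
    average_order = raw.get("average_order", "measures")
    if average_order not in ("measures", "matrix"):
        raise ConfigError("average_order must be 'measures' or 'matrix'")
    out = raw.get("output_dir", "plinet_run")
    return PipelineConfig(
        manifest=manifest,
        output_dir=(path.parent / out).resolve(),
        labels=raw.get("labels"),
        epoch_len=int(raw.get("epoch_len", 4096)),
        n_epochs=int(raw.get("n_epochs", 4)),
        amp_thresh_uv=float(raw.get("amp_thresh_uv", 100.0)),
        flat_run=raw.get("flat_run"),
        bands=bands,
        surrogates=int(raw.get("surrogates", 50)),
        seed=int(raw.get("seed", 0)),
        edge_trim=int(raw.get("edge_trim", 128)),
        filter_order=int(raw.get("filter_order", 4)),
        average_order=average_order,
        epoch_before_filter=bool(raw.get("epoch_before_filter", False)),
        df_method=stats_raw.get("df_method", "between_within"),
        pool_min_n=int(stats_raw.get("pool_min_n", 16)),
        pp_column=raw.get("pp_column", "pp_exclude"),
        raw=raw,
    )


def _derive_seed(master: int, *parts: str) -> int:
    digest = hashlib.sha256(
        ("/".join(map(str, parts)) + f"#{master}").encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _measure_one(rec, cfg: PipelineConfig, band: BandDefinition,
                 offsets: list[int]):
    from .types import Epoch

    bp = BandpassFilter(band.low_hz, band.high_hz, order=cfg.filter_order)
    if cfg.epoch_before_filter:
        epochs = [bp.transform(Epoch(data=rec.data[:, o:o + cfg.epoch_len],
                                     rate=rec.rate, offset=o,
                                     band=band.name))
                  for o in offsets]
    else:
        filt = bp.transform(rec)
        epochs = [Epoch(data=filt.data[:, o:o + cfg.epoch_len],
                        rate=rec.rate, offset=o, band=band.name)
                  for o in offsets]
    mats = PhaseLagIndex(edge_trim=cfg.edge_trim).transform(
        epochs, labels=rec.labels)
    seed = _derive_seed(cfg.seed, rec.subject_id or "?", rec.visit or "?",
                        band.name)
    return measures_per_recording(mats, n_surrogates=cfg.surrogates,
                                  seed=seed, average=cfg.average_order)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a summary dict (also written as JSON).

    Per-file failures are recorded and skipped; the returned dict carries
    a ``failures`` list that the CLI converts into a nonzero exit code.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(config.manifest)
    required = {"file", "subject_id", "site_id", "group", "visit", "rate"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise ConfigError(f"manifest missing columns: {sorted(missing_cols)}")

    failures: list[dict] = []
    measure_rows: list[dict] = []
    offsets_log: dict[str, list[int]] = {}
    base = config.manifest.parent
    for _, row in manifest.iterrows():
        fpath = base / row["file"]
        try:
            rec = read_eeg_ascii(fpath, rate=float(row["rate"]),
                                 labels=config.labels,
                                 subject_id=str(row["subject_id"]),
                                 visit=str(row["visit"]))
            rec = AverageReference().transform(rec)
            mask = detect_artifacts(rec, config.amp_thresh_uv,
                                    config.flat_run)
            selector = EpochSelector(n_epochs=config.n_epochs,
                                     epoch_len=config.epoch_len)
            epochs = selector.transform(rec, mask=mask)
            offsets = [e.offset for e in epochs]
            offsets_log[str(row["file"])] = offsets
            for band in config.bands:
                m = _measure_one(rec, config, band, offsets)
                rec_row = {
                    "subject_id": row["subject_id"],
                    "site_id": row["site_id"],
                    "group": row["group"],
                    "visit": row["visit"],
                    "band": band.name,
                    "epoch": "mean",
                    "cw": m.cw, "lw": m.lw,
                    "gamma": m.gamma, "lambda": m.lambda_,
                    "n_surrogates": m.n_surrogates, "seed": m.seed,
                    "rate": row["rate"],
                }
                for extra in ("pp_exclude", "memory_z"):
                    if extra in manifest.columns:
                        rec_row[extra] = row[extra]
                measure_rows.append(rec_row)
                if m.per_epoch:
                    for k, pe in enumerate(m.per_epoch):
                        sub = dict(rec_row)
                        sub.update(epoch=str(k), cw=pe.cw, lw=pe.lw,
                                   gamma=pe.gamma, **{"lambda": pe.lambda_},
                                   seed=pe.seed)
                        measure_rows.append(sub)
        except Exception as exc:  # noqa: BLE001 - per-file isolation
            failures.append({"file": str(row["file"]), "error": str(exc)})

    measures = pd.DataFrame(measure_rows)
    measures.to_csv(out / "measures.csv", index=False)

    summary_rows = []
    results: dict = {"failures": failures, "bands": {}}
    mean_rows = measures[measures["epoch"] == "mean"] if len(measures) else measures
    populations = {"ITT": mean_rows}
    if len(mean_rows) and config.pp_column in mean_rows.columns:
        populations["PP"] = mean_rows[~mean_rows[config.pp_column].astype(bool)]
    for popname, pop in populations.items():
        for band in config.bands:
            sub = pop[pop["band"] == band.name] if len(pop) else pop
            for outcome in ("gamma", "lambda"):
                col = "lambda" if outcome == "lambda" else outcome
                if not len(sub):
                    continue
                long = _to_longitudinal(sub, col)
                key = f"{popname}/{band.name}/{outcome}"
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est = TrajectoryMMRM(
                            pool_min_n=config.pool_min_n,
                            df_method=config.df_method,
                        ).fit(long)
                    r = est.result_
                    desc = descriptive_table(long)
                    for _, d in desc.iterrows():
                        summary_rows.append({
                            "population": popname, "band": band.name,
                            "measure": outcome, "group": d["group"],
                            "visit": d["visit"], "cell": d["cell"],
                            "trajectory_p": r.trajectory_p,
                            "endpoint_p": r.endpoint_p,
                        })
                    results["bands"][key] = {
                        "trajectory_F": r.trajectory_F,
                        "trajectory_df": list(r.trajectory_df),
                        "trajectory_p": r.trajectory_p,
                        "endpoint_t": r.endpoint_t,
                        "endpoint_p": r.endpoint_p,
                        "icc": r.icc,
                        "df_method": r.df_method,
                        "converged": r.converged,
                        "n_obs": r.n_obs, "n_subjects": r.n_subjects,
                    }
                except Exception as exc:  # noqa: BLE001
                    failures.append({"file": f"<stats:{key}>",
                                     "error": str(exc)})

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.csv", index=False)
    _write_markdown_summary(summary, out / "summary.md")
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    provenance = {
        "plinet_version": __version__,
        "config": {k: str(v) for k, v in config.raw.items()},
        "seed": config.seed,
        "bands": [[b.name, b.low_hz, b.high_hz] for b in config.bands],
        "filter": {"kind": "bandpass", "order": config.filter_order,
                   "zero_phase": True,
                   "filtered_before_epoching": not config.epoch_before_filter},
        "epoch_offsets": offsets_log,
        "versions": _library_versions(),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return results


def _to_longitudinal(measures: pd.DataFrame, outcome_col: str) -> pd.DataFrame:
    """Reshape per-recording measures into the tidy trial-stats layout."""
    df = measures.rename(columns={outcome_col: "outcome",
                                  "rate": "sample_rate_hz"})[
        ["subject_id", "site_id", "group", "visit", "outcome",
         "sample_rate_hz"] + (["memory_z"] if "memory_z" in measures else [])
    ].copy()
    base = df[df["visit"] == "baseline"].set_index("subject_id")["outcome"]
    df["baseline_value"] = df["subject_id"].map(base)
    return df


def _write_markdown_summary(summary: pd.DataFrame, path: Path) -> None:
    lines = ["# Trajectory summary (mean (SD) [n] per group and visit)", ""]
    if not len(summary):
        lines.append("(no results)")
    else:
        for (pop, band, meas), sub in summary.groupby(
                ["population", "band", "measure"]):
            lines.append(f"## {pop} / {band} / {meas}")
            lines.append("")
            lines.append("| group | baseline | wk12 | wk24 |")
            lines.append("|---|---|---|---|")
            for group, g in sub.groupby("group"):
                cells = {v: c for v, c in zip(g["visit"], g["cell"])}
                lines.append(
                    f"| {group} | {cells.get('baseline', '-')} | "
                    f"{cells.get('wk12', '-')} | {cells.get('wk24', '-')} |")
            tp = sub["trajectory_p"].iloc[0]
            ep = sub["endpoint_p"].iloc[0]
            lines.append("")
            lines.append(f"trajectory p = {tp:.4f}; endpoint p = {ep:.4f}")
            lines.append("")
    path.write_text("\n".join(lines))


def _library_versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
    }
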