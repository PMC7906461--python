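"""Study-directory orchestration: run every stage over conventional inputs.

A study directory holds the seven input streams under fixed names
(``peaks.csv``, ``moieties.csv``, ``uvvis_<sample>.csv``, ``eem_<sample>.csv``
+ ``eem_blank_<sample>.csv``, ``ftir_<sample>.csv``, ``gas.csv``,
``metadata.csv``). :func:`run_pipeline` runs whichever stages have inputs,
skips the rest with a warning, and writes per-stage CSV tables plus a run
log carrying the package version and a config hash, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assignment import AssignmentConfig, assign_peaklist, read_peaklist
from .chem import Formula
from .ftir import normalized_band_areas, read_ftir
from .gas import (
    RATIO_WINDOWS,
    IncubationSeries,
    VialGeometry,
    alpha_c,
    classify_pathway,
    co2_ch4_ratio,
    production_rate,
)
from .metrics import metrics_table, sample_summary
from .optics import (
    integrate_coble_peaks,
    peak_ratios,
    raman_normalize,
    read_absorbance,
    read_eem,
    remove_scatter,
    spectral_slope_ratio,
    suva254,
)
from .transforms import load_moiety_db, match_transforms, pairwise_differences, top_transforms

__all__ = ["StudyConfig", "run_pipeline", "summarize_by_group", "load_config"]

HABITATS = ("palsa", "bog", "fen")
DEPTHS = ("shallow", "deep")
TIMEPOINTS = ("field", "setup", "day0", "day25", "day50")

FLOAT_FMT = "%.6g"


@dataclass
class StudyConfig:
    study_dir: str
    out_dir: str
    seed: int = 0
    tolerance_ppm: float = 1.0
    ionization_mode: str = "negative"
    transform_tol_da: float = 0.001
    doc_mg_l: float = 12.5
    pathlength_m: float = 0.01
    headspace_volume_l: float = 0.085
    temperature_k: float = 291.15
    pressure_atm: float = 1.0
    peat_mass_gdw: float = 1.0

    def assignment_config(self) -> AssignmentConfig:
        return AssignmentConfig(
            tolerance_ppm=self.tolerance_ppm, ionization_mode=self.ionization_mode
        )

    def vial(self) -> VialGeometry:
        return VialGeometry(
            headspace_volume_l=self.headspace_volume_l,
            temperature_k=self.temperature_k,
            pressure_atm=self.pressure_atm,
            peat_mass_gdw=self.peat_mass_gdw,
        )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> StudyConfig:
    """Read a YAML (or JSON) study config."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return StudyConfig(**data)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def run_pipeline(config: StudyConfig) -> dict[str, Path]:
    """Run all available stages over a study directory.

    Returns a mapping of stage name -> written table path. Missing input
    streams skip their stage with a warning; any error inside a stage aborts
    with a stage-tagged message.
    """
    study = Path(config.study_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stages_run: list[str] = []

    def _stage(name: str):
        stages_run.append(name)

    # --- formula assignment + DOM metrics ---------------------------------
    peaks_path = study / "peaks.csv"
    per_sample_formulas: dict[str, set[Formula]] = {}
    if peaks_path.exists():
        try:
            _stage("assign")
            peaks = read_peaklist(peaks_path)
            table = assign_peaklist(peaks, config.assignment_config())
            path = out / "assignments.csv"
            table.to_csv(path, index=False, float_format="%.10g")
            written["assign"] = path

            _stage("dom_metrics")
            frames, summaries = [], []
            for sid, grp in table.groupby("sample_id"):
                formulas = {Formula.from_string(s) for s in grp.loc[grp["formula"] != "", "formula"]}
                per_sample_formulas[sid] = formulas
                frames.append(metrics_table(formulas, sample_id=str(sid)))
                summ = sample_summary(table, str(sid))
                summaries.append(asdict(summ))
            path = out / "formula_metrics.csv"
            _write(pd.concat(frames, ignore_index=True), path)
            written["dom_metrics"] = path
            path = out / "dom_summary.csv"
            _write(pd.DataFrame(summaries), path)
            written["dom_summary"] = path
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"[assign] stage failed: {exc}") from exc
    else:
        warnings.warn("peaks.csv missing; assignment and DOM metrics skipped", stacklevel=2)

    # --- transformation analysis ------------------------------------------
    moiety_path = study / "moieties.csv"
    if moiety_path.exists() and per_sample_formulas:
        try:
            _stage("transforms")
            db = load_moiety_db(moiety_path)
            count_rows, top_rows = [], []
            for sid, formulas in sorted(per_sample_formulas.items()):
                masses = sorted(f.mass for f in formulas)
                counts = match_transforms(
                    pairwise_differences(masses), db, tol_da=config.transform_tol_da, sample_id=sid
                )
                for name, k in counts.counts:
                    count_rows.append({"sample_id": sid, "moiety": name, "count": k})
                for rank, (name, pct) in enumerate(top_transforms(counts, k=5), start=1):
                    top_rows.append({"sample_id": sid, "rank": rank, "moiety": name, "percent": pct})
            path = out / "transform_counts.csv"
            _write(pd.DataFrame(count_rows), path)
            written["transforms"] = path
            path = out / "top_transforms.csv"
            _write(pd.DataFrame(top_rows), path)
            written["top_transforms"] = path
        except Exception as exc:
            raise RuntimeError(f"[transforms] stage failed: {exc}") from exc
    else:
        warnings.warn("moiety DB or assignments missing; transform stage skipped", stacklevel=2)

    # --- optics ------------------------------------------------------------
    uvvis_files = sorted(study.glob("uvvis_*.csv"))
    eem_files = sorted(p for p in study.glob("eem_*.csv") if not p.name.startswith("eem_blank"))
    if uvvis_files or eem_files:
        try:
            _stage("optics")
            rows = []
            sids = {p.stem.removeprefix("uvvis_") for p in uvvis_files}
            sids |= {p.stem.removeprefix("eem_") for p in eem_files}
            for sid in sorted(sids):
                row: dict = {"sample_id": sid}
                uv = study / f"uvvis_{sid}.csv"
                if uv.exists():
                    spec = read_absorbance(uv, pathlength_m=config.pathlength_m, doc_mg_l=config.doc_mg_l)
                    row["suva254"] = suva254(spec)
                    row["slope_ratio"] = spectral_slope_ratio(spec)
                eem_p, blank_p = study / f"eem_{sid}.csv", study / f"eem_blank_{sid}.csv"
                if eem_p.exists():
                    eem = remove_scatter(read_eem(eem_p))
                    if blank_p.exists():
                        eem = raman_normalize(eem, read_eem(blank_p))
                    areas = integrate_coble_peaks(eem)
                    row.update({f"peak_{k}": v for k, v in sorted(areas.items())})
                    row.update(
                        {k.replace("/", "_"): v for k, v in peak_ratios(areas).items()}
                    )
                rows.append(row)
            path = out / "optics_summary.csv"
            _write(pd.DataFrame(rows), path)
            written["optics"] = path
        except Exception as exc:
            raise RuntimeError(f"[optics] stage failed: {exc}") from exc
    else:
        warnings.warn("no UV-Vis or EEM inputs; optics stage skipped", stacklevel=2)

    # --- FTIR ---------------------------------------------------------------
    ftir_files = sorted(study.glob("ftir_*.csv"))
    if ftir_files:
        try:
            _stage("ftir")
            rows = []
            for p in ftir_files:
                sid = p.stem.removeprefix("ftir_")
                for res in normalized_band_areas(read_ftir(p)):
                    rows.append(
                        {"sample_id": sid, "band": res.band_center, "area_fraction": res.area_fraction}
                    )
            path = out / "ftir_fractions.csv"
            _write(pd.DataFrame(rows), path)
            written["ftir"] = path
        except Exception as exc:
            raise RuntimeError(f"[ftir] stage failed: {exc}") from exc
    else:
        warnings.warn("no FTIR inputs; FTIR stage skipped", stacklevel=2)

    # --- gas dynamics -------------------------------------------------------
    gas_path = study / "gas.csv"
    if gas_path.exists():
        try:
            _stage("gas")
            gas_df = pd.read_csv(gas_path)
            rate_rows, alpha_rows, ratio_rows = [], [], []
            for sid, grp in gas_df.groupby("sample_id"):
                series = IncubationSeries(
                    sample_id=str(sid), data=grp.drop(columns=["sample_id"]), vial=config.vial()
                )
                for gas_name in ("CO2", "CH4"):
                    for per_gdw, label in ((True, "per_gdw"), (False, "per_vial")):
                        r = production_rate(series, gas_name, per_gdw=per_gdw)
                        rate_rows.append(
                            {
                                "sample_id": sid,
                                "gas": gas_name,
                                "normalization": label,
                                "slope": r.slope,
                                "intercept": r.intercept,
                                "r_squared": r.r_squared,
                                "p_value": r.p_value,
                                "n_points": r.n_points,
                            }
                        )
                if {"d13_co2", "d13_ch4"} <= set(grp.columns):
                    sub = grp.dropna(subset=["d13_co2", "d13_ch4"])
                    if len(sub):
                        alphas = [alpha_c(a, b) for a, b in zip(sub["d13_co2"], sub["d13_ch4"])]
                        mean_alpha = float(np.mean(alphas))
                        alpha_rows.append(
                            {
                                "sample_id": sid,
                                "alpha_c": mean_alpha,
                                "pathway": classify_pathway(mean_alpha),
                                "n_points": len(alphas),
                            }
                        )
                for window in RATIO_WINDOWS:
                    days = grp["day"].to_numpy(float)
                    if not ((days >= window[0]) & (days <= window[1])).any():
                        continue
                    rw = co2_ch4_ratio(series, window)
                    ratio_rows.append(
                        {
                            "sample_id": sid,
                            "window": f"{window[0]:g}-{window[1]:g}",
                            "co2_ch4": rw.co2_ch4,
                            "n_points": rw.n_points,
                        }
                    )
            path = out / "gas_rates.csv"
            _write(pd.DataFrame(rate_rows), path)
            written["gas_rates"] = path
            path = out / "gas_alpha.csv"
            _write(pd.DataFrame(alpha_rows), path)
            written["gas_alpha"] = path
            path = out / "ratio_windows.csv"
            _write(pd.DataFrame(ratio_rows), path)
            written["ratio_windows"] = path
        except Exception as exc:
            raise RuntimeError(f"[gas] stage failed: {exc}") from exc
    else:
        warnings.warn("gas.csv missing; gas stage skipped", stacklevel=2)

    log = {
        "peatdom_version": __version__,
        "config": asdict(config),
        "config_hash": config.hash(),
        "stages_run": stages_run,
        "outputs": {k: str(v) for k, v in written.items()},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    written["run_log"] = out / "run_log.json"
    return written


def summarize_by_group(
    results: pd.DataFrame,
    metadata: pd.DataFrame,
    value_cols: list[str],
    group_cols: tuple[str, ...] = ("habitat", "depth", "timepoint"),
) -> pd.DataFrame:
    """Mean/sd/n of result columns by habitat × depth × timepoint.

    Replicates are averaged within groups as in field-vs-incubation layouts;
    single-member groups carry NaN standard deviations (flagged by n = 1).
    Row order of the input does not affect the output.
    """
    merged = results.merge(metadata, on="sample_id", how="inner")
    merged = merged.sort_values("sample_id", kind="mergesort")
    agg = merged.groupby(list(group_cols), sort=True)[value_cols].agg(["mean", "std", "count"])
    agg.columns = [f"{col}_{stat}" for col, stat in agg.columns]
    return agg.reset_index()
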