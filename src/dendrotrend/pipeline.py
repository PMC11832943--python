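"""End-to-end pipeline: rings + metadata + climate -> growth-decline report.

Stages run in method order — input parsing, core merging and cross-dating
validation, BAI reconstruction, chronology building with EPS/Rbar, PCA
trajectory groups, Mann-Kendall trends with damage thresholds, climate
departures, and bootstrapped climate-growth sensitivity with its
crown-damage dependence.  Every stage writes its tabular output into the run
directory and contributes to a versioned JSON report; any stage error aborts
with a stage-labeled diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chronology as chron_mod
from . import climate as climate_mod
from . import growth as growth_mod
from . import ringio
from . import sensitivity as sens_mod
from . import trajectories as traj_mod
from . import trends as trends_mod

__all__ = ["RunConfig", "StageError", "run_pipeline", "reproduce_replication",
            "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = "1.0"


class StageError(RuntimeError):
    """Pipeline failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """All paths, periods, thresholds and seeds of one pipeline run."""

    rings_path: str = ""
    metadata_path: str = ""
    climate_path: str = ""
    pca_period: tuple[int, int] = (1879, 2014)
    trend_period: tuple[int, int] = (1941, 2021)
    climate_period: tuple[int, int] = (1931, 2021)
    reference_period: tuple[int, int] = (1992, 2021)
    recent_window: tuple[int, int] = (2002, 2021)
    detrend_method: str = "mean_line"  # standardization for sensitivity
    n_boot: int = 1000
    seed: int = 0
    eps_threshold: float = 0.85
    crossdate_r: float = 0.32
    crossdate_t: float = 3.5
    min_sample_depth: int = 5
    rbar_min_overlap: int = 30
    bai_rescale: bool = False
    metadata_columns: dict | None = None
    loess_span: float = 0.75

    def __post_init__(self) -> None:
        for name in ("pca_period", "trend_period", "climate_period",
                     "reference_period", "recent_window"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well-ordered: {lo} > {hi}")
            setattr(self, name, (int(lo), int(hi)))
        if self.eps_threshold <= 0 or self.crossdate_r <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON (same schema)."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _read_rings(path: str) -> list[ringio.RingSeries]:
    if path.endswith(".rwl"):
        return ringio.read_rwl(path)
    return ringio.read_rings_csv(path)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages and write outputs plus ``report.json`` to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": _jsonable(asdict(config)),
    }

    # --- stage: ringio -----------------------------------------------------
    try:
        cores = _read_rings(config.rings_path)
        records = ringio.read_tree_metadata(
            config.metadata_path, columns=config.metadata_columns
        )
        stations = ringio.read_climate(config.climate_path)
        by_tree: dict[str, list[ringio.RingSeries]] = {}
        for c in cores:
            by_tree.setdefault(c.tree_id, []).append(c)
        trees = {tid: ringio.merge_cores_to_tree(cs)
                 for tid, cs in by_tree.items()}
        rec_by_id = {r.tree_id: r for r in records}
        missing = sorted(set(trees) - set(rec_by_id))
        if missing:
            raise ringio.RingIOError(f"no metadata for trees {missing}")
        report["n_cores"] = len(cores)
        report["n_trees"] = len(trees)
    except Exception as exc:  # noqa: BLE001
        raise StageError("ringio", str(exc)) from exc

    # --- stage: crossdating ------------------------------------------------
    try:
        normalized = {c.series_id: chron_mod.normalize_p2yrsl(c) for c in cores}
        xdate = []
        for c in cores:
            others = [v for k, v in normalized.items() if k != c.series_id]
            master = chron_mod.build_chronology(others, min_depth=1)
            master_ix = chron_mod.IndexSeries(
                "master", master.first_year, master.values
            )
            r, t, ok = chron_mod.crossdate_stats(
                normalized[c.series_id], master_ix,
                r_threshold=config.crossdate_r, t_threshold=config.crossdate_t,
            )
            xdate.append({"series_id": c.series_id, "r": r, "t": t, "pass": ok})
        xdate_df = pd.DataFrame(xdate)
        xdate_df.to_csv(outdir / "crossdating.csv", index=False)
        report["crossdating"] = {
            "n_pass": int(xdate_df["pass"].sum()),
            "n_total": len(xdate_df),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("crossdating", str(exc)) from exc

    # --- stage: growth -----------------------------------------------------
    try:
        bai: dict[str, growth_mod.BAISeries] = {}
        traits_rows = []
        for tid, series in sorted(trees.items()):
            rec = rec_by_id[tid]
            bai[tid] = growth_mod.bai_from_dbh(
                series, rec.dbh, rescale=config.bai_rescale
            )
            min_age, mean_rwl = growth_mod.series_summaries(series)
            rec.min_age = min_age
            hegyi = growth_mod.hegyi_index(rec) if rec.neighbors else np.nan
            rg_mean, rg_cv = growth_mod.recent_growth_stats(
                bai[tid], config.recent_window
            )
            traits_rows.append(
                {"tree_id": tid, "dbh": rec.dbh, "height": rec.height,
                 "min_age": min_age, "damage": rec.crown_damage,
                 "hegyi": hegyi, "mean_rwl": mean_rwl,
                 "recent_bai_mean": rg_mean, "recent_bai_cv": rg_cv}
            )
        traits = pd.DataFrame(traits_rows).set_index("tree_id")
        traits.to_csv(outdir / "tree_traits.csv")
        pd.DataFrame(
            [{"tree_id": t, "year": y, "bai_mm2": v}
             for t, b in bai.items() for y, v in zip(b.years, b.bai)]
        ).to_csv(outdir / "bai.csv", index=False)
        report["recent_growth"] = {
            "mean_bai_mm2": float(traits["recent_bai_mean"].mean()),
            "mean_cv": float(traits["recent_bai_cv"].mean()),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("growth", str(exc)) from exc

    # --- stage: chronology -------------------------------------------------
    try:
        rwi = {tid: chron_mod.detrend(s, "spline32")
               for tid, s in trees.items()}
        rwi_list = list(rwi.values())
        bai_list = [
            chron_mod.IndexSeries(t, b.first_year, b.bai)
            for t, b in bai.items()
        ]
        site_rwi = chron_mod.build_chronology(
            rwi_list, min_depth=config.min_sample_depth
        )
        site_bai = chron_mod.build_chronology(
            bai_list, min_depth=config.min_sample_depth
        )
        span = (site_rwi.first_reliable_year or site_rwi.first_year,
                site_rwi.last_year)
        stats_site = chron_mod.rbar_and_eps(
            rwi_list, span, min_overlap=config.rbar_min_overlap
        )
        report["chronology"] = {
            "site": {
                "rbar": stats_site.rbar, "eps": stats_site.eps,
                "n_trees": stats_site.n_trees, "period": list(span),
                "eps_adequate": bool(stats_site.eps > config.eps_threshold),
            }
        }
        _write_chron(site_bai, outdir / "chronology_site_bai.csv")
        _write_chron(site_rwi, outdir / "chronology_site_rwi.csv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("chronology", str(exc)) from exc

    # --- stage: trajectories -----------------------------------------------
    try:
        years_all = np.arange(
            min(b.first_year for b in bai.values()),
            max(b.last_year for b in bai.values()) + 1,
        )
        mat = pd.DataFrame(index=years_all, columns=sorted(bai), dtype=float)
        for tid, b in bai.items():
            mat.loc[b.years, tid] = b.bai
        modes = traj_mod.pca_growth_modes(mat, config.pca_period, k=2)
        assign = traj_mod.assign_to_mode(mat, modes)
        for tid, lab in assign.labels.items():
            rec_by_id[tid].group = lab
        traits["group"] = pd.Series(assign.labels)
        group_tests = traj_mod.compare_groups(
            traits[["dbh", "height", "min_age", "damage", "hegyi", "mean_rwl"]],
            assign.labels,
        )
        group_tests.to_csv(outdir / "group_trait_tests.csv")
        out = assign.correlations.copy()
        out["label"] = [assign.labels[str(t)] for t in out.index]
        out.to_csv(outdir / "group_assignment.csv")
        report["pca"] = {
            "var_explained": [float(v) for v in modes.var_explained],
            "sdevs": [float(v) for v in modes.sdevs],
            "period": list(config.pca_period),
            "groups": {
                lab: sorted(t for t, l2 in assign.labels.items() if l2 == lab)
                for lab in sorted(set(assign.labels.values()))
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("trajectories", str(exc)) from exc

    # --- stage: trends -----------------------------------------------------
    try:
        group_bai_chron: dict[str, chron_mod.Chronology] = {"site": site_bai}
        for lab in sorted(set(assign.labels.values())):
            members = [
                chron_mod.IndexSeries(t, bai[t].first_year, bai[t].bai)
                for t, l2 in assign.labels.items() if l2 == lab
            ]
            group_bai_chron[lab] = chron_mod.build_chronology(
                members, min_depth=1
            )
        taus_chron = {
            name: trends_mod.mann_kendall(ch, config.trend_period)
            for name, ch in group_bai_chron.items()
        }
        per_tree_tau = {
            tid: trends_mod.mann_kendall(
                b.bai, config.trend_period, first_year=b.first_year
            )
            for tid, b in bai.items()
        }
        tau_df = pd.DataFrame(
            [{"tree_id": t, "tau": tr.tau, "p": tr.p,
              "significant": tr.direction_significant}
             for t, tr in per_tree_tau.items()]
        )
        tau_df.to_csv(outdir / "tree_trends.csv", index=False)
        fits = {}
        for trait in ("dbh", "height", "min_age", "damage", "hegyi",
                      "mean_rwl"):
            vals = traits[trait]
            ok = vals.notna()
            try:
                fit = trends_mod.trait_trend_regression(
                    [per_tree_tau[t].tau for t in vals.index[ok]],
                    vals[ok].to_numpy(float), name=trait,
                )
            except trends_mod.TrendError as exc:
                fits[trait] = {"error": str(exc)}
                continue
            fits[trait] = {
                "slope": fit.slope, "intercept": fit.intercept, "p": fit.p,
                "r2": fit.r2, "zero_crossing": fit.zero_crossing,
            }
        thresholds = trends_mod.damage_thresholds(
            per_tree_tau, traits["damage"].to_dict()
        )
        turning = {}
        for name, ch in group_bai_chron.items():
            _, ty = trends_mod.loess_trend(ch, span=config.loess_span)
            turning[name] = ty
        report["trends"] = {
            "chronology_tau": {
                k: {"tau": v.tau, "p": v.p} for k, v in taus_chron.items()
            },
            "trait_fits": _jsonable(fits),
            "damage_thresholds": _jsonable(thresholds),
            "loess_turning_year": _jsonable(turning),
        }
        (outdir / "trait_fits.json").write_text(
            json.dumps(_jsonable(fits), indent=2, sort_keys=True)
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("trends", str(exc)) from exc

    # --- stage: climate ----------------------------------------------------
    try:
        dep_by_var: dict[str, climate_mod.ClimateDeparture] = {}
        for var in ("temperature", "precipitation"):
            deps = [
                climate_mod.standardize_station(t, config.reference_period)
                for t in stations if t.variable == var
            ]
            if not deps:
                raise climate_mod.ClimateError(f"no {var} stations")
            dep_by_var[var] = climate_mod.regional_mean(deps)
        dep_by_var["moisture_index"] = climate_mod.moisture_index(
            dep_by_var["temperature"], dep_by_var["precipitation"]
        )
        rows = []
        for var, dep in dep_by_var.items():
            for (y, m), v in dep.values.items():
                rows.append({"variable": var, "year": y, "month": m,
                             "value": v})
        pd.DataFrame(rows).to_csv(outdir / "climate_departures.csv",
                                  index=False)
        report["climate"] = {
            "n_temperature_stations": sum(
                1 for t in stations if t.variable == "temperature"),
            "n_precipitation_stations": sum(
                1 for t in stations if t.variable == "precipitation"),
            "reference_period": list(config.reference_period),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("climate", str(exc)) from exc

    # --- stage: sensitivity ------------------------------------------------
    try:
        std_chron: dict[tuple[str, str], chron_mod.Chronology] = {}
        for name in group_bai_chron:
            if name == "site":
                members_rings = list(trees.values())
                members_bai = list(bai.values())
            else:
                ids = [t for t, l2 in assign.labels.items() if l2 == name]
                members_rings = [trees[t] for t in ids]
                members_bai = [bai[t] for t in ids]
            for kind, members in (("RWL", members_rings), ("BAI", members_bai)):
                idx = [chron_mod.detrend(m, config.detrend_method)
                       for m in members]
                std_chron[(name, kind)] = chron_mod.build_chronology(
                    idx, min_depth=1
                )
        sens_rows = []
        monthly = {}
        for (name, kind), ch in sorted(std_chron.items()):
            for var, dep in dep_by_var.items():
                res = sens_mod.monthly_correlations(
                    ch, dep, config.climate_period, n_boot=config.n_boot,
                    seed=config.seed, input_kind=kind,
                )
                monthly[f"{name}/{kind}/{var}"] = res
                frame = res.to_frame()
                frame.insert(0, "chronology", name)
                frame.insert(1, "input", kind)
                frame.insert(2, "variable", var)
                sens_rows.append(frame)
        pd.concat(sens_rows).to_csv(outdir / "monthly_correlations.csv",
                                    index=False)

        per_tree = {}
        for tid in sorted(bai):
            std = chron_mod.detrend(bai[tid], config.detrend_method)
            tree_ch = chron_mod.Chronology(
                first_year=std.first_year, values=std.values,
                sample_depth=np.ones(len(std), dtype=int),
            )
            per_tree[tid] = {
                "djf_temperature": sens_mod.seasonal_sensitivity(
                    tree_ch, dep_by_var["temperature"], sens_mod.DJF_SLOTS,
                    config.climate_period),
                "djf_precipitation": sens_mod.seasonal_sensitivity(
                    tree_ch, dep_by_var["precipitation"], sens_mod.DJF_SLOTS,
                    config.climate_period),
                "jfm_moisture_index": sens_mod.seasonal_sensitivity(
                    tree_ch, dep_by_var["moisture_index"], sens_mod.JFM_SLOTS,
                    config.climate_period),
            }
        per_tree_df = pd.DataFrame(per_tree).T
        per_tree_df.index.name = "tree_id"
        per_tree_df.to_csv(outdir / "tree_seasonal_sensitivity.csv")

        gams = {}
        dmg = traits.loc[per_tree_df.index, "damage"].to_numpy(float)
        for col, label in (
            ("djf_temperature", "DJF temperature"),
            ("djf_precipitation", "DJF precipitation"),
            ("jfm_moisture_index", "JFM moisture index"),
        ):
            fit = sens_mod.damage_sensitivity_fit(
                per_tree_df[col].to_numpy(float), dmg, aggregate=label
            )
            gams[col] = {
                "deviance_explained": fit.deviance_explained,
                "p_smooth": fit.p_smooth, "edf": fit.edf,
            }
        report["sensitivity"] = {
            "significant_slots": {
                key: int(res.significant.sum())
                for key, res in monthly.items()
            },
            "damage_gams": _jsonable(gams),
            "n_boot": config.n_boot,
            "period": list(config.climate_period),
        }
        (outdir / "damage_gams.json").write_text(
            json.dumps(_jsonable(gams), indent=2, sort_keys=True)
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("sensitivity", str(exc)) from exc

    report_text = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    (outdir / "report.json").write_text(report_text)
    return report


def _write_chron(ch: chron_mod.Chronology, path: Path) -> None:
    pd.DataFrame(
        {"year": ch.years, "value": ch.values, "sample_depth": ch.sample_depth}
    ).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# Replication-data reproduction
# ---------------------------------------------------------------------------

def reproduce_replication(data_dir: str | Path, seed: int = 0) -> dict:
    """Recompute the headline stand statistics from a local copy of the
    deposited replication tables.

    Expects ``rings.csv`` (or ``rings.rwl``), ``trees.csv`` and
    ``climate.csv`` in ``data_dir`` with the default column schema (see
    :mod:`dendrotrend.ringio`; pass-through of a different schema requires a
    config).  Returns the site and group Mann-Kendall Taus (1941-2021), PC1
    variance explained, the Tau~damage zero crossing, the deviance explained
    of the DJF-temperature damage GAM, and mean crown damage.
    """
    data_dir = Path(data_dir)
    rings = data_dir / "rings.rwl"
    if not rings.exists():
        rings = data_dir / "rings.csv"
    cfg = RunConfig(
        rings_path=str(rings),
        metadata_path=str(data_dir / "trees.csv"),
        climate_path=str(data_dir / "climate.csv"),
        seed=seed,
    )
    report = run_pipeline(cfg, data_dir / "out")
    taus = report["trends"]["chronology_tau"]
    return {
        "tau_site": taus["site"]["tau"],
        "tau_pc1": taus.get("PC1", {}).get("tau"),
        "tau_pc2": taus.get("PC2", {}).get("tau"),
        "pc1_var_explained_pct": 100 * report["pca"]["var_explained"][0],
        "damage_zero_crossing": report["trends"]["damage_thresholds"][
            "tau_zero_crossing"],
        "gam_deviance_djf_temperature_pct": 100
        * report["sensitivity"]["damage_gams"]["djf_temperature"][
            "deviance_explained"],
        "mean_crown_damage": float(
            pd.read_csv(data_dir / "out" / "tree_traits.csv")["damage"].mean()
        ),
    }
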