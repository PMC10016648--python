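"""End-to-end pipeline: simulate/measure -> GC -> stats -> ASR.

A single YAML-style config drives the stages; every run writes its stage
outputs as CSV plus a JSON run report carrying the resolved config, the seed,
a QC summary and a content hash per output file, so a rerun with the same
config and inputs is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asr import BrownianAncestralModel, annotate_tree, read_newick
from .gc_content import add_gc_to_measurements
from .histograms import (
    Dye,
    StandardRef,
    measure_histogram,
    measurements_to_frame,
    read_histogram_tsv,
    write_histogram_tsv,
)
from .simulate import (
    BMSimConfig,
    HistogramSimConfig,
    simulate_histogram,
    simulate_tree_and_tips,
)
from .stats import (
    aggregate_species,
    gc_family_contrasts,
    kruskal_wallis,
    pairwise_mann_whitney_bonferroni,
    pearson_test,
    sex_differences,
    summaries_to_frame,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "orthoflow_out",
    "stages": ["simulate", "measure", "gc", "stats", "asr"],
    "standard": {"name": "Pisum sativum 'Ctirad'",
                 "genome_size_2C_pg": 9.09, "gc_percent": 38.50},
    "standard_window": [80.0, 120.0],
    "binding_length": 4,
    "qc": {"max_cv_percent": 5.0, "min_particles": 3000},
    "simulate": {"n_species": 4, "specimens_per_species": 2,
                 "ratio_range": [0.4, 4.0], "ratio_exclude": [0.8, 1.3],
                 "gc_range": [36.0, 43.0],
                 "standard_channel": 100.0, "n_bins": 1024,
                 "cv_at": 2.31, "cv_intercalating": 3.81,
                 "n_sample": 2000, "n_standard": 2000,
                 "asr_n_tips": 16, "asr_root_state": 6.19, "asr_sigma2": 1.0},
    "measure": {"manifest": None, "histogram_dir": None},
    "asr": {"tree": None, "traits": None},
}


def load_config(source) -> dict:
    """Merge a YAML file / mapping over the embedded defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if source is None:
        return cfg
    user = source if isinstance(source, dict) else yaml.safe_load(
        Path(source).read_text()) or {}
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _standard(cfg: dict) -> StandardRef:
    s = cfg["standard"]
    return StandardRef(s["name"], float(s["genome_size_2C_pg"]),
                       float(s["gc_percent"]))


def run_pipeline(config=None, out_dir: str | Path | None = None) -> dict:
    """Run the configured stages; returns the run report (also written as JSON).

    Stage failures propagate with the stage name; outputs written before the
    failure are retained and the report is written with a FAILED marker.
    """
    cfg = load_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    report = {"package": "orthoflow", "version": __version__,
              "python": platform.python_version(), "seed": cfg["seed"],
              "config": cfg, "stages_run": [], "outputs": {}, "qc": {},
              "results": {}, "status": "OK"}

    def register(path: Path):
        report["outputs"][path.name] = _sha256(path)

    state: dict = {}
    try:
        for stage in stages:
            logger.info("stage %s", stage)
            _STAGES[stage](cfg, out, state, report, register)
            report["stages_run"].append(stage)
    except Exception as exc:
        report["status"] = f"FAILED:{stages[len(report['stages_run'])]}"
        report["error"] = str(exc)
        _write_report(out, report)
        raise
    _write_report(out, report)
    return report


def _write_report(out: Path, report: dict):
    (out / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str))


def _stage_simulate(cfg, out, state, report, register):
    sim = cfg["simulate"]
    rng = np.random.default_rng(cfg["seed"])
    hist_dir = out / "histograms"
    hist_dir.mkdir(exist_ok=True)
    rows = []
    k = 0
    for i in range(int(sim["n_species"])):
        species = f"simsp_{i + 1}"
        gc = float(rng.uniform(*sim["gc_range"]))
        for j in range(int(sim["specimens_per_species"])):
            specimen = f"{species}_sp{j + 1}"
            # a sample peak on top of the standard peak is unmeasurable;
            # real campaigns choose the standard to avoid coincidence
            lo_x, hi_x = sim.get("ratio_exclude", (0.8, 1.3))
            ratio = float(rng.uniform(*sim["ratio_range"]))
            while lo_x < ratio < hi_x:
                ratio = float(rng.uniform(*sim["ratio_range"]))
            sex = "F" if j % 2 == 0 else "M"
            for dye, cv in ((Dye.INTERCALATING, sim["cv_intercalating"]),
                            (Dye.AT_SELECTIVE, sim["cv_at"])):
                # the AT-dye peak shifts with base composition; fold the
                # binding-length factor into the simulated ratio
                from .gc_content import forward_dye_ratio
                std = _standard(cfg)
                factor = 1.0 if dye is Dye.INTERCALATING else forward_dye_ratio(
                    1.0 - gc / 100.0, std.at_fraction, int(cfg["binding_length"]))
                h = simulate_histogram(HistogramSimConfig(
                    standard_channel=float(sim["standard_channel"]),
                    true_ratio=ratio * factor, cv_sample=float(cv),
                    cv_standard=float(cv), n_sample=int(sim["n_sample"]),
                    n_standard=int(sim["n_standard"]),
                    n_bins=int(sim["n_bins"]),
                    seed=int(cfg["seed"]) * 100003 + k), dye=dye)
                k += 1
                fname = f"{specimen}__{dye.value}.tsv"
                write_histogram_tsv(h, hist_dir / fname)
                register(hist_dir / fname)
                rows.append({"specimen_id": specimen, "species": species,
                             "sex": sex, "dye": dye.value,
                             "path": f"histograms/{fname}",
                             "true_ratio": ratio, "true_gc": gc})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    register(out / "manifest.csv")
    state["manifest"] = manifest
    state["manifest_base"] = out


def _stage_measure(cfg, out, state, report, register):
    if "manifest" in state:
        manifest, base = state["manifest"], state["manifest_base"]
    else:
        mpath = cfg["measure"]["manifest"]
        if mpath is None:
            raise FileNotFoundError("measure stage needs a manifest")
        manifest = pd.read_csv(mpath)
        base = Path(cfg["measure"]["histogram_dir"] or Path(mpath).parent)
    std = _standard(cfg)
    lo, hi = cfg["standard_window"]
    qc = cfg["qc"]
    measurements = []
    for _, r in manifest.iterrows():
        hist = read_histogram_tsv(Path(base) / r["path"], dye=r["dye"],
                                  specimen_id=r["specimen_id"],
                                  species=r["species"], sex=r["sex"])
        hist.meta.update({"specimen_id": r["specimen_id"],
                          "species": r["species"], "sex": r["sex"]})
        measurements.append(measure_histogram(
            hist, std, (float(lo), float(hi)),
            max_cv_percent=float(qc["max_cv_percent"]),
            min_particles=float(qc["min_particles"])))
    df = measurements_to_frame(measurements)
    df.to_csv(out / "measurements.csv", index=False)
    register(out / "measurements.csv")
    n_flagged = int((df["qc_flags"] != "").sum())
    report["qc"] = {"n_measurements": int(len(df)),
                    "n_flagged": n_flagged,
                    "n_passed": int(len(df)) - n_flagged}
    state["measurements"] = df


def _stage_gc(cfg, out, state, report, register):
    df = state.get("measurements")
    if df is None:
        df = pd.read_csv(out / "measurements.csv").fillna({"qc_flags": ""})
    df = add_gc_to_measurements(df, _standard(cfg), int(cfg["binding_length"]))
    df.to_csv(out / "measurements_gc.csv", index=False)
    register(out / "measurements_gc.csv")
    state["measurements"] = df


def _stage_stats(cfg, out, state, report, register):
    df = state.get("measurements")
    if df is None:
        df = pd.read_csv(out / "measurements_gc.csv")
    summaries = aggregate_species(df)
    sdf = summaries_to_frame(summaries)
    sdf.to_csv(out / "species_summaries.csv", index=False)
    register(out / "species_summaries.csv")
    results = {}
    deltas = sex_differences(summaries)
    if deltas:
        ddf = pd.DataFrame([{"species": d.species, "delta_pg": d.delta_pg,
                             "provenance": d.provenance.value} for d in deltas])
        ddf.to_csv(out / "sex_differences.csv", index=False)
        register(out / "sex_differences.csv")
        males = sdf.set_index("species")["mean_1C_male_pg"]
        if len(ddf) >= 3 and males.loc[ddf["species"]].notna().all():
            pr = pearson_test(males.loc[ddf["species"]].to_numpy(),
                              ddf["delta_pg"].to_numpy())
            results["pearson_delta_vs_male"] = {"r": pr.statistic,
                                                "p": pr.p_value}
    by_2n = sdf.dropna(subset=["male_2n", "mean_1C_male_pg"])
    if by_2n["male_2n"].nunique() >= 2:
        kw = kruskal_wallis(zip(by_2n["male_2n"].astype(int),
                                by_2n["mean_1C_male_pg"]))
        results["kruskal_wallis_by_2n"] = {"H": kw.statistic, "df": kw.df,
                                           "p": kw.p_value}
        try:
            mat = pairwise_mann_whitney_bonferroni(
                zip(by_2n["male_2n"].astype(int), by_2n["mean_1C_male_pg"]))
            mat.to_csv(out / "pairwise_mw_by_2n.csv")
            register(out / "pairwise_mw_by_2n.csv")
        except Exception as exc:
            logger.warning("pairwise MW skipped: %s", exc)
    fam_col = "family" if "family" in df.columns else None
    if fam_col and "gc_percent" in df.columns:
        per = [(r[fam_col], r.get("sex", ""), r["gc_percent"])
               for _, r in df.iterrows() if pd.notna(r["gc_percent"])]
        if len({f for f, _, _ in per}) >= 2:
            contrasts = gc_family_contrasts(per)
            contrasts.summary.to_csv(out / "gc_family_summary.csv", index=False)
            register(out / "gc_family_summary.csv")
            results["gc_anova"] = {"F": contrasts.anova.statistic,
                                   "p": contrasts.anova.p_value}
    report["results"]["stats"] = results
    state["summaries"] = sdf


def _stage_asr(cfg, out, state, report, register):
    asr_cfg = cfg["asr"]
    if asr_cfg["tree"]:
        phy = read_newick(asr_cfg["tree"])
        traits = pd.read_csv(asr_cfg["traits"])
        model = BrownianAncestralModel.from_dataframe(phy, traits)
    else:
        sim = cfg["simulate"]
        phy, tips = simulate_tree_and_tips(BMSimConfig(
            n_tips=int(sim["asr_n_tips"]), root_state=float(sim["asr_root_state"]),
            sigma2=float(sim["asr_sigma2"]), seed=int(cfg["seed"]) + 7919))
        model = BrownianAncestralModel(phy, tips)
    res = model.fit()
    res.node_estimates.to_csv(out / "asr_nodes.csv", index=False)
    register(out / "asr_nodes.csv")
    newick, _ = annotate_tree(model.phylogeny, res)
    (out / "asr_annotated.nwk").write_text(newick)
    register(out / "asr_annotated.nwk")
    report["results"]["asr"] = {"root_estimate": res.root_estimate,
                                "sigma2_hat": res.sigma2_hat,
                                "n_tips": model.phylogeny.n_tips}


_STAGES = {"simulate": _stage_simulate, "measure": _stage_measure,
           "gc": _stage_gc, "stats": _stage_stats, "asr": _stage_asr}
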