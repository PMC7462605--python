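"""Pipeline orchestration: simulate → ranging → covariates → fit → report.

Each stage reads and writes only its documented delimited files, so stages
can be re-run independently on real-format CSVs or on synthetic output.
A run manifest (JSON) records the config snapshot, seeds, SHA-256 hashes
of every stage output, stage timings, and warnings, so a re-run with the
same config and seed reproduces the hashes of all deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import association, model, spatial, synthetic

logger = logging.getLogger(__name__)

__all__ = ["tally_hunts", "run_pipeline", "RunManifest",
            "ranging_stage", "covariates_stage", "fit_stage", "report_text"]

PREY = list(synthetic.PREY_CATEGORIES)
STAGES = ("simulate", "ranging", "covariates", "fit", "report")

REQUIRED_COLUMNS = {
    "relocations.csv": ["group_id", "timestamp", "x_km", "y_km"],
    "individuals.csv": ["individual_id", "group_id", "sex"],
    "scans.csv": ["scan_id", "timestamp", "individual_id"],
    "hunts.csv": ["hunt_id", "timestamp", "x_km", "y_km", "prey",
                  "catcher_group", "success"],
}


def tally_hunts(hunts):
    """Group × prey counts of successful hunts, with margins.

    Returns ``(successes, attempts_total)``: a DataFrame of successful
    hunt counts per catcher group and prey category including row/column
    totals, and the count of unsuccessful attempt records. Unknown prey
    labels are an error listing the offending rows.
    """
    if len(hunts) == 0:
        tab = pd.DataFrame(0, index=["Total"], columns=PREY + ["Total"])
        return tab, 0
    bad = ~hunts["prey"].isin(PREY)
    if bad.any():
        raise ValueError(
            "unknown prey label(s) in rows "
            f"{hunts.index[bad].tolist()}: "
            f"{sorted(hunts.loc[bad, 'prey'].unique())}")
    success = hunts[hunts["success"].astype(int) == 1]
    attempts = int((hunts["success"].astype(int) == 0).sum())
    tab = pd.crosstab(success["catcher_group"], success["prey"])
    tab = tab.reindex(columns=PREY, fill_value=0)
    tab["Total"] = tab.sum(axis=1)
    tab.loc["Total"] = tab.sum(axis=0)
    tab.index.name = "group"
    return tab, attempts


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_csv(path, name):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required input file missing: {path}")
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS.get(name, [])) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    files: dict = dataclasses.field(default_factory=dict)
    timings: dict = dataclasses.field(default_factory=dict)
    warnings: list = dataclasses.field(default_factory=list)

    def record(self, stage, paths, elapsed):
        self.timings[stage] = round(elapsed, 3)
        for p in paths:
            self.files[str(Path(p).name)] = _sha256(p)

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


# -- stages --------------------------------------------------------------

def ranging_stage(relocations, hunts, out_dir, isopleths=(50, 95),
                  cell_km=0.1):
    """Fit both groups' UDs on a common grid; write grids, GeoJSON
    contours, overlap summary, and per-hunt usage scores."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = sorted(relocations["group_id"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups in relocations, got {groups}")
    xy = relocations[["x_km", "y_km"]].to_numpy()
    pad = 3 * max(xy[:, 0].std(), xy[:, 1].std())
    bounds = (xy[:, 0].min() - pad, xy[:, 0].max() + pad,
              xy[:, 1].min() - pad, xy[:, 1].max() + pad)
    uds, written = {}, []
    for g in groups:
        ud = spatial.fit_kde(relocations[relocations["group_id"] == g],
                             cell_size=cell_km, group_id=g, grid_bounds=bounds)
        uds[g] = ud
        grid_path = out / f"ud_{g}.csv"
        ud.to_frame().to_csv(grid_path, index=False)
        gj_path = out / f"contours_{g}.geojson"
        spatial.write_geojson(spatial.region_to_geojson(ud, isopleths), gj_path)
        written += [grid_path, gj_path]
    fa, fb, shared = spatial.overlap_fraction(uds[groups[0]], uds[groups[1]])
    summary = {
        "groups": groups,
        "area_km2_95": {g: uds[g].area(95) for g in groups},
        "area_km2_50": {g: uds[g].area(50) for g in groups},
        "overlap_fraction_95": {groups[0]: fa, groups[1]: fb},
        "shared_area_km2_95": shared,
    }
    with open(out / "ranging_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    written.append(out / "ranging_summary.json")
    usage = spatial.usage_difference(hunts, uds)
    usage.to_csv(out / "usage_scores.csv", index=False)
    written.append(out / "usage_scores.csv")
    return uds, usage, summary, written


def covariates_stage(scans, hunts, individuals, usage_scores, out_dir,
                     same_group_only=False):
    """Yearly SRI matrices and the per-hunt model covariate table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    years = sorted(pd.to_datetime(scans["timestamp"]).dt.year.unique())
    written = []
    sri_by_year = {}
    for y in years:
        sri = association.compute_sri(scans, int(y))
        sri_by_year[int(y)] = sri
        p = out / f"sri_{y}.csv"
        sri.to_long().to_csv(p, index=False)
        written.append(p)
    cov = association.hunt_party_covariates(
        hunts, scans, individuals, sri_by_year, usage_scores=usage_scores,
        same_group_only=same_group_only)
    p = out / "hunt_covariates.csv"
    cov.to_csv(p, index=False)
    written.append(p)
    return cov, sri_by_year, written


def fit_stage(covariates, out_dir, chains=4, iterations=2000, warmup=1000,
              seed=0, prior_scale=2.5, prior_df=3.0):
    """Fit the categorical prey model and write summaries and draws."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fit = model.fit_categorical(
        covariates.drop(columns=[c for c in ("hunt_id", "is_intergroup")
                                 if c in covariates.columns]),
        "prey", chains=chains, iterations=iterations, warmup=warmup,
        seed=seed, prior_scale=prior_scale, prior_df=prior_df)
    written = []
    summ = fit.summary()
    summ.to_csv(out / "fit_summary.csv", index=False)
    written.append(out / "fit_summary.csv")
    probs = []
    for gv, gname in enumerate([fit.group_levels_.get(0), fit.group_levels_.get(1)]
                               if hasattr(fit, "group_levels_") else [0, 1]):
        p = fit.predict_group_probs(gv)
        p.insert(0, "group", gname)
        probs.append(p)
    pd.concat(probs, ignore_index=True).to_csv(out / "predicted_probs.csv",
                                               index=False)
    written.append(out / "predicted_probs.csv")
    draws = fit.draws_.reshape(-1, fit._k1 * len(fit.terms_))
    cols = [f"{cat}:{t}" for cat in fit.classes_[1:] for t in fit.terms_]
    pd.DataFrame(draws, columns=cols).to_csv(
        out / "posterior_draws.csv.gz", index=False, compression="gzip")
    written.append(out / "posterior_draws.csv.gz")
    return fit, written


def report_text(fit, tally, attempts):
    """Plain-text report: hunt tallies and a coefficient table."""
    lines = ["Successful hunts by group and prey", str(tally),
             f"Hunt attempts (unsuccessful): {attempts}", "",
             "Categorical prey model (reference: "
             f"{fit.classes_[0]}), posterior mean [95% CI]"]
    for row in fit.summary().itertuples(index=False):
        lines.append(f"  {row.category:>10s} {row.term:<22s}"
                     f"{row.estimate:8.2f}  [{row.ci_low:6.2f}, "
                     f"{row.ci_high:6.2f}]  Rhat {row.rhat:.3f}")
    lines.append("")
    lines.append("convergence: " + ("clean" if fit.converged_
                                    else "Rhat above threshold"))
    return "\n".join(lines)


def run_pipeline(config=None, out_dir="pipeline_out", data_dir=None,
                 stop_after=None, chains=4, iterations=2000, warmup=1000,
                 prior_scale=2.5):
    """Execute the full pipeline; synthetic mode when ``config`` is given,
    otherwise reads real-format CSVs from ``data_dir``.

    Returns the :class:`RunManifest`, which is also written to
    ``manifest.json`` in ``out_dir``.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is not None:
        cfg_dict = dataclasses.asdict(config)
        seed = config.seed
    else:
        cfg_dict = {"data_dir": str(data_dir)}
        seed = 0
    manifest = RunManifest(config=cfg_dict, seed=seed)

    t0 = time.perf_counter()
    if config is not None:
        result = synthetic.simulate(config)
        synthetic.write_outputs(result, out)
        manifest.record("simulate",
                        [out / f for f in ("relocations.csv", "individuals.csv",
                                           "scans.csv", "hunts.csv",
                                           "truth.json")],
                        time.perf_counter() - t0)
        relocations, individuals = result.relocations, result.individuals
        scans, hunts = result.scans, result.hunts
    else:
        src = Path(data_dir)
        relocations = _read_csv(src / "relocations.csv", "relocations.csv")
        individuals = _read_csv(src / "individuals.csv", "individuals.csv")
        scans = _read_csv(src / "scans.csv", "scans.csv")
        hunts = _read_csv(src / "hunts.csv", "hunts.csv")
        manifest.timings["simulate"] = 0.0
    if stop_after == "simulate":
        manifest.write(out / "manifest.json")
        return manifest

    t0 = time.perf_counter()
    uds, usage, summary, written = ranging_stage(relocations, hunts, out)
    manifest.record("ranging", written, time.perf_counter() - t0)
    if stop_after == "ranging":
        manifest.write(out / "manifest.json")
        return manifest

    t0 = time.perf_counter()
    cov, sri_by_year, written = covariates_stage(scans, hunts, individuals,
                                                 usage, out)
    manifest.record("covariates", written, time.perf_counter() - t0)
    if stop_after == "covariates":
        manifest.write(out / "manifest.json")
        return manifest

    t0 = time.perf_counter()
    successes = hunts[hunts["success"].astype(int) == 1]
    fit, written = fit_stage(cov[cov["hunt_id"].isin(successes["hunt_id"])],
                             out, chains=chains, iterations=iterations,
                             warmup=warmup, seed=seed,
                             prior_scale=prior_scale)
    if not fit.converged_:
        manifest.warnings.append(
            f"fit convergence: max Rhat {float(fit.rhat_.max()):.4f}")
    manifest.record("fit", written, time.perf_counter() - t0)
    if stop_after == "fit":
        manifest.write(out / "manifest.json")
        return manifest

    t0 = time.perf_counter()
    tally, attempts = tally_hunts(hunts)
    report = report_text(fit, tally, attempts)
    with open(out / "report.txt", "w") as fh:
        fh.write(report + "\n")
    manifest.record("report", [out / "report.txt"], time.perf_counter() - t0)
    manifest.write(out / "manifest.json")
    return manifest
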