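"""Pipeline orchestration: staged artifacts, manifest, reproducible seeds.

Every stage reads its inputs from the output directory written by earlier
stages, so running stages individually through the CLI composes to the
same artifacts as one ``run_pipeline`` call.  All randomness flows from
the root seed through named substreams, and the manifest records a sha256
per artifact so reruns can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from contactrsf import contact_rsf as crsf
from contactrsf import contacts as contacts_mod
from contactrsf import ctmm, rsf
from contactrsf.config import RunConfig
from contactrsf.errors import ContactRSFError, InsufficientDataError
from contactrsf.homerange import kde_homerange, overlap_index, overlap_region
from contactrsf.landscape import EnvStack, write_ascii_grid
from contactrsf.synthfix import SimTruth, gen_landscape, sim_population
from contactrsf.tracks import Trajectory, read_tracks_csv, write_tracks_csv

log = logging.getLogger("contactrsf")

STAGES = [
    "simulate",
    "fit_ctmm",
    "interpolate",
    "detect_contacts",
    "classify_pairs",
    "filter_pairs",
    "individual_rsf",
    "select_model",
    "contact_rsf",
    "aggregate",
    "compare",
]


class StageError(ContactRSFError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(root_seed: int, stage: str) -> np.random.SeedSequence:
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(h,))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _params_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _update_manifest(out: Path, cfg: RunConfig, stage: str, files: list[Path], status="complete"):
    mpath = out / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {"stages": {}}
    manifest["config_hash"] = _params_hash(cfg)
    manifest["seed"] = cfg.seed
    manifest["stages"][stage] = {
        "status": status,
        "params_hash": _params_hash(cfg),
        "artifacts": {str(f.relative_to(out)): _sha256(f) for f in files if f.exists()},
    }
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# per-stage helpers


def _env(cfg: RunConfig, out: Path) -> EnvStack:
    if (out / "env" / "manifest.json").exists():
        return EnvStack.read_dir(out / "env")
    if cfg.env_manifest:
        return EnvStack.read_dir(cfg.env_manifest)
    raise InsufficientDataError("no environment stack available; run simulate or set env_manifest")


def _tracks(out: Path, name: str) -> list[Trajectory]:
    return read_tracks_csv(out / name)


def _itracks(out: Path, cfg: RunConfig) -> dict[str, Trajectory]:
    tracks = {}
    for t in read_tracks_csv(out / "itracks.csv"):
        t.regular = True
        t.interval_min = cfg.interval_min
        tracks[t.animal_id] = t
    return tracks


def _sexes(cfg: RunConfig, out: Path) -> dict[str, str]:
    if (out / "truth.json").exists():
        return SimTruth.load(out / "truth.json").sexes
    return dict(cfg.sexes)


def _layers(cfg: RunConfig) -> list[str]:
    seen: list[str] = []
    for f in cfg.candidate_formulas:
        for c in f:
            if c not in seen:
                seen.append(c)
    return seen


def _load_datasets(out: Path, cfg: RunConfig) -> list[rsf.UseAvailableDataset]:
    df = pd.read_csv(out / "ind_datasets.csv", parse_dates=["date"])
    std = json.loads((out / "ind_standardizers.json").read_text())
    meta = {c for c in ("owner", "used", "x", "y", "date")}
    covs = [c for c in df.columns if c not in meta]
    out_ds = []
    for owner, sub in df.groupby("owner", sort=True):
        out_ds.append(
            rsf.UseAvailableDataset(
                owner=str(owner),
                data=sub.drop(columns=["owner"]).reset_index(drop=True),
                covariates=covs,
                standardizers={k: tuple(v) for k, v in std[str(owner)].items()},
                ratio=cfg.ratio,
            )
        )
    return out_ds


def _pair_window_hr(itracks, aid, window, cfg, grid):
    sub = itracks[aid].window(*window)
    return sub, kde_homerange(
        np.column_stack([sub.x, sub.y]),
        grid,
        isopleth_levels=tuple(cfg.isopleths),
        animal_id=aid,
        window=window,
    )


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    files: list[Path] = []
    if cfg.tracks_csv:
        tracks = read_tracks_csv(cfg.tracks_csv)
        files.append(write_tracks_csv(tracks, out / "tracks.csv"))
        if cfg.env_manifest:
            env = EnvStack.read_dir(cfg.env_manifest)
            files.append(env.write_dir(out / "env"))
        return files
    sc = cfg.simulate
    seed = int(stage_seed(cfg.seed, "simulate").generate_state(1)[0])
    env = gen_landscape(
        sc.extent_m, sc.cell_size_m, sc.n_days, sc.n_food_sites, seed=seed
    )
    tracks, truth = sim_population(
        env,
        n_groups=sc.n_groups,
        animals_per_group=sc.animals_per_group,
        tau_p_min=sc.tau_p_min,
        sigma_m2=sc.sigma_m2,
        fix_interval_min=sc.fix_interval_min,
        n_days=sc.n_days,
        attraction_coeffs=dict(sc.attraction_coeffs),
        seed=seed + 1,
        gps_error_sd=sc.gps_error_sd,
        meetings_per_day=sc.meetings_per_day,
        site_mode=sc.site_mode,
    )
    files.append(env.write_dir(out / "env"))
    files.append(write_tracks_csv(tracks, out / "tracks.csv"))
    truth.save(out / "truth.json")
    files.append(out / "truth.json")
    env_files = sorted((out / "env").glob("*.asc"))
    return files + env_files


def stage_fit_ctmm(cfg: RunConfig, out: Path) -> list[Path]:
    tracks = _tracks(out, "tracks.csv")
    models = {}
    for tr in tracks:
        m = ctmm.select_movement_model(tr)
        models[tr.animal_id] = m.to_dict()
        log.info("fit_ctmm %s -> %s (AIC %.1f)", tr.animal_id, m.family, m.aic)
    path = out / "models.json"
    path.write_text(json.dumps(models, indent=1, sort_keys=True))
    return [path]


def stage_interpolate(cfg: RunConfig, out: Path) -> list[Path]:
    tracks = _tracks(out, "tracks.csv")
    models = json.loads((out / "models.json").read_text())
    try:
        env = _env(cfg, out)
        xmin, ymin, xmax, ymax = env.grid.extent
        pad = 0.5 * env.grid.cell_size
    except InsufficientDataError:
        env = None
    itracks = []
    for tr in tracks:
        model = ctmm.MovementModel.from_dict(models[tr.animal_id])
        it = ctmm.interpolate(tr, model, interval_min=cfg.interval_min)
        if env is not None:
            # smoother overshoot past the landscape edge is clipped back on
            np.clip(it.x, xmin + pad, xmax - pad, out=it.x)
            np.clip(it.y, ymin + pad, ymax - pad, out=it.y)
        itracks.append(it)
    return [write_tracks_csv(itracks, out / "itracks.csv")]


def stage_detect_contacts(cfg: RunConfig, out: Path) -> list[Path]:
    itracks = _itracks(out, cfg)
    ids = sorted(itracks)
    events = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if contacts_mod.temporal_intersection(itracks[a], itracks[b]) is None:
                continue
            events.extend(contacts_mod.detect_contacts(itracks[a], itracks[b], cfg.buffer_m))
    events.sort(key=lambda e: (e.pair, e.timestamp))
    return [contacts_mod.write_contacts_csv(events, out / "contacts.csv")]


def stage_classify_pairs(cfg: RunConfig, out: Path) -> list[Path]:
    itracks = _itracks(out, cfg)
    env = _env(cfg, out)
    sexes = _sexes(cfg, out)
    events = contacts_mod.read_contacts_csv(out / "contacts.csv")
    counts: dict[tuple[str, str], int] = {}
    for e in events:
        counts[e.pair] = counts.get(e.pair, 0) + 1
    ids = sorted(itracks)
    records = []
    core_level = min(cfg.isopleths)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            window = contacts_mod.temporal_intersection(itracks[a], itracks[b])
            if window is None:
                continue
            try:
                rec = contacts_mod.classify_pair(
                    itracks[a],
                    itracks[b],
                    sexes,
                    env.grid,
                    core_isopleth=core_level,
                    overlap_threshold=cfg.overlap_threshold,
                    min_consecutive_weeks=cfg.min_consecutive_weeks,
                )
            except InsufficientDataError:
                # short records: classify on the whole joint window instead
                _, hr_a = _pair_window_hr(itracks, a, window, cfg, env.grid)
                _, hr_b = _pair_window_hr(itracks, b, window, cfg, env.grid)
                ov = overlap_index(hr_a, hr_b, core_level)
                rec = contacts_mod.PairRecord(
                    pair=contacts_mod.canonical_pair(a, b),
                    dyad_class="".join(sorted((sexes[a].upper(), sexes[b].upper()))),
                    relationship="within" if ov > cfg.overlap_threshold else "between",
                    window=window,
                    weekly_overlap={"full-window": ov},
                )
            rec.n_contacts = counts.get(rec.pair, 0)
            # count only contacts inside the analysis window
            if rec.window != window:
                rec.n_contacts = sum(
                    1
                    for e in events
                    if e.pair == rec.pair and rec.window[0] <= e.timestamp <= rec.window[1]
                )
            records.append(rec)
    return [contacts_mod.write_pair_records(records, out / "pairs.jsonl")]


def stage_filter_pairs(cfg: RunConfig, out: Path) -> list[Path]:
    records = contacts_mod.read_pair_records(out / "pairs.jsonl")
    kept = contacts_mod.filter_pairs(records, min_contacts=cfg.min_contacts)
    return [contacts_mod.write_pair_records(kept, out / "pairs_filtered.jsonl")]


def stage_individual_rsf(cfg: RunConfig, out: Path) -> list[Path]:
    itracks = _itracks(out, cfg)
    env = _env(cfg, out)
    kept = contacts_mod.read_pair_records(out / "pairs_filtered.jsonl")
    layers = _layers(cfg)
    rng_root = stage_seed(cfg.seed, "individual_rsf")
    frames = []
    standardizers = {}
    datasets = []
    for rec in kept:
        for aid in rec.pair:
            sub, hr = _pair_window_hr(itracks, aid, rec.window, cfg, env.grid)
            owner = f"{aid}|{rec.pair[0]}-{rec.pair[1]}"
            owner_key = int.from_bytes(hashlib.sha256(owner.encode()).digest()[:4], "big")
            seed = int(
                np.random.SeedSequence(
                    entropy=rng_root.entropy, spawn_key=rng_root.spawn_key + (owner_key,)
                ).generate_state(1)[0]
            )
            ds = rsf.build_individual_dataset(
                sub, hr, env, ratio=cfg.ratio, seed=seed, layers=layers,
                owner=owner, hr_level=max(cfg.isopleths),
            )
            datasets.append(ds)
            frame = ds.data.copy()
            frame.insert(0, "owner", owner)
            frames.append(frame)
            standardizers[owner] = {k: list(v) for k, v in ds.standardizers.items()}
    if not datasets:
        raise InsufficientDataError("no pairs left after filtering")
    pd.concat(frames, ignore_index=True).to_csv(out / "ind_datasets.csv", index=False)
    (out / "ind_standardizers.json").write_text(json.dumps(standardizers, indent=1, sort_keys=True))
    retained = rsf.screen_collinearity(datasets, threshold=cfg.collinearity_threshold)
    (out / "screen.json").write_text(
        json.dumps({"retained": retained, "threshold": cfg.collinearity_threshold}, indent=1)
    )
    return [out / "ind_datasets.csv", out / "ind_standardizers.json", out / "screen.json"]


def _screened_candidates(cfg: RunConfig, retained: list[str]) -> list[list[str]]:
    seen = set()
    candidates = []
    for f in cfg.candidate_formulas:
        cut = [c for c in f if c in retained]
        key = tuple(cut)
        if cut and key not in seen:
            seen.add(key)
            candidates.append(cut)
    return candidates


def stage_select_model(cfg: RunConfig, out: Path) -> list[Path]:
    datasets = _load_datasets(out, cfg)
    retained = json.loads((out / "screen.json").read_text())["retained"]
    candidates = _screened_candidates(cfg, retained)
    top, table = rsf.select_model(candidates, datasets)
    cv_seed = int(stage_seed(cfg.seed, "select_model").generate_state(1)[0])
    models = {}
    for i, ds in enumerate(datasets):
        m = rsf.fit_rsf(ds, top)
        entry = m.to_dict()
        try:
            cv = rsf.crossvalidate(ds, top, k=cfg.cv_folds, n_bins=cfg.cv_bins, seed=cv_seed + i)
            entry["cv_mean_rs"] = cv.mean_rs
            entry["cv_fold_rs"] = cv.fold_rs
        except ContactRSFError:
            entry["cv_mean_rs"] = None
        models[ds.owner] = entry
    (out / "selection.json").write_text(
        json.dumps(
            {"top_formula": top, "table": table.to_dict(orient="records")},
            indent=1,
            sort_keys=True,
        )
    )
    (out / "ind_models.json").write_text(json.dumps(models, indent=1, sort_keys=True))
    return [out / "selection.json", out / "ind_models.json"]


def stage_contact_rsf(cfg: RunConfig, out: Path) -> list[Path]:
    itracks = _itracks(out, cfg)
    env = _env(cfg, out)
    kept = contacts_mod.read_pair_records(out / "pairs_filtered.jsonl")
    events = contacts_mod.read_contacts_csv(out / "contacts.csv")
    top = json.loads((out / "selection.json").read_text())["top_formula"]
    layers = _layers(cfg)
    rng_root = stage_seed(cfg.seed, "contact_rsf")
    models = {}
    frames = []
    for i, rec in enumerate(kept):
        a, b = rec.pair
        _, hr_a = _pair_window_hr(itracks, a, rec.window, cfg, env.grid)
        _, hr_b = _pair_window_hr(itracks, b, rec.window, cfg, env.grid)
        poly = overlap_region(hr_a, hr_b, max(cfg.isopleths))
        seed = int(
            np.random.SeedSequence(
                entropy=rng_root.entropy, spawn_key=rng_root.spawn_key + (i,)
            ).generate_state(1)[0]
        )
        ds = crsf.build_contact_dataset(
            rec, events, itracks, poly, env, ratio_cap=cfg.ratio, seed=seed, layers=layers
        )
        m = crsf.fit_contact_rsf(ds, top)
        entry = m.to_dict()
        entry["n_contacts"] = rec.n_contacts
        models[ds.owner] = entry
        frame = ds.data.copy()
        frame.insert(0, "owner", ds.owner)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(out / "contact_datasets.csv", index=False)
    (out / "contact_models.json").write_text(json.dumps(models, indent=1, sort_keys=True))
    return [out / "contact_models.json", out / "contact_datasets.csv"]


def _model_from_entry(entry: dict) -> rsf.RSFModel:
    fields = {k: entry[k] for k in (
        "owner", "formula", "coef", "se", "loglik", "k", "aic",
        "n_used", "n_available", "converged", "penalized",
    )}
    return rsf.RSFModel(**fields)


def stage_aggregate(cfg: RunConfig, out: Path) -> list[Path]:
    ind_entries = json.loads((out / "ind_models.json").read_text())
    con_entries = json.loads((out / "contact_models.json").read_text())
    ind_models = [_model_from_entry(e) for e in ind_entries.values()]
    # pair-participation count per animal (owner format "animal|pair")
    pair_counts: dict[str, int] = {}
    for owner in ind_entries:
        aid = owner.split("|")[0]
        pair_counts[aid] = pair_counts.get(aid, 0) + 1
    if cfg.weights_mode == "murtaugh_product":
        counts = {o: float(pair_counts[o.split("|")[0]]) for o in ind_entries}
        sizes = None  # defaults to each model's used-point count
    elif cfg.weights_mode == "sum":
        counts = None
        sizes = {
            o: float(pair_counts[o.split("|")[0]]) + e["n_used"] for o, e in ind_entries.items()
        }
    else:  # inverse_variance
        counts = None
        sizes = {
            o: 1.0 / max(float(np.mean([v**2 for v in e["se"].values()])), 1e-12)
            for o, e in ind_entries.items()
        }
    pop_ind = rsf.aggregate_population(ind_models, owner_pair_counts=counts, owner_sample_sizes=sizes)
    con_models = [_model_from_entry(e) for e in con_entries.values()]
    con_counts = {o: float(e["n_contacts"]) for o, e in con_entries.items()}
    pop_con = crsf.aggregate_contact_population(con_models, con_counts)
    pop_ind.save(out / "population_individual.json")
    pop_con.save(out / "population_contact.json")
    return [out / "population_individual.json", out / "population_contact.json"]


def pooled_standardizers(out: Path) -> dict[str, tuple[float, float]]:
    std = json.loads((out / "ind_standardizers.json").read_text())
    pooled: dict[str, list] = {}
    for owner in std.values():
        for name, (mean, sd) in owner.items():
            pooled.setdefault(name, []).append((mean, sd))
    return {
        name: (float(np.mean([m for m, _ in v])), float(np.mean([s for _, s in v])))
        for name, v in pooled.items()
    }


def stage_compare(cfg: RunConfig, out: Path) -> list[Path]:
    env = _env(cfg, out)
    pop_ind = json.loads((out / "population_individual.json").read_text())
    pop_con = json.loads((out / "population_contact.json").read_text())

    def as_pop(d):
        return rsf.PopulationRSF(
            covariates=d["covariates"],
            beta=np.array(d["beta"]),
            se=np.array(d["se"]),
            ci_low=np.array(d["ci_low"]),
            ci_high=np.array(d["ci_high"]),
            weights=d["weights"],
            n_owners=d["n_owners"],
        )

    date = cfg.compare_date or env.days[0].isoformat()
    std = pooled_standardizers(out)
    report = crsf.compare_rsf(as_pop(pop_con), as_pop(pop_ind), env, date, std)
    report.save(out / "comparison.json")
    (out / "comparison.txt").write_text(report.to_text() + "\n")
    s_i = rsf.predict_surface(as_pop(pop_ind), env, date, std)
    s_c = rsf.predict_surface(as_pop(pop_con), env, date, std)
    write_ascii_grid(out / "surface_individual.asc", s_i, env.grid)
    write_ascii_grid(out / "surface_contact.asc", s_c, env.grid)
    return [
        out / "comparison.json",
        out / "comparison.txt",
        out / "surface_individual.asc",
        out / "surface_contact.asc",
    ]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit_ctmm": stage_fit_ctmm,
    "interpolate": stage_interpolate,
    "detect_contacts": stage_detect_contacts,
    "classify_pairs": stage_classify_pairs,
    "filter_pairs": stage_filter_pairs,
    "individual_rsf": stage_individual_rsf,
    "select_model": stage_select_model,
    "contact_rsf": stage_contact_rsf,
    "aggregate": stage_aggregate,
    "compare": stage_compare,
}


def run_stage(cfg: RunConfig, stage: str) -> dict:
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        files = _STAGE_FUNCS[stage](cfg, out)
    except Exception as exc:
        _update_manifest(out, cfg, stage, [], status="failed")
        raise StageError(stage, exc) from exc
    return _update_manifest(out, cfg, stage, [Path(f) for f in files])


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order; returns the final artifact manifest."""
    cfg.validate()
    manifest = {}
    for stage in STAGES:
        log.info("running stage %s", stage)
        manifest = run_stage(cfg, stage)
    return manifest
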