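"""End-to-end orchestration: simulate -> footprints -> dedupe -> group ->
segment -> perception -> sample-size demo -> count models -> report.

Stages communicate only via files (CSV / GeoJSON / JSON) so any stage can be
re-run standalone on user data with the same schemas. A run manifest records
the config hash, master seed, per-stage wall time and output digests;
rerunning with the same config and seed reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from skystrip import geometry
from skystrip.config import SurveyConfig
from skystrip.count_models import backward_select, fit_to_dict, fit_tweedie, fit_ztp
from skystrip.perception import (
    ModelSpec,
    default_candidates,
    estimate_to_dict,
    select_model,
)
from skystrip.samplesize import Scenario, results_to_frame, run_scenario
from skystrip.segments import build_segments, segments_to_long
from skystrip.sightings import (
    build_reviewer_histories,
    deduplicate_imagery,
    group_imagery_individuals,
    histories_to_frame,
    match_double_observer,
    merge_observer_groups,
)
from skystrip.synthetic_data import _cameras, simulate_survey


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_hash(config: SurveyConfig) -> str:
    import dataclasses

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def footprints_from_images(images: pd.DataFrame, config: SurveyConfig) -> dict:
    """image_id -> ImageFootprint for every telemetry row."""
    cams = _cameras(config)
    out = {}
    for r in images.itertuples():
        pose = geometry.Pose(
            r.easting, r.northing, r.altitude, r.pitch, r.roll, r.azimuth, r.time
        )
        out[r.image_id] = geometry.image_footprint(
            pose, cams[r.camera_id], image_id=r.image_id, camera_id=r.camera_id
        )
    return out


def coverage_report(
    images: pd.DataFrame, footprints: dict, config: SurveyConfig
) -> pd.DataFrame:
    """Per-transect coverage stats: forward-lap, width, side-lap, area."""
    rows = []
    for t_idx, sub in images.groupby("transect_id"):
        fwd = []
        widths = []
        unions = {}
        for cam, cam_sub in sub.groupby("camera_id"):
            cam_sub = cam_sub.sort_values("time")
            fps = [footprints[i] for i in cam_sub.image_id]
            widths += [geometry.min_bounding_width(f) for f in fps]
            fwd += [
                geometry.forward_overlap(a, b) for a, b in zip(fps, fps[1:])
            ]
            unions[cam], _ = geometry.dissolve_coverage(fps)
        side = (
            geometry.side_overlap(unions["north"], unions["south"])
            if len(unions) == 2
            else float("nan")
        )
        total, area = geometry.dissolve_coverage(list(unions.values()))
        rows.append(
            dict(
                transect_id=int(t_idx),
                n_images=len(sub),
                mean_forward_lap=float(np.mean(fwd)) if fwd else float("nan"),
                sd_forward_lap=float(np.std(fwd, ddof=1)) if len(fwd) > 1 else float("nan"),
                mean_width_m=float(np.mean(widths)),
                side_lap=side,
                dissolved_area_km2=area / 1e6,
            )
        )
    return pd.DataFrame(rows)


def _imagery_area_fn(images: pd.DataFrame, footprints: dict, config: SurveyConfig):
    """Per-transect dissolved coverage, cut lazily by segment chainage."""
    unions = {}
    for t_idx, sub in images.groupby("transect_id"):
        unions[int(t_idx)], _ = geometry.dissolve_coverage(
            [footprints[i] for i in sub.image_id]
        )

    def area_fn(t_idx: int, start: float, end: float) -> float:
        cov = unions[int(t_idx)]
        origin = (int(t_idx) * config.transect_spacing, 0.0)
        return geometry.cut_by_segments(cov, origin, 0.0, [start, end])[0]

    return area_fn


def run_all(config: SurveyConfig, out_dir, seed: int | None = None) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = config.seed if seed is None else seed
    manifest = {
        "config_hash": _config_hash(config),
        "master_seed": master,
        "stages": [],
    }
    report: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception as err:  # noqa: BLE001 - name the failing stage
            raise RuntimeError(f"stage '{name}' failed: {err}") from err
        elapsed = time.perf_counter() - t0
        digests = {p.name: _digest(p) for p in outputs}
        manifest["stages"].append(
            {"name": name, "wall_s": round(elapsed, 3), "outputs": digests}
        )
        return outputs

    # 1. simulate ----------------------------------------------------------
    tables = {}

    def _simulate():
        nonlocal tables
        tables = simulate_survey(config, seed=master, out_dir=out)
        return sorted(out.glob("*.csv")) + [out / "transects.geojson", out / "config.yaml"]

    stage("simulate", _simulate)

    # 2. footprints --------------------------------------------------------
    footprints = {}

    def _footprints():
        nonlocal footprints
        footprints = footprints_from_images(tables["images"], config)
        feats = [
            {
                "type": "Feature",
                "properties": {"image_id": f.image_id, "camera_id": f.camera_id},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(c) for c in f.corners] + [list(f.corners[0])]],
                },
            }
            for f in footprints.values()
        ]
        with open(out / "footprints.geojson", "w") as fh:
            json.dump(
                {
                    "type": "FeatureCollection",
                    "metadata": {"crs": "local planar metres"},
                    "features": feats,
                },
                fh,
            )
        cov = coverage_report(tables["images"], footprints, config)
        cov.to_csv(out / "coverage.csv", index=False)
        report["coverage"] = cov.to_dict(orient="records")
        return [out / "footprints.geojson", out / "coverage.csv"]

    stage("footprints", _footprints)

    # 3. dedupe + group ----------------------------------------------------
    groups_obs = pd.DataFrame()
    groups_img = pd.DataFrame()
    obs_histories = []
    rev_histories = []

    def _sightings():
        nonlocal groups_obs, groups_img, obs_histories, rev_histories
        dets = tables["detections"]
        dets = dets[dets.certainty == "certain"] if not dets.empty else dets
        # unique animals: union over reviewers, deduped across frames
        if not dets.empty:
            pooled = dets.drop_duplicates(
                subset=["truth_group_id", "member_index", "image_id"]
            )
            deduped, links = deduplicate_imagery(pooled, footprints)
            deduped.to_csv(out / "detections_deduped.csv", index=False)
            links.to_csv(out / "links.csv", index=False)
            groups_img = group_imagery_individuals(deduped)
            if not groups_img.empty:
                groups_img["transect_id"] = (
                    (groups_img.centroid_e / config.transect_spacing).round().astype(int)
                )
                groups_img["chainage"] = groups_img.centroid_n
            # reviewer histories on per-reviewer deduped detections
            per_rev = []
            for rid, rsub in dets.groupby("reviewer_id"):
                rded, _ = deduplicate_imagery(rsub, footprints)
                rded = rded.drop_duplicates(subset=["individual_id"]).copy()
                rded["reviewer_id"] = rid
                per_rev.append(rded)
            rev_histories = build_reviewer_histories(pd.concat(per_rev))
        calls = tables["calls"]
        if not calls.empty:
            hists = []
            for (side,), sub in calls.groupby(["side"]):
                front = sub[sub.seat == "front"]
                back = sub[sub.seat == "back"]
                side_h = match_double_observer(front, back)
                hists.extend(side_h)
            obs_histories = hists
            # observer groups from plotted member positions (zone centres in
            # real data; here the generated positions stand in)
            uniq = calls.drop_duplicates(subset=["truth_group_id", "member_index"])
            base = pd.DataFrame(
                dict(
                    group_id=np.arange(len(uniq)),
                    size=1,
                    centroid_e=uniq.easting.to_numpy(),
                    centroid_n=uniq.northing.to_numpy(),
                )
            )
            groups_obs = merge_observer_groups(base)
            if not groups_obs.empty:
                groups_obs["transect_id"] = (
                    (groups_obs.centroid_e / config.transect_spacing).round().astype(int)
                )
                groups_obs["chainage"] = groups_obs.centroid_n
        groups = pd.concat(
            [g for g in (groups_obs, groups_img) if not g.empty], ignore_index=True
        ) if (not groups_obs.empty or not groups_img.empty) else pd.DataFrame()
        if not groups.empty:
            groups.drop(
                columns=[c for c in ("member_individuals", "merged_from") if c in groups],
                errors="ignore",
            ).to_csv(out / "groups.csv", index=False)
        else:
            pd.DataFrame().to_csv(out / "groups.csv", index=False)
        histories_to_frame(obs_histories).to_csv(out / "histories_observer.csv", index=False)
        histories_to_frame(rev_histories).to_csv(out / "histories_reviewer.csv", index=False)
        return [
            out / "groups.csv",
            out / "histories_observer.csv",
            out / "histories_reviewer.csv",
        ]

    stage("sightings", _sightings)

    # 4. segments ----------------------------------------------------------
    seg_table = pd.DataFrame()

    def _segments():
        nonlocal seg_table
        obs_area = lambda t, s, e: geometry.observer_effective_area(  # noqa: E731
            e - s,
            config.observer_target_altitude,
            config.observer_strip_widths,
            config.observer_target_altitude,
        )
        img_area = _imagery_area_fn(tables["images"], footprints, config)
        seg_table = build_segments(
            tables["visibility"],
            tables["track"],
            tables["cloud"],
            tables["glitter"],
            groups_obs,
            groups_img,
            obs_area,
            img_area,
        )
        seg_table.to_csv(out / "segments.csv", index=False)
        report["segments"] = {
            "n_segments": len(seg_table),
            "total_observer_count": int(seg_table.count_observer.sum()),
            "total_imagery_count": int(seg_table.count_imagery.sum()),
        }
        return [out / "segments.csv"]

    stage("segments", _segments)

    # 5. perception --------------------------------------------------------
    def _perception():
        perc = {}
        if len(obs_histories) >= 10:
            fits = select_model(
                obs_histories, default_candidates(2, with_sides=True)
            )
            perc["observer"] = [estimate_to_dict(f) for f in fits]
        if len(rev_histories) >= 10:
            fits = select_model(rev_histories, default_candidates(3))
            perc["imagery"] = [estimate_to_dict(f) for f in fits]
        with open(out / "perception.json", "w") as fh:
            json.dump(perc, fh, indent=1)
        report["perception"] = perc
        return [out / "perception.json"]

    stage("perception", _perception)

    # 6. sample-size demo --------------------------------------------------
    def _samplesize():
        rng = np.random.default_rng(master + 17)
        results = []
        for n_det in (25, 50, 100, 200):
            sc = Scenario(2, (0.7, 0.7), n_det, n_reps=100,
                          seed=int(rng.integers(0, 2**31 - 1)))
            results.append(run_scenario(sc))
        frame = results_to_frame(results)
        frame.to_csv(out / "scenarios.csv", index=False)
        report["samplesize_demo"] = frame.to_dict(orient="records")
        return [out / "scenarios.csv"]

    stage("samplesize", _samplesize)

    # 7. count models ------------------------------------------------------
    def _models():
        models = {}
        long = segments_to_long(seg_table)
        long = long[long.area > 0].copy()
        usable = (
            not long.empty
            and long["count"].sum() > 0
            and long.platform.nunique() == 2
        )
        if usable:
            long["area_km2"] = long.area / 1e6
            terms = ["platform", "sea_state"]
            if long.visibility.nunique() > 1:
                terms.append("visibility")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit, path = backward_select(
                    long, "count", terms, fit_tweedie, power=1.5,
                    offset_col="area_km2",
                )
            models["individual_counts"] = fit_to_dict(fit)
            models["individual_counts"]["selection_path"] = path
            sizes = []
            for r in long.itertuples():
                if isinstance(r.sizes, str) and r.sizes:
                    for s in r.sizes.split(";"):
                        sizes.append(dict(size=int(s), platform=r.platform))
            szdf = pd.DataFrame(sizes)
            if len(szdf) >= 10 and szdf.platform.nunique() == 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    zfit = fit_ztp(szdf, "size", ["platform"])
                models["group_size"] = fit_to_dict(zfit)
        with open(out / "models.json", "w") as fh:
            json.dump(models, fh, indent=1)
        report["models"] = models
        return [out / "models.json"]

    stage("count_models", _models)

    # 8. report ------------------------------------------------------------
    def _report():
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        lines = ["# Survey run report", ""]
        lines.append("## Coverage (per transect)")
        for row in report.get("coverage", []):
            lines.append(
                f"- transect {row['transect_id']}: {row['n_images']} images, "
                f"forward-lap {row['mean_forward_lap']:.2f}, "
                f"width {row['mean_width_m']:.1f} m, "
                f"side-lap {row['side_lap']:.3f}, "
                f"area {row['dissolved_area_km2']:.2f} km2"
            )
        seg = report.get("segments", {})
        lines += [
            "",
            "## Counts",
            f"- segments: {seg.get('n_segments', 0)}",
            f"- observer individuals: {seg.get('total_observer_count', 0)}",
            f"- imagery individuals: {seg.get('total_imagery_count', 0)}",
            "",
            "## Perception",
        ]
        for platform, fits in report.get("perception", {}).items():
            best = fits[0]
            p_str = ", ".join(f"{p:.3f}" for p in best["p_hat"])
            lines.append(
                f"- {platform}: best model {best['model']} "
                f"(AICc {best['AICc']:.1f}); p = [{p_str}]; "
                f"combined {best['p_d']:.3f} (SE {best['se_d']:.3f})"
            )
        with open(out / "report.md", "w") as fh:
            fh.write("\n".join(lines) + "\n")
        return [out / "report.json", out / "report.md"]

    stage("report", _report)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
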