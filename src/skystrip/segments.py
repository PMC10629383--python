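"""Constant-visibility transect segments: the count-model sample units.

Transects are split into maximal runs of constant water-visibility score;
each segment carries per-platform sampled areas, mean sea state, platform-
specific mean glitter, cloud okta (and its binary form) and per-platform
tallies of unique, certain sightings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TransectSegment:
    flight_id: int
    transect_id: int
    segment_id: int
    start: float
    end: float
    visibility: int
    area_observer: float = np.nan
    area_imagery: float = np.nan
    mean_sea_state: float = np.nan
    glitter_observer: float = np.nan
    glitter_imagery: float = np.nan
    cloud_okta: float = np.nan
    cloud_binary: int = 0
    count_observer: int = 0
    count_imagery: int = 0
    groups_observer: list = field(default_factory=list)
    groups_imagery: list = field(default_factory=list)

    @property
    def length(self) -> float:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("segment length must be > 0")
        if self.visibility not in (1, 2, 3, 4):
            raise ValueError("visibility category must be in {1,2,3,4}")


def segment_by_visibility(scores: pd.DataFrame) -> list[tuple[float, float, int]]:
    """Maximal runs of constant visibility along one transect.

    `scores` must have `chainage`-ordered rows with a `visibility` column;
    either per-image point scores or (start_chainage, end_chainage) runs.
    Returns (start, end, visibility) tuples covering the scored extent.
    """
    if scores.empty:
        raise ValueError("no visibility scores supplied")
    if {"start_chainage", "end_chainage"} <= set(scores.columns):
        runs = scores.sort_values("start_chainage")
        merged: list[list] = []
        for r in runs.itertuples():
            if merged and merged[-1][2] == r.visibility and abs(merged[-1][1] - r.start_chainage) < 1e-9:
                merged[-1][1] = r.end_chainage
            else:
                merged.append([r.start_chainage, r.end_chainage, int(r.visibility)])
        return [tuple(m) for m in merged]
    sc = scores.sort_values("chainage").reset_index(drop=True)
    chain = sc.chainage.to_numpy(dtype=float)
    vis = sc.visibility.to_numpy(dtype=int)
    # boundaries at midpoints between adjacent images with different scores
    bounds = [float(chain[0])]
    out = []
    cur = vis[0]
    for i in range(1, len(vis)):
        if vis[i] != cur:
            mid = (chain[i - 1] + chain[i]) / 2.0
            out.append((bounds[-1], mid, int(cur)))
            bounds.append(mid)
            cur = vis[i]
    out.append((bounds[-1], float(chain[-1]), int(cur)))
    return out


def mean_sea_state(track: pd.DataFrame, start: float, end: float) -> float:
    """Mean Beaufort score of GPS track fixes with chainage in [start, end)."""
    inside = track[(track.chainage >= start) & (track.chainage < end)]
    if inside.empty:
        warnings.warn("no track points in segment; sea state missing", stacklevel=2)
        return float("nan")
    return float(inside.sea_state.mean())


def mean_glitter(
    scores: pd.DataFrame, start: float, end: float, platform: str
) -> float:
    """Mean ordinal glitter {0..3} in the segment, per platform convention.

    Observers: track-fix scores (`glitter_observer` column). Imagery: scores
    of north-camera images only — rows carrying a `camera_id` other than
    'north' are rejected.
    """
    if platform == "observer":
        col = "glitter_observer"
    elif platform == "imagery":
        if "camera_id" in scores.columns and (scores.camera_id != "north").any():
            raise ValueError("imagery glitter must come from north-camera images")
        col = "glitter"
    else:
        raise ValueError("platform must be 'observer' or 'imagery'")
    inside = scores[(scores.chainage >= start) & (scores.chainage < end)]
    if inside.empty:
        warnings.warn("no glitter scores in segment", stacklevel=2)
        return float("nan")
    return float(inside[col].mean())


def cloud_binary(okta: float, threshold: float = 0.0) -> int:
    """0 for clear sky (okta <= threshold, default okta = 0), else 1."""
    if not 0 <= okta <= 8:
        raise ValueError("okta must be in [0, 8]")
    return 0 if okta <= threshold else 1


def tally_segment(
    groups: pd.DataFrame, start: float, end: float, chainage_col: str = "centroid_n"
) -> tuple[int, int, list[int]]:
    """(individual count, group count, sizes) for groups whose centroid
    chainage falls in [start, end)."""
    if groups.empty:
        return 0, 0, []
    inside = groups[(groups[chainage_col] >= start) & (groups[chainage_col] < end)]
    sizes = [int(s) for s in inside["size"]]
    return int(sum(sizes)), len(sizes), sizes


def build_segments(
    visibility: pd.DataFrame,
    track: pd.DataFrame,
    cloud: pd.DataFrame,
    image_glitter: pd.DataFrame,
    groups_observer: pd.DataFrame,
    groups_imagery: pd.DataFrame,
    area_observer_fn,
    area_imagery_fn,
    flight_id: int = 0,
    cloud_threshold: float = 0.0,
) -> pd.DataFrame:
    """Assemble the segments table for one flight.

    `area_*_fn(transect_id, start, end) -> m^2` supply per-platform sampled
    areas (observer: altitude-corrected strip area; imagery: dissolved
    footprint coverage cut to the segment). Group membership is by centroid
    chainage; observer groups use a `chainage` column when present,
    otherwise northing.
    """
    rows = []
    seg_id = 0
    okta_by_transect = dict(zip(cloud.transect_id, cloud.okta))
    for t_idx, vis_t in visibility.groupby("transect_id"):
        track_t = track[track.transect_id == t_idx]
        gl_t = image_glitter[image_glitter.transect_id == t_idx]
        okta = float(okta_by_transect.get(t_idx, np.nan))
        for start, end, vis in segment_by_visibility(vis_t):
            sea = mean_sea_state(track_t, start, end)
            if np.isnan(sea) and not track_t.empty:
                # impute from the nearest fix (short segment between fixes)
                j = (track_t.chainage - (start + end) / 2).abs().idxmin()
                sea = float(track_t.loc[j, "sea_state"])
            g_obs = mean_glitter(track_t, start, end, "observer") if not track_t.empty else np.nan
            g_img = mean_glitter(gl_t, start, end, "imagery") if not gl_t.empty else np.nan
            if np.isnan(g_img) and not gl_t.empty:
                j = (gl_t.chainage - (start + end) / 2).abs().idxmin()
                g_img = float(gl_t.loc[j, "glitter"])

            def _chain_col(df):
                return "chainage" if "chainage" in df.columns else "centroid_n"

            go = groups_observer[groups_observer.get("transect_id", t_idx) == t_idx] \
                if "transect_id" in groups_observer.columns else groups_observer
            gi = groups_imagery[groups_imagery.get("transect_id", t_idx) == t_idx] \
                if "transect_id" in groups_imagery.columns else groups_imagery
            n_obs, k_obs, sizes_obs = tally_segment(go, start, end, _chain_col(go)) \
                if not go.empty else (0, 0, [])
            n_img, k_img, sizes_img = tally_segment(gi, start, end, _chain_col(gi)) \
                if not gi.empty else (0, 0, [])
            rows.append(
                dict(
                    flight_id=flight_id,
                    transect_id=int(t_idx),
                    segment_id=seg_id,
                    start=start,
                    end=end,
                    length=end - start,
                    visibility=int(vis),
                    area_observer=float(area_observer_fn(t_idx, start, end)),
                    area_imagery=float(area_imagery_fn(t_idx, start, end)),
                    mean_sea_state=sea,
                    glitter_observer=g_obs,
                    glitter_imagery=g_img,
                    cloud_okta=okta,
                    cloud_binary=cloud_binary(okta, cloud_threshold)
                    if not np.isnan(okta)
                    else 0,
                    count_observer=n_obs,
                    groups_observer=k_obs,
                    sizes_observer=";".join(map(str, sizes_obs)),
                    count_imagery=n_img,
                    groups_imagery=k_img,
                    sizes_imagery=";".join(map(str, sizes_img)),
                )
            )
            seg_id += 1
    return pd.DataFrame(rows)


def segments_to_long(segments: pd.DataFrame) -> pd.DataFrame:
    """One row per segment x platform, the layout the count models consume."""
    rows = []
    for r in segments.itertuples():
        for platform in ("observer", "imagery"):
            rows.append(
                dict(
                    flight_id=r.flight_id,
                    transect_id=r.transect_id,
                    segment_id=r.segment_id,
                    platform=platform,
                    count=getattr(r, f"count_{platform}"),
                    n_groups=getattr(r, f"groups_{platform}"),
                    sizes=getattr(r, f"sizes_{platform}"),
                    area=getattr(r, f"area_{platform}"),
                    visibility=r.visibility,
                    sea_state=r.mean_sea_state,
                    glitter=getattr(r, f"glitter_{platform}"),
                    cloud=r.cloud_binary,
                )
            )
    return pd.DataFrame(rows)
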