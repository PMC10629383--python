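"""Duplicate resolution, chain-rule grouping and capture-history construction.

Imagery detections of the same animal in overlapping frames are linked into
single individuals; individuals are partitioned into groups by the 200 m
chain rule (single-linkage connected components); observer front/back calls
are matched into 2-occasion histories and reviewer detections into
3-occasion histories for the perception models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


@dataclass
class CaptureHistory:
    """Binary detection vector over occasions plus model covariates."""

    group_id: int
    occasions: tuple[int, ...]
    size: int = 1
    side: str | None = None
    size_bin: str | None = None
    visibility: int | None = None
    glitter: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.occasions) < 1:
            raise ValueError("capture history must contain at least one detection")


def size_bin(size: int) -> str:
    """Group-size bins used by the reviewer detection models: 1, 2-3, 4+."""
    if size < 1:
        raise ValueError("group size must be >= 1")
    if size == 1:
        return "1"
    if size <= 3:
        return "2-3"
    return "4+"


def chain_group(points: np.ndarray, threshold_m: float = 200.0) -> list[list[int]]:
    """Partition point indices into chain-rule groups.

    Two points are in the same group when connected by a chain of pairwise
    distances each <= threshold (connected components of the threshold
    graph). Groups are returned sorted by smallest member index.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = len(pts)
    if n == 0:
        return []
    uf = _UnionFind(n)
    tree = cKDTree(pts)
    for i, j in tree.query_pairs(r=threshold_m):
        uf.union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)
    return sorted(comps.values(), key=lambda g: g[0])


def deduplicate_imagery(
    detections: pd.DataFrame,
    footprints: dict[str, "object"] | None = None,
    tolerance_m: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Link detections of the same individual across overlapping frames.

    Detections (of one reviewer, or of pooled certain detections when
    counting unique animals) in *distinct* images whose ground positions lie
    within `tolerance_m` — and, when footprint polygons are supplied, within
    the two frames' overlap region — are merged into one individual.

    Returns (detections with an added `individual_id` column, link table).
    Conservation: n_unique + n_links = n_raw.
    """
    if tolerance_m < 0:
        raise ValueError("tolerance must be >= 0")
    det = detections.reset_index(drop=True).copy()
    n = len(det)
    if n == 0:
        det["individual_id"] = pd.Series(dtype=int)
        return det, pd.DataFrame(columns=["from_detection", "to_detection"])
    pts = det[["easting", "northing"]].to_numpy(dtype=float)
    uf = _UnionFind(n)
    links = []
    tree = cKDTree(pts)
    for i, j in sorted(tree.query_pairs(r=tolerance_m)):
        if det.image_id.iat[i] == det.image_id.iat[j]:
            continue
        if footprints is not None:
            fa = footprints.get(det.image_id.iat[i])
            fb = footprints.get(det.image_id.iat[j])
            if fa is None or fb is None:
                continue
            pa = fa.polygon if hasattr(fa, "polygon") else fa
            pb = fb.polygon if hasattr(fb, "polygon") else fb
            overlap = pa.intersection(pb)
            mid = ((pts[i] + pts[j]) / 2.0).tolist()
            from shapely.geometry import Point

            if not overlap.buffer(1e-6).contains(Point(mid)):
                continue
        if uf.union(i, j):
            links.append(
                dict(
                    from_detection=int(det.detection_id.iat[i]),
                    to_detection=int(det.detection_id.iat[j]),
                )
            )
    roots = np.array([uf.find(i) for i in range(n)])
    _, individual = np.unique(roots, return_inverse=True)
    det["individual_id"] = individual
    return det, pd.DataFrame(links, columns=["from_detection", "to_detection"])


def group_imagery_individuals(
    individuals: pd.DataFrame, threshold_m: float = 200.0
) -> pd.DataFrame:
    """Chain-rule groups over unique individuals; returns a group table."""
    if individuals.empty:
        return pd.DataFrame(
            columns=["group_id", "platform", "size", "centroid_e", "centroid_n"]
        )
    uniq = (
        individuals.groupby("individual_id")[["easting", "northing"]].mean().reset_index()
    )
    groups = chain_group(uniq[["easting", "northing"]].to_numpy(), threshold_m)
    rows = []
    for gid, idx in enumerate(groups):
        sub = uniq.iloc[idx]
        rows.append(
            dict(
                group_id=gid,
                platform="imagery",
                size=len(idx),
                centroid_e=sub.easting.mean(),
                centroid_n=sub.northing.mean(),
                member_individuals=list(sub.individual_id),
            )
        )
    return pd.DataFrame(rows)


def merge_observer_groups(
    groups: pd.DataFrame, threshold_m: float = 200.0
) -> pd.DataFrame:
    """Chain rule on plotted group centroids; merged size = sum of sizes."""
    if groups.empty:
        return groups.copy()
    parts = chain_group(groups[["centroid_e", "centroid_n"]].to_numpy(), threshold_m)
    rows = []
    for gid, idx in enumerate(parts):
        sub = groups.iloc[idx]
        w = sub["size"].to_numpy(dtype=float)
        rows.append(
            dict(
                group_id=gid,
                platform="observer",
                size=int(w.sum()),
                centroid_e=float(np.average(sub.centroid_e, weights=w)),
                centroid_n=float(np.average(sub.centroid_n, weights=w)),
                merged_from=list(sub.group_id),
            )
        )
    return pd.DataFrame(rows)


def match_double_observer(
    front_calls: pd.DataFrame,
    back_calls: pd.DataFrame,
    time_window_s: float = 5.0,
    same_zone: bool = True,
) -> list[CaptureHistory]:
    """Greedy one-to-one matching of front/back calls into 2-occasion histories.

    Candidate pairs agree in zone (when `same_zone`) and differ in call time
    by at most `time_window_s`; pairs are taken smallest time difference
    first, ties broken by zone proximity then earlier front call. Matched
    pairs score (1,1) with the front seat's group size; unmatched front
    calls score (1,0), unmatched back calls (0,1).
    """
    front = front_calls.reset_index(drop=True)
    back = back_calls.reset_index(drop=True)
    cands = []
    for i, f in front.iterrows():
        for j, b in back.iterrows():
            dt = abs(f.time_abeam - b.time_abeam)
            if dt > time_window_s:
                continue
            dz = abs(int(f.zone) - int(b.zone))
            if same_zone and dz != 0:
                continue
            cands.append((dt, dz, f.time_abeam, i, j))
    cands.sort()
    used_f: set[int] = set()
    used_b: set[int] = set()
    histories: list[CaptureHistory] = []
    gid = 0
    for _, _, _, i, j in cands:
        if i in used_f or j in used_b:
            continue
        used_f.add(i)
        used_b.add(j)
        f = front.iloc[i]
        histories.append(
            CaptureHistory(
                group_id=gid,
                occasions=(1, 1),
                size=int(f.group_size),  # front-seat call taken as correct
                side=f.side if "side" in front.columns else None,
            )
        )
        gid += 1
    for i, f in front.iterrows():
        if i not in used_f:
            histories.append(
                CaptureHistory(
                    group_id=gid,
                    occasions=(1, 0),
                    size=int(f.group_size),
                    side=f.side if "side" in front.columns else None,
                )
            )
            gid += 1
    for j, b in back.iterrows():
        if j not in used_b:
            histories.append(
                CaptureHistory(
                    group_id=gid,
                    occasions=(0, 1),
                    size=int(b.group_size),
                    side=b.side if "side" in back.columns else None,
                )
            )
            gid += 1
    return histories


def build_reviewer_histories(
    per_reviewer_detections: pd.DataFrame,
    threshold_m: float = 200.0,
    n_reviewers: int = 3,
    covariates: pd.DataFrame | None = None,
) -> list[CaptureHistory]:
    """Multi-reviewer capture histories via chain-rule groups on pooled points.

    Each reviewer's detections must already be deduplicated within reviewer.
    Pooled certain detections are chain-grouped; a reviewer scores 1 for a
    group when they detected at least one of its members. Optional
    `covariates` (indexed like the output group ids via nearest centroid) may
    carry visibility/glitter; the size bin comes from the pooled group size.
    """
    det = per_reviewer_detections
    if "certainty" in det.columns:
        det = det[det.certainty == "certain"]
    if det.empty:
        return []
    det = det.reset_index(drop=True)
    pts = det[["easting", "northing"]].to_numpy(dtype=float)
    parts = chain_group(pts, threshold_m)
    histories = []
    for gid, idx in enumerate(parts):
        sub = det.iloc[idx]
        # group size = unique animals, not detection rows
        key = (
            sub["individual_id"]
            if "individual_id" in sub.columns
            else sub.groupby(["easting", "northing"]).ngroup()
        )
        n_animals = int(pd.unique(key).size)
        occ = tuple(
            int((sub.reviewer_id == r + 1).any()) for r in range(n_reviewers)
        )
        hist = CaptureHistory(
            group_id=gid,
            occasions=occ,
            size=n_animals,
            size_bin=size_bin(n_animals),
        )
        if covariates is not None and gid < len(covariates):
            row = covariates.iloc[gid]
            hist.visibility = int(row.get("visibility", 0)) or None
            hist.glitter = row.get("glitter", None)
        histories.append(hist)
    return histories


def histories_to_frame(histories: list[CaptureHistory]) -> pd.DataFrame:
    """Serialize to the histories.csv layout (y1..yk + covariates)."""
    if not histories:
        return pd.DataFrame()
    k = len(histories[0].occasions)
    rows = []
    for h in histories:
        row = {"group_id": h.group_id}
        row.update({f"y{i + 1}": h.occasions[i] for i in range(k)})
        row.update(
            dict(size=h.size, side=h.side, size_bin=h.size_bin,
                 visibility=h.visibility, glitter=h.glitter)
        )
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_histories(df: pd.DataFrame) -> list[CaptureHistory]:
    occ_cols = sorted(
        (c for c in df.columns if c.startswith("y") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    out = []
    for _, row in df.iterrows():
        out.append(
            CaptureHistory(
                group_id=int(row.get("group_id", 0)),
                occasions=tuple(int(row[c]) for c in occ_cols),
                size=int(row.get("size", 1) or 1),
                side=row.get("side", None) if pd.notna(row.get("side", None)) else None,
                size_bin=row.get("size_bin", None)
                if pd.notna(row.get("size_bin", None))
                else None,
                visibility=int(row["visibility"])
                if "visibility" in df.columns and pd.notna(row["visibility"])
                else None,
                glitter=float(row["glitter"])
                if "glitter" in df.columns and pd.notna(row["glitter"])
                else None,
            )
        )
    return out
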