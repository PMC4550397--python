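"""Chamber position tracks to cardinal bearings, and within-run screens.

A deployment observes one larva in a circular chamber drifting at 5 m depth
for 15 minutes, photographed from below every 5 seconds (nominally 180
frames). Each frame gives the larva's pixel position plus the compass
bearing of the image-top direction. Processing converts positions to polar
coordinates about the chamber center, then to world-frame (cardinal)
bearings, and tests bearing-keeping with the Rayleigh test.

Conventions
-----------
The camera looks upward at the chamber, so the image is mirrored; by
default the x axis is flipped before polar conversion (``mirror=True``) and
the chamber angle is *added* to the compass heading of image-top
(``compose="add"``). Both are configurable; they cancel in the resultant
length r (which is rotation-invariant) and only affect the sign convention
of mean bearings. The defaults are fixed by the simulator round-trip
property: a simulated larva holding a fixed world bearing recovers that
bearing exactly through the default pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from discorient.circular import circ_mean_r, rayleigh_test

__all__ = [
    "PositionTrack",
    "WithinRunResult",
    "to_polar",
    "to_cardinal",
    "within_run",
    "artifact_screen",
    "qc_filter",
    "read_tracks_csv",
    "results_to_frame",
]

TRACK_COLUMNS = ["deployment_id", "timestamp_utc", "x_px", "y_px", "heading_top_deg"]

#: default chamber center for a 5-megapixel (2592 x 1944) frame
DEFAULT_CENTER = (1296.0, 972.0)


@dataclass
class PositionTrack:
    """Per-frame positions and compass headings for one deployment.

    ``frames`` holds columns t (UTC), x, y (pixels, image coordinates with
    y increasing downward) and heading_top (degrees, compass bearing of the
    image-top direction), time-ordered.
    """

    deployment_id: str
    frames: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frames
        missing = {"t", "x", "y", "heading_top"} - set(f.columns)
        if missing:
            raise ValueError(f"track frames missing columns: {sorted(missing)}")
        if not f["t"].is_monotonic_increasing:
            self.frames = f.sort_values("t").reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class WithinRunResult:
    """Individual-level directionality for one deployment.

    ``r_card`` and ``mean_bearing`` describe concentration in the cardinal
    (world) frame; ``r_chamber`` in the rotating chamber frame.
    ``rotation_range`` is the total unwrapped compass excursion of the
    chamber. ``artifact`` marks the chamber-locked screen, ``qc_excluded``
    metadata-based rejections. A larva is ``directional`` when it passes
    both screens and the cardinal Rayleigh p-value is below alpha.
    """

    deployment_id: str
    n_frames: int
    r_card: float
    mean_bearing: float
    p_value: float
    r_chamber: float
    rotation_range: float
    artifact: bool = False
    qc_excluded: bool = False
    qc_reason: str = ""
    alpha: float = 0.05

    @property
    def directional(self) -> bool:
        return (not self.artifact) and (not self.qc_excluded) and self.p_value < self.alpha


def to_polar(
    x,
    y,
    center_x: float,
    center_y: float,
    mirror: bool = True,
    chamber_radius_px: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert image positions to polar coordinates about the chamber center.

    Angles are degrees clockwise from the image-top direction, in [0, 360).
    With ``mirror=True`` (default; upward-looking camera) the image x axis
    is flipped about the center first. Radii are in pixels, or as a
    fraction of ``chamber_radius_px`` when given. A frame exactly at the
    center gets radius 0 and angle NaN (undefined).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    dx = (center_x - x) if mirror else (x - center_x)
    dy = y - center_y  # image y grows downward
    radius = np.hypot(dx, dy)
    angle = np.degrees(np.arctan2(dx, -dy)) % 360.0
    angle = np.where(radius < 1e-12, np.nan, angle)
    if chamber_radius_px is not None:
        radius = radius / chamber_radius_px
    return radius, angle


def to_cardinal(angle_chamber, heading_top, compose: str = "add") -> np.ndarray:
    """Chamber-frame angle to cardinal bearing given the image-top heading.

    ``compose="add"`` (default) returns (angle + heading) mod 360;
    "subtract" returns (angle - heading) mod 360 for data digitized with
    the opposite mirror convention.
    """
    a = np.asarray(angle_chamber, dtype=float)
    h = np.asarray(heading_top, dtype=float)
    if compose == "add":
        return (a + h) % 360.0
    if compose == "subtract":
        return (a - h) % 360.0
    raise ValueError(f"unknown compose convention {compose!r}")


def _unwrap_deg(headings: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(headings)))


def interpolate_headings(frames: pd.DataFrame) -> np.ndarray:
    """Fill missing compass headings by linear interpolation on the
    unwrapped series (heading is a smooth instrument signal)."""
    h = frames["heading_top"].to_numpy(dtype=float)
    ok = np.isfinite(h)
    if ok.all():
        return h
    if ok.sum() < 2:
        raise ValueError("need at least two finite headings to interpolate")
    t = frames["t"].astype("int64").to_numpy(dtype=float)
    unwrapped = _unwrap_deg(h[ok])
    return np.interp(t, t[ok], unwrapped) % 360.0


def within_run(
    track: PositionTrack,
    alpha: float = 0.05,
    center: tuple[float, float] = DEFAULT_CENTER,
    mirror: bool = True,
    compose: str = "add",
    acclimation_s: float = 0.0,
    method: str = "analytic",
    n_perm: int = 9999,
    seed: int | None = None,
) -> WithinRunResult:
    """Within-run directionality of one larva.

    Runs the Rayleigh test on the cardinal bearings of the larva's
    positions; also reports the chamber-frame resultant length (for the
    chamber-locked artifact screen) and the chamber's total unwrapped
    compass excursion. Frames within ``acclimation_s`` seconds of the first
    frame are excluded; frames without a position are dropped (positions
    are never interpolated).
    """
    f = track.frames
    if acclimation_s > 0:
        t0 = f["t"].iloc[0]
        f = f[(f["t"] - t0).dt.total_seconds() >= acclimation_s]
    headings = interpolate_headings(f)
    usable = np.isfinite(f["x"].to_numpy(float)) & np.isfinite(f["y"].to_numpy(float))
    f = f[usable]
    headings = headings[usable]
    if len(f) < 2:
        raise ValueError(f"deployment {track.deployment_id}: fewer than 2 usable frames")
    _, angle_chamber = to_polar(f["x"], f["y"], center[0], center[1], mirror=mirror)
    keep = np.isfinite(angle_chamber)  # drop dead-center frames
    angle_chamber = angle_chamber[keep]
    headings = headings[keep]
    if angle_chamber.size < 2:
        raise ValueError(f"deployment {track.deployment_id}: fewer than 2 usable frames")
    bearings = to_cardinal(angle_chamber, headings, compose=compose)
    card = rayleigh_test(bearings, method=method, n_perm=n_perm, seed=seed)
    chamber = circ_mean_r(angle_chamber)
    rotation = float(np.ptp(_unwrap_deg(headings)))
    return WithinRunResult(
        deployment_id=track.deployment_id,
        n_frames=int(angle_chamber.size),
        r_card=card.summary.r,
        mean_bearing=card.summary.mean_bearing,
        p_value=card.p_value,
        r_chamber=chamber.r,
        rotation_range=rotation,
        alpha=alpha,
    )


def artifact_screen(
    result: WithinRunResult,
    rotation_min: float = 180.0,
    delta_threshold: float = 0.17,
) -> bool:
    """Chamber-locked artifact screen.

    Flags deployments where the chamber rotated at least ``rotation_min``
    degrees (total unwrapped excursion) AND the positions were much more
    concentrated in the chamber frame than in the cardinal frame
    (r_chamber - r_card strictly greater than ``delta_threshold``; the
    0.17 default sits in the trough of the bimodal r_chamber - r_card
    distribution). Such larvae held station relative to the structure, not
    to the world, and are excluded from orientation analysis.
    """
    return bool(
        result.rotation_range >= rotation_min
        and (result.r_chamber - result.r_card) > delta_threshold
    )


def qc_filter(deployment, max_vessels: int = 3) -> tuple[bool, str]:
    """Metadata-based quality screen for one deployment.

    Excludes deployments with more than ``max_vessels`` vessels cruising
    nearby (boat traffic measurably increased directionality) or with a
    predator visibly interacting with the chamber (manual annotation
    passed through as input). Returns (excluded, reason) with reason in
    {"", "vessels", "predator"}.
    """
    vessels = getattr(deployment, "vessel_count", None)
    if vessels is None:
        vessels = deployment["vessel_count"]
    predator = getattr(deployment, "predator_flag", None)
    if predator is None:
        predator = deployment["predator_flag"]
    if vessels is not None and int(vessels) > max_vessels:
        return True, "vessels"
    if bool(predator):
        return True, "predator"
    return False, ""


def read_tracks_csv(path) -> list[PositionTrack]:
    """Read one or more deployments' tracks from a CSV file.

    Expected columns: deployment_id, timestamp_utc (ISO-8601), x_px, y_px,
    heading_top_deg. Extra columns are ignored.
    """
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing track columns {sorted(missing)}")
    df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"], utc=True, format="ISO8601")
    tracks = []
    for dep_id, g in df.groupby("deployment_id", sort=True):
        frames = pd.DataFrame(
            {
                "t": g["timestamp_utc"].to_numpy(),
                "x": g["x_px"].to_numpy(float),
                "y": g["y_px"].to_numpy(float),
                "heading_top": g["heading_top_deg"].to_numpy(float),
            }
        )
        tracks.append(PositionTrack(deployment_id=str(dep_id), frames=frames))
    return tracks


def results_to_frame(results: list[WithinRunResult]) -> pd.DataFrame:
    """Tabulate within-run results, one row per deployment."""
    rows = [
        {
            "deployment_id": r.deployment_id,
            "n_frames": r.n_frames,
            "directionality_p_value": r.p_value,
            "r": r.r_card,
            "mean_bearing": r.mean_bearing,
            "r_chamber": r.r_chamber,
            "rotation_range": r.rotation_range,
            "artifact": r.artifact,
            "qc_excluded": r.qc_excluded,
            "qc_reason": r.qc_reason,
            "directional": r.directional,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
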