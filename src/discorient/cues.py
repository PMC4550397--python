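"""Population-level orientation analysis relative to environmental cues.

Within-run analyses only establish that individual larvae keep a bearing.
Orientation toward a common direction is tested across runs: the mean
bearings of directional larvae become the data for a second Rayleigh test,
either in the cardinal frame ("north" reference) or after subtracting a
per-deployment cue bearing (sun azimuth, nearest-coast bearing, wind,
current/drift). A cue-relative angle of 0 means the larva headed toward the
cue, 180 away from it; the across-run resultant length r quantifies the
cue's effect (orientation precision).

Directionality (within-run r, logit-transformed) is additionally regressed
on scalar covariates, and compared between species with rank tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from discorient.circular import WallraffResult, rayleigh_test, relative_angles, wallraff_test
from discorient.solar import mean_time, solar_index, sun_position, sun_times

__all__ = [
    "Deployment",
    "AcrossRunResult",
    "RegressionResult",
    "EARTH_RADIUS_M",
    "great_circle",
    "coast_cue",
    "drift_cue",
    "compute_cues",
    "across_run",
    "across_run_table",
    "directionality_regression",
    "species_comparison",
    "dispersion_comparison",
    "read_coastline_csv",
    "read_deployments_csv",
]

EARTH_RADIUS_M = 6371008.8

CUE_REFERENCES = ("north", "sun", "coast", "wind", "current")


@dataclass
class Deployment:
    """Metadata and covariates for one 15-minute observation run."""

    deployment_id: str
    species: str
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    gps_fixes: pd.DataFrame  # columns t, lat, lon
    cloud_cover: int  # eighths of sky, 0-8
    wind_bearing: float  # meteorological "from" direction, degrees
    wind_speed: float  # m/s
    vessel_count: int
    predator_flag: bool
    standard_length: float  # mm

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(f"{self.deployment_id}: t_start must precede t_end")
        if not 0 <= int(self.cloud_cover) <= 8:
            raise ValueError(f"{self.deployment_id}: cloud cover must be in 0..8 eighths")


@dataclass(frozen=True)
class AcrossRunResult:
    """Population orientation for one species in one reference frame.

    ``status`` is "ok" when the test ran, or "insufficient_n" when the
    species did not reach the inclusion threshold (the test is refused, not
    computed on too few individuals).
    """

    species: str
    reference: str
    n: int
    mean_angle: float
    r: float
    p_value: float
    status: str = "ok"


@dataclass(frozen=True)
class RegressionResult:
    """OLS regression of logit-transformed directionality on a covariate."""

    species: str
    covariate: str
    model: str  # "linear" | "quadratic"
    n: int
    slope: float
    f_statistic: float
    r2_adj: float
    p_value: float
    residual_normality_p: float  # NaN unless the model is significant
    quadratic_term_p: float  # NaN for linear models


# ---------------------------------------------------------------------------
# geodesy


def great_circle(lat1, lon1, lat2, lon2) -> tuple[np.ndarray, np.ndarray]:
    """Great-circle distance (m, haversine) and initial bearing (degrees
    clockwise from North) from point 1 to point 2 on a WGS84 sphere."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    dist = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    bearing = np.degrees(np.arctan2(y, x)) % 360.0
    return dist, bearing


def coast_cue(lat: float, lon: float, coastline: np.ndarray) -> tuple[float, float]:
    """Bearing and distance (m) to the nearest digitized coastline vertex.

    ``coastline`` is an (n, 2) array of (lat, lon) vertices; the nearest
    vertex by great-circle distance is the potential settlement habitat.
    Ties are broken by file order. A point coincident with a vertex gets
    distance 0 and bearing NaN (undefined).
    """
    coast = np.atleast_2d(np.asarray(coastline, dtype=float))
    if coast.size == 0:
        raise ValueError("empty coastline")
    dist, bearing = great_circle(lat, lon, coast[:, 0], coast[:, 1])
    i = int(np.argmin(dist))  # argmin takes the first minimum: file-order tie rule
    if dist[i] < 1e-9:
        return float("nan"), 0.0
    return float(bearing[i]), float(dist[i])


def drift_cue(gps_fixes: pd.DataFrame) -> tuple[float, float]:
    """Drift bearing and speed (m/s) of the instrument over a deployment.

    Bearing is the initial great-circle bearing from the first to the last
    GPS fix; speed is the great-circle distance over elapsed time. The
    drifting chamber is locked into the current by its drogue, so its drift
    measures the current the larva experienced. Identical first/last fixes
    give speed 0 and bearing NaN.
    """
    if len(gps_fixes) < 2:
        raise ValueError("need at least two GPS fixes")
    first, last = gps_fixes.iloc[0], gps_fixes.iloc[-1]
    dt = (pd.Timestamp(last["t"]) - pd.Timestamp(first["t"])).total_seconds()
    if dt <= 0:
        raise ValueError("GPS fixes must span > 0 s")
    dist, bearing = great_circle(first["lat"], first["lon"], last["lat"], last["lon"])
    if dist < 1e-9:
        return float("nan"), 0.0
    return float(bearing), float(dist / dt)


# ---------------------------------------------------------------------------
# cue assembly


def compute_cues(
    deployments: list[Deployment],
    coastline: np.ndarray,
    wind_toward: bool = False,
    sunrise_zenith: float = 90.833,
) -> pd.DataFrame:
    """Per-deployment cue bearings and scalar covariates.

    For each deployment: sun azimuth at the mean observation time and mean
    GPS position; bearing/distance to the nearest coastline vertex; wind
    bearing (station "from" convention by default; ``wind_toward=True``
    flips it 180 deg); current bearing/speed from the instrument drift; and
    the solar index at the mean time.
    """
    rows = []
    for dep in deployments:
        t_mid = mean_time(dep.t_start, dep.t_end)
        lat = float(dep.gps_fixes["lat"].mean())
        lon = float(dep.gps_fixes["lon"].mean())
        sun = sun_position(lat, lon, t_mid)
        st = sun_times(lat, lon, t_mid.date(), zenith=sunrise_zenith)
        coast_b, coast_d = coast_cue(lat, lon, coastline)
        cur_b, cur_s = drift_cue(dep.gps_fixes)
        wind_b = (dep.wind_bearing + 180.0) % 360.0 if wind_toward else dep.wind_bearing % 360.0
        rows.append(
            {
                "deployment_id": dep.deployment_id,
                "species": dep.species,
                "sun_azimuth": sun.azimuth,
                "coast_bearing": coast_b,
                "coast_distance": coast_d,
                "wind_bearing": wind_b,
                "wind_speed": dep.wind_speed,
                "current_bearing": cur_b,
                "current_speed": cur_s,
                "solar_index": solar_index(t_mid, st),
                "cloud_cover": dep.cloud_cover,
                "standard_length": dep.standard_length,
                "vessel_count": dep.vessel_count,
                "predator_flag": dep.predator_flag,
            }
        )
    return pd.DataFrame(rows)


_CUE_COLUMN = {
    "sun": "sun_azimuth",
    "coast": "coast_bearing",
    "wind": "wind_bearing",
    "current": "current_bearing",
}


def _directional_table(results: pd.DataFrame, cues: pd.DataFrame) -> pd.DataFrame:
    merged = results.merge(cues, on="deployment_id", how="inner", suffixes=("", "_cue"))
    if "species" not in merged.columns and "species_cue" in merged.columns:
        merged["species"] = merged["species_cue"]
    return merged


def across_run(
    results: pd.DataFrame,
    cues: pd.DataFrame,
    species: str,
    reference: str = "north",
    min_n: int = 30,
    basis: str = "tested",
    alpha: float = 0.05,
) -> AcrossRunResult:
    """Across-run Rayleigh test for one species in one reference frame.

    Only directional, non-excluded larvae enter the test; their mean
    bearings (or bearings relative to the per-deployment cue) are the data.
    The test is refused (status "insufficient_n") when the species has
    fewer than ``min_n`` individuals, counted on ``basis``: "tested"
    (retained after QC/artifact screens, the default — this reproduces
    which species enter the published orientation analysis) or
    "directional".
    """
    if reference not in CUE_REFERENCES:
        raise ValueError(f"unknown reference {reference!r}; choose from {CUE_REFERENCES}")
    merged = _directional_table(results, cues)
    sp = merged[merged["species"] == species]
    tested = sp[~(sp["artifact"].astype(bool) | sp["qc_excluded"].astype(bool))]
    directional = tested[tested["directionality_p_value"] < alpha]
    n_basis = len(tested) if basis == "tested" else len(directional)
    if n_basis < min_n or len(directional) < 2:
        return AcrossRunResult(species, reference, len(directional), float("nan"),
                               float("nan"), float("nan"), status="insufficient_n")
    bearings = directional["mean_bearing"].to_numpy(float)
    if reference != "north":
        cue = directional[_CUE_COLUMN[reference]].to_numpy(float)
        ok = np.isfinite(cue)
        bearings = relative_angles(bearings[ok], cue[ok])
    res = rayleigh_test(bearings)
    return AcrossRunResult(
        species=species,
        reference=reference,
        n=int(res.summary.n),
        mean_angle=res.summary.mean_bearing,
        r=res.summary.r,
        p_value=res.p_value,
    )


def across_run_table(
    results: pd.DataFrame,
    cues: pd.DataFrame,
    references=CUE_REFERENCES,
    min_n: int = 30,
    basis: str = "tested",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Orientation of every species in every reference frame (tidy table,
    one row per species x reference)."""
    species = sorted(pd.unique(cues["species"]))
    rows = []
    for sp, ref in itertools.product(species, references):
        res = across_run(results, cues, sp, ref, min_n=min_n, basis=basis, alpha=alpha)
        rows.append(vars(res))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# directionality covariates and species comparisons


def _logit(r: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    r = np.clip(np.asarray(r, dtype=float), eps, 1.0 - eps)
    return np.log(r / (1.0 - r))


def directionality_regression(
    r_values,
    covariate_values,
    quadratic: bool = False,
    species: str = "",
    covariate: str = "",
    alpha: float = 0.05,
) -> RegressionResult:
    """OLS regression of logit-transformed within-run r on a covariate.

    r is bounded in [0, 1], so it is logit-transformed (clipped to
    [1e-6, 1 - 1e-6]) before ordinary least squares. With
    ``quadratic=True`` the squared covariate is added (e.g. for the solar
    index, whose directional usefulness could peak at both ends of the
    day). Residual normality (Shapiro) is reported only for significant
    models, mirroring standard practice of checking assumptions of models
    that are interpreted.
    """
    r = np.asarray(r_values, dtype=float)
    x = np.asarray(covariate_values, dtype=float)
    if r.shape != x.shape:
        raise ValueError("r_values and covariate_values must have equal length")
    ok = np.isfinite(r) & np.isfinite(x)
    r, x = r[ok], x[ok]
    if r.size < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    y = _logit(r)
    X = np.column_stack([x, x**2]) if quadratic else x[:, None]
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    p_model = float(fit.f_pvalue)
    shapiro_p = float(stats.shapiro(fit.resid).pvalue) if p_model < alpha else float("nan")
    quad_p = float(fit.pvalues[2]) if quadratic else float("nan")
    return RegressionResult(
        species=species,
        covariate=covariate,
        model="quadratic" if quadratic else "linear",
        n=int(r.size),
        slope=float(fit.params[1]),
        f_statistic=float(fit.fvalue),
        r2_adj=float(fit.rsquared_adj),
        p_value=p_model,
        residual_normality_p=shapiro_p,
        quadratic_term_p=quad_p,
    )


def species_comparison(r_by_species: dict[str, np.ndarray]) -> dict:
    """Non-parametric comparison of directionality (r) between species.

    r is bounded in [0, 1] and not normal, so rank procedures are used:
    Kruskal-Wallis omnibus, all pairwise two-sided Wilcoxon rank-sum tests
    with Benjamini-Hochberg correction, and the Fligner-Killeen test for
    homogeneity of scale. Species with fewer than 2 observations are
    dropped with a warning entry.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in r_by_species.items()}
    dropped = sorted(k for k, v in groups.items() if v.size < 2)
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError("need at least two species with n >= 2")
    names = sorted(groups)
    samples = [groups[k] for k in names]
    kw = stats.kruskal(*samples)
    fl = stats.fligner(*samples)
    pairs = list(itertools.combinations(names, 2))
    raw = [
        float(stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue)
        for a, b in pairs
    ]
    adj = multipletests(raw, method="fdr_bh")[1] if raw else []
    pairwise = pd.DataFrame(
        {
            "species_a": [a for a, _ in pairs],
            "species_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_adjusted": list(adj),
        }
    )
    return {
        "kruskal_statistic": float(kw.statistic),
        "kruskal_p": float(kw.pvalue),
        "fligner_statistic": float(fl.statistic),
        "fligner_p": float(fl.pvalue),
        "pairwise": pairwise,
        "dropped": dropped,
    }


def dispersion_comparison(angle_sets: dict[str, np.ndarray]) -> dict:
    """Wallraff dispersion comparisons between labelled sets of angles.

    Used both to compare dispersions of cue-relative angles between cue
    references and between species. Returns the omnibus test over all sets
    plus every pairwise test (unadjusted, as these are descriptive).
    """
    names = sorted(angle_sets)
    if len(names) < 2:
        raise ValueError("need at least two angle sets")
    omnibus = wallraff_test([angle_sets[k] for k in names])
    rows = []
    for a, b in itertools.combinations(names, 2):
        res: WallraffResult = wallraff_test([angle_sets[a], angle_sets[b]])
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "dispersion_a": res.group_dispersions[0],
                "dispersion_b": res.group_dispersions[1],
            }
        )
    return {"omnibus": omnibus, "pairwise": pd.DataFrame(rows)}


# ---------------------------------------------------------------------------
# file formats


def read_coastline_csv(path) -> np.ndarray:
    """Read a digitized coastline as an (n, 2) array of (lat, lon).

    The file holds lon,lat vertex pairs in WGS84 decimal degrees (the
    common digitizing convention); column order is taken from the header.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "lat" in cols and "lon" in cols:
        return df[[cols["lat"], cols["lon"]]].to_numpy(float)
    raise ValueError(f"{path}: expected 'lon' and 'lat' columns")


def read_deployments_csv(path) -> list[Deployment]:
    """Read deployment metadata from CSV (one row per deployment).

    Columns: deployment_id, species, t_start, t_end (ISO-8601 UTC),
    lat_start, lon_start, lat_end, lon_end, cloud_cover, wind_bearing,
    wind_speed, vessel_count, predator_flag, standard_length.
    """
    df = pd.read_csv(path)
    deployments = []
    for _, row in df.iterrows():
        t_start = pd.Timestamp(row["t_start"])
        t_end = pd.Timestamp(row["t_end"])
        if t_start.tzinfo is None:
            t_start = t_start.tz_localize("UTC")
        if t_end.tzinfo is None:
            t_end = t_end.tz_localize("UTC")
        fixes = pd.DataFrame(
            {
                "t": [t_start, t_end],
                "lat": [row["lat_start"], row["lat_end"]],
                "lon": [row["lon_start"], row["lon_end"]],
            }
        )
        deployments.append(
            Deployment(
                deployment_id=str(row["deployment_id"]),
                species=str(row["species"]),
                t_start=t_start,
                t_end=t_end,
                gps_fixes=fixes,
                cloud_cover=int(row["cloud_cover"]),
                wind_bearing=float(row["wind_bearing"]),
                wind_speed=float(row["wind_speed"]),
                vessel_count=int(row["vessel_count"]),
                predator_flag=bool(row["predator_flag"]),
                standard_length=float(row["standard_length"]),
            )
        )
    return deployments
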