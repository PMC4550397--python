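"""Study-level aggregates from a per-deployment summary table.

The published deliverable of a chamber-drifting orientation study is a
per-deployment table: species, within-run directionality (r), its Rayleigh
p-value, the larva's mean bearing, cue bearings at deployment time and
scalar covariates. This module recomputes the headline quantities of such a
study from that table alone: proportions of directional larvae, mean and
median directionality, species rank comparisons, across-run orientation per
cue reference, and directionality regressions.

The reader tolerates both the R-style dotted column dialect
(``directionality.p.value``, ``mean.bearing``) and the underscore dialect,
plus extra columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from discorient.circular import rayleigh_test, relative_angles
from discorient.cues import directionality_regression, species_comparison

__all__ = ["read_deployment_log", "replicate_study"]

# canonical name <- accepted aliases (after lowercasing and "." -> "_")
_ALIASES = {
    "species": ("species", "sp"),
    "deployment_id": ("deployment_id", "deploy_id", "id"),
    "directionality_p_value": ("directionality_p_value", "p_value", "p"),
    "r": ("r", "directionality", "directionality_r"),
    "mean_bearing": ("mean_bearing", "bearing", "mean_angle"),
    "sun_azimuth": ("sun_azimuth", "sun_bearing", "sun"),
    "coast_bearing": ("coast_bearing", "coast"),
    "wind_bearing": ("wind_bearing", "wind"),
    "current_bearing": ("current_bearing", "current", "drift_bearing"),
    "coast_distance": ("coast_distance", "dist_to_coast", "distance_to_coast", "dist_coast"),
    "solar_index": ("solar_index", "sun_index"),
    "wind_speed": ("wind_speed",),
    "current_speed": ("current_speed", "drift_speed"),
    "cloud_cover": ("cloud_cover", "cloud", "nebulosity"),
    "standard_length": ("standard_length", "length", "sl"),
}

_CUE_COLUMN = {
    "sun": "sun_azimuth",
    "coast": "coast_bearing",
    "wind": "wind_bearing",
    "current": "current_bearing",
}


def read_deployment_log(path_or_frame) -> pd.DataFrame:
    """Load and normalize a per-deployment summary table.

    Accepts a path or a DataFrame. Column names are lowercased and dots
    mapped to underscores, then canonicalized through an alias table;
    unknown columns are kept as-is. Requires at least species, r,
    directionality_p_value and mean_bearing.
    """
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) else pd.read_csv(path_or_frame)
    df = df.copy()
    df.columns = [str(c).strip().lower().replace(".", "_").replace(" ", "_") for c in df.columns]
    rename = {}
    for canonical, aliases in _ALIASES.items():
        for alias in aliases:
            if alias in df.columns and canonical not in df.columns:
                rename[alias] = canonical
                break
    df = df.rename(columns=rename)
    required = {"species", "r", "directionality_p_value", "mean_bearing"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"deployment log missing columns: {sorted(missing)}")
    return df


def _across_run_rows(df: pd.DataFrame, alpha: float, min_n: int) -> list[dict]:
    rows = []
    references = ["north"] + [ref for ref, col in _CUE_COLUMN.items() if col in df.columns]
    for species, sp in df.groupby("species", sort=True):
        directional = sp[sp["directionality_p_value"] < alpha]
        eligible = len(sp) >= min_n and len(directional) >= 2
        for ref in references:
            if not eligible:
                rows.append({"species": species, "reference": ref, "n": len(directional),
                             "mean_angle": np.nan, "r": np.nan, "p_value": np.nan,
                             "status": "insufficient_n"})
                continue
            bearings = directional["mean_bearing"].to_numpy(float)
            if ref != "north":
                cue = directional[_CUE_COLUMN[ref]].to_numpy(float)
                ok = np.isfinite(cue) & np.isfinite(bearings)
                bearings = relative_angles(bearings[ok], cue[ok])
            res = rayleigh_test(bearings)
            rows.append({"species": species, "reference": ref, "n": int(res.summary.n),
                         "mean_angle": res.summary.mean_bearing, "r": res.summary.r,
                         "p_value": res.p_value, "status": "ok"})
    return rows


def replicate_study(
    table,
    alpha: float = 0.05,
    min_n: int = 30,
    covariates: tuple[str, ...] = (
        "solar_index",
        "wind_speed",
        "current_speed",
        "coast_distance",
        "cloud_cover",
    ),
) -> dict:
    """Recompute a study's headline aggregates from its deployment table.

    Returns a dict with:

    - ``proportion_directional_pct`` — overall % of larvae with within-run
      Rayleigh p < alpha, and ``proportion_directional_by_species_pct``.
    - ``mean_r_all`` / ``mean_r_directional`` — mean individual
      directionality over all retained larvae and over directional ones
      (both are reported; summaries in the literature are ambiguous about
      the base population).
    - ``median_r_by_species``.
    - ``species_comparison`` — Kruskal-Wallis/Fligner/pairwise-Wilcoxon-BH
      on r across species.
    - ``across_run`` — DataFrame of species x reference orientation
      (mean angle, precision r, Rayleigh p), restricted to species with at
      least ``min_n`` tested individuals.
    - ``regressions`` — DataFrame of per-species logit(r)-on-covariate OLS
      fits for every available covariate (solar index also quadratic).
    """
    df = read_deployment_log(table)
    directional_mask = df["directionality_p_value"] < alpha
    by_species = df.groupby("species", sort=True)
    prop_by_species = (
        df.assign(directional=directional_mask)
        .groupby("species", sort=True)["directional"]
        .mean()
        * 100.0
    )
    out: dict = {
        "n_deployments": int(len(df)),
        "proportion_directional_pct": float(directional_mask.mean() * 100.0),
        "proportion_directional_by_species_pct": prop_by_species.to_dict(),
        "mean_r_all": float(df["r"].mean()),
        "mean_r_directional": float(df.loc[directional_mask, "r"].mean()),
        "median_r_by_species": by_species["r"].median().to_dict(),
        "species_comparison": species_comparison(
            {sp: g["r"].to_numpy(float) for sp, g in by_species}
        ),
        "across_run": pd.DataFrame(_across_run_rows(df, alpha, min_n)),
    }
    reg_rows = []
    for species, sp in by_species:
        if len(sp) < min_n:
            continue
        for cov in covariates:
            if cov not in df.columns:
                continue
            x = sp[cov].to_numpy(float)
            if np.ptp(x[np.isfinite(x)]) == 0:
                continue
            for quadratic in ((False, True) if cov == "solar_index" else (False,)):
                res = directionality_regression(
                    sp["r"].to_numpy(float), x, quadratic=quadratic,
                    species=species, covariate=cov, alpha=alpha,
                )
                reg_rows.append(vars(res))
    out["regressions"] = pd.DataFrame(reg_rows)
    return out
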