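"""End-to-end workflow: raw tracks + metadata -> within-run results ->
cue-relative population analysis tables.

These functions are the library behind the command-line interface; each
returns plain pandas DataFrames ready to serialize as CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from discorient.circular import relative_angles
from discorient.config import RunConfig
from discorient.cues import (
    Deployment,
    across_run_table,
    directionality_regression,
    dispersion_comparison,
    species_comparison,
)
from discorient.tracks import (
    PositionTrack,
    artifact_screen,
    qc_filter,
    results_to_frame,
    within_run,
)

__all__ = ["process_study", "analyze_study", "rose_bins"]

COVARIATES = ("solar_index", "wind_speed", "current_speed", "coast_distance",
              "cloud_cover", "standard_length")


def process_study(
    tracks: list[PositionTrack],
    deployments: list[Deployment],
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Within-run processing of every deployment.

    Runs the polar/cardinal conversion and Rayleigh test per track, applies
    the chamber-locked artifact screen and the metadata QC screen, and
    returns (results table, exclusion log). Every deployment appears in the
    table — excluded ones carry their flag and reason, so
    retained + excluded = input count.
    """
    config = config or RunConfig()
    config.validate()
    meta = {d.deployment_id: d for d in deployments}
    results = []
    for track in tracks:
        res = within_run(
            track,
            alpha=config.alpha,
            center=(config.center_x, config.center_y),
            mirror=config.mirror,
            compose=config.compose,
            acclimation_s=config.acclimation_s,
            method=config.rayleigh_method,
            seed=config.seed,
        )
        res.artifact = artifact_screen(res, config.rotation_min, config.delta_threshold)
        dep = meta.get(track.deployment_id)
        if dep is None:
            raise ValueError(f"no deployment metadata for track {track.deployment_id!r}")
        res.qc_excluded, res.qc_reason = qc_filter(dep, max_vessels=config.max_vessels)
        results.append(res)
    table = results_to_frame(results)
    table.insert(1, "species", [meta[i].species for i in table["deployment_id"]])
    for key, value in config.convention_flags().items():
        table[key] = value
    log = {
        "n_input": len(table),
        "n_retained": int((~(table["artifact"] | table["qc_excluded"])).sum()),
        "excluded": {
            "artifact": list(table.loc[table["artifact"], "deployment_id"]),
            "vessels": list(table.loc[table["qc_reason"] == "vessels", "deployment_id"]),
            "predator": list(table.loc[table["qc_reason"] == "predator", "deployment_id"]),
        },
    }
    return table, log


def rose_bins(angles, width: float = 10.0) -> pd.DataFrame:
    """Bin bearings into fixed-width sectors (degrees) for rose diagrams.

    Returns bin_start, bin_mid, count; rendering is left to the user.
    """
    a = np.asarray(angles, dtype=float) % 360.0
    edges = np.arange(0.0, 360.0 + width, width)
    counts, _ = np.histogram(a, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_mid": edges[:-1] + width / 2.0, "count": counts}
    )


def analyze_study(
    results: pd.DataFrame,
    cues: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict:
    """Population-level analysis from within-run results and cue bearings.

    Returns a dict of tables:

    - ``summary`` — per-species counts, proportion directional, mean and
      median within-run r;
    - ``across_run`` — species x reference orientation (mean angle,
      precision r, Rayleigh p, n), species under the inclusion threshold
      reported with status instead of dropped;
    - ``regressions`` — per-species logit(r)-on-covariate OLS fits;
    - ``species_comparison`` / ``pairwise`` — rank tests on r;
    - ``dispersion`` — Wallraff comparisons of sun-relative angular
      dispersion between eligible species;
    - ``rose`` — 10-degree binned counts of mean bearings (cardinal and
      sun-relative) per eligible species.
    """
    config = config or RunConfig()
    config.validate()
    merged = results.merge(
        cues.drop(columns=[c for c in ("species",) if c in cues.columns]),
        on="deployment_id",
        how="inner",
    )
    retained = merged[~(merged["artifact"].astype(bool) | merged["qc_excluded"].astype(bool))]
    directional = retained[retained["directionality_p_value"] < config.alpha]

    summary = (
        retained.groupby("species")
        .agg(
            n_tested=("deployment_id", "size"),
            n_directional=("directional", "sum"),
            mean_r=("r", "mean"),
            median_r=("r", "median"),
        )
        .reset_index()
    )
    summary["proportion_directional_pct"] = 100.0 * summary["n_directional"] / summary["n_tested"]

    across = across_run_table(
        results, cues, min_n=config.min_n, basis=config.basis, alpha=config.alpha
    )

    reg_rows = []
    for species, sp in retained.groupby("species"):
        if len(sp) < config.min_n:
            continue
        for cov in COVARIATES:
            if cov not in sp.columns:
                continue
            x = sp[cov].to_numpy(float)
            if np.ptp(x[np.isfinite(x)]) == 0:
                continue
            for quadratic in ((False, True) if cov == "solar_index" else (False,)):
                res = directionality_regression(
                    sp["r"].to_numpy(float), x, quadratic=quadratic,
                    species=species, covariate=cov, alpha=config.alpha,
                )
                reg_rows.append(vars(res))
    regressions = pd.DataFrame(reg_rows)

    r_by_species = {sp: g["r"].to_numpy(float) for sp, g in retained.groupby("species")}
    r_by_species = {k: v for k, v in r_by_species.items() if v.size >= 2}
    comparison = species_comparison(r_by_species) if len(r_by_species) >= 2 else None

    sun_sets = {}
    rose_rows = []
    for species, sp in directional.groupby("species"):
        n_tested = int((retained["species"] == species).sum())
        basis_n = n_tested if config.basis == "tested" else len(sp)
        if basis_n < config.min_n or len(sp) < 2:
            continue
        bearings = sp["mean_bearing"].to_numpy(float)
        sun_rel = relative_angles(bearings, sp["sun_azimuth"].to_numpy(float))
        sun_sets[species] = sun_rel
        for ref, ang in (("north", bearings), ("sun", sun_rel)):
            rb = rose_bins(ang)
            rb.insert(0, "species", species)
            rb.insert(1, "reference", ref)
            rose_rows.append(rb)
    dispersion = dispersion_comparison(sun_sets) if len(sun_sets) >= 2 else None
    rose = pd.concat(rose_rows, ignore_index=True) if rose_rows else pd.DataFrame()

    for table in (summary, across, regressions):
        for key, value in config.convention_flags().items():
            if len(table):
                table[key] = value
    return {
        "summary": summary,
        "across_run": across,
        "regressions": regressions,
        "species_comparison": comparison,
        "dispersion": dispersion,
        "rose": rose,
    }
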