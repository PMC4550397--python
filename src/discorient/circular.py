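"""Circular statistics for bearing data.

All public functions take and return bearings in **degrees clockwise from
true North**, normalized to [0, 360). Radians are used only internally.

The Rayleigh test is the workhorse: within a deployment it measures an
individual larva's ability to keep a bearing (directionality), and across
deployments it measures population-level orientation. Under a unimodal
(ideally von Mises) parent distribution a significant Rayleigh test
indicates concentration around the mean direction, not mere non-uniformity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "CircSummary",
    "RayleighResult",
    "WallraffResult",
    "VonMisesFit",
    "wrap_degrees",
    "circ_mean_r",
    "circ_mean_ci",
    "angular_deviation",
    "rayleigh_test",
    "relative_angles",
    "wallraff_test",
    "vm_sample",
    "vm_fit",
]

#: resultant lengths below this are treated as exactly zero (mean undefined)
_R_EPS = 1e-12

#: analytic Rayleigh p is flagged below this sample size
SMALL_N = 10

#: upper cap for fitted von Mises concentration
KAPPA_MAX = 1e4


def wrap_degrees(angles) -> np.ndarray:
    """Normalize angles to [0, 360)."""
    return np.asarray(angles, dtype=float) % 360.0


@dataclass(frozen=True)
class CircSummary:
    """Circular mean and resultant length of a set of bearings.

    ``r`` is the length of the mean resultant vector: 0 for a perfectly
    uniform spread, 1 when all bearings coincide. ``mean_defined`` is False
    when r is numerically zero, in which case ``mean_bearing`` is reported
    as 0.0 by convention.
    """

    n: int
    mean_bearing: float
    r: float
    mean_defined: bool = True


@dataclass(frozen=True)
class RayleighResult:
    """Rayleigh uniformity test result.

    ``method`` is "analytic" (series approximation in Z = n r^2) or
    "permutation" (Monte-Carlo under the uniform null). ``small_n`` flags
    analytic p-values computed below n = 10 frames/individuals, where the
    series approximation degrades and the permutation method is preferred.
    """

    summary: CircSummary
    p_value: float
    method: str
    small_n: bool = False


@dataclass(frozen=True)
class WallraffResult:
    """Rank test for homogeneity of angular dispersion between groups.

    Each group's members are reduced to their absolute angular deviation
    (shorter arc, in [0, 180]) from that group's own circular mean; the
    deviations are then compared with a rank-sum test (two groups) or a
    Kruskal-Wallis test (more groups).
    """

    statistic: float
    p_value: float
    group_dispersions: tuple[float, ...] = field(default_factory=tuple)
    method: str = "rank-sum"


@dataclass(frozen=True)
class VonMisesFit:
    """Maximum-likelihood von Mises parameters (mu in degrees, kappa >= 0)."""

    mu: float
    kappa: float
    capped: bool = False
    mean_defined: bool = True


def _check_angles(angles, min_n: int = 1) -> np.ndarray:
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    if a.ndim != 1:
        raise ValueError("angles must be one-dimensional")
    if a.size < min_n:
        raise ValueError(f"need at least {min_n} angles, got {a.size}")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    return a % 360.0


def _resultant(angles_deg: np.ndarray) -> tuple[float, float]:
    """Mean-resultant length and mean direction (degrees) of a sample."""
    rad = np.radians(angles_deg)
    c = np.cos(rad).mean()
    s = np.sin(rad).mean()
    r = float(np.hypot(c, s))
    mean = float(np.degrees(np.arctan2(s, c))) % 360.0
    if mean >= 360.0:  # float rounding of tiny negative angles
        mean = 0.0
    return r, mean


def circ_mean_r(angles) -> CircSummary:
    """Circular mean bearing and resultant length r of a set of bearings.

    For bearings measured clockwise from North the mean is
    atan2(mean sin, mean cos) of the angles, mapped back to [0, 360).
    When r is numerically zero (e.g. four bearings at the cardinal points)
    the mean direction is undefined; 0.0 is reported with
    ``mean_defined=False``.
    """
    a = _check_angles(angles, min_n=1)
    r, mean = _resultant(a)
    if r <= _R_EPS:
        return CircSummary(n=a.size, mean_bearing=0.0, r=0.0, mean_defined=False)
    return CircSummary(n=a.size, mean_bearing=mean, r=min(r, 1.0))


def angular_deviation(angles, reference: float | None = None) -> np.ndarray:
    """Absolute angular deviations (shorter arc, degrees in [0, 180]).

    Deviations are taken from ``reference`` if given, otherwise from the
    sample's own circular mean.
    """
    a = _check_angles(angles, min_n=1)
    if reference is None:
        reference = circ_mean_r(a).mean_bearing
    d = np.abs((a - reference) % 360.0)
    return np.minimum(d, 360.0 - d)


def relative_angles(bearings, cue_bearings) -> np.ndarray:
    """Angles of bearings relative to cue bearings, elementwise.

    The result is (bearing - cue) mod 360: 0 deg means the larva headed
    toward the cue, 180 deg away from it.
    """
    b = np.atleast_1d(np.asarray(bearings, dtype=float))
    c = np.atleast_1d(np.asarray(cue_bearings, dtype=float))
    if b.shape != c.shape:
        raise ValueError(f"length mismatch: {b.shape} bearings vs {c.shape} cues")
    return (b - c) % 360.0


def _rayleigh_p_analytic(n: int, r: float) -> float:
    """Series approximation of the Rayleigh p-value in Z = n r^2.

    Second-order correction to exp(-Z); accurate to ~1e-3 for n >= 10.
    """
    z = n * r * r
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return float(min(max(p, 0.0), 1.0))


def rayleigh_test(
    angles,
    method: str = "analytic",
    n_perm: int = 9999,
    seed: int | None = None,
) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    Parameters
    ----------
    angles : array-like of degrees
        At least two bearings.
    method : {"analytic", "permutation"}
        "analytic" uses the classical series approximation in Z = n r^2.
        "permutation" draws ``n_perm`` uniform samples of the same size and
        compares their resultant lengths to the observed one; it requires
        ``n_perm >= 999`` and an explicit ``seed``.

    Notes
    -----
    For fixed n the p-value is strictly decreasing in r. Positions recorded
    a few seconds apart are serially correlated; the test (as used here)
    ignores that, so within-run p-values are anti-conservative in an
    absolute sense and are best read comparatively.
    """
    a = _check_angles(angles, min_n=2)
    n = a.size
    r, mean = _resultant(a)
    summary = CircSummary(n=n, mean_bearing=mean if r > _R_EPS else 0.0,
                          r=min(r, 1.0), mean_defined=r > _R_EPS)
    if method == "analytic":
        p = _rayleigh_p_analytic(n, r)
        return RayleighResult(summary, p, "analytic", small_n=n < SMALL_N)
    if method == "permutation":
        if n_perm < 999:
            raise ValueError("permutation method requires n_perm >= 999")
        if seed is None:
            raise ValueError("permutation method requires an explicit seed")
        rng = np.random.default_rng(seed)
        sim = rng.uniform(0.0, 2.0 * np.pi, size=(n_perm, n))
        r_sim = np.hypot(np.cos(sim).mean(axis=1), np.sin(sim).mean(axis=1))
        # add-one rule keeps p in (0, 1] and unbiased under the null
        p = (1.0 + np.count_nonzero(r_sim >= r - 1e-15)) / (n_perm + 1.0)
        return RayleighResult(summary, float(p), "permutation")
    raise ValueError(f"unknown method {method!r}")


def circ_mean_ci(angles, confidence: float = 0.95) -> tuple[float, float]:
    """Mean bearing and half-width (degrees) of its large-sample CI.

    Uses the dispersion-based normal approximation for the circular mean:
    half-width = asin(z * sigma_hat) with
    sigma_hat^2 = (1 - a2) / (2 n r^2), a2 the mean cosine of twice the
    deviations from the mean. Returns half-width 180 when the interval is
    uninformative (r too small or the asin argument exceeds 1).
    """
    a = _check_angles(angles, min_n=2)
    summ = circ_mean_r(a)
    if not summ.mean_defined or summ.r <= _R_EPS:
        return summ.mean_bearing, 180.0
    rad = np.radians(a - summ.mean_bearing)
    a2 = float(np.cos(2.0 * rad).mean())
    sigma2 = (1.0 - a2) / (2.0 * a.size * summ.r**2)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    arg = z * math.sqrt(max(sigma2, 0.0))
    if arg >= 1.0:
        return summ.mean_bearing, 180.0
    return summ.mean_bearing, float(np.degrees(math.asin(arg)))


def wallraff_test(groups) -> WallraffResult:
    """Wallraff test for differences in angular dispersion between groups.

    Each group (a sequence of bearings, n >= 2) is reduced to the absolute
    angular deviations of its members from its own circular mean; a
    rank-sum test (two groups) or Kruskal-Wallis test (more) then compares
    the deviation samples. Relabelling groups leaves the p-value unchanged.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    devs = []
    for g in groups:
        a = _check_angles(g, min_n=2)
        devs.append(angular_deviation(a))
    dispersions = tuple(float(np.median(d)) for d in devs)
    if len(devs) == 2:
        res = stats.mannwhitneyu(devs[0], devs[1], alternative="two-sided")
        return WallraffResult(float(res.statistic), float(res.pvalue),
                              dispersions, method="rank-sum")
    res = stats.kruskal(*devs)
    return WallraffResult(float(res.statistic), float(res.pvalue),
                          dispersions, method="kruskal-wallis")


def vm_sample(mu: float, kappa: float, n: int, seed: int | None) -> np.ndarray:
    """Draw n bearings (degrees) from a von Mises distribution.

    kappa = 0 yields the circular uniform distribution. Reproducible for a
    given seed.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if kappa == 0:
        return rng.uniform(0.0, 360.0, size=n)
    draws = rng.vonmises(np.radians(mu), kappa, size=n)
    return np.degrees(draws) % 360.0


def _a1(kappa: float) -> float:
    """A(kappa) = I1(kappa)/I0(kappa), the mean resultant of a von Mises."""
    return float(special.i1e(kappa) / special.i0e(kappa))


def _a1inv(r: float) -> float:
    # Best & Fisher piecewise starting value for the MLE of kappa
    if r < 0.53:
        return 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    return 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)


def vm_fit(angles) -> VonMisesFit:
    """Maximum-likelihood von Mises fit (mu, kappa) to a sample of bearings.

    mu is the circular mean. kappa solves A(kappa) = r, started from the
    Best-Fisher approximation and refined by Newton iterations on
    A'(kappa) = 1 - A/kappa - A^2. Degenerate cases: r = 0 gives kappa = 0
    with an undefined mean; r -> 1 is capped at ``KAPPA_MAX`` and flagged.
    """
    a = _check_angles(angles, min_n=5)
    summ = circ_mean_r(a)
    if not summ.mean_defined:
        return VonMisesFit(mu=0.0, kappa=0.0, mean_defined=False)
    r = summ.r
    if r >= 1.0 - 1e-12:
        return VonMisesFit(mu=summ.mean_bearing, kappa=KAPPA_MAX, capped=True)
    kappa = _a1inv(r)
    for _ in range(25):
        if kappa <= 0 or kappa >= KAPPA_MAX:
            break
        f = _a1(kappa) - r
        fp = 1.0 - _a1(kappa) / kappa - _a1(kappa) ** 2
        if fp == 0.0:
            break
        step = f / fp
        kappa -= step
        if abs(step) < 1e-10:
            break
    if not np.isfinite(kappa) or kappa >= KAPPA_MAX:
        return VonMisesFit(mu=summ.mean_bearing, kappa=KAPPA_MAX, capped=True)
    return VonMisesFit(mu=summ.mean_bearing, kappa=max(float(kappa), 0.0))
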