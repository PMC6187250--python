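"""Per-subject log-linear estimation of (x, ln k') and random-effects pooling.

In the noiseless limit the reduced rate law is exactly log-linear:

    ln(d[BP2]/dt) = ln(k') + x * ln([BP1])

so each subject/region series yields an ordinary-least-squares estimate of the
reaction order ``x`` (slope) and ``ln k'`` (intercept), with d[BP2]/dt taken
from finite differences of the measured downstream series.  Nonpositive rate
estimates (which arise from noise and have no logarithm) are dropped and
counted rather than rectified.  Subject-level estimates are pooled per region
with a DerSimonian-Laird random-effects model; an unweighted one-sample t-test
is reported alongside as a robustness line, and Benjamini-Hochberg FDR is
applied across regions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import MeasurementTable
from .kinetics import finite_difference_rates

__all__ = [
    "AxisKindError",
    "SubjectFit",
    "GroupResult",
    "fit_subject",
    "fit_cohort",
    "pool_random_effects",
    "pool_all_regions",
]

_SE_FLOOR = 1e-10  # keeps inverse-variance weights finite on noiseless fits


class AxisKindError(ValueError):
    """A table with the wrong axis kind was passed to an estimator."""


@dataclass(frozen=True)
class SubjectFit:
    """One subject/region estimate of the log-linear model.

    ``ok`` is False when fewer than ``min_points`` usable points survive the
    filtering; batch runs carry such flagged fits along instead of raising.
    ``sign_flipped`` records that the finite-difference rates were
    predominantly negative (as happens when the nominally downstream series is
    in fact depleting) and |rate| was used.
    """

    subject: str
    region: str
    ok: bool
    x_hat: float = float("nan")
    ln_kprime_hat: float = float("nan")
    se_x: float = float("nan")
    se_ln_kprime: float = float("nan")
    r2: float = float("nan")
    n_points_total: int = 0
    n_points_used: int = 0
    n_points_dropped_nonpositive: int = 0
    n_points_dropped_endpoint: int = 0
    sign_flipped: bool = False
    message: str = ""


@dataclass(frozen=True)
class GroupResult:
    """Random-effects summary of subject-level fits for one region."""

    region: str
    ok: bool
    x_hat: float = float("nan")
    x_se: float = float("nan")
    ln_kprime_hat: float = float("nan")
    ln_kprime_se: float = float("nan")
    tau2: float = float("nan")
    z_stat: float = float("nan")
    p_value: float = float("nan")
    t_stat: float = float("nan")
    p_value_t: float = float("nan")
    n_subjects: int = 0
    p_fdr: float | None = None
    message: str = ""


def _log_points(
    times: np.ndarray,
    bp1: np.ndarray,
    bp2: np.ndarray,
    *,
    rates=None,
    drop_endpoints: bool = True,
    pairing: str = "same",
):
    """Usable (ln[BP1], ln rate) pairs for one series, plus filtering counts.

    Returns ``(lx, ly, diag)`` where ``diag`` carries the point accounting
    (total, used, dropped nonpositive, dropped endpoint, sign_flipped).
    Shared by the per-subject estimator and the direction-comparison pooling.
    """
    if pairing not in ("same", "midpoint"):
        raise ValueError(f"unknown pairing {pairing!r}")
    n_endpoint = 0
    if pairing == "same":
        r = np.asarray(rates, dtype=float) if rates is not None else (
            finite_difference_rates(times, bp2)
        )
        conc = bp1
        if drop_endpoints and rates is None and len(r) > 2:
            r, conc = r[1:-1], conc[1:-1]
            n_endpoint = 2
        total = len(times)
    else:
        r = np.diff(bp2) / np.diff(times)
        conc = np.exp((np.log(bp1[:-1]) + np.log(bp1[1:])) / 2)
        total = len(r)

    sign_flipped = False
    if np.median(r) < 0:
        r = -r
        sign_flipped = True

    usable = (r > 0) & (conc > 0)
    diag = dict(
        n_points_total=total,
        n_points_used=int(np.sum(usable)),
        n_points_dropped_nonpositive=int(np.sum(~usable)),
        n_points_dropped_endpoint=n_endpoint,
        sign_flipped=sign_flipped,
    )
    return np.log(conc[usable]), np.log(r[usable]), diag


def fit_subject(
    times,
    bp1,
    bp2,
    subject: str = "",
    region: str = "",
    *,
    rates=None,
    drop_endpoints: bool = True,
    pairing: str = "same",
    min_points: int = 3,
) -> SubjectFit:
    """Fit ln(rate) = ln(k') + x ln([BP1]) for one subject/region series.

    Parameters
    ----------
    times, bp1, bp2
        Visit times (years) and the upstream/downstream measured series.
    rates
        Optional externally supplied d[BP2]/dt values (e.g., analytic rates);
        when omitted they are estimated by finite differences of ``bp2``.
    drop_endpoints
        Drop the two one-sided-difference endpoints (default True: their O(h)
        bias dominates on short series).  Ignored for midpoint pairing.
    pairing
        ``"same"`` regresses the rate at each visit on [BP1] at that visit;
        ``"midpoint"`` uses interval secant slopes paired with the geometric
        midpoint of adjacent [BP1] values.
    """
    times = np.asarray(times, dtype=float)
    bp1 = np.asarray(bp1, dtype=float)
    bp2 = np.asarray(bp2, dtype=float)
    if len(times) < min_points or len(times) < 3:
        return SubjectFit(subject, region, False, n_points_total=len(times),
                          message="fewer than 3 visits")
    lx, ly, base = _log_points(
        times, bp1, bp2, rates=rates, drop_endpoints=drop_endpoints, pairing=pairing
    )
    if base["n_points_used"] < max(min_points, 3):
        return SubjectFit(subject, region, False,
                          message="fewer than 3 usable points after dropping",
                          **base)
    if np.ptp(lx) == 0:
        return SubjectFit(subject, region, False,
                          message="degenerate regressor (constant [BP1])", **base)
    res = stats.linregress(lx, ly)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return SubjectFit(
        subject, region, True,
        x_hat=float(res.slope),
        ln_kprime_hat=float(res.intercept),
        se_x=float(res.stderr),
        se_ln_kprime=float(res.intercept_stderr),
        r2=r2,
        **base,
    )


def _parse_direction(direction, labels: tuple[str, ...]) -> tuple[str, str]:
    if isinstance(direction, str):
        parts = [p.strip() for p in direction.split("->")]
        if len(parts) != 2:
            raise ValueError(f"direction must look like 'BP1->BP2', got {direction!r}")
        direction = tuple(parts)
    up, down = direction
    if {up, down} != set(labels):
        raise ValueError(
            f"direction labels {direction} do not match table biomarkers {labels}"
        )
    return up, down


def fit_cohort(
    table: MeasurementTable,
    direction="BP1->BP2",
    *,
    drop_endpoints: bool = True,
    pairing: str = "same",
) -> list[SubjectFit]:
    """Fit every (subject, region) series of a longitudinal table.

    ``direction`` names which biomarker label plays the upstream role, as a
    ``"UP->DOWN"`` string or a label pair.  Output is ordered by (subject,
    region); series that cannot be fit are returned flagged, not raised.
    """
    if table.axis_kind != "time":
        raise AxisKindError(
            f"longitudinal fitting requires axis_kind 'time', got {table.axis_kind!r}"
        )
    up, down = _parse_direction(direction, table.biomarkers)
    piv = table.measurements.pivot_table(
        index=["subject", "region", "axis_value"], columns="biomarker", values="value"
    ).reset_index()
    fits = []
    for (subj, region), g in piv.groupby(["subject", "region"], sort=True):
        fits.append(
            fit_subject(
                g["axis_value"].to_numpy(), g[up].to_numpy(), g[down].to_numpy(),
                subject=str(subj), region=str(region),
                drop_endpoints=drop_endpoints, pairing=pairing,
            )
        )
    return fits


def _dersimonian_laird(est: np.ndarray, se: np.ndarray):
    """Closed-form DerSimonian-Laird pooling; returns (pooled, se, tau2)."""
    w = 1.0 / np.maximum(se, _SE_FLOOR) ** 2
    mu_fixed = np.sum(w * est) / np.sum(w)
    q = np.sum(w * (est - mu_fixed) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (len(est) - 1)) / c) if c > 0 else 0.0
    wstar = 1.0 / (np.maximum(se, _SE_FLOOR) ** 2 + tau2)
    pooled = np.sum(wstar * est) / np.sum(wstar)
    return float(pooled), float(np.sqrt(1.0 / np.sum(wstar))), float(tau2)


def pool_random_effects(fits: list[SubjectFit], region: str | None = None) -> GroupResult:
    """Pool subject-level fits for one region with a random-effects model.

    Reports the DerSimonian-Laird pooled x (weights 1/(se^2 + tau^2)) with a
    two-sided z test of x = 0, the analogous pooling of ln k', and an
    unweighted one-sample t-test on the x estimates as a robustness line.
    """
    sel = [f for f in fits if f.ok and (region is None or f.region == region)]
    label = region if region is not None else (sel[0].region if sel else "")
    if len(sel) < 2:
        return GroupResult(label or "", False, n_subjects=len(sel),
                           message="fewer than 2 usable fits")
    x = np.array([f.x_hat for f in sel])
    se = np.array([f.se_x for f in sel])
    pooled, pooled_se, tau2 = _dersimonian_laird(x, se)
    lnk, lnk_se, _ = _dersimonian_laird(
        np.array([f.ln_kprime_hat for f in sel]),
        np.array([f.se_ln_kprime for f in sel]),
    )
    z = pooled / pooled_se if pooled_se > 0 else np.inf * np.sign(pooled)
    p = float(2 * stats.norm.sf(abs(z)))
    if np.ptp(x) == 0:
        t_stat, p_t = (np.inf if x[0] != 0 else 0.0), (0.0 if x[0] != 0 else 1.0)
    else:
        t_res = stats.ttest_1samp(x, 0.0)
        t_stat, p_t = float(t_res.statistic), float(t_res.pvalue)
    return GroupResult(
        label, True,
        x_hat=pooled, x_se=pooled_se,
        ln_kprime_hat=lnk, ln_kprime_se=lnk_se,
        tau2=tau2, z_stat=float(z), p_value=p,
        t_stat=t_stat, p_value_t=p_t,
        n_subjects=len(sel),
    )


def pool_all_regions(fits: list[SubjectFit], fdr_level: float = 0.05) -> list[GroupResult]:
    """Pool every region and attach Benjamini-Hochberg FDR-adjusted p-values."""
    regions = sorted({f.region for f in fits})
    results = [pool_random_effects(fits, region=r) for r in regions]
    okmask = [r.ok for r in results]
    if any(okmask):
        pvals = [r.p_value for r in results if r.ok]
        _, p_adj, _, _ = multipletests(pvals, alpha=fdr_level, method="fdr_bh")
        it = iter(p_adj)
        results = [replace(r, p_fdr=float(next(it))) if r.ok else r for r in results]
    return results


def fits_to_frame(fits: list[SubjectFit]) -> pd.DataFrame:
    """Tabulate subject fits (one row per fit) for reporting/serialization."""
    return pd.DataFrame([f.__dict__ for f in fits])
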