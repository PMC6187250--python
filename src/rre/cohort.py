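"""Synthetic cohort generation for the kinetic estimators.

Emulates multi-subject, multi-region, two-tracer concentration panels with the
statistical structure the estimators assume: positive SUVR-like measurements,
subject-level onset heterogeneity (time shifts along a shared trajectory),
multiplicative log-normal measurement noise, and small additive covariate
effects (age, sex, education).  Longitudinal cohorts observe each subject on a
common visit grid; cross-sectional cohorts observe each subject once at a
latent disease time mapped linearly from a severity score tau
(``time = severity_to_time * tau + onset``).

Every draw is reproducible from the design's master seed, which is expanded
into independent per-subject streams so that growing ``n_subjects`` does not
reshuffle existing subjects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import ReactionSpec, SystemState, simulate_closed

__all__ = [
    "SchemaError",
    "CovariateEffects",
    "CohortDesign",
    "MeasurementTable",
    "generate_longitudinal",
    "generate_cross_sectional",
    "write_cohort",
    "read_cohort",
    "longitudinal_benchmark_design",
    "cross_sectional_benchmark_design",
]

MEASUREMENT_COLUMNS = ["subject", "region", "axis_value", "axis_kind", "biomarker", "value"]
COVARIATE_COLUMNS = ["subject", "age", "sex", "education", "severity"]

# population the covariate draws emulate (typical dementia-cohort demographics)
_AGE_MEAN, _AGE_SD = 70.0, 8.0
_EDU_MEAN, _EDU_SD = 14.0, 3.0


class SchemaError(ValueError):
    """A measurements/covariates table violates the cohort file contract."""


@dataclass(frozen=True)
class CovariateEffects:
    """Additive effects of (centered) covariates on measured values.

    Units: concentration per year of age, per sex indicator, per year of
    education.  Defaults are small (a few percent of a unit-scale signal) so
    they act as removable confounds rather than dominating structure.
    """

    age: float = 0.001
    sex: float = 0.02
    education: float = 0.002

    @classmethod
    def zero(cls) -> "CovariateEffects":
        return cls(0.0, 0.0, 0.0)

    def apply(self, age: float, sex: float, education: float) -> float:
        return (
            self.age * (age - _AGE_MEAN)
            + self.sex * (sex - 0.5)
            + self.education * (education - _EDU_MEAN)
        )


@dataclass(frozen=True)
class CohortDesign:
    """Generative parameters for a synthetic cohort.

    ``visit_times`` drives longitudinal generation (shared biennial grid by
    default); ``severity_range``/``severities`` drive cross-sectional
    generation (tau on a 0-10 unitless scale, one observation per subject).
    ``region_kprime_multipliers`` scale the shared k' per region;
    ``region_bp1_multipliers`` scale the baseline upstream concentration per
    region (the source of the across-region [BP1] spread the cross-sectional
    regression needs).  ``onset_sd`` is the SD (years) of the subject onset
    offset; ``noise_sigma`` the SD of log-normal measurement noise on the log
    scale.
    """

    n_subjects: int = 50
    regions: tuple[str, ...] = ("r01",)
    spec: ReactionSpec = field(default_factory=ReactionSpec)
    visit_times: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    severity_range: tuple[float, float] = (0.0, 10.0)
    severities: tuple[float, ...] | None = None
    severity_to_time: float = 1.0  # alpha: years per severity unit
    bp1_0: float = 1.0
    bp2_0: float = 0.1
    region_kprime_multipliers: tuple[float, ...] | None = None
    region_bp1_multipliers: tuple[float, ...] | None = None
    onset_sd: float = 2.0
    noise_sigma: float = 0.05
    noise_kind: str = "lognormal"  # or "additive"
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.onset_sd < 0:
            raise ValueError("onset_sd must be >= 0")
        if self.noise_kind not in ("lognormal", "additive"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if not self.regions:
            raise ValueError("need at least one region")
        for name, mult in (
            ("region_kprime_multipliers", self.region_kprime_multipliers),
            ("region_bp1_multipliers", self.region_bp1_multipliers),
        ):
            if mult is not None:
                if len(mult) != len(self.regions):
                    raise ValueError(f"{name} must have one entry per region")
                if any(v <= 0 for v in mult):
                    raise ValueError(f"{name} must be positive")
        if self.severities is not None:
            if len(self.severities) != self.n_subjects:
                raise ValueError("severities must have one entry per subject")
            if any(s < 0 for s in self.severities):
                raise ValueError("severity scores must be nonnegative")
        lo, hi = self.severity_range
        if lo < 0 or hi < lo:
            raise ValueError("severity_range must be 0 <= lo <= hi")

    def kprime_multiplier(self, r: int) -> float:
        return 1.0 if self.region_kprime_multipliers is None else float(
            self.region_kprime_multipliers[r]
        )

    def bp1_multiplier(self, r: int) -> float:
        return 1.0 if self.region_bp1_multipliers is None else float(
            self.region_bp1_multipliers[r]
        )


@dataclass(frozen=True)
class MeasurementTable:
    """A tidy measurements panel plus per-subject covariates.

    ``measurements`` columns: subject, region, axis_value, axis_kind
    (``time`` or ``severity``), biomarker, value.  ``covariates`` columns:
    subject, age, sex, education, severity.
    """

    measurements: pd.DataFrame
    covariates: pd.DataFrame

    @property
    def axis_kind(self) -> str:
        kinds = self.measurements["axis_kind"].unique()
        if len(kinds) != 1:
            raise SchemaError(f"mixed axis kinds {sorted(kinds)}")
        return str(kinds[0])

    @property
    def biomarkers(self) -> tuple[str, ...]:
        return tuple(sorted(self.measurements["biomarker"].unique()))

    def with_swapped_labels(self) -> "MeasurementTable":
        """Exchange the two biomarker labels (used by relabeling tests)."""
        a, b = self.biomarkers
        meas = self.measurements.copy()
        meas["biomarker"] = meas["biomarker"].map({a: b, b: a})
        return MeasurementTable(meas, self.covariates.copy())

    def validate(self) -> None:
        _validate_measurements(self.measurements)
        _validate_covariates(self.covariates, self.measurements)


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # per-subject stream: stable under changes to n_subjects
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _subject_ids(n: int) -> list[str]:
    return [f"s{i + 1:04d}" for i in range(n)]


def _region_spec(design: CohortDesign, r: int) -> ReactionSpec:
    s = design.spec
    return ReactionSpec(
        kprime=s.kprime * design.kprime_multiplier(r),
        x=s.x, a=s.a, m=s.m, direction=s.direction,
    )


def _region_curve(design: CohortDesign, r: int, disease_times: np.ndarray):
    """Evaluate the shared closed-system curve of region ``r`` at arbitrary
    nonnegative times (all subjects in a region lie on one trajectory)."""
    uniq = np.unique(np.asarray(disease_times, dtype=float))
    grid = uniq if uniq[0] == 0.0 else np.concatenate(([0.0], uniq))
    if len(grid) < 2:
        grid = np.array([grid[0], grid[0] + 1.0])
    init = SystemState(design.bp1_0 * design.bp1_multiplier(r), design.bp2_0)
    traj = simulate_closed(_region_spec(design, r), init, grid)
    idx = np.searchsorted(grid, disease_times)
    return traj.bp1[idx], traj.bp2[idx]


def _noisy(true: float, z: float, eff: float, design: CohortDesign) -> float:
    if design.noise_kind == "lognormal":
        v = true * float(np.exp(design.noise_sigma * z)) + eff
    else:
        v = true + design.noise_sigma * z + eff
    if v <= 0:
        raise ValueError(
            "generated a nonpositive measurement; reduce noise or covariate effects"
        )
    return v


def generate_longitudinal(design: CohortDesign) -> MeasurementTable:
    """Generate a longitudinal panel: every subject, region, visit, both tracers.

    Each subject's disease clock is its visit grid shifted by an onset offset
    ~ Normal(0, onset_sd), truncated so all disease times stay nonnegative;
    the measured axis is the (unshifted) study clock.  Measurement noise is
    multiplicative log-normal; covariate effects are additive.
    """
    visits = np.asarray(design.visit_times, dtype=float)
    if visits.size == 0:
        raise ValueError("visit_times must be nonempty for longitudinal generation")
    if not np.all(np.diff(visits) > 0):
        raise ValueError("visit_times must be strictly increasing")

    subjects = _subject_ids(design.n_subjects)
    R, V = len(design.regions), len(visits)
    ages, sexes, edus, onsets, noises = [], [], [], [], []
    for i in range(design.n_subjects):
        rng = _subject_rng(design.seed, i)
        ages.append(rng.normal(_AGE_MEAN, _AGE_SD))
        sexes.append(float(rng.integers(0, 2)))
        edus.append(float(np.clip(rng.normal(_EDU_MEAN, _EDU_SD), 8.0, 22.0)))
        delta = rng.normal(0.0, design.onset_sd) if design.onset_sd > 0 else 0.0
        onsets.append(max(delta, -float(visits.min())))
        noises.append(rng.standard_normal((R, V, 2)))

    up, down = design.spec.direction
    rows = []
    for r, region in enumerate(design.regions):
        all_times = np.concatenate([visits + d for d in onsets])
        bp1_flat, bp2_flat = _region_curve(design, r, all_times)
        for i, subj in enumerate(subjects):
            eff = design.covariate_effects.apply(ages[i], sexes[i], edus[i])
            sl = slice(i * V, (i + 1) * V)
            for v in range(V):
                z1, z2 = noises[i][r, v]
                rows.append(
                    (subj, region, visits[v], "time", up,
                     _noisy(bp1_flat[sl][v], z1, eff, design))
                )
                rows.append(
                    (subj, region, visits[v], "time", down,
                     _noisy(bp2_flat[sl][v], z2, eff, design))
                )

    measurements = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    measurements = measurements.sort_values(
        ["subject", "region", "axis_value", "biomarker"], kind="mergesort"
    ).reset_index(drop=True)
    covariates = pd.DataFrame(
        {
            "subject": subjects,
            "age": ages,
            "sex": sexes,
            "education": edus,
            # baseline disease progression mapped to the severity scale
            "severity": np.asarray(onsets) / design.severity_to_time,
        }
    )
    return MeasurementTable(measurements, covariates)


def generate_cross_sectional(design: CohortDesign) -> MeasurementTable:
    """Generate a cross-sectional panel: one observation per subject.

    Subject severity tau is drawn uniformly on ``severity_range`` (or taken
    from ``design.severities``); the latent disease time is
    ``severity_to_time * tau + onset`` truncated at 0.
    """
    subjects = _subject_ids(design.n_subjects)
    R = len(design.regions)
    ages, sexes, edus, taus, times, noises = [], [], [], [], [], []
    for i in range(design.n_subjects):
        rng = _subject_rng(design.seed, i)
        ages.append(rng.normal(_AGE_MEAN, _AGE_SD))
        sexes.append(float(rng.integers(0, 2)))
        edus.append(float(np.clip(rng.normal(_EDU_MEAN, _EDU_SD), 8.0, 22.0)))
        if design.severities is not None:
            tau = float(design.severities[i])
        else:
            tau = float(rng.uniform(*design.severity_range))
        if tau < 0:
            raise ValueError("severity scores must be nonnegative")
        delta = rng.normal(0.0, design.onset_sd) if design.onset_sd > 0 else 0.0
        taus.append(tau)
        times.append(max(design.severity_to_time * tau + delta, 0.0))
        noises.append(rng.standard_normal((R, 2)))

    up, down = design.spec.direction
    times = np.asarray(times)
    rows = []
    for r, region in enumerate(design.regions):
        bp1_vals, bp2_vals = _region_curve(design, r, times)
        for i, subj in enumerate(subjects):
            eff = design.covariate_effects.apply(ages[i], sexes[i], edus[i])
            z1, z2 = noises[i][r]
            rows.append(
                (subj, region, taus[i], "severity", up,
                 _noisy(bp1_vals[i], z1, eff, design))
            )
            rows.append(
                (subj, region, taus[i], "severity", down,
                 _noisy(bp2_vals[i], z2, eff, design))
            )

    measurements = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    measurements = measurements.sort_values(
        ["subject", "region", "axis_value", "biomarker"], kind="mergesort"
    ).reset_index(drop=True)
    covariates = pd.DataFrame(
        {"subject": subjects, "age": ages, "sex": sexes, "education": edus,
         "severity": taus}
    )
    return MeasurementTable(measurements, covariates)


# ---------------------------------------------------------------------------
# benchmark designs: the study conditions used by the validation suite


def longitudinal_benchmark_design(
    x: float = 1.0,
    kprime: float = 0.05,
    n_subjects: int = 50,
    noise_sigma: float = 0.05,
    seed: int = 0,
    **overrides,
) -> CohortDesign:
    """The reference longitudinal cohort: biennial visits over a decade."""
    spec = ReactionSpec(kprime=kprime, x=x)
    return CohortDesign(
        n_subjects=n_subjects, spec=spec, noise_sigma=noise_sigma, seed=seed,
        **overrides,
    )


def cross_sectional_benchmark_design(
    x: float = 1.0,
    kprime: float = 0.05,
    n_subjects: int = 200,
    n_regions: int = 10,
    noise_sigma: float = 0.05,
    kprime_span: float = 4.0,
    bp1_span: float = 4.0,
    seed: int = 0,
    **overrides,
) -> CohortDesign:
    """The reference cross-sectional cohort: early-phase severity, 10 regions.

    Region baseline upstream concentrations follow a geometric grid spanning
    ``bp1_span``; region rate-constant multipliers span ``kprime_span`` on a
    mirror-symmetric grid.  The symmetric k' grid is exactly orthogonal (in
    sample) to the antisymmetric log-baseline grid, so rate-constant
    heterogeneity does not confound the whole-brain reaction-order regression
    (which, like the model it fits, carries a single intercept ln k').
    """
    regions = tuple(f"r{i + 1:02d}" for i in range(n_regions))
    bp1_mult = tuple(np.geomspace(1 / np.sqrt(bp1_span), np.sqrt(bp1_span), n_regions))
    half = np.geomspace(1 / np.sqrt(kprime_span), np.sqrt(kprime_span),
                        (n_regions + 1) // 2)
    kp_mult = tuple(np.concatenate([half, half[: n_regions - len(half)][::-1]]))
    spec = ReactionSpec(kprime=kprime, x=x)
    defaults = dict(
        n_subjects=n_subjects,
        regions=regions,
        spec=spec,
        severity_range=(0.0, 3.0),  # early phase: limited BP1 depletion
        region_kprime_multipliers=kp_mult,
        region_bp1_multipliers=bp1_mult,
        onset_sd=1.0,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortDesign(**defaults)


# ---------------------------------------------------------------------------
# delimited-text round trip


def write_cohort(table: MeasurementTable, directory, header_comment: str | None = None) -> dict:
    """Write measurements.csv and covariates.csv under ``directory``.

    Returns the mapping of logical names to paths.  ``header_comment`` lines
    (if given) are prepended to each file as ``#``-comments.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": directory / "measurements.csv",
        "covariates": directory / "covariates.csv",
    }
    for name, df in (("measurements", table.measurements), ("covariates", table.covariates)):
        with open(paths[name], "w", newline="") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            df.to_csv(fh, index=False)
    return paths


def _validate_measurements(df: pd.DataFrame) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurements table missing columns {missing}")
    if len(df) == 0:
        raise SchemaError("measurements table is empty")
    kinds = set(df["axis_kind"].unique())
    if not kinds <= {"time", "severity"} or len(kinds) != 1:
        raise SchemaError(f"axis_kind must be uniformly 'time' or 'severity', got {sorted(kinds)}")
    bad = df.index[~(df["value"] > 0)]
    if len(bad):
        raise SchemaError(f"non-positive value at row {bad[0]}")
    labels = sorted(df["biomarker"].unique())
    if len(labels) != 2:
        raise SchemaError(f"expected exactly 2 biomarker labels, got {labels}")
    counts = df.groupby(["subject", "region", "axis_value"])["biomarker"].agg(
        lambda s: tuple(sorted(s))
    )
    bad_keys = counts.index[counts != tuple(labels)]
    if len(bad_keys):
        raise SchemaError(
            f"unpaired biomarker rows for (subject, region, axis_value)={bad_keys[0]}"
        )


def _validate_covariates(cov: pd.DataFrame, meas: pd.DataFrame) -> None:
    missing = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing:
        raise SchemaError(f"covariates table missing columns {missing}")
    absent = set(meas["subject"].unique()) - set(cov["subject"].unique())
    if absent:
        raise SchemaError(f"covariates missing for subjects {sorted(absent)[:3]}")


def read_cohort(directory) -> MeasurementTable:
    """Read and validate a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    mpath, cpath = directory / "measurements.csv", directory / "covariates.csv"
    for p in (mpath, cpath):
        if not p.exists():
            raise FileNotFoundError(str(p))
    try:
        meas = pd.read_csv(mpath, comment="#", float_precision="round_trip")
        cov = pd.read_csv(cpath, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError as err:
        raise SchemaError(f"empty cohort file under {directory}") from err
    table = MeasurementTable(meas, cov)
    table.validate()
    return table
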