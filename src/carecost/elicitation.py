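"""Stage-1 expert-elicitation pipeline.

Clinicians report, for an ordered severity scale, the typical
frequency with which each state is diagnosed, the frequency of false
treatment per state, and (optionally) full accuracy/transition
matrices.  This module

* generates synthetic clinician cohorts emulating such reports (the
  study data behind the default means are not public);
* screens out reports violating the expected strict severity ordering
  of diagnosis frequencies (the outlier pattern used to exclude
  reports in practice);
* runs the validation battery — Shapiro-Wilk normality per state, a
  one-factor ANOVA homogeneity check with a +/-2% band around the
  grand mean, and the six pairwise ordering t-tests; and
* aggregates retained reports into the mean vectors/matrices consumed
  by the prescriptive stage.

Cohort noise is compositional: a report's frequency vector is drawn
from a Dirichlet distribution centred on the target means with
concentration ``dispersion`` (larger = tighter cohort).  The default
concentration of 10 000 keeps a ~100-clinician cohort inside the 2%
homogeneity band that practitioners describe as realistic agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import AccuracyMatrix, RawTransitionMatrix
from .errors import ConfigError, SampleSizeError, StructuralError

__all__ = [
    "TABLE_MEAN_FREQUENCIES",
    "ClinicianReport",
    "GeneratorSpec",
    "generate_reports",
    "generate_cohort",
    "filter_outliers",
    "normality_test",
    "homogeneity_test",
    "ordering_tests",
    "aggregate_reports",
    "AggregateResult",
]

#: Published cohort mean diagnosis frequencies for the 4-state cardiac
#: scale (minor, moderate, major); the severe mean is the remainder.
TABLE_MEAN_FREQUENCIES = (0.54366667, 0.31075, 0.117333)


@dataclass(frozen=True)
class ClinicianReport:
    """One expert's frequency estimates.

    ``state_frequencies`` must be a probability vector (sum 1 within
    1e-6); ``false_treatment`` holds per-state false-treatment
    frequencies in [0, 1]; the matrix estimates are optional.
    """

    clinician_id: str
    state_frequencies: np.ndarray
    false_treatment: np.ndarray | None = None
    transition_estimates: RawTransitionMatrix | None = None
    accuracy_estimates: AccuracyMatrix | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.state_frequencies, dtype=float).copy()
        if f.ndim != 1 or f.size < 2:
            raise StructuralError("state_frequencies must be a vector of length >= 2")
        if np.any(f < 0) or np.any(f > 1) or abs(f.sum() - 1.0) > 1e-6:
            raise StructuralError(
                f"report {self.clinician_id!r}: frequencies must lie in [0, 1] "
                f"and sum to 1 (got sum {f.sum()!r})"
            )
        f.setflags(write=False)
        object.__setattr__(self, "state_frequencies", f)
        if self.false_treatment is not None:
            ft = np.asarray(self.false_treatment, dtype=float).copy()
            if ft.shape != f.shape or np.any(ft < 0) or np.any(ft > 1):
                raise StructuralError(
                    f"report {self.clinician_id!r}: false-treatment frequencies "
                    "must match the state vector and lie in [0, 1]"
                )
            ft.setflags(write=False)
            object.__setattr__(self, "false_treatment", ft)

    @property
    def n_states(self) -> int:
        return self.state_frequencies.size

    def violates_ordering(self) -> bool:
        """True when diagnosis frequencies are not strictly decreasing
        with severity — the screening pattern for outlier reports."""
        f = self.state_frequencies
        return bool(np.any(np.diff(f) >= 0))


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic clinician-cohort generator.

    ``mean_frequencies`` defaults to the published cohort means with
    the severe state taking the remainder.  ``dispersion`` is the
    Dirichlet concentration of report-level noise.  ``contamination``
    is the fraction of reports whose frequencies get a random adjacent
    pair swapped, creating ordering violations like the outlier reports
    observed in practice.  Matrix means, when given, make each report
    carry noisy accuracy/transition estimates centred on them.
    """

    n_clinicians: int = 115
    mean_frequencies: tuple[float, ...] | None = None
    dispersion: float = 10_000.0
    contamination: float = 13 / 115
    seed: int = 0
    mean_accuracy: AccuracyMatrix | None = None
    mean_transitions: RawTransitionMatrix | None = None

    def __post_init__(self) -> None:
        if self.mean_frequencies is None:
            base = TABLE_MEAN_FREQUENCIES
            remainder = 1.0 - sum(base)
            if remainder < 0:
                raise ConfigError("default means exceed 1")  # pragma: no cover
            object.__setattr__(self, "mean_frequencies", (*base, remainder))
        means = tuple(float(v) for v in self.mean_frequencies)
        if any(v < 0 for v in means) or abs(sum(means) - 1.0) > 1e-9:
            raise ConfigError(
                f"mean frequencies must be nonnegative and sum to 1, got {means}"
            )
        object.__setattr__(self, "mean_frequencies", means)
        if not 0.0 <= self.contamination <= 1.0:
            raise ConfigError("contamination must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.n_clinicians < 1:
            raise ConfigError("n_clinicians must be >= 1")

    @property
    def n_states(self) -> int:
        return len(self.mean_frequencies)

    @property
    def n_contaminated(self) -> int:
        """Exact number of ordering-violating reports injected."""
        return int(round(self.n_clinicians * self.contamination))


def _dirichlet_row(rng, means: np.ndarray, concentration: float) -> np.ndarray:
    """Dirichlet draw on the positive support of ``means``, preserving
    structural zeros and the (possibly non-unit) row total."""
    means = np.asarray(means, dtype=float)
    out = np.zeros_like(means)
    pos = means > 0
    total = means[pos].sum()
    if pos.sum() == 1:
        out[pos] = total
        return out
    draw = rng.dirichlet(concentration * means[pos] / total)
    out[pos] = draw * total
    return out


def generate_reports(spec: GeneratorSpec) -> list[ClinicianReport]:
    """Draw a synthetic clinician cohort (see :func:`generate_cohort`)."""
    return generate_cohort(spec)[0]


def generate_cohort(
    spec: GeneratorSpec,
) -> tuple[list[ClinicianReport], set[str]]:
    """Draw a synthetic clinician cohort, returning the contaminated ids too.

    Clean reports are Dirichlet draws centred on the spec means; exactly
    ``spec.n_contaminated`` reports (chosen at random) have a random
    adjacent frequency pair swapped.  When matrix means are supplied,
    each report also carries row-wise Dirichlet-noised accuracy and
    transition estimates (structural zeros preserved, elicited row
    totals kept).  Identical seeds give identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    means = np.asarray(spec.mean_frequencies)
    n = spec.n_clinicians
    contaminated = set(
        rng.choice(n, size=spec.n_contaminated, replace=False).tolist()
    )
    reports = []
    for i in range(n):
        freqs = _dirichlet_row(rng, means, spec.dispersion)
        if i in contaminated:
            j = int(rng.integers(0, spec.n_states - 1))
            freqs[[j, j + 1]] = freqs[[j + 1, j]]
        false_treatment = None
        accuracy = None
        transitions = None
        if spec.mean_accuracy is not None:
            rows = [
                _dirichlet_row(rng, row, spec.dispersion)
                for row in spec.mean_accuracy.values
            ]
            accuracy = AccuracyMatrix(np.vstack(rows), states=spec.mean_accuracy.states)
            false_treatment = 1.0 - np.diag(accuracy.values)
        if spec.mean_transitions is not None:
            rows = [
                _dirichlet_row(rng, row, spec.dispersion)
                for row in spec.mean_transitions.values
            ]
            transitions = RawTransitionMatrix(
                np.vstack(rows), states=spec.mean_transitions.states
            )
        reports.append(
            ClinicianReport(
                clinician_id=f"clinician_{i + 1:03d}",
                state_frequencies=freqs,
                false_treatment=false_treatment,
                accuracy_estimates=accuracy,
                transition_estimates=transitions,
            )
        )
    contaminated_ids = {reports[i].clinician_id for i in contaminated}
    return reports, contaminated_ids


def filter_outliers(
    reports: list[ClinicianReport],
) -> tuple[list[ClinicianReport], list[ClinicianReport]]:
    """Split a cohort into (retained, flagged) by the ordering screen.

    A report is flagged when its diagnosis frequencies are not strictly
    decreasing with severity; all others are retained.  The rule is
    threshold-free: it encodes the one outlier pattern practitioners
    describe (e.g. a 'moderate' frequency above 'minor').
    """
    if not reports:
        raise SampleSizeError("at least one report is required")
    retained = [r for r in reports if not r.violates_ordering()]
    flagged = [r for r in reports if r.violates_ordering()]
    return retained, flagged


def _frequency_matrix(reports: list[ClinicianReport]) -> np.ndarray:
    sizes = {r.n_states for r in reports}
    if len(sizes) != 1:
        raise StructuralError(f"mixed report sizes {sorted(sizes)}")
    return np.vstack([r.state_frequencies for r in reports])


@dataclass(frozen=True)
class NormalityResult:
    state: int
    statistic: float
    p_value: float
    normal_at_05: bool | None  # None when the sample is degenerate


def normality_test(reports: list[ClinicianReport], state: int) -> NormalityResult:
    """Shapiro-Wilk test of the chosen state's frequencies across clinicians.

    Requires at least 3 reports.  A constant-valued sample has no
    defined test statistic; it is reported with NaN statistic/p-value
    and ``normal_at_05=None`` rather than raising.
    """
    if len(reports) < 3:
        raise SampleSizeError("Shapiro-Wilk needs at least 3 reports")
    sample = _frequency_matrix(reports)[:, state]
    if np.ptp(sample) == 0.0:
        return NormalityResult(state, float("nan"), float("nan"), None)
    stat, p = stats.shapiro(sample)
    return NormalityResult(state, float(stat), float(p), bool(p > 0.05))


@dataclass(frozen=True)
class HomogeneityResult:
    """Per-state ANOVA and band findings plus the combined verdict.

    ``anova`` maps state index to (F, p); ``band_ok`` maps state index
    to whether every retained report lies within the cutoff of the
    grand mean.  ``homogeneous`` is True when no state's ANOVA rejects
    at the 5% level and every band holds.
    """

    anova: dict[int, tuple[float, float]]
    band_ok: dict[int, bool]
    max_band_deviation: dict[int, float]
    cutoff: float
    homogeneous: bool


def homogeneity_test(
    reports: list[ClinicianReport],
    cutoff: float = 0.02,
    n_groups: int = 2,
    relative: bool = False,
) -> HomogeneityResult:
    """Cohort homogeneity: block ANOVA plus a band check per state.

    With one frequency per clinician per state, a clinician-level ANOVA
    is not defined; the cohort is instead split into ``n_groups``
    consecutive blocks and a one-factor ANOVA asks whether block means
    differ for each state — under a homogeneous cohort the blocks are
    exchangeable and the test fails to reject.  A zero-variance state
    (identical reports) has an undefined F statistic and counts as
    fail-to-reject.

    The band check asks that every retained report's frequency lie
    within ``cutoff`` of the grand mean — absolute by default (the
    customary '2%' reading), or relative to the grand mean when
    ``relative=True``.
    """
    if len(reports) < 2:
        raise SampleSizeError("homogeneity check needs at least 2 reports")
    freq = _frequency_matrix(reports)
    n, m = freq.shape
    groups = np.array_split(np.arange(n), min(n_groups, n))
    anova: dict[int, tuple[float, float]] = {}
    band_ok: dict[int, bool] = {}
    max_dev: dict[int, float] = {}
    rejected = False
    for s in range(m):
        col = freq[:, s]
        if np.ptp(col) == 0.0:
            anova[s] = (float("nan"), float("nan"))
        else:
            f_stat, p = stats.f_oneway(*[col[g] for g in groups])
            anova[s] = (float(f_stat), float(p))
            if np.isfinite(p) and p < 0.05:
                rejected = True
        grand = col.mean()
        dev = np.abs(col - grand)
        limit = cutoff * abs(grand) if relative else cutoff
        band_ok[s] = bool(np.all(dev <= limit))
        max_dev[s] = float(dev.max())
    homogeneous = (not rejected) and all(band_ok.values())
    return HomogeneityResult(anova, band_ok, max_dev, cutoff, homogeneous)


def ordering_tests(reports: list[ClinicianReport]) -> pd.DataFrame:
    """Six pairwise paired two-tailed t-tests on state frequencies.

    One record per state pair ``(i, j)`` with ``i`` less severe,
    reporting both sample means, their Pearson correlation (the pairing
    rationale), the paired t statistic, one- and two-tailed p-values,
    the 5% critical values, and the sample-mean ordering verdict
    (``mean_i > mean_j``).  Always emits C(M, 2) records.
    """
    if len(reports) < 2:
        raise SampleSizeError("ordering tests need at least 2 reports")
    freq = _frequency_matrix(reports)
    n, m = freq.shape
    df = n - 1
    records = []
    for i, j in combinations(range(m), 2):
        a, b = freq[:, i], freq[:, j]
        if np.ptp(a - b) == 0.0:
            t_stat, p_two = float("nan"), float("nan")
        else:
            t_stat, p_two = stats.ttest_rel(a, b)
        corr = (
            float(stats.pearsonr(a, b)[0])
            if np.ptp(a) > 0 and np.ptp(b) > 0
            else float("nan")
        )
        records.append(
            {
                "state_low": i,
                "state_high": j,
                "mean_low": float(a.mean()),
                "mean_high": float(b.mean()),
                "pearson_correlation": corr,
                "t_stat": float(t_stat),
                "p_one_tailed": float(p_two) / 2 if np.isfinite(t_stat) else float("nan"),
                "t_critical_one_tailed": float(stats.t.ppf(0.95, df)),
                "p_two_tailed": float(p_two),
                "t_critical_two_tailed": float(stats.t.ppf(0.975, df)),
                "ordered": bool(a.mean() > b.mean()),
            }
        )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class AggregateResult:
    """Elementwise means over retained reports."""

    state_frequencies: np.ndarray
    false_treatment: np.ndarray | None
    accuracy: AccuracyMatrix | None
    transitions: RawTransitionMatrix | None
    n_reports: int


def aggregate_reports(
    reports: list[ClinicianReport], renormalize: bool = False
) -> AggregateResult:
    """Unweighted elementwise mean over retained reports.

    Matrix means are taken over the reports that carry matrices (all or
    none per field; mixed shapes raise).  With ``renormalize=True``
    matrix rows are rescaled to sum to 1 and a note is logged; by
    default elicited row totals are preserved as reported.
    """
    if not reports:
        raise SampleSizeError("cannot aggregate an empty report list")
    freq = _frequency_matrix(reports).mean(axis=0)
    ft_list = [r.false_treatment for r in reports if r.false_treatment is not None]
    ft = np.vstack(ft_list).mean(axis=0) if len(ft_list) == len(reports) else None

    def _mean_matrix(mats, cls):
        if not mats:
            return None
        if len(mats) != len(reports):
            raise StructuralError(
                "matrix estimates present on some reports but not all"
            )
        shapes = {m.values.shape for m in mats}
        if len(shapes) != 1:
            raise StructuralError(f"mixed matrix shapes {sorted(shapes)}")
        mean = np.mean([m.values for m in mats], axis=0)
        if renormalize:
            import logging

            logging.getLogger(__name__).info(
                "renormalizing aggregated %s rows to sum to 1", cls.__name__
            )
            mean = mean / mean.sum(axis=1, keepdims=True)
        return cls(mean, states=mats[0].states)

    accuracy = _mean_matrix(
        [r.accuracy_estimates for r in reports if r.accuracy_estimates is not None],
        AccuracyMatrix,
    )
    transitions = _mean_matrix(
        [r.transition_estimates for r in reports if r.transition_estimates is not None],
        RawTransitionMatrix,
    )
    return AggregateResult(freq, ft, accuracy, transitions, len(reports))
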