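"""Incidence-based taxon richness estimation and accumulation curves.

Given a binary taxon x survey detection matrix, the incidence frequency
counts Q_1, Q_2, ... (Q_n = number of taxa detected in exactly n surveys)
summarize how often taxa recur across surveys.  Rarely detected taxa carry
the information about taxa not yet detected at all (Q_0), which the
estimators extrapolate:

* Chao2: lower-bound estimator from Q_1 and Q_2;
* iChao2: Chao2 plus a correction using Q_3 and Q_4;
* ICE: coverage-based estimator using Q_1..Q_10 and a coefficient of
  variation among infrequent taxa (classic gamma^2 variant);
* tWLRM: weighted linear regression on the log-ratios of consecutive
  frequency counts, extrapolated to n = 0.

Accumulation ("collector's") curves show the expected number of taxa
detected in n randomly chosen surveys; their final/initial slope ratio r
is the expected fraction of taxa in one additional survey that would be
novel.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class IncidenceCounts:
    """Observed richness, number of surveys, and frequency counts.

    ``q[n]`` (index 1..m) counts taxa detected in exactly n surveys;
    ``matrix`` retains the raw taxon x survey detections (needed by ICE).
    """

    m: int
    s_obs: int
    q: np.ndarray                 # length m + 1; q[0] unused (0)
    matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InputError(f"number of surveys must be >= 1, got {self.m}")
        if int(self.q[1:].sum()) != self.s_obs:
            raise InputError("frequency counts must sum to S_obs")


@dataclass
class RichnessEstimate:
    estimator: str
    estimate: float
    standard_error: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class AccumulationCurve:
    """Expected taxon count at each number of surveys n = 0..m (0 at n=0)."""

    values: np.ndarray            # length m + 1
    repeats: int

    @property
    def slope_ratio(self) -> float:
        return slope_ratio(self)


def incidence_counts(matrix: np.ndarray) -> IncidenceCounts:
    """Frequency counts from a binary taxon x survey detection matrix.

    Taxa with zero detections are excluded from S_obs (they are, by
    definition, unobserved).
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise InputError(f"detection matrix must be 2-D, got shape {matrix.shape}")
    if not np.isin(matrix, (0, 1)).all():
        raise InputError("detection matrix must be binary (0/1)")
    m = matrix.shape[1]
    row_sums = matrix.sum(axis=1).astype(int)
    observed = row_sums > 0
    q = np.zeros(m + 1, dtype=int)
    for n in range(1, m + 1):
        q[n] = int(np.sum(row_sums == n))
    return IncidenceCounts(m=m, s_obs=int(observed.sum()), q=q,
                           matrix=matrix[observed])


def chao2(counts: IncidenceCounts) -> RichnessEstimate:
    """Chao2 incidence estimator with its analytic standard error.

    S = S_obs + ((m-1)/m) * Q1^2 / (2 Q2) when Q2 > 0, else the
    bias-corrected form S_obs + ((m-1)/m) * Q1 (Q1-1) / (2 (Q2+1)).
    """
    if counts.m < 2:
        raise InputError(f"Chao2 needs >= 2 surveys, got {counts.m}")
    q1, q2 = float(counts.q[1]), float(counts.q[2])
    a = (counts.m - 1) / counts.m
    flags: list[str] = []
    if q2 > 0:
        extra = a * q1 * q1 / (2.0 * q2)
        r = q1 / q2
        var = q2 * (0.5 * a * r**2 + a**2 * r**3 + 0.25 * a**2 * r**4)
    else:
        extra = a * q1 * (q1 - 1.0) / 2.0
        var = (a * q1 * (q1 - 1.0) / 2.0
               + a**2 * q1 * (2.0 * q1 - 1.0) ** 2 / 4.0)
        est0 = counts.s_obs + extra
        if est0 > 0:
            var -= a**2 * q1**4 / (4.0 * est0)
        flags.append("bias_corrected")
    return RichnessEstimate("chao2", counts.s_obs + extra,
                            float(np.sqrt(max(var, 0.0))), flags)


def ichao2(counts: IncidenceCounts, se_bootstrap: int = 200,
           seed: int = 0) -> RichnessEstimate:
    """Improved Chao2: adds a Q3/Q4-based correction term to Chao2.

    S = S_chao2 + ((m-3)/(4m)) * (Q3/Q4)
                * max(Q1 - ((m-3)/(2(m-1))) * Q2 Q3 / Q4, 0).

    Q4 = 0 is handled by the continuity substitution Q4 -> 1 (flagged).
    The correction is non-negative, so iChao2 >= Chao2.  The standard
    error is obtained by bootstrap over surveys (the estimator's reference
    variance has no simple closed form).
    """
    if counts.m < 4:
        raise InputError(f"iChao2 needs >= 4 surveys, got {counts.m}")
    base = chao2(counts)
    est, flags = _ichao2_point(counts)
    se = None
    if counts.matrix is not None and se_bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(se_bootstrap):
            cols = rng.integers(counts.m, size=counts.m)
            try:
                reps.append(_ichao2_point(incidence_counts(counts.matrix[:, cols]))[0])
            except InputError:
                continue
        if len(reps) > 10:
            se = float(np.std(reps, ddof=1))
    return RichnessEstimate("ichao2", est, se, sorted(set(base.flags) | set(flags)))


def _ichao2_point(counts: IncidenceCounts) -> tuple[float, list[str]]:
    base = chao2(counts)
    q1, q2, q3, q4 = (float(counts.q[n]) for n in (1, 2, 3, 4))
    flags: list[str] = []
    if q4 == 0.0:
        q4 = 1.0
        flags.append("q4_substituted")
    m = counts.m
    correction = ((m - 3.0) / (4.0 * m)) * (q3 / q4) * max(
        q1 - ((m - 3.0) / (2.0 * (m - 1.0))) * q2 * q3 / q4, 0.0)
    return base.estimate + correction, flags


def ice(counts: IncidenceCounts, cutoff: int = 10) -> RichnessEstimate:
    """Incidence coverage-based estimator (classic gamma^2 variant).

    Taxa are split into frequent (> cutoff detections) and infrequent
    (<= cutoff).  With N_inf = sum_{k<=cutoff} k Q_k incidences among
    infrequent taxa, sample coverage C = 1 - Q1/N_inf, and m_inf the
    number of surveys containing at least one infrequent taxon:

        gamma^2 = max( (S_inf/C) * (m_inf/(m_inf-1))
                       * sum k(k-1) Q_k / N_inf^2 - 1, 0 )
        ICE = S_freq + S_inf/C + (Q1/C) * gamma^2

    Degenerate inputs: no infrequent taxa -> S_obs; coverage 0 (every
    infrequent taxon a singleton) -> falls back to bias-corrected Chao2,
    flagged.
    """
    if counts.m < 2:
        raise InputError(f"ICE needs >= 2 surveys, got {counts.m}")
    if counts.matrix is None:
        raise InputError("ICE needs the raw detection matrix")
    k_max = min(cutoff, counts.m)
    q = counts.q.astype(float)
    s_inf = float(q[1:k_max + 1].sum())
    s_freq = counts.s_obs - s_inf
    if s_inf == 0.0:
        return RichnessEstimate("ice", float(counts.s_obs), None, ["no_infrequent"])
    n_inf = float(sum(k * q[k] for k in range(1, k_max + 1)))
    coverage = 1.0 - q[1] / n_inf
    if coverage <= 0.0:
        fallback = chao2(counts)
        logger.warning("ICE coverage is 0 (all infrequent taxa are singletons); "
                       "falling back to Chao2")
        return RichnessEstimate("ice", fallback.estimate, fallback.standard_error,
                                ["unstable_coverage", "chao2_fallback"])
    row_sums = counts.matrix.sum(axis=1)
    infrequent = (row_sums >= 1) & (row_sums <= k_max)
    m_inf = int(np.sum(counts.matrix[infrequent].sum(axis=0) > 0))
    if m_inf > 1:
        gamma2 = max(
            (s_inf / coverage) * (m_inf / (m_inf - 1.0))
            * float(sum(k * (k - 1) * q[k] for k in range(1, k_max + 1)))
            / (n_inf * n_inf) - 1.0,
            0.0,
        )
    else:
        gamma2 = 0.0
    est = s_freq + s_inf / coverage + (q[1] / coverage) * gamma2
    return RichnessEstimate("ice", est, None, [])


def twlrm(counts: IncidenceCounts) -> RichnessEstimate:
    """Transformed weighted linear regression on consecutive count ratios.

    Models the log-ratio y_n = log(Q_{n+1} / Q_n) as linear in n, with
    weights 1 / (1/Q_n + 1/Q_{n+1}) (the inverse delta-method variance of
    a log-ratio of Poisson counts).  The fitted line extrapolated to n = 0
    gives the ratio Q_1 / Q_0, whence Q_0 = Q_1 / exp(y_hat(0)) and the
    estimate S_obs + Q_0.  Exactly geometric counts (constant ratio rho)
    yield Q_0 = Q_1 / rho; the estimate may fall below S_obs for
    increasing count sequences, in which case it is flagged.
    """
    q = counts.q.astype(float)
    n_max = 1
    while n_max + 1 <= counts.m and q[n_max + 1] > 0:
        n_max += 1
    if n_max < 3 or np.any(q[1:n_max + 1] <= 0):
        raise InputError(
            "tWLRM needs at least 3 consecutive nonzero frequency counts from Q1"
        )
    ns = np.arange(1, n_max)                  # ratio index: Q_{n+1}/Q_n
    y = np.log(q[ns + 1] / q[ns])
    w = 1.0 / (1.0 / q[ns] + 1.0 / q[ns + 1])
    sw = w.sum()
    x_bar = float((w * ns).sum() / sw)
    y_bar = float((w * y).sum() / sw)
    sxx = float((w * (ns - x_bar) ** 2).sum())
    slope = float((w * (ns - x_bar) * (y - y_bar)).sum() / sxx) if sxx > 0 else 0.0
    intercept = y_bar - slope * x_bar
    ratio0 = float(np.exp(intercept))          # extrapolated Q1/Q0 ratio
    if ratio0 <= 0:
        raise InputError("tWLRM extrapolated a non-positive ratio")
    q0 = q[1] / ratio0
    flags = []
    if q0 < 0:
        flags.append("below_s_obs")
    return RichnessEstimate("twlrm", counts.s_obs + q0, None, flags)


def accumulation_curve(matrix: np.ndarray, repeats: int = 10_000,
                       seed: int = 0) -> AccumulationCurve:
    """Expected taxon count in n randomly chosen surveys, n = 0..m.

    For 1 <= n < m the expectation is a Monte-Carlo mean over ``repeats``
    without-replacement survey subsets (or the exact mean over all subsets
    when there are no more than ``repeats`` of them); at n = m the count
    is computed exactly on the full matrix.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise InputError("need a 2-D detection matrix with >= 2 surveys")
    if not np.isin(matrix, (0, 1)).all():
        raise InputError("detection matrix must be binary (0/1)")
    m = matrix.shape[1]
    rng = np.random.default_rng(seed)
    values = np.zeros(m + 1)
    mat = matrix.astype(bool)
    from math import comb

    for n in range(1, m):
        if comb(m, n) <= repeats:
            # exact expectation by enumerating all subsets
            totals = [int(mat[:, list(cols)].any(axis=1).sum())
                      for cols in itertools.combinations(range(m), n)]
            values[n] = float(np.mean(totals))
        else:
            total = 0
            for _ in range(repeats):
                cols = rng.choice(m, size=n, replace=False)
                total += int(mat[:, cols].any(axis=1).sum())
            values[n] = total / repeats
    values[m] = float(mat.any(axis=1).sum())
    return AccumulationCurve(values=values, repeats=repeats)


def slope_ratio(curve: AccumulationCurve) -> float:
    """Final slope over initial slope, r = (S(m)-S(m-1)) / (S(1)-S(0))."""
    v = curve.values
    if len(v) < 3:
        raise InputError("curve needs at least 2 points after the origin")
    initial = v[1] - v[0]
    if initial <= 0:
        raise InputError("initial slope is zero; slope ratio undefined")
    return float((v[-1] - v[-2]) / initial)


def estimate_all(counts: IncidenceCounts, seed: int = 0) -> list[RichnessEstimate]:
    """Run every estimator that is defined for the given counts."""
    out: list[RichnessEstimate] = []
    for fn in (chao2, lambda c: ichao2(c, seed=seed), ice, twlrm):
        try:
            out.append(fn(counts))
        except InputError as exc:
            name = getattr(fn, "__name__", "ichao2")
            logger.warning("estimator %s not applicable: %s", name, exc)
    return out


def breakaway_estimate(counts: IncidenceCounts) -> RichnessEstimate | None:
    """Optional adapter to the external `breakaway` estimator.

    Returns None (with a log message) when the package is unavailable;
    the estimator's mixture machinery is deliberately not re-implemented.
    """
    try:
        import breakaway  # type: ignore  # noqa: F401
    except ImportError:
        logger.info("breakaway package not installed; estimator skipped")
        return None
    raise NotImplementedError(
        "breakaway adapter: installed package found but no stable API contract"
    )
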