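"""Circular statistics for cell-angle distributions.

Descriptives (circular mean, variance, median), a nonparametric multi-sample
common-median test (the circular analogue of Kruskal-Wallis), a two-sample
Kuiper test with permutation p-values, dispersion-based confidence intervals
for the mean direction, and Benjamini-Hochberg FDR adjustment.

All public interfaces take and return degrees in [0, 360); radians are used
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


class UndefinedMeanError(ValueError):
    """Mean resultant length too small for a mean direction to be defined."""


class AmbiguousMedianError(ValueError):
    """Antipodally symmetric data admit no unique circular median."""


class DegeneratePartitionError(ValueError):
    """The pooled median fails to partition every group."""


def _to_rad(angles_deg) -> np.ndarray:
    a = np.asarray(angles_deg, dtype=float)
    if a.ndim != 1:
        a = a.ravel()
    return np.deg2rad(a % 360.0)


def resultant_length(angles_deg) -> float:
    """Mean resultant length R-bar of a sample of angles."""
    a = _to_rad(angles_deg)
    if a.size == 0:
        raise ValueError("empty sample")
    return float(np.hypot(np.sin(a).mean(), np.cos(a).mean()))


def circular_mean(angles_deg, eps: float = 1e-9) -> float:
    """Direction of the mean resultant vector, in [0, 360) degrees."""
    a = _to_rad(angles_deg)
    if a.size == 0:
        raise ValueError("empty sample")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    if np.hypot(s, c) <= eps:
        raise UndefinedMeanError("resultant length below eps; mean undefined")
    return float(np.degrees(np.arctan2(s, c)) % 360.0)


def circular_variance(angles_deg) -> float:
    """1 - R-bar, in [0, 1]; 0 for identical angles, 1 for a zero resultant."""
    return 1.0 - resultant_length(angles_deg)


def _mean_arc_distance(angles_rad: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Mean arc distance of the sample to each candidate direction."""
    d = np.abs(angles_rad[:, None] - phi[None, :]) % (2 * np.pi)
    return (np.pi - np.abs(np.pi - d)).mean(axis=0)


def circular_median(angles_deg) -> float:
    """Circular median: the direction minimising mean arc distance.

    Candidates are the data points and the circular midpoints of adjacent
    sorted pairs (the minimiser of the piecewise-linear objective always lies
    at one of these).  Ties are broken toward the candidate closest to the
    circular mean; antipodally symmetric data (zero resultant) raise.
    """
    a = _to_rad(angles_deg)
    if a.size == 0:
        raise ValueError("empty sample")
    if a.size == 1:
        return float(np.degrees(a[0]) % 360.0)
    try:
        mean_dir = np.deg2rad(circular_mean(angles_deg))
    except UndefinedMeanError as exc:
        raise AmbiguousMedianError("zero resultant; median ambiguous") from exc
    srt = np.sort(a)
    gaps = np.diff(np.concatenate([srt, srt[:1] + 2 * np.pi]))
    midpoints = (srt + gaps / 2.0) % (2 * np.pi)
    candidates = np.concatenate([srt, midpoints])
    obj = _mean_arc_distance(a, candidates)
    best = obj.min()
    tied = candidates[obj <= best + 1e-12]
    d_mean = np.pi - np.abs(np.pi - np.abs(tied - mean_dir) % (2 * np.pi))
    return float(np.degrees(tied[np.argmin(d_mean)]) % 360.0)


def _signed_deviation(angles_rad: np.ndarray, ref_rad: float) -> np.ndarray:
    """Signed circular deviation in (-pi, pi]."""
    d = (angles_rad - ref_rad) % (2 * np.pi)
    return np.where(d > np.pi, d - 2 * np.pi, d)


@dataclass
class CircularTestResult:
    """Outcome of one circular hypothesis test."""

    statistic: float
    p_value: float
    label: str = ""
    df: int | None = None
    q_value: float | None = None
    group_means: dict = field(default_factory=dict)


def common_median_test(groups, labels=None) -> CircularTestResult:
    """Fisher's nonparametric common-median test for k circular samples.

    All angles are pooled and their circular median found; for each group,
    m_i counts the angles lying in the half-circle clockwise of the pooled
    median (signed deviation < 0).  The statistic

        P = N^2 / (M (N - M)) * sum(m_i^2 / n_i) - N M / (N - M)

    with M = sum(m_i) is referred to a chi-squared distribution with k - 1
    degrees of freedom.  This is the multi-sample median test of the
    standard circular-statistics toolbox, the circular analogue of a
    Kruskal-Wallis test.
    """
    samples = [_to_rad(g) for g in groups]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two groups")
    n = np.array([s.size for s in samples])
    if (n < 10).any():
        raise ValueError("each group needs n >= 10")
    pooled_deg = np.concatenate([np.degrees(s) for s in samples])
    med = np.deg2rad(circular_median(pooled_deg))
    m = np.array([int((_signed_deviation(s, med) < 0).sum()) for s in samples])
    big_n = int(n.sum())
    big_m = int(m.sum())
    if big_m == 0 or big_m == big_n:
        raise DegeneratePartitionError(
            "pooled median does not split the data; test undefined"
        )
    stat = (big_n**2 / (big_m * (big_n - big_m))) * float((m**2 / n).sum()) \
        - big_n * big_m / (big_n - big_m)
    p = float(stats.chi2.sf(stat, k - 1))
    means = {}
    lab = labels if labels is not None else list(range(k))
    for name, g in zip(lab, groups):
        try:
            means[name] = circular_mean(g)
        except UndefinedMeanError:
            means[name] = float("nan")
    return CircularTestResult(float(stat), p, label="common_median_test",
                              df=k - 1, group_means=means)


def kuiper_statistic(a_deg, b_deg) -> float:
    """Two-sample Kuiper statistic V = max(Fa - Fb) + max(Fb - Fa).

    Computed over the circular empirical distribution functions; V is
    invariant under a common rotation of both samples and under the choice
    of cut point.  Tied values across samples jump simultaneously.
    """
    a = np.sort(np.asarray(a_deg, dtype=float) % 360.0)
    b = np.sort(np.asarray(b_deg, dtype=float) % 360.0)
    if a.size < 1 or b.size < 1:
        raise ValueError("empty sample")
    vals = np.concatenate([a, b])
    w = np.concatenate([np.full(a.size, 1.0 / a.size),
                        np.full(b.size, -1.0 / b.size)])
    order = np.argsort(vals, kind="stable")
    vals = vals[order]
    w = w[order]
    # evaluate the ECDF difference only after all ties at a value have jumped
    group_end = np.nonzero(np.diff(vals, append=np.inf) > 0)[0]
    cum = np.cumsum(w)[group_end]
    return float(max(cum.max(), 0.0) - min(cum.min(), 0.0))


def _kuiper_perm_pvalue(a: np.ndarray, b: np.ndarray, v_obs: float,
                        n_perm: int, rng: np.random.Generator) -> float:
    """Label-permutation p-value, vectorised across permutations."""
    na, nb = a.size, b.size
    vals = np.concatenate([a, b]) % 360.0
    order = np.argsort(vals, kind="stable")
    vals = vals[order]
    group_end = np.nonzero(np.diff(vals, append=np.inf) > 0)[0]
    base_w = np.concatenate([np.full(na, 1.0 / na), np.full(nb, -1.0 / nb)])
    count = 0
    chunk = max(1, min(n_perm, int(2e6 / (na + nb))))
    done = 0
    while done < n_perm:
        p = min(chunk, n_perm - done)
        # each row: a random assignment of the group labels to sorted positions
        perm = np.argsort(rng.random((p, na + nb)), axis=1)
        w = base_w[perm]
        cum = np.cumsum(w, axis=1)[:, group_end]
        v = np.maximum(cum.max(axis=1), 0.0) - np.minimum(cum.min(axis=1), 0.0)
        count += int((v >= v_obs - 1e-12).sum())
        done += p
    return (1.0 + count) / (n_perm + 1.0)


def _kuiper_asymptotic_pvalue(v: float, na: int, nb: int) -> float:
    """Stephens' asymptotic tail probability for the two-sample Kuiper V."""
    ne = na * nb / (na + nb)
    lam = (np.sqrt(ne) + 0.155 + 0.24 / np.sqrt(ne)) * v
    if lam < 0.4:
        return 1.0
    k = np.arange(1, 101)
    terms = (4.0 * k**2 * lam**2 - 1.0) * np.exp(-2.0 * k**2 * lam**2)
    return float(np.clip(2.0 * terms.sum(), 0.0, 1.0))


def kuiper_two_sample(
    a_deg,
    b_deg,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    method: str = "permutation",
) -> CircularTestResult:
    """Two-sample Kuiper test for circular data.

    ``method='permutation'`` (default) estimates the p-value by ``n_perm``
    seeded label permutations; ``method='asymptotic'`` uses Stephens'
    approximation.  Identical samples give V = 0, p = 1.
    """
    a = np.asarray(a_deg, dtype=float) % 360.0
    b = np.asarray(b_deg, dtype=float) % 360.0
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs n >= 5")
    v = kuiper_statistic(a, b)
    if method == "permutation":
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        p = _kuiper_perm_pvalue(a, b, v, n_perm, rng)
    elif method == "asymptotic":
        p = _kuiper_asymptotic_pvalue(v, a.size, b.size)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CircularTestResult(v, float(p), label="kuiper_two_sample")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mean_angle_ci(angles_deg, level: float = 0.95) -> tuple[float, float, float]:
    """Mean direction with a dispersion-based confidence interval.

    Uses the standard large-sample interval for the mean direction
    (Fisher 1993, as implemented in the common circular toolbox): the
    half-width d satisfies cos(d) = t / R with t depending on the resultant
    length regime.  Raises when the resultant is too small for the interval
    to exist.  Returns ``(mean, lower, upper)`` in degrees, bounds wrapped
    to [0, 360).
    """
    a = _to_rad(angles_deg)
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2")
    mean = circular_mean(angles_deg)
    r = resultant_length(angles_deg)
    big_r = n * r
    chi = stats.chi2.ppf(level, 1)
    if r >= 0.9:
        t2 = n**2 - (n**2 - big_r**2) * np.exp(chi / n)
    else:
        t2 = (2 * n * (2 * big_r**2 - n * chi)) / (4 * n - chi)
    if t2 < 0:
        raise UndefinedMeanError("resultant too small; CI undefined")
    t = np.sqrt(t2)
    ratio = np.clip(t / big_r, -1.0, 1.0)
    d = float(np.degrees(np.arccos(ratio)))
    return mean, (mean - d) % 360.0, (mean + d) % 360.0
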