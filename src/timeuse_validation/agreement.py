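"""Inter-method agreement and reliability statistics.

The suite compares a criterion measurement (direct observation) with a test
method (24-h recall, image-assisted recall) on paired per-participant values:

* Bland-Altman bias and limits of agreement (LOA).  The sign convention is
  fixed project-wide as criterion minus test, so a positive bias means the
  test method *underestimates* the criterion on average.  The LOA multiplier
  defaults to 2 (bias +/- 2 SD of the differences).
* Threshold-exceedance counts (participants within / beyond an absolute
  difference threshold).
* Cronbach's coefficient alpha with the two methods as the two items,
  interpreted on the Nunnally benchmark scale.
* Weighted Cohen's kappa (linear or quadratic disagreement weights) for
  ordinal summaries such as the per-participant median number of concurrent
  activities, interpreted on the Landis-Koch scale.
* The Wilcoxon signed-rank test, with an exact null distribution (midranks,
  configurable zero-difference rule) for small effective n and a
  tie-corrected normal approximation otherwise.
* Bland-Altman plot-shape diagnostics: a least-squares trend test of the
  differences on the means and a spread test of |residual| on the means,
  classifying plots as cloud / fan / sloped / fan+sloped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AgreementResult",
    "ReliabilityResult",
    "KappaResult",
    "WilcoxonResult",
    "ShapeDiagnostic",
    "bland_altman",
    "threshold_counts",
    "cronbach_alpha",
    "weighted_kappa",
    "wilcoxon_signed_rank",
    "shape_diagnostics",
    "interpret_alpha",
    "interpret_kappa",
]


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman bias, limits of agreement, and plot data for one method pair."""

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    multiplier: float
    means: np.ndarray
    differences: np.ndarray
    counts_above_zero: int
    counts_below_zero: int
    ties: int
    label: str = ""
    method_pair: tuple[str, str] = ("", "")


def bland_altman(
    criterion: Sequence[float],
    test: Sequence[float],
    multiplier: float = 2.0,
    label: str = "",
    method_pair: tuple[str, str] = ("criterion", "test"),
) -> AgreementResult:
    """Bland-Altman agreement between paired criterion and test values.

    Differences are criterion - test; bias is their mean, sd the sample
    standard deviation (n-1 denominator), and the limits of agreement are
    bias +/- multiplier x sd.  Plot pairs are ((criterion+test)/2, diff).
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    c = np.asarray(criterion, dtype=float)
    t = np.asarray(test, dtype=float)
    if c.shape != t.shape or c.ndim != 1:
        raise ValueError(f"paired 1-d inputs required; got shapes {c.shape} and {t.shape}")
    n = c.size
    if n < 2:
        raise ValueError("at least 2 pairs required (sd of differences undefined)")
    d = c - t
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - multiplier * sd,
        loa_high=bias + multiplier * sd,
        multiplier=multiplier,
        means=(c + t) / 2.0,
        differences=d,
        counts_above_zero=int((d > 0).sum()),
        counts_below_zero=int((d < 0).sum()),
        ties=int((d == 0).sum()),
        label=label,
        method_pair=method_pair,
    )


def threshold_counts(
    differences: Sequence[float],
    thresholds: Sequence[float] = (30.0, 120.0),
) -> list[dict[str, float]]:
    """Counts/percentages of participants within (|d| <= t) and beyond (|d| > t) each threshold."""
    d = np.abs(np.asarray(differences, dtype=float))
    n = d.size
    out = []
    for t in thresholds:
        if t <= 0:
            raise ValueError("thresholds must be positive")
        within = int((d <= t).sum())
        out.append(
            {
                "threshold": float(t),
                "n": n,
                "n_within": within,
                "pct_within": 100.0 * within / n if n else math.nan,
                "n_beyond": n - within,
                "pct_beyond": 100.0 * (n - within) / n if n else math.nan,
            }
        )
    return out


# ---------------------------------------------------------------------------
# Cronbach's alpha


def interpret_alpha(alpha: float) -> str:
    """Nunnally/Peterson benchmark labels for Cronbach's alpha."""
    if math.isnan(alpha):
        return "undefined"
    if alpha > 0.95:
        return "suspect"
    if alpha >= 0.90:
        return "high"
    if alpha > 0.80:
        return "moderate"
    if alpha > 0.70:
        return "acceptable"
    return "unacceptable"


@dataclass(frozen=True)
class ReliabilityResult:
    """Cronbach's alpha with the two compared methods as the two items."""

    alpha: float
    label: str
    n: int
    defined: bool = True


def cronbach_alpha(
    method_a: Sequence[float], method_b: Sequence[float]
) -> ReliabilityResult:
    """Two-item Cronbach's coefficient alpha.

    alpha = (k/(k-1)) (1 - sum(item variances)/variance(sum)) with k = 2 and
    sample (n-1) variances.  Zero total variance makes alpha undefined; the
    result is flagged rather than raised so tabulations can report it.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-d inputs required")
    n = a.size
    if n < 3:
        raise ValueError("at least 3 pairs required for a variance-based coefficient")
    var_total = float((a + b).var(ddof=1))
    if var_total == 0.0:
        return ReliabilityResult(alpha=math.nan, label="undefined", n=n, defined=False)
    alpha = 2.0 * (1.0 - (float(a.var(ddof=1)) + float(b.var(ddof=1))) / var_total)
    return ReliabilityResult(alpha=alpha, label=interpret_alpha(alpha), n=n)


# ---------------------------------------------------------------------------
# Weighted Cohen's kappa


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch benchmark labels for Cohen's kappa."""
    if math.isnan(kappa):
        return "undefined"
    if kappa < 0.0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


@dataclass(frozen=True)
class KappaResult:
    """Weighted Cohen's kappa on a shared ordered category range."""

    kappa: float
    scheme: Literal["linear", "quadratic"]
    categories: tuple[int, ...]
    label: str
    n: int
    defined: bool = True


def _to_ordinal(values: np.ndarray) -> np.ndarray:
    """Cast ratings to integers, doubling half-integer values when present."""
    doubled = values * 2.0
    if not np.allclose(doubled, np.round(doubled), atol=1e-9):
        raise ValueError("ratings must be integers or half-integers")
    if np.allclose(values, np.round(values), atol=1e-9):
        return np.round(values).astype(int)
    return np.round(doubled).astype(int)


def weighted_kappa(
    ratings_a: Sequence[float],
    ratings_b: Sequence[float],
    scheme: Literal["linear", "quadratic"] = "linear",
) -> KappaResult:
    """Weighted Cohen's kappa between two raters' ordinal ratings.

    Ratings are cast to a shared integer category range spanning the observed
    min..max of both raters (half-integer values, e.g. medians over an even
    number of timeslots, are doubled first).  Disagreement weights are
    |i-j|/(R-1) (linear) or ((i-j)/(R-1))^2 (quadratic); kappa is
    1 - sum(w O)/sum(w E) with O the observed joint proportions and E the
    outer product of the marginals.
    """
    if scheme not in ("linear", "quadratic"):
        raise ValueError(f"unknown weight scheme {scheme!r}")
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("paired non-empty 1-d inputs required")
    both = _to_ordinal(np.concatenate([a, b]))
    ia, ib = both[: a.size], both[a.size :]
    lo, hi = int(both.min()), int(both.max())
    categories = tuple(range(lo, hi + 1))
    R = len(categories)
    n = a.size
    if R < 2:
        return KappaResult(
            kappa=math.nan, scheme=scheme, categories=categories,
            label="undefined", n=n, defined=False,
        )
    obs = np.zeros((R, R))
    for x, y in zip(ia, ib):
        obs[x - lo, y - lo] += 1.0
    obs /= n
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    idx = np.arange(R)
    dist = np.abs(idx[:, None] - idx[None, :]) / (R - 1)
    weights = dist if scheme == "linear" else dist**2
    kappa = 1.0 - float((weights * obs).sum()) / float((weights * expected).sum())
    return KappaResult(
        kappa=kappa, scheme=scheme, categories=categories,
        label=interpret_kappa(kappa), n=n,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank statistic (W+, sum of ranks of positive differences) and p-values."""

    statistic: float
    p_value: float
    p_one_sided: float
    n_eff: int
    testable: bool
    zero_rule: Literal["drop", "pratt"]
    p_method: Literal["exact", "normal_approx", "none"]


def _exact_signed_rank_p(doubled_ranks: np.ndarray, w_doubled: int) -> tuple[float, float]:
    """Exact tail probabilities of W+ (on doubled ranks) under the symmetric null.

    Builds the full null distribution by dynamic programming over sign
    assignments: each rank contributes to W+ with probability 1/2.  Returns
    (two-sided, one-sided-upper) p-values, both inclusive of the observed value.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    counts /= counts.sum()
    p_le = float(counts[: w_doubled + 1].sum())
    p_ge = float(counts[w_doubled:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge)), p_ge


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    zero_rule: Literal["drop", "pratt"] = "drop",
    p_mode: Literal["exact_when_small", "normal_approx"] = "exact_when_small",
    exact_threshold: int = 12,
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of x versus y.

    Differences d = x - y; tied |d| get midranks.  Zero differences are
    handled by the configured rule: ``drop`` (classic Wilcoxon) removes them
    before ranking; ``pratt`` ranks them with the rest and then discards
    their ranks from the statistic.  The exact null distribution is
    enumerated when the effective n is at most ``exact_threshold``;
    otherwise a normal approximation with tie and continuity corrections is
    used.  If every difference is zero the result is flagged not testable.
    """
    if zero_rule not in ("drop", "pratt"):
        raise ValueError(f"unknown zero rule {zero_rule!r}")
    if p_mode not in ("exact_when_small", "normal_approx"):
        raise ValueError(f"unknown p mode {p_mode!r}")
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("paired 1-d inputs required")
    d = xv - yv
    nonzero = d != 0
    n_eff = int(nonzero.sum())
    if n_eff == 0:
        return WilcoxonResult(
            statistic=math.nan, p_value=math.nan, p_one_sided=math.nan,
            n_eff=0, testable=False, zero_rule=zero_rule, p_method="none",
        )

    if zero_rule == "drop":
        d_used = d[nonzero]
        ranks = stats.rankdata(np.abs(d_used))
        signs = d_used > 0
        active_ranks = ranks
    else:  # pratt: rank zeros too, then discard their ranks from W+
        ranks_all = stats.rankdata(np.abs(d))
        active_ranks = ranks_all[nonzero]
        signs = d[nonzero] > 0
    w_plus = float(active_ranks[signs].sum())

    use_exact = p_mode == "exact_when_small" and n_eff <= exact_threshold
    if use_exact:
        doubled = np.round(active_ranks * 2).astype(int)
        w2 = int(round(w_plus * 2))
        p_two, p_upper = _exact_signed_rank_p(doubled, w2)
        return WilcoxonResult(
            statistic=w_plus, p_value=p_two, p_one_sided=p_upper,
            n_eff=n_eff, testable=True, zero_rule=zero_rule, p_method="exact",
        )

    # normal approximation with tie and continuity corrections
    if zero_rule == "drop":
        mean_w = n_eff * (n_eff + 1) / 4.0
        var_w = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0
        abs_used = np.abs(d[nonzero])
    else:
        n_all = d.size
        n_zero = n_all - n_eff
        mean_w = (n_all * (n_all + 1) - n_zero * (n_zero + 1)) / 4.0
        var_w = (
            n_all * (n_all + 1) * (2 * n_all + 1)
            - n_zero * (n_zero + 1) * (2 * n_zero + 1)
        ) / 24.0
        abs_used = np.abs(d[nonzero])
    _, tie_counts = np.unique(abs_used, return_counts=True)
    var_w -= float((tie_counts**3 - tie_counts).sum()) / 48.0
    if var_w <= 0:
        return WilcoxonResult(
            statistic=w_plus, p_value=math.nan, p_one_sided=math.nan,
            n_eff=n_eff, testable=False, zero_rule=zero_rule, p_method="normal_approx",
        )
    sd_w = math.sqrt(var_w)
    delta = w_plus - mean_w
    cc = 0.5 if delta != 0 else 0.0
    z_two = (abs(delta) - cc) / sd_w
    p_two = 2.0 * float(stats.norm.sf(max(z_two, 0.0)))
    z_upper = (delta - (0.5 if delta > 0 else 0.0) + (0.5 if delta < 0 else 0.0)) / sd_w
    p_upper = float(stats.norm.sf(z_upper))
    return WilcoxonResult(
        statistic=w_plus, p_value=min(1.0, p_two), p_one_sided=min(1.0, p_upper),
        n_eff=n_eff, testable=True, zero_rule=zero_rule, p_method="normal_approx",
    )


# ---------------------------------------------------------------------------
# Bland-Altman plot-shape diagnostics


@dataclass(frozen=True)
class ShapeDiagnostic:
    """Operationalised Bland-Altman plot-shape classification.

    A least-squares trend of difference on mean (slope test) and of
    |residual| on mean (spread test) replace visual inspection: neither
    significant -> cloud; spread only -> fan; slope only -> sloped; both ->
    fan+sloped.
    """

    slope: float
    slope_p: float
    spread_slope: float
    spread_p: float
    alpha_level: float
    classification: Literal["cloud", "fan", "sloped", "fan+sloped", "undefined"]
    defined: bool = True


def shape_diagnostics(
    result: AgreementResult, alpha_level: float = 0.05
) -> ShapeDiagnostic:
    """Classify a Bland-Altman plot's shape from its (mean, difference) pairs."""
    if not 0 < alpha_level < 1:
        raise ValueError("alpha_level must be in (0, 1)")
    m = np.asarray(result.means, dtype=float)
    d = np.asarray(result.differences, dtype=float)
    if m.size < 4:
        raise ValueError("at least 4 pairs required for shape diagnostics")
    if np.ptp(m) == 0:
        return ShapeDiagnostic(
            slope=math.nan, slope_p=math.nan, spread_slope=math.nan,
            spread_p=math.nan, alpha_level=alpha_level,
            classification="undefined", defined=False,
        )
    fit = stats.linregress(m, d)
    resid = d - (fit.intercept + fit.slope * m)
    spread_fit = stats.linregress(m, np.abs(resid))
    sloped = fit.pvalue < alpha_level
    fanned = spread_fit.pvalue < alpha_level
    classification = {
        (False, False): "cloud",
        (False, True): "fan",
        (True, False): "sloped",
        (True, True): "fan+sloped",
    }[(sloped, fanned)]
    return ShapeDiagnostic(
        slope=float(fit.slope),
        slope_p=float(fit.pvalue),
        spread_slope=float(spread_fit.slope),
        spread_p=float(spread_fit.pvalue),
        alpha_level=alpha_level,
        classification=classification,
    )
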