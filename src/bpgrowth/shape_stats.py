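"""Nonparametric association battery for the growth-curve shape ratio.

Thirteen brood-specific and environmental indicators per nest are
related to the per-bird shape ratio within each of four strata
(species x sex).  Three complementary tests guard against spurious
findings:

  a) Spearman rank correlation of ratio vs. indicator,
  b) Mann-Whitney location test on the ratio after splitting each
     stratum at the indicator median (ties to the high class),
  c) Mann-Whitney location test on the indicator after classifying
     birds as high-ratio (ratio >= 0.5, the logistic value) vs.
     low-ratio.

An association counts as reliable only when all three tests are
significant at 5%, at least one reaches 1%, and the same direction
holds in at least two strata.  Family-wise error is assessed the
nonparametric way: a binomial estimate of the expected count of
spurious 5%-significant tests out of 13, sharpened by a permutation
null that reshuffles birds among nest-sites (nest characteristics
unaltered), which remains valid when indicators are correlated.  A
representative-bird resampling (one bird per nest) checks that nest
effects do not drive the findings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INDICATORS",
    "SPECIES",
    "SEXES",
    "NestEnvironment",
    "BirdRecord",
    "SpearmanResult",
    "SplitTestResult",
    "SignTestResult",
    "TestBatteryResult",
    "spearman_test",
    "median_split_test",
    "ratio_class_test",
    "sign_test_vs_value",
    "spurious_count_pvalue",
    "shuffle_null",
    "representative_resampling",
    "run_battery",
    "reliability_verdict",
]

#: the 13 brood-specific and environmental nest indicators
INDICATORS = (
    "hatching_day",
    "hatchlings_initial",
    "hatchlings_final",
    "nest_size_difference",
    "human_activity",
    "isa",
    "light",
    "ndvi",
    "path_distance",
    "road_distance",
    "sound",
    "temperature",
    "tree_cover",
)

SPECIES = ("blue tit", "great tit")
SEXES = ("female", "male")

#: ratio threshold separating high- from low-ratio birds (logistic value)
HIGH_RATIO_THRESHOLD = 0.5


@dataclass(frozen=True)
class NestEnvironment:
    """The 13 brood-specific and environmental indicators of one nest-box."""

    nest_id: str
    hatching_day: float
    hatchlings_initial: int
    hatchlings_final: int
    nest_size_difference: int
    human_activity: float
    isa: float
    light: float
    ndvi: float
    path_distance: float
    road_distance: float
    sound: float
    temperature: float
    tree_cover: float

    def __post_init__(self) -> None:
        if self.hatchlings_initial < 0 or self.hatchlings_final < 0:
            raise ValueError("hatchling counts must be non-negative")
        if self.nest_size_difference != self.hatchlings_initial - self.hatchlings_final:
            raise ValueError("nest_size_difference must equal initial - final count")
        for name in ("isa", "tree_cover"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in INDICATORS}


@dataclass(frozen=True)
class BirdRecord:
    """One bird: identity, stratum, mass series, and (optionally) its fit."""

    bird_id: str
    nest_id: str
    species: str
    sex: str
    series: "object" = None   # MassSeries; untyped to avoid a hard import cycle
    fit: "object" = None      # FitResult

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def stratum(self) -> tuple[str, str]:
        return (self.species, self.sex)

    @property
    def ratio(self) -> float:
        if self.fit is None:
            raise ValueError(f"bird {self.bird_id} has no fit")
        return self.fit.shape.ratio

    @property
    def sigmoidal(self) -> bool:
        return self.fit is not None and self.fit.params.a > 0


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    n: int


@dataclass(frozen=True)
class SplitTestResult:
    median_high: float
    median_low: float
    pvalue: float
    n_high: int
    n_low: int


@dataclass(frozen=True)
class SignTestResult:
    pvalue: float
    median: float
    ci_low: float
    ci_high: float
    n_effective: int


def _check_paired(x: np.ndarray, y: np.ndarray, min_n: int = 5) -> None:
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant sample")


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman_test(ratios: Sequence[float], indicator: Sequence[float],
                  *, seed: int = 0) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  For n <= 8 the permutation null is
    enumerated exactly; for 9 <= n <= 12 it is sampled (20,000 seeded
    permutations); larger samples use the t approximation.
    """
    x = np.asarray(ratios, float)
    y = np.asarray(indicator, float)
    _check_paired(x, y)
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if n <= 8:
        perms = np.array(list(itertools.permutations(range(n))))
        null = _batch_rho(rx[perms], ry)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    elif n <= 12:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(20_000)])
        null = _batch_rho(rx[perms], ry)
        p = float((np.sum(np.abs(null) >= abs(rho) - 1e-12) + 1) / (null.size + 1))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return SpearmanResult(rho=rho, pvalue=p, n=n)


def _batch_rho(rx_rows: np.ndarray, ry: np.ndarray) -> np.ndarray:
    rx_c = rx_rows - rx_rows.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    num = rx_c @ ry_c
    den = np.sqrt(np.sum(rx_c**2, axis=1) * np.sum(ry_c**2))
    return num / den


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney; exact when tie-free and small, otherwise
    normal approximation with tie and continuity correction."""
    combined = np.concatenate([x, y])
    exact = combined.size <= 20 and np.unique(combined).size == combined.size
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.pvalue)


def median_split_test(ratios: Sequence[float], indicator: Sequence[float]) -> SplitTestResult:
    """Mann-Whitney on the ratio after splitting at the indicator median.

    Birds whose indicator equals or exceeds the stratum median form the
    high class.  Returns the ratio medians of both classes.
    """
    r = np.asarray(ratios, float)
    v = np.asarray(indicator, float)
    if r.size != v.size or r.size == 0:
        raise ValueError("paired samples required")
    med = float(np.median(v))
    high = v >= med
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError(f"degenerate median split: {n_high} high vs {n_low} low")
    return SplitTestResult(
        median_high=float(np.median(r[high])),
        median_low=float(np.median(r[~high])),
        pvalue=_mann_whitney(r[high], r[~high]),
        n_high=n_high, n_low=n_low)


def ratio_class_test(ratios: Sequence[float], indicator: Sequence[float],
                     threshold: float = HIGH_RATIO_THRESHOLD) -> SplitTestResult:
    """Mann-Whitney on the indicator between high- and low-ratio birds.

    A bird is high-ratio when its fitted ratio is >= the threshold
    (0.5, the fixed ratio of logistic growth).
    """
    r = np.asarray(ratios, float)
    v = np.asarray(indicator, float)
    if r.size != v.size or r.size == 0:
        raise ValueError("paired samples required")
    high = r >= threshold
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError(f"one ratio class is empty: {n_high} high-ratio vs {n_low} low-ratio")
    return SplitTestResult(
        median_high=float(np.median(v[high])),
        median_low=float(np.median(v[~high])),
        pvalue=_mann_whitney(v[high], v[~high]),
        n_high=n_high, n_low=n_low)


def sign_test_vs_value(values: Sequence[float], reference: float = 1.0 / 3.0,
                       alternative: Literal["greater", "less"] = "greater") -> SignTestResult:
    """One-sided sign test of the median against a reference value.

    Ties with the reference are dropped.  The 95% confidence interval
    for the median is the order-statistic interval obtained by
    inverting one-sided sign tests at 2.5% on each limit.
    """
    x = np.sort(np.asarray(values, float))
    keep = x != reference
    if not np.any(keep):
        raise ValueError("all values tie with the reference")
    xk = x[keep]
    n = xk.size
    if n < 5:
        raise ValueError("need at least 5 non-tied values")
    k = int(np.sum(xk > reference)) if alternative == "greater" else int(np.sum(xk < reference))
    p = float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)
    # order-statistic CI on the full sample
    m = x.size
    j = 0
    while j + 1 <= m and stats.binom.cdf(j, m, 0.5) <= 0.025:
        j += 1
    lo = x[max(j - 1, 0)] if j >= 1 else -np.inf
    hi = x[m - j] if j >= 1 else np.inf
    return SignTestResult(pvalue=p, median=float(np.median(x)),
                          ci_low=float(lo), ci_high=float(hi), n_effective=n)


def spurious_count_pvalue(n_tests: int, alpha: float, k: int) -> float:
    """P(X >= k) for X ~ Binomial(n_tests, alpha).

    The chance of seeing k or more nominally significant tests out of
    n_tests when every null holds and tests are independent.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 <= k <= n_tests + 1:
        raise ValueError("k out of range")
    if k == 0:
        return 1.0
    if k > n_tests:
        return 0.0
    return float(stats.binom.sf(k - 1, n_tests, alpha))


def shuffle_null(ratios: Sequence[float], nest_ids: Sequence[str],
                 indicators: pd.DataFrame, n_shuffles: int = 10_000,
                 seed: int = 0, alpha: float = 0.05) -> tuple[int, np.ndarray]:
    """Permutation estimate of the spurious-correlation count.

    Birds are reshuffled at random among the nest-sites (nest
    characteristics unaltered) and the per-shuffle count of nominally
    significant Spearman correlations between ratio and the indicator
    columns is recorded.  Returns the 95% quantile of the counts and
    the counts themselves.  Unlike the binomial estimate this remains
    valid when indicators are correlated.
    """
    r = np.asarray(ratios, float)
    nests = np.asarray(nest_ids)
    if np.unique(nests).size < 2:
        raise ValueError("need at least 2 nests")
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    ind = indicators.to_numpy(float)
    n = r.size
    if ind.shape[0] != n:
        raise ValueError("indicator rows must match birds")
    rng = np.random.default_rng(seed)
    rank_r = stats.rankdata(r)
    rank_ind = np.column_stack([stats.rankdata(ind[:, j]) for j in range(ind.shape[1])])
    rc = rank_ind - rank_ind.mean(axis=0)
    denom_ind = np.sqrt(np.sum(rc**2, axis=0))
    counts = np.empty(n_shuffles, dtype=int)
    # t-approximation, vectorized over shuffles x indicators
    for s in range(n_shuffles):
        perm = rng.permutation(n)
        pr = rank_r[perm] - rank_r.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (pr @ rc) / (np.sqrt(pr @ pr) * denom_ind)
            rho = np.clip(rho, -0.999999, 0.999999)
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        # constant columns give nan rho -> nan p, which never counts
        counts[s] = int(np.sum(p <= alpha))
    q95 = int(np.percentile(counts, 95, method="higher"))
    return q95, counts


def representative_resampling(ratios: Sequence[float], nest_ids: Sequence[str],
                              bird_ids: Sequence[str], indicators: pd.DataFrame,
                              mode: Literal["deterministic", "bootstrap"] = "deterministic",
                              seed: int = 0, n_boot: int = 1000,
                              alpha: float = 0.05):
    """Per-nest representative-bird check of the correlation findings.

    Deterministic mode keeps, per nest, the bird whose ratio is nearest
    the nest median (ties to the lexicographically smaller bird id) and
    reruns the Spearman tests on the reduced sample, returning
    ``{indicator: SpearmanResult}``.  Bootstrap mode picks the
    representative uniformly at random per nest, ``n_boot`` times, and
    returns ``{indicator: fraction of resamples significant at alpha}``.
    """
    r = np.asarray(ratios, float)
    nests = np.asarray(nest_ids)
    birds = np.asarray(bird_ids)
    ind = indicators.reset_index(drop=True)
    nest_groups = {n: np.where(nests == n)[0] for n in pd.unique(nests)}

    def reduced_spearman(idx: np.ndarray):
        out = {}
        for col in ind.columns:
            v = ind[col].to_numpy(float)[idx]
            try:
                out[col] = spearman_test(r[idx], v, seed=seed)
            except ValueError:
                out[col] = SpearmanResult(rho=float("nan"), pvalue=1.0, n=idx.size)
        return out

    if mode == "deterministic":
        picked = []
        for nest, idx in nest_groups.items():
            med = np.median(r[idx])
            dist = np.abs(r[idx] - med)
            order = sorted(range(idx.size), key=lambda i: (dist[i], str(birds[idx[i]])))
            picked.append(idx[order[0]])
        return reduced_spearman(np.array(sorted(picked)))
    if mode == "bootstrap":
        rng = np.random.default_rng(seed)
        hits = {col: 0 for col in ind.columns}
        for _ in range(n_boot):
            idx = np.array(sorted(rng.choice(idx_group) for idx_group in nest_groups.values()))
            res = reduced_spearman(idx)
            for col, sr in res.items():
                hits[col] += int(sr.pvalue <= alpha)
        return {col: hits[col] / n_boot for col in ind.columns}
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class TestBatteryResult:
    """Per (stratum, indicator) outcome of the three-test battery.

    ``table`` has one row per stratum x indicator with the Spearman
    rho/p (test a), median-split medians and p (test b), ratio-class
    medians and p (test c), and the direction (sign of rho).
    """

    table: pd.DataFrame
    alpha: float = 0.05
    alpha_high: float = 0.01

    __test__ = False  # name starts with "Test" but this is not a test class

    def for_stratum(self, species: str, sex: str) -> pd.DataFrame:
        t = self.table
        return t[(t.species == species) & (t.sex == sex)]


def run_battery(df: pd.DataFrame, indicators: Iterable[str] = INDICATORS,
                ratio_threshold: float = HIGH_RATIO_THRESHOLD,
                seed: int = 0) -> TestBatteryResult:
    """Run tests a/b/c for every stratum and indicator.

    ``df`` needs columns ``species, sex, ratio`` plus the indicator
    columns (per-bird rows; nest indicators repeated within a nest).
    Tests that are undefined on a stratum (constant values, empty
    classes) are recorded with NaN p-values rather than raised.
    """
    rows = []
    for (species, sex), g in df.groupby(["species", "sex"], sort=True):
        ratios = g["ratio"].to_numpy(float)
        for ind_name in indicators:
            v = g[ind_name].to_numpy(float)
            row = {"species": species, "sex": sex, "indicator": ind_name,
                   "n": ratios.size}
            try:
                sp = spearman_test(ratios, v, seed=seed)
                row.update(rho=sp.rho, p_spearman=sp.pvalue,
                           direction=float(np.sign(sp.rho)))
            except ValueError:
                row.update(rho=np.nan, p_spearman=np.nan, direction=0.0)
            try:
                ms = median_split_test(ratios, v)
                row.update(ratio_median_high_env=ms.median_high,
                           ratio_median_low_env=ms.median_low,
                           p_median_split=ms.pvalue)
            except ValueError:
                row.update(ratio_median_high_env=np.nan,
                           ratio_median_low_env=np.nan, p_median_split=np.nan)
            try:
                rc = ratio_class_test(ratios, v, threshold=ratio_threshold)
                row.update(env_median_high_ratio=rc.median_high,
                           env_median_low_ratio=rc.median_low,
                           p_ratio_class=rc.pvalue)
            except ValueError:
                row.update(env_median_high_ratio=np.nan,
                           env_median_low_ratio=np.nan, p_ratio_class=np.nan)
            rows.append(row)
    return TestBatteryResult(table=pd.DataFrame(rows))


def reliability_verdict(battery: TestBatteryResult) -> pd.DataFrame:
    """Apply the three-test reliability rule per (indicator, direction).

    A stratum supports an association when all three tests are
    significant at ``alpha`` and at least one reaches ``alpha_high``.
    The verdict is true when at least two strata support the same
    indicator with the same direction.
    """
    t = battery.table
    pcols = ["p_spearman", "p_median_split", "p_ratio_class"]
    supported = (t[pcols].le(battery.alpha).all(axis=1)
                 & t[pcols].min(axis=1).le(battery.alpha_high)
                 & (t["direction"] != 0))
    sup = t[supported]
    out = []
    for ind_name in t["indicator"].unique():
        for direction in (-1.0, 1.0):
            strata = sup[(sup.indicator == ind_name) & (sup.direction == direction)]
            out.append({
                "indicator": ind_name,
                "direction": direction,
                "n_supporting_strata": len(strata),
                "reliable": len(strata) >= 2,
                "strata": [f"{r.species}/{r.sex}" for r in strata.itertuples()],
            })
    return pd.DataFrame(out)
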