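"""Paired statistical comparison protocol for contour metrics and ratings.

Contour-set comparisons (with vs. without slice-plane adjustment, model vs.
expert, model vs. intraobserver recontouring) are paired by case, with small
samples (typically 10-20 cases), so the protocol is nonparametric:

- paired Wilcoxon signed-rank test for location differences between two
  conditions measured on the same cases;
- Wilcoxon rank-sum (Mann-Whitney) test for two independent groups
  (e.g. contrast vs. non-contrast cases);
- a paired robust dispersion test in the Brown-Forsythe spirit: per-case
  absolute deviations from each condition's median are formed and their
  paired differences tested with the signed-rank procedure.

The signed-rank null distribution is enumerated exactly (over all 2^n sign
assignments, via a shift-polynomial convolution that also handles midranks
from ties) for n <= 25 effective pairs, and approximated by a tie-corrected
normal otherwise. Zero differences are dropped, following Wilcoxon's
original convention and common statistical-package defaults.

No multiple-testing correction is applied; reported p-values are unadjusted
and conventionally compared against 0.05.

The module also generates blinded-evaluation manifests: seeded, per-rater
randomized presentation orders of (case, contour set) pairs with contour-set
names replaced by neutral aliases, for rating on a continuous 0-100 scale
with four guidance categories (0-25 complete recontouring necessary, 26-50
major editing, 51-75 minor editing, >75 clinically usable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

EXACT_LIMIT = 25  # largest n for exact signed-rank enumeration
ALPHA = 0.05

RATING_SCALE = {
    "min": 0.0,
    "max": 100.0,
    "categories": [
        (0, 25, "complete recontouring of segmentation necessary"),
        (26, 50, "major manual editing necessary"),
        (51, 75, "minor manual editing necessary"),
        (76, 100, "segmentation clinically usable"),
    ],
}


@dataclass(frozen=True)
class PairedSample:
    """Per-case values of two conditions measured on the same cases."""

    ids: tuple
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if len(self.ids) != len(x) or len(x) != len(y):
            raise ValidationError("ids, x and y must have equal lengths")
        if len(x) < 2:
            raise ValidationError("paired sample needs at least 2 cases")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("case ids must be unique")

    @classmethod
    def from_arrays(cls, x: Sequence[float], y: Sequence[float]) -> "PairedSample":
        return cls(ids=tuple(range(len(x))), x=np.asarray(x), y=np.asarray(y))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    degenerate: bool = False


def _signed_rank_exact_sf_cdf(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """Exact P(W2 <= w2) and P(W2 >= w2) for the sum of a random subset of
    the (doubled, hence integer) ranks, each included with probability 1/2."""
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1, dtype=float)
    pmf[0] = 1.0
    upper = 0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r : upper + r + 1] = pmf[: upper + 1]
        upper += r
        pmf[: upper + 1] = 0.5 * (pmf[: upper + 1] + shifted[: upper + 1])
    cdf = float(pmf[: w2 + 1].sum())
    sf = float(pmf[w2:].sum())
    return cdf, sf


def wilcoxon_signed_rank(sample: PairedSample) -> TestResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Returns the signed-rank statistic ``W+ - W-`` (antisymmetric under
    swapping conditions) and the two-sided p-value: exact for up to 25
    nonzero differences (midranks handled), tie-corrected normal
    approximation beyond. All differences zero yields a degenerate result
    with p = 1.
    """
    d = sample.y - sample.x
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, n=0, method="degenerate", degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = w_plus - w_minus

    if n <= EXACT_LIMIT:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        cdf, sf = _signed_rank_exact_sf_cdf(ranks2, w2)
        p = min(1.0, 2.0 * min(cdf, sf))
        return TestResult(statistic=statistic, p_value=p, n=n, method="exact")

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var == 0:
        return TestResult(statistic=statistic, p_value=1.0, n=n, method="degenerate", degenerate=True)
    z = (w_plus - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(statistic=statistic, p_value=p, n=n, method="normal")


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for independent groups.

    The statistic is the rank sum W of the first group (so three values
    {1,2,3} against {4,5,6} give the minimum possible W = 6). Exact null
    distribution for small tie-free samples (m + n <= 20), normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and m + n <= 20) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + m * (m + 1) / 2.0
    return TestResult(statistic=w, p_value=float(res.pvalue), n=m + n, method=method)


def paired_dispersion_test(sample: PairedSample) -> TestResult:
    """Paired robust test for equal dispersion of two conditions.

    Brown-Forsythe-style absolute deviations from each condition's median
    are computed per case; their paired differences are tested with the
    signed-rank procedure. The reported statistic is the mean deviation
    difference (condition B minus A), so swapping conditions negates it. A
    pure location shift gives identical deviations and a degenerate p = 1.
    """
    if len(sample.x) < 3:
        raise ValidationError("paired dispersion test needs at least 3 cases")
    dev_x = np.abs(sample.x - np.median(sample.x))
    dev_y = np.abs(sample.y - np.median(sample.y))
    inner = wilcoxon_signed_rank(PairedSample(sample.ids, dev_x, dev_y))
    return TestResult(
        statistic=float(np.mean(dev_y - dev_x)),
        p_value=inner.p_value,
        n=inner.n,
        method=f"signed-rank-on-deviations/{inner.method}",
        degenerate=inner.degenerate,
    )


# ---------------------------------------------------------------------------
# blinded evaluation design


@dataclass(frozen=True)
class BlindedManifest:
    """Randomized, blinded presentation plan for an expert rating study."""

    table: pd.DataFrame
    alias_map: dict[str, str]
    seed: int
    scale: dict = field(default_factory=lambda: dict(RATING_SCALE))

    @property
    def n_slots(self) -> int:
        return len(self.table)


def generate_blinded_manifest(
    case_ids: Sequence[str],
    contour_set_ids: Sequence[str],
    n_raters: int,
    levels: Sequence[str],
    seed: int,
) -> BlindedManifest:
    """Build a blinded, per-rater randomized rating manifest.

    Each rater receives every (case, contour set) combination exactly once,
    in an independently shuffled order, with contour-set identities replaced
    by neutral aliases; each presentation asks for one rating per level on
    the 0-100 scale. Total rating slots:
    ``n_raters * |cases| * |contour sets| * |levels|``.
    """
    for name, ids in (("case_ids", case_ids), ("contour_set_ids", contour_set_ids), ("levels", levels)):
        ids = list(ids)
        if not ids:
            raise ValidationError(f"{name} must be non-empty")
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate entries in {name}")
    if n_raters < 1:
        raise ValidationError("n_raters must be >= 1")

    rng = np.random.default_rng(seed)
    sets = list(contour_set_ids)
    alias_order = rng.permutation(len(sets))
    alias_map = {sets[int(i)]: f"set_{k + 1}" for k, i in enumerate(alias_order)}

    presentations = [(c, s) for c in case_ids for s in sets]
    rows = []
    for rater in range(1, n_raters + 1):
        order = rng.permutation(len(presentations))
        for pos, idx in enumerate(order, start=1):
            case, cset = presentations[int(idx)]
            for level in levels:
                rows.append(
                    {
                        "rater": rater,
                        "presentation_index": pos,
                        "case": case,
                        "contour_set_alias": alias_map[cset],
                        "level": level,
                        "rating": np.nan,
                    }
                )
    return BlindedManifest(table=pd.DataFrame(rows), alias_map=alias_map, seed=seed)


# ---------------------------------------------------------------------------
# rating summaries


@dataclass(frozen=True)
class RatingsSummary:
    per_set: pd.DataFrame  # contour_set_alias, mean, median, iqr_low, iqr_high, n_cases
    comparisons: dict[tuple[str, str], TestResult]


def summarize_ratings(ratings: pd.DataFrame) -> RatingsSummary:
    """Summarize a completed ratings table per contour set.

    Expects columns ``rater, case, contour_set_alias, level, rating`` with
    ratings in [0, 100]. Case-level means (over raters and levels) are the
    unit of analysis: per contour set the mean, median and IQR across cases
    are reported, and each pair of contour sets is compared with the paired
    signed-rank test on case means.
    """
    required = {"rater", "case", "contour_set_alias", "level", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValidationError(f"ratings table missing columns: {sorted(missing)}")
    vals = ratings["rating"].to_numpy(dtype=float)
    if np.any(np.isnan(vals)) or vals.min() < RATING_SCALE["min"] or vals.max() > RATING_SCALE["max"]:
        raise ValidationError("ratings must be numeric and within [0, 100]")

    case_means = (
        ratings.groupby(["contour_set_alias", "case"])["rating"].mean().unstack(level=0)
    )
    records = []
    for cset in case_means.columns:
        v = case_means[cset].dropna().to_numpy()
        q1, q3 = np.quantile(v, [0.25, 0.75])
        records.append(
            {
                "contour_set_alias": cset,
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "iqr_low": float(q1),
                "iqr_high": float(q3),
                "n_cases": int(v.size),
            }
        )
    per_set = pd.DataFrame(records).set_index("contour_set_alias")

    comparisons: dict[tuple[str, str], TestResult] = {}
    for a, b in combinations(case_means.columns, 2):
        sub = case_means[[a, b]].dropna()
        comparisons[(a, b)] = wilcoxon_signed_rank(
            PairedSample(tuple(sub.index), sub[a].to_numpy(), sub[b].to_numpy())
        )
    return RatingsSummary(per_set=per_set, comparisons=comparisons)
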