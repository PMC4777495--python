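"""Statistical battery: rater reliability, correlations, exact binomial tests.

The analysis of a rating study proceeds in three stages.  First, the
reliability of the rater-mean for each semantic-differential scale is
quantified with average-measure intraclass correlations (Shrout & Fleiss
two-way forms, F-based 95% CIs).  Second, per-stimulus mean ratings are
related to each other and to the kinematic measures with Pearson
correlations (Fisher-z confidence intervals, two-sided t-test p-values).
Third, a forced-choice follow-up is analysed with exact one-sided binomial
tests against chance (p0 = 0.5) and two-sided Clopper-Pearson intervals,
overall and stratified by word condition.

No multiple-testing correction is applied; correlation tables report raw
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError, ParameterError

#: The two artificial-word conditions of the forced-choice task.
WORDS = ("takete", "maluma")


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """Pearson coefficient with Fisher-z CI and two-sided p-value."""

    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float
    conf: float = 0.95

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass(frozen=True)
class ICCResult:
    """Average-measure intraclass correlation with an F-based CI."""

    icc: float
    variant: str
    ci_low: float
    ci_high: float
    n_targets: int
    n_raters: int
    conf: float = 0.95


@dataclass(frozen=True)
class BinomialResult:
    """Exact binomial test of k successes in n trials against ``p0``."""

    k: int
    n: int
    p0: float
    p_value: float
    ci_low: float
    ci_high: float
    alternative: str = "greater"

    @property
    def p_hat(self) -> float:
        return self.k / self.n

    @property
    def percent(self) -> int:
        """The success proportion as a rounded whole percentage."""
        return round(100 * self.k / self.n)


@dataclass(frozen=True)
class TrialRecord:
    """One forced-choice trial: which animation was picked for which word.

    ``correct`` means the choice matched the prediction — the high-feature
    stimulus for *takete*, the low-feature stimulus for *maluma*.
    """

    trial_id: int
    rater_id: int
    word: str
    low_stimulus: str
    high_stimulus: str
    chosen: str
    correct: bool

    def __post_init__(self) -> None:
        if self.word not in WORDS:
            raise DataValidationError(f"unknown word condition {self.word!r}")
        if self.chosen not in (self.low_stimulus, self.high_stimulus):
            raise DataValidationError(
                f"chosen stimulus {self.chosen!r} is neither alternative"
            )


@dataclass(frozen=True)
class RatingMatrix:
    """Rater x stimulus semantic-differential scores in [-100, 100].

    ``values`` has rater ids as index and stimulus ids as columns.  NaN
    cells mark stimuli a rater did not judge (stimuli are shown in subsets);
    reliability estimates require the submatrix they work on to be complete.
    """

    values: pd.DataFrame
    scale_label: str = "rating"

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if vals.size == 0:
            raise DataValidationError("rating matrix is empty")
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -100 or finite.max() > 100):
            raise DataValidationError("ratings must lie within [-100, 100]")

    @property
    def stimuli(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def raters(self) -> list[str]:
        return [str(r) for r in self.values.index]

    @classmethod
    def from_long(cls, df: pd.DataFrame, scale_label: str = "rating") -> "RatingMatrix":
        """Build from long records with columns rater_id, stimulus_id, value."""
        required = {"rater_id", "stimulus_id", "value"}
        missing = required - set(df.columns)
        if missing:
            raise DataValidationError(f"long ratings are missing columns {sorted(missing)}")
        wide = df.pivot_table(
            index="rater_id", columns="stimulus_id", values="value", aggfunc="first"
        )
        return cls(wide, scale_label)


def mean_ratings(matrix: RatingMatrix) -> pd.Series:
    """Per-stimulus mean across the raters who judged it."""
    means = matrix.values.mean(axis=0, skipna=True)
    means.name = matrix.scale_label
    return means


# ---------------------------------------------------------------------------
# Pearson correlation with Fisher-z CI
# ---------------------------------------------------------------------------

def pearson_ci(
    x: Sequence[float], y: Sequence[float], conf: float = 0.95
) -> CorrelationResult:
    """Pearson r with a Fisher-z confidence interval.

    The CI is ``tanh(atanh(r) +/- z * 1/sqrt(n - 3))``; the p-value is the
    two-sided t-test with ``n - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1D sequences of equal length")
    if x.size < 3:
        raise DataValidationError("correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataValidationError("correlation undefined: an input has zero variance")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=conf)
    return CorrelationResult(
        r=float(res.statistic),
        n=int(x.size),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p=float(res.pvalue),
        conf=conf,
    )


# ---------------------------------------------------------------------------
# Intraclass correlation (Shrout & Fleiss average-measure forms)
# ---------------------------------------------------------------------------

def _two_way_mean_squares(y: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (targets, raters, residual) of a complete n x k matrix."""
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msj = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float(msb), float(msj), float(mse)


def icc_average(
    matrix: RatingMatrix, variant: str = "icc2k", conf: float = 0.95
) -> ICCResult:
    """Average-measure ICC of a complete rating matrix.

    ``icc2k`` is the two-way random-effects, absolute-agreement form
    ICC(2,k); ``icc3k`` the two-way mixed, consistency form ICC(3,k).  Both
    are computed from the two-way ANOVA mean squares with the F-based
    confidence intervals of Shrout & Fleiss.  Stimuli are the targets
    (rows of the ANOVA), raters the columns.
    """
    if variant not in ("icc2k", "icc3k"):
        raise ParameterError(f"unknown ICC variant {variant!r}")
    y = matrix.values.to_numpy(dtype=float).T  # targets x raters
    if np.isnan(y).any():
        raise DataValidationError("ICC requires a complete rating matrix")
    n, k = y.shape
    if n < 2 or k < 2:
        raise DataValidationError("ICC needs at least 2 stimuli and 2 raters")
    msb, msj, mse = _two_way_mean_squares(y)
    if msb == 0:
        raise DataValidationError("ICC undefined: no between-stimulus variance")
    alpha = 1 - conf

    if variant == "icc3k":
        icc = (msb - mse) / msb
        if mse == 0:
            lo, hi = 1.0, 1.0
        else:
            f_obs = msb / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo, hi = 1 - 1 / fl, 1 - 1 / fu
    else:
        icc = (msb - mse) / (msb + (msj - mse) / n)
        if mse == 0 and msj == 0:
            lo, hi = 1.0, 1.0
        else:
            icc_single = (msb - mse) / (msb + (k - 1) * mse + k * (msj - mse) / n)
            a = k * icc_single / (n * (1 - icc_single)) if icc_single < 1 else np.inf
            b = (
                1 + k * icc_single * (n - 1) / (n * (1 - icc_single))
                if icc_single < 1
                else np.inf
            )
            if np.isinf(a):
                v = k - 1.0
            else:
                v = (a * msj + b * mse) ** 2 / (
                    (a * msj) ** 2 / (k - 1)
                    + (b * mse) ** 2 / ((n - 1) * (k - 1))
                )
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            l_single = (n * (msb - f1 * mse)) / (
                f1 * (k * msj + (k * n - k - n) * mse) + n * msb
            )
            u_single = (n * (f2 * msb - mse)) / (
                k * msj + (k * n - k - n) * mse + n * f2 * msb
            )
            lo = l_single * k / (1 + l_single * (k - 1))
            hi = u_single * k / (1 + u_single * (k - 1))
    return ICCResult(
        icc=float(icc),
        variant=variant,
        ci_low=float(min(lo, icc)),
        ci_high=float(min(max(hi, icc), 1.0)),
        n_targets=n,
        n_raters=k,
        conf=conf,
    )


def icc_by_subset(long_df: pd.DataFrame, variant: str = "icc2k") -> pd.DataFrame:
    """Average-measure ICCs computed per stimulus subset and scale.

    Stimuli are grouped into subsets by the set of raters who judged them
    (each participant rated one subset, so subsets have disjoint rater
    panels).  Expects long records with columns
    ``rater_id, stimulus_id, scale, value``.
    """
    required = {"rater_id", "stimulus_id", "scale", "value"}
    missing = required - set(long_df.columns)
    if missing:
        raise DataValidationError(f"ratings table is missing columns {sorted(missing)}")
    rater_sets = long_df.groupby("stimulus_id")["rater_id"].agg(frozenset)
    subset_of = {}
    for i, raters in enumerate(sorted(set(rater_sets), key=sorted)):
        for sid in rater_sets[rater_sets == raters].index:
            subset_of[sid] = i
    rows = []
    long_df = long_df.assign(subset=long_df["stimulus_id"].map(subset_of))
    for (subset, scale), grp in long_df.groupby(["subset", "scale"], sort=True):
        matrix = RatingMatrix.from_long(grp, scale_label=str(scale))
        res = icc_average(matrix, variant=variant)
        rows.append(
            {
                "subset": subset,
                "scale": scale,
                "icc": res.icc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_targets": res.n_targets,
                "n_raters": res.n_raters,
                "variant": variant,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exact binomial analysis
# ---------------------------------------------------------------------------

def binomial_exact(
    k: int, n: int, p0: float = 0.5, alternative: str = "greater", conf: float = 0.95
) -> BinomialResult:
    """Exact binomial test with a two-sided Clopper-Pearson interval.

    The p-value sums the binomial mass of outcomes at least as extreme as
    ``k`` in the direction of ``alternative``; the interval is the
    conventional two-sided exact (tail-inversion) CI for ``k / n``.
    """
    if not (0 <= k <= n) or n < 1:
        raise ParameterError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not (0 < p0 < 1):
        raise ParameterError(f"null probability must be in (0, 1), got {p0}")
    test = stats.binomtest(k, n, p0, alternative=alternative)
    ci = stats.binomtest(k, n, p0).proportion_ci(confidence_level=conf, method="exact")
    return BinomialResult(
        k=int(k),
        n=int(n),
        p0=float(p0),
        p_value=float(test.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        alternative=alternative,
    )


def select_extremes(
    values: Mapping[str, float] | pd.Series, k: int
) -> tuple[list[str], list[str]]:
    """Ids of the ``k`` lowest- and ``k`` highest-valued stimuli.

    Undefined values (None/NaN) are excluded before ranking.  Ties are
    broken by stimulus id ascending; the low tail is selected first and the
    high tail is drawn from the remaining stimuli, so the two groups are
    always disjoint.
    """
    series = pd.Series(dict(values)) if not isinstance(values, pd.Series) else values
    series = series.dropna()
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if series.size < 2 * k:
        raise DataValidationError(
            f"need at least {2 * k} stimuli with defined values, have {series.size}"
        )
    items = sorted(series.items(), key=lambda kv: (kv[1], str(kv[0])))
    low = [str(sid) for sid, _ in items[:k]]
    remaining = [kv for kv in items[k:]]
    remaining.sort(key=lambda kv: (-kv[1], str(kv[0])))
    high = [str(sid) for sid, _ in remaining[:k]]
    return low, high


def analyze_choices(
    trials: Sequence[TrialRecord] | pd.DataFrame, p0: float = 0.5
) -> dict[str, BinomialResult]:
    """Exact one-sided binomial tests, overall and per word condition.

    Under random guessing half the choices would match the prediction; the
    tests ask whether observers score significantly higher than that.
    Returns results keyed ``overall``, ``takete``, ``maluma``.
    """
    if isinstance(trials, pd.DataFrame):
        df = trials
    else:
        df = pd.DataFrame(
            [{"word": t.word, "correct": bool(t.correct)} for t in trials]
        )
    if df.empty:
        raise DataValidationError("no trials to analyse")
    if not set(df["word"]) <= set(WORDS):
        raise DataValidationError(
            f"unknown word condition(s): {sorted(set(df['word']) - set(WORDS))}"
        )
    correct = df["correct"].astype(bool)
    out = {"overall": binomial_exact(int(correct.sum()), len(df), p0)}
    for word in WORDS:
        mask = df["word"] == word
        if mask.any():
            out[word] = binomial_exact(int(correct[mask].sum()), int(mask.sum()), p0)
    return out


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tabulate trial records with the on-disk column layout."""
    return pd.DataFrame(
        [
            {
                "trial_id": t.trial_id,
                "rater_id": t.rater_id,
                "word": t.word,
                "low_stimulus": t.low_stimulus,
                "high_stimulus": t.high_stimulus,
                "chosen": t.chosen,
                "correct": t.correct,
            }
            for t in trials
        ]
    )


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    """Parse trial records from a table (e.g. a trials CSV)."""
    required = {
        "trial_id",
        "rater_id",
        "word",
        "low_stimulus",
        "high_stimulus",
        "chosen",
        "correct",
    }
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"trials table is missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        correct = row.correct
        if isinstance(correct, str):
            correct = correct.strip().lower() in ("true", "1", "yes")
        records.append(
            TrialRecord(
                trial_id=int(row.trial_id),
                rater_id=int(row.rater_id),
                word=str(row.word),
                low_stimulus=str(row.low_stimulus),
                high_stimulus=str(row.high_stimulus),
                chosen=str(row.chosen),
                correct=bool(correct),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Correlation tables
# ---------------------------------------------------------------------------

def correlation_table(
    left: pd.DataFrame, right: pd.DataFrame | None = None, conf: float = 0.95
) -> pd.DataFrame:
    """Pairwise Pearson correlations with CIs, as a long report table.

    With one argument, correlates every unordered pair of its columns; with
    two, correlates each column of ``left`` with each column of ``right``.
    Rows are aligned on the shared index; pairs with missing values drop
    those observations.
    """
    rows = []
    if right is None:
        cols = list(left.columns)
        pairs = [
            (cols[i], cols[j]) for i in range(len(cols)) for j in range(i + 1, len(cols))
        ]
        get = lambda name, side: left[name]  # noqa: E731
    else:
        common = left.index.intersection(right.index)
        if len(common) < 3:
            raise DataValidationError(
                "fewer than 3 shared stimulus ids between the two tables"
            )
        left = left.loc[common]
        right = right.loc[common]
        pairs = [(a, b) for a in left.columns for b in right.columns]
        get = lambda name, side: (left if side == 0 else right)[name]  # noqa: E731
    for a, b in pairs:
        x = pd.to_numeric(get(a, 0), errors="coerce")
        y = pd.to_numeric(get(b, 1), errors="coerce")
        keep = x.notna() & y.notna()
        res = pearson_ci(x[keep].to_numpy(), y[keep].to_numpy(), conf=conf)
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "r": res.r,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)
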