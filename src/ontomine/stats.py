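"""Statistical layer: forum-comparison chi-square tests, lexicon sentiment
scoring, per-forum quartile retention, and logistic models of negative
sentiment with odds ratios, Wald CIs, likelihood-ratio tests, AIC/BIC
backward elimination and AUC.

The built-in sentiment scorer is the lexicon mean: tokenize a post (no
stemming, no stopword removal), average the polarities of tokens found in
the lexicon, 0.0 when none match.  External scorers (TextBlob-style,
VADER-style) can be plugged in through any callable mapping text to a score
in [-1, 1]; the downstream operations only see scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ontomine.textprep import tokenize

try:  # statsmodels moved/renamed this exception across versions
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass

import statsmodels.api as sm


class StatsError(ValueError):
    pass


class SeparationError(StatsError):
    """Perfect separation: a covariate fully predicts the outcome."""


# ---------------------------------------------------------------------------
# Chi-square forum comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) = forum-1 mentions / non-mentions, (c, d) = forum-2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise StatsError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise StatsError("empty contingency table")

    @classmethod
    def from_counts(cls, n1: int, total1: int, n2: int, total2: int) -> "ContingencyTable2x2":
        """Build from per-forum mention counts and forum post totals."""
        return cls(a=n1, b=total1 - n1, c=n2, d=total2 - n2)


def chi2_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction.

    Returns (statistic, upper-tail p).  A zero row or column margin leaves
    the test undefined and raises :class:`StatsError`.
    """
    arr = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise StatsError("chi-square undefined: zero row or column margin")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Sentiment scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SentimentLexicon:
    polarities: Mapping[str, float]

    def __post_init__(self) -> None:
        for tok, pol in self.polarities.items():
            if tok != tok.lower():
                raise StatsError(f"lexicon token {tok!r} not lowercase")
            if not -1.0 <= pol <= 1.0:
                raise StatsError(f"polarity of {tok!r} outside [-1, 1]")

    def __contains__(self, token: str) -> bool:
        return token in self.polarities

    def negative_pool(self, threshold: float = -0.3) -> list[str]:
        return sorted(t for t, p in self.polarities.items() if p <= threshold)

    def positive_pool(self, threshold: float = 0.3) -> list[str]:
        return sorted(t for t, p in self.polarities.items() if p >= threshold)


def load_lexicon(path: str | Path | None = None) -> SentimentLexicon:
    """Load a ``token<TAB>polarity`` lexicon; default is the packaged list."""
    if path is None:
        text = (resources.files("ontomine") / "data" / "sentiment_lexicon.tsv").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    polarities: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tok, _, val = line.partition("\t")
        polarities[tok.strip().lower()] = float(val)
    return SentimentLexicon(polarities)


@dataclass(frozen=True)
class SentimentScore:
    post_id: str
    score: float
    n_matched_tokens: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.score <= 1.0:
            raise StatsError(f"sentiment score {self.score} outside [-1, 1]")


def sentiment_score(
    text: str, lexicon: SentimentLexicon, *, post_id: str = ""
) -> SentimentScore:
    """Arithmetic mean of lexicon polarities over the post's tokens.

    Tokenization matches preprocessing (lowercase, non-alphanumeric splits)
    but applies no stemming or stopword removal; posts with no lexicon token
    score 0.0.
    """
    matched = [lexicon.polarities[tok] for tok in tokenize(text) if tok in lexicon]
    score = float(np.mean(matched)) if matched else 0.0
    return SentimentScore(post_id=post_id, score=score, n_matched_tokens=len(matched))


# ---------------------------------------------------------------------------
# Quartile retention
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    retain_fraction: float = 0.25
    screen_alpha: float = 0.1
    sig_alpha: float = 0.05
    ci_level: float = 0.95
    criterion: str = "aic"  # or "bic"

    def __post_init__(self) -> None:
        if not 0 < self.retain_fraction <= 0.5:
            raise StatsError("retain_fraction must be in (0, 0.5]")
        for alpha in (self.screen_alpha, self.sig_alpha):
            if not 0 < alpha < 1:
                raise StatsError("alphas must be in (0, 1)")
        if self.criterion not in ("aic", "bic"):
            raise StatsError("criterion must be 'aic' or 'bic'")


def quartile_retain(
    scores: Sequence[SentimentScore],
    forums: Mapping[str, str],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Keep each forum's most negative and most positive tails, drop the middle.

    Within each forum, posts are sorted ascending by (score, post_id) — the
    stable post_id tie-break makes retention deterministic when scores tie.
    The lowest floor(retain_fraction*n) posts are labelled negative=1, the
    highest floor(retain_fraction*n) negative=0.  Forums with fewer than 4
    scored posts are skipped with a warning.
    """
    config = config or AnalysisConfig()
    rows = []
    by_forum: dict[str, list[SentimentScore]] = {}
    for s in scores:
        by_forum.setdefault(forums[s.post_id], []).append(s)
    for fid in sorted(by_forum):
        group = sorted(by_forum[fid], key=lambda s: (s.score, s.post_id))
        n = len(group)
        k = int(np.floor(config.retain_fraction * n))
        if n < 4 or k == 0:
            warnings.warn(f"forum {fid!r}: {n} scores < 4; skipped in retention")
            continue
        for s in group[:k]:
            rows.append((s.post_id, fid, s.score, 1))
        for s in group[n - k:]:
            rows.append((s.post_id, fid, s.score, 0))
    return pd.DataFrame(rows, columns=["post_id", "forum_id", "score", "negative"])


# ---------------------------------------------------------------------------
# Logistic modelling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateEffect:
    coef: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    covariates: dict[str, CovariateEffect]
    loglik: float
    aic: float
    bic: float
    lrt_p: float
    auc: float
    n: int
    trace: tuple[dict, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "covariate": name,
                    "OR": eff.odds_ratio,
                    "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high,
                    "p": eff.p,
                }
                for name, eff in self.covariates.items()
            ]
        )


def _auc_mann_whitney(probs: np.ndarray, y: np.ndarray) -> float:
    """Concordance of fitted probabilities with outcomes (rank formulation)."""
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise StatsError("AUC undefined: single-class outcome")
    ranks = sps.rankdata(probs)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def fit_logistic(
    design: pd.DataFrame,
    y: Sequence[int],
    config: AnalysisConfig | None = None,
) -> RegressionResult:
    """Maximum-likelihood logistic regression (Newton/IRLS) with intercept.

    Reports per-covariate odds ratios with Wald CIs, model AIC/BIC, the LRT
    against the intercept-only model and the Mann-Whitney AUC of the fitted
    probabilities.  Diverging coefficients (|coef| > 15) or a statsmodels
    separation failure raise :class:`SeparationError`; a rank-deficient
    design raises :class:`StatsError`.
    """
    config = config or AnalysisConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if design.shape[0] != n:
        raise StatsError("design and outcome lengths differ")
    for col in design.columns:
        if design[col].nunique() < 2:
            raise StatsError(f"covariate {col!r} is constant")
    X = sm.add_constant(design.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise StatsError("singular design matrix")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100, tol=1e-8)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"perfect separation: {exc}") from exc
    coefs = fit.params
    diverged = [c for c in design.columns if abs(coefs[c]) > 15]
    if diverged:
        raise SeparationError(f"perfect separation: covariate(s) {diverged} diverged")

    z = sps.norm.ppf(0.5 + config.ci_level / 2)
    se = fit.bse
    covariates = {}
    for col in design.columns:
        b = float(coefs[col])
        covariates[col] = CovariateEffect(
            coef=b,
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - z * se[col])),
            ci_high=float(np.exp(b + z * se[col])),
            p=float(fit.pvalues[col]),
        )
    k = X.shape[1]
    llf = float(fit.llf)
    llnull = float(fit.llnull)
    df = k - 1
    lrt_p = float(sps.chi2.sf(2 * (llf - llnull), df)) if df > 0 else 1.0
    probs = np.asarray(fit.predict(X))
    return RegressionResult(
        covariates=covariates,
        loglik=llf,
        aic=2 * k - 2 * llf,
        bic=k * np.log(n) - 2 * llf,
        lrt_p=lrt_p,
        auc=_auc_mann_whitney(probs, y),
        n=n,
    )


def fit_intercept_only(y: Sequence[int]) -> RegressionResult:
    """Null model: intercept only; AUC 0.5 and LRT p 1 by construction."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        raise StatsError("degenerate outcome: single class")
    llf = float(n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
    coef = float(np.log(pbar / (1 - pbar)))
    return RegressionResult(
        covariates={},
        loglik=llf,
        aic=2 - 2 * llf,
        bic=float(np.log(n)) - 2 * llf,
        lrt_p=1.0,
        auc=0.5,
        n=n,
    )


def screen_univariable(
    candidates: pd.DataFrame,
    y: Sequence[int],
    config: AnalysisConfig | None = None,
) -> list[str]:
    """Single-variable screen: keep covariates with LRT p below screen_alpha.

    Covariates whose single-covariate model fails to fit (separation,
    constancy) are dropped with a warning.
    """
    config = config or AnalysisConfig()
    retained = []
    for col in candidates.columns:
        try:
            res = fit_logistic(candidates[[col]], y, config)
        except StatsError as exc:
            warnings.warn(f"covariate {col!r} dropped in screening: {exc}")
            continue
        if res.lrt_p < config.screen_alpha:
            retained.append(col)
    return retained


def backward_eliminate(
    design: pd.DataFrame,
    y: Sequence[int],
    config: AnalysisConfig | None = None,
    forced: Iterable[str] = (),
) -> RegressionResult:
    """Stepwise backward elimination toward the most parsimonious model.

    Repeatedly drops the single covariate whose removal most reduces the
    information criterion (AIC by default, BIC via config); stops when no
    removal improves it.  Covariates in *forced* (e.g. the first-post
    indicator) are never eliminated.  Both criteria are recorded at every
    step in the elimination trace.
    """
    config = config or AnalysisConfig()
    forced = set(forced)
    missing = forced - set(design.columns)
    if missing:
        raise StatsError(f"forced covariate(s) {sorted(missing)} not in design")
    current = list(design.columns)

    def crit(res: RegressionResult) -> float:
        return res.aic if config.criterion == "aic" else res.bic

    def fit_cols(cols: list[str]) -> RegressionResult:
        if cols:
            return fit_logistic(design[cols], y, config)
        return fit_intercept_only(y)

    best = fit_cols(current)
    trace = [{"step": 0, "covariates": tuple(current), "aic": best.aic,
              "bic": best.bic, "removed": None}]
    step = 0
    while True:
        removable = [c for c in current if c not in forced]
        options = []
        for col in removable:
            cols = [c for c in current if c != col]
            try:
                options.append((col, fit_cols(cols)))
            except StatsError:
                continue
        improving = [(col, res) for col, res in options if crit(res) < crit(best)]
        if not improving:
            break
        col, res = min(improving, key=lambda item: crit(item[1]))
        current = [c for c in current if c != col]
        best = res
        step += 1
        trace.append({"step": step, "covariates": tuple(current), "aic": best.aic,
                      "bic": best.bic, "removed": col})
    return RegressionResult(
        covariates=best.covariates,
        loglik=best.loglik,
        aic=best.aic,
        bic=best.bic,
        lrt_p=best.lrt_p,
        auc=best.auc,
        n=best.n,
        trace=tuple(trace),
    )
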