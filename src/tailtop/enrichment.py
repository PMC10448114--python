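"""TOP-motif classification, hypergeometric enrichment, and the
assumption-guided group-comparison test selector.

The TOP (5′-terminal oligopyrimidine) motif is a pyrimidine tract of about
4–15 nt at the transcript's 5′ end.  The classifier requires the first
nucleotide to be a pyrimidine and the maximal pyrimidine run starting there
to reach at least 4 nt; runs longer than 15 are still classified TOP but
flagged.  A strict mode additionally requires the canonical C start.

Set enrichment is the upper-tail hypergeometric probability of drawing at
least ``k`` TOP genes in a sample of ``s`` from a universe of ``N`` genes
containing ``M`` TOP genes, computed in log space.

:func:`compare_groups` reproduces the test-selection procedure used for
group comparisons: Shapiro-Wilk normality and Levene variance screens at
α = 0.05 route the data to Student's/paired t, Wilcoxon, one-way ANOVA with
Dunnett's comparisons, Games-Howell, or Kruskal-Wallis with Bonferroni.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TopMotifCall",
    "EnrichmentResult",
    "GroupComparisonResult",
    "classify_top_motif",
    "hypergeometric_enrichment",
    "ks_two_sided",
    "games_howell",
    "compare_groups",
]

PYRIMIDINES = frozenset("CUTcut")
ALPHABET = frozenset("ACGUTNacgutn")


@dataclass(frozen=True)
class TopMotifCall:
    is_top: bool
    run_length: int
    exceeds_canonical: bool  # run longer than the canonical 15 nt


def classify_top_motif(utr5_sequence: str, strict_c_start: bool = False) -> TopMotifCall:
    """Classify a 5′UTR as TOP from its terminal pyrimidine tract.

    Accepts RNA or DNA alphabet (T ≡ U).  TOP requires the +1 nucleotide to
    be a pyrimidine (C with ``strict_c_start``) and the maximal pyrimidine
    run from position 1 to span at least 4 nt.
    """
    seq = str(utr5_sequence)
    if not seq:
        raise ValueError("empty 5'UTR sequence")
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide character {sorted(bad)[0]!r} in sequence")
    run = 0
    for base in seq:
        if base in PYRIMIDINES:
            run += 1
        else:
            break
    is_top = run >= 4
    if strict_c_start and seq[0] not in "Cc":
        is_top = False
    return TopMotifCall(is_top=is_top, run_length=run, exceeds_canonical=run > 15)


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a gene set.

    ``k`` successes in a tested set of size ``s``, from a universe of ``N``
    genes containing ``M`` successes; ``p_upper`` is P(X ≥ k).
    """

    k: int
    s: int
    M: int
    N: int
    p_upper: float


_LOG_FACT = np.array([0.0])


def _log_fact(n: int) -> float:
    global _LOG_FACT
    if n >= _LOG_FACT.size:
        start = _LOG_FACT.size
        ext = np.log(np.arange(start, n + 1, dtype=float))
        _LOG_FACT = np.concatenate([_LOG_FACT, _LOG_FACT[-1] + np.cumsum(ext)])
    return float(_LOG_FACT[n])


def _log_comb(n: int, r: int) -> float:
    return _log_fact(n) - _log_fact(r) - _log_fact(n - r)


def hypergeometric_enrichment(k: int, s: int, M: int, N: int) -> EnrichmentResult:
    """Upper-tail hypergeometric probability, stable in log space.

    ``p_upper = Σ_{i=k}^{min(s,M)} C(M,i)·C(N−M,s−i) / C(N,s)``.
    Raises on any violated bound, naming the inequality.
    """
    k, s, M, N = int(k), int(s), int(M), int(N)
    if k < 0:
        raise ValueError("bound violated: k >= 0")
    if s > N:
        raise ValueError("bound violated: s <= N")
    if M > N:
        raise ValueError("bound violated: M <= N")
    if k > min(s, M):
        raise ValueError("bound violated: k <= min(s, M)")
    i_lo = max(k, s - (N - M))
    i_hi = min(s, M)
    if i_lo > i_hi:
        return EnrichmentResult(k, s, M, N, 0.0)
    log_den = _log_comb(N, s)
    log_terms = [
        _log_comb(M, i) + _log_comb(N - M, s - i) - log_den for i in range(i_lo, i_hi + 1)
    ]
    peak = max(log_terms)
    p = math.exp(peak) * sum(math.exp(t - peak) for t in log_terms)
    return EnrichmentResult(k, s, M, N, min(p, 1.0))


def ks_two_sided(sample_a, sample_b, method: str = "auto") -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (scipy-backed).

    ``method`` follows scipy: ``"auto"`` picks the exact small-sample
    distribution when feasible, ``"asymp"`` forces the asymptotic one.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def games_howell(groups, labels=None) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for heteroscedastic groups.

    Welch degrees of freedom per pair, with p-values from the studentized
    range distribution on ``k`` groups (q = |t|·√2).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    means = [g.mean() for g in groups]
    variances = [g.var(ddof=1) for g in groups]
    ns = [g.size for g in groups]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = variances[i] / ns[i], variances[j] / ns[j]
            se = math.sqrt(vi + vj)
            t = (means[i] - means[j]) / se
            df = (vi + vj) ** 2 / (vi**2 / (ns[i] - 1) + vj**2 / (ns[j] - 1))
            p = float(stats.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df))
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": means[i] - means[j],
                    "se": se,
                    "t": t,
                    "df": df,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GroupComparisonResult:
    """Outcome of the automatic test selection for a group comparison."""

    test_name: str
    statistic: float
    p_value: float
    trace: dict = field(default_factory=dict)
    comparisons: pd.DataFrame | None = None


def compare_groups(
    groups,
    paired: bool = False,
    reference: int = 0,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Select and run the appropriate comparison test for ``groups``.

    Selection is a pure function of the Shapiro-Wilk and Levene screening
    p-values (both at ``alpha``) and the group count:

    * 2 groups, normal, equal variance → Student's t (paired variant when
      ``paired``);
    * 2 groups, normal, unequal variance → Games-Howell (equivalent to a
      Welch comparison at k = 2);
    * 2 groups, non-normal → Wilcoxon (signed-rank when paired, rank-sum
      otherwise);
    * >2 groups, normal, homoscedastic → one-way ANOVA with Dunnett's
      comparisons against the reference group;
    * >2 groups, normal, heteroscedastic → Games-Howell;
    * >2 groups, non-normal → Kruskal-Wallis with Bonferroni-corrected
      pairwise rank-sum comparisons.

    The full decision trace (screening p-values, branch taken) is returned.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size < 3:
            raise ValueError(f"group {i} has fewer than 3 observations; normality untestable")
    if paired and len({g.size for g in groups}) != 1:
        raise ValueError("paired comparison requires equal group sizes")

    shapiro_p = [float(stats.shapiro(g).pvalue) for g in groups]
    normal = all(p > alpha for p in shapiro_p)
    levene_p = float(stats.levene(*groups, center="mean").pvalue)
    equal_var = levene_p > alpha
    trace = {
        "shapiro_p": shapiro_p,
        "levene_p": levene_p,
        "normal": normal,
        "equal_variance": equal_var,
        "n_groups": len(groups),
        "paired": paired,
        "alpha": alpha,
    }
    comparisons = None
    if len(groups) == 2:
        a, b = groups
        if normal and equal_var:
            if paired:
                res = stats.ttest_rel(a, b)
                name = "paired_t"
            else:
                res = stats.ttest_ind(a, b, equal_var=True)
                name = "student_t"
            statistic, p = float(res.statistic), float(res.pvalue)
        elif normal:
            comparisons = games_howell(groups)
            name = "games_howell"
            statistic = float(comparisons["t"].iloc[0])
            p = float(comparisons["p_value"].iloc[0])
        else:
            if paired:
                res = stats.wilcoxon(a, b)
                name = "wilcoxon_paired"
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                name = "wilcoxon_unpaired"
            statistic, p = float(res.statistic), float(res.pvalue)
    else:
        if normal and equal_var:
            omnibus = stats.f_oneway(*groups)
            control = groups[reference]
            treatments = [g for i, g in enumerate(groups) if i != reference]
            dunnett = stats.dunnett(*treatments, control=control)
            comparisons = pd.DataFrame(
                {
                    "group": [i for i in range(len(groups)) if i != reference],
                    "statistic": np.atleast_1d(dunnett.statistic),
                    "p_value": np.atleast_1d(dunnett.pvalue),
                }
            )
            name = "anova_dunnett"
            statistic, p = float(omnibus.statistic), float(omnibus.pvalue)
        elif normal:
            comparisons = games_howell(groups)
            name = "games_howell"
            statistic = float(comparisons["t"].abs().max())
            p = float(comparisons["p_value"].min())
        else:
            omnibus = stats.kruskal(*groups)
            n_pairs = len(groups) * (len(groups) - 1) // 2
            rows = []
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    mw = stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
                    rows.append(
                        {
                            "group_a": i,
                            "group_b": j,
                            "statistic": float(mw.statistic),
                            "p_value": min(float(mw.pvalue) * n_pairs, 1.0),
                        }
                    )
            comparisons = pd.DataFrame(rows)
            name = "kruskal_bonferroni"
            statistic, p = float(omnibus.statistic), float(omnibus.pvalue)
    trace["selected"] = name
    return GroupComparisonResult(
        test_name=name, statistic=statistic, p_value=p, trace=trace, comparisons=comparisons
    )
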