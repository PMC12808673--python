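"""Group-level nonparametric inference and parameter-space separability.

Model RMSEs are compared across models (per sex) with a Kruskal–Wallis
omnibus test followed, on rejection, by all-pairs Dunn post-hoc tests with
Benjamini–Hochberg FDR adjustment.  Fitted parameters are compared across
male (M), female non-estrous (NE) and female estrous (E) groups: male-vs-
female contrasts use Mann–Whitney U (independent animals); NE-vs-E uses the
Wilcoxon signed-rank test because both fits come from different days of the
same animals.  Effect sizes for paired model contrasts are paired Cohen's d.
Sex separability in (T_min, a1, a2) space is assessed with a quadratic
decision surface (quadratic discriminant analysis) and reported as in-sample
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairwiseTest", "GroupComparison",
    "dunn_posthoc", "compare_model_errors", "compare_params_by_state",
    "paired_cohens_d", "parameter_separability",
]

ALPHA = 0.05


@dataclass
class PairwiseTest:
    pair: tuple[str, str]
    statistic: float
    raw_p: float
    adjusted_p: float
    test_name: str


@dataclass
class GroupComparison:
    groups: dict[str, np.ndarray]
    omnibus_p: float | None
    pairwise: list[PairwiseTest]
    alpha: float = ALPHA

    def to_report(self) -> list[dict]:
        return [{
            "test": t.test_name, "pair": list(t.pair),
            "n": [int(len(self.groups[g])) for g in t.pair],
            "statistic": t.statistic, "raw_p": t.raw_p, "adjusted_p": t.adjusted_p,
        } for t in self.pairwise]


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "fdr_bh") -> list[PairwiseTest]:
    """All-pairs Dunn tests on pooled ranks with tie correction.

    z for pair (i, j) is the difference of mean pooled ranks scaled by
    sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) where T corrects for ties; raw
    two-sided normal p-values are then BH-adjusted (adjust=None skips
    adjustment).
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[start:start + v.size].mean()
        sizes[name] = v.size
        start += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    tests = []
    for a, b in combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        tests.append(PairwiseTest((a, b), float(z), float(p), float(p), "dunn"))
    if adjust and tests:
        adj = multipletests([t.raw_p for t in tests], method=adjust)[1]
        for t, q in zip(tests, adj):
            t.adjusted_p = float(q)
    return tests


def compare_model_errors(rmse_by_model: dict[str, np.ndarray],
                         alpha: float = ALPHA) -> GroupComparison:
    """Kruskal–Wallis across models; Dunn + BH post-hoc on rejection.

    ``rmse_by_model`` maps model names to per-animal RMSE arrays for one sex.
    """
    if len(rmse_by_model) < 2:
        raise ValueError("need at least two models to compare")
    arrays = [np.asarray(v, dtype=float) for v in rmse_by_model.values()]
    if any(a.size < 3 for a in arrays):
        raise ValueError("need at least 3 values per group")
    if np.ptp(np.concatenate(arrays)) == 0:
        raise ValueError("all values identical; rank tests degenerate")
    _, omnibus_p = sps.kruskal(*arrays)
    groups = {k: np.asarray(v, float) for k, v in rmse_by_model.items()}
    pairwise = dunn_posthoc(groups) if omnibus_p < alpha else []
    return GroupComparison(groups, float(omnibus_p), pairwise, alpha)


def compare_params_by_state(values_by_group: dict[str, "np.ndarray | dict[str, float]"],
                            alpha: float = ALPHA) -> GroupComparison:
    """Compare one scalar quantity across the M / NE / E day groups.

    ``values_by_group["M"]`` is an array over male mice; ``"NE"`` and ``"E"``
    are mouse_id -> value dicts so the NE-vs-E contrast can be paired within
    animal.  M-vs-NE and M-vs-E use Mann–Whitney U; NE-vs-E uses Wilcoxon
    signed-rank on the within-mouse pairs.
    """
    m = np.asarray(values_by_group["M"], dtype=float)
    ne, e = values_by_group["NE"], values_by_group["E"]
    if not isinstance(ne, dict) or not isinstance(e, dict):
        raise ValueError("NE and E values must be mouse_id-keyed for pairing")
    shared = sorted(set(ne) & set(e))
    if set(ne) != set(e):
        raise ValueError("NE and E groups are not paired by mouse_id")
    ne_v = np.array([ne[k] for k in shared], dtype=float)
    e_v = np.array([e[k] for k in shared], dtype=float)

    tests = []
    for name, other in (("NE", ne_v), ("E", e_v)):
        u, p = sps.mannwhitneyu(m, other, alternative="two-sided")
        tests.append(PairwiseTest(("M", name), float(u), float(p), float(p), "mannwhitneyu"))
    w, p = sps.wilcoxon(ne_v, e_v)
    tests.append(PairwiseTest(("NE", "E"), float(w), float(p), float(p), "wilcoxon"))
    groups = {"M": m, "NE": ne_v, "E": e_v}
    return GroupComparison(groups, None, tests, alpha)


def paired_cohens_d(values_a, values_b) -> float:
    """Paired Cohen's d: mean(a-b) / sample SD(a-b) (ddof=1)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: d undefined")
    return float(d.mean() / sd)


def parameter_separability(params_with_sex, include_report: bool = False):
    """In-sample male/female separation accuracy of a quadratic surface.

    ``params_with_sex`` is an iterable of ``((t_min, a1, a2), sex)`` or
    ``(SSParams, sex)`` pairs.  A quadratic discriminant (one Gaussian per
    class, quadratic decision boundary) is trained on all points and scored
    on the same points; 100.0 means a perfect separating quadratic surface
    exists for this sample.  Returns accuracy in percent (and, when
    ``include_report``, a dict with the per-point predictions).
    """
    X, y = [], []
    for p, sex in params_with_sex:
        if hasattr(p, "t_min"):
            X.append([p.t_min, p.a1, p.a2])
        else:
            X.append(list(p))
        y.append(sex)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValueError("both sexes must be present")
    # standardise: the raw parameters live on scales spanning 5 orders of
    # magnitude, which makes per-class covariances numerically singular
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    qda = QuadraticDiscriminantAnalysis(store_covariance=False, reg_param=1e-3)
    qda.fit(Z, y)
    pred = qda.predict(Z)
    acc = 100.0 * float(np.mean(pred == y))
    if include_report:
        return acc, {"predicted": pred.tolist(), "actual": y.tolist(),
                     "perfect_separation": acc == 100.0}
    return acc
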