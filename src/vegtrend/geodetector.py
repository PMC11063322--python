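"""Geographical detector: spatial stratified heterogeneity and its drivers.

The central quantity is the q-statistic.  Given a response y over N sample
units and a partition of those units into L strata (the discretized levels of
a candidate driver X), q measures how much of the response variance the
stratification explains:

    q = 1 - SSW / SST,
    SSW = sum_h sum_{i in h} (y_i - mean_h)^2,
    SST = sum_i (y_i - mean)^2.

q = 0 means the stratum means all equal the grand mean (X explains nothing);
q = 1 means y is constant within every stratum (X explains everything).
Sums of squared deviations (the population-variance form N_h * sigma_h^2) are
used throughout, which makes q exactly 1 - SSW/SST for any stratum sizes.

Four detectors build on q:

* factor detector — q per driver, with significance from the noncentral-F
  transform F = (N-L)/(L-1) * q/(1-q) (noncentrality
  lambda = [sum_h mean_h^2 - (sum_h sqrt(N_h) mean_h)^2 / N] / sigma^2),
  or from a seeded permutation test;
* interaction detector — q of two drivers' cross-classification compared
  with their individual q values, categorized into the five canonical
  interaction types;
* ecological detector — the F-ratio
  F = N_X1 (N_X2 - 1) SSW_X1 / [N_X2 (N_X1 - 1) SSW_X2]
  testing whether two drivers differ in their within-strata variance;
* risk detector — stratum means with pairwise Welch t-tests
  t = (mean_1 - mean_2) / sqrt(var_1/n_1 + var_2/n_2)
  identifying the stratum with the highest response.

Continuous drivers are discretized by equal-width, quantile, natural-breaks
(Fisher–Jenks), geometric, or standard-deviation breaks; optimal
discretization searches (method, k) candidates for the assignment with the
largest q.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StrataAssignment",
    "FactorResult",
    "InteractionResult",
    "EcoResult",
    "RiskResult",
    "DISCRETIZE_METHODS",
    "discretize",
    "optimal_discretize",
    "factor_q",
    "interaction_detect",
    "ecological_detect",
    "risk_detect",
    "detector_report",
]

DISCRETIZE_METHODS = ("equal", "quantile", "natural_breaks", "geometric", "sd")

INTERACTION_CATEGORIES = (
    "nonlinear weaken",
    "single-factor nonlinear weaken",
    "two-factor enhancement",
    "independent",
    "nonlinear enhancement",
)


class DetectorError(ValueError):
    """Degenerate input to a detector (constant response, < 2 strata...)."""


@dataclasses.dataclass
class StrataAssignment:
    """Integer stratum label per sample unit for one factor.

    Labels are 1..L with every stratum nonempty.  ``break_spec`` records the
    discretization provenance when the strata come from a continuous
    covariate.
    """

    labels: np.ndarray
    source: str = "X"
    break_spec: dict | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise DetectorError("stratum labels must be 1-D")
        present = np.unique(self.labels)
        if present.size == 0:
            raise DetectorError("empty stratum assignment")
        # compact to 1..L keeping order of stratum values
        remap = {int(v): i + 1 for i, v in enumerate(present)}
        if present[0] != 1 or present[-1] != present.size:
            self.labels = np.array([remap[int(v)] for v in self.labels])

    @property
    def L(self) -> int:
        return int(self.labels.max())

    @property
    def n(self) -> int:
        return self.labels.size


@dataclasses.dataclass
class FactorResult:
    q: float
    SSW: float
    SST: float
    N: int
    Nh: np.ndarray
    mean_h: np.ndarray
    sigma2: float
    sigma2_h: np.ndarray
    p_value: float
    p_method: str
    source: str = "X"


@dataclasses.dataclass
class InteractionResult:
    q1: float
    q2: float
    q12: float
    category: str
    n_cells: int


@dataclasses.dataclass
class EcoResult:
    F: float
    N_X1: int
    N_X2: int
    SSW_X1: float
    SSW_X2: float
    L1: int
    L2: int
    significant: bool
    alpha: float = 0.05
    degenerate: bool = False


@dataclasses.dataclass
class RiskResult:
    mean_h: np.ndarray
    var_h: np.ndarray
    n_h: np.ndarray
    t_matrix: np.ndarray
    df_matrix: np.ndarray
    sig_matrix: np.ndarray
    best_stratum: int
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Discretization


def _fisher_jenks_breaks(x_sorted: np.ndarray, k: int) -> np.ndarray:
    """Optimal 1-D k-class partition minimizing within-class sum of squares.

    Dynamic program over the sorted values using prefix sums; O(k n^2).
    Returns the k-1 upper boundaries (last member of each lower class).
    """
    n = x_sorted.size
    cs = np.concatenate(([0.0], np.cumsum(x_sorted)))
    cs2 = np.concatenate(([0.0], np.cumsum(x_sorted ** 2)))

    def sse(i: int, j: int) -> np.ndarray:
        """Within-class SSE of x[i:j] for vector j (exclusive)."""
        m = j - i
        s = cs[j] - cs[i]
        s2 = cs2[j] - cs2[i]
        return s2 - s * s / m

    # cost[c, j] = min SSE partitioning x[:j] into c classes
    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    j_idx = np.arange(1, n + 1)
    cost[1, 1:] = sse(0, j_idx)
    cost[0, 0] = 0.0
    for c in range(2, k + 1):
        for j in range(c, n + 1):
            i_opts = np.arange(c - 1, j)
            cand = cost[c - 1, i_opts] + sse(i_opts, j)
            best = int(np.argmin(cand))
            cost[c, j] = cand[best]
            back[c, j] = i_opts[best]
    # trace back boundaries; report midpoints so left-closed labelling keeps
    # the boundary value in its optimal (lower) class
    bounds = []
    j = n
    for c in range(k, 1, -1):
        i = back[c, j]
        bounds.append((x_sorted[i - 1] + x_sorted[i]) / 2.0)
        j = i
    return np.array(sorted(bounds))


def _compute_breaks(x: np.ndarray, method: str, k: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if method == "equal":
        return np.linspace(lo, hi, k + 1)[1:-1]
    if method == "quantile":
        qs = np.linspace(0, 1, k + 1)[1:-1]
        return np.quantile(x, qs)
    if method == "natural_breaks":
        xs = np.sort(x)
        if xs.size > 2000:  # subsample for the O(n^2) DP; breaks stay stable
            rng = np.random.default_rng(0)
            xs = np.sort(rng.choice(xs, 2000, replace=False))
        return _fisher_jenks_breaks(xs, k)
    if method == "geometric":
        shift = 1.0 - lo if lo <= 0 else 0.0
        g = np.geomspace(lo + shift, hi + shift, k + 1)[1:-1]
        return g - shift
    if method == "sd":
        mu, sd = float(x.mean()), float(x.std())
        if sd == 0:
            return np.array([])
        offsets = (np.arange(k - 1) - (k - 2) / 2.0) * sd
        breaks = mu + offsets
        return breaks[(breaks > lo) & (breaks < hi)]
    raise DetectorError(f"unknown discretization method {method!r}")


def discretize(x: Sequence[float], method: str = "quantile",
               k: int = 5, source: str = "X") -> StrataAssignment:
    """Bin a continuous covariate into k strata by the chosen method.

    Labels come from left-closed intervals over the break vector; empty
    strata are merged (with a warning), so the realized stratum count can be
    below k for heavily tied data.  A constant covariate yields a single
    stratum flagged unusable in ``break_spec``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise DetectorError("covariate must be a nonempty 1-D array")
    if not np.all(np.isfinite(x)):
        raise DetectorError("covariate contains non-finite values")
    if k < 2:
        raise DetectorError("k must be >= 2")
    if np.unique(x).size == 1:
        warnings.warn(f"covariate {source!r} is constant; single stratum")
        return StrataAssignment(np.ones(x.size, dtype=int), source=source,
                                break_spec={"method": method, "k": 1,
                                            "breaks": [], "usable": False})
    breaks = np.unique(_compute_breaks(x, method, k))
    labels = 1 + np.searchsorted(breaks, x, side="right")
    present = np.unique(labels)
    if present.size < 2:
        # degenerate break vector; fall back to a median split
        med = float(np.median(x))
        labels = 1 + (x > med).astype(int)
        breaks = np.array([med])
        present = np.unique(labels)
    if present.size < len(breaks) + 1:
        warnings.warn(f"{source}: empty strata merged "
                      f"({len(breaks) + 1 - present.size} dropped)")
    return StrataAssignment(labels, source=source,
                            break_spec={"method": method, "k": int(present.size),
                                        "breaks": [float(b) for b in breaks],
                                        "usable": present.size >= 2})


def optimal_discretize(y: Sequence[float], x: Sequence[float],
                       methods: Iterable[str] = DISCRETIZE_METHODS,
                       k_range: Iterable[int] = range(3, 9),
                       source: str = "X") -> tuple[StrataAssignment, float]:
    """Pick the (method, k) stratification of x maximizing q for y.

    Ties are broken toward smaller k, then method order as given.
    """
    y = np.asarray(y, dtype=float)
    best: tuple[float, int, int, StrataAssignment] | None = None
    methods = list(methods)
    for k in sorted(set(k_range)):
        for mi, method in enumerate(methods):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    s = discretize(x, method=method, k=k, source=source)
                except DetectorError:
                    continue
            if s.L < 2:
                continue
            try:
                q = factor_q(y, s, p_method="none").q
            except DetectorError:
                continue
            key = (-q, k, mi)
            if best is None or key < (-best[0], best[1], best[2]):
                best = (q, k, mi, s)
    if best is None:
        raise DetectorError(f"no usable discretization for covariate {source!r}")
    return best[3], best[0]


# ---------------------------------------------------------------------------
# Factor detector


def _group_sums(y: np.ndarray, labels: np.ndarray):
    strata = np.unique(labels)
    Nh = np.array([np.sum(labels == h) for h in strata])
    mean_h = np.array([y[labels == h].mean() for h in strata])
    ssw_h = np.array([np.sum((y[labels == h] - m) ** 2)
                      for h, m in zip(strata, mean_h)])
    return strata, Nh, mean_h, ssw_h


def factor_q(y: Sequence[float], strata: StrataAssignment,
             p_method: str = "ncf", n_perm: int = 999,
             seed: int | None = None) -> FactorResult:
    """q = 1 - SSW/SST for one stratification, with optional significance.

    ``p_method``: ``"ncf"`` for the noncentral-F transform, ``"perm"`` for a
    seeded permutation test over shuffled labels, ``"none"`` to skip.
    """
    y = np.asarray(y, dtype=float)
    labels = strata.labels
    if y.shape != labels.shape:
        raise DetectorError("response and strata must have equal length")
    N = y.size
    L = strata.L
    if L < 2:
        raise DetectorError(f"factor {strata.source!r}: need >= 2 strata")
    if N < L:
        raise DetectorError("fewer samples than strata")
    SST = float(np.sum((y - y.mean()) ** 2))
    if SST == 0:
        raise DetectorError("constant response: q undefined (SST = 0)")
    _, Nh, mean_h, ssw_h = _group_sums(y, labels)
    SSW = float(ssw_h.sum())
    q = 1.0 - SSW / SST

    p = float("nan")
    if p_method == "ncf":
        p = _ncf_pvalue(q, N, L, Nh, mean_h, SST)
    elif p_method == "perm":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            _, _, _, ssw_p = _group_sums(y, perm)
            if 1.0 - ssw_p.sum() / SST >= q:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
    elif p_method != "none":
        raise DetectorError(f"unknown p_method {p_method!r}")
    return FactorResult(q=q, SSW=SSW, SST=SST, N=N, Nh=Nh, mean_h=mean_h,
                        sigma2=SST / N, sigma2_h=ssw_h / Nh, p_value=p,
                        p_method=p_method, source=strata.source)


def _ncf_pvalue(q: float, N: int, L: int, Nh: np.ndarray,
                mean_h: np.ndarray, SST: float) -> float:
    """Noncentral-F significance of q (standard geodetector test)."""
    if q >= 1.0:
        return 0.0
    F = (N - L) / (L - 1) * q / (1.0 - q)
    sigma2 = SST / N
    lam = (np.sum(mean_h ** 2)
           - (np.sum(np.sqrt(Nh) * mean_h)) ** 2 / N) / sigma2
    lam = max(float(lam), 0.0)
    return float(stats.ncf.sf(F, L - 1, N - L, lam))


# ---------------------------------------------------------------------------
# Interaction detector


def _categorize_interaction(q1: float, q2: float, q12: float,
                            tol: float = 1e-10) -> str:
    lo, hi = min(q1, q2), max(q1, q2)
    if abs(q12 - (q1 + q2)) <= tol:
        return "independent"
    if q12 < lo:
        return "nonlinear weaken"
    if q12 < hi:
        return "single-factor nonlinear weaken"
    if q12 > q1 + q2:
        return "nonlinear enhancement"
    return "two-factor enhancement"


def interaction_detect(y: Sequence[float], s1: StrataAssignment,
                       s2: StrataAssignment) -> InteractionResult:
    """q of the two-factor cross-classification versus the individual q's.

    The intersection strata are the nonempty (h1, h2) label pairs.  The
    category follows the canonical five-way scheme: weaken below min,
    single-factor weaken between min and max, enhancement at or above max,
    with "independent" (q12 = q1 + q2) and "nonlinear enhancement"
    (q12 > q1 + q2) distinguished above it.
    """
    y = np.asarray(y, dtype=float)
    q1 = factor_q(y, s1, p_method="none").q
    q2 = factor_q(y, s2, p_method="none").q
    pair = s1.labels.astype(np.int64) * (s2.labels.max() + 1) + s2.labels
    cells = np.unique(pair)
    if cells.size < 2:
        raise DetectorError("interaction: cross-classification has < 2 cells")
    s12 = StrataAssignment(np.searchsorted(cells, pair) + 1,
                           source=f"{s1.source}∩{s2.source}")
    q12 = factor_q(y, s12, p_method="none").q
    return InteractionResult(q1=q1, q2=q2, q12=q12,
                             category=_categorize_interaction(q1, q2, q12),
                             n_cells=int(cells.size))


# ---------------------------------------------------------------------------
# Ecological detector


def ecological_detect(y1: Sequence[float], s1: StrataAssignment,
                      s2: StrataAssignment,
                      y2: Sequence[float] | None = None,
                      alpha: float = 0.05) -> EcoResult:
    """F-ratio of two factors' within-strata sums of squares.

    F = N_X1 (N_X2 - 1) SSW_X1 / [N_X2 (N_X1 - 1) SSW_X2]; the difference is
    significant (one-sided) when F exceeds the F(alpha; N_X1-1, N_X2-1)
    critical value.  ``y2`` defaults to ``y1`` (both factors stratifying the
    same response sample, the usual case).
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = y1 if y2 is None else np.asarray(y2, dtype=float)
    r1 = factor_q(y1, s1, p_method="none")
    r2 = factor_q(y2, s2, p_method="none")
    N1, N2 = r1.N, r2.N
    if r2.SSW == 0:
        return EcoResult(F=float("inf"), N_X1=N1, N_X2=N2, SSW_X1=r1.SSW,
                         SSW_X2=0.0, L1=len(r1.Nh), L2=len(r2.Nh),
                         significant=True, alpha=alpha, degenerate=True)
    F = (N1 * (N2 - 1) * r1.SSW) / (N2 * (N1 - 1) * r2.SSW)
    crit = stats.f.ppf(1 - alpha, N1 - 1, N2 - 1)
    return EcoResult(F=float(F), N_X1=N1, N_X2=N2, SSW_X1=r1.SSW,
                     SSW_X2=r2.SSW, L1=len(r1.Nh), L2=len(r2.Nh),
                     significant=bool(F > crit), alpha=alpha)


# ---------------------------------------------------------------------------
# Risk detector


def risk_detect(y: Sequence[float], strata: StrataAssignment,
                alpha: float = 0.05) -> RiskResult:
    """Stratum means with pairwise Welch t-tests on mean differences.

    t = (mean_1 - mean_2)/sqrt(var_1/n_1 + var_2/n_2) with sample variances
    (ddof=1) and Welch–Satterthwaite degrees of freedom; two-sided test at
    the given alpha.  Strata with fewer than 2 samples keep their mean but
    are excluded from the pairwise tests (t = NaN).
    """
    y = np.asarray(y, dtype=float)
    labels = strata.labels
    L = strata.L
    mean_h = np.empty(L)
    var_h = np.empty(L)
    n_h = np.empty(L, dtype=int)
    for h in range(1, L + 1):
        yh = y[labels == h]
        n_h[h - 1] = yh.size
        mean_h[h - 1] = yh.mean()
        var_h[h - 1] = yh.var(ddof=1) if yh.size > 1 else float("nan")
    t_mat = np.full((L, L), np.nan)
    df_mat = np.full((L, L), np.nan)
    sig = np.zeros((L, L), dtype=bool)
    for a, b in itertools.combinations(range(L), 2):
        if n_h[a] < 2 or n_h[b] < 2:
            continue
        se2a, se2b = var_h[a] / n_h[a], var_h[b] / n_h[b]
        denom = se2a + se2b
        if denom == 0:
            diff = mean_h[a] - mean_h[b]
            t = 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
            df = n_h[a] + n_h[b] - 2.0
        else:
            t = (mean_h[a] - mean_h[b]) / np.sqrt(denom)
            df = denom ** 2 / (se2a ** 2 / (n_h[a] - 1)
                               + se2b ** 2 / (n_h[b] - 1))
        t_mat[a, b], t_mat[b, a] = t, -t
        df_mat[a, b] = df_mat[b, a] = df
        sig[a, b] = sig[b, a] = bool(
            2 * stats.t.sf(abs(t), df) < alpha) if denom > 0 else False
    return RiskResult(mean_h=mean_h, var_h=var_h, n_h=n_h, t_matrix=t_mat,
                      df_matrix=df_mat, sig_matrix=sig,
                      best_stratum=int(np.argmax(mean_h)) + 1, alpha=alpha)


# ---------------------------------------------------------------------------
# Whole-table report


def detector_report(table: pd.DataFrame, response: str,
                    factor_types: dict[str, str] | None = None,
                    k_range: Iterable[int] = range(3, 9),
                    methods: Iterable[str] = DISCRETIZE_METHODS,
                    p_method: str = "ncf", n_perm: int = 999,
                    seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Run all four detectors on a sample table.

    Continuous covariates are optimally discretized; categorical ones are
    used as-is.  Returns factor, interaction, ecological and per-factor risk
    tables keyed by name.
    """
    factor_types = factor_types or {}
    y = table[response].to_numpy(dtype=float)
    covars = [c for c in table.columns
              if c not in (response, "point_id", "x", "y", "valid")]
    assignments: dict[str, StrataAssignment] = {}
    for name in covars:
        x = table[name].to_numpy()
        kind = factor_types.get(name, "continuous")
        if kind == "categorical":
            codes = pd.factorize(x)[0] + 1
            assignments[name] = StrataAssignment(codes, source=name)
        else:
            s, _ = optimal_discretize(y, x.astype(float), methods=methods,
                                      k_range=k_range, source=name)
            assignments[name] = s

    factor_rows = []
    for name, s in assignments.items():
        r = factor_q(y, s, p_method=p_method, n_perm=n_perm, seed=seed)
        spec = s.break_spec or {}
        factor_rows.append({"factor": name, "q": r.q, "p_value": r.p_value,
                            "L": len(r.Nh), "method": spec.get("method", "categorical")})
    factor_df = pd.DataFrame(factor_rows).sort_values("q", ascending=False,
                                                      kind="mergesort")

    names = list(assignments)
    inter_rows, eco_rows = [], []
    for a, b in itertools.combinations(names, 2):
        ir = interaction_detect(y, assignments[a], assignments[b])
        inter_rows.append({"factor_1": a, "factor_2": b, "q1": ir.q1,
                           "q2": ir.q2, "q12": ir.q12, "category": ir.category})
        er = ecological_detect(y, assignments[a], s2=assignments[b])
        eco_rows.append({"factor_1": a, "factor_2": b, "F": er.F,
                         "significant": "Y" if er.significant else "N"})

    risk_rows = []
    for name, s in assignments.items():
        rr = risk_detect(y, s)
        for h in range(len(rr.mean_h)):
            risk_rows.append({"factor": name, "stratum": h + 1,
                              "n": int(rr.n_h[h]), "mean": rr.mean_h[h],
                              "is_best": (h + 1) == rr.best_stratum})
    return {
        "factor": factor_df.reset_index(drop=True),
        "interaction": pd.DataFrame(inter_rows),
        "ecological": pd.DataFrame(eco_rows),
        "risk": pd.DataFrame(risk_rows),
    }
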