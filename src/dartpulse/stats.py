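"""Inference layer for the cross-reactivity and shortening analyses.

The centrepiece is the Steel many-one rank test — the nonparametric
analogue of Dunnett's test, comparing several treatments against a shared
control — implemented from scratch with tie-corrected rank-sum Z statistics
and family-wise adjusted p-values via the equicorrelated multivariate-normal
bound (or joint permutation of group labels).  The supporting tests are the
paired Wilcoxon signed-rank Z, tie-corrected Kruskal-Wallis, a 2x2
chi-square on responder counts, a split-plot (mixed) two-way ANOVA with
Fisher-LSD simple effects of the repeated factor, log-link GLMs compared by
AICc, and a one-way ANOVA.  Standard machinery (Kruskal-Wallis, chi-square,
GLM fitting) delegates to scipy/statsmodels; everything with a bespoke
contract is implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats as sps

__all__ = [
    "SteelComparison",
    "SteelResult",
    "steel_many_one",
    "wilcoxon_paired",
    "kruskal_wallis",
    "chi_square_responders",
    "MixedAnovaResult",
    "mixed_anova",
    "GlmFit",
    "glm_fit",
    "compare_glm_aicc",
    "one_way_anova",
]


# ---------------------------------------------------------------------------
# Steel many-one rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteelComparison:
    """One treatment-vs-control comparison within a Steel family."""

    name: str
    n: int
    rank_sum: float
    z: float
    p_adj: float


@dataclass(frozen=True)
class SteelResult:
    """Family of many-one comparisons against a shared control.

    ``z`` is negative when the treatment sample sits stochastically below
    the control.  ``p_adj`` is family-wise adjusted over the k comparisons.
    """

    comparisons: list[SteelComparison]
    k: int
    rho: float
    mode: str
    n_control: int

    def __getitem__(self, name: str) -> SteelComparison:
        for c in self.comparisons:
            if c.name == name:
                return c
        raise KeyError(name)


_HERME_NODES, _HERME_WEIGHTS = hermegauss(80)


def _equicorr_max_abs_cdf(z: np.ndarray, k: int, rho: float) -> np.ndarray:
    """P(max_i |Z_i| <= z) for k equicorrelated standard normals.

    Uses the one-factor representation Z_i = sqrt(rho) U + sqrt(1-rho) e_i
    and Gauss-Hermite quadrature over U.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if k == 1:
        return sps.norm.cdf(z) - sps.norm.cdf(-z)
    rho = min(max(rho, 0.0), 1.0 - 1e-9)
    s, t = np.sqrt(rho), np.sqrt(1.0 - rho)
    u = _HERME_NODES[None, :]
    hi = sps.norm.cdf((z[:, None] - s * u) / t)
    lo = sps.norm.cdf((-z[:, None] - s * u) / t)
    inner = np.clip(hi - lo, 0.0, 1.0) ** k
    return inner @ _HERME_WEIGHTS / np.sqrt(2.0 * np.pi)


def _ranksum_z(control: np.ndarray, treatment: np.ndarray, continuity: bool) -> tuple[float, float]:
    """Tie-corrected standardized rank sum of the treatment sample."""
    pooled = np.concatenate([control, treatment])
    n0, nt = len(control), len(treatment)
    N = n0 + nt
    ranks = sps.rankdata(pooled)
    R = float(ranks[n0:].sum())
    E = nt * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n0 * nt * (N + 1) / 12.0 - n0 * nt * tie_term / (12.0 * N * (N - 1))
    if var <= 0:
        warnings.warn("all pooled values identical: Z undefined, reported as 0", stacklevel=3)
        return R, 0.0
    diff = R - E
    if continuity:
        diff = np.sign(diff) * max(abs(diff) - 0.5, 0.0)
    return R, float(diff / np.sqrt(var))


def steel_many_one(
    control,
    treatments: dict,
    alternative: str = "two-sided",
    mode: str = "normal",
    adjustment: str = "mvn",
    n_perm: int = 5000,
    seed: int | None = None,
    continuity: bool = True,
) -> SteelResult:
    """Steel's many-one rank test of k treatments against a shared control.

    For each treatment the pooled (control, treatment) sample is midranked;
    the statistic is the treatment rank sum, standardized with tie-corrected
    variance.  Family-wise adjusted two-sided p-values come either from the
    equicorrelated multivariate-normal bound over the k comparisons
    (``mode='normal'``; correlation implied by the shared control,
    ``rho_jl = sqrt(n_j n_l / ((n_j+n0)(n_l+n0)))``, a common rho taken as
    the mean off-diagonal; ``adjustment='sidak'`` gives the conservative
    fallback) or from joint permutation of the group labels using the
    max-|Z| null distribution (``mode='permutation'``).

    A continuity correction of 1/2 is applied to the rank sum by default.
    """
    if alternative != "two-sided":
        raise NotImplementedError("only two-sided comparisons are provided")
    if not treatments:
        raise ValueError("empty treatment set")
    control = np.asarray(control, dtype=float)
    samples = {k: np.asarray(v, dtype=float) for k, v in treatments.items()}
    if len(control) < 2 or any(len(v) < 2 for v in samples.values()):
        raise ValueError("control and every treatment need n >= 2")

    names = list(samples)
    k = len(names)
    n0 = len(control)
    zs, rsums = {}, {}
    for name in names:
        rsums[name], zs[name] = _ranksum_z(control, samples[name], continuity)

    ns = np.array([len(samples[name]) for name in names], dtype=float)
    if k > 1:
        frac = ns / (ns + n0)
        rho_mat = np.sqrt(np.outer(frac, frac))
        rho = float(rho_mat[~np.eye(k, dtype=bool)].mean())
    else:
        rho = 0.0

    comparisons = []
    if mode == "normal":
        for name in names:
            z = zs[name]
            if adjustment == "mvn":
                p = float(1.0 - _equicorr_max_abs_cdf(abs(z), k, rho)[0])
            elif adjustment == "sidak":
                p1 = 2.0 * sps.norm.sf(abs(z))
                p = float(1.0 - (1.0 - min(p1, 1.0)) ** k)
            else:
                raise ValueError(f"unknown adjustment {adjustment!r}")
            comparisons.append(SteelComparison(name, len(samples[name]), rsums[name], zs[name], min(p, 1.0)))
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([control] + [samples[n] for n in names])
        sizes = [n0] + [len(samples[n]) for n in names]
        cuts = np.cumsum(sizes)[:-1]
        max_null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, cuts)
            zb = [
                _ranksum_z(parts[0], parts[j + 1], continuity)[1]
                for j in range(k)
            ]
            max_null[b] = np.max(np.abs(zb))
        for name in names:
            z = zs[name]
            p = (1 + int(np.sum(max_null >= abs(z) - 1e-12))) / (n_perm + 1)
            comparisons.append(SteelComparison(name, len(samples[name]), rsums[name], z, p))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return SteelResult(comparisons=comparisons, k=k, rho=rho, mode=mode, n_control=n0)


# ---------------------------------------------------------------------------
# paired and one-way nonparametrics
# ---------------------------------------------------------------------------

def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, normal approximation.

    Zero differences are dropped; ties among |differences| are midranked
    with the variance reduced accordingly.  Returns the signed Z (negative
    when x tends to be below y) and the two-sided p.  All-zero differences
    give (0, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        return 0.0, 1.0
    z = (w_pos - mu) / np.sqrt(var)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 d.f.)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def chi_square_responders(species_counts: tuple[int, int], control_counts: tuple[int, int]):
    """Pearson chi-square (1 d.f., no continuity correction) on a 2x2 table.

    ``species_counts`` and ``control_counts`` are (responded, total) pairs.
    A zero margin leaves the statistic undefined (NaN) with a warning.
    """
    r1, n1 = species_counts
    r2, n2 = control_counts
    table = np.array([[r1, n1 - r1], [r2, n2 - r2]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must satisfy responded <= total")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table: chi-square undefined", stacklevel=2)
        return float("nan"), 1, float("nan")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# split-plot (mixed) ANOVA
# ---------------------------------------------------------------------------

@dataclass
class MixedAnovaResult:
    """Split-plot ANOVA with one repeated factor at two levels.

    ``anova_table`` rows: Species (between, tested against Subject-within-
    Species), Time and Time x Species (within, tested against the
    subject-by-time error).  ``simple_effects`` holds per-species paired
    contrasts of Time using the pooled within-subject error (Fisher's LSD:
    deliberately unadjusted across species).
    """

    anova_table: pd.DataFrame
    simple_effects: pd.DataFrame
    n_subjects: int
    dropped_subjects: list = field(default_factory=list)

    def f(self, effect: str) -> float:
        return float(self.anova_table.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.anova_table.loc[effect, "p"])


def _f_p(ss_num: float, df_num: int, ms_err: float, df_err: int) -> tuple[float, float]:
    if ss_num <= 0:
        return 0.0, 1.0
    if ms_err <= 0:
        return float("inf"), 0.0
    F = (ss_num / df_num) / ms_err
    return float(F), float(sps.f.sf(F, df_num, df_err))


def mixed_anova(
    data: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    within: str = "time",
    between: str = "species",
) -> MixedAnovaResult:
    """Mixed (split-plot) ANOVA: one between factor, one 2-level repeated factor.

    Every subject must contribute both levels of ``within``; subjects
    missing a level are dropped with a warning.  Group sizes may differ
    between levels of ``between``; the Time and interaction tests use
    Type-III-style (unweighted) marginal means so unequal group sizes do not
    leak the between-factor into the Time test.

    With the repeated factor at two levels the split-plot strata reduce to
    an analysis of per-subject sums and differences, which is how the sums
    of squares are computed here.
    """
    df = data[[subject, between, within, value]].dropna()
    levels = np.sort(df[within].unique())
    if len(levels) != 2:
        raise ValueError("the repeated factor must have exactly two levels")
    wide = df.pivot_table(index=[subject, between], columns=within, values=value)
    complete = wide.dropna()
    dropped = [idx[0] for idx in wide.index.difference(complete.index)]
    if dropped:
        warnings.warn(f"dropping subjects missing a time point: {dropped}", stacklevel=2)
    if complete.empty:
        raise ValueError("no complete subjects")
    y0 = complete[levels[0]].to_numpy()
    y1 = complete[levels[1]].to_numpy()
    groups = complete.index.get_level_values(1).to_numpy()
    group_names = pd.unique(groups)
    G = len(group_names)
    N = len(complete)
    if N <= G:
        raise ValueError("need more subjects than between-factor levels")

    m = (y0 + y1) / 2.0  # subject means -> between stratum
    d = y1 - y0          # subject differences -> within stratum

    n_g = np.array([(groups == g).sum() for g in group_names], dtype=float)
    mbar_g = np.array([m[groups == g].mean() for g in group_names])
    dbar_g = np.array([d[groups == g].mean() for g in group_names])

    # between stratum (scale of subject totals: factor 2 on the means scale)
    grand_m = m.mean()
    ss_species = 2.0 * float(np.sum(n_g * (mbar_g - grand_m) ** 2))
    ss_subj = 2.0 * float(sum(np.sum((m[groups == g] - mg) ** 2) for g, mg in zip(group_names, mbar_g)))

    # within stratum (differences carry twice the within-cell variance)
    dbar_w = d.mean()
    dbar_u = dbar_g.mean()  # unweighted marginal mean (Type-III-style Time test)
    ss_time = (dbar_u**2) * G**2 / (2.0 * float(np.sum(1.0 / n_g)))
    ss_int = 0.5 * float(np.sum(n_g * (dbar_g - dbar_w) ** 2))
    ss_err_w = 0.5 * float(sum(np.sum((d[groups == g] - dg) ** 2) for g, dg in zip(group_names, dbar_g)))

    ms_subj = ss_subj / (N - G)
    ms_err_w = ss_err_w / (N - G)
    f_sp, p_sp = _f_p(ss_species, G - 1, ms_subj, N - G)
    f_t, p_t = _f_p(ss_time, 1, ms_err_w, N - G)
    f_i, p_i = _f_p(ss_int, G - 1, ms_err_w, N - G)

    table = pd.DataFrame(
        {
            "SS": [ss_species, ss_subj, ss_time, ss_int, ss_err_w],
            "df": [G - 1, N - G, 1, G - 1, N - G],
            "F": [f_sp, np.nan, f_t, f_i, np.nan],
            "p": [p_sp, np.nan, p_t, p_i, np.nan],
        },
        index=["Species", "Subject(Species)", "Time", "Time x Species", "Error(within)"],
    )

    # Fisher LSD simple effects of Time within each species: paired contrast
    # against the pooled within-subject error (Var(dbar_g) = 2 MS_err / n_g).
    mse_d = 2.0 * ms_err_w  # = variance of a subject difference
    se = np.sqrt(mse_d / n_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, dbar_g / se, 0.0)
    pvals = 2.0 * sps.t.sf(np.abs(tvals), N - G)
    simple = pd.DataFrame(
        {
            "species": group_names,
            "n": n_g.astype(int),
            "mean_diff": dbar_g,
            "t": tvals,
            "p": pvals,
        }
    )
    return MixedAnovaResult(anova_table=table, simple_effects=simple, n_subjects=N, dropped_subjects=dropped)


# ---------------------------------------------------------------------------
# GLMs with AICc
# ---------------------------------------------------------------------------

@dataclass
class GlmFit:
    """A fitted log-link GLM with its small-sample Akaike score."""

    formula: str
    family: str
    params: pd.Series
    deviance: float
    aic: float
    aicc: float
    n: int
    k: int
    converged: bool
    result: object = field(repr=False, default=None)


def glm_fit(data: pd.DataFrame, response: str, factors: list[str], family: str = "poisson",
            eps: float = 1e-3, maxiter: int = 200) -> GlmFit:
    """Fit ``response ~ factors`` with a log link.

    ``family='poisson'`` fits Poisson counts; ``family='gaussian-log'`` fits
    a normal response through a log link (for contraction intensities),
    initialized from an OLS fit to ``log(max(response, eps))``.  AICc is
    AIC + 2k(k+1)/(n-k-1) with k the number of estimated parameters
    (including the Gaussian scale).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if not factors:
        raise ValueError("need at least one factor")
    terms = " + ".join(f"C({f})" for f in factors)
    formula = f"{response} ~ {terms}"
    y = data[response].to_numpy(dtype=float)
    if family == "poisson":
        if np.any(y < 0):
            raise ValueError("Poisson response must be non-negative")
        model = smf.glm(formula, data=data, family=sm.families.Poisson())
        start = None
        extra_k = 0
    elif family == "gaussian-log":
        model = smf.glm(formula, data=data, family=sm.families.Gaussian(sm.families.links.Log()))
        zlog = np.log(np.maximum(y, eps))
        start, *_ = np.linalg.lstsq(model.exog, zlog, rcond=None)
        extra_k = 1  # scale parameter
    else:
        raise ValueError(f"unknown family {family!r}")

    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise ValueError("design matrix not full rank after reference coding")

    res = model.fit(start_params=start, maxiter=maxiter)
    if not res.converged:
        raise RuntimeError(f"GLM did not converge after {maxiter} iterations: {formula}")
    n = int(res.nobs)
    k = int(res.df_model) + 1 + extra_k
    aic = float(res.aic) + 2 * extra_k  # count the scale parameter for gaussian
    if n - k - 1 <= 0:
        raise ValueError("too few observations for AICc")
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    return GlmFit(
        formula=formula,
        family=family,
        params=res.params,
        deviance=float(res.deviance),
        aic=aic,
        aicc=aicc,
        n=n,
        k=k,
        converged=bool(res.converged),
        result=res,
    )


def compare_glm_aicc(data: pd.DataFrame, response: str, factor: str, extra_factor: str,
                     family: str = "poisson") -> dict:
    """AICc comparison of models with and without ``extra_factor``.

    Mirrors the order-effect check: does adding the previously tested
    species improve ``response ~ species``?  Lower AICc wins.
    """
    without = glm_fit(data, response, [factor], family=family)
    with_ = glm_fit(data, response, [factor, extra_factor], family=family)
    return {
        "aicc_without": without.aicc,
        "aicc_with": with_.aicc,
        "preferred": "without" if without.aicc <= with_.aicc else "with",
        "fit_without": without,
        "fit_with": with_,
    }


def one_way_anova(groups) -> tuple[float, tuple[int, int], float]:
    """One-way fixed-effects ANOVA: F, (df_between, df_within), p."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    N = sum(len(g) for g in groups)
    kk = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ssw = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df = (kk - 1, N - kk)
    if ssb == 0:
        return 0.0, df, 1.0
    if ssw == 0:
        return float("inf"), df, 0.0
    F = (ssb / df[0]) / (ssw / df[1])
    return float(F), df, float(sps.f.sf(F, *df))
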