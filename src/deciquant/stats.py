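"""Group statistics for subject-level and band-level measurements.

The layer mirrors common practice for repeated tissue measures:

* ROUT-style outlier removal — a robust location/scale fit (median and
  MAD) followed by FDR control on t-like residual statistics at rate Q.
  This follows the published robust-regression-plus-FDR idea; it is an
  approximation built on the constant model, not a bit-level clone of any
  proprietary implementation.
* Kruskal-Wallis omnibus test with Dunn's pairwise z tests (Bonferroni
  adjusted by default), with an exact label-permutation p-value available
  for small samples.
* One-way ANOVA with Tukey's HSD for trophoblast amount/density.
* A site-adjusted linear model for maternal-tissue and overall intensities
  (group contrasts against normal pregnancies, estimated marginal means).
* A linear mixed model with subject random intercept for the
  trophoblast-containing density bands (low, high), fitted by REML;
  group × band estimated means ± SEM and within-band group contrasts.

The project-wide significance level is 0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ModelResult",
    "rout_outliers",
    "kruskal_dunn",
    "anova_tukey",
    "fit_site_adjusted_linear",
    "fit_density_band_mixed",
    "benjamini_hochberg",
]

ALPHA = 0.05


@dataclass
class ModelResult:
    """Fitted-model summary shared by the linear and mixed models.

    ``fixed_effects`` maps coefficient names to (estimate, SE);
    ``estimated_means`` has one row per group (× band for the mixed model)
    with columns ``mean`` and ``sem``; ``pairwise`` lists contrasts with
    raw and adjusted p-values.
    """

    fixed_effects: dict[str, tuple[float, float]]
    estimated_means: pd.DataFrame
    pairwise: pd.DataFrame
    n_used: int
    extra: dict = field(default_factory=dict)


def benjamini_hochberg(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Boolean rejection mask of the step-up FDR procedure at rate q."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    thresh = q * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresh
    reject = np.zeros(n, dtype=bool)
    if passed.any():
        k = np.max(np.flatnonzero(passed))
        reject[order[: k + 1]] = True
    return reject


def rout_outliers(values, Q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Robust outlier detection on a single sample (constant model).

    Location and scale are the median and the normal-consistent MAD; each
    point's t-like statistic ``(x − median) / MAD`` is converted to a
    two-sided p-value (t distribution, n − 1 df) and flagged by
    Benjamini-Hochberg FDR control at rate ``Q``.  Returns
    (kept values, flagged indices).  A sample with zero spread flags
    nothing.  Requires n ≥ 5 and Q in (0, 0.1].
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size < 5:
        raise ValueError("need at least 5 values for a robust scale estimate")
    if not (0.0 < Q <= 0.1):
        raise ValueError("Q must lie in (0, 0.1]")
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    if mad == 0:
        # fall back to mean absolute deviation; if still zero, no spread
        mad = np.mean(np.abs(x - med)) * 1.2533
    if mad == 0:
        return x.copy(), np.empty(0, dtype=int)
    t = (x - med) / mad
    p = 2.0 * sps.t.sf(np.abs(t), df=x.size - 1)
    reject = benjamini_hochberg(p, Q)
    flagged = np.flatnonzero(reject)
    kept = x[~reject]
    return kept, flagged


def _tie_correction_term(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def _kruskal_h(ranks: np.ndarray, sizes: list[int], tie_term: float) -> float:
    n = ranks.size
    h = 0.0
    start = 0
    for m in sizes:
        r = ranks[start : start + m]
        h += r.sum() ** 2 / m
        start += m
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    correction = 1.0 - tie_term / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def _exact_kruskal_p(values: list[np.ndarray]) -> float:
    """Exhaustive label-permutation p-value of the Kruskal-Wallis H."""
    sizes = [len(v) for v in values]
    pooled = np.concatenate(values)
    ranks = sps.rankdata(pooled)
    tie_term = _tie_correction_term(pooled)
    h_obs = _kruskal_h(ranks, sizes, tie_term)

    n = pooled.size
    count = total = 0
    indices = list(range(n))

    def assignments(remaining: list[int], sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        m = sizes_left[0]
        for combo in itertools.combinations(remaining, m):
            # groups are labeled, so all ordered assignments are enumerated
            rest = [i for i in remaining if i not in combo]
            for tail in assignments(rest, sizes_left[1:]):
                yield [list(combo)] + tail

    for groups_idx in assignments(indices, sizes):
        perm_ranks = np.concatenate([ranks[idx] for idx in groups_idx])
        h = _kruskal_h(perm_ranks, sizes, tie_term)
        total += 1
        if h >= h_obs - 1e-9:
            count += 1
    return count / total


def kruskal_dunn(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    method: str = "auto",
    adjust: str = "bonferroni",
    exact_max_n: int = 9,
):
    """Kruskal-Wallis omnibus test with Dunn's pairwise comparisons.

    ``method`` is ``"asymptotic"`` (chi-squared), ``"exact"`` (exhaustive
    label permutation), or ``"auto"`` (exact when total n ≤ ``exact_max_n``).
    Dunn z statistics use the tie-corrected rank variance; pairwise
    p-values are reported raw and Bonferroni-adjusted (``adjust="none"``
    disables the adjustment).

    Returns an object with ``h``, ``omnibus_p``, ``method``, and a
    ``pairwise`` DataFrame.
    """
    if isinstance(groups, dict):
        names = list(groups)
        values = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        values = [np.asarray(v, dtype=float) for v in groups]
        names = [f"group{i + 1}" for i in range(len(values))]
    if len(values) < 2:
        raise ValueError("need at least two groups")
    for name, v in zip(names, values):
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")

    pooled = np.concatenate(values)
    n = pooled.size
    sizes = [v.size for v in values]
    ranks = sps.rankdata(pooled)
    tie_term = _tie_correction_term(pooled)
    h = _kruskal_h(ranks, sizes, tie_term)

    if method == "auto":
        method = "exact" if n <= exact_max_n else "asymptotic"
    if method == "exact":
        omnibus_p = _exact_kruskal_p(values)
    elif method == "asymptotic":
        omnibus_p = float(sps.chi2.sf(h, df=len(values) - 1))
    else:
        raise ValueError(f"unknown method {method!r}")

    # Dunn pairwise z tests on mean ranks
    mean_ranks = []
    start = 0
    for m in sizes:
        mean_ranks.append(ranks[start : start + m].mean())
        start += m
    var_term = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    rows = []
    k = len(values)
    n_comp = k * (k - 1) // 2
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_comp) if adjust == "bonferroni" else p_raw
        rows.append(
            {
                "contrast": f"{names[i]} vs {names[j]}",
                "z": z,
                "p_raw": p_raw,
                "p_adj": p_adj,
            }
        )
    pairwise = pd.DataFrame(rows)

    @dataclass
    class KruskalDunnResult:
        h: float
        omnibus_p: float
        method: str
        pairwise: pd.DataFrame

    return KruskalDunnResult(h=float(h), omnibus_p=float(omnibus_p), method=method, pairwise=pairwise)


def anova_tukey(groups: dict[str, np.ndarray] | list[np.ndarray]):
    """One-way ANOVA with Tukey's HSD pairwise comparisons.

    Returns an object with ``f``, ``omnibus_p``, and a ``pairwise``
    DataFrame with studentized-range p-values.  An all-constant input (zero
    within-group variance everywhere) is rejected.
    """
    if isinstance(groups, dict):
        names = list(groups)
        values = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        values = [np.asarray(v, dtype=float) for v in groups]
        names = [f"group{i + 1}" for i in range(len(values))]
    if len(values) < 2:
        raise ValueError("need at least two groups")
    for name, v in zip(names, values):
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    if all(np.ptp(v) == 0 for v in values):
        raise ValueError("zero within-group variance in every group; F undefined")

    f, p = sps.f_oneway(*values)
    if not np.isfinite(f):  # identical groups with zero variance across groups
        f, p = 0.0, 1.0
    endog = np.concatenate(values)
    labels = np.concatenate([[name] * v.size for name, v in zip(names, values)])
    tukey = pairwise_tukeyhsd(endog, labels, alpha=ALPHA)
    frame = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    pairwise = pd.DataFrame(
        {
            "contrast": frame["group1"].astype(str) + " vs " + frame["group2"].astype(str),
            "estimate": frame["meandiff"].astype(float),
            "p_adj": frame["p-adj"].astype(float),
        }
    )

    @dataclass
    class AnovaTukeyResult:
        f: float
        omnibus_p: float
        pairwise: pd.DataFrame

    return AnovaTukeyResult(f=float(f), omnibus_p=float(p), pairwise=pairwise)


def _check_levels(series: pd.Series, what: str) -> list:
    if series.isna().any():
        raise ValueError(f"{what} has missing values")
    return sorted(series.unique())


def _emm_rows(result, design_rows: list[np.ndarray]):
    """Estimate and SE of averaged prediction rows L·β."""
    params = np.asarray(result.params)[: design_rows[0].size]
    cov = np.asarray(result.cov_params())[: design_rows[0].size, : design_rows[0].size]
    out = []
    for L in design_rows:
        est = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        out.append((est, se))
    return out


def fit_site_adjusted_linear(
    values,
    group,
    site,
    reference: str | None = None,
) -> ModelResult:
    """Linear model of a subject-level measurement with a site covariate.

    ``value ~ group + site``; group contrasts are taken against the
    reference group (default: first level alphabetically, "normal" when
    present).  Estimated marginal means average predictions over the site
    levels with equal weight.  A constant site is dropped from the model;
    a rank-deficient design raises an error naming the collinear columns.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float), "group": group, "site": site}
    ).dropna(subset=["value"])
    group_levels = _check_levels(df["group"], "group")
    site_levels = _check_levels(df["site"], "site")
    if reference is None:
        reference = "normal" if "normal" in group_levels else group_levels[0]

    use_site = len(site_levels) > 1
    formula = f"value ~ C(group, Treatment({reference!r}))"
    if use_site:
        formula += " + C(site)"
    model = smf.ols(formula, data=df)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        _, r = np.linalg.qr(model.exog)
        bad = [
            model.exog_names[i]
            for i in range(model.exog.shape[1])
            if abs(r[i, i]) < 1e-8
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    result = model.fit()

    fixed = {
        name: (float(result.params[name]), float(result.bse[name]))
        for name in result.params.index
    }

    # estimated marginal means: average the design row over site levels
    exog_names = result.model.exog_names
    design_rows = []
    for g in group_levels:
        rows = [
            _design_row(exog_names, g, s, reference)
            for s in (site_levels if use_site else site_levels[:1])
        ]
        design_rows.append(np.mean(rows, axis=0))
    means = _emm_rows(result, design_rows)
    emm = pd.DataFrame(
        {
            "group": group_levels,
            "mean": [m for m, _ in means],
            "sem": [s for _, s in means],
        }
    )

    rows = []
    for i, j in itertools.combinations(range(len(group_levels)), 2):
        L = design_rows[i] - design_rows[j]
        tt = result.t_test(L)
        rows.append(
            {
                "contrast": f"{group_levels[i]} vs {group_levels[j]}",
                "estimate": float(np.atleast_1d(tt.effect)[0]),
                "p_raw": float(np.atleast_1d(tt.pvalue)[0]),
            }
        )
    pairwise = pd.DataFrame(rows, columns=["contrast", "estimate", "p_raw"])
    pairwise["p_adj"] = np.minimum(1.0, pairwise["p_raw"] * max(len(pairwise), 1))

    return ModelResult(
        fixed_effects=fixed,
        estimated_means=emm,
        pairwise=pairwise,
        n_used=int(result.nobs),
        extra={"reference": reference, "site_in_model": use_site},
    )


def _design_row(exog_names: list[str], g, s, reference) -> np.ndarray:
    """Design row for one (group, site) cell under treatment coding."""
    row = np.zeros(len(exog_names))
    for i, name in enumerate(exog_names):
        if name == "Intercept":
            row[i] = 1.0
        elif name.startswith("C(group"):
            level = name.split("[T.")[-1].rstrip("]")
            row[i] = 1.0 if str(g) == level else 0.0
        elif name.startswith("C(site"):
            level = name.split("[T.")[-1].rstrip("]")
            row[i] = 1.0 if str(s) == level else 0.0
    return row


def fit_density_band_mixed(
    data: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    site_col: str = "site",
    band_col: str = "band",
    subject_col: str = "subject",
    bands: tuple[str, ...] = ("low", "high"),
    reference: str | None = None,
) -> ModelResult:
    """Linear mixed model for band-level intensity means.

    Fixed effects: group, band, their interaction, and recruitment site;
    a subject-specific random intercept accounts for within-subject
    correlation across bands.  Only trophoblast-containing bands (default
    low, high) enter the model.  Fitted by REML; fixed-effect significance
    by Wald z tests.  When the random intercept is inestimable (no subject
    with two bands, or a degenerate fit) the function falls back to the
    corresponding fixed-effects-only OLS with a warning.

    Returns group × band estimated means ± SEM and within-band pairwise
    group contrasts (raw and Bonferroni-adjusted p-values).
    """
    df = data.rename(
        columns={
            value_col: "value",
            group_col: "group",
            site_col: "site",
            band_col: "band",
            subject_col: "subject",
        }
    )[["value", "group", "site", "band", "subject"]].copy()
    df = df[df["band"].isin(bands)].dropna(subset=["value"])
    if df.empty:
        raise ValueError("no observations in the requested bands")
    group_levels = _check_levels(df["group"], "group")
    site_levels = _check_levels(df["site"], "site")
    band_levels = [b for b in bands if b in set(df["band"])]
    if reference is None:
        reference = "normal" if "normal" in group_levels else group_levels[0]
    band_ref = band_levels[0]

    use_site = len(site_levels) > 1
    use_band = len(band_levels) > 1
    terms = [f"C(group, Treatment({reference!r}))"]
    if use_band:
        terms.append(f"C(band, Treatment({band_ref!r}))")
        terms.append(f"C(group, Treatment({reference!r})):C(band, Treatment({band_ref!r}))")
    if use_site:
        terms.append("C(site)")
    formula = "value ~ " + " + ".join(terms)

    multi_band = df.groupby("subject")["band"].nunique().max() > 1
    used_mixed = False
    result = None
    if multi_band:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data=df, groups=df["subject"])
                result = model.fit(reml=True)
            if np.isfinite(result.cov_re.iloc[0, 0]):
                used_mixed = True
        except Exception:
            result = None
    if not used_mixed:
        warnings.warn(
            "random intercept inestimable; falling back to fixed-effects-only fit",
            stacklevel=2,
        )
        result = smf.ols(formula, data=df).fit()

    exog_names = (
        result.model.exog_names if not used_mixed else list(result.fe_params.index)
    )
    params = (
        np.asarray(result.params)[: len(exog_names)]
        if not used_mixed
        else np.asarray(result.fe_params)
    )
    cov = np.asarray(result.cov_params())[: len(exog_names), : len(exog_names)]

    fixed = {
        name: (float(params[i]), float(np.sqrt(cov[i, i])))
        for i, name in enumerate(exog_names)
    }

    def cell_row(g, b, s) -> np.ndarray:
        row = np.zeros(len(exog_names))
        for i, name in enumerate(exog_names):
            if name == "Intercept":
                row[i] = 1.0
            elif ":" in name and "C(group" in name and "C(band" in name:
                gpart, bpart = name.split(":")
                glevel = gpart.split("[T.")[-1].rstrip("]")
                blevel = bpart.split("[T.")[-1].rstrip("]")
                row[i] = 1.0 if (str(g) == glevel and str(b) == blevel) else 0.0
            elif name.startswith("C(group"):
                level = name.split("[T.")[-1].rstrip("]")
                row[i] = 1.0 if str(g) == level else 0.0
            elif name.startswith("C(band"):
                level = name.split("[T.")[-1].rstrip("]")
                row[i] = 1.0 if str(b) == level else 0.0
            elif name.startswith("C(site"):
                level = name.split("[T.")[-1].rstrip("]")
                row[i] = 1.0 if str(s) == level else 0.0
        return row

    def emm_row(g, b) -> np.ndarray:
        rows = [cell_row(g, b, s) for s in (site_levels if use_site else site_levels[:1])]
        return np.mean(rows, axis=0)

    emm_records = []
    rows_by_cell = {}
    for g in group_levels:
        for b in band_levels:
            L = emm_row(g, b)
            rows_by_cell[(g, b)] = L
            est = float(L @ params)
            se = float(np.sqrt(L @ cov @ L))
            emm_records.append({"group": g, "band": b, "mean": est, "sem": se})
    emm = pd.DataFrame(emm_records)

    pair_records = []
    for b in band_levels:
        for i, j in itertools.combinations(range(len(group_levels)), 2):
            gi, gj = group_levels[i], group_levels[j]
            L = rows_by_cell[(gi, b)] - rows_by_cell[(gj, b)]
            est = float(L @ params)
            se = float(np.sqrt(L @ cov @ L))
            z = est / se if se > 0 else 0.0
            p_raw = 2.0 * sps.norm.sf(abs(z))
            pair_records.append(
                {
                    "band": b,
                    "contrast": f"{gi} vs {gj}",
                    "estimate": est,
                    "p_raw": p_raw,
                }
            )
    pairwise = pd.DataFrame(
        pair_records, columns=["band", "contrast", "estimate", "p_raw"]
    )
    n_per_band = len(pairwise) // max(len(band_levels), 1)
    pairwise["p_adj"] = np.minimum(1.0, pairwise["p_raw"] * max(n_per_band, 1))

    random_var = (
        float(result.cov_re.iloc[0, 0]) if used_mixed else 0.0
    )
    return ModelResult(
        fixed_effects=fixed,
        estimated_means=emm,
        pairwise=pairwise,
        n_used=int(len(df)),
        extra={
            "random_intercept_var": random_var,
            "used_mixed": used_mixed,
            "reference": reference,
            "bands": band_levels,
        },
    )
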