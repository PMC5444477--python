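"""Layer-by-position growth statistics.

The central quantity is the ratio of sample means between two time points,
computed on the log scale,

    ratio = exp(ln x̄ − ln ȳ)  (algebraically x̄ / ȳ),

with a t-based confidence interval built from the variances of the
log-transformed samples,

    interval = t_{level, n_x + n_y − 2} · sqrt(S²_ln(x)/n_x + S²_ln(y)/n_y)
    CI = exp(ln x̄ − ln ȳ ± interval).

Note the asymmetry implemented deliberately: the point estimate uses the
log of the mean while the interval uses the variance of the logs; this is
the intended estimator, not a geometric-mean ratio. Multiple comparisons
across cell layers are handled by the Bonferroni correction, expressed as
a corrected confidence level 1 − α/m. Pairwise differences between time
points use pooled-variance two-tailed Student's t-tests; position
dependence of growth is tested by the interaction term of a two-way
(time × position) ANOVA on the log-transformed response.

`LayerGrowthModel` / `LayerGrowthResults` organise these per
layer × position × metric for whole per-cell tables, in the usual
model-object style: build the model from the two tables, call ``fit()``,
inspect ``results.table`` or ``results.summary()``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

DEFAULT_METRICS = ("volume_um3", "len_long_um", "len_rad_um")


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class RatioResult:
    """Ratio of means x̄/ȳ with its log-scale t interval."""

    ratio: float
    interval_halfwidth: float  # log scale
    ci_low: float
    ci_high: float
    level: float
    df: int


@dataclass
class TestResult:
    statistic: float
    df: tuple
    pvalue: float
    significant: bool | None = None


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def bonferroni_level(alpha: float = 0.05, m: int = 7) -> float:
    """Bonferroni-corrected confidence level 1 − α/m.

    With α = 0.05 and m = 7 comparisons (one per analysed cell layer) this
    is 0.99286 ≈ 99.3%.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if int(m) != m or m < 1:
        raise ValueError("m must be a positive integer")
    return 1.0 - alpha / m


def bootstrap_ci(values, statistic=np.mean, n_iter: int = 1000,
                 level: float = 0.95, seed=None) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of a statistic.

    Resamples ``values`` with replacement ``n_iter`` times and returns the
    empirical (1−level)/2 and (1+level)/2 quantiles of the statistic.
    Deterministic for a fixed seed.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_iter, v.size))
    samples = v[idx]
    try:
        stats = np.asarray(statistic(samples, axis=1), dtype=float)
        if stats.shape != (n_iter,):
            raise TypeError
    except TypeError:
        stats = np.array([statistic(row) for row in samples], dtype=float)
    lo, hi = np.quantile(stats, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def _check_positive(x, name):
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError(f"{name} is empty")
    if np.any(x <= 0):
        raise ValueError(f"{name} contains nonpositive values; log-scale ratio undefined")
    return x


def ratio_of_means(x, y) -> float:
    """exp(ln x̄ − ln ȳ); identical to x̄/ȳ for positive data."""
    x = _check_positive(x, "x")
    y = _check_positive(y, "y")
    r = float(np.exp(np.log(x.mean()) - np.log(y.mean())))
    assert np.isclose(r, x.mean() / y.mean(), rtol=1e-12), "log identity violated"
    return r


def ratio_interval(x, y, level: float = 0.95) -> RatioResult:
    """Ratio of means with its t-based log-scale confidence interval.

    halfwidth = t_{level, n_x+n_y−2} · sqrt(S²_ln(x)/n_x + S²_ln(y)/n_y),
    CI = exp(ln x̄ − ln ȳ ± halfwidth). Both groups constant gives a
    degenerate (ratio, ratio) interval with a warning.
    """
    x = _check_positive(x, "x")
    y = _check_positive(y, "y")
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need n >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    df = x.size + y.size - 2
    s2x = np.var(np.log(x), ddof=1)
    s2y = np.var(np.log(y), ddof=1)
    log_ratio = np.log(x.mean()) - np.log(y.mean())
    ratio = float(np.exp(log_ratio))
    if s2x == 0 and s2y == 0:
        warnings.warn("zero variance in both groups: degenerate confidence interval")
        return RatioResult(ratio, 0.0, ratio, ratio, level, df)
    tcrit = sps.t.ppf(0.5 + level / 2.0, df)
    half = float(tcrit * np.sqrt(s2x / x.size + s2y / y.size))
    return RatioResult(
        ratio=ratio,
        interval_halfwidth=half,
        ci_low=float(np.exp(log_ratio - half)),
        ci_high=float(np.exp(log_ratio + half)),
        level=level,
        df=df,
    )


def t_test(x, y) -> TestResult:
    """Two-sample pooled-variance Student's t-test, two-tailed.

    df = n_x + n_y − 2. Zero pooled variance with equal means returns
    t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need n >= 2")
    df = x.size + y.size - 2
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.isclose(x.mean(), y.mean()):
            return TestResult(0.0, (df,), 1.0)
    with warnings.catch_warnings():
        # near-constant groups trip scipy's precision-loss warning; the
        # pooled statistic itself is well defined
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(float(t), (df,), float(p))


def anova_interaction(table: pd.DataFrame, response: str,
                      time_col: str = "time_hai", position_col: str = "position",
                      log_scale: bool = True) -> TestResult:
    """Interaction term of a two-way (time × position) ANOVA.

    Fits the full two-factor model with interaction on the (by default
    log-transformed) response and returns the interaction F statistic, its
    degrees of freedom, and p-value. Balanced designs use the classical
    closed-form decomposition (so noiseless additive data give interaction
    SS exactly 0 and F = 0); unbalanced input falls back to an OLS fit with
    Type II sums of squares, which coincides with the classical
    decomposition in the balanced case.

    Raises ``ValueError`` when a factor has fewer than two levels or a
    design cell is empty (the offending cell is named).
    """
    df = table[[time_col, position_col, response]].dropna().copy()
    times = sorted(df[time_col].unique())
    positions = sorted(df[position_col].unique())
    if len(times) < 2 or len(positions) < 2:
        raise ValueError("both factors need at least 2 levels")
    counts = np.zeros((len(times), len(positions)), dtype=int)
    for i, t in enumerate(times):
        for j, p in enumerate(positions):
            counts[i, j] = ((df[time_col] == t) & (df[position_col] == p)).sum()
            if counts[i, j] == 0:
                raise ValueError(f"empty design cell: {time_col}={t}, {position_col}={p}")
    y = df[response].to_numpy(dtype=float)
    if log_scale:
        if np.any(y <= 0):
            raise ValueError("log-scale ANOVA requires a positive response")
        df["_resp"] = np.log(y)
    else:
        df["_resp"] = y

    df_int = (len(times) - 1) * (len(positions) - 1)
    df_err = len(df) - len(times) * len(positions)
    if df_err < 1:
        raise ValueError("no residual degrees of freedom (need replication within cells)")

    resp = df["_resp"].to_numpy()
    ss_total = float(((resp - resp.mean()) ** 2).sum())
    if ss_total <= 1e-12 * max(1.0, float(np.abs(resp).max()) ** 2 * len(resp)):
        # constant response: nothing to decompose
        return TestResult(statistic=0.0, df=(df_int, df_err), pvalue=1.0)

    if counts.min() == counts.max():
        # balanced: classical decomposition
        gm = df["_resp"].mean()
        n = counts[0, 0]
        row_mean = df.groupby(time_col)["_resp"].mean()
        col_mean = df.groupby(position_col)["_resp"].mean()
        cell_mean = df.groupby([time_col, position_col])["_resp"].mean()
        ss_int = 0.0
        ss_err = 0.0
        for t in times:
            for p in positions:
                cm = cell_mean.loc[(t, p)]
                ss_int += n * (cm - row_mean.loc[t] - col_mean.loc[p] + gm) ** 2
                resid = df.loc[(df[time_col] == t) & (df[position_col] == p), "_resp"] - cm
                ss_err += float((resid**2).sum())
        tol = 1e-12 * max(float(((df["_resp"] - gm) ** 2).sum()), 1e-300)
        if ss_int <= tol:
            F = 0.0
        elif ss_err <= tol:
            F = np.inf
        else:
            F = (ss_int / df_int) / (ss_err / df_err)
        pvalue = float(sps.f.sf(F, df_int, df_err)) if np.isfinite(F) else 0.0
        return TestResult(statistic=float(F), df=(df_int, df_err), pvalue=pvalue)

    df["_t"] = df[time_col].astype(str)
    df["_p"] = df[position_col].astype(str)
    fit = smf.ols("_resp ~ C(_t) * C(_p)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    row = tab.loc["C(_t):C(_p)"]
    return TestResult(
        statistic=float(row["F"]),
        df=(int(row["df"]), int(tab.loc["Residual", "df"])),
        pvalue=float(row["PR(>F)"]),
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class LayerGrowthModel:
    """Layer-by-position growth comparison between two time points.

    Parameters
    ----------
    records_t0, records_t1 : DataFrame
        Per-cell tables (canonical schema) at the earlier and later time
        point; cells are the observational units, pooled across replicates.
    metrics : sequence of column names
        Measurements to compare (default volume, longitudinal length,
        radial length).
    layers : sequence of int, optional
        Layers to analyse; defaults to the layers present at both time
        points (one-sided layers are excluded with a warning).
    alpha : float
        Family-wise error rate before correction.
    m : int, optional
        Number of comparisons for the Bonferroni correction; defaults to
        the number of analysed layers.
    ci_level : float, optional
        Level of the reported ratio confidence intervals. Defaults to the
        Bonferroni-corrected level 1 − α/m; pass 0.95 for uncorrected
        intervals.
    log_scale_anova : bool
        Analyse the ANOVA response on the log scale (default), consistent
        with the multiplicative growth model.
    """

    def __init__(self, records_t0: pd.DataFrame, records_t1: pd.DataFrame,
                 metrics=DEFAULT_METRICS, layers=None, alpha: float = 0.05,
                 m: int | None = None, ci_level: float | None = None,
                 log_scale_anova: bool = True):
        self.records_t0 = records_t0
        self.records_t1 = records_t1
        self.metrics = tuple(metrics)
        self.alpha = float(alpha)
        self.log_scale_anova = log_scale_anova
        l0 = set(int(v) for v in records_t0["layer"].dropna().unique())
        l1 = set(int(v) for v in records_t1["layer"].dropna().unique())
        common = sorted(l0 & l1)
        if layers is None:
            dropped = sorted((l0 | l1) - set(common))
            if dropped:
                warnings.warn(f"layers present at one time point only, excluded: {dropped}")
            self.layers = common
        else:
            self.layers = sorted(int(v) for v in layers)
            missing = [l for l in self.layers if l not in common]
            if missing:
                raise ValueError(f"requested layers absent from one time point: {missing}")
        if not self.layers:
            raise ValueError("no layer is present at both time points")
        self.m = int(m) if m is not None else len(self.layers)
        self.corrected_level = bonferroni_level(self.alpha, self.m)
        self.ci_level = float(ci_level) if ci_level is not None else self.corrected_level
        self.positions = sorted(
            set(records_t0["position"].dropna()) & set(records_t1["position"].dropna())
        )
        if len(self.positions) < 1:
            raise ValueError("no common position between time points")

    @classmethod
    def from_csv(cls, path_t0, path_t1, **kwargs) -> "LayerGrowthModel":
        return cls(pd.read_csv(path_t0), pd.read_csv(path_t1), **kwargs)

    def _group(self, records, layer, position, metric) -> np.ndarray:
        sel = (records["layer"] == layer) & (records["position"] == position)
        return records.loc[sel, metric].to_numpy(dtype=float)

    def fit(self) -> "LayerGrowthResults":
        """Compute ratios, intervals, t-tests and ANOVA interactions."""
        corrected_alpha = self.alpha / self.m
        rows = []
        anova_cache: dict[tuple[int, str], TestResult] = {}
        for layer in self.layers:
            for metric in self.metrics:
                sub = pd.concat(
                    [
                        self.records_t0[self.records_t0["layer"] == layer],
                        self.records_t1[self.records_t1["layer"] == layer],
                    ]
                )
                try:
                    anova_cache[(layer, metric)] = anova_interaction(
                        sub, metric, log_scale=self.log_scale_anova
                    )
                except ValueError:
                    anova_cache[(layer, metric)] = TestResult(np.nan, (0, 0), np.nan)
            for position in self.positions:
                for metric in self.metrics:
                    x = self._group(self.records_t1, layer, position, metric)  # later
                    y = self._group(self.records_t0, layer, position, metric)  # earlier
                    if x.size < 2 or y.size < 2:
                        warnings.warn(
                            f"layer {layer} position {position} metric {metric}: "
                            "fewer than 2 cells in a group, skipped"
                        )
                        continue
                    rr = ratio_interval(x, y, level=self.ci_level)
                    tt = t_test(x, y)
                    av = anova_cache[(layer, metric)]
                    rows.append(
                        {
                            "layer": layer,
                            "position": position,
                            "metric": metric,
                            "n_t0": y.size,
                            "n_t1": x.size,
                            "ratio": rr.ratio,
                            "ci_low": rr.ci_low,
                            "ci_high": rr.ci_high,
                            "ci_level": rr.level,
                            "t_stat": tt.statistic,
                            "t_p": tt.pvalue,
                            "t_sig": bool(tt.pvalue < corrected_alpha),
                            "anova_F": av.statistic,
                            "anova_p": av.pvalue,
                            "anova_sig": bool(av.pvalue < corrected_alpha)
                            if np.isfinite(av.pvalue)
                            else False,
                        }
                    )
        table = pd.DataFrame(rows)
        return LayerGrowthResults(self, table)


class LayerGrowthResults:
    """Fitted layer-by-position growth comparison.

    Attributes
    ----------
    table : DataFrame
        One row per (layer, position, metric): ratio of means (t1 over t0),
        its confidence bounds, the pooled t-test against the
        Bonferroni-corrected threshold, and the shared (per layer × metric)
        ANOVA time × position interaction.
    """

    def __init__(self, model: LayerGrowthModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    def summary(self) -> str:
        m = self.model
        lines = [
            "Layer-by-position growth comparison",
            f"  layers analysed: {m.layers}",
            f"  positions: {m.positions}   metrics: {list(m.metrics)}",
            f"  alpha = {m.alpha:g}, m = {m.m} comparisons -> corrected level "
            f"{100 * m.corrected_level:.1f}%",
            f"  ratio CIs at {100 * m.ci_level:.1f}%",
            "",
        ]
        with pd.option_context("display.width", 120, "display.max_columns", None):
            cols = [
                "layer", "position", "metric", "ratio", "ci_low", "ci_high",
                "t_p", "t_sig", "anova_p", "anova_sig",
            ]
            lines.append(self.table[cols].round(4).to_string(index=False))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "alpha": self.model.alpha,
            "m": self.model.m,
            "corrected_level": self.model.corrected_level,
            "ci_level": self.model.ci_level,
            "layers": list(self.model.layers),
            "positions": list(self.model.positions),
            "metrics": list(self.model.metrics),
            "comparisons": self.table.to_dict(orient="records"),
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def plot(self, metric="volume_um3", ax=None):
        """Ratio ± CI per layer, one line per position (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.table[self.table["metric"] == metric]
        for pos in self.model.positions:
            s = sub[sub["position"] == pos].sort_values("layer")
            ax.errorbar(
                s["layer"], s["ratio"],
                yerr=[s["ratio"] - s["ci_low"], s["ci_high"] - s["ratio"]],
                marker="o", capsize=3, label=pos,
            )
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xlabel("cell layer (1 = epidermis)")
        ax.set_ylabel(f"ratio of means, {metric}")
        ax.legend()
        return ax


def compare_layers(records_t0: pd.DataFrame, records_t1: pd.DataFrame,
                   **kwargs) -> LayerGrowthResults:
    """Functional wrapper: build a LayerGrowthModel and fit it."""
    return LayerGrowthModel(records_t0, records_t1, **kwargs).fit()
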