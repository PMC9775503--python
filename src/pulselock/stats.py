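"""Group-level aggregation and inference.

Aggregation follows the study design: per-recording, per-channel PLVs at
the six metrical levels are averaged over recordings and channels into one
grand-averaged PLV per participant and level (and, for topographic
analyses, over the six channels of each electrode cluster).  Inference
uses linear mixed-effects models with participant as the random unit,
normal-approximation bootstrap confidence intervals over participants, a
two-sample Kolmogorov-Smirnov test for pulse-frequency distributions, and
Holm's step-down familywise correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import ElectrodeClusters

__all__ = [
    "grand_average",
    "cluster_means",
    "bootstrap_ci",
    "ks_two_sample",
    "holm_correct",
    "fit_level_group_model",
    "ContrastResult",
    "ElectrodeClusters",
]


def grand_average(levels_long: pd.DataFrame) -> pd.DataFrame:
    """One grand-averaged PLV per participant and metrical level.

    Input: long table with columns participant, group, recording, channel,
    level, plv.  The mean is unweighted over the full recording x channel
    cross (missing cells are simply absent from the mean); participants
    with zero surviving recordings do not appear.  Returns participant,
    group, level, plv, n_cells.
    """
    required = {"participant", "group", "recording", "channel", "level", "plv"}
    missing = required - set(levels_long.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = levels_long.dropna(subset=["plv"])
    out = (
        df.groupby(["participant", "group", "level"], as_index=False)
        .agg(plv=("plv", "mean"), n_cells=("plv", "size"))
        .sort_values(["participant", "level"])
        .reset_index(drop=True)
    )
    return out


def cluster_means(
    levels_long: pd.DataFrame, clusters: ElectrodeClusters | None = None
) -> pd.DataFrame:
    """Per-participant cluster x level means (averaged over recordings and
    the six channels of each cluster); channels outside every cluster
    (e.g. the mastoid pair) are dropped."""
    clusters = clusters or ElectrodeClusters()
    df = levels_long.dropna(subset=["plv"]).copy()
    df["cluster"] = df["channel"].map(clusters.cluster_of)
    df = df.dropna(subset=["cluster"])
    return (
        df.groupby(["participant", "group", "cluster", "level"], as_index=False)
        .agg(plv=("plv", "mean"), n_cells=("plv", "size"))
        .reset_index(drop=True)
    )


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int | None = None,
    statistic=np.mean,
) -> tuple[float, float]:
    """Normal-approximation bootstrap interval, bias-adjusted:
    (2*theta_hat - mean(theta*)) +- z * sd(theta*).  Resamples the supplied
    values (here: participants, the unit of the grand average)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    est = float(statistic(values))
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boots = statistic(values[idx], axis=1)
    z = sps.norm.ppf(0.5 + level / 2.0)
    center = 2.0 * est - float(np.mean(boots))
    half = z * float(np.std(boots, ddof=1))
    return center - half, center + half


def ks_two_sample(freqs_a: np.ndarray, freqs_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p), e.g. comparing the
    pulse-frequency distributions of the two age groups."""
    freqs_a, freqs_b = np.asarray(freqs_a), np.asarray(freqs_b)
    if freqs_a.size == 0 or freqs_b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(freqs_a, freqs_b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def holm_correct(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values.

    Sort ascending; adjusted_(i) = max_{j<=i} min(1, (m-j+1) * p_(j));
    original order restored.  Adjusted values are >= raw values and
    non-decreasing in the sorted order.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class ContrastResult:
    table: pd.DataFrame  # effect, df_num, df_den, F, p, p_holm
    cell_means: pd.DataFrame  # factor cells with mean and SE
    method: str  # 'mixed' or 'paired-contrast fallback'
    converged: bool

    def effect(self, name: str) -> pd.Series:
        hit = self.table[self.table["effect"] == name]
        if hit.empty:
            raise KeyError(f"no effect {name!r}; have {list(self.table['effect'])}")
        return hit.iloc[0]


def _term_param_indices(exog_names: list[str]) -> dict[str, list[int]]:
    terms: dict[str, list[int]] = {}
    for i, name in enumerate(exog_names):
        if name == "Intercept":
            continue
        # strip the Sum-coding bracket parts to recover the term label
        parts = name.split(":")
        label = ":".join(p.split("[")[0] for p in parts)
        terms.setdefault(label, []).append(i)
    return terms


def _pretty(term: str) -> str:
    return (
        term.replace("C(level, Sum)", "level")
        .replace("C(group, Sum)", "group")
        .replace("C(cluster, Sum)", "cluster")
    )


def _cells(df: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    return (
        df.groupby(factors, as_index=False)
        .agg(mean=("plv", "mean"), se=("plv", "sem"), n=("plv", "size"))
        .reset_index(drop=True)
    )


def _fallback_contrasts(df: pd.DataFrame) -> pd.DataFrame:
    """Paired-contrast approximation for the two-level grand design:
    per-participant level differences tested against zero (level effect),
    compared across groups (interaction); participant means compared across
    groups (group effect)."""
    lv = sorted(df["level"].unique())
    if len(lv) != 2:
        raise RuntimeError("fallback contrast requires exactly two levels")
    wide = df.pivot_table(index=["participant", "group"], columns="level", values="plv").reset_index()
    d = wide[lv[0]] - wide[lv[1]]
    m = (wide[lv[0]] + wide[lv[1]]) / 2.0
    g = wide["group"].to_numpy()
    groups = sorted(set(g))
    rows = []
    t, p = sps.ttest_1samp(d, 0.0)
    rows.append(("level", 1, d.size - 1, t**2, p))
    if len(groups) == 2:
        a, b = (m[g == groups[0]], m[g == groups[1]])
        t, p = sps.ttest_ind(a, b)
        rows.append(("group", 1, a.size + b.size - 2, t**2, p))
        da, db = (d[g == groups[0]], d[g == groups[1]])
        t, p = sps.ttest_ind(da, db)
        rows.append(("level:group", 1, da.size + db.size - 2, t**2, p))
    out = pd.DataFrame(rows, columns=["effect", "df_num", "df_den", "F", "p"])
    out["p_holm"] = holm_correct(out["p"].to_numpy())
    return out


def fit_level_group_model(
    table: pd.DataFrame,
    include_cluster: bool | None = None,
    alpha: float = 0.05,
) -> ContrastResult:
    """Mixed-effects contrasts of PLV by metrical level and age group.

    Without clusters: PLV ~ level * group with a participant random
    intercept (the grand-average design, two levels per participant).
    With clusters: PLV ~ cluster * group * level with participant random
    intercept and uncorrelated random slopes for cluster and level
    (variance components).  Fitting is delegated to statsmodels' MixedLM
    (REML); each fixed-effect term is tested with a Wald F whose
    denominator degrees of freedom are n_participants - 2 for the
    grand-average design and the residual count for the cluster design —
    a deliberate approximation to Satterthwaite df, adequate at these
    sample sizes.  If the mixed fit fails to converge, a documented
    paired-contrast approximation is used for the two-level design.
    Holm-adjusted p-values are reported across the model's effect family.
    """
    import statsmodels.formula.api as smf

    df = table.dropna(subset=["plv"]).copy()
    for col in ("participant", "group", "level"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
        df[col] = df[col].astype(str)
    if include_cluster is None:
        include_cluster = "cluster" in df.columns
    n_part = df["participant"].nunique()

    # F/Wald statistics are invariant to affine response scaling; fitting on
    # the standardized response avoids optimizer trouble with the tiny
    # variances typical of PLV data
    sd = df["plv"].std()
    df["_y"] = (df["plv"] - df["plv"].mean()) / (sd if sd > 0 else 1.0)
    if include_cluster:
        formula = "_y ~ C(cluster, Sum) * C(group, Sum) * C(level, Sum)"
        vc = {"vcluster": "0 + C(cluster)", "vlevel": "0 + C(level)"}
        factors = ["cluster", "group", "level"]
    else:
        formula = "_y ~ C(level, Sum) * C(group, Sum)"
        vc = None
        factors = ["level", "group"]
    cells = _cells(df, factors)

    res = None
    for method in (None, ["powell"]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, df, groups=df["participant"], vc_formula=vc)
                fit_kw = {"reml": True, "maxiter": 500}
                if method is not None:
                    fit_kw["method"] = method
                res = model.fit(**fit_kw)
            if res.converged and np.all(np.isfinite(res.bse.iloc[: len(res.fe_params)])):
                break
            res = None
        except Exception:
            res = None

    if res is None:
        if include_cluster:
            raise RuntimeError(
                "mixed model failed to converge and no fallback is defined for the "
                "cluster design; inspect the input table"
            )
        tab = _fallback_contrasts(df)
        return ContrastResult(tab, cells, "paired-contrast fallback", False)

    exog_names = list(res.model.exog_names)
    terms = _term_param_indices(exog_names)
    k_fe = len(res.fe_params)
    df_den = (df.shape[0] - k_fe) if include_cluster else max(n_part - 2, 1)
    rows = []
    for term, idx in terms.items():
        R = np.zeros((len(idx), len(res.params)))
        for r, i in enumerate(idx):
            R[r, i] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wt = res.wald_test(R, scalar=True)
        chi2 = float(np.squeeze(wt.statistic))
        df_num = len(idx)
        F = chi2 / df_num
        p = float(sps.f.sf(F, df_num, df_den))
        rows.append((_pretty(term), df_num, df_den, F, p))
    tab = pd.DataFrame(rows, columns=["effect", "df_num", "df_den", "F", "p"])
    tab["p_holm"] = holm_correct(tab["p"].to_numpy())
    return ContrastResult(tab, cells, "mixed", True)
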