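"""Replicate-level ANOVA, broad-sense heritability and per-line CV.

The study design is a (near-)balanced randomized complete block layout: each
RIL line grown in two independent experiments with two blocks per
experiment.  Variance components are estimated by equating observed mean
squares to their expectations (the expected-mean-squares method), which on a
balanced design is exact and hand-checkable:

within one experiment (r replicates per line)
    Vg = (MS_line - MS_error) / r,              Vp = Vg + Verr
across experiments (e experiments, b blocks each)
    Vg   = (MS_line - MS_lineXexp) / (e b)
    Vgxe = (MS_lineXexp - MS_error) / b
    Vexp = (MS_exp - MS_lineXexp) / (n_lines b)
    Vp   = Vg + Vexp + Vgxe + Verr,             H2 = Vg / Vp

Negative estimates are truncated to zero.  The combined-scope Vg excludes
the interaction variance (strict among-line variance); because Vp retains
the experiment and G x E components, combined-scope H2 falls below the
within-experiment estimates whenever those components are real.

The per-line coefficient of variation (sd / mean over all replicates) is the
stochastic-variation phenotype; it feeds the same QTL scan machinery as any
other trait.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

HERITABILITY_COLUMNS = ["trait", "scope", "Vg", "Vexp", "Vgxe", "Verr", "Vp", "H2"]


def _truncate(x):
    return float(max(x, 0.0))


def _components_within(df: pd.DataFrame) -> dict:
    """One-way line ANOVA within a single experiment."""
    g = df.groupby("line")["value"]
    counts = g.count()
    if (counts < 2).all():
        raise ValueError("single replicate per line: H2 undefined")
    means = g.mean()
    grand = df["value"].mean()
    r_h = len(counts) / np.sum(1.0 / counts)
    n_l = len(counts)
    ms_line = r_h * np.sum((means - grand) ** 2) / (n_l - 1)
    within = df["value"] - df["line"].map(means)
    dfe = int((counts - 1).sum())
    ms_err = float((within**2).sum() / dfe) if dfe > 0 else 0.0
    vg = _truncate((ms_line - ms_err) / r_h)
    verr = _truncate(ms_err)
    vp = vg + verr
    return {
        "Vg": vg,
        "Vexp": 0.0,
        "Vgxe": 0.0,
        "Verr": verr,
        "Vp": vp,
        "H2": vg / vp if vp > 0 else 0.0,
    }


def _components_combined(df: pd.DataFrame) -> dict:
    """Two-way (line x experiment) random-effects components."""
    cell = df.groupby(["line", "experiment"])["value"].agg(["mean", "count", "var"])
    counts = cell["count"]
    if cell.index.get_level_values("experiment").nunique() < 2:
        raise ValueError("combined scope needs at least two experiments")
    if (df.groupby("line")["value"].count() < 2).all():
        raise ValueError("single replicate per line: H2 undefined")
    b_h = len(counts) / np.sum(1.0 / counts)
    wide = cell["mean"].unstack("experiment")
    if wide.isna().any().any():
        raise ValueError("combined scope needs every line in every experiment")
    n_l, e = wide.shape
    grand = wide.to_numpy().mean()
    line_means = wide.mean(axis=1).to_numpy()
    exp_means = wide.mean(axis=0).to_numpy()
    ms_line = e * b_h * np.sum((line_means - grand) ** 2) / (n_l - 1)
    ms_exp = n_l * b_h * np.sum((exp_means - grand) ** 2) / (e - 1)
    inter = wide.to_numpy() - line_means[:, None] - exp_means[None, :] + grand
    ms_ge = b_h * np.sum(inter**2) / ((n_l - 1) * (e - 1))
    sse = float((cell["var"].fillna(0.0) * (counts - 1)).sum())
    dfe = int((counts - 1).sum())
    ms_err = sse / dfe if dfe > 0 else 0.0
    vg = _truncate((ms_line - ms_ge) / (e * b_h))
    vgxe = _truncate((ms_ge - ms_err) / b_h)
    vexp = _truncate((ms_exp - ms_ge) / (n_l * b_h))
    verr = _truncate(ms_err)
    vp = vg + vexp + vgxe + verr
    return {
        "Vg": vg,
        "Vexp": vexp,
        "Vgxe": vgxe,
        "Verr": verr,
        "Vp": vp,
        "H2": vg / vp if vp > 0 else 0.0,
    }


def broad_sense_h2(
    trait: pd.DataFrame, scope: str = "combined", include_gxe_in_vg: bool = False
) -> dict:
    """Variance components and H2 for one trait's replicated values.

    ``trait`` has columns line, experiment, block, value; ``scope`` is
    "combined", "exp1" or "exp2".  Combined-scope Vg is the strict
    among-line variance by default; ``include_gxe_in_vg`` folds the
    line x experiment component into the numerator instead.  All-equal
    values give Vg = Vp = 0 and H2 defined as 0.
    """
    df = trait.dropna(subset=["value"])
    if scope in ("exp1", "exp2"):
        sub = df[df["experiment"] == int(scope[-1])]
        if len(sub) == 0:
            raise ValueError(f"no data for scope {scope}")
        return _components_within(sub)
    if scope == "combined":
        comp = _components_combined(df)
        if include_gxe_in_vg and comp["Vp"] > 0:
            comp["H2"] = (comp["Vg"] + comp["Vgxe"]) / comp["Vp"]
        return comp
    raise ValueError(f"unknown scope: {scope!r}")


def heritability_table(traits: pd.DataFrame, scopes=("exp1", "exp2", "combined")) -> pd.DataFrame:
    """Per-trait variance components for each scope (long output table)."""
    rows = []
    for trait, sub in traits.groupby("trait", sort=False):
        for scope in scopes:
            try:
                comp = broad_sense_h2(sub, scope)
            except ValueError as err:
                warnings.warn(f"trait {trait} scope {scope}: {err}")
                continue
            rows.append({"trait": trait, "scope": scope, **comp})
    return pd.DataFrame(rows, columns=HERITABILITY_COLUMNS)


def fit_gxe_anova(trait: pd.DataFrame, include_block: bool = False) -> pd.DataFrame:
    """Type III ANOVA of value ~ line + experiment + line x experiment.

    Sum-to-zero contrasts; returns a term table with sum_sq, df, F and p.
    ``include_block`` adds a block-within-experiment term.  If the design
    is fully confounded (each line observed in only one experiment) the
    interaction is dropped with a warning.
    """
    df = trait.dropna(subset=["value"]).copy()
    df["line"] = df["line"].astype(str)
    df["experiment"] = df["experiment"].astype(str)
    n_exp_per_line = df.groupby("line")["experiment"].nunique()
    formula = "value ~ C(line, Sum) + C(experiment, Sum) + C(line, Sum):C(experiment, Sum)"
    if (n_exp_per_line < 2).all() or df["experiment"].nunique() < 2:
        warnings.warn("confounded design: line x experiment term dropped")
        formula = "value ~ C(line, Sum) + C(experiment, Sum)"
        if df["experiment"].nunique() < 2:
            formula = "value ~ C(line, Sum)"
    if include_block:
        df["block"] = df["block"].astype(str)
        formula += " + C(experiment, Sum):C(block, Sum)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    table = table.rename(
        index=lambda s: s.replace("C(line, Sum)", "line").replace(
            "C(experiment, Sum)", "experiment"
        ).replace(":", " x ")
    )
    out = table.rename(columns={"PR(>F)": "p"}).drop(index="Intercept", errors="ignore")
    return out


def gxe_anova_panel(traits: pd.DataFrame) -> pd.DataFrame:
    """Vectorized balanced two-way ANOVA (line, experiment, interaction)
    for every trait; F and p per term.  Exact for balanced complete panels
    (on which sequential, Type II and Type III SS coincide)."""
    from scipy import stats

    rows = []
    for trait, sub in traits.groupby("trait", sort=False):
        df = sub.dropna(subset=["value"])
        cell = df.groupby(["line", "experiment"])["value"].agg(["mean", "count", "var"])
        wide = cell["mean"].unstack("experiment")
        counts = cell["count"]
        b = float(counts.mean())
        n_l, e = wide.shape
        grand = wide.to_numpy().mean()
        lm = wide.mean(axis=1).to_numpy()
        em = wide.mean(axis=0).to_numpy()
        ss_line = e * b * np.sum((lm - grand) ** 2)
        ss_exp = n_l * b * np.sum((em - grand) ** 2)
        inter = wide.to_numpy() - lm[:, None] - em[None, :] + grand
        ss_ge = b * np.sum(inter**2)
        sse = float((cell["var"].fillna(0.0) * (counts - 1)).sum())
        dfe = int((counts - 1).sum())
        mse = sse / dfe if dfe > 0 else np.nan
        for term, ss, d in (
            ("line", ss_line, n_l - 1),
            ("experiment", ss_exp, e - 1),
            ("line x experiment", ss_ge, (n_l - 1) * (e - 1)),
        ):
            F = (ss / d) / mse if mse and mse > 0 else np.inf
            p = float(stats.f.sf(F, d, dfe)) if np.isfinite(F) else 0.0
            rows.append(
                {"trait": trait, "term": term, "sum_sq": ss, "df": d, "F": F, "p": p}
            )
    return pd.DataFrame(rows)


def line_cv(trait: pd.DataFrame, per_experiment: bool = False) -> pd.Series:
    """Per-line coefficient of variation: sd(n-1) / mean over replicates.

    By default the CV pools all replicates across experiments;
    ``per_experiment`` instead computes the CV within each experiment and
    averages.  Lines with fewer than two replicates or non-positive mean
    get NaN (with a warning for the non-positive means); dimensionless and
    invariant to positive rescaling of the trait.
    """
    if per_experiment:
        parts = [
            line_cv(sub, per_experiment=False)
            for _, sub in trait.groupby("experiment")
        ]
        return pd.concat(parts, axis=1).mean(axis=1)
    g = trait.dropna(subset=["value"]).groupby("line")["value"]
    mean = g.mean()
    sd = g.std(ddof=1)
    n = g.count()
    cv = sd / mean
    cv[n < 2] = np.nan
    bad = mean <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} lines with non-positive mean: CV set missing")
        cv[bad] = np.nan
    return cv


def cv_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Lines x traits matrix of per-line CV over all replicates."""
    out = {}
    for trait, sub in traits.groupby("trait", sort=False):
        out[trait] = line_cv(sub)
    return pd.DataFrame(out)


def cv_trait_table(traits: pd.DataFrame) -> pd.DataFrame:
    """CV values as a long-format trait table (single pseudo-replicate), so
    the scan stages consume it unchanged."""
    wide = cv_table(traits)
    long = wide.reset_index().melt(id_vars="line", var_name="trait", value_name="value")
    long["experiment"] = 1
    long["block"] = 1
    return long[["line", "experiment", "block", "trait", "value"]].dropna(
        subset=["value"]
    )


def median_normalize(traits: pd.DataFrame, per_trait: bool = False) -> pd.DataFrame:
    """Divide each sample's values by that sample's median across traits.

    A sample is one (line, experiment, block) measurement; after scaling the
    per-sample median is 1.  Samples with zero median are flagged and left
    unscaled.  ``per_trait`` instead scales each trait by its median across
    samples.
    """
    out = traits.copy()
    if per_trait:
        med = out.groupby("trait")["value"].transform("median")
    else:
        med = out.groupby(["line", "experiment", "block"])["value"].transform("median")
    zero = med == 0
    if zero.any():
        warnings.warn("samples with zero median left unscaled")
        med = med.mask(zero, 1.0)
    out["value"] = out["value"] / med
    return out
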