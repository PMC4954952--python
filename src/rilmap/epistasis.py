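"""All-pairs hotspot-marker epistasis ANOVA, enrichment and network export.

For the hotspot markers M_1..M_k the per-trait model is

    y ~ sum_m M_m + sum_{m<n} M_m x M_n + experiment
        + sum_{m<n} M_m x M_n x experiment

fitted on per-(line, experiment) trait means with all factors coded +-1
(sum-to-zero), under which every term has one degree of freedom and its
Type III sum of squares is b_j^2 / (X'X)^{-1}_{jj} — the quantity a Type III
ANOVA of the full model returns.  P-values are BH-FDR corrected within each
trait's model.

Whether a marker pair interacts for *more traits than expected by chance*
is decided by permutation: line labels of the trait matrix are shuffled
against the genotypes (preserving the trait-trait correlation structure)
and the per-pair significant-trait counts recomputed; an edge is retained
when its observed count strictly exceeds the per-pair (1 - alpha) null
quantile.  The per-trait fraction of model variance attributable to the
pairwise terms measures the scale of epistasis.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import ensure_rng

logger = logging.getLogger("rilmap")

EDGE_TABLE_COLUMNS = [
    "marker1",
    "marker2",
    "n_significant_traits",
    "null_q",
    "enrichment_p",
    "retained",
    "experiment_dependent",
]


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone); empty in, empty out."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def epistasis_design(marker_x: np.ndarray, exp_sign: np.ndarray, three_way: bool = True):
    """Design matrix and term labels for the pairwise epistasis model.

    ``marker_x``: rows x k matrix of +-1 marker codes (already expanded to
    the row structure); ``exp_sign``: +-1 experiment code per row.
    Terms: intercept, main (k), pair (k choose 2), experiment, pair x exp.
    """
    n, k = marker_x.shape
    cols = [np.ones(n)]
    terms = [("intercept", "intercept")]
    for m in range(k):
        cols.append(marker_x[:, m])
        terms.append((f"M{m}", "main"))
    pair_idx = []
    for m in range(k):
        for nn in range(m + 1, k):
            cols.append(marker_x[:, m] * marker_x[:, nn])
            terms.append((f"M{m}:M{nn}", "pair"))
            pair_idx.append((m, nn))
    cols.append(exp_sign)
    terms.append(("experiment", "experiment"))
    if three_way:
        for m, nn in pair_idx:
            cols.append(marker_x[:, m] * marker_x[:, nn] * exp_sign)
            terms.append((f"M{m}:M{nn}:experiment", "pair_x_exp"))
    X = np.column_stack(cols)
    return X, terms, pair_idx


def _fit_terms(X: np.ndarray, Y: np.ndarray):
    """Type III SS, F and p for every 1-df term, vectorized over traits.

    Returns (ss[T, J], F, p, dfe, rss[T]).  Aliased (rank-deficient)
    columns are handled through the pseudoinverse with a warning.
    """
    n, J = X.shape
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < J:
        warnings.warn("aliased terms in the epistasis design (rank deficient)")
    XtXinv = np.linalg.pinv(XtX)
    B = XtXinv @ (X.T @ Y)
    resid = Y - X @ B
    rss = np.einsum("ij,ij->j", resid, resid)
    dfe = n - rank
    d = np.diag(XtXinv).copy()
    d[d <= 0] = np.inf
    ss = (B**2) / d[:, None]
    mse = rss / max(dfe, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(mse > 0, ss / mse[None, :], np.inf)
    p = stats.f.sf(F, 1, max(dfe, 1))
    return ss.T, F.T, p.T, dfe, rss


def _panel_matrices(traits: pd.DataFrame, genotypes, markers, gmap):
    from .hotspots import _line_exp_means, _marker_codes

    x = _marker_codes(genotypes, list(markers), gmap)
    cell, sign, rows = _line_exp_means(traits, genotypes.line_ids)
    Y = cell.to_numpy(dtype=float)
    finite = np.isfinite(Y)
    if not finite.all():
        col_mean = np.nanmean(np.where(finite, Y, np.nan), axis=0)
        Y = np.where(finite, Y, col_mean)
    return x, Y, list(cell.columns), sign, rows


def epistasis_anova_panel(
    traits: pd.DataFrame,
    hotspot_markers,
    genotypes,
    gmap,
    three_way: bool = True,
    fdr: float = 0.05,
    mode: str = "joint",
) -> pd.DataFrame:
    """Tidy per-trait, per-term Type III table for the full panel.

    Columns: trait, term, kind, sum_sq, df, F, p, q (BH within each trait's
    model, intercept excluded).  ``mode="joint"`` (default) fits all
    markers and pairs in one model; ``mode="pairwise"`` fits each marker
    pair in its own model, the fallback for degenerate-rank marker sets.
    """
    markers = list(hotspot_markers)
    if len(markers) < 2:
        raise ValueError("need at least two hotspot markers")
    if mode == "pairwise":
        return _pair_at_a_time_panel(traits, markers, genotypes, gmap, three_way, fdr)
    if mode != "joint":
        raise ValueError(f"unknown mode: {mode!r}")
    x, Y, trait_names, sign, rows = _panel_matrices(traits, genotypes, markers, gmap)
    X, terms, pair_idx = epistasis_design(x[rows], sign, three_way)
    ss, F, p, dfe, rss = _fit_terms(X, Y)
    labels = [("intercept", "intercept")]
    labels += [(mk, "main") for mk in markers]
    labels += [(f"{markers[m]}:{markers[nn]}", "pair") for m, nn in pair_idx]
    labels.append(("experiment", "experiment"))
    if three_way:
        labels += [
            (f"{markers[m]}:{markers[nn]}:experiment", "pair_x_exp")
            for m, nn in pair_idx
        ]
    records = []
    for t, trait in enumerate(trait_names):
        pv = p[t, 1:]
        qv = fdr_adjust(pv)
        for j, (lab, kind) in enumerate(labels):
            if kind == "intercept":
                continue
            records.append(
                {
                    "trait": trait,
                    "term": lab,
                    "kind": kind,
                    "sum_sq": ss[t, j],
                    "df": 1,
                    "F": F[t, j],
                    "p": p[t, j],
                    "q": qv[j - 1],
                }
            )
    return pd.DataFrame(records)


def _pair_at_a_time_panel(traits, markers, genotypes, gmap, three_way, fdr):
    """Each marker pair fitted in its own small model; pair/three-way terms
    collected across pairs with BH within each trait over the tested
    terms."""
    x, Y, trait_names, sign, rows = _panel_matrices(traits, genotypes, markers, gmap)
    records = []
    per_trait_rows: dict = {t: [] for t in trait_names}
    for m in range(len(markers)):
        for nn in range(m + 1, len(markers)):
            X, terms, _ = epistasis_design(x[rows][:, [m, nn]], sign, three_way)
            ss, F, p, dfe, _ = _fit_terms(X, Y)
            labels = [("intercept", "intercept"),
                      (markers[m], "main"), (markers[nn], "main"),
                      (f"{markers[m]}:{markers[nn]}", "pair"),
                      ("experiment", "experiment")]
            if three_way:
                labels.append((f"{markers[m]}:{markers[nn]}:experiment", "pair_x_exp"))
            for t, trait in enumerate(trait_names):
                for j, (lab, kind) in enumerate(labels):
                    if kind in ("pair", "pair_x_exp"):
                        per_trait_rows[trait].append(
                            {"trait": trait, "term": lab, "kind": kind,
                             "sum_sq": ss[t, j], "df": 1, "F": F[t, j], "p": p[t, j]}
                        )
    for trait in trait_names:
        recs = per_trait_rows[trait]
        qv = fdr_adjust([r["p"] for r in recs])
        for r, q in zip(recs, qv):
            r["q"] = q
            records.append(r)
    return pd.DataFrame(records)


def pairwise_epistasis_anova(
    trait: pd.DataFrame,
    hotspot_markers,
    genotypes,
    gmap,
    three_way: bool = True,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Single-trait convenience wrapper around :func:`epistasis_anova_panel`."""
    return epistasis_anova_panel(
        trait, hotspot_markers, genotypes, gmap, three_way=three_way, fdr=fdr
    ).drop(columns=["trait"])


def _pair_counts(X, Y, terms, fdr) -> tuple:
    """(pair counts, three-way counts) of FDR-significant traits per pair."""
    _, _, p, _, _ = _fit_terms(X, Y)
    kinds = np.array([k for _, k in terms])
    tested = p[:, kinds != "intercept"]
    kinds_t = kinds[kinds != "intercept"]
    q = np.vstack([fdr_adjust(row) for row in tested])
    pair_cols = kinds_t == "pair"
    three_cols = kinds_t == "pair_x_exp"
    pair_counts = (q[:, pair_cols] < fdr).sum(axis=0)
    three_counts = (
        (q[:, three_cols] < fdr).sum(axis=0) if three_cols.any() else None
    )
    return pair_counts, three_counts


def epistasis_enrichment(
    traits: pd.DataFrame,
    hotspot_markers,
    genotypes,
    gmap,
    n_perm: int = 500,
    alpha: float = 0.05,
    fdr: float = 0.05,
    three_way: bool = True,
    pooled: bool = False,
    rng=None,
) -> pd.DataFrame:
    """Which marker pairs control more traits than expected by chance.

    Null: permute line labels of the trait matrix against the genotypes
    (every line keeps its pair of experiment rows), recompute per-pair
    significant-trait counts.  An edge is retained when observed count >
    per-pair (1 - alpha) null quantile (``pooled`` compares against the
    quantile of all pairs' null counts pooled together); experiment
    dependence is flagged the same way on the three-way term counts.
    """
    rng = ensure_rng(rng)
    markers = list(hotspot_markers)
    x, Y, trait_names, sign, rows = _panel_matrices(traits, genotypes, markers, gmap)
    X, terms, pair_idx = epistasis_design(x[rows], sign, three_way)
    obs_pair, obs_three = _pair_counts(X, Y, terms, fdr)
    n_lines = len(genotypes.line_ids)
    null_pair = np.empty((n_perm, len(pair_idx)), dtype=int)
    null_three = np.empty((n_perm, len(pair_idx)), dtype=int)
    for pi in range(n_perm):
        perm = rng.permutation(n_lines)
        Xp, _, _ = epistasis_design(x[perm][rows], sign, three_way)
        pc, tc = _pair_counts(Xp, Y, terms, fdr)
        null_pair[pi] = pc
        null_three[pi] = tc if tc is not None else 0
    k = int(np.ceil((1.0 - alpha) * n_perm)) - 1
    if pooled:
        kp = int(np.ceil((1.0 - alpha) * null_pair.size)) - 1
        q_pair = np.full(null_pair.shape[1], np.sort(null_pair, axis=None)[kp])
        q_three = np.full(null_three.shape[1], np.sort(null_three, axis=None)[kp])
    else:
        q_pair = np.sort(null_pair, axis=0)[k]
        q_three = np.sort(null_three, axis=0)[k]
    enr_p = (1.0 + (null_pair >= obs_pair[None, :]).sum(axis=0)) / (n_perm + 1.0)
    rows_out = []
    for j, (m, nn) in enumerate(pair_idx):
        exp_dep = bool(obs_three is not None and obs_three[j] > q_three[j])
        rows_out.append(
            {
                "marker1": markers[m],
                "marker2": markers[nn],
                "n_significant_traits": int(obs_pair[j]),
                "null_q": int(q_pair[j]),
                "enrichment_p": float(enr_p[j]),
                "retained": bool(obs_pair[j] > q_pair[j]),
                "experiment_dependent": exp_dep,
            }
        )
    return pd.DataFrame(rows_out, columns=EDGE_TABLE_COLUMNS)


def epistatic_variance_fraction(term_table: pd.DataFrame) -> pd.Series:
    """Percent of total model (Type III) SS in the pairwise terms, per trait.

    fraction = 100 * sum(SS_pair) / sum(SS_all non-intercept terms); zero
    model SS gives 0 with a warning.
    """
    out = {}
    for trait, sub in term_table.groupby("trait", sort=False):
        total = sub["sum_sq"].sum()
        pair = sub.loc[sub["kind"] == "pair", "sum_sq"].sum()
        if total <= 0:
            warnings.warn(f"zero model SS for trait {trait}")
            out[trait] = 0.0
        else:
            out[trait] = 100.0 * pair / total
    return pd.Series(out, name="epistatic_pct")


def compare_variance_fractions(group_a, group_b) -> dict:
    """Welch two-sample t-test of epistatic variance fractions."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_a": float(a.mean()),
        "se_a": float(a.std(ddof=1) / np.sqrt(a.size)),
        "mean_b": float(b.mean()),
        "se_b": float(b.std(ddof=1) / np.sqrt(b.size)),
        "t": float(t),
        "p": float(p),
    }


def export_network(edges: pd.DataFrame, sif_path, attrs_path) -> None:
    """Write the epistasis network as SIF plus an edge-attribute TSV.

    SIF rows: ``marker1 epistasis marker2``.  The attribute table carries
    the significant-trait count, enrichment p and the experiment-dependence
    flag mapped to the solid/dashed line style convention.
    """
    with open(sif_path, "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['marker1']}\tepistasis\t{row['marker2']}\n")
    attrs = edges.copy()
    attrs["style"] = np.where(attrs["experiment_dependent"], "dashed", "solid")
    attrs.to_csv(attrs_path, sep="\t", index=False)


def read_sif(path) -> list:
    """Read a SIF file back as a list of (node1, interaction, node2)."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 3:
                out.append((parts[0], parts[1], parts[2]))
    return out
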