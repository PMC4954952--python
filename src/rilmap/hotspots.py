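"""Sliding-window QTL hotspots, permutation nulls and marker-model checks.

A hotspot is a map position where significantly more trait QTLs co-localize
than expected if the detected QTLs were scattered at random.  The statistic
is the count of QTL peaks inside a sliding window (default 10 cM full
width); its null distribution comes from re-placing every QTL peak uniformly
on the genetic map and recording the genome-wide maximum window count.  A
position is called a hotspot when its count strictly exceeds the
(1 - alpha) order statistic of that null.

Candidate hotspots found in the combined / experiment-1 / experiment-2
surveys are merged by single-linkage clustering and then validated against
the full trait panel with a joint linear model
``trait ~ sum(markers) + experiment`` — a hotspot is valid when the number
of traits its marker moves (after per-model BH-FDR) exceeds the null count
obtained by permuting line labels of the genotypes.  A second model adds
marker x experiment terms to separate genotype main effects from
genotype-by-experiment dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import ensure_rng
from .epistasis import fdr_adjust
from .mapping import (
    A,
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    ScanGrid,
)
from .scan import line_means

logger = logging.getLogger("rilmap")

HOTSPOT_TABLE_COLUMNS = [
    "dataset",
    "chromosome",
    "peak_cM",
    "nearest_marker",
    "count",
    "threshold",
    "validated",
    "n_main",
    "n_gxe",
]


def window_counts(
    qtls: pd.DataFrame, grid: ScanGrid, window: float = 10.0
) -> pd.DataFrame:
    """QTL peaks within +- window/2 of every grid position (full width).

    ``qtls`` needs columns chromosome and position_cM; an empty list gives
    an all-zero profile.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    half = window / 2.0
    out = grid.table[["chromosome", "position_cm"]].copy()
    counts = np.zeros(len(out), dtype=int)
    if len(qtls):
        for chrom, sub in qtls.groupby("chromosome"):
            try:
                sl = grid.chrom_slice(chrom)
            except KeyError:
                continue
            peaks = np.sort(sub["position_cM"].to_numpy(dtype=float))
            gpos = grid.positions[sl]
            counts[sl] = np.searchsorted(peaks, gpos + half, side="right") - np.searchsorted(
                peaks, gpos - half, side="left"
            )
    out["count"] = counts
    return out


def _null_max_counts(
    n_qtl: int, grid: ScanGrid, window: float, n_perm: int, rng
) -> np.ndarray:
    """Null genome-wide max window count under uniform re-placement."""
    half = window / 2.0
    chroms = []
    for chrom in dict.fromkeys(grid.chromosome):
        sl = grid.chrom_slice(chrom)
        pos = grid.positions[sl]
        chroms.append((pos, pos[-1] - pos[0], pos[0]))
    lengths = np.array([max(c[1], 1e-9) for c in chroms])
    cum = np.cumsum(lengths)
    total = cum[-1]
    out = np.empty(n_perm, dtype=int)
    for p in range(n_perm):
        u = np.sort(rng.random(n_qtl) * total)
        best = 0
        lo = 0.0
        for (gpos, length, start), hi in zip(chroms, cum):
            peaks = u[(u >= lo) & (u < hi)] - lo + start
            if peaks.size:
                c = np.searchsorted(peaks, gpos + half, side="right") - np.searchsorted(
                    peaks, gpos - half, side="left"
                )
                best = max(best, int(c.max()))
            lo = hi
        out[p] = best
    return out


def hotspot_permutation_threshold(
    n_qtl: int,
    grid: ScanGrid,
    window: float = 10.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng=None,
) -> int:
    """(1-alpha) order statistic of the null genome-wide max window count.

    Positions are declared hotspots when their count strictly exceeds this
    threshold (so with a single QTL the threshold is 1 and nothing is
    significant).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = ensure_rng(rng)
    if n_qtl == 0:
        return 0
    null = np.sort(_null_max_counts(n_qtl, grid, window, n_perm, rng))
    k = int(np.ceil((1.0 - alpha) * n_perm)) - 1
    return int(null[k])


def find_hotspots(
    counts: pd.DataFrame,
    threshold: float,
    gmap: GeneticMap,
    dataset: str = "combined",
) -> pd.DataFrame:
    """Local peaks of contiguous above-threshold runs of the count profile.

    Ties at equal count break toward the lower cM position.
    """
    rows = []
    for chrom, sub in counts.groupby("chromosome", sort=False):
        c = sub["count"].to_numpy()
        pos = sub["position_cm"].to_numpy()
        above = c > threshold
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            seg = c[start:stop]
            peak = start + int(np.argmax(seg))
            rows.append(
                {
                    "dataset": dataset,
                    "chromosome": chrom,
                    "peak_cM": float(pos[peak]),
                    "nearest_marker": gmap.nearest_marker(chrom, pos[peak]),
                    "count": int(c[peak]),
                    "threshold": threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["dataset", "chromosome", "peak_cM", "nearest_marker", "count", "threshold"],
    )


def merge_hotspots(
    hotspots: pd.DataFrame, radius: float = 10.0, gmap: GeneticMap | None = None
) -> pd.DataFrame:
    """Single-linkage merge of hotspot peaks across datasets.

    Peaks on the same chromosome within ``radius`` cM chain into one cluster;
    each cluster is represented by its highest-count peak (ties toward lower
    cM) and that peak's nearest marker.  Idempotent.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(hotspots) == 0:
        return pd.DataFrame(
            columns=["chromosome", "peak_cM", "nearest_marker", "count", "n_members"]
        )
    rows = []
    for chrom, sub in hotspots.groupby("chromosome", sort=False):
        sub = sub.sort_values(["peak_cM", "count"]).reset_index(drop=True)
        pos = sub["peak_cM"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > radius)
        starts = np.concatenate([[0], breaks + 1])
        stops = np.concatenate([breaks + 1, [len(sub)]])
        for s, e in zip(starts, stops):
            cluster = sub.iloc[s:e]
            best = cluster.sort_values(
                ["count", "peak_cM"], ascending=[False, True]
            ).iloc[0]
            marker = best["nearest_marker"]
            if gmap is not None:
                marker = gmap.nearest_marker(chrom, best["peak_cM"])
            rows.append(
                {
                    "chromosome": chrom,
                    "peak_cM": float(best["peak_cM"]),
                    "nearest_marker": marker,
                    "count": int(best["count"]),
                    "n_members": len(cluster),
                }
            )
    return pd.DataFrame(rows)


def hotspot_threshold_by_trait_permutation(
    traits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    window: float = 10.0,
    n_perm: int = 20,
    alpha: float = 0.05,
    scan_config=None,
    rng=None,
) -> int:
    """Alternative hotspot null: permute line labels of the trait table and
    re-run the whole panel scan each round.

    Far slower than :func:`hotspot_permutation_threshold` (each permutation
    is a full scan), but it preserves the trait-trait correlation structure
    instead of assuming QTLs scatter independently.  Intended for small
    n_perm sanity checks of the faster placement null.
    """
    from .mapping import build_scan_grid
    from .scan import ScanConfig, line_means, scan_value_matrix

    rng = ensure_rng(rng)
    scan_config = scan_config or ScanConfig()
    grid = build_scan_grid(gmap, scan_config.step)
    values = line_means(traits, "combined").reindex(index=genotypes.line_ids)
    maxima = np.empty(n_perm, dtype=int)
    for p in range(n_perm):
        perm = rng.permutation(len(values))
        shuffled = pd.DataFrame(
            values.to_numpy()[perm], index=values.index, columns=values.columns
        )
        qtls, _ = scan_value_matrix(
            shuffled, genotypes, gmap, scan_config,
            seed=int(rng.integers(2**31)), grid=grid,
        )
        counts = window_counts(qtls, grid, window)
        maxima[p] = int(counts["count"].max()) if len(counts) else 0
    k = int(np.ceil((1.0 - alpha) * n_perm)) - 1
    return int(np.sort(maxima)[k])


# ---------------------------------------------------------------------------
# marker linear models over the full trait panel


def _marker_codes(
    genotypes: GenotypeMatrix, markers, gmap: GeneticMap | None
) -> np.ndarray:
    """+-1 genotype coding per line for the named markers; missing calls are
    replaced by their conditional expectation 2 P(A) - 1 from flanking
    markers when a map is supplied (0 otherwise)."""
    if gmap is None:
        raise ValueError("a genetic map is required to code markers")
    from .mapping import conditional_genotype_prob

    idx = [gmap.marker_index(m) for m in markers]
    calls = genotypes.calls[:, idx].astype(float)
    x = np.where(calls == A, 1.0, -1.0)
    miss = calls == MISSING
    if miss.any():
        sub = gmap.table.iloc[idx]
        for i, j in zip(*np.nonzero(miss)):
            row = sub.iloc[j]
            p = conditional_genotype_prob(
                gmap, genotypes.calls[i], row["chromosome"], row["position_cm"]
            )
            x[i, j] = 2.0 * p - 1.0
    return x


def _line_exp_means(traits: pd.DataFrame, line_ids) -> tuple:
    """(Y, exp_sign, line_index) for per-(line, experiment) trait means."""
    cell = traits.pivot_table(
        index=["line", "experiment"], columns="trait", values="value", aggfunc="mean"
    )
    cell = cell.loc[[ix for ix in cell.index if ix[0] in set(line_ids)]]
    lines = cell.index.get_level_values("line")
    exps = cell.index.get_level_values("experiment").to_numpy()
    line_pos = {l: i for i, l in enumerate(line_ids)}
    rows = np.array([line_pos[l] for l in lines])
    sign = np.where(exps == exps.min(), -1.0, 1.0)
    return cell, sign, rows


def _ols_pvalues(X: np.ndarray, Y: np.ndarray) -> tuple:
    """Columnwise OLS of every trait in Y on X; returns (p, B, sigma2).

    p[t, j] is the two-sided t-test p-value of coefficient j for trait t.
    """
    n, k = X.shape
    XtX = X.T @ X
    XtXinv = np.linalg.pinv(XtX)
    B = XtXinv @ (X.T @ Y)
    resid = Y - X @ B
    dfe = n - np.linalg.matrix_rank(XtX)
    sigma2 = np.einsum("ij,ij->j", resid, resid) / max(dfe, 1)
    se = np.sqrt(np.outer(np.diag(XtXinv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, B / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tval), max(dfe, 1))
    return p.T, B, sigma2


def _marker_model_counts(
    Y: np.ndarray,
    marker_x: np.ndarray,
    rows: np.ndarray,
    exp_sign: np.ndarray,
    interactions: bool,
    fdr: float,
) -> tuple:
    """Counts of FDR-significant traits per marker term (and interaction)."""
    n_mark = marker_x.shape[1]
    Xm = marker_x[rows]
    cols = [np.ones(len(rows)), exp_sign] + [Xm[:, j] for j in range(n_mark)]
    if interactions:
        cols += [Xm[:, j] * exp_sign for j in range(n_mark)]
    X = np.column_stack(cols)
    finite = np.isfinite(Y)
    Yf = np.where(finite, Y, 0.0)
    # traits with missing cells: fall back to per-trait masked fits is slow;
    # mean-impute instead (panel means are near-complete in this design)
    col_mean = np.nanmean(np.where(finite, Y, np.nan), axis=0)
    Yf = np.where(finite, Y, col_mean)
    p, _, _ = _ols_pvalues(X, Yf)
    tested = p[:, 1:]  # experiment + markers (+ interactions)
    q = np.vstack([fdr_adjust(row) for row in tested])
    main_q = q[:, 1 : 1 + n_mark]
    main_counts = (main_q < fdr).sum(axis=0)
    if interactions:
        int_q = q[:, 1 + n_mark :]
        int_counts = (int_q < fdr).sum(axis=0)
    else:
        int_counts = np.zeros(n_mark, dtype=int)
    return main_counts, int_counts


def validate_hotspots_marker_model(
    traits: pd.DataFrame,
    hotspot_markers,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    n_perm: int = 500,
    alpha: float = 0.05,
    fdr: float = 0.05,
    rng=None,
) -> pd.DataFrame:
    """Validate hotspots against the full panel with a joint marker model.

    Observed: per marker, the number of traits significant (BH-FDR < fdr
    within each trait's model) in trait ~ sum(markers) + experiment.  Null:
    the same counts with line labels of the genotype rows permuted.  A
    hotspot is validated when its observed count strictly exceeds the
    (1 - alpha) null quantile.
    """
    rng = ensure_rng(rng)
    markers = list(hotspot_markers)
    x = _marker_codes(genotypes, markers, gmap)
    cell, sign, rows = _line_exp_means(traits, genotypes.line_ids)
    Y = cell.to_numpy(dtype=float)
    obs_main, _ = _marker_model_counts(Y, x, rows, sign, False, fdr)
    null = np.empty((n_perm, len(markers)), dtype=int)
    n_lines = genotypes.n_lines
    for p in range(n_perm):
        perm = rng.permutation(n_lines)
        m, _ = _marker_model_counts(Y, x[perm], rows, sign, False, fdr)
        null[p] = m
    k = int(np.ceil((1.0 - alpha) * n_perm)) - 1
    null_q = np.sort(null, axis=0)[k]
    return pd.DataFrame(
        {
            "marker": markers,
            "n_significant": obs_main,
            "null_q": null_q,
            "validated": obs_main > null_q,
        }
    )


def marker_by_experiment_model(
    traits: pd.DataFrame,
    hotspot_markers,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-marker counts of traits significant for the genotype main effect
    and for the marker x experiment interaction, from
    trait ~ sum(markers) + experiment + sum(marker x experiment)."""
    markers = list(hotspot_markers)
    x = _marker_codes(genotypes, markers, gmap)
    cell, sign, rows = _line_exp_means(traits, genotypes.line_ids)
    Y = cell.to_numpy(dtype=float)
    n_main, n_gxe = _marker_model_counts(Y, x, rows, sign, True, fdr)
    return pd.DataFrame(
        {
            "marker": markers,
            "n_main": n_main,
            "n_gxe": n_gxe,
            "main_dominant": n_main > n_gxe,
        }
    )


def hotspot_effect_table(
    traits: pd.DataFrame,
    hotspot_marker: str,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Standardized allelic effect of one hotspot marker on every trait.

    effect = (mean_Lemont - mean_Teqing) / grand mean; positive means the
    Lemont (A) allele raises the trait, i.e. the Teqing allele raises it
    when the effect is negative (the network-figure convention).  q-values
    are BH-adjusted across traits.
    """
    from .scan import standardized_additive_effect

    x = _marker_codes(genotypes, [hotspot_marker], gmap)[:, 0]
    values = line_means(traits, "combined").reindex(index=genotypes.line_ids)
    p_at = (x + 1.0) / 2.0
    rows = []
    for trait in values.columns:
        y = values[trait].to_numpy(dtype=float)
        try:
            effect, se = standardized_additive_effect(y, p_at)
        except ValueError:
            rows.append((trait, hotspot_marker, np.nan, np.nan, np.nan))
            continue
        mask = np.isfinite(y) & (p_at != 0.5)
        a = y[mask][p_at[mask] > 0.5]
        b = y[mask][p_at[mask] < 0.5]
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append((trait, hotspot_marker, effect, se, p))
    out = pd.DataFrame(
        rows, columns=["trait", "marker", "effect", "effect_se", "p"]
    )
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = fdr_adjust(out.loc[ok, "p"].to_numpy())
    out["qvalue"] = q
    out["direction"] = np.select(
        [out["effect"] > 0, out["effect"] < 0],
        ["lemont_up", "teqing_up"],
        default="none",
    )
    out["significant"] = out["qvalue"] < fdr
    return out.drop(columns=["p"])
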