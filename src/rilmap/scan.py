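"""Haley-Knott interval mapping, permutation thresholds and multi-QTL models.

At every grid position the trait is regressed on the conditional probability
of carrying the A allele (Haley-Knott regression); the LOD score is

    LOD(p) = (n / 2) * log10(RSS0 / RSS1(p))

with RSS0 from the intercept-only fit.  With complete genotypes the
probabilities at marker positions are exactly 0/1, so the scan reduces to
two-group marker regression there — an identity exploited by the test suite.

Genome-wide significance uses the permutation null of the maximum LOD
(trait values shuffled across lines); multi-QTL models are built by forward
selection / backward elimination on a penalized LOD score with the penalty
taken from that permutation threshold.  Support intervals are 1.5-LOD drops.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import ensure_rng, substream
from .mapping import (
    GeneticMap,
    GenotypeMatrix,
    ScanGrid,
    build_scan_grid,
    genotype_probabilities,
)

logger = logging.getLogger("rilmap")

LOD_CAP = 300.0  # guards log10 of an underflowing residual SS
_EPS = 1e-12


@dataclass
class LODProfile:
    """Scan result on the full grid: LOD, fitted line, residual SS."""

    grid: ScanGrid
    lod: np.ndarray
    intercept: np.ndarray
    slope: np.ndarray
    rss: np.ndarray
    rss0: float
    n: int

    def class_means(self, j: int) -> tuple:
        """Fitted (A-class, B-class) trait means at grid position ``j``."""
        return (
            float(self.intercept[j] + self.slope[j]),
            float(self.intercept[j]),
        )

    def peak(self) -> int:
        """Index of the maximum LOD (ties broken toward lower index/cM)."""
        return int(np.argmax(self.lod))


def _lod_from_r2(r2: np.ndarray, n: int) -> np.ndarray:
    r2 = np.clip(r2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        lod = -(n / 2.0) * np.log10(1.0 - r2)
    return np.minimum(lod, LOD_CAP)


def hk_scan(
    y, probs: np.ndarray, grid: ScanGrid | None = None, min_lines: int = 10
) -> LODProfile:
    """Haley-Knott regression of a trait on P(A) at every grid position.

    Missing trait values are dropped; requires >= ``min_lines`` informative
    lines (default 10; tiny hand-checkable designs may lower it).  A
    zero-variance trait yields an all-zero profile with a warning.
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    n = int(mask.sum())
    if n < max(min_lines, 3):
        raise ValueError(f"need >= {min_lines} lines with non-missing trait, got {n}")
    yv = y[mask]
    P = probs[mask]
    ybar = yv.mean()
    yc = yv - ybar
    rss0 = float(yc @ yc)
    m = P.shape[1]
    if rss0 <= 0:
        warnings.warn("zero-variance trait: all-zero LOD profile")
        return LODProfile(
            grid=grid,
            lod=np.zeros(m),
            intercept=np.full(m, ybar),
            slope=np.zeros(m),
            rss=np.zeros(m),
            rss0=0.0,
            n=n,
        )
    pbar = P.mean(axis=0)
    Pc = P - pbar
    sxx = np.einsum("ij,ij->j", Pc, Pc)
    sxy = yc @ Pc
    ok = sxx > _EPS
    slope = np.zeros(m)
    slope[ok] = sxy[ok] / sxx[ok]
    r2 = np.zeros(m)
    r2[ok] = sxy[ok] ** 2 / (sxx[ok] * rss0)
    lod = _lod_from_r2(r2, n)
    rss = rss0 * (1.0 - np.clip(r2, 0.0, 1.0))
    intercept = ybar - slope * pbar
    return LODProfile(
        grid=grid, lod=lod, intercept=intercept, slope=slope, rss=rss, rss0=rss0, n=n
    )


def _normalized_columns(P: np.ndarray) -> np.ndarray:
    Pc = P - P.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", Pc, Pc))
    out = np.zeros_like(Pc)
    ok = norms > _EPS
    out[:, ok] = Pc[:, ok] / norms[ok]
    return out


def permutation_max_lods(y, probs: np.ndarray, n_perm: int, rng=None) -> np.ndarray:
    """Genome-wide maximum LOD for ``n_perm`` trait permutations."""
    rng = ensure_rng(rng)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    yv = y[mask]
    n = yv.size
    yc = yv - yv.mean()
    nrm = np.sqrt(yc @ yc)
    if nrm <= 0:
        return np.zeros(n_perm)
    yn = yc / nrm
    Pn = _normalized_columns(probs[mask])
    idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    R = yn[idx] @ Pn
    r2max = np.max(R * R, axis=1)
    return _lod_from_r2(r2max, n)


def permutation_threshold(
    y, probs: np.ndarray, n_perm: int = 1000, alpha: float = 0.05, rng=None
) -> float:
    """Genome-wide LOD threshold: (1-alpha) order statistic of the null max.

    Requires n_perm >= 1/alpha (e.g. >= 20 at alpha = 0.05).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_perm < 1.0 / alpha:
        raise ValueError(f"n_perm={n_perm} too small for alpha={alpha}")
    maxlod = np.sort(permutation_max_lods(y, probs, n_perm, rng))
    k = int(np.ceil((1.0 - alpha) * n_perm)) - 1
    return float(maxlod[k])


# ---------------------------------------------------------------------------
# multi-QTL models


@dataclass
class MultiQTLModel:
    """Stepwise model: grid indices of QTLs plus interaction pairs."""

    positions: list = field(default_factory=list)  # grid indices
    interactions: list = field(default_factory=list)  # (grid_i, grid_j)
    lod: float = 0.0
    penalized_lod: float = 0.0
    drop_one_lod: dict = field(default_factory=dict)  # grid index -> LOD
    rss: float = 0.0
    rss0: float = 0.0
    n: int = 0

    def __post_init__(self):
        for i, j in self.interactions:
            if i not in self.positions or j not in self.positions:
                raise ValueError("interaction loci must be in the QTL set")


def _design(yn: int, P: np.ndarray, positions, interactions) -> np.ndarray:
    cols = [np.ones(P.shape[0])]
    cols += [P[:, i] for i in positions]
    cols += [P[:, i] * P[:, j] for i, j in interactions]
    return np.column_stack(cols)


def _model_rss(y: np.ndarray, D: np.ndarray) -> tuple:
    """(rss, Q) for the least-squares fit of y on D (economic QR)."""
    Q, _ = np.linalg.qr(D)
    resid = y - Q @ (Q.T @ y)
    return float(resid @ resid), Q


def _model_lod(rss: float, rss0: float, n: int) -> float:
    if rss <= rss0 * 10 ** (-2 * LOD_CAP / n):
        return LOD_CAP
    return min(LOD_CAP, (n / 2.0) * np.log10(rss0 / rss))


def _penalized(lod, n_qtl, n_int, main_penalty, int_penalty):
    return lod - main_penalty * n_qtl - int_penalty * n_int


def _single_addition_gains(ry, rssc, Pres, n):
    """LOD gain of adding each residualized column to the current model."""
    norms2 = np.einsum("ij,ij->j", Pres, Pres)
    sxy = ry @ Pres
    ok = norms2 > _EPS * max(1.0, float(np.max(norms2, initial=0.0)))
    r2 = np.zeros(Pres.shape[1])
    r2[ok] = sxy[ok] ** 2 / (norms2[ok] * rssc)
    return _lod_from_r2(r2, n)


def _pair_scan_best(yr, rssc, Q, X_raw, n):
    """Best (gain, a, b) over all column pairs of X_raw for adding the two
    loci plus their product jointly, residualized against Q."""
    m = X_raw.shape[1]
    Xr = X_raw - Q @ (Q.T @ X_raw)
    best = (-np.inf, -1, -1)
    ridge = 1e-9
    for a in range(m - 1):
        xa = X_raw[:, a]
        XB = X_raw[:, a + 1 :]
        Pd = xa[:, None] * XB
        Pdr = Pd - Q @ (Q.T @ Pd)
        xar = Xr[:, a]
        XBr = Xr[:, a + 1 :]
        g11 = float(xar @ xar)
        g12 = xar @ XBr
        g13 = xar @ Pdr
        g22 = np.einsum("ij,ij->j", XBr, XBr)
        g23 = np.einsum("ij,ij->j", XBr, Pdr)
        g33 = np.einsum("ij,ij->j", Pdr, Pdr)
        b1 = float(xar @ yr)
        b2 = yr @ XBr
        b3 = yr @ Pdr
        J = XBr.shape[1]
        G = np.empty((J, 3, 3))
        G[:, 0, 0] = g11 + ridge
        G[:, 0, 1] = G[:, 1, 0] = g12
        G[:, 0, 2] = G[:, 2, 0] = g13
        G[:, 1, 1] = g22 + ridge
        G[:, 1, 2] = G[:, 2, 1] = g23
        G[:, 2, 2] = g33 + ridge
        rhs = np.empty((J, 3))
        rhs[:, 0] = b1
        rhs[:, 1] = b2
        rhs[:, 2] = b3
        try:
            sol = np.linalg.solve(G, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            continue
        red = np.einsum("ij,ij->i", rhs, sol)
        r2 = np.clip(red / rssc, 0.0, 1.0 - 1e-15)
        gains = _lod_from_r2(r2, n)
        jbest = int(np.argmax(gains))
        if gains[jbest] > best[0]:
            best = (float(gains[jbest]), a, a + 1 + jbest)
    return best


def fit_multiqtl_stepwise(
    y,
    probs: np.ndarray,
    grid: ScanGrid,
    main_penalty: float,
    int_penalty: float | None = None,
    max_qtl: int = 10,
    pair_search: bool = False,
) -> MultiQTLModel:
    """Forward selection / backward elimination on the penalized LOD.

    Score = model LOD - main_penalty * n_QTL - int_penalty * n_interactions.
    Forward candidates are every grid position, interaction terms among
    already-selected loci, and (``pair_search``) the best two-marker set
    entering jointly with its interaction (how a purely epistatic pair with
    no marginal effects can enter).  An empty model is a valid result.
    """
    if int_penalty is None:
        int_penalty = 2.0 * main_penalty
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    yv = y[mask]
    P = probs[mask]
    n = yv.size
    yc = yv - yv.mean()
    rss0 = float(yc @ yc)
    model = MultiQTLModel(rss0=rss0, n=n)
    if rss0 <= 0:
        return model
    marker_cols = grid.marker_positions() if pair_search else None

    def refit(positions, interactions):
        D = _design(n, P, positions, interactions)
        rss, Q = _model_rss(yv, D)
        lod = _model_lod(rss, rss0, n)
        return rss, Q, lod

    positions: list = []
    interactions: list = []
    rss, Q, lod = refit(positions, interactions)
    plod = 0.0
    # forward
    while len(positions) < max_qtl:
        ry = yv - Q @ (Q.T @ yv)
        rssc = float(ry @ ry)
        if rssc <= 0:
            break
        moves = []
        Pres = P - Q @ (Q.T @ P)
        gains = _single_addition_gains(ry, rssc, Pres, n)
        gains_model = lod + gains  # LOD is additive over nested RSS ratios
        j = int(np.argmax(gains))
        moves.append(("add", j, gains_model[j] - main_penalty * (len(positions) + 1)
                      - int_penalty * len(interactions)))
        have = set(map(tuple, interactions))
        if len(positions) >= 2:
            cand = [
                (i, k)
                for ii, i in enumerate(positions)
                for k in positions[ii + 1 :]
                if (i, k) not in have and (k, i) not in have
            ]
            if cand:
                C = np.column_stack([P[:, i] * P[:, k] for i, k in cand])
                Cres = C - Q @ (Q.T @ C)
                g = _single_addition_gains(ry, rssc, Cres, n)
                jj = int(np.argmax(g))
                moves.append(
                    ("addint", cand[jj], lod + g[jj] - main_penalty * len(positions)
                     - int_penalty * (len(interactions) + 1))
                )
        if pair_search and len(positions) + 2 <= max_qtl:
            gain, a, b = _pair_scan_best(ry, rssc, Q, P[:, marker_cols], n)
            if a >= 0:
                moves.append(
                    ("addpair", (int(marker_cols[a]), int(marker_cols[b])),
                     lod + gain - main_penalty * (len(positions) + 2)
                     - int_penalty * (len(interactions) + 1))
                )
        best = max(moves, key=lambda m: m[2])
        if best[2] <= plod + 1e-9:
            break
        kind, payload, new_plod = best
        if kind == "add":
            positions = positions + [payload]
        elif kind == "addint":
            interactions = interactions + [payload]
        else:
            a, b = payload
            if a in positions or b in positions:
                break  # already represented; no productive pair move
            positions = positions + [a, b]
            interactions = interactions + [(a, b)]
        rss, Q, lod = refit(positions, interactions)
        plod = _penalized(lod, len(positions), len(interactions), main_penalty, int_penalty)
    # backward
    improved = True
    while improved and (positions or interactions):
        improved = False
        candidates = []
        for q in positions:
            keep_pos = [p for p in positions if p != q]
            keep_int = [(i, k) for i, k in interactions if q not in (i, k)]
            candidates.append((keep_pos, keep_int))
        for idx in range(len(interactions)):
            keep_int = interactions[:idx] + interactions[idx + 1 :]
            candidates.append((list(positions), keep_int))
        best_drop = None
        for keep_pos, keep_int in candidates:
            r, Qd, l = refit(keep_pos, keep_int)
            pl = _penalized(l, len(keep_pos), len(keep_int), main_penalty, int_penalty)
            if pl > plod + 1e-9 and (best_drop is None or pl > best_drop[0]):
                best_drop = (pl, keep_pos, keep_int)
        if best_drop is not None:
            plod, positions, interactions = best_drop
            rss, Q, lod = refit(positions, interactions)
            plod = _penalized(lod, len(positions), len(interactions), main_penalty, int_penalty)
            improved = True
    model.positions = sorted(positions)
    model.interactions = [tuple(sorted(p)) for p in interactions]
    model.lod = lod
    model.penalized_lod = plod
    model.rss = rss
    return model


def drop_one_refine(
    model: MultiQTLModel,
    y,
    probs: np.ndarray,
    threshold: float = 0.0,
) -> MultiQTLModel:
    """Per-QTL LOD from drop-one refits; prune QTLs below ``threshold``.

    The per-QTL LOD is the full-model LOD minus the LOD of the model with
    that QTL (and its interactions) removed; pruning iterates to stability.
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    yv = y[mask]
    P = probs[mask]
    n = yv.size
    yc = yv - yv.mean()
    rss0 = float(yc @ yc)
    # an exact duplicate position adds nothing: keep one copy
    positions = list(dict.fromkeys(model.positions))
    interactions = list(dict.fromkeys(tuple(sorted(p)) for p in model.interactions))

    def lod_of(pos, ints):
        D = _design(n, P, pos, ints)
        rss, _ = _model_rss(yv, D)
        return _model_lod(rss, rss0, n), rss

    while True:
        if not positions:
            break
        full_lod, full_rss = lod_of(positions, interactions)
        drops = {}
        for q in positions:
            keep_pos = [p for p in positions if p != q]
            keep_int = [(i, k) for i, k in interactions if q not in (i, k)]
            sub_lod, _ = lod_of(keep_pos, keep_int)
            drops[q] = full_lod - sub_lod
        worst = min(drops, key=lambda q: (drops[q], -q))
        if drops[worst] < threshold:
            positions = [p for p in positions if p != worst]
            interactions = [(i, k) for i, k in interactions if worst not in (i, k)]
            continue
        model.positions = positions
        model.interactions = interactions
        model.drop_one_lod = drops
        model.lod, model.rss = full_lod, full_rss
        model.rss0, model.n = rss0, n
        return model
    model.positions = []
    model.interactions = []
    model.drop_one_lod = {}
    model.lod, model.rss = 0.0, rss0
    model.rss0, model.n = rss0, n
    return model


def qtl_profile(
    model: MultiQTLModel, q: int, y, probs: np.ndarray, grid: ScanGrid
) -> tuple:
    """Profile LOD for QTL ``q`` along its chromosome, others held fixed.

    Returns (chrom_slice, lods) where lods[j] = LOD(model with q moved to
    position j) - LOD(model without q).  At the selected position this is
    the drop-one LOD.
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    yv = y[mask]
    P = probs[mask]
    n = yv.size
    chrom = grid.chromosome[q]
    sl = grid.chrom_slice(chrom)
    others = [p for p in model.positions if p != q]
    partner_of = [k if i == q else i for i, k in model.interactions if q in (i, k)]
    other_ints = [(i, k) for i, k in model.interactions if q not in (i, k)]
    D0 = _design(n, P, others, other_ints)
    rss_wo, Q0 = _model_rss(yv, D0)
    ry = yv - Q0 @ (Q0.T @ yv)
    rssc = float(ry @ ry)
    idx = np.arange(sl.start, sl.stop)
    if rssc <= 0:
        return sl, np.zeros(len(idx))
    if not partner_of:
        Pres = P[:, idx] - Q0 @ (Q0.T @ P[:, idx])
        lods = _single_addition_gains(ry, rssc, Pres, n)
    else:
        lods = np.empty(len(idx))
        for jj, j in enumerate(idx):
            cols = [P[:, j]] + [P[:, j] * P[:, s] for s in partner_of]
            C = np.column_stack(cols)
            Cres = C - Q0 @ (Q0.T @ C)
            rss_j, _ = _model_rss(ry, Cres)
            r2 = max(0.0, 1.0 - rss_j / rssc)
            lods[jj] = _lod_from_r2(np.asarray([r2]), n)[0]
    return sl, lods


def lod_support_interval(
    positions: np.ndarray, lods: np.ndarray, peak_idx: int, drop: float = 1.5
) -> tuple:
    """1.5-LOD support interval on one chromosome's profile.

    Returns (low_cm, high_cm, low_idx, high_idx): the maximal contiguous run
    around the peak with LOD >= peak - drop, clipped at chromosome ends.
    """
    cutoff = lods[peak_idx] - drop
    lo = peak_idx
    while lo > 0 and lods[lo - 1] >= cutoff - 1e-12:
        lo -= 1
    hi = peak_idx
    while hi < len(lods) - 1 and lods[hi + 1] >= cutoff - 1e-12:
        hi += 1
    return float(positions[lo]), float(positions[hi]), lo, hi


def standardized_additive_effect(y, prob_at_peak) -> tuple:
    """Dimensionless additive effect (mean_A - mean_B) / grand mean, with SE.

    Lines are classified A/B by their genotype probability at the peak
    (> 0.5 vs < 0.5; exactly 0.5 is uninformative and excluded).  Positive
    sign means the Lemont (A) allele raises the trait.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(prob_at_peak, dtype=float)
    mask = np.isfinite(y)
    y, p = y[mask], p[mask]
    in_a = p > 0.5
    in_b = p < 0.5
    if not in_a.any() or not in_b.any():
        raise ValueError("both genotype classes must be represented")
    grand = y.mean()
    scale = np.mean(np.abs(y)) + _EPS
    if abs(grand) < 1e-9 * scale:
        raise ValueError("grand mean ~ 0: standardized effect undefined")
    ya, yb = y[in_a], y[in_b]
    effect = (ya.mean() - yb.mean()) / grand
    va = ya.var(ddof=1) if ya.size > 1 else 0.0
    vb = yb.var(ddof=1) if yb.size > 1 else 0.0
    se = np.sqrt(va / ya.size + vb / yb.size) / abs(grand)
    return float(effect), float(se)


# ---------------------------------------------------------------------------
# panel scanning


@dataclass
class ScanConfig:
    """Settings for panel scans; defaults follow the study's conventions
    (1000 permutations at alpha 0.05, 1 cM pseudomarker step, 1.5-LOD
    support intervals, at most 10 QTLs per trait)."""

    step: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    max_qtl: int = 10
    pair_search: bool = False
    interaction_penalty: float | None = None  # default: 2 x main threshold
    lod_drop: float = 1.5
    min_lines: int = 10
    map_function: str = "haldane"


QTL_TABLE_COLUMNS = [
    "trait",
    "dataset",
    "chromosome",
    "position_cM",
    "lod",
    "scan_lod",
    "effect",
    "effect_se",
    "pve",
    "ci_low_cM",
    "ci_high_cM",
    "ci_low_marker",
    "ci_high_marker",
]

INTERACTION_TABLE_COLUMNS = [
    "trait",
    "dataset",
    "chromosome_1",
    "position_1_cM",
    "chromosome_2",
    "position_2_cM",
]


def line_means(traits: pd.DataFrame, dataset: str = "combined") -> pd.DataFrame:
    """Per-line trait means for a dataset selector.

    combined = mean over all replicates; exp1/exp2 = mean over that
    experiment's replicates; missing replicates tolerated.
    """
    if dataset == "combined":
        sub = traits
    elif dataset in ("exp1", "exp2"):
        sub = traits[traits["experiment"] == int(dataset[-1])]
    else:
        raise ValueError(f"unknown dataset selector: {dataset!r}")
    return sub.pivot_table(index="line", columns="trait", values="value", aggfunc="mean")


def _flanking_markers(gmap: GeneticMap, chrom, lo_cm, hi_cm) -> tuple:
    sub = gmap.markers_on(chrom)
    pos = sub["position_cm"].to_numpy()
    names = sub["marker"].to_numpy()
    below = np.flatnonzero(pos <= lo_cm + 1e-9)
    above = np.flatnonzero(pos >= hi_cm - 1e-9)
    lo_m = names[below[-1]] if below.size else names[0]
    hi_m = names[above[0]] if above.size else names[-1]
    return str(lo_m), str(hi_m)


def scan_value_matrix(
    values: pd.DataFrame,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    config: ScanConfig | None = None,
    seed: int = 0,
    dataset: str = "combined",
    probs: np.ndarray | None = None,
    grid: ScanGrid | None = None,
) -> tuple:
    """Scan every column of a lines x traits value matrix.

    Per trait: permutation threshold, Haley-Knott scan, stepwise multi-QTL
    model with drop-one refinement, profile-based 1.5-LOD intervals and
    standardized effects.  Returns (qtl_table, interaction_table).  The
    per-trait permutation stream is keyed on the trait's values, so an
    identical trait always yields identical results.
    """
    config = config or ScanConfig()
    if grid is None:
        grid = build_scan_grid(gmap, config.step)
    if probs is None:
        probs = genotype_probabilities(gmap, genotypes, grid, config.map_function)
    values = values.reindex(index=genotypes.line_ids)
    qtl_rows, int_rows = [], []
    chrom_arr = grid.chromosome
    pos_arr = grid.positions
    for trait in values.columns:
        y = values[trait].to_numpy(dtype=float)
        n_obs = int(np.isfinite(y).sum())
        if n_obs < config.min_lines:
            logger.info("trait %s skipped: %d informative lines", trait, n_obs)
            continue
        ykey = zlib.crc32(y[np.isfinite(y)].tobytes())
        rng = substream(seed, "scan", dataset, ykey)
        threshold = permutation_threshold(y, probs, config.n_perm, config.alpha, rng)
        profile = hk_scan(y, probs, grid)
        if profile.lod.max() < threshold and not config.pair_search:
            continue
        model = fit_multiqtl_stepwise(
            y,
            probs,
            grid,
            main_penalty=threshold,
            int_penalty=config.interaction_penalty,
            max_qtl=config.max_qtl,
            pair_search=config.pair_search,
        )
        model = drop_one_refine(model, y, probs, threshold)
        for q in model.positions:
            sl, plods = qtl_profile(model, q, y, probs, grid)
            local = np.arange(sl.start, sl.stop)
            peak_local = int(np.flatnonzero(local == q)[0])
            lo_cm, hi_cm, _, _ = lod_support_interval(
                pos_arr[sl], plods, peak_local, config.lod_drop
            )
            chrom = chrom_arr[q]
            lo_marker, hi_marker = _flanking_markers(gmap, chrom, lo_cm, hi_cm)
            try:
                effect, se = standardized_additive_effect(y, probs[:, q])
            except ValueError:
                effect, se = np.nan, np.nan
            pve = _pve_from_drop(model, q)
            qtl_rows.append(
                (
                    trait,
                    dataset,
                    chrom,
                    float(pos_arr[q]),
                    float(model.drop_one_lod[q]),
                    float(profile.lod[q]),
                    effect,
                    se,
                    pve,
                    lo_cm,
                    hi_cm,
                    lo_marker,
                    hi_marker,
                )
            )
        for i, j in model.interactions:
            int_rows.append(
                (
                    trait,
                    dataset,
                    chrom_arr[i],
                    float(pos_arr[i]),
                    chrom_arr[j],
                    float(pos_arr[j]),
                )
            )
    qtl_df = pd.DataFrame(qtl_rows, columns=QTL_TABLE_COLUMNS)
    int_df = pd.DataFrame(int_rows, columns=INTERACTION_TABLE_COLUMNS)
    return qtl_df, int_df


def _pve_from_drop(model: MultiQTLModel, q: int) -> float:
    """Percent variance explained by QTL q: drop-one RSS gain over total SS."""
    if model.rss0 <= 0:
        return 0.0
    dlod = model.drop_one_lod[q]
    rss_without = model.rss * 10 ** (2.0 * dlod / model.n)
    pve = 100.0 * (rss_without - model.rss) / model.rss0
    return float(np.clip(pve, 0.0, 100.0))


def scan_trait_panel(
    traits: pd.DataFrame,
    dataset: str,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    config: ScanConfig | None = None,
    seed: int = 0,
) -> tuple:
    """Scan a replicated trait table: per-line means for the chosen dataset
    (combined / exp1 / exp2), then the full per-trait scan pipeline."""
    values = line_means(traits, dataset)
    return scan_value_matrix(
        values, genotypes, gmap, config=config, seed=seed, dataset=dataset
    )
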