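"""Synthetic RIL genotypes and replicated multi-trait panels.

The generator emulates the design of the Lemont x Teqing rice RIL study that
this package analyses: 280 lines genotyped at 175 RFLP markers on 12
chromosomes, grown in two independent experiments with two randomized
complete blocks each (four replicates per line), and a few hundred positive
metabolite-like traits with polygenic additive effects, pairwise epistasis,
experiment and genotype-by-experiment effects, and (optionally) a
genotype-dependent residual standard deviation that creates heritable
stochastic variation (a "variance QTL").

Simulation starts at the normalized-abundance table; no attempt is made to
emulate GC-TOF spectra, retention times or instrument drift.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import ensure_rng
from .mapping import (
    A,
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    MAP_FUNCTIONS,
    ril_recfrac,
)

# (chromosome, marker count, genetic length in cM); counts sum to 175,
# lengths follow published rice genetic-map lengths chromosome by chromosome.
_TEMPLATE_CHROMS = [
    (1, 20, 181.0),
    (2, 18, 157.0),
    (3, 17, 166.0),
    (4, 16, 129.0),
    (5, 15, 122.0),
    (6, 14, 125.0),
    (7, 14, 118.0),
    (8, 13, 121.0),
    (9, 12, 93.0),
    (10, 11, 83.0),
    (11, 13, 117.0),
    (12, 12, 109.0),
]

_TEMPLATE_SEED = 30143  # fixed: the template is deterministic
_GAP_CHROMS = {3: 40.0, 9: 30.0}  # deliberate map gaps (cM), mid-chromosome


def lt_ril_template() -> GeneticMap:
    """Deterministic 12-chromosome, 175-marker map with uneven spacing.

    Chromosomes 3 and 9 carry one deliberately large gap, mirroring the gaps
    in the source population's RFLP map.
    """
    rng = np.random.default_rng(_TEMPLATE_SEED)
    rows = []
    for chrom, n_mark, length in _TEMPLATE_CHROMS:
        w = rng.gamma(1.6, 1.0, size=n_mark - 1)
        gap_extra = _GAP_CHROMS.get(chrom, 0.0)
        pos = np.concatenate([[0.0], np.cumsum(w)])
        pos = pos / pos[-1] * (length - gap_extra)
        if gap_extra:
            mid = (n_mark - 1) // 2
            pos[mid + 1 :] += gap_extra
        for i, p in enumerate(pos):
            rows.append((f"M{chrom:02d}.{i + 1:02d}", chrom, round(float(p), 2)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))


def simulate_ril_genotypes(
    gmap: GeneticMap,
    n_lines: int,
    rng=None,
    map_function: str = "haldane",
) -> GenotypeMatrix:
    """Simulate fully-genotyped RIL lines as two-state Markov chains.

    Each chromosome starts A or B with probability 1/2 and switches between
    adjacent markers with probability ``ril_recfrac(mapfun(d))``; lines are
    independent.  Use :func:`mask_missing` to add missing calls afterwards.
    """
    if n_lines < 2:
        raise ValueError("need at least two lines")
    rng = ensure_rng(rng)
    mapfun = MAP_FUNCTIONS[map_function]
    calls = np.empty((n_lines, gmap.n_markers), dtype=np.int8)
    for chrom in gmap.chromosomes:
        midx = gmap.chrom_marker_indices(chrom)
        pos = gmap.table["position_cm"].to_numpy()[midx]
        R = ril_recfrac(mapfun(np.diff(pos)))
        state = (rng.random(n_lines) < 0.5).astype(np.int8)
        switch = rng.random((n_lines, len(midx) - 1)) < R
        cum = np.cumsum(switch.astype(np.int8), axis=1) % 2
        geno = np.column_stack([state, state[:, None] ^ cum])
        calls[:, midx] = geno
    return GenotypeMatrix([f"RIL{i + 1:03d}" for i in range(n_lines)], calls)


def mask_missing(genotypes: GenotypeMatrix, rate: float, rng=None) -> GenotypeMatrix:
    """Return a copy with calls set missing independently at ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("missing rate must be in [0, 1)")
    rng = ensure_rng(rng)
    calls = genotypes.calls.copy()
    mask = rng.random(calls.shape) < rate
    # keep the invariant that no marker is entirely missing
    full = mask.all(axis=0)
    mask[0, full] = False
    calls[mask] = MISSING
    return GenotypeMatrix(genotypes.line_ids, calls, genotypes.parents)


@dataclass
class StudyDesign:
    """Replication structure: two experiments x two blocks by default."""

    n_lines: int
    n_experiments: int = 2
    n_blocks: int = 2
    seed: int | None = None

    @property
    def replicates_per_line(self) -> int:
        return self.n_experiments * self.n_blocks


@dataclass
class TraitArchitecture:
    """Generative model of one trait.

    additive: [(chromosome, cM, a)] with genotype coded x = +1 (A, Lemont)
        / -1 (B, Teqing), so ``a`` is half the A-vs-B class difference.
    epistatic: [((c1, p1), (c2, p2), w)] product-coded interactions.
    exp_effect: added to every experiment-2 observation.
    gxe: [(chromosome, cM, c)] adds c * x * s with s = -1/+1 for exp 1/2.
    sigma: residual standard deviation; variance_qtl = (chromosome, cM, k)
        multiplies sigma by ``k`` for lines carrying B at that locus,
        changing within-line dispersion without moving the line mean.
    baseline: positive offset keeping trait values (and so CV) meaningful.
    """

    name: str
    additive: list = field(default_factory=list)
    epistatic: list = field(default_factory=list)
    exp_effect: float = 0.0
    gxe: list = field(default_factory=list)
    sigma: float = 1.0
    baseline: float = 10.0
    variance_qtl: tuple | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.variance_qtl is not None and self.variance_qtl[2] <= 0:
            raise ValueError("variance-QTL multiplier k must be positive")


def _locus_column(gmap: GeneticMap, genotypes: GenotypeMatrix, chrom, pos) -> np.ndarray:
    """Signed genotype x in {-1, +1} at the marker nearest (chrom, pos)."""
    marker = gmap.nearest_marker(chrom, pos)  # raises off-map chromosome
    j = gmap.marker_index(marker)
    calls = genotypes.calls[:, j].astype(float)
    x = np.where(calls == A, 1.0, -1.0)
    x[calls == MISSING] = 0.0
    return x


def simulate_trait_panel(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    architectures: list,
    design: StudyDesign,
    rng=None,
) -> pd.DataFrame:
    """Replicated long-format trait table from a list of architectures.

    y(line, exp, block) = baseline + sum a_i x_i + sum w_ij x_i x_j
    + exp_effect * 1[exp = 2] + sum c_i x_i s(exp) + eps,
    eps ~ N(0, (sigma * k^{1[B at variance locus]})^2).
    """
    if not architectures:
        raise ValueError("architectures must be non-empty")
    if design.n_lines != genotypes.n_lines:
        raise ValueError("design n_lines does not match genotype matrix")
    rng = ensure_rng(rng if rng is not None else design.seed)
    n = genotypes.n_lines
    ne, nb = design.n_experiments, design.n_blocks
    frames = []
    line_ids = np.asarray(genotypes.line_ids)
    exp_idx = np.repeat(np.arange(1, ne + 1), nb)
    block_idx = np.tile(np.arange(1, nb + 1), ne)
    for arch in architectures:
        genetic = np.zeros(n)
        for chrom, pos, a in arch.additive:
            genetic += a * _locus_column(gmap, genotypes, chrom, pos)
        for (c1, p1), (c2, p2), w in arch.epistatic:
            genetic += (
                w
                * _locus_column(gmap, genotypes, c1, p1)
                * _locus_column(gmap, genotypes, c2, p2)
            )
        gxe_part = np.zeros(n)
        for chrom, pos, c in arch.gxe:
            gxe_part += c * _locus_column(gmap, genotypes, chrom, pos)
        sd = np.full(n, arch.sigma)
        if arch.variance_qtl is not None:
            chrom, pos, k = arch.variance_qtl
            sd = sd * np.where(
                _locus_column(gmap, genotypes, chrom, pos) < 0, k, 1.0
            )
        # (n, ne*nb) replicate matrix
        mean = arch.baseline + genetic
        vals = np.empty((n, ne * nb))
        for r in range(ne * nb):
            e = exp_idx[r]
            s = -1.0 if e == 1 else 1.0
            shift = (arch.exp_effect if e == 2 else 0.0) + s * gxe_part
            vals[:, r] = mean + shift + rng.normal(0.0, sd)
        frames.append(
            pd.DataFrame(
                {
                    "line": np.repeat(line_ids, ne * nb),
                    "experiment": np.tile(exp_idx, n),
                    "block": np.tile(block_idx, n),
                    "trait": arch.name,
                    "value": vals.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _random_marker_locus(gmap: GeneticMap, rng) -> tuple:
    row = gmap.table.iloc[int(rng.integers(gmap.n_markers))]
    return row["chromosome"], float(row["position_cm"])


def sample_architectures(
    gmap: GeneticMap,
    n_traits: int,
    rng=None,
    *,
    frac_genetic: float = 0.85,
    mean_qtl: float = 4.0,
    additive_var: float = 0.9,
    gxe_frac: float = 0.25,
    gxe_var: float = 0.3,
    epi_frac: float = 0.3,
    epi_var: float = 0.15,
    exp_sd: float = 2.5,
    sigma: float = 1.0,
    baseline: float = 10.0,
    variance_qtl_frac: float = 0.0,
    variance_qtl_k: float = 2.0,
    n_hotspot_loci: int = 12,
    hotspot_qtl_frac: float = 0.5,
    n_epistatic_pairs: int = 15,
    prefix: str = "met",
) -> list:
    """Random metabolite-like trait architectures at the study's conditions.

    The default variance budget is calibrated to the study design the
    package targets: most traits (85%) carry genetic signal spread over
    1 + Poisson(3) small additive QTLs with total additive variance 0.9
    sigma^2, a quarter of those also carry genotype-by-experiment variance
    0.3 sigma^2, and strong experiment main effects (sd 2.5) dominate the
    between-experiment variance.  With the 2 x 2 replicate structure this
    puts the panel's median within-experiment broad-sense heritability
    near 0.5 while the combined-experiment median drops to roughly 0.25 —
    the replication signature the pipeline is designed to expose.

    Half of all QTLs are drawn from ``n_hotspot_loci`` shared loci so the
    panel carries hotspot structure (set ``hotspot_qtl_frac`` to 0 for
    independent placement), and epistatic traits draw their interaction
    from ``n_epistatic_pairs`` recurring hotspot-locus pairs, mirroring a
    network of repeated locus-locus interactions.
    """
    rng = ensure_rng(rng)
    hotspot_loci = [
        _random_marker_locus(gmap, rng) for _ in range(max(n_hotspot_loci, 0))
    ]
    active_pairs = []
    if len(hotspot_loci) >= 2:
        for _ in range(max(n_epistatic_pairs, 0)):
            i, j = rng.choice(len(hotspot_loci), size=2, replace=False)
            active_pairs.append((hotspot_loci[int(i)], hotspot_loci[int(j)]))
    archs = []
    for t in range(n_traits):
        name = f"{prefix}{t + 1:04d}"
        additive, epistatic, gxe = [], [], []
        if rng.random() < frac_genetic:
            n_qtl = 1 + rng.poisson(mean_qtl - 1)
            a_mag = np.sqrt(additive_var / n_qtl)
            for _ in range(n_qtl):
                if hotspot_loci and rng.random() < hotspot_qtl_frac:
                    chrom, pos = hotspot_loci[int(rng.integers(len(hotspot_loci)))]
                else:
                    chrom, pos = _random_marker_locus(gmap, rng)
                additive.append((chrom, pos, float(rng.choice([-1, 1]) * a_mag)))
            if rng.random() < gxe_frac:
                c_mag = np.sqrt(gxe_var / n_qtl)
                for chrom, pos, _a in additive:
                    gxe.append((chrom, pos, float(rng.choice([-1, 1]) * c_mag)))
            if rng.random() < epi_frac:
                if active_pairs:
                    l1, l2 = active_pairs[int(rng.integers(len(active_pairs)))]
                elif len(additive) >= 2:
                    l1 = additive[0][:2]
                    l2 = additive[1][:2]
                else:
                    l1 = l2 = None
                if l1 is not None and l1 != l2:
                    epistatic.append(
                        (l1, l2, float(rng.choice([-1, 1]) * np.sqrt(epi_var)))
                    )
        variance_qtl = None
        if rng.random() < variance_qtl_frac:
            chrom, pos = _random_marker_locus(gmap, rng)
            variance_qtl = (chrom, pos, variance_qtl_k)
        archs.append(
            TraitArchitecture(
                name=name,
                additive=additive,
                epistatic=epistatic,
                exp_effect=float(rng.normal(0.0, exp_sd)),
                gxe=gxe,
                sigma=sigma,
                baseline=baseline,
                variance_qtl=variance_qtl,
            )
        )
    return archs


def additive_architecture_for_h2(
    gmap: GeneticMap,
    h2: float,
    n_qtl: int = 10,
    sigma: float = 1.0,
    baseline: float = 10.0,
    name: str = "trait",
    gxe_var: float = 0.0,
) -> TraitArchitecture:
    """Architecture whose combined-scope broad-sense heritability is ``h2``.

    QTLs are placed on distinct chromosomes (so their +-1 genotype codes are
    independent) with equal squared effects summing to Vg = h2 sigma^2 /
    (1 - h2); combined-scope Vp = Vg + Vgxe + sigma^2 counts the G x E
    variance in the phenotype but not in Vg, so planted ``gxe_var`` lowers
    the combined H2 below the within-experiment one.
    """
    if not 0 <= h2 < 1:
        raise ValueError("h2 must lie in [0, 1)")
    chroms = gmap.chromosomes
    if n_qtl > len(chroms):
        raise ValueError("at most one QTL per chromosome")
    vg = h2 / (1.0 - h2) * sigma**2 if h2 > 0 else 0.0
    a = np.sqrt(vg / n_qtl) if n_qtl else 0.0
    additive, gxe = [], []
    for i in range(n_qtl):
        sub = gmap.markers_on(chroms[i])
        mid = sub.iloc[len(sub) // 2]
        sign = 1.0 if i % 2 == 0 else -1.0
        additive.append((chroms[i], float(mid["position_cm"]), float(sign * a)))
        if gxe_var > 0:
            gxe.append(
                (chroms[i], float(mid["position_cm"]), float(np.sqrt(gxe_var / n_qtl)))
            )
    return TraitArchitecture(
        name=name, additive=additive, gxe=gxe, sigma=sigma, baseline=baseline
    )
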