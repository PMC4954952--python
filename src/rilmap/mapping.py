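"""Genetic-map arithmetic and RIL genotype probabilities.

A recombinant inbred line (RIL) derived by repeated selfing is effectively
homozygous at every marker, so its genome along a chromosome is a two-state
sequence over the parental classes A and B.  Between two mapped positions a
genetic distance d (in centimorgan) is converted to a meiotic recombination
fraction by a map function (Haldane by default, Kosambi optionally) and then
to the *effective* RIL recombination fraction R = 2r/(1 + 2r), which accounts
for the map expansion accumulated over the selfing generations.

Interval mapping evaluates the trait model on a grid of positions that
includes every marker plus pseudomarkers inserted so that no gap exceeds a
configured step.  At each grid position the probability that a line carries
the A (Lemont-type) allele is obtained by conditioning on the nearest
non-missing flanking markers under a two-state Markov chain whose
off-diagonal transition probability over distance d is
``ril_recfrac(haldane_cm_to_recfrac(d))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: genotype codes used throughout the package
A = 0
B = 1
MISSING = -1

_CODE_FROM_STR = {"A": A, "B": B, "NA": MISSING, "": MISSING, "-": MISSING}
_STR_FROM_CODE = {A: "A", B: "B", MISSING: "NA"}


def haldane_cm_to_recfrac(d):
    """Haldane map function: cM distance ``d`` -> recombination fraction.

    r = 0.5 * (1 - exp(-2 d / 100)); assumes no crossover interference.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def kosambi_cm_to_recfrac(d):
    """Kosambi map function: r = 0.5 * tanh(2 d / 100)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


MAP_FUNCTIONS = {
    "haldane": haldane_cm_to_recfrac,
    "kosambi": kosambi_cm_to_recfrac,
}


def ril_recfrac(r):
    """Effective recombination fraction of a selfed RIL: R = 2r/(1+2r).

    Accepts meiotic recombination fractions in [0, 0.5]; R >= r with
    R(0) = 0 and R(0.5) = 0.5 (free recombination is a fixed point).
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    out = 2.0 * r / (1.0 + 2.0 * r)
    return float(out) if out.ndim == 0 else out


def ril_transition(d, map_function: str = "haldane"):
    """Two-point RIL transition probability over ``d`` cM (off-diagonal)."""
    return ril_recfrac(MAP_FUNCTIONS[map_function](d))


class GeneticMap:
    """Ordered marker map: unique marker names, chromosome, cM position.

    The coordinate system for every scan.  Markers must be sorted by
    position within a chromosome (use :meth:`from_frame` to sort on load).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "chromosome", "position_cm"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        if len(table) == 0:
            raise ValueError("empty genetic map")
        t = table.loc[:, ["marker", "chromosome", "position_cm"]].copy()
        t["marker"] = t["marker"].astype(str)
        t["position_cm"] = t["position_cm"].astype(float)
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker name: {dup!r}")
        if (t["position_cm"] < 0).any():
            raise ValueError("marker positions must be non-negative")
        for chrom, sub in t.groupby("chromosome", sort=False):
            if not np.all(np.diff(sub["position_cm"].to_numpy()) >= 0):
                raise ValueError(
                    f"marker positions not non-decreasing on chromosome {chrom}"
                )
        self.table = t.reset_index(drop=True)
        self._index = {m: i for i, m in enumerate(self.table["marker"])}

    @classmethod
    def from_frame(cls, table: pd.DataFrame) -> "GeneticMap":
        """Build a map from an unordered frame (sorts within chromosome)."""
        t = table.copy()
        t["_order"] = np.arange(len(t))
        chrom_order = {c: i for i, c in enumerate(pd.unique(t["chromosome"]))}
        t["_c"] = t["chromosome"].map(chrom_order)
        t = t.sort_values(["_c", "position_cm", "_order"]).drop(columns=["_c", "_order"])
        return cls(t)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.table["chromosome"]))

    def marker_index(self, marker: str) -> int:
        return self._index[marker]

    def markers_on(self, chromosome) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chromosome]

    def chrom_marker_indices(self, chromosome) -> np.ndarray:
        return np.flatnonzero((self.table["chromosome"] == chromosome).to_numpy())

    def nearest_marker(self, chromosome, position_cm: float) -> str:
        """Marker on ``chromosome`` closest to ``position_cm`` (tie: lower cM)."""
        sub = self.markers_on(chromosome)
        if len(sub) == 0:
            raise ValueError(f"chromosome {chromosome!r} not on the map")
        d = np.abs(sub["position_cm"].to_numpy() - position_cm)
        return str(sub["marker"].iloc[int(np.argmin(d))])


class GenotypeMatrix:
    """RIL genotype calls: lines x markers in {A, B, missing}.

    ``calls`` is an int8 array with codes ``mapping.A`` (Lemont-type),
    ``mapping.B`` (Teqing-type) and ``mapping.MISSING``.
    """

    def __init__(self, line_ids, calls, parents=("Lemont", "Teqing")):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2:
            raise ValueError("calls must be a 2-D lines x markers array")
        line_ids = [str(x) for x in line_ids]
        if len(line_ids) != calls.shape[0]:
            raise ValueError("line_ids length does not match calls rows")
        if len(set(line_ids)) != len(line_ids):
            raise ValueError("line ids must be unique")
        bad = ~np.isin(calls, (A, B, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be A, B or missing")
        if calls.shape[0] > 0:
            frac_missing = (calls == MISSING).mean(axis=0)
            if np.any(frac_missing >= 1.0):
                j = int(np.argmax(frac_missing))
                raise ValueError(f"marker column {j} is entirely missing")
        self.line_ids = line_ids
        self.calls = calls
        self.parents = tuple(parents)

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @classmethod
    def from_strings(cls, line_ids, calls_str, parents=("Lemont", "Teqing")):
        arr = np.asarray(calls_str, dtype=object)
        coded = np.empty(arr.shape, dtype=np.int8)
        for s, c in _CODE_FROM_STR.items():
            coded[arr == s] = c
        known = np.isin(arr, list(_CODE_FROM_STR))
        if not known.all():
            bad = sorted({str(v) for v in arr[~known]})
            raise ValueError(f"unknown genotype codes: {bad}")
        return cls(line_ids, coded, parents)

    def to_strings(self) -> np.ndarray:
        out = np.empty(self.calls.shape, dtype=object)
        for c, s in _STR_FROM_CODE.items():
            out[self.calls == c] = s
        return out


@dataclass
class ScanGrid:
    """Ordered evaluation positions for interval mapping.

    ``table`` holds chromosome, position_cm, is_marker and marker (name of a
    mapped marker at that position, "" for pseudomarkers); positions are
    strictly increasing within a chromosome and every marker position is
    included.
    """

    table: pd.DataFrame
    step: float
    _chrom_slices: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        chrom = self.table["chromosome"].to_numpy()
        self._chrom_slices = {}
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                self._chrom_slices[chrom[start]] = slice(start, i)
                start = i

    @property
    def n_positions(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table["position_cm"].to_numpy()

    @property
    def chromosome(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    def chrom_slice(self, chromosome) -> slice:
        return self._chrom_slices[chromosome]

    def marker_positions(self) -> np.ndarray:
        """Indices of grid positions that coincide with mapped markers."""
        return np.flatnonzero(self.table["is_marker"].to_numpy())


def build_scan_grid(gmap: GeneticMap, step: float = 1.0) -> ScanGrid:
    """Grid covering each chromosome, marker positions always included.

    Intervals longer than ``step`` are subdivided evenly so that no gap
    between adjacent grid positions exceeds ``step``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    rows = []
    for chrom in gmap.chromosomes:
        sub = gmap.markers_on(chrom)
        pos = sub["position_cm"].to_numpy()
        names = sub["marker"].to_numpy()
        upos, first = np.unique(pos, return_index=True)
        unames = names[first]
        for i, p in enumerate(upos):
            rows.append((chrom, float(p), True, str(unames[i])))
            if i + 1 < len(upos):
                gap = upos[i + 1] - p
                if gap > step:
                    nsub = int(np.ceil(gap / step))
                    for k in range(1, nsub):
                        rows.append(
                            (chrom, float(p + gap * k / nsub), False, "")
                        )
    table = pd.DataFrame(
        rows, columns=["chromosome", "position_cm", "is_marker", "marker"]
    )
    return ScanGrid(table=table, step=float(step))


def _chromosome_probs(mpos, calls, gpos, map_function="haldane"):
    """P(A) at grid positions ``gpos`` for one line on one chromosome.

    ``mpos``: sorted marker positions; ``calls``: this line's codes at those
    markers (may contain MISSING); conditioning uses the nearest non-missing
    flanking markers under the two-state RIL chain.
    """
    informative = calls != MISSING
    if not informative.any():
        warnings.warn("chromosome with all genotypes missing: returning 0.5")
        return np.full(len(gpos), 0.5)
    ip = mpos[informative]
    ic = calls[informative]
    li = np.searchsorted(ip, gpos, side="right") - 1
    ri = np.searchsorted(ip, gpos, side="left")
    has_l = li >= 0
    has_r = ri < len(ip)
    lif = np.where(has_l, li, 0)
    rif = np.where(has_r, ri, len(ip) - 1)
    dl = np.where(has_l, gpos - ip[lif], 0.0)
    dr = np.where(has_r, ip[rif] - gpos, 0.0)
    RL = ril_recfrac(MAP_FUNCTIONS[map_function](dl))
    RR = ril_recfrac(MAP_FUNCTIONS[map_function](dr))
    # P(left call -> A over dl) and P(A/B -> right call over dr)
    pA_from_l = np.where(ic[lif] == A, 1.0 - RL, RL)
    pB_from_l = 1.0 - pA_from_l
    pr_given_A = np.where(ic[rif] == A, 1.0 - RR, RR)
    pr_given_B = 1.0 - pr_given_A
    num = np.where(has_l, pA_from_l, 0.5) * np.where(has_r, pr_given_A, 1.0)
    alt = np.where(has_l, pB_from_l, 0.5) * np.where(has_r, pr_given_B, 1.0)
    den = num + alt
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)


def genotype_probabilities(
    gmap: GeneticMap,
    genotypes: GenotypeMatrix,
    grid: ScanGrid,
    map_function: str = "haldane",
) -> np.ndarray:
    """P(genotype = A) for every line at every grid position.

    Returns an (n_lines, n_positions) array; exactly 0/1 at non-missing
    genotyped markers.
    """
    if genotypes.n_markers != gmap.n_markers:
        raise ValueError("genotype column count does not match the map")
    n = genotypes.n_lines
    out = np.empty((n, grid.n_positions))
    for chrom in gmap.chromosomes:
        midx = gmap.chrom_marker_indices(chrom)
        mpos = gmap.table["position_cm"].to_numpy()[midx]
        gsl = grid.chrom_slice(chrom)
        gpos = grid.positions[gsl]
        calls = genotypes.calls[:, midx]
        for i in range(n):
            out[i, gsl] = _chromosome_probs(mpos, calls[i], gpos, map_function)
    return out


def conditional_genotype_prob(
    gmap: GeneticMap,
    line_calls,
    chromosome,
    position_cm: float,
    map_function: str = "haldane",
) -> float:
    """P(genotype = A) for a single line at one position.

    ``line_calls`` is that line's full row of genotype codes over all mapped
    markers.  The position must lie on a mapped chromosome.
    """
    midx = gmap.chrom_marker_indices(chromosome)
    if len(midx) == 0:
        raise ValueError(f"chromosome {chromosome!r} not on the map")
    mpos = gmap.table["position_cm"].to_numpy()[midx]
    calls = np.asarray(line_calls, dtype=np.int8)[midx]
    p = _chromosome_probs(mpos, calls, np.asarray([float(position_cm)]), map_function)
    return float(p[0])
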