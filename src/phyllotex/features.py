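"""Texture-feature computation on a quantized whole-tumor VOI.

Four families, 314 features under the default configuration:

* histogram (9): first-order statistics of the gray-level distribution;
* gray-level co-occurrence matrix, GLCM (275 = 11 statistics x 5 offsets x
  5 distances): second-order statistics of how often pairs of gray levels
  co-occur at a fixed voxel offset;
* run-length matrix, RLM (25 = 5 statistics x 5 directions): statistics of
  maximal same-level voxel runs along lattice lines;
* absolute gradient (5): statistics of the finite-difference gradient
  magnitude inside the VOI.

Co-occurrence matrices are accumulated symmetrically (both pair orders) and
only voxel pairs with BOTH ends inside the VOI are counted.  Runs break at
any non-VOI voxel.  Entropies use the natural logarithm.  Statistics whose
denominator degenerates (e.g. Correlat on a constant image) are reported as
0 with an explicit undefined reason so the selection stage can drop them
transparently rather than silently imputing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import registry as reg
from .voi import QuantizedVOI, VolumeWithMask, normalize_voi

__all__ = [
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "FeatureVector",
    "ExtractionConfig",
    "histogram_features",
    "build_glcm",
    "glcm_features",
    "build_rlm",
    "rlm_features",
    "gradient_features",
    "extract_all",
]


@dataclass
class CooccurrenceMatrix:
    """Normalized symmetric co-occurrence matrix for one voxel offset."""

    p: np.ndarray  # Ng x Ng, sums to 1 when n_pairs > 0
    offset: tuple[int, int, int]
    n_pairs: int  # symmetric pair count (each unordered pair counted twice)

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


@dataclass
class RunLengthMatrix:
    """Run counts r(level, length) for one direction."""

    r: np.ndarray  # Ng x Lmax counts
    direction: str
    n_runs: int
    n_voxels: int  # Np of the VOI


@dataclass
class FeatureVector:
    """Ordered feature-name -> value map with undefined-reason annotations."""

    values: dict[str, float] = field(default_factory=dict)
    undefined: dict[str, str] = field(default_factory=dict)

    def set(self, name: str, value: float, undefined_reason: str | None = None) -> None:
        self.values[name] = float(value)
        if undefined_reason is not None:
            self.undefined[name] = undefined_reason

    def update(self, other: "FeatureVector") -> None:
        self.values.update(other.values)
        self.undefined.update(other.undefined)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self, mask_undefined: bool = False):
        import pandas as pd

        s = pd.Series(self.values, dtype=float)
        if mask_undefined:
            s[list(self.undefined)] = np.nan
        return s


def _moments(values: np.ndarray) -> tuple[float, float, float, float, bool]:
    """Population mean/variance/skewness/excess-kurtosis; flag degenerate."""
    mean = float(values.mean())
    var = float(values.var())  # ddof=0
    if var == 0.0:
        return mean, 0.0, 0.0, 0.0, True
    centered = values - mean
    skew = float((centered**3).mean() / var**1.5)
    kurt = float((centered**4).mean() / var**2 - 3.0)
    return mean, var, skew, kurt, False


def histogram_features(q: QuantizedVOI) -> FeatureVector:
    """First-order statistics of the gray-level histogram.

    Variance is population (divide by Np); Kurtosis is excess (minus 3).
    Percentile q% is the smallest level whose cumulative count reaches
    ``(q/100) * Np``.
    """
    fv = FeatureVector()
    levels = q.levels
    mean, var, skew, kurt, degenerate = _moments(levels.astype(float))
    fv.set("Mean", mean)
    fv.set("Variance", var)
    reason = "zero-variance VOI" if degenerate else None
    fv.set("Skewness", skew, undefined_reason=reason)
    fv.set("Kurtosis", kurt, undefined_reason=reason)
    sorted_levels = np.sort(levels)
    np_count = len(levels)
    for pct, name in (
        (1, "Perc.01%"),
        (10, "Perc.10%"),
        (50, "Perc.50%"),
        (90, "Perc.90%"),
        (99, "Perc.99%"),
    ):
        # smallest level with cumulative count >= (pct/100)*Np
        rank = int(np.ceil(pct / 100.0 * np_count))
        rank = max(rank, 1)
        fv.set(name, float(sorted_levels[rank - 1]))
    return fv


def build_glcm(q: QuantizedVOI, offset: tuple[int, int, int]) -> CooccurrenceMatrix:
    """Accumulate the symmetric co-occurrence matrix for one offset.

    Only pairs with both voxels inside the VOI count; each unordered pair
    contributes to (i, j) and (j, i).
    """
    if all(o == 0 for o in offset):
        raise ValueError("offset must be nonzero")
    dense = q.to_dense()
    ng = q.n_levels
    # Slice the array against its offset copy; valid where both in VOI.
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, d in enumerate(offset):
        n = dense.shape[axis]
        if abs(d) >= n:
            counts = np.zeros((ng, ng), dtype=float)
            return CooccurrenceMatrix(p=counts, offset=tuple(offset), n_pairs=0)
        if d >= 0:
            src[axis] = slice(0, n - d)
            dst[axis] = slice(d, n)
        else:
            src[axis] = slice(-d, n)
            dst[axis] = slice(0, n + d)
    a = dense[tuple(src)]
    b = dense[tuple(dst)]
    valid = (a > 0) & (b > 0)
    ai = a[valid] - 1
    bi = b[valid] - 1
    counts = np.bincount(ai * ng + bi, minlength=ng * ng).reshape(ng, ng).astype(float)
    counts = counts + counts.T  # symmetric accumulation
    total = counts.sum()
    if total == 0:
        return CooccurrenceMatrix(
            p=np.zeros((ng, ng)), offset=tuple(offset), n_pairs=0
        )
    return CooccurrenceMatrix(p=counts / total, offset=tuple(offset), n_pairs=int(total))


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln(p) with the 0*ln(0) = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def glcm_features(
    m: CooccurrenceMatrix, prefix: str | None = None
) -> FeatureVector:
    """The 11 classical co-occurrence statistics of one normalized matrix.

    Gray-level indices run 1..Ng.  Entropies use natural log.  Correlat is
    flagged undefined (value 0) when the marginal standard deviations vanish.
    """
    fv = FeatureVector()
    names = {
        stat: (reg.glcm_feature_name(m.offset, stat) if prefix is None else prefix + stat)
        for stat in reg.GLCM_STATISTICS
    }
    if m.empty:
        for stat in reg.GLCM_STATISTICS:
            fv.set(names[stat], 0.0, undefined_reason="empty co-occurrence matrix")
        return fv
    p = m.p
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj

    fv.set(names["AngScMom"], float((p**2).sum()))
    fv.set(names["Contrast"], float((diff**2 * p).sum()))
    cov = float((ii * jj * p).sum()) - mu_x * mu_y
    if sd_x * sd_y == 0:
        fv.set(names["Correlat"], 0.0, undefined_reason="zero marginal variance")
    else:
        fv.set(names["Correlat"], cov / (sd_x * sd_y))
    fv.set(names["SumOfSqs"], float(((ii - mu_x) ** 2 * p).sum()))
    fv.set(names["InvDfMom"], float((p / (1.0 + diff**2)).sum()))

    # p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
    sum_idx = (ii + jj).astype(int)
    p_sum = np.bincount(sum_idx.ravel(), weights=p.ravel(), minlength=2 * ng + 1)
    k_sum = np.arange(2 * ng + 1, dtype=float)
    sum_avg = float(k_sum @ p_sum)
    fv.set(names["SumAverg"], sum_avg)
    fv.set(names["SumVarnc"], float(((k_sum - sum_avg) ** 2) @ p_sum))
    fv.set(names["SumEntrp"], float(-_xlogx(p_sum).sum()))
    fv.set(names["Entropy"], float(-_xlogx(p).sum()))

    abs_diff = np.abs(diff).astype(int)
    p_diff = np.bincount(abs_diff.ravel(), weights=p.ravel(), minlength=ng)
    k_diff = np.arange(len(p_diff), dtype=float)
    diff_avg = float(k_diff @ p_diff)
    fv.set(names["DifVarnc"], float(((k_diff - diff_avg) ** 2) @ p_diff))
    fv.set(names["DifEntrp"], float(-_xlogx(p_diff).sum()))
    return fv


_RLM_OFFSETS = dict(reg.RLM_DIRECTIONS)


def _direction_lines(dense: np.ndarray, direction: str) -> list[np.ndarray]:
    """Lattice lines of the dense level array along one run direction."""
    n0, n1, n2 = dense.shape
    if direction == "Z":  # (0, 0, 1): along slices
        return [dense[r, c, :] for r in range(n0) for c in range(n1)]
    if direction == "Horzl":  # (0, 1, 0): along columns
        return [dense[r, :, k] for r in range(n0) for k in range(n2)]
    if direction == "Vertl":  # (1, 0, 0): along rows
        return [dense[:, c, k] for c in range(n1) for k in range(n2)]
    if direction == "45dgr":  # (1, 1, 0): in-plane main diagonals
        return [
            np.diagonal(dense[:, :, k], offset=off)
            for k in range(n2)
            for off in range(-(n0 - 1), n1)
        ]
    if direction == "135dr":  # (1, -1, 0): in-plane anti-diagonals
        flipped = dense[:, ::-1, :]
        return [
            np.diagonal(flipped[:, :, k], offset=off)
            for k in range(n2)
            for off in range(-(n0 - 1), n1)
        ]
    raise ValueError(f"unknown run direction {direction!r}")


def build_rlm(q: QuantizedVOI, direction: str) -> RunLengthMatrix:
    """Count maximal same-level runs along one direction's lattice lines.

    Runs are restricted to VOI voxels; any non-VOI voxel breaks a run.
    ``direction`` is one of Z, Horzl, Vertl, 45dgr, 135dr.
    """
    dense = q.to_dense()
    lines = _direction_lines(dense, direction)
    # Concatenate all lines with a 0 separator, then run-length encode once.
    sep = np.zeros(1, dtype=dense.dtype)
    seq = np.concatenate([x for line in lines for x in (np.ascontiguousarray(line), sep)])
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(seq)]))
    run_values = seq[starts]
    run_lengths = ends - starts
    keep = run_values > 0
    run_values = run_values[keep].astype(np.int64)
    run_lengths = run_lengths[keep].astype(np.int64)
    lmax = max(dense.shape) if run_lengths.size == 0 else int(run_lengths.max())
    r = np.zeros((q.n_levels, lmax), dtype=float)
    np.add.at(r, (run_values - 1, run_lengths - 1), 1.0)
    return RunLengthMatrix(
        r=r, direction=direction, n_runs=int(len(run_values)), n_voxels=q.n_voxels
    )


def rlm_features(rlm: RunLengthMatrix) -> FeatureVector:
    """The 5 run-length statistics of one direction's run matrix.

    GLevNonU (gray-level non-uniformity) grows as runs concentrate into
    fewer gray levels, i.e. with heterogeneity of the level histogram of
    runs; Fraction is the run count over the voxel count.
    """
    fv = FeatureVector()
    names = {s: reg.rlm_feature_name(rlm.direction, s) for s in reg.RLM_STATISTICS}
    nr = rlm.n_runs
    if nr == 0:
        for s in reg.RLM_STATISTICS:
            fv.set(names[s], 0.0, undefined_reason="no runs in direction")
        return fv
    r = rlm.r
    per_level = r.sum(axis=1)
    per_length = r.sum(axis=0)
    j = np.arange(1, r.shape[1] + 1, dtype=float)
    fv.set(names["RLNonUni"], float((per_length**2).sum()) / nr)
    fv.set(names["GLevNonU"], float((per_level**2).sum()) / nr)
    fv.set(names["LngREmph"], float((per_length * j**2).sum()) / nr)
    fv.set(names["ShrtREmp"], float((per_length / j**2).sum()) / nr)
    fv.set(names["Fraction"], nr / rlm.n_voxels)
    return fv


def gradient_features(q: QuantizedVOI) -> FeatureVector:
    """Statistics of the central-difference gradient magnitude.

    Evaluated on the quantized levels, only at voxels whose six axial
    neighbors all lie inside the VOI (and off the array edge).  GrNonZeros
    is the fraction of those voxels with nonzero magnitude.
    """
    fv = FeatureVector()
    dense = q.to_dense().astype(float)
    mask = q.mask
    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1, 1:-1] = (
        mask[1:-1, 1:-1, 1:-1]
        & mask[:-2, 1:-1, 1:-1]
        & mask[2:, 1:-1, 1:-1]
        & mask[1:-1, :-2, 1:-1]
        & mask[1:-1, 2:, 1:-1]
        & mask[1:-1, 1:-1, :-2]
        & mask[1:-1, 1:-1, 2:]
    )
    if not interior.any():
        for name in reg.GRADIENT_FEATURES:
            fv.set(name, 0.0, undefined_reason="no interior voxels for gradient")
        return fv
    gx = np.zeros_like(dense)
    gy = np.zeros_like(dense)
    gz = np.zeros_like(dense)
    gx[1:-1, :, :] = (dense[2:, :, :] - dense[:-2, :, :]) / 2.0
    gy[:, 1:-1, :] = (dense[:, 2:, :] - dense[:, :-2, :]) / 2.0
    gz[:, :, 1:-1] = (dense[:, :, 2:] - dense[:, :, :-2]) / 2.0
    mag = np.sqrt(gx**2 + gy**2 + gz**2)[interior]
    mean, var, skew, kurt, degenerate = _moments(mag)
    fv.set("GrMean", mean)
    fv.set("GrVariance", var)
    reason = "zero-variance gradient magnitudes" if degenerate else None
    fv.set("GrSkewness", skew, undefined_reason=reason)
    fv.set("GrKurtosis", kurt, undefined_reason=reason)
    fv.set("GrNonZeros", float((mag > 0).mean()))
    return fv


@dataclass
class ExtractionConfig:
    """Configuration of the default 314-feature extraction."""

    n_levels: int = 64
    distances: tuple[int, ...] = reg.GLCM_DISTANCES
    base_offsets: tuple[tuple[int, int, int], ...] = reg.GLCM_BASE_OFFSETS
    rlm_directions: tuple[str, ...] = tuple(p for p, _ in reg.RLM_DIRECTIONS)


def extract_all(
    vm: VolumeWithMask, config: ExtractionConfig | None = None
) -> FeatureVector:
    """Normalize the VOI and compute every feature family.

    Under the default configuration this yields exactly the 314-feature
    inventory of the registry: 9 histogram + 275 co-occurrence + 25
    run-length + 5 gradient.
    """
    config = config or ExtractionConfig()
    q, _params = normalize_voi(vm, n_levels=config.n_levels)
    fv = FeatureVector()
    fv.update(histogram_features(q))
    for distance in config.distances:
        for base in config.base_offsets:
            offset = tuple(distance * o for o in base)
            fv.update(glcm_features(build_glcm(q, offset)))
    for direction in config.rlm_directions:
        fv.update(rlm_features(build_rlm(q, direction)))
    fv.update(gradient_features(q))
    return fv
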