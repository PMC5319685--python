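"""Empirical mode decomposition (EMD) by envelope-mean sifting.

EMD adaptively splits a signal x(t) into a small set of oscillatory
components called intrinsic mode functions (IMFs) plus a slowly varying
residue, with x(t) = sum_i g_i(t) + r_m(t) exact by construction.  An IMF
has (i) extrema and zero-crossing counts equal or differing by one and
(ii) a local envelope mean near zero.  Each IMF is obtained by repeatedly
subtracting the mean of the cubic-spline envelopes through the local
maxima and minima (sifting) until a Cauchy-type stopping criterion and the
IMF conditions are met; the procedure then restarts on the remainder until
it is monotone or has too few extrema to envelope.

The sifting stop is the classical normalized squared-difference statistic
SD = sum_t (h_prev - h)^2 / sum_t h_prev^2 compared against a threshold
(default 0.2), the standard choice in the EMD literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InvalidInputError, NotSiftableError
from .series import TimeSeries

__all__ = [
    "SiftConfig",
    "Decomposition",
    "find_extrema",
    "compute_envelopes",
    "mean_envelope",
    "is_imf",
    "sift_one_imf",
    "decompose",
]


@dataclass(frozen=True)
class SiftConfig:
    """Tunable knobs of the sifting procedure.

    sd_threshold
        Cauchy-type stopping threshold on the normalized squared change of
        the candidate between consecutive sifts.  0.2 is the classical
        default; smaller values sift harder and split modes more finely.
    max_sift_iterations
        Hard cap on inner sifting iterations per IMF.
    max_imfs
        Hard cap on the number of IMFs extracted.
    boundary_policy
        How envelopes are extended past the outermost extrema: ``mirror``
        reflects two extrema across each end before spline fitting (keeps
        the envelope from diverging at the boundaries), ``clamp`` pins the
        envelope to the nearest extremum value at each end.
    symmetry_tolerance
        Fraction of the signal's amplitude half-range below which the mean
        envelope counts as "locally zero" in the IMF test.
    """

    sd_threshold: float = 0.2
    max_sift_iterations: int = 100
    max_imfs: int = 16
    boundary_policy: Literal["mirror", "clamp"] = "mirror"
    symmetry_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise InvalidInputError("sd_threshold must be positive")
        if self.max_sift_iterations < 1:
            raise InvalidInputError("max_sift_iterations must be >= 1")
        if self.boundary_policy not in ("mirror", "clamp"):
            raise InvalidInputError(f"unknown boundary policy {self.boundary_policy!r}")


@dataclass(frozen=True)
class Decomposition:
    """Ordered IMFs g_1..g_m (fast to slow) plus the final residue r_m(t)."""

    imfs: tuple[np.ndarray, ...]
    residue: np.ndarray
    source_length: int = field(default=0)

    def __post_init__(self) -> None:
        residue = np.asarray(self.residue, dtype=float)
        imfs = tuple(np.asarray(g, dtype=float) for g in self.imfs)
        for g in imfs:
            if g.shape != residue.shape:
                raise InvalidInputError("every IMF must match the residue length")
        object.__setattr__(self, "imfs", imfs)
        object.__setattr__(self, "residue", residue)
        object.__setattr__(self, "source_length", residue.size)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Elementwise sum of all IMFs and the residue (equals the source)."""
        total = self.residue.copy()
        for g in self.imfs:
            total += g
        return total

    def components(self) -> list[np.ndarray]:
        """IMFs followed by the residue, as one flat list."""
        return [*self.imfs, self.residue]


def find_extrema(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    A plateau of equal values bounded by strictly smaller (larger)
    neighbours counts as a single maximum (minimum) at the plateau
    midpoint, rounded down.  Endpoints are never extrema.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise InvalidInputError("extremum search needs a 1-D series of length >= 3")

    # Collapse runs of equal values to (start, end) index pairs, then
    # compare each interior run with its distinct neighbours.
    change = np.flatnonzero(np.diff(x) != 0)
    run_starts = np.concatenate(([0], change + 1))
    run_ends = np.concatenate((change, [x.size - 1]))

    maxima: list[int] = []
    minima: list[int] = []
    for k in range(1, len(run_starts) - 1):
        left = x[run_ends[k - 1]]
        here = x[run_starts[k]]
        right = x[run_starts[k + 1]]
        mid = (run_starts[k] + run_ends[k]) // 2
        if here > left and here > right:
            maxima.append(mid)
        elif here < left and here < right:
            minima.append(mid)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _extend_knots(
    idx: np.ndarray, val: np.ndarray, n: int, policy: str
) -> tuple[np.ndarray, np.ndarray]:
    """Add boundary knots so the spline is well-behaved on [0, n-1]."""
    if policy == "mirror":
        # Reflect up to two extrema across each end of the index range.
        k = min(2, idx.size)
        left_idx = -idx[:k][::-1]
        left_val = val[:k][::-1]
        right_idx = 2 * (n - 1) - idx[-k:][::-1]
        right_val = val[-k:][::-1]
        xs = np.concatenate((left_idx, idx, right_idx))
        ys = np.concatenate((left_val, val, right_val))
    else:  # clamp
        xs, ys = idx, val
        if idx[0] > 0:
            xs = np.concatenate(([0], xs))
            ys = np.concatenate(([val[0]], ys))
        if idx[-1] < n - 1:
            xs = np.concatenate((xs, [n - 1]))
            ys = np.concatenate((ys, [val[-1]]))
    # Mirroring can duplicate knot positions (e.g. extremum at midpoint);
    # keep the first occurrence.
    xs, keep = np.unique(xs, return_index=True)
    return xs, ys[keep]


def compute_envelopes(
    series: np.ndarray, boundary_policy: str = "mirror"
) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic-spline upper and lower envelopes at every sample.

    Raises :class:`NotSiftableError` when the series has fewer than two
    maxima or two minima, in which case no further IMF can be extracted.
    """
    x = np.asarray(series, dtype=float)
    max_idx, min_idx = find_extrema(x)
    if max_idx.size < 2 or min_idx.size < 2:
        raise NotSiftableError(
            f"need >= 2 maxima and >= 2 minima, found {max_idx.size} and {min_idx.size}"
        )
    t = np.arange(x.size)
    envelopes = []
    for idx in (max_idx, min_idx):
        xs, ys = _extend_knots(idx, x[idx], x.size, boundary_policy)
        if xs.size >= 3:
            spline = CubicSpline(xs, ys, bc_type="natural")
            envelopes.append(spline(t))
        else:  # 2 knots: the cubic spline degenerates to a straight line
            envelopes.append(np.interp(t, xs, ys))
    return envelopes[0], envelopes[1]


def mean_envelope(upper: np.ndarray, lower: np.ndarray) -> np.ndarray:
    """m(t) = (e_max(t) + e_min(t)) / 2, elementwise."""
    upper = np.asarray(upper, dtype=float)
    lower = np.asarray(lower, dtype=float)
    if upper.shape != lower.shape:
        raise InvalidInputError("upper and lower envelopes must have equal length")
    return (upper + lower) / 2.0


def _count_zero_crossings(x: np.ndarray) -> int:
    signs = np.sign(x)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs)))


def is_imf(series: np.ndarray, cfg: SiftConfig | None = None) -> bool:
    """Check the two IMF conditions.

    (1) extrema and zero-crossing counts equal or differing by at most one;
    (2) the envelope mean stays within ``symmetry_tolerance`` times the
    amplitude half-range of zero (a practical reading of "symmetric with
    respect to the local zero mean").
    """
    cfg = cfg or SiftConfig()
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise InvalidInputError("IMF test needs length >= 3")
    max_idx, min_idx = find_extrema(x)
    n_extrema = max_idx.size + min_idx.size
    if abs(n_extrema - _count_zero_crossings(x)) > 1:
        return False
    try:
        upper, lower = compute_envelopes(x, cfg.boundary_policy)
    except NotSiftableError:
        return False
    half_range = (x.max() - x.min()) / 2.0
    if half_range == 0:
        return False
    m = mean_envelope(upper, lower)
    return bool(np.max(np.abs(m)) <= cfg.symmetry_tolerance * half_range)


def sift_one_imf(
    series: np.ndarray, cfg: SiftConfig | None = None
) -> tuple[np.ndarray, int]:
    """Extract one IMF from ``series`` by iterated envelope-mean subtraction.

    Iterates h <- h - m(h) until SD < sd_threshold and the IMF conditions
    hold, or the iteration cap is reached.  Returns the final candidate and
    the number of sifting iterations performed.
    """
    cfg = cfg or SiftConfig()
    h = np.asarray(series, dtype=float).copy()
    # A non-siftable input is an error; becoming non-siftable mid-sift just
    # stops the refinement with the current candidate.
    upper, lower = compute_envelopes(h, cfg.boundary_policy)
    n_iter = 0
    while n_iter < cfg.max_sift_iterations:
        m = mean_envelope(upper, lower)
        h_new = h - m
        n_iter += 1
        denom = float(np.sum(h * h))
        sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < cfg.sd_threshold and is_imf(h, cfg):
            break
        try:
            upper, lower = compute_envelopes(h, cfg.boundary_policy)
        except NotSiftableError:
            break
    return h, n_iter


def _is_monotone(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def decompose(series: TimeSeries | np.ndarray, cfg: SiftConfig | None = None) -> Decomposition:
    """Full EMD: peel IMFs off the running residue until it is monotone,
    has fewer than two maxima or minima, or the IMF cap is reached."""
    cfg = cfg or SiftConfig()
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, dtype=float)
    if x.size < 8:
        raise InvalidInputError(
            f"decomposition needs >= 8 samples for envelope fitting, got {x.size}"
        )
    residue = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < cfg.max_imfs:
        if _is_monotone(residue):
            break
        try:
            max_idx, min_idx = find_extrema(residue)
        except InvalidInputError:
            break
        if max_idx.size < 2 or min_idx.size < 2:
            break
        imf, _ = sift_one_imf(residue, cfg)
        imfs.append(imf)
        residue = residue - imf
    return Decomposition(imfs=tuple(imfs), residue=residue)
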