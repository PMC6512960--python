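"""Quantification of contact-map features: insulation (TADs), corner peaks,
peak grids, flames, and barrier-orientation preference.

All peak/flame scores are observed/expected ratios against distance-matched
local backgrounds, so they are invariant under rescaling the map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, UndefinedScoreError
from .lef_engine import LEFTWARD, RIGHTWARD, Barrier
from .observables import ContactMap


@dataclass
class InsulationProfile:
    """Diamond-window insulation along the diagonal; minima mark TAD boundaries.

    ``values[i]`` is the mean contact frequency in the w x w window straddling
    bin i (rows i-w..i-1, columns i+1..i+w), divided by the profile mean when
    normalized; bins within w of the map edge are NaN-masked.
    """

    values: np.ndarray
    window: float  # kb
    bin_size: float  # kb

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def positions_kb(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size


def insulation_profile(
    cmap: ContactMap, window: float = 100.0, normalized: bool = True
) -> InsulationProfile:
    """Sliding diamond-window insulation score of a contact map."""
    w = int(round(window / cmap.bin_size))
    if w < 2:
        raise ConfigError(f"window of {window} kb is < 2 bins at {cmap.bin_size} kb")
    n = cmap.n_bins
    if 2 * w >= n:
        raise ConfigError(f"window of {w} bins too large for a {n}-bin map")
    mat = cmap.matrix
    values = np.full(n, np.nan)
    for i in range(w, n - w):
        values[i] = mat[i - w : i, i + 1 : i + 1 + w].mean()
    if normalized:
        mean = np.nanmean(values)
        if mean > 0:
            values = values / mean
    return InsulationProfile(values=values, window=window, bin_size=cmap.bin_size)


@dataclass
class PeakScore:
    """Observed/expected contact enrichment at a barrier-pair anchor pixel."""

    anchor: tuple
    observed: float
    expected: float
    flank: int

    @property
    def score(self) -> float:
        return self.observed / self.expected


def corner_peak_score(
    cmap: ContactMap, barrier_pair: tuple, flank: int = 3
) -> PeakScore:
    """Corner-peak enrichment at the pixel joining two barrier bins.

    Observed is the mean over the anchor pixel +/- 1; expected is the mean of
    the surrounding ring of width ``flank``, restricted to pixels at a matched
    diagonal distance (|offset from the anchor diagonal| <= flank) and away
    from the main diagonal.
    """
    a, b = (int(v) for v in barrier_pair)
    if a > b:
        a, b = b, a
    n = cmap.n_bins
    pad = flank + 1
    if a < pad or b < pad or a >= n - pad or b >= n - pad:
        raise ConfigError(
            f"anchor ({a}, {b}) closer than flank+1 = {pad} bins to the map edge"
        )
    mat = cmap.matrix
    observed = mat[a - 1 : a + 2, b - 1 : b + 2].mean()
    box = mat[a - pad : a + pad + 1, b - pad : b + pad + 1]
    ii, jj = np.mgrid[a - pad : a + pad + 1, b - pad : b + pad + 1]
    ring = (np.abs(ii - a) > 1) | (np.abs(jj - b) > 1)
    matched = np.abs((jj - ii) - (b - a)) <= flank
    off_diag = np.abs(jj - ii) > 1
    sel = ring & matched & off_diag
    if not sel.any() or box[sel].mean() == 0:
        raise UndefinedScoreError(
            f"background ring at anchor ({a}, {b}) is empty or all zeros"
        )
    return PeakScore(
        anchor=(a, b), observed=float(observed), expected=float(box[sel].mean()),
        flank=flank,
    )


@dataclass
class FlameScore:
    """Enrichment of a barrier-anchored row/column over matched background."""

    anchor: int
    direction: str
    observed: float
    expected: float
    length: int

    @property
    def score(self) -> float:
        return self.observed / self.expected


def flame_score(
    cmap: ContactMap,
    barrier_bin: int,
    direction: str = "right",
    length: float = 300.0,
    background_offsets: Sequence[int] = (3, 4, 5, -3, -4, -5),
) -> FlameScore:
    """Flame (track) enrichment emerging from a barrier bin.

    The anchored segment is row ``barrier_bin`` over columns 2..2+L to the
    ``direction`` side (starting 2 bins off the diagonal); background segments
    are the same diagonal-distance range anchored at off-barrier rows
    ``barrier_bin + offset``.
    """
    b = int(barrier_bin)
    L = int(round(length / cmap.bin_size))
    if direction not in ("right", "left"):
        raise ConfigError(f"direction must be 'right' or 'left', got {direction!r}")
    n = cmap.n_bins
    sgn = 1 if direction == "right" else -1

    def segment(row):
        cols = row + sgn * np.arange(2, 2 + L)
        if row < 0 or row >= n or cols.min() < 0 or cols.max() >= n:
            return None
        return cmap.matrix[row, cols]

    seg = segment(b)
    if seg is None:
        raise ConfigError(f"flame of {L} bins at bin {b} does not fit the map")
    bg = [segment(b + o) for o in background_offsets]
    bg = [s for s in bg if s is not None]
    if not bg:
        raise ConfigError("no background segment fits within the map")
    expected = float(np.mean([s.mean() for s in bg]))
    if expected == 0:
        raise UndefinedScoreError(f"flame background at bin {b} is all zeros")
    return FlameScore(
        anchor=b,
        direction=direction,
        observed=float(seg.mean()),
        expected=expected,
        length=L,
    )


def barrier_bin(cmap: ContactMap, barrier: Barrier) -> int:
    """Map a barrier's lattice site to its contact-map bin."""
    return int(barrier.site * cmap.monomer_size // cmap.bin_size)


def classify_pair(b1: Barrier, b2: Barrier) -> str:
    """Orientation class of a barrier pair (b1 upstream of b2).

    ``convergent`` pairs (upstream blocks leftward, downstream blocks
    rightward) halt both legs of a LEF between them and form corner peaks;
    ``divergent`` is the opposite; mixed same-direction pairs are ``tandem``.
    """
    if b1.site > b2.site:
        b1, b2 = b2, b1
    if b1.blocked_direction == LEFTWARD and b2.blocked_direction == RIGHTWARD:
        return "convergent"
    if b1.blocked_direction == RIGHTWARD and b2.blocked_direction == LEFTWARD:
        return "divergent"
    return "tandem"


def orientation_preference(
    cmap: ContactMap,
    barriers: Sequence[Barrier],
    flank: int = 3,
    max_spacings: int = 1,
) -> float:
    """Mean corner-peak score over convergent pairs / mean over divergent pairs.

    Pairs are consecutive barriers by default (``max_spacings = 1``); raise
    ``max_spacings`` to include more distal pairs.  Requires at least two
    scorable pairs of each class.
    """
    bs = sorted(barriers, key=lambda b: b.site)
    scores = {"convergent": [], "divergent": []}
    for i, b1 in enumerate(bs):
        for j in range(i + 1, min(i + max_spacings + 1, len(bs))):
            b2 = bs[j]
            cls = classify_pair(b1, b2)
            if cls == "tandem":
                continue
            try:
                s = corner_peak_score(
                    cmap, (barrier_bin(cmap, b1), barrier_bin(cmap, b2)), flank
                ).score
            except ConfigError:
                continue  # too close to the map edge
            scores[cls].append(s)
    if len(scores["convergent"]) < 2 or len(scores["divergent"]) < 2:
        raise ConfigError(
            "need >= 2 scorable convergent and >= 2 divergent barrier pairs "
            f"(got {len(scores['convergent'])} / {len(scores['divergent'])})"
        )
    return float(np.mean(scores["convergent"]) / np.mean(scores["divergent"]))


def insulation_minima(
    profile: InsulationProfile, depth_sd: float = 2.0
) -> np.ndarray:
    """Bins that are local insulation minima deeper than ``depth_sd`` x SD.

    A bin qualifies when it is a strict local minimum of the profile and lies
    more than ``depth_sd`` standard deviations below the profile median
    (median/SD over unmasked bins).
    """
    v = profile.values
    ok = np.isfinite(v)
    med = np.median(v[ok])
    sd = np.std(v[ok])
    minima = []
    for i in range(1, len(v) - 1):
        if not (ok[i] and ok[i - 1] and ok[i + 1]):
            continue
        if v[i] <= v[i - 1] and v[i] <= v[i + 1] and v[i] < med - depth_sd * sd:
            minima.append(i)
    return np.asarray(minima, dtype=int)
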