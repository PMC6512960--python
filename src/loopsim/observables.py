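"""Hi-C-style observables from conformational ensembles.

Contacts are defined by a capture radius (default 2 monomer diameters): two
monomers are in contact in a conformation when their Euclidean distance is at
most the radius.  Averaging over the ensemble and binning genomically yields a
contact map; collapsing by genomic separation yields the contact-probability
curve P(s), whose shallow-slope "shoulder" (~100-500 kb) reports compaction by
extruded loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import linregress

from ._kernels import count_contacts_by_separation
from .errors import ConfigError
from .polymer import Conformation, Ensemble

DEFAULT_CONTACT_RADIUS = 2.0  # monomer diameters


def contacts_from_conformation(
    conformation: Conformation, contact_radius: float = DEFAULT_CONTACT_RADIUS
) -> np.ndarray:
    """All monomer index pairs (i, j), i < j, within the capture radius."""
    if contact_radius <= 0:
        raise ConfigError(f"contact_radius must be positive, got {contact_radius}")
    tree = cKDTree(conformation.coordinates)
    pairs = tree.query_pairs(r=contact_radius, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.sort(pairs, axis=1)
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))].astype(np.int64)


@dataclass
class ContactMap:
    """Symmetric binned contact-count matrix averaged over an ensemble."""

    matrix: np.ndarray
    bin_size: float  # kb
    contact_radius: float
    n_conformations: int
    monomer_size: float

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def aggregate_contact_map(
    ensemble: Ensemble,
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
    bin_size: float | None = None,
) -> ContactMap:
    """Accumulate ensemble contacts into a symmetric binned matrix.

    Entry (a, b) counts, over all conformations, monomer pairs in contact that
    map to bins (a, b); the diagonal additionally counts each monomer's trivial
    self-contact once per conformation, so it is the per-bin maximum.
    """
    if ensemble.n_conformations == 0:
        raise ConfigError("ensemble is empty")
    m = ensemble.monomer_size
    if bin_size is None:
        bin_size = m
    factor = bin_size / m
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ConfigError(
            f"bin_size {bin_size} kb is not a positive multiple of the "
            f"monomer size {m} kb"
        )
    factor = int(round(factor))
    n = ensemble.n_monomers
    counts = np.zeros((n, n))
    for conf in ensemble:
        pairs = contacts_from_conformation(conf, contact_radius)
        if len(pairs):
            np.add.at(counts, (pairs[:, 0], pairs[:, 1]), 1.0)
    counts = counts + counts.T
    np.fill_diagonal(counts, counts.diagonal() + ensemble.n_conformations)
    n_bins = -(-n // factor)
    padded = np.zeros((n_bins * factor, n_bins * factor))
    padded[:n, :n] = counts
    binned = padded.reshape(n_bins, factor, n_bins, factor).sum(axis=(1, 3))
    return ContactMap(
        matrix=binned,
        bin_size=bin_size,
        contact_radius=contact_radius,
        n_conformations=ensemble.n_conformations,
        monomer_size=m,
    )


@dataclass
class PsCurve:
    """Contact probability vs genomic separation on log-spaced bins (kb)."""

    bin_centers: np.ndarray  # kb, geometric centers
    prob: np.ndarray
    bin_edges: np.ndarray  # kb
    normalized_at: float | None = None

    def band(self, lo_kb: float, hi_kb: float) -> np.ndarray:
        """Boolean mask selecting bins whose center lies in [lo_kb, hi_kb]."""
        return (self.bin_centers >= lo_kb) & (self.bin_centers <= hi_kb)


def _log_bin(s_kb, counts, pair_counts, bins_per_decade):
    """Weighted geometric binning of per-separation contact frequencies."""
    lo, hi = s_kb[0], s_kb[-1]
    n_edges = int(np.ceil(np.log10(hi / lo) * bins_per_decade)) + 1
    edges = np.geomspace(lo, hi * (1 + 1e-12), n_edges + 1)
    idx = np.searchsorted(edges, s_kb, side="right") - 1
    idx = np.clip(idx, 0, n_edges - 1)
    c = np.bincount(idx, weights=counts, minlength=n_edges)
    p = np.bincount(idx, weights=pair_counts, minlength=n_edges)
    keep = p > 0
    centers = np.sqrt(edges[:-1] * edges[1:])[keep]
    prob = c[keep] / p[keep]
    return centers, prob, edges


def ps_curve(
    source,
    bins_per_decade: int = 8,
    normalize_at: float | None = None,
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
) -> PsCurve:
    """Contact probability P(s) from an :class:`Ensemble` or a :class:`ContactMap`.

    Raw contact counts per separation are divided by the number of locus pairs
    at that separation (making P(s) a probability), then averaged over
    log-spaced separation bins with geometric bin centers.  With
    ``normalize_at`` set, the curve is scaled so the bin containing that
    separation (kb) equals 1.
    """
    if isinstance(source, Ensemble):
        n = source.n_monomers
        m = source.monomer_size
        counts = np.zeros(n, dtype=np.int64)
        for xyz in source.coordinates:
            count_contacts_by_separation(
                np.ascontiguousarray(xyz), contact_radius, counts
            )
        seps = np.arange(1, n)
        pair_counts = source.n_conformations * (n - seps).astype(float)
        s_kb = seps * m
        raw = counts[1:].astype(float)
    elif isinstance(source, ContactMap):
        mat = source.matrix
        nb = mat.shape[0]
        factor = int(round(source.bin_size / source.monomer_size))
        n_mono = nb * factor
        seps = np.arange(1, nb)
        raw = np.array([np.trace(mat, offset=k) for k in seps])
        # monomer pairs contributing to each off-diagonal of the binned map
        pair_counts = (
            source.n_conformations * (nb - seps).astype(float) * factor * factor
        )
        s_kb = seps * source.bin_size
    else:
        raise TypeError(f"expected Ensemble or ContactMap, got {type(source)!r}")
    if s_kb[-1] / s_kb[0] < 100:
        raise ConfigError(
            "fewer than 2 decades of genomic separation available "
            f"({s_kb[0]:g}-{s_kb[-1]:g} kb)"
        )
    centers, prob, edges = _log_bin(s_kb, raw, pair_counts, bins_per_decade)
    curve = PsCurve(bin_centers=centers, prob=prob, bin_edges=edges)
    if normalize_at is not None:
        if not (edges[0] <= normalize_at <= edges[-1]):
            raise ConfigError(
                f"normalization anchor {normalize_at} kb outside the binned "
                f"range [{edges[0]:g}, {edges[-1]:g}] kb"
            )
        i = int(np.argmin(np.abs(np.log(curve.bin_centers / normalize_at))))
        if curve.prob[i] <= 0:
            raise ConfigError("anchor bin has zero contact probability")
        curve = PsCurve(
            bin_centers=curve.bin_centers,
            prob=curve.prob / curve.prob[i],
            bin_edges=edges,
            normalized_at=normalize_at,
        )
    return curve


def ps_slope(curve: PsCurve, lo_kb: float, hi_kb: float) -> float:
    """Log-log slope of P(s) fitted over the band [lo_kb, hi_kb]."""
    mask = curve.band(lo_kb, hi_kb) & (curve.prob > 0)
    if mask.sum() < 3:
        raise ConfigError(f"fewer than 3 usable bins in {lo_kb}-{hi_kb} kb")
    fit = linregress(np.log10(curve.bin_centers[mask]), np.log10(curve.prob[mask]))
    return float(fit.slope)


@dataclass
class ShoulderMetric:
    """P(s) shoulder diagnostics contrasting a perturbation against a reference.

    Slopes are log-log slopes over the shoulder band (default 100-500 kb);
    ``ratio`` is perturbed/reference per shared bin.
    """

    slope_perturbed: float
    slope_reference: float
    bin_centers: np.ndarray
    ratio: np.ndarray
    band: tuple

    @property
    def delta_slope(self) -> float:
        return self.slope_perturbed - self.slope_reference


def shoulder_metric(
    ps_reference: PsCurve, ps_perturbed: PsCurve, band=(100.0, 500.0)
) -> ShoulderMetric:
    """Shoulder slope of both curves plus the per-bin perturbed/reference ratio."""
    if len(ps_reference.bin_centers) != len(ps_perturbed.bin_centers) or not np.allclose(
        ps_reference.bin_centers, ps_perturbed.bin_centers
    ):
        raise ConfigError("P(s) curves do not share separation bins")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            ps_reference.prob > 0, ps_perturbed.prob / ps_reference.prob, np.nan
        )
    return ShoulderMetric(
        slope_perturbed=ps_slope(ps_perturbed, *band),
        slope_reference=ps_slope(ps_reference, *band),
        bin_centers=ps_reference.bin_centers.copy(),
        ratio=ratio,
        band=tuple(band),
    )
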