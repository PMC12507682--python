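"""Assign a lipid fluorescence channel to organelles.

Pixel-classifier probability maps for each organelle marker are binarized
into masks.  Pixels covered by exactly one mask are unambiguous and donate
their whole lipid intensity to that organelle; their intensities also define
per-organelle empirical intensity distributions.  Where masks overlap, each
pixel's intensity I is split between the overlapping organelles o in
proportion to the likelihoods f_o(I) of the observed intensity under those
distributions.  Pixels outside every mask are counted as unassigned.  Total
lipid intensity is conserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5
DEFAULT_BINS = 64
MIN_PIXELS = 50


@dataclass
class OrganelleMaps:
    """One lipid intensity channel plus per-organelle probability maps in [0, 1]."""

    lipid: np.ndarray
    prob_maps: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.lipid = np.asarray(self.lipid, dtype=float)
        if not self.prob_maps:
            raise ValueError("at least one organelle probability map required")
        self.prob_maps = {k: np.asarray(v, dtype=float) for k, v in self.prob_maps.items()}
        for name, pm in self.prob_maps.items():
            if pm.shape != self.lipid.shape:
                raise ValueError(f"probability map {name!r} shape {pm.shape} != lipid {self.lipid.shape}")
            if pm.min() < 0 or pm.max() > 1:
                raise ValueError(f"probability map {name!r} has values outside [0, 1]")


@dataclass
class IntensityDistribution:
    """Histogram density of lipid intensities over one organelle's unambiguous pixels.

    Bins span the whole image's intensity range so that densities of
    different organelles are directly comparable; add-one smoothing keeps
    every in-range intensity at non-zero density.
    """

    bin_edges: np.ndarray
    density: np.ndarray  # normalized, len(bin_edges) - 1
    n_pixels: int
    flagged: bool = False  # below the minimum-pixel floor

    def pdf(self, intensities) -> np.ndarray:
        x = np.asarray(intensities, dtype=float)
        idx = np.clip(np.searchsorted(self.bin_edges, x, side="right") - 1, 0, len(self.density) - 1)
        out = self.density[idx]
        # outside the binned range the density is zero
        out = np.where((x < self.bin_edges[0]) | (x > self.bin_edges[-1]), 0.0, out)
        return out


@dataclass
class PartitionResult:
    """Per-organelle assigned lipid intensity and fractions, with pixel accounting."""

    assigned_intensity: dict[str, float]
    fractions: dict[str, float]
    n_unambiguous: dict[str, int]
    n_ambiguous: int
    n_unassigned: int
    unassigned_intensity: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "organelle": o,
                "assigned_intensity": self.assigned_intensity[o],
                "fraction": self.fractions[o],
                "n_unambiguous": self.n_unambiguous[o],
            }
            for o in sorted(self.assigned_intensity)
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "assigned_intensity": self.assigned_intensity,
            "fractions": self.fractions,
            "n_unambiguous": self.n_unambiguous,
            "n_ambiguous": self.n_ambiguous,
            "n_unassigned": self.n_unassigned,
            "unassigned_intensity": self.unassigned_intensity,
        }


def threshold_maps(maps: OrganelleMaps, threshold: float = DEFAULT_THRESHOLD) -> dict[str, np.ndarray]:
    """Binarize probability maps: mask true where probability >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return {name: pm >= threshold for name, pm in maps.prob_maps.items()}


def _membership_count(masks: Mapping[str, np.ndarray]) -> np.ndarray:
    return np.sum([m.astype(int) for m in masks.values()], axis=0)


def intensity_distributions(
    maps: OrganelleMaps,
    masks: Mapping[str, np.ndarray],
    bins: int = DEFAULT_BINS,
    min_pixels: int = MIN_PIXELS,
) -> dict[str, IntensityDistribution]:
    """Empirical lipid-intensity distribution per organelle from unambiguous pixels.

    Uses a fixed ``bins``-bin histogram over the image's full intensity
    range with add-one smoothing.  Organelles with fewer than ``min_pixels``
    unambiguous pixels are flagged; organelles with zero unambiguous pixels
    are excluded (with a warning) and take no part in overlap weighting.
    """
    count = _membership_count(masks)
    lo, hi = float(maps.lipid.min()), float(maps.lipid.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    out: dict[str, IntensityDistribution] = {}
    for name, mask in masks.items():
        unambiguous = mask & (count == 1)
        n = int(unambiguous.sum())
        if n == 0:
            logger.warning("organelle %r has no unambiguous pixels; excluded from overlap weighting", name)
            continue
        counts, _ = np.histogram(maps.lipid[unambiguous], bins=edges)
        smoothed = counts + 1.0  # add-one smoothing
        density = smoothed / smoothed.sum()
        out[name] = IntensityDistribution(
            bin_edges=edges, density=density, n_pixels=n, flagged=n < min_pixels
        )
        if n < min_pixels:
            logger.warning("organelle %r has only %d unambiguous pixels (< %d)", name, n, min_pixels)
    return out


def partition_signal(
    maps: OrganelleMaps,
    masks: Mapping[str, np.ndarray],
    distributions: Mapping[str, IntensityDistribution],
    winner_takes_all: bool = False,
) -> PartitionResult:
    """Split the lipid channel between organelles.

    Unambiguous pixels assign their full intensity to their single
    organelle.  Each ambiguous pixel's intensity is divided between its
    overlapping organelles with weights w_o = f_o(I) / sum f_o'(I); with
    ``winner_takes_all`` the whole pixel goes to the organelle with the
    highest likelihood instead.  When every available density is zero at I
    the pixel is split equally (logged).  Pixels in no mask are unassigned.
    """
    names = sorted(masks)
    count = _membership_count(masks)
    lipid = maps.lipid

    assigned = {n: 0.0 for n in names}
    n_unamb = {n: 0 for n in names}
    for name in names:
        unambiguous = masks[name] & (count == 1)
        n_unamb[name] = int(unambiguous.sum())
        assigned[name] = float(lipid[unambiguous].sum())

    amb = count >= 2
    n_ambiguous = int(amb.sum())
    if n_ambiguous:
        intens = lipid[amb]
        member = np.stack([masks[n][amb] for n in names])  # (orgs, pix)
        weights = np.zeros_like(member, dtype=float)
        have_dist = np.array([n in distributions for n in names])
        for i, name in enumerate(names):
            if have_dist[i]:
                weights[i] = distributions[name].pdf(intens)
        weights *= member
        # pixels whose overlapping organelles all lack a distribution -> unassigned
        eligible = (member & have_dist[:, None]).any(axis=0)
        totals = weights.sum(axis=0)
        zero = eligible & (totals == 0)
        if zero.any():
            logger.warning("%d ambiguous pixels with all-zero densities split equally", int(zero.sum()))
            eq = member[:, zero] & have_dist[:, None]
            weights[:, zero] = eq / eq.sum(axis=0)
            totals = weights.sum(axis=0)
        ok = eligible & (totals > 0)
        if winner_takes_all:
            w = np.zeros_like(weights)
            winners = np.argmax(weights, axis=0)
            w[winners, np.arange(weights.shape[1])] = 1.0
            weights = np.where(ok, w, 0.0)
        else:
            weights = np.where(ok, weights / np.where(totals > 0, totals, 1.0), 0.0)
        for i, name in enumerate(names):
            assigned[name] += float((weights[i] * intens).sum())
        n_unassigned_amb = int((~eligible).sum())
        unassigned_intensity_amb = float(intens[~eligible].sum())
    else:
        n_unassigned_amb = 0
        unassigned_intensity_amb = 0.0

    outside = count == 0
    n_unassigned = int(outside.sum()) + n_unassigned_amb
    unassigned_intensity = float(lipid[outside].sum()) + unassigned_intensity_amb

    total_assigned = sum(assigned.values())
    fractions = {
        n: (assigned[n] / total_assigned if total_assigned > 0 else 0.0) for n in names
    }
    return PartitionResult(
        assigned_intensity=assigned,
        fractions=fractions,
        n_unambiguous=n_unamb,
        n_ambiguous=n_ambiguous,
        n_unassigned=n_unassigned,
        unassigned_intensity=unassigned_intensity,
    )


def partition_image(
    lipid: np.ndarray,
    prob_maps: Mapping[str, np.ndarray],
    threshold: float = DEFAULT_THRESHOLD,
    bins: int = DEFAULT_BINS,
    min_pixels: int = MIN_PIXELS,
    winner_takes_all: bool = False,
) -> PartitionResult:
    """Convenience wrapper chaining thresholding, distributions and partitioning."""
    maps = OrganelleMaps(lipid=lipid, prob_maps=dict(prob_maps))
    masks = threshold_maps(maps, threshold)
    dists = intensity_distributions(maps, masks, bins=bins, min_pixels=min_pixels)
    return partition_signal(maps, masks, dists, winner_takes_all=winner_takes_all)
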