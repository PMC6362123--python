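"""Greater-park-ecosystem (GPE) delineation.

Each protected area is matched with an equal-area control sample drawn from
its immediate surroundings: a square search window grows outward one pixel
ring at a time (Chebyshev distance) collecting unmasked pixels until a
candidate region twice the footprint's area is assembled, then pixels equal
in number to the footprint are sampled uniformly without replacement.

Water, agriculture, the target footprint itself, and every other protected
area are excluded from the candidate region, so the control never overlaps
protection or non-land.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import PreconditionError
from .landscape import LandscapeGrid, PPARecord, PixelSet, pixel_bool_mask
from .rng import substream_seed

logger = logging.getLogger(__name__)

# 100 km at 30 m per pixel: the default cap on search-window growth
DEFAULT_MAX_RADIUS_PX = 3333


@dataclass
class GPESample:
    """The matched neighbourhood of one protected area."""

    ppa_id: str
    candidate_region: PixelSet
    sample: PixelSet
    max_ring_used: int
    complete: bool
    seed: int

    @property
    def n_candidate(self) -> int:
        return len(self.candidate_region)

    @property
    def n_sample(self) -> int:
        return len(self.sample)


def build_exclusion_mask(
    grid: LandscapeGrid,
    all_ppas: Sequence[PPARecord],
    target_ppa: PPARecord,
) -> np.ndarray:
    """Pixels that may NOT enter the GPE: water, agriculture, the target
    footprint, and every other protected area's footprint."""
    mask = grid.water_mask | grid.agri_mask
    mask = mask | pixel_bool_mask(target_ppa.footprint, grid.shape)
    for ppa in all_ppas:
        if ppa.id != target_ppa.id:
            mask = mask | pixel_bool_mask(ppa.footprint, grid.shape)
    return mask


def chebyshev_distance_to(footprint: PixelSet, shape) -> np.ndarray:
    """Minimum Chebyshev distance from every pixel to the footprint (0 inside)."""
    fp = pixel_bool_mask(footprint, shape)
    return ndimage.distance_transform_cdt(~fp, metric="chessboard")


def grow_candidate_region(
    ppa: PPARecord,
    mask: np.ndarray,
    grid: LandscapeGrid,
    max_radius_px: int = DEFAULT_MAX_RADIUS_PX,
    seed: int = 0,
) -> GPESample:
    """Grow the search window until the candidate reaches twice the footprint.

    Complete rings (all unmasked pixels at Chebyshev distance d = 1, 2, ...)
    are accumulated; the overshooting final ring is trimmed by seeded uniform
    sampling without replacement so the candidate hits exactly 2x the
    footprint size.  If ``max_radius_px`` is exhausted first, whatever was
    found is returned with ``complete = False``.
    """
    if len(ppa.footprint) == 0:
        raise PreconditionError(f"PPA {ppa.id}: empty footprint")
    target = 2 * len(ppa.footprint)
    dist = chebyshev_distance_to(ppa.footprint, grid.shape)
    eligible = ~mask
    candidate: list = []
    max_ring_used = 0
    complete = False
    rng = np.random.default_rng(seed)
    max_d = int(min(max_radius_px, dist.max()))
    for d in range(1, max_d + 1):
        ring_mask = (dist == d) & eligible
        ring = [(int(r), int(c)) for r, c in np.argwhere(ring_mask)]
        if not ring:
            continue
        need = target - len(candidate)
        if len(ring) >= need:
            ring.sort()
            idx = rng.choice(len(ring), size=need, replace=False)
            candidate.extend(ring[i] for i in sorted(idx))
            max_ring_used = d
            complete = True
            break
        candidate.extend(ring)
        max_ring_used = d
    if not complete:
        logger.warning(
            "PPA %s: candidate region incomplete (%d of %d pixels within radius %d)",
            ppa.id,
            len(candidate),
            target,
            max_radius_px,
        )
    return GPESample(
        ppa_id=ppa.id,
        candidate_region=frozenset(candidate),
        sample=frozenset(),
        max_ring_used=max_ring_used,
        complete=complete,
        seed=seed,
    )


def sample_gpe(candidate_region: PixelSet, n: int, seed: int) -> PixelSet:
    """Uniform sample without replacement of ``min(n, |candidate|)`` pixels."""
    pool = sorted(candidate_region)
    if not pool:
        logger.warning("empty candidate region; returning empty sample")
        return frozenset()
    rng = np.random.default_rng(seed)
    k = min(n, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    return frozenset(pool[i] for i in idx)


def delineate(
    ppa: PPARecord,
    all_ppas: Sequence[PPARecord],
    grid: LandscapeGrid,
    max_radius_px: int = DEFAULT_MAX_RADIUS_PX,
    master_seed: int = 0,
) -> GPESample:
    """Full delineation of one unit: exclusion mask, ring growth, sampling.

    The per-unit seed is a substream of ``(master_seed, "gpe", ppa.id)`` so
    results for one unit are independent of which other distant units exist.
    """
    mask = build_exclusion_mask(grid, all_ppas, ppa)
    seed = substream_seed(master_seed, "gpe", ppa.id)
    gpe = grow_candidate_region(ppa, mask, grid, max_radius_px=max_radius_px, seed=seed)
    sample = sample_gpe(gpe.candidate_region, len(ppa.footprint), seed=seed + 1)
    gpe.sample = sample
    return gpe


def delineate_all(
    ppas: Sequence[PPARecord],
    grid: LandscapeGrid,
    max_radius_px: int = DEFAULT_MAX_RADIUS_PX,
    master_seed: int = 0,
) -> Dict[str, GPESample]:
    return {
        ppa.id: delineate(ppa, ppas, grid, max_radius_px=max_radius_px, master_seed=master_seed)
        for ppa in ppas
    }
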