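"""Seeded synthetic worlds: suitability stacks and fossil-record tables.

The generator emulates the statistical structure a paleometric evaluation
assumes, without any real data:

* per-slice suitability surfaces that are smooth in space (mixtures of
  Gaussian bumps) and drift gradually between consecutive slices, over a
  coastline-like validity mask;
* fossil sites placed on the grid whose probability of *recording* the
  target taxon rises logistically with the true suitability of their cell;
* taphonomic structure: site species richness is skewed (most sites hold
  only a few species) and rises with habitat suitability — richer, more
  productive environments accumulate and preserve more taxa — while a
  richness-dependent false-absence rate erases the target taxon from the
  most sparsely sampled sites;
* dating uncertainty: each site carries a calibrated interval whose width
  ranges from a fraction of a time slice to several slices;
* a configurable fraction of sites displaced onto invalid (off-grid /
  coastal) cells, exercising the snapping step.

Everything is driven by one seed per spec; identical specs give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridTransform, SuitabilityGrid, SuitabilityStack
from .records import DEFAULT_SCHEME, PaleoSite, TimeSliceScheme


@dataclass(frozen=True)
class WorldSpec:
    """Shape and dynamics of a synthetic suitability world.

    Defaults mirror a continental-scale study box (lon -23..63.4, lat
    -45..45 at 1.8-degree cells) with eight Holocene slices.
    """

    nrows: int = 50
    ncols: int = 48
    x_origin: float = -23.0
    y_origin: float = 45.0
    cell_size: float = 1.8
    scheme: TimeSliceScheme = DEFAULT_SCHEME
    smoothness: float = 6.0  # Gaussian bump sigma, in cells
    n_bumps: int = 25
    drift: float = 0.05  # max mean |difference| between consecutive slices
    invalid_fraction: float = 0.2  # share of cells masked out ("sea")
    seed: int = 0

    def __post_init__(self):
        if self.nrows < 5 or self.ncols < 5:
            raise ValueError("grid must be at least 5x5")
        if self.drift < 0:
            raise ValueError("drift must be >= 0")
        if not 0.0 <= self.invalid_fraction < 1.0:
            raise ValueError("invalid_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class RecordSpec:
    """Statistical structure of a synthetic fossil-record table.

    detection_slope
        Slope of the logistic link between true suitability (centred at
        0.5) and the probability that the target taxon is recorded at a
        site; ``math.inf`` gives a hard threshold at 0.5.
    detection_ceiling
        Upper bound on the recording probability: even in ideal habitat a
        taxon is preserved *and* recovered well short of certainty, so the
        logistic link is scaled by this ceiling.
    richness_coupling
        How strongly site species richness rises with suitability; 0
        decouples them.  Richness itself is geometric (mode 1-2 species),
        matching the right-skew of real faunal compilations.
    recovery_scale
        Site richness is also a proxy for preservation/sampling quality, so
        detection is further damped by ``1 - exp(-richness/recovery_scale)``:
        a sparsely sampled assemblage is unlikely to record any given taxon
        even in ideal habitat.  Larger values damp harder; 0 disables.
    false_absence_max / false_absence_scale
        A recorded presence at a site of richness r is erased (turned into
        a false absence) with probability ``max * exp(-(r-1)/scale)`` —
        the sparser the site, the likelier the taxon was missed.
    interval_width_range
        Date-interval widths drawn uniformly between these multiples of
        the mean slice width, so records span anything from a fraction of
        a slice to several slices.
    displaced_fraction
        Exact fraction of sites whose coordinates are moved onto an
        invalid cell adjacent to their home cell (coastal off-grid points).
    """

    n_sites: int = 200
    taxon: str = "Alcelaphus buselaphus"
    detection_slope: float = 6.0
    detection_ceiling: float = 0.6
    richness_coupling: float = 0.65
    richness_base_p: float = 0.85
    recovery_scale: float = 2.0
    false_absence_max: float = 0.35
    false_absence_scale: float = 4.0
    interval_width_range: tuple[float, float] = (0.1, 3.0)
    displaced_fraction: float = 0.1
    n_filler_taxa: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.false_absence_max <= 1.0:
            raise ValueError("false_absence_max must lie in [0, 1]")
        if not 0.0 < self.detection_ceiling <= 1.0:
            raise ValueError("detection_ceiling must lie in (0, 1]")
        if not 0.0 <= self.displaced_fraction <= 1.0:
            raise ValueError("displaced_fraction must lie in [0, 1]")
        lo, hi = self.interval_width_range
        if lo <= 0 or hi < lo:
            raise ValueError("bad interval_width_range")


def _bump_field(rng: np.random.Generator, nrows: int, ncols: int,
                n_bumps: int, sigma: float) -> np.ndarray:
    """Smooth random field as a signed mixture of Gaussian bumps."""
    rr, cc = np.mgrid[0:nrows, 0:ncols].astype(float)
    out = np.zeros((nrows, ncols))
    for _ in range(n_bumps):
        r0 = rng.uniform(0, nrows)
        c0 = rng.uniform(0, ncols)
        amp = rng.uniform(-1.0, 1.0)
        out += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2))
    return out


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def generate_stack(spec: WorldSpec) -> tuple[SuitabilityStack, dict[str, np.ndarray]]:
    """Generate a per-slice suitability stack plus its latent truth.

    Each slice is a bounded perturbation of the previous one: the mean
    absolute difference between consecutive slices never exceeds
    ``spec.drift``.  The returned truth dict maps slice label to the same
    arrays the stack holds (the stack *is* a perfect model of this world;
    imperfect models are made by perturbing or refitting on top of it).
    """
    rng = np.random.default_rng(spec.seed)
    transform = GridTransform(
        x_origin=spec.x_origin,
        y_origin=spec.y_origin,
        cell_size=spec.cell_size,
        nrows=spec.nrows,
        ncols=spec.ncols,
    )

    land = _bump_field(rng, spec.nrows, spec.ncols, spec.n_bumps, spec.smoothness)
    if spec.invalid_fraction > 0:
        mask = land > np.quantile(land, spec.invalid_fraction)
    else:
        mask = np.ones_like(land, dtype=bool)

    current = _minmax(
        _bump_field(rng, spec.nrows, spec.ncols, spec.n_bumps, spec.smoothness)
    )
    grids: dict[str, SuitabilityGrid] = {}
    truth: dict[str, np.ndarray] = {}
    for ts in spec.scheme.slices:
        if truth:  # perturb the previous slice
            g = _bump_field(rng, spec.nrows, spec.ncols, spec.n_bumps, spec.smoothness)
            gmax = np.abs(g).max()
            if gmax > 0:
                g = g / gmax  # |g| <= 1, so mean |delta| <= drift
            current = np.clip(current + spec.drift * g, 0.0, 1.0)
        values = np.where(mask, current, np.nan)
        grids[ts.label] = SuitabilityGrid(values=values, transform=transform, mask=mask)
        truth[ts.label] = values.copy()
    return SuitabilityStack(grids=grids), truth


def perturb_stack(
    stack: SuitabilityStack,
    magnitude: float,
    seed: int,
    n_bumps: int = 25,
    smoothness: float = 6.0,
) -> SuitabilityStack:
    """An imperfect model of a world: each slice plus a smooth error field.

    ``magnitude`` scales a smooth random field normalised to [-1, 1], so the
    per-cell absolute prediction error is bounded by it.  Use this to turn
    the latent truth into the kind of partially wrong projection a fitted
    SDM produces, e.g. before studying how evaluation metrics respond to
    record biases.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, SuitabilityGrid] = {}
    for label, grid in stack.grids.items():
        g = _bump_field(rng, *grid.shape, n_bumps, smoothness)
        gmax = np.abs(g).max()
        if gmax > 0:
            g = g / gmax
        values = np.clip(grid.values + magnitude * g, 0.0, 1.0)
        values = np.where(grid.mask, values, np.nan)
        out[label] = SuitabilityGrid(
            values=values, transform=grid.transform, mask=grid.mask.copy()
        )
    return SuitabilityStack(grids=out)


def _detection_probability(s: float, slope: float, ceiling: float = 1.0) -> float:
    if math.isinf(slope):
        base = 1.0 if s > 0.5 else (0.5 if s == 0.5 else 0.0)
    else:
        base = 1.0 / (1.0 + math.exp(-slope * (s - 0.5)))
    return ceiling * base


def generate_records(
    stack: SuitabilityStack,
    spec: RecordSpec,
    scheme: TimeSliceScheme = DEFAULT_SCHEME,
) -> tuple[list[PaleoSite], pd.DataFrame]:
    """Generate a dated fossil-record table over a synthetic world.

    Returns the sites plus a per-site truth table (home cell, true
    suitability, detection probability, recorded/false-absence flags,
    richness, displacement) for oracle tests.
    """
    rng = np.random.default_rng(spec.seed)
    ref = next(iter(stack.grids.values()))
    mask = ref.mask
    transform = ref.transform
    valid_rows, valid_cols = np.nonzero(mask)
    if valid_rows.size == 0:
        raise ValueError("stack has no valid cells")

    # invalid 8-neighbours per cell, for coastal displacement
    def invalid_neighbours(row: int, col: int) -> list[tuple[int, int]]:
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                r, c = row + dr, col + dc
                if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and not mask[r, c]:
                    out.append((r, c))
        return out

    coastal = [
        k
        for k in range(valid_rows.size)
        if invalid_neighbours(int(valid_rows[k]), int(valid_cols[k]))
    ]
    n_displaced = round(spec.displaced_fraction * spec.n_sites)
    if n_displaced > 0 and not coastal:
        raise ValueError("mask has no coastal cells to displace sites onto")

    slice_width = (scheme.end_bp - scheme.start_bp + 1) / len(scheme.slices)
    wlo, whi = spec.interval_width_range
    filler_pool = np.array([f"taxon_{i:02d}" for i in range(spec.n_filler_taxa)])

    displaced_flags = np.zeros(spec.n_sites, dtype=bool)
    displaced_flags[:n_displaced] = True

    sites: list[PaleoSite] = []
    rows = []
    for i in range(spec.n_sites):
        if displaced_flags[i]:
            k = int(rng.choice(coastal))
        else:
            k = int(rng.integers(0, valid_rows.size))
        row, col = int(valid_rows[k]), int(valid_cols[k])

        center = rng.uniform(scheme.start_bp, scheme.end_bp)
        width = rng.uniform(wlo, whi) * slice_width
        earliest = int(round(center + width / 2.0))
        latest = max(0, int(round(center - width / 2.0)))
        home_slice = scheme.slice_of(int(round(center)))
        s = float(stack[home_slice.label].values[row, col])

        p_geo = float(
            np.clip(spec.richness_base_p - spec.richness_coupling * s, 0.2, 0.9)
        )
        richness = int(rng.geometric(p_geo))

        q = _detection_probability(s, spec.detection_slope, spec.detection_ceiling)
        if spec.recovery_scale > 0:
            q *= 1.0 - math.exp(-richness / spec.recovery_scale)
        recorded = bool(rng.random() < q)

        fa_rate = spec.false_absence_max * math.exp(
            -(richness - 1) / spec.false_absence_scale
        )
        false_absence = bool(recorded and rng.random() < fa_rate)
        presence = recorded and not false_absence

        n_fillers = richness - 1 if presence else richness
        n_fillers = min(n_fillers, spec.n_filler_taxa)
        fillers = rng.choice(filler_pool, size=n_fillers, replace=False)
        taxa = frozenset(fillers) | ({spec.taxon} if presence else frozenset())
        if not taxa:  # presence-less site with richness 1 and no fillers left
            taxa = frozenset({str(filler_pool[0])})

        if displaced_flags[i]:
            nbrs = invalid_neighbours(row, col)
            r2, c2 = nbrs[int(rng.integers(0, len(nbrs)))]
            lon, lat = transform.cell_center(r2, c2)
        else:
            lon, lat = transform.cell_center(row, col)

        site_id = f"site_{i:04d}"
        sites.append(
            PaleoSite(
                site_id=site_id,
                longitude=float(lon),
                latitude=float(lat),
                taxa=taxa,
                earliest_bp=earliest,
                latest_bp=latest,
            )
        )
        rows.append(
            {
                "site_id": site_id,
                "row": row,
                "col": col,
                "displaced": bool(displaced_flags[i]),
                "home_slice": home_slice.label,
                "suitability": s,
                "detection_prob": q,
                "recorded": recorded,
                "false_absence": false_absence,
                "presence": presence,
                "richness": len(sites[-1].taxa),
                "earliest_bp": earliest,
                "latest_bp": latest,
            }
        )
    return sites, pd.DataFrame(rows)
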