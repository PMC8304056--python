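"""Assemble measurable systems from free-floating bilayer SLD profiles.

A simulated bilayer floats in water with no substrate; the measured system is a
supported film (or a multilayer of tens of repeats).  The operations here splice
a semi-infinite substrate with its native oxide in front of the profile, adjust
the substrate–membrane water gap, tile a unit cell into a lamellar multilayer,
draw disorder ensembles over the interlamellar water thicknesses, rescale
solvent regions (contamination scenarios) and coarsen binned profiles to slab
stacks for the reflectivity kernels.

Splicing is guarded: a discontinuous junction between the substrate block and
the membrane profile would create spurious high-frequency structure in the
reflectivity, so junction mismatches beyond a tolerance raise instead of
silently producing artefacts.  Likewise, tiling enforces that the unit cell
terminates in equal half water gaps — an unequal merge would double the lattice
constant and introduce a spurious Bragg peak at half the first-order position
(available deliberately via ``allow_asymmetry=True``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import erf

from .profiles import SLDProfile

__all__ = [
    "SubstrateSpec",
    "DisorderSpec",
    "Slab",
    "SlabStack",
    "splice_substrate",
    "adjust_water_gap",
    "tile_unit_cell",
    "jitter_ensemble",
    "scale_region_sld",
    "profile_to_slabs",
]

#: Default junction-continuity tolerance, Å⁻² (0.2e-6 in display units).
SPLICE_TOL = 2.0e-7


@dataclass(frozen=True)
class SubstrateSpec:
    """Semi-infinite fronting (e.g. Si) plus a native oxide layer.

    ``oxide_roughness`` smooths the fronting/oxide interface, ``sample_roughness``
    the oxide/solvent interface; both are Gaussian sigmas in Å realized as
    erf-shaped micro-slab transitions when splicing into a binned profile.
    """

    fronting_sld: float
    oxide_thickness: float = 0.0
    oxide_sld: float = 3.47e-6
    oxide_roughness: float = 0.0
    sample_roughness: float = 0.0

    def __post_init__(self) -> None:
        if self.oxide_thickness < 0:
            raise ValueError("oxide thickness must be >= 0")
        if self.oxide_roughness < 0 or self.sample_roughness < 0:
            raise ValueError("roughness sigmas must be >= 0")


@dataclass(frozen=True)
class DisorderSpec:
    """Zero-mean jitter of interlamellar water thicknesses.

    ``distribution`` 'uniform' draws from ±width, 'normal' from N(0, width²);
    ``n_realizations`` independent stacks are generated from ``seed``.
    """

    width: float
    distribution: Literal["uniform", "normal"] = "uniform"
    n_realizations: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError("jitter width must be >= 0")
        if self.n_realizations < 1:
            raise ValueError("need at least one realization")
        if self.distribution not in ("uniform", "normal"):
            raise ValueError("distribution must be 'uniform' or 'normal'")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.distribution == "uniform":
            return rng.uniform(-self.width, self.width, size=n)
        return rng.normal(0.0, self.width, size=n)


@dataclass(frozen=True)
class Slab:
    """One homogeneous layer: thickness (Å), SLD (Å⁻²), roughness σ (Å) of the
    interface between this slab and the medium before it (fronting side)."""

    thickness: float
    sld: complex
    roughness: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("slab thickness must be > 0")
        if self.roughness < 0:
            raise ValueError("roughness must be >= 0")


@dataclass
class SlabStack:
    """Fronting medium, ordered slabs (beam-incidence order), backing medium.

    ``backing_roughness`` is the σ of the last-slab/backing interface (or of the
    bare fronting/backing interface when there are no slabs).
    """

    fronting_sld: complex
    slabs: list[Slab]
    backing_sld: complex
    backing_roughness: float = 0.0

    @property
    def n_slabs(self) -> int:
        return len(self.slabs)

    @property
    def total_thickness(self) -> float:
        return sum(s.thickness for s in self.slabs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(slds of all media, slab thicknesses, per-interface sigmas)."""
        slds = np.array(
            [self.fronting_sld] + [s.sld for s in self.slabs] + [self.backing_sld],
            dtype=complex,
        )
        d = np.array([s.thickness for s in self.slabs], dtype=float)
        sigma = np.array(
            [s.roughness for s in self.slabs] + [self.backing_roughness], dtype=float
        )
        return slds, d, sigma

    def reversed(self) -> "SlabStack":
        rough = [s.roughness for s in self.slabs] + [self.backing_roughness]
        slabs = [
            Slab(s.thickness, s.sld, rough[i + 1])
            for i, s in reversed(list(enumerate(self.slabs)))
        ]
        return SlabStack(self.backing_sld, slabs, self.fronting_sld, rough[0])


def _n_bins(thickness: float, width: float) -> int:
    return int(round(thickness / width))


def splice_substrate(
    profile: SLDProfile,
    substrate: SubstrateSpec,
    water_gap: float,
    bulk_solvent_sld: float,
    tol: float = SPLICE_TOL,
) -> SLDProfile:
    """Prepend [fronting | oxide | water gap] to a membrane profile.

    The membrane profile must begin in bulk solvent (its first bin within
    ``tol`` of ``bulk_solvent_sld``), otherwise the junction would be
    discontinuous and the reflectivity would carry splice artefacts.  Roughness
    of the fronting/oxide and oxide/solvent interfaces is realized as erf
    transitions evaluated on the bin grid; a fronting pad of 4σ is included so
    the transition is fully contained in the binned region.
    """
    if water_gap < 0:
        raise ValueError("water_gap must be >= 0")
    dz = profile.bin_width
    if abs(profile.rho[0] - bulk_solvent_sld) > tol:
        raise ValueError(
            "membrane profile does not start in bulk solvent: "
            f"|{profile.rho[0]:.3e} - {bulk_solvent_sld:.3e}| > {tol:.1e}"
        )
    sig1, sig2 = substrate.oxide_roughness, substrate.sample_roughness
    pad = _n_bins(4.0 * max(sig1, sig2), dz) if max(sig1, sig2) > 0 else 0
    n_ox = _n_bins(substrate.oxide_thickness, dz)
    n_gap = _n_bins(water_gap, dz)

    n_front = pad + n_ox + n_gap
    z = (np.arange(n_front) + 0.5) * dz
    z_ox = pad * dz          # fronting/oxide interface position
    z_gap = (pad + n_ox) * dz  # oxide/solvent interface position

    rho_front = np.full(n_front, substrate.fronting_sld)
    if n_ox > 0:
        step1 = (
            0.5 * (1.0 + erf((z - z_ox) / (sig1 * math.sqrt(2.0))))
            if sig1 > 0
            else (z > z_ox).astype(float)
        )
        step2 = (
            0.5 * (1.0 + erf((z - z_gap) / (sig2 * math.sqrt(2.0))))
            if sig2 > 0
            else (z > z_gap).astype(float)
        )
        rho_front = (
            substrate.fronting_sld
            + (substrate.oxide_sld - substrate.fronting_sld) * step1
            + (bulk_solvent_sld - substrate.oxide_sld) * step2
        )
    else:
        # no oxide: single fronting/solvent transition at z_gap's left edge
        step = (
            0.5 * (1.0 + erf((z - z_ox) / (sig2 * math.sqrt(2.0))))
            if sig2 > 0
            else (z >= z_ox).astype(float)
        )
        rho_front = substrate.fronting_sld + (
            bulk_solvent_sld - substrate.fronting_sld
        ) * step

    # junction continuity guards
    if n_front > 0 and abs(rho_front[-1] - profile.rho[0]) > max(tol, 4.0 * tol):
        raise ValueError("discontinuous splice between water gap and membrane profile")

    rho = np.concatenate([rho_front, profile.rho])
    edges = np.arange(len(rho) + 1) * dz
    meta = dict(profile.metadata)
    meta.update(
        substrate=substrate, water_gap=n_gap * dz, bulk_solvent_sld=bulk_solvent_sld
    )
    return SLDProfile(
        edges, rho, fronting=substrate.fronting_sld, backing=bulk_solvent_sld, metadata=meta
    )


def adjust_water_gap(
    profile: SLDProfile,
    region: tuple[int, int],
    new_thickness: float,
    tol: float = SPLICE_TOL,
) -> SLDProfile:
    """Resize a flat solvent region to ``new_thickness`` (rounded to bins).

    ``region`` is a (start, stop) bin-index range that must be flat (all bins
    within ``tol`` of their mean).  Whole bins of the region's solvent SLD are
    inserted or removed at the region start; everything else is untouched.
    """
    if new_thickness < 0:
        raise ValueError("new_thickness must be >= 0")
    start, stop = region
    if not (0 <= start < stop <= len(profile.rho)):
        raise ValueError("invalid region bin range")
    seg = profile.rho[start:stop]
    solvent = float(np.mean(seg))
    if np.max(np.abs(seg - solvent)) > tol:
        raise ValueError("water-gap region is not flat within tolerance")
    dz = profile.bin_width
    n_new = _n_bins(new_thickness, dz)
    # keep existing solvent bins bit-identical; only insert/remove whole bins
    if n_new <= stop - start:
        new_seg = seg[:n_new]
    else:
        new_seg = np.concatenate([seg, np.full(n_new - (stop - start), solvent)])
    rho = np.concatenate([profile.rho[:start], new_seg, profile.rho[stop:]])
    edges = profile.bin_edges[0] + np.arange(len(rho) + 1) * dz
    out = profile.copy()
    out.bin_edges, out.rho, out.breakdown = edges, rho, None
    return out


def _solvent_run_lengths(rho: np.ndarray, solvent: float, tol: float) -> list[tuple[int, int]]:
    """Maximal runs of bins within tol of the solvent SLD, as (start, stop)."""
    mask = np.abs(rho - solvent) <= tol
    runs = []
    i = 0
    n = len(rho)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _split_unit(unit: SLDProfile, tol: float):
    """Split a unit cell into (lead gap bins, interior, trail gap bins, solvent)."""
    solvent = 0.5 * (unit.rho[0] + unit.rho[-1])
    if abs(unit.rho[0] - unit.rho[-1]) > tol:
        raise ValueError("unit cell must start and end in the same bulk solvent")
    runs = _solvent_run_lengths(unit.rho, solvent, tol)
    if not runs or runs[0][0] != 0 or runs[-1][1] != len(unit.rho):
        raise ValueError("unit cell must start and end in bulk solvent")
    lead = runs[0][1] - runs[0][0]
    trail = runs[-1][1] - runs[-1][0]
    internal = [b - a for a, b in runs[1:-1]]
    return lead, trail, internal, solvent


def tile_unit_cell(
    unit: SLDProfile,
    n: int,
    tol: float = SPLICE_TOL,
    allow_asymmetry: bool = False,
    gap_tol_bins: int = 2,
) -> SLDProfile:
    """Repeat a lamellar unit cell n times along z.

    The unit must terminate in half water gaps that merge into one full
    interlamellar gap equal (within ``gap_tol_bins`` bins) to any gaps interior
    to the unit; violating this silently would double the lattice constant and
    fabricate a Bragg peak at half the first-order position, so it is an error
    unless ``allow_asymmetry=True`` is passed deliberately.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lead, trail, internal, solvent = _split_unit(unit, tol)
    if not allow_asymmetry:
        if abs(lead - trail) > gap_tol_bins:
            raise ValueError(
                f"unequal end half-gaps ({lead} vs {trail} bins) would double the "
                "lattice constant (spurious half-order Bragg peak); equalize them "
                "or pass allow_asymmetry=True"
            )
        merged = lead + trail
        for g in internal:
            if abs(g - merged) > gap_tol_bins:
                raise ValueError(
                    f"interior water gap ({g} bins) differs from merged end gap "
                    f"({merged} bins): period-doubling artefact; equalize or pass "
                    "allow_asymmetry=True"
                )
    rho = np.tile(unit.rho, n)
    dz = unit.bin_width
    edges = np.arange(len(rho) + 1) * dz
    out = SLDProfile(
        edges,
        rho,
        fronting=unit.fronting,
        backing=unit.backing if unit.backing is not None else solvent,
        metadata=dict(unit.metadata, n_repeats=n, d_spacing=unit.thickness),
    )
    return out


def jitter_ensemble(
    unit: SLDProfile,
    n: int,
    disorder: DisorderSpec,
    tol: float = SPLICE_TOL,
) -> list[SLDProfile]:
    """Stacks with independently jittered interlamellar water thicknesses.

    Each realization tiles the unit's interior (membrane plus any interior
    gaps) with the n−1 merged junction gaps resized by zero-mean jitter; end
    half-gaps stay fixed.  Reproducible for a fixed ``disorder.seed``; averaging
    over the ensemble happens in reflectivity space (incoherent addition), not
    on the profiles.
    """
    lead, trail, internal, solvent = _split_unit(unit, tol)
    dz = unit.bin_width
    base_gap = (lead + trail) * dz
    interior = unit.rho[lead : len(unit.rho) - trail]
    rng = np.random.default_rng(disorder.seed)
    out = []
    for _ in range(disorder.n_realizations):
        deltas = disorder.draw(rng, max(n - 1, 0))
        gaps = base_gap + deltas
        if np.any(gaps <= 0):
            raise ValueError("jitter produced a non-positive water gap")
        parts = [np.full(lead, solvent), interior]
        for g in gaps:
            parts.append(np.full(_n_bins(g, dz), solvent))
            parts.append(interior)
        parts.append(np.full(trail, solvent))
        rho = np.concatenate(parts)
        edges = np.arange(len(rho) + 1) * dz
        out.append(
            SLDProfile(
                edges,
                rho,
                fronting=unit.fronting,
                backing=unit.backing if unit.backing is not None else solvent,
                metadata=dict(unit.metadata, n_repeats=n),
            )
        )
    return out


def scale_region_sld(
    profile: SLDProfile,
    region,
    factor: float,
    solvent_tol_rel: float = 0.01,
) -> SLDProfile:
    """Multiply the SLD of a solvent region by ``factor``.

    ``region`` is 'bulk_only' (the trailing solvent run adjoining the backing,
    plus the semi-infinite backing itself — detached-contaminant scenario),
    'all_solvent' (every bin within 1% of the backing SLD, plus backing —
    isotopic-contamination scenario), or an explicit boolean mask / index array
    over bins.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    out = profile.copy()
    out.breakdown = None
    if isinstance(region, str):
        if out.backing is None:
            raise ValueError("profile has no backing SLD to identify solvent against")
        solvent = out.backing
        tol = abs(solvent) * solvent_tol_rel
        if region == "bulk_only":
            n = len(out.rho)
            j = n
            while j > 0 and abs(out.rho[j - 1] - solvent) <= tol:
                j -= 1
            out.rho[j:] *= factor
            out.backing *= factor
        elif region == "all_solvent":
            mask = np.abs(out.rho - solvent) <= tol
            if not np.any(mask):
                raise ValueError("no solvent bins found within tolerance")
            out.rho[mask] *= factor
            out.backing *= factor
        else:
            raise ValueError(f"unknown region {region!r}")
    else:
        idx = np.asarray(region)
        out.rho[idx] *= factor
    return out


def profile_to_slabs(profile: SLDProfile, coarsen_tolerance: float = 0.0) -> SlabStack:
    """Discretize a binned profile into a zero-roughness slab stack.

    Adjacent bins whose SLD spread stays within ``coarsen_tolerance`` are merged
    into one slab with thickness-weighted SLD; tolerance 0 keeps one slab per
    bin.  Fronting/backing default to the profile's end media, or its end bins
    for free profiles.
    """
    fronting = profile.fronting if profile.fronting is not None else float(profile.rho[0])
    backing = profile.backing if profile.backing is not None else float(profile.rho[-1])
    dz = profile.bin_width
    rho = profile.rho
    if coarsen_tolerance <= 0.0:
        slabs = [Slab(dz, float(r), 0.0) for r in rho]
        return SlabStack(fronting, slabs, backing)
    slabs: list[Slab] = []
    i = 0
    n = len(rho)
    while i < n:
        j = i + 1
        lo = hi = rho[i]
        while j < n:
            lo2, hi2 = min(lo, rho[j]), max(hi, rho[j])
            if hi2 - lo2 > coarsen_tolerance:
                break
            lo, hi = lo2, hi2
            j += 1
        seg = rho[i:j]
        slabs.append(Slab((j - i) * dz, float(np.mean(seg)), 0.0))
        i = j
    return SlabStack(fronting, slabs, backing)
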