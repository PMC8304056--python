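"""Number-density histograms along the membrane normal and their SLD profiles.

Trajectory frames are sliced into thin z-bins (default 0.13 Å); per-species atom
counts per slice, divided by the slice volume, give number densities that are
averaged over frames.  Multiplying each species density by its coherent
scattering length yields the SLD profile, and selective deuteration is a pure
relabelling of the density histogram (H → D on the chosen species) — densities
never change, only the b they are multiplied with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .tables import FM_TO_ANGSTROM, IsotopeTable, default_table

__all__ = [
    "Frame",
    "DensityProfile",
    "SLDProfile",
    "bin_number_density",
    "average_profiles",
    "apply_isotope_substitution",
    "density_to_sld",
]

GROUPS = ("head", "tail", "water", "other")


@dataclass
class Frame:
    """One trajectory frame: per-atom isotope labels, group tags and coordinates.

    ``positions`` is (n_atoms, 3) in Å; ``box`` is (Lx, Ly, Lz) in Å.  Group tags
    are 'head' / 'tail' / 'water' / 'other'.
    """

    isotopes: np.ndarray
    groups: np.ndarray
    positions: np.ndarray
    box: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.isotopes = np.asarray(self.isotopes, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_atoms, 3)")
        if len(self.isotopes) != len(self.positions) or len(self.groups) != len(
            self.positions
        ):
            raise ValueError("isotopes/groups/positions length mismatch")
        if any(L <= 0 for L in self.box):
            raise ValueError("box lengths must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def species(self) -> set[tuple[str, str]]:
        """The set of (group, isotope) species present in the frame."""
        return set(zip(self.groups, self.isotopes))


@dataclass
class DensityProfile:
    """Per-species mean number density (Å⁻³) on a uniform z grid.

    ``densities`` maps (group, isotope) -> array of length n_bins.  ``axis_area``
    is the mean in-plane box area (Å²) over the contributing frames, so that
    density · Δz · axis_area integrates back to atom counts per frame.
    """

    bin_edges: np.ndarray
    densities: dict[tuple[str, str], np.ndarray]
    n_frames: int
    axis_area: float

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def counts_per_frame(self, species: tuple[str, str]) -> float:
        """Number of atoms of a species per frame implied by the histogram."""
        return float(np.sum(self.densities[species]) * self.bin_width * self.axis_area)


@dataclass
class SLDProfile:
    """Binned SLD profile ρ(z) in Å⁻², optionally flanked by semi-infinite media.

    ``fronting``/``backing`` are the SLDs of the semi-infinite media before the
    first and after the last bin (None for a free-floating profile).
    ``breakdown`` optionally keeps per-group SLD contributions summing bin-wise
    to ``rho``.
    """

    bin_edges: np.ndarray
    rho: np.ndarray
    fronting: float | None = None
    backing: float | None = None
    breakdown: dict[str, np.ndarray] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if len(self.bin_edges) != len(self.rho) + 1:
            raise ValueError("bin_edges must have len(rho) + 1 entries")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bin grid must be uniform")
        if not np.all(np.isfinite(self.rho)):
            raise ValueError("SLD profile contains non-finite values")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def thickness(self) -> float:
        return float(self.bin_edges[-1] - self.bin_edges[0])

    def copy(self) -> "SLDProfile":
        return SLDProfile(
            self.bin_edges.copy(),
            self.rho.copy(),
            self.fronting,
            self.backing,
            None
            if self.breakdown is None
            else {k: v.copy() for k, v in self.breakdown.items()},
            dict(self.metadata),
        )


def _center_shift(frame: Frame) -> float:
    """z shift placing the non-water centroid at 0 (all-water frames unshifted)."""
    mask = frame.groups != "water"
    if not np.any(mask):
        return 0.0
    return float(np.mean(frame.positions[mask, 2]))


def bin_number_density(
    frames: Sequence[Frame],
    bin_width: float = 0.13,
    center: bool = True,
) -> DensityProfile:
    """Histogram atoms of each (group, isotope) species into z slices.

    Each frame is optionally re-centered so the non-water centroid sits at z = 0
    (suppresses drift broadening of the time average), wrapped into its own box,
    and histogrammed on a fixed grid spanning the first frame's Lz symmetrically
    about zero.  Slice volumes use each frame's instantaneous in-plane area, so
    NPT box fluctuations are handled per frame.
    """
    if not frames:
        raise ValueError("need at least one frame")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    species = frames[0].species()
    for i, fr in enumerate(frames[1:], start=1):
        if fr.species() != species:
            raise ValueError(f"frame {i} has a different species set than frame 0")

    Lz0 = frames[0].box[2]
    n_bins = max(1, int(round(Lz0 / bin_width)))
    edges = np.linspace(-Lz0 / 2.0, Lz0 / 2.0, n_bins + 1)
    # keep requested bin width; grid length is Lz rounded to a whole bin count
    if abs(edges[1] - edges[0] - bin_width) > 1e-9:
        half = n_bins * bin_width / 2.0
        edges = np.linspace(-half, half, n_bins + 1)

    acc = {sp: np.zeros(n_bins) for sp in species}
    areas = []
    for fr in frames:
        Lx, Ly, Lz = fr.box
        z = fr.positions[:, 2].copy()
        if center:
            z -= _center_shift(fr)
        # wrap into (-Lz/2, Lz/2] with the frame's own box length
        z = (z + Lz / 2.0) % Lz - Lz / 2.0
        area = Lx * Ly
        areas.append(area)
        vol = bin_width * area
        for sp in species:
            mask = (fr.groups == sp[0]) & (fr.isotopes == sp[1])
            counts, _ = np.histogram(z[mask], bins=edges)
            acc[sp] += counts / vol
    n = len(frames)
    return DensityProfile(
        bin_edges=edges,
        densities={sp: a / n for sp, a in acc.items()},
        n_frames=n,
        axis_area=float(np.mean(areas)),
    )


def average_profiles(profiles: Sequence[DensityProfile]) -> DensityProfile:
    """Frame-count-weighted mean of density profiles on identical grids."""
    if not profiles:
        raise ValueError("need at least one profile")
    ref = profiles[0]
    for p in profiles[1:]:
        if len(p.bin_edges) != len(ref.bin_edges) or not np.allclose(
            p.bin_edges, ref.bin_edges
        ):
            raise ValueError("profiles are on different grids")
        if set(p.densities) != set(ref.densities):
            raise ValueError("profiles have different species sets")
    weights = np.array([p.n_frames for p in profiles], dtype=float)
    total = weights.sum()
    densities = {
        sp: sum(w * p.densities[sp] for w, p in zip(weights, profiles)) / total
        for sp in ref.densities
    }
    area = float(np.dot(weights, [p.axis_area for p in profiles]) / total)
    return DensityProfile(ref.bin_edges.copy(), densities, int(total), area)


Selection = Callable[[tuple[str, str]], bool]


def _as_predicate(selection) -> Selection:
    if callable(selection):
        return selection
    if isinstance(selection, str):  # a group tag
        return lambda sp: sp[0] == selection
    if isinstance(selection, tuple) and len(selection) == 2:
        return lambda sp: sp == tuple(selection)
    raise TypeError("selection must be a group tag, (group, isotope) pair or predicate")


def apply_isotope_substitution(
    profile: DensityProfile, selection, new_isotope: str
) -> DensityProfile:
    """Relabel selected species' densities with a new isotope (e.g. H → D).

    This is the histogram-level implementation of selective deuteration: the
    number densities are untouched, only the label (and hence the scattering
    length used later) changes.  Densities falling onto an existing label sum.
    """
    pred = _as_predicate(selection)
    matched = [sp for sp in profile.densities if pred(sp)]
    if not matched:
        raise ValueError("isotope substitution selection matched no species")
    out: dict[tuple[str, str], np.ndarray] = {}
    for sp, dens in profile.densities.items():
        key = (sp[0], new_isotope) if sp in matched else sp
        if key in out:
            out[key] = out[key] + dens
        else:
            out[key] = dens.copy()
    return DensityProfile(profile.bin_edges.copy(), out, profile.n_frames, profile.axis_area)


def density_to_sld(
    profile: DensityProfile,
    table: IsotopeTable | None = None,
    solvent_d2o_fraction: float | None = None,
    water_group: str = "water",
    keep_breakdown: bool = True,
) -> SLDProfile:
    """Multiply species densities by coherent scattering lengths and sum.

    ``solvent_d2o_fraction`` re-weights the *water* hydrogens with the linear
    H/D mix b = (1−f)·b_H + f·b_D before summation, implementing solvent
    contrast variation on a single density histogram.
    """
    table = table or default_table()
    n_bins = len(profile.bin_edges) - 1
    per_group: dict[str, np.ndarray] = {}
    for (group, isotope), dens in profile.densities.items():
        b = table.b_coherent(isotope)
        if (
            solvent_d2o_fraction is not None
            and group == water_group
            and isotope in ("H", "1H")
        ):
            f = solvent_d2o_fraction
            if not 0.0 <= f <= 1.0:
                raise ValueError("solvent_d2o_fraction must be in [0, 1]")
            b = (1.0 - f) * table.b_coherent("H") + f * table.b_coherent("2H")
        contrib = dens * b * FM_TO_ANGSTROM
        per_group[group] = per_group.get(group, np.zeros(n_bins)) + contrib
    rho = sum(per_group.values())
    meta = {"bin_width": profile.bin_width, "n_frames": profile.n_frames}
    if solvent_d2o_fraction is not None:
        meta["solvent_d2o_fraction"] = solvent_d2o_fraction
    return SLDProfile(
        profile.bin_edges.copy(),
        np.asarray(rho, dtype=float),
        breakdown=per_group if keep_breakdown else None,
        metadata=meta,
    )
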