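"""Synthetic stand-ins for every pipeline input: no downloads, fully seeded.

The bilayer fixture emulates the statistical structure of a free-floating
phospholipid bilayer trajectory — Gaussian head-group densities at ±z_h, a
Gaussian tail distribution about the midplane and uniform water outside the
membrane — with defaults on the scale of the study systems (128 lipids at
~60 Å² each, 3000 waters, ~66 Å repeat, 0.13 Å bins).  These are statistical
stand-ins, not physically realistic MD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .profiles import Frame, SLDProfile
from .reflectivity import ReflectivityCurve
from .sans import SansCurve

__all__ = [
    "BilayerFixtureSpec",
    "make_bilayer_frames",
    "make_water_frames",
    "make_slab_profile",
    "make_noisy_curve",
]

#: Pseudo-molecule compositions per group (isotope label -> atoms per molecule).
DEFAULT_COMPOSITIONS: dict[str, dict[str, int]] = {
    # phosphatidylcholine head + glycerol backbone (DMPC minus the two chains)
    "head": {"C": 10, "H": 18, "N": 1, "O": 8, "P": 1},
    # two myristoyl chains
    "tail": {"C": 26, "H": 54},
    "water": {"O": 1, "H": 2},
}


@dataclass(frozen=True)
class BilayerFixtureSpec:
    """Parameters of the Gaussian head/tail/uniform-water bilayer fixture.

    Heads are split evenly between leaflets at ±``z_head``; water fills the two
    slabs |z| > ``water_exclusion`` uniformly.  All lengths in Å.
    """

    n_lipids: int = 128
    n_waters: int = 3000
    z_head: float = 17.0
    head_width: float = 3.0
    tail_width: float = 6.0
    water_exclusion: float = 23.0
    box: tuple[float, float, float] = (62.0, 62.0, 66.0)
    n_frames: int = 10
    seed: int = 0
    compositions: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: DEFAULT_COMPOSITIONS
    )

    def __post_init__(self) -> None:
        if self.n_lipids <= 0 or self.n_waters <= 0:
            raise ValueError("molecule counts must be > 0")
        if self.head_width <= 0 or self.tail_width <= 0:
            raise ValueError("widths must be > 0")
        if self.water_exclusion >= self.box[2] / 2:
            raise ValueError("water exclusion zone fills the whole box")


def _molecule_atoms(comp: Mapping[str, int], n_mol: int, z: np.ndarray):
    """Expand per-molecule compositions into per-atom label arrays (point molecules)."""
    labels = []
    for iso, count in comp.items():
        labels.extend([iso] * count)
    labels = np.array(labels, dtype=object)
    iso_arr = np.tile(labels, n_mol)
    z_arr = np.repeat(z, len(labels))
    return iso_arr, z_arr


def make_bilayer_frames(spec: BilayerFixtureSpec) -> list[Frame]:
    """Draw seeded frames of the Gaussian bilayer fixture."""
    rng = np.random.default_rng(spec.seed)
    Lx, Ly, Lz = spec.box
    frames = []
    n_per_leaflet = spec.n_lipids // 2
    for _ in range(spec.n_frames):
        isotopes = []
        groups = []
        zs = []
        # heads: equal leaflet split, Gaussian about ±z_head
        z_head = np.concatenate(
            [
                rng.normal(spec.z_head, spec.head_width, n_per_leaflet),
                rng.normal(-spec.z_head, spec.head_width,
                           spec.n_lipids - n_per_leaflet),
            ]
        )
        iso, z = _molecule_atoms(spec.compositions["head"], spec.n_lipids, z_head)
        isotopes.append(iso)
        groups.append(np.full(len(iso), "head", dtype=object))
        zs.append(z)
        # tails: Gaussian about the midplane
        z_tail = rng.normal(0.0, spec.tail_width, spec.n_lipids)
        iso, z = _molecule_atoms(spec.compositions["tail"], spec.n_lipids, z_tail)
        isotopes.append(iso)
        groups.append(np.full(len(iso), "tail", dtype=object))
        zs.append(z)
        # water: uniform over the two slabs outside the membrane
        half = Lz / 2.0
        span = half - spec.water_exclusion
        u = rng.uniform(0.0, 2.0 * span, spec.n_waters)
        z_wat = np.where(
            u < span, -half + u, spec.water_exclusion + (u - span)
        )
        iso, z = _molecule_atoms(spec.compositions["water"], spec.n_waters, z_wat)
        isotopes.append(iso)
        groups.append(np.full(len(iso), "water", dtype=object))
        zs.append(z)

        iso_all = np.concatenate(isotopes)
        z_all = np.concatenate(zs)
        n_atoms = len(z_all)
        xy = rng.uniform(0.0, [Lx, Ly], size=(n_atoms, 2))
        pos = np.column_stack([xy, z_all])
        frames.append(Frame(iso_all, np.concatenate(groups), pos, (Lx, Ly, Lz)))
    return frames


def make_water_frames(
    n_waters: int = 2133,
    box: tuple[float, float, float] = (40.0, 40.0, 40.0),
    n_frames: int = 5,
    seed: int = 0,
) -> list[Frame]:
    """Uniform bulk-water frames (flat-profile fixture).

    The default fills a 40 Å cube at 0.0333 molecules/Å³, i.e. liquid water
    density, so the derived SLD should sit at the bulk H2O value in every bin.
    """
    rng = np.random.default_rng(seed)
    Lx, Ly, Lz = box
    frames = []
    for _ in range(n_frames):
        z = rng.uniform(-Lz / 2.0, Lz / 2.0, n_waters)
        iso, z_all = _molecule_atoms(DEFAULT_COMPOSITIONS["water"], n_waters, z)
        xy = rng.uniform(0.0, [Lx, Ly], size=(len(z_all), 2))
        pos = np.column_stack([xy, z_all])
        frames.append(
            Frame(iso, np.full(len(iso), "water", dtype=object), pos, box)
        )
    return frames


def make_slab_profile(
    slabs: Sequence[tuple[float, float]],
    bin_width: float = 0.13,
    fronting: float | None = None,
    backing: float | None = None,
) -> SLDProfile:
    """Piecewise-constant analytic SLD profile on a uniform grid.

    Each bin takes the SLD of the slab containing its center (midpoint rule);
    the total length is preserved to within one bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    total = sum(t for t, _ in slabs)
    n_bins = max(1, int(round(total / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    bounds = np.cumsum([t for t, _ in slabs])
    idx = np.searchsorted(bounds, centers, side="right")
    idx = np.clip(idx, 0, len(slabs) - 1)
    rho = np.array([slabs[i][1] for i in idx], dtype=float)
    return SLDProfile(edges, rho, fronting=fronting, backing=backing)


def make_noisy_curve(curve, relative_noise: float, seed: int = 0):
    """Multiplicative Gaussian noise with matching stated uncertainties.

    Intensities become y·(1 + ε), ε ~ N(0, relative_noise²), clipped at zero;
    the uncertainty column is set to relative_noise·y of the noise-free model.
    Works for both reflectivity and SANS curves.
    """
    if relative_noise < 0:
        raise ValueError("relative_noise must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(curve, ReflectivityCurve):
        y = curve.R
    elif isinstance(curve, SansCurve):
        y = curve.I
    else:
        raise TypeError("curve must be a ReflectivityCurve or SansCurve")
    noise = relative_noise * rng.standard_normal(len(y))
    y_noisy = np.clip(y * (1.0 + noise), 0.0, None)
    dy = relative_noise * y
    out = curve.copy()
    if isinstance(curve, ReflectivityCurve):
        out.R, out.dR = y_noisy, dy
    else:
        out.I, out.dI = y_noisy, dy
    out.metadata = dict(curve.metadata, relative_noise=relative_noise, seed=seed)
    return out
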