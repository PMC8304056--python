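"""File formats: PDB/GRO trajectories, TSV profiles, ASCII Q-curves, chi-square.

Coordinate convention: z increases from the substrate into the solvent and
profiles are stored fronting-first.  Curves are plain ASCII with '#'-prefixed
header comments: reflectivity files carry Q, R, dR[, dQ]; SANS files Q, I, dI.
Profiles round-trip through TSV with z_center, total SLD and optional
per-group columns.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .profiles import Frame, SLDProfile
from .reflectivity import ReflectivityCurve
from .sans import SansCurve

__all__ = [
    "GroupingRules",
    "read_structure",
    "read_curve",
    "write_curve",
    "read_profile_tsv",
    "write_profile_tsv",
    "chi_square",
]

_WATER_RESNAMES = ("SOL", "WAT", "HOH", "TIP3", "TIP4", "SPC", "W")

_TWO_LETTER = (
    "Cl", "Br", "Na", "Mg", "Al", "Si", "Ca", "Fe", "Cu", "Zn", "Ni", "Mn",
    "Cr", "Ti", "Au", "Li",
)


@dataclass(frozen=True)
class GroupingRules:
    """First-match rules assigning (resname, atomname) to head/tail/water/other.

    ``rules`` is a sequence of (resname_pattern, atomname_pattern, group)
    with fnmatch-style wildcards; common water residue names fall back to
    'water' and anything unmatched to 'other'.  ``isotopes`` optionally
    overrides the element guess per atom-name pattern (e.g. deuterated
    selections), and ``implicit_h`` adds united-atom implicit hydrogens per
    (resname_pattern, atomname_pattern) — no silent guessing.
    """

    rules: Sequence[tuple[str, str, str]] = ()
    isotopes: Mapping[str, str] = field(default_factory=dict)
    implicit_h: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def group_of(self, resname: str, atomname: str) -> str:
        for res_pat, atom_pat, group in self.rules:
            if fnmatch.fnmatch(resname, res_pat) and fnmatch.fnmatch(atomname, atom_pat):
                return group
        if resname.upper() in _WATER_RESNAMES:
            return "water"
        return "other"

    def isotope_of(self, atomname: str) -> str:
        for pat, iso in self.isotopes.items():
            if fnmatch.fnmatch(atomname, pat):
                return iso
        return _guess_element(atomname)

    def implicit_h_of(self, resname: str, atomname: str) -> int:
        for (res_pat, atom_pat), n in self.implicit_h.items():
            if fnmatch.fnmatch(resname, res_pat) and fnmatch.fnmatch(atomname, atom_pat):
                return int(n)
        return 0


def _guess_element(atomname: str) -> str:
    name = "".join(c for c in atomname if c.isalpha())
    if not name:
        raise ValueError(f"cannot derive an element from atom name {atomname!r}")
    cand = name[:2].capitalize()
    if cand in _TWO_LETTER:
        return cand
    return name[0].upper()


def read_structure(
    path: str | Path,
    grouping: GroupingRules | None = None,
) -> list[Frame]:
    """Read a (multi-frame) PDB or GRO file into Frames, coordinates in Å.

    Uses MDAnalysis for parsing (GRO nm → Å conversion is applied by the
    reader); each frame requires box dimensions.  Grouping rules assign
    head/tail/water tags and isotope labels from residue/atom names.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    grouping = grouping or GroupingRules()
    try:
        u = mda.Universe(str(path))
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ValueError(f"could not parse structure file {path}: {exc}") from exc

    resnames = [a.resname for a in u.atoms]
    atomnames = [a.name for a in u.atoms]
    base_iso = [grouping.isotope_of(nm) for nm in atomnames]
    base_grp = [grouping.group_of(rn, nm) for rn, nm in zip(resnames, atomnames)]
    extra_h = [grouping.implicit_h_of(rn, nm) for rn, nm in zip(resnames, atomnames)]

    # expand united-atom implicit hydrogens as extra H entries at the same site
    idx_extra = [i for i, n in enumerate(extra_h) for _ in range(n)]
    isotopes = np.array(base_iso + ["H"] * len(idx_extra), dtype=object)
    groups = np.array(base_grp + [base_grp[i] for i in idx_extra], dtype=object)

    frames = []
    for ts in u.trajectory:
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            raise ValueError(
                f"{path}: frame {ts.frame} has no box dimensions (CRYST1/box line)"
            )
        pos = u.atoms.positions.astype(float)
        if idx_extra:
            pos = np.vstack([pos, pos[idx_extra]])
        box = tuple(float(x) for x in ts.dimensions[:3])
        frames.append(Frame(isotopes.copy(), groups.copy(), pos, box))
    return frames


def _load_columns(path: Path, min_cols: int, what: str) -> np.ndarray:
    rows = []
    comments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                comments.append(stripped.lstrip("# "))
                continue
            parts = stripped.split()
            try:
                rows.append([float(x) for x in parts])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed numeric record") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    if ncol < min_cols:
        raise ValueError(
            f"{path}: found {ncol} columns but {what} needs at least {min_cols} "
            "(Q, intensity, uncertainty)"
        )
    data = np.array([r[:ncol] for r in rows], dtype=float)
    return data, comments


def read_curve(path: str | Path, kind: str = "reflectivity"):
    """Read a 3/4-column ASCII curve (Q, y, dy[, dQ]); '#' comments allowed."""
    path = Path(path)
    data, comments = _load_columns(path, 3, f"a {kind} curve")
    Q, y, dy = data[:, 0], data[:, 1], data[:, 2]
    if np.any(np.diff(Q) <= 0):
        raise ValueError(f"{path}: Q column is not strictly ascending")
    if np.any(dy < 0):
        raise ValueError(f"{path}: negative uncertainties")
    dQ = data[:, 3] if data.shape[1] >= 4 else None
    meta = {"path": str(path), "comments": comments}
    if kind == "reflectivity":
        return ReflectivityCurve(Q, y, dR=dy, dQ=dQ, metadata=meta)
    if kind == "sans":
        return SansCurve(Q, y, dI=dy, metadata=meta)
    raise ValueError(f"kind must be 'reflectivity' or 'sans', got {kind!r}")


def write_curve(path: str | Path, curve, header: str | None = None) -> None:
    """Write a curve as ASCII columns with '#' header lines."""
    path = Path(path)
    if isinstance(curve, ReflectivityCurve):
        cols = [curve.Q, curve.R]
        names = ["Q(1/A)", "R"]
        if curve.dR is not None:
            cols.append(curve.dR)
            names.append("dR")
        if curve.dQ is not None:
            cols.append(curve.dQ)
            names.append("dQ(1/A)")
    elif isinstance(curve, SansCurve):
        cols = [curve.Q, curve.I]
        names = ["Q(1/A)", "I(1/cm)"]
        if curve.dI is not None:
            cols.append(curve.dI)
            names.append("dI(1/cm)")
    else:
        raise TypeError("curve must be a ReflectivityCurve or SansCurve")
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# " + "\t".join(names) + "\n")
        for row in zip(*cols):
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def write_profile_tsv(path: str | Path, profile: SLDProfile) -> None:
    """TSV: z_center, total SLD, then one column per group contribution."""
    groups = sorted(profile.breakdown) if profile.breakdown else []
    with open(path, "w") as fh:
        fh.write(f"# bin_width: {profile.bin_width:.6g} A\n")
        if profile.fronting is not None:
            fh.write(f"# fronting_sld: {profile.fronting:.10g}\n")
        if profile.backing is not None:
            fh.write(f"# backing_sld: {profile.backing:.10g}\n")
        fh.write("# " + "\t".join(["z(A)", "sld(1/A2)"] + [f"sld_{g}" for g in groups]) + "\n")
        for i, z in enumerate(profile.z_centers):
            row = [z, profile.rho[i]] + [profile.breakdown[g][i] for g in groups]
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_profile_tsv(path: str | Path) -> SLDProfile:
    path = Path(path)
    fronting = backing = None
    rows = []
    header_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                body = s.lstrip("# ")
                if body.startswith("fronting_sld:"):
                    fronting = float(body.split(":")[1])
                elif body.startswith("backing_sld:"):
                    backing = float(body.split(":")[1])
                elif body.startswith("z(A)"):
                    header_cols = body.split("\t")
                continue
            try:
                rows.append([float(x) for x in s.split()])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed profile record") from None
    if len(rows) < 2:
        raise ValueError(f"{path}: profile needs at least two bins")
    data = np.array(rows, dtype=float)
    z, rho = data[:, 0], data[:, 1]
    dz = z[1] - z[0]
    edges = np.concatenate([[z[0] - dz / 2.0], z + dz / 2.0])
    breakdown = None
    if header_cols and len(header_cols) > 2 and data.shape[1] >= len(header_cols):
        breakdown = {
            col.removeprefix("sld_"): data[:, 2 + i]
            for i, col in enumerate(header_cols[2:])
        }
    return SLDProfile(edges, rho, fronting=fronting, backing=backing, breakdown=breakdown)


def chi_square(data, model, n_free: int = 0) -> float:
    """Reduced chi-square of a model curve against a measured curve.

    The model is linearly interpolated onto the data grid; the data grid must
    lie inside the model's Q support.  ``n_free`` subtracts fitted parameters
    from the degrees of freedom.
    """
    if isinstance(data, ReflectivityCurve):
        qd, yd, dyd = data.Q, data.R, data.dR
        qm, ym = model.Q, model.R
    elif isinstance(data, SansCurve):
        qd, yd, dyd = data.Q, data.I, data.dI
        qm, ym = model.Q, model.I
    else:
        raise TypeError("data must be a ReflectivityCurve or SansCurve")
    if dyd is None or np.any(dyd <= 0):
        raise ValueError("data must carry positive uncertainties")
    if qd[0] < qm[0] - 1e-12 or qd[-1] > qm[-1] + 1e-12:
        raise ValueError("data Q range extends beyond the model curve")
    y_interp = np.interp(qd, qm, ym)
    dof = len(qd) - n_free
    if dof <= 0:
        raise ValueError("no degrees of freedom left")
    return float(np.sum(((yd - y_interp) / dyd) ** 2) / dof)
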