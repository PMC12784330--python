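"""Crystal structure containers: unit cell, symmetry operations, atomic sites.

Fractional coordinates are stored wrapped to [0, 1).  Symmetry operations are
fractional affine maps represented by ``gemmi.Op`` (triplet strings such as
``-x,y+1/2,-z``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = ["UnitCell", "Site", "CrystalStructure"]


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def volume(self) -> float:
        """Cell volume in A^3 from the standard triclinic formula."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca**2 - cb**2 - cg**2 + 2.0 * ca * cb * cg
        return float(self.a * self.b * self.c * np.sqrt(max(arg, 0.0)))

    @property
    def is_orthorhombic(self) -> bool:
        return all(abs(ang - 90.0) < 1e-8 for ang in (self.alpha, self.beta, self.gamma))

    def frac_to_cart(self) -> np.ndarray:
        """3x3 matrix taking fractional to Cartesian (A) coordinates."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = self.volume / (self.a * self.b * self.c)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )


@dataclass(frozen=True)
class Site:
    """One atomic site: element symbol, fractional coordinates, label."""

    element: str
    frac: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        wrapped = tuple(float(x) % 1.0 for x in self.frac)
        object.__setattr__(self, "frac", wrapped)


IDENTITY_OP = gemmi.Op("x,y,z")


@dataclass
class CrystalStructure:
    """Unit cell + symmetry operations + asymmetric-unit sites.

    The identity operation is always present exactly once; a structure built
    with no symmetry list is P1.
    """

    cell: UnitCell
    sites: list[Site]
    symmetry_ops: list[gemmi.Op] = field(default_factory=lambda: [IDENTITY_OP])
    name: str = ""

    def __post_init__(self) -> None:
        n_id = sum(1 for op in self.symmetry_ops if op == IDENTITY_OP)
        if n_id == 0:
            self.symmetry_ops = [IDENTITY_OP] + list(self.symmetry_ops)
        elif n_id > 1:
            seen_id = False
            ops = []
            for op in self.symmetry_ops:
                if op == IDENTITY_OP:
                    if seen_id:
                        continue
                    seen_id = True
                ops.append(op)
            self.symmetry_ops = ops

    def apply_op(self, op: gemmi.Op, frac: tuple[float, float, float]) -> tuple[float, float, float]:
        """Apply a symmetry op to fractional coordinates, wrapped to [0,1)."""
        x = op.apply_to_xyz(list(frac))
        return tuple(float(v) % 1.0 for v in x)

    def expand_p1(self, tol: float = 1e-4) -> list[Site]:
        """All symmetry-equivalent sites in the cell, duplicates merged."""
        out: list[Site] = []
        for site in self.sites:
            for op in self.symmetry_ops:
                frac = self.apply_op(op, site.frac)
                dup = False
                for other in out:
                    d = np.array(frac) - np.array(other.frac)
                    d -= np.round(d)
                    if np.linalg.norm(d) < tol and other.element == site.element:
                        dup = True
                        break
                if not dup:
                    out.append(Site(site.element, frac, site.label))
        return out
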