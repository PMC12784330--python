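"""Readers/writers for the exchange formats: a small-molecule CIF subset and
typed CSV tables.

CSV schemas (exact column names) are the package's tabular contracts:

===========  =============================================================
schema       required columns
===========  =============================================================
phonon       freq_cm1 [, weight]
cp           T_K, form, cp_J_per_molK
dsc          lab, heating_rate_K_per_min, onset_T_C, dH_kJ_per_mol,
             u_dH_kJ_per_mol
lattice      T_K, a_A, b_A, c_A [, V_A3]
solubility   T_C, form, solubility_mg_per_g
===========  =============================================================

Temperatures are explicit about K vs Celsius in the column name; everything
internal is Kelvin.
"""
from __future__ import annotations

import os

import gemmi
import numpy as np
import pandas as pd

from .structures import CrystalStructure, Site, UnitCell

__all__ = [
    "CifFormatError",
    "SchemaError",
    "read_cif",
    "write_cif",
    "read_table",
    "write_table",
    "TABLE_SCHEMAS",
]


class CifFormatError(ValueError):
    """Raised for CIF files missing required tags or with bad symops."""


class SchemaError(ValueError):
    """Raised when a CSV does not match its declared schema."""


_CELL_TAGS = (
    "_cell_length_a",
    "_cell_length_b",
    "_cell_length_c",
    "_cell_angle_alpha",
    "_cell_angle_beta",
    "_cell_angle_gamma",
)

_SYMOP_TAGS = ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz")


def _cif_number(raw: str) -> float:
    # strip an s.u. in parentheses, e.g. "5.234(2)"
    return float(raw.split("(")[0])


def read_cif(path: str | os.PathLike) -> CrystalStructure:
    """Read one data block of a small-molecule CIF.

    Accepts both ``_symmetry_equiv_pos_as_xyz`` and
    ``_space_group_symop_operation_xyz`` symop loops; a file with neither is
    taken as P1.
    """
    doc = gemmi.cif.read_file(os.fspath(path))
    block = doc.sole_block()

    vals = []
    for tag in _CELL_TAGS:
        raw = block.find_value(tag)
        if raw is None:
            raise CifFormatError(f"missing cell tag {tag!r} in {path}")
        vals.append(_cif_number(gemmi.cif.as_string(raw) if raw.startswith("'") else raw))
    cell = UnitCell(*vals)

    ops: list[gemmi.Op] = []
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        strings = list(col) if col else []
        if not strings:
            v = block.find_value(tag)
            if v is not None:
                strings = [v]
        for s in strings:
            s = gemmi.cif.as_string(s)
            try:
                ops.append(gemmi.Op(s))
            except (RuntimeError, ValueError) as exc:
                raise CifFormatError(f"unparseable symmetry operation {s!r}") from exc
        if ops:
            break

    table = block.find(
        "_atom_site_", ["type_symbol", "fract_x", "fract_y", "fract_z", "?label"]
    )
    sites = []
    for row in table:
        label = row[4] if table.has_column(4) else ""
        sites.append(
            Site(
                element=gemmi.cif.as_string(row[0]),
                frac=tuple(_cif_number(row[i]) for i in (1, 2, 3)),
                label=gemmi.cif.as_string(label) if label else "",
            )
        )

    return CrystalStructure(
        cell=cell,
        sites=sites,
        symmetry_ops=ops or None or [gemmi.Op("x,y,z")],
        name=block.name,
    )


def write_cif(structure: CrystalStructure, path: str | os.PathLike) -> None:
    """Write the CIF subset this package reads (lossless round trip)."""
    c = structure.cell
    lines = [f"data_{structure.name or 'crystherm'}"]
    for tag, v in zip(_CELL_TAGS, (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)):
        lines.append(f"{tag} {v:.9f}")
    lines += ["loop_", "_space_group_symop_operation_xyz"]
    lines += [f"'{op.triplet()}'" for op in structure.symmetry_ops]
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for i, s in enumerate(structure.sites):
        label = s.label or f"{s.element}{i + 1}"
        lines.append(
            f"{label} {s.element} {s.frac[0]:.9f} {s.frac[1]:.9f} {s.frac[2]:.9f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


TABLE_SCHEMAS: dict[str, dict] = {
    "phonon": {
        "required": ["freq_cm1"],
        "optional": {"weight": 1.0},
        "numeric": ["freq_cm1", "weight"],
    },
    "cp": {
        "required": ["T_K", "form", "cp_J_per_molK"],
        "optional": {},
        "numeric": ["T_K", "cp_J_per_molK"],
    },
    "dsc": {
        "required": [
            "lab",
            "heating_rate_K_per_min",
            "onset_T_C",
            "dH_kJ_per_mol",
            "u_dH_kJ_per_mol",
        ],
        "optional": {},
        "numeric": ["heating_rate_K_per_min", "onset_T_C", "dH_kJ_per_mol", "u_dH_kJ_per_mol"],
    },
    "lattice": {
        "required": ["T_K", "a_A", "b_A", "c_A"],
        "optional": {"V_A3": np.nan},
        "numeric": ["T_K", "a_A", "b_A", "c_A", "V_A3"],
    },
    "solubility": {
        "required": ["T_C", "form", "solubility_mg_per_g"],
        "optional": {},
        "numeric": ["T_C", "solubility_mg_per_g"],
    },
}


def read_table(path: str | os.PathLike, schema: str) -> pd.DataFrame:
    """Read a CSV against a named schema, validating columns and units."""
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; choose from {sorted(TABLE_SCHEMAS)}")
    spec = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path)
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: schema {schema!r} missing required columns {missing}")
    for col, default in spec["optional"].items():
        if col not in df.columns:
            df[col] = default

    for col in spec["numeric"]:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad:
            raise SchemaError(
                f"{path}: column {col!r} has non-numeric values at rows {bad}"
            )
        df[col] = coerced.astype(float)

    if schema == "dsc" and (df["heating_rate_K_per_min"] <= 0).any():
        raise SchemaError(f"{path}: heating rates must be positive")
    for col in ("T_K",):
        if col in df.columns and (df[col] <= 0).any():
            raise SchemaError(f"{path}: temperatures in K must be positive")
    return df


def write_table(df: pd.DataFrame, path: str | os.PathLike, schema: str | None = None) -> None:
    if schema is not None:
        spec = TABLE_SCHEMAS[schema]
        missing = [c for c in spec["required"] if c not in df.columns]
        if missing:
            raise SchemaError(f"refusing to write {schema!r} table without {missing}")
    df.to_csv(path, index=False)
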