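"""96-well plate layouts: roles per well, parsed from a small YAML config.

The screen convention places all positive and negative controls in the two
outer columns (1 and 12) and library siRNAs everywhere else.  Roles:
``mock`` (lipid-only negative control), ``siCDC42`` and ``siCDH5`` (positive
controls), ``non_targeting_ref`` (recorded but excluded from analysis) and
``library``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

ROWS = "ABCDEFGH"
N_COLS = 12
ROLES = ("mock", "siCDC42", "siCDH5", "non_targeting_ref", "library")

_CODE = {"mock": "mock", "m": "mock",
         "cdc42": "siCDC42", "sicdc42": "siCDC42",
         "cdh5": "siCDH5", "sicdh5": "siCDH5",
         "nt": "non_targeting_ref", "non_targeting_ref": "non_targeting_ref",
         "lib": "library", "library": "library", "l": "library"}


class LayoutError(ValueError):
    """Malformed or inconsistent plate-layout configuration."""


def well_name(row_idx: int, col: int) -> str:
    return f"{ROWS[row_idx]}{col:02d}"


@dataclass
class PlateLayout:
    """Role assignment for every well of an 8 x 12 plate."""

    roles: dict[str, str]
    control_columns: tuple[int, ...] = (1, 12)

    def __post_init__(self) -> None:
        expected = {well_name(r, c) for r in range(len(ROWS)) for c in range(1, N_COLS + 1)}
        got = set(self.roles)
        if got != expected:
            missing = sorted(expected - got)[:5]
            extra = sorted(got - expected)[:5]
            raise LayoutError(f"layout must assign all 96 wells exactly once "
                              f"(missing {missing}, unexpected {extra})")
        bad = sorted(set(self.roles.values()) - set(ROLES))
        if bad:
            raise LayoutError(f"unknown roles: {bad}")
        for well, role in self.roles.items():
            col = int(well[1:])
            if role == "library" and col in self.control_columns:
                raise LayoutError(f"library well {well} inside control column {col}")
            if role != "library" and col not in self.control_columns:
                raise LayoutError(f"control well {well} outside control columns")
        if not self.mock_wells():
            raise LayoutError("layout defines no mock wells (normalization impossible)")

    def wells(self) -> list[str]:
        return sorted(self.roles)

    def role(self, well: str) -> str:
        return self.roles[well]

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, r in self.roles.items() if r == role)

    def mock_wells(self) -> list[str]:
        return self.wells_with_role("mock")

    def library_wells(self) -> list[str]:
        return self.wells_with_role("library")


def parse_layout(config_text: str) -> PlateLayout:
    """Parse a layout from YAML text.

    Expected document::

        plate_layout: v1
        control_columns: [1, 12]
        grid:
          - [mock, lib, lib, ..., mock]   # row A, 12 entries
          ...                             # 8 rows total

    Codes are case-insensitive; accepted values: mock/m, cdc42, cdh5, nt,
    lib/library/l.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:  # pragma: no cover - yaml's message suffices
        raise LayoutError(f"layout config is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "grid" not in doc:
        raise LayoutError("layout config must be a mapping with a 'grid' key")
    grid = doc["grid"]
    if len(grid) != len(ROWS) or any(len(row) != N_COLS for row in grid):
        raise LayoutError("grid must have 8 rows of 12 entries")
    roles = {}
    for r, row in enumerate(grid):
        for c, code in enumerate(row, start=1):
            key = str(code).strip().lower()
            if key not in _CODE:
                raise LayoutError(f"unknown well code {code!r} at {well_name(r, c)}")
            roles[well_name(r, c)] = _CODE[key]
    control_columns = tuple(doc.get("control_columns", (1, 12)))
    return PlateLayout(roles=roles, control_columns=control_columns)


def default_layout() -> PlateLayout:
    """The standard screen layout: controls in columns 1 and 12.

    Column 1: mocks in rows A-D, siCDC42 in E-F, siCDH5 in G-H.
    Column 12: mocks in A-B, non-targeting reference in C-D, siCDC42 in E-F,
    siCDH5 in G-H.  All 80 remaining wells are library.
    """
    col1 = ["mock"] * 4 + ["siCDC42"] * 2 + ["siCDH5"] * 2
    col12 = ["mock"] * 2 + ["non_targeting_ref"] * 2 + ["siCDC42"] * 2 + ["siCDH5"] * 2
    roles = {}
    for r in range(len(ROWS)):
        for c in range(1, N_COLS + 1):
            if c == 1:
                roles[well_name(r, c)] = col1[r]
            elif c == N_COLS:
                roles[well_name(r, c)] = col12[r]
            else:
                roles[well_name(r, c)] = "library"
    return PlateLayout(roles=roles)


def layout_to_yaml(layout: PlateLayout) -> str:
    """Serialise a layout back to the YAML grid format."""
    inverse = {"mock": "mock", "siCDC42": "cdc42", "siCDH5": "cdh5",
               "non_targeting_ref": "nt", "library": "lib"}
    grid = [[inverse[layout.role(well_name(r, c))] for c in range(1, N_COLS + 1)]
            for r in range(len(ROWS))]
    return yaml.safe_dump({"plate_layout": "v1",
                           "control_columns": list(layout.control_columns),
                           "grid": grid}, sort_keys=False, default_flow_style=None)
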