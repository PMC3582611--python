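"""Tiled-volume data model, hierarchy import, substack loading and XML state.

A tiled acquisition is a full R x C matrix of 3D tiles (stacks).  The two
grid axes are called V (vertical, the slow/row image axis) and H
(horizontal, the column image axis); each tile is an ordered sequence of 2D
slices along the depth axis D.  On disk the volume is a two-level directory
hierarchy: first-level directories encode the V stage position, second-level
directories encode V_H, and slice files encode V_H_D, all as zero-padded
six-digit numbers in tenths of a micrometre.  Lexicographic order of names
therefore equals spatial order.

All voxel coordinates are 0-based; intervals are half-open.  Stage
coordinates read from names are converted to voxels with the voxel size
supplied at import (rounding to the nearest voxel).

Pipeline state (volume descriptor, pairwise displacements, stitchable
flags, absolute placements) is serialized to an editable XML file between
steps, so that steps can be run, inspected, hand-corrected and resumed
independently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from lxml import etree

__all__ = [
    "STAGES",
    "StitchError",
    "GridError",
    "ValidationError",
    "StageError",
    "Tile",
    "TiledVolume",
    "SubstackRef",
    "PairDisplacement",
    "StitchState",
    "import_volume",
    "load_substack",
    "save_state",
    "load_state",
    "state_to_xml_bytes",
    "pair_axis",
    "grid_pairs",
]

#: Pipeline stages in execution order.
STAGES = ("imported", "displacements_computed", "projected", "thresholded", "placed")

DIRECTIONS = ("V", "H", "D")


class StitchError(Exception):
    """Base class for stitching errors."""


class GridError(StitchError):
    """The on-disk hierarchy does not describe a complete, consistent grid."""


class ValidationError(StitchError):
    """A state file (or hand-edited field) violates the schema or an invariant."""


class StageError(StitchError):
    """A pipeline step was invoked on a state in the wrong stage."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class Tile:
    """One stack of the tile matrix.

    Nominal positions are the stage coordinates converted to voxels; they are
    trusted only approximately (small mechanical drift), which is what the
    alignment step corrects.
    """

    row: int
    col: int
    nominal_v: int
    nominal_h: int
    nominal_d: int
    slice_paths: tuple[Path, ...] = ()
    stitchable: bool = True


@dataclass
class TiledVolume:
    """Descriptor of an R x C grid of identically shaped tiles."""

    n_rows: int
    n_cols: int
    tile_height_v: int
    tile_width_h: int
    n_slices_total: int
    voxel_size: tuple[float, float, float]
    tiles: dict[tuple[int, int], Tile]
    root_path: Path
    dtype: str = "uint8"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_slices_total < 1:
            raise ValidationError("grid and depth dimensions must be >= 1")
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                if (r, c) not in self.tiles:
                    raise GridError(f"incomplete grid: missing tile (row {r}, col {c})")

    def tile(self, row: int, col: int) -> Tile:
        return self.tiles[(row, col)]

    @property
    def tile_shape(self) -> tuple[int, int, int]:
        return (self.tile_height_v, self.tile_width_h, self.n_slices_total)


@dataclass(frozen=True)
class SubstackRef:
    """A contiguous half-open run of slices [z0, z1) of one tile along D."""

    tile: Tile
    z0: int
    z1: int


PairKey = tuple[tuple[int, int], tuple[int, int]]


def pair_axis(key: PairKey) -> str:
    """Adjacency direction of a pair key: 'H' for row neighbours, 'V' for column."""
    (ar, ac), (br, bc) = key
    if (br, bc) == (ar, ac + 1):
        return "H"
    if (br, bc) == (ar + 1, ac):
        return "V"
    raise ValidationError(f"tiles {key[0]} and {key[1]} are not grid-adjacent")


def grid_pairs(n_rows: int, n_cols: int) -> list[PairKey]:
    """All adjacent pairs of the grid, lexicographically ordered.

    There are exactly n_rows*(n_cols-1) horizontal and (n_rows-1)*n_cols
    vertical adjacencies.
    """
    pairs: list[PairKey] = []
    for r in range(n_rows):
        for c in range(n_cols):
            if c + 1 < n_cols:
                pairs.append(((r, c), (r, c + 1)))
            if r + 1 < n_rows:
                pairs.append(((r, c), (r + 1, c)))
    return sorted(pairs)


@dataclass
class PairDisplacement:
    """Best per-direction displacement of one adjacent tile pair.

    ``offsets`` are signed voxel *corrections relative to the nominal stage
    displacement* (offset 0 means the stage coordinates were exact); each
    direction carries its own reliability in [0, 1] (0 = totally unreliable,
    1 = reliable).  ``default_flag`` marks a pair whose displacement was
    reset to the stage default by thresholding.  ``z0``/``z1`` record the
    substack (layer) the estimate came from.
    """

    pair: PairKey
    offsets: tuple[int, int, int]
    reliabilities: tuple[float, float, float]
    default_flag: bool = False
    stitchable: bool = True
    z0: int = 0
    z1: int = 0

    def __post_init__(self) -> None:
        for r in self.reliabilities:
            if not (0.0 <= r <= 1.0):
                raise ValidationError(
                    f"reliability {r!r} of pair {self.pair} outside [0, 1]"
                )

    def reliability(self, direction: str) -> float:
        return self.reliabilities[DIRECTIONS.index(direction)]

    def offset(self, direction: str) -> int:
        return self.offsets[DIRECTIONS.index(direction)]


@dataclass
class StitchState:
    """Serializable pipeline state: the XML payload passed between steps.

    ``pair_displacements`` maps each adjacent pair to a *list* of per-substack
    displacements while stage == 'displacements_computed' and to a single
    projected displacement afterwards.  ``placements`` holds absolute per-tile
    (V, H, D) voxel coordinates once stage == 'placed'.
    """

    stage: str
    volume: TiledVolume
    pair_displacements: dict[PairKey, list[PairDisplacement] | PairDisplacement] = field(
        default_factory=dict
    )
    placements: dict[tuple[int, int], tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"state is at stage {self.stage!r}; expected one of {allowed}"
            )

    def pairs_cover_grid(self) -> bool:
        return sorted(self.pair_displacements) == grid_pairs(
            self.volume.n_rows, self.volume.n_cols
        )


# --------------------------------------------------------------------------
# hierarchy import
# --------------------------------------------------------------------------

_DIR_RE = re.compile(r"^(\d{6})$")
_SUBDIR_RE = re.compile(r"^(\d{6})_(\d{6})$")
_SLICE_RE = re.compile(r"^(\d{6})_(\d{6})_(\d{6})\.tiff?$", re.IGNORECASE)


def _tenths_to_voxels(tenths: int, voxel_um: float) -> int:
    return int(round(tenths / 10.0 / voxel_um))


def import_volume(
    root_path: str | Path,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> TiledVolume:
    """Scan a two-level tile hierarchy and build a :class:`TiledVolume`.

    Stage coordinates embedded in directory/file names (tenths of a
    micrometre) are converted to voxels using ``voxel_size`` (micrometres per
    voxel along V, H, D).  The grid must be complete and all tiles must have
    the same number of slices and the same slice shape.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise GridError(f"volume root {root} is not a directory")

    # first level: V groups; stray regular files (e.g. sidecars) are ignored
    tile_dirs: dict[tuple[int, int], Path] = {}
    level1 = sorted(p for p in root.iterdir() if p.is_dir())
    if not level1:
        raise GridError(f"no tile directories under {root}")
    for vdir in level1:
        if not _DIR_RE.match(vdir.name):
            raise GridError(f"unparsable first-level directory name: {vdir}")
        for hdir in sorted(p for p in vdir.iterdir() if p.is_dir()):
            m = _SUBDIR_RE.match(hdir.name)
            if not m:
                raise GridError(f"unparsable tile directory name: {hdir}")
            v_tenths, h_tenths = int(m.group(1)), int(m.group(2))
            if f"{v_tenths:06d}" != vdir.name:
                raise GridError(
                    f"tile directory {hdir} disagrees with parent V position {vdir.name}"
                )
            tile_dirs[(v_tenths, h_tenths)] = hdir

    v_values = sorted({v for v, _ in tile_dirs})
    h_values = sorted({h for _, h in tile_dirs})
    n_rows, n_cols = len(v_values), len(h_values)
    for r, v in enumerate(v_values):
        for c, h in enumerate(h_values):
            if (v, h) not in tile_dirs:
                raise GridError(f"incomplete grid: missing tile (row {r}, col {c})")

    tiles: dict[tuple[int, int], Tile] = {}
    n_slices: int | None = None
    slice_shape: tuple[int, int] | None = None
    dtype: str | None = None
    for r, v in enumerate(v_values):
        for c, h in enumerate(h_values):
            tdir = tile_dirs[(v, h)]
            paths: list[Path] = []
            d_tenths: list[int] = []
            for p in sorted(tdir.iterdir()):
                if p.is_dir():
                    raise GridError(f"unexpected directory inside tile: {p}")
                m = _SLICE_RE.match(p.name)
                if not m:
                    raise GridError(f"unparsable slice file name: {p}")
                paths.append(p)
                d_tenths.append(int(m.group(3)))
            if not paths:
                raise GridError(f"tile directory {tdir} contains no slices")
            if n_slices is None:
                n_slices = len(paths)
            elif len(paths) != n_slices:
                raise GridError(
                    f"inconsistent slice count: tile (row {r}, col {c}) has "
                    f"{len(paths)} slices, expected {n_slices}"
                )
            with tifffile.TiffFile(paths[0]) as tf:
                page = tf.pages[0]
                shape = tuple(page.shape)
                dt = np.dtype(page.dtype).name
            if slice_shape is None:
                slice_shape, dtype = shape, dt
            elif shape != slice_shape:
                raise GridError(
                    f"inconsistent slice shape {shape} in tile (row {r}, col {c}), "
                    f"expected {slice_shape}"
                )
            tiles[(r, c)] = Tile(
                row=r,
                col=c,
                nominal_v=_tenths_to_voxels(v, voxel_size[0]),
                nominal_h=_tenths_to_voxels(h, voxel_size[1]),
                nominal_d=_tenths_to_voxels(d_tenths[0], voxel_size[2]),
                slice_paths=tuple(paths),
            )

    assert n_slices is not None and slice_shape is not None and dtype is not None
    return TiledVolume(
        n_rows=n_rows,
        n_cols=n_cols,
        tile_height_v=slice_shape[0],
        tile_width_h=slice_shape[1],
        n_slices_total=n_slices,
        voxel_size=tuple(float(x) for x in voxel_size),  # type: ignore[arg-type]
        tiles=tiles,
        root_path=root,
        dtype=dtype,
    )


def load_substack(
    volume: TiledVolume, ref: SubstackRef, counters=None
) -> np.ndarray:
    """Read slices [z0, z1) of a tile into a (V, H, D_sub) array, bit-exactly.

    ``counters`` (see :mod:`mipstitch.instrumentation`) records one file open
    per slice when given, so I/O contracts can be asserted in tests.
    """
    if not (0 <= ref.z0 < ref.z1 <= volume.n_slices_total):
        raise ValidationError(
            f"substack interval [{ref.z0}, {ref.z1}) outside [0, {volume.n_slices_total}]"
        )
    tile = ref.tile
    if not tile.slice_paths:
        raise StitchError(
            f"tile (row {tile.row}, col {tile.col}) has no slice files attached; "
            "is the volume root available?"
        )
    planes = []
    for path in tile.slice_paths[ref.z0 : ref.z1]:
        try:
            plane = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - re-raise with the file name
            raise IOError(f"cannot read slice file {path}: {exc}") from exc
        if counters is not None:
            counters.record_open(path)
        if plane.shape != (volume.tile_height_v, volume.tile_width_h):
            raise GridError(
                f"slice {path} has shape {plane.shape}, expected "
                f"({volume.tile_height_v}, {volume.tile_width_h})"
            )
        planes.append(plane)
    return np.stack(planes, axis=-1)


# --------------------------------------------------------------------------
# XML state serialization
# --------------------------------------------------------------------------


def _fmt_float(x: float) -> str:
    return repr(float(x))


def state_to_xml_bytes(state: StitchState) -> bytes:
    """Serialize a state to canonical XML bytes (stable across round-trips)."""
    root = etree.Element("stitch_state", stage=state.stage)
    vol = state.volume
    vel = etree.SubElement(
        root,
        "volume",
        root=str(vol.root_path),
        rows=str(vol.n_rows),
        cols=str(vol.n_cols),
        tile_v=str(vol.tile_height_v),
        tile_h=str(vol.tile_width_h),
        slices=str(vol.n_slices_total),
        voxel_v=_fmt_float(vol.voxel_size[0]),
        voxel_h=_fmt_float(vol.voxel_size[1]),
        voxel_d=_fmt_float(vol.voxel_size[2]),
        dtype=vol.dtype,
    )
    for key in sorted(vol.tiles):
        t = vol.tiles[key]
        etree.SubElement(
            vel,
            "tile",
            row=str(t.row),
            col=str(t.col),
            nominal_v=str(t.nominal_v),
            nominal_h=str(t.nominal_h),
            nominal_d=str(t.nominal_d),
            stitchable="true" if t.stitchable else "false",
        )
    pairs_el = etree.SubElement(root, "pairs")
    for key in sorted(state.pair_displacements):
        (ar, ac), (br, bc) = key
        entry = state.pair_displacements[key]
        pel = etree.SubElement(
            pairs_el,
            "pair",
            a_row=str(ar),
            a_col=str(ac),
            b_row=str(br),
            b_col=str(bc),
            axis=pair_axis(key),
        )
        records = entry if isinstance(entry, list) else [entry]
        for pd in records:
            etree.SubElement(
                pel,
                "displacement",
                v=str(pd.offsets[0]),
                h=str(pd.offsets[1]),
                d=str(pd.offsets[2]),
                r_v=_fmt_float(pd.reliabilities[0]),
                r_h=_fmt_float(pd.reliabilities[1]),
                r_d=_fmt_float(pd.reliabilities[2]),
                default="true" if pd.default_flag else "false",
                stitchable="true" if pd.stitchable else "false",
                z0=str(pd.z0),
                z1=str(pd.z1),
            )
    if state.placements:
        plc = etree.SubElement(root, "placements")
        for key in sorted(state.placements):
            v, h, d = state.placements[key]
            etree.SubElement(
                plc, "placement", row=str(key[0]), col=str(key[1]),
                v=str(v), h=str(h), d=str(d),
            )
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def save_state(state: StitchState, path: str | Path) -> None:
    Path(path).write_bytes(state_to_xml_bytes(state))


def _xml_path(el) -> str:
    return el.getroottree().getpath(el)


def _req_attr(el, name: str) -> str:
    val = el.get(name)
    if val is None:
        raise ValidationError(f"missing attribute {name!r} at {_xml_path(el)}")
    return val


def _parse_bool(el, name: str) -> bool:
    val = _req_attr(el, name)
    if val not in ("true", "false"):
        raise ValidationError(f"attribute {name!r} at {_xml_path(el)} must be true/false")
    return val == "true"


def load_state(path: str | Path, attach_data: bool = True) -> StitchState:
    """Parse and validate a state XML; hand-edited fields are re-validated.

    When ``attach_data`` is true and the stored volume root exists on disk,
    slice file lists are re-discovered so data-dependent steps can run; pure
    metadata steps work without the data being present.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"not well-formed XML: {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "stitch_state":
        raise ValidationError(f"root element is {root.tag!r} at {_xml_path(root)}")
    stage = _req_attr(root, "stage")
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r} at {_xml_path(root)}")

    vel = root.find("volume")
    if vel is None:
        raise ValidationError("missing <volume> element at /stitch_state")
    n_rows = int(_req_attr(vel, "rows"))
    n_cols = int(_req_attr(vel, "cols"))
    tiles: dict[tuple[int, int], Tile] = {}
    for tel in vel.findall("tile"):
        t = Tile(
            row=int(_req_attr(tel, "row")),
            col=int(_req_attr(tel, "col")),
            nominal_v=int(_req_attr(tel, "nominal_v")),
            nominal_h=int(_req_attr(tel, "nominal_h")),
            nominal_d=int(_req_attr(tel, "nominal_d")),
            stitchable=_parse_bool(tel, "stitchable"),
        )
        tiles[(t.row, t.col)] = t
    volume = TiledVolume(
        n_rows=n_rows,
        n_cols=n_cols,
        tile_height_v=int(_req_attr(vel, "tile_v")),
        tile_width_h=int(_req_attr(vel, "tile_h")),
        n_slices_total=int(_req_attr(vel, "slices")),
        voxel_size=(
            float(_req_attr(vel, "voxel_v")),
            float(_req_attr(vel, "voxel_h")),
            float(_req_attr(vel, "voxel_d")),
        ),
        tiles=tiles,
        root_path=Path(_req_attr(vel, "root")),
        dtype=_req_attr(vel, "dtype"),
    )

    pair_displacements: dict[PairKey, list[PairDisplacement] | PairDisplacement] = {}
    pairs_el = root.find("pairs")
    if pairs_el is not None:
        for pel in pairs_el.findall("pair"):
            key: PairKey = (
                (int(_req_attr(pel, "a_row")), int(_req_attr(pel, "a_col"))),
                (int(_req_attr(pel, "b_row")), int(_req_attr(pel, "b_col"))),
            )
            pair_axis(key)  # validates adjacency
            records: list[PairDisplacement] = []
            for del_ in pel.findall("displacement"):
                rels = tuple(
                    float(_req_attr(del_, k)) for k in ("r_v", "r_h", "r_d")
                )
                for r in rels:
                    if not (0.0 <= r <= 1.0):
                        raise ValidationError(
                            f"reliability {r} outside [0, 1] at {_xml_path(del_)}"
                        )
                records.append(
                    PairDisplacement(
                        pair=key,
                        offsets=tuple(
                            int(_req_attr(del_, k)) for k in ("v", "h", "d")
                        ),  # type: ignore[arg-type]
                        reliabilities=rels,  # type: ignore[arg-type]
                        default_flag=_parse_bool(del_, "default"),
                        stitchable=_parse_bool(del_, "stitchable"),
                        z0=int(_req_attr(del_, "z0")),
                        z1=int(_req_attr(del_, "z1")),
                    )
                )
            if not records:
                raise ValidationError(f"pair without displacement at {_xml_path(pel)}")
            if stage == "displacements_computed":
                pair_displacements[key] = records
            else:
                if len(records) != 1:
                    raise ValidationError(
                        f"stage {stage!r} requires one displacement per pair, got "
                        f"{len(records)} at {_xml_path(pel)}"
                    )
                pair_displacements[key] = records[0]

    placements: dict[tuple[int, int], tuple[int, int, int]] = {}
    plc = root.find("placements")
    if plc is not None:
        for pe in plc.findall("placement"):
            placements[(int(_req_attr(pe, "row")), int(_req_attr(pe, "col")))] = (
                int(_req_attr(pe, "v")),
                int(_req_attr(pe, "h")),
                int(_req_attr(pe, "d")),
            )

    state = StitchState(
        stage=stage,
        volume=volume,
        pair_displacements=pair_displacements,
        placements=placements,
    )
    # pairs must be grid adjacencies; a preview-restricted alignment may
    # legitimately cover only part of the grid
    for key in pair_displacements:
        for node in key:
            if node not in tiles:
                raise ValidationError(
                    f"pair {key} references tile outside the grid at /stitch_state/pairs"
                )
    if stage != "imported" and not pair_displacements:
        raise ValidationError("no pairs recorded at /stitch_state/pairs")
    if stage == "placed" and sorted(placements) != sorted(tiles):
        raise ValidationError("placements do not cover all tiles at /stitch_state/placements")

    if attach_data and volume.root_path.is_dir():
        _attach_slice_paths(volume)
    return state


def _attach_slice_paths(volume: TiledVolume) -> None:
    """Re-discover slice file lists for a descriptor loaded from XML."""
    scanned = import_volume(volume.root_path, volume.voxel_size)
    if (scanned.n_rows, scanned.n_cols) != (volume.n_rows, volume.n_cols):
        raise GridError(
            f"hierarchy at {volume.root_path} is a {scanned.n_rows}x{scanned.n_cols} "
            f"grid but the state describes {volume.n_rows}x{volume.n_cols}"
        )
    if scanned.tile_shape != volume.tile_shape:
        raise GridError(
            f"hierarchy tile shape {scanned.tile_shape} disagrees with state "
            f"{volume.tile_shape}"
        )
    for key, tile in volume.tiles.items():
        tile.slice_paths = scanned.tiles[key].slice_paths
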