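"""Synthetic 2D atrial tissue sheets with seeded diffuse-fibrosis realizations.

Regular quadrilateral grids stand in for the 3D atrial mesh: nodes carry a
region tag (left-atrium-like / right-atrium-like / excluded structure) and a
cell kind, elements carry a conductivity.  Diffuse fibrosis is implemented by
relabeling a uniformly random subset of eligible cardiomyocyte nodes as
fibrotic cells; any element touching a fibrotic node inherits that cell
kind's (lower) conductivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_models import CELL_PARAMS, KIND_CODE, KIND_NAME

REGION_CODE = {"left_atrium": 0, "right_atrium": 1, "excluded": 2}
REGION_NAME = {v: k for k, v in REGION_CODE.items()}

DEFAULT_SPACING_CM = 0.03           # 300 um uniform node spacing
MYO_CONDUCTIVITY = CELL_PARAMS["cardiomyocyte"].tissue_conductivity  # 0.26 S/cm
ELECTRODE_OFFSET_CM = 0.02          # virtual electrodes 0.2 mm above the sheet


@dataclass
class TissueGrid:
    """Regular 2D sheet: (ny, nx) nodes, (ny-1, nx-1) quadrilateral elements."""

    nx: int
    ny: int
    spacing: float                       # cm
    node_region: np.ndarray              # (ny, nx) int, REGION_CODE
    node_kind: np.ndarray                # (ny, nx) int, KIND_CODE
    fiber_angle: np.ndarray              # (ny, nx) float, radians
    element_conductivity: np.ndarray     # (ny-1, nx-1) float, S/cm
    fibrosis_manifest: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def n_elements(self) -> int:
        return (self.nx - 1) * (self.ny - 1)

    def node_positions(self) -> np.ndarray:
        """(ny, nx, 3) node coordinates in cm (sheet in the z = 0 plane)."""
        x = np.arange(self.nx) * self.spacing
        y = np.arange(self.ny) * self.spacing
        xx, yy = np.meshgrid(x, y)
        return np.stack([xx, yy, np.zeros_like(xx)], axis=-1)

    def validate(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("degenerate grid dimensions")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if np.any(self.element_conductivity <= 0):
            raise ValueError("element conductivity must be positive everywhere")

    def copy(self) -> "TissueGrid":
        return TissueGrid(self.nx, self.ny, self.spacing,
                          self.node_region.copy(), self.node_kind.copy(),
                          self.fiber_angle.copy(),
                          self.element_conductivity.copy(),
                          dict(self.fibrosis_manifest))

    def default_eligible_mask(self) -> np.ndarray:
        """Cardiomyocyte nodes outside excluded structures."""
        return ((self.node_kind == KIND_CODE["cardiomyocyte"])
                & (self.node_region != REGION_CODE["excluded"]))


@dataclass
class FibrosisConfig:
    """Which fibrotic kinds to intersperse, at what density, where, and how."""

    kinds: tuple                          # nonempty subset of fibrotic kinds
    density: float                        # fraction of eligible nodes
    eligible_mask: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.kinds:
            raise ValueError("kinds must be nonempty")
        for k in self.kinds:
            if k not in ("fibroblast", "myofibroblast", "fibrocyte"):
                raise ValueError(f"not a fibrotic cell kind: {k!r}")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")


def make_sheet(nx: int, ny: int, spacing: float = DEFAULT_SPACING_CM,
               region_layout="left_atrium") -> TissueGrid:
    """Build an all-cardiomyocyte sheet with the requested region partition.

    ``region_layout`` is a region name applied uniformly, the string
    ``"split"`` (left half of the columns RA-like, right half LA-like), or an
    (ny, nx) array of region codes/names.
    """
    if nx < 2 or ny < 2:
        raise ValueError("degenerate grid dimensions: need nx, ny >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if isinstance(region_layout, str):
        if region_layout == "split":
            region = np.full((ny, nx), REGION_CODE["right_atrium"], dtype=np.int8)
            region[:, nx // 2:] = REGION_CODE["left_atrium"]
        elif region_layout in REGION_CODE:
            region = np.full((ny, nx), REGION_CODE[region_layout], dtype=np.int8)
        else:
            raise ValueError(f"unknown region layout: {region_layout!r}")
    else:
        region = np.asarray(region_layout)
        if region.dtype.kind in "UO":
            region = np.vectorize(REGION_CODE.__getitem__)(region).astype(np.int8)
        region = region.astype(np.int8)
        if region.shape != (ny, nx):
            raise ValueError("region layout shape must be (ny, nx)")
    grid = TissueGrid(
        nx=nx, ny=ny, spacing=spacing,
        node_region=region,
        node_kind=np.zeros((ny, nx), dtype=np.int8),
        fiber_angle=np.zeros((ny, nx)),
        element_conductivity=np.full((ny - 1, nx - 1), MYO_CONDUCTIVITY),
    )
    grid.validate()
    return grid


def generate_fibrosis(grid: TissueGrid, config: FibrosisConfig) -> TissueGrid:
    """Relabel a seeded uniform random subset of eligible nodes as fibrotic.

    Exactly round(density * n_eligible) nodes are drawn without replacement
    (round half up).  Multi-kind configurations split the drawn nodes into
    equal-count groups; the remainder of the integer division goes to the
    kinds in canonical order so per-kind counts do not depend on the seed.
    Returns a new grid; the input is untouched.
    """
    config.validate()
    mask = (grid.default_eligible_mask() if config.eligible_mask is None
            else np.asarray(config.eligible_mask, dtype=bool))
    if np.any(mask & (grid.node_kind != KIND_CODE["cardiomyocyte"])):
        raise ValueError("eligible mask must select only cardiomyocyte nodes")
    if np.any(mask & (grid.node_region == REGION_CODE["excluded"])):
        raise ValueError("eligible mask must not touch excluded structures")

    eligible = np.flatnonzero(mask.ravel())
    n_eligible = eligible.size
    n_fibrotic = int(np.floor(config.density * n_eligible + 0.5))
    if 0 < n_fibrotic < len(config.kinds):
        raise ValueError(
            f"density gives {n_fibrotic} fibrotic nodes, fewer than the "
            f"{len(config.kinds)} requested kinds")

    out = grid.copy()
    counts = {k: 0 for k in config.kinds}
    if n_fibrotic > 0:
        rng = np.random.default_rng(config.seed)
        chosen = rng.choice(eligible, size=n_fibrotic, replace=False)
        rng.shuffle(chosen)
        n_kinds = len(config.kinds)
        base, rem = divmod(n_fibrotic, n_kinds)
        kinds_sorted = sorted(config.kinds, key=lambda k: KIND_CODE[k])
        start = 0
        flat_kind = out.node_kind.ravel()
        for i, kind in enumerate(kinds_sorted):
            cnt = base + (1 if i < rem else 0)
            flat_kind[chosen[start:start + cnt]] = KIND_CODE[kind]
            counts[kind] = cnt
            start += cnt
    out.fibrosis_manifest = {
        "kinds": list(config.kinds),
        "density": config.density,
        "seed": config.seed,
        "n_eligible": int(n_eligible),
        "n_fibrotic": int(n_fibrotic),
        "per_kind_counts": {k: int(v) for k, v in counts.items()},
    }
    return assign_element_conductivity(out)


def assign_element_conductivity(grid: TissueGrid) -> TissueGrid:
    """Derive element conductivities from the corner-node cell kinds.

    An element whose four corners are all cardiomyocytes keeps the myocardial
    0.26 S/cm; an element touching one fibrotic kind takes that kind's
    conductivity; with several fibrotic kinds present the minimum conductivity
    among them is used (conservative with respect to conduction slowing).
    """
    kind = grid.node_kind
    corners = np.stack([kind[:-1, :-1], kind[:-1, 1:],
                        kind[1:, :-1], kind[1:, 1:]])
    sigma = np.full((grid.ny - 1, grid.nx - 1), MYO_CONDUCTIVITY)
    for kname in ("fibroblast", "myofibroblast", "fibrocyte"):
        has = np.any(corners == KIND_CODE[kname], axis=0)
        cond = CELL_PARAMS[kname].tissue_conductivity
        sigma[has] = np.minimum(sigma[has], cond)
    grid.element_conductivity = sigma
    return grid


@dataclass
class ElectrodeArray:
    """Virtual unipolar electrodes above the sheet (positions in cm)."""

    positions: np.ndarray     # (n, 3)
    region: np.ndarray        # (n,) int, REGION_CODE of the tissue underneath

    @property
    def n_electrodes(self) -> int:
        return len(self.positions)

    def region_names(self):
        return [REGION_NAME[int(r)] for r in self.region]


def place_electrodes(tissue, layout=(5, 5),
                     offset: float = ELECTRODE_OFFSET_CM,
                     per_region: bool = True) -> ElectrodeArray:
    """Regular electrode coverage at ``offset`` cm above the tissue surface.

    ``layout`` is (rows, cols) per covered region, or a list of one (rows,
    cols) pair per region to emulate unequal coverage.  With ``per_region``
    a separate regular array is placed over each non-excluded region present;
    otherwise one array spans the whole sheet.  For a slab the offset is
    measured from the top layer.  A zero or negative offset would put
    electrodes inside the tissue and is rejected.
    """
    if offset <= 0:
        raise ValueError("electrode offset must be positive (inside tissue)")
    if hasattr(tissue, "layers"):
        grid = tissue.layers[0]
        offset = offset + (tissue.nz - 1) * tissue.spacing
    else:
        grid = tissue
    pos = grid.node_positions()
    pos_list, reg_list = [], []
    if per_region:
        regions = [int(c) for c in np.unique(grid.node_region)
                   if c != REGION_CODE["excluded"]]
    else:
        regions = [None]
    layouts = layout if isinstance(layout, list) else [layout] * len(regions)
    if len(layouts) != len(regions):
        raise ValueError("one (rows, cols) layout needed per covered region")
    for rc, (nrow, ncol) in zip(regions, layouts):
        if rc is None:
            sel = np.ones_like(grid.node_region, dtype=bool)
        else:
            sel = grid.node_region == rc
        xs = pos[..., 0][sel]
        ys = pos[..., 1][sel]
        ex = np.linspace(xs.min(), xs.max(), ncol + 2)[1:-1]
        ey = np.linspace(ys.min(), ys.max(), nrow + 2)[1:-1]
        for y in ey:
            for x in ex:
                pos_list.append((x, y, offset))
                if rc is None:
                    i = int(round(x / grid.spacing))
                    j = int(round(y / grid.spacing))
                    reg_list.append(int(grid.node_region[j, i]))
                else:
                    reg_list.append(rc)
    return ElectrodeArray(positions=np.array(pos_list),
                          region=np.array(reg_list, dtype=np.int8))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_vtk(grid: TissueGrid, path) -> None:
    """Write the sheet as an ASCII VTK legacy structured grid.

    Node scalars: region and cell kind; cell scalar: conductivity.
    """
    pos = grid.node_positions().reshape(-1, 3)
    lines = [
        "# vtk DataFile Version 3.0",
        "atriafib tissue sheet",
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {grid.nx} {grid.ny} 1",
        f"POINTS {grid.n_nodes} float",
    ]
    lines += [f"{x:.6g} {y:.6g} {z:.6g}" for x, y, z in pos]
    lines.append(f"POINT_DATA {grid.n_nodes}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(v)) for v in grid.node_region.ravel()]
    lines.append("SCALARS kind int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(v)) for v in grid.node_kind.ravel()]
    lines.append(f"CELL_DATA {grid.n_elements}")
    lines.append("SCALARS conductivity float 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{v:.6g}" for v in grid.element_conductivity.ravel()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def electrodes_to_csv(electrodes: ElectrodeArray, path) -> None:
    """Electrode array as CSV (id, x, y, z in mm, region)."""
    with open(path, "w") as fh:
        fh.write("id,x_mm,y_mm,z_mm,region\n")
        for i, (p, r) in enumerate(zip(electrodes.positions, electrodes.region)):
            fh.write(f"{i},{p[0]*10:.4f},{p[1]*10:.4f},{p[2]*10:.4f},"
                     f"{REGION_NAME[int(r)]}\n")


def kind_counts(grid: TissueGrid) -> dict:
    """Node counts per cell kind (by name)."""
    vals, cnts = np.unique(grid.node_kind, return_counts=True)
    return {KIND_NAME[int(v)]: int(c) for v, c in zip(vals, cnts)}


# ---------------------------------------------------------------------------
# Thin slabs (quasi-3D stand-in: a few stacked sheets)
# ---------------------------------------------------------------------------

@dataclass
class TissueSlab:
    """A thin wall: ``nz`` stacked sheets with independent fibrosis maps.

    Each layer is a full TissueGrid (own node kinds) at z = layer * spacing;
    the solver couples stacked nodes through the myocardial wall.  Emulates
    the finite wall thickness of the atrial mesh, which carries slow zigzag
    conduction that a single 2D sheet cannot sustain at high fibrosis
    density.  Conduction uses the hexahedral elements between consecutive
    layers: an element with any of its 8 corner nodes fibrotic takes that
    kind's conductivity (minimum across kinds when mixed).
    """

    layers: list                 # [TissueGrid, ...], identical shape
    hex_conductivity: np.ndarray | None = None   # (nz-1, ny-1, nx-1), S/cm

    @property
    def nz(self) -> int:
        return len(self.layers)

    @property
    def nx(self) -> int:
        return self.layers[0].nx

    @property
    def ny(self) -> int:
        return self.layers[0].ny

    @property
    def spacing(self) -> float:
        return self.layers[0].spacing

    @property
    def n_nodes(self) -> int:
        return self.nz * self.layers[0].n_nodes

    def node_kind_stack(self) -> np.ndarray:
        return np.stack([g.node_kind for g in self.layers])

    def node_region_stack(self) -> np.ndarray:
        return np.stack([g.node_region for g in self.layers])

    def validate(self) -> None:
        if self.nz < 1:
            raise ValueError("slab needs at least one layer")
        for g in self.layers:
            g.validate()
            if (g.nx, g.ny, g.spacing) != (self.nx, self.ny, self.spacing):
                raise ValueError("slab layers must share shape and spacing")

    @property
    def fibrosis_manifest(self) -> dict:
        per_layer = [g.fibrosis_manifest for g in self.layers]
        if not any(per_layer):
            return {}
        return {
            "per_layer": per_layer,
            "n_fibrotic": int(sum(m.get("n_fibrotic", 0) for m in per_layer)),
            "n_eligible": int(sum(m.get("n_eligible", 0) for m in per_layer)),
        }


def make_slab(nx: int, ny: int, nz: int = 3,
              spacing: float = DEFAULT_SPACING_CM,
              region_layout="left_atrium") -> TissueSlab:
    """Stack of ``nz`` identical all-cardiomyocyte sheets."""
    if nz < 1:
        raise ValueError("nz must be >= 1")
    slab = TissueSlab([make_sheet(nx, ny, spacing, region_layout)
                       for _ in range(nz)])
    return assign_hex_conductivity(slab)


def assign_hex_conductivity(slab: TissueSlab) -> TissueSlab:
    """Hexahedral-element conductivities from the 8 corner-node cell kinds.

    The volumetric analog of assign_element_conductivity: any fibrotic
    corner assigns that kind's conductivity to the element, the minimum
    winning when several kinds are present.
    """
    if slab.nz < 2:
        slab.hex_conductivity = None
        return slab
    kinds = slab.node_kind_stack()
    corners = []
    for dl in (0, 1):
        for dj in (0, 1):
            for di in (0, 1):
                corners.append(kinds[dl:slab.nz - 1 + dl,
                                     dj:slab.ny - 1 + dj,
                                     di:slab.nx - 1 + di])
    corners = np.stack(corners)
    sigma = np.full((slab.nz - 1, slab.ny - 1, slab.nx - 1), MYO_CONDUCTIVITY)
    for kname in ("fibroblast", "myofibroblast", "fibrocyte"):
        has = np.any(corners == KIND_CODE[kname], axis=0)
        sigma[has] = np.minimum(sigma[has], CELL_PARAMS[kname].tissue_conductivity)
    slab.hex_conductivity = sigma
    return slab


def generate_fibrosis_slab(slab: TissueSlab, config: FibrosisConfig) -> TissueSlab:
    """Seeded diffuse fibrosis with an independent map per layer.

    Per-layer seeds derive from ``config.seed`` through a SeedSequence, so
    one integer reproduces the whole slab; the 2D eligibility mask applies
    to every layer.
    """
    child_seeds = np.random.SeedSequence(config.seed).generate_state(slab.nz)
    layers = []
    for g, s in zip(slab.layers, child_seeds):
        cfg = FibrosisConfig(kinds=config.kinds, density=config.density,
                             eligible_mask=config.eligible_mask,
                             seed=int(s) % (2 ** 31))
        layers.append(generate_fibrosis(g, cfg))
    return assign_hex_conductivity(TissueSlab(layers))
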