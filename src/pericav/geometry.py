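"""Synthetic paired geometries: a 2D coronal brain-slice analog.

The brain is an annular plane-strain slice (outer boundary = skull, small
central opening standing in for the ventricular body).  A thin crescent
(annular-sector) cavity embedded near mid-radius represents the CSF-filled
temporal horn, which anatomically forms the roof of the hippocampus; labeled
bands hugging the cavity's concave (inner) border stand in for hippocampal
subfields, with amygdala / ventral-diencephalon analogs at the cavity ends
and a distal control band diametrically opposite.

Two meshes are produced per parameter set: they share nodes, connectivity,
and ROI labels exactly, and differ only in the material of the cavity
elements (``cavity_fluid`` vs ``cavity_substitute_solid``).  This mirrors a
paired experimental design in which the cavity is either fluid or replaced
by parenchyma.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BandSpec",
    "GeometryParams",
    "QuadMesh",
    "build_paired_geometry",
    "default_roi_bands",
    "HIPPOCAMPAL_SUBFIELDS",
    "PERICAVITY_ROIS",
    "DISTAL_CONTROL",
]

MAT_BRAIN = "brain"
MAT_FLUID = "cavity_fluid"
MAT_SUBSTITUTE = "cavity_substitute_solid"

HIPPOCAMPAL_SUBFIELDS = ("subiculum", "presubiculum", "CA1", "CA2/3",
                         "CA4/DG", "HP Tail")
PERICAVITY_ROIS = HIPPOCAMPAL_SUBFIELDS + ("amygdala", "ventral DC")
DISTAL_CONTROL = "distal control"


@dataclass(frozen=True)
class BandSpec:
    """An annular-sector ROI band in polar coordinates (radians, meters)."""

    label: str
    r0: float
    r1: float
    th0: float
    th1: float

    def contains(self, r, th) -> np.ndarray:
        """Membership test; angles are compared modulo 2*pi."""
        span = (self.th1 - self.th0) % (2 * np.pi)
        rel = (np.asarray(th) - self.th0) % (2 * np.pi)
        return ((self.r0 <= r) & (r < self.r1)
                & (rel >= 0) & (rel < span))

    def overlaps(self, other: "BandSpec") -> bool:
        eps_r = 1e-12
        if (self.r1 - self.r0 <= eps_r or other.r1 - other.r0 <= eps_r
                or abs(self.th1 - self.th0) <= 1e-12
                or abs(other.th1 - other.th0) <= 1e-12):
            return False
        if self.r1 <= other.r0 or other.r1 <= self.r0:
            return False
        twopi = 2 * np.pi
        a0, aspan = self.th0 % twopi, (self.th1 - self.th0) % twopi
        b0, bspan = other.th0 % twopi, (other.th1 - other.th0) % twopi
        eps = 1e-9
        return ((b0 - a0) % twopi < aspan - eps
                or (a0 - b0) % twopi < bspan - eps)


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the synthetic paired geometry.

    Defaults are calibrated so that the cavity/brain area ratio is 0.13%,
    matching the temporal-horn-to-brain volume ratio of a healthy adult
    (0.1-0.3%).  ``target_element_size`` is the far-field element size; the
    cavity band is always refined to ``cavity_layers`` elements across its
    thickness regardless (at least 3 are required to resolve the cavity).
    """

    brain_radius: float = 0.070          # m, outer (skull) radius
    inner_radius: float = 0.012          # m, central ventricular opening
    cavity_center_radius: float = 0.032  # m, mid-radius of the crescent
    cavity_thickness: float = 1.35e-3    # m, radial thickness
    cavity_theta_center: float = 1.2     # rad, angular position
    cavity_theta_extent: float = 0.45    # rad, angular span
    cavity_layers: int = 3               # elements across cavity thickness
    target_element_size: float = 2.5e-3  # m, far-field element size
    hippocampal_band_width: float = 2.7e-3  # m, subfield band radial width
    end_band_width: float = 0.12         # rad, amygdala / ventral-DC span
    roi_band_spec: tuple = ()            # custom bands; default set if empty
    jitter: float = 0.0                  # fraction of local spacing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cavity_layers < 3:
            raise ValueError(
                "cavity under-resolved: the cavity thickness must be "
                "resolved with at least 3 elements across")
        if not (0 < self.inner_radius < self.brain_radius):
            raise ValueError("need 0 < inner_radius < brain_radius")
        r_lo = self.cavity_center_radius - self.cavity_thickness / 2
        r_hi = self.cavity_center_radius + self.cavity_thickness / 2
        if self.cavity_thickness > 0 and not (
                self.inner_radius < r_lo and r_hi < self.brain_radius):
            raise ValueError("cavity band must lie strictly inside the brain")


def default_roi_bands(p: GeometryParams) -> list[BandSpec]:
    """ROI bands hugging the cavity: six hippocampal-subfield analogs under
    the concave border, amygdala / ventral-DC analogs at the angular ends,
    and a distal control diametrically opposite."""
    r_lo = p.cavity_center_radius - p.cavity_thickness / 2
    r_hi = p.cavity_center_radius + p.cavity_thickness / 2
    th0 = p.cavity_theta_center - p.cavity_theta_extent / 2
    th1 = p.cavity_theta_center + p.cavity_theta_extent / 2
    hb = p.hippocampal_band_width
    bands = []
    edges = np.linspace(th0, th1, len(HIPPOCAMPAL_SUBFIELDS) + 1)
    for name, a, b in zip(HIPPOCAMPAL_SUBFIELDS, edges[:-1], edges[1:]):
        bands.append(BandSpec(name, r_lo - hb, r_lo, a, b))
    bands.append(BandSpec("amygdala", r_lo - hb, r_hi,
                          th0 - p.end_band_width, th0))
    # ventral diencephalon lies medial to the hippocampus: one band
    # width further inward, spanning the cavity arc
    bands.append(BandSpec("ventral DC", r_lo - 2 * hb, r_lo - hb,
                          th0, th1))
    dc = p.cavity_theta_center + np.pi
    bands.append(BandSpec(DISTAL_CONTROL, r_lo - hb, r_hi,
                          dc - p.cavity_theta_extent / 2,
                          dc + p.cavity_theta_extent / 2))
    return bands


@dataclass
class QuadMesh:
    """2D quadrilateral mesh with per-element region and material labels."""

    node_coordinates: np.ndarray        # (N, 2), m
    element_connectivity: np.ndarray    # (E, 4), CCW
    element_region: np.ndarray          # (E,) str, '' for unlabeled
    element_material: np.ndarray        # (E,) str
    boundary_sets: dict                 # name -> (M, 2) node-index pairs

    @property
    def n_nodes(self) -> int:
        return self.node_coordinates.shape[0]

    @property
    def n_elements(self) -> int:
        return self.element_connectivity.shape[0]

    def element_areas(self) -> np.ndarray:
        """Shoelace area per element (positive for CCW quads)."""
        xy = self.node_coordinates[self.element_connectivity]  # (E,4,2)
        x, y = xy[..., 0], xy[..., 1]
        xn, yn = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        return 0.5 * np.sum(x * yn - xn * y, axis=1)

    def element_centers(self) -> np.ndarray:
        return self.node_coordinates[self.element_connectivity].mean(axis=1)

    def corner_jacobians(self) -> np.ndarray:
        """Bilinear-map Jacobian determinant at the four corners, (E, 4)."""
        xy = self.node_coordinates[self.element_connectivity]
        out = np.empty(xy.shape[:2])
        for c in range(4):
            prev = xy[:, (c - 1) % 4] - xy[:, c]
            nxt = xy[:, (c + 1) % 4] - xy[:, c]
            out[:, c] = 0.25 * (nxt[:, 0] * prev[:, 1] - nxt[:, 1] * prev[:, 0])
        return out

    def cavity_area(self) -> float:
        mask = self.element_material != MAT_BRAIN
        return float(self.element_areas()[mask].sum())

    def brain_area(self) -> float:
        mask = self.element_material == MAT_BRAIN
        return float(self.element_areas()[mask].sum())

    def area_ratio(self) -> float:
        """Cavity area over brain area (the 0.13% calibration quantity)."""
        return self.cavity_area() / self.brain_area()


def _graded_spacing(length: float, h0: float, h1: float) -> np.ndarray:
    """Breakpoints over [0, length] grading from spacing h0 to h1."""
    if length <= 0:
        return np.array([0.0])
    if abs(h1 - h0) < 1e-12 * max(h0, h1):
        n = max(1, round(length / h0))
        return np.linspace(0.0, length, n + 1)
    ratio = 1.3 if h1 > h0 else 1 / 1.3
    hs, total = [], 0.0
    h = h0
    while total + h < length:
        hs.append(h)
        total += h
        h = min(h * ratio, h1) if ratio > 1 else max(h * ratio, h1)
    hs.append(length - total)
    # merge a trailing sliver into the previous interval
    if len(hs) > 1 and hs[-1] < 0.4 * hs[-2]:
        hs[-2] += hs.pop()
    return np.concatenate([[0.0], np.cumsum(hs)])


def _theta_grid(p: GeometryParams, extra_breaks=()) -> np.ndarray:
    """Angular grid: fine over the cavity + end bands, coarse elsewhere."""
    th0 = p.cavity_theta_center - p.cavity_theta_extent / 2 - p.end_band_width
    th1 = p.cavity_theta_center + p.cavity_theta_extent / 2 + p.end_band_width
    rc = p.cavity_center_radius
    band_dr = max(p.cavity_thickness / p.cavity_layers, 1e-6)
    dth_f = min(2.0 * band_dr / rc, p.target_element_size / rc)
    dth_c = p.target_element_size / (0.5 * (p.brain_radius + p.inner_radius))
    if p.cavity_theta_extent <= 0:
        n = max(16, round(2 * np.pi / dth_c))
        return np.linspace(0.0, 2 * np.pi, n + 1)[:-1] + p.cavity_theta_center
    # fine part built piecewise so the cavity ends, the six subfield edges,
    # and the end-band edges all fall exactly on grid lines
    c0 = p.cavity_theta_center - p.cavity_theta_extent / 2
    c1 = p.cavity_theta_center + p.cavity_theta_extent / 2
    n_sub = len(HIPPOCAMPAL_SUBFIELDS)
    n_c = n_sub * max(1, round(p.cavity_theta_extent / (n_sub * dth_f)))
    n_a = max(2, round(p.end_band_width / dth_f))
    fine = np.concatenate([
        np.linspace(th0, c0, n_a + 1)[:-1],
        np.linspace(c0, c1, n_c + 1)[:-1],
        np.linspace(c1, th1, n_a + 1),
    ])
    fine_span = th1 - th0
    # coarse arc from th1 around to th0 + 2*pi, honoring extra breakpoints
    breaks = sorted({th1, th0 + 2 * np.pi}
                    | {th1 + ((b - th1) % (2 * np.pi)) for b in extra_breaks
                       if 1e-9 < (b - th1) % (2 * np.pi)
                       < 2 * np.pi - fine_span - 1e-9})
    coarse = [np.array([th1])]
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(2, round((b - a) / dth_c))
        coarse.append(np.linspace(a, b, n + 1)[1:])
    return np.concatenate([fine[:-1]] + coarse)[:-1]  # drop duplicate wrap


def _radial_grid(p: GeometryParams, band_breaks=()) -> np.ndarray:
    """Radial grid: fine through the cavity band, graded elsewhere."""
    r_lo = p.cavity_center_radius - p.cavity_thickness / 2
    r_hi = p.cavity_center_radius + p.cavity_thickness / 2
    band_dr = p.cavity_thickness / p.cavity_layers
    h_far = p.target_element_size
    if p.cavity_thickness <= 0:
        n = max(4, round((p.brain_radius - p.inner_radius) / h_far))
        return np.linspace(p.inner_radius, p.brain_radius, n + 1)
    hb_lo = max(b for b in (p.inner_radius,) + tuple(band_breaks) if b < r_lo - 1e-12)
    segs = []
    # inner coarse region up to the hippocampal band edge
    inner = _graded_spacing(hb_lo - p.inner_radius, h_far, h_far) + p.inner_radius
    segs.append(inner)
    # hippocampal band: uniform, ~2x band_dr
    n_h = max(2, round((r_lo - hb_lo) / (2 * band_dr)))
    segs.append(np.linspace(hb_lo, r_lo, n_h + 1)[1:])
    # cavity band
    segs.append(np.linspace(r_lo, r_hi, p.cavity_layers + 1)[1:])
    # outer grading from band size back to far-field size
    outer = _graded_spacing(p.brain_radius - r_hi, 2 * band_dr, h_far) + r_hi
    segs.append(outer[1:])
    return np.concatenate(segs)


def build_paired_geometry(params: GeometryParams = GeometryParams()
                          ) -> tuple[QuadMesh, QuadMesh]:
    """Build the paired (cavity-as-fluid, cavity-as-solid) meshes.

    The returned meshes are node-for-node and element-for-element identical
    and differ only in ``element_material`` of the cavity elements.
    """
    p = params
    bands = list(p.roi_band_spec) if p.roi_band_spec else default_roi_bands(p)
    for i, a in enumerate(bands):
        for b in bands[i + 1:]:
            if a.overlaps(b):
                raise ValueError(f"overlapping ROI bands: {a.label!r} and {b.label!r}")

    band_r_breaks = sorted({b.r0 for b in bands} | {b.r1 for b in bands})
    band_th_breaks = sorted({b.th0 for b in bands} | {b.th1 for b in bands})
    r = _radial_grid(p, tuple(band_r_breaks))
    th = _theta_grid(p, tuple(band_th_breaks))
    nr, nth = len(r) - 1, len(th)

    # nodes: index = j * (nr + 1) + i, periodic in theta (j)
    TH, RR = np.meshgrid(th, r, indexing="ij")
    nodes = np.column_stack([(RR * np.cos(TH)).ravel(),
                             (RR * np.sin(TH)).ravel()])

    if p.jitter > 0:
        rng = np.random.default_rng(p.seed)
        dr_local = np.minimum(np.diff(r).min(), RR * np.diff(th).min())
        amp = p.jitter * np.broadcast_to(dr_local, RR.shape).ravel()
        interior = np.ones(nodes.shape[0], bool)
        ring = np.arange(nth) * (nr + 1)
        interior[ring] = False            # inner boundary
        interior[ring + nr] = False       # outer (skull) boundary
        # keep cavity-band and band-edge radii exact
        keep_r = {0, nr}
        for rb in np.concatenate([band_r_breaks,
                                  [p.cavity_center_radius - p.cavity_thickness / 2,
                                   p.cavity_center_radius + p.cavity_thickness / 2]]):
            i = int(np.argmin(np.abs(r - rb)))
            if abs(r[i] - rb) < 1e-9:
                keep_r.add(i)
        for i in keep_r:
            interior[ring + i] = False
        disp = rng.uniform(-1, 1, nodes.shape) * amp[:, None]
        nodes[interior] += disp[interior]

    def nid(j, i):
        return (j % nth) * (nr + 1) + i

    jj, ii = np.meshgrid(np.arange(nth), np.arange(nr), indexing="ij")
    conn = np.stack([nid(jj, ii), nid(jj, ii + 1),
                     nid(jj + 1, ii + 1), nid(jj + 1, ii)], axis=-1)
    conn = conn.reshape(-1, 4)

    # cell-center polar coordinates from the grid (exact, jitter-free)
    r_c = 0.5 * (r[:-1] + r[1:])
    th_ext = np.append(th, th[0] + 2 * np.pi)
    th_c = 0.5 * (th_ext[:-1] + th_ext[1:])
    THc, RRc = np.meshgrid(th_c, r_c, indexing="ij")
    rc_flat, thc_flat = RRc.ravel(), THc.ravel()

    r_lo = p.cavity_center_radius - p.cavity_thickness / 2
    r_hi = p.cavity_center_radius + p.cavity_thickness / 2
    th0 = p.cavity_theta_center - p.cavity_theta_extent / 2
    cavity = np.zeros(conn.shape[0], bool)
    if p.cavity_thickness > 0 and p.cavity_theta_extent > 0:
        rel = (thc_flat - th0) % (2 * np.pi)
        cavity = ((r_lo < rc_flat) & (rc_flat < r_hi)
                  & (rel < p.cavity_theta_extent))

    region = np.full(conn.shape[0], "", dtype=object)
    for band in bands:
        mask = band.contains(rc_flat, thc_flat) & ~cavity
        clash = mask & (region != "")
        if clash.any():
            raise ValueError(f"ROI band {band.label!r} overlaps a previous band")
        region[mask] = band.label

    # distal control must sit well away from the cavity
    if p.cavity_thickness > 0 and any(b.label == DISTAL_CONTROL for b in bands):
        dc = next(b for b in bands if b.label == DISTAL_CONTROL)
        mid = np.array([np.cos(p.cavity_theta_center),
                        np.sin(p.cavity_theta_center)]) * p.cavity_center_radius
        dmid = np.array([np.cos((dc.th0 + dc.th1) / 2),
                         np.sin((dc.th0 + dc.th1) / 2)]) * (dc.r0 + dc.r1) / 2
        if np.linalg.norm(mid - dmid) < 5 * p.cavity_thickness:
            raise ValueError("distal control ROI closer than 5 cavity widths")

    ring = np.arange(nth) * (nr + 1)
    outer_edges = np.column_stack([ring + nr, np.roll(ring, -1) + nr])
    cav_wall = _cavity_wall_edges(conn, cavity)
    boundary_sets = {"outer_skull": outer_edges, "cavity_wall": cav_wall}

    material = np.full(conn.shape[0], MAT_BRAIN, dtype=object)
    material[cavity] = MAT_FLUID
    th_mesh = QuadMesh(nodes, conn, region.copy(), material,
                       {k: v.copy() for k, v in boundary_sets.items()})

    material_nth = np.full(conn.shape[0], MAT_BRAIN, dtype=object)
    material_nth[cavity] = MAT_SUBSTITUTE
    nth_mesh = QuadMesh(nodes.copy(), conn.copy(), region.copy(), material_nth,
                        {k: v.copy() for k, v in boundary_sets.items()})

    for m in (th_mesh, nth_mesh):
        if np.any(m.corner_jacobians() <= 0):
            raise ValueError("mesh contains a non-positive corner Jacobian")
    return th_mesh, nth_mesh


def _cavity_wall_edges(conn: np.ndarray, cavity: np.ndarray) -> np.ndarray:
    """Edges separating cavity elements from brain elements.

    Returned node pairs are ordered so that the cavity lies to the left of
    the edge direction (outward normal of the brain wall points into the
    cavity)."""
    if not cavity.any():
        return np.empty((0, 2), dtype=int)
    edge_count: dict[tuple, list] = {}
    for e in np.flatnonzero(cavity):
        quad = conn[e]
        for k in range(4):
            a, b = int(quad[k]), int(quad[(k + 1) % 4])
            edge_count.setdefault((min(a, b), max(a, b)), []).append((a, b))
    brain_edges = set()
    for e in np.flatnonzero(~cavity):
        quad = conn[e]
        for k in range(4):
            a, b = int(quad[k]), int(quad[(k + 1) % 4])
            brain_edges.add((min(a, b), max(a, b)))
    wall = []
    for key, oriented in edge_count.items():
        if key in brain_edges and len(oriented) == 1:
            # CCW element traversal puts the cavity element on the left of
            # (a, b); reverse so the brain is on the left, cavity on right
            a, b = oriented[0]
            wall.append((b, a))
    return np.array(sorted(wall), dtype=int)
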