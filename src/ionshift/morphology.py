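"""Branched compartmental geometry.

A neuron is represented as a rooted tree of cylindrical compartments.
The root is the soma, represented as an equivalent cylinder of equal
membrane area.  Each compartment carries an extracellular shell whose
volume is a fixed fraction (default 15%) of the intracellular volume;
ion concentrations evolve in both pools.

Morphologies come from three sources:

* :func:`load_swc` -- standard 7-column SWC reconstructions,
* :func:`attach_axon` -- a tapering initial segment plus a thin cable
  appended at the soma,
* :func:`make_fixture` -- small deterministic synthetic morphologies
  (single compartment, ball-and-stick, branched tree) used throughout
  the test suite so that nothing needs to be downloaded.

Regions
-------
Each compartment is classified into one of the anatomical layers that
carry distinct GABA_A synapse densities:

``soma``, ``axon``, ``apical_proximal`` (apical < 150 um from soma),
``radiatum_thick_medial`` (thick apical trunk 150-300 um),
``radiatum_thick_distal_or_thin`` (remaining apical < 400 um),
``lacunosum_moleculare`` (apical beyond 400 um),
``oriens_proximal`` (basal < 100 um), ``oriens_distal`` (other basal).

The numeric layer boundaries are not anatomical constants and are
exposed on :class:`RegionRules`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StructuralError, ValidationError

REGIONS = (
    "soma",
    "axon",
    "apical_proximal",
    "radiatum_thick_medial",
    "radiatum_thick_distal_or_thin",
    "lacunosum_moleculare",
    "oriens_proximal",
    "oriens_distal",
)

#: Default fraction of intracellular volume taken by the extracellular shell.
DEFAULT_SHELL_FRACTION = 0.15


@dataclass
class RegionRules:
    """Distance/radius boundaries used to map compartments onto layers."""

    apical_proximal_max: float = 150.0   # um
    radiatum_medial_max: float = 300.0   # um
    radiatum_distal_max: float = 400.0   # um
    thick_trunk_min_radius: float = 0.7  # um; below this a 150-300 um apical
    oriens_proximal_max: float = 100.0   # um                 # is "thin"


@dataclass
class AxonSpec:
    """Axon appended at the soma: tapering initial segment then a thin cable."""

    initial_segment_lengths: tuple = (10.0, 10.0, 10.0, 10.0, 10.0)  # um
    initial_segment_radius_start: float = 1.5   # um
    initial_segment_radius_end: float = 0.5     # um
    cable_n: int = 10
    cable_length: float = 300.0                 # um total
    cable_radius: float = 0.5                   # um


@dataclass
class CompartmentGeometry:
    """One cylindrical compartment."""

    id: int
    parent_id: int | None
    length: float                  # um
    radius: float                  # um
    membrane_area: float           # um^2, lateral cylinder area
    intra_volume: float            # um^3
    shell_volume: float            # um^3
    path_distance_from_soma: float  # um, at the compartment midpoint
    region: str


def _cyl_area(radius, length):
    return 2.0 * math.pi * radius * length


def _cyl_volume(radius, length):
    return math.pi * radius ** 2 * length


@dataclass
class CompartmentalModel:
    """Tree of cylindrical compartments plus mechanism placements.

    Geometry is stored as flat arrays indexed by compartment, ordered so
    that ``parent_index[i] < i`` for every non-root compartment (the
    ordering required by the direct tree solve).  ``mechanisms`` maps a
    mechanism name to a per-compartment density array; it is filled in
    by the membrane builder and preserved (per area) under refinement.
    """

    parent_index: np.ndarray        # (N,) int, -1 for the root
    length: np.ndarray              # (N,) um
    radius: np.ndarray              # (N,) um
    region: np.ndarray              # (N,) str
    shell_fraction: np.ndarray      # (N,)
    mechanisms: dict = field(default_factory=dict)

    def __post_init__(self):
        self.parent_index = np.asarray(self.parent_index, dtype=int)
        self.length = np.asarray(self.length, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.region = np.asarray(self.region, dtype=object)
        self.shell_fraction = np.asarray(self.shell_fraction, dtype=float)
        self.validate()

    # -- derived geometry ------------------------------------------------
    @property
    def n(self) -> int:
        return self.parent_index.size

    @property
    def area(self) -> np.ndarray:
        """Lateral membrane area, um^2."""
        return 2.0 * np.pi * self.radius * self.length

    @property
    def volume(self) -> np.ndarray:
        """Intracellular volume, um^3."""
        return np.pi * self.radius ** 2 * self.length

    @property
    def shell_volume(self) -> np.ndarray:
        """Extracellular shell volume, um^3."""
        return self.shell_fraction * self.volume

    @property
    def cross_section(self) -> np.ndarray:
        """Intracellular cross-sectional area, um^2."""
        return np.pi * self.radius ** 2

    @property
    def path_distance(self) -> np.ndarray:
        """Distance from the soma centroid to each compartment midpoint, um.

        The soma itself is at distance zero and its length does not
        contribute to the path of its children.
        """
        d = np.zeros(self.n)
        for i in range(self.n):
            p = self.parent_index[i]
            if p < 0:
                d[i] = 0.0
            elif p == self.root:
                d[i] = self.length[i] / 2.0
            else:
                d[i] = d[p] + (self.length[p] + self.length[i]) / 2.0
        return d

    @property
    def root(self) -> int:
        return int(np.where(self.parent_index < 0)[0][0])

    def children(self, i: int) -> np.ndarray:
        return np.where(self.parent_index == i)[0]

    # -- validation ------------------------------------------------------
    def validate(self):
        n = self.n
        roots = np.where(self.parent_index < 0)[0]
        if len(roots) != 1:
            raise StructuralError(
                f"model must have exactly one root, found {len(roots)}"
            )
        if np.any(self.radius <= 0) or np.any(self.length <= 0):
            bad = int(np.where((self.radius <= 0) | (self.length <= 0))[0][0])
            raise ValidationError(
                f"compartment {bad} has non-positive radius or length"
            )
        for i in range(n):
            p = self.parent_index[i]
            if p >= n:
                raise StructuralError(f"compartment {i} has out-of-range parent {p}")
            if p >= i and p >= 0:
                raise StructuralError(
                    f"compartment {i} is not in parent-before-child order"
                )
        unknown = set(self.region) - set(REGIONS)
        if unknown:
            raise ConfigurationError(f"unlabeled/unknown regions: {sorted(unknown)}")

    # -- operations ------------------------------------------------------
    def axial_conductance(self, axial_resistivity: float) -> np.ndarray:
        """Conductance (in S) between each compartment and its parent.

        Uses the series resistance of the two half-cylinders.  Entry for
        the root is 0.  ``axial_resistivity`` in Ohm*cm.
        """
        g = np.zeros(self.n)
        # R = Ra * (L/2) / (pi r^2); with L, r in um and Ra in Ohm*cm the
        # resistance in Ohm carries a factor 1e4.
        half_r = 1.0e4 * axial_resistivity * (self.length / 2.0) / self.cross_section
        for i in range(self.n):
            p = self.parent_index[i]
            if p >= 0:
                g[i] = 1.0 / (half_r[i] + half_r[p])
        return g

    def compartments(self) -> list[CompartmentGeometry]:
        """Materialize the per-compartment geometry records."""
        area, vol, shell, dist = self.area, self.volume, self.shell_volume, self.path_distance
        out = []
        for i in range(self.n):
            p = self.parent_index[i]
            out.append(
                CompartmentGeometry(
                    id=i,
                    parent_id=None if p < 0 else int(p),
                    length=float(self.length[i]),
                    radius=float(self.radius[i]),
                    membrane_area=float(area[i]),
                    intra_volume=float(vol[i]),
                    shell_volume=float(shell[i]),
                    path_distance_from_soma=float(dist[i]),
                    region=str(self.region[i]),
                )
            )
        return out

    def summary_table(self) -> pd.DataFrame:
        """Per-compartment geometry and region labels as a DataFrame."""
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "parent": self.parent_index,
                "length_um": self.length,
                "radius_um": self.radius,
                "area_um2": self.area,
                "volume_um3": self.volume,
                "shell_volume_um3": self.shell_volume,
                "path_distance_um": self.path_distance,
                "region": self.region,
            }
        )

    def with_shell_fraction(self, fraction: float, min_distance: float = 0.0):
        """Copy with the shell fraction overridden beyond ``min_distance``."""
        sf = self.shell_fraction.copy()
        sf[self.path_distance >= min_distance] = fraction
        return replace(self, shell_fraction=sf, mechanisms=dict(self.mechanisms))


# ---------------------------------------------------------------------------
# construction helpers


def _assemble(parents, lengths, radii, regions, shell_fraction=DEFAULT_SHELL_FRACTION):
    n = len(parents)
    return CompartmentalModel(
        parent_index=np.asarray(parents, dtype=int),
        length=np.asarray(lengths, dtype=float),
        radius=np.asarray(radii, dtype=float),
        region=np.asarray(regions, dtype=object),
        shell_fraction=np.full(n, shell_fraction, dtype=float),
    )


def classify_regions(model: CompartmentalModel, hints: np.ndarray,
                     rules: RegionRules | None = None) -> CompartmentalModel:
    """Assign layer labels from structural hints.

    ``hints`` holds per-compartment SWC-style type codes: 1 soma, 2 axon,
    3 basal dendrite, 4 apical dendrite.
    """
    rules = rules or RegionRules()
    dist = model.path_distance
    region = np.empty(model.n, dtype=object)
    for i in range(model.n):
        h, d, r = int(hints[i]), dist[i], model.radius[i]
        if h == 1:
            region[i] = "soma"
        elif h == 2:
            region[i] = "axon"
        elif h == 3:
            region[i] = ("oriens_proximal" if d < rules.oriens_proximal_max
                         else "oriens_distal")
        elif h == 4:
            if d < rules.apical_proximal_max:
                region[i] = "apical_proximal"
            elif d < rules.radiatum_medial_max and r >= rules.thick_trunk_min_radius:
                region[i] = "radiatum_thick_medial"
            elif d < rules.radiatum_distal_max:
                region[i] = "radiatum_thick_distal_or_thin"
            else:
                region[i] = "lacunosum_moleculare"
        else:
            raise ConfigurationError(f"compartment {i}: unknown type hint {h}")
    return replace(model, region=region, mechanisms=dict(model.mechanisms))


def load_swc(path, axon_spec: AxonSpec | None = None,
             rules: RegionRules | None = None) -> CompartmentalModel:
    """Load a standard 7-column SWC reconstruction.

    Soma points are merged into one equivalent cylinder of equal
    membrane area.  Every other SWC point becomes a cylinder spanning
    from its parent point with the point's own radius.  If ``axon_spec``
    is given an axon is appended at the soma.

    Raises :class:`StructuralError` for cyclic or disconnected files and
    :class:`ValidationError` for non-positive radii.
    """
    nodes = {}
    order = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValidationError(f"malformed SWC line: {line!r}")
            nid, ntype = int(parts[0]), int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            parent = int(parts[6])
            if r <= 0:
                raise ValidationError(f"SWC node {nid} has non-positive radius {r}")
            nodes[nid] = (ntype, np.array([x, y, z]), r, parent)
            order.append(nid)
    if not nodes:
        raise ValidationError(f"{path}: no SWC nodes found")

    # structural checks: single root, acyclic, connected
    roots = [nid for nid in order if nodes[nid][3] == -1]
    if len(roots) != 1:
        raise StructuralError(f"SWC must have exactly one root, found {roots}")
    for nid in order:
        parent = nodes[nid][3]
        if parent != -1 and parent not in nodes:
            raise StructuralError(f"SWC node {nid} references missing parent {parent}")
        seen = {nid}
        cur = parent
        while cur != -1:
            if cur in seen:
                raise StructuralError(f"cycle detected in SWC at node {nid}")
            seen.add(cur)
            cur = nodes[cur][3]

    # soma: equivalent cylinder of equal area
    soma_ids = [nid for nid in order if nodes[nid][0] == 1]
    if soma_ids:
        if len(soma_ids) == 1:
            r = nodes[soma_ids[0]][2]
            soma_area = 4.0 * math.pi * r ** 2          # sphere of that radius
            soma_radius = r
        else:
            soma_area = 0.0
            rs = []
            for a, b in zip(soma_ids[:-1], soma_ids[1:]):
                seg = np.linalg.norm(nodes[a][1] - nodes[b][1])
                rm = 0.5 * (nodes[a][2] + nodes[b][2])
                soma_area += _cyl_area(rm, max(seg, 1e-9))
                rs.append(rm)
            soma_radius = float(np.mean(rs))
        soma_length = soma_area / (2.0 * math.pi * soma_radius)
    else:
        raise StructuralError("SWC file contains no soma (type 1) node")
    soma_set = set(soma_ids)

    parents, lengths, radii, hints = [-1], [soma_length], [soma_radius], [1]
    index_of = {nid: 0 for nid in soma_ids}

    # children in file order; SWC files list parents before children
    for nid in order:
        if nid in soma_set:
            continue
        ntype, xyz, r, parent = nodes[nid]
        if parent == -1:
            raise StructuralError(f"non-soma node {nid} is a root")
        if parent not in index_of:
            raise StructuralError(
                f"SWC node {nid} appears before its parent {parent}"
            )
        pidx = index_of[parent]
        pxyz = nodes[parent][1]
        seg = float(np.linalg.norm(xyz - pxyz))
        if seg <= 0:
            seg = 2.0 * r   # coincident points: keep a stub
        parents.append(pidx)
        lengths.append(seg)
        radii.append(r)
        hints.append(ntype)
        index_of[nid] = len(parents) - 1

    model = _assemble(parents, lengths, radii, ["soma"] * len(parents))
    model = classify_regions(model, np.asarray(hints), rules)
    if axon_spec is not None:
        model = attach_axon(model, axon_spec)
    return model


#: Alias: SWC is the one supported morphology interchange format.
load_morphology = load_swc


def write_swc(model: CompartmentalModel, path):
    """Write the model as a chain-structured SWC file (one point per
    compartment, placed along x by path distance; radii preserved)."""
    type_of = {"soma": 1, "axon": 2}
    dist = model.path_distance
    with open(path, "w") as fh:
        fh.write("# synthetic morphology written by ionshift\n")
        for i in range(model.n):
            region = model.region[i]
            ntype = type_of.get(region, 3 if region.startswith("oriens") else 4)
            parent = model.parent_index[i]
            x = dist[i] + model.length[i] / 2.0
            fh.write(
                f"{i + 1} {ntype} {x:.3f} 0 0 {model.radius[i]:.4f} "
                f"{parent + 1 if parent >= 0 else -1}\n"
            )


def attach_axon(model: CompartmentalModel, spec: AxonSpec) -> CompartmentalModel:
    """Append a tapering initial segment plus a thin cable at the soma."""
    parents = list(model.parent_index)
    lengths = list(model.length)
    radii = list(model.radius)
    regions = list(model.region)
    sf = list(model.shell_fraction)

    prev = model.root
    n_ais = len(spec.initial_segment_lengths)
    for j, L in enumerate(spec.initial_segment_lengths):
        frac = (j + 0.5) / n_ais
        r = (spec.initial_segment_radius_start
             + frac * (spec.initial_segment_radius_end
                       - spec.initial_segment_radius_start))
        parents.append(prev)
        lengths.append(L)
        radii.append(r)
        regions.append("axon")
        sf.append(DEFAULT_SHELL_FRACTION)
        prev = len(parents) - 1
    seg = spec.cable_length / spec.cable_n
    for _ in range(spec.cable_n):
        parents.append(prev)
        lengths.append(seg)
        radii.append(spec.cable_radius)
        regions.append("axon")
        sf.append(DEFAULT_SHELL_FRACTION)
        prev = len(parents) - 1

    return CompartmentalModel(
        parent_index=np.asarray(parents),
        length=np.asarray(lengths),
        radius=np.asarray(radii),
        region=np.asarray(regions, dtype=object),
        shell_fraction=np.asarray(sf),
        mechanisms={},
    )


def refine(model: CompartmentalModel, factor: int) -> CompartmentalModel:
    """Split every cylinder into ``factor`` equal sub-cylinders.

    Total membrane area, intracellular volume and shell volume are
    conserved exactly; per-area mechanism densities are carried over.
    """
    if factor < 1 or int(factor) != factor:
        raise ValidationError("refine factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return replace(model, mechanisms=dict(model.mechanisms))

    parents, lengths, radii, regions, sf = [], [], [], [], []
    src = []   # originating compartment of each new one
    new_of_last = {}
    for i in range(model.n):
        p = model.parent_index[i]
        if model.region[i] == "soma":
            # the soma stays one equivalent cylinder
            parents.append(-1 if p < 0 else new_of_last[p])
            lengths.append(model.length[i])
            radii.append(model.radius[i])
            regions.append(model.region[i])
            sf.append(model.shell_fraction[i])
            src.append(i)
            new_of_last[i] = len(parents) - 1
            continue
        prev = -1 if p < 0 else new_of_last[p]
        for _ in range(factor):
            parents.append(prev)
            lengths.append(model.length[i] / factor)
            radii.append(model.radius[i])
            regions.append(model.region[i])
            sf.append(model.shell_fraction[i])
            src.append(i)
            prev = len(parents) - 1
        new_of_last[i] = prev

    mech = {name: np.asarray(vals)[src] for name, vals in model.mechanisms.items()}
    return CompartmentalModel(
        parent_index=np.asarray(parents),
        length=np.asarray(lengths),
        radius=np.asarray(radii),
        region=np.asarray(regions, dtype=object),
        shell_fraction=np.asarray(sf),
        mechanisms=mech,
    )


def make_fixture(kind: str, **params) -> CompartmentalModel:
    """Deterministic synthetic morphologies for tests and examples.

    ``single``
        one somatic cylinder; ``radius`` (default 10 um), ``length`` (20 um).
    ``ball_and_stick``
        soma plus an unbranched thin apical stick; ``stick_length``
        (400 um), ``n_segments`` (8), ``stick_radius`` (0.5 um),
        optional ``taper`` (distal end radius), ``soma_radius``,
        ``soma_length``.
    ``branched``
        a reduced CA1-like tree: soma, thick apical trunk, a thin
        proximal oblique branch, ``n_daughters`` thin distal tuft
        daughters and one basal stick, so that every synapse-density
        class is populated and radii are mixed.
    """
    if kind == "single":
        r = params.get("radius", 10.0)
        L = params.get("length", 20.0)
        return _assemble([-1], [L], [r], ["soma"])

    if kind == "ball_and_stick":
        soma_r = params.get("soma_radius", 10.0)
        soma_l = params.get("soma_length", 20.0)
        stick = params.get("stick_length", 400.0)
        nseg = params.get("n_segments", 8)
        r0 = params.get("stick_radius", 0.5)
        r1 = params.get("taper", r0)
        parents = [-1]
        lengths = [soma_l]
        radii = [soma_r]
        hints = [1]
        seg = stick / nseg
        for j in range(nseg):
            parents.append(j)     # chain: previous compartment
            lengths.append(seg)
            radii.append(r0 + (r1 - r0) * (j + 0.5) / nseg)
            hints.append(4)
        model = _assemble(parents, lengths, radii, ["soma"] * len(parents))
        return classify_regions(model, np.asarray(hints),
                                params.get("rules"))

    if kind == "branched":
        n_d = params.get("n_daughters", 2)
        trunk_len = params.get("trunk_length", 300.0)
        trunk_nseg = params.get("trunk_segments", 6)
        trunk_r = params.get("trunk_radius", 1.2)
        oblique_len = params.get("oblique_length", 150.0)
        oblique_nseg = params.get("oblique_segments", 3)
        oblique_r = params.get("oblique_radius", 0.35)
        oblique_at = params.get("oblique_at_segment", 1)
        daughter_len = params.get("daughter_length", 150.0)
        daughter_nseg = params.get("daughter_segments", 2)
        daughter_r = params.get("daughter_radius", 0.4)
        basal_len = params.get("basal_length", 150.0)
        basal_nseg = params.get("basal_segments", 2)
        basal_r = params.get("basal_radius", 0.6)

        parents, lengths, radii, hints = [-1], [20.0], [10.0], [1]
        prev = 0
        trunk_idx = []
        for _ in range(trunk_nseg):
            parents.append(prev)
            lengths.append(trunk_len / trunk_nseg)
            radii.append(trunk_r)
            hints.append(4)
            prev = len(parents) - 1
            trunk_idx.append(prev)
        branch_point = prev
        # thin oblique branch off the proximal trunk (the high-density,
        # high surface-to-volume region where chloride builds up most)
        prev = trunk_idx[min(oblique_at, trunk_nseg - 1)]
        for _ in range(oblique_nseg):
            parents.append(prev)
            lengths.append(oblique_len / oblique_nseg)
            radii.append(oblique_r)
            hints.append(4)
            prev = len(parents) - 1
        # distal tuft daughters
        for _ in range(n_d):
            prev = branch_point
            for _ in range(daughter_nseg):
                parents.append(prev)
                lengths.append(daughter_len / daughter_nseg)
                radii.append(daughter_r)
                hints.append(4)
                prev = len(parents) - 1
        # basal stick
        prev = 0
        for _ in range(basal_nseg):
            parents.append(prev)
            lengths.append(basal_len / basal_nseg)
            radii.append(basal_r)
            hints.append(3)
            prev = len(parents) - 1
        model = _assemble(parents, lengths, radii, ["soma"] * len(parents))
        return classify_regions(model, np.asarray(hints), params.get("rules"))

    raise ValidationError(f"unknown fixture kind {kind!r}")
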