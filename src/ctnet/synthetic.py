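"""Synthetic 3D nuclei with planted interchromosomal interaction networks.

The generator emulates the study design the downstream statistics assume:

* 7 chromosome types × 2 homologs per diploid nucleus;
* territory volumes apportioned to chromosome sequence length, with the
  larger copy of each chromosome tagged ``a``;
* size-dependent radial placement (larger chromosomes seeded more
  peripherally);
* per-chromosome-pair interaction probabilities that differ by condition
  (cell type × G1/S), with 1–4 homolog-level contacts per interacting pair;
* ~90 % of planted contacts realized as direct mask overlap (PBD = 0),
  the remainder as abutment within the 0.28 µm calling threshold;
* S-phase nuclei ~12.5 % larger in volume than G1.

Planted contacts are realized exactly: territories that are not planted
partners are kept > 0.28 µm apart by exclusion buffers, so the interaction
matrix recomputed from the rendered masks equals the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .constants import CHROMOSOME_LENGTH_MB
from .core import (CHROMOSOME_PANEL, STRUCT_6, HomologID, LabeledVolume,
                   NucleusRecord, VoxelSpacing)
from .growth import InfeasiblePackingError, grow_region


class _PlacementError(InfeasiblePackingError):
    """Packing failure that names the territory, enabling retry reordering."""

    def __init__(self, node, message):
        super().__init__(message)
        self.node = node
from .interactions import InteractionMatrix, chromosome_pairs

# geometry constants of the planting procedure (µm)
EXCLUSION_RADIUS_UM = 0.30   # minimum border distance kept between non-partner CTs
OVERLAP_SHELL_UM = 0.55      # how deep inside a partner an overlap contact may reach
CONTACT_SEED_BAND_UM = 0.15  # abutment seeds/tendrils stop within this border distance
OVERLAP_FILL_FRACTION = 0.09  # of the growing CT's volume spent inside each overlap partner

#: canonical homolog-slot order used when a pair interacts 1–4 times;
#: two contacts therefore form the disjoint (2a) configuration, three the chain.
CANONICAL_SLOTS = (("a", "a"), ("b", "b"), ("a", "b"), ("b", "a"))


@dataclass
class PopulationSpec:
    """Statistical recipe for one synthetic population (a single condition)."""

    n_nuclei: int
    condition: str = "WI38-G1"
    semi_axes: Tuple[float, float, float] = (7.0, 5.5, 2.5)  # (x, y, z) µm
    pair_probabilities: Mapping[Tuple[int, int], float] = field(default_factory=dict)
    homolog_probability: float = 0.08
    multiplicity_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.30, 3: 0.10, 4: 0.05}
    )
    volume_fractions: Mapping[int, float] = field(default_factory=dict)
    radial_exponent: float = 1.0
    overlap_fraction: float = 0.9
    irregularity: float = 0.2
    size_cv: float = 0.08
    persistence: float = 0.3
    compactness: float = 0.5
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)
    chromosomes: Tuple[int, ...] = CHROMOSOME_PANEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        self.chromosomes = tuple(sorted(self.chromosomes))
        if not self.pair_probabilities:
            self.pair_probabilities = {
                p: 0.5 for p in chromosome_pairs(self.chromosomes)
            }
        for p, v in self.pair_probabilities.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"pair probability out of [0,1] for {p}")
        if not 0.0 <= self.homolog_probability <= 1.0:
            raise ValueError("homolog_probability out of [0,1]")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction out of [0,1]")
        if not self.volume_fractions:
            self.volume_fractions = default_volume_fractions(self.chromosomes)
        if sum(self.volume_fractions.values()) >= 1.0:
            raise ValueError("territory volume fractions must sum to < 1")

    def planted_pairs(self, min_probability: float = 0.5) -> set:
        """Chromosome pairs whose probability is at or above ``min_probability``."""
        return {p for p, v in self.pair_probabilities.items() if v >= min_probability}


def default_volume_fractions(
    chromosomes: Sequence[int] = CHROMOSOME_PANEL, total: float = 0.15
) -> Dict[int, float]:
    """Apportion a total nuclear volume fraction to chromosomes ∝ sequence length."""
    lengths = {c: CHROMOSOME_LENGTH_MB[c] for c in chromosomes}
    s = sum(lengths.values())
    return {c: total * l / s for c, l in lengths.items()}


#: baseline per-pair interaction probabilities: deliberately heterogeneous
#: (pair preference is the signal the consensus network resolves), with
#: chromosome-17 pairs elevated — the gene-rich, most interactive member.
BASE_PAIR_PROBABILITIES: Dict[Tuple[int, int], float] = {
    (1, 4): 0.30, (1, 11): 0.45, (1, 12): 0.35, (1, 16): 0.50,
    (1, 17): 0.65, (1, 18): 0.40, (4, 11): 0.35, (4, 12): 0.55,
    (4, 16): 0.30, (4, 17): 0.60, (4, 18): 0.45, (11, 12): 0.50,
    (11, 16): 0.35, (11, 17): 0.70, (11, 18): 0.30, (12, 16): 0.40,
    (12, 17): 0.65, (12, 18): 0.25, (16, 17): 0.55, (16, 18): 0.35,
    (17, 18): 0.50,
}


def default_pair_probabilities(cell_type: str, stage: str) -> Dict[Tuple[int, int], float]:
    """Condition-specific per-pair interaction probabilities.

    The heterogeneous baseline above, with cell-type and stage shifts that
    mimic the qualitative population structure the analysis is meant to
    resolve (few altered pairs in the fibroblast line, chromosome-18 gains
    and chromosome-12 losses in S phase of the epithelial line).
    """
    probs = dict(BASE_PAIR_PROBABILITIES)
    shifts: Dict[Tuple[int, int], float] = {}
    if cell_type.upper() in ("10A", "MCF10A"):
        shifts[(4, 17)] = +0.15
        if stage.upper() == "S":
            for p in [(1, 12), (4, 12), (11, 12), (12, 16), (12, 17)]:
                shifts[p] = shifts.get(p, 0.0) - 0.15
            for p in [(1, 18), (4, 18), (11, 18)]:
                shifts[p] = shifts.get(p, 0.0) + 0.15
    elif stage.upper() == "S":  # WI38 S: only two pairs altered
        shifts[(1, 4)] = -0.15
        shifts[(12, 16)] = +0.15
    for p, d in shifts.items():
        probs[p] = float(np.clip(probs[p] + d, 0.05, 0.95))
    return probs


def default_spec(
    cell_type: str = "WI38",
    stage: str = "G1",
    n_nuclei: int = 50,
    seed: int = 0,
    **overrides,
) -> PopulationSpec:
    """Build the default condition spec for a cell type × cell-cycle stage."""
    semi = np.array((7.0, 5.5, 2.5))
    if stage.upper() == "S":
        semi = semi * 1.125 ** (1.0 / 3.0)  # +12.5 % nuclear volume in S
    spec = PopulationSpec(
        n_nuclei=n_nuclei,
        condition=f"{cell_type}-{stage}",
        semi_axes=tuple(semi),
        pair_probabilities=default_pair_probabilities(cell_type, stage),
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# nucleus mask
# ---------------------------------------------------------------------------

def generate_nucleus_mask(
    semi_axes: Tuple[float, float, float],
    irregularity: float,
    spacing: VoxelSpacing,
    seed: int = 0,
    shape: Optional[Tuple[int, int, int]] = None,
) -> LabeledVolume:
    """Discretized (optionally lumpy) ellipsoid nucleus mask.

    ``irregularity`` perturbs the radius by a smooth zero-mean directional
    field scaled to ±``irregularity``; 0 gives the plain ellipsoid and is
    seed-independent.  The construction is star-shaped about the centre,
    hence always one filled connected component.
    """
    ax, ay, az = (float(v) for v in semi_axes)
    if min(ax, ay, az) <= 0:
        raise ValueError("semi-axes must be strictly positive")
    pitch = np.array(spacing.sampling)  # (dz, dy, dx)
    semi_zyx = np.array([az, ay, ax])
    reach = semi_zyx * (1.0 + max(0.0, irregularity))
    need = 2 * np.ceil(reach / pitch).astype(int) + 5
    if shape is None:
        shape = tuple(need)
    elif any(s < n for s, n in zip(shape, need)):
        raise ValueError(f"grid {shape} too small for ellipsoid needing {tuple(need)}")
    center = (np.array(shape) - 1) / 2.0
    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) - center[0]) * pitch[0] / semi_zyx[0],
        (np.arange(shape[1]) - center[1]) * pitch[1] / semi_zyx[1],
        (np.arange(shape[2]) - center[2]) * pitch[2] / semi_zyx[2],
        indexing="ij",
        sparse=True,
    )
    rho = np.sqrt(zz**2 + yy**2 + xx**2)
    if irregularity == 0.0:
        mask = rho <= 1.0
    else:
        rng = np.random.default_rng(seed)
        b = rng.standard_normal((3, 3))
        b = (b + b.T) / 2.0
        w = rng.standard_normal((3, 3))
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = [np.where(rho > 0, g / rho, 0.0) for g in (zz, yy, xx)]
        quad = sum(b[i, j] * u[i] * u[j] for i in range(3) for j in range(3))
        cubic = (
            (w[0, 0] * u[0] + w[0, 1] * u[1] + w[0, 2] * u[2])
            * (w[1, 0] * u[0] + w[1, 1] * u[1] + w[1, 2] * u[2])
            * (w[2, 0] * u[0] + w[2, 1] * u[1] + w[2, 2] * u[2])
        )
        f = quad + cubic
        inside = rho <= 1.5
        f = f - f[inside].mean()
        peak = np.abs(f[inside]).max()
        if peak > 0:
            f = f / peak
        mask = rho <= 1.0 + irregularity * f
    return LabeledVolume(mask, spacing)


# ---------------------------------------------------------------------------
# matrix-level sampling (the planted statistical structure)
# ---------------------------------------------------------------------------

@dataclass
class SampledMatrices:
    """Matrix-level draw from a population spec.

    ``truths`` are in the population reference gauge (consistent homolog
    roles across nuclei); ``matrices`` are the same nuclei after random
    per-chromosome homolog-label flips — the arbitrary volume-based
    labeling the chromatic median has to undo.  ``flips`` records the
    applied scramble, one row of 7 bits per nucleus.
    """

    matrices: List[InteractionMatrix]
    truths: List[InteractionMatrix]
    flips: np.ndarray
    spec: PopulationSpec


def _draw_nucleus_edges(spec: PopulationSpec, rng: np.random.Generator):
    """Draw one nucleus's planted edges in the reference gauge.

    Returns (edges, kinds): edges as HomologID pairs, kinds as a parallel
    list with 'overlap' or 'abut' per edge.
    """
    mults = sorted(spec.multiplicity_weights)
    weights = np.array([spec.multiplicity_weights[m] for m in mults], dtype=float)
    weights = weights / weights.sum()
    edges, kinds = [], []
    for ci, cj in chromosome_pairs(spec.chromosomes):
        if rng.random() < spec.pair_probabilities[(ci, cj)]:
            m = int(rng.choice(mults, p=weights))
            for ti, tj in CANONICAL_SLOTS[:m]:
                edges.append((HomologID(ci, ti), HomologID(cj, tj)))
                kinds.append("overlap" if rng.random() < spec.overlap_fraction else "abut")
    for c in spec.chromosomes:
        if rng.random() < spec.homolog_probability:
            edges.append((HomologID(c, "a"), HomologID(c, "b")))
            kinds.append("overlap" if rng.random() < spec.overlap_fraction else "abut")
    return edges, kinds


def _flip_edges(edges, flips: Mapping[int, int]):
    out = []
    for u, v in edges:
        fu = HomologID(u.chromosome, "ab"[1 - "ab".index(u.tag)] if flips.get(u.chromosome) else u.tag)
        fv = HomologID(v.chromosome, "ab"[1 - "ab".index(v.tag)] if flips.get(v.chromosome) else v.tag)
        out.append((fu, fv))
    return out


def sample_interaction_matrices(spec: PopulationSpec, seed: Optional[int] = None) -> SampledMatrices:
    """Draw a population of interaction matrices without rendering images.

    This is the statistical core of the generator — the image pipeline
    draws its ground truth the same way and then realizes it geometrically.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    g = len(spec.chromosomes)
    truths, matrices, all_flips = [], [], []
    for _ in range(spec.n_nuclei):
        edges, _ = _draw_nucleus_edges(spec, rng)
        truth = InteractionMatrix.from_edges(edges, spec.chromosomes)
        bits = rng.integers(0, 2, size=g)
        flip_map = {c: int(b) for c, b in zip(spec.chromosomes, bits)}
        scrambled = InteractionMatrix.from_edges(_flip_edges(edges, flip_map), spec.chromosomes)
        truths.append(truth)
        matrices.append(scrambled)
        all_flips.append(bits)
    return SampledMatrices(matrices, truths, np.array(all_flips), spec)


# ---------------------------------------------------------------------------
# geometric realization
# ---------------------------------------------------------------------------

def _target_volumes(spec: PopulationSpec, nucleus_voxels: int, rng: np.random.Generator):
    """Exact per-homolog voxel targets; tag 'a' strictly larger than 'b'."""
    out: Dict[HomologID, int] = {}
    for c in spec.chromosomes:
        total = max(8, int(round(spec.volume_fractions[c] * nucleus_voxels)))
        asym = 0.04 * (1.0 + 0.5 * rng.random())  # a is 4–6 % larger than b
        va = int(round(total * (0.5 + asym / 2)))
        vb = total - va
        if va <= vb:
            va, vb = vb + 1, va - 1
        out[HomologID(c, "a")] = va
        out[HomologID(c, "b")] = max(4, vb)
    return out


def _growth_order(nodes, adjacency, volumes, rng: Optional[np.random.Generator] = None):
    """Planted-graph components first (BFS from the highest-degree node).

    With ``rng``, ordering keys get a small random perturbation so that
    packing retries explore different growth sequences.
    """
    if rng is None:
        jitter = {v: 0.0 for v in nodes}
    else:
        jitter = {v: 0.15 * float(rng.random()) for v in nodes}

    def vol(v):
        return volumes[v] * (1.0 + jitter[v])

    seen = set()
    order: List[HomologID] = []
    comp_nodes = [v for v in nodes if adjacency[v]]
    for start in sorted(comp_nodes, key=lambda v: (-len(adjacency[v]), -vol(v))):
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        while queue:
            v = queue.pop(0)
            order.append(v)
            for u, _ in sorted(adjacency[v], key=lambda e: -vol(e[0])):
                if u not in seen:
                    seen.add(u)
                    queue.append(u)
    isolated = sorted((v for v in nodes if v not in seen), key=lambda v: -vol(v))
    return order + list(isolated)


def _ball_footprint(radius_um: float, spacing: VoxelSpacing) -> np.ndarray:
    """Anisotropic voxel ball of physical radius ``radius_um``."""
    nz = int(radius_um / spacing.dz)
    ny = int(radius_um / spacing.dy)
    nx = int(radius_um / spacing.dx)
    zz, yy, xx = np.meshgrid(
        np.arange(-nz, nz + 1) * spacing.dz,
        np.arange(-ny, ny + 1) * spacing.dy,
        np.arange(-nx, nx + 1) * spacing.dx,
        indexing="ij",
    )
    # tiny slack so a radius that is an exact multiple of the pitch
    # includes its boundary voxels despite binary rounding
    return zz**2 + yy**2 + xx**2 <= radius_um**2 + 1e-9


def _dilate(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Dilation restricted to the mask's bounding box (plus the footprint)."""
    idx = np.argwhere(mask)
    pad = [s // 2 for s in footprint.shape]
    lo = np.maximum(idx.min(0) - pad, 0)
    hi = np.minimum(idx.max(0) + pad + 1, mask.shape)
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    out = np.zeros_like(mask)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = ndimage.binary_dilation(
        sub, structure=footprint
    )
    return out


class _GrownCT:
    """A placed territory with the derived masks the packer needs.

    ``excl``: keep-out zone for non-partner territories (border distance ≤
    0.30 µm); ``near``: within the 0.28 µm calling threshold; ``band``:
    thin abutment-seeding ring; ``core``: interior deeper than the overlap
    shell, kept out of partners so overlap stays a border phenomenon.
    The full distance field is computed lazily (only needed to steer
    multi-partner connection tendrils).
    """

    __slots__ = ("mask", "spacing", "centroid", "excl", "near", "band", "core", "_edt")

    _fp_cache: dict = {}

    def __init__(self, mask: np.ndarray, spacing: VoxelSpacing):
        self.mask = mask
        self.spacing = spacing
        self.centroid = np.argwhere(mask).mean(0) * np.asarray(spacing.sampling)
        fps = self._footprints(spacing)
        self.excl = _dilate(mask, fps["excl"])
        self.near = _dilate(mask, fps["near"])
        self.band = _dilate(mask, fps["band"]) & ~mask
        eroded = ndimage.binary_erosion(mask, structure=fps["shell"], border_value=1)
        self.core = mask & eroded
        self._edt = None

    @classmethod
    def _footprints(cls, spacing: VoxelSpacing) -> dict:
        key = spacing.sampling
        if key not in cls._fp_cache:
            cls._fp_cache[key] = {
                "excl": _ball_footprint(EXCLUSION_RADIUS_UM, spacing),
                "near": _ball_footprint(0.28, spacing),
                "band": _ball_footprint(CONTACT_SEED_BAND_UM, spacing),
                "shell": _ball_footprint(OVERLAP_SHELL_UM, spacing),
            }
        return cls._fp_cache[key]

    @property
    def edt(self) -> np.ndarray:
        if self._edt is None:
            self._edt = ndimage.distance_transform_edt(
                ~self.mask, sampling=self.spacing.sampling
            ).astype(np.float32)
        return self._edt


def _pick_seed(cand: np.ndarray, rng: np.random.Generator):
    idx = np.flatnonzero(cand.ravel())
    if idx.size == 0:
        return None
    flat = int(rng.choice(idx))
    return np.unravel_index(flat, cand.shape)


def _target_rho(rank_frac: float, exponent: float, rng: np.random.Generator) -> float:
    """Preferred normalized anchor radius, stratified by chromosome size rank.

    Targets run from centre-leaning (smallest chromosome) to peripheral
    (largest), spread scaled by the radial-preference exponent; exponent 0
    removes the size dependence.  Growth against the nuclear border pulls
    large-territory centroids inward, so the anchor spread is deliberately
    wider than the radial spread the rendered centroids end up showing.
    """
    spread = 0.25 * max(0.0, exponent)
    rho = 0.65 + 2.0 * spread * (rank_frac - 0.5) + rng.uniform(-0.08, 0.08)
    return float(np.clip(rho, 0.05, 0.88))


def _layout_anchors(
    nodes,
    adjacency,
    volumes,
    semi_axes,
    voxel_volume: float,
    rank_frac,
    exponent: float,
    rng: np.random.Generator,
    n_iter: int = 120,
):
    """Force-layout anchor positions (µm offsets from the nucleus centre).

    Planted partners are pulled into contact range, non-partners pushed
    apart, and every territory feels a weak spring towards its
    size-dependent preferred radius; positions stay inside the nucleus
    ellipsoid.  Anchors only *seed* the stochastic growth — they make
    multi-partner contact sets co-locatable, not deterministic.
    """
    semi = np.array([semi_axes[2], semi_axes[1], semi_axes[0]])  # (z, y, x)
    radius = {
        v: (3.0 * volumes[v] * voxel_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        for v in nodes
    }
    rho_target = {}
    pos = {}
    for v in nodes:
        rho_target[v] = _target_rho(rank_frac[v.chromosome], exponent, rng)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        pos[v] = rho_target[v] * semi * u
    pairs = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
    adj = {frozenset((u, v)) for u in adjacency for v, _ in adjacency[u]}
    for it in range(n_iter):
        step = 0.25 * (1.0 - it / n_iter) + 0.05
        for u, v in pairs:
            delta = pos[u] - pos[v]
            d = float(np.linalg.norm(delta)) or 1e-6
            unit = delta / d
            if frozenset((u, v)) in adj:
                d0 = 0.75 * (radius[u] + radius[v])
                if d > d0:
                    shift = step * min(d - d0, 1.0) * 0.5 * unit
                    pos[u] = pos[u] - shift
                    pos[v] = pos[v] + shift
            else:
                d0 = 0.8 * (radius[u] + radius[v])
                if d < d0:
                    shift = step * (d0 - d) * 0.5 * unit
                    pos[u] = pos[u] + shift
                    pos[v] = pos[v] - shift
        for v in nodes:
            rho = float(np.linalg.norm(pos[v] / semi)) or 1e-6
            pos[v] = pos[v] * (1.0 + 0.5 * step * (rho_target[v] - rho) / rho)
            rho = float(np.linalg.norm(pos[v] / semi))
            if rho > 0.9:
                pos[v] = pos[v] * (0.9 / rho)
    return pos


def _grow_territories(
    spec: PopulationSpec,
    nucleus: LabeledVolume,
    edges,
    kinds,
    volumes: Mapping[HomologID, int],
    rng: np.random.Generator,
    relax: bool = False,
    semi_axes: Optional[Tuple[float, float, float]] = None,
    grow_first: Sequence[HomologID] = (),
):
    """Place and grow all homolog territories, honouring planted contacts.

    With ``relax`` (used on late packing retries of crowded draws) every
    planted contact is realized as overlap and partners open their whole
    interior to the growing territory, so a contact never needs an
    outside corridor; the ground-truth matrix is unaffected.
    """
    spacing = nucleus.spacing
    nuc_mask = nucleus.mask
    semi_axes = spec.semi_axes if semi_axes is None else semi_axes
    nodes = [HomologID(c, t) for c in spec.chromosomes for t in ("a", "b")]
    adjacency: Dict[HomologID, list] = {v: [] for v in nodes}
    for (u, v), kind in zip(edges, kinds):
        kind = "overlap" if relax else kind
        adjacency[u].append((v, kind))
        adjacency[v].append((u, kind))
    ranks = {c: r for r, c in enumerate(sorted(spec.chromosomes, key=lambda c: volumes[HomologID(c, "a")]))}
    nrank = max(1, len(spec.chromosomes) - 1)
    rank_frac = {c: ranks[c] / nrank for c in spec.chromosomes}
    anchors = _layout_anchors(
        nodes, adjacency, volumes, semi_axes, spacing.voxel_volume,
        rank_frac, spec.radial_exponent, rng,
    )
    pitch = np.asarray(spacing.sampling)
    center = (np.asarray(nuc_mask.shape) - 1) / 2.0
    coords = np.meshgrid(
        (np.arange(nuc_mask.shape[0]) - center[0]) * pitch[0],
        (np.arange(nuc_mask.shape[1]) - center[1]) * pitch[1],
        (np.arange(nuc_mask.shape[2]) - center[2]) * pitch[2],
        indexing="ij",
        sparse=True,
    )

    center_um = center * pitch

    def _contact_seed(cand: np.ndarray, others_abs):
        """Seed inside a contact band, drawn towards remaining partners."""
        if not cand.any():
            return None
        if not others_abs:
            return _pick_seed(cand, rng)
        score = np.zeros(cand.shape, dtype=np.float32)
        for c in others_abs:
            rel = c - center_um
            score += sum((g - a) ** 2 for g, a in zip(coords, rel)).astype(np.float32)
        score += rng.random(cand.shape).astype(np.float32)
        score[~cand] = np.inf
        return np.unravel_index(int(score.argmin()), cand.shape)

    def _anchor_seed(allowed: np.ndarray, anchor: np.ndarray, spread: float = 0.3):
        """Allowed voxel nearest the anchor, with placement jitter.

        ``spread`` (µm²) grows across retries so repeated attempts can
        escape a too-small pocket of allowed space near the anchor.
        """
        if not allowed.any():
            return None
        d2 = sum((g - a) ** 2 for g, a in zip(coords, anchor))
        score = d2 + spread * rng.random(allowed.shape)
        score[~allowed] = np.inf
        return np.unravel_index(int(score.argmin()), allowed.shape)

    grown: Dict[HomologID, _GrownCT] = {}
    order = _growth_order(nodes, adjacency, volumes, rng)
    # territories that failed on a previous packing attempt are grown first,
    # while the nucleus is still empty, and their partners come to them
    order = [v for v in grow_first if v in order] + [v for v in order if v not in grow_first]
    for v in order:
        partners = {u: kind for u, kind in adjacency[v] if u in grown}
        allowed = nuc_mask.copy()
        for u, g in grown.items():
            if u in partners:
                if partners[u] != "overlap":
                    allowed &= ~g.mask
                elif not relax:
                    allowed &= ~g.core
            else:
                allowed &= ~g.excl
        # seeds only in connected pockets that can hold the target volume
        # and from which every grown partner is reachable within threshold
        labels, _ = ndimage.label(allowed, structure=STRUCT_6)
        sizes = np.bincount(labels.ravel())
        big = sizes >= volumes[v]
        big[0] = False
        okset = set(np.flatnonzero(big))
        for u in partners:
            okset &= set(np.unique(labels[allowed & grown[u].near])) - {0}
        if partners and not okset:
            raise _PlacementError(
                v, f"no allowed component can reach all partners of {v}"
            )
        seedable = np.isin(labels, sorted(okset)) if partners else big[labels]

        mask = None
        for attempt in range(8):
            seed = None
            if partners:
                plist = sorted(
                    partners,
                    key=lambda u: sum(
                        float(np.linalg.norm(grown[u].centroid - grown[w].centroid))
                        for w in partners if w is not u
                    ),
                )
                # rotate the primary partner across attempts
                plist = plist[attempt % len(plist):] + plist[:attempt % len(plist)]
                for u in plist:
                    g = grown[u]
                    # preferred seeding realizes the drawn contact kind, but a
                    # crowded partner may leave no overlap seed: fall back to
                    # ever wider abutment bands (the edge stays a valid
                    # interaction as long as the border distance is <= 0.28 µm)
                    cands = []
                    if partners[u] == "overlap":
                        cands.append(seedable & g.mask)
                    cands.append(seedable & g.band)
                    cands.append(seedable & g.near & ~g.mask)
                    others = [grown[w].centroid for w in partners if w is not u]
                    for cand in cands:
                        seed = _contact_seed(cand, others)
                        if seed is not None:
                            break
                    if seed is not None:
                        primary = u
                        break
            if seed is None:
                seed = _anchor_seed(seedable, anchors[v], spread=0.3 * 4.0**attempt)
                primary = None
            if seed is None:
                break

            pending = [u for u in partners if u is not primary]
            connect = [
                (grown[u].edt, 0.0 if partners[u] == "overlap" else CONTACT_SEED_BAND_UM)
                for u in pending
            ]
            n_ov = max(1, int(round(OVERLAP_FILL_FRACTION * volumes[v])))
            fill = [
                (grown[u].mask, n_ov)
                for u in partners
                if partners[u] == "overlap" and (u is primary or u in pending)
            ]
            try:
                mask = grow_region(
                    allowed, seed, volumes[v], spacing, rng,
                    persistence=spec.persistence, compactness=spec.compactness,
                    connect=connect or None, fill=fill or None,
                )
            except InfeasiblePackingError:
                mask = None
                continue
            # a planted contact counts as realized once the border distance is
            # within the calling threshold (overlap gives distance 0)
            ok = all(bool((mask & grown[u].near).any()) for u in partners)
            if ok:
                break
            mask = None
        if mask is None:
            raise _PlacementError(v, f"could not place territory {v}")
        grown[v] = _GrownCT(mask, spacing)

    return {v: LabeledVolume(g.mask, spacing) for v, g in grown.items()}


def plant_and_grow_population(spec: PopulationSpec) -> List[NucleusRecord]:
    """Generate a seeded population of nuclei realizing the planted networks.

    Fully reproducible from ``spec.seed``.  Raises
    :class:`~ctnet.growth.InfeasiblePackingError` naming the nucleus when a
    planted configuration cannot be packed (volume fractions too high for
    the requested contacts).
    """
    master = np.random.SeedSequence(spec.seed)
    records: List[NucleusRecord] = []
    for i, child in enumerate(master.spawn(spec.n_nuclei)):
        rng = np.random.default_rng(child)
        edges_ref, kinds = _draw_nucleus_edges(spec, rng)
        bits = rng.integers(0, 2, size=len(spec.chromosomes))
        flip_map = {c: int(b) for c, b in zip(spec.chromosomes, bits)}
        edges = _flip_edges(edges_ref, flip_map)  # volume-gauge (observable) edges
        truth = InteractionMatrix.from_edges(edges, spec.chromosomes)

        record = None
        last_err: Optional[Exception] = None
        grow_first: List[HomologID] = []
        for attempt in range(20):
            sub = np.random.default_rng(child.spawn(1)[0]) if attempt else rng
            # natural cell-to-cell nuclear volume variability
            scale = 1.0 + spec.size_cv * float(np.clip(sub.standard_normal(), -2, 2))
            semi = tuple(a * scale ** (1.0 / 3.0) for a in spec.semi_axes)
            nucleus = generate_nucleus_mask(
                semi, spec.irregularity, spec.spacing,
                seed=int(sub.integers(2**31)),
            )
            volumes = _target_volumes(spec, nucleus.volume_voxels(), sub)
            try:
                terr = _grow_territories(
                    spec, nucleus, edges, kinds, volumes, sub,
                    relax=attempt >= 12, semi_axes=semi,
                    grow_first=grow_first,
                )
            except InfeasiblePackingError as err:
                last_err = err
                if isinstance(err, _PlacementError) and err.node not in grow_first:
                    grow_first.insert(0, err.node)
                continue
            record = NucleusRecord(
                nucleus=nucleus,
                territories=terr,
                condition=spec.condition,
                truth=truth,
                meta={
                    "nucleus_id": i,
                    "seed": spec.seed,
                    "scramble_flips": bits.tolist(),
                    "attempt": attempt,
                },
            )
            break
        if record is None:
            raise InfeasiblePackingError(
                f"nucleus {i} of condition '{spec.condition}': {last_err}"
            )
        records.append(record)
    return records
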