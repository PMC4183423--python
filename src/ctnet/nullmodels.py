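"""Null baselines: random territory placement and input-matrix randomization.

The placement null re-grows each nucleus's territories at their exact
experimental voxel volumes from uniformly sampled in-nucleus seeds, with
growth blocked at the nuclear border but territory–territory overlap
permitted — interactions in this null arise from crowding alone, so a
planted population should show more partners per chromosome than its
random twin.

The matrix null reshuffles each nucleus's edges uniformly over the 91
informative matrix positions, preserving the per-nucleus edge count; it
isolates interaction *pattern* from interaction *density* when
calibrating consensus-network thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .core import LabeledVolume, NucleusRecord
from .growth import grow_region
from .interactions import InteractionMatrix


@dataclass
class NullConfig:
    """Configuration of the random-placement simulator."""

    source: Sequence[NucleusRecord]
    n_replicates: int = 1
    seed: int = 0
    persistence: float = 0.3
    compactness: float = 0.5

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_random_population(cfg: NullConfig) -> List[NucleusRecord]:
    """Random-placement twins of a source population.

    For every source nucleus (repeated ``n_replicates`` times) each
    territory is re-grown to its exact source voxel volume from a uniform
    random seed inside the nucleus mask.  Raises ``ValueError`` when a
    territory volume exceeds the nucleus volume.
    """
    master = np.random.SeedSequence(cfg.seed)
    out: List[NucleusRecord] = []
    for rep in range(cfg.n_replicates):
        for i, rec in enumerate(cfg.source):
            rng = np.random.default_rng(master.spawn(1)[0])
            nuc_mask = rec.nucleus.mask
            nuc_vox = int(nuc_mask.sum())
            terr = {}
            for hid in sorted(rec.territories):
                target = rec.territories[hid].volume_voxels()
                if target > nuc_vox:
                    raise ValueError(
                        f"territory {hid} volume {target} exceeds nucleus volume {nuc_vox}"
                    )
                seed_vox = _uniform_seed(nuc_mask, rng)
                mask = grow_region(
                    nuc_mask, seed_vox, target, rec.spacing, rng,
                    persistence=cfg.persistence, compactness=cfg.compactness,
                )
                terr[hid] = LabeledVolume(mask, rec.spacing)
            out.append(
                NucleusRecord(
                    nucleus=rec.nucleus,
                    territories=terr,
                    condition=rec.condition,
                    truth=None,
                    meta={**rec.meta, "null": True, "replicate": rep, "source_index": i},
                )
            )
    return out


def _uniform_seed(mask: np.ndarray, rng: np.random.Generator):
    idx = np.flatnonzero(mask.ravel())
    return np.unravel_index(int(rng.choice(idx)), mask.shape)


def randomize_matrix(m: InteractionMatrix, seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None) -> InteractionMatrix:
    """Uniform edge reshuffle over the informative matrix positions.

    The nucleus's edge count is preserved; the destination slots are drawn
    uniformly without replacement from the 91 upper-triangle positions.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(m.index)
    iu, ju = np.triu_indices(n, k=1)
    k = m.n_edges()
    chosen = rng.choice(iu.size, size=k, replace=False) if k else np.array([], dtype=int)
    data = np.zeros_like(m.data)
    data[iu[chosen], ju[chosen]] = True
    data |= data.T
    return InteractionMatrix(data, m.chromosomes)


def randomize_population(matrices: Sequence[InteractionMatrix],
                         seed: Optional[int] = None) -> List[InteractionMatrix]:
    """Randomize every matrix of a population with one seeded stream."""
    rng = np.random.default_rng(seed)
    return [randomize_matrix(m, rng=rng) for m in matrices]
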