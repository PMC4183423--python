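"""Chromatic-median consensus of homolog-level interaction matrices.

The homolog labels 'a'/'b' assigned per nucleus (by territory volume) are
arbitrary with respect to the population's interaction structure.  The
chromatic-median problem chooses, for every nucleus, a per-chromosome
label flip (2⁷ = 128 possibilities for a 7-chromosome panel) and a single
binary *median* matrix minimizing the total Hamming disagreement between
the flipped nuclei and the median over the 91 informative matrix
positions.  From the aligned nuclei a percent matrix (percent of nuclei
showing each homolog-pair interaction) is computed, thresholded above the
randomization controls, and turned into a tiered consensus network.

:class:`ChromaticMedian` is the model object; :meth:`ChromaticMedian.fit`
runs alternating optimization — exhaustive per-nucleus best-response over
all flip vectors against the current median, then an entry-wise majority
update — with multi-restart, and returns a
:class:`ChromaticMedianResults`.  :func:`brute_force_median` solves tiny
instances by joint enumeration and serves as the optimality oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import HomologID
from .interactions import InteractionMatrix

EdgeKey = frozenset  # frozenset of two HomologIDs


# ---------------------------------------------------------------------------
# flips
# ---------------------------------------------------------------------------

def flip_permutation(bits: Sequence[int]) -> np.ndarray:
    """Row/column permutation that swaps homolog indices of flipped chromosomes."""
    g = len(bits)
    perm = np.arange(2 * g)
    for j, b in enumerate(bits):
        if b:
            perm[2 * j], perm[2 * j + 1] = perm[2 * j + 1], perm[2 * j]
    return perm


def all_flip_permutations(g: int) -> np.ndarray:
    """All 2^g flip permutations; row k encodes bits of k (bit j = chromosome j)."""
    perms = np.empty((2**g, 2 * g), dtype=np.intp)
    for k in range(2**g):
        bits = [(k >> j) & 1 for j in range(g)]
        perms[k] = flip_permutation(bits)
    return perms


def apply_flips(m: InteractionMatrix, bits: Sequence[int]) -> InteractionMatrix:
    """Swap the a/b labels of flipped chromosomes (rows and columns at once).

    An involution: applying the same flips twice restores the matrix.
    """
    if len(bits) != len(m.chromosomes):
        raise ValueError("one flip bit per chromosome is required")
    p = flip_permutation(bits)
    return InteractionMatrix(m.data[np.ix_(p, p)], m.chromosomes)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ChromaticMedian:
    """Chromatic-median model over a population of interaction matrices."""

    def __init__(self, matrices: Sequence[InteractionMatrix]):
        if not matrices:
            raise ValueError("at least one interaction matrix is required")
        self.chromosomes = matrices[0].chromosomes
        for m in matrices:
            if m.chromosomes != self.chromosomes:
                raise ValueError("all matrices must share one chromosome panel")
        self.matrices = list(matrices)
        g = len(self.chromosomes)
        self._g = g
        self._iu, self._ju = np.triu_indices(2 * g, k=1)
        self._perms = all_flip_permutations(g)
        stack = np.stack([m.data for m in self.matrices]).astype(np.uint8)
        rows = self._perms[:, self._iu]  # (K, E)
        cols = self._perms[:, self._ju]
        # variants[i, k, e]: entry e of nucleus i under flip vector k
        self._variants = stack[:, rows, cols]
        # entry_perm[k, e]: upper-triangle position that entry e draws from
        # under flip k (flip permutations compose by XOR of their indices)
        pos = np.zeros((2 * g, 2 * g), dtype=np.intp)
        pos[self._iu, self._ju] = np.arange(self._iu.size)
        pos[self._ju, self._iu] = np.arange(self._iu.size)
        self._entry_perm = pos[rows, cols]

    @property
    def nobs(self) -> int:
        return len(self.matrices)

    def fit(
        self,
        restarts: int = 50,
        seed: Optional[int] = None,
        max_iter: int = 200,
    ) -> "ChromaticMedianResults":
        """Alternating optimization with multi-restart.

        The first restart initializes all nuclei at identity flips and the
        second from a sequential greedy build; the remainder alternate
        between fresh seeded random flip vectors and kicks — partial
        re-randomizations of the best assignment found so far (iterated
        local search).  Within a run the objective is non-increasing; the
        best run is kept.
        """
        rng = np.random.default_rng(seed)
        n, K, E = self._variants.shape
        best = None
        for r in range(max(1, restarts)):
            if r == 0:
                k = np.zeros(n, dtype=np.intp)
            elif r == 1:
                k = self._greedy_init()
            elif r == 2:
                k = self._progressive_init(np.arange(n))
            elif r == 3:
                k = self._spectral_init()
            elif r % 8 == 5:
                k = self._spectral_init(rng.integers(0, K, size=n))
            elif r % 4 == 3:
                k = self._progressive_init(rng.permutation(n))
            elif r % 2 == 0:
                k = rng.integers(0, K, size=n)
            else:  # kick the incumbent: re-randomize a third of the nuclei
                k = best[1].copy()
                kick = rng.choice(n, size=max(1, n // 3), replace=False)
                k[kick] = rng.integers(0, K, size=kick.size)
            obj, k, median, iters = self._run(k, max_iter, rng)
            if best is None or obj < best[0]:
                best = (obj, k.copy(), median.copy(), iters)
        obj, k, median, iters = best
        aligned = self._variants[np.arange(n), k]  # (n, E)
        percent = 100.0 * aligned.mean(axis=0)
        flips = ((k[:, None] >> np.arange(self._g)[None, :]) & 1).astype(bool)
        return ChromaticMedianResults(
            model=self,
            objective=int(obj),
            flips=flips,
            median_triu=median.astype(bool),
            percent_triu=percent,
            aligned_triu=aligned.astype(bool),
            n_iter=iters,
            restarts=restarts,
        )

    def _progressive_init(self, order: np.ndarray) -> np.ndarray:
        """Divide-and-conquer consensus: align halves recursively, then
        merge by the global flip minimizing the joint majority objective.

        Pairs of nuclei sharing true edges align coherently with high
        probability and the majority amplifies that signal upward — this
        reaches coherent gauges that single-nucleus moves cannot assemble.
        """
        V = self._variants
        EP = self._entry_perm  # (K, E)
        K = V.shape[1]

        def solve(ids):
            if len(ids) == 1:
                i = ids[0]
                return {i: 0}, V[i, 0].astype(np.int32)
            half = len(ids) // 2
            kl, cl = solve(ids[:half])
            kr, cr = solve(ids[half:])
            cr_g = cr[EP]  # (K, E): right-half counts under each global flip
            tot = cl[None, :] + cr_g
            n = len(ids)
            obj = np.minimum(tot, n - tot).sum(axis=1)
            g = int(obj.argmin())
            merged = {**kl, **{i: k ^ g for i, k in kr.items()}}
            counts = cl + cr_g[g]
            # refine the merged subset with a few best-response rounds
            sub = np.array(ids)
            k = np.array([merged[i] for i in ids], dtype=np.intp)
            for _ in range(3):
                median = (2 * counts > n).astype(np.uint8)
                knew = (V[sub] != median[None, None, :]).sum(axis=2).argmin(axis=1)
                if np.array_equal(knew, k):
                    break
                k = knew
                counts = V[sub, k].astype(np.int32).sum(axis=0)
            return dict(zip(ids, (int(v) for v in k))), counts

        kmap, _ = solve(list(order))
        return np.array([kmap[i] for i in range(V.shape[0])], dtype=np.intp)

    def _spectral_init(self, k: Optional[np.ndarray] = None, passes: int = 3) -> np.ndarray:
        """Per-chromosome spectral 2-coloring of the nuclei.

        With all other chromosomes' flips held fixed, the choice of one
        chromosome's flip per nucleus is a signed-agreement partition
        problem; the sign of the leading eigenvector of the pairwise
        agreement-difference Gram matrix assigns coherent flips.  Cycling
        through chromosomes a few times yields a gauge that accumulates
        weak pairwise signal globally — single-nucleus moves cannot.
        """
        V = self._variants
        n, K, E = V.shape
        idx = np.arange(n)
        if k is None:
            k = np.zeros(n, dtype=np.intp)
        else:
            k = k.copy()
        index = self.matrices[0].index
        for _ in range(passes):
            for j in range(self._g):
                bit = 1 << j
                touches = np.array(
                    [index[i].chromosome == self.chromosomes[j]
                     or index[jj].chromosome == self.chromosomes[j]
                     for i, jj in zip(self._iu, self._ju)]
                )
                V0 = V[idx, k][:, touches].astype(np.float64)
                V1 = V[idx, k ^ bit][:, touches].astype(np.float64)
                D = V0 - V1
                gram = D @ D.T
                if not gram.any():
                    continue
                w, vecs = np.linalg.eigh(gram)
                lead = vecs[:, -1]
                flips = lead < 0
                k = np.where(flips, k ^ bit, k)
        return k

    def _greedy_init(self) -> np.ndarray:
        """Sequential build: align each nucleus to the running vote of its
        predecessors (the first nucleus keeps identity flips)."""
        V = self._variants
        n = V.shape[0]
        k = np.zeros(n, dtype=np.intp)
        counts = V[0, 0].astype(np.int32).copy()
        for i in range(1, n):
            median = (2 * counts > i).astype(np.uint8)
            k[i] = int((V[i] != median[None, :]).sum(axis=1).argmin())
            counts += V[i, k[i]]
        return k

    def _run(self, k: np.ndarray, max_iter: int, rng: np.random.Generator):
        """Alternating optimization to a fixed point.

        Batch (Jacobi) rounds — exhaustive per-nucleus best response
        against the current median, then an entry-wise majority update —
        interleaved with sequential plateau sweeps that update the
        majority after every single-nucleus move and break best-response
        ties at random (equal-objective moves traverse the plateaus that
        separate local optima).  Every move is non-increasing in the
        objective.
        """
        V = self._variants
        n = V.shape[0]
        k = k.copy()
        idx = np.arange(n)
        it = 0
        obj = None
        while it < max_iter:
            # batch phase
            median = self._majority(V[idx, k])
            prev = None
            while it < max_iter:
                it += 1
                d = (V != median[None, None, :]).sum(axis=2)  # (n, K)
                k = d.argmin(axis=1)
                o = int(d[idx, k].sum())
                median_new = self._majority(V[idx, k])
                if prev is not None and o >= prev and np.array_equal(median_new, median):
                    break
                median, prev = median_new, o
            # sequential plateau sweeps
            counts = V[idx, k].astype(np.int32).sum(axis=0)
            median = self._majority_from_counts(counts, n)
            improved = False
            for _ in range(3):
                for i in range(n):
                    d = (V[i] != median[None, :]).sum(axis=1)
                    ties = np.flatnonzero(d == d.min())
                    ki = int(ties[0]) if ties.size == 1 else int(rng.choice(ties))
                    if d[ki] <= d[k[i]] and ki != k[i]:
                        if d[ki] < d[k[i]]:
                            improved = True
                        counts += V[i, ki].astype(np.int32) - V[i, k[i]]
                        k[i] = ki
                        median = self._majority_from_counts(counts, n)
            new_obj = int((V[idx, k] != median[None, :]).sum())
            if obj is not None and new_obj >= obj and not improved:
                obj = min(obj, new_obj)
                break
            obj = new_obj
        return obj, k, median, it

    @staticmethod
    def _majority(aligned: np.ndarray) -> np.ndarray:
        """Entry-wise majority; exact ties resolve to 0 (conservative)."""
        n = aligned.shape[0]
        return (2 * aligned.sum(axis=0) > n).astype(np.uint8)

    @staticmethod
    def _majority_from_counts(counts: np.ndarray, n: int) -> np.ndarray:
        return (2 * counts > n).astype(np.uint8)

    # convenient labels for the informative positions
    def triu_labels(self) -> List[Tuple[HomologID, HomologID]]:
        index = self.matrices[0].index
        return [(index[i], index[j]) for i, j in zip(self._iu, self._ju)]


@dataclass
class NetworkEdge:
    u: HomologID
    v: HomologID
    percent: float
    tier: str

    @property
    def key(self) -> EdgeKey:
        return frozenset((self.u, self.v))


@dataclass
class Network:
    """Thresholded, tiered consensus network."""

    edges: List[NetworkEdge]
    threshold: float

    @property
    def edge_set(self) -> Set[EdgeKey]:
        return {e.key for e in self.edges}

    def chromosome_pairs(self) -> Set[Tuple[int, int]]:
        """Edges projected to unordered chromosome pairs (gauge-invariant)."""
        out = set()
        for e in self.edges:
            ci, cj = sorted((e.u.chromosome, e.v.chromosome))
            out.add((ci, cj))
        return out

    def __len__(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        gr = nx.Graph()
        for e in self.edges:
            gr.add_edge(str(e.u), str(e.v), percent=e.percent, tier=e.tier)
        return gr


@dataclass
class ChromaticMedianResults:
    """Fitted chromatic median: flips, objective, percent matrix, network."""

    model: ChromaticMedian
    objective: int
    flips: np.ndarray          # (n, g) bool, per-nucleus converged flips
    median_triu: np.ndarray    # (91,) bool binary median
    percent_triu: np.ndarray   # (91,) percent of aligned nuclei with the edge
    aligned_triu: np.ndarray   # (n, 91) aligned nuclei
    n_iter: int
    restarts: int

    # -- views ----------------------------------------------------------------
    @property
    def percent_series(self) -> pd.Series:
        labels = self.model.triu_labels()
        idx = pd.MultiIndex.from_tuples(
            [(str(u), str(v)) for u, v in labels], names=["homolog_i", "homolog_j"]
        )
        return pd.Series(np.round(self.percent_triu, 1), index=idx, name="percent")

    @property
    def percent_matrix(self) -> pd.DataFrame:
        index = [str(h) for h in self.model.matrices[0].index]
        n = len(index)
        full = np.zeros((n, n))
        iu, ju = self.model._iu, self.model._ju
        full[iu, ju] = self.percent_triu
        full[ju, iu] = self.percent_triu
        return pd.DataFrame(np.round(full, 1), index=index, columns=index)

    def aligned_matrices(self) -> List[InteractionMatrix]:
        out = []
        for bits, m in zip(self.flips, self.model.matrices):
            out.append(apply_flips(m, bits.astype(int)))
        return out

    # -- network ---------------------------------------------------------------
    def network(self, threshold: float) -> Network:
        return build_network(self.percent_triu, self.model.triu_labels(), threshold)

    def sorenson_per_nucleus(self, network: Network) -> np.ndarray:
        """Sørensen similarity of each aligned nucleus to the network model."""
        labels = self.model.triu_labels()
        model_edges = network.edge_set
        out = []
        for row in self.aligned_triu:
            nucleus_edges = {frozenset(labels[e]) for e in np.flatnonzero(row)}
            out.append(sorenson(nucleus_edges, model_edges))
        return np.array(out)

    def summary(self) -> str:
        n, g = self.flips.shape
        lines = [
            "Chromatic median consensus",
            "=" * 42,
            f"nuclei:              {n}",
            f"chromosomes:         {', '.join(map(str, self.model.chromosomes))}",
            f"objective (Hamming): {self.objective}",
            f"restarts / iters:    {self.restarts} / {self.n_iter}",
            f"flipped labels:      {int(self.flips.sum())} of {n * g}",
            f"percent range:       {self.percent_triu.min():.1f}–{self.percent_triu.max():.1f}",
            "",
            "top homolog-pair interactions (percent of nuclei):",
        ]
        top = self.percent_series.sort_values(ascending=False, kind="stable").head(10)
        lines.append(top.to_string())
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_median(
    matrices: Sequence[InteractionMatrix], max_ct: int = 3, max_n: int = 6
) -> ChromaticMedianResults:
    """Globally optimal chromatic median by joint enumeration of all flips.

    Refuses instances beyond ``max_ct`` chromosomes or ``max_n`` nuclei
    (the search space is (2^g)^n).
    """
    model = ChromaticMedian(matrices)
    g, n = model._g, model.nobs
    if g > max_ct or n > max_n:
        raise ValueError(f"instance too large for enumeration (g={g}, n={n})")
    V = model._variants  # (n, K, E)
    K, E = V.shape[1], V.shape[2]
    sums = V[0].astype(np.int16)  # (K, E) partial sums over nuclei
    for i in range(1, n):
        sums = (sums[:, None, :] + V[i][None, :, :]).reshape(-1, E)
    objective = np.minimum(sums, n - sums).sum(axis=1)
    best = int(objective.argmin())
    obj = int(objective[best])
    # decode the mixed-radix combo index back to per-nucleus flip indices
    ks = []
    rem = best
    for _ in range(n):
        ks.append(rem % K)
        rem //= K
    ks = np.array(ks[::-1], dtype=np.intp)
    idx = np.arange(n)
    aligned = V[idx, ks]
    median = ChromaticMedian._majority(aligned)
    percent = 100.0 * aligned.mean(axis=0)
    flips = ((ks[:, None] >> np.arange(g)[None, :]) & 1).astype(bool)
    return ChromaticMedianResults(
        model=model,
        objective=obj,
        flips=flips,
        median_triu=median.astype(bool),
        percent_triu=percent,
        aligned_triu=aligned.astype(bool),
        n_iter=1,
        restarts=1,
    )


# ---------------------------------------------------------------------------
# threshold, network, comparison
# ---------------------------------------------------------------------------

def _percent_values(x) -> np.ndarray:
    if isinstance(x, ChromaticMedianResults):
        return x.percent_triu
    return np.asarray(x, dtype=float).ravel()


def select_threshold(experimental, controls: Iterable) -> int:
    """Smallest integer percent strictly above every control entry.

    ``controls`` are percent matrices from randomization / random-placement
    baselines.  Warns (does not fail) when the threshold exceeds every
    experimental value, which would yield an empty network.
    """
    controls = list(controls)
    if not controls:
        raise ValueError("at least one control percent matrix is required")
    cmax = max(float(_percent_values(c).max()) for c in controls)
    tau = int(math.floor(cmax)) + 1
    exp = _percent_values(experimental)
    if not (exp >= tau).any():
        warnings.warn(
            f"threshold {tau} exceeds all experimental percent values; network is empty",
            RuntimeWarning,
            stacklevel=2,
        )
    return tau


def build_network(percent_triu, labels, threshold: float) -> Network:
    """Edges at or above the threshold, tiered into top/middle/bottom thirds.

    Edges are sorted by percent (stable); tier boundaries at ⌈n/3⌉ and
    ⌈2n/3⌉ with boundary ties promoted to the higher tier.
    """
    percent_triu = np.asarray(percent_triu, dtype=float)
    keep = np.flatnonzero(percent_triu >= threshold)
    order = keep[np.argsort(-percent_triu[keep], kind="stable")]
    n = order.size
    edges: List[NetworkEdge] = []
    if n:
        b1, b2 = math.ceil(n / 3), math.ceil(2 * n / 3)
        tiers = ["top"] * b1 + ["middle"] * (b2 - b1) + ["bottom"] * (n - b2)
        pct = percent_triu[order]
        for i in range(1, n):
            if pct[i] == pct[i - 1] and tiers[i] != tiers[i - 1]:
                tiers[i] = tiers[i - 1]
        for e, tier in zip(order, tiers):
            u, v = labels[e]
            edges.append(NetworkEdge(u, v, float(percent_triu[e]), tier))
    return Network(edges, float(threshold))


def sorenson(a: Set, b: Set) -> float:
    """Sørensen–Dice similarity 2|A∩B|/(|A|+|B|) of two edge sets."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("Sørensen similarity of two empty sets is undefined")
    return 2.0 * len(a & b) / (len(a) + len(b))


class NetworkComparison(NamedTuple):
    shared: Set
    unique_to_1: Set
    unique_to_2: Set


def compare_networks(net1, net2) -> NetworkComparison:
    """Exact shared / unique edge decomposition of two networks."""
    e1 = net1.edge_set if isinstance(net1, Network) else set(net1)
    e2 = net2.edge_set if isinstance(net2, Network) else set(net2)
    return NetworkComparison(e1 & e2, e1 - e2, e2 - e1)
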