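"""Interaction calling and population-level interaction statistics.

A homolog pair *interacts* when the minimal 3D border-to-border distance
between the two territory masks is at or below the threshold (0.28 µm,
i.e. 4 in-plane pixels at 0.07 µm pitch).  Each nucleus is summarised as
a symmetric 14×14 binary matrix over the homolog copies of the 7-member
panel; its upper triangle holds 91 informative positions (84 heterologous
+ 7 homologous).  Because each chromosome pair has 2×2 homolog slots, a
pair can interact 0–4 times per nucleus, and the 2- and 3-contact
configurations fall into distinct topological patterns (2a/2b/2c/3/4).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .constants import CHROMOSOME_LENGTH_MB, GENE_DENSITY, INTERACTION_THRESHOLD_UM
from .core import CHROMOSOME_PANEL, HomologID


class InteractionMatrix:
    """Symmetric binary homolog-level adjacency for one nucleus.

    Rows/columns are ordered ``(c1, a), (c1, b), (c2, a), ...`` over the
    sorted chromosome panel; the diagonal is ignored.
    """

    def __init__(self, data: np.ndarray | None = None, chromosomes: Sequence[int] = CHROMOSOME_PANEL):
        self.chromosomes = tuple(sorted(chromosomes))
        n = 2 * len(self.chromosomes)
        if data is None:
            data = np.zeros((n, n), dtype=bool)
        data = np.asarray(data, dtype=bool)
        if data.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix for {len(self.chromosomes)} chromosomes")
        if not np.array_equal(data, data.T):
            raise ValueError("interaction matrix must be symmetric")
        self.data = data.copy()
        np.fill_diagonal(self.data, False)
        self.index: Tuple[HomologID, ...] = tuple(
            HomologID(c, t) for c in self.chromosomes for t in ("a", "b")
        )
        self._pos: Dict[HomologID, int] = {h: i for i, h in enumerate(self.index)}

    # -- construction --------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[HomologID, HomologID]],
        chromosomes: Sequence[int] = CHROMOSOME_PANEL,
    ) -> "InteractionMatrix":
        m = cls(chromosomes=chromosomes)
        for u, v in edges:
            m.set_edge(u, v)
        return m

    # -- basic access ---------------------------------------------------------
    def position(self, hid: HomologID) -> int:
        return self._pos[HomologID(*hid)]

    def set_edge(self, u: HomologID, v: HomologID, value: bool = True) -> None:
        i, j = self.position(u), self.position(v)
        if i == j:
            raise ValueError("self-edges are not defined")
        self.data[i, j] = self.data[j, i] = value

    def has_edge(self, u: HomologID, v: HomologID) -> bool:
        return bool(self.data[self.position(u), self.position(v)])

    def edges(self) -> List[Tuple[HomologID, HomologID]]:
        iu, ju = np.triu_indices(len(self.index), k=1)
        return [
            (self.index[i], self.index[j])
            for i, j in zip(iu, ju)
            if self.data[i, j]
        ]

    def n_edges(self) -> int:
        return int(np.triu(self.data, k=1).sum())

    def triu_values(self) -> np.ndarray:
        """The 91 informative upper-triangle entries, row-major."""
        iu, ju = np.triu_indices(len(self.index), k=1)
        return self.data[iu, ju].astype(np.uint8)

    def pair_block(self, ci: int, cj: int) -> np.ndarray:
        """2×2 block for chromosomes ci < cj: rows = copies of ci, cols of cj."""
        if ci == cj:
            raise ValueError("pair_block is defined for heterologous pairs")
        ri = [self.position(HomologID(ci, "a")), self.position(HomologID(ci, "b"))]
        rj = [self.position(HomologID(cj, "a")), self.position(HomologID(cj, "b"))]
        return self.data[np.ix_(ri, rj)].copy()

    def copy(self) -> "InteractionMatrix":
        return InteractionMatrix(self.data.copy(), self.chromosomes)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, InteractionMatrix)
            and self.chromosomes == other.chromosomes
            and np.array_equal(self.data, other.data)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"InteractionMatrix({len(self.chromosomes)} chromosomes, {self.n_edges()} edges)"


def chromosome_pairs(chromosomes: Sequence[int] = CHROMOSOME_PANEL) -> List[Tuple[int, int]]:
    """All unordered heterologous chromosome pairs (21 for the 7-member panel)."""
    cs = sorted(chromosomes)
    return [(cs[i], cs[j]) for i in range(len(cs)) for j in range(i + 1, len(cs))]


# ---------------------------------------------------------------------------
# interaction calling
# ---------------------------------------------------------------------------

def call_interactions(table, threshold: float = INTERACTION_THRESHOLD_UM) -> InteractionMatrix:
    """Call the binary interaction matrix of one nucleus from its pair table.

    An edge is set when PBD ≤ ``threshold`` (inclusive, so direct overlap
    with PBD = 0 always counts).  ``table`` is a
    :class:`~ctnet.morphometry.MeasurementTable` or anything exposing a
    ``pairs`` DataFrame with chrom/tag/pbd_um columns.
    """
    pairs = table.pairs
    chromosomes = sorted(set(pairs["chrom_i"]) | set(pairs["chrom_j"]))
    n = 2 * len(chromosomes)
    expected = n * (n - 1) // 2
    if len(pairs) != expected or pairs["pbd_um"].isna().any():
        raise ValueError(
            f"incomplete pair table: {len(pairs)} rows (expected {expected}) "
            "or missing PBD values"
        )
    m = InteractionMatrix(chromosomes=chromosomes)
    # inclusive bound; the 1e-6 µm guard keeps an exactly-4-pixel distance
    # (4 × 0.07 µm, which rounds just above 0.28 in binary) inside it
    hit = pairs[pairs["pbd_um"] <= threshold + 1e-6]
    for row in hit.itertuples():
        m.set_edge(
            HomologID(int(row.chrom_i), row.tag_i),
            HomologID(int(row.chrom_j), row.tag_j),
        )
    return m


def matrices_from_records(records, threshold: float = INTERACTION_THRESHOLD_UM) -> List[InteractionMatrix]:
    """Measure each nucleus record and call its interaction matrix."""
    from .morphometry import MeasurementTable  # local import avoids cycles

    return [call_interactions(MeasurementTable.measure(r), threshold) for r in records]


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------

def partners_per_ct(matrices: Sequence[InteractionMatrix], by: str = "copy") -> pd.Series:
    """Mean number of distinct heterologous partner copies per chromosome.

    ``by='copy'`` (default) counts partners of each homolog copy (maximum
    12 for a 7-chromosome panel) and averages over both copies and nuclei.
    ``by='type'`` counts the union of partner copies over a chromosome's
    two copies (maximum 12 as well) before averaging over nuclei.
    """
    if not matrices:
        raise ValueError("at least one matrix is required")
    chromosomes = matrices[0].chromosomes
    acc = {c: [] for c in chromosomes}
    for m in matrices:
        het = _heterolog_mask(m)
        counts = (m.data & het).sum(axis=1)  # partners of each copy
        for k, hid in enumerate(m.index):
            if by == "copy":
                acc[hid.chromosome].append(int(counts[k]))
        if by == "type":
            for c in chromosomes:
                ia = m.position(HomologID(c, "a"))
                ib = m.position(HomologID(c, "b"))
                union = (m.data[ia] | m.data[ib]) & het[ia]
                acc[c].append(int(union.sum()))
    return pd.Series({c: float(np.mean(acc[c])) for c in chromosomes}, name=f"partners_{by}")


def _heterolog_mask(m: InteractionMatrix) -> np.ndarray:
    chrom = np.array([h.chromosome for h in m.index])
    return chrom[:, None] != chrom[None, :]


def classify_multiplet(block: np.ndarray) -> str:
    """Classify a 2×2 pair block by its contact topology.

    Returns '0', '1', '2a' (two disjoint contacts), '2b' (two contacts
    sharing one copy of the lower-numbered chromosome, i.e. a triplet with
    both copies of the higher-numbered one), '2c' (the opposite triplet),
    '3' (alternating four-territory chain) or '4' (saturated).
    """
    block = np.asarray(block, dtype=bool)
    if block.shape != (2, 2):
        raise ValueError("pair block must be 2x2")
    k = int(block.sum())
    if k != 2:
        return str(k)
    rows = block.sum(axis=1)
    if rows.max() == 2:  # one copy of i carries both contacts
        return "2b"
    if block.sum(axis=0).max() == 2:  # one copy of j carries both
        return "2c"
    return "2a"


MULTIPLET_PATTERNS = ("2a", "2b", "2c", "3", "4")


def pair_profiles(matrices: Sequence[InteractionMatrix]) -> pd.DataFrame:
    """Per-chromosome-pair interaction profile over a population.

    One row per unordered chromosome pair with nucleus counts and percents
    for ≥1, =1 and ≥2 contacts (``pct_ge1 = pct_eq1 + pct_ge2`` exactly)
    plus multiplet-pattern tallies over the ≥2 nuclei.
    """
    if not matrices:
        raise ValueError("at least one matrix is required")
    chromosomes = matrices[0].chromosomes
    n = len(matrices)
    rows = []
    for ci, cj in chromosome_pairs(chromosomes):
        counts = np.array([int(m.pair_block(ci, cj).sum()) for m in matrices])
        pats = [classify_multiplet(m.pair_block(ci, cj)) for m in matrices]
        row = {
            "chrom_i": ci,
            "chrom_j": cj,
            "n": n,
            "n_ge1": int((counts >= 1).sum()),
            "n_eq1": int((counts == 1).sum()),
            "n_ge2": int((counts >= 2).sum()),
        }
        row["pct_ge1"] = 100.0 * row["n_ge1"] / n
        row["pct_eq1"] = 100.0 * row["n_eq1"] / n
        row["pct_ge2"] = 100.0 * row["n_ge2"] / n
        for p in MULTIPLET_PATTERNS:
            row[f"pat_{p}"] = sum(1 for q in pats if q == p)
        rows.append(row)
    return pd.DataFrame(rows).set_index(["chrom_i", "chrom_j"])


def homolog_vs_heterolog_ranking(matrices: Sequence[InteractionMatrix]) -> pd.DataFrame:
    """Normalized interaction frequencies, homologous and heterologous jointly.

    Heterologous pair frequency = interacting slots / (4·n) since four
    homolog-level contacts are possible per nucleus; homologous frequency =
    interacting nuclei / n (one possible contact).  Rows sorted low→high.
    """
    if not matrices:
        raise ValueError("at least one matrix is required")
    chromosomes = matrices[0].chromosomes
    n = len(matrices)
    rows = []
    for ci, cj in chromosome_pairs(chromosomes):
        total = sum(int(m.pair_block(ci, cj).sum()) for m in matrices)
        rows.append(
            {"pair": f"{ci}-{cj}", "kind": "heterologous", "frequency": total / (4.0 * n)}
        )
    for c in chromosomes:
        total = sum(int(m.has_edge(HomologID(c, "a"), HomologID(c, "b"))) for m in matrices)
        rows.append({"pair": f"{c}-{c}", "kind": "homologous", "frequency": total / float(n)})
    df = pd.DataFrame(rows).sort_values("frequency", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


class RadialFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    pvalue: float


def radial_regression(
    mean_sr: Mapping[int, float],
    covariate: Mapping[int, float] | str = "length",
) -> RadialFit:
    """OLS of per-chromosome mean subtended radius against a covariate.

    ``covariate`` may be a mapping chromosome→value, or ``'length'`` /
    ``'gene_density'`` to use the bundled constants.
    """
    if covariate == "length":
        covariate = CHROMOSOME_LENGTH_MB
    elif covariate == "gene_density":
        covariate = GENE_DENSITY
    chroms = sorted(mean_sr)
    x = np.array([covariate[c] for c in chroms], dtype=float)
    y = np.array([mean_sr[c] for c in chroms], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; the fit is undefined")
    if np.ptp(y) == 0:  # flat response: slope 0 and nothing explained
        return RadialFit(0.0, float(y[0]), 0.0, 1.0)
    res = stats.linregress(x, y)
    return RadialFit(res.slope, res.intercept, res.rvalue**2, res.pvalue)
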