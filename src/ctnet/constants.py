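"""Chromosome-level covariates and default experimental-design constants.

Sequence lengths are GRCh37-scale values in Mb; gene densities are
protein-coding genes per Mb.  Both are plain numeric inputs used as
regression covariates and to apportion territory volumes — edit freely
for other panels.
"""

from __future__ import annotations

#: Chromosome sequence length, Mb.
CHROMOSOME_LENGTH_MB = {
    1: 249.0,
    4: 191.0,
    11: 135.0,
    12: 134.0,
    16: 90.0,
    17: 81.0,
    18: 78.0,
}

#: Approximate protein-coding gene density, genes/Mb.
GENE_DENSITY = {
    1: 8.3,
    4: 4.0,
    11: 9.6,
    12: 7.7,
    16: 9.4,
    17: 14.6,
    18: 3.5,
}

#: Interaction threshold on the minimal 3D border distance, µm (= 4 px at 0.07 µm/px).
INTERACTION_THRESHOLD_UM = 0.28
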