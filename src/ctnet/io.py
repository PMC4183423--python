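"""On-disk layout: TIFF mask stacks, metadata, and documented-schema CSVs.

A population is written one directory per nucleus::

    population/
      nucleus_000/
        nucleus.tif      # multi-page TIFF, one z-slice per page, uint8 {0,1}
        ct1a.tif ...     # one stack per homolog territory
        meta.json        # spacing, condition, seed, null flag
        truth.csv        # planted edge list (chrom_i,tag_i,chrom_j,tag_j)
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import HomologID, LabeledVolume, NucleusRecord, VoxelSpacing
from .interactions import InteractionMatrix
from .median import ChromaticMedianResults, Network


# ---------------------------------------------------------------------------
# populations of mask stacks
# ---------------------------------------------------------------------------

def write_population(records: Sequence[NucleusRecord], root) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for i, rec in enumerate(records):
        d = root / f"nucleus_{i:03d}"
        d.mkdir(exist_ok=True)
        _write_mask(d / "nucleus.tif", rec.nucleus)
        for hid, vol in sorted(rec.territories.items()):
            _write_mask(d / f"ct{hid.chromosome}{hid.tag}.tif", vol)
        meta = {
            "spacing": {"dx": rec.spacing.dx, "dy": rec.spacing.dy, "dz": rec.spacing.dz},
            "condition": rec.condition,
            "null": bool(rec.meta.get("null", False)),
            **{k: v for k, v in rec.meta.items() if k != "null"},
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))
        if rec.truth is not None:
            rows = [
                {"chrom_i": u.chromosome, "tag_i": u.tag, "chrom_j": v.chromosome, "tag_j": v.tag}
                for u, v in rec.truth.edges()
            ]
            pd.DataFrame(rows, columns=["chrom_i", "tag_i", "chrom_j", "tag_j"]).to_csv(
                d / "truth.csv", index=False
            )


def read_population(root) -> List[NucleusRecord]:
    root = Path(root)
    records = []
    for d in sorted(root.glob("nucleus_*")):
        meta = json.loads((d / "meta.json").read_text())
        spacing = VoxelSpacing(**meta.pop("spacing"))
        condition = meta.pop("condition", "")
        nucleus = LabeledVolume(tifffile.imread(d / "nucleus.tif").astype(bool), spacing)
        territories = {}
        for f in sorted(d.glob("ct*.tif")):
            m = re.fullmatch(r"ct(\d+)([ab])\.tif", f.name)
            if m:
                territories[HomologID(int(m.group(1)), m.group(2))] = LabeledVolume(
                    tifffile.imread(f).astype(bool), spacing
                )
        truth = None
        tf = d / "truth.csv"
        if tf.exists():
            df = pd.read_csv(tf)
            chromosomes = sorted({h.chromosome for h in territories})
            truth = InteractionMatrix.from_edges(
                [
                    (HomologID(int(r.chrom_i), r.tag_i), HomologID(int(r.chrom_j), r.tag_j))
                    for r in df.itertuples()
                ],
                chromosomes,
            )
        records.append(NucleusRecord(nucleus, territories, condition, truth, meta))
    return records


def _write_mask(path, vol: LabeledVolume) -> None:
    tifffile.imwrite(path, vol.mask.astype(np.uint8), photometric="minisblack")


# ---------------------------------------------------------------------------
# analysis tables
# ---------------------------------------------------------------------------

def write_interactions(matrices: Sequence[InteractionMatrix], path) -> None:
    """Per-nucleus interaction edge list (`interactions.csv` schema)."""
    rows = []
    for i, m in enumerate(matrices):
        for u, v in m.edges():
            rows.append(
                {"nucleus": i, "chrom_i": u.chromosome, "tag_i": u.tag,
                 "chrom_j": v.chromosome, "tag_j": v.tag}
            )
    pd.DataFrame(rows, columns=["nucleus", "chrom_i", "tag_i", "chrom_j", "tag_j"]).to_csv(
        path, index=False
    )


def write_median_outputs(results: ChromaticMedianResults, directory) -> None:
    """`median_matrix.csv` (91 homolog-pair percents), `flips.csv`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    results.percent_series.rename_axis(["homolog_i", "homolog_j"]).reset_index().to_csv(
        directory / "median_matrix.csv", index=False
    )
    flips = pd.DataFrame(
        results.flips.astype(int),
        columns=[f"flip_{c}" for c in results.model.chromosomes],
    )
    flips.insert(0, "nucleus", np.arange(len(flips)))
    flips.to_csv(directory / "flips.csv", index=False)


def write_network(network: Network, json_path, tsv_path: Optional[object] = None) -> None:
    """`network.json` plus an optional graph-tool-loadable edge-list TSV."""
    payload = {
        "threshold": network.threshold,
        "edges": [
            {"u": str(e.u), "v": str(e.v), "percent": e.percent, "tier": e.tier}
            for e in network.edges
        ],
    }
    Path(json_path).write_text(json.dumps(payload, indent=1))
    if tsv_path is not None:
        pd.DataFrame(
            [{"source": str(e.u), "target": str(e.v), "percent": e.percent, "tier": e.tier}
             for e in network.edges]
        ).to_csv(tsv_path, sep="\t", index=False)


def read_measurement_export(path) -> pd.DataFrame:
    """Optional reader for a deposited distance/volume workbook exported as CSV.

    Expects a tidy export with columns ``nucleus``, ``item`` (a homolog like
    ``CT1a``, a pair like ``CT1a-CT4b``, or ``nucleus``), ``metric``
    (volume/PBD/PCD/PBCD/SR/MPD/overlap) and ``value``.  Returns the frame
    with parsed ``chrom_i``/``tag_i``/``chrom_j``/``tag_j`` columns added
    where applicable.
    """
    df = pd.read_csv(path)
    required = {"nucleus", "item", "metric", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"export must have columns {sorted(required)}")
    pat_h = re.compile(r"CT(\d+)([ab])$", re.IGNORECASE)
    pat_p = re.compile(r"CT(\d+)([ab])-CT(\d+)([ab])$", re.IGNORECASE)
    ci, ti, cj, tj = [], [], [], []
    for item in df["item"].astype(str):
        mp = pat_p.match(item)
        mh = pat_h.match(item)
        if mp:
            ci.append(int(mp.group(1))); ti.append(mp.group(2).lower())
            cj.append(int(mp.group(3))); tj.append(mp.group(4).lower())
        elif mh:
            ci.append(int(mh.group(1))); ti.append(mh.group(2).lower())
            cj.append(np.nan); tj.append(None)
        else:
            ci.append(np.nan); ti.append(None); cj.append(np.nan); tj.append(None)
    df["chrom_i"], df["tag_i"], df["chrom_j"], df["tag_j"] = ci, ti, cj, tj
    return df
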