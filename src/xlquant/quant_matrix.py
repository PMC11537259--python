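"""Residue-pair level quantification matrices.

Aggregation of reporter intensities to unique residue pairs, sample
(column) normalisation to the maximum total, row-mean scaling with log2
transform, and replicate coefficient-of-variation summaries.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .linkmap import LinkAnnotation, LONG_LOOP_MIN_DISTANCE, ResiduePairKey, csm_residue_pair
from .plink_io import CsmRecord

__all__ = [
    "ResiduePairQuant",
    "aggregate",
    "normalize_samples",
    "scale_log2",
    "replicate_cv",
]

logger = logging.getLogger(__name__)

STAGES = ("raw", "normalized", "scaled_log2", "regressed")


@dataclass
class ResiduePairQuant:
    """Residue pairs × samples matrix with a processing-stage tag."""

    data: pd.DataFrame  # index: canonical pair strings, columns: sample labels
    stage: str
    keys: Dict[str, ResiduePairKey] = field(default_factory=dict)
    n_dropped_zero_rows: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicated residue-pair row keys")
        if self.stage in ("raw", "normalized") and (self.data.values < 0).any():
            raise ValueError(f"negative values at stage {self.stage!r}")

    @property
    def samples(self) -> List[str]:
        return list(self.data.columns)

    def key_of(self, row: str) -> ResiduePairKey:
        return self.keys.get(row) or ResiduePairKey.from_string(row)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w", encoding="utf-8") as fh:
            fh.write(f"# stage: {self.stage}\n")
            self.data.to_csv(fh, sep="\t", index_label="residue_pair")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ResiduePairQuant":
        with open(os.fspath(path), "r", encoding="utf-8") as fh:
            first = fh.readline().strip()
            stage = first.split("stage:", 1)[1].strip() if "stage:" in first else "raw"
            data = pd.read_csv(fh, sep="\t", index_col="residue_pair")
        data.index.name = None
        return cls(data=data, stage=stage)


def aggregate(
    csms: Sequence[CsmRecord],
    annotations: Sequence[LinkAnnotation],
    samples: Optional[Sequence[str]] = None,
    long_loop_min: int = LONG_LOOP_MIN_DISTANCE,
) -> ResiduePairQuant:
    """Sum attached reporter intensities channel-wise per unique residue pair.

    Included: cross-links and loop-links with sequence distance >=
    ``long_loop_min``.  Excluded: short loop-links, monolinks, regular
    peptides, shared-peptide pairs, and CSMs without attached reporters.
    The result is permutation-invariant in CSM order (rows are sorted by
    canonical key).
    """
    shared = {
        (a.key.protein_a, a.key.pos_a, a.key.protein_b, a.key.pos_b)
        for a in annotations
        if a.shared_peptide
    }
    if samples is None:
        for csm in csms:
            if csm.reporter_intensities is not None:
                samples = list(csm.reporter_intensities.keys())
                break
        else:
            raise ValueError("no CSM carries reporter intensities")
    samples = list(samples)

    sums: Dict[str, np.ndarray] = {}
    keys: Dict[str, ResiduePairKey] = {}
    n_skipped = 0
    for csm in csms:
        if csm.link_type not in ("cross", "loop"):
            continue
        if csm.link_type == "loop":
            acc_a, site_a = csm.proteins_a[0]
            _, site_b = csm.proteins_b[0]
            if abs(site_b - site_a) < long_loop_min:
                continue
        key = csm_residue_pair(csm)
        assert key is not None
        tup = (key.protein_a, key.pos_a, key.protein_b, key.pos_b)
        if tup in shared:
            continue
        if csm.reporter_intensities is None:
            n_skipped += 1
            continue
        name = key.as_string()
        vec = np.array([csm.reporter_intensities[s] for s in samples], dtype=float)
        if name in sums:
            sums[name] += vec
        else:
            sums[name] = vec
            keys[name] = key
    if n_skipped:
        logger.info("aggregate: %d quantifiable CSMs lacked reporter intensities", n_skipped)

    order = sorted(sums)
    data = pd.DataFrame([sums[n] for n in order], index=order, columns=samples, dtype=float)
    return ResiduePairQuant(data=data, stage="raw", keys={n: keys[n] for n in order})


def normalize_samples(q: ResiduePairQuant) -> ResiduePairQuant:
    """Equalise sample totals to the pre-normalisation maximum.

    Factor per sample = its total / max total; values divide by the
    factor, so every sample total afterwards equals the original
    maximum.  Rank order within a sample and all cross-pair ratios are
    preserved.
    """
    if q.stage != "raw":
        raise ValueError(f"normalize_samples expects stage 'raw', got {q.stage!r}")
    totals = q.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total intensity: {list(zero.index)}")
    factors = totals / totals.max()
    data = q.data / factors
    return ResiduePairQuant(data=data, stage="normalized", keys=dict(q.keys))


def scale_log2(q: ResiduePairQuant) -> ResiduePairQuant:
    """Scale each row to its mean, then log2-transform.

    Rows containing any zero are dropped (complete-case) with a logged
    count rather than pseudo-counted.  For every retained row the mean
    of ``2**value`` is exactly 1.
    """
    if q.stage != "normalized":
        raise ValueError(f"scale_log2 expects stage 'normalized', got {q.stage!r}")
    has_zero = (q.data.values <= 0).any(axis=1)
    n_dropped = int(has_zero.sum())
    if n_dropped:
        logger.info("scale_log2: dropped %d rows containing zero intensities", n_dropped)
    kept = q.data.loc[~has_zero]
    scaled = np.log2(kept.div(kept.mean(axis=1), axis=0))
    keys = {k: v for k, v in q.keys.items() if k in scaled.index}
    return ResiduePairQuant(
        data=scaled, stage="scaled_log2", keys=keys, n_dropped_zero_rows=n_dropped
    )


def replicate_cv(
    q: ResiduePairQuant,
    replicate_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-pair, per-cell-line CV% from normalised (pre-log) intensities.

    CV = sample SD (n-1) / mean x 100 over the replicate channels of
    each cell line; cell lines with fewer than two channels are omitted.
    The result carries per-cell-line and pooled medians in ``attrs``.
    """
    if q.stage != "normalized":
        raise ValueError(f"replicate_cv expects stage 'normalized', got {q.stage!r}")
    groups: Dict[str, List[str]] = {}
    for sample in q.samples:
        if sample in replicate_map:
            groups.setdefault(replicate_map[sample], []).append(sample)
    replicated = {cl: cols for cl, cols in groups.items() if len(cols) >= 2}
    if not replicated:
        raise ValueError("no cell line has >= 2 replicate channels")

    out = {}
    for cl, cols in sorted(replicated.items()):
        block = q.data[cols]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        cv = sd / mean * 100.0
        cv[mean == 0] = np.nan
        out[cl] = cv
    cvs = pd.DataFrame(out)
    cvs.attrs["median_per_cell_line"] = cvs.median(axis=0).to_dict()
    cvs.attrs["median_pooled"] = float(np.nanmedian(cvs.values))
    return cvs
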