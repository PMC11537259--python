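"""Associating genomic mutations with structural quantification.

Regresses protein abundance out of intralink profiles by per-pair
ordinary least squares (residuals = net cross-linking differences),
overlays missense mutation positions on cross-link sequence intervals,
and selects mutation-associated structural events by effect-size and
dispersion filters.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .linkmap import ResiduePairKey
from .quant_matrix import ResiduePairQuant

__all__ = [
    "MutationTable",
    "RegressedProfile",
    "StructuralEvent",
    "regress_out_protein",
    "mutation_overlap",
    "select_events",
    "residual_matrix",
]

logger = logging.getLogger(__name__)

RATIO_THRESHOLD = 0.4  # |regressed log2 ratio| cutoff
SD_MULTIPLIER = 2.0  # |residual| must exceed this multiple of the row SD


@dataclass
class MutationTable:
    """Per-gene, per-cell-line missense mutation positions."""

    entries: List[Tuple[str, str, int]]  # (gene, cell_line, 1-based position)

    def __post_init__(self) -> None:
        for gene, cell_line, pos in self.entries:
            if pos < 1:
                raise ValueError(f"mutation position must be >= 1 ({gene}/{cell_line}: {pos})")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "MutationTable":
        df = pd.read_csv(os.fspath(path), sep="\t")
        cols = {c.lower(): c for c in df.columns}
        gene = cols.get("gene", df.columns[0])
        cell = cols.get("cell_line", df.columns[1])
        pos = cols.get("position", df.columns[2])
        return cls([(str(r[gene]), str(r[cell]), int(r[pos])) for _, r in df.iterrows()])

    def genes(self) -> List[str]:
        return sorted({g for g, _, _ in self.entries})

    def cell_lines(self) -> List[str]:
        return sorted({c for _, c, _ in self.entries})

    def by_gene(self, gene: str) -> List[Tuple[str, int]]:
        return [(c, p) for g, c, p in self.entries if g == gene]

    def binary_matrix(self) -> pd.DataFrame:
        """Gene x cell-line matrix; 1 marks at least one missense mutation."""
        genes, cells = self.genes(), self.cell_lines()
        mat = pd.DataFrame(0, index=genes, columns=cells, dtype=int)
        for g, c, _ in self.entries:
            mat.loc[g, c] = 1
        return mat

    def label(self, gene: str) -> str:
        """Aggregated per-gene label, e.g. ``"MCM7 | LS411N_284; SNU1040_611"``."""
        parts = [f"{c}_{p}" for g, c, p in self.entries if g == gene]
        return f"{gene} | " + "; ".join(parts)


@dataclass
class RegressedProfile:
    """OLS fit of one intralink's log2 profile on its protein's profile."""

    key: ResiduePairKey
    protein_accession: str
    samples: List[str]
    residuals: np.ndarray  # per-sample, log2 scale; sums to ~0
    slope: float
    intercept: float


@dataclass
class StructuralEvent:
    """One (residue pair, cell line) passing both event filters."""

    key: ResiduePairKey
    cell_line: str
    residual: float
    sign: int  # -1 or +1
    mutation_positions: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")


def regress_out_protein(
    xl: ResiduePairQuant,
    protein: pd.DataFrame,
) -> List[RegressedProfile]:
    """Per-intralink OLS of cross-link on protein abundance, with intercept.

    ``xl`` must be at stage ``scaled_log2``; ``protein`` is an accession
    x sample matrix processed the same way.  Only intralink rows are
    regressed; rows whose protein is absent are skipped and counted.
    Residuals sum to zero and are orthogonal to the predictor.  When the
    predictor has zero variance the slope is undefined and residuals
    fall back to the intercept-only model with a warning.
    """
    if xl.stage != "scaled_log2":
        raise ValueError(f"regress_out_protein expects stage 'scaled_log2', got {xl.stage!r}")
    missing = [s for s in xl.samples if s not in protein.columns]
    if missing:
        raise ValueError(f"protein matrix lacks sample columns {missing}")

    profiles: List[RegressedProfile] = []
    n_skipped = 0
    samples = xl.samples
    for row_name, row in xl.data.iterrows():
        key = xl.key_of(row_name)
        if not key.is_intra:
            continue
        acc = key.protein_a
        if acc not in protein.index:
            n_skipped += 1
            continue
        x = protein.loc[acc, samples].to_numpy(dtype=float)
        y = row.to_numpy(dtype=float)
        sxx = float(np.var(x))
        if sxx == 0.0:
            logger.warning(
                "zero-variance protein profile for %s; using intercept-only model", acc
            )
            slope = float("nan")
            intercept = float(np.mean(y))
            resid = y - intercept
        else:
            slope = float(np.cov(x, y, bias=True)[0, 1] / sxx)
            intercept = float(np.mean(y) - slope * np.mean(x))
            resid = y - (slope * x + intercept)
        profiles.append(
            RegressedProfile(
                key=key,
                protein_accession=acc,
                samples=list(samples),
                residuals=resid,
                slope=slope,
                intercept=intercept,
            )
        )
    if n_skipped:
        logger.info("regress_out_protein: %d intralinks without a quantified protein", n_skipped)
    return profiles


def residual_matrix(profiles: Sequence[RegressedProfile]) -> pd.DataFrame:
    """Residuals as a pairs x samples DataFrame (stage 'regressed')."""
    if not profiles:
        return pd.DataFrame()
    return pd.DataFrame(
        [p.residuals for p in profiles],
        index=[p.key.as_string() for p in profiles],
        columns=profiles[0].samples,
    )


def mutation_overlap(
    pairs: Sequence[ResiduePairKey],
    mutations: MutationTable,
    gene_to_accession: Mapping[str, str],
) -> Dict[Tuple[str, str], List[int]]:
    """Mutations falling inside cross-link sequence intervals.

    Returns ``{(pair string, cell line): [positions...]}`` for every
    intralink whose protein carries a missense mutation with
    ``min(pos_a, pos_b) <= position <= max(pos_a, pos_b)`` (closed
    interval — a mutation of the linked residue itself counts).  Genes
    missing from the mapping are reported and excluded.
    """
    by_accession: Dict[str, List[Tuple[str, int]]] = {}
    unmapped = set()
    for gene, cell_line, pos in mutations.entries:
        acc = gene_to_accession.get(gene)
        if acc is None:
            unmapped.add(gene)
            continue
        by_accession.setdefault(acc, []).append((cell_line, pos))
    if unmapped:
        logger.warning("mutation_overlap: unmapped gene symbols excluded: %s", sorted(unmapped))

    overlaps: Dict[Tuple[str, str], List[int]] = {}
    for key in pairs:
        if not key.is_intra:
            continue
        lo, hi = min(key.pos_a, key.pos_b), max(key.pos_a, key.pos_b)
        for cell_line, pos in by_accession.get(key.protein_a, []):
            if lo <= pos <= hi:
                overlaps.setdefault((key.as_string(), cell_line), []).append(pos)
    return overlaps


def select_events(
    profiles: Sequence[RegressedProfile],
    overlaps: Mapping[Tuple[str, str], List[int]],
    replicate_map: Optional[Mapping[str, str]] = None,
    ratio_threshold: float = RATIO_THRESHOLD,
    sd_multiplier: float = SD_MULTIPLIER,
    average_replicates: bool = True,
) -> List[StructuralEvent]:
    """Mutation-associated structural events.

    For each regressed intralink, replicate channels of one cell line
    are averaged (switchable), the sample SD (n-1) is taken across all
    cell-line values, and a (pair, mutated cell line) becomes an event
    iff ``|residual| > ratio_threshold`` and ``|residual| >
    sd_multiplier x SD``.  The sign is discretised to -1/+1.  Raising
    either threshold can only remove events.
    """
    events: List[StructuralEvent] = []
    for profile in profiles:
        if average_replicates and replicate_map is not None:
            groups: Dict[str, List[float]] = {}
            order: List[str] = []
            for sample, value in zip(profile.samples, profile.residuals):
                cl = replicate_map.get(sample, sample)
                if cl not in groups:
                    order.append(cl)
                groups.setdefault(cl, []).append(float(value))
            cell_values = {cl: float(np.mean(groups[cl])) for cl in order}
        else:
            cell_values = {
                (replicate_map.get(s, s) if replicate_map else s): float(v)
                for s, v in zip(profile.samples, profile.residuals)
            }
        values = np.array(list(cell_values.values()), dtype=float)
        if len(values) < 2:
            continue
        sd = float(np.std(values, ddof=1))
        pair_name = profile.key.as_string()
        for cell_line, value in cell_values.items():
            positions = overlaps.get((pair_name, cell_line))
            if positions is None:
                continue
            if abs(value) > ratio_threshold and abs(value) > sd_multiplier * sd:
                events.append(
                    StructuralEvent(
                        key=profile.key,
                        cell_line=cell_line,
                        residual=value,
                        sign=1 if value > 0 else -1,
                        mutation_positions=sorted(positions),
                    )
                )
    return events


def events_table(events: Sequence[StructuralEvent]) -> pd.DataFrame:
    """Events as a flat table with the discrete -1/+1 column."""
    return pd.DataFrame(
        [
            {
                "residue_pair": e.key.as_string(),
                "cell_line": e.cell_line,
                "residual": e.residual,
                "sign": e.sign,
                "mutation_positions": ";".join(str(p) for p in e.mutation_positions),
            }
            for e in events
        ],
        columns=["residue_pair", "cell_line", "residual", "sign", "mutation_positions"],
    )
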