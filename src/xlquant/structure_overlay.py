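"""Overlay of cross-links on predicted structure models and disorder
annotations.

Distances are CA-CA Euclidean distances in Angstrom, the community
default for short NHS-ester cross-linker constraints; per-residue model
confidence (pLDDT) is read from the B-factor column of AlphaFold-style
model files.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .linkmap import LinkAnnotation, ResiduePairKey

__all__ = [
    "StructureModel",
    "DisorderRegion",
    "DISTANCE_CONSTRAINT",
    "link_distance",
    "protein_distance_profile",
    "mean_plddt",
    "disorder_overlap",
    "load_models",
    "read_disorder_table",
]

#: Expected maximum CA-CA constraint (Angstrom) for the cross-linker.
DISTANCE_CONSTRAINT = 20.0


@dataclass
class StructureModel:
    """Per-residue CA coordinates and pLDDT for one protein model."""

    accession: str
    residues: List[Tuple[int, Tuple[float, float, float], float]]
    # (1-based index, (x, y, z), plddt)

    def __post_init__(self) -> None:
        indices = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError(f"residue indices not strictly increasing in {self.accession!r}")
        for _, _, plddt in self.residues:
            if not (0.0 <= plddt <= 100.0):
                raise ValueError(f"pLDDT outside [0, 100] in {self.accession!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def _index(self) -> Dict[int, Tuple[Tuple[float, float, float], float]]:
        return {idx: (xyz, plddt) for idx, xyz, plddt in self.residues}

    def ca(self, residue_index: int) -> Optional[Tuple[float, float, float]]:
        entry = self._index.get(residue_index)
        return entry[0] if entry else None

    @classmethod
    def from_file(cls, path: str | os.PathLike, accession: Optional[str] = None) -> "StructureModel":
        """Read CA coordinates and B-factor pLDDT from a PDB or mmCIF file.

        The accession defaults to the AlphaFold file-name convention
        ``AF-<accession>-F1-model_v4.{pdb,cif}`` when it applies,
        otherwise the file stem.
        """
        from Bio.PDB import MMCIFParser, PDBParser

        path = os.fspath(path)
        stem = os.path.splitext(os.path.basename(path))[0]
        if accession is None:
            parts = stem.split("-")
            accession = parts[1] if len(parts) >= 3 and parts[0] == "AF" else stem
        parser = (
            MMCIFParser(QUIET=True)
            if path.lower().endswith((".cif", ".mmcif"))
            else PDBParser(QUIET=True)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(stem, path)
        residues = []
        model = next(iter(structure))
        for chain in model:
            for residue in chain:
                if "CA" not in residue:
                    continue
                ca = residue["CA"]
                x, y, z = (float(v) for v in ca.coord)
                residues.append((residue.id[1], (x, y, z), float(ca.bfactor)))
            break  # single-chain monomer models
        residues.sort(key=lambda r: r[0])
        return cls(accession=accession, residues=residues)


@dataclass(frozen=True)
class DisorderRegion:
    """Closed 1-based interval of experimentally verified disorder."""

    accession: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def link_distance(model: StructureModel, pair: ResiduePairKey) -> Optional[float]:
    """CA-CA Euclidean distance (Angstrom) for an intralink, or None when
    either site is missing from the model ("unmappable")."""
    if not pair.is_intra:
        raise ValueError(f"link_distance requires an intralink, got {pair.as_string()}")
    a = model.ca(pair.pos_a)
    b = model.ca(pair.pos_b)
    if a is None or b is None:
        return None
    return math.dist(a, b)


def mean_plddt(model: StructureModel) -> float:
    """Arithmetic mean of the per-residue pLDDT values."""
    if not model.residues:
        raise ValueError(f"model {model.accession!r} has no residues")
    return sum(r[2] for r in model.residues) / len(model.residues)


def protein_distance_profile(
    models: Mapping[str, StructureModel],
    annotations: Sequence[LinkAnnotation],
    min_intralinks: int = 6,
    constraint: float = DISTANCE_CONSTRAINT,
) -> pd.DataFrame:
    """Per-protein distance statistics and constraint classification.

    Only proteins with at least ``min_intralinks`` mappable intralinks —
    long loop-links excluded from the count — are reported, with the
    mean and SD (n-1) of their intralink distances, the mean CSM count,
    the mean model pLDDT, and class ``shorter`` for mean < constraint,
    ``longer`` otherwise (exact ties class as longer, following the
    strict-< shorter rule).
    """
    per_protein: Dict[str, List[Tuple[float, int]]] = {}
    n_unmappable = 0
    for ann in annotations:
        if not ann.is_intra or ann.shared_peptide:
            continue
        if ann.key.origin != "cross":
            continue  # long loop-links excluded from intralink counting
        model = models.get(ann.key.protein_a)
        if model is None:
            continue
        dist = link_distance(model, ann.key)
        if dist is None:
            n_unmappable += 1
            continue
        per_protein.setdefault(ann.key.protein_a, []).append((dist, ann.csm_count))

    rows = []
    for acc in sorted(per_protein):
        entries = per_protein[acc]
        if len(entries) < min_intralinks:
            continue
        dists = [d for d, _ in entries]
        n = len(dists)
        mean = sum(dists) / n
        sd = math.sqrt(sum((d - mean) ** 2 for d in dists) / (n - 1)) if n > 1 else 0.0
        rows.append(
            {
                "accession": acc,
                "n_intralinks": n,
                "mean_distance": mean,
                "sd_distance": sd,
                "mean_csms": sum(c for _, c in entries) / n,
                "mean_plddt": mean_plddt(models[acc]),
                "class": "shorter" if mean < constraint else "longer",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "accession",
            "n_intralinks",
            "mean_distance",
            "sd_distance",
            "mean_csms",
            "mean_plddt",
            "class",
        ],
    )
    df.attrs["n_unmappable"] = n_unmappable
    return df


def disorder_overlap(
    annotations: Sequence[LinkAnnotation],
    regions: Iterable[DisorderRegion],
) -> pd.DataFrame:
    """Flag links touching catalogued disordered proteins/regions.

    ``in_disprot``: either accession has at least one region on record.
    ``in_disordered_region``: additionally, one linked side falls inside
    a region of its own protein (closed interval, boundaries inside).
    ``attrs`` carries the fraction with ``in_disprot`` and, among those,
    the fraction with ``in_disordered_region``.
    """
    by_acc: Dict[str, List[DisorderRegion]] = {}
    for region in regions:
        by_acc.setdefault(region.accession, []).append(region)

    rows = []
    for ann in annotations:
        key = ann.key
        regions_a = by_acc.get(key.protein_a, [])
        regions_b = by_acc.get(key.protein_b, [])
        flag1 = bool(regions_a or regions_b)
        flag2 = flag1 and (
            any(r.contains(key.pos_a) for r in regions_a)
            or any(r.contains(key.pos_b) for r in regions_b)
        )
        rows.append(
            {
                "residue_pair": key.as_string(),
                "in_disprot": flag1,
                "in_disordered_region": flag2,
            }
        )
    df = pd.DataFrame(rows, columns=["residue_pair", "in_disprot", "in_disordered_region"])
    n = len(df)
    n_prot = int(df["in_disprot"].sum()) if n else 0
    df.attrs["fraction_in_disprot"] = (n_prot / n) if n else float("nan")
    df.attrs["fraction_region_among_disprot"] = (
        int(df["in_disordered_region"].sum()) / n_prot if n_prot else float("nan")
    )
    return df


def load_models(directory: str | os.PathLike) -> Dict[str, StructureModel]:
    """Load every ``*.pdb``/``*.cif`` model in a directory, keyed by accession."""
    directory = os.fspath(directory)
    models: Dict[str, StructureModel] = {}
    for name in sorted(os.listdir(directory)):
        if not name.lower().endswith((".pdb", ".cif", ".mmcif")):
            continue
        model = StructureModel.from_file(os.path.join(directory, name))
        models[model.accession] = model
    return models


def read_disorder_table(path: str | os.PathLike) -> List[DisorderRegion]:
    """Read a TSV of (accession, start, end) disorder regions."""
    df = pd.read_csv(os.fspath(path), sep="\t")
    cols = {c.lower(): c for c in df.columns}
    acc = cols.get("accession", df.columns[0])
    start = cols.get("start", df.columns[1])
    end = cols.get("end", df.columns[2])
    return [
        DisorderRegion(str(row[acc]), int(row[start]), int(row[end]))
        for _, row in df.iterrows()
    ]
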