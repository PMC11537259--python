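"""Mapping peptide-level identifications to protein residue pairs.

Covers canonicalisation of residue pairs, intra/inter classification,
the loop-link sequence-distance rule, shared-peptide exclusion,
seeded shuffled-decoy (entrapment) FASTA construction, and preparation
of the CSM table consumed by external PPI-FDR tools.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .plink_io import CsmRecord

__all__ = [
    "ResiduePairKey",
    "LinkAnnotation",
    "LONG_LOOP_MIN_DISTANCE",
    "csm_residue_pair",
    "is_shared_peptide",
    "to_residue_pairs",
    "loop_distance",
    "make_entrapment_fasta",
    "xifdr_input",
    "read_fasta",
    "write_fasta",
]

#: Minimum sequence separation (in amino acids) for a loop-link to count
#: as "long" and be treated like a cross-link downstream.
LONG_LOOP_MIN_DISTANCE = 5


@dataclass(frozen=True, order=True)
class ResiduePairKey:
    """Canonical protein-residue pair: (protein_a, pos_a) <= (protein_b, pos_b)."""

    protein_a: str
    pos_a: int
    protein_b: str
    pos_b: int
    origin: str = "cross"  # cross | long_loop

    def __post_init__(self) -> None:
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError("residue positions are 1-based (>= 1)")
        if (self.protein_a, self.pos_a) > (self.protein_b, self.pos_b):
            raise ValueError("key not canonical; use ResiduePairKey.make")

    @classmethod
    def make(
        cls, protein_a: str, pos_a: int, protein_b: str, pos_b: int, origin: str = "cross"
    ) -> "ResiduePairKey":
        if (protein_a, pos_a) <= (protein_b, pos_b):
            return cls(protein_a, pos_a, protein_b, pos_b, origin)
        return cls(protein_b, pos_b, protein_a, pos_a, origin)

    @property
    def is_intra(self) -> bool:
        return self.protein_a == self.protein_b

    def as_string(self) -> str:
        return f"{self.protein_a}:{self.pos_a}--{self.protein_b}:{self.pos_b}"

    @classmethod
    def from_string(cls, text: str, origin: str = "cross") -> "ResiduePairKey":
        left, right = text.split("--")
        pa, sa = left.rsplit(":", 1)
        pb, sb = right.rsplit(":", 1)
        return cls.make(pa, int(sa), pb, int(sb), origin)


@dataclass
class LinkAnnotation:
    key: ResiduePairKey
    is_intra: bool
    shared_peptide: bool
    csm_count: int
    loop_seq_distance: Optional[int] = None  # loop links only

    def __post_init__(self) -> None:
        if self.csm_count < 1:
            raise ValueError("csm_count must be >= 1")
        if self.is_intra != self.key.is_intra:
            raise ValueError("is_intra inconsistent with key accessions")


def is_shared_peptide(csm: CsmRecord) -> bool:
    """True when either peptide maps to more than one protein accession."""
    accs_a = {acc for acc, _ in csm.proteins_a}
    accs_b = {acc for acc, _ in csm.proteins_b}
    return len(accs_a) > 1 or len(accs_b) > 1


def loop_distance(csm: CsmRecord) -> Tuple[int, bool]:
    """Sequence distance of a loop-link: |site_b - site_a| amino acids,
    with the long flag set at >= LONG_LOOP_MIN_DISTANCE."""
    if csm.link_type != "loop":
        raise ValueError(f"loop_distance requires a loop-link, got {csm.link_type!r}")
    dist = abs(csm.link_pos_b - csm.link_pos_a)
    return dist, dist >= LONG_LOOP_MIN_DISTANCE


def csm_residue_pair(csm: CsmRecord) -> Optional[ResiduePairKey]:
    """Canonical residue-pair key for a cross- or loop-link CSM, using
    the first listed protein mapping per side; None for mono/regular."""
    if csm.link_type == "cross":
        acc_a, site_a = csm.proteins_a[0]
        acc_b, site_b = csm.proteins_b[0]
        return ResiduePairKey.make(acc_a, site_a, acc_b, site_b, origin="cross")
    if csm.link_type == "loop":
        acc_a, site_a = csm.proteins_a[0]
        acc_b, site_b = csm.proteins_b[0]
        dist = abs(site_b - site_a)
        origin = "long_loop" if dist >= LONG_LOOP_MIN_DISTANCE else "short_loop"
        return ResiduePairKey.make(acc_a, site_a, acc_b, site_b, origin=origin)
    return None


def _validate_csm_against_fasta(csm: CsmRecord, fasta: Mapping[str, str]) -> None:
    sides = [(csm.peptide_a, csm.link_pos_a, csm.proteins_a)]
    if csm.link_type == "cross":
        sides.append((csm.peptide_b, csm.link_pos_b, csm.proteins_b))
    for peptide, link_pos, mappings in sides:
        for acc, site in mappings:
            if acc not in fasta:
                raise KeyError(f"accession {acc!r} (CSM {csm.spectrum_title!r}) not in FASTA")
            start = site - link_pos  # 0-based peptide start in protein
            seq = fasta[acc]
            if start < 0 or seq[start : start + len(peptide)] != peptide:
                raise ValueError(
                    f"peptide {peptide!r} not found in {acc!r} at claimed site {site} "
                    f"(CSM {csm.spectrum_title!r})"
                )


def to_residue_pairs(
    csms: Sequence[CsmRecord],
    fasta: Optional[Mapping[str, str]] = None,
    long_loop_min: int = LONG_LOOP_MIN_DISTANCE,
) -> List[LinkAnnotation]:
    """Collapse cross-link and long loop-link CSMs to unique residue pairs.

    The protein site of a linked residue equals the peptide's protein
    offset plus the within-peptide link position minus one; when a FASTA
    is supplied every claimed mapping is verified against it.  CSMs with
    the same canonical key are merged with their CSM counts summed; a
    merged pair is flagged shared when any contributing CSM has a
    peptide mapping to more than one protein.  Short loop-links
    (< ``long_loop_min``), monolinks and regular peptides produce no
    annotation.
    """
    merged: Dict[Tuple[str, int, str, int], LinkAnnotation] = {}
    for csm in csms:
        if csm.link_type not in ("cross", "loop"):
            continue
        if fasta is not None:
            _validate_csm_against_fasta(csm, fasta)
        loop_dist: Optional[int] = None
        if csm.link_type == "loop":
            loop_dist, _ = loop_distance(csm)
            if loop_dist < long_loop_min:
                continue
        key = csm_residue_pair(csm)
        assert key is not None
        shared = is_shared_peptide(csm)
        k = (key.protein_a, key.pos_a, key.protein_b, key.pos_b)
        if k in merged:
            ann = merged[k]
            ann.csm_count += 1
            ann.shared_peptide = ann.shared_peptide or shared
        else:
            merged[k] = LinkAnnotation(
                key=key,
                is_intra=key.is_intra,
                shared_peptide=shared,
                csm_count=1,
                loop_seq_distance=loop_dist,
            )
    return [merged[k] for k in sorted(merged)]


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA into an insertion-ordered {accession: sequence} dict.

    The accession is the first whitespace-delimited token of the header.
    """
    from Bio import SeqIO

    records: Dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_entrapment_fasta(
    true_targets: Mapping[str, str],
    seed: int,
    path: Optional[str | os.PathLike] = None,
    decoy_prefix: str = "DECOY_",
    preserve_tryptic: bool = False,
) -> Dict[str, str]:
    """Targets plus one seeded shuffled decoy per target.

    Each decoy is a uniformly random permutation of its target's
    residues (same length, same amino-acid multiset).  With
    ``preserve_tryptic`` the K/R positions stay fixed and only the
    remaining residues are permuted.  Identical seeds give identical
    output, byte-for-byte when written.
    """
    if not true_targets:
        raise ValueError("entrapment database requires at least one target sequence")
    rng = random.Random(seed)
    out: Dict[str, str] = dict(true_targets)
    for acc, seq in true_targets.items():
        if preserve_tryptic:
            movable = [i for i, aa in enumerate(seq) if aa not in "KR"]
            residues = [seq[i] for i in movable]
            rng.shuffle(residues)
            decoy = list(seq)
            for i, aa in zip(movable, residues):
                decoy[i] = aa
            decoy_seq = "".join(decoy)
        else:
            residues = list(seq)
            rng.shuffle(residues)
            decoy_seq = "".join(residues)
        out[decoy_prefix + acc] = decoy_seq
    if path is not None:
        write_fasta(out, path)
    return out


_XIFDR_COLUMNS = [
    "SpectrumTitle",
    "PepSeq1",
    "PepSeq2",
    "LinkPos1",
    "LinkPos2",
    "Protein1",
    "Protein2",
    "ProteinPos1",
    "ProteinPos2",
    "Decoy1",
    "Decoy2",
    "Score",
]


def xifdr_input(
    csms: Sequence[CsmRecord],
    annotations: Optional[Iterable[LinkAnnotation]] = None,
    decoy_prefix: str = "DECOY_",
) -> pd.DataFrame:
    """Build the CSM-level table for external PPI-FDR filtering.

    Only cross-link CSMs with unambiguous (non-shared) peptides are
    emitted; decoy flags come from the accession prefix.  When
    annotations are given, pairs flagged shared at the merged level are
    excluded as well.
    """
    shared_keys = set()
    if annotations is not None:
        shared_keys = {
            (a.key.protein_a, a.key.pos_a, a.key.protein_b, a.key.pos_b)
            for a in annotations
            if a.shared_peptide
        }
    rows = []
    for csm in csms:
        if csm.link_type != "cross":
            continue
        if is_shared_peptide(csm):
            continue
        key = csm_residue_pair(csm)
        if key is not None and (key.protein_a, key.pos_a, key.protein_b, key.pos_b) in shared_keys:
            continue
        acc_a, site_a = csm.proteins_a[0]
        acc_b, site_b = csm.proteins_b[0]
        rows.append(
            {
                "SpectrumTitle": csm.spectrum_title,
                "PepSeq1": csm.peptide_a,
                "PepSeq2": csm.peptide_b,
                "LinkPos1": csm.link_pos_a,
                "LinkPos2": csm.link_pos_b,
                "Protein1": acc_a,
                "Protein2": acc_b,
                "ProteinPos1": site_a,
                "ProteinPos2": site_b,
                "Decoy1": acc_a.startswith(decoy_prefix),
                "Decoy2": acc_b.startswith(decoy_prefix),
                "Score": csm.score,
            }
        )
    return pd.DataFrame(rows, columns=_XIFDR_COLUMNS)


def intra_inter_fractions(annotations: Sequence[LinkAnnotation]) -> Tuple[float, float]:
    """Percentages of intra- and interprotein links; sums to 100."""
    if not annotations:
        raise ValueError("no annotations")
    n_intra = sum(1 for a in annotations if a.is_intra)
    pct_intra = 100.0 * n_intra / len(annotations)
    return pct_intra, 100.0 - pct_intra
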