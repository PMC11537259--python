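"""pLink2-style hierarchical result files.

The cross-linked-peptides report is a three-level CSV: protein header
rows, indented peptide header rows, and doubly indented PSM rows, each
level introduced by its own sub-header line.  Indentation is expressed
as leading empty CSV fields, as emitted by pLink 2.3.x.

This module parses that hierarchy, attaches reporter-ion intensities to
PSMs by spectrum title, rolls intensities up to peptide and protein
headers by channel-wise summation, and writes the annotated file back
with the intensity columns appended at every level.
"""

from __future__ import annotations

import csv
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .reporter_quant import ReporterRow

__all__ = [
    "LINK_TYPES",
    "CsmRecord",
    "PsmRow",
    "PeptideHeader",
    "ProteinHeader",
    "PlinkReport",
    "PlinkParseError",
    "parse_plink_csv",
    "write_plink_csv",
    "attach_reporters",
    "rollup",
    "parse_peptide_string",
    "parse_proteins_string",
    "title_core_rule",
]

logger = logging.getLogger(__name__)

LINK_TYPES = ("cross", "loop", "mono", "regular")

_PEPTIDE_TYPE_TO_LINK = {
    "Cross-Linked": "cross",
    "Loop-Linked": "loop",
    "Mono-Linked": "mono",
    "Common": "regular",
}
_LINK_TO_PEPTIDE_TYPE = {v: k for k, v in _PEPTIDE_TYPE_TO_LINK.items()}

_PROTEIN_HEADER = ["Protein_Order", "Proteins", "Protein_Type"]
_PEPTIDE_HEADER = ["Peptide_Order", "Peptide", "Peptide_Type", "Linker", "Peptide_Mass"]
_PSM_HEADER = ["Spectrum_Order", "Title", "Charge", "Precursor_Mass", "Score"]


class PlinkParseError(ValueError):
    def __init__(self, message: str, path: str, line_no: int):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


@dataclass
class CsmRecord:
    """One cross-link spectrum match in engine-neutral form."""

    spectrum_title: str
    peptide_a: str
    peptide_b: str  # empty for loop/mono/regular
    link_pos_a: int  # 1-based within peptide_a; 0 for regular
    link_pos_b: int  # 1-based within peptide_a (loop) or peptide_b (cross)
    proteins_a: List[Tuple[str, int]]  # (accession, 1-based protein site)
    proteins_b: List[Tuple[str, int]]
    score: float
    link_type: str
    reporter_intensities: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.link_type not in LINK_TYPES:
            raise ValueError(f"unknown link type {self.link_type!r}")
        if self.link_type == "cross" and not self.peptide_b:
            raise ValueError("cross-link record requires two peptides")
        if self.link_type != "cross" and self.peptide_b:
            raise ValueError(f"{self.link_type} record must not carry a second peptide")
        if self.link_pos_a > len(self.peptide_a):
            raise ValueError("link_pos_a outside peptide_a")
        if self.link_type == "cross" and self.link_pos_b > len(self.peptide_b):
            raise ValueError("link_pos_b outside peptide_b")
        if self.link_type == "loop" and self.link_pos_b > len(self.peptide_a):
            raise ValueError("loop link_pos_b outside peptide")


@dataclass
class PsmRow:
    order: int
    title: str
    charge: int
    precursor_mass: float
    score: float
    reporter_intensities: Optional[Dict[str, float]] = None
    no_quant: bool = False


@dataclass
class PeptideHeader:
    order: int
    peptide: str
    peptide_type: str
    linker: str
    peptide_mass: float
    proteins: str = ""
    psms: List[PsmRow] = field(default_factory=list)
    reporter_intensities: Optional[Dict[str, float]] = None

    @property
    def link_type(self) -> str:
        return _PEPTIDE_TYPE_TO_LINK[self.peptide_type]


@dataclass
class ProteinHeader:
    order: int
    proteins: str
    protein_type: str
    peptides: List[PeptideHeader] = field(default_factory=list)
    reporter_intensities: Optional[Dict[str, float]] = None


@dataclass
class PlinkReport:
    protein_headers: List[ProteinHeader]
    provenance: str = ""
    n_no_quant: int = 0

    @property
    def peptide_headers(self) -> List[PeptideHeader]:
        return [pep for prot in self.protein_headers for pep in prot.peptides]

    @property
    def psms(self) -> List[PsmRow]:
        return [psm for pep in self.peptide_headers for psm in pep.psms]

    def csms(self) -> List[CsmRecord]:
        """Flatten the hierarchy into engine-neutral CSM records."""
        records: List[CsmRecord] = []
        for pep in self.peptide_headers:
            link_type = pep.link_type
            pep_a, pep_b, pos_a, pos_b = parse_peptide_string(pep.peptide, link_type)
            prots_a, prots_b = parse_proteins_string(pep.proteins, link_type)
            for psm in pep.psms:
                records.append(
                    CsmRecord(
                        spectrum_title=psm.title,
                        peptide_a=pep_a,
                        peptide_b=pep_b,
                        link_pos_a=pos_a,
                        link_pos_b=pos_b,
                        proteins_a=list(prots_a),
                        proteins_b=list(prots_b),
                        score=psm.score,
                        link_type=link_type,
                        reporter_intensities=(
                            dict(psm.reporter_intensities)
                            if psm.reporter_intensities is not None
                            else None
                        ),
                    )
                )
        return records


_PEP_CROSS_RE = re.compile(r"^([A-Z]+)\((\d+)\)-([A-Z]+)\((\d+)\)$")
_PEP_LOOP_RE = re.compile(r"^([A-Z]+)\((\d+)\)\((\d+)\)$")
_PEP_MONO_RE = re.compile(r"^([A-Z]+)\((\d+)\)$")
_PEP_PLAIN_RE = re.compile(r"^([A-Z]+)$")


def parse_peptide_string(text: str, link_type: str) -> Tuple[str, str, int, int]:
    """Parse pLink peptide notation into (pep_a, pep_b, pos_a, pos_b).

    ``"PEPTK(5)-AKDE(2)"`` (cross), ``"PEPTKIDKR(5)(8)"`` (loop),
    ``"PEPTK(5)"`` (mono), ``"PEPTIDER"`` (regular).
    """
    text = text.strip()
    if link_type == "cross":
        m = _PEP_CROSS_RE.match(text)
        if not m:
            raise ValueError(f"bad cross-linked peptide token {text!r}")
        return m.group(1), m.group(3), int(m.group(2)), int(m.group(4))
    if link_type == "loop":
        m = _PEP_LOOP_RE.match(text)
        if not m:
            raise ValueError(f"bad loop-linked peptide token {text!r}")
        return m.group(1), "", int(m.group(2)), int(m.group(3))
    if link_type == "mono":
        m = _PEP_MONO_RE.match(text)
        if not m:
            raise ValueError(f"bad mono-linked peptide token {text!r}")
        return m.group(1), "", int(m.group(2)), 0
    m = _PEP_PLAIN_RE.match(text)
    if not m:
        raise ValueError(f"bad regular peptide token {text!r}")
    return m.group(1), "", 0, 0


_PROT_SITE_RE = re.compile(r"^\s*(\S+)\s*\((\d+)\)\s*$")
_PROT_LOOP_RE = re.compile(r"^\s*(\S+)\s*\((\d+)\)\((\d+)\)\s*$")


def parse_proteins_string(
    text: str, link_type: str
) -> Tuple[List[Tuple[str, int]], List[Tuple[str, int]]]:
    """Parse the pLink Proteins column into per-side (accession, site) lists.

    Multiple mappings are ``/``-separated; a cross mapping is
    ``"acc1 (s1)-acc2 (s2)"``, a loop mapping ``"acc (s1)(s2)"``.
    """
    side_a: List[Tuple[str, int]] = []
    side_b: List[Tuple[str, int]] = []
    for mapping in filter(None, (p.strip() for p in text.strip().split("/"))):
        if link_type == "cross":
            parts = mapping.split(")-")
            if len(parts) != 2:
                raise ValueError(f"bad cross-link protein mapping {mapping!r}")
            ma = _PROT_SITE_RE.match(parts[0] + ")")
            mb = _PROT_SITE_RE.match(parts[1])
            if not ma or not mb:
                raise ValueError(f"bad cross-link protein mapping {mapping!r}")
            side_a.append((ma.group(1), int(ma.group(2))))
            side_b.append((mb.group(1), int(mb.group(2))))
        elif link_type == "loop":
            m = _PROT_LOOP_RE.match(mapping)
            if not m:
                raise ValueError(f"bad loop-link protein mapping {mapping!r}")
            side_a.append((m.group(1), int(m.group(2))))
            side_b.append((m.group(1), int(m.group(3))))
        elif link_type == "mono":
            m = _PROT_SITE_RE.match(mapping)
            if not m:
                raise ValueError(f"bad mono-link protein mapping {mapping!r}")
            side_a.append((m.group(1), int(m.group(2))))
        else:  # regular
            side_a.append((mapping, 0))
    return side_a, side_b


def _leading_blanks(row: List[str]) -> int:
    n = 0
    for cell in row:
        if cell.strip() == "":
            n += 1
        else:
            break
    return n


def _intensity_labels(header: Sequence[str]) -> List[str]:
    return [c[len("Intensity_"):] for c in header if c.startswith("Intensity_")]


def parse_plink_csv(path: str | os.PathLike) -> PlinkReport:
    """Parse a hierarchical cross-linked-peptides CSV into a report.

    Protein/peptide/PSM counts are preserved exactly; unknown row shapes
    raise :class:`PlinkParseError` with the line number.
    """
    path = os.fspath(path)
    report = PlinkReport(protein_headers=[], provenance=path)
    cur_prot: Optional[ProteinHeader] = None
    cur_pep: Optional[PeptideHeader] = None
    pep_labels: List[str] = []
    psm_labels: List[str] = []
    prot_labels: List[str] = []

    with open(path, "r", encoding="utf-8", newline="") as fh:
        for line_no, row in enumerate(csv.reader(fh), start=1):
            if not row or all(c.strip() == "" for c in row):
                continue
            depth = _leading_blanks(row)
            body = row[depth:]
            first = body[0].strip()

            if first == "Protein_Order":
                prot_labels = _intensity_labels(body)
                continue
            if first == "Peptide_Order":
                pep_labels = _intensity_labels(body)
                continue
            if first == "Spectrum_Order":
                psm_labels = _intensity_labels(body)
                continue

            if depth == 0:
                if len(body) < len(_PROTEIN_HEADER):
                    raise PlinkParseError("short protein header row", path, line_no)
                try:
                    order = int(first)
                except ValueError:
                    raise PlinkParseError(f"bad protein order {first!r}", path, line_no)
                cur_prot = ProteinHeader(order=order, proteins=body[1], protein_type=body[2])
                if prot_labels and len(body) >= 3 + len(prot_labels):
                    vals = body[3 : 3 + len(prot_labels)]
                    if any(v.strip() for v in vals):
                        cur_prot.reporter_intensities = {
                            l: float(v) for l, v in zip(prot_labels, vals)
                        }
                report.protein_headers.append(cur_prot)
                cur_pep = None
            elif depth == 1:
                if cur_prot is None:
                    raise PlinkParseError("peptide row before any protein header", path, line_no)
                if len(body) < len(_PEPTIDE_HEADER) + 1:
                    raise PlinkParseError("short peptide header row", path, line_no)
                try:
                    cur_pep = PeptideHeader(
                        order=int(first),
                        peptide=body[1],
                        peptide_type=body[2],
                        linker=body[3],
                        peptide_mass=float(body[4]),
                        proteins=body[5],
                    )
                except ValueError as exc:
                    raise PlinkParseError(f"bad peptide row: {exc}", path, line_no)
                if cur_pep.peptide_type not in _PEPTIDE_TYPE_TO_LINK:
                    raise PlinkParseError(
                        f"unknown Peptide_Type {cur_pep.peptide_type!r}", path, line_no
                    )
                base = len(_PEPTIDE_HEADER) + 1
                if pep_labels and len(body) >= base + len(pep_labels):
                    vals = body[base : base + len(pep_labels)]
                    if any(v.strip() for v in vals):
                        cur_pep.reporter_intensities = {
                            l: float(v) for l, v in zip(pep_labels, vals)
                        }
                cur_prot.peptides.append(cur_pep)
            elif depth == 2:
                if cur_pep is None:
                    raise PlinkParseError("PSM row before any peptide header", path, line_no)
                if len(body) < len(_PSM_HEADER):
                    raise PlinkParseError("short PSM row", path, line_no)
                try:
                    psm = PsmRow(
                        order=int(first),
                        title=body[1],
                        charge=int(body[2]),
                        precursor_mass=float(body[3]),
                        score=float(body[4]),
                    )
                except ValueError as exc:
                    raise PlinkParseError(f"bad PSM row: {exc}", path, line_no)
                base = len(_PSM_HEADER)
                if psm_labels and len(body) >= base + len(psm_labels):
                    vals = body[base : base + len(psm_labels)]
                    if any(v.strip() for v in vals):
                        psm.reporter_intensities = {
                            l: float(v) for l, v in zip(psm_labels, vals)
                        }
                cur_pep.psms.append(psm)
            else:
                raise PlinkParseError(f"unexpected indentation depth {depth}", path, line_no)
    return report


def _report_labels(report: PlinkReport) -> List[str]:
    for psm in report.psms:
        if psm.reporter_intensities is not None:
            return list(psm.reporter_intensities.keys())
    return []


def write_plink_csv(report: PlinkReport, path: str | os.PathLike) -> None:
    """Write the hierarchy back to CSV, appending intensity columns at
    each level where they are present."""
    labels = _report_labels(report)
    int_cols = [f"Intensity_{l}" for l in labels]

    def _vals(d: Optional[Dict[str, float]]) -> List[str]:
        if not labels:
            return []
        if d is None:
            return [""] * len(labels)
        return [repr(d[l]) for l in labels]

    with open(os.fspath(path), "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PROTEIN_HEADER + int_cols)
        for prot in report.protein_headers:
            writer.writerow(
                [str(prot.order), prot.proteins, prot.protein_type]
                + _vals(prot.reporter_intensities)
            )
            for pep in prot.peptides:
                writer.writerow([""] + _PEPTIDE_HEADER + ["Proteins"] + int_cols)
                writer.writerow(
                    [
                        "",
                        str(pep.order),
                        pep.peptide,
                        pep.peptide_type,
                        pep.linker,
                        repr(pep.peptide_mass),
                        pep.proteins,
                    ]
                    + _vals(pep.reporter_intensities)
                )
                writer.writerow(["", ""] + _PSM_HEADER + int_cols)
                for psm in pep.psms:
                    writer.writerow(
                        [
                            "",
                            "",
                            str(psm.order),
                            psm.title,
                            str(psm.charge),
                            repr(psm.precursor_mass),
                            repr(psm.score),
                        ]
                        + _vals(psm.reporter_intensities)
                    )


def title_core_rule(pattern: str = r"^(.+?\.\d+)\.\d+\.(\d+)(?:\.\d+)?\.dta$") -> Callable[[str], str]:
    """Build a title-normalisation rule reducing both sides to
    ``file.scan.charge`` via a regex with two capture groups."""
    rx = re.compile(pattern)

    def rule(title: str) -> str:
        m = rx.match(title.strip())
        if not m:
            return title.strip()
        return ".".join(m.groups())

    return rule


def attach_reporters(
    report: PlinkReport,
    table: Sequence[ReporterRow],
    title_rule: Optional[Callable[[str], str]] = None,
) -> PlinkReport:
    """Attach reporter intensities to PSMs by spectrum title.

    The default matching rule is exact equality after stripping
    leading/trailing whitespace; pass a callable to normalise titles on
    both sides (e.g. :func:`title_core_rule`).  Unmatched PSMs get the
    ``no_quant`` flag and are counted on the report.
    """
    rule = title_rule or (lambda t: t.strip())
    index: Dict[str, ReporterRow] = {}
    for row in table:
        key = rule(row.spectrum_title)
        if key in index:
            raise ValueError(f"duplicate spectrum title in reporter table: {key!r}")
        index[key] = row

    n_no_quant = 0
    for psm in report.psms:
        row = index.get(rule(psm.title))
        if row is None:
            psm.no_quant = True
            psm.reporter_intensities = None
            n_no_quant += 1
        else:
            psm.no_quant = False
            psm.reporter_intensities = dict(row.intensities)
    report.n_no_quant = n_no_quant
    if n_no_quant:
        logger.info("attach_reporters: %d PSMs without a matching spectrum", n_no_quant)
    return report


def rollup(report: PlinkReport) -> PlinkReport:
    """Sum attached intensities channel-wise onto peptide and protein
    headers; no-quant PSMs contribute zero."""
    labels = _report_labels(report)
    for prot in report.protein_headers:
        prot_sum = {l: 0.0 for l in labels}
        for pep in prot.peptides:
            pep_sum = {l: 0.0 for l in labels}
            for psm in pep.psms:
                if psm.reporter_intensities is not None:
                    for l in labels:
                        pep_sum[l] += psm.reporter_intensities[l]
            pep.reporter_intensities = pep_sum
            for l in labels:
                prot_sum[l] += pep_sum[l]
        prot.reporter_intensities = prot_sum
    return report
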