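"""Fully synthetic, ground-truthed inputs for every pipeline stage.

Generates a small proteome, cross-link/loop-link/monolink identifications
in the hierarchical CSV dialect, MGF spectra with planted reporter ions,
a protein abundance matrix, mutation and disorder tables, toy structure
models, and truth tables against which every downstream stage can be
checked — all deterministic under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genostruct import MutationTable
from .linkmap import write_fasta
from .plink_io import PeptideHeader, PlinkReport, ProteinHeader, PsmRow, write_plink_csv
from .reporter_quant import TMTPRO_18PLEX
from .spectra_io import Ms2Spectrum, write_mgf
from .structure_overlay import DisorderRegion, StructureModel

__all__ = [
    "CrosslinkerSpec",
    "SimulationConfig",
    "SimulationBundle",
    "simulate",
    "toy_structure",
    "write_bundle",
    "default_replicate_map",
]

# Monoisotopic residue masses (Da), standard values.
_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406, "N": 114.04293,
    "D": 115.02694, "Q": 128.05858, "K": 128.09496, "E": 129.04259, "M": 131.04049,
    "H": 137.05891, "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
_WATER = 18.0105646863

_AMINO_ACIDS = list(_RESIDUE_MASS.keys())
# Lysines oversampled so every protein has plenty of linkable sites.
_AA_WEIGHTS = np.array([3.0 if aa == "K" else 1.0 for aa in _AMINO_ACIDS])
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()


@dataclass(frozen=True)
class CrosslinkerSpec:
    """Masses of the phosphonate cross-linker and fixed modifications."""

    linker_mass: float = 209.972
    monolink_hydrolyzed: float = 227.982
    monolink_amidated: float = 226.998
    reactive_residue: str = "K"  # plus protein N-terminus
    carbamidomethyl_c: float = 57.021464
    tmt_nterm: float = 304.207146

    def __post_init__(self) -> None:
        if self.linker_mass <= 0:
            raise ValueError("linker mass must be positive")
        if min(self.monolink_hydrolyzed, self.monolink_amidated) <= self.linker_mass:
            raise ValueError("monolink masses must exceed the linker mass")

    def peptide_mass(self, sequence: str) -> float:
        """Tryptic peptide mass incl. water, N-terminal label and Cys alkylation."""
        m = _WATER + self.tmt_nterm
        for aa in sequence:
            m += _RESIDUE_MASS[aa]
            if aa == "C":
                m += self.carbamidomethyl_c
        return m


def default_replicate_map(channels: Sequence[str], n_cell_lines: int = 14) -> Dict[str, str]:
    """Channel -> cell line map: first ``n_cell_lines`` channels get one
    cell line each, remaining channels replicate the first cell lines."""
    cells = [f"CL{i + 1:02d}" for i in range(n_cell_lines)]
    mapping = {}
    for i, ch in enumerate(channels):
        mapping[ch] = cells[i % n_cell_lines] if i < n_cell_lines else cells[i - n_cell_lines]
    return mapping


@dataclass
class SimulationConfig:
    n_proteins: int = 12
    protein_length_range: Tuple[int, int] = (150, 300)
    n_crosslinks: int = 40
    n_looplinks: int = 10
    n_monolinks: int = 5
    n_regular: int = 3
    n_shared: int = 0  # cross-links whose first peptide maps to two proteins
    inter_fraction: float = 0.1
    channels: Tuple[str, ...] = tuple(TMTPRO_18PLEX.labels)
    n_cell_lines: int = 14
    noise_sd_log2: float = 0.1
    pair_spread_log2: float = 0.7
    protein_spread_log2: float = 0.5
    base_intensity: float = 1e5
    max_csms_per_link: int = 3
    n_mgf_files: int = 2
    n_mutations: int = 20
    n_disorder_regions: int = 6
    planted_effects: Tuple[Tuple[int, str, float], ...] = ()  # (link index, cell line, log2 shift)
    linker: CrosslinkerSpec = field(default_factory=CrosslinkerSpec)
    seed: int = 0

    def replicate_map(self) -> Dict[str, str]:
        return default_replicate_map(self.channels, self.n_cell_lines)


@dataclass
class SimulationBundle:
    """In-memory fixture bundle plus ground truth for every stage."""

    config: SimulationConfig
    fasta: Dict[str, str]
    report: PlinkReport
    spectra: Dict[str, List[Ms2Spectrum]]  # mgf file name -> spectra
    protein_matrix: pd.DataFrame  # accession x channel, linear scale
    mutations: MutationTable
    gene_map: Dict[str, str]  # gene symbol -> accession
    disorder: List[DisorderRegion]
    models: Dict[str, StructureModel]
    replicate_map: Dict[str, str]
    truth_raw: pd.DataFrame  # residue pair x channel raw aggregated intensities
    truth_links: pd.DataFrame  # per generated link: key, type, sites, shared flag
    truth_reporters: Dict[str, Dict[str, float]]  # spectrum title -> channel intensities
    planted_events: List[Tuple[str, str, float]]  # (pair string, cell line, shift)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(_AMINO_ACIDS), size=length, p=_AA_WEIGHTS)
    return "".join(_AMINO_ACIDS[i] for i in idx)


def _lysine_positions(seq: str) -> List[int]:
    return [i + 1 for i, aa in enumerate(seq) if aa == "K"]


def _peptide_around(
    rng: np.random.Generator, seq: str, site: int
) -> Tuple[str, int]:
    """A peptide window covering 1-based ``site``; returns (peptide, link pos)."""
    left = int(rng.integers(3, 9))
    right = int(rng.integers(3, 9))
    start = max(0, site - 1 - left)  # 0-based
    end = min(len(seq), site + right)
    return seq[start:end], site - start


def toy_structure(
    length: int,
    fold: str = "extended",
    seed: int = 0,
    accession: str = "TOY",
    plddt: Optional[Sequence[float]] = None,
) -> StructureModel:
    """Deterministic toy CA trace.

    ``extended`` places CA atoms on a straight line at 3.8 A per residue
    (distance between residues i and j is exactly 3.8 x |i - j|);
    ``compact`` scatters them inside a 30 A-radius sphere with a minimum
    1.5 A separation, so no pairwise distance exceeds 60 A.
    """
    if length < 2:
        raise ValueError("toy structure needs at least 2 residues")
    rng = np.random.default_rng(seed)
    if plddt is None:
        plddt_values = [float(p) for p in rng.uniform(50.0, 95.0, size=length)]
    else:
        plddt_values = [float(p) for p in plddt]
        if len(plddt_values) != length:
            raise ValueError("plddt length mismatch")

    coords: List[Tuple[float, float, float]] = []
    if fold == "extended":
        coords = [(3.8 * i, 0.0, 0.0) for i in range(length)]
    elif fold == "compact":
        while len(coords) < length:
            candidate = rng.uniform(-30.0, 30.0, size=3)
            if float(np.linalg.norm(candidate)) > 30.0:
                continue
            if coords and min(
                float(np.linalg.norm(candidate - np.array(c))) for c in coords
            ) < 1.5:
                continue
            coords.append((float(candidate[0]), float(candidate[1]), float(candidate[2])))
    else:
        raise ValueError(f"unknown fold {fold!r}")
    residues = [
        (i + 1, coords[i], plddt_values[i]) for i in range(length)
    ]
    return StructureModel(accession=accession, residues=residues)


def write_structure_pdb(model: StructureModel, path: str | os.PathLike) -> None:
    """Write a CA-only PDB with pLDDT in the B-factor column."""
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        for serial, (idx, (x, y, z), plddt) in enumerate(model.residues, start=1):
            fh.write(
                f"ATOM  {serial:5d}  CA  ALA A{idx:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{plddt:6.2f}           C\n"
            )
        fh.write("END\n")


def simulate(config: SimulationConfig) -> SimulationBundle:
    """Generate a full synthetic bundle; identical seeds give identical bundles."""
    rng = np.random.default_rng(config.seed)
    linker = config.linker
    channels = list(config.channels)
    replicate_map = config.replicate_map()
    cell_lines = sorted(set(replicate_map.values()))

    # --- proteome ---------------------------------------------------------
    accessions = [f"PROT{i + 1:03d}" for i in range(config.n_proteins)]
    lo, hi = config.protein_length_range
    fasta: Dict[str, str] = {}
    for acc in accessions:
        length = int(rng.integers(lo, hi + 1))
        seq = _random_protein(rng, length)
        while len(_lysine_positions(seq)) < 12:  # guarantee linkable sites
            seq = _random_protein(rng, length)
        fasta[acc] = seq

    # protein log2 abundance per cell line (shared by protein matrix and links)
    protein_log2 = {
        acc: {cl: float(rng.normal(0.0, config.protein_spread_log2)) for cl in cell_lines}
        for acc in accessions
    }

    # --- links ------------------------------------------------------------
    links: List[dict] = []  # per link: type, acc/site pairs, peptides, shared

    for li in range(config.n_crosslinks):
        is_inter = bool(rng.random() < config.inter_fraction)
        acc_a = accessions[int(rng.integers(len(accessions)))]
        if is_inter:
            others = [a for a in accessions if a != acc_a]
            acc_b = others[int(rng.integers(len(others)))]
        else:
            acc_b = acc_a
        ks_a = _lysine_positions(fasta[acc_a])
        ks_b = _lysine_positions(fasta[acc_b])
        site_a = int(ks_a[int(rng.integers(len(ks_a)))])
        if acc_a == acc_b:
            choices = [k for k in ks_b if k != site_a]
            site_b = int(choices[int(rng.integers(len(choices)))])
        else:
            site_b = int(ks_b[int(rng.integers(len(ks_b)))])
        pep_a, pos_a = _peptide_around(rng, fasta[acc_a], site_a)
        pep_b, pos_b = _peptide_around(rng, fasta[acc_b], site_b)
        links.append(
            dict(
                link_type="cross",
                acc_a=acc_a, site_a=site_a, pep_a=pep_a, pos_a=pos_a,
                acc_b=acc_b, site_b=site_b, pep_b=pep_b, pos_b=pos_b,
                shared=False,
            )
        )

    # shared-peptide cross-links: duplicate peptide A at the end of another protein
    for li in range(config.n_shared):
        link = links[li % max(1, len(links))]
        host = [a for a in accessions if a not in (link["acc_a"], link["acc_b"])]
        acc_extra = host[int(rng.integers(len(host)))]
        offset = len(fasta[acc_extra])
        fasta[acc_extra] = fasta[acc_extra] + link["pep_a"]
        link["shared"] = True
        link["extra_mapping"] = (acc_extra, offset + link["pos_a"])

    for _ in range(config.n_looplinks):
        acc = accessions[int(rng.integers(len(accessions)))]
        ks = _lysine_positions(fasta[acc])
        i = int(rng.integers(len(ks) - 1))
        span = int(rng.integers(1, 12))
        j = min(len(ks) - 1, i + 1)
        # pick a partner site at a target sequence distance when possible
        candidates = [k for k in ks if 1 <= abs(k - ks[i]) <= span + 6]
        site_a = ks[i]
        site_b = int(candidates[int(rng.integers(len(candidates)))]) if candidates else ks[j]
        lo_s, hi_s = min(site_a, site_b), max(site_a, site_b)
        start = max(0, lo_s - 1 - int(rng.integers(2, 6)))
        end = min(len(fasta[acc]), hi_s + int(rng.integers(2, 6)))
        pep = fasta[acc][start:end]
        links.append(
            dict(
                link_type="loop",
                acc_a=acc, site_a=lo_s, pep_a=pep, pos_a=lo_s - start,
                acc_b=acc, site_b=hi_s, pep_b="", pos_b=hi_s - start,
                shared=False,
            )
        )

    for _ in range(config.n_monolinks):
        acc = accessions[int(rng.integers(len(accessions)))]
        ks = _lysine_positions(fasta[acc])
        site = int(ks[int(rng.integers(len(ks)))])
        pep, pos = _peptide_around(rng, fasta[acc], site)
        links.append(
            dict(
                link_type="mono",
                acc_a=acc, site_a=site, pep_a=pep, pos_a=pos,
                acc_b="", site_b=0, pep_b="", pos_b=0, shared=False,
            )
        )

    for _ in range(config.n_regular):
        acc = accessions[int(rng.integers(len(accessions)))]
        start = int(rng.integers(0, len(fasta[acc]) - 12))
        pep = fasta[acc][start : start + int(rng.integers(6, 12))]
        links.append(
            dict(
                link_type="regular",
                acc_a=acc, site_a=0, pep_a=pep, pos_a=0,
                acc_b="", site_b=0, pep_b="", pos_b=0, shared=False,
            )
        )

    # validate planted effects up front
    planted: Dict[Tuple[int, str], float] = {}
    for link_index, cell_line, shift in config.planted_effects:
        if not (0 <= link_index < len(links)) or links[link_index]["link_type"] != "cross":
            raise ValueError(f"planted effect references invalid cross-link index {link_index}")
        if cell_line not in cell_lines:
            raise ValueError(f"planted effect references unknown cell line {cell_line!r}")
        planted[(link_index, cell_line)] = shift

    # --- intensities and spectra -----------------------------------------
    mgf_names = [f"run{i + 1}.mgf" for i in range(config.n_mgf_files)]
    spectra: Dict[str, List[Ms2Spectrum]] = {name: [] for name in mgf_names}
    scan_counter = {name: 0 for name in mgf_names}
    truth_reporters: Dict[str, Dict[str, float]] = {}

    prot_rows = []
    ref_mzs = dict(zip(TMTPRO_18PLEX.labels, TMTPRO_18PLEX.ref_mzs))

    for idx, link in enumerate(links):
        n_csms = int(rng.integers(1, config.max_csms_per_link + 1))
        link["n_csms"] = n_csms
        pair_offset = float(rng.normal(0.0, config.pair_spread_log2))
        base_log2 = float(np.log2(config.base_intensity))
        csm_intensities: List[Dict[str, float]] = [dict() for _ in range(n_csms)]
        fractions = rng.dirichlet(np.ones(n_csms) * 5.0)
        for ch in channels:
            cl = replicate_map[ch]
            level = base_log2 + pair_offset + config.noise_sd_log2 * float(rng.standard_normal())
            if link["link_type"] in ("cross", "loop") and link["acc_a"]:
                level += protein_log2[link["acc_a"]][cl]
            level += planted.get((idx, cl), 0.0)
            total = float(2.0 ** level)
            for ci in range(n_csms):
                csm_intensities[ci][ch] = round(total * float(fractions[ci]), 4)
        link["csm_intensities"] = csm_intensities

        titles = []
        for ci in range(n_csms):
            mgf = mgf_names[int(rng.integers(len(mgf_names)))]
            scan_counter[mgf] += 1
            scan = 1000 + 7 * scan_counter[mgf] + (mgf_names.index(mgf) * 50000)
            charge = int(rng.integers(3, 6))
            title = f"{mgf[:-4]}.{scan}.{scan}.{charge}.dta"
            titles.append(title)
            peaks = [(ref_mzs[ch], csm_intensities[ci][ch]) for ch in channels]
            # high-mass decoy peaks well above the reporter region
            for _ in range(int(rng.integers(5, 15))):
                peaks.append(
                    (float(rng.uniform(200.0, 1500.0)), round(float(rng.uniform(10, 5000)), 4))
                )
            if link["link_type"] == "cross":
                prec = (
                    linker.peptide_mass(link["pep_a"])
                    + linker.peptide_mass(link["pep_b"])
                    + linker.linker_mass
                )
            elif link["link_type"] == "loop":
                prec = linker.peptide_mass(link["pep_a"]) + linker.linker_mass
            elif link["link_type"] == "mono":
                prec = linker.peptide_mass(link["pep_a"]) + linker.monolink_hydrolyzed
            else:
                prec = linker.peptide_mass(link["pep_a"])
            link.setdefault("precursor_mass", prec)
            spectra[mgf].append(
                Ms2Spectrum(
                    source_file=mgf,
                    title=title,
                    precursor_mz=round(prec / charge + 1.00728, 5),
                    precursor_charge=charge,
                    peaks=peaks,
                )
            )
            truth_reporters[title] = dict(csm_intensities[ci])
        link["titles"] = titles

    # --- hierarchical report ---------------------------------------------
    protein_headers: List[ProteinHeader] = []
    for idx, link in enumerate(links):
        lt = link["link_type"]
        if lt == "cross":
            pep_str = f"{link['pep_a']}({link['pos_a']})-{link['pep_b']}({link['pos_b']})"
            prot_str = f"{link['acc_a']} ({link['site_a']})-{link['acc_b']} ({link['site_b']})/"
            if link["shared"]:
                extra_acc, extra_site = link["extra_mapping"]
                prot_str += f"{extra_acc} ({extra_site})-{link['acc_b']} ({link['site_b']})/"
            ptype = "Intra-Protein" if link["acc_a"] == link["acc_b"] else "Inter-Protein"
            peptide_type = "Cross-Linked"
        elif lt == "loop":
            pep_str = f"{link['pep_a']}({link['pos_a']})({link['pos_b']})"
            prot_str = f"{link['acc_a']} ({link['site_a']})({link['site_b']})/"
            ptype = "Intra-Protein"
            peptide_type = "Loop-Linked"
        elif lt == "mono":
            pep_str = f"{link['pep_a']}({link['pos_a']})"
            prot_str = f"{link['acc_a']} ({link['site_a']})/"
            ptype = "Mono"
            peptide_type = "Mono-Linked"
        else:
            pep_str = link["pep_a"]
            prot_str = f"{link['acc_a']}/"
            ptype = "Common"
            peptide_type = "Common"

        pep = PeptideHeader(
            order=1,
            peptide=pep_str,
            peptide_type=peptide_type,
            linker="PhoX" if lt != "regular" else "",
            peptide_mass=round(link["precursor_mass"], 5),
            proteins=prot_str,
        )
        for order, title in enumerate(link["titles"], start=1):
            pep.psms.append(
                PsmRow(
                    order=order,
                    title=title,
                    charge=3,
                    precursor_mass=round(link["precursor_mass"], 5),
                    score=float(f"{rng.uniform(1e-9, 1e-3):.6e}"),
                )
            )
        protein_headers.append(
            ProteinHeader(order=idx + 1, proteins=prot_str, protein_type=ptype, peptides=[pep])
        )
    report = PlinkReport(protein_headers=protein_headers, provenance="simulated")

    # --- truth tables -----------------------------------------------------
    from .linkmap import ResiduePairKey  # local import to avoid cycle at module load

    truth_rows: Dict[str, np.ndarray] = {}
    link_records = []
    planted_events: List[Tuple[str, str, float]] = []
    for idx, link in enumerate(links):
        lt = link["link_type"]
        key_str = ""
        included = False
        if lt == "cross" and not link["shared"]:
            key = ResiduePairKey.make(link["acc_a"], link["site_a"], link["acc_b"], link["site_b"])
            key_str = key.as_string()
            included = True
        elif lt == "loop" and abs(link["site_b"] - link["site_a"]) >= 5:
            key = ResiduePairKey.make(link["acc_a"], link["site_a"], link["acc_b"], link["site_b"])
            key_str = key.as_string()
            included = True
        elif lt in ("cross", "loop"):
            key = ResiduePairKey.make(link["acc_a"], link["site_a"], link["acc_b"], link["site_b"])
            key_str = key.as_string()
        if included:
            vec = np.zeros(len(channels))
            for csm in link["csm_intensities"]:
                vec += np.array([csm[ch] for ch in channels])
            if key_str in truth_rows:
                truth_rows[key_str] += vec
            else:
                truth_rows[key_str] = vec
        link_records.append(
            dict(
                link_index=idx,
                link_type=lt,
                residue_pair=key_str,
                shared=link["shared"],
                n_csms=link["n_csms"],
                loop_distance=(abs(link["site_b"] - link["site_a"]) if lt == "loop" else np.nan),
            )
        )
        for (li, cl), shift in planted.items():
            if li == idx and key_str:
                planted_events.append((key_str, cl, shift))

    order = sorted(truth_rows)
    truth_raw = pd.DataFrame(
        [truth_rows[k] for k in order], index=order, columns=channels, dtype=float
    )
    truth_links = pd.DataFrame(link_records)

    # --- protein abundance matrix ----------------------------------------
    for acc in accessions:
        row = {}
        for ch in channels:
            cl = replicate_map[ch]
            level = (
                np.log2(config.base_intensity)
                + protein_log2[acc][cl]
                + config.noise_sd_log2 * float(rng.standard_normal())
            )
            row[ch] = round(float(2.0 ** level), 4)
        prot_rows.append(row)
    protein_matrix = pd.DataFrame(prot_rows, index=accessions, columns=channels, dtype=float)

    # --- mutations, gene map, disorder, models ---------------------------
    gene_map = {f"G{acc}": acc for acc in accessions}
    genes = list(gene_map.keys())
    entries: List[Tuple[str, str, int]] = []
    # mutations guaranteed inside each planted link's interval, in its cell line
    for (li, cl), _shift in sorted(planted.items()):
        link = links[li]
        lo_s, hi_s = sorted((link["site_a"], link["site_b"]))
        pos = int(rng.integers(lo_s, hi_s + 1))
        entries.append((f"G{link['acc_a']}", cl, pos))
    for _ in range(config.n_mutations):
        gene = genes[int(rng.integers(len(genes)))]
        cl = cell_lines[int(rng.integers(len(cell_lines)))]
        pos = int(rng.integers(1, len(fasta[gene_map[gene]]) + 1))
        entries.append((gene, cl, pos))
    mutations = MutationTable(entries=entries)

    disorder: List[DisorderRegion] = []
    for _ in range(config.n_disorder_regions):
        acc = accessions[int(rng.integers(len(accessions)))]
        start = int(rng.integers(1, max(2, len(fasta[acc]) - 30)))
        end = min(len(fasta[acc]), start + int(rng.integers(10, 40)))
        disorder.append(DisorderRegion(accession=acc, start=start, end=end))

    models = {
        acc: toy_structure(
            len(fasta[acc]),
            fold="compact",
            seed=config.seed * 1000 + i,
            accession=acc,
        )
        for i, acc in enumerate(accessions)
    }

    return SimulationBundle(
        config=config,
        fasta=fasta,
        report=report,
        spectra=spectra,
        protein_matrix=protein_matrix,
        mutations=mutations,
        gene_map=gene_map,
        disorder=disorder,
        models=models,
        replicate_map=replicate_map,
        truth_raw=truth_raw,
        truth_links=truth_links,
        truth_reporters=truth_reporters,
        planted_events=planted_events,
    )


def write_bundle(bundle: SimulationBundle, out_dir: str | os.PathLike) -> Dict[str, str]:
    """Write every bundle component under ``out_dir``; returns the path map.

    Output is byte-identical for identical bundles.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    mgf_dir = os.path.join(out_dir, "mgf")
    model_dir = os.path.join(out_dir, "models")
    os.makedirs(mgf_dir, exist_ok=True)
    os.makedirs(model_dir, exist_ok=True)

    paths = {
        "fasta": os.path.join(out_dir, "proteome.fasta"),
        "plink": os.path.join(out_dir, "plink_results.csv"),
        "mgf_dir": mgf_dir,
        "protein_matrix": os.path.join(out_dir, "protein_matrix.tsv"),
        "mutations": os.path.join(out_dir, "mutations.tsv"),
        "gene_map": os.path.join(out_dir, "gene_map.tsv"),
        "disorder": os.path.join(out_dir, "disorder.tsv"),
        "model_dir": model_dir,
        "replicate_map": os.path.join(out_dir, "replicate_map.tsv"),
        "truth_raw": os.path.join(out_dir, "truth_raw.tsv"),
    }

    write_fasta(bundle.fasta, paths["fasta"])
    write_plink_csv(bundle.report, paths["plink"])
    for name, specs in bundle.spectra.items():
        write_mgf(specs, os.path.join(mgf_dir, name))
    bundle.protein_matrix.to_csv(paths["protein_matrix"], sep="\t", index_label="accession")
    pd.DataFrame(
        bundle.mutations.entries, columns=["gene", "cell_line", "position"]
    ).to_csv(paths["mutations"], sep="\t", index=False)
    with open(paths["gene_map"], "w", encoding="utf-8") as fh:
        fh.write("gene\taccession\n")
        for gene, acc in bundle.gene_map.items():
            fh.write(f"{gene}\t{acc}\n")
    pd.DataFrame(
        [(r.accession, r.start, r.end) for r in bundle.disorder],
        columns=["accession", "start", "end"],
    ).to_csv(paths["disorder"], sep="\t", index=False)
    for acc, model in bundle.models.items():
        write_structure_pdb(model, os.path.join(model_dir, f"AF-{acc}-F1-model_v4.pdb"))
    with open(paths["replicate_map"], "w", encoding="utf-8") as fh:
        fh.write("channel\tcell_line\n")
        for ch, cl in bundle.replicate_map.items():
            fh.write(f"{ch}\t{cl}\n")
    bundle.truth_raw.to_csv(paths["truth_raw"], sep="\t", index_label="residue_pair")
    return paths
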