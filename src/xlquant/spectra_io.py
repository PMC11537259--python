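"""Reading and writing Mascot Generic Format (MGF) MS2 spectra.

Only the subset of MGF needed for reporter-ion work is supported:
``BEGIN IONS``/``END IONS`` blocks with ``TITLE``, ``PEPMASS`` and
``CHARGE`` keys plus whitespace-separated peak lines.  Titles are kept
verbatim because downstream spectrum-to-identification matching relies
on exact string identity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple

__all__ = ["Ms2Spectrum", "MgfParseError", "read_mgf", "write_mgf"]


class MgfParseError(ValueError):
    """Raised for malformed MGF content; carries the offending line number."""

    def __init__(self, message: str, path: str, line_no: int):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


@dataclass
class Ms2Spectrum:
    """One MS2 scan: title, precursor information and its peak list.

    Peaks are ``(mz, intensity)`` pairs sorted ascending by m/z; the
    sort happens at construction so tolerance searches can assume order.
    """

    source_file: str
    title: str
    precursor_mz: float
    peaks: List[Tuple[float, float]] = field(default_factory=list)
    precursor_charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.title:
            raise ValueError("spectrum title must be non-empty")
        for _, inten in self.peaks:
            if inten < 0:
                raise ValueError(f"negative peak intensity in {self.title!r}")
        self.peaks = sorted(self.peaks, key=lambda p: p[0])

    @property
    def mzs(self) -> List[float]:
        return [p[0] for p in self.peaks]

    @property
    def intensities(self) -> List[float]:
        return [p[1] for p in self.peaks]


def _parse_charge(token: str) -> int:
    token = token.strip()
    if token.endswith("+"):
        token = token[:-1]
    elif token.endswith("-"):
        token = "-" + token[:-1]
    return int(token)


def read_mgf(path: str | os.PathLike) -> List[Ms2Spectrum]:
    """Parse an MGF file into a list of :class:`Ms2Spectrum`.

    Block order is preserved; the number of returned spectra equals the
    number of ``BEGIN IONS`` lines.  An unterminated block or a
    non-numeric peak line raises :class:`MgfParseError` naming the line.
    """
    path = os.fspath(path)
    source = os.path.basename(path)
    spectra: List[Ms2Spectrum] = []

    in_block = False
    block_start = 0
    title: Optional[str] = None
    pepmass: Optional[float] = None
    charge: Optional[int] = None
    peaks: List[Tuple[float, float]] = []

    with open(path, "r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if stripped == "BEGIN IONS":
                if in_block:
                    raise MgfParseError("nested BEGIN IONS", path, line_no)
                in_block = True
                block_start = line_no
                title, pepmass, charge, peaks = None, None, None, []
            elif stripped == "END IONS":
                if not in_block:
                    raise MgfParseError("END IONS without BEGIN IONS", path, line_no)
                if title is None:
                    raise MgfParseError("block missing TITLE", path, block_start)
                if pepmass is None:
                    raise MgfParseError("block missing PEPMASS", path, block_start)
                spectra.append(
                    Ms2Spectrum(
                        source_file=source,
                        title=title,
                        precursor_mz=pepmass,
                        precursor_charge=charge,
                        peaks=peaks,
                    )
                )
                in_block = False
            elif in_block:
                if "=" in line and not line.split("=", 1)[0].strip().replace(".", "").replace("-", "").isdigit():
                    key, value = line.split("=", 1)
                    key = key.strip().upper()
                    if key == "TITLE":
                        title = value  # verbatim, including inner whitespace
                    elif key == "PEPMASS":
                        try:
                            pepmass = float(value.split()[0])
                        except (ValueError, IndexError):
                            raise MgfParseError(f"bad PEPMASS {value!r}", path, line_no)
                    elif key == "CHARGE":
                        try:
                            charge = _parse_charge(value)
                        except ValueError:
                            raise MgfParseError(f"bad CHARGE {value!r}", path, line_no)
                    # other KEY=VALUE lines (RTINSECONDS, SCANS, ...) ignored
                else:
                    fields = stripped.split()
                    if len(fields) < 2:
                        raise MgfParseError(f"bad peak line {stripped!r}", path, line_no)
                    try:
                        mz, inten = float(fields[0]), float(fields[1])
                    except ValueError:
                        raise MgfParseError(f"non-numeric peak line {stripped!r}", path, line_no)
                    peaks.append((mz, inten))
            # content outside blocks is ignored

    if in_block:
        raise MgfParseError("unterminated BEGIN IONS block", path, block_start)
    return spectra


def write_mgf(spectra: Sequence[Ms2Spectrum], path: str | os.PathLike) -> None:
    """Write spectra as MGF; ``read_mgf`` round-trips titles, precursor
    fields and peaks to well below 1e-6 m/z (values use repr precision)."""
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec.title}\n")
            fh.write(f"PEPMASS={spec.precursor_mz!r}\n")
            if spec.precursor_charge is not None:
                sign = "+" if spec.precursor_charge >= 0 else "-"
                fh.write(f"CHARGE={abs(spec.precursor_charge)}{sign}\n")
            for mz, inten in spec.peaks:
                fh.write(f"{mz!r} {inten!r}\n")
            fh.write("END IONS\n")


def iter_mgf_dir(directory: str | os.PathLike) -> Iterator[Tuple[str, List[Ms2Spectrum]]]:
    """Yield ``(file name, spectra)`` for every ``*.mgf`` in a directory,
    sorted by file name for deterministic downstream ordering."""
    directory = os.fspath(directory)
    names = sorted(n for n in os.listdir(directory) if n.lower().endswith(".mgf"))
    for name in names:
        yield name, read_mgf(os.path.join(directory, name))
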