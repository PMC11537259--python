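"""Reporter-ion extraction from MS2 spectra.

Matches low-mass peaks against a reference table of isobaric reporter
m/z values within a ppm tolerance, sums multiple in-tolerance peaks per
channel, and writes a tab-delimited extraction table with one row per
spectrum.  An optional (off by default) channel-total normalisation is
provided; it is unsuitable for fractionated data because it assumes
equal total signal per channel.
"""

from __future__ import annotations

import bisect
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .spectra_io import Ms2Spectrum, iter_mgf_dir

__all__ = [
    "ReporterReference",
    "ReporterRow",
    "TMTPRO_18PLEX",
    "match_reporters",
    "extract_table",
    "write_reporter_table",
    "read_reporter_table",
    "normalize_channel_totals",
]

# Monoisotopic reporter-ion m/z values derived from the published TMTpro
# reporter elemental compositions.  Editable: any plex can be supplied
# via ReporterReference.from_pairs or a two-column file.
_TMTPRO_18PLEX_MZ: List[Tuple[str, float]] = [
    ("126", 126.127726),
    ("127N", 127.124761),
    ("127C", 127.131081),
    ("128N", 128.128116),
    ("128C", 128.134436),
    ("129N", 129.131471),
    ("129C", 129.137790),
    ("130N", 130.134825),
    ("130C", 130.141145),
    ("131N", 131.138180),
    ("131C", 131.144500),
    ("132N", 132.141535),
    ("132C", 132.147855),
    ("133N", 133.144890),
    ("133C", 133.151210),
    ("134N", 134.148245),
    ("134C", 134.154565),
    ("135N", 135.151590),
]


@dataclass(frozen=True)
class ReporterReference:
    """Ordered channel-label → reference-m/z table for one plex."""

    channels: Tuple[Tuple[str, float], ...]
    plex_name: str = "custom"

    def __post_init__(self) -> None:
        labels = [c[0] for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        mzs = [c[1] for c in self.channels]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("reference m/z values must be strictly increasing")

    @property
    def labels(self) -> List[str]:
        return [c[0] for c in self.channels]

    @property
    def ref_mzs(self) -> List[float]:
        return [c[1] for c in self.channels]

    def check_tolerance(self, tol_ppm: float) -> None:
        """Warn when adjacent channels are closer than twice the
        tolerance window — overlapping windows merge distinct reporters."""
        for (la, ma), (lb, mb) in zip(self.channels, self.channels[1:]):
            width = (ma + mb) * tol_ppm * 1e-6  # tol window of each, combined
            if (mb - ma) <= width:
                warnings.warn(
                    f"channels {la} and {lb} are {mb - ma:.5f} Th apart, closer "
                    f"than twice the {tol_ppm} ppm tolerance; peaks may overlap",
                    UserWarning,
                    stacklevel=3,
                )

    @classmethod
    def from_pairs(cls, pairs: Sequence[Tuple[str, float]], plex_name: str = "custom") -> "ReporterReference":
        return cls(channels=tuple((str(l), float(m)) for l, m in pairs), plex_name=plex_name)

    @classmethod
    def from_file(cls, path: str | os.PathLike, plex_name: Optional[str] = None) -> "ReporterReference":
        """Read a two-column (label, m/z) whitespace/tab-delimited file."""
        pairs = []
        with open(os.fspath(path), "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                label, mz = line.split()[:2]
                pairs.append((label, float(mz)))
        return cls.from_pairs(pairs, plex_name or os.path.basename(os.fspath(path)))


TMTPRO_18PLEX = ReporterReference.from_pairs(_TMTPRO_18PLEX_MZ, plex_name="tmtpro18")


@dataclass
class ReporterRow:
    """Per-spectrum reporter intensities and matched-peak mass deltas.

    Unmatched channels carry intensity 0 and ``None`` delta; for a
    multi-peak match the delta reports the most intense matched peak.
    """

    mgf_file: str
    spectrum_title: str
    intensities: Dict[str, float] = field(default_factory=dict)
    abs_delta_mz: Dict[str, Optional[float]] = field(default_factory=dict)
    normalized: Optional[Dict[str, float]] = None
    scaled: Optional[Dict[str, float]] = None


def match_reporters(
    spectrum: Ms2Spectrum,
    ref: ReporterReference = TMTPRO_18PLEX,
    tol_ppm: float = 15.0,
) -> ReporterRow:
    """Match reporter channels in one spectrum within ``tol_ppm``.

    A peak matches channel ``c`` when ``|mz - ref_mz| / ref_mz * 1e6 <=
    tol_ppm`` (boundary inclusive).  Multiple peaks matching one channel
    are summed.  A peak falling inside the window of more than one
    channel (possible only at wide tolerances) is assigned to the
    nearest channel only.  Only the low-mass region up to
    ``max(ref_mz) + 1`` Th is scanned.
    """
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    if tol_ppm > 20:
        warnings.warn(
            f"tolerance {tol_ppm} ppm exceeds 20 ppm and is not recommended: "
            "reporter windows may overlap",
            UserWarning,
            stacklevel=2,
        )
    ref.check_tolerance(tol_ppm)

    mzs = spectrum.mzs
    intens = spectrum.intensities
    upper_bound = max(ref.ref_mzs) + 1.0
    n_low = bisect.bisect_right(mzs, upper_bound)

    # peak index -> (channel index, |delta|) for the nearest in-tolerance channel
    assignment: Dict[int, Tuple[int, float]] = {}
    for ci, ref_mz in enumerate(ref.ref_mzs):
        # multiplicative bounds so a peak exactly at ref*(1 +/- tol*1e-6) matches
        lo = bisect.bisect_left(mzs, ref_mz * (1.0 - tol_ppm * 1e-6), 0, n_low)
        hi = bisect.bisect_right(mzs, ref_mz * (1.0 + tol_ppm * 1e-6), 0, n_low)
        for pi in range(lo, hi):
            delta = abs(mzs[pi] - ref_mz)
            if pi not in assignment or delta < assignment[pi][1]:
                assignment[pi] = (ci, delta)

    sums = [0.0] * len(ref.channels)
    best: List[Optional[Tuple[float, float]]] = [None] * len(ref.channels)  # (intensity, delta)
    for pi, (ci, delta) in assignment.items():
        sums[ci] += intens[pi]
        if best[ci] is None or intens[pi] > best[ci][0]:
            best[ci] = (intens[pi], delta)

    intensities = {label: sums[ci] for ci, label in enumerate(ref.labels)}
    deltas = {
        label: (best[ci][1] if best[ci] is not None else None)
        for ci, label in enumerate(ref.labels)
    }
    return ReporterRow(
        mgf_file=spectrum.source_file,
        spectrum_title=spectrum.title,
        intensities=intensities,
        abs_delta_mz=deltas,
    )


def extract_table(
    mgf_dir: str | os.PathLike,
    ref: ReporterReference = TMTPRO_18PLEX,
    tol_ppm: float = 15.0,
) -> List[ReporterRow]:
    """Extract reporter rows for every spectrum of every MGF in a directory.

    Rows are ordered by file name, then by spectrum order within each
    file, so output is deterministic.
    """
    mgf_dir = os.fspath(mgf_dir)
    rows: List[ReporterRow] = []
    n_files = 0
    for name, spectra in iter_mgf_dir(mgf_dir):
        n_files += 1
        for spec in spectra:
            rows.append(match_reporters(spec, ref, tol_ppm))
    if n_files == 0:
        raise FileNotFoundError(f"no MGF files found in {mgf_dir!r}")
    return rows


def _table_header(labels: Sequence[str], normalized: bool) -> List[str]:
    cols = ["mgf_file", "spectrum_title"]
    cols += [f"intensity_{l}" for l in labels]
    cols += [f"abs_delta_mz_{l}" for l in labels]
    if normalized:
        cols += [f"normalized_{l}" for l in labels]
        cols += [f"scaled_{l}" for l in labels]
    return cols


def write_reporter_table(rows: Sequence[ReporterRow], path: str | os.PathLike) -> None:
    """Write the extraction table as UTF-8 TSV, one row per spectrum."""
    if not rows:
        raise ValueError("no rows to write")
    labels = list(rows[0].intensities.keys())
    normalized = rows[0].normalized is not None
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        fh.write("\t".join(_table_header(labels, normalized)) + "\n")
        for row in rows:
            cells = [row.mgf_file, row.spectrum_title]
            cells += [repr(row.intensities[l]) for l in labels]
            cells += [
                "" if row.abs_delta_mz[l] is None else repr(row.abs_delta_mz[l])
                for l in labels
            ]
            if normalized:
                cells += [repr(row.normalized[l]) for l in labels]
                cells += [repr(row.scaled[l]) for l in labels]
            fh.write("\t".join(cells) + "\n")


def read_reporter_table(path: str | os.PathLike) -> List[ReporterRow]:
    """Read a table written by :func:`write_reporter_table`."""
    rows: List[ReporterRow] = []
    with open(os.fspath(path), "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = [c[len("intensity_"):] for c in header if c.startswith("intensity_")]
        has_norm = any(c.startswith("normalized_") for c in header)
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            rec = dict(zip(header, cells))
            row = ReporterRow(
                mgf_file=rec["mgf_file"],
                spectrum_title=rec["spectrum_title"],
                intensities={l: float(rec[f"intensity_{l}"]) for l in labels},
                abs_delta_mz={
                    l: (float(rec[f"abs_delta_mz_{l}"]) if rec[f"abs_delta_mz_{l}"] else None)
                    for l in labels
                },
            )
            if has_norm:
                row.normalized = {l: float(rec[f"normalized_{l}"]) for l in labels}
                row.scaled = {l: float(rec[f"scaled_{l}"]) for l in labels}
            rows.append(row)
    return rows


def normalize_channel_totals(rows: Sequence[ReporterRow]) -> List[ReporterRow]:
    """Equalise channel totals (beta; OFF by default in the CLI).

    Per-channel factor ``f_c = total_c / max_c(total_c)``; normalised
    value is ``raw / f_c`` so every channel total afterwards equals the
    pre-normalisation maximum.  Scaled values divide each normalised row
    by its row mean, putting spectra on a common relative scale.
    Channels with zero total pass through unchanged with a warning.
    Raw columns are retained; normalised/scaled columns are appended.
    """
    if not rows:
        raise ValueError("no rows to normalize")
    labels = list(rows[0].intensities.keys())
    totals = {l: sum(r.intensities[l] for r in rows) for l in labels}
    max_total = max(totals.values())
    if max_total <= 0:
        raise ValueError("all channel totals are zero; cannot normalize")

    factors: Dict[str, float] = {}
    for l in labels:
        if totals[l] == 0:
            warnings.warn(
                f"channel {l} has zero total intensity; left unnormalized",
                UserWarning,
                stacklevel=2,
            )
            factors[l] = 1.0
        else:
            factors[l] = totals[l] / max_total

    out: List[ReporterRow] = []
    for r in rows:
        normalized = {l: r.intensities[l] / factors[l] for l in labels}
        row_mean = sum(normalized.values()) / len(labels)
        if row_mean > 0:
            scaled = {l: normalized[l] / row_mean for l in labels}
        else:
            scaled = {l: 0.0 for l in labels}
        out.append(
            ReporterRow(
                mgf_file=r.mgf_file,
                spectrum_title=r.spectrum_title,
                intensities=dict(r.intensities),
                abs_delta_mz=dict(r.abs_delta_mz),
                normalized=normalized,
                scaled=scaled,
            )
        )
    return out
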