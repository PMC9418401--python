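"""CSV readers/writers and configuration for all package interfaces.

All files are comma-separated UTF-8 with ``#`` comment lines and period
decimal separators. Formats:

* TIA vector: header ``region,value``; optional ``# phantom: CE|ICRP`` and
  ``# units: ...`` comment lines.
* Blood distribution: header ``region,fraction_of_total_blood``.
* Emission spectrum: header ``etype,energy_MeV,yield``.
* SAF matrix (long format): header ``etype,target,source,energy_MeV,phi_per_g``.
* Dose report: header ``target,dose_mGy,source,contribution_mGy``.

Parse errors carry the file path and 1-based line number.
"""

from __future__ import annotations

import csv
import io as _io
import re
from pathlib import Path

import pandas as pd
import yaml

from .blood import BloodDistribution
from .dose import DoseReport, EmissionSpectrum, SAFMatrix
from .errors import ParseError
from .mapping import TIAVector
from .units import TIA_UNITS


def _read_lines(path) -> tuple[list[tuple[int, str]], dict[str, str]]:
    """Non-blank data lines with 1-based numbers, plus ``# key: value`` comments."""
    meta: dict[str, str] = {}
    data: list[tuple[int, str]] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*([A-Za-z_][\w-]*)\s*:\s*(.+)$", line)
            if m:
                meta[m.group(1).lower()] = m.group(2).strip()
            continue
        data.append((lineno, raw))
    return data, meta


def _parse_table(path, required: list[str]) -> list[tuple[int, dict[str, str]]]:
    data, meta = _read_lines(path)
    if not data:
        raise ParseError(path, None, "file contains no data rows")
    header_lineno, header_raw = data[0]
    header = next(csv.reader([header_raw]))
    header = [h.strip() for h in header]
    for col in required:
        if col not in header:
            raise ParseError(path, header_lineno, f"missing required column {col!r}")
    rows = []
    for lineno, raw in data[1:]:
        fields = next(csv.reader([raw]))
        if len(fields) != len(header):
            raise ParseError(
                path, lineno, f"expected {len(header)} fields, found {len(fields)}"
            )
        rows.append((lineno, dict(zip(header, (f.strip() for f in fields)))))
    return rows


def _float(path, lineno: int, row: dict[str, str], col: str) -> float:
    try:
        return float(row[col])
    except ValueError:
        raise ParseError(path, lineno, f"invalid number {row[col]!r} in column {col!r}") from None


def read_tia(path, phantom: str | None = None) -> TIAVector:
    """Read a TIA vector; ``phantom`` overrides the file's comment tag."""
    _, meta = _read_lines(path)
    rows = _parse_table(path, ["region", "value"])
    tag = phantom or meta.get("phantom")
    if tag is None:
        raise ParseError(path, None, "no '# phantom:' comment and no phantom argument")
    tag = tag.upper()
    if tag not in ("CE", "ICRP"):
        raise ParseError(path, None, f"unknown phantom tag {tag!r}")
    entries: dict[str, float] = {}
    for lineno, row in rows:
        value = _float(path, lineno, row, "value")
        if value < 0:
            raise ParseError(path, lineno, f"negative value for {row['region']!r}")
        region = row["region"]
        entries[region] = entries.get(region, 0.0) + value
    return TIAVector(phantom=tag, entries=entries, units=meta.get("units", TIA_UNITS))


def write_tia(vec: TIAVector, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# phantom: {vec.phantom}\n# units: {vec.units}\n")
        writer = csv.writer(fh)
        writer.writerow(["region", "value"])
        for region in sorted(vec.entries):
            writer.writerow([region, repr(vec.entries[region])])


def read_blood_distribution(path) -> BloodDistribution:
    rows = _parse_table(path, ["region", "fraction_of_total_blood"])
    fractions: dict[str, float] = {}
    for lineno, row in rows:
        frac = _float(path, lineno, row, "fraction_of_total_blood")
        if not 0.0 <= frac <= 1.0:
            raise ParseError(path, lineno, f"fraction out of [0, 1]: {frac}")
        fractions[row["region"]] = fractions.get(row["region"], 0.0) + frac
    return BloodDistribution(fractions=fractions)


def read_spectrum(path, name: str | None = None) -> EmissionSpectrum:
    rows = _parse_table(path, ["etype", "energy_MeV", "yield"])
    lines = []
    for lineno, row in rows:
        energy = _float(path, lineno, row, "energy_MeV")
        yld = _float(path, lineno, row, "yield")
        if energy <= 0:
            raise ParseError(path, lineno, f"nonpositive energy {energy}")
        if yld < 0:
            raise ParseError(path, lineno, f"negative yield {yld}")
        lines.append((row["etype"], energy, yld))
    return EmissionSpectrum.from_rows(lines, name=name or Path(path).stem)


def write_spectrum(spectrum: EmissionSpectrum, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["etype", "energy_MeV", "yield"])
        for line in spectrum.lines:
            writer.writerow([line.etype, repr(line.energy_MeV), repr(line.yield_per_decay)])


def read_saf(path, phantom: str | None = None) -> SAFMatrix:
    rows = _parse_table(path, ["etype", "target", "source", "energy_MeV", "phi_per_g"])
    records = []
    for lineno, row in rows:
        energy = _float(path, lineno, row, "energy_MeV")
        phi = _float(path, lineno, row, "phi_per_g")
        if phi < 0:
            raise ParseError(path, lineno, f"negative SAF {phi}")
        records.append((row["etype"], row["target"], row["source"], energy, phi))
    df = pd.DataFrame(
        records, columns=["etype", "target", "source", "energy_MeV", "phi_per_g"]
    )
    _, meta = _read_lines(path)
    return SAFMatrix.from_frame(df, phantom=phantom or meta.get("phantom"))


def write_saf(saf: SAFMatrix, path) -> None:
    buf = _io.StringIO()
    if saf.phantom:
        buf.write(f"# phantom: {saf.phantom}\n")
    saf.to_frame().to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_report(report: DoseReport, path) -> None:
    buf = _io.StringIO()
    for key, value in report.metadata.items():
        buf.write(f"# {key}: {value}\n")
    report.to_frame().to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_report(path) -> pd.DataFrame:
    """Read a dose report back as a DataFrame (round-trip convenience)."""
    rows = _parse_table(path, ["target", "dose_mGy", "source", "contribution_mGy"])
    records = [
        (
            row["target"],
            _float(path, lineno, row, "dose_mGy"),
            row["source"],
            _float(path, lineno, row, "contribution_mGy"),
        )
        for lineno, row in rows
    ]
    return pd.DataFrame(
        records, columns=["target", "dose_mGy", "source", "contribution_mGy"]
    )


def load_config(path) -> dict:
    """Load a YAML key/value configuration file.

    Recognized keys (all optional): ``units``, ``map_policy``,
    ``blood_policy``, ``fail_on``, ``recompute_factors``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(path, None, "config must be a mapping of keys to values")
    return cfg
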