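"""Mascot Generic Format (MGF) peak-list dialect.

Supported per ``BEGIN IONS``/``END IONS`` block: ``TITLE``, ``PEPMASS``
(first token is the precursor m/z; any further tokens are preserved
verbatim), ``CHARGE`` (``2+`` → +2, ``1-`` → -1; magnitude is stored), and
``RTINSECONDS``. Any other ``KEY=value`` header is preserved as an opaque
annotation. A block with no ``CHARGE`` line yields charge 0 (*unknown*), and
a charge-0 spectrum is written back without a ``CHARGE`` line — this is how
the missing-precursor-charge defect survives a round trip.

The spectrum id is the first whitespace-delimited token of the ``TITLE``
line (the whole line is kept as the title); an untitled block gets a
positional id. Precursor m/z is written with full float precision, peaks
with six decimals.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, TextIO

from idmigrate.formats.model import Spectrum

__all__ = ["MgfParseError", "read_mgf", "write_mgf"]

_KNOWN_KEYS = {"TITLE", "PEPMASS", "CHARGE", "RTINSECONDS"}


class MgfParseError(ValueError):
    """MGF syntax error, annotated with the offending line number."""

    def __init__(self, path: str, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _parse_charge(text: str, path: str, lineno: int) -> int:
    tok = text.strip().split()[0] if text.strip() else ""
    sign = 1
    if tok.endswith("+"):
        tok = tok[:-1]
    elif tok.endswith("-"):
        tok = tok[:-1]
        sign = -1
    try:
        value = int(tok)
    except ValueError:
        raise MgfParseError(path, lineno, f"unparseable CHARGE value {text!r}")
    return abs(sign * value)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse an MGF file into spectra, preserving block order."""
    path = Path(path)
    spectra: list[Spectrum] = []
    with path.open("r", encoding="utf-8") as handle:
        in_block = False
        block_line = 0
        headers: dict[str, str] = {}
        peaks: list[tuple[float, float]] = []
        for lineno, raw in enumerate(handle, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise MgfParseError(
                        str(path), lineno,
                        f"BEGIN IONS inside unterminated block opened at line {block_line}",
                    )
                in_block, block_line = True, lineno
                headers, peaks = {}, []
            elif line == "END IONS":
                if not in_block:
                    raise MgfParseError(str(path), lineno, "END IONS outside a block")
                spectra.append(
                    _build_spectrum(headers, peaks, len(spectra), str(path), block_line)
                )
                in_block = False
            elif not in_block:
                raise MgfParseError(str(path), lineno, f"content outside block: {line!r}")
            elif "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                headers[key.strip()] = value.strip()
            else:
                fields = line.split()
                if len(fields) < 2:
                    raise MgfParseError(str(path), lineno, f"malformed peak line {line!r}")
                try:
                    peaks.append((float(fields[0]), float(fields[1])))
                except ValueError:
                    raise MgfParseError(
                        str(path), lineno, f"non-numeric peak line {line!r}"
                    ) from None
        if in_block:
            raise MgfParseError(
                str(path), block_line, "unterminated BEGIN IONS block (no END IONS)"
            )
    return spectra


def _build_spectrum(
    headers: dict[str, str],
    peaks: list[tuple[float, float]],
    index: int,
    path: str,
    lineno: int,
) -> Spectrum:
    if "PEPMASS" not in headers:
        raise MgfParseError(path, lineno, "block missing PEPMASS")
    try:
        precursor_mz = float(headers["PEPMASS"].split()[0])
    except (ValueError, IndexError):
        raise MgfParseError(
            path, lineno, f"unparseable PEPMASS {headers['PEPMASS']!r}"
        ) from None
    charge = (
        _parse_charge(headers["CHARGE"], path, lineno) if "CHARGE" in headers else 0
    )
    title = headers.get("TITLE", "")
    spectrum_id = title.split()[0] if title.split() else f"index_{index}"
    rt = float(headers["RTINSECONDS"]) if "RTINSECONDS" in headers else None
    annotations = {k: v for k, v in headers.items() if k not in _KNOWN_KEYS}
    pepmass_rest = headers["PEPMASS"].split()[1:]
    if pepmass_rest:
        annotations["_PEPMASS_EXTRA"] = " ".join(pepmass_rest)
    return Spectrum(
        spectrum_id=spectrum_id,
        title=title or spectrum_id,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        peaks=peaks,
        rt_seconds=rt,
        annotations=annotations,
    )


def _write_block(handle: TextIO, s: Spectrum) -> None:
    handle.write("BEGIN IONS\n")
    title = s.title
    if title.split()[:1] != [s.spectrum_id]:
        title = f"{s.spectrum_id} {title}".strip()
    handle.write(f"TITLE={title}\n")
    pepmass = repr(s.precursor_mz)
    extra = s.annotations.get("_PEPMASS_EXTRA")
    if extra:
        pepmass += f" {extra}"
    handle.write(f"PEPMASS={pepmass}\n")
    if s.precursor_charge > 0:
        handle.write(f"CHARGE={s.precursor_charge}+\n")
    if s.rt_seconds is not None:
        handle.write(f"RTINSECONDS={s.rt_seconds!r}\n")
    for key in sorted(s.annotations):
        if key != "_PEPMASS_EXTRA":
            handle.write(f"{key}={s.annotations[key]}\n")
    for mz, intensity in s.peaks:
        handle.write(f"{mz:.6f} {intensity:.6f}\n")
    handle.write("END IONS\n")


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to ``path``; an empty iterable yields a valid empty file."""
    with Path(path).open("w", encoding="utf-8") as handle:
        for i, s in enumerate(spectra):
            if i:
                handle.write("\n")
            _write_block(handle, s)
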