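"""Minimal JCAMP-DX reader/writer for 1D NMR data.

Supports the uncompressed AFFN ``(X++(Y..Y))`` table form only:

* **write**: real spectra as ``XYDATA`` records, FIDs as two-page
  ``NTUPLES`` records (real and imaginary pages).  Intensities are stored
  as scaled integers via ``YFACTOR`` with ~9 significant digits.
* **read**: the records above.  ASDF compressed dialects (SQZ/DIF/DUP/PAC
  packed forms) are rejected with an explicit error naming the record;
  truncated tables raise instead of returning a silent partial read.

Acquisition parameters ride along in standard labels where they exist
(``.OBSERVE FREQUENCY``) and private ``$`` labels otherwise (``$DWELLTIME``
seconds, ``$SPECTRALOFFSET`` ppm).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .spectra import FID, AcquisitionParams, Spectrum

__all__ = ["read_jcamp", "write_jcamp", "JcampError"]


class JcampError(ValueError):
    """Malformed or unsupported JCAMP-DX content."""


_AFFN_LINE = re.compile(r"^[+\-]?[0-9.EeDd+\- \t]*$")
_ASDF_CHARS = re.compile(r"[@A-IJ-Ra-ij-r%sS-Zt-z?]")


def _format_table(x: np.ndarray, y: np.ndarray, yfactor: float) -> list[str]:
    lines = []
    scaled = np.round(y / yfactor).astype(np.int64)
    per_line = 6
    for i in range(0, x.size, per_line):
        xs = f"{x[i]:.6f}"
        ys = " ".join(str(v) for v in scaled[i : i + per_line])
        lines.append(f"{xs} {ys}")
    return lines


def _yfactor(y: np.ndarray) -> float:
    m = float(np.max(np.abs(y))) if y.size else 0.0
    return m / 1e9 if m > 0 else 1.0


def write_jcamp(obj: Spectrum | FID, path, title: str = "qnmrfit export") -> None:
    """Write a Spectrum (AFFN XYDATA) or FID (AFFN NTUPLES) to ``path``."""
    path = Path(path)
    p = obj.params
    common = [
        f"##TITLE= {title}",
        "##JCAMP-DX= 5.00",
        "##ORIGIN= qnmrfit",
        "##OWNER= qnmrfit",
        f"##.OBSERVE FREQUENCY= {p.spectrometer_frequency!r}",
        f"##$DWELLTIME= {p.dwell_time!r}",
        f"##$SPECTRALOFFSET= {p.spectral_offset!r}",
    ]
    if isinstance(obj, Spectrum):
        y = obj.real_values
        yf = _yfactor(y)
        lines = (
            ["##TITLE= " + title]
            + common[1:]
            + [
                "##DATA TYPE= NMR SPECTRUM",
                "##DATA CLASS= XYDATA",
                "##XUNITS= HZ",
                "##YUNITS= ARBITRARY UNITS",
                f"##NPOINTS= {obj.n}",
                f"##FIRSTX= {float(obj.frequency[0])!r}",
                f"##LASTX= {float(obj.frequency[-1])!r}",
                "##XFACTOR= 1.0",
                f"##YFACTOR= {yf!r}",
                "##XYDATA= (X++(Y..Y))",
            ]
            + _format_table(obj.frequency, y, yf)
            + ["##END="]
        )
    elif isinstance(obj, FID):
        t = p.time_grid()
        pages = []
        for name, vals in (("R", obj.samples.real), ("I", obj.samples.imag)):
            yf = _yfactor(vals)
            pages += [
                f"##PAGE= N={1 if name == 'R' else 2}",
                f"##$YFACTOR{name}= {yf!r}",
                f"##DATA TABLE= (X++({name}..{name})), XYDATA",
            ] + _format_table(t, vals, yf)
        lines = (
            common
            + [
                "##DATA TYPE= NMR FID",
                "##DATA CLASS= NTUPLES",
                "##NTUPLES= NMR FID",
                "##VAR_NAME= TIME, FID/REAL, FID/IMAG",
                "##SYMBOL= X, R, I",
                f"##VAR_DIM= {obj.n}, {obj.n}, {obj.n}",
                "##UNITS= SECONDS, ARBITRARY UNITS, ARBITRARY UNITS",
            ]
            + pages
            + ["##END NTUPLES= NMR FID", "##END="]
        )
    else:
        raise TypeError(f"can only write Spectrum or FID, got {type(obj)}")
    path.write_text("\n".join(lines) + "\n")


def _parse_labels(text: str):
    """Split a JCAMP file into (label → value-up-to-next-label) plus data blocks."""
    entries = []
    for m in re.finditer(r"^##([^=\n]*)=(.*)$", text, flags=re.MULTILINE):
        entries.append((m.group(1).strip().upper(), m.group(2).strip(), m.end()))
    return entries, text


def _read_table(text: str, start: int, npoints: int, label: str, symbols: int = 1):
    """Parse an AFFN (X++(Y..Y)) block starting after ``start``; returns the Y column."""
    ys: list[float] = []
    for raw in text[start:].splitlines()[1:]:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            break
        stripped = re.sub(r"[EeDd]", "", line)  # exponent markers are legal AFFN
        if _ASDF_CHARS.search(stripped):
            raise JcampError(
                f"record {label!r} uses an ASDF compressed dialect; only "
                "uncompressed AFFN tables are supported"
            )
        parts = line.replace("D", "E").split()
        try:
            vals = [float(v) for v in parts]
        except ValueError as exc:
            raise JcampError(f"unparseable AFFN line in {label!r}: {line!r}") from exc
        ys.extend(vals[1:])  # first token is the X start of the line
    if len(ys) != npoints:
        raise JcampError(
            f"record {label!r} holds {len(ys)} points but NPOINTS/VAR_DIM says "
            f"{npoints}; truncated or corrupt file"
        )
    return np.asarray(ys, dtype=float)


def _get(labels: dict, key: str, path, cast=float, default=None):
    if key in labels:
        return cast(labels[key])
    if default is not None:
        return default
    raise JcampError(f"{path}: required label ##{key}= is missing")


def read_jcamp(path) -> FID | Spectrum:
    """Read a JCAMP-DX file, returning an :class:`FID` for NTUPLES time-domain
    records and a :class:`Spectrum` for XYDATA real spectra.

    Raises
    ------
    JcampError
        For unsupported dialects, missing required labels (e.g. dwell time
        for an FID), or truncated data tables.
    """
    path = Path(path)
    text = path.read_text()
    entries, _ = _parse_labels(text)
    if not entries or entries[0][0] != "TITLE":
        raise JcampError(f"{path}: not a JCAMP-DX file (no ##TITLE= record)")
    labels = {k: v for k, v, _ in entries}
    positions = {k: pos for k, v, pos in entries}

    b0 = _get(labels, ".OBSERVE FREQUENCY", path, default=labels.get("$B0"))
    if b0 is None:
        raise JcampError(f"{path}: spectrometer frequency label is missing")
    b0 = float(b0)
    offset = float(labels.get("$SPECTRALOFFSET", 0.0))

    if "NTUPLES" in labels:
        if "$DWELLTIME" not in labels:
            raise JcampError(f"{path}: FID record lacks a dwell time (##$DWELLTIME=)")
        dt = float(labels["$DWELLTIME"])
        dims = [int(v) for v in labels["VAR_DIM"].replace(",", " ").split()]
        n = dims[0]
        params = AcquisitionParams(dt, n, b0, offset)
        tables = [
            (m.group(1), m.end())
            for m in re.finditer(r"##DATA TABLE=\s*\(X\+\+\((\w)\.\.\1\)\)[^\n]*", text)
        ]
        if len(tables) != 2:
            raise JcampError(
                f"{path}: expected two NTUPLES pages (R and I), found {len(tables)}"
            )
        cols = {}
        for sym, pos in tables:
            cols[sym] = _read_table(text, pos, n, f"DATA TABLE ({sym})")
            yf = labels.get(f"$YFACTOR{sym}")
            if yf is not None:
                cols[sym] = cols[sym] * float(yf)
        if set(cols) != {"R", "I"}:
            raise JcampError(f"{path}: NTUPLES pages {sorted(cols)} are not R/I")
        return FID(samples=cols["R"] + 1j * cols["I"], params=params)

    if "XYDATA" in labels:
        form = labels["XYDATA"].upper().replace(" ", "")
        if form not in ("(X++(Y..Y))",):
            raise JcampError(
                f"{path}: XYDATA form {labels['XYDATA']!r} is not supported "
                "(only uncompressed AFFN (X++(Y..Y)))"
            )
        n = int(_get(labels, "NPOINTS", path, cast=float))
        firstx = _get(labels, "FIRSTX", path)
        lastx = _get(labels, "LASTX", path)
        yfactor = float(labels.get("YFACTOR", 1.0))
        xfactor = float(labels.get("XFACTOR", 1.0))
        y = _read_table(text, positions["XYDATA"], n, "XYDATA") * yfactor
        grid = np.linspace(firstx * xfactor, lastx * xfactor, n)
        if "$DWELLTIME" in labels:
            dt = float(labels["$DWELLTIME"])
        else:
            span = (lastx - firstx) * n / (n - 1) * xfactor
            dt = 1.0 / span
        params = AcquisitionParams(dt, n, b0, offset)
        return Spectrum(
            frequency=grid,
            real_values=y,
            complex_values=None,
            phase=(0.0, 0.0),
            params=params,
        )

    raise JcampError(
        f"{path}: no supported data record (need ##XYDATA= or ##NTUPLES=); "
        f"data type {labels.get('DATA TYPE', 'unknown')!r}"
    )
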