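"""Parsing of multi-valued table cells and index pairing into peaks.

Literature tables often pack several absorption maxima into one cell
("416, 514, 602") with the matching intensities in a sibling cell, and report
intensities in standard form ("2.1" under a header "ε ×10⁴") or as base-10
logarithms ("log ε").  This module tokenizes such cells, normalizes the unit
forms, and pairs wavelength and intensity lists by index when their lengths
agree.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum

from .records import CANONICAL_EXTINCTION_UNIT, Peak

__all__ = [
    "CellForm",
    "CellParse",
    "CellParseError",
    "AmbiguousCellError",
    "parse_wavelength_cell",
    "parse_extinction_cell",
    "standardize_extinction",
    "pair_peaks",
]


class CellForm(str, Enum):
    PLAIN = "plain"
    STANDARD_FORM = "standard_form"
    LOG = "log"


@dataclass
class CellParse:
    """Ordered numeric contents of one table cell plus its unit form."""

    values: list[float]
    unit: str | None = None
    form: CellForm = CellForm.PLAIN
    exponent: int | None = None


class CellParseError(ValueError):
    """No numeric content could be extracted from a cell."""


class AmbiguousCellError(CellParseError):
    """A cell carries conflicting unit-form markers (both log and ×10ⁿ)."""


_SUPERSCRIPTS = str.maketrans("⁰¹²³⁴⁵⁶⁷⁸⁹⁻⁺", "0123456789-+")

# "×10⁴", "x10^4", "*10 4", "× 10-3" ... exponent in ASCII or superscript.
_STD_FORM_RE = re.compile(
    r"[×x*]\s*10\s*(?:\^\s*)?([-+]?\d+|[⁰¹²³⁴⁵⁶⁷⁸⁹⁻⁺]+)",
    re.IGNORECASE,
)
_LOG_RE = re.compile(r"\blog\b|\blg\b", re.IGNORECASE)
_PAREN_RE = re.compile(r"\([^)]*\)|\[[^\]]*\]")
_NUMBER_RE = re.compile(r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")
_WAVELENGTH_UNIT_RE = re.compile(r"\b(nm|μm|um|cm-?1|cm⁻¹|a|å)\b", re.IGNORECASE)


def _extract_numbers(text: str) -> list[float]:
    return [float(tok) for tok in _NUMBER_RE.findall(text)]


def _find_std_form(text: str) -> tuple[str, int | None]:
    """Remove a ×10ⁿ marker from ``text``; return (cleaned text, exponent)."""
    m = _STD_FORM_RE.search(text)
    if not m:
        return text, None
    exponent = int(m.group(1).translate(_SUPERSCRIPTS))
    return text[: m.start()] + " " + text[m.end():], exponent


def parse_wavelength_cell(text: str, header_unit: str | None = None) -> CellParse:
    """Extract the ordered wavelength values printed in one cell.

    Parenthesized annotations such as "(sh)" are stripped before
    tokenization; the unit is taken from the cell when printed, else from the
    header context.
    """
    if not text or not text.strip():
        raise CellParseError("empty wavelength cell")
    cleaned = _PAREN_RE.sub(" ", text)
    unit = None
    m = _WAVELENGTH_UNIT_RE.search(cleaned)
    if m:
        unit = m.group(1)
        cleaned = cleaned[: m.start()] + " " + cleaned[m.end():]
    values = _extract_numbers(cleaned)
    if not values:
        raise CellParseError(f"no numeral found in wavelength cell {text!r}")
    return CellParse(values=values, unit=unit or header_unit, form=CellForm.PLAIN)


def parse_extinction_cell(text: str, header_unit: str | None = None) -> CellParse:
    """Extract intensity values and detect standard-form / log unit markers.

    The exponent of a ×10ⁿ marker may sit in the cell or in the column
    header; the header wins on conflict (single-table consistency).  Values
    are kept exactly as printed — scaling is deferred to
    :func:`standardize_extinction`.
    """
    if not text or not text.strip():
        raise CellParseError("empty extinction cell")
    header = header_unit or ""
    cell_clean, cell_exp = _find_std_form(text)
    header_clean, header_exp = _find_std_form(header)
    is_log = bool(_LOG_RE.search(text) or _LOG_RE.search(header))
    exponent = header_exp if header_exp is not None else cell_exp
    if is_log and exponent is not None:
        raise AmbiguousCellError(
            f"cell {text!r} with header {header_unit!r} carries both log and ×10ⁿ markers"
        )
    cleaned = _PAREN_RE.sub(" ", _LOG_RE.sub(" ", cell_clean))
    values = _extract_numbers(cleaned)
    if not values:
        raise CellParseError(f"no numeral found in extinction cell {text!r}")
    if is_log:
        form = CellForm.LOG
    elif exponent is not None:
        form = CellForm.STANDARD_FORM
    else:
        form = CellForm.PLAIN
    return CellParse(values=values, unit=header_unit, form=form, exponent=exponent)


def standardize_extinction(parse: CellParse) -> list[float]:
    """Map printed intensity values to L mol⁻¹ cm⁻¹.

    Standard-form values are multiplied by 10^exponent, log values are
    exponentiated (base 10), plain values pass through unchanged.
    """
    if parse.form is CellForm.STANDARD_FORM:
        if parse.exponent is None:
            raise CellParseError("standard-form parse lacks an exponent")
        factor = 10.0 ** parse.exponent
        out = [v * factor for v in parse.values]
    elif parse.form is CellForm.LOG:
        out = [10.0 ** v for v in parse.values]
    else:
        out = list(parse.values)
    for v in out:
        if not math.isfinite(v):
            raise OverflowError(f"non-finite extinction after standardization: {v}")
    return out


def pair_peaks(lambda_cell: CellParse, eps_cell: CellParse | None) -> list[Peak]:
    """Pair wavelength and intensity lists by index.

    When the two lists have equal length n, the i-th wavelength is paired
    with the i-th intensity.  Otherwise all values are emitted as isolated
    peaks (wavelength-only then intensity-only, order preserved); no value is
    ever dropped or invented.
    """
    wl_unit = lambda_cell.unit or "nm"
    if eps_cell is None:
        return [Peak(wavelength=v, wavelength_unit=wl_unit) for v in lambda_cell.values]
    eps_values = standardize_extinction(eps_cell)
    if len(lambda_cell.values) == len(eps_values):
        return [
            Peak(
                wavelength=wl,
                wavelength_unit=wl_unit,
                extinction=eps,
                extinction_unit=CANONICAL_EXTINCTION_UNIT,
            )
            for wl, eps in zip(lambda_cell.values, eps_values)
        ]
    peaks = [Peak(wavelength=v, wavelength_unit=wl_unit) for v in lambda_cell.values]
    peaks.extend(
        Peak(
            wavelength=None,
            wavelength_unit=None,
            extinction=eps,
            extinction_unit=CANONICAL_EXTINCTION_UNIT,
        )
        for eps in eps_values
    )
    return peaks
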