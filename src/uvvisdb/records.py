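"""Compound-record data model and (de)serialization.

A record is a document tree keyed by InChIKey.  The ``PRISTINE`` branch holds
as-extracted experimental data (SMILES spellings and UV/vis entries, each tied
to a source DOI); the optional ``FILTERED`` branch holds the canonical
structure that survived the opto-electronic filter together with
electronic-structure result blocks (``orca`` = sTDA, ``nwchem`` = TD-DFT,
``mopac`` = semi-empirical screening).

Missing experimental values and the literal string ``"NULL"`` both map to
Python ``None`` on load; on write, JSON emits native ``null`` and CSV emits
the literal string ``NULL``.  Unknown keys are preserved verbatim in per-node
``extras`` maps so the richer MongoDB-style tree survives a round trip.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Any, Iterable

__all__ = [
    "NULL_STRING",
    "TABLE1_COLUMNS",
    "Peak",
    "UvVisEntry",
    "ComputedState",
    "ComputedBlock",
    "FilteredBlock",
    "CompoundRecord",
    "Issue",
    "RecordError",
    "InchiKeyError",
    "load_database",
    "write_database",
    "dedupe_by_inchikey",
    "make_inchikey",
    "validate_record",
]

#: Literal used for absent values in the flat CSV form.
NULL_STRING = "NULL"

#: Flat export columns, one row per (compound, peak).
TABLE1_COLUMNS = [
    "inchikey",
    "doi",
    "lambda",
    "lambda_unit",
    "extinction",
    "extinction_unit",
    "solvent",
    "amplitude",
    "oscillator_strength",
]

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

CANONICAL_WAVELENGTH_UNIT = "nm"
CANONICAL_EXTINCTION_UNIT = "L mol-1 cm-1"

COMPUTED_SOURCES = ("orca", "nwchem", "mopac")


class RecordError(ValueError):
    """A document could not be interpreted as a compound record."""


class InchiKeyError(RecordError):
    """A SMILES string could not be resolved to an InChIKey."""


def _null(value: Any) -> Any:
    """Map the explicit NULL marker (and empty strings) to ``None``."""
    if value is None:
        return None
    if isinstance(value, str) and value.strip().upper() == NULL_STRING:
        return None
    return value


def _as_float(value: Any) -> float | None:
    value = _null(value)
    if value is None:
        return None
    return float(value)


@dataclass
class Peak:
    """One absorption feature: a wavelength and, where present, an intensity."""

    wavelength: float | None
    wavelength_unit: str | None = CANONICAL_WAVELENGTH_UNIT
    extinction: float | None = None
    extinction_unit: str | None = None
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_doc(cls, doc: dict) -> "Peak":
        known = {"lambda", "lambda_unit", "extinction", "extinction_unit"}
        return cls(
            wavelength=_as_float(doc.get("lambda")),
            wavelength_unit=_null(doc.get("lambda_unit")),
            extinction=_as_float(doc.get("extinction")),
            extinction_unit=_null(doc.get("extinction_unit")),
            extras={k: v for k, v in doc.items() if k not in known},
        )

    def to_doc(self) -> dict:
        doc = {
            "lambda": self.wavelength,
            "lambda_unit": self.wavelength_unit,
            "extinction": self.extinction,
            "extinction_unit": self.extinction_unit,
        }
        doc.update(self.extras)
        return doc


@dataclass
class UvVisEntry:
    """One extracted set of peaks, tied to the DOI of its source article."""

    doi: str
    peaks: list[Peak] = field(default_factory=list)
    solvent: str | None = None
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_doc(cls, doc: dict) -> "UvVisEntry":
        known = {"doi", "peaks", "solvent"}
        peaks = [Peak.from_doc(p) for p in doc.get("peaks") or []]
        return cls(
            doi=str(_null(doc.get("doi")) or ""),
            peaks=peaks,
            solvent=_null(doc.get("solvent")),
            extras={k: v for k, v in doc.items() if k not in known},
        )

    def to_doc(self) -> dict:
        doc = {
            "doi": self.doi,
            "solvent": self.solvent,
            "peaks": [p.to_doc() for p in self.peaks],
        }
        doc.update(self.extras)
        return doc


@dataclass
class ComputedState:
    """One excited state of an electronic-structure result block.

    ``index`` 1 is the first (longest-wavelength, lowest-energy) excitation.
    The computed wavelength is stored under the flat key ``amplitude``.
    """

    index: int
    wavelength: float | None
    oscillator_strength: float | None = None
    orbital_energies: list | None = None
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_doc(cls, doc: dict) -> "ComputedState":
        known = {"index", "amplitude", "oscillator_strength", "orbital_energy_list"}
        orb = doc.get("orbital_energy_list")
        return cls(
            index=int(doc.get("index", 1)),
            wavelength=_as_float(doc.get("amplitude")),
            oscillator_strength=_as_float(doc.get("oscillator_strength")),
            orbital_energies=[list(pair) for pair in orb] if orb is not None else None,
            extras={k: v for k, v in doc.items() if k not in known},
        )

    def to_doc(self) -> dict:
        doc = {
            "index": self.index,
            "amplitude": self.wavelength,
            "oscillator_strength": self.oscillator_strength,
        }
        if self.orbital_energies is not None:
            doc["orbital_energy_list"] = [list(pair) for pair in self.orbital_energies]
        doc.update(self.extras)
        return doc


@dataclass
class ComputedBlock:
    """All excited states produced by one computational source."""

    source: str  # one of COMPUTED_SOURCES
    states: list[ComputedState] = field(default_factory=list)
    version: str | None = None
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_doc(cls, source: str, doc: dict) -> "ComputedBlock":
        known = {"excited_states", "version"}
        states = [ComputedState.from_doc(s) for s in doc.get("excited_states") or []]
        states.sort(key=lambda s: s.index)
        return cls(
            source=source,
            states=states,
            version=_null(doc.get("version")),
            extras={k: v for k, v in doc.items() if k not in known},
        )

    def to_doc(self) -> dict:
        doc = {
            "version": self.version,
            "excited_states": [s.to_doc() for s in self.states],
        }
        doc.update(self.extras)
        return doc

    def first_state(self) -> ComputedState | None:
        for state in self.states:
            if state.index == 1:
                return state
        return None


@dataclass
class FilteredBlock:
    """Post-filter branch: canonical structure, electron count, HPC band."""

    smiles: str | None = None
    nel: int | None = None
    band: str | None = None
    blocks: list[ComputedBlock] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_doc(cls, doc: dict) -> "FilteredBlock":
        known = {"SMI", "nel", "band", *COMPUTED_SOURCES}
        blocks = [
            ComputedBlock.from_doc(src, doc[src])
            for src in COMPUTED_SOURCES
            if isinstance(doc.get(src), dict)
        ]
        nel = _null(doc.get("nel"))
        return cls(
            smiles=_null(doc.get("SMI")),
            nel=int(nel) if nel is not None else None,
            band=_null(doc.get("band")),
            blocks=blocks,
            extras={k: v for k, v in doc.items() if k not in known},
        )

    def to_doc(self) -> dict:
        doc: dict = {"SMI": self.smiles, "nel": self.nel, "band": self.band}
        for block in self.blocks:
            doc[block.source] = block.to_doc()
        doc.update(self.extras)
        return doc

    def block(self, source: str) -> ComputedBlock | None:
        for b in self.blocks:
            if b.source == source:
                return b
        return None


@dataclass
class CompoundRecord:
    """One unique compound: InChIKey, PRISTINE data, optional FILTERED branch."""

    inchikey: str | None
    smiles: list[str] = field(default_factory=list)
    uvvis: list[UvVisEntry] = field(default_factory=list)
    filtered: FilteredBlock | None = None
    extras: dict = field(default_factory=dict)
    pristine_extras: dict = field(default_factory=dict)

    @classmethod
    def from_doc(cls, doc: dict) -> "CompoundRecord":
        if not isinstance(doc, dict):
            raise RecordError(f"expected a document object, got {type(doc).__name__}")
        known = {"inchikey", "PRISTINE", "FILTERED"}
        pristine = doc.get("PRISTINE") or {}
        if not isinstance(pristine, dict):
            raise RecordError("PRISTINE branch is not an object")
        smi = pristine.get("SMI")
        if smi is None:
            smiles: list[str] = []
        elif isinstance(smi, str):
            smiles = [smi]
        else:
            smiles = [str(s) for s in smi]
        uvvis = [UvVisEntry.from_doc(u) for u in pristine.get("uvvis") or []]
        filtered_doc = doc.get("FILTERED")
        return cls(
            inchikey=_null(doc.get("inchikey")),
            smiles=smiles,
            uvvis=uvvis,
            filtered=FilteredBlock.from_doc(filtered_doc)
            if isinstance(filtered_doc, dict)
            else None,
            extras={k: v for k, v in doc.items() if k not in known},
            pristine_extras={
                k: v for k, v in pristine.items() if k not in {"SMI", "uvvis"}
            },
        )

    def to_doc(self) -> dict:
        pristine = {"SMI": list(self.smiles), "uvvis": [u.to_doc() for u in self.uvvis]}
        pristine.update(self.pristine_extras)
        doc: dict = {"inchikey": self.inchikey, "PRISTINE": pristine}
        if self.filtered is not None:
            doc["FILTERED"] = self.filtered.to_doc()
        doc.update(self.extras)
        return doc

    # -- convenience queries -------------------------------------------------

    def experimental_wavelengths(self) -> list[float]:
        """All non-null experimental wavelengths, in document order."""
        return [
            p.wavelength
            for entry in self.uvvis
            for p in entry.peaks
            if p.wavelength is not None
        ]

    def computed_block(self, source: str) -> ComputedBlock | None:
        if self.filtered is None:
            return None
        return self.filtered.block(source)

    def first_computed_wavelength(self, source: str = "orca") -> float | None:
        block = self.computed_block(source)
        if block is None:
            return None
        state = block.first_state()
        return state.wavelength if state is not None else None


# ---------------------------------------------------------------------------
# Load / write
# ---------------------------------------------------------------------------


def _open_text(stream, mode: str):
    if isinstance(stream, (str, Path)):
        return open(stream, mode, encoding="utf-8", newline=""), True
    return stream, False


def load_database(stream, format: str = "json", errors: list | None = None) -> list[CompoundRecord]:
    """Read a database from ``stream`` (path or text file object).

    Malformed documents are collected into ``errors`` (as ``(index, message)``
    tuples) and the load continues; an empty stream yields an empty list.
    """
    fh, close = _open_text(stream, "r")
    try:
        if format == "json":
            text = fh.read()
            docs = json.loads(text) if text.strip() else []
            if isinstance(docs, dict):
                docs = [docs]
            records = []
            for i, doc in enumerate(docs):
                try:
                    records.append(CompoundRecord.from_doc(doc))
                except (RecordError, TypeError, ValueError) as exc:
                    if errors is None:
                        raise
                    errors.append((i, str(exc)))
            return records
        if format == "csv":
            return _load_csv(fh, errors)
        raise ValueError(f"unknown format: {format!r}")
    finally:
        if close:
            fh.close()


def _load_csv(fh: IO[str], errors: list | None) -> list[CompoundRecord]:
    reader = csv.DictReader(fh)
    by_key: dict[str, CompoundRecord] = {}
    order: list[str] = []
    for i, row in enumerate(reader):
        try:
            key = _null(row.get("inchikey"))
            doi = _null(row.get("doi")) or ""
            solvent = _null(row.get("solvent"))
            peak = Peak(
                wavelength=_as_float(row.get("lambda")),
                wavelength_unit=_null(row.get("lambda_unit")),
                extinction=_as_float(row.get("extinction")),
                extinction_unit=_null(row.get("extinction_unit")),
            )
            amplitude = _as_float(row.get("amplitude"))
            osc = _as_float(row.get("oscillator_strength"))
        except (TypeError, ValueError) as exc:
            if errors is None:
                raise RecordError(f"row {i}: {exc}") from exc
            errors.append((i, str(exc)))
            continue
        ident = key if key is not None else f"__row_{i}"
        record = by_key.get(ident)
        if record is None:
            record = CompoundRecord(inchikey=key)
            by_key[ident] = record
            order.append(ident)
        entry = None
        if record.uvvis and record.uvvis[-1].doi == doi and record.uvvis[-1].solvent == solvent:
            entry = record.uvvis[-1]
        if entry is None:
            entry = UvVisEntry(doi=doi, solvent=solvent)
            record.uvvis.append(entry)
        if peak.wavelength is not None or peak.extinction is not None:
            entry.peaks.append(peak)
        if amplitude is not None or osc is not None:
            if record.filtered is None:
                record.filtered = FilteredBlock(
                    blocks=[
                        ComputedBlock(
                            source="orca",
                            states=[
                                ComputedState(
                                    index=1,
                                    wavelength=amplitude,
                                    oscillator_strength=osc,
                                )
                            ],
                        )
                    ]
                )
    return [by_key[k] for k in order]


def write_database(records: Iterable[CompoundRecord], stream, format: str = "json") -> None:
    """Write ``records`` to ``stream`` (path or text file object).

    JSON preserves the full nested tree and is byte-stable under a
    load/write round trip; CSV is the lossy flat projection, one row per
    (compound, peak).
    """
    fh, close = _open_text(stream, "w")
    try:
        if format == "json":
            docs = [r.to_doc() for r in records]
            json.dump(docs, fh, indent=1, sort_keys=True, ensure_ascii=False)
            fh.write("\n")
        elif format == "csv":
            writer = csv.writer(fh)
            writer.writerow(TABLE1_COLUMNS)
            for record in records:
                for row in _csv_rows(record):
                    writer.writerow(row)
        else:
            raise ValueError(f"unknown format: {format!r}")
    finally:
        if close:
            fh.close()


def _fmt(value: Any) -> str:
    if value is None:
        return NULL_STRING
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _csv_rows(record: CompoundRecord) -> list[list[str]]:
    amplitude = record.first_computed_wavelength("orca")
    osc = None
    block = record.computed_block("orca")
    if block is not None and block.first_state() is not None:
        osc = block.first_state().oscillator_strength
    rows = []
    for entry in record.uvvis:
        peaks = entry.peaks or [Peak(wavelength=None, wavelength_unit=None)]
        for peak in peaks:
            rows.append(
                [
                    _fmt(record.inchikey),
                    _fmt(entry.doi or None),
                    _fmt(peak.wavelength),
                    _fmt(peak.wavelength_unit),
                    _fmt(peak.extinction),
                    _fmt(peak.extinction_unit),
                    _fmt(entry.solvent),
                    _fmt(amplitude),
                    _fmt(osc),
                ]
            )
    if not rows:
        rows.append(
            [_fmt(record.inchikey)] + [NULL_STRING] * 6 + [_fmt(amplitude), _fmt(osc)]
        )
    return rows


def dumps_database(records: Iterable[CompoundRecord], format: str = "json") -> str:
    buf = io.StringIO()
    write_database(records, buf, format=format)
    return buf.getvalue()


def loads_database(text: str, format: str = "json", errors: list | None = None) -> list[CompoundRecord]:
    return load_database(io.StringIO(text), format=format, errors=errors)


# ---------------------------------------------------------------------------
# Deduplication and identity
# ---------------------------------------------------------------------------


def dedupe_by_inchikey(
    records: Iterable[CompoundRecord], rejects: list | None = None
) -> list[CompoundRecord]:
    """Merge records sharing an InChIKey into one record per distinct key.

    UV/vis entries of merged instances are concatenated, each keeping its own
    DOI; SMILES spellings are pooled (order-preserving, de-duplicated).
    Records with a null key are routed to ``rejects`` rather than merged.
    """
    merged: dict[str, CompoundRecord] = {}
    order: list[str] = []
    for record in records:
        if record.inchikey is None:
            if rejects is not None:
                rejects.append(record)
            continue
        existing = merged.get(record.inchikey)
        if existing is None:
            merged[record.inchikey] = CompoundRecord(
                inchikey=record.inchikey,
                smiles=list(record.smiles),
                uvvis=list(record.uvvis),
                filtered=record.filtered,
                extras=dict(record.extras),
                pristine_extras=dict(record.pristine_extras),
            )
            order.append(record.inchikey)
        else:
            for s in record.smiles:
                if s not in existing.smiles:
                    existing.smiles.append(s)
            existing.uvvis.extend(record.uvvis)
            if existing.filtered is None:
                existing.filtered = record.filtered
    return [merged[k] for k in order]


def make_inchikey(smiles: str) -> str:
    """Standard InChIKey of the standard InChI of ``smiles`` (via RDKit)."""
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InchiKeyError(f"unparseable SMILES: {smiles!r}")
    key = Chem.MolToInchiKey(mol)
    if not key:
        raise InchiKeyError(f"InChIKey generation failed for {smiles!r}")
    return key


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Issue:
    """One invariant violation, locating the offending node by path."""

    path: str
    rule: str
    message: str


BANDS = {"small", "medium", "large", "xlarge", "too_small", "too_large"}


def validate_record(record: CompoundRecord) -> list[Issue]:
    """Check all type invariants; returns an empty list iff the record is valid."""
    issues: list[Issue] = []

    def bad(path: str, rule: str, message: str) -> None:
        issues.append(Issue(path=path, rule=rule, message=message))

    if record.inchikey is not None and not INCHIKEY_RE.match(record.inchikey):
        bad("inchikey", "inchikey_format", f"not a 14-10-1 hyphenated key: {record.inchikey!r}")
    for i, entry in enumerate(record.uvvis):
        base = f"PRISTINE.uvvis[{i}]"
        if not entry.doi:
            bad(f"{base}.doi", "doi_nonempty", "doi is empty")
        for j, peak in enumerate(entry.peaks):
            ppath = f"{base}.peaks[{j}]"
            if peak.wavelength is not None and not peak.wavelength > 0:
                bad(f"{ppath}.wavelength", "wavelength_positive",
                    f"wavelength must be > 0, got {peak.wavelength}")
            if peak.extinction is not None:
                import math

                if not math.isfinite(peak.extinction) or not peak.extinction > 0:
                    bad(f"{ppath}.extinction", "extinction_positive",
                        f"extinction must be finite and > 0, got {peak.extinction}")
    if record.filtered is not None:
        if record.filtered.band is not None and record.filtered.band not in BANDS:
            bad("FILTERED.band", "band_enum", f"unknown band {record.filtered.band!r}")
        if record.filtered.nel is not None and record.filtered.nel < 1:
            bad("FILTERED.nel", "nel_positive", f"nel must be >= 1, got {record.filtered.nel}")
        for block in record.filtered.blocks:
            bpath = f"FILTERED.{block.source}"
            if block.source not in COMPUTED_SOURCES:
                bad(bpath, "source_enum", f"unknown source {block.source!r}")
            indices = [s.index for s in block.states]
            if indices != sorted(indices):
                bad(f"{bpath}.excited_states", "state_order", "states not ordered by index")
            for k, state in enumerate(block.states):
                spath = f"{bpath}.excited_states[{k}]"
                if state.index < 1:
                    bad(f"{spath}.index", "index_positive", f"index must be >= 1, got {state.index}")
                if state.wavelength is not None and not state.wavelength > 0:
                    bad(f"{spath}.amplitude", "wavelength_positive",
                        f"computed wavelength must be > 0, got {state.wavelength}")
                if state.oscillator_strength is not None and state.oscillator_strength < 0:
                    bad(f"{spath}.oscillator_strength", "oscillator_nonnegative",
                        f"oscillator strength must be >= 0, got {state.oscillator_strength}")
    return issues
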