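"""Deterministic queries over a loaded compound database.

These mirror the counts and statistics used to validate the deposited
database: counts of filtered compounds, strong first excitations,
wavelength-window membership, and the dual-method comparison subset.  They
work on any list of :class:`~uvvisdb.records.CompoundRecord`, whether loaded
from the public deposit or generated by :mod:`uvvisdb.fixtures`.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import valstats
from .records import CompoundRecord

__all__ = [
    "count_filtered",
    "count_strong_first_excitation",
    "count_lambda_below",
    "count_lambda_in_window",
    "dual_method_subset",
    "experimental_vs_computed_intersection",
]


def count_filtered(records: list[CompoundRecord]) -> int:
    """Compounds carrying a FILTERED block (passed all five filter rules)."""
    return sum(1 for r in records if r.filtered is not None)


def count_strong_first_excitation(
    records: list[CompoundRecord], threshold: float = 0.8, source: str = "orca"
) -> int:
    """Compounds whose first excited state of ``source`` has f > threshold."""
    n = 0
    for r in records:
        block = r.computed_block(source)
        if block is None:
            continue
        state = block.first_state()
        if state is not None and state.oscillator_strength is not None:
            if state.oscillator_strength > threshold:
                n += 1
    return n


def count_lambda_below(records: list[CompoundRecord], cutoff: float = 1200.0) -> int:
    """Compounds with at least one valid experimental wavelength, all of them
    below ``cutoff``."""
    n = 0
    for r in records:
        wl = r.experimental_wavelengths()
        if wl and max(wl) < cutoff:
            n += 1
    return n


def count_lambda_in_window(
    records: list[CompoundRecord], low: float = 600.0, high: float = 750.0
) -> int:
    """Compounds with at least one experimental wavelength inside [low, high]."""
    n = 0
    for r in records:
        if any(low <= w <= high for w in r.experimental_wavelengths()):
            n += 1
    return n


@dataclass
class DualMethodPair:
    inchikey: str | None
    experimental: float
    stda: float
    tddft: float


def dual_method_subset(records: list[CompoundRecord]) -> list[DualMethodPair]:
    """Compounds with both sTDA and TD-DFT first excitations and exactly one
    experimental wavelength."""
    out = []
    for r in records:
        wl = r.experimental_wavelengths()
        if len(wl) != 1:
            continue
        stda = r.first_computed_wavelength("orca")
        tddft = r.first_computed_wavelength("nwchem")
        if stda is None or tddft is None:
            continue
        out.append(
            DualMethodPair(inchikey=r.inchikey, experimental=wl[0], stda=stda, tddft=tddft)
        )
    return out


def experimental_vs_computed_intersection(
    records: list[CompoundRecord],
    bin_width: float = 12.0,
    origin: float = 0.0,
    source: str = "orca",
) -> float:
    """Histogram-intersection similarity between the experimental wavelength
    distribution and the computed first-excitation distribution, over
    compounds having both."""
    exp_vals = []
    comp_vals = []
    for r in records:
        wl = r.experimental_wavelengths()
        comp = r.first_computed_wavelength(source)
        if wl and comp is not None:
            exp_vals.extend(wl)
            comp_vals.append(comp)
    h_exp = valstats.build_histogram(exp_vals, origin=origin, bin_width=bin_width)
    h_comp = valstats.build_histogram(comp_vals, origin=origin, bin_width=bin_width)
    return valstats.histogram_intersection(h_exp, h_comp)
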