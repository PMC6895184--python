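"""Seeded synthetic-data generators.

Everything here is deterministic in (spec, seed) and statistically shaped the
way the validation suite expects: positively skewed absorption maxima on
190-1,200 nm, log-uniform extinction coefficients with a sub-population of
corrupted exponents, solvent names with spelling variants, and computed
first-excitation wavelengths systematically blue-shifted against experiment.
No chemical realism is claimed beyond what the statistics require.
"""

from __future__ import annotations

import copy
import math
import string
from dataclasses import dataclass, field

import numpy as np

from .records import (
    CompoundRecord,
    ComputedBlock,
    ComputedState,
    FilteredBlock,
    Peak,
    UvVisEntry,
)

__all__ = [
    "FixtureSpec",
    "gen_records",
    "gen_molecule_suite",
    "gen_computed_overlay",
    "lambda_law_skew",
]

_DEFAULT_SOLVENTS = [
    ("ethanol", ["ethanol", "Ethanol", "EtOH"]),
    ("methanol", ["methanol", "MeOH", "Methanol"]),
    ("chloroform", ["chloroform", "CHCl3"]),
    ("dichloromethane", ["DCM", "dichloromethane", "CH2Cl2"]),
    ("acetonitrile", ["acetonitrile", "MeCN", "ACN"]),
    ("toluene", ["toluene", "Toluene"]),
    ("tetrahydrofuran", ["THF", "tetrahydrofuran"]),
    ("acetone", ["acetone", "Acetone"]),
    ("dimethylformamide", ["DMF", "dimethylformamide"]),
    ("dimethyl sulfoxide", ["DMSO", "dimethyl sulfoxide"]),
]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic record generator.

    The absorption-maximum law is a shifted lognormal: 190 nm offset, scale
    (median above offset) 245 nm, sigma 0.4, which puts the mode near 400 nm
    and keeps essentially all mass inside 190-1,200 nm (draws beyond the cap
    are resampled).
    """

    n_compounds: int = 100
    seed: int = 0
    lambda_shift: float = 190.0
    lambda_scale: float = 245.0
    lambda_sigma: float = 0.4
    lambda_cap: float = 1200.0
    eps_min: float = 1e3
    eps_max: float = 5e5
    eps_fraction: float = 0.5  # fraction of peaks carrying an extinction value
    corruption_fraction: float = 0.0  # of eps values, lowest-decile, exponent shifted
    corruption_factor: float = 0.1
    max_peaks: int = 3
    blueshift: float = 50.0
    noise_sd: float = 15.0
    solvent_palette: list = field(default_factory=lambda: list(_DEFAULT_SOLVENTS))


def lambda_law_skew(spec: FixtureSpec) -> float:
    """Closed-form skewness of the (uncapped) shifted lognormal law."""
    w = math.exp(spec.lambda_sigma**2)
    return (w + 2) * math.sqrt(w - 1)


def _random_inchikey(rng: np.random.Generator) -> str:
    letters = np.array(list(string.ascii_uppercase))
    first = "".join(rng.choice(letters, size=14))
    second = "".join(rng.choice(letters, size=9))
    return f"{first}-{second}A-N"


def _draw_lambda(rng: np.random.Generator, spec: FixtureSpec, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = spec.lambda_shift + spec.lambda_scale * np.exp(
            rng.normal(0.0, spec.lambda_sigma, size=size - filled)
        )
        keep = draw[draw < spec.lambda_cap]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _draw_eps(rng: np.random.Generator, spec: FixtureSpec, size: int) -> np.ndarray:
    lo, hi = math.log10(spec.eps_min), math.log10(spec.eps_max)
    return 10.0 ** rng.uniform(lo, hi, size=size)


def gen_records(spec: FixtureSpec) -> list[CompoundRecord]:
    """Generate ``spec.n_compounds`` synthetic compound records.

    Each record has 1..max_peaks peaks with skewed wavelengths; a fraction of
    peaks carry extinction values, of which the configured corruption
    fraction (drawn from the lowest decile) has its exponent shifted by the
    corruption factor.  Solvents are drawn with alias spellings and every
    record carries a synthetic DOI and a valid-format InChIKey.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    if n == 0:
        return []
    n_peaks = rng.integers(1, spec.max_peaks + 1, size=n)
    total_peaks = int(n_peaks.sum())
    lambdas = _draw_lambda(rng, spec, total_peaks)
    eps = _draw_eps(rng, spec, total_peaks)
    has_eps = rng.random(total_peaks) < spec.eps_fraction

    # exponent corruption hits the lowest-decile extinction values
    corrupted = np.zeros(total_peaks, dtype=bool)
    if spec.corruption_fraction > 0:
        candidates = np.argsort(eps)
        k = int(round(spec.corruption_fraction * total_peaks))
        chosen = candidates[:k]
        eps = eps.copy()
        eps[chosen] *= spec.corruption_factor
        corrupted[chosen] = True

    records = []
    cursor = 0
    for i in range(n):
        k = int(n_peaks[i])
        peaks = []
        for j in range(cursor, cursor + k):
            peaks.append(
                Peak(
                    wavelength=round(float(lambdas[j]), 1),
                    wavelength_unit="nm",
                    extinction=float(eps[j]) if has_eps[j] else None,
                    extinction_unit="L mol-1 cm-1" if has_eps[j] else None,
                    extras={"corrupted_exponent": True} if corrupted[j] else {},
                )
            )
        cursor += k
        canonical, aliases = spec.solvent_palette[
            int(rng.integers(0, len(spec.solvent_palette)))
        ]
        alias = aliases[int(rng.integers(0, len(aliases)))]
        records.append(
            CompoundRecord(
                inchikey=_random_inchikey(rng),
                smiles=[f"C{'=C' * int(rng.integers(1, 5))}"],
                uvvis=[
                    UvVisEntry(
                        doi=f"10.5555/fixture.{spec.seed}.{i:05d}",
                        peaks=peaks,
                        solvent=alias,
                    )
                ],
            )
        )
    return records


# ---------------------------------------------------------------------------
# Molecule suite for the filter
# ---------------------------------------------------------------------------

# Expected electron counts are frozen from molecular-formula arithmetic
# (sum of atomic numbers, hydrogens included), independent of the filter code.
# The band boundaries at odd electron counts (49/141/221/301/371) cannot be
# hit by closed-shell neutral organics (their electron count is even), so the
# suite straddles each boundary with the nearest even values.
_BOUNDARY_MOLECULES = [
    # (smiles, nel = formula sum, band)
    ("N#Cc1cc[nH]c1", 48, "too_small"),  # C5H4N2: 30+4+14
    ("Cc1ccccc1", 50, "small"),  # C7H8: 42+8
    ("Brc1ccc2ccc3cccc4ccc1c2c34", 140, "small"),  # C16H9Br: 96+9+35
    ("Cc1ccc(-c2ccc(I)cc2)cc1", 142, "medium"),  # C13H11I: 78+11+53
    ("Cc1cc(C)cc(C)c1-c1ccc(-c2ccc(-c3ccc(Br)cc3)cc2)cc1", 220, "medium"),
    # C27H23Br: 162+23+35
    ("Fc1ccc(-c2ccc(-c3ccc(-c4ccc(I)cc4)cc3)cc2)cc1", 222, "large"),
    # C24H16FI: 144+16+9+53
    (
        "Cc1cc(C)cc(C)c1-c1ccc(-c2ccc(-c3ccc(-c4ccc(-c5ccc(Br)cc5)cc4)cc3)cc2)cc1",
        300,
        "large",
    ),  # C39H31Br: 234+31+35
    (
        "Fc1ccc(-c2ccc(-c3ccc(-c4ccc(-c5ccc(-c6ccc(I)cc6)cc5)cc4)cc3)cc2)cc1",
        302,
        "xlarge",
    ),  # C36H24FI: 216+24+9+53
    (
        "Clc1cc(Cl)cc(Cl)c1-c1ccc(-c2ccc(-c3ccc(-c4ccc(-c5ccc(-c6ccc(-c7ccccc7)"
        "cc6)cc5)cc4)cc3)cc2)cc1",
        370,
        "xlarge",
    ),  # C48H31Cl3: 288+31+51
    (
        "Clc1ccc(-c2ccc(-c3ccc(-c4ccc(-c5ccc(-c6ccc(-c7ccc(-c8ccc(Br)cc8)cc7)"
        "cc6)cc5)cc4)cc3)cc2)cc1",
        372,
        "too_large",
    ),  # C48H32BrCl: 288+32+35+17
]


def gen_molecule_suite(seed: int = 0) -> list[tuple[str, dict]]:
    """Curated molecules with their expected filter fates.

    Covers: invalid tokens, metal salts, a zwitterion, non-conjugated
    alkanes, an isolated diene, aromatic cores with alkyl chains of lengths
    1-8, and molecules straddling every electron-count band boundary.  The
    seed only shuffles the order.
    """
    toluene_nel = 50  # C7H8 by atomic-number sum
    suite: list[tuple[str, dict]] = [
        ("[<S>]", {"accepted": False, "failed": "sanitize"}),
        ("not a molecule!!", {"accepted": False, "failed": "sanitize"}),
        ("[O-]c1ccccc1.[Na+]", {"accepted": False, "failed": "composition"}),
        ("C[N+](C)(C)CC([O-])=O", {"accepted": False, "failed": "composition"}),
        ("C[Hg]C", {"accepted": False, "failed": "composition"}),
        ("CC", {"accepted": False, "failed": "conjugation"}),
        ("CCCCCC", {"accepted": False, "failed": "conjugation"}),
        ("C=CCC=C", {"accepted": False, "failed": "conjugation"}),
        (
            "C=CC=C",
            {"accepted": False, "failed": "band", "nel": 30, "band": "too_small"},
        ),  # C4H6: 24+6
        (
            "c1ccccc1",
            {"accepted": False, "failed": "band", "nel": 42, "band": "too_small"},
        ),  # C6H6: 36+6
    ]
    # aromatic cores with alkyl chains of lengths 1..8; all trim to toluene
    for length in range(1, 9):
        suite.append(
            (
                "C" * length + "c1ccccc1",
                {
                    "accepted": True,
                    "failed": None,
                    "nel": toluene_nel,
                    "band": "small",
                    "trims_to": "Cc1ccccc1",
                },
            )
        )
    for smiles, nel, band in _BOUNDARY_MOLECULES:
        suite.append(
            (
                smiles,
                {
                    "accepted": band in ("small", "medium", "large", "xlarge"),
                    "failed": None if band in ("small", "medium", "large", "xlarge") else "band",
                    "nel": nel,
                    "band": band,
                },
            )
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(suite))
    return [suite[i] for i in order]


# ---------------------------------------------------------------------------
# Computed overlays
# ---------------------------------------------------------------------------


def gen_computed_overlay(
    records: list[CompoundRecord],
    blueshift: float,
    noise_sd: float,
    seed: int,
    attach_nwchem: bool = False,
    nwchem_blueshift: float | None = None,
) -> list[CompoundRecord]:
    """Attach sTDA-like computed blocks blue-shifted from experiment.

    For every record with at least one experimental wavelength, a first
    excited state is added at ``lambda - blueshift + N(0, noise_sd)`` with a
    lognormal oscillator strength.  Optionally a TD-DFT-like block with a
    (typically smaller) bias is attached too.  Input records are not
    modified.
    """
    rng = np.random.default_rng(seed)
    if nwchem_blueshift is None:
        nwchem_blueshift = 0.7 * blueshift
    out = []
    for record in records:
        record = copy.deepcopy(record)
        wavelengths = record.experimental_wavelengths()
        if wavelengths:
            base = wavelengths[0]

            def state(shift: float) -> ComputedState:
                wl = base - shift + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                return ComputedState(
                    index=1,
                    wavelength=float(max(wl, 1.0)),
                    oscillator_strength=float(rng.lognormal(math.log(0.5), 0.6)),
                )

            blocks = [ComputedBlock(source="orca", states=[state(blueshift)])]
            if attach_nwchem:
                blocks.append(
                    ComputedBlock(source="nwchem", states=[state(nwchem_blueshift)])
                )
            if record.filtered is None:
                record.filtered = FilteredBlock(blocks=blocks)
            else:
                record.filtered.blocks.extend(blocks)
        out.append(record)
    return out
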